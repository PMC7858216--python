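"""Nucleotide-diversity scanning and hypervariable-region selection.

This is the marker-design core: classify alignment columns, compute
per-site nucleotide diversity (pi), slide a window along the alignment,
and pick the top-ranked hypervariable regions as barcode candidates.

Definitions
-----------
* A column is *excluded* (complete-deletion convention) when any included
  sequence carries a gap or ambiguity code there; only unambiguous A/C/G/T
  columns are scored.  A pairwise-deletion variant is available for pi.
* pi over a span is the average proportion of differing sites between two
  sequences: ``pi = [2 / (n(n-1))] * sum_{i<j} d_ij / L_used`` with ``d_ij``
  the mismatch count over included columns and ``L_used`` the number of
  included columns.
* A column is *parsimony-informative* when at least two states each occur
  in at least two included sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .errors import DataError
from .seqio import Alignment

_BASE_BITS = np.array([1, 2, 4, 8], dtype=np.uint8)


class SiteClass(str, Enum):
    EXCLUDED = "excluded"
    INVARIANT = "invariant"
    VARIABLE = "variable"
    PARSIMONY_INFORMATIVE = "parsimony_informative"


@dataclass(frozen=True)
class WindowStats:
    """Diversity and site-class tallies for one window [start, end)."""

    start: int
    end: int
    pi: float
    n_sites_used: int
    n_variable: int
    n_pi_sites: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi <= 1.0):
            raise DataError(f"pi out of range: {self.pi}")
        if not (self.n_pi_sites <= self.n_variable <= self.n_sites_used <= self.end - self.start):
            raise DataError("inconsistent window site counts")


@dataclass(frozen=True)
class Region:
    """A merged, ranked candidate barcode region."""

    name: str
    start: int
    end: int
    mean_pi: float
    rank: int


@dataclass(frozen=True)
class ScanConfig:
    """Sliding-scan parameters.

    Window and step are in alignment columns.  The defaults (800/100) are
    sized so that merged top regions come out around the 1-1.6 kb scale that
    makes a PCR-amplifiable barcode, with 36 candidates retained for
    tree-based follow-up; all of it is configurable because there is no
    single canonical choice.
    """

    window_length: int = 800
    step: int = 100
    min_region_length: int = 600
    n_candidates: int = 36
    gap_policy: str = "complete"  # or "pairwise"

    def __post_init__(self) -> None:
        if self.step < 1:
            raise DataError("step must be >= 1")
        if self.window_length < self.step:
            raise DataError("window_length must be >= step")
        if self.gap_policy not in {"complete", "pairwise"}:
            raise DataError(f"unknown gap_policy {self.gap_policy!r}")


# ---------------------------------------------------------------------------
# site classification
# ---------------------------------------------------------------------------

def _column_state_counts(aln: Alignment, include_ids: Sequence[str] | None):
    """Return (counts[L,4], included_mask[L]) for the included rows."""
    if include_ids is None:
        sub = aln
    else:
        if not include_ids:
            raise DataError("include_ids is empty")
        sub = aln.subset(list(include_ids))
    codes = sub.codes()  # (n, L)
    det = (codes & (codes - 1)) == 0  # unambiguous single base
    included = det.all(axis=0)  # complete-deletion columns
    counts = (codes[:, :, None] == _BASE_BITS[None, None, :]).sum(axis=0)  # (L, 4)
    return counts, included, codes, det


def classify_sites(
    aln: Alignment, include_ids: Sequence[str] | None = None
) -> list[SiteClass]:
    """One :class:`SiteClass` per column under complete deletion.

    ``include_ids`` restricts the rows considered, which is how "with /
    without outgroups" site tallies are produced.
    """
    counts, included, _, _ = _column_state_counts(aln, include_ids)
    n_states = (counts > 0).sum(axis=1)
    n_states_ge2 = (counts >= 2).sum(axis=1)
    out = []
    for col in range(counts.shape[0]):
        if not included[col]:
            out.append(SiteClass.EXCLUDED)
        elif n_states[col] <= 1:
            out.append(SiteClass.INVARIANT)
        elif n_states_ge2[col] >= 2:
            out.append(SiteClass.PARSIMONY_INFORMATIVE)
        else:
            out.append(SiteClass.VARIABLE)
    return out


def count_site_classes(classes: Iterable[SiteClass]) -> dict[str, int]:
    tally = {c.value: 0 for c in SiteClass}
    for c in classes:
        tally[c.value] += 1
    # parsimony-informative sites are variable sites too
    tally["variable"] += tally["parsimony_informative"]
    return tally


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def nucleotide_diversity(
    aln: Alignment,
    start: int = 0,
    end: int | None = None,
    include_ids: Sequence[str] | None = None,
    gap_policy: str = "complete",
) -> float:
    """Per-site nucleotide diversity over columns [start, end).

    Returns 0.0 (with a warning) when no column survives the gap policy.
    """
    end = aln.length if end is None else end
    if not (0 <= start < end <= aln.length):
        raise DataError(f"span [{start},{end}) out of range")
    counts, included, codes, det = _column_state_counts(aln, include_ids)
    n = codes.shape[0]
    if n < 2:
        raise DataError("nucleotide diversity needs >= 2 sequences")
    counts = counts[start:end]
    included = included[start:end]
    codes = codes[:, start:end]
    det = det[:, start:end]
    n_pairs = n * (n - 1) // 2

    if gap_policy == "complete":
        L_used = int(included.sum())
        if L_used == 0:
            warnings.warn("no columns usable under complete deletion; pi set to 0")
            return 0.0
        c = counts[included]
        mism = _pair_mismatches(c, n)
        return float(mism.sum() / (n_pairs * L_used))

    # pairwise deletion: average of per-pair mismatch fractions
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            comp = det[i] & det[j]
            m = int(comp.sum())
            if m == 0:
                warnings.warn(f"pair {i},{j} shares no comparable column; skipped")
                continue
            total += float((comp & (codes[i] != codes[j])).sum()) / m
    return total / n_pairs


def _pair_mismatches(counts: np.ndarray, n: int) -> np.ndarray:
    """Mismatching pairs per fully determined column from base counts."""
    same = (counts * (counts - 1) // 2).sum(axis=1)
    return n * (n - 1) // 2 - same


# ---------------------------------------------------------------------------
# sliding scan
# ---------------------------------------------------------------------------

def window_spans(length: int, cfg: ScanConfig) -> list[tuple[int, int]]:
    """Window coordinates: starts at 0, step, 2*step, ...; a final clipped
    window is appended when the full windows stop short of the end and the
    remainder is at least one step long."""
    if cfg.window_length > length:
        raise DataError(
            f"window_length {cfg.window_length} exceeds alignment length {length}"
        )
    spans = []
    start = 0
    while start + cfg.window_length <= length:
        spans.append((start, start + cfg.window_length))
        start += cfg.step
    if spans[-1][1] < length and length - start >= cfg.step:
        spans.append((start, length))
    return spans


def sliding_scan(
    aln: Alignment,
    cfg: ScanConfig | None = None,
    include_ids: Sequence[str] | None = None,
) -> list[WindowStats]:
    """Slide a window along the alignment and score each placement.

    Every window carries pi plus site-class counts; the whole scan is one
    vectorised pass with prefix sums, so window/step choices are cheap.
    """
    cfg = cfg or ScanConfig()
    counts, included, codes, _ = _column_state_counts(aln, include_ids)
    n = codes.shape[0]
    if n < 2:
        raise DataError("sliding scan needs >= 2 sequences")
    if cfg.gap_policy != "complete":
        raise DataError("sliding_scan supports the complete-deletion policy only")

    n_pairs = n * (n - 1) // 2
    mism = np.where(included, _pair_mismatches(counts, n), 0)
    n_states = (counts > 0).sum(axis=1)
    variable = included & (n_states >= 2)
    pi_site = included & ((counts >= 2).sum(axis=1) >= 2) & (n_states >= 2)

    def prefix(x):
        return np.concatenate([[0], np.cumsum(x)])

    P_used, P_mism = prefix(included), prefix(mism)
    P_var, P_pi = prefix(variable), prefix(pi_site)

    out = []
    for s, e in window_spans(aln.length, cfg):
        used = int(P_used[e] - P_used[s])
        if used == 0:
            warnings.warn(f"window [{s},{e}) has no usable column; pi set to 0")
            pi = 0.0
        else:
            pi = float((P_mism[e] - P_mism[s]) / (n_pairs * used))
        out.append(
            WindowStats(
                start=s,
                end=e,
                pi=pi,
                n_sites_used=used,
                n_variable=int(P_var[e] - P_var[s]),
                n_pi_sites=int(P_pi[e] - P_pi[s]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# region selection
# ---------------------------------------------------------------------------

def _window_rank_key(w: WindowStats):
    # highest pi first; ties -> more variable sites -> leftmost start
    return (-w.pi, -w.n_variable, w.start)


def select_regions(windows: Sequence[WindowStats], cfg: ScanConfig | None = None) -> list[Region]:
    """Greedy ranked merge of top windows into candidate barcode regions.

    Windows are ranked by (pi desc, n_variable desc, start asc); windows with
    no variable site never seed or extend a region.  Walking down the
    ranking, a window either merges into a region it overlaps or abuts, or
    opens a new region; the walk stops as soon as ``n_candidates`` regions
    exist, so low-ranked windows cannot chain regions across the background.
    Regions shorter than ``min_region_length`` are then dropped, and the
    survivors are ranked by the best window they contain.
    """
    cfg = cfg or ScanConfig()
    if not windows:
        raise DataError("no windows to select from")
    ranked = sorted((w for w in windows if w.n_variable > 0), key=_window_rank_key)

    regions: list[dict] = []  # {"start","end","pis":[..],"best":key}
    for w in ranked:
        hits = [r for r in regions if w.start <= r["end"] and w.end >= r["start"]]
        if hits:
            merged = {
                "start": min([w.start] + [r["start"] for r in hits]),
                "end": max([w.end] + [r["end"] for r in hits]),
                "pis": sum([r["pis"] for r in hits], [w.pi]),
                "best": min([_window_rank_key(w)] + [r["best"] for r in hits]),
            }
            regions = [r for r in regions if r not in hits] + [merged]
        else:
            regions.append(
                {"start": w.start, "end": w.end, "pis": [w.pi], "best": _window_rank_key(w)}
            )
        if len(regions) >= cfg.n_candidates:
            break

    regions = [r for r in regions if r["end"] - r["start"] >= cfg.min_region_length]
    regions.sort(key=lambda r: r["best"])
    return [
        Region(
            name=f"region_{i + 1:03d}",
            start=r["start"],
            end=r["end"],
            mean_pi=float(np.mean(r["pis"])),
            rank=i + 1,
        )
        for i, r in enumerate(regions)
    ]
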