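"""Marker discrimination power via bootstrap-supported monophyly.

A species is *resolved* by a marker when all of its samples form a clade
on the marker's bootstrap tree with support above the threshold (default
75, strict), or trivially when only one sample exists.  A marker-level
summary counts resolved species and reports which species remain entangled
in shared clades, alongside the marker's aligned length and variable /
parsimony-informative site tallies (outgroups included, matching how such
tallies are conventionally reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy

from . import divscan, phylo
from .errors import DataError
from .seqio import Alignment, SampleTable

DEFAULT_SUPPORT_THRESHOLD = 75


@dataclass(frozen=True)
class MonophylyResult:
    species_label: str
    n_samples: int
    is_monophyletic: bool
    support: int | None  # None when n/a (singleton or unsupported edge)
    resolved: bool


@dataclass(frozen=True)
class MarkerResolution:
    marker_name: str
    aligned_length: int
    n_variable: int
    n_pi_sites: int
    n_species_total: int
    n_species_resolved: int
    unresolved_groups: tuple[tuple[str, ...], ...]
    species_results: tuple[MonophylyResult, ...] = field(repr=False, default=())


def _clade_sets(tree: dendropy.Tree):
    """(node, leaf-label set) for every non-root node."""
    out = []
    for nd in tree.postorder_node_iter():
        if nd.parent_node is None:
            continue
        out.append((nd, frozenset(lf.taxon.label for lf in nd.leaf_iter())))
    return out


def monophyly_test(
    tree: dendropy.Tree,
    samples: SampleTable,
    species_label: str,
    support_threshold: int = DEFAULT_SUPPORT_THRESHOLD,
) -> MonophylyResult:
    """Is a species' sample set exclusive and supported on this tree?

    Monophyly is assessed against non-outgroup samples only: an edge must
    separate exactly the species' samples from every other ingroup sample
    (outgroups may fall on either side).  Singletons are resolved by
    convention, with support n/a.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    og = set(samples.outgroup_ids) & leaves
    ingroup = leaves - og
    target = {
        sid
        for sid in samples.samples_of(species_label, reference_only=False)
        if sid in ingroup
    }
    if not target:
        raise DataError(f"species {species_label!r} has no ingroup sample on the tree")
    if len(target) == 1:
        return MonophylyResult(species_label, 1, True, None, True)

    # prefer the species' own stem node; fall back to an edge whose other
    # side isolates the species (can happen near the root of rooted trees)
    stem: int | None = None
    complement: int | None = None
    found = False
    for nd, clade in _clade_sets(tree):
        if clade - og == target:
            found = True
            s = phylo.support_of(nd)
            if s is not None and (stem is None or s < stem):
                stem = s  # innermost stem edge governs; ties take the weakest
        elif (leaves - clade) - og == target:
            found = True
            s = phylo.support_of(nd)
            if s is not None and (complement is None or s > complement):
                complement = s
    best = stem if stem is not None else complement
    resolved = found and best is not None and best > support_threshold
    return MonophylyResult(species_label, len(target), found, best, resolved)


def _evaluation_alignment(aln: Alignment, samples: SampleTable) -> Alignment:
    """Reference + outgroup rows, in sample-table order."""
    present = set(aln.ids)
    keep = [
        sid
        for sid in samples.sample_ids
        if sid in present and sid not in set(samples.query_ids)
    ]
    missing = [
        sid
        for sid in samples.sample_ids
        if sid not in present and sid not in set(samples.query_ids)
    ]
    if missing:
        raise DataError(f"marker lacks reference sample(s): {missing[:5]}")
    return aln.subset(keep)


def resolution_summary(
    aln: Alignment,
    samples: SampleTable,
    marker_name: str = "marker",
    support_threshold: int = DEFAULT_SUPPORT_THRESHOLD,
    method: str = "mp",
    n_bootstrap: int = 200,
    seed: int = 0,
    search_params: phylo.SearchParams | None = None,
) -> MarkerResolution:
    """Evaluate one marker: bootstrap tree, per-species monophyly, tallies.

    The tree is built from reference and outgroup samples only, rooted on
    the outgroups when present.  ``method`` picks the tree engine (``mp``,
    the default, or ``nj``).
    """
    sub = _evaluation_alignment(aln, samples)
    classes = divscan.classify_sites(sub)
    tally = divscan.count_site_classes(classes)
    tree = phylo.bootstrap(
        sub, builder=method, n_reps=n_bootstrap, seed=seed, search_params=search_params
    )
    og = [o for o in samples.outgroup_ids if o in set(sub.ids)]
    if og:
        tree = phylo.root_with_outgroup(tree, og)

    species = [
        sp for sp in samples.reference_species
        if any(s in set(sub.ids) for s in samples.samples_of(sp))
    ]
    results = [
        monophyly_test(tree, samples, sp, support_threshold) for sp in species
    ]
    unresolved = [r.species_label for r in results if not r.resolved]
    groups = _group_unresolved(tree, samples, unresolved, support_threshold)
    return MarkerResolution(
        marker_name=marker_name,
        aligned_length=sub.length,
        n_variable=tally["variable"],
        n_pi_sites=tally["parsimony_informative"],
        n_species_total=len(species),
        n_species_resolved=sum(r.resolved for r in results),
        unresolved_groups=groups,
        species_results=tuple(results),
    )


def _group_unresolved(
    tree: dendropy.Tree,
    samples: SampleTable,
    unresolved: Sequence[str],
    support_threshold: int,
) -> tuple[tuple[str, ...], ...]:
    """Group unresolved species by the smallest supported clade holding all
    their samples -- these are the species sets a marker cannot take apart."""
    if not unresolved:
        return ()
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    keyed: dict[frozenset, list[str]] = {}
    for sp in unresolved:
        target = {s for s in samples.samples_of(sp, reference_only=False) if s in leaves}
        best_key = frozenset(leaves)
        best_size = len(leaves) + 1
        for nd, clade in _clade_sets(tree):
            s = phylo.support_of(nd)
            if s is None or s <= support_threshold:
                continue
            if target <= clade and len(clade) < best_size:
                best_key, best_size = clade, len(clade)
        keyed.setdefault(best_key, []).append(sp)
    return tuple(tuple(sorted(v)) for v in sorted(keyed.values(), key=lambda g: sorted(g)))


def compare_markers(
    markers: Mapping[str, Alignment],
    samples: SampleTable,
    support_threshold: int = DEFAULT_SUPPORT_THRESHOLD,
    method: str = "mp",
    n_bootstrap: int = 200,
    seed: int = 0,
    search_params: phylo.SearchParams | None = None,
) -> list[MarkerResolution]:
    """Side-by-side evaluation of several markers.

    Every marker must carry all reference and outgroup samples.  The report
    is ranked by species resolved (ties broken by parsimony-informative
    sites, then name).
    """
    if not markers:
        raise DataError("no markers given")
    out = [
        resolution_summary(
            aln,
            samples,
            marker_name=name,
            support_threshold=support_threshold,
            method=method,
            n_bootstrap=n_bootstrap,
            seed=seed,
            search_params=search_params,
        )
        for name, aln in markers.items()
    ]
    out.sort(key=lambda r: (-r.n_species_resolved, -r.n_pi_sites, r.marker_name))
    return out
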