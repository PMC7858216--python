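"""Input/output and alignment bookkeeping.

The pipeline operates on one shared in-memory representation of a multiple
sequence alignment (:class:`Alignment`), a per-sample metadata table
(:class:`SampleTable`), and Newick trees (held as :class:`dendropy.Tree`).
Coordinates are 0-based half-open everywhere inside the code; every
user-facing report converts to 1-based inclusive.

FASTA parsing goes through Biopython; Newick through dendropy.  On read,
sequences are uppercased, ``U`` is normalised to ``T`` and ``?`` to ``N`` so
that GenBank-derived dialects ingest cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import DataError, FormatError

# IUPAC nucleotide codes as bitmasks over (A=1, C=2, G=4, T=8).  Gap, N and
# '?' are treated as fully ambiguous (all four bits): downstream code decides
# whether that means "exclude the column" (diversity scans, complete
# deletion) or "free wildcard" (Fitch parsimony).
_MASK = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15, "-": 15,
}
#: Characters that denote a single, unambiguous base.
_DETERMINED = frozenset("ACGT")
#: Every character legal in an alignment row (post-normalisation).
ALPHABET = frozenset(_MASK)

_MASK_TABLE = np.zeros(128, dtype=np.uint8)
for _ch, _m in _MASK.items():
    _MASK_TABLE[ord(_ch)] = _m


def _normalize(seq: str, seq_id: str) -> str:
    s = seq.upper().replace("U", "T").replace("?", "N")
    bad = set(s) - ALPHABET
    if bad:
        pos = next(i for i, c in enumerate(s) if c in bad)
        raise FormatError(
            f"illegal character {s[pos]!r} at position {pos + 1} in sequence {seq_id!r}"
        )
    return s


@dataclass(frozen=True)
class Alignment:
    """A rectangular DNA alignment: ordered unique ids, equal-length rows."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ids:
            raise DataError("alignment has no sequences")
        if len(set(self.ids)) != len(self.ids):
            dup = next(i for i in self.ids if self.ids.count(i) > 1)
            raise DataError(f"duplicate sequence id {dup!r}")
        L = len(self.rows[0])
        if L < 1:
            raise DataError(f"empty sequence {self.ids[0]!r}")
        for sid, row in zip(self.ids, self.rows):
            if len(row) != L:
                raise DataError(
                    f"ragged alignment: sequence {sid!r} has length {len(row)}, expected {L}"
                )

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise DataError(f"sequence id {seq_id!r} not in alignment") from None

    def codes(self) -> np.ndarray:
        """(n_sequences, length) uint8 matrix of IUPAC bitmasks."""
        raw = np.frombuffer("".join(self.rows).encode("ascii"), dtype=np.uint8)
        return _MASK_TABLE[raw.reshape(self.n_sequences, self.length)]

    def determined(self) -> np.ndarray:
        """Boolean matrix: True where the character is a single unambiguous base."""
        c = self.codes()
        return (c & (c - 1)) == 0  # power of two <=> exactly one bit

    def subset(self, keep_ids: Sequence[str]) -> "Alignment":
        """Row subset in the given order; ids must exist."""
        return Alignment(tuple(keep_ids), tuple(self.row(i) for i in keep_ids))

    @classmethod
    def from_dict(cls, seqs: dict[str, str]) -> "Alignment":
        return cls(
            tuple(seqs),
            tuple(_normalize(s, i) for i, s in seqs.items()),
        )


@dataclass(frozen=True)
class SampleTable:
    """Per-sample metadata: species label, reference/query role, outgroup flag."""

    table: pd.DataFrame = field(repr=False)

    COLUMNS = ("sample_id", "species", "role", "outgroup")
    ROLES = ("reference", "query")

    def __post_init__(self) -> None:
        t = self.table
        missing = {"sample_id", "species"} - set(t.columns)
        if missing:
            raise DataError(f"sample table missing column(s): {sorted(missing)}")
        dup = t["sample_id"][t["sample_id"].duplicated()]
        if len(dup):
            raise DataError(f"duplicate sample_id {dup.iloc[0]!r} in sample table")
        bad = set(t["role"]) - set(self.ROLES)
        if bad:
            raise DataError(f"unknown role token(s) {sorted(bad)}; expected reference/query")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleTable":
        t = df.copy()
        if "role" not in t.columns:
            t["role"] = "reference"
        if "outgroup" not in t.columns:
            t["outgroup"] = False
        else:
            t["outgroup"] = t["outgroup"].map(_parse_flag)
        t["role"] = t["role"].fillna("reference")
        return cls(t[list(cls.COLUMNS)].reset_index(drop=True))

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def species_of(self, sample_id: str) -> str:
        row = self.table[self.table["sample_id"] == sample_id]
        if row.empty:
            raise DataError(f"sample {sample_id!r} not in sample table")
        return row["species"].iloc[0]

    def is_outgroup(self, sample_id: str) -> bool:
        row = self.table[self.table["sample_id"] == sample_id]
        if row.empty:
            raise DataError(f"sample {sample_id!r} not in sample table")
        return bool(row["outgroup"].iloc[0])

    @property
    def outgroup_ids(self) -> list[str]:
        return list(self.table.loc[self.table["outgroup"], "sample_id"])

    @property
    def reference_ids(self) -> list[str]:
        m = (self.table["role"] == "reference") & ~self.table["outgroup"]
        return list(self.table.loc[m, "sample_id"])

    @property
    def query_ids(self) -> list[str]:
        return list(self.table.loc[self.table["role"] == "query", "sample_id"])

    @property
    def reference_species(self) -> list[str]:
        """Distinct non-outgroup reference species, in first-appearance order."""
        m = (self.table["role"] == "reference") & ~self.table["outgroup"]
        return list(dict.fromkeys(self.table.loc[m, "species"]))

    def samples_of(self, species: str, reference_only: bool = True) -> list[str]:
        m = (self.table["species"] == species) & ~self.table["outgroup"]
        if reference_only:
            m &= self.table["role"] == "reference"
        return list(self.table.loc[m, "sample_id"])


def _parse_flag(v: object) -> bool:
    if isinstance(v, bool):
        return v
    if pd.isna(v):
        return False
    s = str(v).strip().lower()
    if s in {"1", "true", "yes", "y"}:
        return True
    if s in {"0", "false", "no", "n", ""}:
        return False
    raise DataError(f"cannot parse outgroup flag {v!r}")


@dataclass(frozen=True)
class PartitionMap:
    """Ordered, contiguous (marker_name, start, end) spans of a concatenation."""

    spans: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        pos = 0
        for name, start, end in self.spans:
            if start != pos or end <= start:
                raise DataError(f"partition {name!r} spans [{start},{end}) but expected start {pos}")
            pos = end

    @property
    def total_length(self) -> int:
        return self.spans[-1][2] if self.spans else 0

    def span_of(self, name: str) -> tuple[int, int]:
        for n, s, e in self.spans:
            if n == name:
                return s, e
        raise DataError(f"no partition named {name!r}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file.

    Sequences are uppercased; ``U``→``T`` and ``?``→``N``.  Ragged rows,
    empty files and illegal characters raise :class:`FormatError` /
    :class:`DataError` naming the offending record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    ids = tuple(r.id for r in records)
    rows = tuple(_normalize(str(r.seq), r.id) for r in records)
    return Alignment(ids, rows)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n")
            for i in range(0, len(row), 80):
                fh.write(row[i : i + 80] + "\n")


def read_sample_table(path: str | Path) -> SampleTable:
    """Read a TSV with columns sample_id, species[, role, outgroup].

    ``role`` defaults to ``reference`` and ``outgroup`` to false when the
    columns are absent.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty sample table {path}") from None
    df.columns = [c.strip().lower() for c in df.columns]
    if "species" not in df.columns and "species_label" in df.columns:
        df = df.rename(columns={"species_label": "species"})
    return SampleTable.from_frame(df)


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    out = samples.table.copy()
    out["outgroup"] = out["outgroup"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# alignment surgery
# ---------------------------------------------------------------------------

def extract_region(aln: Alignment, start: int, end: int) -> Alignment:
    """Column span [start, end) as a new alignment (same ids, same order)."""
    if not (0 <= start < end <= aln.length):
        raise DataError(
            f"region [{start},{end}) out of range for alignment of length {aln.length}"
        )
    return Alignment(aln.ids, tuple(r[start:end] for r in aln.rows))


def concatenate(
    alns: Sequence[Alignment], names: Sequence[str] | None = None
) -> tuple[Alignment, PartitionMap]:
    """Concatenate marker alignments joined on sequence id.

    All inputs must carry the same id set; rows are joined per id, with the
    id order of the first alignment defining the output order.
    """
    if not alns:
        raise DataError("nothing to concatenate")
    if names is None:
        names = [f"marker{i + 1}" for i in range(len(alns))]
    if len(names) != len(alns):
        raise DataError("names and alignments differ in length")
    base_ids = alns[0].ids
    base_set = set(base_ids)
    for name, a in zip(names, alns):
        if set(a.ids) != base_set:
            missing = sorted(base_set.symmetric_difference(a.ids))
            raise DataError(f"id sets differ at marker {name!r}: {missing}")
    rows = []
    for sid in base_ids:
        rows.append("".join(a.row(sid) for a in alns))
    spans, pos = [], 0
    for name, a in zip(names, alns):
        spans.append((name, pos, pos + a.length))
        pos += a.length
    return Alignment(base_ids, tuple(rows)), PartitionMap(tuple(spans))


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse one Newick tree from a path or a literal Newick string.

    Integer internal-node labels are interpreted as bootstrap supports and
    kept as node labels.  Malformed input raises :class:`FormatError`.
    """
    text = None
    p = Path(str(source))
    if isinstance(source, Path) or (p.suffix in {".nwk", ".tre", ".newick", ".txt"} and p.exists()):
        text = p.read_text()
    elif isinstance(source, str) and not source.lstrip().startswith("("):
        if not p.exists():
            raise FormatError(f"no such tree file: {source}")
        text = p.read_text()
    else:
        text = str(source)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"malformed Newick: {exc}") from None
    if len(tree.leaf_nodes()) < 2:
        raise DataError("tree has fewer than 2 leaves")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialise a tree; branch lengths to 6 decimals, supports as labels."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    ).strip() + "\n"
    if path is not None:
        Path(path).write_text(s)
    return s


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}
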