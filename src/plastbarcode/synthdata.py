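"""Synthetic data with the structure of a crop species complex.

The generator emulates what the pipeline assumes about a plastome panel of
a young genus: a handful of deep clades ("genome types"), each holding a
few closely related species with one to a few sampled accessions; a low
background nucleotide diversity with localized hypervariable blocks; a set
of query accessions of known (but possibly wrongly declared) species; and
a couple of fast-evolving nuclear-like loci.

The model is a fixed-depth ultrametric hierarchy rather than a coalescent:
samples of a species split at ``intra_species_divergence / 2`` from the
present, species within a clade at ``inter_species_divergence / 2``, clades
at ``inter_clade_divergence / 2``, and outgroup samples at
``outgroup_divergence / 2``, so the expected pairwise divergence between
two tips equals the corresponding parameter.  Sequences evolve by
Jukes-Cantor substitution, sampled exactly per site from the transition
probability ``p = (3/4)(1 - exp(-4*l/3))`` for a branch of length ``l``
(times the block's rate multiplier inside hypervariable blocks).
Everything is deterministic given ``SimParams.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import DataError
from .seqio import Alignment, SampleTable

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    """Simulation settings; divergences are expected substitutions/site."""

    n_clades: int = 8
    species_per_clade: tuple[int, int] = (1, 4)
    samples_per_species: tuple[int, int] = (1, 3)
    n_species_total: int | None = None  # pin the species count exactly
    seq_length: int = 20000
    inter_clade_divergence: float = 0.005
    inter_species_divergence: float = 0.002
    intra_species_divergence: float = 0.0002
    outgroup_divergence: float = 0.025
    n_outgroups: int = 2
    hypervariable_blocks: tuple[tuple[int, int, float], ...] = ()
    n_queries: int = 0
    mislabel_fraction: float = 0.0
    nuclear_loci: tuple[tuple[str, int, float], ...] = ()  # (name, length, rate scale)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            self.intra_species_divergence
            < self.inter_species_divergence
            < self.inter_clade_divergence
        ):
            raise DataError("divergences must satisfy intra < inter_species < inter_clade")
        if not (0.0 <= self.mislabel_fraction < 1.0):
            raise DataError("mislabel_fraction must be in [0, 1)")
        for s, e, m in self.hypervariable_blocks:
            if not (0 <= s < e <= self.seq_length):
                raise DataError(f"block [{s},{e}) outside sequence of length {self.seq_length}")
            if m < 1.0:
                raise DataError("block rate_multiplier must be >= 1")
        if self.n_clades < 1 or self.n_outgroups < 0:
            raise DataError("bad clade/outgroup counts")


def oryza_like(seed: int = 0) -> SimParams:
    """The default study-scale preset: 8 clades, 21 species, 53 query
    accessions of which 17% carry a wrong label, a 20 kb plastome-like
    alignment of background pi ~ 0.006 with six hypervariable blocks, and
    two fast nuclear-like loci."""
    blocks = tuple(
        (start, start + 800, mult)
        for start, mult in zip(
            (2000, 5000, 8000, 11000, 14000, 17000),
            (2.0, 2.2, 2.5, 2.0, 2.2, 2.5),
        )
    )
    return SimParams(
        n_clades=8,
        species_per_clade=(1, 4),
        samples_per_species=(1, 3),
        n_species_total=21,
        seq_length=20000,
        hypervariable_blocks=blocks,
        n_queries=53,
        mislabel_fraction=0.17,
        nuclear_loci=(("NPX", 1000, 12.0), ("RX", 1000, 22.0)),
        seed=seed,
    )


@dataclass(frozen=True)
class TruthTable:
    """Per-sample ground truth: the species a sample really belongs to and
    the species label it was handed to the pipeline under."""

    table: pd.DataFrame = field(repr=False)

    COLUMNS = ("sample_id", "true_species", "given_species", "role", "outgroup", "is_planted_mislabel")

    def __post_init__(self) -> None:
        t = self.table
        bad = (t["true_species"] != t["given_species"]) != t["is_planted_mislabel"]
        if bad.any():
            raise DataError("is_planted_mislabel inconsistent with label columns")

    @property
    def planted_mislabels(self) -> list[str]:
        return list(self.table.loc[self.table["is_planted_mislabel"], "sample_id"])

    def to_sample_table(self) -> SampleTable:
        df = self.table.rename(columns={"given_species": "species"})[
            ["sample_id", "species", "role", "outgroup"]
        ]
        return SampleTable.from_frame(df)


# ---------------------------------------------------------------------------
# study design (who exists and who is sampled)
# ---------------------------------------------------------------------------

def _design(p: SimParams):
    """Draw the sampling design: species per clade, reference samples,
    query-to-species assignment.  Deterministic given p.seed."""
    rng = np.random.default_rng([p.seed, 11])
    lo, hi = p.species_per_clade
    counts = rng.integers(lo, hi + 1, size=p.n_clades)
    if p.n_species_total is not None:
        # nudge clade sizes until the total matches, staying within bounds
        guard = 0
        while counts.sum() != p.n_species_total:
            i = int(rng.integers(p.n_clades))
            if counts.sum() > p.n_species_total and counts[i] > lo:
                counts[i] -= 1
            elif counts.sum() < p.n_species_total and counts[i] < hi:
                counts[i] += 1
            guard += 1
            if guard > 10000:
                raise DataError("cannot reach n_species_total within species_per_clade bounds")
    species, clade_of = [], {}
    for c in range(p.n_clades):
        for s in range(int(counts[c])):
            name = f"sp{len(species) + 1:02d}"
            species.append(name)
            clade_of[name] = f"clade{c + 1}"
    slo, shi = p.samples_per_species
    rows = []  # (sample_id, species, role, outgroup)
    for sp in species:
        for k in range(int(rng.integers(slo, shi + 1))):
            rows.append((f"{sp}_r{k + 1}", sp, "reference", False))
    for q in range(p.n_queries):
        sp = species[int(rng.integers(len(species)))]
        rows.append((f"BOP{q + 1:04d}", sp, "query", False))
    for o in range(p.n_outgroups):
        rows.append((f"out{o + 1}", f"outgroup_sp{o + 1}", "reference", True))
    return species, clade_of, rows


def simulate_species_tree(p: SimParams) -> tuple[dendropy.Tree, dict[str, str]]:
    """Rooted ultrametric sample tree plus the species-to-clade map.

    Clade stems split at half the inter-clade divergence, species at half
    the inter-species divergence, samples at half the intra-species
    divergence; outgroup tips hang from the root at half the outgroup
    divergence.  Branch lengths are expected substitutions/site.
    """
    species, clade_of, rows = _design(p)
    d_root = p.outgroup_divergence / 2.0 if p.n_outgroups else p.inter_clade_divergence / 2.0
    d_clade = p.inter_clade_divergence / 2.0
    d_sp = p.inter_species_divergence / 2.0
    d_sam = p.intra_species_divergence / 2.0

    ns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    ingroup = dendropy.Node()
    ingroup.edge.length = d_root - d_clade
    root.add_child(ingroup)
    for o in range(p.n_outgroups):
        lf = dendropy.Node(taxon=ns.require_taxon(label=f"out{o + 1}"))
        lf.edge.length = d_root
        root.add_child(lf)

    samples_of: dict[str, list[str]] = {sp: [] for sp in species}
    for sid, sp, role, og in rows:
        if not og:
            samples_of[sp].append(sid)

    clades: dict[str, dendropy.Node] = {}
    for clade in dict.fromkeys(clade_of.values()):
        nd = dendropy.Node()
        nd.edge.length = d_clade - d_sp
        ingroup.add_child(nd)
        clades[clade] = nd
    for sp in species:
        sp_node = dendropy.Node()
        sp_node.edge.length = d_sp - d_sam
        clades[clade_of[sp]].add_child(sp_node)
        for sid in samples_of[sp]:
            lf = dendropy.Node(taxon=ns.require_taxon(label=sid))
            lf.edge.length = d_sam
            sp_node.add_child(lf)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = True
    return tree, dict(clade_of)


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def simulate_alignment(
    tree: dendropy.Tree,
    p: SimParams,
    length: int | None = None,
    rate_scale: float = 1.0,
    blocks: Sequence[tuple[int, int, float]] | None = None,
    stream: int = 0,
) -> Alignment:
    """Evolve sequences down ``tree`` under Jukes-Cantor.

    ``blocks`` columns multiply the branch length by their rate factor.
    ``stream`` decorrelates loci simulated on the same tree.
    """
    L = p.seq_length if length is None else length
    blocks = p.hypervariable_blocks if blocks is None else blocks
    mult = np.ones(L)
    for s, e, m in blocks:
        mult[s:e] = m
    rng = np.random.default_rng([p.seed, 23, stream])
    root_seq = rng.integers(0, 4, size=L)
    seqs: dict[str, np.ndarray] = {}

    def evolve(parent_seq, node):
        for child in node.child_nodes():
            ln = (child.edge.length or 0.0) * rate_scale
            p_sub = 0.75 * -np.expm1(-4.0 * ln * mult / 3.0)
            hit = rng.random(L) < p_sub
            child_seq = parent_seq.copy()
            if hit.any():
                shift = rng.integers(1, 4, size=int(hit.sum()))
                child_seq[hit] = (child_seq[hit] + shift) % 4
            if child.is_leaf():
                seqs[child.taxon.label] = child_seq
            else:
                evolve(child_seq, child)

    evolve(root_seq, tree.seed_node)
    ids = [lf.taxon.label for lf in tree.leaf_node_iter()]
    rows = tuple(_BASES[seqs[i]].tobytes().decode("ascii") for i in ids)
    return Alignment(tuple(ids), rows)


# ---------------------------------------------------------------------------
# mislabel planting
# ---------------------------------------------------------------------------

def plant_mislabels(truth: TruthTable, p: SimParams) -> tuple[SampleTable, TruthTable]:
    """Reassign the declared species of a seeded random floor(fraction * n)
    subset of the query samples; reference samples are never touched."""
    t = truth.table.copy()
    ingroup_species = sorted(set(t.loc[~t["outgroup"], "true_species"]))
    queries = t.index[t["role"] == "query"].to_numpy()
    n_mis = int(np.floor(p.mislabel_fraction * len(queries)))
    if n_mis > 0 and len(ingroup_species) < 2:
        raise DataError("cannot plant mislabels with a single species")
    rng = np.random.default_rng([p.seed, 31])
    chosen = rng.choice(queries, size=n_mis, replace=False) if n_mis else []
    for idx in chosen:
        true_sp = t.at[idx, "true_species"]
        others = [s for s in ingroup_species if s != true_sp]
        t.at[idx, "given_species"] = others[int(rng.integers(len(others)))]
    t["is_planted_mislabel"] = t["true_species"] != t["given_species"]
    out = TruthTable(t)
    return out.to_sample_table(), out


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedDataset:
    alignment: Alignment
    samples: SampleTable
    truth: TruthTable
    tree: dendropy.Tree
    species_to_clade: dict[str, str]
    nuclear: dict[str, Alignment]


def generate_dataset(p: SimParams) -> SimulatedDataset:
    """Simulate tree, sequences, sample table and planted mislabels."""
    tree, clade_of = simulate_species_tree(p)
    _, _, rows = _design(p)
    truth0 = TruthTable(
        pd.DataFrame(
            [
                {
                    "sample_id": sid,
                    "true_species": sp,
                    "given_species": sp,
                    "role": role,
                    "outgroup": og,
                    "is_planted_mislabel": False,
                }
                for sid, sp, role, og in rows
            ]
        )
    )
    samples, truth = plant_mislabels(truth0, p)
    aln = simulate_alignment(tree, p)
    nuclear = {
        name: simulate_alignment(
            tree, p, length=ln, rate_scale=scale, blocks=(), stream=i + 1
        )
        for i, (name, ln, scale) in enumerate(p.nuclear_loci)
    }
    return SimulatedDataset(aln, samples, truth, tree, clade_of, nuclear)
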