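"""Phylogenetic assignment of query accessions and mislabel flagging.

Each query (e.g. a seed-bank accession) is placed on a joint
reference+query bootstrap tree and assigned to the species whose reference
samples share its smallest well-supported enclosing clade.  If that clade
mixes several reference species the query stays ``unresolved`` -- the
method degrades to "don't know", never to a guess.  A query whose assigned
species differs from its declared label is flagged ``mislabeled``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import phylo
from .errors import DataError
from .seqio import Alignment, SampleTable

UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class IdentificationResult:
    query_id: str
    given_label: str
    assigned_label: str  # species name or "unresolved"
    support: int | None
    verdict: str  # confirmed | mislabeled | unresolved

    def __post_init__(self) -> None:
        if self.verdict == "mislabeled" and self.assigned_label in (self.given_label, UNRESOLVED):
            raise DataError("mislabeled verdict requires a different, resolved assignment")
        if self.verdict == "confirmed" and self.assigned_label != self.given_label:
            raise DataError("confirmed verdict requires assigned == given label")


def assign_queries(
    marker: Alignment,
    samples: SampleTable,
    method: str = "nj",
    n_bootstrap: int = 200,
    seed: int = 0,
    support_threshold: int = 75,
    synonyms: dict[str, str] | None = None,
    search_params: phylo.SearchParams | None = None,
) -> list[IdentificationResult]:
    """Assign every query sample to a species by clade membership.

    The tree spans references, outgroups and queries, built with the chosen
    engine (NJ by default for speed; MP optional) and bootstrap supports,
    rooted on the outgroups when present.  Walking from the query tip
    towards the root, the first clade with support above the threshold that
    contains at least one reference sample decides: exactly one reference
    species there means assignment, several mean ``unresolved``.  A query
    whose aligned sequence is byte-identical to references of exactly one
    species is assigned to it even without a supported clade (reported with
    support 100).

    ``synonyms`` maps species labels to canonical names, so a query whose
    declared label is a synonym of the assigned species counts as
    confirmed.
    """
    refs = samples.reference_ids
    if not refs:
        raise DataError("no reference samples")
    queries = samples.query_ids
    present = set(marker.ids)
    missing = [q for q in queries if q not in present]
    if missing:
        raise DataError(f"query sample(s) absent from alignment: {missing[:5]}")
    og = [o for o in samples.outgroup_ids if o in present]
    keep = [s for s in refs if s in present] + og + list(queries)
    if len(keep) < len(refs) + len(og) + len(queries):
        missing_refs = [s for s in refs if s not in present]
        raise DataError(f"reference sample(s) absent from alignment: {missing_refs[:5]}")
    sub = marker.subset(keep)

    tree = phylo.bootstrap(
        sub, builder=method, n_reps=n_bootstrap, seed=seed, search_params=search_params
    )
    if og:
        tree = phylo.root_with_outgroup(tree, og)

    ref_set = set(refs)
    species_of = {sid: samples.species_of(sid) for sid in keep}
    node_of = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}

    canon = (lambda s: synonyms.get(s, s)) if synonyms else (lambda s: s)

    results = []
    for q in queries:
        assigned, support = _place(node_of[q], ref_set, species_of, support_threshold)
        if assigned == UNRESOLVED:
            twin = _identical_reference_species(sub, q, refs, species_of)
            if twin is not None:
                assigned, support = twin, 100
        given = species_of[q]
        if assigned == UNRESOLVED:
            verdict = UNRESOLVED
        elif canon(assigned) == canon(given):
            verdict = "confirmed"
            assigned = given  # report under the declared (synonymous) name
        else:
            verdict = "mislabeled"
        results.append(IdentificationResult(q, given, assigned, support, verdict))
    return results


def _place(leaf, ref_set, species_of, threshold):
    node = leaf.parent_node
    while node is not None and node.parent_node is not None:
        s = phylo.support_of(node)
        if s is not None and s > threshold:
            ref_species = {
                species_of[lf.taxon.label]
                for lf in node.leaf_iter()
                if lf.taxon.label in ref_set
            }
            if len(ref_species) == 1:
                return next(iter(ref_species)), s
            if len(ref_species) > 1:
                return UNRESOLVED, None
        node = node.parent_node
    return UNRESOLVED, None


def _identical_reference_species(aln: Alignment, query: str, refs, species_of):
    qrow = aln.row(query)
    hits = {species_of[r] for r in refs if aln.row(r) == qrow}
    if len(hits) == 1:
        return next(iter(hits))
    return None


def mislabel_report(results: list[IdentificationResult]) -> tuple[dict, pd.DataFrame]:
    """Summary counts plus a per-query table.

    The headline number is the mislabel percentage, ``100 * n_mislabeled /
    n_queries`` rounded half-up to the nearest integer.
    """
    if not results:
        raise DataError("no identification results")
    n = len(results)
    n_mis = sum(r.verdict == "mislabeled" for r in results)
    summary = {
        "n_queries": n,
        "n_confirmed": sum(r.verdict == "confirmed" for r in results),
        "n_mislabeled": n_mis,
        "n_unresolved": sum(r.verdict == UNRESOLVED for r in results),
        "percent_mislabeled": int(np.floor(100.0 * n_mis / n + 0.5)),
    }
    order = {"confirmed": 0, "mislabeled": 1, UNRESOLVED: 2}
    rows = pd.DataFrame(
        [
            {
                "query_id": r.query_id,
                "given_label": r.given_label,
                "assigned_label": r.assigned_label,
                "support": "" if r.support is None else r.support,
                "verdict": r.verdict,
            }
            for r in sorted(results, key=lambda r: (order[r.verdict], r.query_id))
        ]
    )
    return summary, rows
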