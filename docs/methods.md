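# Methods

This note records the statistical and algorithmic choices behind
`plastbarcode`, the defaults that matter, and what the synthetic tests do
and do not demonstrate.

## Diversity scanning

Nucleotide diversity is the average proportion of differing sites between
two sequences, π = [2/n(n−1)] Σ_{i<j} d_ij / L_used. The denominator is the
number of *included* columns, not the nominal span length, so windows full
of gaps shrink their denominator rather than diluting π; a span with no
usable column returns π = 0 with a warning instead of NaN.

Gap policy. The default is complete deletion per column within the scored
span: a column is excluded when any included sequence carries a gap or an
ambiguity code there. This matches the convention of the standard
sliding-window tools biologists use for this job. Pairwise deletion (each
pair scored over its own comparable columns) is available for
`nucleotide_diversity`; the windowed scan supports complete deletion only,
because that is what makes the scan a single prefix-sum pass.

Site classes. A column is parsimony-informative when at least two states
each occur in at least two included sequences; informative sites are a
subset of variable sites, and excluded columns are counted in neither. The
`include_ids` argument reproduces "with / without outgroups" tallies.

Windows and regions. Windows start at 0, step, 2·step, …; a final clipped
window is appended when the full windows stop short of the alignment end
and the remainder is at least one step long. Defaults: window 800 columns,
step 100, minimum region length 600, 36 candidates retained. These sizes
target merged regions on the 1–1.6 kb scale of a PCR-amplifiable barcode;
there is no canonical value, so all are configurable. Region selection is
deliberately simple and fully deterministic: rank windows by (π desc,
variable sites desc, start asc), walk down the ranking merging each window
into any region it overlaps or abuts (else opening a new region), and stop
the walk as soon as `n_candidates` regions exist. The hard stop matters:
without it, weakly variable background windows chain neighbouring regions
together until the whole alignment merges into one region. Regions shorter
than the minimum are dropped; survivors are ranked by their best member
window. Ties everywhere break deterministically, so no seed is involved.

## Tree engines

Distances. p-distance is the mismatch fraction over pairwise-complete
columns; the Jukes–Cantor transform is −(3/4)·ln(1 − 4p/3), with p ≥ 0.75
capped just below the singularity (with a warning) rather than raising,
since saturated pairs still need a finite entry for clustering. A pair with
no comparable column at all is an error naming the pair.

Neighbor joining follows the standard Q-matrix agglomeration. Tie-breaking
is by the lexicographically smallest pair of cluster labels (a cluster's
label is its smallest member id), so output is reproducible without a
seed. Internal edges of (near-)zero length are collapsed into polytomies
after construction. This collapse is load-bearing: with deterministic
tie-breaks, a group with no signal would otherwise come out as the same
arbitrary binary shape in every bootstrap replicate and earn 100% support
for edges that reflect the tie-break rule, not the data. A zero-variation
marker must resolve nothing.

Parsimony. Fitch scoring treats gaps, N and IUPAC ambiguity as free
wildcards (standard missing-data practice; "gap as state" is out of
scope). Scoring runs on compressed site patterns — unique columns with
multiplicities — which is also what makes bootstrapping cheap: a replicate
is a new multinomial weight vector over patterns, not a new alignment.

The heuristic search does seeded random stepwise addition followed by
subtree-prune-regraft (SPR) swapping with first-improvement acceptance
(NNI available as a restricted SPR; tree-bisection-reconnection is not
implemented — its classic retention rule is ambiguous and SPR local optima
suffice at barcode scale, as the exhaustive-equivalence tests confirm up
to 8 taxa). Both addition and SPR score candidate placements exactly in
O(1) vector operations per edge using directional Fitch state sets: for an
edge with side sets D1, D2, attaching a subtree with root set S costs
`base + Σ_p w_p·[S_p ∩ E_p = ∅]` where E = D1∩D2 if non-empty else D1∪D2.
Because the Fitch length is invariant to root placement this is exact, and
an addition replicate costs O(n²) vector operations instead of O(n³).
Default 10 addition replicates (overridable; bootstrap replicates default
to 2) with up to 100 equally-best distinct trees retained.

Consensus, bootstrap, rooting. Strict consensus keeps exactly the splits
present in every input tree. The bootstrap resamples columns with
replacement; support on each internal edge of the point-estimate tree is
the percentage of replicate trees containing that split, rounded half-up
to an integer (with the MP builder, the point estimate and each
replicate's contribution are strict consensi of the equally-best trees).
Outgroup rooting places the root on the edge separating the outgroups —
which must be monophyletic on the unrooted tree, else an error — and
supports are re-attached by bipartition, since rerooting reshuffles which
clade sits below which node.

## Discrimination scoring

A species is resolved by a marker when n = 1 (a singleton cannot fail
monophyly; support reported n/a) or when its samples form a clade with
bootstrap support strictly greater than the threshold (default 75).
Monophyly is judged against non-outgroup samples only, and the support
used is the label on the species' own stem node (falling back to a
complement-side edge only when no stem node exists, as can happen next to
the root). Species inside an unresolved polytomy have no stem edge and are
unresolved. Unresolved species are grouped by the smallest supported clade
containing all their samples — the species sets the marker cannot take
apart. Marker comparison ranks by species resolved, then informative
sites. Both MP (default, matching how such comparisons are conventionally
built) and NJ engines are supported; the two must and do agree on the
synthetic recovery properties.

## Query identification

A joint reference+query bootstrap tree is built (NJ by default — at
identification scale it is an order of magnitude faster than MP and
satisfies the same recovery properties; MP is a flag away), rooted on the
outgroups. Walking from a query tip towards the root, the first clade with
support above the threshold that contains at least one reference sample
decides: exactly one reference species there means assignment; several
mean `unresolved`. Supported clades containing only queries cannot decide
and the walk continues. One deterministic shortcut guards a degenerate
case: a query byte-identical to references of exactly one species is
assigned to that species (support reported as 100) even when the tree walk
is uninformative — with three or more identical sequences, no single
cherry is consistently present across replicates, yet the identity of the
sequences is unambiguous evidence.

Verdicts: `confirmed` when the assignment matches the declared label
(optionally through a user-supplied synonym map, for taxonomies where
e.g. a crop and its wild progenitor are conspecific), `mislabeled` when it
differs, `unresolved` otherwise. The headline mislabel percentage is
100·n_mislabeled/n_queries rounded half-up.

## Synthetic data

The generator is a fixed-depth ultrametric hierarchy, not a coalescent:
samples split at intra/2, species at inter_species/2, clades at
inter_clade/2, outgroups at outgroup_divergence/2, so expected pairwise
divergence equals the named parameter. Sequences evolve by Jukes–Cantor
substitution sampled exactly per site from p = (3/4)(1 − e^(−4ℓ/3));
hypervariable blocks multiply branch lengths column-wise. There are no
indels by default — gap handling is tested with hand-built gapped
fixtures — and everything derives from one seed.

The `oryza-like` preset models the study scale this package is built for:
8 clades, exactly 21 species (clade sizes 1–4), 1–3 reference samples per
species, two outgroup taxa, a 20 kb plastome-like alignment, 53 queries
with 17% planted mislabels (⌊0.17·53⌋ = 9), and two nuclear-like loci at
12× and 22× the base rate. Divergences (intra 2·10⁻⁴, inter-species
2·10⁻³, inter-clade 5·10⁻³, outgroup 2.5·10⁻²) and block multipliers
(2.0/2.2/2.5) were calibrated once so that whole-alignment π lands near
0.006 (within [0.004, 0.008] across seeds), block π spans ≈0.009–0.017 —
the spectrum real hypervariable chloroplast regions occupy — and the
nuclear loci reach π ≈ 0.06 and 0.10. The 20 kb length is a deliberate
scale-down of a ~150 kb plastome that preserves the quantities the
pipeline consumes (per-site diversity, tens of diagnostic sites per
species pair) at desk-scale runtime.

What passing tests show — and don't. The simulator produces clean,
clock-like, recombination-free data with abundant signal between species.
Full mislabel recovery on it demonstrates the pipeline's logic, not field
performance: real plastomes bring alignment error, heterotachy,
chloroplast capture/introgression (a seed can carry the "wrong" plastome
legitimately), and species pairs with genuinely zero plastome divergence,
where any method must and should return `unresolved` or collapse the pair
to one species.

## Numerical choices and degenerate inputs

Scores and supports compare with a 10⁻⁹ slack where floats are summed;
supports round half-up. Degenerate inputs have defined behaviour rather
than crashes: all-gap windows (π = 0 + warning), saturated JC distances
(capped + warning), zero-variation markers (nothing resolved beyond
singletons), non-monophyletic outgroups (error, caller may fall back to a
single-taxon root), queries missing from the alignment (error naming
them). Problem sizes in the test suite (≤ 12 taxa for oracle equivalence,
≤ 8 for exhaustive search, 200-replicate bootstraps, 5 seeds end-to-end)
are the package's own choice of desk-scale verification; the same code
paths run unchanged at larger sizes.

## Known limitations

Maximum likelihood and Bayesian engines are out of scope by design; the
claims rest on MP and NJ. TBR swapping and PAUP-style multi-tree retention
per replicate are not reproduced. The MP bootstrap can in principle retain
a tie-break artifact edge on signal-free data (the NJ engine collapses
these via zero-length branches; MP mitigates it with ≥2 addition
replicates per bootstrap replicate but has no branch lengths to collapse).
Manual alignment curation, assembly, and primer design live upstream of
this package.
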