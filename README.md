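# plastbarcode

Design organelle DNA barcodes and identify mislabeled accessions, the way it
is done for crop species complexes such as rice (*Oryza*): scan aligned
plastomes for hypervariable regions, evaluate each candidate marker's power
to discriminate species by bootstrap-supported monophyly, and assign query
samples (e.g. seed-bank accessions) to species by clade membership on a
joint reference+query tree — flagging accessions whose declared species
conflicts with their phylogenetic placement.

The package is aimed at people curating germplasm collections or building
group-specific barcoding panels: closely related congeners (sister species a
few thousand substitutions apart genome-wide) defeat universal barcodes like
*matK*/*rbcL*, but a handful of hypervariable plastome windows — or the
whole plastome as a "super barcode" — resolves them.

## What it computes

**Nucleotide diversity.** For sequences *i < j* over the *L*<sub>used</sub>
alignment columns that survive the gap policy (complete deletion by
default),

π = [2 / *n*(*n*−1)] · Σ<sub>i&lt;j</sub> *d*<sub>ij</sub> / *L*<sub>used</sub>,

with *d*<sub>ij</sub> the pairwise mismatch count. A sliding window (default
800 bp, step 100) localises π along the genome; top-ranked windows are
merged into candidate barcode regions.

**Trees and support.** Neighbor joining on p- or Jukes–Cantor distances, and
heuristic maximum parsimony (seeded random stepwise addition + SPR swapping,
Fitch optimality) with strict consensus of equally-parsimonious trees.
Branch support is the nonparametric bootstrap: resample columns, rebuild,
report the percentage of replicates containing each split.

**Discrimination and identification.** A species is *resolved* by a marker
when its samples form a clade with bootstrap support > 75 (strict, after
the usual "reliably resolvable" convention). A query is assigned to species
*S* when the smallest supported clade containing it holds reference samples
of exactly *S*; a disagreement with the declared label is a *mislabel*, and
anything else degrades to *unresolved* — never to a guess.

**Synthetic data.** A seeded generator emulates an *Oryza*-like complex:
8 deep clades ("genome types") holding 21 species, 1–3 samples each,
background π ≈ 0.006 with six hypervariable blocks (π ≈ 0.009–0.017), two
fast nuclear-like loci (π ≈ 0.06/0.10), 53 query accessions with 17%
deliberately mislabeled.

## Worked example

```sh
$ plastbarcode simulate --preset oryza-like --seed 1 --out-prefix sim
simulated 95 samples x 20000 bp (9 planted mislabels) -> sim.*

$ plastbarcode scan --alignment sim.fasta --out windows.tsv
scanned 193 windows over 20000 columns -> windows.tsv

$ plastbarcode select --windows windows.tsv --n-candidates 6 --out regions.tsv
selected 6 regions -> regions.tsv

$ head -4 regions.tsv
# plastbarcode 0.1.0 select windows=windows.tsv n_candidates=6 min_length=600
name        start   end     start_1based    end_1based      mean_pi  rank
region_001  7800    9300    7801            9300            0.011799 1
region_002  1800    3100    1801            3100            0.011746 2

$ plastbarcode identify --alignment sim.fasta --samples sim.samples.tsv \
      --bootstrap 200 --seed 1 --out ident.tsv
53 queries: 44 confirmed, 9 mislabeled (17%), 0 unresolved -> ident.tsv
```

The selected regions sit exactly on the simulated hypervariable blocks
(e.g. `region_001` covers the block at 8000–8800 plus flanks), and the
identification step recovers all nine planted mislabels — 17% of the 53
queries — with none of the correctly labeled accessions flagged. Per-query
rows report the declared label, the assigned species, the bootstrap support
of the deciding clade, and the verdict:

```
query_id  given_label  assigned_label  support  verdict
BOP0001   sp04         sp04            100      confirmed
```

The same steps are available as library calls (`divscan.sliding_scan`,
`divscan.select_regions`, `identify.assign_queries`, …); marker comparison
— e.g. whole plastome vs each selected region — goes through
`discriminate.compare_markers`, and `plastbarcode evaluate` on the command
line.

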