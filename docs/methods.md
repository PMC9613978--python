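# Methods

This note documents the models and procedures implemented in `syngenmark`,
the defaults they use, and what the synthetic data can and cannot show.

## Data model

All stages operate on `MarkerAlignment` objects: equal-length, pre-aligned
sequence records for one of four markers (SSU, ITS, COI nucleotide, COI
amino acid). Alignment columns are 1-based in every user-facing report,
following the convention of published signature tables. Nucleotide records
are uppercased with U canonicalised to T (rDNA and rRNA representations are
used interchangeably in the source data). Syngen labels R1–R5 and a
six-continent region vocabulary come from a tab-separated metadata table;
blanks map to `UNKNOWN`. De novo multiple alignment is deliberately out of
scope — the reference alignments for these markers are curated against rRNA
secondary structure, a step that cannot be automated faithfully here.

**Missing data.** Gaps and ambiguity codes (and `X` in peptides) are not
character states: they are excluded from state sets during discovery and
never match anything during typing (an `R` is *missing*, not "A or G").
This is conservative — GenBank fragments have ragged ends, and treating an
ambiguity as a possible match would manufacture diagnostic coverage that
is not there. A `missing_policy="as_state"` switch exists for sensitivity
analysis because the published variable-position counts do not state how
gap columns were treated. A `drop_gap_only_columns` utility is provided but
never applied implicitly, since it renumbers columns.

## Synapomorphy discovery

For each variable column (≥ 2 distinct non-missing states) the per-clade
state multisets decide exactly one category:

* **SYNAPOMORPHY** — some clade is *fixed* (all non-missing members share one
  state, at least one non-missing member) for a state carried by no record
  outside the clade. `diagnostic_for` is a set: one column can be diagnostic
  for several clades simultaneously, each for its own private state.
* **WITHIN_CLADE_VARIABLE** — no clade is diagnostic and at least one clade
  shows ≥ 2 states.
* **OTHER_VARIABLE** — everything else, notably a fixed state shared by
  exactly two clades (the R1+R2 pattern in the SSU).

Unlabelled records never define a clade but do veto privacy. The
`min_clade_size` default is 1 because syngen R5 is represented by a single
strain in the reference set; single-member clades still yield synapomorphies
but are logged as weakly supported. Combining markers takes, per clade, the
union of its diagnostic (marker, column, state) triples; a clade is
*separable* by a marker set iff that union is non-empty there, which is what
makes R1/R2 non-separable by SSU alone but separable once ITS is added.

## COI translation

COI signatures are read at the amino-acid level. The default genetic code is
NCBI translation table 4 (mold/protozoan mitochondrial, TGA→Trp), the
standard choice for ciliate mitochondria; tables 1 and 6 are selectable
because the table used for previously published COI haplotypes is not
recorded, and TGA handling can move individual columns. Codons containing
any gap or ambiguity translate to `X` rather than raising, since database
fragments are expected to be ragged. A `CodonColumnMap` links every
amino-acid column to its three nucleotide columns so each amino-acid
synapomorphy is traceable to its codon. `pick_frame` suggests the reading
frame with the fewest internal stops (ties to the lower frame), but the CLI
default is an explicit frame with the suggestion logged — silently changing
frame on real data would be worse than asking.

## Query typing

Queries are not re-aligned into the reference alignment; they are mapped
onto reference columns by a global pairwise alignment (match +1, mismatch
−1, gap −2, end gaps free) against the reference *consensus* (majority
state per column, gap-majority columns dropped). Free end gaps matter
because database records are typically partial. Per clade and marker, the
query is checked at the clade's diagnostic columns it covers: any mismatch
*excludes* the clade, full agreement on ≥ 1 column *matches* it, and a clade
with no testable column is *neutral*. Positive evidence outranks
untestability: exactly one matched clade → `ASSIGNED`; several matched, or
none matched but several neutral survivors → `AMBIGUOUS`; everything
excluded → `CONFLICT`; fewer than `min_evaluable` (default 3) diagnostic
columns covered in total, or no positive evidence for a lone survivor →
`INSUFFICIENT`. The threshold of 3 prevents confident calls from tiny
fragments; it is a package choice, not an empirical constant, and is
exposed in the CLI. Multi-marker strains are combined conservatively
(excluded anywhere = excluded; matched somewhere and excluded nowhere =
matched). Batch typing isolates per-record failures instead of aborting.

## Haplotype networks and the connection limit

Records collapse to haplotypes either by exact string identity (`strict`,
default) or by compatibility over mutually determinate columns (`infer`,
closed transitively via union–find; compatibility itself is not transitive,
so the closure is documented behaviour, not an accident). The
representative is the member with the fewest missing characters, ties
broken by smallest id. Mutational steps between haplotypes are Hamming
distances over mutually determinate columns (gap columns excluded by
default).

The statistical-parsimony criterion caps the number of steps that may link
two haplotypes. This package models the parsimony probability explicitly:
if `j` mutations fall independently and uniformly over `L` compared sites,
the probability that they are homoplasy-free (no site hit twice, hence no
hidden, parallel or reverted change) is

    P_j = Π_{i=0}^{j-1} (1 − i/L) = L! / ((L−j)! · L^j),

and the connection limit is `J = max{ j : P_j > α }` with α = 0.95 by
default. `P_0 = 1`, `P_j` decreases strictly in `j` and increases in `L`,
so `J` is non-decreasing in `L`, non-increasing in α, and every connection
up to `L` steps becomes admissible as α → 0. `L` defaults to the number of
columns determinate in ≥ 90 % of records, not the raw alignment length —
heavily ragged columns are not compared characters. The implementation is
validated in the tests against an independent log-gamma evaluation of the
closed form and a Monte-Carlo simulation. For a 600-site marker at
α = 0.95 this yields J = 7; published statistical-parsimony tools built on
the original pairwise-homoplasy estimator can admit somewhat longer
connections, so absolute limits (though not the qualitative structure)
may differ from their output.

Edges are added in non-decreasing step order. Within one step count,
connectivity is frozen at the start of the tier and every tied edge joining
two previously disconnected components is retained — this is what produces
reticulations — while tied edges internal to an already-connected component
are dropped. The result is deterministic for any input order, contains a
minimum spanning forest of the thresholded step graph, and never contains
an edge above `J`. Median vectors (inferred unsampled haplotypes) are not
inserted; nodes are always observed haplotypes, which can make renderings
sparser than tools that add them. Biogeography summaries report, per
syngen, the set of observed regions and a Europe-only flag (records of
unknown region do not defeat the flag, but a syngen observed *only* in
unknown regions is never flagged Europe-only).

## Tree check

The monophyly check is a desk-scale verification, not a phylogenetic
analysis: p-distances (mismatch fraction over shared determinate columns),
neighbour joining with ties broken deterministically by the smallest index
pair and negative branch lengths clamped to zero, and a test that some edge
bipartition isolates exactly the labelled members of each syngen
(unlabelled leaves ignored). SSU and ITS are concatenated column-wise for
this check, mirroring standard practice for these markers. The bootstrap
resamples columns with replacement, seeded and reproducible. No likelihood
or parsimony tree search, no substitution-model selection: clade recovery is
the contract, branch lengths are incidental.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions of the reference set:
five clades with 11/12/20/4/1 members (48 records), marker lengths
SSU 1700, ITS 500, COI 600 nt, and the `fig3` preset plants

* SSU: 6 synapomorphies each for R3/R4/R5, 6 columns with one derived state
  shared by R1+R2, 6 within-clade variable columns → 30 variable;
* ITS: 4/4/3/3/3 synapomorphies + 6 within-clade variable → 23 variable;
* COI: 3/3/3/2/2 amino-acid synapomorphies + 5 within-clade variable
  amino-acid columns → 18 variable, 13 diagnostic.

Only the totals (30, 23, 18/13) and the R1/R2 SSU ambiguity are anchored in
the published analysis; the split across clades is the generator's own
design and fixed once here. COI is generated as an open reading frame under
the configured code (no internal stops) and every planted COI change is
nonsynonymous, so the amino-acid alignment carries exactly the planted
structure. The region model makes R1 and R5 Europe-only; clades whose model
has mass outside Europe are guaranteed at least one non-European record, so
the planted Europe-only set is exactly {R1, R5} at every seed. All
randomness flows from one seed through per-marker substreams; identical
configs give byte-identical output.

Limitations to keep in mind when reading green tests: there is no
within-clade branching process (each clade is a star of near-identical
sequences), no indels beyond query fragmentation, no rate heterogeneity,
and no sequencing chemistry — query noise is i.i.d. substitution at a
configurable rate. Passing tests therefore demonstrate the correctness of
the discovery/typing/network logic under the assumed structure, not
robustness to alignment error or deep within-syngen divergence in real
data.

## Numerical and degenerate-input choices

* Consensus ties during query mapping break alphabetically; NJ Q-matrix ties
  break toward the smallest index pair — both purely for determinism.
* A pair of records sharing zero determinate columns is an error in
  p-distance (no defensible distance exists) but merely unlinked in the
  haplotype network.
* `batch_type` never aborts on a bad record; it emits an `ERROR` row.
* Bootstrap with `n_reps = 1` legitimately returns supports in {0, 1}.
* Typing thresholds, alignment scores, α, the 90 % coverage rule for `L`,
  and the genetic-code table are all exposed as function/CLI parameters;
  the defaults above are the package's standing choices.
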