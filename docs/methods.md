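# Methods

`dinomir` re-implements, as a tested desk-scale package, the classic
small-RNA sequencing workflow used to discover and profile miRNAs in a
non-model unicellular alga sampled in two batch-culture growth phases
(lag vs logarithmic). This note records the models, conventions and
numerical choices behind each stage, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Read cleaning and accounting (`preprocess`)

Raw reads carry a 3' sequencing adapter. Trimming takes the leftmost
exact full-adapter occurrence, or failing that the longest exact
read-suffix/adapter-prefix overlap of at least `min_overlap` (default
6) nt. Reads with no adapter evidence are kept only when their raw
length already lies in the gel-cut window (15–40 nt); all inserts must
then fall in the 18–25 nt analysis window.

Each raw read is assigned to exactly **one** terminal category, in a
fixed precedence: (1) `3ADT&length filter` (no adapter / out of
window), (2) `Junk reads` (any `N`, or a poly-A run covering ≥ 80 % of
the read — the source workflow never defines "junk", so this threshold
is explicit and configurable), (3) `Clean reads`. The accounting table
is therefore a strict partition of the raw total. Note that the
reference study's own published accounting rows sum to *more* than its
raw total, i.e. its categories overlap in an unstated way; this package
deliberately enforces the partition instead, so per-category counts on
the same data will not reproduce that table row-for-row.

Quality strings are carried but never used: no quality-trimming rule is
defined in the source workflow.

## Annotation (`annotate`)

Contaminant classification is exact substring containment (either
strand) against class-labelled reference sets, applied in the fixed
order rRNA → tRNA → snoRNA → snRNA → otherRfam → repeats. Containment,
not alignment, is used because this step is a discard filter; the first
matching class wins, which makes the accounting reproducible.

Known-miRNA matching emulates catalog-variant reporting: a read is
aligned to every catalog mature at end shifts of up to ±2 nt per side
(the published variant grammar uses ±1; 2 gives headroom and is
configurable), accepting at most one substitution over the aligned
overlap. The best hit is chosen by (fewest substitutions, smallest
total |shift|, highest species priority, lexicographic name). Variant
suffixes follow the convention `_L±k`, `_R±k`, `_1ss<pos><ref><read>`;
the substitution position is **1-based on the detected read** — the
convention is stated here because the source material does not define
the coordinate origin. Sequences are handled internally in T-space
(U→T) and reported in U-space.

Family assignment takes the numeric core of the catalog name
(`zma-miR169f-5p` → `miR169`); unparseable names become `unknown`.

## Precursor prediction (`hairpin`)

For every unannotated read mapping uniquely (forward strand, exact) to
a transcriptome contig, three candidate windows are cut: 60 nt upstream
flank, 60 nt downstream flank, and both, truncated at contig bounds.
Coordinates are 1-based inclusive throughout.

**Folding.** The internal folder is a maximum-pairing dynamic program
with a stacking bonus, *not* a thermodynamic model: pair scores
AU/AT = 2, GC = 3, GU/GT = 1, +1 per directly stacked pair, minimum
loop 3 nt, and a reported pseudo-energy of −0.5 kcal/mol per score
unit. Traceback is deterministic (prefer a paired 3' base, then the
leftmost partner, then the stacked continuation). With uniform pair
scores and zero stacking bonus it reduces exactly to Nussinov maximum
base pairing, which is how it is oracle-tested. Real RNAfold output can
be supplied instead through the Vienna-format reader (`read_vienna`),
bypassing the internal folder for "faithful" runs; the pseudo-energies
are internally consistent but not comparable to published ΔG values.

**Criteria.** A candidate is accepted when all eleven stem-loop
criteria pass: (1) largest stem bulge ≤ 12 nt; (2) stem pairs ≥ 16;
(3) energy ≤ −15 kcal/mol; (4) folded hairpin length ≥ 50 nt
(measured on the folded region, excluding unpaired external tails);
(5) terminal loop ≤ 200 nt; (6) largest bulge in the mature region
≤ 4 nt; (7) biased errors per event in the mature region ≤ 4;
(8) biased bulges in the mature region ≤ 2; (9) errors in the mature
region ≤ 2; (10) paired mature positions ≥ 12; (11) ≥ 80 % of mature
positions inside the stem.

The structure is decomposed at the innermost hairpin loop with the
longest enclosing helix chain (ties: leftmost); the chain stops at
multiloop junctions. Between adjacent stem pairs with unpaired run
lengths (l5, l3), min(l5, l3) nucleotides count as *errors*
(mismatch-like) and |l5 − l3| as a *bulge* on the longer arm; "biased"
means asymmetric (one-arm-only surplus), configurable to "any". These
event definitions are this package's own, stated because the source
criteria never define "biased errors/bulges"; the criteria engine is
tested against construction-time ground truth on designed hairpins.
When several windows pass for one mature, the lowest-energy (tie:
shortest) precursor is kept.

## Differential expression (`diffexpr`)

Counts are normalized to reads per million of each library's clean
total. Effect size is log2(lag/logarithmic) with ±∞ sentinels for
presence/absence (serialized `+inf`/`-inf` in TSV). Significance uses
the 2×2 table [[a, La−a], [b, Lb−b]]: a two-sided Fisher exact test
(scipy) and a 1-df chi-square without continuity correction are both
reported; the call gates on the chi-square p when all expected cells
are ≥ 5 (matching the convention of the published DE table, which
prints chi-square p values) and on the Fisher p otherwise. DE requires
|log2FC| > 1 and p < 0.05; "significant" additionally p < 0.01.
Bonferroni-adjusted p values (multiplier = miRNAs tested) are reported
but do not gate by default, since the published calls use raw p; a
`use_adjusted` switch flips this. Direction is literally the sign of
log2(lag/log), matching the published table's labels even though its
narrative frames direction relative to the logarithmic phase.

Because per-million normalization shifts every log2FC by the
library-composition offset log2(La/Lb · Eb/Ea), small planted
magnitudes (~1.1) can land just under the DE gate in simulation; the
recoverable quantity there is the sign, which is what the acceptance
suite asserts.

## Enrichment (`enrichment`)

The enrichment p value is the hypergeometric upper tail
P = 1 − Σ_{i=0}^{m−1} C(M,i)·C(N−M,n−i)/C(N,n) = P(X ≥ m), evaluated
in exact rational arithmetic (`fractions` + `math.comb`), with the
one-sided Fisher exact test as an independent, identical-by-construction
cross-check. One widely circulated rendering of this formula prints
"C(M−N, n−i)"; the prose definitions of N, n, M, m force N−M, which is
what is implemented. Terms with p < 0.05 are flagged; no multiplicity
correction by default (Benjamini–Hochberg available, off by default).
N/n are computed per annotation database (GO and KEGG maps are separate
inputs). Target-site prediction itself is out of scope: the module
ingests a precomputed target-gene list.

## qPCR (`qpcr`)

Relative expression is 2^−ΔΔCt with ΔCt = mean Ct(target) − mean
Ct(reference gene, default 5.8S) per sample and ΔΔCt relative to a
calibrator sample. SE is propagated from replicate Ct variances by the
delta method. Significance is a two-sided paired t-test on
per-replicate ΔCt values against the calibrator, paired on the
replicate label (biological replicates are the test unit), with tiers
at 0.05 (*) and 0.01 (**).

## Synthetic data (`simulate`)

The generator states a toy world mirroring the structure, not the
scale, of the real experiment: default 8 contigs × 400 nt, 10 planted
miRNAs with matures of 20–24 nt (60 % copied into the "known" catalog,
the rest novel-by-construction), 13 contaminant fragments across five
classes (20 expected reads each per library), 20 out-of-window
fragments, 2 % junk (poly-A and N-containing), a TruSeq-style 3'
adapter, 36-nt platform reads, and 200 expected reads per miRNA per
library unless a fold-change spec says otherwise. These defaults are
desk-scale choices made once: large enough that every planted feature
is exercised, small enough that the full pipeline runs in about a
second.

Precursors are designed as mature + 5 extra stem pairs + 8-nt loop +
(partially) complementary arm, verified at generation time to pass all
eleven criteria, and planted on the forward strand at non-overlapping
slots. Deterministic mode emits exactly the expected counts
(conservation is exact, enabling equality assertions); multinomial mode
draws a total depth split across the libraries in proportion to
expected totals, so between-library count ratios — including the
presence/absence sentinels `only-A`/`only-B`, which yield exactly zero
on the absent side — hold in expectation.

Not emulated: sequencing errors, quality-score structure, 5' adapters,
multiplexing, reverse-strand miRNAs, multi-mapping loci, and realistic
transcriptome composition. A green synthetic test therefore establishes
algorithmic correctness on planted truths, not performance on real
libraries.

## Determinism and tolerances

Every stochastic step is seeded (`numpy.random.default_rng`); the same
seed gives byte-identical FASTA/FASTQ/manifest/report files. Exact
rational arithmetic is used where feasible (enrichment tails); float
comparisons in tests use relative tolerances of 1e-9 against
enumeration oracles. The type-I calibration check (1000 null miRNAs at
100 expected reads each) asserts a raw-p < 0.05 fraction in
[0.03, 0.07], a ±2σ band around the nominal level for 1000 tests.

## Limitations

* The pseudo-energy scale is internal; criterion 3's −15 kcal/mol
  threshold is meaningful for real RNAfold energies supplied via the
  Vienna adapter, while the internal folder's energies are a proxy that
  designed-stem precursors comfortably clear.
* Contaminant matching by exact containment will miss diverged copies
  that alignment-based filters would catch.
* Transcriptome mapping is exact and unique-only; multi-mappers are
  dropped rather than resolved.
* The headline discovery counts of the original study (88 known
  miRNAs, 32 families, 15 novel, 12 DE) depend on its raw libraries
  and catalog version and are not recomputable here; the package
  validates against the arithmetic its published tables make
  self-contained, plus planted-truth simulations.
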