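# Methods

This note documents the models, decision rules and numerical choices behind
`mirdeg`, in the order data flows through the pipeline.

## Synthetic data model

The generator emulates a factorial stress experiment on a cereal crop:
genotypes TL (stress-tolerant) and SL (stress-sensitive); treatments CG
(control), WS (pre-anthesis water deficit), HS (post-anthesis heat), WH
(combined); sampling time-points in days post-anthesis (DPA, default 5–45
for sRNA profiling, a single 5 DPA point for the integrated mRNA/degradome
layers, mirroring designs where only flowering-stage RNA is deep-sequenced);
3 biological replicates. Sample names encode their design cell
(`TL5_WS_2`) and parse back losslessly, which is what ties count-matrix
columns to contrasts.

**Reference.** Transcripts are uniform-random nucleotide sequences of
400–1200 nt (≥ 200 nt enforced). Each miRNA is a random 21-mer embedded in
a synthetic precursor as `flank – mature – loop – revcomp(mature) – flank`,
so every mature is an exact substring of its precursor and folds onto the 5′
arm. Each miRNA also receives one exactly complementary target site placed
at a random interior position of one transcript (≥ 30 nt from either end so
degradome tags fit); the expected cleavage coordinate is the transcript base
opposite miRNA position 10. One site per transcript is the default
capacity; requesting more miRNAs than sites raises a capacity error.
Optional extra hairpins without catalog entries exercise novel-miRNA
discovery.

**Counts.** Feature baselines are lognormal (miRNAs: median 200 counts per
million-scale units, σ = 1; genes: median 150, σ = 1). For sample *j* with
library size *L<sub>j</sub>* (uniform in 0.8–1.2 M by default) the expected
count of feature *i* is `base_i · 2^effect · L_j / 1e6`, with the planted
log2 effect applied only in samples of the module's stressed treatment.
Counts are negative-binomial via the gamma–Poisson mixture with common
dispersion φ = 0.1 (variance µ + φµ²), matching the overdispersion the NB
exact test assumes; φ = 0 degenerates to Poisson. Planted antagonistic
modules couple with sign −1: the target gene receives exactly the
opposite-signed effect of its miRNA in the same condition. The default
planted magnitude is |log2FC| = 3 (an 8-fold change, a typical order for
clearly stress-responsive miRNAs, and large enough that a 3-replicate design
has power to see it on both layers).

**Degradome.** A library of depth *D* allocates a `signal_fraction`
(default 0.3) of tags equally among planted modules, each tag starting
exactly at the module's cleavage position; the rest is uniform background
over transcripts and positions. Tags are exact 20–21 nt substrings (typical
PARE tag length). Read-length draws for the sRNA layer use a categorical
distribution over 18–26 nt with modes at 21 nt (42%) and 24 nt (30%),
reproducing the classic two-peak pattern.

**Seeding.** All randomness flows from one top-level seed through numpy
`SeedSequence(seed, spawn_key=(stream, index))`, with named streams for
reference, truth, sRNA counts, gene counts, degradome libraries and read
simulation. Every artifact is byte-identical for a fixed seed.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequencing error and adapter artifacts, GC and
positional biases, correlated gene–gene expression, isoform complexity,
miRNA families with shared seeds, partial-complementarity target sites, and
degradome noise concentrated at 5′ ends of abundant transcripts. Recovery
results measure the pipeline's logic under its own statistical assumptions,
not field performance.

## Small-RNA processing and miRNA catalogs

Reads are length-filtered to 18–26 nt and collapsed to unique sequences.
Known-miRNA matching tolerates end-shifts up to 2 nt per terminus (trims, or
extensions drawn from the precursor context when available) plus at most one
internal substitution, enumerated into a variant→(id, suffix) index; ties
resolve to the lexicographically lowest catalog id, so assignment is
deterministic. Variant suffixes follow the field's mature-variant grammar:
`_L±n` (3′ length change), `_R±n` (5′), `_kssPXY` (substitution at position
P, catalog base X, read base Y), and `-p5`/`-p3` for non-canonical matures
lifted verbatim from a precursor arm.

Novel discovery maps unmatched reads exactly to the reference (forward
strand; > 20 loci ⇒ discarded as repeat-derived), extracts a read ± 120 nt
window (both arm placements tried with the far flank on one side at a time)
and folds it by Nussinov-style base-pair maximization with G:U wobble and a
minimum loop of 3 nt. A read is accepted as a novel mature when it lies
entirely on one arm, ≥ 16 of its bases pair into the star region, no more
than 4 consecutive mature bases are unpaired, and the closing loop is
≥ 3 nt. Pair maximization (not thermodynamics) is deliberate: the hairpin
decision needs topology only, and the folding engine is a plug-in point
(`fold_fn`) for an energy model. On ≤ 60 nt windows the DP provably equals
an independent top-down enumeration (tested).

The G1–G5 tiers: G1 mature and precursor both in the catalog with the
precursor mapping to the reference; G2 as G1 but the precursor entry comes
from another species; G3 mature known, no precursor mapping; G4
variant-matched mature with a recovered precursor; G5 novel. G1–G4 are
"conserved". These boundaries are this package's own operational table —
published pipelines rarely print theirs — and are isolated in
`assign_group` for easy replacement.

Presence ("expressed") for Venn partitions: CPM ≥ 1 in ≥ 2 replicates of a
factor level, pooled over the other factors; both thresholds are exposed.

## Differential expression

CPM: column × 1e6 / library size (column sum unless overridden). FPKM:
count × 1e9 / (length<sub>nt</sub> × total mapped fragments).

ANOVA and the two-sample test run on log2(CPM + floor) with floor 0.001;
log counts stabilize NB variance enough for moment-based tests at n = 3.
The two-sample test defaults to the **pooled-variance Student t**: with 3
replicates per group the Welch–Satterthwaite df estimate is so noisy that
Welch is materially conservative under the null (measured FPR ≈ 0.033 at
α = 0.05 on the simulated count model, vs ≈ 0.048 for the pooled test);
`equal_var=False` switches to Welch for genuinely heteroscedastic designs.
Zero-variance features with identical group values are flagged degenerate,
get p = 1 and are never called. DE calls use raw p < α (α = 0.05) by
design — per-contrast screening at n = 3 — with a BH-adjusted column always
emitted alongside.

The gene-layer test is a two-group **negative-binomial exact test**: counts
are scaled to a common library size (geometric mean) and rounded; the
common dispersion is the median method-of-moments estimate
`(var − mean)/mean²` over features (floored at 0); group-sum distributions
`NB(n·µ, φ/n)` give the conditional law of the group-A sum given the total,
and the p-value sums all outcomes no more likely than the observed one.
φ → 0 reduces to the exact conditional binomial (Poisson limit; tested
against the closed form). This is an exact-conditional test in the same
family as count-based DE packages but intentionally simpler: no tagwise
empirical-Bayes shrinkage, no TMM normalization — stated limitations, not
omissions. Totals above 200k pseudo-counts use a normal approximation to
the conditional law (noted per row).

Fold-changes use the zero-floor rule (0 → 0.001 on both sides before the
log2 ratio), making every reported log2FC finite; the `inf` dialect instead
reports ±inf when exactly one side is 0, matching the tabulation convention
for miRNAs undetected under stress. The rule is antisymmetric,
f(a,b) = −f(b,a) (property-tested).

qPCR relative expression: 2^−((Ct_t,s − Ct_r,s) − (Ct_t,c − Ct_r,c)).

## Degradome

Duplex scoring follows the standard plant-target convention: penalties
mismatch 1.0, G:U 0.5, gap 2.0, doubled across miRNA positions 2–13; accept
≤ 4.5; at most one gap; cleavage opposite miRNA position 10 (1-based
inclusive transcript coordinates throughout). The implementation is a
banded DP with a gap-count state; a gap is weighted by the miRNA position at
which it occurs (deletion of base k: position k; insertion after k consumed
bases: position min(k+1, L)). If position 10 itself is deleted the nearest
paired neighbour's partner is used. Ambiguous bases count as mismatches.
The DP equals direct enumeration of all ≤ 1-gap alignments (tested on
random pairs).

Genome-scale scans anchor candidate windows at exact reverse-complement
matches of the miRNA seed (positions 2–9) before running the DP — adequate
for near-complementary plant sites whose doubled-core scoring tolerates few
core edits, and orders of magnitude faster than scoring every window; an
exhaustive `mode="full"` exists and the seed scan is verified to be a subset
of it. Lowering the penalty threshold never enlarges the accepted set
(monotonicity, tested).

Tags map by exact full-length match (configurable mismatches are a
non-goal; tags are short and references repeat-rich). A tag hitting several
transcripts counts once in each; several occurrences within one transcript
count only at the 5′-most (an arbitrary but deterministic rule; synthetic
tags virtually never recur within a transcript). Profiles record raw counts
and TPB = raw × 1e9 / total mapped tags in the library.

Categories, with r the count at the queried position, M the transcript
maximum and med the median over positions with ≥ 1 read: r = 0 → no event;
r = 1 → category 4; r = M uniquely → 0; r = M tied → 1; med < r < M → 2;
else → 3. When rules overlap (e.g. every occupied position tied at M) the
max-based rules win, after the single-read rule — the precedence is fixed in
the docstring and cross-checked against an independently structured
classifier on random profiles. All categories 0–4 are kept by default and
recorded (filterable via `category_max`), since downstream validity cuts
vary between studies.

Event calling: an alignment becomes a cleavage event in a library when a
position within ± 1 (the shift window) of the predicted coordinate carries
≥ 1 tag; candidates rank by count, then proximity, then smaller coordinate.
Differential degradation is the floored log2 TPB ratio stress/control; "up"
means more miRNA-guided degradation under stress.

## Integration

A regulatory pair must be evidenced by all three layers. Degradome
transcript ids resolve to gene ids by stripping a trailing isoform suffix
(`-\d+$`). By default an event from any condition's library qualifies a
pair for every contrast (`condition_matched` restricts to libraries naming
the contrast's stress level). The classifier demands both raw p < α and
strictly opposite-signed, non-zero log2 fold-changes; ±inf sentinels carry
their sign. Genotype contrasts (TL vs SL per treatment) use the same
classifier with "up" = more abundant in the tolerant genotype; swapping
genotypes provably flips every antagonistic label. The exported network is
a miRNA→gene multigraph (one edge per contrast), written as SIF and TSV
with a node-degree report exposing multiple-to-multiple regulation.

## Enrichment

Hypergeometric upper tail p = P[X ≥ k] with X ~ Hypergeom(N, K, n), BH
adjustment across tested terms, rich factor k/K. The universe defaults to
all annotated genes in the map (override available); results depend only on
(N, K, n, k), verified by label permutation. K = 0 terms are skipped. GO
graph propagation is out of scope: maps are accepted pre-propagated. KEGG
class tables count a gene once per top-level class it reaches; percentages
are over class assignments of classified genes, with unclassified genes
reported as a count.

## Pipeline and problem sizes

`run_all` executes simulate → presence partitions → DE (miRNA: pooled t;
genes: NB exact) → degradome (seed-anchored target scan, 4 per-treatment
libraries, event calling) → integration → enrichment, writing per-stage
TSVs and a manifest with parameters, per-stage seeds and SHA-256 output
hashes; a fixed config + seed reproduces every byte. Default scale —
2,000 transcripts, 200 miRNAs, 50 planted modules, 100k degradome tags per
library, 2 genotypes × 4 treatments × 3 replicates at 5 DPA — runs in well
under a minute on one core and is the scale at which planted-module
recovery is evaluated (recall ≥ 90%, spurious ≤ 10% against the generator's
ground truth). Calibration checks use 200 null datasets of 100 features
(pooled-t FPR) and one 2,000-feature null dataset (ANOVA p uniformity,
KS distance < 0.05 as the sanity bound).

## Known limitations

* Forward-strand, exact novel-miRNA mapping; no genome-scale aligner.
* Pair-maximization folding ignores stacking energies; borderline hairpins
  differ from thermodynamic calls (plug-in point provided).
* The NB exact test's common dispersion underfits genes with atypical
  dispersion; no shrinkage toward a trend.
* The seed-anchored target scan can miss sites with seed-region edits;
  use `mode="full"` when completeness matters more than speed.
* ANOVA's reported log2fc is a summary (largest deviation from the first
  level), not an estimand of the omnibus test.
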