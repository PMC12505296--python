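# Methods

## The measurement being modeled

A DHFR protein-fragment complementation assay couples cell division to a
protein–protein interaction: prey variants fused to DHFR F[3] are pooled
and mated/combined with a bait fused to DHFR F[1,2]; under methotrexate
only cells whose bait–prey pair reconstitutes DHFR proliferate, at a rate
that increases with the amount of complex formed. Sequencing the prey
locus before and after selection turns each variant's frequency change
into an interaction phenotype. Two baits separate the two ways a prey
mutation can move the signal: the SH3-domain bait (Sho1) responds to both
binding and prey abundance, while the Hog1 bait binds Pbs2 outside the
SH3 motif and therefore responds to abundance only.

## Interaction scores

For variant *v* with pre- and post-selection counts *c* over assigned
depths *D*,

    raw_v = log2((c_post + p) / D_post) − log2((c_pre + p) / D_pre),

with pseudocount p = 0.5 applied to counts only (keeps dropouts finite
while perturbing well-covered variants negligibly; configurable). Raw
scores are rescaled per library — one library being one bait × condition
× replicate — by the affine map

    scaled_v = (raw_v − W) / (W − N),

where W is the median raw score of the wild-type-identical and silent
variants and N the median raw score of nonsense variants. Because the map
is affine and monotone, medians commute with it: the nonsense median
lands at exactly −1 and the wild-type anchor at exactly 0, which is what
the acceptance script verifies. The wild-type anchor policy
(`wt_and_silent`, the default, versus `wt_only`) is configurable; silent
variants are true synonymous re-encodings of the wild-type protein and
pooling them stabilizes the anchor, at the cost of absorbing any codon-
level (non-protein) effect into it.

Variants with fewer than 20 pre-selection reads are excluded before
anything else — low counts inflate fold-changes — and per-amino-acid
scores are medians over all synonymous codon variants across replicates
of a condition, reported only when at least 3 replicate-level values
survive. The even-n median is the midpoint of the central pair.

Selection coefficients for proliferation competitions are wild-type-
relative log2 enrichment rates per generation,
s = [log2(f_v′/f_v) − log2(f_wt′/f_wt)] / g, with g computed as the log2
fold-change in optical density per growth cycle and summed over cycles.

## The statistical cascade

All tests run on replicate-level scaled scores pooled over synonymous
codons. The Mann–Whitney U statistic uses average ranks for ties; the
p-value is exact (enumeration) for tie-free samples with n_x + n_y ≤ 12
and otherwise uses the tie-corrected normal approximation with continuity
correction. FDR control is Benjamini–Hochberg throughout.

1. **Control outliers** — each nonsense (silent) variant versus all other
   variants of its class, two-sided, unadjusted P < 0.05: flagged
   variants are removed and the library is rescaled again without them.
   The unadjusted threshold intentionally over-flags (~5% of healthy
   controls); it is a conservative control-hygiene step, not an
   inference.
2. **Control-condition defects** — in the no-MTX control, each missense
   mutant versus the pooled nonsense scores, BH-corrected; mutants *not*
   significantly different from nonsense (adjusted P > 0.05) are removed.
   Note the logic: absence of evidence is treated as evidence of a
   defect. The step is only informative when nonsense mutants actually
   display a phenotype in the control condition (in the organism, loss of
   the kinase makes cells osmosensitive; in the generator, the
   `couple_abundance_to_growth` switch reproduces this). If the control
   condition carries no selection at all, every mutant resembles
   nonsense and the rule removes everything — the cascade applies the
   rule as stated and leaves the interpretation to the run summary.
3. **Abundance exclusion** — each missense mutant's Hog1-bait scores
   (MTX conditions only; the abundance readout is itself a PCA selection)
   versus the pooled wild-type + silent Hog1 scores, two-sided,
   BH-corrected, adjusted P < 0.05 ⇒ excluded from the binding dataset.
4. **Classification** — surviving missense mutants versus the pooled
   wild-type + silent scores, BH-corrected; significant mutants are
   labeled stronger or weaker by the sign of their median score.

Re-running the cascade on its own survivors is stable but not exactly
idempotent: step 1's unadjusted 5% test may flag a few fresh borderline
controls on each pass, and BH thresholds shift slightly as the test
family shrinks. The tests assert ≥97% stability rather than strict
equality.

## Synthetic data: what it emulates, what it does not

Selection is multiplicative per generation: expected post-selection
frequency ∝ f_pre · 2^{s·G} with G = generations_per_cycle × n_cycles
(defaults 4 × 2, matching a dilute-to-0.1-OD, grow-to-saturation cycle
design), followed by a multinomial read draw at the configured depth.
Per-variant rates compose as s = b_v·[MTX ∧ Sho1 bait]·m + a_v, where m
is the sorbitol multiplier (default 1.5; osmotic stress strengthens
motif binding, amplifying differences). Initial frequencies are a
Dirichlet perturbation of uniform (concentration 200 per member).

Binding and abundance effects are assigned at the amino-acid-change
level, so synonymous codons share an effect, as the aggregation step
assumes. Two landscape generators exist: `classes` (10% stronger, 60%
weaker missense by default — fractions of the same order as the screen's
outcome — with uniform effect sizes of 0.05–0.25 per generation against a
nonsense floor of s_null = 0.25) and `continuous` (uniform effects, used
where rank recovery is measured, since ranks of exactly tied effects are
unrecoverable).

Nonsense variants are modeled as an abundance effect a = −s_null with no
binding term. Stop codons truncate the prey before its C-terminal DHFR
fusion, which abolishes the PCA signal under either bait; modeling the
floor as bait-agnostic is what makes the Hog1 library rescalable
(anchors exist) and mirrors the assay. The binding-specific term b is
reserved for effects the Hog1 control should *not* see.

Reads are emitted pre-merged as full-length amplicons flanked by row and
column sample barcodes (8 nt, pairwise Hamming distance ≥ 3), with iid
per-base substitution errors and constant Phred qualities. No PCR
jackpots, no quality degradation, no indel errors: passing round-trip
tests demonstrate the counting logic, not robustness to every real
sequencing artifact.

### A note on error-carrying reads

Under the single-codon calling policy, a read with a sequencing error
outside its mutated codon shows mismatches in two codons and is excluded
(class `multi_codon`). At error rate 1e-3 on a 168-nt amplicon this
removes ~15% of reads; because the loss is random per read, each
variant's recovered count is thinned binomially, leaving an irreducible
per-variant frequency noise of ~2–3% (relative) at 100–200 reads per
variant, even though the systematic miscall bias (errors inside the
mutated codon) is only ~0.3%. Frequencies are computed over assigned
reads only, so the thinning cancels in expectation but not per variant.
Error-free data round-trips exactly.

## Growth curves

The maximal growth rate is the 98th percentile (linear interpolation
between order statistics) of least-squares slopes of log2 OD over every
window of 5 consecutive points; OD is floored at 1e-3 before the log.
The window slope (rather than endpoint differencing) resists single-point
jitter, and the 98th percentile rather than the maximum means a lone
spike — which contaminates only 5 of the ~285 windows of a 72-h,
15-minute-interval run — cannot carry the estimate.

Known limitation: an upper percentile of noisy slopes is upward-biased.
With iid measurement noise of standard deviation σ on log2 OD, window
slopes carry noise ≈ 1.26σ per hour-long window, and the 98th percentile
sits roughly two of those standard deviations above the true rate. With
5%-of-OD noise this inflates a 0.05 log2/h rate several-fold; recovery
within a few percent requires effective OD noise well below 1% of signal
(plate readers achieve this at moderate-to-high OD, and smooth real
trajectories violate the iid worst case). The estimator is kept exactly
as defined — it is a comparative, not absolute, measure across strains
measured under identical noise.

Fragment interaction scores are growth-rate ratios to the strain carrying
the same bait with a fragment-free DHFR fusion (a difference convention is
available). Manual per-strain exclusions (a strain whose no-MTX controls
all fail suggests a construction problem) are a config list, not an
algorithm.

## Colony arrays

Sizes are log2 transformed; each plate is centered on its median and then
corrected by one round of row/column median polish (iterations
configurable) — a transparent stand-in for dedicated grid-normalization
tools, adequate for multiplicative row/column/plate bias. Colonies that
failed diploid selection and the border control positions are removed
first; zero sizes are treated as missing measurements, not as zero
interaction. The centered values are rescaled by the affine map sending
the stuffer-prey reference median to 0 and the wild-type-prey reference
median to 1. The four repeated array quadrants are treated as independent
replicates of each bait–prey pair. Bait-versus-reference comparisons use
the one-sided Mann–Whitney test with BH correction.

## Numerical conventions

- Alignment: global Needleman–Wunsch with affine gaps at EMBOSS-needle
  DNA defaults (match +5, mismatch −4, gap open 10, gap extend 0.5, free
  end gaps); N is score-neutral. Equal-length reads within a small
  Hamming distance of the reference take an exact gapless fast path.
- Reads whose single mutated codon lies outside the mutagenized window
  are tallied as `unassigned` (they cannot be library members); gaps make
  a read `indel_other`. Neither enters the frequency denominator.
- Percentiles use linear interpolation; medians of even counts are
  midpoints; all randomness descends from one named integer seed, and
  identical seeds give byte-identical FASTQ and tables.
- TSV everywhere, `NA` for missing, audit header comments (version,
  config hash, seed) on every written table.

## Problem sizes used in the test suite

Full-scale checks use the extended-motif library (16 codons × 32 NNK
codons, 3 replicates, 100,000 reads per sample) — large enough that
count noise is at the few-percent level and every amino-acid change has
≥3 contributing measurements — with smaller grids and trajectories for
unit-level properties. Colony checks use complete 1,536-position arrays
across 6 plates.
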