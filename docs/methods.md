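# Methods

## Mechanism and model

Bisulfite treatment deaminates unmethylated cytosine to uracil, so after
PCR an unmethylated C is read as T while 5-methylcytosine remains C. Post
conversion, two templates of identical sequence but different methylation
differ in GC content, and GC-dependent polymerase efficiency then skews
their relative abundance. We model amplification at the level of expected
copy number: a fragment whose converted sequence has GC fraction *g* is
assigned per-cycle efficiency

    e(g) = clamp(e0 + γ·(g − 0.5), 0, 1),

optionally held flat above a saturation GC, and copy weight
*(1 + e(g))^C* after *C* cycles. Reads are drawn with replacement,
probability proportional to weight; each read is the whole fragment. This
deterministic-weight model reproduces the expectation-level bias exactly;
the per-cycle branching stochasticity of real PCR is deliberately omitted
(it adds variance, not bias) and sampling variance is reintroduced by the
multinomial read draw. A strictly monotone linear form is the simplest
model that produces the three qualitative behaviours of interest — strong
GC bias, no bias, and bias saturating at high GC — and is isolated behind
`EnzymeProfile` so it can be replaced.

No published quantitative efficiency curve exists for the polymerases the
presets are named after; the parameters are modelling choices, chosen so
the three behaviours are clearly distinguishable at desk scale:

| preset         | e0  | γ   | saturation GC |
|----------------|-----|-----|---------------|
| `pfu-like`     | 0.5 | 0.8 | —             |
| `kapa-like`    | 0.5 | 0.0 | —             |
| `epimark-like` | 0.5 | 0.4 | 0.6           |

## Synthetic data

`generate_genome` builds one main contig of homogeneous blocks whose
expected GC interpolates a gradient (bases i.i.d.), plus an unmethylated
control contig (chloroplast stand-in, default GC 0.36). `generate_methylome`
assigns one (CG, CHG, CHH) probability triple per block to every cytosine
on both strands, H ∈ {A, C, T}; region levels are scaled per context by
(1.0, 0.7, 0.3) by default, approximating the CG > CHG > CHH hierarchy of
plant heterochromatin. The generator accepts a seed for optional per-site
jitter; the default assignment is deterministic. Conversion retains each C
with probability *p + (1 − p)·r* (methylated, or unmethylated but
unconverted), with non-conversion rate *r* = 0.005 by default (0.01 in the
calibration scenario), typical of a good conversion reaction.

The default pipeline genome uses a modest GC contrast (0.38 → 0.32) with a
strong methylation contrast (0.1 → 0.9). On much steeper GC gradients the
base-composition effect can overwhelm the methylation effect at low cycle
numbers and flip the coverage-vs-methylation slope; the modest,
*Arabidopsis*-like contrast keeps methylation the dominant driver of
post-conversion GC, which is the phenomenon under study. The
cycle-recovery scenario goes further and holds GC constant across blocks —
the epiallele design, where sequences of identical composition differ only
in methylation — so the fitted slope is attributable to the amplification
model alone.

What the simulator does *not* emulate: sequencing error, quality
variation, adapter remnants, indels/SNPs, paired-end geometry, sub-read
sampling from longer fragments, per-cycle PCR duplication trees, and the
original-top/original-bottom strand asymmetry of real bisulfite libraries.
Reads are error-free whole fragments, so placement can be exact
full-length matching in fully-converted (three-letter) space, with
multi-hit reads discarded as ambiguous — the unique-alignment filter of
WGBS practice. Passing tests therefore demonstrate the amplification-bias
mechanism and the correctness of the statistics, not robustness to
alignment noise or error models; those are extension points.

## Analysis stack

* **Placement & pileup.** Both reference strands and each read are
  reduced by C→T; exact full-length matches only; unique hits become
  placements, and every covered reference cytosine on the placed strand
  accumulates a methylated (read C) or unmethylated (read T) basecall.
  Other read bases at a reference C are ignored. Coordinates are 0-based,
  intervals half-open, everywhere.
* **Calling.** The null rate is the pooled methylated-basecall fraction
  over the control contig (zero control coverage is a hard error — the
  null cannot be formed). The test is the exact one-sided upper binomial
  tail: non-conversion can only inflate methylated basecalls, and exact
  tails keep the caller honest at the low coverages where a normal
  approximation fails. BH runs jointly over all tested sites by default;
  per-context batching is a configuration option (`by_context`), since the
  batching convention is not dictated by the data. Sites below
  `min_coverage` (default 1) are reported untested.
* **Coverage.** A read belongs to the window containing its start
  coordinate — the simplest rule that conserves totals. Window counts are
  scaled by the first tile (first window of the first contig in genome
  order); because an empty or atypical first tile makes that scaling
  fragile, scaling by library total (×10⁵) is provided and the first-tile
  path fails loudly with a pointer to it. Enrichment is scaled bisulfite
  minus scaled genomic counts, the genomic reads having been fully C→T
  converted before placement so the subtraction isolates bisulfite/PCR
  effects from mappability; counts are scaled first, then subtracted.
  Zero-count windows propagate as missing in log-ratio profiles rather
  than being pseudocounted (a +0.5 pseudocount option exists). When cycle
  conditions are compared, the methylation axis can be pinned to a
  reference condition so points move only vertically between panels.
* **GC profiles.** Windowed GC is reported raw, under computed full
  conversion, and under methylation-aware conversion; the last uses the
  *expected* retention (probability-weighted) because the profile
  describes the methylome, not one realised library. GC is computed on
  the + strand: raw GC is strand-symmetric but post-conversion GC is not,
  and we report the + strand value rather than averaging the asymmetry
  away. Partial terminal windows use their true length as denominator.
  A cytosine too close to the contig end to resolve its context is
  classified CHH (the absent neighbour cannot be a G).
* **Regression.** Outliers are screened with the Bonferroni outlier test
  on externally studentized residuals (two-sided t, n − 3 df, p × n),
  removing the worst point and refitting until nothing is flagged or
  ceil(0.05·n) points are removed; iterative removal with refitting is
  standard outlier-test practice, and a one-shot mode is provided because
  the choice is genuinely open. The two constraints — Bonferroni
  significance and a 5% trim cap — are both enforced; the cap uses the
  ceiling so that a single gross outlier among a dozen points can still be
  removed. With the cap at 0 the procedure is exactly plain OLS.

## Determinism and numerics

Every stage is a pure function of its inputs and seed (NumPy
`default_rng`); pipeline stage seeds are spawned from the run seed and
logged. Reruns of a fixed configuration are byte-identical in all data
artifacts. Probabilities are exact binomial tails (`scipy.stats.binom.sf`);
BH is the standard step-up with q-values monotone-enforced and capped at 1;
degenerate regression inputs (zero variance, near-perfect fits where
studentized residuals are 0/0) return missing values or skip the outlier
screen rather than erroring. Weighted methylation of a region with no
basecalls is missing, never 0.

## Problem sizes

The preset experiments are sized so the full suite and the acceptance
script run comfortably on one CPU: cycle-recovery and null scenarios use a
100 kb main contig (20 × 5 kb blocks) plus 8 kb control, 12,000 fragments
of 150 bp, 40,000 reads per cycle condition (≈55× coverage) over 200
windows of 500 bp, with 20 seeds per Monte-Carlo property; the
AT-depletion scenario uses the same geometry with a 0.25 → 0.55 GC
gradient and an all-zero methylome (a genomic-DNA stand-in); the
calibration scenario uses four 2.5 kb strata (p = 0, 0.3, 0.7, 1.0) at
≈25× coverage with ≥10⁴ control basecalls. These sizes put 3-SE recovery
bands in the third decimal for rates and levels, which is the resolution
the checks require.

## Known limitations

The efficiency model is phenomenological; real polymerase bias also
depends on fragment length, sequence structure and reaction conditions.
First-tile scaling inherits the noise of the first window. Exact-match
placement understates the placement losses of real aligners at repeats and
errors. The simulator's read depth per fragment pool is drawn with
replacement, so very deep libraries over small pools carry
duplication-clustered basecalls; recovery checks account for this design
effect where it is non-negligible.
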