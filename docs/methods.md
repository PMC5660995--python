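# Methods

This note documents the models, conventions and numerical choices behind
`stresspanel`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the procedure was genuinely open.

## 1. Quantification model

### Cq calling

A well's raw fluorescence Rn(c) over cycles c = 1…40 is baseline-corrected by
an ordinary least-squares line fitted over the **baseline window**, cycles
5–17 inclusive (1-based). Fitting a line rather than subtracting a window
mean makes the call exactly invariant to any linear drift added to the trace
(a property test asserts this to 1e-9) and reduces to the mean for flat
baselines. The quantification cycle is the first fractional cycle at which
ΔRn = Rn − baseline crosses the **Rn threshold** (default 0.2) from below,
linearly interpolated between the bracketing integer cycles. Traces that
never reach the threshold are *no-amplification* (propagated as missing,
never imputed); a trace already above threshold at cycle 1 has no baseline
region and is an error.

### Amplification efficiency

Per gene, Cq is regressed on log10(input quantity) over a dilution series
(≥ 3 distinct dilutions; the conventional design is five five-fold steps).
With slope *a*, efficiency is E = 10^(−1/a) − 1: E = 1 means the amplicon
doubles every cycle (slope −3.32). QC passes when 100·E ∈ [90, 110]
(equivalently |slope| = 3.3 ± 0.33). The emitted fit always satisfies the
identity E = 10^(−1/a) − 1 exactly, so the efficiency is recomputable from
the slope.

### Relative quantity and normalization

The expression ratio of a target gene t in a sample versus the control
genotype, normalized to reference genes r ∈ R, is the efficiency-corrected
(Pfaffl-style) ratio with a geometric-mean multi-reference normalization
factor:

    ratio = (1+E_t)^(Cq_ctrl,t − Cq_s,t) / geomean_{r∈R} (1+E_r)^(Cq_ctrl,r − Cq_s,r)

computed on the log2 scale as a difference of efficiency-weighted ΔCq terms.
The source study names the three reference genes (*ACT*, *TIF*, *TIF-GTP*)
but not the arithmetic; the geometric mean is the standard multi-reference
choice and is consistent with the efficiency QC used. Genes without a
standard curve are treated as 100% efficient.

Aggregation order: technical replicates are averaged first (arithmetic mean
of Cq; spread > 0.5 cycles raises a QC flag — a conventional lab limit, made
configurable); the control Cq per gene and location is the mean across the
control samples' biological replicates; each sample biological replicate then
yields one log2 ratio, summarised as mean / sd / n across biological
replicates (sd reported only for n ≥ 2). A missing reference-gene Cq makes
that biological replicate's ratio undefined rather than silently
renormalising over fewer references. Ratios are always computed against
**both** control genotypes (tolerant and sensitive); downstream stages state
which they use.

Sign convention, used everywhere: upregulation by d log2 units lowers Cq by
d cycles.

## 2. Significance screening

Log2 relative quantities are treated as approximately normal (the log
transform is what makes qPCR ratios parametric). Per gene × location ×
control reference, the groups are the per-variety biological-replicate log2
quantities plus the control genotype's own replicates; a one-way ANOVA gates
a Tukey HSD post-hoc test (studentized-range adjusted p), and a variety is
flagged significant when its comparison against control is below α = 0.05.
One-way ANOVA per gene is the minimal factor structure consistent with the
design; no correction is applied across genes (stated in the run summary).
Varieties with fewer than two usable replicates are never flagged and raise a
warning.

The Tukey implementation (Tukey-Kramer for unequal group sizes, exact
studentized-range distribution via scipy) optionally computes only the pairs
involving the control; the adjusted p-values are identical to the all-pairs
run because the studentized range always spans all k groups. With exactly
two groups the procedure reduces to the ANOVA itself, so the per-comparison
false-positive rate equals α; with more groups the gate plus family-wise
adjustment make the per-pair rate conservative.

## 3. Marker retention (majority rule)

A marker matches in a variety when the sign of its mean log2 ratio equals the
a-priori expected direction (gates: `sign` with an optional minimum effect,
default 0; `sign+threshold` requiring |log2| > 1.5; `sign+significant`
requiring the ANOVA/Tukey flag — the source procedure does not bind a
specific gate, so sign-only is the default and the others are opt-in).
"Discard when the expected result is missing in more than half of the
varieties" is read literally: a gene *passes* a location when failures are at
most ⌊V/2⌋ of the V varieties evaluated there — an exact tie passes. A gene
must pass **every** location (an array meant for different climates must work
in all of them); a location with no evaluable variety counts as a failed
location. Ratios for matching come from the control reference against which
each gene's expected direction was originally defined (a per-gene panel
column, default the tolerant control). The filter is monotone in the gate
strength and invariant to variety order (property tests). Reference genes
are always retained; the final array lists markers grouped by stress
assignment with the references last.

## 4. Stress matrix and tolerance classification

A variety × stress × location cell scores the mean |log2 ratio| of the
stress's markers that **qualify**: |log2 ratio| strictly above the threshold
(default 1.5) *and* regulated in the expected direction. A cell with no
qualifying marker has an *undefined* score (NaN), deliberately distinct from
0: "no stress signal" is not "weak signal". Since every qualifying term
exceeds the threshold, a defined score always does — an invariant under
randomized inputs. Per-location marginal means over defined cells make
"location A imposed more stress than location B" a computable output.
Locations are kept separate throughout (how the source display combined them
is unstated).

Tolerance is called by Pearson correlation between the variety's per-gene
log2 profile over a stress's markers and the tolerant / sensitive reference
profiles ("correlated closely" read literally as correlation), over
pairwise-complete genes (≥ 3 required). The call is tolerant when
sim_tolerant − sim_sensitive > δ, sensitive below −δ, else indeterminate;
δ = 0.2 by default to prevent over-confident calls near equidistance.
Reference profiles can be supplied as a TSV or measured from the dataset's
own reference genotypes (stressed vs their own controls, per location).
Combined field stress (FIELD) is modelled as a fourth stress label rather
than folded into WS/HS/LS.

Functional-bin aggregation averages gene-level log2 ratios per MapMan-style
bin separately for a-priori up- and downregulated sets and flags inversions
(a nominally downregulated bin observed up, or vice versa); the bin means
weighted by bin size reconstruct the overall mean (conservation check).
Distribution summaries use type-7 quartiles (linear interpolation between
order statistics — conventions differ, so this is pinned here), 1.5×IQR
whiskers, and report the IQR as the stability score (smaller = more stable).

## 5. Synthetic data generator

The generator emulates the screen's design: a marker panel plus three stable
reference genes measured in test varieties and the two reference genotypes at
two locations, three biological × two technical replicates (the study's
design), with unstressed control samples for both reference genotypes. The
Cq model is

    Cq = baseline_cq(gene) − Σ_s effect(gene, s, archetype) · intensity(location, s)
         + bio_noise + tech_noise

with additive Gaussian noise on the Cq scale: biological noise drawn once per
biological sample and gene (shared by its technical replicates), technical
noise i.i.d. per well — the simplest error structure that makes replicate
aggregation meaningful. Defaults sd_bio = 0.3 and sd_tech = 0.15 cycles are
conventional qPCR magnitudes; the source reports no inter-replicate variance,
so these are field-typical choices, not derived values. Cq above 38 (default)
is recorded as no-amplification, exercising the missing-data paths. The
ground-truth effect table, the per-cell resolved archetypes and the planted
reference profiles are always emitted beside the data, so every downstream
stage has an oracle.

The default world has 10 test varieties (five tolerant, five sensitive —
matching the screen it emulates), 48 markers (12 per stress) and two
locations at stress intensities 1.0 and 0.6 (a harsher and a milder site).
Marker effects are ±2 log2 at unit intensity and come in three responder
classes per stress — tolerant-archetype-only, sensitive-archetype-only, and
shared — so the two planted archetype profiles are genuinely distinguishable
(their planted correlation is 0.5); a world where the archetypes differed
only in amplitude would make correlation-based classification ill-posed.
"Mixed" varieties resolve to the tolerant archetype on WS/LS and the
sensitive one on HS/FIELD, recorded per cell in the ground truth.

Simulated fluorescence traces are logistic sigmoids plus a linear baseline;
the sigmoid midpoint is calibrated numerically (Brent's method) so that the
*exact Cq-calling procedure* returns the requested Cq. This matters: with a
realistic per-cycle gain the chord between integer cycles deviates from the
exponential by ~0.1 cycles, so an uncalibrated curve would not round-trip
within the 0.05-cycle band.

**What a green test does not establish.** The generator draws i.i.d. Gaussian
noise with no plate spatial effects, no melting-curve artifacts, no
primer-dimer or genomic-DNA contamination, no inter-season transcriptome
plasticity, and archetypes are exact (real varieties are mixtures of
genotypes). Recovery of planted effects therefore validates the analysis
arithmetic and its missing-data handling, not the biological
reproducibility of any particular marker panel.

## 6. Degenerate inputs and tie-breaks

- ANOVA with zero between- and within-group variance: F undefined (NaN),
  reported as such; zero within-group variance with real differences: F = ∞,
  p = 0.
- A variety whose mean log2 ratio is exactly 0 matches neither direction.
- Exactly half of varieties failing a marker's direction: the marker passes
  (the rule only discards strict majorities).
- Empty qualifying set: stress-matrix score NaN, n_qualifying = 0.
- Zero-variance profiles or < 3 common genes: tolerance call indeterminate
  with an explanatory flag.
- No-amplification is never imputed anywhere; it propagates as missing and
  is visible in replicate counts.

## 7. Known limitations

- The one-way ANOVA treats locations separately; a mixed model with
  variety × location interaction would use the data more efficiently but is
  beyond the stated procedure.
- Efficiency estimates are applied as point values; their uncertainty is not
  propagated into the log2 ratios.
- The CLI's `simulate` always uses the default world; bespoke worlds are
  built through the Python API (`SimulationConfig`).
- Classification assumes reference profiles and test profiles are on the
  same log2 scale; correlation makes this scale-free per stress, but a
  margin δ tuned for one panel size may be loose or tight for another.
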