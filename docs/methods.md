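# Methods

This note records the models, parameter choices and numerical decisions
behind `otomir`, in the order the pipeline runs.

## Synthetic cohort and the latent damage model

The generator emulates a small occupational cohort: `n_roller = 11` and
`n_spray = 6` exposed painters (spray painters carry roughly double the
solvent dose and a higher noise level) plus `n_controls = 17` non-exposed
subjects, ages uniform on 21–54 years. Daily A-weighted noise exposure
L_ex,8h is Normal(81.7, 2.5) dB(A) for roller and Normal(87.2, 2.5) for
spray painters; controls are assigned the 70 dB(A) baseline. Urinary
metabolite concentrations (MA, PGA, MHIPP, SPMA, SBMA, plus cotinine as a
smoking marker) are log-normal around published-scale medians in µg/g
creatinine; cumulative dose is concentration × exposure years. hOGG1 and
XRCC1 genotypes follow Hardy–Weinberg at minor-allele frequency 0.3.

All outcomes hang off one latent, per-subject damage score

```
d = 0.6·(L_ex,8h − 70) + 3.5·z⁺·g(hOGG1) + ε,   ε ~ N(0, 4²)
```

where `z⁺` is log1p cumulative dose scaled by the cohort SD and shifted to
start at zero (a non-negative harm score — this is what makes the genotype
multiplier `g(wt)=1 ≤ g(het)=1.3 ≤ g(mut)=1.6` shift damage upward rather
than merely widen it), in units of dB HL. The linear-Gaussian link is a
deliberate simplification chosen for identifiability: recovery tests can
regress generated outcomes on `d` and compare slopes exactly.

**Audiology.** Hearing level at frequency f is
`HL = 12 + slope_age(f)·(age−20)/10 + w_HL(f)·d + noise`, generated per
ear, quantized to the audiometer's 5 dB steps per ear, then ear-averaged
(so stored values are multiples of 2.5 dB; a `quantize=False` switch
exists for exact-baseline tests). DPOAE band levels are
`DP = 30 − w_DP(band)·d + noise`, ear-averaged, unquantized. The damage
weights emphasize low/mid frequencies (w_HL = 1.0 up to 2 kHz falling to
0.5 at 6–8 kHz; w_DP = 1.0 → 0.7 across the five bands), reproducing the
solvent-specific low/mid-frequency signature; the age slopes are a simple
1–4 dB/decade ramp, not an ISO-style model. The shared damage variable
makes mean HL and mean DPOAE strongly negatively correlated (≈ −0.9 in the
exposed group), and the 12/30 dB baselines place the exposed group's means
astride the 29 dB HL and 16 dB EPL dichotomization thresholds, so both
splits are populated at the default cohort size.

**Counts.** Gene baseline abundances are log-normal (σ = 1.5 natural-log
units); library sizes log-normal around `mean_depth`; counts are negative
binomial with common dispersion 0.1 (Poisson when 0). Twelve named
microRNA analogues carry the planted exposed-vs-control log2 fold changes
(−3.72 … +7.77) and are additionally coupled to damage with slope 1.0 log2
units per damage SD, with the sign that induces the intended correlation
(HL rises with damage, DPOAE falls). Two details matter:

- the damage coupling is centered *within* exposure condition, otherwise
  it would add a second group-mean shift on top of the planted fold change
  and fold-change recovery would be biased by ~1.8 log2 units;
- strongly upregulated genes get their *baseline* abundance lowered by
  their fold change, so they rise into the normal range instead of growing
  to dominate exposed libraries (a +7.7 log2fc gene starting at average
  abundance would end up as ~95 % of an exposed library, an unrealistic
  composition under which TMM under-corrects by ~0.2 log2).

The coupling slope of 1.0 together with 4 dB per-ear DPOAE band noise
yields a mean planted |r| of ≈ 0.6 between coupled microRNAs and DPOAE
bands within the 17 exposed subjects, and an inter-band outcome
correlation of ≈ 0.75 — the regime in which the published screening filter
operates sensibly.

**What the generator does not emulate:** realistic audiogram shapes (e.g.
4 kHz noise notches), pharmacokinetics of the metabolites, per-gene
dispersion trends, batch effects, or sequencing artefacts. Passing tests
therefore demonstrate correctness of the estimators under the stated
statistical structure, not robustness to every property of real data.

## DPOAE processing

Spectra live on a uniform f_DP grid, 1–4 kHz at 20 Hz. A measured spectrum
is modelled as a short-delay (≈0.5 ms) distortion phasor plus a long-delay
(≈10 ms) coherent-reflection phasor plus complex Gaussian noise; their
interference produces the familiar fine structure with ripple spacing
≈ 1/delay = 100 Hz. Coherent averaging takes the complex mean of N = 20
repetitions and estimates the averaged noise floor from half-differences
of repetition pairs (variance s²/2 each, scaled by 2/N), guarded at
−120 dB when the input is noiseless.

Unmixing is delay-domain filtering: inverse DFT over the grid, zero all
bins with circular delay magnitude above the 4 ms cutoff, forward DFT.
This is an orthogonal projection — idempotent and never power-increasing —
and recovers planted zero-latency band levels within 0.05 dB even under an
equal-level reflection. The rectangular window's truncation error
concentrates within ~400 Hz of the grid edges (up to ~15 dB at the
outermost bins, < 0.3 dB in the interior); band levels are unaffected
because the third-octave bands average tens of bins. The cutoff must lie
in (0, 25 ms), half the 50 ms delay period of a 20 Hz grid. The default
4 ms separates distortion (< 2 ms) from reflection (~10 ms) in the
simulated regime. Band membership uses half-open geometric edges
[c·2^(−1/6), c·2^(1/6)); five bands (1153–2904 Hz) are the default, the
scheme is configurable.

## Differential expression

TMM: the reference sample is the one whose upper-quartile count rate is
closest to the cohort mean upper quartile; per sample, zero-count genes
are excluded, M values are trimmed 30 % per tail and A values 5 % per
tail, and the factor is 2^(precision-weighted mean M) with delta-method
binomial weights, rescaled to geometric mean one. This matches edgeR's
`calcNormFactors(method="TMM")` within 2 % on test matrices. TMM assumes
most genes are not differential; with a DE fraction above ~20 % of library
mass the factors are biased (quantified in the ledgered small-gene-count
experiments) — the pipeline's 56/2000 regime is safe.

Testing is a per-gene negative-binomial log-link GLM with an
exposed/control indicator and offset log(library size × TMM factor),
dispersion from a per-gene method of moments (floored at 1e-8), Wald
z-test on the condition coefficient, log2fc = coefficient/ln 2. No
empirical-Bayes shrinkage of dispersion or fold change is applied; the
plain Wald test is mildly anti-conservative at n = 17/group (type-I
≈ 0.07 at α = 0.05) and calibrated by n = 100/group (measured 0.055).
Genes with zero counts in both conditions are excluded from the testing
universe and the BH denominator. If the GLM fails to converge the
continuity-corrected log ratio of normalized group means with a
delta-method SE is reported instead.

## Screening

Pearson correlation of log2(normalized count + 1) with each outcome band,
selection iff |r| strictly exceeds 0.3 in at least 3 bands, applied
independently to HL (11 bands) and DPOAE (5 bands); constant columns get
r = 0. The log2 transform matches the linear models downstream; no
multiplicity correction is applied (the screen is a heuristic whose
operating characteristics are quantified by simulation: at n = 17 with
planted |r| ≈ 0.6, TPR ≈ 0.9 and FPR ≈ 0.19 on the 5-band screen). The
`dominant_sign` of a selection is positive/negative when all passing
correlations agree and "mixed" otherwise. Note that on the 11-band HL
screen the null false-positive rate is bounded below by ≈ 0.24 whenever
bands are highly correlated — an intrinsic property of the strict-0.3 /
3-band rule at n = 17.

## Association models

For one (outcome, microRNA) pair the default is a single REML linear mixed
model over all bands: `level ~ 0 + band + band:mirna` with a subject
random intercept; the per-band interaction slopes are the reported β
(dB per unit of normalized expression, unstandardized). This honors the
repeated-measures structure while reproducing the per-band layout of the
published coefficient tables; a per-band OLS variant exists behind
`per_band=True`. In the balanced complete design the mixed-model fixed
effects coincide with OLS, which gives an exact cross-check; degenerate
fits (zero residual variance) fall back to OLS with a diagnostic string
rather than silent NaNs. The genotype model adds hOGG1 as a categorical
fixed effect with "het" as reference so per-variant coefficients
(`hOGG1mut`, `hOGG1wt`) are emitted; a pooling argument collapses
variants into the two-level grouping. Significance stars: * p<0.05,
** p<0.01, *** p<0.001, "n.s." otherwise. Age and noise covariates are
not included by default.

## Discriminant analysis

Dichotomization: impaired iff mean HL > 29 dB HL, or mean DPOAE < 16 dB
EPL (boundary values go to the normal group — the thresholds were stated
as set points, so strict inequality was chosen); genotype bases pool
hOGG1 {wt} vs {mut, het} and XRCC1 {wt, mut} vs {het}. sPLS-DA centers
and unit-scales the variables (scaling is on by default; the choice is
configurable), codes the two classes ±1 and runs NIPALS PLS where each
component's weight vector is hard-thresholded to its `keep` = 5
largest-magnitude entries and unit-normalized, with data and label
deflation between components. Sign convention: the largest-|weight| entry
is positive, which fixes the score orientation under variable reordering.
With `keep` equal to all variables, component 1 equals classical PLS-DA
(verified against scikit-learn to 1e-6). Biplot arrows are
variable–score correlations kept when the two-component correlation norm
exceeds 0.75; the discrimination direction is the unit vector between
group centroids in score space. `keep` is fixed, not cross-validated.

## AutoCM, MST, Spin Net

Variables (screened microRNAs as log2 levels, HL frequencies, DPOAE
bands, genotype indicators per variant) are min–max scaled to [0,1] and
entered together with their complements (`Max_x`, `Min_x = 1 − Max_x`), so
negative association can appear as proximity to a complement. Constant
variables are dropped with a warning. Training presents each record once
per epoch and applies the contractive updates

```
h_i   = m_i (1 − v_i/C)            Δv_i  = (m_i − h_i)(1 − v_i/C)
Net_j = Σ_i h_i (1 − W_ij/C)       out_j = h_j (1 − Net_j/C)
ΔW_ij = (h_i − out_i)(1 − W_ij/C) h_j
```

with C = number of records and initialization C/10⁶. Under non-negative
inputs every update is non-negative and vanishes as weights approach C, so
weights grow monotonically and stay in [0, C) (the per-step shrink factor
of the gap is ≥ 1 − p/C², p = number of variables); duplicated columns
attain the largest mutual weight in their rows (co-activation dominance).
Training is deterministic given record order; it stops when the mean |ΔW|
per epoch falls below 1e-6 or at the epoch cap.

The trained matrix is symmetrized, mapped to distances `d = 1 − w̄/C ∈
(0,1]`, and reduced by Kruskal's MST with lexicographic tie-breaking
(verified against exhaustive spanning-tree enumeration for n ≤ 6). Spin
Net clamps a query set at activation 1 and iterates a damped weighted
average over the row-normalized symmetrized weights, `a ← 0.95·W̃a` with
clamps pinned, from zero elsewhere. Each row of W̃ sums to one, so the map
is a sup-norm contraction: the equilibrium is unique, independent of
initialization, lies in [0,1], and the cycle count (the query network's
depth) is logged. Note the orientation: each variable averages its
neighbours with its *own* outgoing weights; the transposed orientation
would not keep activations bounded by the clamp. At ~100 variables the
absolute equilibrium activations are small (the clamp's influence is
diluted across the dense weight matrix); the scientifically meaningful
output is the *ranking*, which concentrates on variables close to the
clamped one in the weight graph.

## Pipeline

One run = one directory; stages run in fixed order, read only files from
earlier stages, and fail fast with a stage-named dependency error when a
required input is missing. The manifest records seed, config hash,
package version and per-stage input hashes; floats are serialized with a
fixed `%.10g` format, so identical configurations yield byte-identical
trees. The screen, association, discriminant and graph stages operate on
the exposed painters only — audiological variation within the exposed
group is the estimand; the control group exists for the expression
contrast. The default run size (17 + 17 subjects, 2000 genes, 56 planted
DE) completes in well under a minute on one CPU; simulation sizes used in
the test suite (e.g. n = 500/group for recovery, 100 seeds for screening
characteristics, 50 for sPLS-DA and mixed-model coverage) were chosen as
the smallest that make the Monte-Carlo error negligible against the
tested tolerances.

## Known limitations

- The NB Wald test without shrinkage is anti-conservative at the real
  cohort's n = 17/group; published shrinkage estimators would be needed
  for honest per-gene inference at that size.
- TMM factors degrade when differential genes carry a large share of
  library mass (see above).
- The 11-band HL screen cannot achieve a null FPR below ~0.24 at n = 17
  with the strict 0.3/3-band rule.
- Spin Net's absolute activation scale depends on graph size; only ranks
  are comparable across runs.
- The delay-domain unmixing assumes a uniform frequency grid and
  stationary component delays; within ~400 Hz of the grid edges the
  per-bin reconstruction is unreliable.
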