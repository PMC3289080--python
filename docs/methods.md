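# Methods

## Signal model

An LC-FTMS elution profile is a sampled intensity trace y = [y(t₁), y(t₂), …]
for one ion species. We model the instrument's intensity-dependent
suppression as a monotone distortion g acting pointwise on the true profile
x: y = g(x), with g the identity at and above a distortion-free threshold
(default 10⁶ ion counts) and g(x) ≤ x below it. The correction function
f = g⁻¹ maps observed back to true intensity. Suppression is assumed
homogeneous within a peptide — the ¹²C monoisotopic species and the first
¹³C isotope species of one peptide share the same f — but heterogeneous
across peptides.

The two isotope profiles of a peptide are tied by the theoretical isotope
ratio r: the true profiles satisfy x₂ = r·x₁ pointwise, where r is the
M+1/M0 abundance ratio of the peptide's elemental composition under natural
isotope abundances. r is computed by exact polynomial convolution of
per-element isotope distributions (exponentiation-by-squaring of each
element's abundance polynomial, truncated to the needed mass shifts); the
M+1/M0 value equals Σₑ nₑ·p₁ₑ/p₀ₑ, which the test suite verifies against an
independent single-heavy-atom enumeration to 1e-9 relative error.

## Correction-function estimation (ICM)

For a pair (y₁, y₂) with known r, f is estimated by iterative conditional
modes over the detected elution-peak interval:

1. T ← y₁ + y₂ (initial total ion count);
2. targets x₁\* = T/(1+r), x₂\* = r·T/(1+r);
3. f ← best monotone piecewise-linear map in log₁₀-log₁₀ space from the
   pooled observed values {y₁(t)} ∪ {y₂(t)} to the pooled targets;
4. x₁ ← f(y₁), x₂ ← f(y₂), T ← x₁ + x₂;
5. repeat 2–4 until the relative change of Σx₁+Σx₂ falls below `tol`.

Both observed profiles enter the fit: they share one f and pooling doubles
the support. The fit is restricted to the peak interval because the
low-intensity tail contributes many points but no reliable ratio signal;
including it measurably biases the converged fixed point.

**Functional family and fitting.** f is piecewise linear in log₁₀ intensity
with knots at data quantiles below the threshold (default 16, merged to a
minimum spacing of 0.02 decades) plus an identity anchor at the threshold.
Knot values are parameterized as the anchor minus cumulative non-negative
decrements, which turns monotone least squares into a non-negative least
squares (NNLS) problem. Two constraints encode the physics: f is the
identity at and above the threshold, and f(y) ≥ y below it (suppression only
attenuates). A light curvature penalty (weight 0.01, scaled with point
count) selects the smoothest monotone solution in directions the data do
not pin down; without it the fit is exact at the data positions but free to
kink between them, and the ICM can settle into self-consistent kinked fixed
points that corrupt evaluation away from the fitted data. Ties are broken
by a 1e-9 log-space offset so the inverse g always exists.

**Extrapolation.** Below its lowest knot, a fitted function follows the
chord from that knot to the identity anchor — the average log-log slope of
the whole fit. This is exact when the true distortion is a power law in log
space and is far more robust than the lowest segment's slope, which matters
because null prediction evaluates library functions one to two decades
below the intensity range they were fitted on.

**Convergence.** Default tolerance 1e-5 on the relative change of total
corrected area, at most 3000 iterations. Convergence is geometric;
information propagates downward from the identity-anchored region in rungs
of γ·log₁₀(1/r) decades per iteration, so small r and strong suppression
converge fastest and some near-threshold cases take a few thousand cheap
iterations. With measurement noise the alternation can settle into a tiny
limit cycle instead of a point; a non-improving delta below 1e-3 after 30
stagnant iterations is accepted as converged. At convergence the corrected
area ratio Σx₂/Σx₁ must agree with r within `ratio_tol` (default 10%),
otherwise the fit is rejected.

**Correction conditions.** A pair is correctable iff 0.2 ≤ r ≤ 0.8 (outside
this window y₂/y₁ carries too little suppression contrast) and
max(y₂) > 10⁶ (otherwise f cannot be anchored over the range that needs
correction). Uncorrectable peptides pass through unchanged and are flagged.

## Preprocessing

Per identified peptide: elemental composition = residue sum + H₂O
(unmodified sequences assumed); monoisotopic m/z with CODATA/IUPAC masses
and proton adducts; +1 species at mono m/z + 1.0033548/z. XICs sum all peak
intensities within ±10 ppm (default) of the target m/z per MS1 scan. The
elution peak is located as the maximum of a 3-point moving average (edge
samples left unsmoothed) within ±120 s of the identified elution time, then
expanded while the smoothed intensity stays ≥ 5% of the apex and positive;
intervals are half-open 0-based index ranges.

## Null distributions and significance

**Experimental null.** In a 1:1 replicate run pair, peptides whose ¹²C apex
exceeds the distortion-free threshold in both runs estimate the
between-run (sample-handling) variation. Their log₁₀ area ratios are
computed over the profile portion above the threshold in *both* runs (the
below-threshold tails are still suppressed and would leak instrumental
variation into the experimental null; with different scan grids, run 2 is
linearly resampled onto run 1's grid first). Fewer than 5 qualifying
peptides is an error; fewer than 30 attaches a warning and blocks P-value
use.

**Predicted null.** At intensity level L, a unit Gaussian elution template
y_p (SD 5 scan intervals by default) is scaled to apex L; for each draw
aʲ (resampled with replacement from the experimental null) and each library
distortion gᵢ the predicted ratio is
r^ij = area(gᵢ(aʲ·y_p)) / area(gᵢ(y_p)). The pooled log₁₀ r^ij form the
predicted null at L; the construction is deterministic given the seed. In
the fully suppressed power-law regime r^ij = (aʲ)^γᵢ independently of the
template shape, so the template choice matters only near the threshold.

**Significance.** Peptides correctable in both runs are corrected and their
fold change (ratio of corrected ¹²C areas over the peak interval) is tested
against the experimental null. All other peptides are tested against the
predicted null of the half-decade log₁₀ stratum holding the taller
profile's apex (one cached predicted null per stratum). P-values are
two-sided empirical with the add-one rule: p = (k+1)/(m+1), k = number of
null log-ratios at least as far from the null median as the measured
log-ratio. P-values against a predicted null are floored at 1/(n_exp+1):
the predicted sample contains N·n_draws points but only n_exp independent
experimental draws stand behind it, and smaller values would be
anticonservative (resampling makes the predicted support discrete, so a
fold change just outside it would otherwise get p ≈ 1/(N·n_draws)). No
multiple-testing correction is applied; P-values are reported raw.

## Synthetic data generator

The generator emulates the study conditions end to end: Gaussian elution
peaks (SD 5 scan intervals, 61 scans at 1 s) for ¹²C/¹³C pairs sharing one
true ratio; a per-peptide power-law distortion
g(x) = thr·(x/thr)^γ below thr = 10⁶ (identity above; γ ∈ [1.1, 2.0]
uniform), identical for both isotopes and both runs; iid multiplicative
lognormal point noise with CV 0.01; per-run lognormal abundance factors
with σ = 0.05 log₁₀ around a shared base (so suppression-free log₁₀ fold
changes have SD ≈ 0.05·√2); apexes log-uniform over 10⁴–10⁷; 200 peptides
per run pair. Sequences are sampled from the 20 standard residues (length
4–16) and kept only if their theoretical isotope ratio falls in [0.2, 0.8],
so mzXML fixtures remain self-consistent when the pipeline recomputes r
from the sequence. Every generator is a pure function of its seed, and each
run pair carries a truth table (true areas, r, γ, per-run factors).

The power-law family was chosen because it is monotone, anchored to the
identity at the threshold, strictly intensity-dependent, and has a single
shape parameter; it is linear in log-log space, hence exactly representable
by the estimator's functional family. What the generator does **not**
emulate: chromatographic tailing, co-eluting interferences, full isotope
envelopes beyond two species, detector saturation, retention-time drift
between runs, or modified residues. Passing tests therefore demonstrate
correctness of the estimation machinery under the stated suppression model,
not robustness to every artifact of real LC-MS data.

## Validation sizes and determinism

The acceptance script and test suite run at desk scale, chosen to keep the
whole validation around a minute while leaving the statistical checks well
powered: correction recovery over γ ∈ {1.2, 1.5, 2.0} × r ∈ {0.3, 0.5, 0.7}
(20 noise replicates per combination for the noisy variant); null transport
and end-to-end null prediction over 20 seeded replicates of 200-peptide run
pairs with 500–1000 draws per predicted null; type-I error on one
200-peptide 1:1 pair plus 500 null-drawn fold changes for P-value
uniformity. All randomness flows from explicit seeds; identical seeds give
bit-identical predicted nulls, P-values and output files.

Known numerical edges: predicted-null SD saturates once a level lies fully
inside the suppressed regime, so across half-decade levels the SD ordering
is monotone only up to ~1e-3 wiggle from the piecewise-linear knots;
fold changes exactly at the null median rely on a 1e-12 slack in the
extremeness count to survive the log/exp float round trip; profiles with
fewer than 3 usable points in the peak interval are rejected as degenerate
rather than fitted.

## Design choices on genuinely open points

* Intensity strata for predicted nulls are half-decade log₁₀ bins of the
  taller profile's apex — narrow enough that suppression severity is
  roughly constant within a bin, wide enough to cache few nulls.
* Experimental-null draws aʲ are resampled nonparametrically rather than
  fitted to a parametric family; nothing in the method requires a family.
* The null-prediction template is a unit Gaussian by default; in the fully
  suppressed regime the predicted ratio is template-free (see above), which
  the variance-ordering and transport tests exploit.
* The ¹²C profile (not the isotope sum) defines reported abundances and
  fold changes; it is the taller, better-measured species.
* Caches are JSON rather than a binary format: the arrays involved are
  small (one XIC pair per peptide) and byte-stable serialization makes
  reruns verifiable by checksum.
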