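# Methods

## Model

Immunostaining signal is modeled as irreversible accumulation: washing
removes weakly bound antibodies, so the unbinding rate is taken as zero and
the bound amount of epitope class i after incubation at free-antibody
concentration a for time τ is x_i = g_i (1 − e^{−k_a,i a τ}).  All
system-specific effects (diffusion obstruction, secondary-antibody
amplification, temporary binding) are absorbed into the empirical
accessibility constant K_i = 1/(k_a,i τ), which has concentration units and
marks the dilution-quotient scale at which class i picks up signal.
Concentrations are dilution quotients (1:n ≙ 1/n of a stock); epitope
amounts g and responses share one arbitrary "normalized response" unit.

The package also provides, for contrast and diagnostics rather than
fitting:

* the equilibrium Langmuir isotherm x_eq = g / (1 + k_d/(k_a a)), which the
  accumulation picture replaces;
* a simulator of the finite-volume depletion system dx_i/dt = k_a,i a(t)
  (g_i − x_i), a(t) = a0 − β Σ x_j, integrated with LSODA at rtol 1e-10
  (the free-pool balance a + βΣx = a0 holds identically; x_i are
  monotone); and
* a worst-case depletion check that replaces each nominal dilution by
  d_i′ = d_i − β·r_i, i.e. assumes the entire observed response was removed
  from the free pool.  This subtraction rule is an interpretation — it is
  the most conservative concentration correction expressible without
  modeling the kinetics — and is intended only to flag assays where the
  corrected histogram differs materially from the uncorrected one.
  Estimating parameters *under* depletion is out of scope.

## Preprocessing

Single-cell mean intensities (long CSV: plate, well, channel, cell,
intensity) are reduced to well means; each plate/channel is normalized by
the mean of its normalization-well means (normalization is linear, so the
order of averaging and dividing is immaterial); wells sharing a dilution
quotient are replicates contributing a mean r_i and sample (n−1) standard
deviation Δr_i.  The zero-control baseline is subtracted per plate by
default (configurable to global; the choice only matters when replicates of
one condition span plates with different backgrounds).  If subtraction
would drive a response negative, the lowest response of the curve is
subtracted instead, pinning it at exactly zero.  Uncertainties below a
floor (default 0.01 response units) — including the exact zeros produced by
baseline removal and single-replicate conditions — are replaced by the
floor, because Δr_i enters the fitting objective as 1/(2Δr_i)² and
near-zero values would dominate it.

## Inversion

The class structure is relaxed to a density g(K) and the dose-response
becomes x(d) = ∫ g(K)(1 − e^{−d/K}) dK.  The density is represented as a
Riemann sum over intervals [p_j, p_{j+1}) of an adaptively refined grid;
the per-interval epitope amounts λ_j are the parameters, and the model
curve uses each interval's arithmetic midpoint as its effective K.  The
objective is the sign-flipped log-posterior

    obj(λ) = (α/m²) Σ_j (λ_{j+1}/w_{j+1} − λ_j/w_j)²
             + Σ_i (r_i − f(d_i, λ))² / (2 Δr_i)²,

with w_j = log10 p_{j+1} − log10 p_j.  The prior penalizes differences of
*bar heights* (contribution values c_j = λ_j/w_j), i.e. it is a Tikhonov
smoothness term on the histogram as drawn; α = 500 by default, α = 50 for
weak regularization.  Histogram bars plot c_j over log10 K, so the visual
area equals the total amount of equivalent epitopes exactly.

Fitting alternates optimization and grid refinement:

1. Start from the two-interval grid p = (min d, log-midpoint, max d) with
   λ_j = max(r)/2 — the total mass starts at the response plateau scale,
   which keeps the first Nelder–Mead search in range.
2. Minimize with box-constrained Nelder–Mead (≤ 2000 iterations, bounds
   [0, 10·max r] per λ_j).
3. Refine: split one interval at its log-midpoint, giving each half λ_j/2
   (mass is conserved exactly — binary halving is lossless).
4. Repeat the optimize–refine cycle 50 times (52 intervals), then polish
   with box-constrained L-BFGS-B using numerically calculated
   central-difference gradients (iteration cap 2000, gradient tolerance
   1e-12).

Everything is deterministic; no randomness enters the fit.

**Which interval to split.**  The refinement criterion is the contribution
difference to neighbors, measured on the epitope-amount scale:
score_j = w_j · max_neighbor |c_j − c_neighbor|, ties broken toward the
larger contribution value, then the lowest index.  The width factor is a
deliberate design choice: comparing raw heights |c_j − c_neighbor| alone
looks equivalent but diverges in practice, because c = λ/w grows without
bound as intervals narrow — once a peak has been resolved by a few narrow
intervals, their height jitter dominates every raw-height comparison and
all remaining splits chase it, leaving wide intervals elsewhere unresolved.
On a nine-decade four-fold dilution ladder the raw-height rule reproducibly
stalls (fitted mass ~1.9 for a one-class system with g=1, none of it within
a decade of the true K, even when each cycle's optimization is replaced by
an exact bounded least-squares solve); the width-weighted rule recovers
mass 1.00–1.03 with ≥98% within the decade across seeds.  The tie rule
matters for the very first split, where the two intervals flanking the
single interior edge always tie: splitting the loaded flank lets refinement
descend toward a peak inside a wide interval.

**Final polish in height space.**  The final L-BFGS-B stage optimizes the
contribution values c_j rather than λ_j — an exact reparameterization
(λ = c·w) with rescaled box bounds.  Refined grids mix interval widths over
many orders of magnitude, which makes the quadratic objective so
ill-conditioned in λ that L-BFGS-B stalls about 1e-6 relative above the
optimum even with exact gradients; in c-space it reaches the independently
computed bounded-NNLS optimum to machine precision.  Gradients are central
differences with step 1e-4·(|c_j| + 0.01) — exact for a quadratic up to
rounding, per-coordinate scaled so neither tiny nor large heights lose
precision.

**Properties.**  The fitted histogram inherits the model's structure:
responses rescaled by a constant rescale λ proportionally (exactly up to
the fixed prior weight — rescaling responses by c is equivalent to
rescaling α by c², so strict unit independence holds in the α-insensitive
regime; at c=2 the deviation measures below 1%); dilutions rescaled by c
shift the histogram by log10 c with the same λ pattern; the fit of a sum of
dose-responses reproduces the union of the individual peaks
(superposition).  These are exercised in the test suite on synthetic data.

## Peaks, d\* and D\*

Peaks partition the histogram intervals — either at user-supplied K
boundaries (preferred, as in published figures) or automatically as maximal
runs of bars above 5% of the maximum height, with each below-threshold
valley cut at its lowest bar so the partition stays exhaustive.
Exhaustiveness makes the stacked per-peak contribution curves sum to the
model curve exactly.

The characteristic dilutions are usually read off contribution plots by
eye; this package operationalizes them as:

* **d\*** — the largest d at which the combined contribution of all peaks
  above the lowest-K peak is ≤ δ (default 1%) of the total signal.  Located
  by a log-spaced scan plus Brent root refinement; agrees with a dense
  brute-force scan to ~1e-5 relative.
* **D\*** — the d where the low-K and combined high-K contributions cross;
  reported as absent when no crossing exists (crossings where both curves
  agree only at saturation rounding level are rejected).

Round planning for multiplexing picks, per non-final peak, the smallest d
saturating that peak to 95% of its plateau while the next peak contributes
at most a contamination budget of the total (default 5% — deliberately
looser than the 1% δ of d\*, since a staining round must *saturate* its
peak, which necessarily sits slightly past d\*; on a validation-like
two-peak system the first round comes out ≈2× more concentrated than d\*).
The final round uses the largest feasible concentration.  Overlapping peaks
that cannot satisfy both constraints raise an error instead of producing a
misleading plan.

## Synthetic data

Generators (numpy Philox, fully seed-determined) emulate the three
experimental data types:

* **Dilution series** — replicate well means x(d)·(1 + CV·N(0,1)) +
  baseline, truncated at zero; defaults 8 replicates and 10% CV, matching
  typical plate replication; ensemble means converge to the forward model
  (checked at n=64 with 3σ CLT bounds).
* **Single-cell plates** — per-cell log-normal intensities around the
  well's expected raw intensity, with normalization wells at a reference
  level and zero-control wells at the baseline, so the full preprocessing
  chain can be round-tripped.
* **Two-round image scenes** — filament-like and punctate structures
  tagged with epitope classes; round-1 intensity x_c(d1), round-2 intensity
  fold·x_c(d1) + (x_c(d1+d2) − x_c(d1)) (cumulative exposure plus
  secondary-antibody brightening of round-1 signal); a known integer
  inter-round shift; a shared fiducial-blob alignment channel; additive
  Gaussian noise.  A secondary-only control variant omits the round-2
  primary exposure.

What the generators do **not** emulate: optics (PSF, shading,
bleed-through), depletion, temporary binding, outlier replicates, cell
segmentation errors, or sample movement beyond rigid translation.  Passing
tests therefore demonstrate correctness of the computational pipeline under
the stated noise model, not robustness to those real-data effects.

## Multiplexing

Rounds are aligned by phase cross-correlation on the alignment channel
(subpixel estimate, applied as the nearest-integer translation — avoiding
resampling artifacts in difference images; interpolation would only matter
for sub-pixel drift), then cropped to the common overlap; a Pearson
correlation below 0.2 after alignment raises an alignment failure.  The
secondary-antibody fold-change is the round-2/round-1 mean ratio of the
secondary-only control, over either the whole frame or the Otsu foreground
(default; approximates quantified-cell means).  The corrected difference
image is max(img2 − fold·img1, 0); negatives are clipped because negative
bound-antibody signal is unphysical.  Composites sum brightness-scaled
intensity×color per channel with optional k×k mean binning and clipping.
n-round experiments are processed pairwise in order and need n−1
secondary-only controls.

## Problem sizes and numerical defaults

Default test/analysis sizes: 16-condition dilution ladders with 8
replicates, 50 refinement cycles (52 final intervals), 512×512 image
scenes; a full inversion takes a few seconds and the complete acceptance
run about a minute on one CPU.  Nelder–Mead uses xatol = fatol = 1e-10;
L-BFGS-B uses ftol = 1e-18, gtol = 1e-12, 50 correction pairs; dense scans
for characteristic dilutions use 400 log-spaced points before Brent
refinement (2×10⁶ for brute-force cross-checks).  Degenerate inputs are
rejected early with instructive errors: non-positive uncertainties (must be
floored upstream), fewer than two distinct dilutions, corrected dilutions
≤ 0 in the worst-case check, empty designed wells, peaks with no mass.

## Known limitations

* Histogram peak *widths* depend on α and should not be over-interpreted;
  positions and counts are the robust features.
* The choice of optimal dilution from d\* presumes high-K peaks are
  unspecific — a heuristic valid for monoclonal antibodies only, and the
  histogram alone cannot identify what produces a high-K peak.
* A dose-response that never leaves the baseline, or clips at the highest
  concentration, yields an uninformative single-peak histogram.
* Strict unit independence of the fitted amounts holds only in the
  α-insensitive regime (see above).
* Depletion-aware inversion and channel bleed-through correction are not
  implemented.
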