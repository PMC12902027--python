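# accesshist

Epitope-heterogeneity analysis for immunostainings, from antibody-dilution
series to **accessibility histograms**, optimal staining dilutions, and
single-channel computational multiplexing.

## The problem

Antibody staining intensity depends not only on how much target is present
but on how *accessible* each epitope is in the fixed, crowded cellular
environment.  Standard equilibrium descriptions (the Langmuir isotherm) do
not apply: immunostaining protocols wash away loosely bound antibodies, so
the observed signal is the *accumulation* of wash-resistant binding.  For a
mixture of epitope classes with amounts g_i and accessibility constants
K_i, the dose-response over the staining dilution quotient d (`1:n` ≙ 1/n of
a stock) is

    x(d) = Σ_i g_i (1 − exp(−d / K_i)),        K_i = 1 / (k_a,i · τ)

with binding rate constant k_a,i and incubation time τ.  Treating the class
structure as a continuous density g(K) turns this into a Fredholm integral
equation of the first kind.  `accesshist` inverts it: given a measured
dilution series (d_i, r_i ± Δr_i) it estimates the distribution of
"equivalent epitopes" over log K — the accessibility histogram — by
minimizing

    obj(λ) = ℓ0(λ) + Σ_i (r_i − f(d_i, λ))² / (2 Δr_i)²

over per-interval epitope amounts λ on an adaptively refined logarithmic
grid, where ℓ0 is a Tikhonov-type smoothness prior on neighboring bar
heights (weight α, default 500).  Peaks in the histogram are epitope
classes; their positions tell you at which dilutions they light up, which
yields the optimal staining dilution d\* (just before potentially
unspecific high-K classes start contributing) and a plan of staining rounds
for splitting one color channel into per-class images ("computational
multiplexing": stain, image, re-stain more concentrated, align, subtract).

Intended users: imaging labs doing quantitative immunofluorescence or
high-content screening who want to characterize antibody binding in their
own system instead of trusting a vendor dilution.

## Worked example

Simulate a two-class system (g=1 at K=10⁻⁵ and g=0.8 at K=10⁻³ — a specific
signal plus a weaker "background" class two decades less accessible), fit
it, and analyze the peaks:

```
$ accesshist simulate --classes "1@1e-5,0.8@1e-3" --dilutions 16 --stock 1:100 --seed 42 --out-dir sim
$ accesshist fit sim/series.csv --out-prefix fit
total mass 1.948, objective 0.503
$ accesshist peaks fit_histogram.csv --delta 0.01 --max-dilution 1e-2 --out-prefix peaks
{"n_peaks": 2, "peaks": [{..., "mass": 1.0355}, {..., "mass": 0.9122}],
 "delta": 0.01, "d_star": 4.12e-06, "D_star": null,
 "round_plan": [4.50e-05, 0.01]}
```

Reading the output: the histogram recovers two peaks whose masses (1.04 and
0.91 equivalent epitopes) match the generating amounts within the replicate
noise; total fitted mass is 1.948.  `d_star = 4.12e-06` (≈ 1:243000) is the
most concentrated dilution at which the high-K peak still contributes less
than δ = 1% of the signal — the recommended staining dilution if the high-K
peak is unspecific.  `D_star` is `null` because the smaller high-K peak
never overtakes the low-K peak.  The round plan stains first at 1:22000
(saturating the low-K peak) and then at the maximum feasible concentration,
for two-round multiplexing.  `fit_histogram.png` and
`peaks_contributions.png` show the histogram with the fitted curve and the
stacked per-peak contributions.

The same operations are available as library functions
(`accesshist.fit_histogram`, `accesshist.peaks.characteristic_dilutions`,
`accesshist.multiplex.register_rounds`, ...); see the docstrings and
`docs/methods.md`.

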