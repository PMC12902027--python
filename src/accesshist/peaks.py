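"""Peak analysis of accessibility histograms.

Peaks in the accessibility histogram group epitope classes by the antibody
concentration scale at which they pick up signal.  Because low-K peaks
saturate before high-K peaks begin to contribute, the per-peak contribution
curves can be stacked from low K to high K to reconstruct the full
dose-response curve, and two characteristic dilution quotients follow:

* ``d_star`` — the largest dilution at which the higher-K (potentially
  unspecific) contribution is still negligible: the recommended staining
  dilution for monoclonal antibodies.
* ``D_star`` — the dilution at which the low-K and high-K contributions are
  equal (may not exist).

Both are defined here operationally: ``d_star`` via a relative contamination
tolerance ``delta`` and ``D_star`` as a contribution crossing, each located
by bisection on a logarithmic dilution axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .inversion import HistogramFit, model_curve

__all__ = [
    "Peak",
    "PeakSet",
    "PeakContributions",
    "CharacteristicDilutions",
    "RoundPlan",
    "PlanError",
    "partition_peaks",
    "peak_contributions",
    "characteristic_dilutions",
    "multiplex_round_plan",
]


@dataclass(frozen=True)
class Peak:
    """A contiguous run of histogram intervals treated as one epitope group."""

    start: int  # first interval index (inclusive)
    stop: int  # last interval index (exclusive)
    k_lo: float
    k_hi: float
    mass: float

    @property
    def indices(self) -> slice:
        return slice(self.start, self.stop)


@dataclass(frozen=True)
class PeakSet:
    """Ordered, disjoint peaks covering all histogram intervals."""

    peaks: tuple
    mode: str  # "manual" | "auto"

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i) -> Peak:
        return self.peaks[i]

    @property
    def total_mass(self) -> float:
        return float(sum(p.mass for p in self.peaks))


class PlanError(RuntimeError):
    pass


def _runs_to_peaks(fit: HistogramFit, cuts: list[int]) -> tuple:
    """Turn interval cut positions into Peak objects covering everything."""
    pts = fit.grid.points
    bounds = [0, *cuts, fit.grid.n_intervals]
    peaks = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b > a:
            peaks.append(Peak(a, b, float(pts[a]), float(pts[b]), float(fit.lambdas[a:b].sum())))
    return tuple(peaks)


def partition_peaks(
    fit: HistogramFit,
    boundaries=None,
    height_threshold_frac: float = 0.05,
) -> PeakSet:
    """Partition histogram intervals into peaks.

    Manual mode (``boundaries`` given as strictly increasing K values):
    intervals are assigned to peaks by comparing their midpoints to the
    boundary values; every interval belongs to exactly one peak.

    Automatic mode: peaks are maximal runs of bars with height at least
    ``height_threshold_frac`` of the maximum height, separated by valleys
    below that threshold.  To keep the partition exhaustive (so stacked
    contributions reproduce the model curve exactly), below-threshold
    intervals are attached to the nearest run, splitting each valley at its
    lowest bar.
    """
    heights = fit.grid.contributions(fit.lambdas)
    n = fit.grid.n_intervals
    mids = fit.grid.midpoints

    if boundaries is not None:
        bvals = np.atleast_1d(np.asarray(boundaries, dtype=float))
        if np.any(np.diff(bvals) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        cuts = [int(np.searchsorted(mids, b)) for b in bvals]
        return PeakSet(_runs_to_peaks(fit, sorted(set(c for c in cuts if 0 < c < n))), "manual")

    if not np.any(heights > 0):
        raise ValueError("no peaks detected: histogram has no mass")
    thr = height_threshold_frac * heights.max()
    above = heights >= thr
    if not above.any():
        raise ValueError("no peaks detected: no bars above the height threshold")

    # Runs of above-threshold bars; cut each separating valley at its minimum.
    idx = np.flatnonzero(above)
    run_breaks = np.flatnonzero(np.diff(idx) > 1)
    cuts = []
    for b in run_breaks:
        lo, hi = idx[b] + 1, idx[b + 1]  # valley intervals [lo, hi)
        valley_min = lo + int(np.argmin(heights[lo:hi]))
        cuts.append(valley_min + 1 if heights[valley_min] == 0 else valley_min)
    return PeakSet(_runs_to_peaks(fit, cuts), "auto")


@dataclass
class PeakContributions:
    """Per-peak response curves and their low-to-high-K stacked sums."""

    d: np.ndarray
    curves: np.ndarray  # (n_peaks, n_d)
    peaks: PeakSet = field(repr=False)

    @property
    def stacked(self) -> np.ndarray:
        return np.cumsum(self.curves, axis=0)

    @property
    def total(self) -> np.ndarray:
        return self.curves.sum(axis=0)


def _peak_curve(fit: HistogramFit, peak: Peak, d: np.ndarray) -> np.ndarray:
    lam = fit.lambdas[peak.indices]
    mids = fit.grid.midpoints[peak.indices]
    return np.sum(lam * (1.0 - np.exp(-np.asarray(d, dtype=float)[..., None] / mids)), axis=-1)


def peak_contributions(peaks: PeakSet, fit: HistogramFit, d_values) -> PeakContributions:
    """Evaluate each peak's contribution to the dose-response curve.

    Because the peaks partition all intervals, the top stacked curve equals
    the full model curve at every d, to machine precision.
    """
    d = np.atleast_1d(np.asarray(d_values, dtype=float))
    if np.any(d <= 0):
        raise ValueError("d_values must be positive")
    curves = np.vstack([_peak_curve(fit, p, d) for p in peaks])
    return PeakContributions(d=d, curves=curves, peaks=peaks)


@dataclass(frozen=True)
class CharacteristicDilutions:
    """d_star (optimal staining dilution) and D_star (equal-contribution)."""

    d_star: float
    D_star: float | None
    delta: float


def _log_bisect(func, d_lo: float, d_hi: float, n_scan: int = 400, min_magnitude: float = 0.0) -> float | None:
    """First sign change of ``func`` on a log-spaced scan, refined by brentq.

    Sign changes where the function stays within ``min_magnitude`` of zero on
    both sides are ignored: they are rounding chatter (e.g. two saturated
    contribution curves meeting at machine precision), not real crossings.
    """
    ds = np.geomspace(d_lo, d_hi, n_scan)
    vals = np.array([func(x) for x in np.log10(ds)])
    sign_change = np.flatnonzero(np.diff(np.signbit(vals)))
    for i in sign_change:
        if max(abs(vals[i]), abs(vals[i + 1])) <= min_magnitude:
            continue
        lo, hi = np.log10(ds[i]), np.log10(ds[i + 1])
        return float(10 ** brentq(func, lo, hi, xtol=1e-12))
    return None


def characteristic_dilutions(
    peaks: PeakSet,
    fit: HistogramFit,
    delta: float = 0.01,
    d_range: tuple[float, float] | None = None,
) -> CharacteristicDilutions:
    """Locate d_star and D_star from the peak contribution curves.

    d_star is the largest d at which the combined contribution of all peaks
    above the lowest-K peak stays at or below ``delta`` times the total
    contribution.  D_star is the d where the low-K and combined high-K
    contributions cross; it is reported as None when no crossing exists in
    the search range.  Roots are found by bisection on a log-d axis and a
    dense log-spaced scan for bracketing.
    """
    if not 0 < delta < 1:
        raise ValueError("delta must be in (0, 1)")
    if d_range is None:
        d_range = (fit.grid.points[0] / 1e3, fit.grid.points[-1] * 1e3)
    d_lo, d_hi = d_range

    if len(peaks) < 2:
        d_max = float(fit.series.d.max()) if fit.series is not None else float(fit.grid.points[-1])
        warnings.warn("single peak: no high-K peak to avoid; d_star set to the largest measured dilution")
        return CharacteristicDilutions(d_star=d_max, D_star=None, delta=delta)

    low_peak = peaks[0]

    def low(d):
        return _peak_curve(fit, low_peak, np.asarray(d))

    def high(d):
        d = np.asarray(d)
        return sum(_peak_curve(fit, p, d) for p in peaks.peaks[1:])

    def excess(logd):
        d = 10.0**logd
        total = low(d) + high(d)
        return float(high(d) - delta * total)

    d_star = _log_bisect(excess, d_lo, d_hi)
    if d_star is None:
        # Contamination never reaches delta (or always exceeds it) in range.
        d_star = d_hi if excess(np.log10(d_hi)) <= 0 else d_lo
        warnings.warn("contamination tolerance not bracketed in search range; d_star clipped to range edge")

    D_star = _log_bisect(
        lambda logd: float(high(10.0**logd) - low(10.0**logd)),
        d_lo,
        d_hi,
        min_magnitude=1e-9 * fit.total_mass,
    )
    return CharacteristicDilutions(d_star=float(d_star), D_star=D_star, delta=delta)


@dataclass(frozen=True)
class RoundPlan:
    """Strictly increasing staining dilutions, one round per peak."""

    dilutions: tuple
    saturation_frac: float
    contamination_delta: float


def multiplex_round_plan(
    peaks: PeakSet,
    fit: HistogramFit,
    max_dilution: float,
    saturation_frac: float = 0.95,
    contamination_delta: float = 0.05,
) -> RoundPlan:
    """Plan staining dilutions for peak-by-peak computational multiplexing.

    For each peak except the last, the round dilution is the smallest d at
    which the peak reaches ``saturation_frac`` of its plateau (its mass)
    while the next peak still contributes at most ``contamination_delta`` of
    the total signal.  The final round uses the largest feasible
    concentration, ``max_dilution``.  Raises :class:`PlanError` when the
    peaks overlap too much to satisfy both constraints — manual peak
    boundaries may still produce a usable plan.
    """
    if not 0 < saturation_frac < 1:
        raise ValueError("saturation_frac must be in (0, 1)")
    if max_dilution <= 0:
        raise ValueError("max_dilution must be positive")
    if len(peaks) == 1:
        return RoundPlan((float(max_dilution),), saturation_frac, contamination_delta)

    d_lo = fit.grid.points[0] / 1e3
    rounds = []
    for k, peak in enumerate(peaks.peaks[:-1]):
        target = saturation_frac * peak.mass
        if peak.mass <= 0:
            raise PlanError(f"peak {k} has no mass; use manual boundaries")
        d_sat = _log_bisect(
            lambda logd: float(_peak_curve(fit, peak, np.asarray(10.0**logd)) - target),
            d_lo,
            float(fit.grid.points[-1]) * 1e3,
        )
        if d_sat is None:
            raise PlanError(f"peak {k} never reaches {saturation_frac:.0%} of its plateau in range")
        nxt = peaks[k + 1]
        total = float(model_curve(d_sat, fit.grid, fit.lambdas))
        contamination = float(_peak_curve(fit, nxt, np.asarray(d_sat)))
        if contamination > contamination_delta * total:
            raise PlanError(
                f"at the saturating dilution {d_sat:g} of peak {k}, peak {k + 1} already "
                f"contributes {contamination / total:.1%} of the signal "
                f"(> {contamination_delta:.0%}); peaks overlap too much — consider manual boundaries"
            )
        rounds.append(float(d_sat))
    rounds.append(float(max_dilution))
    if np.any(np.diff(rounds) <= 0):
        raise PlanError(f"planned rounds are not strictly increasing: {rounds}")
    return RoundPlan(tuple(rounds), saturation_frac, contamination_delta)
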