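"""Forward models of antibody binding in immunostainings.

Immunostaining protocols wash away loosely bound antibodies before imaging,
so the observed signal reflects accumulated, wash-resistant binding rather
than a binding equilibrium.  With the unbinding rate set to zero and the
free-antibody concentration held constant, each epitope class ``i`` with
amount ``g_i`` and accessibility constant ``K_i`` accumulates signal

    x(d) = sum_i g_i * (1 - exp(-d / K_i)),

where ``d`` is the antibody concentration expressed as a dilution quotient.
The accessibility constant ``K_i = 1 / (k_a,i * tau)`` folds the binding rate
constant and the incubation time ``tau`` into a single empirical scale with
the units of ``d``.  This module provides that accumulation response, the
equilibrium Langmuir isotherm it should be contrasted with, a simulator for
the finite-volume depletion case (which has no closed form), and a
conservative worst-case correction to detect when depletion matters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .series import DoseResponseSeries

__all__ = [
    "KineticsSpec",
    "EpitopeClassSet",
    "DepletionSpec",
    "DepletionTrajectory",
    "IntegrationError",
    "accumulation_response",
    "langmuir_equilibrium",
    "simulate_depletion_kinetics",
    "worst_case_depletion_correction",
]


@dataclass(frozen=True)
class KineticsSpec:
    """Binding kinetics of a single epitope class.

    g : epitope amount (response units); k_a : binding rate constant
    (per concentration per time); k_d : unbinding rate constant (per time);
    tau : incubation time.
    """

    g: float
    k_a: float
    k_d: float = 0.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValueError("g must be non-negative")
        if self.k_a <= 0:
            raise ValueError("k_a must be positive")
        if self.k_d < 0:
            raise ValueError("k_d must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    @property
    def accessibility_constant(self) -> float:
        """K = 1 / (k_a * tau), in concentration (dilution-quotient) units."""
        return 1.0 / (self.k_a * self.tau)


@dataclass(frozen=True)
class EpitopeClassSet:
    """Epitope classes (g_i, K_i), stored sorted ascending by K."""

    g: np.ndarray
    K: np.ndarray

    def __post_init__(self) -> None:
        g = np.atleast_1d(np.asarray(self.g, dtype=float))
        K = np.atleast_1d(np.asarray(self.K, dtype=float))
        if g.shape != K.shape or g.ndim != 1:
            raise ValueError("g and K must be 1-D arrays of equal length")
        if np.any(g < 0):
            raise ValueError("epitope amounts g must be non-negative")
        if np.any(K <= 0):
            raise ValueError("accessibility constants K must be positive")
        order = np.argsort(K, kind="stable")
        object.__setattr__(self, "g", g[order])
        object.__setattr__(self, "K", K[order])

    @classmethod
    def from_pairs(cls, pairs) -> "EpitopeClassSet":
        """Build from an iterable of (g, K) pairs."""
        pairs = list(pairs)
        return cls(np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs]))

    def __len__(self) -> int:
        return self.g.size

    @property
    def total(self) -> float:
        return float(self.g.sum())

    def response(self, d) -> np.ndarray | float:
        return accumulation_response(d, self)

    def __add__(self, other: "EpitopeClassSet") -> "EpitopeClassSet":
        return EpitopeClassSet(np.concatenate([self.g, other.g]), np.concatenate([self.K, other.K]))


@dataclass(frozen=True)
class DepletionSpec:
    """Finite-volume coupling: free concentration a(t) = a0 - beta * sum_j x_j(t).

    beta converts bound response units back to concentration units; a0 is the
    initial free-antibody concentration (dilution-quotient units).
    """

    beta: float
    a0: float

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.a0 <= 0:
            raise ValueError("a0 must be positive")


@dataclass
class DepletionTrajectory:
    """Time grid, per-class bound amounts (steps x N), free concentration."""

    t: np.ndarray
    x: np.ndarray
    a: np.ndarray


class IntegrationError(RuntimeError):
    pass


def accumulation_response(d, classes: EpitopeClassSet):
    """Accumulated bound-antibody signal at dilution quotient(s) ``d``.

    Returns ``sum_i g_i (1 - exp(-d / K_i))``; strictly increasing in ``d``
    whenever some ``g_i > 0`` and bounded by ``sum_i g_i``.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("dilution quotient d must be non-negative")
    out = np.sum(classes.g * (1.0 - np.exp(-d_arr[..., None] / classes.K)), axis=-1)
    return float(out) if np.isscalar(d) or d_arr.ndim == 0 else out


def langmuir_equilibrium(a, spec: KineticsSpec):
    """Equilibrium Langmuir isotherm ``g / (1 + k_d / (k_a a))``.

    Provided for contrast with the accumulation response: at equilibrium the
    signal depends on the ratio k_d/k_a only, and with k_d = 0 every positive
    concentration saturates to ``g`` — unlike the washed, accumulated signal.
    """
    a_arr = np.asarray(a, dtype=float)
    if np.any(a_arr < 0):
        raise ValueError("concentration a must be non-negative")
    with np.errstate(divide="ignore"):
        out = np.where(a_arr > 0, spec.g / (1.0 + spec.k_d / (spec.k_a * np.where(a_arr > 0, a_arr, 1.0))), 0.0)
    return float(out) if np.isscalar(a) or a_arr.ndim == 0 else out


def simulate_depletion_kinetics(
    classes: EpitopeClassSet,
    depletion: DepletionSpec,
    k_a_list,
    t_end: float,
    steps: int = 200,
    rtol: float = 1e-10,
) -> DepletionTrajectory:
    """Integrate the coupled accumulation system with antibody depletion.

    dx_i/dt = k_a,i * a(t) * (g_i - x_i),  a(t) = a0 - beta * sum_j x_j(t).

    Deterministic adaptive-step integration (LSODA, stiff-capable).  The
    free-pool balance ``a(t) + beta * sum_j x_j(t) = a0`` holds by
    construction; a negative free concentration at any output step raises
    :class:`IntegrationError` with the offending time.
    """
    if steps < 2:
        raise ValueError("steps must be >= 2")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    k_a = np.atleast_1d(np.asarray(k_a_list, dtype=float))
    if k_a.shape != classes.g.shape:
        raise ValueError("k_a_list must provide one rate constant per class")
    if np.any(k_a <= 0):
        raise ValueError("rate constants must be positive")

    g, beta, a0 = classes.g, depletion.beta, depletion.a0

    def rhs(t, x):
        a = a0 - beta * x.sum()
        return k_a * a * (g - x)

    t_eval = np.linspace(0.0, t_end, steps)
    sol = solve_ivp(rhs, (0.0, t_end), np.zeros_like(g), method="LSODA", t_eval=t_eval, rtol=rtol, atol=1e-14)
    if not sol.success:
        raise IntegrationError(f"depletion integration failed: {sol.message}")
    x = sol.y.T
    a = a0 - beta * x.sum(axis=1)
    if np.any(a < -rtol * a0):
        t_bad = t_eval[np.argmax(a < -rtol * a0)]
        raise IntegrationError(
            f"free-antibody concentration became negative at t={t_bad:g} "
            f"(a0={a0:g}, beta={beta:g}); depletion parameters are inconsistent"
        )
    return DepletionTrajectory(t=t_eval, x=x, a=a)


def worst_case_depletion_correction(series: DoseResponseSeries, beta: float) -> DoseResponseSeries:
    """Conservative depletion check: d_i' = d_i - beta * r_i.

    Assumes, as worst case, that the entire observed response was removed
    from the free-antibody pool, and shifts each nominal dilution quotient
    down accordingly.  Responses are unchanged.  If the corrected histogram
    differs materially from the uncorrected one, depletion cannot be
    neglected for the assay.  This simple subtraction rule is this package's
    operational reading of a "worst case"; see the methods note.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    d_new = series.d - beta * series.r
    if np.any(d_new <= 0):
        i = int(np.argmax(d_new <= 0))
        raise ValueError(
            f"worst-case correction drives condition d={series.d[i]:g} (r={series.r[i]:g}) "
            f"to d'={d_new[i]:g} <= 0: depletion is not negligible at beta={beta:g}"
        )
    if np.any(np.diff(d_new) <= 0):
        warnings.warn("worst-case correction reordered conditions; interpret with care")
        order = np.argsort(d_new)
    else:
        order = slice(None)
    n = None if series.n_replicates is None else series.n_replicates[order]
    meta = dict(series.meta)
    meta.update(corrected="worst-case-depletion", beta=beta)
    return DoseResponseSeries(d_new[order], series.r[order], series.dr[order], n, meta)
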