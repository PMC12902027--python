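"""Dose-response series containers and dilution-quotient notation.

Antibody concentrations are expressed as dilution quotients: ``1:n`` denotes
the fraction ``1/n`` of a stock solution.  A dose-response series collects,
for each dilution quotient ``d_i``, the mean normalized response ``r_i``
across replicate wells and its sample standard deviation ``dr_i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["parse_dilution", "format_dilution", "DoseResponseSeries"]


def parse_dilution(value: float | str) -> float:
    """Parse a dilution quotient given as a float or a ``"1:n"`` string.

    ``"1:6400"`` means the quotient 1/6400 (a fraction of the stock), not a
    "1 part to n parts" mixing ratio.
    """
    if isinstance(value, str):
        text = value.strip()
        if ":" in text:
            num, _, den = text.partition(":")
            d = float(num) / float(den)
        else:
            d = float(text)
    else:
        d = float(value)
    if not np.isfinite(d) or d <= 0:
        raise ValueError(f"dilution quotient must be positive and finite, got {value!r}")
    return d


def format_dilution(d: float) -> str:
    """Render a dilution quotient in ``1:n`` notation."""
    if d <= 0:
        raise ValueError("dilution quotient must be positive")
    n = 1.0 / d
    if abs(n - round(n)) < 1e-9 * max(1.0, n):
        return f"1:{int(round(n))}"
    return f"1:{n:g}"


@dataclass
class DoseResponseSeries:
    """One dilution series: quotients ``d``, responses ``r``, uncertainties ``dr``.

    Parameters
    ----------
    d
        Dilution quotients, strictly increasing, all positive.
    r
        Mean normalized responses per condition (non-negative after baseline
        removal).
    dr
        Replicate sample standard deviations (measurement uncertainty),
        non-negative.
    n_replicates
        Replicate wells per condition (optional).
    meta
        Free-form provenance: baseline value removed, removal method,
        channel, correction flags.
    """

    d: np.ndarray
    r: np.ndarray
    dr: np.ndarray
    n_replicates: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.dr = np.asarray(self.dr, dtype=float)
        if self.d.ndim != 1 or self.d.shape != self.r.shape or self.d.shape != self.dr.shape:
            raise ValueError("d, r, dr must be 1-D arrays of equal length")
        if np.any(self.d <= 0):
            raise ValueError("dilution quotients must be positive")
        if np.any(np.diff(self.d) <= 0):
            raise ValueError("dilution quotients must be strictly increasing and unique")
        if np.any(self.dr < 0):
            raise ValueError("uncertainties must be non-negative")
        if self.n_replicates is not None:
            self.n_replicates = np.asarray(self.n_replicates, dtype=int)

    def __len__(self) -> int:
        return self.d.size

    @classmethod
    def from_arrays(cls, d, r, dr, n_replicates=None, meta=None) -> "DoseResponseSeries":
        """Build a series from unordered condition arrays, sorting by ``d``."""
        d = np.array([parse_dilution(v) for v in np.atleast_1d(np.asarray(d, dtype=object))])
        r = np.asarray(r, dtype=float)
        dr = np.asarray(dr, dtype=float)
        order = np.argsort(d)
        n = None if n_replicates is None else np.asarray(n_replicates)[order]
        return cls(d[order], r[order], dr[order], n, dict(meta or {}))

    def scaled(self, response_scale: float = 1.0, dilution_scale: float = 1.0) -> "DoseResponseSeries":
        """Rescale responses and/or dilutions (unit changes)."""
        n = None if self.n_replicates is None else self.n_replicates.copy()
        return DoseResponseSeries(
            self.d * dilution_scale, self.r * response_scale, self.dr * response_scale, n, dict(self.meta)
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"d": self.d, "r": self.r, "dr": self.dr}
        if self.n_replicates is not None:
            data["n_replicates"] = self.n_replicates
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DoseResponseSeries":
        df = pd.read_csv(path)
        n = df["n_replicates"].to_numpy() if "n_replicates" in df.columns else None
        return cls.from_arrays(df["d"].to_numpy(), df["r"].to_numpy(), df["dr"].to_numpy(), n)
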