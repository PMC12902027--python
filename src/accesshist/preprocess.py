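"""From single-cell intensity tables to normalized dose-response series.

High-content microscopes export one mean fluorescence intensity per cell
(within a nucleus-derived cell mask) per channel.  This module reduces such
long-format tables to per-well means, normalizes plates against dedicated
normalization wells, removes the zero-control baseline, and assembles the
(d, r, dr) dose-response series consumed by the inversion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .series import DoseResponseSeries, parse_dilution

__all__ = [
    "PlateDesign",
    "SingleCellTable",
    "NormalizationSpec",
    "well_summaries",
    "normalize_intensities",
    "assemble_dose_response",
]

ROLES = ("condition", "normalization", "zero")


@dataclass
class PlateDesign:
    """Well roles and dilution quotients.

    ``wells`` maps ``(plate, well)`` to a role in {"condition",
    "normalization", "zero"}; ``dilutions`` maps condition wells to their
    dilution quotient.  Roles are disjoint per well by construction.
    """

    wells: dict = field(default_factory=dict)
    dilutions: dict = field(default_factory=dict)

    def add(self, plate: str, well: str, role: str, dilution=None) -> None:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
        if role == "condition":
            if dilution is None:
                raise ValueError(f"condition well {plate}/{well} needs a dilution quotient")
            self.dilutions[(plate, well)] = parse_dilution(dilution)
        elif dilution is not None:
            raise ValueError(f"{role} well {plate}/{well} must not carry a dilution")
        self.wells[(plate, well)] = role

    def wells_with_role(self, role: str, plate: str | None = None):
        return [
            key
            for key, r in self.wells.items()
            if r == role and (plate is None or key[0] == plate)
        ]

    @property
    def plates(self):
        return sorted({plate for plate, _ in self.wells})

    @classmethod
    def from_dict(cls, data: dict) -> "PlateDesign":
        """Build from ``{"plates": {plate: {well: {"role": ..., "dilution": ...}}}}``."""
        design = cls()
        for plate, wells in data["plates"].items():
            for well, entry in wells.items():
                design.add(plate, well, entry["role"], entry.get("dilution"))
        return design

    @classmethod
    def from_json(cls, path: str | Path) -> "PlateDesign":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SingleCellTable:
    """Long-format per-cell intensities plus the plate design.

    ``data`` columns: plate, well, channel, cell, intensity.
    """

    data: pd.DataFrame
    design: PlateDesign

    REQUIRED = ("plate", "well", "channel", "cell", "intensity")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"single-cell table missing columns: {missing}")
        if (self.data["intensity"] < 0).any():
            raise ValueError("cell intensities must be non-negative")

    @classmethod
    def from_csv(cls, csv_path, design_path) -> "SingleCellTable":
        return cls(pd.read_csv(csv_path), PlateDesign.from_json(design_path))


@dataclass
class NormalizationSpec:
    """Per-(plate, channel) normalization values (all positive)."""

    values: dict

    def __post_init__(self) -> None:
        for key, v in self.values.items():
            if not v > 0:
                raise ValueError(f"normalization value for {key} must be positive, got {v}")

    def quotient(self, plate: str, channel_a: str, channel_b: str) -> float:
        """Cross-channel brightness quotient r = value(channel_a) / value(channel_b)."""
        return self.values[(plate, channel_a)] / self.values[(plate, channel_b)]

    @classmethod
    def from_table(cls, table: SingleCellTable) -> "NormalizationSpec":
        """Mean of the normalization-well means, per plate and channel."""
        wells = well_summaries(table)
        norm_wells = set(table.design.wells_with_role("normalization"))
        values = {}
        for plate in table.design.plates:
            plate_norm = wells[
                wells.apply(lambda row: (row["plate"], row["well"]) in norm_wells, axis=1)
                & (wells["plate"] == plate)
            ]
            if plate_norm.empty:
                raise ValueError(f"plate {plate!r} has no normalization wells with data")
            for channel, group in plate_norm.groupby("channel"):
                values[(plate, channel)] = float(group["mean_intensity"].mean())
        return cls(values)


def well_summaries(table: SingleCellTable) -> pd.DataFrame:
    """Per-(plate, well, channel) mean intensity with cell counts for QC.

    Raises if a designed well has no cell records in some channel present on
    its plate.
    """
    out = (
        table.data.groupby(["plate", "well", "channel"], sort=True)["intensity"]
        .agg(mean_intensity="mean", n_cells="size")
        .reset_index()
    )
    observed = set(zip(out["plate"], out["well"]))
    empty = [key for key in table.design.wells if key not in observed]
    if empty:
        raise ValueError(f"designed wells without any cell records: {sorted(empty)}")
    return out


def normalize_intensities(table: SingleCellTable, spec: NormalizationSpec | None = None) -> SingleCellTable:
    """Divide each cell intensity by its plate/channel normalization value.

    When ``spec`` is omitted it is computed from the table's normalization
    wells.  Normalization is linear, so normalizing cells and then averaging
    wells equals averaging first and dividing after.
    """
    if spec is None:
        spec = NormalizationSpec.from_table(table)
    present = set(zip(table.data["plate"], table.data["channel"]))
    missing = [key for key in present if key not in spec.values]
    if missing:
        raise ValueError(f"normalization spec missing (plate, channel) pairs: {sorted(missing)}")
    factors = table.data.apply(lambda row: spec.values[(row["plate"], row["channel"])], axis=1)
    data = table.data.copy()
    data["intensity"] = data["intensity"] / factors
    return SingleCellTable(data, table.design)


def assemble_dose_response(
    wells: pd.DataFrame,
    design: PlateDesign,
    channel: str,
    baseline_policy: str = "per-plate",
    uncertainty_floor: float = 0.01,
) -> DoseResponseSeries:
    """Reduce per-well means to a dose-response series for one channel.

    Wells sharing a dilution quotient are replicates: the condition response
    is their mean, the uncertainty their sample (n-1) standard deviation.
    The zero-control baseline is removed (with a min-response
    fallback that prevents negative responses), per plate or globally per ``baseline_policy``.
    Uncertainties below ``uncertainty_floor`` — including exact zeros created
    by baseline removal or single-replicate conditions — are replaced by the
    floor so the fitting objective stays well behaved.

    ``wells`` is the output of :func:`well_summaries` (normalized upstream).
    """
    if baseline_policy not in ("per-plate", "global"):
        raise ValueError("baseline_policy must be 'per-plate' or 'global'")
    if uncertainty_floor <= 0:
        raise ValueError("uncertainty_floor must be positive")

    wells = wells[wells["channel"] == channel]
    if wells.empty:
        raise ValueError(f"no well summaries for channel {channel!r}")
    lookup = {(p, w): m for p, w, m in zip(wells["plate"], wells["well"], wells["mean_intensity"])}

    def _mean_of(keys):
        vals = [lookup[k] for k in keys if k in lookup]
        return float(np.mean(vals)) if vals else None

    cond_wells = design.wells_with_role("condition")
    if not cond_wells:
        raise ValueError("design contains no condition wells")

    # Baseline removal happens at the well level so that per-plate baselines
    # are consistent when replicates of a condition span plates.
    baselines: dict = {}
    if baseline_policy == "global":
        zero = _mean_of(design.wells_with_role("zero"))
        baselines = {plate: zero for plate in design.plates}
    else:
        for plate in design.plates:
            baselines[plate] = _mean_of(design.wells_with_role("zero", plate))

    per_dilution: dict[float, list[float]] = {}
    for key in cond_wells:
        if key not in lookup:
            continue
        baseline = baselines.get(key[0]) or 0.0
        per_dilution.setdefault(design.dilutions[key], []).append(lookup[key] - baseline)
    if len(per_dilution) < 2:
        raise ValueError("need at least 2 distinct dilution quotients")

    d = np.array(sorted(per_dilution))
    r = np.array([np.mean(per_dilution[di]) for di in d])
    dr = np.array([np.std(per_dilution[di], ddof=1) if len(per_dilution[di]) > 1 else 0.0 for di in d])
    n_rep = np.array([len(per_dilution[di]) for di in d])

    # Min-response fallback: if the zero-control baseline overshoots, shift so
    # the lowest response sits at exactly zero instead of going negative.
    method = "zero-control"
    if r.min() < 0:
        r = r - r.min()
        method = "min-response"
    dr = np.maximum(dr, uncertainty_floor)

    meta = {
        "channel": channel,
        "baselines": {plate: baselines.get(plate) for plate in design.plates},
        "baseline_method": method,
        "baseline_policy": baseline_policy,
        "uncertainty_floor": uncertainty_floor,
    }
    return DoseResponseSeries(d, r, dr, n_rep, meta)
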