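"""Single-cell table reduction, normalization, and series assembly."""

import numpy as np
import pandas as pd
import pytest

from accesshist import (
    EpitopeClassSet,
    NoiseSpec,
    NormalizationSpec,
    PlateDesign,
    SingleCellTable,
    accumulation_response,
    assemble_dose_response,
    normalize_intensities,
    well_summaries,
)
from accesshist.synthetic import generate_plate_table


def _table(rows, design):
    return SingleCellTable(pd.DataFrame(rows, columns=["plate", "well", "channel", "cell", "intensity"]), design)


def _design(entries):
    design = PlateDesign()
    for plate, well, role, *dil in entries:
        design.add(plate, well, role, dil[0] if dil else None)
    return design


class TestWellSummaries:
    def test_arithmetic_means_and_counts(self):
        design = _design([("P1", "A1", "condition", 1e-3), ("P1", "A2", "condition", 1e-2)])
        table = _table(
            [("P1", "A1", "ch", 0, 1.0), ("P1", "A1", "ch", 1, 3.0), ("P1", "A2", "ch", 0, 5.0)], design
        )
        out = well_summaries(table)
        a1 = out[out["well"] == "A1"].iloc[0]
        a2 = out[out["well"] == "A2"].iloc[0]
        assert a1["mean_intensity"] == 2.0 and a1["n_cells"] == 2
        assert a2["mean_intensity"] == 5.0 and a2["n_cells"] == 1

    def test_designed_well_without_cells_raises(self):
        design = _design([("P1", "A1", "condition", 1e-3), ("P1", "B9", "zero")])
        table = _table([("P1", "A1", "ch", 0, 1.0)], design)
        with pytest.raises(ValueError, match="B9"):
            well_summaries(table)


class TestNormalization:
    def _norm_table(self):
        design = _design(
            [("P1", "A1", "condition", 1e-3), ("P1", "N1", "normalization"), ("P1", "N2", "normalization")]
        )
        rows = [
            ("P1", "A1", "ch", 0, 4.0),
            ("P1", "A1", "ch", 1, 8.0),
            ("P1", "N1", "ch", 0, 1.0),
            ("P1", "N2", "ch", 0, 3.0),
        ]
        return _table(rows, design)

    def test_division_by_mean_of_normalization_well_means(self):
        out = normalize_intensities(self._norm_table())
        # normalization value = mean(1.0, 3.0) = 2.0
        a1 = out.data[out.data["well"] == "A1"]["intensity"].to_numpy()
        assert np.allclose(a1, [2.0, 4.0])

    def test_normalize_then_average_commutes(self):
        table = self._norm_table()
        spec = NormalizationSpec.from_table(table)
        first = well_summaries(normalize_intensities(table, spec))
        second = well_summaries(table)
        key = (second["plate"] == "P1") & (second["well"] == "A1")
        direct = second[key]["mean_intensity"].iloc[0] / spec.values[("P1", "ch")]
        assert first[key]["mean_intensity"].iloc[0] == pytest.approx(direct, rel=1e-14)

    def test_missing_normalization_wells_raise(self):
        design = _design([("P1", "A1", "condition", 1e-3)])
        table = _table([("P1", "A1", "ch", 0, 4.0)], design)
        with pytest.raises(ValueError, match="normalization"):
            normalize_intensities(table)


class TestAssembleDoseResponse:
    def _wells(self, entries):
        return pd.DataFrame(entries, columns=["plate", "well", "channel", "mean_intensity", "n_cells"])

    def test_replicate_mean_and_sample_std(self):
        design = _design(
            [
                ("P1", "A1", "condition", 1e-3),
                ("P1", "A2", "condition", 1e-3),
                ("P1", "B1", "condition", 1e-2),
                ("P1", "B2", "condition", 1e-2),
            ]
        )
        wells = self._wells(
            [
                ("P1", "A1", "ch", 1.0, 5),
                ("P1", "A2", "ch", 3.0, 5),
                ("P1", "B1", "ch", 5.0, 5),
                ("P1", "B2", "ch", 5.0, 5),
            ]
        )
        series = assemble_dose_response(wells, design, "ch")
        assert series.r[0] == pytest.approx(2.0)
        assert series.dr[0] == pytest.approx(np.sqrt(2.0))  # sample (n-1) std of {1, 3}
        # identical replicates give zero std, floored at the default 0.01
        assert series.dr[1] == pytest.approx(0.01)
        assert list(series.n_replicates) == [2, 2]

    def test_baseline_fallback_subtracts_minimum_response(self):
        design = _design(
            [("P1", "A1", "condition", 1e-3), ("P1", "B1", "condition", 1e-2), ("P1", "Z1", "zero")]
        )
        wells = self._wells(
            [("P1", "A1", "ch", 0.1, 5), ("P1", "B1", "ch", 1.0, 5), ("P1", "Z1", "ch", 0.2, 5)]
        )
        series = assemble_dose_response(wells, design, "ch")
        # zero-control 0.2 exceeds the lowest response 0.1: subtract 0.1 instead
        assert series.meta["baseline_method"] == "min-response"
        assert series.r[0] == 0.0
        assert series.r[1] == pytest.approx(0.9)

    def test_baseline_from_zero_controls_when_safe(self):
        design = _design(
            [("P1", "A1", "condition", 1e-3), ("P1", "B1", "condition", 1e-2), ("P1", "Z1", "zero")]
        )
        wells = self._wells(
            [("P1", "A1", "ch", 0.5, 5), ("P1", "B1", "ch", 1.0, 5), ("P1", "Z1", "ch", 0.2, 5)]
        )
        series = assemble_dose_response(wells, design, "ch")
        assert series.meta["baseline_method"] == "zero-control"
        assert np.allclose(series.r, [0.3, 0.8])

    def test_global_rescaling_scales_series_linearly(self):
        design = _design([("P1", "A1", "condition", 1e-3), ("P1", "B1", "condition", 1e-2)])
        wells = self._wells([("P1", "A1", "ch", 1.0, 5), ("P1", "B1", "ch", 3.0, 5)])
        base = assemble_dose_response(wells, design, "ch", uncertainty_floor=1e-9)
        scaled_wells = wells.assign(mean_intensity=wells["mean_intensity"] * 7.0)
        scaled = assemble_dose_response(scaled_wells, design, "ch", uncertainty_floor=1e-9)
        assert np.allclose(scaled.r, 7.0 * base.r)


class TestPlateRoundTrip:
    def test_generated_plate_recovers_forward_model(self):
        classes = EpitopeClassSet.from_pairs([(1.0, 1e-4)])
        dilutions = np.geomspace(1e-6, 1e-2, 8)
        noise = NoiseSpec(replicates=4, cv=0.03, cell_sigma=0.3, cells_per_well=150, baseline=0.05, seed=42)
        table = generate_plate_table(classes, dilutions, noise)
        normalized = normalize_intensities(table)
        series = assemble_dose_response(well_summaries(normalized), table.design, "ch1")
        expected = accumulation_response(series.d, classes)
        # baseline removed; replicate/cell noise leaves a few percent scatter
        assert np.allclose(series.r, expected, atol=5 * 0.03 * max(expected))
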