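"""Synthetic data emulating dilution-series immunostaining experiments.

Three generators cover the pipeline end to end: replicate dose-response
series (well means with multiplicative replicate noise), single-cell plate
tables (log-normal per-cell intensities with normalization and zero-control
wells), and two-round image pairs for computational multiplexing (filament-
and punctum-shaped structures with known epitope-class membership, a known
inter-round pixel shift, shared alignment fiducials, and a configurable
secondary-antibody fold-change).

All generators are pure functions of their spec and seed (counter-based
Philox generator), so fixtures are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inversion import AccessibilityGrid, FitConfig, HistogramFit
from .model import EpitopeClassSet, accumulation_response
from .multiplex import ImageRound
from .preprocess import PlateDesign, SingleCellTable
from .series import DoseResponseSeries

__all__ = [
    "NoiseSpec",
    "SceneSpec",
    "GeneratedSeries",
    "SceneData",
    "generate_series",
    "generate_plate_table",
    "generate_image_rounds",
    "histogram_from_classes",
    "fourfold_dilutions",
]


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(seed))


def fourfold_dilutions(stock: float = 1e-2, n: int = 16) -> np.ndarray:
    """A four-fold dilution ladder 1:4^(n-1) ... 1:1 of a stock quotient."""
    return stock * 4.0 ** -np.arange(n - 1, -1, -1)


@dataclass(frozen=True)
class NoiseSpec:
    """Replicate and per-cell noise settings.

    replicates : wells per condition; cv : coefficient of variation of well
    means; cell_sigma : log-normal shape of per-cell intensities;
    cells_per_well : cells emitted per well; baseline : additive background
    in normalized response units; seed : fixed seed, identical seeds give
    bit-identical output.
    """

    replicates: int = 8
    cv: float = 0.1
    cell_sigma: float = 0.5
    cells_per_well: int = 200
    baseline: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


@dataclass
class GeneratedSeries:
    """A generated dilution series plus its ground truth."""

    series: DoseResponseSeries
    well_means: np.ndarray  # (replicates, n_dilutions)
    classes: EpitopeClassSet
    noise: NoiseSpec


def generate_series(
    classes: EpitopeClassSet,
    dilutions,
    noise: NoiseSpec = NoiseSpec(),
    uncertainty_floor: float = 0.01,
) -> GeneratedSeries:
    """Simulate replicate well means around the accumulation dose-response.

    Each replicate well mean is ``x(d) * (1 + cv * N(0,1)) + baseline``,
    truncated at zero.  The reduced series carries the replicate means and
    sample standard deviations (floored at ``uncertainty_floor``); the
    baseline is left in place — remove it downstream as for real data.
    """
    d = np.sort(np.asarray(dilutions, dtype=float))
    if np.any(d <= 0):
        raise ValueError("dilutions must be positive")
    rng = _rng(noise.seed)
    expected = accumulation_response(d, classes)
    wells = expected[None, :] * (1.0 + noise.cv * rng.standard_normal((noise.replicates, d.size)))
    wells = np.clip(wells + noise.baseline, 0.0, None)
    r = wells.mean(axis=0)
    dr = wells.std(axis=0, ddof=1) if noise.replicates > 1 else np.zeros_like(r)
    dr = np.maximum(dr, uncertainty_floor)
    series = DoseResponseSeries(
        d, r, dr, np.full(d.size, noise.replicates), {"generator": "accumulation", "seed": noise.seed}
    )
    return GeneratedSeries(series=series, well_means=wells, classes=classes, noise=noise)


def generate_plate_table(
    classes: EpitopeClassSet,
    dilutions,
    noise: NoiseSpec = NoiseSpec(),
    normalization_value: float = 1000.0,
    n_normalization_wells: int = 4,
    n_zero_wells: int = 4,
    plate: str = "P1",
    channel: str = "ch1",
) -> SingleCellTable:
    """Simulate a single-cell export of one dilution-series plate.

    Condition wells draw ``cells_per_well`` log-normal cell intensities whose
    mean equals the well's expected raw intensity (normalized response times
    ``normalization_value``); normalization wells sit at the reference level
    and zero-control wells at the baseline.  Running the result through the
    preprocessing chain recovers the generating dose-response within noise.
    """
    d = np.sort(np.asarray(dilutions, dtype=float))
    rng = _rng(noise.seed)
    design = PlateDesign()
    records = []

    def _emit(well, expected_norm):
        well_mean = max(expected_norm, 1e-12) * normalization_value
        well_mean *= max(1.0 + noise.cv * rng.standard_normal(), 0.0)
        mu = np.log(max(well_mean, 1e-300)) - noise.cell_sigma**2 / 2.0
        cells = rng.lognormal(mu, noise.cell_sigma, noise.cells_per_well)
        for cell_id, intensity in enumerate(cells):
            records.append((plate, well, channel, cell_id, intensity))

    for i, di in enumerate(d):
        for rep in range(noise.replicates):
            well = f"C{i:02d}R{rep}"
            design.add(plate, well, "condition", di)
            _emit(well, accumulation_response(di, classes) + noise.baseline)
    for j in range(n_normalization_wells):
        well = f"N{j}"
        design.add(plate, well, "normalization")
        _emit(well, 1.0)
    for j in range(n_zero_wells):
        well = f"Z{j}"
        design.add(plate, well, "zero")
        _emit(well, max(noise.baseline, 1e-6))

    data = pd.DataFrame(records, columns=["plate", "well", "channel", "cell", "intensity"])
    return SingleCellTable(data, design)


@dataclass(frozen=True)
class SceneSpec:
    """Two-round multiplexing scene.

    Filament structures carry ``filament_class`` and puncta ``puncta_class``
    (indices into the epitope class set).  ``round_dilutions`` are the two
    staining dilution quotients (round 2 more concentrated); ``shift`` is the
    known integer inter-round translation in pixels; ``fold_change`` the
    secondary-antibody signal increase applied to round-1 signal in round 2;
    ``noise_level`` additive Gaussian noise relative to the intensity scale.
    """

    shape: tuple = (512, 512)
    n_filaments: int = 6
    n_puncta: int = 40
    filament_class: int = 0
    puncta_class: int = 1
    round_dilutions: tuple = (1e-5, 1e-3)
    shift: tuple = (3, -2)
    fold_change: float = 1.15
    secondary_only_round2: bool = False  # control well: no new primary in round 2
    noise_level: float = 0.002
    n_fiducials: int = 30
    intensity_scale: float = 20000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.round_dilutions[1] <= self.round_dilutions[0]:
            raise ValueError("round-2 dilution must exceed round-1 dilution")
        if abs(self.shift[0]) >= self.shape[0] or abs(self.shift[1]) >= self.shape[1]:
            raise ValueError("shift larger than the image")


@dataclass
class SceneData:
    """Generated rounds plus ground truth in the round-1 frame."""

    round1: ImageRound
    round2: ImageRound
    labels: np.ndarray  # 0 background, 1 + class index for structure pixels
    scene: SceneSpec
    classes: EpitopeClassSet


def _draw_filament(mask: np.ndarray, rng: np.random.Generator, thickness: int = 2) -> None:
    h, w = mask.shape
    y, x = rng.uniform(0, h), rng.uniform(0, w)
    angle = rng.uniform(0, 2 * np.pi)
    for _ in range(rng.integers(150, 400)):
        angle += rng.normal(0, 0.15)
        y += np.sin(angle)
        x += np.cos(angle)
        yi, xi = int(round(y)), int(round(x))
        if not (0 <= yi < h and 0 <= xi < w):
            break
        mask[max(0, yi - thickness) : yi + thickness, max(0, xi - thickness) : xi + thickness] = True


def _draw_puncta(mask: np.ndarray, rng: np.random.Generator, n: int, radius_range=(2, 5)) -> None:
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        rad = rng.uniform(*radius_range)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2


def _integer_shift(img: np.ndarray, shift: tuple) -> np.ndarray:
    """Translate by integer pixels, zero-filling the exposed border."""
    out = np.zeros_like(img)
    dy, dx = int(shift[0]), int(shift[1])
    h, w = img.shape
    src = (slice(max(0, -dy), min(h, h - dy)), slice(max(0, -dx), min(w, w - dx)))
    dst = (slice(max(0, dy), min(h, h + dy)), slice(max(0, dx), min(w, w + dx)))
    out[dst] = img[src]
    return out


def generate_image_rounds(classes: EpitopeClassSet, scene: SceneSpec = SceneSpec()) -> SceneData:
    """Simulate a two-round staining of one fixed sample.

    Structure pixels of class c shine at ``x_c(d1)`` in round 1 and at
    ``fold_change * x_c(d1) + (x_c(d1 + d2) - x_c(d1))`` in round 2 — the
    cumulative accumulation of both exposures, with re-applied secondary
    antibodies brightening the round-1 signal.  Round-2 images are shifted by
    the known offset; a fiducial-blob alignment channel is shared by both
    rounds.  Intensities fit a 16-bit range.
    """
    rng = _rng(scene.seed)
    h, w = scene.shape
    fil_mask = np.zeros(scene.shape, dtype=bool)
    for _ in range(scene.n_filaments):
        _draw_filament(fil_mask, rng)
    pun_mask = np.zeros(scene.shape, dtype=bool)
    _draw_puncta(pun_mask, rng, scene.n_puncta)
    pun_mask &= ~fil_mask  # labels partition structure pixels exactly

    labels = np.zeros(scene.shape, dtype=np.uint8)
    labels[fil_mask] = 1 + scene.filament_class
    labels[pun_mask] = 1 + scene.puncta_class

    d1, d2 = scene.round_dilutions
    scale = scene.intensity_scale

    def _class_signal(class_idx: int, cumulative_d: float) -> float:
        sub = EpitopeClassSet(classes.g[class_idx : class_idx + 1], classes.K[class_idx : class_idx + 1])
        return accumulation_response(cumulative_d, sub)

    sig1 = np.zeros(scene.shape)
    sig2 = np.zeros(scene.shape)
    for mask, cls in ((fil_mask, scene.filament_class), (pun_mask, scene.puncta_class)):
        x1 = _class_signal(cls, d1)
        x12 = x1 if scene.secondary_only_round2 else _class_signal(cls, d1 + d2)
        sig1[mask] = x1 * scale
        sig2[mask] = (scene.fold_change * x1 + (x12 - x1)) * scale

    # Shared fiducials for the alignment channel.
    align = np.zeros(scene.shape)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(scene.n_fiducials):
        cy, cx = rng.uniform(5, h - 5), rng.uniform(5, w - 5)
        align += 3000.0 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 2.0**2))

    def _noisy(img):
        noisy = img + scene.noise_level * scale * rng.standard_normal(img.shape)
        return np.clip(noisy, 0.0, 65535.0)

    round1 = ImageRound(
        images={"signal": _noisy(sig1), "alignment": _noisy(align)},
        alignment_channel="alignment",
        round_index=1,
    )
    round2 = ImageRound(
        images={
            "signal": _noisy(_integer_shift(sig2, scene.shift)),
            "alignment": _noisy(_integer_shift(align, scene.shift)),
        },
        alignment_channel="alignment",
        round_index=2,
    )
    return SceneData(round1=round1, round2=round2, labels=labels, scene=scene, classes=classes)


def histogram_from_classes(
    classes: EpitopeClassSet,
    rel_half_width: float = 1e-3,
    pad_decades: float = 1.0,
) -> HistogramFit:
    """Construct the idealized histogram of a known class set.

    Each class occupies one narrow interval whose arithmetic midpoint equals
    its K exactly, so the discretized model curve coincides with the
    closed-form accumulation response.  Useful as a ground-truth fit for
    peak-analysis checks; synthetic — not the result of an inversion.
    """
    K, g = classes.K, classes.g
    points = [K[0] * 10.0**-pad_decades]
    lambdas = []
    for i, k in enumerate(K):
        a, b = k * (1 - rel_half_width), k * (1 + rel_half_width)
        if a <= points[-1]:
            raise ValueError("classes too close for the requested interval width")
        points.extend([a, b])
        lambdas.extend([0.0, float(g[i])])
    points.append(K[-1] * 10.0**pad_decades)
    lambdas.append(0.0)
    grid = AccessibilityGrid(np.array(points))
    fit = HistogramFit(
        grid=grid,
        lambdas=np.array(lambdas),
        objective_value=0.0,
        config=FitConfig(),
        provenance={"synthetic": "constructed from known classes"},
    )
    return fit
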