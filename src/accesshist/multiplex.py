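"""Computational multiplexing of repeated staining rounds.

The same fixed sample is stained repeatedly at increasing, histogram-derived
antibody concentrations, imaged between rounds, and the per-peak signals are
recovered as differences of aligned images.  Because secondary antibodies
are re-applied each round and also bind primaries from earlier rounds, the
earlier-round image is first scaled by a fold-change measured on a
secondary-only control.  This module covers rigid alignment via phase cross-
correlation on a dedicated alignment channel (e.g. a nuclear stain),
fold-change estimation, corrected difference images, color composites, and
16-bit TIFF / PNG round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.registration import phase_cross_correlation

__all__ = [
    "ImageRound",
    "MultiplexCorrection",
    "RegistrationResult",
    "AlignmentError",
    "register_rounds",
    "secondary_correction_factor",
    "correction_from_images",
    "difference_image",
    "DifferenceImage",
    "composite_image",
    "assign_structure_pixels",
    "read_image",
    "write_image",
]


@dataclass
class ImageRound:
    """Monochrome channel images of one staining round.

    ``images`` maps channel names to 2-D arrays (16-bit integer ranges or
    unit-scaled floats, all the same shape, non-negative);
    ``alignment_channel`` names the channel used for registration (all other
    channels are treated as signal).
    """

    images: dict
    alignment_channel: str
    round_index: int = 0
    acquisition: str = ""

    def __post_init__(self) -> None:
        if self.alignment_channel not in self.images:
            raise ValueError(f"alignment channel {self.alignment_channel!r} not among images")
        shapes = {name: np.asarray(img).shape for name, img in self.images.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"all channel images must share a shape, got {shapes}")
        self.images = {name: np.asarray(img, dtype=float) for name, img in self.images.items()}
        for name, img in self.images.items():
            if img.ndim != 2:
                raise ValueError(f"channel {name!r} must be 2-D monochrome")
            if np.any(img < 0):
                raise ValueError(f"channel {name!r} has negative pixel values")

    @property
    def shape(self) -> tuple:
        return next(iter(self.images.values())).shape

    def signal_channels(self):
        return {k: v for k, v in self.images.items() if k != self.alignment_channel}


@dataclass(frozen=True)
class MultiplexCorrection:
    """Secondary-antibody fold-change from the secondary-only control."""

    fold_change: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.fold_change) or self.fold_change < 0:
            raise ValueError("fold_change must be finite and non-negative")


class AlignmentError(RuntimeError):
    pass


@dataclass
class RegistrationResult:
    """Estimated shift and the aligned, cropped rounds."""

    shift: tuple  # subpixel estimate (dy, dx): round 2 is displaced by this
    applied_shift: tuple  # integer translation actually applied to round 2
    round1: ImageRound
    round2: ImageRound
    crop: tuple  # (slice, slice) into the original round-1 frame
    correlation: float

    @property
    def round2_displacement(self) -> tuple:
        """How far round 2 was displaced relative to round 1 (negated shift)."""
        return tuple(-s for s in self.applied_shift)


def _translate_and_crop(shape, shift):
    """Slices selecting the overlap of an image and its shifted copy."""
    h, w = shape
    dy, dx = shift
    ref = (slice(max(0, dy), min(h, h + dy)), slice(max(0, dx), min(w, w + dx)))
    mov = (slice(max(0, -dy), min(h, h - dy)), slice(max(0, -dx), min(w, w - dx)))
    return ref, mov


def register_rounds(
    round1: ImageRound,
    round2: ImageRound,
    upsample_factor: int = 20,
    min_correlation: float = 0.2,
) -> RegistrationResult:
    """Align round 2 onto round 1 using their alignment channels.

    The translation is estimated by phase cross-correlation with subpixel
    refinement, applied as the nearest-integer shift (avoiding resampling
    artifacts in later difference images), and every channel of both rounds
    is cropped to the common overlap.  A Pearson correlation of the aligned
    alignment channels below ``min_correlation`` raises
    :class:`AlignmentError`.
    """
    ref = round1.images[round1.alignment_channel]
    mov = round2.images[round2.alignment_channel]
    if ref.shape != mov.shape:
        raise ValueError("alignment channels must have equal shape")
    shift, _, _ = phase_cross_correlation(ref, mov, upsample_factor=upsample_factor)
    applied = (int(round(shift[0])), int(round(shift[1])))
    # phase_cross_correlation returns the shift that maps mov onto ref, i.e.
    # ref ≈ translate(mov, shift); round 2 was displaced by -shift.
    ref_sl, mov_sl = _translate_and_crop(ref.shape, applied)
    aligned_ref = ref[ref_sl]
    aligned_mov = mov[mov_sl]
    if aligned_ref.size == 0:
        raise AlignmentError("no overlap after applying the estimated shift")
    denom = aligned_ref.std() * aligned_mov.std()
    corr = 0.0 if denom == 0 else float(
        np.mean((aligned_ref - aligned_ref.mean()) * (aligned_mov - aligned_mov.mean())) / denom
    )
    if corr < min_correlation:
        raise AlignmentError(
            f"alignment failed: correlation {corr:.3f} below threshold {min_correlation:.3f}"
        )
    r1 = ImageRound(
        {k: v[ref_sl] for k, v in round1.images.items()},
        round1.alignment_channel,
        round1.round_index,
        round1.acquisition,
    )
    r2 = ImageRound(
        {k: v[mov_sl] for k, v in round2.images.items()},
        round2.alignment_channel,
        round2.round_index,
        round2.acquisition,
    )
    return RegistrationResult(
        shift=tuple(float(s) for s in shift),
        applied_shift=applied,
        round1=r1,
        round2=r2,
        crop=ref_sl,
        correlation=corr,
    )


def secondary_correction_factor(control_round1_mean: float, control_round2_mean: float) -> MultiplexCorrection:
    """Fold-change of the secondary-only control between rounds."""
    if control_round1_mean <= 0:
        raise ValueError("round-1 control mean must be positive")
    return MultiplexCorrection(fold_change=control_round2_mean / control_round1_mean)


def correction_from_images(img1: np.ndarray, img2: np.ndarray, mode: str = "foreground") -> MultiplexCorrection:
    """Fold-change from control images, over the whole frame or foreground.

    ``mode='foreground'`` restricts the means to pixels above the round-1
    Otsu threshold (approximating quantified-cell means);
    ``mode='whole'`` uses every pixel.
    """
    img1 = np.asarray(img1, dtype=float)
    img2 = np.asarray(img2, dtype=float)
    if img1.shape != img2.shape:
        raise ValueError("control images must share a shape")
    if mode == "foreground":
        from skimage.filters import threshold_otsu

        mask = img1 > threshold_otsu(img1)
        if not mask.any():
            raise ValueError("no foreground pixels above the Otsu threshold")
        return secondary_correction_factor(float(img1[mask].mean()), float(img2[mask].mean()))
    if mode == "whole":
        return secondary_correction_factor(float(img1.mean()), float(img2.mean()))
    raise ValueError("mode must be 'foreground' or 'whole'")


@dataclass
class DifferenceImage:
    """Pixel-wise round difference with its provenance."""

    data: np.ndarray
    fold_change: float
    rounds: tuple = (1, 2)


def difference_image(img1: np.ndarray, img2: np.ndarray, correction: MultiplexCorrection) -> DifferenceImage:
    """Corrected signal increase between rounds.

    diff = img2 - fold_change * img1, clipped at zero (negative bound-antibody
    signal is unphysical).
    """
    img1 = np.asarray(img1, dtype=float)
    img2 = np.asarray(img2, dtype=float)
    if img1.shape != img2.shape:
        raise ValueError("images must be aligned to the same shape")
    return DifferenceImage(
        data=np.clip(img2 - correction.fold_change * img1, 0.0, None),
        fold_change=correction.fold_change,
    )


def composite_image(
    channels,
    brightness: float = 1.0,
    binning: int = 1,
    clip: float = 1.0,
) -> np.ndarray:
    """Additive color composite of monochrome channels.

    ``channels`` is a sequence of ``(image, rgb_color)`` pairs; each pixel
    accumulates ``brightness * intensity * color``.  Optional k x k mean
    binning halves (etc.) the dimensions; values are clipped to ``[0, clip]``.
    """
    channels = list(channels)
    if not channels:
        raise ValueError("need at least one channel")
    shape = np.asarray(channels[0][0]).shape
    out = np.zeros((*shape, 3))
    for img, color in channels:
        img = np.asarray(img, dtype=float)
        if img.shape != shape:
            raise ValueError("all channel images must share a shape")
        out += brightness * img[..., None] * np.asarray(color, dtype=float)
    if binning > 1:
        h, w = (shape[0] // binning) * binning, (shape[1] // binning) * binning
        out = out[:h, :w].reshape(h // binning, binning, w // binning, binning, 3).mean(axis=(1, 3))
    return np.clip(out, 0.0, clip)


def assign_structure_pixels(round1_signal: np.ndarray, diff: DifferenceImage) -> np.ndarray:
    """Assign each pixel to the low-K peak (1) or the high-K peak (2).

    The round-1 image carries the low-K peak signal and the corrected
    difference image the high-K peak signal; each pixel goes to whichever is
    larger (the corrected round-1 value keeps both sides on the same
    secondary-antibody footing).
    """
    r1 = diff.fold_change * np.asarray(round1_signal, dtype=float)
    return np.where(r1 >= diff.data, 1, 2).astype(np.uint8)


def read_image(path: str | Path) -> np.ndarray:
    """Read a monochrome TIFF/PNG image as a float array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path), dtype=float)
    import imageio.v3 as iio

    return np.asarray(iio.imread(path), dtype=float)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a monochrome image; 16-bit for TIFF/PNG integer formats."""
    path = Path(path)
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 65535.0).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)
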