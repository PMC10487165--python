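"""Preprocessing between raw shots and CNN inputs.

Shot-to-shot drift in LED intensity is compensated by scaling each shot so
its mean brightness matches a per-wavelength reference: the scale factor is
alpha = mu_shot / mu_ref and pixels are divided by alpha.  Frames are then
resized to 64x64 by bilinear interpolation over the full frame (no
cropping), the RGB shot is split into its three planes, and channels are
assembled in canonical order with intensities rescaled to [0, 1].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .io import FULL_SCALE, ImageShot, MultispectralStack
from .wavelengths import WavelengthLabel

INPUT_SIZE = 64


@dataclass(frozen=True)
class NormalizationReference:
    """Per-wavelength reference mean intensities (16-bit scale)."""

    mu_ref: Mapping[WavelengthLabel, float]

    def __post_init__(self) -> None:
        for w, mu in self.mu_ref.items():
            if not mu > 0:
                raise ValueError(f"reference intensity for {w} must be positive")

    def __getitem__(self, w: WavelengthLabel) -> float:
        return self.mu_ref[w]


def compute_reference(shots: Iterable[ImageShot]) -> float:
    """Reference intensity for one wavelength: the mean of per-shot mean
    intensities (an estimate of the drift-free illumination level)."""
    means = [s.mean_intensity() for s in shots]
    if not means:
        raise ValueError("compute_reference needs at least one shot")
    return float(np.mean(means))


def compute_reference_table(stacks: Iterable[MultispectralStack]) -> NormalizationReference:
    by_wl: dict[WavelengthLabel, list[ImageShot]] = {}
    for stack in stacks:
        for w, shot in stack.shots.items():
            by_wl.setdefault(w, []).append(shot)
    return NormalizationReference({w: compute_reference(s) for w, s in by_wl.items()})


def normalize_shot(shot: ImageShot, mu_ref: float) -> ImageShot:
    """Divide pixels by alpha = mu_shot / mu_ref so the output mean equals
    mu_ref (up to clipping at the 16-bit ceiling)."""
    mu_shot = shot.mean_intensity()
    if mu_shot <= 0:
        raise ValueError("cannot normalize a zero-mean shot")
    alpha = mu_shot / mu_ref
    pixels = np.clip(np.asarray(shot.pixels, dtype=float) / alpha, 0, FULL_SCALE)
    return dataclasses.replace(shot, pixels=pixels)


def resize_to_input(pixels: np.ndarray | ImageShot, size: int = INPUT_SIZE) -> np.ndarray:
    """Resize a frame (or each plane of an RGB frame) to size x size by
    bilinear interpolation.  The 640x480 aspect ratio is deliberately not
    preserved; constant images stay constant."""
    if isinstance(pixels, ImageShot):
        pixels = pixels.pixels
    pixels = np.asarray(pixels, dtype=float)
    h, w = pixels.shape[-2:]
    if h < size or w < size:
        raise ValueError(f"frame {h}x{w} smaller than target {size}x{size}")
    out_shape = pixels.shape[:-2] + (size, size)
    return _sk_resize(pixels, out_shape, order=1, anti_aliasing=False,
                      preserve_range=True)


def split_rgb(shot: ImageShot | np.ndarray) -> list[np.ndarray]:
    """Split a 3-plane RGB shot into [R, G, B] single-plane images."""
    pixels = shot.pixels if isinstance(shot, ImageShot) else np.asarray(shot)
    if pixels.ndim != 3 or pixels.shape[0] != 3:
        raise ValueError("split_rgb expects a (3, H, W) RGB shot")
    return [pixels[0], pixels[1], pixels[2]]


@dataclass
class InputStack:
    """CNN-ready channel stack for one (item, view).

    ``channels`` is (C, 64, 64) with intensities in [0, 1]; ``channel_map``
    lists (wavelength, plane) per channel, where plane is 'R'/'G'/'B' for the
    RGB shot and '' for narrow-band channels.
    """

    channels: np.ndarray
    channel_map: tuple[tuple[WavelengthLabel, str], ...]
    item_id: int
    view_index: int
    class_index: int | None = None
    calorie_kcal: float | None = None

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def image_count(self) -> int:
        """Number of camera shots represented; the three RGB planes come
        from a single shot and count as one image."""
        return len({w for w, _ in self.channel_map})


def assemble_input(stack: MultispectralStack,
                   selected: Iterable[WavelengthLabel],
                   *, reference: NormalizationReference | None = None,
                   size: int = INPUT_SIZE,
                   class_index: int | None = None,
                   calorie_kcal: float | None = None) -> InputStack:
    """Assemble the selected wavelengths of a stack into a CNN input.

    Channels are ordered with the RGB planes first (R, G, B), then the
    narrow-band channels by ascending wavelength; the ordering is
    deterministic for a given selection.
    """
    selected = sorted(set(selected))
    channels: list[np.ndarray] = []
    channel_map: list[tuple[WavelengthLabel, str]] = []
    for w in selected:
        if w not in stack:
            raise ValueError(f"stack (item {stack.item_id}, view {stack.view_index}) "
                             f"is missing wavelength {w}")
        shot = stack[w]
        if reference is not None:
            shot = normalize_shot(shot, reference[w])
        if w.is_rgb:
            for plane_name, plane in zip("RGB", split_rgb(shot)):
                channels.append(resize_to_input(plane, size))
                channel_map.append((w, plane_name))
        else:
            channels.append(resize_to_input(shot.pixels, size))
            channel_map.append((w, ""))
    arr = np.stack(channels).astype(np.float32) / FULL_SCALE
    return InputStack(channels=arr, channel_map=tuple(channel_map),
                      item_id=stack.item_id, view_index=stack.view_index,
                      class_index=class_index, calorie_kcal=calorie_kcal)


MIN_CALORIE_KCAL = 5.0


def replace_zero_calories(labels: Sequence[float] | np.ndarray,
                          minimum: float = MIN_CALORIE_KCAL) -> np.ndarray:
    """Replace exact-zero caloric labels by the nutrition-table minimum.

    A printed zero means "below the table's minimum", not a true zero, and a
    zero ground truth would make the relative-error loss undefined.
    """
    labels = np.asarray(labels, dtype=float)
    if (labels < 0).any():
        raise ValueError("caloric labels must be non-negative")
    out = labels.copy()
    out[out == 0.0] = minimum
    return out
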