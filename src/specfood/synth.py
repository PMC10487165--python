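"""Synthetic multispectral food datasets.

The generator emulates the statistical structure a multispectral acquisition
rig produces, so every downstream stage (feasibility statistics, CNN
training, wavelength selection) can be exercised without the physical
dataset:

* one item per food class, photographed from ``n_views`` rotation angles,
  with 19 narrow-band shots plus one RGB shot per view;
* per-class reflectance spectra; reflectance in the NIR band is coupled to a
  latent composition (water/sugar/fat), so caloric content is readable from
  NIR brightness but not from visible channels;
* *confusable pairs*: two classes with identical silhouette, texture and
  reflectance everywhere except one designated NIR channel, where they
  differ by exactly ``nir_delta`` — visually identical foods with different
  caloric content;
* shot-to-shot multiplicative illumination jitter (log-normal) and additive
  Gaussian sensor noise on the 16-bit scale.

Everything is deterministic given the spec seed; each shot derives its own
random stream from (seed, item, view, wavelength).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .io import (FULL_SCALE, ImageShot, Manifest, MANIFEST_COLUMNS,
                 MultispectralStack, write_manifest, write_shot)
from .wavelengths import (ALL_LABELS, NARROW_BAND, RGB, Band,
                          WavelengthLabel, wl)

SHAPES = ("disk", "square", "annulus", "blob")

#: Atwater-style energy densities, kcal per gram of ingredient.
KCAL_PER_G_SUGAR = 4.0
KCAL_PER_G_FAT = 9.0


@dataclass(frozen=True)
class ConfusablePair:
    """Two classes indistinguishable under visible light, separated only at
    one designated NIR wavelength by a reflectance gap of ``nir_delta``."""

    class_a: int
    class_b: int
    nir_delta: float = 0.3
    nir_wavelength: WavelengthLabel = wl(890)

    def __post_init__(self) -> None:
        if not self.nir_delta > 0:
            raise ValueError("nir_delta must be positive")
        if self.nir_wavelength.band is not Band.NIR:
            raise ValueError("designated separating channel must be NIR")
        if self.class_a == self.class_b:
            raise ValueError("a confusable pair needs two distinct classes")


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic dataset."""

    n_classes: int = 6
    n_views: int = 8
    image_size: tuple[int, int] = (72, 96)
    confusable_pairs: tuple[ConfusablePair, ...] = (
        ConfusablePair(0, 1), ConfusablePair(2, 3),
    )
    illumination_jitter_sigma: float = 0.05
    sensor_noise_sigma: float = 200.0
    texture_amp: float = 0.3
    #: 1.0 couples NIR reflectance to caloric density, 0.0 decouples it.
    nir_coupling: float = 1.0
    #: mean/sd of per-item served weight, grams.
    weight_mean_g: float = 141.0
    weight_sd_g: float = 20.0
    background_level: float = 300.0
    val_view_period: int = 4  # every k-th view held out for validation
    seed: int = 0

    def __post_init__(self) -> None:
        pairs = tuple(ConfusablePair(*p) if not isinstance(p, ConfusablePair) else p
                      for p in self.confusable_pairs)
        self.confusable_pairs = pairs
        if self.n_views < 1:
            raise ValueError("need at least one view")
        if self.illumination_jitter_sigma < 0 or self.sensor_noise_sigma < 0:
            raise ValueError("noise scales must be non-negative")
        paired = [c for p in pairs for c in (p.class_a, p.class_b)]
        if len(set(paired)) != len(paired):
            raise ValueError("a class may appear in at most one confusable pair")
        if self.n_classes < 2 * len(pairs) or (paired and max(paired) >= self.n_classes):
            raise ValueError("confusable pair list infeasible for n_classes")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["image_size"] = list(self.image_size)
        d["confusable_pairs"] = [
            {"class_a": p.class_a, "class_b": p.class_b, "nir_delta": p.nir_delta,
             "nir_wavelength": p.nir_wavelength.name}
            for p in self.confusable_pairs
        ]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorSpec":
        d = yaml.safe_load(Path(path).read_text())
        d["image_size"] = tuple(d["image_size"])
        d["confusable_pairs"] = tuple(
            ConfusablePair(p["class_a"], p["class_b"], p["nir_delta"],
                           wl(p["nir_wavelength"]))
            for p in d.get("confusable_pairs", ())
        )
        return cls(**d)


@dataclass
class ClassSpectrum:
    """Latent description of one food class."""

    class_index: int
    reflectance: dict[WavelengthLabel, float | tuple[float, float, float]]
    composition: tuple[float, float, float]  # (water, sugar, fat) mass fractions
    shape_id: str
    texture_scale: float
    texture_phases: tuple[float, float] = (0.0, 0.0)
    blob_phase: float = 0.0
    weight_g: float = 141.0

    def __post_init__(self) -> None:
        w, s, f = self.composition
        if min(w, s, f) < 0 or max(w, s, f) > 1 or w + s + f > 1 + 1e-9:
            raise ValueError("composition fractions must lie in [0,1] and sum <= 1")
        for lab, r in self.reflectance.items():
            vals = np.atleast_1d(np.asarray(r, dtype=float))
            if vals.min() < 0 or vals.max() > 1:
                raise ValueError(f"reflectance at {lab} outside [0,1]")
        if self.shape_id not in SHAPES:
            raise ValueError(f"unknown silhouette {self.shape_id!r}")

    @property
    def caloric_density(self) -> float:
        """kcal per gram implied by the composition."""
        _, sugar, fat = self.composition
        return KCAL_PER_G_SUGAR * sugar + KCAL_PER_G_FAT * fat


def calorie_from_composition(composition: Sequence[float], weight_g: float) -> float:
    """kcal = weight * (4 * sugar_frac + 9 * fat_frac); water contributes 0."""
    water, sugar, fat = composition
    if min(water, sugar, fat) < 0 or max(water, sugar, fat) > 1 or water + sugar + fat > 1 + 1e-9:
        raise ValueError("composition fractions must lie in [0,1] and sum <= 1")
    if not weight_g > 0:
        raise ValueError("weight must be positive")
    return weight_g * (KCAL_PER_G_SUGAR * sugar + KCAL_PER_G_FAT * fat)


def _smooth_curve(rng: np.random.Generator, nms: np.ndarray) -> np.ndarray:
    """Random smooth reflectance curve over wavelengths, values in [0.2, 0.8]."""
    knots_x = np.linspace(nms.min(), nms.max(), 5)
    knots_y = rng.uniform(0.2, 0.8, size=5)
    return np.interp(nms, knots_x, knots_y)


def build_class_spectra(spec: GeneratorSpec) -> list[ClassSpectrum]:
    """Draw per-class spectra, compositions and silhouettes; deterministic in
    ``spec.seed``.  Confusable-pair partners copy everything from their mate
    except the designated NIR reflectance (shifted by exactly ``nir_delta``)
    and the sugar fraction (so calories differ too)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    nms = np.array([w.nm for w in NARROW_BAND], dtype=float)
    spectra: list[ClassSpectrum] = []
    for c in range(spec.n_classes):
        water = rng.uniform(0.4, 0.85)
        sugar = rng.uniform(0.0, 0.8 * (1 - water))
        fat = rng.uniform(0.0, 0.8 * (1 - water - sugar))
        density = KCAL_PER_G_SUGAR * sugar + KCAL_PER_G_FAT * fat
        curve = _smooth_curve(rng, nms)
        reflectance: dict[WavelengthLabel, float | tuple] = {}
        for w, nm, r in zip(NARROW_BAND, nms, curve):
            if w.band is Band.NIR:
                coupled = 0.15 + 0.75 * min(density / KCAL_PER_G_FAT, 1.0)
                r = (1 - spec.nir_coupling) * r + spec.nir_coupling * coupled
                r += rng.normal(0.0, 0.02)
            reflectance[w] = float(np.clip(r, 0.02, 0.98))
        vis_of = lambda target: float(curve[np.argmin(np.abs(nms - target))])
        reflectance[RGB] = (vis_of(625), vis_of(560), vis_of(470))
        spectra.append(ClassSpectrum(
            class_index=c,
            reflectance=reflectance,
            composition=(water, sugar, fat),
            shape_id=SHAPES[c % len(SHAPES)],
            texture_scale=float(rng.uniform(8.0, 16.0)),
            texture_phases=(float(rng.uniform(0, 2 * np.pi)),
                            float(rng.uniform(0, 2 * np.pi))),
            blob_phase=float(rng.uniform(0, 2 * np.pi)),
            weight_g=float(np.clip(rng.normal(spec.weight_mean_g, spec.weight_sd_g),
                                   30.0, 400.0)),
        ))
    for pair in spec.confusable_pairs:
        a = spectra[pair.class_a]
        water, sugar, fat = a.composition
        # shift the sugar fraction by a fixed amount tied to nir_delta so the
        # pair's calories differ by a guaranteed margin; make room by drying
        # the item (less water) when sugar has no headroom
        shift = 0.8 * pair.nir_delta
        if sugar + shift + water + fat <= 1:
            sugar_b, water_b, sign = sugar + shift, water, 1.0
        elif sugar - shift >= 0:
            sugar_b, water_b, sign = sugar - shift, water, -1.0
        else:
            sugar_b, sign = sugar + shift, 1.0
            water_b = max(0.0, 1.0 - fat - sugar_b)
        refl_b = dict(a.reflectance)
        r_a = refl_b[pair.nir_wavelength]
        r_b = r_a + sign * pair.nir_delta
        if not 0.0 <= r_b <= 1.0:
            r_b = r_a - sign * pair.nir_delta
        if not 0.0 <= r_b <= 1.0:
            raise ValueError(f"cannot place nir_delta={pair.nir_delta} around "
                             f"reflectance {r_a:.2f} at {pair.nir_wavelength}")
        refl_b[pair.nir_wavelength] = float(r_b)
        spectra[pair.class_b] = dataclasses.replace(
            a, class_index=pair.class_b, reflectance=refl_b,
            composition=(water_b, sugar_b, fat),
        )
    return spectra


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _silhouette_and_texture(cs: ClassSpectrum, view_index: int,
                            spec: GeneratorSpec) -> tuple[np.ndarray, np.ndarray]:
    """Boolean food mask and multiplicative texture field for one view.

    The silhouette and texture are defined in object coordinates and the view
    rotates those coordinates, so in-mask content is rotation-covariant: all
    views of a class share the same brightness distribution up to sampling.
    """
    h, w_ = spec.image_size
    theta = np.deg2rad(view_index * 360.0 / spec.n_views)
    yy, xx = np.mgrid[0:h, 0:w_].astype(float)
    x = xx - (w_ - 1) / 2
    y = yy - (h - 1) / 2
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    radius = 0.35 * min(h, w_)
    r = np.hypot(xr, yr)
    if cs.shape_id == "disk":
        mask = r <= radius
    elif cs.shape_id == "square":
        mask = np.maximum(np.abs(xr), np.abs(yr)) <= 0.8 * radius
    elif cs.shape_id == "annulus":
        mask = (r >= 0.45 * radius) & (r <= radius)
    else:  # blob
        phi = np.arctan2(yr, xr)
        mask = r <= radius * (0.8 + 0.2 * np.cos(3 * phi + cs.blob_phase))
    p1, p2 = cs.texture_phases
    f = (np.sin(2 * np.pi * xr / cs.texture_scale + p1)
         * np.sin(2 * np.pi * yr / cs.texture_scale + p2))
    texture = 1.0 + spec.texture_amp * f
    return mask, texture


def _shot_rng(spec: GeneratorSpec, item_id: int, view_index: int,
              wavelength: WavelengthLabel) -> np.random.Generator:
    code = -1 if wavelength.is_rgb else wavelength.nm
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed, 7, item_id, view_index, code + 2]))


def render_shot(cs: ClassSpectrum, view_index: int, wavelength: WavelengthLabel,
                spec: GeneratorSpec, *, camera_index: int = 0) -> ImageShot:
    """Render one frame: silhouette filled with reflectance x jitter x
    texture on the 16-bit scale, dark background, additive sensor noise."""
    rng = _shot_rng(spec, cs.class_index, view_index, wavelength)
    mask, texture = _silhouette_and_texture(cs, view_index, spec)
    jitter = float(np.exp(rng.normal(0.0, spec.illumination_jitter_sigma))) \
        if spec.illumination_jitter_sigma > 0 else 1.0
    refl = cs.reflectance[wavelength]
    planes = np.atleast_1d(np.asarray(refl, dtype=float))
    out = np.empty((len(planes),) + spec.image_size, dtype=float)
    for i, r in enumerate(planes):
        # the whole frame scales with the LED intensity, background included,
        # so mean-normalization can cancel the jitter exactly
        img = jitter * np.where(mask, r * FULL_SCALE * texture,
                                spec.background_level)
        if spec.sensor_noise_sigma > 0:
            img = img + rng.normal(0.0, spec.sensor_noise_sigma, size=img.shape)
        out[i] = img
    out = np.clip(out, 0, FULL_SCALE)
    pixels = out if wavelength.is_rgb else out[0]
    return ImageShot(item_id=cs.class_index, view_index=view_index,
                     camera_index=camera_index, wavelength=wavelength,
                     pixels=pixels, mask=mask)


def render_stack(cs: ClassSpectrum, view_index: int, spec: GeneratorSpec,
                 wavelengths: Sequence[WavelengthLabel] = ALL_LABELS) -> MultispectralStack:
    shots = {w: render_shot(cs, view_index, w, spec) for w in wavelengths}
    return MultispectralStack(item_id=cs.class_index, view_index=view_index,
                              shots=shots)


def split_tag(view_index: int, spec: GeneratorSpec) -> str:
    return "val" if (view_index + 1) % spec.val_view_period == 0 else "train"


def generate_stacks(spec: GeneratorSpec,
                    wavelengths: Sequence[WavelengthLabel] = ALL_LABELS,
                    ) -> tuple[list[MultispectralStack], pd.DataFrame]:
    """In-memory dataset: stacks plus a label table (one row per item/view
    with class index, weight, calorie and split tag)."""
    spectra = build_class_spectra(spec)
    stacks, rows = [], []
    for cs in spectra:
        calorie = calorie_from_composition(cs.composition, cs.weight_g)
        for v in range(spec.n_views):
            stacks.append(render_stack(cs, v, spec, wavelengths))
            rows.append((cs.class_index, v, cs.class_index, cs.weight_g,
                         calorie, split_tag(v, spec)))
    labels = pd.DataFrame(rows, columns=["item_id", "view_index", "class_index",
                                         "weight_g", "calorie_kcal", "split"])
    return stacks, labels


def generate_dataset(spec: GeneratorSpec, out_dir: str | Path) -> Manifest:
    """Render the full dataset to ``out_dir`` as 16-bit TIFFs plus a CSV
    manifest (written to ``out_dir/manifest.csv``); the generator spec is
    saved alongside as YAML."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spectra = build_class_spectra(spec)
    rows = []
    for cs in spectra:
        calorie = calorie_from_composition(cs.composition, cs.weight_g)
        for v in range(spec.n_views):
            rel_dir = Path(f"item{cs.class_index:03d}") / f"view{v:02d}"
            (out_dir / rel_dir).mkdir(parents=True, exist_ok=True)
            mask_rel = None
            for w in ALL_LABELS:
                shot = render_shot(cs, v, w, spec)
                rel = rel_dir / f"{w.name}.tif"
                write_shot(shot, out_dir / rel)
                if mask_rel is None:
                    mask_rel = rel_dir / "mask.tif"
                    tifffile.imwrite(str(out_dir / mask_rel),
                                     shot.mask.astype(np.uint16) * FULL_SCALE)
                rows.append((str(rel), str(mask_rel), cs.class_index,
                             cs.class_index, v, 0, w.name, cs.weight_g,
                             calorie, split_tag(v, spec)))
    df = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    manifest = Manifest(rows=df, root=out_dir)
    write_manifest(manifest, out_dir / "manifest.csv")
    spec.to_yaml(out_dir / "generator.yaml")
    return manifest
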