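"""Core domain containers and file I/O: the food table, image shots,
multispectral stacks and dataset manifests.

Shots are stored one file per (item, view, wavelength, camera) as lossless
16-bit TIFF — single-plane for narrow-band channels, three-plane for the RGB
shot.  A dataset is indexed by a CSV manifest whose paths are relative to the
manifest file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

from .wavelengths import WavelengthLabel, wl

FULL_SCALE = 65535  # 16-bit sensor range


# ---------------------------------------------------------------------------
# Food table (per-item weights and calories)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoodItem:
    """One food item: name, served weight and caloric content.

    ``calorie_kcal`` is ``None`` when the nutrition table gives no value
    ("N/a"); this is distinct from a printed 0.00, which is kept as 0.0.
    """

    item_id: int
    name: str
    weight_g: float
    calorie_kcal: float | None
    class_index: int

    def __post_init__(self) -> None:
        if not self.weight_g > 0:
            raise ValueError(f"{self.name!r}: weight must be positive, got {self.weight_g}")
        if self.calorie_kcal is not None and self.calorie_kcal < 0:
            raise ValueError(f"{self.name!r}: calorie must be non-negative")


@dataclass(frozen=True)
class FoodTableSummary:
    mean_weight_g: float
    std_weight_g: float
    mean_calorie_kcal: float
    std_calorie_kcal: float
    n_items: int
    n_missing_calorie: int


_MISSING_TOKENS = {"n/a", "na", "nan", ""}


def load_food_table(source: str | Path | None = None) -> list[FoodItem]:
    """Read a food table CSV (columns ``name, weight, calorie``).

    With no argument, loads the packaged 101-item table.  Calorie cells
    reading "N/a" are parsed as missing, never as zero.
    """
    if source is None:
        source = resources.files("specfood.data") / "food_table.csv"
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = {"name", "weight", "calorie"} - set(df.columns)
    if missing:
        raise ValueError(f"food table missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValueError("food table is empty")
    items: list[FoodItem] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            weight = float(row.weight)
            cal_text = str(row.calorie).strip()
            calorie = None if cal_text.lower() in _MISSING_TOKENS else float(cal_text)
        except ValueError as exc:
            raise ValueError(f"malformed food table row {i} ({row.name!r}): {exc}") from None
        items.append(FoodItem(item_id=i, name=str(row.name), weight_g=weight,
                              calorie_kcal=calorie, class_index=i))
    return items


def summarize_food_table(items: Iterable[FoodItem]) -> FoodTableSummary:
    """Mean and sample standard deviation (ddof=1) of weights and calories.

    Weights are summarized over all items; calories only over items with a
    value present.
    """
    items = list(items)
    weights = np.array([it.weight_g for it in items], dtype=float)
    calories = np.array([it.calorie_kcal for it in items
                         if it.calorie_kcal is not None], dtype=float)
    if len(weights) < 2 or len(calories) < 2:
        raise ValueError("need at least 2 usable values per column to summarize")
    return FoodTableSummary(
        mean_weight_g=float(weights.mean()),
        std_weight_g=float(weights.std(ddof=1)),
        mean_calorie_kcal=float(calories.mean()),
        std_calorie_kcal=float(calories.std(ddof=1)),
        n_items=len(items),
        n_missing_calorie=len(items) - len(calories),
    )


# ---------------------------------------------------------------------------
# Image shots and stacks
# ---------------------------------------------------------------------------

@dataclass
class ImageShot:
    """One captured frame under one light source.

    ``pixels`` is an (H, W) float/int array for narrow-band shots or
    (3, H, W) for the RGB shot; intensities live on the 16-bit scale
    [0, 65535].  ``mask`` is an optional (H, W) boolean food mask.
    """

    item_id: int
    view_index: int
    camera_index: int
    wavelength: WavelengthLabel
    pixels: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if self.wavelength.is_rgb:
            if px.ndim != 3 or px.shape[0] != 3:
                raise ValueError("RGB shot requires a (3, H, W) pixel array")
        elif px.ndim != 2:
            raise ValueError("narrow-band shot requires a (H, W) pixel array")
        if px.min() < 0 or px.max() > FULL_SCALE:
            raise ValueError("pixel intensities must lie in the 16-bit range [0, 65535]")
        self.pixels = px
        if self.mask is not None:
            mask = np.asarray(self.mask).astype(bool)
            if mask.shape != self.shape:
                raise ValueError(f"mask shape {mask.shape} != image shape {self.shape}")
            self.mask = mask

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[-2:]

    def mean_intensity(self) -> float:
        return float(np.asarray(self.pixels, dtype=float).mean())


@dataclass
class MultispectralStack:
    """All shots of one (item, view): the unit the CNN consumes."""

    item_id: int
    view_index: int
    shots: dict[WavelengthLabel, ImageShot] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {s.shape for s in self.shots.values()}
        if len(shapes) > 1:
            raise ValueError(f"shots disagree on image size: {shapes}")
        for s in self.shots.values():
            if (s.item_id, s.view_index) != (self.item_id, self.view_index):
                raise ValueError("stack members must share item and view identity")

    def __contains__(self, wavelength: WavelengthLabel) -> bool:
        return wavelength in self.shots

    def __getitem__(self, wavelength: WavelengthLabel) -> ImageShot:
        return self.shots[wavelength]


def write_shot(shot: ImageShot, path: str | Path) -> None:
    """Write a shot as 16-bit TIFF (planar for RGB). Lossless round-trip."""
    px = np.asarray(shot.pixels)
    data = np.clip(np.rint(px), 0, FULL_SCALE).astype(np.uint16)
    if data.ndim == 3:
        tifffile.imwrite(str(path), data, photometric="rgb", planarconfig="separate")
    else:
        tifffile.imwrite(str(path), data, photometric="minisblack")


def read_shot(path: str | Path, *, item_id: int = 0, view_index: int = 0,
              camera_index: int = 0,
              wavelength: WavelengthLabel | str | int = "RGB",
              mask: np.ndarray | None = None) -> ImageShot:
    """Read a 16-bit TIFF shot written by :func:`write_shot`."""
    try:
        data = tifffile.imread(str(path))
    except Exception as exc:
        raise ValueError(f"not a readable TIFF image: {path}: {exc}") from None
    if data.dtype != np.uint16:
        raise ValueError(f"{path}: expected 16-bit pixels, got dtype {data.dtype}")
    label = wavelength if isinstance(wavelength, WavelengthLabel) else wl(wavelength)
    if label.is_rgb and data.ndim == 3 and data.shape[-1] == 3:
        data = np.moveaxis(data, -1, 0)  # tolerate H,W,3 layout
    return ImageShot(item_id=item_id, view_index=view_index,
                     camera_index=camera_index, wavelength=label,
                     pixels=data, mask=mask)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = (
    "path", "mask_path", "item_id", "class_index", "view_index",
    "camera_index", "wavelength", "weight_g", "calorie_kcal", "split",
)


@dataclass
class Manifest:
    """Index of a dataset on disk; ``rows`` is a DataFrame with
    :data:`MANIFEST_COLUMNS`, paths relative to ``root``."""

    rows: pd.DataFrame
    root: Path

    def __post_init__(self) -> None:
        missing = set(MANIFEST_COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        key = ["item_id", "view_index", "wavelength", "camera_index"]
        dup = self.rows.duplicated(subset=key)
        if dup.any():
            bad = self.rows.loc[dup, key].iloc[0].tolist()
            raise ValueError(f"duplicate manifest entry for (item, view, wavelength, camera) = {bad}")

    def __len__(self) -> int:
        return len(self.rows)

    def validate_files(self) -> None:
        for col in ("path", "mask_path"):
            for p in self.rows[col].dropna():
                if p and not (self.root / p).exists():
                    raise FileNotFoundError(f"manifest references missing file: {self.root / p}")

    def subset(self, *, split: str | None = None,
               wavelengths: Iterable[WavelengthLabel] | None = None) -> "Manifest":
        df = self.rows
        if split is not None:
            df = df[df["split"] == split]
        if wavelengths is not None:
            names = {w.name for w in wavelengths}
            df = df[df["wavelength"].isin(names)]
        return Manifest(rows=df.reset_index(drop=True), root=self.root)

    def load_shot(self, row: Mapping) -> ImageShot:
        mask = None
        mp = row["mask_path"]
        if isinstance(mp, str) and mp:
            mask = tifffile.imread(str(self.root / mp)).astype(bool)
        return read_shot(self.root / row["path"], item_id=int(row["item_id"]),
                         view_index=int(row["view_index"]),
                         camera_index=int(row["camera_index"]),
                         wavelength=str(row["wavelength"]), mask=mask)

    def load_stacks(self, *, split: str | None = None) -> list[MultispectralStack]:
        """Group shots by (item, view) into stacks, in manifest order."""
        df = self.subset(split=split).rows
        stacks: list[MultispectralStack] = []
        for (item, view), grp in df.groupby(["item_id", "view_index"], sort=True):
            shots = {wl(r["wavelength"]): self.load_shot(r) for _, r in grp.iterrows()}
            stacks.append(MultispectralStack(item_id=int(item), view_index=int(view),
                                             shots=shots))
        return stacks

    def labels(self, *, split: str | None = None) -> pd.DataFrame:
        """One row per (item, view) with class_index, weight and calorie."""
        df = self.subset(split=split).rows
        return (df.groupby(["item_id", "view_index"], sort=True)
                  .agg(class_index=("class_index", "first"),
                       weight_g=("weight_g", "first"),
                       calorie_kcal=("calorie_kcal", "first"),
                       split=("split", "first"))
                  .reset_index())


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    manifest.rows.loc[:, list(MANIFEST_COLUMNS)].to_csv(path, index=False)


def read_manifest(path: str | Path, *, check_files: bool = True) -> Manifest:
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False,
                     dtype={"path": str, "mask_path": str, "wavelength": str, "split": str})
    df["calorie_kcal"] = pd.to_numeric(df["calorie_kcal"], errors="coerce")
    man = Manifest(rows=df, root=path.parent)
    if check_files:
        man.validate_files()
    return man
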