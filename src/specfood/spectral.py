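"""Feasibility statistics for UV/NIR imaging of food.

Given masked brightness histograms of two food items photographed under the
same light source, the Bhattacharyya distance

    D_B(p, q) = -log sum_y sqrt(p(y) q(y))

measures how distinguishable the items are at that wavelength.  The module
computes pairwise distance tables across wavelengths, the cumulative ratio
F_C of pairs that are confusable under visible light yet separable in the
UV/NIR bands, absolute relative caloric differences, and per-wavelength
Pearson correlations between image distance and caloric difference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import FULL_SCALE, ImageShot
from .wavelengths import (Band, NON_VISIBLE_LABELS, VIS_LABELS,
                          WavelengthLabel, wl)

DEFAULT_BINS = 256


@dataclass(frozen=True)
class BrightnessHistogram:
    """Probability vector over brightness bins (in-mask pixels only)."""

    probs: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("histogram must be a probability vector (sum 1, non-negative)")
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))


def masked_histogram(shot: ImageShot | np.ndarray, bins: int = DEFAULT_BINS,
                     mask: np.ndarray | None = None) -> BrightnessHistogram:
    """Brightness histogram of the food region of a shot.

    Bins are equal-width over the full 16-bit range so histograms from
    different shots share a common binning.  RGB shots pool all three planes.
    """
    if isinstance(shot, ImageShot):
        pixels, mask = shot.pixels, shot.mask if mask is None else mask
    else:
        pixels = np.asarray(shot)
    if mask is None:
        raise ValueError("masked_histogram requires a food mask")
    mask = np.asarray(mask, dtype=bool)
    values = pixels[..., mask] if pixels.ndim == 3 else pixels[mask]
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("mask selects no pixels")
    counts, edges = np.histogram(values, bins=bins, range=(0.0, FULL_SCALE + 1.0))
    return BrightnessHistogram(probs=counts / counts.sum(), bin_edges=edges)


def pooled_histogram(shots: Iterable[ImageShot], bins: int = DEFAULT_BINS) -> BrightnessHistogram:
    """Histogram pooled over several shots (e.g. all views of one item)."""
    shots = list(shots)
    if not shots:
        raise ValueError("no shots to pool")
    total = None
    edges = None
    for s in shots:
        h = masked_histogram(s, bins=bins)
        total = h.probs if total is None else total + h.probs
        edges = h.bin_edges
    return BrightnessHistogram(probs=total / total.sum(), bin_edges=edges)


def bhattacharyya_distance(p: BrightnessHistogram, q: BrightnessHistogram,
                           *, clamp: bool = False) -> float:
    """Bhattacharyya distance between two brightness histograms.

    Returns ``-log`` (natural log) of the Bhattacharyya coefficient
    ``sum sqrt(p q)``; 0 iff the histograms match bin-wise and ``inf`` for
    disjoint supports.  With ``clamp=True`` returns ``1 - coefficient``
    instead, a variant bounded to [0, 1].
    """
    if p.probs.shape != q.probs.shape or not np.array_equal(p.bin_edges, q.bin_edges):
        raise ValueError("histograms must share an identical binning")
    coeff = float(np.sqrt(p.probs * q.probs).sum())
    coeff = min(coeff, 1.0)  # guard rounding above 1
    if clamp:
        return 1.0 - coeff
    return float("inf") if coeff == 0.0 else -float(np.log(coeff))


# ---------------------------------------------------------------------------
# Pairwise tables over items and wavelengths
# ---------------------------------------------------------------------------

def pairwise_distance_table(
    histograms: Mapping[int, Mapping[WavelengthLabel, BrightnessHistogram]],
    *, clamp: bool = False,
) -> pd.DataFrame:
    """All-pairs Bhattacharyya distances.

    ``histograms`` maps item_id -> wavelength -> representative histogram
    (one per item, typically pooled over views).  Returns a long-format
    DataFrame with columns ``item_m, item_n, wavelength, d_b`` over unordered
    distinct pairs m < n.
    """
    items = sorted(histograms)
    rows = []
    for m, n in itertools.combinations(items, 2):
        common = sorted(set(histograms[m]) & set(histograms[n]))
        for w in common:
            d = bhattacharyya_distance(histograms[m][w], histograms[n][w], clamp=clamp)
            rows.append((m, n, w.name, d))
    return pd.DataFrame(rows, columns=["item_m", "item_n", "wavelength", "d_b"])


def band_representative_distance(table: pd.DataFrame, pair: tuple[int, int],
                                 band_set: Sequence[WavelengthLabel]) -> float:
    """Representative distance of a band for one pair: the maximum D_B over
    the band's wavelengths."""
    m, n = sorted(pair)
    names = [w.name for w in band_set]
    sub = table[(table.item_m == m) & (table.item_n == n) & table.wavelength.isin(names)]
    if len(sub) < len(names):
        have = set(sub.wavelength)
        missing = [nm for nm in names if nm not in have]
        raise ValueError(f"pair ({m},{n}) missing wavelengths {missing}")
    return float(sub.d_b.max())


def band_maxima(table: pd.DataFrame,
                vis: Sequence[WavelengthLabel] = VIS_LABELS,
                non_vis: Sequence[WavelengthLabel] = NON_VISIBLE_LABELS) -> pd.DataFrame:
    """Per-pair representative distances D_B(V) and D_B(NV)."""
    rows = []
    for (m, n), _ in table.groupby(["item_m", "item_n"]):
        rows.append((m, n,
                     band_representative_distance(table, (m, n), vis),
                     band_representative_distance(table, (m, n), non_vis)))
    return pd.DataFrame(rows, columns=["item_m", "item_n", "d_b_v", "d_b_nv"])


def cumulative_ratio(maxima: pd.DataFrame, t_v: float, t_nv: float) -> float:
    """F_C(T_V, T_NV): of the pairs confusable under visible light
    (D_B(V) < T_V), the fraction that are separable in the non-visible bands
    (D_B(NV) > T_NV)."""
    confusable = maxima[maxima.d_b_v < t_v]
    if len(confusable) == 0:
        raise ValueError(f"no pairs with D_B(V) < {t_v}: F_C undefined")
    return float((confusable.d_b_nv > t_nv).mean())


def cumulative_ratio_grid(maxima: pd.DataFrame, t_v_list: Sequence[float],
                          t_nv_list: Sequence[float]) -> pd.DataFrame:
    """F_C over a grid of thresholds; undefined cells are NaN (flagged, not 0)."""
    grid = np.full((len(t_v_list), len(t_nv_list)), np.nan)
    for i, tv in enumerate(t_v_list):
        for j, tnv in enumerate(t_nv_list):
            try:
                grid[i, j] = cumulative_ratio(maxima, tv, tnv)
            except ValueError:
                pass
    return pd.DataFrame(grid, index=pd.Index(t_v_list, name="t_v"),
                        columns=pd.Index(t_nv_list, name="t_nv"))


# ---------------------------------------------------------------------------
# Caloric differences and wavelength correlations
# ---------------------------------------------------------------------------

def caloric_difference(c_n: float, c_m: float) -> float:
    """Absolute relative caloric difference |c_n - c_m| / (c_n + c_m)."""
    if c_n < 0 or c_m < 0:
        raise ValueError("calories must be non-negative")
    if c_n + c_m == 0:
        raise ValueError("caloric difference undefined for two zero-calorie items")
    return abs(c_n - c_m) / (c_n + c_m)


def wavelength_correlation(d_b: Sequence[float], d_c: Sequence[float]) -> float:
    """Pearson correlation, over item pairs, between image distance at one
    wavelength and caloric difference."""
    d_b = np.asarray(d_b, dtype=float)
    d_c = np.asarray(d_c, dtype=float)
    if d_b.shape != d_c.shape or d_b.size < 3:
        raise ValueError("need >= 3 paired observations")
    if d_b.std() == 0 or d_c.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(stats.pearsonr(d_b, d_c).statistic)


def correlation_profile(table: pd.DataFrame, calories: Mapping[int, float],
                        *, min_pairs: int = 3) -> pd.DataFrame:
    """rho(lambda_k) for every wavelength in the distance table.

    Pairs involving an item without a caloric value are excluded.  Returns a
    DataFrame with columns ``wavelength, band, rho``.
    """
    rows = []
    for name, grp in table.groupby("wavelength"):
        label = wl(name)
        if label.is_rgb:
            continue
        ok = grp[grp.item_m.isin(calories) & grp.item_n.isin(calories)]
        ok = ok[np.isfinite(ok.d_b)]
        d_c = [caloric_difference(calories[m], calories[n])
               for m, n in zip(ok.item_m, ok.item_n)]
        if len(d_c) >= min_pairs:
            rows.append((name, label.band.value,
                         wavelength_correlation(ok.d_b.to_numpy(), d_c)))
    df = pd.DataFrame(rows, columns=["wavelength", "band", "rho"])
    return df.assign(_nm=[wl(n).nm for n in df.wavelength]).sort_values("_nm").drop(columns="_nm").reset_index(drop=True)


def compare_band_correlations(profile: pd.DataFrame) -> tuple[float, float, float]:
    """Band-mean correlations and a significance test for their difference.

    Returns ``(mean_V, mean_NV, p)`` where the means are plain averages of
    rho over the VIS band and over the UV+NIR bands, and ``p`` comes from a
    two-sided two-sample t-test on Fisher-z transformed correlations.
    """
    vis = profile.loc[profile.band == Band.VIS.value, "rho"].to_numpy(dtype=float)
    non_vis = profile.loc[profile.band.isin([Band.UV.value, Band.NIR.value]), "rho"].to_numpy(dtype=float)
    if len(vis) < 2 or len(non_vis) < 2:
        raise ValueError("need >= 2 wavelengths per band to compare")
    z_v, z_nv = np.arctanh(vis), np.arctanh(non_vis)
    if z_v.std(ddof=1) == 0 and z_nv.std(ddof=1) == 0:
        p = 1.0 if np.isclose(z_v.mean(), z_nv.mean()) else 0.0
    else:
        p = float(stats.ttest_ind(z_v, z_nv, equal_var=False).pvalue)
    return float(vis.mean()), float(non_vis.mean()), p
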