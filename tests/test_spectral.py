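import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import specfood as sf
from specfood.spectral import BrightnessHistogram

from conftest import make_shot


def hist(probs):
    probs = np.asarray(probs, dtype=float)
    edges = np.linspace(0, 65536, len(probs) + 1)
    return BrightnessHistogram(probs=probs, bin_edges=edges)


# ---------------------------------------------------------------------------
# masked histograms
# ---------------------------------------------------------------------------

def test_constant_region_single_bin():
    px = np.full((10, 10), 30000.0)
    mask = np.zeros((10, 10), bool)
    mask[:5] = True
    h = sf.masked_histogram(make_shot(px, wavelength=890, mask=mask), bins=16)
    assert h.probs.max() == 1.0 and h.probs.sum() == 1.0


def test_histogram_ignores_out_of_mask_pixels():
    px = np.where(np.arange(100).reshape(10, 10) < 50, 1000.0, 60000.0)
    mask = np.arange(100).reshape(10, 10) < 50
    h = sf.masked_histogram(make_shot(px, wavelength=890, mask=mask), bins=4)
    assert h.probs[0] == 1.0  # the out-of-mask high value never appears
    assert h.probs[-1] == 0.0


def test_uniform_pixels_fill_bins_uniformly():
    rng = np.random.default_rng(11)
    px = rng.integers(0, 65536, size=(256, 256)).astype(float)
    h = sf.masked_histogram(px, bins=256, mask=np.ones((256, 256), bool))
    counts = h.probs * px.size
    chi2 = ((counts - px.size / 256) ** 2 / (px.size / 256)).sum()
    assert chi2 < stats.chi2.ppf(0.999, df=255)


def test_empty_mask_errors():
    with pytest.raises(ValueError):
        sf.masked_histogram(np.zeros((4, 4)), bins=4, mask=np.zeros((4, 4), bool))


# ---------------------------------------------------------------------------
# Bhattacharyya distance
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p,q,expected", [
    ([1.0, 0.0], [0.5, 0.5], 0.34657),           # -ln sqrt(0.5)
    ([0.25, 0.75], [0.75, 0.25], 0.14384),       # -ln 2 sqrt(0.1875)
])
def test_worked_distances(p, q, expected):
    assert sf.bhattacharyya_distance(hist(p), hist(q)) == pytest.approx(expected, abs=1e-5)


def test_identical_histograms_have_zero_distance():
    h = hist([0.2, 0.3, 0.5])
    assert sf.bhattacharyya_distance(h, h) == 0.0


def test_disjoint_supports_are_infinite_unless_clamped():
    p, q = hist([1.0, 0.0]), hist([0.0, 1.0])
    assert math.isinf(sf.bhattacharyya_distance(p, q))
    assert sf.bhattacharyya_distance(p, q, clamp=True) == 1.0


def test_binning_mismatch_rejected():
    with pytest.raises(ValueError):
        sf.bhattacharyya_distance(hist([1.0]), hist([0.5, 0.5]))


@settings(deadline=None, max_examples=40)
@given(st.integers(0, 2 ** 31 - 1), st.integers(2, 12))
def test_distance_oracle_and_properties(seed, nbins):
    """Matches the direct -log sum sqrt(pq) computation; symmetric,
    non-negative, invariant to a common bin permutation."""
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.ones(nbins))
    q = rng.dirichlet(np.ones(nbins))
    d = sf.bhattacharyya_distance(hist(p), hist(q))
    brute = -math.log(sum(math.sqrt(pi * qi) for pi, qi in zip(p, q)))
    assert d == pytest.approx(brute, abs=1e-9)
    assert d >= 0
    assert d == sf.bhattacharyya_distance(hist(q), hist(p))
    perm = rng.permutation(nbins)
    assert sf.bhattacharyya_distance(hist(p[perm]), hist(q[perm])) == pytest.approx(d, abs=1e-9)


# ---------------------------------------------------------------------------
# band maxima and F_C
# ---------------------------------------------------------------------------

def _table(values):
    import pandas as pd
    rows = [(m, n, w, v) for (m, n, w), v in values.items()]
    return pd.DataFrame(rows, columns=["item_m", "item_n", "wavelength", "d_b"])


def test_band_representative_is_the_maximum():
    tab = _table({(0, 1, "430"): 0.2, (0, 1, "470"): 0.5, (0, 1, "490"): 0.1})
    band = [sf.wl(430), sf.wl(470), sf.wl(490)]
    assert sf.band_representative_distance(tab, (0, 1), band) == 0.5
    assert sf.band_representative_distance(tab, (0, 1), [sf.wl(430)]) == 0.2
    with pytest.raises(ValueError, match="missing"):
        sf.band_representative_distance(tab, (0, 1), [sf.wl(430), sf.wl(510)])


def test_cumulative_ratio_worked_example():
    import pandas as pd
    maxima = pd.DataFrame({"item_m": [0, 0, 1], "item_n": [1, 2, 2],
                           "d_b_v": [0.1, 0.3, 0.5],
                           "d_b_nv": [0.6, 0.2, 0.9]})
    assert sf.cumulative_ratio(maxima, 0.4, 0.5) == pytest.approx(0.5)
    assert sf.cumulative_ratio(maxima, 0.4, 0.0) == 1.0
    with pytest.raises(ValueError):
        sf.cumulative_ratio(maxima, 0.05, 0.5)  # empty denominator


@settings(deadline=None, max_examples=30)
@given(st.integers(0, 2 ** 31 - 1), st.integers(4, 30))
def test_cumulative_ratio_oracle_and_monotonicity(seed, n_pairs):
    import pandas as pd
    rng = np.random.default_rng(seed)
    maxima = pd.DataFrame({"item_m": np.arange(n_pairs), "item_n": np.arange(n_pairs) + 100,
                           "d_b_v": rng.uniform(0, 1, n_pairs),
                           "d_b_nv": rng.uniform(0, 1, n_pairs)})
    t_v = float(rng.uniform(0.2, 1.0))
    prev = None
    for t_nv in (0.1, 0.3, 0.5, 0.7):
        denom = [i for i in range(n_pairs) if maxima.d_b_v[i] < t_v]
        if not denom:
            continue
        num = [i for i in denom if maxima.d_b_nv[i] > t_nv]
        fc = sf.cumulative_ratio(maxima, t_v, t_nv)
        assert fc == pytest.approx(len(num) / len(denom))
        assert 0.0 <= fc <= 1.0
        if prev is not None:
            assert fc <= prev + 1e-12  # non-increasing in T_NV
        prev = fc


def test_fc_grid_flags_undefined_cells():
    import pandas as pd
    maxima = pd.DataFrame({"item_m": [0], "item_n": [1],
                           "d_b_v": [0.5], "d_b_nv": [0.6]})
    grid = sf.cumulative_ratio_grid(maxima, [0.1, 0.9], [0.1])
    assert np.isnan(grid.loc[0.1, 0.1])
    assert grid.loc[0.9, 0.1] == 1.0


# ---------------------------------------------------------------------------
# caloric difference and correlations
# ---------------------------------------------------------------------------

def test_caloric_difference_examples():
    assert sf.caloric_difference(100.0, 100.0) == 0.0
    # coffee vs coffee with 10% sugar from the packaged table
    items = {it.name: it.calorie_kcal for it in sf.load_food_table()}
    d = sf.caloric_difference(items["coffee"], items["coffee with sugar (10%)"])
    assert d == pytest.approx(0.5004, abs=1e-4)
    assert sf.caloric_difference(50.0, 0.0) == 1.0
    with pytest.raises(ValueError):
        sf.caloric_difference(0.0, 0.0)


def test_wavelength_correlation_examples():
    assert sf.wavelength_correlation([0.1, 0.2, 0.3], [0.2, 0.4, 0.6]) == pytest.approx(1.0)
    assert sf.wavelength_correlation([0, 1, 2], [1, 3, 2]) == pytest.approx(0.5)
    assert sf.wavelength_correlation([0.1, 0.2, 0.3], [0.6, 0.4, 0.2]) == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        sf.wavelength_correlation([1.0, 1.0, 1.0], [0.2, 0.4, 0.6])


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2 ** 31 - 1))
def test_correlation_oracle(seed):
    """Matches cov/(sigma sigma) computed by hand on random pairs."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 40))
    a, b = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
    if a.std() == 0 or b.std() == 0:
        return
    brute = (np.mean(a * b) - a.mean() * b.mean()) / (a.std() * b.std())
    assert sf.wavelength_correlation(a, b) == pytest.approx(brute, abs=1e-9)


def test_band_comparison_identical_profiles():
    import pandas as pd
    prof = pd.DataFrame({"wavelength": ["430", "470", "890", "970"],
                         "band": ["VIS", "VIS", "NIR", "NIR"],
                         "rho": [0.5, 0.5, 0.5, 0.5]})
    mean_v, mean_nv, p = sf.compare_band_correlations(prof)
    assert mean_v == mean_nv == 0.5
    assert p == 1.0


def test_band_comparison_separated_profiles():
    import pandas as pd
    prof = pd.DataFrame({"wavelength": ["430", "470", "510", "890", "970", "385"],
                         "band": ["VIS", "VIS", "VIS", "NIR", "NIR", "UV"],
                         "rho": [0.9, 0.88, 0.92, 0.1, 0.12, 0.08]})
    mean_v, mean_nv, p = sf.compare_band_correlations(prof)
    assert mean_v == pytest.approx(0.9, abs=0.01)
    assert mean_nv == pytest.approx(0.1, abs=0.01)
    assert p < 0.01


def test_band_comparison_null_p_values_are_calibrated():
    """When both bands' correlations are drawn from one population the
    p-value is uniform: check across many simulated profiles."""
    import pandas as pd
    rng = np.random.default_rng(42)
    pvals = []
    for _ in range(60):
        rho = np.tanh(rng.normal(0.5, 0.2, size=19))
        bands = ["VIS"] * 9 + ["NIR"] * 8 + ["UV"] * 2
        prof = pd.DataFrame({"wavelength": [str(w) for w in range(19)],
                             "band": bands, "rho": rho})
        pvals.append(sf.compare_band_correlations(prof)[2])
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01
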