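import numpy as np
import pytest

import specfood as sf
from specfood.io import FULL_SCALE
from specfood.synth import build_class_spectra, render_shot, split_tag


@pytest.fixture(scope="module")
def spectra(default_spec):
    return build_class_spectra(default_spec)


def test_confusable_pairs_identical_in_visible(default_spec, spectra):
    """Pair partners match at every UV/VIS wavelength and in RGB, and differ
    by exactly nir_delta at the designated NIR channel only."""
    for pair in default_spec.confusable_pairs:
        a, b = spectra[pair.class_a], spectra[pair.class_b]
        for w in sf.NARROW_BAND:
            if w == pair.nir_wavelength:
                assert abs(a.reflectance[w] - b.reflectance[w]) == pytest.approx(
                    pair.nir_delta, abs=1e-12)
            else:
                assert a.reflectance[w] == b.reflectance[w]
        assert a.reflectance[sf.RGB] == b.reflectance[sf.RGB]
        assert a.shape_id == b.shape_id
        # the pair's compositions (hence calories) genuinely differ
        assert a.composition != b.composition


def test_spectra_deterministic_and_counted(default_spec):
    s1 = build_class_spectra(default_spec)
    s2 = build_class_spectra(default_spec)
    assert len(s1) == default_spec.n_classes
    for a, b in zip(s1, s2):
        assert a.reflectance == b.reflectance and a.composition == b.composition


def test_eight_classes_two_pairs_counts():
    spec = sf.GeneratorSpec(n_classes=8, confusable_pairs=(
        sf.ConfusablePair(0, 1), sf.ConfusablePair(4, 5)))
    spectra = build_class_spectra(spec)
    assert len(spectra) == 8
    paired = {0, 1, 4, 5}
    for c in paired - {1, 5}:
        assert spectra[c].reflectance[sf.RGB] == spectra[c + 1].reflectance[sf.RGB]


def test_infeasible_pair_lists_rejected():
    with pytest.raises(ValueError):
        sf.GeneratorSpec(n_classes=3, confusable_pairs=(
            sf.ConfusablePair(0, 1), sf.ConfusablePair(1, 2)))
    with pytest.raises(ValueError):
        sf.GeneratorSpec(n_classes=2, confusable_pairs=(sf.ConfusablePair(0, 5),))
    with pytest.raises(ValueError):
        sf.ConfusablePair(0, 1, nir_delta=-0.1)
    with pytest.raises(ValueError, match="NIR"):
        sf.ConfusablePair(0, 1, nir_wavelength=sf.wl(560))


@pytest.mark.parametrize("composition,weight,expected", [
    ((0.9, 0.1, 0.0), 100.0, 40.0),
    ((1.0, 0.0, 0.0), 57.0, 0.0),
    ((0.5, 0.2, 0.1), 150.0, 255.0),
])
def test_calorie_from_composition(composition, weight, expected):
    assert sf.calorie_from_composition(composition, weight) == pytest.approx(expected)


def test_calorie_from_composition_rejects_bad_fractions():
    with pytest.raises(ValueError):
        sf.calorie_from_composition((0.7, 0.5, 0.2), 100.0)  # sums past 1
    with pytest.raises(ValueError):
        sf.calorie_from_composition((-0.1, 0.5, 0.2), 100.0)
    with pytest.raises(ValueError):
        sf.calorie_from_composition((0.5, 0.2, 0.1), 0.0)


def test_noise_free_render_mean_tracks_reflectance():
    """With jitter, noise and texture off, the in-mask mean is reflectance
    times full scale."""
    spec = sf.GeneratorSpec(illumination_jitter_sigma=0.0, sensor_noise_sigma=0.0,
                            texture_amp=0.0, nir_coupling=0.0, seed=5)
    cs = build_class_spectra(spec)[0]
    w = sf.wl(890)
    shot = render_shot(cs, 0, w, spec)
    expected = cs.reflectance[w] * FULL_SCALE
    assert shot.pixels[shot.mask].mean() == pytest.approx(expected, rel=1e-6)
    # background stays near the floor level
    assert shot.pixels[~shot.mask].mean() == pytest.approx(spec.background_level, rel=1e-6)


def test_zero_reflectance_renders_background_dark():
    spec = sf.GeneratorSpec(illumination_jitter_sigma=0.0, sensor_noise_sigma=0.0,
                            texture_amp=0.0, seed=5)
    cs = build_class_spectra(spec)[0]
    cs.reflectance[sf.wl(385)] = 0.0
    shot = render_shot(cs, 0, sf.wl(385), spec)
    assert shot.pixels[shot.mask].mean() <= spec.background_level


def test_views_are_rotations_of_the_same_content(default_spec):
    """Silhouette and texture rotate with the view, so two views of one
    class at one wavelength share the in-mask brightness distribution up to
    noise and resampling."""
    spec = sf.GeneratorSpec(illumination_jitter_sigma=0.0, seed=7)
    cs = build_class_spectra(spec)[2]
    w = sf.wl(660)
    h0 = sf.masked_histogram(render_shot(cs, 0, w, spec), bins=32)
    h3 = sf.masked_histogram(render_shot(cs, 3, w, spec), bins=32)
    assert sf.bhattacharyya_distance(h0, h3) < 0.05


def test_render_deterministic_per_key(default_spec, spectra):
    a = render_shot(spectra[0], 1, sf.wl(890), default_spec)
    b = render_shot(spectra[0], 1, sf.wl(890), default_spec)
    assert np.array_equal(a.pixels, b.pixels)


def test_generate_dataset_layout(tmp_path, tiny_spec):
    manifest = sf.generate_dataset(tiny_spec, tmp_path / "ds")
    # K classes x V views x 20 wavelengths x 1 camera
    assert len(manifest) == tiny_spec.n_classes * tiny_spec.n_views * 20
    manifest.validate_files()
    again = sf.generate_dataset(tiny_spec, tmp_path / "ds2")
    assert manifest.rows.drop(columns=[]).equals(again.rows)
    # split tags hold out every k-th view
    tags = {v: split_tag(v, tiny_spec) for v in range(tiny_spec.n_views)}
    assert tags[tiny_spec.val_view_period - 1] == "val"


def test_confusable_pair_separable_only_in_nir(default_spec, default_dataset):
    """Generated pair shots: RGB histograms nearly coincide while the
    designated NIR channel carries a large Bhattacharyya distance."""
    stacks, _ = default_dataset
    pair = default_spec.confusable_pairs[0]
    by_item = {}
    for s in stacks:
        by_item.setdefault(s.item_id, []).append(s)
    def pooled(item, w):
        return sf.pooled_histogram([st[w] for st in by_item[item]], bins=64)
    d_nir = sf.bhattacharyya_distance(pooled(pair.class_a, pair.nir_wavelength),
                                      pooled(pair.class_b, pair.nir_wavelength))
    d_vis = max(sf.bhattacharyya_distance(pooled(pair.class_a, w),
                                          pooled(pair.class_b, w))
                for w in sf.VIS_LABELS)
    d_rgb = sf.bhattacharyya_distance(pooled(pair.class_a, sf.RGB),
                                      pooled(pair.class_b, sf.RGB))
    assert d_nir > d_vis
    assert d_nir > d_rgb
    assert d_vis < 0.1  # visually near-identical


def test_generator_spec_yaml_roundtrip(tmp_path, default_spec):
    default_spec.to_yaml(tmp_path / "g.yaml")
    back = sf.GeneratorSpec.from_yaml(tmp_path / "g.yaml")
    assert back == default_spec


def test_planted_nir_correlation_peak():
    """With composition-to-NIR coupling on, the correlation profile peaks in
    the NIR band across seeds (planted structure is recoverable)."""
    peaks = []
    for seed in range(5):
        spec = sf.GeneratorSpec(n_classes=14, n_views=2, seed=seed,
                                val_view_period=2)
        stacks, labels = sf.generate_stacks(spec)
        rep = sf.feasibility_report(stacks, labels, bins=64)
        prof = rep["correlation_profile"]
        peaks.append(prof.loc[prof.rho.idxmax(), "band"])
    assert sum(b == "NIR" for b in peaks) >= 4
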