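"""Phantom presets, voxelization, rendering, noise and bias operators."""

import math

import numpy as np
import pytest

import dectrsp as d
from dectrsp.errors import GeometryError, InvalidInputError
from dectrsp.phantom import PRESET_NAMES

from conftest import BODY_NOISE_KEYS


# -- presets -----------------------------------------------------------------

@pytest.mark.parametrize(
    "name,n_inserts,eq_diam",
    [
        ("model467", 16, 33.0),
        ("aed_body", 16, 34.64),
        ("aed_head", 10, 20.0),
        ("george_body", 6, 27.0),
        ("george_head", 8, 18.0),
    ],
)
def test_preset_counts_and_outlines(name, n_inserts, eq_diam):
    spec = d.preset_phantom(name)
    assert len(spec.inserts) == n_inserts
    assert spec.outline.equivalent_diameter_cm == pytest.approx(eq_diam, abs=0.01)


def test_unknown_preset_rejected():
    with pytest.raises(KeyError):
        d.preset_phantom("model468")


def test_george_head_sinus_between_enamel_and_cortical():
    spec = d.preset_phantom("george_head")
    sinus = spec.insert("Sinus")
    for neighbor in ("Enamel", "Cortical bone"):
        o = spec.insert(neighbor)
        edge_gap = (
            math.dist(sinus.center_cm, o.center_cm)
            - sinus.radius_cm
            - o.radius_cm
        )
        assert edge_gap == pytest.approx(1.6, abs=0.01)


def test_preset_ring_geometry_matches_documented_distances():
    """Center-to-outer-edge radii and neighbor edge gaps per phantom."""
    cases = {
        # preset: [(plugs, edge_radius_cm, gap_cm)]
        "model467": [
            (["Adipose", "LN-300", "Breast", "Solid Water 1", "LN-450",
              "Solid Water 2", "Solid Water 3", "Solid Water 4"], 12.0, 5.0),
            (["Brain", "Cortical bone", "CB2-30%", "CB2-50%", "B-200",
              "Inner bone", "Liver", "True Water"], 7.0, 1.4),
        ],
        "george_body": [
            (["Brain", "Spinal cord", "Cortical bone", "Enamel",
              "Trabecular bone", "Spinal disk"], 10.0, 3.5),
        ],
        "george_head": [
            (["Brain", "Spinal cord", "Spinal disk", "Trabecular bone",
              "Dentin", "Cortical bone", "Enamel"], 7.0, 3.3),
        ],
    }
    for preset, rings in cases.items():
        spec = d.preset_phantom(preset)
        for names, edge_r, gap in rings:
            ins = [spec.insert(n) for n in names]
            for i in ins:
                assert math.hypot(*i.center_cm) + i.radius_cm == pytest.approx(
                    edge_r, abs=0.1
                ), (preset, i.name)
            for a, b in zip(ins, ins[1:]):
                measured = (
                    math.dist(a.center_cm, b.center_cm)
                    - a.radius_cm
                    - b.radius_cm
                )
                assert measured == pytest.approx(gap, abs=0.1), (preset, a.name)


def test_preset_reference_values_from_table():
    spec = d.preset_phantom("model467")
    tw = spec.insert("True Water")
    assert (tw.red, tw.zeff) == (pytest.approx(1.00), pytest.approx(7.42))
    sinus = d.preset_phantom("george_head").insert("Sinus")
    assert sinus.red == pytest.approx(0.200)
    assert sinus.zeff == pytest.approx(7.42)


def test_overlapping_inserts_rejected():
    outline = d.PhantomOutline("circle", diameter_cm=20.0)
    mk = lambda name, x: d.InsertSpec(name, (x, 0.0), 3.0, zeff=7.4, red=1.0)
    with pytest.raises(GeometryError):
        d.PhantomSpec("bad", outline, "Air", 7.7, 0.001,
                      [mk("a", 0.0), mk("b", 2.0)])
    with pytest.raises(GeometryError):
        d.PhantomSpec("bad", outline, "Air", 7.7, 0.001, [mk("a", 9.5)])


# -- voxelization ------------------------------------------------------------

def _one_insert_phantom(diameter_cm=2.8):
    outline = d.PhantomOutline("circle", diameter_cm=15.0)
    ins = d.InsertSpec("plug", (0.0, 0.0), diameter_cm, zeff=10.0, red=1.3)
    return d.PhantomSpec("one", outline, "Air", 7.59, 0.99, [ins])


def test_label_volume_insert_area_matches_circle():
    labels = d.build_label_volume(_one_insert_phantom(2.8), 1.0, 2.5, 4)
    per_slice = int((labels.values[:, :, 0] == 2).sum())
    assert per_slice == pytest.approx(math.pi * 14.0**2, rel=0.03)
    # identical across slices
    assert (labels.values == labels.values[:, :, :1]).all()


def test_label_volume_center_and_outside():
    labels = d.build_label_volume(d.preset_phantom("model467"), 2.0, 2.5, 2)
    nx, ny, _ = labels.shape
    assert labels.values[nx // 2, ny // 2, 0] == 1  # no insert at the center
    assert labels.values[0, 0, 0] == 0  # corner is outside the outline


def test_render_piecewise_constant_values():
    spec = d.preset_phantom("george_head")
    labels = d.build_label_volume(spec, 1.0, 2.5, 2)
    zeff, red = d.render_property_maps(labels, spec)
    k = spec.inserts.index(spec.insert("Sinus")) + 2
    sinus_vals = red.values[labels.values == k]
    assert np.all(sinus_vals == 0.200)  # exact before noise
    assert np.all(red.values[labels.values == 0] == 0.001)
    assert zeff.values[labels.values == 1][0] == pytest.approx(spec.background_zeff)


def test_render_all_background_constant():
    outline = d.PhantomOutline("circle", diameter_cm=10.0)
    spec = d.PhantomSpec("bg", outline, "Air", 7.59, 0.99, [])
    labels = d.build_label_volume(spec, 1.0, 2.5, 2)
    _, red = d.render_property_maps(labels, spec)
    inside = red.values[labels.values == 1]
    assert np.unique(inside).size == 1


# -- noise -------------------------------------------------------------------

def _flat_volume(n=120, value=1.0):
    return d.PropertyVolume.centered(
        np.full((n, n, 1), value), (1.0, 1.0, 2.5), "rsp"
    )


def test_noise_zero_sigma_is_identity_and_negative_rejected():
    vol = _flat_volume()
    out = d.add_noise(vol, 0.0, seed=3)
    assert np.array_equal(out.values, vol.values)
    with pytest.raises(InvalidInputError):
        d.add_noise(vol, -0.1, seed=3)


def test_noise_deterministic_under_seed():
    vol = _flat_volume()
    a = d.add_noise(vol, 0.018, seed=11)
    b = d.add_noise(vol, 0.018, seed=11)
    c = d.add_noise(vol, 0.018, seed=12)
    assert np.array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)


def test_noise_sigma_recovered_on_large_region():
    vol = _flat_volume(n=120)  # 14400 voxels
    noisy = d.add_noise(vol, 0.018, seed=5)
    assert noisy.values.std(ddof=1) == pytest.approx(0.018, rel=0.05)


def test_noise_presets_match_measured_table():
    presets = d.noise_presets()
    assert presets["george_head_82.77"].sigma_rsp == pytest.approx(0.003)
    assert presets["model467_14.55"].sigma_zeff == pytest.approx(0.496)
    assert set(BODY_NOISE_KEYS.values()) <= set(presets)


def test_noise_sigma_recovery_at_every_measured_setting():
    """Injected sigma is recovered within 10 % for each acquisition row."""
    vol = _flat_volume(n=120)
    for key, nm in d.noise_presets().items():
        for sigma in (nm.sigma_zeff, nm.sigma_red, nm.sigma_rsp):
            noisy = d.add_noise(vol, sigma, seed=17)
            est = d.noise_sigma(noisy, diameter_cm=2.8)
            assert est == pytest.approx(sigma, rel=0.10), (key, sigma)


# -- bias --------------------------------------------------------------------

def test_bias_amplitude_zero_is_identity():
    vol = _flat_volume()
    out = d.add_highz_bias(vol, [d.BiasSource((1.0, 1.0), 0.0, 2.0)])
    assert np.array_equal(out.values, vol.values)


def test_bias_peak_and_monotone_decay():
    vol = _flat_volume(n=121)
    src = d.BiasSource((0.0, 0.0), amplitude=0.05, decay_cm=2.0)
    out = d.add_highz_bias(vol, [src])
    nx, ny, _ = out.shape
    center = out.values[nx // 2, ny // 2, 0] - 1.0
    assert center == pytest.approx(0.05, abs=1e-9)
    at_14mm = out.values[nx // 2 + 14, ny // 2, 0] - 1.0
    at_30mm = out.values[nx // 2 + 30, ny // 2, 0] - 1.0
    assert at_14mm > at_30mm > 0


def test_noise_and_bias_preserve_grid():
    spec = d.preset_phantom("george_head")
    labels = d.build_label_volume(spec, 2.0, 2.5, 2)
    zeff, _ = d.render_property_maps(labels, spec)
    for op in (
        lambda v: d.add_noise(v, 0.1, seed=0),
        lambda v: d.add_highz_bias(v, [d.BiasSource((0, 0), 0.1, 1.0)]),
    ):
        out = op(zeff)
        assert out.same_grid(zeff)
        assert out.quantity == zeff.quantity


# -- simulation + YAML round trip -------------------------------------------

def test_simulate_deterministic_and_noise_key_checked():
    a = d.simulate("george_head", noise="george_head_82.77", seed=9, n_slices=2)
    b = d.simulate("george_head", noise="george_head_82.77", seed=9, n_slices=2)
    assert np.array_equal(a.zeff.values, b.zeff.values)
    assert np.array_equal(a.red.values, b.red.values)
    with pytest.raises(KeyError):
        d.simulate("george_head", noise="nonsense_key", n_slices=2)


def test_phantom_spec_yaml_roundtrip(tmp_path):
    spec = d.preset_phantom("george_body")
    path = tmp_path / "george_body.yaml"
    d.save_phantom_spec(spec, path)
    back = d.load_phantom_spec(path)
    assert back.name == spec.name
    assert len(back.inserts) == len(spec.inserts)
    for a, b in zip(back.inserts, spec.inserts):
        assert a.center_cm == pytest.approx(b.center_cm)
        assert a.red == pytest.approx(b.red)
    assert back.outline.equivalent_diameter_cm == pytest.approx(
        spec.outline.equivalent_diameter_cm
    )
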