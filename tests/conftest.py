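import math

import numpy as np
import pytest
from hypothesis import settings

import dectrsp as d

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: Body-SFOV acquisition noise key for each phantom preset.
BODY_NOISE_KEYS = {
    "model467": "model467_14.55",
    "aed_body": "aed_body_18.85",
    "aed_head": "aed_head_18.85",
    "george_body": "george_body_18.85",
    "george_head": "george_head_18.85",
}

ELEMENT_POOL = ["H", "C", "N", "O", "Mg", "P", "S", "Cl", "Ca"]


def random_composition(rng: np.random.Generator) -> d.Composition:
    """A random 2-5 element composition from common tissue elements."""
    k = int(rng.integers(2, 6))
    symbols = rng.choice(ELEMENT_POOL, size=k, replace=False)
    w = rng.dirichlet(np.ones(k))
    return d.Composition.from_fractions(dict(zip(symbols, w)))


@pytest.fixture(scope="session")
def water():
    return d.Composition.from_fractions(d.physics.WATER_MASS_FRACTIONS)


@pytest.fixture(scope="session")
def correlation():
    return d.default_correlation()


@pytest.fixture(scope="session")
def recovery_stats(correlation):
    """End-to-end recovery over 100 noise seeds for all five presets.

    For each preset: simulate noiseless maps once, then for each seed add
    measured-magnitude noise, convert to RSP, and count, per insert, the
    seeds where the ROI mean misses the noiseless ROI mean by more than
    three standard errors (SE estimated from the ROI sample SD).
    """
    from dectrsp.evaluation import _roi_mask

    n_seeds = 100
    out = {}
    for preset, key in BODY_NOISE_KEYS.items():
        sim0 = d.simulate(preset, noise=None, n_slices=10)
        rsp0 = d.rsp_map(sim0.zeff, sim0.red, correlation)
        masks = [
            _roi_mask(rsp0, ins.center_cm, math.sqrt(0.6) * 10 * ins.radius_cm)
            for ins in sim0.spec.inserts
        ]
        ref_means = [float(rsp0.values[m, :].mean()) for m in masks]
        nm = d.noise_presets()[key]
        fails = np.zeros(len(masks), dtype=int)
        for seed in range(n_seeds):
            child = np.random.SeedSequence(seed).spawn(2)
            z = d.add_noise(sim0.zeff, nm.sigma_zeff, child[0])
            r = d.add_noise(sim0.red, nm.sigma_red, child[1])
            rsp = d.rsp_map(z, r, correlation)
            for k, m in enumerate(masks):
                v = rsp.values[m, :]
                se = v.std(ddof=1) / math.sqrt(v.size)
                if abs(v.mean() - ref_means[k]) > 3 * se:
                    fails[k] += 1
        out[preset] = {
            "inserts": [i.name for i in sim0.spec.inserts],
            "fails": fails,
            "n_seeds": n_seeds,
        }
    return out
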