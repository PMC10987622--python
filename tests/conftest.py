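import numpy as np
import pandas as pd
import pytest

from photogam import build_schedule
from photogam.gam import GamSpec, SmoothSpec, fit_reml
from photogam.synth import GenotypeEffect, SynthConfig


@pytest.fixture(scope="session")
def rep2_schedule():
    return build_schedule(30, 4, 7.5, 2, 25)


@pytest.fixture(scope="session")
def rep75_schedule():
    return build_schedule(30, 4, 7.5, 7.5, 25)


@pytest.fixture(scope="session")
def tiny_schedule():
    # 2-min acclimation + 2 x [2-min dark + 1-min light] + 2-min dark
    return build_schedule(2, 2, 2, 1, 2)


def make_synth_config(schedule, **overrides):
    defaults = dict(
        schedule=schedule,
        n_assays=2,
        fish_per_group_per_assay=4,
        genotype_effects=(
            GenotypeEffect("WT"),
            GenotypeEffect("HM", surge_scale_by_light_duration={60: 0.1, 450: 1.0}),
        ),
        zero_prob=0.3,
        lognormal_sigma=0.8,
        assay_sd=0.05,
        fish_sd=0.05,
        base_seed=7,
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_synth_config(tiny_schedule):
    return make_synth_config(tiny_schedule)


def make_sinusoid_data(seed=0, n_per_group=200, noise=0.5, offsets=None):
    """Smooth sinusoid + genotype offsets + iid noise; known truth for recovery tests."""
    rng = np.random.default_rng(seed)
    offsets = offsets or {"WT": 0.0, "HT": 1.0, "HM": -2.0}
    t = np.tile(np.arange(1.0, n_per_group + 1.0), len(offsets))
    geno = np.repeat(list(offsets), n_per_group)
    assay = np.tile(
        np.repeat(["a1", "a2"], n_per_group // 2), len(offsets)
    )
    mu = 3.0 * np.sin(t / 20.0) + np.array([offsets[g] for g in geno])
    y = mu + rng.normal(0.0, noise, t.size)
    df = pd.DataFrame(
        {
            "rsum": y,
            "Time": t,
            "genotype": pd.Categorical(geno, categories=list(offsets)),
            "assay_id": assay,
        }
    )
    return df, mu


@pytest.fixture(scope="session")
def sinusoid_fit():
    df, mu = make_sinusoid_data(seed=3)
    spec = GamSpec(
        "rsum",
        ("genotype",),
        (SmoothSpec("Time", 15, by="genotype"),),
        ("assay_id",),
    )
    fit = fit_reml(spec, df, restarts=3, seed=1)
    return fit, df, mu
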