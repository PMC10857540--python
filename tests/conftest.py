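import dataclasses

import numpy as np
import pandas as pd
import pytest

import fallsense as fs


@pytest.fixture(scope="session")
def small_cohort():
    """4 fallers + 4 non-fallers at default effects and noise."""
    spec = fs.CohortSpec(n_fallers=4, n_nonfallers=4, seed=7)
    profiles, trials, annotations, clinical = fs.generate_cohort(spec)
    return {"spec": spec, "profiles": profiles, "trials": trials,
            "annotations": annotations, "clinical": clinical}


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return fs.assemble_feature_table(small_cohort["profiles"],
                                     small_cohort["trials"])


@pytest.fixture(scope="session")
def nonfaller_profile(small_cohort):
    return next(p for p in small_cohort["profiles"] if p.group == "nonfaller")


def make_twin(profile, group, unmasking=0.0):
    """Same latent traits, different group label (for monotonicity checks)."""
    latents = dict(profile.latents)
    latents["unmasking"] = unmasking if group == "faller" else 0.0
    return dataclasses.replace(profile, group=group, latents=latents)


@pytest.fixture
def twin_pair(nonfaller_profile):
    faller = make_twin(nonfaller_profile, "faller", unmasking=0.3)
    return faller, nonfaller_profile


def toy_table(n_pos=11, n_neg=10, n_noise=9, seed=0, leak=False,
              effect=2.0):
    """Direct feature-table fixture: one informative column + noise columns."""
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    y = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
    cols = {}
    cols["signal"] = y * effect + rng.normal(0, 1.0, n)
    if leak:
        cols["leak"] = y.astype(float)
    for k in range(n_noise):
        cols[f"noise_{k}"] = rng.normal(0, 1.0, n)
    table = pd.DataFrame(cols, index=[f"S{i:02d}" for i in range(n)])
    table["label"] = y
    return table
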