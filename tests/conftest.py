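"""Shared fixtures: small synthetic sessions generated once per run."""

import numpy as np
import pandas as pd
import pytest

from thetaquant.profiles import FERRET, RAT
from thetaquant.synth import ArtifactSpec, GeneratorConfig, generate_session

FS = 1000.0


@pytest.fixture(scope="session")
def rat_session():
    cfg = GeneratorConfig.default("rat", duration_s=180.0, seed=3)
    sess, truth = generate_session(cfg)
    return sess, truth


@pytest.fixture(scope="session")
def ferret_session():
    cfg = GeneratorConfig.default("ferret", duration_s=180.0, seed=3)
    sess, truth = generate_session(cfg)
    return sess, truth


@pytest.fixture(scope="session")
def rat_session_with_artifacts():
    spec = ArtifactSpec(transient_rate=0.02, scratch_rate=0.01,
                        zero_rate=0.005, saturation_rate=0.003)
    cfg = GeneratorConfig.default("rat", duration_s=180.0, seed=5, artifact_spec=spec)
    sess, truth = generate_session(cfg)
    return sess, truth


def simulate_state_table(rng, interaction=0.15, n_per=20, n_ids=3, n_sessions=3,
                         sd_id=0.05, sd_session=0.03, sd_eps=0.1):
    """Nested two-species epoch table with a locomotion x species interaction.

    The moving-state effect is 0.1 + ``interaction`` in the rat and 0.1 in
    the ferret, so the treatment-coded interaction coefficient (ferret
    difference) is ``-interaction``.
    """
    rows = []
    for species in ("rat", "ferret"):
        for i in range(n_ids):
            id_fx = rng.normal(0, sd_id)
            for s in range(n_sessions):
                ses_fx = rng.normal(0, sd_session)
                for chan in ("SO", "SRSLM"):
                    for mov in ("immobile", "moving"):
                        mu = (0.4 + 0.1 * (mov == "moving")
                              + interaction * ((mov == "moving") and (species == "rat"))
                              + 0.02 * (chan == "SRSLM"))
                        for v in mu + id_fx + ses_fx + rng.normal(0, sd_eps, n_per):
                            rows.append(dict(peak_range=v, MovFlag=mov, Species=species,
                                             Chan=chan, ID=f"{species[0]}{i}", Session=f"s{s}"))
    return pd.DataFrame(rows)


def simulate_epoch_table(rng, effects=None, n_per=30, n_ids=3, n_sessions=3):
    """Single-species trial-epoch table with Hold/Run/Reward level means."""
    effects = effects or {"Hold": 0.0, "Run": 0.0, "Reward": 0.0}
    rows = []
    for i in range(n_ids):
        id_fx = rng.normal(0, 0.05)
        for s in range(n_sessions):
            ses_fx = rng.normal(0, 0.03)
            for epoch, mu in effects.items():
                for v in 0.5 + mu + id_fx + ses_fx + rng.normal(0, 0.1, n_per):
                    rows.append(dict(peak_range=v, Epoch=epoch, Chan="SRSLM",
                                     ID=f"F{i}", Session=f"s{s}"))
    return pd.DataFrame(rows)
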