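"""Shared fixtures: small synthetic membranes for unit tests and one
full-scale two-membrane feature matrix reused by the classification tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import poremap
from poremap.events import events_to_frame


def small_config(seed: int = 7, **overrides) -> poremap.SyntheticConfig:
    defaults = dict(n_lipids_per_leaflet=300, box_xy=30.0, box_z=9.0,
                    water_density=0.3, seed=seed)
    defaults.update(overrides)
    return poremap.SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def config():
    return small_config()


@pytest.fixture(scope="session")
def fields(config):
    return poremap.gen_composition_fields(config)


@pytest.fixture(scope="session")
def frame(config, fields):
    return poremap.gen_frame(config, fields)


@pytest.fixture(scope="session")
def traj(config, fields):
    return poremap.gen_trajectory(config, 30, dt=0.1, fields=fields)


def build_membrane_features(mem_id: str, seed: int, n_lipids: int = 1500,
                            n_frames: int = 15, coupling: float = 3.0,
                            composition: str = "APM",
                            n_events: int = 60) -> pd.DataFrame:
    """Feature matrix of one membrane with pores planted proportional to
    exp(coupling * standardized local PU density)."""
    cfg = poremap.SyntheticConfig(n_lipids_per_leaflet=n_lipids, box_xy=30.0,
                                  composition=composition, seed=seed)
    fl = poremap.gen_composition_fields(cfg)
    hz = poremap.HazardSpec(np.array([0.0, 3.0, 15.0]), np.array([0.0, 0.25]),
                            {"dep": 0.0}, censor_time=15.0)
    events = events_to_frame(poremap.sample_poration_dataset(
        hz, n_events, pu_field=fl.pu_field(smooth_nm=1.5), coupling=coupling,
        seed=seed, membrane_id=mem_id))
    events = events[~events["censored"]]
    porated = events[["x_rel", "y_rel"]].to_numpy()
    nonporated = poremap.sample_nonporated(cfg.box_xy, porated, target=300,
                                           seed=seed)
    locations = pd.DataFrame({
        "x_rel": np.concatenate([porated[:, 0], nonporated[:, 0]]),
        "y_rel": np.concatenate([porated[:, 1], nonporated[:, 1]]),
        "label": np.concatenate([np.ones(len(porated), int),
                                 np.zeros(len(nonporated), int)]),
    })
    trajectory = poremap.gen_trajectory(cfg, n_frames, fields=fl, seed=seed)
    return poremap.feature_matrix(trajectory, locations, membrane_id=mem_id)


@pytest.fixture(scope="session")
def planted_features():
    """Two same-composition membranes at study-scale lipid density with
    PU-coupled pores; shared by the divergence and classification tests."""
    return pd.concat([build_membrane_features("mem1", seed=1),
                      build_membrane_features("mem2", seed=2)],
                     ignore_index=True)
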