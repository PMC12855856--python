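import numpy as np
import pytest

import rmsfnet as rn


@pytest.fixture(scope="session")
def null26():
    """Shared 1e5-resample permutation null for n=26 trajectories."""
    return rn.build_null(26, resamples=100_000, seed=424242)


@pytest.fixture(scope="session")
def default_study():
    return rn.simulate_rmsf(rn.default_truth(seed=11))


@pytest.fixture(scope="session")
def default_corr(default_study, null26):
    return rn.correlate(default_study.dataset, null=null26)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250925)


def toy_profiles(matrix, residues=None, conditions=None):
    """Build RmsfProfiles from a (n_residues, n_trajectories) array."""
    matrix = np.asarray(matrix, dtype=float)
    n_res, n_traj = matrix.shape
    assert n_traj % 2 == 0
    if residues is None:
        residues = [rn.ResidueKey("heavy", i + 1) for i in range(n_res)]
    profiles = []
    for j in range(n_traj):
        cond = "V" if j % 2 == 0 else "P"
        copy = f"c{j // 2 + 1:02d}"
        profiles.append(
            rn.RmsfProfile(
                trajectory_id=f"{copy}_{cond}",
                copy_id=copy,
                condition=cond,
                provenance="crystal",
                values=dict(zip(residues, matrix[:, j])),
            )
        )
    return profiles


def toy_dataset(matrix, residues=None):
    return rn.harmonize_residues(toy_profiles(matrix, residues))
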