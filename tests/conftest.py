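import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ambiclass.synthetic import SyntheticConfig, gen_class_features


def brute_force_rmsd(p: np.ndarray, q: np.ndarray, seed: int = 0) -> float:
    """Independent superposition oracle: random-rotation grid + local refinement.

    Minimizes the RMSD over rotations numerically (after centering),
    without using the SVD-based closed form, so it can cross-check it.
    """
    rng = np.random.default_rng(seed)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)

    def rmsd_of(rotvec):
        rotated = Rotation.from_rotvec(rotvec).apply(qc)
        return float(np.sqrt(np.mean(np.sum((pc - rotated) ** 2, axis=1))))

    candidates = rng.uniform(-np.pi, np.pi, size=(400, 3))
    mats = Rotation.from_rotvec(candidates).as_matrix()
    rotated = np.einsum("rij,nj->rni", mats, qc)
    scores = np.sqrt(np.mean(np.sum((pc[None] - rotated) ** 2, axis=2), axis=1))
    best = np.inf
    for idx in np.argsort(scores)[:3]:
        res = minimize(
            rmsd_of,
            candidates[idx],
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-13, "maxiter": 2000},
        )
        best = min(best, res.fun)
    return best


@pytest.fixture(scope="session")
def class_features() -> pd.DataFrame:
    """Labeled three-class feature table at the generator's default separations."""
    return gen_class_features(SyntheticConfig(seed=11, n_proteins=40))
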