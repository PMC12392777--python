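"""Shared fixtures: a scaled-down pathological detector with its full
calibration chain (scans -> DRF, flood -> blur + uniformity), built
once per session and reused by the integration and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from mlprecond.evaluate import StudyChain, build_study_chain


@pytest.fixture(scope="session")
def study_chain() -> StudyChain:
    """The fitted preconditioning chain under the default study
    conditions (24x24 precondition grid, 0.5 mm-RMS distortion,
    boundary artifact, 5% gain nonuniformity)."""
    return build_study_chain(seed=0)


@pytest.fixture(scope="session")
def toy_spec(study_chain):
    return study_chain.spec


@pytest.fixture(scope="session")
def pathologies(study_chain):
    return study_chain.pathologies


@pytest.fixture(scope="session")
def toy_drf(study_chain):
    return study_chain.drf


@pytest.fixture(scope="session")
def fitted_blur(study_chain):
    return study_chain.blur


@pytest.fixture(scope="session")
def fitted_corrector(study_chain):
    return study_chain.corrector


def random_sparse_drf(rng: np.random.Generator, M: int = 60, N: int = 12,
                      density: float = 0.3):
    """Small random non-negative DRF with full row and column coverage,
    for MLEM unit and property tests."""
    from scipy import sparse

    from mlprecond.drf import DRFMatrix, compute_sensitivity

    mask = rng.random((M, N)) < density
    mask[rng.integers(0, M, N), np.arange(N)] = True   # no empty columns
    mask[np.arange(M), rng.integers(0, N, M)] = True   # every raw bin covered
    P = sparse.csc_matrix(np.where(mask, rng.random((M, N)), 0.0))
    return DRFMatrix(P=P, s=compute_sensitivity(P), raw_shape=(M, 1),
                     precond_shape=(N, 1))
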