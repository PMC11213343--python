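import numpy as np
import pytest

from pbpsensor import (
    AnalysisConfig,
    HingeSpec,
    PearsonMatrix,
    Structure,
    Trajectory,
    fixture_config,
    generate_hinge_trajectory,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def hinge():
    """Default zero-noise opening hinge with its ground truth."""
    return generate_hinge_trajectory(HingeSpec())


@pytest.fixture
def hinge_config():
    return fixture_config(HingeSpec())


def make_structure(coords, residue_ids=None, atom_names=None, elements=None):
    """Cα-per-residue structure from raw coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    residue_ids = residue_ids if residue_ids is not None else np.arange(1, n + 1)
    return Structure(
        residue_ids=np.asarray(residue_ids),
        residue_names=["ALA"] * n,
        atom_names=atom_names or ["CA"] * n,
        elements=elements or ["C"] * n,
        coords=coords,
    )


def make_trajectory(frame_list, frame_times=None, **structure_kwargs):
    frames = np.asarray(frame_list, dtype=float)
    topo = make_structure(frames[0], **structure_kwargs)
    times = (
        np.asarray(frame_times, dtype=float)
        if frame_times is not None
        else np.arange(len(frames), dtype=float)
    )
    return Trajectory(topology=topo, frames=frames, frame_times=times)


def matrix_from_pixels(n, pixels, offset=1):
    """Symmetric PearsonMatrix with given {(res_i, res_j): value} pixels."""
    values = np.zeros((n, n))
    ids = np.arange(offset, offset + n)
    pos = {int(r): k for k, r in enumerate(ids)}
    for (i, j), v in pixels.items():
        values[pos[i], pos[j]] = values[pos[j], pos[i]] = v
    return PearsonMatrix(values=values, residue_ids=ids)


def random_sparse_matrix(rng, n=12, density=0.18):
    """Random symmetric sign-mixed sparse matrix for cluster fuzzing."""
    values = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            if rng.random() < density:
                v = rng.uniform(0.05, 1.0) * rng.choice([-1.0, 1.0])
                values[a, b] = values[b, a] = v
    return PearsonMatrix(values=values, residue_ids=np.arange(1, n + 1))
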