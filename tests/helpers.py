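"""Shared construction helpers for the test suite."""

import numpy as np
from scipy.spatial.transform import Rotation

import stainfit as sf


def make_fit(quat_deg_axis=None, translation=(0, 0, 0), objective=1.0, scores=None):
    """Build a Fit rotated by (degrees, axis) and translated, for clustering tests."""
    angle, axis = (0.0, (0, 0, 1)) if quat_deg_axis is None else quat_deg_axis
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis) if np.linalg.norm(axis) else np.array([0, 0, 1.0])
    rot = Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
    return sf.Fit(transform=sf.RigidTransform(rot, np.asarray(translation, float)),
                  objective=objective, coverage=1.0, scores=scores)


def toy_model(positions, chain="A"):
    """Ca-only AtomicModel from raw coordinates."""
    positions = np.asarray(positions, float)
    n = len(positions)
    return sf.AtomicModel(
        chains=np.array([chain] * n, dtype=object), resnums=np.arange(1, n + 1),
        resnames=np.array(["ALA"] * n, dtype=object),
        atom_names=np.array(["CA"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        positions=positions, weights=np.ones(n),
    )
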