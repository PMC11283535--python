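"""Independent oracles used only by the tests.

The quaternion-eigenvalue superposition (Horn's method) solves the same
least-squares rigid-superposition problem as the package's SVD-based
routine by an entirely different route: the optimal rotation is the
eigenvector of a 4x4 quaternion matrix with the largest eigenvalue.
"""

from __future__ import annotations

import numpy as np


def quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q / np.linalg.norm(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def quaternion_superpose(mobile: np.ndarray, target: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray, float]:
    """Horn quaternion superposition: returns (R, t, rmsd).

    R, t minimise ||R @ mobile_i + t - target_i|| in the least-squares
    sense, with R a proper rotation.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    a = mobile - cm
    b = target - ct
    S = a.T @ b
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    evals, evecs = np.linalg.eigh(N)
    q = evecs[:, np.argmax(evals)]
    R = quaternion_to_matrix(q)
    t = ct - R @ cm
    dev = mobile @ R.T + t - target
    value = float(np.sqrt((dev ** 2).sum() / len(mobile)))
    return R, t, value


def axis_angle_degrees(R: np.ndarray) -> float:
    """Rotation magnitude via quaternion conversion (independent route)."""
    # trace-based quaternion extraction; |w| = cos(angle/2)
    w = 0.5 * np.sqrt(max(0.0, 1.0 + np.trace(R)))
    w = min(w, 1.0)
    return float(np.degrees(2.0 * np.arccos(w)))
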