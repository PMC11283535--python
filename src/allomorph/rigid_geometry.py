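"""Rigid-body geometry: Kabsch superposition, RMSD, principal axes and
Euler-angle rotation algebra.

The Euler convention used throughout is an intrinsic Tait–Bryan sequence
roll → pitch → yaw, applied about the x, y and z axes of the canonical
cap-principal-axes frame respectively (tag ``"XYZ"``).  In that frame the
cap's largest-variance axis is the roll axis, the second the pitch axis
and the third the yaw axis, so pitch measures domain closing, roll domain
twisting and yaw lateral rotation.  Other intrinsic sequences are
selectable by tag; every :class:`EulerAngles` carries its tag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_CONVENTION = "XYZ"
_INTRINSIC_SEQUENCES = ("XYZ", "XZY", "YXZ", "YZX", "ZXY", "ZYX")
#: Axis → angle-name assignment (roll about x, pitch about y, yaw about z).
_AXIS_ANGLE = {"X": "roll", "Y": "pitch", "Z": "yaw"}

_ORTHO_TOL = 1e-8
_GIMBAL_TOL_DEG = 1e-6


def _check_rotation(R: np.ndarray, tol: float = _ORTHO_TOL) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        raise ValueError("matrix is not orthonormal")
    if not np.isclose(np.linalg.det(R), 1.0, atol=tol):
        raise ValueError("matrix determinant is not +1 (improper rotation)")
    return R


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation plus translation: x ↦ R x + t (Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation",
                           _check_rotation(self.rotation, tol=1e-9))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation
                              + self.translation)


@dataclass(frozen=True)
class EulerAngles:
    """Intrinsic Tait–Bryan angles in degrees, each in (−180, 180]."""

    pitch: float
    roll: float
    yaw: float
    convention: str = DEFAULT_CONVENTION

    def __post_init__(self) -> None:
        if self.convention not in _INTRINSIC_SEQUENCES:
            raise ValueError(f"unknown Euler convention {self.convention!r}; "
                             f"expected one of {_INTRINSIC_SEQUENCES}")
        for name in ("pitch", "roll", "yaw"):
            v = getattr(self, name)
            if not (-180.0 < v <= 180.0 + 1e-12):
                raise ValueError(f"{name} = {v} outside (-180, 180]")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.pitch, self.roll, self.yaw)


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares superposition outcome."""

    transform: RigidTransform
    rmsd: float
    n_atoms: int


def _as_points(x, min_n: int = 1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("expected an (n, 3) coordinate array")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} points, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates")
    return x


def kabsch_superpose(mobile, target) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the proper rotation (reflections excluded) and translation
    minimising the RMSD of the transformed mobile set to the target.
    Collinear point sets leave the rotation about the line undetermined
    and raise an error.
    """
    mobile = _as_points(mobile, 3)
    target = _as_points(target, 3)
    if len(mobile) != len(target):
        raise ValueError(f"length mismatch: {len(mobile)} vs {len(target)}")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, S, Vt = np.linalg.svd(H)
    scale = max(S[0], 1e-30)
    if S[1] / scale < 1e-9:
        raise ValueError("degenerate geometry: collinear point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ct - R @ cm
    transform = RigidTransform(R, t)
    dev = transform.apply(mobile) - target
    value = float(np.sqrt((dev ** 2).sum() / len(mobile)))
    return SuperpositionResult(transform, value, len(mobile))


def rmsd(a, b, superpose: bool = False) -> float:
    """Root-mean-square deviation between paired coordinate sets (Å)."""
    a = _as_points(a, 3 if superpose else 1)
    b = _as_points(b, 3 if superpose else 1)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if superpose:
        return kabsch_superpose(a, b).rmsd
    return float(np.sqrt(((a - b) ** 2).sum() / len(a)))


def principal_axes(points, orient_toward: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Principal axes of a point cloud about its centroid.

    Returns a right-handed orthonormal basis (axes as *columns*, ordered
    by decreasing positional variance) and the three variances.

    Eigenvector signs are fixed deterministically: each axis is oriented
    to have a positive projection onto ``orient_toward`` (for domain work,
    the core-centroid → cap-centroid vector); where that projection is
    negligible the fallback is a positive projection onto the file-frame
    +x/+y/+z axis of matching rank.  Handedness is then forced to det=+1
    by flipping the third axis if necessary.
    """
    points = _as_points(points, 3)
    centred = points - points.mean(axis=0)
    cov = centred.T @ centred / len(points)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    variances = evals[order]
    axes = evecs[:, order]
    if variances[0] < 1e-12 or variances[1] / max(variances[0], 1e-30) < 1e-12:
        raise ValueError("degenerate geometry: collinear point set")
    if abs(variances[1] - variances[2]) < 1e-12 or \
            abs(variances[0] - variances[1]) < 1e-12:
        warnings.warn("near-degenerate principal variances; axis order "
                      "resolved by eigendecomposition index", stacklevel=2)
    for i in range(3):
        ref = None if orient_toward is None else np.asarray(orient_toward,
                                                            dtype=float)
        proj = 0.0 if ref is None else float(axes[:, i] @ ref)
        if abs(proj) < 1e-10:
            proj = float(axes[i, i])  # fallback: file-frame axis of same rank
        if abs(proj) < 1e-10:
            # last resort: first non-negligible component decides the sign
            j = int(np.argmax(np.abs(axes[:, i])))
            proj = float(axes[j, i])
        if proj < 0:
            axes[:, i] = -axes[:, i]
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return axes, variances


def rotation_angle(R) -> float:
    """Total rotation magnitude of ``R`` in degrees, in [0, 180].

    This axis–angle magnitude serves as the interdomain hinge-closure
    angle when ``R`` is a cap-versus-core rotation.
    """
    R = _check_rotation(R)
    c = (np.trace(R) - 1.0) / 2.0
    # atan2 form of arccos((tr-1)/2): numerically stable near 0 and 180 deg
    s = 0.5 * np.sqrt((R[2, 1] - R[1, 2]) ** 2 + (R[0, 2] - R[2, 0]) ** 2
                      + (R[1, 0] - R[0, 1]) ** 2)
    return float(np.degrees(np.arctan2(s, c)))


def _elementary(axis: str, angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    if axis == "X":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == "Y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def rotation_from_euler(angles: EulerAngles) -> np.ndarray:
    """Rotation matrix of intrinsic Tait–Bryan angles.

    For the default ``"XYZ"`` tag the matrix is Rx(roll)·Ry(pitch)·Rz(yaw):
    the elementary rotations applied intrinsically in roll → pitch → yaw
    order.
    """
    seq = angles.convention
    values = [getattr(angles, _AXIS_ANGLE[ax]) for ax in seq]
    R = np.eye(3)
    for ax, v in zip(seq, values):
        R = R @ _elementary(ax, v)
    return R


def _wrap(deg: float) -> float:
    v = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if v == -180.0 else v


def euler_from_rotation(R, convention: str = DEFAULT_CONVENTION) -> EulerAngles:
    """Intrinsic Tait–Bryan decomposition of a rotation matrix.

    For the default ``"XYZ"`` sequence (roll about x, then pitch about y,
    then yaw about z):

        pitch = asin(R[0,2]); roll = atan2(−R[1,2], R[2,2]);
        yaw = atan2(−R[0,1], R[0,0]).

    Near gimbal lock (|pitch| within 1e-6° of 90°) roll and yaw are not
    separable; roll is set to 0, yaw absorbs the free angle and a warning
    is issued.  Other intrinsic sequences are delegated to
    scipy.spatial.transform.
    """
    R = _check_rotation(R)
    if convention not in _INTRINSIC_SEQUENCES:
        raise ValueError(f"unknown Euler convention {convention!r}")
    if convention != "XYZ":
        from scipy.spatial.transform import Rotation as _Rot
        vals = _Rot.from_matrix(R).as_euler(convention, degrees=True)
        named = {_AXIS_ANGLE[ax]: float(v) for ax, v in zip(convention, vals)}
        return EulerAngles(convention=convention, **named)
    s = np.clip(R[0, 2], -1.0, 1.0)
    pitch = np.degrees(np.arcsin(s))
    if 90.0 - abs(pitch) < _GIMBAL_TOL_DEG:
        warnings.warn("gimbal lock: |pitch| ~ 90 deg; roll set to 0 and yaw "
                      "absorbs the free angle", stacklevel=2)
        roll = 0.0
        yaw = np.degrees(np.arctan2(R[1, 0], R[1, 1]))
    else:
        roll = np.degrees(np.arctan2(-R[1, 2], R[2, 2]))
        yaw = np.degrees(np.arctan2(-R[0, 1], R[0, 0]))
    return EulerAngles(pitch=_wrap(float(pitch)), roll=_wrap(float(roll)),
                       yaw=_wrap(float(yaw)), convention="XYZ")
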