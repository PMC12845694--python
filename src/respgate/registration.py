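"""Markerless rigid registration between CT and world coordinate frames.

A calibration plate carrying five non-coplanar fiducials is located in both
the CT frame (preloaded coordinates) and the world frame (tracked
positions).  The least-squares rigid transform mapping CT points onto world
points is the closed-form SVD solution (Umeyama/Kabsch): minimize
``sum_i || R p_i + t - q_i ||^2`` over proper rotations R and translations
t, with the reflection ambiguity resolved through the sign of the SVD
determinant.  Three non-collinear correspondences suffice; extra fiducials
overdetermine the fit and average out detection noise.

All coordinates are metric millimetres in right-handed frames; no scale
change is assumed between CT and world (a similarity fit is available
behind ``with_scale=True``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PointSet",
    "RigidTransform",
    "umeyama_rigid",
    "apply_transform",
    "invert_transform",
    "point_error",
    "fiducial_rmse",
]

_DEGENERACY_TOL = 1e-6  # min singular-value ratio of centered coordinates


@dataclass
class PointSet:
    """Labelled 3-D fiducial coordinates in a named frame ("ct" or "world")."""

    labels: list[str]
    points: np.ndarray
    frame: str = "ct"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        n = self.points.shape[0]
        if n < 3:
            raise ValueError(f"need >= 3 points, got {n}")
        if len(self.labels) != n:
            raise ValueError("labels/points length mismatch")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite coordinates")
        d = self.points[:, None, :] - self.points[None, :, :]
        dist = np.linalg.norm(d, axis=-1)
        np.fill_diagonal(dist, np.inf)
        if dist.min() < 1e-9:
            raise ValueError("coincident points in point set")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def is_degenerate(self) -> bool:
        """True when the centered points are (near-)collinear."""
        sv = np.linalg.svd(self.points - self.points.mean(axis=0),
                           compute_uv=False)
        return sv[1] < _DEGENERACY_TOL * sv[0]


@dataclass
class RigidTransform:
    """q = scale * R p + t, with R a proper rotation (scale = 1 when rigid)."""

    R: np.ndarray
    t: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        if np.max(np.abs(self.R @ self.R.T - np.eye(3))) > 1e-6:
            raise ValueError("R is not orthonormal")
        if abs(np.linalg.det(self.R) - 1.0) > 1e-6:
            raise ValueError("R is not a proper rotation (det != +1)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return self.scale * pts @ self.R.T + self.t


def umeyama_rigid(src: PointSet, dst: PointSet,
                  with_scale: bool = False) -> RigidTransform:
    """Closed-form least-squares rigid (or similarity) fit src -> dst.

    Points are matched by label; the source geometry must be non-degenerate
    (not collinear).  The returned rotation is always proper, also for noise
    configurations whose raw SVD solution would be a reflection.
    """
    if src.n != dst.n:
        raise ValueError(f"point counts differ: {src.n} vs {dst.n}")
    if sorted(src.labels) != sorted(dst.labels):
        raise ValueError("label sets differ between source and destination")
    order = [dst.labels.index(lab) for lab in src.labels]
    p = src.points
    q = dst.points[order]
    if src.is_degenerate():
        raise ValueError("degenerate (collinear/coincident) source geometry")

    mu_p = p.mean(axis=0)
    mu_q = q.mean(axis=0)
    pc = p - mu_p
    qc = q - mu_q
    cov = qc.T @ pc / src.n
    U, D, Vt = np.linalg.svd(cov)
    s = np.ones(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        s[2] = -1.0
    R = U @ np.diag(s) @ Vt
    if with_scale:
        var_p = np.mean(np.sum(pc**2, axis=1))
        scale = float(np.sum(D * s) / var_p)
    else:
        scale = 1.0
    t = mu_q - scale * R @ mu_p
    return RigidTransform(R, t, scale)


def apply_transform(T: RigidTransform, pts: PointSet) -> PointSet:
    """Map a point set through T, flipping its frame tag."""
    frame = {"ct": "world", "world": "ct"}.get(pts.frame, pts.frame)
    return PointSet(list(pts.labels), T(pts.points), frame)


def invert_transform(T: RigidTransform) -> RigidTransform:
    """Inverse transform: (R', t') with R' = R^T / s, t' = -R^T t / s."""
    Rt = T.R.T
    return RigidTransform(Rt, -Rt @ T.t / T.scale, 1.0 / T.scale)


def point_error(p: np.ndarray, q: np.ndarray) -> float:
    """Euclidean distance between two 3-D points [mm]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("non-finite coordinates")
    return float(np.linalg.norm(p - q))


def fiducial_rmse(T: RigidTransform, src: PointSet, dst: PointSet) -> float:
    """Root-mean-square residual of the fitted correspondences [mm]."""
    if src.n != dst.n:
        raise ValueError("point counts differ")
    order = [dst.labels.index(lab) for lab in src.labels]
    res = T(src.points) - dst.points[order]
    return float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
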