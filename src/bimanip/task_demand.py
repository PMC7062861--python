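"""Task-demand extraction from force recordings.

Each motion segment's 3-D force samples are enclosed in a minimum-volume
enclosing ellipsoid (MVEE, Khachiyan's barycentric coordinate-descent).
The ellipsoid's major axis is the direction along which the task demands
force; averaging the (sign-aligned) major axes of the successful segments
gives the task-demanded direction f*, which is split into a vertical
component for the assistant hand (pressing the pegwood down) and a
horizontal component for the dominant hand (pushing the tweezers).

Axis sign convention: ellipsoid axes are ambiguous up to sign, so axes are
canonicalized into the hemisphere with negative Z (the task presses down
onto the watch face).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np


class TaskDemandError(ValueError):
    pass


class DegenerateEllipsoidError(TaskDemandError):
    def __init__(self, msg: str, direction: Optional[np.ndarray] = None):
        super().__init__(msg)
        self.direction = direction


@dataclass
class ForceSegment:
    """Force samples (N, task frame) for one swipe attempt at 70 Hz nominal."""

    timestamps: np.ndarray
    forces: np.ndarray
    success: bool
    subject: str = ""
    segment_id: str = ""

    def __post_init__(self):
        t = np.asarray(self.timestamps, dtype=float)
        f = np.asarray(self.forces, dtype=float)
        if f.ndim != 2 or f.shape[1] != 3 or t.shape[0] != f.shape[0]:
            raise TaskDemandError("forces must be (n, 3) aligned with timestamps")
        if f.shape[0] < 10:
            raise TaskDemandError("a force segment needs at least 10 samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(f))):
            raise TaskDemandError("non-finite force data")
        self.timestamps, self.forces = t, f


@dataclass
class Ellipsoid:
    """{x : (x - c)^T A (x - c) <= 1} with A symmetric positive definite."""

    center: np.ndarray
    shape: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        A = np.asarray(self.shape, dtype=float)
        if c.shape != (3,) or A.shape != (3, 3):
            raise TaskDemandError("ellipsoid needs a 3-vector centre and 3x3 shape")
        if not np.allclose(A, A.T, atol=1e-9):
            raise TaskDemandError("shape matrix must be symmetric")
        w = np.linalg.eigvalsh(A)
        if np.any(w <= 0):
            raise DegenerateEllipsoidError("shape matrix must be positive definite")
        self.center, self.shape = c, 0.5 * (A + A.T)

    @property
    def semi_axes(self) -> np.ndarray:
        """Semi-axis lengths, descending."""
        return np.sort(1.0 / np.sqrt(np.linalg.eigvalsh(self.shape)))[::-1]

    def contains(self, points: np.ndarray, tol: float = 1e-6) -> np.ndarray:
        d = np.asarray(points, dtype=float) - self.center
        return np.einsum("ni,ij,nj->n", d, self.shape, d) <= 1.0 + tol


@dataclass(frozen=True)
class TaskDemand:
    """f* and its per-hand decomposition (all unit vectors)."""

    f_star: np.ndarray
    u_left: np.ndarray   # vertical component: assistant hand / pegwood
    u_right: np.ndarray  # horizontal component: dominant hand / tweezers

    def __post_init__(self):
        for name in ("f_star", "u_left", "u_right"):
            v = np.asarray(getattr(self, name), dtype=float)
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise TaskDemandError(f"{name} must be unit norm")
            object.__setattr__(self, name, v)
        if abs(self.u_left[0]) > 1e-9 or abs(self.u_left[1]) > 1e-9:
            raise TaskDemandError("u_left must be vertical")
        if abs(self.u_right[2]) > 1e-9:
            raise TaskDemandError("u_right must be horizontal")


def fit_mvee(points: np.ndarray, tolerance: float = 1e-6,
             max_iter: int = 10_000, center: bool = True) -> Ellipsoid:
    """Minimum-volume enclosing ellipsoid of a 3-D point cloud.

    Khachiyan's algorithm on the lifted (d+1)-dimensional problem; the
    returned ellipsoid contains every point within ``1 + tolerance`` and
    its volume is within the same factor of the optimum.  ``center=True``
    subtracts the sample mean first (forces are fitted about their mean);
    the returned centre is in the original coordinates either way.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise TaskDemandError("points must be (n, 3)")
    n, d = P.shape
    if n < d + 1:
        raise TaskDemandError(f"need at least {d + 1} points, got {n}")
    mean = P.mean(axis=0)
    X = P - mean if center else P.copy()

    cov = np.cov(X.T) if center else np.cov((X - X.mean(axis=0)).T)
    w, V = np.linalg.eigh(cov)
    if w[0] < 1e-12 * max(w[-1], 1e-30):
        raise DegenerateEllipsoidError(
            "rank-deficient point cloud: no volume along one direction",
            direction=V[:, 0])

    Q = np.column_stack([X, np.ones(n)])  # lifted points, (n, d+1)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        Xu = Q.T @ (u[:, None] * Q)
        try:
            M = np.einsum("ni,ij,nj->n", Q, np.linalg.inv(Xu), Q)
        except np.linalg.LinAlgError:
            raise DegenerateEllipsoidError("singular moment matrix during MVEE")
        j = int(np.argmax(M))
        maximum = M[j]
        step = (maximum - d - 1.0) / ((d + 1.0) * (maximum - 1.0))
        if step < tolerance / (d + 1.0):
            break
        u = (1.0 - step) * u
        u[j] += step
    c_local = X.T @ u
    S = X.T @ (u[:, None] * X) - np.outer(c_local, c_local)
    A = np.linalg.inv(S) / d
    ell = Ellipsoid(center=c_local + (mean if center else 0.0), shape=A)
    # containment guard: numerical safety net, not a fit parameter
    dd = (P if center else P) - ell.center
    vals = np.einsum("ni,ij,nj->n", dd, ell.shape, dd)
    if vals.max() > 1.0 + 100 * max(tolerance, 1e-9):
        ell = Ellipsoid(center=ell.center, shape=ell.shape / vals.max())
    return ell


def major_axis(e: Ellipsoid, ambiguity_tol: float = 1e-9) -> np.ndarray:
    """Unit major-axis direction (eigenvector of the smallest eigenvalue).

    Sign-canonicalized into the negative-Z hemisphere.  A (near-)spherical
    cross-section makes the axis ill-defined and raises with an ambiguity
    flag in the message.
    """
    w, V = np.linalg.eigh(e.shape)
    if (w[1] - w[0]) <= ambiguity_tol * max(w[-1], 1e-30):
        raise TaskDemandError(
            "ambiguous major axis: smallest eigenvalue is (near-)degenerate")
    v = V[:, 0]
    if v[2] > 1e-12:
        v = -v
    elif abs(v[2]) <= 1e-12:
        # horizontal axis: canonicalize by the first nonzero component
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size and v[nz[0]] < 0:
            v = -v
    return v / np.linalg.norm(v)


def mean_demand(axes: Sequence[np.ndarray]) -> np.ndarray:
    """Average (sign-aligned) major-axis direction f*.

    Axes are flipped into the hemisphere of the first axis before the
    component-wise mean, so the result is invariant to per-axis sign flips.
    """
    if len(axes) == 0:
        raise TaskDemandError("mean_demand needs at least one axis")
    A = np.array([np.asarray(a, dtype=float) for a in axes])
    A = A / np.linalg.norm(A, axis=1, keepdims=True)
    ref = A[0]
    signs = np.where(A @ ref < 0, -1.0, 1.0)
    m = (signs[:, None] * A).mean(axis=0)
    nm = np.linalg.norm(m)
    if nm < 1e-12:
        raise TaskDemandError("axes cancel: mean direction undefined")
    return m / nm


def decompose_demand(f_star: np.ndarray, tol: float = 1e-6) -> TaskDemand:
    """Split f* into the vertical (left/pegwood) and horizontal
    (right/tweezers) unit demand vectors."""
    f = np.asarray(f_star, dtype=float)
    nf = np.linalg.norm(f)
    if abs(nf - 1.0) > 1e-6:
        f = f / nf
    if abs(f[2]) < tol:
        raise TaskDemandError("f* has no vertical component: u_left undefined")
    horizontal = np.array([f[0], f[1], 0.0])
    nh = np.linalg.norm(horizontal)
    if nh < tol:
        raise TaskDemandError("f* has no horizontal component: u_right undefined")
    u_left = np.array([0.0, 0.0, np.sign(f[2])])
    return TaskDemand(f_star=f, u_left=u_left, u_right=horizontal / nh)


def demand_from_segments(segments: Sequence[ForceSegment],
                         tolerance: float = 1e-6,
                         center: bool = True) -> TaskDemand:
    """Full pipeline: successful segments -> MVEE axes -> f* -> (u_L, u_R)."""
    good = [s for s in segments if s.success]
    if not good:
        raise TaskDemandError("no successful segments to extract demands from")
    axes: List[np.ndarray] = []
    for seg in good:
        ell = fit_mvee(seg.forces, tolerance=tolerance, center=center)
        axes.append(major_axis(ell))
    return decompose_demand(mean_demand(axes))
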