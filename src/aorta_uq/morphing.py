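"""Wall-motion morphing with radial basis functions and phase interpolation.

A displacement field known at control points (wall vertices) is extended to
arbitrary points by an RBF interpolant augmented with a full affine
polynomial, the standard mesh-morphing formulation: the augmented linear
system enforces exact interpolation at the controls and the four moment
conditions (weights orthogonal to constants and coordinates), which makes
any affine field — in particular rigid motion — reproduced globally.  This
is the operator a flow solver would call to move its volume nodes without
re-meshing.

Temporal continuity across the gated phases is provided by a periodic cubic
spline through the phase snapshots, exact at the knots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.distance import cdist

from .mesh import CardiacPhaseSeries


def _kernel(tag: str, r: np.ndarray, support: float | None) -> np.ndarray:
    if tag == "wendland_c2":
        if support is None or support <= 0:
            raise ValueError("wendland_c2 requires a positive support radius")
        q = np.clip(r / support, 0.0, 1.0)
        return (1.0 - q) ** 4 * (4.0 * q + 1.0)
    if tag == "thin_plate":
        return r ** 3
    if tag == "gaussian":
        if support is None or support <= 0:
            raise ValueError("gaussian requires a positive support radius")
        return np.exp(-(r / support) ** 2)
    raise ValueError(f"unknown kernel {tag!r}")


@dataclass
class RBFModel:
    """Fitted RBF displacement interpolant.

    ``weights`` is (n_controls, 3); ``affine`` is (4, 3) holding the
    constant and linear polynomial coefficients per displacement component.
    """

    control_points: np.ndarray
    weights: np.ndarray
    affine: np.ndarray
    kernel: str = "wendland_c2"
    support_radius: float | None = None

    def moment_residual(self) -> float:
        """Max violation of the 4 moment conditions (should be ~ solver eps)."""
        P = np.hstack([np.ones((len(self.control_points), 1)),
                       self.control_points])
        return float(np.abs(P.T @ self.weights).max())


def fit_rbf(control_points: np.ndarray, displacements: np.ndarray,
            kernel: str = "wendland_c2",
            support_radius: float | None = None) -> RBFModel:
    """Solve the augmented RBF interpolation system.

    The default compact Wendland C2 kernel gets, when no support radius is
    given, a support of 0.75 of the control-cloud bounding-box diagonal
    (large enough to keep the system coupled, finite so distant points see
    only the affine part).

    Raises
    ------
    ValueError
        for fewer than 4 controls, coplanar degeneracy, or duplicate control
        points (named in the message).
    """
    x = np.asarray(control_points, dtype=np.float64)
    d = np.asarray(displacements, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("control points must be (n, 3)")
    if d.shape != x.shape:
        raise ValueError("one 3D displacement per control point required")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 control points")
    r = cdist(x, x)
    close = np.argwhere((r < 1e-9) & ~np.eye(n, dtype=bool))
    if len(close):
        i, j = close[0]
        raise ValueError(f"duplicate control points {i} and {j}")
    if kernel in ("wendland_c2", "gaussian") and support_radius is None:
        diag = np.linalg.norm(x.max(axis=0) - x.min(axis=0))
        support_radius = 0.75 * diag if diag > 0 else 1.0
    K = _kernel(kernel, r, support_radius)
    P = np.hstack([np.ones((n, 1)), x])
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = d
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular RBF system (degenerate controls): {exc}")
    return RBFModel(control_points=x, weights=sol[:n], affine=sol[n:],
                    kernel=kernel, support_radius=support_radius)


def apply_rbf(model: RBFModel, points: np.ndarray,
              chunk: int = 2048) -> np.ndarray:
    """Evaluate the interpolated displacement at arbitrary points."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    out = np.empty_like(pts)
    for lo in range(0, len(pts), chunk):
        block = pts[lo:lo + chunk]
        K = _kernel(model.kernel, cdist(block, model.control_points),
                    model.support_radius)
        P = np.hstack([np.ones((len(block), 1)), block])
        out[lo:lo + chunk] = K @ model.weights + P @ model.affine
    return out


def morph_volume_stub(model: RBFModel, interior_points: np.ndarray) -> np.ndarray:
    """Displace arbitrary (e.g. volume-interior) sample points.

    Identical to :func:`apply_rbf`; exposed separately as the hook a CFD
    solver would call for its volume nodes.
    """
    return apply_rbf(model, interior_points)


def rbf_model_to_dict(model: RBFModel) -> dict:
    """JSON-serializable representation of a fitted model."""
    return {"kernel": model.kernel,
            "support_radius": model.support_radius,
            "control_points": model.control_points.tolist(),
            "weights": model.weights.tolist(),
            "affine": model.affine.tolist()}


def rbf_model_from_dict(d: dict) -> RBFModel:
    return RBFModel(control_points=np.asarray(d["control_points"]),
                    weights=np.asarray(d["weights"]),
                    affine=np.asarray(d["affine"]),
                    kernel=d["kernel"], support_radius=d["support_radius"])


# ---------------------------------------------------------------------------
# temporal interpolation across gated phases


def _phase_spline(series: CardiacPhaseSeries) -> CubicSpline:
    pos = series.positions()
    t = np.append(series.phase_times, series.period)
    y = np.concatenate([pos, pos[:1]], axis=0)  # close the cycle
    return CubicSpline(t, y, axis=0, bc_type="periodic")


def phase_displacement(series: CardiacPhaseSeries, t: float) -> np.ndarray:
    """Per-vertex wall displacement at cycle time ``t`` relative to phase 0.

    Periodic cubic-spline interpolation of the phase snapshots; exact at the
    phase times.
    """
    if series.n_phases < 2:
        raise ValueError("need at least 2 phases to interpolate")
    if not 0.0 <= t < series.period + 1e-12:
        raise ValueError("t must lie within the cardiac period")
    spline = _phase_spline(series)
    return spline(np.mod(t, series.period)) - series.phases[0].vertices


def phase_positions(series: CardiacPhaseSeries, t) -> np.ndarray:
    """Interpolated vertex positions at one or many cycle times."""
    spline = _phase_spline(series)
    return spline(np.mod(np.asarray(t, dtype=float), series.period))
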