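"""Penalized B-spline bases with difference penalties and centering.

Each smooth term is a degree-3 B-spline basis over a fixed domain with a
second-order difference penalty on the coefficients (P-spline). The penalty
null space is {constant, linear}; the constant is removed by a sum-to-zero
centering constraint so smooths are identifiable next to the intercept.
Evaluation outside the domain continues linearly from the boundary value
and slope (first-order continuation). This keeps standardization-year
prediction — which extrapolates beyond the last survey year — a stable,
penalty-independent linear trend, the asymptotic behaviour of thin-plate
and difference-penalized splines.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline


def bspline_design(x: np.ndarray, domain: tuple[float, float],
                   n_basis: int = 10, degree: int = 3) -> np.ndarray:
    """Evaluate an (len(x), n_basis) B-spline design matrix on a fixed domain.

    Points outside the domain get the boundary basis row plus the boundary
    derivative row times the overshoot, i.e. linear extrapolation that stays
    linear in the coefficients.
    """
    lo, hi = float(domain[0]), float(domain[1])
    if not hi > lo:
        hi = lo + 1.0
    if n_basis <= degree:
        raise ValueError(f"n_basis={n_basis} too small for degree {degree}")
    # uniform unclamped knots extending past the domain: on this grid the
    # difference penalty's null space is exactly {constant, linear in x}
    h = (hi - lo) / (n_basis - degree)
    knots = lo + h * (np.arange(n_basis + degree + 1) - degree)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.zeros((len(x), n_basis))
    inside = (x >= lo) & (x <= hi)
    if inside.any():
        out[inside] = BSpline.design_matrix(x[inside], knots, degree).toarray()
    for bound, mask in ((lo, x < lo), (hi, x > hi)):
        if mask.any():
            eps = (hi - lo) * 1e-6
            x_in = bound + eps if bound == lo else bound - eps
            b0 = BSpline.design_matrix(np.array([bound]), knots,
                                       degree).toarray()[0]
            b1 = BSpline.design_matrix(np.array([x_in]), knots,
                                       degree).toarray()[0]
            slope = (b0 - b1) / (bound - x_in)
            out[mask] = b0 + np.outer(x[mask] - bound, slope)
    return out


def difference_penalty(n_basis: int, order: int = 2) -> np.ndarray:
    """Penalty matrix D'D from order-th differences of adjacent coefficients."""
    d = np.diff(np.eye(n_basis), n=order, axis=0)
    return d.T @ d


def centering_transform(basis: np.ndarray) -> np.ndarray:
    """(n_basis, n_basis-1) map onto the sum-to-zero constraint space.

    Columns of the returned Z span the null space of the column-mean vector
    of ``basis`` over the fitting data, so (basis @ Z) has zero-mean fitted
    contributions.
    """
    c = basis.mean(axis=0)
    norm = np.linalg.norm(c)
    if norm == 0:
        return np.eye(basis.shape[1])
    q, _ = np.linalg.qr(c[:, None] / norm, mode="complete")
    return q[:, 1:]


def penalty_rank_logdet(s: np.ndarray) -> tuple[int, float]:
    """Rank and log pseudo-determinant of a PSD penalty block."""
    ev = np.linalg.eigvalsh((s + s.T) / 2.0)
    tol = max(ev.max(), 0.0) * len(ev) * np.finfo(float).eps * 100
    pos = ev[ev > tol]
    return len(pos), float(np.sum(np.log(pos)))
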