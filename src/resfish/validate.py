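"""Calibration of pipeline predictions against independent surveys.

A random-intercept regression of ln(observed standing stock) on
ln(predicted standing stock), with the classification schema as the
grouping factor, summarizes how close predictions are to a one-to-one line:
slope ~ 1 and a conditional pseudo-R^2 near 1 indicate the areal scale-up
reproduces independent whole-reservoir censuses. REML is profiled in closed
form over the single variance ratio theta = var(random)/var(residual).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


def conditional_r2(sigma2_fixed: float, sigma2_random: float,
                   sigma2_resid: float) -> tuple[float, float]:
    """Marginal and conditional pseudo-R^2 from variance components.

    R2_marginal = fixed / total; R2_conditional = (fixed + random) / total.
    """
    comps = (sigma2_fixed, sigma2_random, sigma2_resid)
    if any(c < 0 for c in comps):
        raise ValueError("variance components must be >= 0")
    total = sum(comps)
    if total == 0:
        raise ValueError("all variance components are zero")
    return (sigma2_fixed / total, (sigma2_fixed + sigma2_random) / total)


def sma_slope(x, y) -> float:
    """Standardized-major-axis slope: sign(corr) * sd(y)/sd(x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("sma_slope requires non-degenerate x and y")
    r = np.corrcoef(x, y)[0, 1]
    if r == 0:
        warnings.warn("zero correlation: SMA slope sign undefined, "
                      "returning positive slope")
        return float(sy / sx)
    return float(np.sign(r) * sy / sx)


@dataclass
class CalibrationResults:
    """Mixed-calibration estimates on the ln-ln scale."""

    slope: float
    intercept: float
    slope_se: float
    wald_z: float
    p_slope_eq_1: float
    sigma2_fixed: float
    sigma2_random: float
    sigma2_resid: float
    r2_marginal: float
    r2_conditional: float
    sma_slope: float
    n_obs: int
    n_groups: int
    theta: float
    group_effects: dict

    def summary(self) -> str:
        lines = [
            "Mixed-effects calibration: ln(observed) ~ ln(predicted)",
            f"  n = {self.n_obs} pairs, {self.n_groups} group(s)",
            f"  slope     = {self.slope:.4f} (SE {self.slope_se:.4f})",
            f"  intercept = {self.intercept:.4f}",
            f"  H0 slope=1: z = {self.wald_z:.3f}, p = {self.p_slope_eq_1:.3f}",
            f"  variance components: fixed {self.sigma2_fixed:.4f}, "
            f"random {self.sigma2_random:.4f}, residual {self.sigma2_resid:.4f}",
            f"  R2 marginal = {self.r2_marginal:.4f}, "
            f"conditional = {self.r2_conditional:.4f}",
            f"  SMA slope = {self.sma_slope:.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "group_effects"}
        d["group_effects"] = {str(k): float(v)
                              for k, v in self.group_effects.items()}
        return d


class MixedCalibration:
    """Random-intercept model of ln(observed) on ln(predicted).

    Parameters
    ----------
    observed, predicted : positive standing stocks (kg).
    groups : label per pair (e.g. the classification schema); with a single
        group the random effect is degenerate and the fit reduces to OLS
        with a warning.
    log_scale : fit on ln-ln scale (default) or raw scale.
    """

    def __init__(self, observed, predicted, groups=None,
                 log_scale: bool = True):
        obs = np.asarray(observed, dtype=float)
        pred = np.asarray(predicted, dtype=float)
        if len(obs) != len(pred):
            raise ValueError("observed and predicted must be equal length")
        if len(obs) < 3:
            raise ValueError("need at least 3 pairs")
        if log_scale and (np.any(obs <= 0) or np.any(pred <= 0)):
            raise ValueError("log-scale calibration needs positive values")
        self.y = np.log(obs) if log_scale else obs
        self.x = np.log(pred) if log_scale else pred
        self.groups = np.asarray(["g0"] * len(obs) if groups is None
                                 else groups)
        self.log_scale = log_scale
        self.levels = sorted(set(self.groups.tolist()))

    # REML profile over theta = sigma2_random / sigma2_resid
    def _reml_pieces(self, theta: float):
        n = len(self.y)
        x_mat = np.column_stack([np.ones(n), self.x])
        z = np.column_stack([(self.groups == g).astype(float)
                             for g in self.levels])
        v = np.eye(n) + theta * (z @ z.T)
        v_inv = np.linalg.inv(v)
        xtvx = x_mat.T @ v_inv @ x_mat
        beta = np.linalg.solve(xtvx, x_mat.T @ v_inv @ self.y)
        r = self.y - x_mat @ beta
        quad = float(r @ v_inv @ r)
        sigma2 = quad / (n - 2)
        sign, logdet_v = np.linalg.slogdet(v)
        _, logdet_xtvx = np.linalg.slogdet(xtvx)
        neg2_reml = ((n - 2) * np.log(max(sigma2, 1e-300)) + logdet_v
                     + logdet_xtvx)
        return beta, sigma2, xtvx, v_inv, z, neg2_reml

    def fit(self) -> CalibrationResults:
        single_group = len(self.levels) < 2
        if single_group:
            warnings.warn("single group: random effect degenerate, "
                          "reducing to ordinary least squares")
            theta = 0.0
        else:
            res = optimize.minimize_scalar(
                lambda lt: self._reml_pieces(np.exp(lt))[5],
                bounds=(-12.0, 12.0), method="bounded",
                options={"xatol": 1e-8})
            theta = float(np.exp(res.x))
            # boundary check: no-random-effect model may be better
            if self._reml_pieces(0.0)[5] <= self._reml_pieces(theta)[5]:
                theta = 0.0
        beta, sigma2, xtvx, v_inv, z, _ = self._reml_pieces(theta)
        cov_beta = np.linalg.inv(xtvx) * sigma2
        slope_se = float(np.sqrt(cov_beta[1, 1]))
        if slope_se > 0:
            wald = (beta[1] - 1.0) / slope_se
        else:  # perfect fit: slope exactly determined
            wald = 0.0 if abs(beta[1] - 1.0) < 1e-10 else np.inf
        p = float(2 * stats.norm.sf(abs(wald)))

        sigma2_resid = float(sigma2)
        sigma2_random = float(theta * sigma2)
        fitted_fixed = beta[0] + beta[1] * self.x
        sigma2_fixed = float(np.var(fitted_fixed, ddof=0))
        if sigma2_fixed + sigma2_random + sigma2_resid == 0:
            r2m, r2c = 1.0, 1.0
        else:
            r2m, r2c = conditional_r2(sigma2_fixed, sigma2_random,
                                      sigma2_resid)
        # BLUPs of the group intercepts
        resid = self.y - fitted_fixed
        blup = {}
        for g in self.levels:
            mask = self.groups == g
            n_g = int(mask.sum())
            shrink = theta / (theta + 1.0 / n_g) if theta > 0 else 0.0
            blup[g] = float(shrink * resid[mask].mean())
        try:
            sma = sma_slope(self.x, self.y)
        except ValueError:
            sma = np.nan
        return CalibrationResults(
            slope=float(beta[1]), intercept=float(beta[0]),
            slope_se=slope_se, wald_z=float(wald), p_slope_eq_1=p,
            sigma2_fixed=sigma2_fixed, sigma2_random=sigma2_random,
            sigma2_resid=sigma2_resid, r2_marginal=r2m, r2_conditional=r2c,
            sma_slope=sma, n_obs=len(self.y), n_groups=len(self.levels),
            theta=theta, group_effects=blup)


def fit_mixed_calibration(observed, predicted, groups=None,
                          log_scale: bool = True) -> CalibrationResults:
    """Convenience wrapper: build and fit :class:`MixedCalibration`."""
    return MixedCalibration(observed, predicted, groups,
                            log_scale=log_scale).fit()
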