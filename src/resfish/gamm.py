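"""Gamma/log-link penalized-spline mixed model of survey biomass density.

The model for corrected density y (kg/ha) of survey i in class c on
reservoir r is

    y_i ~ Gamma(mean mu_i),   log mu_i = b0 + a_c + f_c(age_i) + g(year_i) + u_r

with a separate penalized smooth of reservoir age for every class (a factor
smooth sharing one smoothing parameter), a penalized smooth of sampling
year, and ridge-penalized per-reservoir intercepts (the random effect).
Fitting is penalized IRLS; for a log-link Gamma the IRLS working weights are
identically 1, so each step is a penalized least-squares solve on the
working response. Smoothing parameters are chosen by a Gaussian
working-model REML criterion (Nelder-Mead on log-lambda) with a GCV
coordinate-grid fallback.

The model/results split follows the usual statsmodels pattern:
``FishDensityGAMM(table).fit()`` returns a ``FishDensityGAMMResults`` that
carries coefficients, smoothing parameters, effective degrees of freedom,
deviance explained, and prediction methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .classify import UNCLASSIFIED
from .splines import (bspline_design, centering_transform, difference_penalty,
                      penalty_rank_logdet)


class EstimationError(RuntimeError):
    """Model could not be estimated; carries diagnostics in args."""


@dataclass
class ModelSpec:
    """Structure and tuning of the density model."""

    basis_dim: int = 10
    min_class_n: int = 5
    standardization_year: int = 1993
    smoothing_method: str = "reml"  # "reml" or "gcv"
    include_random: bool = True
    include_year_smooth: bool = True
    age_domain: tuple[float, float] | None = None
    year_domain: tuple[float, float] | None = None
    max_pirls_iter: int = 100
    tol: float = 1e-6
    log_lambda_bounds: tuple[float, float] = (-10.0, 20.0)

    def __post_init__(self) -> None:
        if self.basis_dim < 3:
            raise ValueError("basis_dim must be >= 3")
        if self.min_class_n < 1:
            raise ValueError("min_class_n must be >= 1")
        if self.smoothing_method not in ("reml", "gcv"):
            raise ValueError("smoothing_method must be 'reml' or 'gcv'")


def prepare_model_table(linked: pd.DataFrame, assignments: pd.DataFrame,
                        spec: ModelSpec | None = None
                        ) -> tuple[pd.DataFrame, dict]:
    """Join surveys to class labels and apply the modelling exclusions.

    Drops rows with a missing/unclassified class, missing age or year, or
    non-positive density (outside Gamma support), then removes classes with
    fewer than ``min_class_n`` remaining rows. The report itemizes every
    removal.
    """
    spec = spec or ModelSpec()
    df = linked.merge(assignments[["reservoir_id", "class_label"]],
                      on="reservoir_id", how="left")
    out = pd.DataFrame({
        "reservoir_id": df["reservoir_id"],
        "class_label": df["class_label"],
        "age": pd.to_numeric(df.get("reservoir_age"), errors="coerce"),
        "year": pd.to_numeric(df.get("year_sampled"), errors="coerce"),
        "density": pd.to_numeric(df.get("corrected_density_kg_ha"),
                                 errors="coerce"),
    })
    report: dict = {"rows_in": len(out)}
    bad_class = out["class_label"].isna() | (out["class_label"] == UNCLASSIFIED)
    bad_age = out["age"].isna()
    bad_year = out["year"].isna()
    bad_density = out["density"].isna() | (out["density"] <= 0)
    report["missing_class"] = int(bad_class.sum())
    report["missing_age"] = int((~bad_class & bad_age).sum())
    report["missing_year"] = int((~bad_class & ~bad_age & bad_year).sum())
    report["nonpositive_density"] = int(
        (~bad_class & ~bad_age & ~bad_year & bad_density).sum())
    out = out[~(bad_class | bad_age | bad_year | bad_density)]

    counts = out["class_label"].value_counts()
    small = counts[counts < spec.min_class_n].index.tolist()
    report["dropped_classes"] = sorted(small)
    report["small_class_rows"] = int(out["class_label"].isin(small).sum())
    out = out[~out["class_label"].isin(small)].reset_index(drop=True)
    report["rows_out"] = len(out)
    if len(out) == 0:
        raise EstimationError("no usable rows after exclusions", report)
    return out, report


def gamma_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return float(2.0 * np.sum((y - mu) / mu - np.log(y / mu)))


class FishDensityGAMM:
    """Penalized Gamma/log-link additive mixed model of survey density.

    Parameters
    ----------
    table : DataFrame with columns reservoir_id, class_label, age, year,
        density (the output of :func:`prepare_model_table`).
    spec : ModelSpec
    """

    def __init__(self, table: pd.DataFrame, spec: ModelSpec | None = None):
        self.spec = spec or ModelSpec()
        if len(table) == 0:
            raise EstimationError("empty model table")
        t = table.reset_index(drop=True)
        if (t["density"] <= 0).any():
            raise EstimationError("density must be positive (Gamma support)")
        self.table = t
        self.y = t["density"].to_numpy(dtype=float)
        self.classes = sorted(t["class_label"].unique())
        self.reservoirs = sorted(t["reservoir_id"].unique()) \
            if self.spec.include_random else []
        age = t["age"].to_numpy(dtype=float)
        year = t["year"].to_numpy(dtype=float)
        # bases span the observed data; later years/ages extrapolate linearly
        self.age_domain = self.spec.age_domain or (0.0, float(age.max()) + 1.0)
        self.year_domain = self.spec.year_domain or (float(year.min()),
                                                     float(year.max()))
        # per-reservoir completion year (year - age), for prediction ages
        self.year_completed = (t["year"] - t["age"]).groupby(
            t["reservoir_id"]).first().to_dict()
        self.class_of_reservoir = t.groupby("reservoir_id")["class_label"] \
            .first().to_dict()
        self._build_design(age, year)

    # ------------------------------------------------------------ design
    def _build_design(self, age: np.ndarray, year: np.ndarray) -> None:
        n = len(self.y)
        k = self.spec.basis_dim
        cols: list[np.ndarray] = [np.ones((n, 1))]
        self.slices: dict[str, slice] = {"intercept": slice(0, 1)}
        p = 1

        cls = self.table["class_label"].to_numpy()
        self.class_index = {c: i for i, c in enumerate(self.classes)}
        if len(self.classes) > 1:
            d = np.zeros((n, len(self.classes) - 1))
            for c in self.classes[1:]:
                d[cls == c, self.class_index[c] - 1] = 1.0
            cols.append(d)
            self.slices["class"] = slice(p, p + d.shape[1])
            p += d.shape[1]

        b_age = bspline_design(age, self.age_domain, k)
        s_raw = difference_penalty(k, order=2)
        self.age_z: dict[str, np.ndarray] = {}
        self.age_slices: dict[str, slice] = {}
        age_pen_blocks: list[tuple[slice, np.ndarray]] = []
        for c in self.classes:
            rows = cls == c
            z = centering_transform(b_age[rows])
            self.age_z[c] = z
            block = np.zeros((n, z.shape[1]))
            block[rows] = b_age[rows] @ z
            cols.append(block)
            sl = slice(p, p + z.shape[1])
            self.age_slices[c] = sl
            age_pen_blocks.append((sl, z.T @ s_raw @ z))
            p += z.shape[1]

        self.year_z = None
        if self.spec.include_year_smooth:
            b_year = bspline_design(year, self.year_domain, k)
            self.year_z = centering_transform(b_year)
            cols.append(b_year @ self.year_z)
            self.slices["year"] = slice(p, p + self.year_z.shape[1])
            p += self.year_z.shape[1]

        self.res_index = {r: i for i, r in enumerate(self.reservoirs)}
        if self.reservoirs:
            d = np.zeros((n, len(self.reservoirs)))
            rid = self.table["reservoir_id"].to_numpy()
            for r, i in self.res_index.items():
                d[rid == r, i] = 1.0
            cols.append(d)
            self.slices["random"] = slice(p, p + d.shape[1])
            p += d.shape[1]

        self.X = np.hstack(cols)
        self.p = p

        # penalty blocks: (name, embedded p x p matrix, rank, log pseudo-det)
        self.penalties: list[tuple[str, np.ndarray, int, float]] = []
        s_age = np.zeros((p, p))
        for sl, sz in age_pen_blocks:
            s_age[sl, sl] = sz
        rank, ldet = penalty_rank_logdet(s_age)
        self.penalties.append(("age", s_age, rank, ldet))
        if "year" in self.slices:
            s_year = np.zeros((p, p))
            sl = self.slices["year"]
            s_year[sl, sl] = self.year_z.T @ s_raw @ self.year_z
            rank, ldet = penalty_rank_logdet(s_year[sl, sl])
            self.penalties.append(("year", s_year, rank, ldet))
        if "random" in self.slices:
            s_re = np.zeros((p, p))
            sl = self.slices["random"]
            s_re[sl, sl] = np.eye(sl.stop - sl.start)
            self.penalties.append(("random", s_re,
                                   sl.stop - sl.start, 0.0))

        self.XtX = self.X.T @ self.X
        self._jitter = 1e-9 * np.trace(self.XtX) / p
        self._eta_warm = np.log(self.y)

    # ------------------------------------------------------------ fitting
    def _penalty_total(self, log_lambdas: np.ndarray) -> np.ndarray:
        s = np.zeros((self.p, self.p))
        for (name, mat, _, _), ll in zip(self.penalties, log_lambdas):
            s += np.exp(ll) * mat
        return s

    def _pirls(self, log_lambdas: np.ndarray, strict: bool = False):
        """Penalized IRLS at fixed smoothing parameters.

        Returns (beta, eta, z, factor, S, converged, n_iter). Working
        weights are 1 for the log-link Gamma, so each step solves
        (X'X + S) beta = X'z.
        """
        s = self._penalty_total(log_lambdas)
        a = self.XtX + s + self._jitter * np.eye(self.p)
        try:
            factor = cho_factor(a, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise EstimationError("singular penalized system") from exc
        eta = np.clip(self._eta_warm, -30.0, 30.0)
        crit_old = np.inf
        converged = False
        beta = None
        z = None
        for it in range(1, self.spec.max_pirls_iter + 1):
            mu = np.exp(np.clip(eta, -30.0, 30.0))
            z = eta + (self.y - mu) / mu
            beta = cho_solve(factor, self.X.T @ z)
            eta_new = self.X @ beta
            crit = gamma_deviance(self.y, np.exp(np.clip(eta_new, -30, 30))) \
                + float(beta @ s @ beta)
            if not np.isfinite(crit):
                # retreat halfway toward the previous linear predictor
                eta = 0.5 * (eta + eta_new)
                continue
            if abs(crit - crit_old) < self.spec.tol * (abs(crit) + 0.1):
                eta = eta_new
                converged = True
                break
            crit_old = crit
            eta = eta_new
        if strict and not converged:
            raise EstimationError(
                "penalized IRLS did not converge",
                {"iterations": self.spec.max_pirls_iter,
                 "last_criterion": crit_old})
        self._eta_warm = eta
        return beta, eta, z, factor, s, converged, it

    def _score(self, log_lambdas: np.ndarray, method: str) -> float:
        lo, hi = self.spec.log_lambda_bounds
        ll = np.clip(log_lambdas, lo, hi)
        try:
            beta, eta, z, factor, s, _, _ = self._pirls(ll)
        except EstimationError:
            return 1e12
        n = len(self.y)
        rss = float(np.sum((z - eta) ** 2))
        pen = float(beta @ s @ beta)
        if method == "gcv":
            h = cho_solve(factor, self.XtX)
            edf = float(np.trace(h))
            score = n * rss / max(n - edf, 1e-3) ** 2
        else:
            mp = self.p - sum(r for _, _, r, _ in self.penalties)
            dp = rss + pen
            phi = max(dp / max(n - mp, 1.0), 1e-300)
            logdet_a = 2.0 * float(np.sum(np.log(np.diag(factor[0]))))
            logdet_s = sum(r * ll_j + ld for (_, _, r, ld), ll_j
                           in zip(self.penalties, ll))
            score = ((n - mp) * (np.log(2 * np.pi * phi) + 1.0)
                     + logdet_a - logdet_s)
        # soft barrier keeps the search inside the bounds
        score += float(np.sum((log_lambdas - ll) ** 2))
        return score if np.isfinite(score) else 1e12

    def _grid_fallback(self, method: str) -> np.ndarray:
        """Coordinate search on a coarse log-lambda grid."""
        grid = np.linspace(-4.0, 14.0, 10)
        best = np.zeros(len(self.penalties))
        for _ in range(2):
            for j in range(len(best)):
                scores = []
                for g in grid:
                    trial = best.copy()
                    trial[j] = g
                    scores.append(self._score(trial, method))
                best[j] = grid[int(np.argmin(scores))]
        return best

    def fit(self, lambdas: dict[str, float] | None = None
            ) -> "FishDensityGAMMResults":
        """Estimate coefficients; select smoothing parameters unless given.

        ``lambdas`` maps penalty-block names ("age", "year", "random") to
        fixed smoothing parameters, bypassing selection (useful for
        penalty-limit checks).
        """
        names = [nm for nm, _, _, _ in self.penalties]
        method_used = self.spec.smoothing_method
        if lambdas is not None:
            ll = np.array([np.log(lambdas.get(nm, 1.0)) for nm in names])
            method_used = "fixed"
        else:
            x0 = np.zeros(len(names))
            # explicit wide initial simplex: log-lambda moves in units of ~2
            simplex = np.vstack([x0] + [x0 + 2.0 * e
                                        for e in np.eye(len(names))])
            res = optimize.minimize(
                self._score, x0, args=(self.spec.smoothing_method,),
                method="Nelder-Mead",
                options={"maxiter": 120 * max(len(names), 1),
                         "initial_simplex": simplex,
                         "xatol": 1e-2, "fatol": 1e-3})
            ll = np.clip(res.x, *self.spec.log_lambda_bounds)
            if not np.isfinite(self._score(ll, self.spec.smoothing_method)) \
                    or not res.success and not np.isfinite(res.fun):
                ll = self._grid_fallback("gcv")
                method_used = "gcv-grid"

        beta, eta, z, factor, s, converged, n_iter = self._pirls(ll, strict=True)
        mu = np.exp(np.clip(eta, -30, 30))
        n = len(self.y)
        h = cho_solve(factor, self.XtX)
        edf_total = float(np.trace(h))
        edf_blocks: dict[str, float] = {}
        diag_h = np.diag(h)
        for c in self.classes:
            edf_blocks[f"age:{c}"] = float(diag_h[self.age_slices[c]].sum())
        for key in ("year", "random"):
            if key in self.slices:
                edf_blocks[key] = float(diag_h[self.slices[key]].sum())
        dev = gamma_deviance(self.y, mu)
        dev_null = gamma_deviance(self.y, np.full(n, self.y.mean()))
        pearson = float(np.sum(((self.y - mu) / mu) ** 2))
        dispersion = pearson / max(n - edf_total, 1.0)
        return FishDensityGAMMResults(
            model=self, beta=beta,
            lambdas={nm: float(np.exp(v)) for nm, v in zip(names, ll)},
            edf=edf_blocks, edf_total=edf_total,
            deviance=dev,
            deviance_explained=1.0 - dev / dev_null if dev_null > 0 else 0.0,
            dispersion=dispersion, converged=converged, n_iter=n_iter,
            smoothing_method=method_used)

    # ---------------------------------------------------------- prediction
    def design_row(self, class_label: str, age: float, year: float,
                   reservoir_id: str | None = None) -> np.ndarray:
        if class_label not in self.class_index:
            raise KeyError(f"class {class_label!r} not in fitted model")
        row = np.zeros(self.p)
        row[0] = 1.0
        ci = self.class_index[class_label]
        if len(self.classes) > 1 and ci > 0:
            row[self.slices["class"].start + ci - 1] = 1.0
        b = bspline_design(np.array([age], dtype=float), self.age_domain,
                           self.spec.basis_dim)[0]
        row[self.age_slices[class_label]] = b @ self.age_z[class_label]
        if self.year_z is not None:
            by = bspline_design(np.array([year], dtype=float),
                                self.year_domain, self.spec.basis_dim)[0]
            row[self.slices["year"]] = by @ self.year_z
        if reservoir_id is not None and reservoir_id in self.res_index:
            row[self.slices["random"].start + self.res_index[reservoir_id]] = 1.0
        return row


@dataclass
class FishDensityGAMMResults:
    """Fitted density model: estimates, smoothness, fit quality, prediction."""

    model: FishDensityGAMM
    beta: np.ndarray
    lambdas: dict[str, float]
    edf: dict[str, float]
    edf_total: float
    deviance: float
    deviance_explained: float
    dispersion: float
    converged: bool
    n_iter: int
    smoothing_method: str

    def predict(self, class_label: str, year: float,
                reservoir_id: str | None = None,
                age: float | None = None) -> float:
        """Predicted density (kg/ha) for a class at a calendar year.

        With ``reservoir_id`` given (a sampled reservoir) the reservoir's
        own random intercept is included and its age is advanced to the
        prediction year; otherwise the prediction is population-level
        (random intercept 0) at the supplied ``age``, or at the class mean
        age for that year.
        """
        m = self.model
        if age is None:
            if reservoir_id is not None and reservoir_id in m.year_completed:
                age = max(year - m.year_completed[reservoir_id], 0.0)
            else:
                ages = [year - yc for r, yc in m.year_completed.items()
                        if m.class_of_reservoir.get(r) == class_label]
                if not ages:
                    raise KeyError(f"no sampled reservoirs in {class_label!r}")
                age = max(float(np.mean(ages)), 0.0)
        row = m.design_row(class_label, float(age), float(year), reservoir_id)
        return float(np.exp(row @ self.beta))

    def class_mean_density(self, year: float | None = None
                           ) -> dict[str, float]:
        """Per-class arithmetic mean of per-sampled-reservoir predictions."""
        m = self.model
        year = m.spec.standardization_year if year is None else year
        out: dict[str, float] = {}
        for c in m.classes:
            rids = [r for r, cl in m.class_of_reservoir.items() if cl == c]
            preds = [self.predict(c, year, reservoir_id=r) for r in rids]
            if preds:
                out[c] = float(np.mean(preds))
        return out

    def global_mean_density(self, year: float | None = None) -> float:
        """Mean predicted density over all sampled reservoirs."""
        m = self.model
        year = m.spec.standardization_year if year is None else year
        preds = [self.predict(m.class_of_reservoir[r], year, reservoir_id=r)
                 for r in m.class_of_reservoir]
        return float(np.mean(preds))

    def random_intercept_sd(self) -> float:
        """Random-intercept sd (log scale).

        Uses the ridge/random-effect equivalence sigma_u^2 = phi / lambda_re;
        falls back to the empirical sd of the fitted intercepts when the
        smoothing parameter is unavailable.
        """
        if "random" not in self.model.slices:
            return 0.0
        lam = self.lambdas.get("random")
        if lam and lam > 0 and self.dispersion > 0:
            return float(np.sqrt(self.dispersion / lam))
        u = self.beta[self.model.slices["random"]]
        return float(np.std(u, ddof=1)) if len(u) > 1 else 0.0

    def summary(self) -> str:
        lines = [
            "Gamma/log-link penalized-spline density model",
            f"  observations:        {len(self.model.y)}",
            f"  classes:             {len(self.model.classes)}",
            f"  reservoirs (random): {len(self.model.reservoirs)}",
            f"  smoothing selection: {self.smoothing_method}",
            f"  converged:           {self.converged} ({self.n_iter} it)",
            f"  total edf:           {self.edf_total:.2f}",
            f"  deviance explained:  {100 * self.deviance_explained:.1f}%",
            f"  dispersion (Pearson):{self.dispersion: .4f}",
            "  smoothing parameters:",
        ]
        for nm, lam in self.lambdas.items():
            lines.append(f"    lambda[{nm}] = {lam:.4g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "lambdas": self.lambdas, "edf": self.edf,
            "edf_total": self.edf_total,
            "deviance_explained": self.deviance_explained,
            "dispersion": self.dispersion, "converged": self.converged,
            "smoothing_method": self.smoothing_method,
            "n_classes": len(self.model.classes),
            "n_obs": len(self.model.y),
        }
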