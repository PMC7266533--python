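"""Flexible parametric relative-survival (excess hazard) model.

The all-cause hazard of patient i decomposes as

    h(t | Z = z_i) = h*(t | Z1 = z1_i) + lambda(t | Z2 = z2_i)

with h* the expected (life-table) rate and lambda the excess hazard due
to the cancer.  The model is parametric on the log cumulative excess
hazard scale:

    ln Lambda(t | z) = eta(ln t, z)  =>  R(t | z) = exp(-exp(eta)),
    lambda(t | z) = exp(eta) * (d eta / d ln t) / t,

with eta a restricted cubic spline in ln t plus covariate effects and
optional time-dependent effects.  Right-censored data contribute

    l_i = d_i * ln(h*(t_i) + lambda(t_i)) - Lambda(t_i)

to the log likelihood (the expected-survival term ln S*(t_i) is free of
the parameters and is dropped).  Negative fitted excess hazards are
admissible at some times; only positivity of the *total* hazard at the
observed event times is required, enforced through a linearly extended
log in the likelihood and a post-fit admissibility check.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import Cohort
from .design import DesignInfo, ModelSpec
from .lifetable import LifeTable

logger = logging.getLogger(__name__)

__all__ = ["ExcessHazardModel", "ExcessHazardResults", "ConvergenceError"]



class ConvergenceError(RuntimeError):
    """Raised when the optimizer fails; carries the diagnostics dict."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ExcessHazardModel:
    """Maximum-likelihood excess-hazard model against a life table.

    Parameters
    ----------
    cohort : Cohort
        Patient-level data (positive follow-up times, 0/1 events).
    life_table : LifeTable
        Source of the expected rates h*(t | Z1).
    spec : ModelSpec
        Baseline spline df, covariate terms and time-dependent effects.
    """

    def __init__(self, cohort: Cohort, life_table: LifeTable,
                 spec: ModelSpec | None = None):
        self.cohort = cohort
        self.life_table = life_table
        self.spec = spec or ModelSpec()
        cohort.validate_against(life_table)

        t = cohort.times()
        d = cohort.events()
        if d.sum() < 1:
            raise ValueError("cohort contains no events")
        self.design = DesignInfo(self.spec, cohort.data, np.log(t[d == 1]))
        self._t = t
        self._d = d
        self._X, self._Xd = self.design.design(cohort.data, np.log(t))
        self._check_rank()
        # expected rate and cumulative expected hazard at each patient's
        # event/censoring time (one life-table path pass per patient)
        ages, years, sexes, strata = cohort.z1_records()
        self._hstar = np.empty(cohort.n)
        self._expected_cum = np.empty(cohort.n)
        for i in range(cohort.n):
            path = life_table.hazard_path(ages[i], years[i], sexes[i],
                                          strata[i], t_max=t[i])
            self._hstar[i] = path.rates[-1]
            self._expected_cum[i] = path.cum[-1]

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, life_table: LifeTable,
                       spec: ModelSpec | None = None, **cohort_columns
                       ) -> "ExcessHazardModel":
        return cls(Cohort(data, **cohort_columns), life_table, spec)

    # ------------------------------------------------------------------
    def _check_rank(self):
        q, r = np.linalg.qr(self._X)
        diag = np.abs(np.diag(r))
        bad = diag < 1e-8 * max(diag.max(), 1.0)
        if bad.any():
            names = [self.design.column_names[j] for j in np.flatnonzero(bad)]
            raise ValueError(f"design matrix is rank deficient; collinear term(s): {names}")

    @property
    def n_params(self) -> int:
        return self.design.n_params

    def _eta_parts(self, params):
        eta = self._X @ params
        etad = self._Xd @ params          # d eta / d ln t
        return eta, etad

    # The event term ln(h* + lambda) is undefined when the total hazard is
    # not positive.  For the optimizer's sake ln is extended linearly below
    # _HFLOOR: continuous and differentiable everywhere, strongly negative
    # and sloping back toward the admissible region.  The fitted optimum is
    # checked to lie strictly inside it.
    _HFLOOR = 1e-8

    def _safe_log(self, total):
        bad = total < self._HFLOOR
        out = np.log(np.where(bad, self._HFLOOR, total))
        return np.where(bad, out + (total - self._HFLOOR) / self._HFLOOR, out), bad

    def loglike(self, params) -> float:
        """Log likelihood (up to the constant ln S* terms)."""
        eta, etad = self._eta_parts(params)
        eta = np.clip(eta, -200, 200)
        Lam = np.exp(eta)
        lam = Lam * etad / self._t
        total = self._hstar + lam
        ev = self._d == 1
        logs, _ = self._safe_log(total[ev])
        return float(np.sum(logs) - np.sum(Lam))

    def score(self, params) -> np.ndarray:
        """Analytic gradient of :meth:`loglike`."""
        eta, etad = self._eta_parts(params)
        eta = np.clip(eta, -200, 200)
        Lam = np.exp(eta)
        lam = Lam * etad / self._t
        total = self._hstar + lam
        ev = self._d == 1
        _, bad_ev = self._safe_log(total[ev])
        # d ln(total)/d total, with the linear extension's constant slope
        dlog = np.zeros_like(self._t)
        dlog[ev] = np.where(bad_ev, 1.0 / self._HFLOOR, 1.0 / total[ev])
        # d lambda / d theta = (Lam / t) * (etad * x + x')
        w = dlog * self._d * (Lam / self._t)
        grad = (
            (w * etad) @ self._X + w @ self._Xd
            - Lam @ self._X
        )
        return grad

    def _start_params(self) -> np.ndarray:
        """Deterministic start: crude constant-excess-hazard fit."""
        t, d = self._t, self._d
        excess_events = max(d.sum() - self._expected_cum.sum(), 0.5)
        lam0 = max(excess_events / t.sum(), 1e-6)
        target = np.log(lam0 * t)   # eta for Lambda(t) = lam0 * t
        theta0, *_ = np.linalg.lstsq(self._X, target, rcond=None)
        return theta0

    def fit(self, start_params=None, maxiter: int = 500,
            gtol: float = 1e-6) -> "ExcessHazardResults":
        """Maximize the likelihood (BFGS with analytic gradient, with a
        derivative-free Nelder-Mead fallback), and return results with
        the covariance taken as the inverse observed information."""
        x0 = np.asarray(start_params, float) if start_params is not None \
            else self._start_params()
        neg = lambda p: -self.loglike(p)
        njac = lambda p: -self.score(p)
        res = optimize.minimize(neg, x0, jac=njac, method="BFGS",
                                options={"gtol": gtol, "maxiter": maxiter})
        grad_norm = float(np.linalg.norm(self.score(res.x), np.inf))
        niter = int(res.nit)
        if grad_norm > 1e-3 * (1.0 + abs(res.fun)):
            # gradient-free fallback from the best point so far
            res2 = optimize.minimize(neg, res.x, method="Nelder-Mead",
                                     options={"maxiter": 2000, "fatol": 1e-10,
                                              "xatol": 1e-10})
            if res2.fun <= res.fun:
                res = res2
            grad_norm = float(np.linalg.norm(self.score(res.x), np.inf))
            niter += int(res2.nit)
        llf = -float(res.fun)
        diagnostics = {"loglike": llf, "grad_norm": grad_norm,
                       "iterations": niter, "message": str(res.message)}
        eta, etad = self._eta_parts(res.x)
        total = self._hstar + np.exp(np.clip(eta, -200, 200)) * etad / self._t
        if not np.isfinite(llf) or (total[self._d == 1] <= 0).any():
            raise ConvergenceError(
                "optimum has non-positive total hazard at an event time",
                diagnostics)
        if grad_norm > 1e-2 * (1.0 + abs(llf)):
            raise ConvergenceError(
                f"gradient norm {grad_norm:.3g} above tolerance", diagnostics)
        cov = self._covariance(res.x)
        return ExcessHazardResults(self, res.x, cov, diagnostics)

    def _covariance(self, params) -> np.ndarray:
        """Inverse observed information; Hessian by central differences of
        the analytic score."""
        p = len(params)
        H = np.empty((p, p))
        for k in range(p):
            h = 1e-5 * (1.0 + abs(params[k]))
            up = params.copy(); up[k] += h
            dn = params.copy(); dn[k] -= h
            H[k] = -(self.score(up) - self.score(dn)) / (2 * h)
        H = 0.5 * (H + H.T)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            logger.warning("observed information singular; using pseudo-inverse")
            cov = np.linalg.pinv(H)
        cov = 0.5 * (cov + cov.T)
        if (np.diag(cov) < -1e-10).any():
            logger.warning("covariance has negative diagonal entries")
        return cov


@dataclass
class ExcessHazardResults:
    """Fitted excess-hazard model: coefficients, covariance, predictions."""

    model: ExcessHazardModel
    params: np.ndarray
    cov: np.ndarray
    diagnostics: dict

    # -- basic accessors -------------------------------------------------
    @property
    def llf(self) -> float:
        return self.diagnostics["loglike"]

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0, None))

    def cov_params(self) -> np.ndarray:
        return self.cov

    @property
    def converged(self) -> bool:
        return True

    def summary(self) -> str:
        """Coefficient table with Wald z statistics."""
        names = self.model.design.column_names
        se = self.bse
        z = np.divide(self.params, se, out=np.full_like(self.params, np.nan),
                      where=se > 0)
        pv = 2 * stats.norm.sf(np.abs(z))
        lines = [
            "Excess hazard model (log cumulative excess hazard scale)",
            f"  n = {self.model.cohort.n}, events = {int(self.model.cohort.events().sum())}, "
            f"log-likelihood = {self.llf:.3f}",
            f"  converged: grad_norm = {self.diagnostics['grad_norm']:.2e}, "
            f"iterations = {self.diagnostics['iterations']}",
            "",
            f"{'term':<24}{'coef':>12}{'se':>12}{'z':>9}{'P>|z|':>9}",
        ]
        for j, nm in enumerate(names):
            lines.append(
                f"{nm:<24}{self.params[j]:>12.5f}{se[j]:>12.5f}"
                f"{z[j]:>9.3f}{pv[j]:>9.4f}"
            )
        return "\n".join(lines)

    # -- conditional predictions ----------------------------------------
    def _records(self, records, x_override):
        df = self.model.cohort.data if records is None else records
        if x_override is not None:
            if self.model.cohort.exposure is None:
                raise ValueError("cohort declares no exposure column")
            df = df.copy()
            df[self.model.cohort.exposure] = x_override
        return df

    def linear_predictor(self, records=None, times=None, x_override=None,
                         params=None, deriv: bool = False) -> np.ndarray:
        """eta (or d eta / d ln t) on a records x times grid."""
        times = np.asarray(times, dtype=float)
        if np.any(times <= 0):
            raise ValueError("times must be > 0 for conditional predictions")
        theta = self.params if params is None else np.asarray(params, float)
        df = self._records(records, x_override)
        g = self.model.design.covariate_parts(df)
        f = self.model.design.time_parts(np.log(times), deriv=deriv)
        return (g * theta) @ f.T

    def predict_relative_survival(self, records=None, times=None,
                                  x_override=None, params=None) -> np.ndarray:
        """R(t | Z2) = exp(-exp(eta)); shape (n_records, n_times)."""
        eta = self.linear_predictor(records, times, x_override, params)
        return np.exp(-np.exp(np.clip(eta, -700, 700)))

    def predict_excess_hazard(self, records=None, times=None,
                              x_override=None, params=None) -> np.ndarray:
        """lambda(t | Z2) = exp(eta) * (d eta / d ln t) / t."""
        times = np.asarray(times, dtype=float)
        eta = self.linear_predictor(records, times, x_override, params)
        etad = self.linear_predictor(records, times, x_override, params,
                                     deriv=True)
        return np.exp(np.clip(eta, -700, 700)) * etad / times[None, :]

    # -- marginal measures (regression standardization) ------------------
    def marginal_relative_survival(self, times, **kw):
        from . import standardize
        return standardize.marginal_relative_survival(self, times, **kw)

    def marginal_all_cause_survival(self, times, **kw):
        from . import standardize
        return standardize.marginal_all_cause_survival(self, times, **kw)

    def marginal_crude_probability(self, times, cause="cancer", **kw):
        from . import standardize
        return standardize.marginal_crude_probability(self, times, cause=cause,
                                                      **kw)

    def marginal_difference(self, times, **kw):
        from . import contrasts
        return contrasts.marginal_difference(self, times, **kw)

    def avoidable_deaths(self, times, **kw):
        from . import contrasts
        return contrasts.avoidable_deaths(self, times, **kw)

    # -- serialization ---------------------------------------------------
    def save(self, path) -> None:
        """Write coefficients, covariance, knots and layout to JSON text."""
        payload = {
            "params": self.params.tolist(),
            "cov": self.cov.tolist(),
            "diagnostics": self.diagnostics,
            "design": self.model.design.to_dict(),
            "column_names": self.model.design.column_names,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @staticmethod
    def load(path, cohort: Cohort, life_table: LifeTable) -> "ExcessHazardResults":
        """Rebuild results against the same cohort/life table."""
        with open(path) as fh:
            payload = json.load(fh)
        design = DesignInfo.from_dict(payload["design"])
        model = ExcessHazardModel.__new__(ExcessHazardModel)
        model.cohort = cohort
        model.life_table = life_table
        model.spec = design.spec
        model.design = design
        t = cohort.times()
        model._t = t
        model._d = cohort.events()
        model._X, model._Xd = design.design(cohort.data, np.log(t))
        ages, years, sexes, strata = cohort.z1_records()
        model._hstar = np.empty(cohort.n)
        model._expected_cum = np.empty(cohort.n)
        for i in range(cohort.n):
            path = life_table.hazard_path(ages[i], years[i], sexes[i],
                                          strata[i], t_max=t[i])
            model._hstar[i] = path.rates[-1]
            model._expected_cum[i] = path.cum[-1]
        return ExcessHazardResults(
            model,
            np.asarray(payload["params"], float),
            np.asarray(payload["cov"], float),
            payload["diagnostics"],
        )
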