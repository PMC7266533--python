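"""Pointwise confidence intervals for standardized measures.

Two routes are provided:

* **delta method** (default everywhere): the gradient of the measure
  with respect to the fitted coefficients is taken by central finite
  differences, the variance is g' V g with V the coefficient covariance,
  and the interval is built on a transformed scale - log(-log) for
  survival-type measures, logit for probability-type measures, identity
  for differences and death counts - then back-transformed, which keeps
  survival/probability intervals inside [0, 1].

* **nonparametric bootstrap**: resample patients with replacement,
  refit the model from scratch (knots included) on each resample, and
  take percentile intervals.  Slower, but makes no large-sample
  approximation; it serves as the reference method in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["UncertaintySpec", "delta_interval", "bootstrap_curve",
           "BootstrapResult"]


@dataclass
class UncertaintySpec:
    """How intervals are computed for a measure."""

    method: str = "delta"           # delta | bootstrap
    transform: str | None = None    # loglog | logit | identity | None=auto
    n_boot: int = 200
    seed: int = 0
    level: float = 0.95

    def __post_init__(self):
        if self.method not in ("delta", "bootstrap"):
            raise ValueError("method must be 'delta' or 'bootstrap'")
        if not (0.0 < self.level < 1.0):
            raise ValueError("confidence level must be in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("bootstrap replicates must be >= 1")


_EPS = 1e-12


def _to_transformed(est: np.ndarray, se: np.ndarray, transform: str):
    if transform == "identity":
        return est, se
    p = np.clip(est, _EPS, 1.0 - _EPS)
    if transform == "loglog":
        g = np.log(-np.log(p))
        gse = se / np.abs(p * np.log(p))
    elif transform == "logit":
        g = np.log(p / (1.0 - p))
        gse = se / (p * (1.0 - p))
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return g, gse


def _from_transformed(lo: np.ndarray, hi: np.ndarray, transform: str):
    if transform == "identity":
        return lo, hi
    if transform == "loglog":
        # decreasing map: exp(-exp(g)); swap bounds
        return np.exp(-np.exp(hi)), np.exp(-np.exp(lo))
    if transform == "logit":
        return 1.0 / (1.0 + np.exp(-lo)), 1.0 / (1.0 + np.exp(-hi))
    raise ValueError(f"unknown transform {transform!r}")


def delta_interval(fun, params, cov, level: float = 0.95,
                   transform: str = "identity", names=None):
    """SE and CI of a vector-valued measure ``fun(params)``.

    The gradient is taken coefficient-by-coefficient with central
    differences of step ``1e-5 * (1 + |theta_k|)``.
    """
    params = np.asarray(params, dtype=float)
    est = np.asarray(fun(params), dtype=float)
    p = params.size
    G = np.empty((p, est.size))
    for k in range(p):
        h = 1e-5 * (1.0 + abs(params[k]))
        up = params.copy(); up[k] += h
        dn = params.copy(); dn[k] -= h
        G[k] = (np.asarray(fun(up)) - np.asarray(fun(dn))) / (2.0 * h)
        if not np.isfinite(G[k]).all():
            nm = names[k] if names is not None else f"#{k}"
            raise ValueError(f"non-finite measure gradient for coefficient {nm}")
    var = np.einsum("kt,kl,lt->t", G, cov, G)
    se = np.sqrt(np.clip(var, 0.0, None))
    z = stats.norm.ppf(0.5 + level / 2.0)
    g, gse = _to_transformed(est, se, transform)
    lo, hi = _from_transformed(g - z * gse, g + z * gse, transform)
    # degenerate (se == 0) points collapse to the estimate
    flat = se == 0
    if flat.any():
        lo = np.where(flat, est, lo)
        hi = np.where(flat, est, hi)
    return se, lo, hi


@dataclass
class BootstrapResult:
    """Percentile bootstrap summary for a vector-valued measure."""

    estimate: np.ndarray       # measure on the original fit
    replicates: np.ndarray     # (n_successful, n_times)
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_failed: int
    level: float
    seed: int


def bootstrap_curve(results, measure_fn, n_boot: int = 200, seed: int = 0,
                    level: float = 0.95,
                    max_fail_frac: float = 0.10) -> BootstrapResult:
    """Nonparametric bootstrap of ``measure_fn(results)``.

    ``measure_fn`` maps a fitted :class:`ExcessHazardResults` to a 1-d
    array (e.g. a standardized curve's point estimates).  Patients are
    resampled with replacement; each resample is refit with the same
    model specification (spline knots re-placed on the resample).
    Replicates that fail to converge are skipped; more than
    ``max_fail_frac`` failures is an error.
    """
    from .cohort import Cohort
    from .model import ConvergenceError, ExcessHazardModel

    cohort = results.model.cohort
    spec = results.model.spec
    table = results.model.life_table
    rng = np.random.default_rng(seed)
    est = np.atleast_1d(np.asarray(measure_fn(results), dtype=float))

    reps = []
    failed = 0
    n = cohort.n
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = Cohort(
            cohort.data.iloc[idx].reset_index(drop=True),
            time=cohort.time, event=cohort.event, age=cohort.age,
            sex=cohort.sex, year=cohort.year, exposure=cohort.exposure,
            lifetable_strata=cohort.lifetable_strata,
        )
        try:
            model = ExcessHazardModel(boot, table, spec)
            res_b = model.fit()
            reps.append(np.atleast_1d(np.asarray(measure_fn(res_b), float)))
        except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
            failed += 1
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
    if failed > max_fail_frac * n_boot:
        raise RuntimeError(
            f"{failed}/{n_boot} bootstrap replicates failed to converge")
    reps = np.vstack(reps)
    alpha = 1.0 - level
    lo = np.quantile(reps, alpha / 2.0, axis=0)
    hi = np.quantile(reps, 1.0 - alpha / 2.0, axis=0)
    se = reps.std(axis=0, ddof=1) if len(reps) > 1 else np.zeros(est.size)
    return BootstrapResult(estimate=est, replicates=reps, se=se,
                           ci_lower=lo, ci_upper=hi, n_failed=failed,
                           level=level, seed=seed)
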