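"""Model specification and design-matrix construction.

The linear predictor of the excess-hazard model is

    eta(ln t, z) = s0(ln t; gamma) + x'beta + sum_k z_k * s_k(ln t; delta_k)

where s0 is the baseline restricted cubic spline in log time, x'beta the
(possibly spline-expanded) covariate effects, and the last sum the
time-dependent effects (covariate x time-spline interactions).  Every
design column factorizes as f(ln t) * g(z) - a pure time part times a
pure covariate part - which lets predictions over an N-patient by
M-time grid be computed as a single (N, p) x (p, M) product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .splines import SplineBasis

__all__ = ["TermSpec", "ModelSpec", "DesignInfo", "linear", "spline", "categorical"]


@dataclass(frozen=True)
class TermSpec:
    """One covariate term: a column of the cohort frame plus its expansion."""

    name: str
    kind: str = "linear"        # linear | spline | categorical
    df: int = 3                 # spline df (spline terms only)
    knots: tuple | None = None  # explicit spline knots

    def __post_init__(self):
        if self.kind not in ("linear", "spline", "categorical"):
            raise ValueError(f"unknown term kind {self.kind!r}")


def linear(name: str) -> TermSpec:
    return TermSpec(name, "linear")


def spline(name: str, df: int = 3, knots=None) -> TermSpec:
    return TermSpec(name, "spline", df=df,
                    knots=None if knots is None else tuple(knots))


def categorical(name: str) -> TermSpec:
    return TermSpec(name, "categorical")


@dataclass
class ModelSpec:
    """Specification of the excess-hazard model.

    Parameters
    ----------
    baseline_df : int
        Degrees of freedom of the baseline log-time spline (default 5;
        knots at equally spaced centiles of the uncensored log event
        times unless ``baseline_knots`` is given).
    terms : sequence of TermSpec
        Covariate effects (proportional on the log cumulative excess
        hazard scale unless listed in ``tvc``).
    tvc : dict
        Time-dependent effects: term name -> df of the interaction
        time-spline (default df 3 conventionally).
    orthogonalize : bool
        Orthogonalize spline bases for optimizer conditioning; an affine
        reparameterization with no effect on predictions.
    """

    baseline_df: int = 5
    terms: tuple = ()
    tvc: dict = field(default_factory=dict)
    baseline_knots: tuple | None = None
    tvc_knots: dict = field(default_factory=dict)
    orthogonalize: bool = True

    def __post_init__(self):
        self.terms = tuple(
            t if isinstance(t, TermSpec) else TermSpec(**t) for t in self.terms
        )
        names = {t.name for t in self.terms}
        for k in self.tvc:
            if k not in names:
                raise ValueError(
                    f"time-dependent effect {k!r} does not reference a declared term"
                )
        if self.baseline_df < 1 and self.baseline_knots is None:
            raise ValueError("baseline_df must be >= 1")

    def to_dict(self) -> dict:
        return {
            "baseline_df": self.baseline_df,
            "terms": [vars(t) | {"knots": list(t.knots) if t.knots else None}
                      for t in self.terms],
            "tvc": dict(self.tvc),
            "baseline_knots": list(self.baseline_knots) if self.baseline_knots else None,
            "tvc_knots": {k: list(v) for k, v in self.tvc_knots.items()},
            "orthogonalize": self.orthogonalize,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["terms"] = tuple(TermSpec(
            name=t["name"], kind=t.get("kind", "linear"), df=t.get("df", 3),
            knots=tuple(t["knots"]) if t.get("knots") else None,
        ) for t in d.get("terms", ()))
        d["baseline_knots"] = tuple(d["baseline_knots"]) if d.get("baseline_knots") else None
        d["tvc_knots"] = {k: tuple(v) for k, v in (d.get("tvc_knots") or {}).items()}
        return cls(**d)


class _CovariateColumns:
    """Expansion of one term into numeric covariate columns."""

    def __init__(self, term: TermSpec, values: pd.Series, orthogonalize: bool):
        self.term = term
        self.basis: SplineBasis | None = None
        self.levels: list | None = None
        if term.kind == "linear":
            self.names = [term.name]
        elif term.kind == "spline":
            self.basis = SplineBasis.from_data(
                values.to_numpy(float), df=term.df,
                knots=None if term.knots is None else np.asarray(term.knots),
                orthogonalize=orthogonalize,
            )
            self.names = [f"rcs({term.name}){j + 1}" for j in range(self.basis.df)]
        else:  # categorical, reference = first sorted level
            self.levels = sorted(values.unique(), key=str)
            if len(self.levels) < 2:
                raise ValueError(f"categorical term {term.name!r} has one level")
            self.names = [f"{term.name}[{lv}]" for lv in self.levels[1:]]

    @property
    def n_cols(self) -> int:
        return len(self.names)

    def matrix(self, records: pd.DataFrame) -> np.ndarray:
        v = records[self.term.name]
        if self.term.kind == "linear":
            return v.to_numpy(float)[:, None]
        if self.term.kind == "spline":
            return self.basis.evaluate(v.to_numpy(float))
        out = np.zeros((len(records), len(self.levels) - 1))
        for j, lv in enumerate(self.levels[1:]):
            out[:, j] = (v == lv).to_numpy(float)
        return out

    def to_dict(self) -> dict:
        return {
            "term": vars(self.term) | {
                "knots": list(self.term.knots) if self.term.knots else None},
            "basis": self.basis.to_dict() if self.basis else None,
            "levels": self.levels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_CovariateColumns":
        obj = cls.__new__(cls)
        t = d["term"]
        obj.term = TermSpec(name=t["name"], kind=t["kind"], df=t.get("df", 3),
                            knots=tuple(t["knots"]) if t.get("knots") else None)
        obj.basis = SplineBasis.from_dict(d["basis"]) if d.get("basis") else None
        obj.levels = d.get("levels")
        if obj.term.kind == "linear":
            obj.names = [obj.term.name]
        elif obj.term.kind == "spline":
            obj.names = [f"rcs({obj.term.name}){j + 1}" for j in range(obj.basis.df)]
        else:
            obj.names = [f"{obj.term.name}[{lv}]" for lv in obj.levels[1:]]
        return obj


class DesignInfo:
    """Frozen design: all spline bases, column layout and factorization."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame,
                 log_event_times: np.ndarray):
        self.spec = spec
        if spec.baseline_knots is not None:
            self.time_basis = SplineBasis.from_data(
                log_event_times, knots=np.asarray(spec.baseline_knots),
                orthogonalize=spec.orthogonalize)
        else:
            self.time_basis = SplineBasis.from_data(
                log_event_times, df=spec.baseline_df,
                orthogonalize=spec.orthogonalize)
        self.cov_cols = [
            _CovariateColumns(t, data[t.name], spec.orthogonalize)
            for t in spec.terms
        ]
        self.tvc_bases: dict[str, SplineBasis] = {}
        for name, df_t in spec.tvc.items():
            knots = spec.tvc_knots.get(name)
            if knots is not None:
                self.tvc_bases[name] = SplineBasis.from_data(
                    log_event_times, knots=np.asarray(knots),
                    orthogonalize=spec.orthogonalize)
            else:
                self.tvc_bases[name] = SplineBasis.from_data(
                    log_event_times, df=df_t, orthogonalize=spec.orthogonalize)
        self._layout()

    def _layout(self):
        names = ["intercept"]
        names += [f"ln_t_rcs{j + 1}" for j in range(self.time_basis.df)]
        for cc in self.cov_cols:
            names += cc.names
        for cc in self.cov_cols:
            if cc.term.name in self.tvc_bases:
                b = self.tvc_bases[cc.term.name]
                for cn in cc.names:
                    names += [f"{cn}:ln_t_rcs{j + 1}" for j in range(b.df)]
        self.column_names = names
        self.n_params = len(names)

    # -- factorized evaluation ------------------------------------------
    def covariate_parts(self, records: pd.DataFrame) -> np.ndarray:
        """g(z) for every design column; shape (n_records, p)."""
        n = len(records)
        mats = {cc.term.name: cc.matrix(records) for cc in self.cov_cols}
        cols = [np.ones((n, 1)), np.ones((n, self.time_basis.df))]
        for cc in self.cov_cols:
            cols.append(mats[cc.term.name])
        for cc in self.cov_cols:
            if cc.term.name in self.tvc_bases:
                b = self.tvc_bases[cc.term.name]
                m = mats[cc.term.name]
                cols.append(np.repeat(m, b.df, axis=1))
        return np.concatenate(cols, axis=1)

    def time_parts(self, log_t: np.ndarray, deriv: bool = False) -> np.ndarray:
        """f(ln t) (or df/d ln t) for every design column; shape (m, p)."""
        log_t = np.asarray(log_t, dtype=float)
        m = log_t.shape[0]
        tb = (self.time_basis.evaluate_deriv(log_t) if deriv
              else self.time_basis.evaluate(log_t))
        cols = [np.zeros((m, 1)) if deriv else np.ones((m, 1)), tb]
        n_cov = sum(cc.n_cols for cc in self.cov_cols)
        cols.append(np.zeros((m, n_cov)) if deriv else np.ones((m, n_cov)))
        for cc in self.cov_cols:
            if cc.term.name in self.tvc_bases:
                b = self.tvc_bases[cc.term.name]
                bt = b.evaluate_deriv(log_t) if deriv else b.evaluate(log_t)
                cols.append(np.tile(bt, (1, cc.n_cols)))
        return np.concatenate(cols, axis=1)

    def design(self, records: pd.DataFrame, log_t: np.ndarray):
        """Row-wise design X and its d/d ln t at each record's own time."""
        g = self.covariate_parts(records)
        f = self.time_parts(log_t)
        fd = self.time_parts(log_t, deriv=True)
        return g * f, g * fd

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "time_basis": self.time_basis.to_dict(),
            "cov_cols": [cc.to_dict() for cc in self.cov_cols],
            "tvc_bases": {k: b.to_dict() for k, b in self.tvc_bases.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignInfo":
        obj = cls.__new__(cls)
        obj.spec = ModelSpec.from_dict(d["spec"])
        obj.time_basis = SplineBasis.from_dict(d["time_basis"])
        obj.cov_cols = [_CovariateColumns.from_dict(c) for c in d["cov_cols"]]
        obj.tvc_bases = {k: SplineBasis.from_dict(b)
                         for k, b in d["tvc_bases"].items()}
        obj._layout()
        return obj
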