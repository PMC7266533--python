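"""Restricted cubic spline (RCS) bases with analytic first derivatives.

The excess-hazard model expresses the log cumulative excess hazard as a
restricted cubic spline in log time, so both the basis values (for the
cumulative hazard) and their first derivatives (for the hazard itself,
via d eta / d ln t) are needed.  The basis is the classical
truncated-power RCS: cubic between the boundary knots, constrained to be
linear beyond them, with continuous value, first and second derivative
at every interior knot.  With K knots the basis has K - 1 columns; with
two knots it degenerates to a single linear column.

An optional orthogonalization (Gram-Schmidt against the intercept and
earlier columns, fixed at construction from the data the knots were
placed on) improves the conditioning of the likelihood optimization.
It is an affine map of the raw basis, so the column span - and hence
every model prediction - is unchanged.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SplineBasis"]


def _rcs_raw(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Truncated-power RCS basis values, shape (n, K-1)."""
    x = np.asarray(x, dtype=float)
    k = knots
    K = len(k)
    out = np.empty(x.shape + (K - 1,), dtype=float)
    out[..., 0] = x
    if K > 2:
        kmin, kmax = k[0], k[-1]
        denom = kmax - kmin
        for j in range(1, K - 1):
            lam = (kmax - k[j]) / denom
            out[..., j] = (
                np.clip(x - k[j], 0.0, None) ** 3
                - lam * np.clip(x - kmin, 0.0, None) ** 3
                - (1.0 - lam) * np.clip(x - kmax, 0.0, None) ** 3
            )
    return out


def _rcs_raw_deriv(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """d/dx of the truncated-power RCS basis, shape (n, K-1)."""
    x = np.asarray(x, dtype=float)
    k = knots
    K = len(k)
    out = np.empty(x.shape + (K - 1,), dtype=float)
    out[..., 0] = 1.0
    if K > 2:
        kmin, kmax = k[0], k[-1]
        denom = kmax - kmin
        for j in range(1, K - 1):
            lam = (kmax - k[j]) / denom
            out[..., j] = 3.0 * (
                np.clip(x - k[j], 0.0, None) ** 2
                - lam * np.clip(x - kmin, 0.0, None) ** 2
                - (1.0 - lam) * np.clip(x - kmax, 0.0, None) ** 2
            )
    return out


class SplineBasis:
    """A fixed RCS basis: knots plus an optional orthogonalization map.

    Parameters
    ----------
    knots : array-like
        Strictly increasing knot locations (boundary knots included).
    rinv : ndarray, optional
        Upper-triangular (df+1, df+1) map applied to the
        intercept-augmented raw basis; produced by :meth:`from_data`
        when ``orthogonalize=True``.
    """

    def __init__(self, knots, rinv: np.ndarray | None = None):
        knots = np.asarray(knots, dtype=float)
        if knots.ndim != 1 or len(knots) < 2:
            raise ValueError("at least two knots are required")
        if np.any(np.diff(knots) <= 0):
            raise ValueError(f"knots must be strictly increasing, got {knots!r}")
        self.knots = knots
        self.df = len(knots) - 1
        self._rinv = None if rinv is None else np.asarray(rinv, dtype=float)

    @classmethod
    def from_data(
        cls,
        values,
        df: int | None = None,
        knots=None,
        orthogonalize: bool = True,
    ) -> "SplineBasis":
        """Build a basis with knots at equally spaced centiles of ``values``.

        ``df`` basis columns require ``df + 1`` knots, placed at the
        0, 100/df, ..., 100th centiles (boundary knots at the min and
        max).  Explicit ``knots`` override the centile rule.
        """
        values = np.asarray(values, dtype=float)
        if knots is None:
            if df is None or df < 1:
                raise ValueError("df must be >= 1 when knots are not given")
            if values.size < df + 1:
                raise ValueError("not enough values to place knots")
            probs = np.linspace(0.0, 100.0, df + 1)
            knots = np.percentile(values, probs)
            if np.any(np.diff(knots) <= 0):
                raise ValueError(
                    "centile knots are not distinct; supply fewer df or explicit knots"
                )
        basis = cls(knots)
        if orthogonalize:
            raw = np.column_stack(
                [np.ones(values.size), _rcs_raw(values, basis.knots)]
            )
            # QR scaled by sqrt(n): columns of raw @ rinv have unit RMS and
            # are mutually orthogonal over the construction sample.
            _, r = np.linalg.qr(raw)
            r = r / np.sqrt(values.size)
            basis._rinv = np.linalg.inv(r)
        return basis

    @property
    def orthogonalized(self) -> bool:
        return self._rinv is not None

    def evaluate(self, x) -> np.ndarray:
        """Basis values at ``x``; shape (n, df)."""
        raw = _rcs_raw(np.asarray(x, dtype=float), self.knots)
        if self._rinv is None:
            return raw
        aug = np.concatenate([np.ones(raw.shape[:-1] + (1,)), raw], axis=-1)
        return (aug @ self._rinv)[..., 1:]

    def evaluate_deriv(self, x) -> np.ndarray:
        """First derivative of each basis column at ``x``; shape (n, df)."""
        raw = _rcs_raw_deriv(np.asarray(x, dtype=float), self.knots)
        if self._rinv is None:
            return raw
        aug = np.concatenate([np.zeros(raw.shape[:-1] + (1,)), raw], axis=-1)
        return (aug @ self._rinv)[..., 1:]

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {"knots": self.knots.tolist()}
        if self._rinv is not None:
            d["rinv"] = self._rinv.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SplineBasis":
        rinv = np.asarray(d["rinv"]) if "rinv" in d else None
        return cls(np.asarray(d["knots"]), rinv=rinv)

    def __repr__(self) -> str:  # pragma: no cover
        tag = ", orthogonalized" if self.orthogonalized else ""
        return f"SplineBasis(df={self.df}, knots={np.round(self.knots, 4)}{tag})"
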