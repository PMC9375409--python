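"""Restricted cubic spline bases and their orthogonalisation.

These splines are the building blocks of the flexible parametric survival
models in :mod:`standcomp.fpm`: a restricted cubic spline of log time models
the baseline log cumulative hazard, and additional spline-covariate
interactions model time-dependent effects.  The same machinery can be used
to expand continuous covariates (e.g. age) non-linearly.

Conventions
-----------
* A spline with ``df`` basis columns has ``df + 1`` knots (boundary knots at
  the extremes plus ``df - 1`` internal knots).
* Raw basis: the restricted truncated-power construction, linear beyond the
  boundary knots, with the cubic terms scaled by ``(k_max - k_min)**2`` for
  numerical balance.  The first raw column is ``x`` itself.
* Orthogonalised basis: modified Gram-Schmidt of ``[1, v_1, ..., v_df]``
  over the sample the basis was built from, each column scaled to unit root
  mean square.  The triangular transform is stored as the *projection*
  matrix so the fitted basis can be reproduced exactly at any new input.
* Internal knots are placed at equally spaced centiles of the (log) event
  times, computed with linear-interpolation (type-7) quantiles.  Users who
  need to match another software's centile convention can pass knots
  explicitly to every fitting routine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KnotSet",
    "SplineBasis",
    "place_knots",
    "rcs",
    "rcs_raw",
    "rcs_derivative",
]


@dataclass(frozen=True)
class KnotSet:
    """An ordered set of spline knots on the spline's input scale."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) < 2:
            raise ValueError("a knot set needs at least 2 knots (df >= 1)")
        if not all(np.isfinite(vals)):
            raise ValueError("knots must be finite")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError(f"knots must be strictly increasing, got {vals}")

    @property
    def df(self) -> int:
        """Number of basis columns (= number of knots minus 1)."""
        return len(self.values) - 1

    @property
    def boundary(self) -> tuple[float, float]:
        return self.values[0], self.values[-1]

    def to_dict(self) -> dict:
        return {"values": list(self.values)}

    @classmethod
    def from_dict(cls, d: dict) -> "KnotSet":
        return cls(tuple(d["values"]))


def place_knots(event_log_times: np.ndarray, df: int) -> KnotSet:
    """Place ``df + 1`` knots on the distribution of (log) event times.

    Boundary knots sit at the minimum and maximum, internal knots at the
    ``100*j/df`` centiles (``j = 1..df-1``) computed with type-7 quantiles.
    """
    x = np.asarray(event_log_times, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot place knots on an empty event-time vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("event times must be finite on the log scale")
    if df < 1:
        raise ValueError("df must be >= 1")
    distinct = np.unique(x)
    if df >= distinct.size:
        raise ValueError(
            f"insufficient distinct event times: df={df} requires more than "
            f"{distinct.size} distinct values"
        )
    if df == 1:
        knots = [distinct[0], distinct[-1]]
    else:
        centiles = 100.0 * np.arange(1, df) / df
        internal = np.percentile(x, centiles, method="linear")
        knots = [distinct[0], *internal.tolist(), distinct[-1]]
    return KnotSet(tuple(knots))


def _raw_basis(x: np.ndarray, knots: KnotSet) -> np.ndarray:
    """Raw restricted-cubic basis, n x df; first column is x itself."""
    k = np.asarray(knots.values)
    kmin, kmax = k[0], k[-1]
    scale = (kmax - kmin) ** 2
    out = np.empty((x.size, knots.df))
    out[:, 0] = x
    for j in range(1, knots.df):
        kj = k[j]
        lam = (kmax - kj) / (kmax - kmin)
        out[:, j] = (
            np.clip(x - kj, 0.0, None) ** 3
            - lam * np.clip(x - kmin, 0.0, None) ** 3
            - (1.0 - lam) * np.clip(x - kmax, 0.0, None) ** 3
        ) / scale
    return out


def _raw_derivative(x: np.ndarray, knots: KnotSet) -> np.ndarray:
    k = np.asarray(knots.values)
    kmin, kmax = k[0], k[-1]
    scale = (kmax - kmin) ** 2
    out = np.empty((x.size, knots.df))
    out[:, 0] = 1.0
    for j in range(1, knots.df):
        kj = k[j]
        lam = (kmax - kj) / (kmax - kmin)
        out[:, j] = (
            3.0 * np.clip(x - kj, 0.0, None) ** 2
            - 3.0 * lam * np.clip(x - kmin, 0.0, None) ** 2
            - 3.0 * (1.0 - lam) * np.clip(x - kmax, 0.0, None) ** 2
        ) / scale
    return out


def _gram_schmidt_transform(W: np.ndarray) -> np.ndarray:
    """Modified Gram-Schmidt transform ``T`` such that ``W @ T`` has
    mutually orthogonal columns of unit root mean square.

    ``W`` must have the intercept column first; it is left untouched
    (its RMS is already 1), so standardised bases keep an exact constant.
    """
    n, m = W.shape
    Wk = np.array(W, dtype=float, copy=True)
    T = np.eye(m)
    for j in range(m):
        for i in range(j):
            denom = Wk[:, i] @ Wk[:, i]
            c = (Wk[:, i] @ Wk[:, j]) / denom
            Wk[:, j] = Wk[:, j] - c * Wk[:, i]
            T[:, j] = T[:, j] - c * T[:, i]
        s = np.sqrt(Wk[:, j] @ Wk[:, j] / n)
        if not np.isfinite(s) or s <= 1e-12:
            raise ValueError("collinear spline basis columns; check knots/data")
        Wk[:, j] /= s
        T[:, j] /= s
    return T


@dataclass
class SplineBasis:
    """A restricted cubic spline basis with a frozen orthogonalisation.

    ``projection`` is the ``(df+1) x (df+1)`` triangular transform applied
    to ``[1, raw columns]``; storing it guarantees that post-estimation
    evaluations at arbitrary new inputs reproduce the fitted-time basis
    exactly.  ``projection=None`` means the raw basis is used as-is.
    """

    knots: KnotSet
    projection: np.ndarray | None = None
    column_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.column_names:
            self.column_names = tuple(
                f"_rcs{i}" for i in range(1, self.knots.df + 1)
            )
        if len(self.column_names) != self.df:
            raise ValueError("column_names length must equal df")
        if self.projection is not None:
            P = np.asarray(self.projection, dtype=float)
            m = self.df + 1
            if P.shape != (m, m):
                raise ValueError(f"projection must be {m}x{m}")
            if abs(np.linalg.det(P)) < 1e-300:
                raise ValueError("projection matrix is singular")
            self.projection = P

    @property
    def df(self) -> int:
        return self.knots.df

    @classmethod
    def from_data(
        cls,
        x: np.ndarray,
        knots: KnotSet,
        orthogonalise: bool = True,
        prefix: str = "_rcs",
    ) -> "SplineBasis":
        """Build a basis, orthogonalising over the sample ``x``."""
        x = _check_input(x)
        names = tuple(f"{prefix}{i}" for i in range(1, knots.df + 1))
        if not orthogonalise:
            return cls(knots=knots, projection=None, column_names=names)
        V = _raw_basis(x, knots)
        W = np.column_stack([np.ones(x.size), V])
        T = _gram_schmidt_transform(W)
        return cls(knots=knots, projection=T, column_names=names)

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = _check_input(x)
        V = _raw_basis(x, self.knots)
        if self.projection is None:
            return V
        W = np.column_stack([np.ones(x.size), V])
        return (W @ self.projection)[:, 1:]

    def derivative(self, x: np.ndarray) -> np.ndarray:
        x = _check_input(x)
        D = _raw_derivative(x, self.knots)
        if self.projection is None:
            return D
        W = np.column_stack([np.zeros(x.size), D])
        return (W @ self.projection)[:, 1:]

    def to_dict(self) -> dict:
        return {
            "knots": self.knots.to_dict(),
            "projection": None
            if self.projection is None
            else self.projection.tolist(),
            "column_names": list(self.column_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineBasis":
        proj = d["projection"]
        return cls(
            knots=KnotSet.from_dict(d["knots"]),
            projection=None if proj is None else np.asarray(proj, dtype=float),
            column_names=tuple(d["column_names"]),
        )


def _check_input(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("spline input contains non-finite values")
    return x


def rcs(x: np.ndarray, basis: SplineBasis | KnotSet) -> np.ndarray:
    """Evaluate a restricted cubic spline basis at ``x`` (n x df).

    Passing a bare :class:`KnotSet` computes a fresh orthogonalisation from
    ``x``; passing a :class:`SplineBasis` reuses its stored projection.
    """
    if isinstance(basis, KnotSet):
        basis = SplineBasis.from_data(x, basis, orthogonalise=True)
    return basis.evaluate(x)


def rcs_raw(x: np.ndarray, knots: KnotSet) -> np.ndarray:
    """Raw (un-orthogonalised) restricted cubic spline basis at ``x``."""
    return _raw_basis(_check_input(x), knots)


def rcs_derivative(x: np.ndarray, basis: SplineBasis) -> np.ndarray:
    """Column-wise derivative of :func:`rcs` with respect to ``x``."""
    if isinstance(basis, KnotSet):
        basis = SplineBasis(knots=basis, projection=None)
    return basis.derivative(x)
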