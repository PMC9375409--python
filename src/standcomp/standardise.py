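"""Regression standardisation of survival-model predictions.

Given fitted cause-specific flexible parametric models, this module
averages individual predictions over the empirical covariate distribution
under counterfactual "at" settings (g-formula for a point treatment):

* :func:`std_failure` — standardised failure probability 1 - S from a
  single model (the controlled-direct-effect world where competing events
  are eliminated);
* :func:`std_cif` — standardised cause-specific cumulative incidence in
  the presence of competing events, integrating all-cause survival times
  the cause-specific hazard by Gauss-Legendre quadrature;
* :func:`std_survival` — standardised all-cause survival from the same
  cause-specific models;
* :func:`std_rmft` — standardised restricted mean failure time (expected
  months lost to a cause before ``t_star``);
* :func:`contrast` — differences, ratios and linear combinations of
  standardised curves;
* :func:`separable` — separable direct/indirect effects with the treatment
  cloned into cause-specific components.

Standard errors come from the delta method: a central finite-difference
Jacobian of the standardised quantity with respect to the joint parameter
vector of all involved models, whose covariance is assembled block
diagonally (the cause-specific likelihoods share no parameters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import block_diag
from scipy.stats import norm

from .fpm import FittedFPM, SurvivalDataset

__all__ = [
    "AtSpec",
    "CauseModelSet",
    "StandardisedCurve",
    "ContrastSpec",
    "ContrastResult",
    "SeparableResult",
    "delta_method",
    "std_failure",
    "std_survival",
    "std_cif",
    "std_rmft",
    "contrast",
    "user_contrast",
    "separable",
    "default_timevar",
]

_JAC_STEP = 1e-5


def default_timevar(stop: float = 60.0, n: int = 121, start: float = 0.0) -> np.ndarray:
    """The default prediction grid: 121 points from 0 to 60 months."""
    return np.linspace(start, stop, n)


@dataclass(frozen=True)
class AtSpec:
    """A counterfactual covariate assignment.

    ``assignments`` maps covariate names to fixed values; covariates not
    listed keep each subject's observed value.  ``subset`` optionally
    restricts the rows standardised over: ``"first"`` keeps only the first
    row (the non-marginal mode, where the standardised quantity equals a
    conditional prediction), or a boolean mask / index array.
    """

    assignments: dict[str, float] = field(default_factory=dict)
    subset: object | None = None
    label: str | None = None

    def apply(self, covariates: pd.DataFrame) -> pd.DataFrame:
        cov = covariates
        if self.subset is not None:
            if isinstance(self.subset, str):
                if self.subset != "first":
                    raise ValueError("subset must be 'first', a mask, or None")
                cov = cov.iloc[:1]
            else:
                cov = cov.loc[np.asarray(self.subset)]
        cov = cov.reset_index(drop=True).copy()
        for name, value in self.assignments.items():
            if name not in cov.columns:
                raise ValueError(f"at-assignment targets unknown covariate '{name}'")
            lo, hi = covariates[name].min(), covariates[name].max()
            if not (lo <= value <= hi):
                warnings.warn(
                    f"assigned value {value} for '{name}' lies outside the "
                    f"observed support [{lo}, {hi}]; the standardised "
                    "prediction extrapolates",
                    RuntimeWarning,
                )
            cov[name] = float(value)
        if len(cov) == 0:
            raise ValueError("empty dataset after applying at-subset")
        return cov

    def describe(self) -> str:
        if self.label:
            return self.label
        return ",".join(f"{k}={v:g}" for k, v in self.assignments.items()) or "observed"


@dataclass
class CauseModelSet:
    """An ordered, labelled set of cause-specific models."""

    models: tuple[FittedFPM, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.models = tuple(self.models)
        self.labels = tuple(self.labels)
        if len(self.models) != len(self.labels):
            raise ValueError("one label per model is required")
        causes = [m.event_cause for m in self.models]
        if len(set(causes)) != len(causes):
            raise ValueError("models must have distinct event causes")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("model labels must be unique")

    def __len__(self) -> int:
        return len(self.models)

    def __getitem__(self, label: str) -> FittedFPM:
        return self.models[self.labels.index(label)]

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class StandardisedCurve:
    """A standardised quantity on a time grid with delta-method inference."""

    times: np.ndarray
    estimate: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    at: AtSpec
    kind: str  # failure | cif | survival | rmft
    cause: str | None = None
    t_star: float | None = None
    ci_level: float = 0.95
    _fn: object = field(default=None, repr=False, compare=False)
    _theta: np.ndarray | None = field(default=None, repr=False, compare=False)
    _vcov: np.ndarray | None = field(default=None, repr=False, compare=False)
    _model_key: tuple = field(default=(), repr=False, compare=False)

    def at_time(self, t: float) -> dict:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-9:
            raise ValueError(f"time {t} not on the prediction grid")
        return {
            "time": float(self.times[i]),
            "estimate": float(self.estimate[i]),
            "se": float(self.se[i]),
            "ci_low": float(self.ci_low[i]),
            "ci_high": float(self.ci_high[i]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at": self.at.describe(),
                "kind": self.kind,
                "cause": self.cause if self.cause is not None else "",
                "estimate": self.estimate,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


@dataclass(frozen=True)
class ContrastSpec:
    kind: str = "difference"  # difference | ratio | lincom
    ref: int = 0
    coefficients: tuple[float, ...] | None = None
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.kind not in ("difference", "ratio", "lincom"):
            raise ValueError(f"unknown contrast kind '{self.kind}'")
        if self.kind == "lincom" and self.coefficients is None:
            raise ValueError("lincom requires coefficients")


@dataclass
class ContrastResult:
    kind: str
    reference: int
    coefficients: tuple[float, ...] | None
    times: np.ndarray
    estimate: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    labels: tuple[str, ...]
    ci_level: float = 0.95

    def at_time(self, t: float) -> dict:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-9:
            raise ValueError(f"time {t} not on the prediction grid")
        return {
            "time": float(self.times[i]),
            "estimate": float(self.estimate[i]),
            "se": float(self.se[i]),
            "ci_low": float(self.ci_low[i]),
            "ci_high": float(self.ci_high[i]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at": " vs ".join(self.labels),
                "kind": self.kind,
                "estimate": self.estimate,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


# ---------------------------------------------------------------------------
# delta method


def _num_jacobian(fn, theta: np.ndarray, step: float = _JAC_STEP) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    f0 = np.atleast_1d(fn(theta))
    G = np.empty((f0.size, theta.size))
    for j in range(theta.size):
        h = step * (1.0 + abs(theta[j]))
        up = theta.copy()
        dn = theta.copy()
        up[j] += h
        dn[j] -= h
        G[:, j] = (np.atleast_1d(fn(up)) - np.atleast_1d(fn(dn))) / (2.0 * h)
    if not np.all(np.isfinite(G)):
        raise ValueError("non-finite entries in the delta-method Jacobian")
    return G


def delta_method(fn, theta: np.ndarray, vcov: np.ndarray, step: float = _JAC_STEP) -> np.ndarray:
    """Delta-method standard errors of ``fn(theta)``.

    ``se = sqrt(diag(G V G'))`` with ``G`` the central finite-difference
    Jacobian of ``fn`` at ``theta``.
    """
    G = _num_jacobian(fn, theta, step)
    var = np.einsum("ij,jk,ik->i", G, np.asarray(vcov, float), G)
    return np.sqrt(np.maximum(var, 0.0))


def _wald_ci(est, se, level, transform=None):
    z = norm.ppf(0.5 + level / 2.0)
    est = np.asarray(est, float)
    se = np.asarray(se, float)
    if transform is None:
        return est - z * se, est + z * se
    if transform == "loglog":
        # on log(-log(1 - F)) for failure-type quantities; exact at F in {0,1}
        lo = np.empty_like(est)
        hi = np.empty_like(est)
        interior = (est > 0) & (est < 1) & (se > 0)
        F = est[interior]
        g = np.log(-np.log(1.0 - F))
        dg = se[interior] / np.abs((1.0 - F) * np.log(1.0 - F))
        lo[interior] = 1.0 - np.exp(-np.exp(g - z * dg))
        hi[interior] = 1.0 - np.exp(-np.exp(g + z * dg))
        lo[~interior] = est[~interior]
        hi[~interior] = est[~interior]
        return lo, hi
    raise ValueError(f"unknown CI transform '{transform}'")


# ---------------------------------------------------------------------------
# cached model evaluation on a fixed log-time grid


class _ModelGrid:
    """Pre-evaluated spline bases of one model on a fixed set of times."""

    def __init__(self, model: FittedFPM, t: np.ndarray, columns: list[str]):
        self.model = model
        self.t = np.asarray(t, dtype=float)
        u = np.log(self.t)
        self.B0 = model.baseline_basis.evaluate(u)
        self.dB0 = model.baseline_basis.derivative(u)
        self.slices = model._slices()
        self.tvc = []
        for name in model.spec.tvc:
            basis = model.tvc_bases[name]
            self.tvc.append(
                (
                    name,
                    columns.index(name),
                    basis.evaluate(u),
                    basis.derivative(u),
                    self.slices[f"delta:{name}"],
                )
            )
        self.cov_idx = [columns.index(c) for c in model.spec.covariates]

    def eta_dsdu(self, theta: np.ndarray, Zpat: np.ndarray):
        """eta and d(s_total)/d(log t), both (n_times x n_patterns)."""
        Z = Zpat[:, self.cov_idx]
        base = theta[self.slices["cons"]][0] + self.B0 @ theta[self.slices["gamma"]]
        dbase = self.dB0 @ theta[self.slices["gamma"]]
        eta = base[:, None] + (Z @ theta[self.slices["beta"]])[None, :]
        dsdu = np.broadcast_to(dbase[:, None], eta.shape).copy()
        for _, jcol, B, dB, sl in self.tvc:
            zj = Zpat[:, jcol][None, :]
            eta = eta + (B @ theta[sl])[:, None] * zj
            dsdu = dsdu + (dB @ theta[sl])[:, None] * zj
        return eta, dsdu


def _patterns(cov: pd.DataFrame, columns: list[str]):
    """Collapse covariate rows to unique patterns with empirical weights."""
    if not columns:
        return np.zeros((1, 0)), np.ones(1)
    arr = cov[columns].to_numpy(float)
    uniq, counts = np.unique(arr, axis=0, return_counts=True)
    return uniq, counts / counts.sum()


def _used_columns(models: list[FittedFPM], data: SurvivalDataset, at: AtSpec):
    cols: list[str] = []
    for m in models:
        for c in m.spec.covariates:
            if c not in cols:
                cols.append(c)
    for name in at.assignments:
        if name not in cols:
            raise ValueError(
                f"at-assignment '{name}' does not appear in any model"
            )
    missing = [c for c in cols if c not in data.covariates.columns]
    if missing:
        raise ValueError(f"dataset lacks model covariates: {missing}")
    return cols


def _joint(models: list[FittedFPM]):
    theta = np.concatenate([m.params for m in models])
    vcov = block_diag(*[m.vcov for m in models])
    offsets = np.cumsum([0] + [m.params.size for m in models])
    return theta, vcov, offsets


def _curve(fn, theta, vcov, times, at, kind, cause, t_star, ci_level, transform, step, key):
    est = fn(theta)
    se = delta_method(fn, theta, vcov, step)
    lo, hi = _wald_ci(est, se, ci_level, transform)
    return StandardisedCurve(
        times=np.asarray(times, float),
        estimate=est,
        se=se,
        ci_low=lo,
        ci_high=hi,
        at=at,
        kind=kind,
        cause=cause,
        t_star=t_star,
        ci_level=ci_level,
        _fn=fn,
        _theta=theta,
        _vcov=vcov,
        _model_key=key,
    )


# ---------------------------------------------------------------------------
# standardised quantities


def std_failure(
    model: FittedFPM,
    data: SurvivalDataset,
    at: AtSpec,
    times: np.ndarray,
    ci_level: float = 0.95,
    transform: str | None = None,
    step: float = _JAC_STEP,
) -> StandardisedCurve:
    """Standardised failure probability ``E[1 - S(t | x, Z)]`` from one model.

    With competing events censored in the fit, this is the failure
    probability in the hypothetical world where competing events are
    eliminated (the controlled-direct-effect scale).
    """
    times = np.asarray(times, dtype=float).ravel()
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if data.n == 0:
        raise ValueError("empty dataset")
    cols = _used_columns([model], data, at)
    Zpat, w = _patterns(at.apply(data.covariates), cols)
    pos = times > 0
    grid = _ModelGrid(model, times[pos], cols)

    def fn(theta):
        out = np.zeros(times.size)
        eta, _ = grid.eta_dsdu(theta, Zpat)
        out[pos] = (1.0 - np.exp(-np.exp(eta))) @ w
        return out

    return _curve(
        fn, model.params, model.vcov, times, at, "failure", None, None,
        ci_level, transform, step, (id(model),),
    )


def std_survival(
    models: CauseModelSet | FittedFPM,
    data: SurvivalDataset,
    at: AtSpec,
    times: np.ndarray,
    ci_level: float = 0.95,
    transform: str | None = None,
    step: float = _JAC_STEP,
) -> StandardisedCurve:
    """Standardised all-cause survival, the product of the cause-specific
    survivals from every model in the set."""
    if isinstance(models, FittedFPM):
        models = CauseModelSet((models,), ("all",))
    times = np.asarray(times, dtype=float).ravel()
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    mlist = list(models.models)
    cols = _used_columns(mlist, data, at)
    Zpat, w = _patterns(at.apply(data.covariates), cols)
    pos = times > 0
    grids = [_ModelGrid(m, times[pos], cols) for m in mlist]
    theta0, vcov, offs = _joint(mlist)

    def fn(theta):
        out = np.ones(times.size)
        H = 0.0
        for g, a, b in zip(grids, offs[:-1], offs[1:]):
            eta, _ = g.eta_dsdu(theta[a:b], Zpat)
            H = H + np.exp(eta)
        out[pos] = np.exp(-H) @ w
        return out

    key = tuple(id(m) for m in mlist)
    return _curve(
        fn, theta0, vcov, times, at, "survival", None, None,
        ci_level, transform, step, key,
    )


def _cif_machinery(models, data, at, cause, nodes):
    if len(models) < 2:
        raise ValueError("cause-specific CIFs need at least 2 cause models")
    mlist = list(models.models)
    cidx = models.index(cause)
    cols = _used_columns(mlist, data, at)
    Zpat, w = _patterns(at.apply(data.covariates), cols)
    xg, wg = np.polynomial.legendre.leggauss(nodes)
    return mlist, cidx, cols, Zpat, w, xg, wg


def _cif_fn(mlist, cidx, cols, Zpat, w, xg, wg, times, offs):
    """Build fn(theta) -> standardised CIF on `times` via per-time quadrature."""
    times = np.asarray(times, dtype=float)
    pos = times > 0
    tpos = times[pos]
    nt, Q = tpos.size, xg.size
    if nt:
        # cubic substitution u = t s^3 concentrates nodes near 0, where the
        # hazard may have an integrable singularity (spline slope < 1)
        s = 0.5 * (xg + 1.0)
        U = tpos[:, None] * (s**3)[None, :]  # (nt, Q)
        Wq = tpos[:, None] * (1.5 * s**2 * wg)[None, :]
        uflat = U.ravel()
        grids = [_ModelGrid(m, uflat, cols) for m in mlist]

    def fn(theta):
        out = np.zeros(times.size)
        if not nt:
            return out
        H = 0.0
        dsdu_c = eta_c = None
        for i, (g, a, b) in enumerate(zip(grids, offs[:-1], offs[1:])):
            eta, dsdu = g.eta_dsdu(theta[a:b], Zpat)
            H = H + np.exp(eta)
            if i == cidx:
                eta_c, dsdu_c = eta, dsdu
        hc = dsdu_c * np.exp(eta_c) / uflat[:, None]
        integrand = (np.exp(-H) * hc).reshape(nt, Q, -1)
        cif_pat = np.einsum("tqp,tq->tp", integrand, Wq)
        out[pos] = cif_pat @ w
        return out

    return fn


def std_cif(
    models: CauseModelSet,
    data: SurvivalDataset,
    at: AtSpec,
    times: np.ndarray,
    cause: str,
    nodes: int = 100,
    ci_level: float = 0.95,
    transform: str | None = None,
    step: float = _JAC_STEP,
    check_quadrature: bool = True,
) -> StandardisedCurve:
    """Standardised cause-specific cumulative incidence in the presence of
    competing events:

        F_c^x(t) = E[ integral_0^t S(u|x,Z) h_c(u|x,Z) du ]

    with all-cause survival ``S`` the product of the cause-specific
    survivals.  The integral uses Gauss-Legendre quadrature with ``nodes``
    points on (0, t] for every grid time.
    """
    times = np.asarray(times, dtype=float).ravel()
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    mlist, cidx, cols, Zpat, w, xg, wg = _cif_machinery(models, data, at, cause, nodes)
    theta0, vcov, offs = _joint(mlist)
    fn = _cif_fn(mlist, cidx, cols, Zpat, w, xg, wg, times, offs)

    if check_quadrature and times.size:
        x2, w2 = np.polynomial.legendre.leggauss(2 * nodes)
        t_check = np.array([times.max()]) if times.max() > 0 else times[:0]
        if t_check.size:
            fn2 = _cif_fn(mlist, cidx, cols, Zpat, w, x2, w2, t_check, offs)
            fn1 = _cif_fn(mlist, cidx, cols, Zpat, w, xg, wg, t_check, offs)
            drift = abs(float(fn2(theta0)[0] - fn1(theta0)[0]))
            if drift > 1e-4:
                warnings.warn(
                    f"quadrature may be inaccurate: doubling nodes moves the "
                    f"CIF by {drift:.2e}; increase `nodes`",
                    RuntimeWarning,
                )

    key = tuple(id(m) for m in mlist)
    return _curve(
        fn, theta0, vcov, times, at, "cif", cause, None,
        ci_level, transform, step, key,
    )


def std_rmft(
    models: CauseModelSet,
    data: SurvivalDataset,
    at: AtSpec,
    t_star: float,
    cause: str,
    nodes: int = 100,
    ci_level: float = 0.95,
    step: float = _JAC_STEP,
) -> StandardisedCurve:
    """Standardised restricted mean failure time: expected time lost to
    ``cause`` before ``t_star``,

        L_k^x(0, t*) = E[ integral_0^{t*} F_k(u|x,Z) du ]
                     = E[ integral_0^{t*} (t* - u) S(u|x,Z) h_k(u|x,Z) du ]

    (the inner CIF integral is folded into a single quadrature by Fubini).
    """
    t_star = float(t_star)
    if t_star < 0:
        raise ValueError("t_star must be >= 0")
    mlist, cidx, cols, Zpat, w, xg, wg = _cif_machinery(models, data, at, cause, nodes)
    theta0, vcov, offs = _joint(mlist)

    last_knot = np.exp(models[cause].baseline_basis.knots.boundary[1])
    if t_star > last_knot * (1 + 1e-9):
        warnings.warn(
            f"t_star={t_star:g} lies beyond the last baseline knot "
            f"({last_knot:g}); the spline's linear tail is extrapolated",
            RuntimeWarning,
        )

    if t_star == 0:
        u = np.empty(0)
        wq = np.empty(0)
    else:
        s = 0.5 * (xg + 1.0)
        u = t_star * s**3  # cubic substitution, as in std_cif
        wq = t_star * 1.5 * s**2 * wg
    grids = [_ModelGrid(m, u, cols) for m in mlist] if t_star > 0 else None

    def fn(theta):
        if t_star == 0:
            return np.zeros(1)
        H = 0.0
        eta_c = dsdu_c = None
        for i, (g, a, b) in enumerate(zip(grids, offs[:-1], offs[1:])):
            eta, dsdu = g.eta_dsdu(theta[a:b], Zpat)
            H = H + np.exp(eta)
            if i == cidx:
                eta_c, dsdu_c = eta, dsdu
        hc = dsdu_c * np.exp(eta_c) / u[:, None]
        integrand = np.exp(-H) * hc * (t_star - u)[:, None]
        return np.array([(wq @ integrand) @ w])

    key = tuple(id(m) for m in mlist)
    return _curve(
        fn, theta0, vcov, np.array([t_star]), at, "rmft", cause, t_star,
        ci_level, None, step, key,
    )


# ---------------------------------------------------------------------------
# contrasts


def _check_contrastable(curves: list[StandardisedCurve], lincom: bool):
    if len(curves) < 2:
        raise ValueError("a contrast needs at least two curves")
    base = curves[0]
    for c in curves[1:]:
        if not np.array_equal(c.times, base.times):
            raise ValueError("curves have mismatched time grids")
        if c._model_key != base._model_key:
            raise ValueError("curves must come from the same fitted models")
        if not lincom and (c.kind != base.kind or c.cause != base.cause):
            raise ValueError("difference/ratio requires matching kind and cause")
        if lincom and c.kind != base.kind:
            raise ValueError("lincom requires curves of the same kind")


def contrast(
    curves: list[StandardisedCurve],
    spec: ContrastSpec | None = None,
    **kwargs,
) -> ContrastResult | list[ContrastResult]:
    """Pointwise difference, ratio, or linear combination of standardised
    curves, with delta-method SEs over the joint model parameters.

    For ``difference``/``ratio``, ``spec.ref`` indexes the reference curve
    and one result is returned per non-reference curve (a bare result when
    there is a single comparison, standsurv's at2 - at1 convention).  Ratios
    where the reference estimate is 0 are flagged as NaN.
    """
    if spec is None:
        spec = ContrastSpec(**kwargs)
    lincom = spec.kind == "lincom"
    _check_contrastable(curves, lincom)
    theta = curves[0]._theta
    vcov = curves[0]._vcov
    fns = [c._fn for c in curves]
    z_level = spec.ci_level

    if lincom:
        coefs = tuple(float(c) for c in spec.coefficients)
        if len(coefs) != len(curves):
            raise ValueError("one lincom coefficient per curve is required")

        def fn(th):
            return sum(c * f(th) for c, f in zip(coefs, fns))

        est = fn(theta)
        se = delta_method(fn, theta, vcov)
        lo, hi = _wald_ci(est, se, z_level)
        return ContrastResult(
            kind="lincom",
            reference=-1,
            coefficients=coefs,
            times=curves[0].times,
            estimate=est,
            se=se,
            ci_low=lo,
            ci_high=hi,
            labels=tuple(c.at.describe() for c in curves),
            ci_level=z_level,
        )

    ref = spec.ref
    if not (0 <= ref < len(curves)):
        raise ValueError("contrast reference index out of range")
    results = []
    for i, c in enumerate(curves):
        if i == ref:
            continue
        if spec.kind == "difference":

            def fn(th, i=i):
                return fns[i](th) - fns[ref](th)

            est = fn(theta)
            se = delta_method(fn, theta, vcov)
            lo, hi = _wald_ci(est, se, z_level)
        else:  # ratio

            def fn(th, i=i):
                a = fns[i](th)
                b = fns[ref](th)
                with np.errstate(divide="ignore", invalid="ignore"):
                    return np.where(b != 0, a / b, np.nan)

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                est = fn(theta)
                ok = np.isfinite(est)
                se = np.full_like(est, np.nan)
                if np.any(ok):
                    # Jacobian only where defined
                    def fn_ok(th, i=i):
                        return fn(th)[ok]

                    se[ok] = delta_method(fn_ok, theta, vcov)
                lo, hi = _wald_ci(est, se, z_level)
        results.append(
            ContrastResult(
                kind=spec.kind,
                reference=ref,
                coefficients=None,
                times=c.times,
                estimate=est,
                se=se,
                ci_low=lo,
                ci_high=hi,
                labels=(c.at.describe(), curves[ref].at.describe()),
                ci_level=z_level,
            )
        )
    return results[0] if len(results) == 1 else results


def user_contrast(
    curves: list[StandardisedCurve],
    func,
    label: str = "user",
    ci_level: float = 0.95,
) -> ContrastResult:
    """Apply a user-defined contrast function with delta-method inference.

    ``func`` receives one estimate vector per curve (in order, each of
    length ``len(times)``) and must return a vector of the same length; it
    must be smooth in its inputs (it is differentiated through numerically).
    This is the in-language replacement for a compiled contrast plugin: any
    functional of the standardised curves — e.g. a number-needed-to-treat
    ``lambda a, b: 1.0 / (b - a)`` — gets pointwise delta-method standard
    errors over the joint parameter vector of the underlying models.
    """
    _check_contrastable(curves, lincom=True)
    theta = curves[0]._theta
    vcov = curves[0]._vcov
    fns = [c._fn for c in curves]

    def fn(th):
        return np.asarray(func(*[f(th) for f in fns]), dtype=float)

    est = fn(theta)
    se = delta_method(fn, theta, vcov)
    lo, hi = _wald_ci(est, se, ci_level)
    return ContrastResult(
        kind=label,
        reference=-1,
        coefficients=None,
        times=curves[0].times,
        estimate=est,
        se=se,
        ci_low=lo,
        ci_high=hi,
        labels=tuple(c.at.describe() for c in curves),
        ci_level=ci_level,
    )


# ---------------------------------------------------------------------------
# separable effects


@dataclass
class SeparableResult:
    """Standardised CIFs under independent settings of the treatment
    components, plus the derivable direct/indirect contrasts."""

    curves: dict[tuple[float, float], StandardisedCurve]
    direct: dict[float, ContrastResult] = field(default_factory=dict)
    indirect: dict[float, ContrastResult] = field(default_factory=dict)


def separable(
    models: CauseModelSet,
    data: SurvivalDataset,
    x_c: str,
    x_o: str,
    at_pairs: list[tuple[float, float]],
    times: np.ndarray,
    cause: str | None = None,
    nodes: int = 100,
    ci_level: float = 0.95,
) -> SeparableResult:
    """Separable direct/indirect effects of a two-component treatment.

    The dataset must contain ``x_c`` and ``x_o`` as exact copies of the
    treatment column; the cause-of-interest model includes only ``x_c``
    among the clones and the competing-cause model only ``x_o``.  For every
    pair ``(a, b)`` in ``at_pairs`` the standardised CIF of ``cause`` under
    ``x_c = a, x_o = b`` is computed.  Where both settings of one component
    are present (the other held fixed), the direct contrast
    ``CIF(1, b) - CIF(0, b)`` and the indirect contrast
    ``CIF(a, 1) - CIF(a, 0)`` are also returned.
    """
    if data.treatment is None:
        raise ValueError("dataset must declare its treatment column")
    cov = data.covariates
    for clone in (x_c, x_o):
        if clone not in cov.columns:
            raise ValueError(f"clone column '{clone}' not found in dataset")
        if not np.array_equal(
            cov[clone].to_numpy(float), cov[data.treatment].to_numpy(float)
        ):
            raise ValueError(
                f"clone column '{clone}' must be an exact copy of the "
                f"treatment column '{data.treatment}'"
            )
    if cause is None:
        cause = next(
            lbl
            for lbl, m in zip(models.labels, models.models)
            if x_c in m.spec.covariates
        )
    cancer_model = models[cause]
    if x_c not in cancer_model.spec.covariates or x_o in cancer_model.spec.covariates:
        raise ValueError(
            f"the '{cause}' model must include '{x_c}' and exclude '{x_o}'"
        )
    for lbl, m in zip(models.labels, models.models):
        if lbl == cause:
            continue
        if x_o not in m.spec.covariates or x_c in m.spec.covariates:
            raise ValueError(
                f"the '{lbl}' model must include '{x_o}' and exclude '{x_c}'"
            )

    curves: dict[tuple[float, float], StandardisedCurve] = {}
    for a, b in at_pairs:
        at = AtSpec(
            {x_c: float(a), x_o: float(b)}, label=f"{x_c}={a:g},{x_o}={b:g}"
        )
        curves[(float(a), float(b))] = std_cif(
            models, data, at, times, cause, nodes=nodes, ci_level=ci_level,
            check_quadrature=False,
        )

    result = SeparableResult(curves=curves)
    pairs = set(curves)
    for b in {p[1] for p in pairs}:
        if (1.0, b) in pairs and (0.0, b) in pairs:
            result.direct[b] = contrast(
                [curves[(0.0, b)], curves[(1.0, b)]],
                ContrastSpec(kind="difference", ref=0, ci_level=ci_level),
            )
    for a in {p[0] for p in pairs}:
        if (a, 1.0) in pairs and (a, 0.0) in pairs:
            result.indirect[a] = contrast(
                [curves[(a, 0.0)], curves[(a, 1.0)]],
                ContrastSpec(kind="difference", ref=0, ci_level=ci_level),
            )
    return result
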