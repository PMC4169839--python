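"""Donor segment effect estimation: LSQ, ridge BLUP and heteroscedastic RMLV.

All three estimators work on the linear model

    y = 1 * beta0 + Z u + e

where ``y`` holds phenotypic values of the introgression lines (or their
replicated plot values), ``Z`` is the zygosity-coded segment design matrix,
``u`` the donor segment effects and ``e`` residual noise.

* **LSQ** treats ``u`` as fixed and drops the intercept; it requires a
  full-column-rank ``Z`` and admits exact F-tests.
* **BLUP** treats the segment effects as random with a common variance
  ``sigma_u^2``, which turns the fit into ridge regression with a single
  shrinkage factor ``lambda = sigma_e^2 / sigma_u^2``.  When ``lambda`` is
  not supplied it is estimated by REML via a one-dimensional profile of the
  restricted log-likelihood over ``log10 lambda``.
* **RMLV** starts from the BLUP solution and re-estimates a separate
  variance ``sigma_i^2`` per segment from the squared first-stage effect,
  giving each segment its own shrinkage ``lambda_i = sigma_e^2 / sigma_i^2``.
  Large effects are shrunken less, small effects are pushed towards zero —
  the appropriate behaviour for oligogenic donor-recipient differences.

Rank-deficient designs (overlapping donor segments, S > N) are handled by
BLUP/RMLV; LSQ raises :class:`RankDeficiencyError`.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import linalg, optimize

from .segments import DesignMatrix

__all__ = [
    "PhenotypeVector",
    "ModelFit",
    "RankDeficiencyError",
    "fit_lsq",
    "fit_blup",
    "fit_rmlv",
    "predict",
]

#: log10(lambda) search interval for the REML profile.
REML_LOG10_BOUNDS = (-6.0, 6.0)
#: relative floor of the RMLV per-segment variances (times sigma_u^2).
RMLV_VARIANCE_EPS = 1e-6

_TINY = 1e-300


class RankDeficiencyError(ValueError):
    """Z lacks full column rank; the requested fixed-effect fit is undefined."""


@dataclasses.dataclass
class PhenotypeVector:
    """Phenotypic values aligned with the rows of a design matrix."""

    line_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = [str(l) for l in self.line_ids]
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size != len(self.line_ids):
            raise ValueError(
                f"{v.size} phenotype values for {len(self.line_ids)} line ids"
            )
        if not np.all(np.isfinite(v)):
            bad = [self.line_ids[i] for i in np.flatnonzero(~np.isfinite(v))]
            raise ValueError(f"non-finite phenotype value(s) for line(s) {bad}")
        self.values = v

    def __len__(self) -> int:
        return self.values.size


@dataclasses.dataclass
class ModelFit:
    """Result of an LSQ / BLUP / RMLV fit.

    ``intercept`` is ``None`` for the intercept-free LSQ model.  ``lambda_``
    is the common BLUP shrinkage (also the RMLV first stage);
    ``lambdas``/``segment_variances`` are the per-segment RMLV quantities.
    """

    method: str
    segment_ids: list
    effects: np.ndarray
    intercept: float | None
    fitted: np.ndarray
    residuals: np.ndarray
    sigma2_e: float
    sigma2_u: float | None = None
    lambda_: float | None = None
    lambdas: np.ndarray | None = None
    segment_variances: np.ndarray | None = None
    n_obs: int = 0

    @property
    def n_segments(self) -> int:
        return len(self.segment_ids)


def _as_design(Z) -> tuple[np.ndarray, list | None, list | None]:
    if isinstance(Z, DesignMatrix):
        return np.asarray(Z.Z, float), list(Z.row_ids), list(Z.col_ids)
    Zm = np.asarray(Z, dtype=float)
    if Zm.ndim != 2:
        raise ValueError("Z must be a 2-D matrix")
    return Zm, None, None


def _as_response(y, row_ids) -> np.ndarray:
    if isinstance(y, PhenotypeVector):
        if row_ids is not None and y.line_ids != row_ids:
            raise ValueError(
                "phenotype line ids do not match design rows; align or expand "
                "the design matrix first"
            )
        return y.values
    v = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite phenotype values")
    return v


def _col_ids(col_ids, s) -> list:
    return col_ids if col_ids is not None else [f"seg{j + 1}" for j in range(s)]


def fit_lsq(Z, y) -> ModelFit:
    """Ordinary least squares with fixed segment effects and no intercept.

    Raises
    ------
    RankDeficiencyError
        If Z is not of full column rank (overlapping-segment populations);
        use :func:`fit_blup` or :func:`fit_rmlv` instead.
    """
    Zm, row_ids, col_ids = _as_design(Z)
    yv = _as_response(y, row_ids)
    n, s = Zm.shape
    if yv.size != n:
        raise ValueError(f"{yv.size} phenotypes for {n} design rows")
    rank = np.linalg.matrix_rank(Zm)
    if rank < s:
        raise RankDeficiencyError(
            f"Z has column rank {rank} < {s}: donor segment effects are not "
            "estimable by ordinary least squares; use fit_blup or fit_rmlv"
        )
    u, _, _, _ = np.linalg.lstsq(Zm, yv, rcond=None)
    fitted = Zm @ u
    resid = yv - fitted
    sse = float(resid @ resid)
    sigma2_e = sse / (n - s) if n > s else float("nan")
    return ModelFit(
        method="LSQ",
        segment_ids=_col_ids(col_ids, s),
        effects=u,
        intercept=None,
        fitted=fitted,
        residuals=resid,
        sigma2_e=sigma2_e,
        n_obs=n,
    )


def solve_ridge(
    Zm: np.ndarray,
    yv: np.ndarray,
    penalties: np.ndarray,
    include_intercept: bool = True,
) -> tuple[float, np.ndarray]:
    """Solve the ridge / mixed-model equations with per-segment penalties.

    Minimises ``||y - beta0 - Z u||^2 + sum_i penalties[i] * u_i^2`` (the
    intercept is unpenalised).  Returns ``(beta0, u)``; ``beta0`` is 0.0
    when ``include_intercept`` is false.
    """
    n, s = Zm.shape
    d = np.asarray(penalties, dtype=float)
    if d.shape != (s,):
        raise ValueError(f"expected {s} penalties, got shape {d.shape}")
    if (d < 0).any():
        raise ValueError("negative ridge penalties")
    if include_intercept:
        W = np.column_stack([np.ones(n), Zm])
        pen = np.concatenate([[0.0], d])
    else:
        W = Zm
        pen = d
    C = W.T @ W + np.diag(pen)
    rhs = W.T @ yv
    if np.all(d > 0):
        coef = linalg.cho_solve(linalg.cho_factor(C, lower=True), rhs)
    elif np.all(d == 0):
        # zero penalty: fall back to least squares; demand identifiability
        if np.linalg.matrix_rank(W) < W.shape[1]:
            raise RankDeficiencyError(
                "zero shrinkage requested on a rank-deficient system"
            )
        coef = np.linalg.lstsq(W, yv, rcond=None)[0]
    else:
        raise ValueError("penalties must be all positive or all zero")
    if include_intercept:
        return float(coef[0]), coef[1:]
    return 0.0, coef


class _RemlProfile:
    """Restricted log-likelihood of lambda for y = 1*b0 + Zu + e.

    Works in S-dimensional space via the Woodbury identity, so the cost per
    evaluation is O(S^3) regardless of the number of observations:

        H(lambda)   = I_N + Z Z^T / lambda
        H^{-1}      = I - Z (lambda I + Z^T Z)^{-1} Z^T
        log|H|      = log|lambda I + Z^T Z| - S log lambda
    """

    def __init__(self, Zm: np.ndarray, yv: np.ndarray):
        self.n, self.s = Zm.shape
        self.ZtZ = Zm.T @ Zm
        x = np.ones(self.n)
        self.Ztx = Zm.T @ x
        self.Zty = Zm.T @ yv
        self.xtx = float(x @ x)
        self.xty = float(x @ yv)
        self.yty = float(yv @ yv)

    def quadratics(self, lam: float) -> tuple[float, float, float, float]:
        """(x'H^-1 x, x'H^-1 y, y'H^-1 y, log|H|) at the given lambda."""
        A = self.ZtZ + lam * np.eye(self.s)
        cf = linalg.cho_factor(A, lower=True)
        ax = linalg.cho_solve(cf, self.Ztx)
        ay = linalg.cho_solve(cf, self.Zty)
        xhx = self.xtx - float(self.Ztx @ ax)
        xhy = self.xty - float(self.Ztx @ ay)
        yhy = self.yty - float(self.Zty @ ay)
        logdet_a = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        logdet_h = logdet_a - self.s * np.log(lam)
        return xhx, xhy, yhy, logdet_h

    def sigma2_e(self, lam: float) -> float:
        xhx, xhy, yhy, _ = self.quadratics(lam)
        ypy = yhy - xhy**2 / max(xhx, _TINY)
        return max(ypy, 0.0) / (self.n - 1)

    def neg_restricted_ll(self, log10_lam: float) -> float:
        lam = 10.0**log10_lam
        xhx, xhy, yhy, logdet_h = self.quadratics(lam)
        ypy = max(yhy - xhy**2 / max(xhx, _TINY), _TINY)
        s2 = ypy / (self.n - 1)
        return (self.n - 1) * np.log(max(s2, _TINY)) + logdet_h + np.log(
            max(xhx, _TINY)
        )


def reml_lambda(Zm: np.ndarray, yv: np.ndarray) -> tuple[float, float]:
    """REML estimate of the common shrinkage lambda and of sigma_e^2.

    The restricted log-likelihood is profiled over ``log10 lambda`` on
    :data:`REML_LOG10_BOUNDS` with bounded scalar optimisation (tolerance
    1e-6).  Hitting an interval bound triggers a warning and the boundary
    value is used.
    """
    prof = _RemlProfile(Zm, yv)
    res = optimize.minimize_scalar(
        prof.neg_restricted_ll,
        bounds=REML_LOG10_BOUNDS,
        method="bounded",
        options={"xatol": 1e-6},
    )
    x = float(res.x)
    lo, hi = REML_LOG10_BOUNDS
    if x - lo < 1e-2 or hi - x < 1e-2:
        warnings.warn(
            f"REML profile optimum at log10(lambda) = {x:.3f}, near the "
            f"search bound [{lo}, {hi}]; boundary value used",
            RuntimeWarning,
            stacklevel=3,
        )
    lam = 10.0**x
    return lam, prof.sigma2_e(lam)


def fit_blup(
    Z,
    y,
    lambda_: float | None = None,
    include_intercept: bool = True,
) -> ModelFit:
    """Ridge-regression BLUP of the donor segment effects.

    A single shrinkage factor ``lambda = sigma_e^2 / sigma_u^2`` is applied
    to every segment; when ``lambda_`` is not supplied it is estimated by
    REML (requires an intercept and N >= 3).  Rank-deficient designs are
    allowed for any ``lambda_ > 0``.
    """
    Zm, row_ids, col_ids = _as_design(Z)
    yv = _as_response(y, row_ids)
    n, s = Zm.shape
    if yv.size != n:
        raise ValueError(f"{yv.size} phenotypes for {n} design rows")
    if lambda_ is None:
        if not include_intercept:
            raise ValueError("REML shrinkage estimation requires the intercept")
        if n < 3:
            raise ValueError(f"REML needs at least 3 observations, got {n}")
        lam, sigma2_e = reml_lambda(Zm, yv)
    else:
        lam = float(lambda_)
        if lam < 0:
            raise ValueError("lambda_ must be non-negative")
        if n < 2:
            raise ValueError("need at least 2 observations")
        if include_intercept and lam > 0:
            sigma2_e = _RemlProfile(Zm, yv).sigma2_e(lam)
        else:
            sigma2_e = float("nan")
    beta0, u = solve_ridge(Zm, yv, np.full(s, lam), include_intercept)
    fitted = beta0 + Zm @ u
    resid = yv - fitted
    if not np.isfinite(sigma2_e) and lam == 0 and n > s:
        sigma2_e = float(resid @ resid) / (n - s - int(include_intercept))
    sigma2_u = sigma2_e / lam if lam > 0 and np.isfinite(sigma2_e) else float("inf")
    return ModelFit(
        method="BLUP",
        segment_ids=_col_ids(col_ids, s),
        effects=u,
        intercept=beta0 if include_intercept else None,
        fitted=fitted,
        residuals=resid,
        sigma2_e=sigma2_e,
        sigma2_u=sigma2_u,
        lambda_=lam,
        n_obs=n,
    )


def update_segment_variances(
    effects: np.ndarray, sigma2_u: float, eps: float = RMLV_VARIANCE_EPS
) -> np.ndarray:
    """RMLV per-segment variance rule: sigma_i^2 = max(u_i^2, eps*sigma_u^2).

    Isolated so an alternative heteroscedastic variance update can be
    swapped in without touching the fitting loop.  The floor keeps every
    variance strictly positive (and every shrinkage finite).
    """
    floor = max(eps * sigma2_u, _TINY) if np.isfinite(sigma2_u) else _TINY
    return np.maximum(np.asarray(effects, float) ** 2, floor)


def fit_rmlv(
    Z,
    y,
    n_updates: int = 1,
    eps: float = RMLV_VARIANCE_EPS,
    lambda_: float | None = None,
) -> ModelFit:
    """Heteroscedastic ridge regression (RMLV) of donor segment effects.

    Stage 1 is the homoscedastic BLUP fit (REML shrinkage unless ``lambda_``
    is given).  Each of the ``n_updates`` passes then sets per-segment
    variances from the current squared effects via
    :func:`update_segment_variances` and re-solves the ridge system with
    segment-specific shrinkage ``lambda_i = sigma_e^2 / sigma_i^2``.  The
    residual variance is carried over from stage 1 rather than re-estimated,
    which avoids feedback between shrinkage and the noise estimate.
    """
    if n_updates < 1:
        raise ValueError("n_updates must be >= 1")
    stage1 = fit_blup(Z, y, lambda_=lambda_)
    Zm, row_ids, col_ids = _as_design(Z)
    yv = _as_response(y, row_ids)
    sigma2_e = stage1.sigma2_e
    sigma2_u = stage1.sigma2_u
    if not np.isfinite(sigma2_u) or sigma2_u <= 0:
        sigma2_u = float(np.mean(stage1.effects**2)) or _TINY
    u = stage1.effects
    beta0 = stage1.intercept or 0.0
    num = sigma2_e if np.isfinite(sigma2_e) and sigma2_e > 0 else _TINY
    for _ in range(n_updates):
        variances = update_segment_variances(u, sigma2_u, eps)
        lambdas = num / variances
        beta0, u = solve_ridge(Zm, yv, lambdas, include_intercept=True)
    fitted = beta0 + Zm @ u
    return ModelFit(
        method="RMLV",
        segment_ids=list(stage1.segment_ids),
        effects=u,
        intercept=beta0,
        fitted=fitted,
        residuals=yv - fitted,
        sigma2_e=sigma2_e,
        sigma2_u=stage1.sigma2_u,
        lambda_=stage1.lambda_,
        lambdas=lambdas,
        segment_variances=variances,
        n_obs=stage1.n_obs,
    )


def predict(fit: ModelFit, Z) -> PhenotypeVector:
    """Predict phenotypes ``1*beta0 + Z u`` for new (or training) lines."""
    Zm, row_ids, col_ids = _as_design(Z)
    if col_ids is not None and col_ids != list(fit.segment_ids):
        raise ValueError(
            "design matrix segment ids do not match the fitted effects"
        )
    if Zm.shape[1] != fit.n_segments:
        raise ValueError(
            f"design has {Zm.shape[1]} columns, fit has {fit.n_segments} effects"
        )
    values = (fit.intercept or 0.0) + Zm @ fit.effects
    if row_ids is None:
        row_ids = [f"row{i + 1}" for i in range(Zm.shape[0])]
    return PhenotypeVector(line_ids=row_ids, values=values)
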