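"""Penalized regression-spline GAM with by-factor smooths and assay random effects.

Gaussian identity-link additive models of the form

    response ~ factor terms + s(covariate, k, by=factor) + (random intercepts)

fitted by penalized least squares with smoothing parameters selected by
REML.  Smooths use a cubic regression spline basis on quantile-spaced knots
with a second-derivative (curvature) penalty; each smooth block is centered
(sum-to-zero over its active rows) so one null-space direction — the linear
trend — survives per block.  Random-effect blocks are level indicators under
an identity (ridge) penalty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .errors import DesignError, FitError, PredictionError

__all__ = [
    "SmoothSpec",
    "GamSpec",
    "SmoothBasis",
    "Design",
    "GamFit",
    "KCheckResult",
    "spline_basis",
    "build_design",
    "fit_penalized",
    "reml_score",
    "fit_reml",
    "diagnostics",
    "predict_mean",
]

_EIG_TOL = 1e-8


# ---------------------------------------------------------------------------
# smooth basis


@dataclass(frozen=True)
class SmoothSpec:
    covariate: str = "Time"
    k: int = 10
    by: str | None = None

    def __post_init__(self) -> None:
        if self.k < 3:
            raise DesignError("smooth basis dimension k must be >= 3")


@dataclass(frozen=True)
class GamSpec:
    """Model formula: linear factors + by-factor smooths + random intercepts."""

    response: str = "rsum"
    linear_factors: tuple[str, ...] = ()
    smooths: tuple[SmoothSpec, ...] = ()
    random_effects: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.response:
            raise DesignError("spec needs exactly one response")


def _cr_penalty(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-regression-spline interior-curvature map F and penalty S.

    With coefficients equal to function values at the knots, the second
    derivatives at interior knots are F @ beta and the integrated squared
    second derivative is beta' S beta  (S = D' B^-1 D).
    """
    k = knots.size
    h = np.diff(knots)
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i < k - 3:
            B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
    F = linalg.solve(B, D, assume_a="pos")
    S = D.T @ F
    return F, 0.5 * (S + S.T)


class SmoothBasis:
    """Centered cubic regression spline basis with curvature penalty.

    Attributes: ``basis`` (n x (k-1) centered design block at the
    construction points), ``penalty`` ((k-1) x (k-1) PSD matrix) and
    ``null_space_dim`` (1: the linear trend is unpenalized).
    """

    def __init__(self, times: Sequence[float], k: int):
        x = np.asarray(times, dtype=float)
        uniq = np.unique(x)
        if k < 3:
            raise DesignError("k must be >= 3")
        if uniq.size < k:
            raise DesignError(f"need at least k={k} distinct covariate values, got {uniq.size}")
        knots = np.quantile(uniq, np.linspace(0.0, 1.0, k))
        knots = np.unique(knots)
        if knots.size < k:
            raise DesignError("quantile knots are not distinct; reduce k")
        self.knots = knots
        self.k = k
        self._F, self._S_raw = _cr_penalty(knots)
        self._F_full = np.vstack([np.zeros(k), self._F, np.zeros(k)])
        self.cov_min = float(x.min())
        self.cov_max = float(x.max())

        raw = self._raw(x)
        c = raw.sum(axis=0)
        # Z spans the null space of the sum-to-zero constraint c' beta = 0
        q, _ = np.linalg.qr(c.reshape(-1, 1), mode="complete")
        self._Z = q[:, 1:]
        self.basis = raw @ self._Z
        S = self._Z.T @ self._S_raw @ self._Z
        self.penalty = 0.5 * (S + S.T)
        self.null_space_dim = 1

    def _raw(self, x: np.ndarray) -> np.ndarray:
        knots = self.knots
        k = knots.size
        j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, k - 2)
        h = knots[j + 1] - knots[j]
        dr = knots[j + 1] - x
        dl = x - knots[j]
        am = dr / h
        ap = dl / h
        cm = (dr**3 / h - h * dr) / 6.0
        cp = (dl**3 / h - h * dl) / 6.0
        X = np.zeros((x.size, k))
        rows = np.arange(x.size)
        X[rows, j] += am
        X[rows, j + 1] += ap
        X += cm[:, None] * self._F_full[j] + cp[:, None] * self._F_full[j + 1]
        return X

    def evaluate(self, x: Sequence[float], check_range: bool = True) -> np.ndarray:
        """Centered basis rows at new covariate values (no extrapolation)."""
        x = np.asarray(x, dtype=float)
        if check_range and (x.min() < self.cov_min - 1e-9 or x.max() > self.cov_max + 1e-9):
            raise PredictionError(
                f"covariate outside fitted range [{self.cov_min}, {self.cov_max}]"
            )
        return self._raw(x) @ self._Z


def spline_basis(times: Sequence[float], k: int, knot_rule: str = "quantile") -> SmoothBasis:
    """Build the centered spline block for a covariate vector.

    Only quantile-spaced knots are implemented; the returned object exposes
    ``basis``, ``penalty``, ``null_space_dim`` and ``evaluate``.
    """
    if knot_rule != "quantile":
        raise DesignError(f"unknown knot rule {knot_rule!r}")
    return SmoothBasis(times, k)


# ---------------------------------------------------------------------------
# design


@dataclass
class _PenaltyBlock:
    name: str
    sl: slice
    S: np.ndarray
    rank: int
    logdet_pos: float
    null_dim: int


@dataclass
class _SmoothTerm:
    name: str
    spec: SmoothSpec
    level: str | None  # by-level, None for a plain smooth
    basis: SmoothBasis
    sl: slice


@dataclass
class Design:
    """Model matrix, penalty list and enough metadata to rebuild rows."""

    spec: GamSpec
    X: np.ndarray
    y: np.ndarray
    factor_levels: dict[str, list[str]]
    re_levels: dict[str, list[str]]
    smooth_terms: list[_SmoothTerm]
    penalties: list[_PenaltyBlock]
    term_slices: dict[str, slice]
    column_names: list[str]

    def __post_init__(self) -> None:
        self.n, self.p = self.X.shape
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        self._check_unpenalized_rank()

    @property
    def n_penalties(self) -> int:
        return len(self.penalties)

    @property
    def null_space_total(self) -> int:
        """Dimension of the total-penalty null space (unpenalized coefficients)."""
        return self.p - sum(b.rank for b in self.penalties)

    def _check_unpenalized_rank(self) -> None:
        pen_cols = np.zeros(self.p, dtype=bool)
        for b in self.penalties:
            pen_cols[b.sl] = True
        unpen = ~pen_cols
        if unpen.sum() == 0:
            return
        sub = self.XtX[np.ix_(unpen, unpen)]
        ev = np.linalg.eigvalsh(sub)
        if ev[0] < _EIG_TOL * max(ev[-1], 1.0):
            raise FitError("rank-deficient unpenalized model part (collinear factor terms)")

    def penalized_matrix(self, lam: Sequence[float]) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        if lam.size != self.n_penalties:
            raise FitError(f"expected {self.n_penalties} smoothing parameters, got {lam.size}")
        if np.any(lam < 0):
            raise FitError("smoothing parameters must be nonnegative")
        A = self.XtX.copy()
        for b, l in zip(self.penalties, lam):
            A[b.sl, b.sl] += l * b.S
        return A

    def build_rows(self, newdata: pd.DataFrame, include_re: bool = True) -> np.ndarray:
        """Design rows for new data; random-effect columns zeroed when excluded."""
        n = len(newdata)
        X = np.zeros((n, self.p))
        X[:, self.term_slices["(intercept)"]] = 1.0
        for f, levels in self.factor_levels.items():
            vals = newdata[f].astype(str).to_numpy()
            unseen = set(vals) - set(levels)
            if unseen:
                raise PredictionError(f"unseen level(s) {sorted(unseen)} for factor {f!r}")
            sl = self.term_slices[f"factor:{f}"]
            for idx, lev in enumerate(levels[1:]):
                X[vals == lev, sl.start + idx] = 1.0
        for term in self.smooth_terms:
            cov = newdata[term.spec.covariate].to_numpy(dtype=float)
            if term.level is None:
                active = np.ones(n, dtype=bool)
            else:
                vals = newdata[term.spec.by].astype(str).to_numpy()
                active = vals == term.level
            if active.any():
                X[np.ix_(active, np.arange(term.sl.start, term.sl.stop))] = term.basis.evaluate(
                    cov[active]
                )
        for re_name, levels in self.re_levels.items():
            sl = self.term_slices[f"re:{re_name}"]
            if not include_re:
                continue
            vals = newdata[re_name].astype(str).to_numpy()
            unseen = set(vals) - set(levels)
            if unseen:
                raise PredictionError(f"unseen level(s) {sorted(unseen)} for random effect {re_name!r}")
            for idx, lev in enumerate(levels):
                X[vals == lev, sl.start + idx] = 1.0
        return X


def _levels_of(series: pd.Series) -> list[str]:
    if isinstance(series.dtype, pd.CategoricalDtype):
        observed = set(series.astype(str))
        return [str(l) for l in series.cat.categories if str(l) in observed]
    return sorted(pd.unique(series.astype(str)))


def build_design(spec: GamSpec, data: pd.DataFrame) -> Design:
    """Assemble the model matrix and penalty blocks for a data frame.

    Factor coding is treatment contrasts (first/reference level dropped);
    each by-factor smooth contributes an independent centered block per
    level sharing k and penalty structure; random effects contribute one
    indicator column per level with an identity penalty.
    """
    for col in (spec.response, *spec.linear_factors, *spec.random_effects):
        if col not in data.columns:
            raise DesignError(f"column {col!r} missing from data")
    for sm in spec.smooths:
        if sm.covariate not in data.columns:
            raise DesignError(f"smooth covariate {sm.covariate!r} missing from data")
        if sm.by is not None and sm.by not in data.columns:
            raise DesignError(f"by-factor {sm.by!r} missing from data")

    y = data[spec.response].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise DesignError("response contains NaN; filter invalid rows before fitting")
    n = len(data)

    blocks: list[np.ndarray] = [np.ones((n, 1))]
    names = ["(intercept)"]
    term_slices: dict[str, slice] = {"(intercept)": slice(0, 1)}
    pos = 1

    factor_levels: dict[str, list[str]] = {}
    for f in spec.linear_factors:
        levels = _levels_of(data[f])
        if len(levels) < 2:
            raise DesignError(f"factor {f!r} needs >= 2 observed levels")
        factor_levels[f] = levels
        vals = data[f].astype(str).to_numpy()
        dummies = np.column_stack([(vals == lev).astype(float) for lev in levels[1:]])
        blocks.append(dummies)
        term_slices[f"factor:{f}"] = slice(pos, pos + dummies.shape[1])
        names += [f"{f}[{lev}]" for lev in levels[1:]]
        pos += dummies.shape[1]

    smooth_terms: list[_SmoothTerm] = []
    penalties: list[_PenaltyBlock] = []
    for sm in spec.smooths:
        cov = data[sm.covariate].to_numpy(dtype=float)
        if sm.by is None:
            sub_levels: list[str | None] = [None]
        else:
            sub_levels = list(_levels_of(data[sm.by]))
        for lev in sub_levels:
            if lev is None:
                active = np.ones(n, dtype=bool)
                tname = f"s({sm.covariate})"
            else:
                active = data[sm.by].astype(str).to_numpy() == lev
                tname = f"s({sm.covariate}):{sm.by}[{lev}]"
            if active.sum() < sm.k:
                raise DesignError(f"term {tname}: fewer active rows than k={sm.k}")
            basis = SmoothBasis(cov[active], sm.k)
            width = basis.basis.shape[1]
            block = np.zeros((n, width))
            block[active] = basis.basis
            sl = slice(pos, pos + width)
            blocks.append(block)
            term_slices[tname] = sl
            names += [f"{tname}.{i + 1}" for i in range(width)]
            smooth_terms.append(_SmoothTerm(tname, sm, lev, basis, sl))
            ev = np.linalg.eigvalsh(basis.penalty)
            rank = int((ev > _EIG_TOL * max(ev[-1], 1.0)).sum())
            logdet = float(np.log(ev[ev > _EIG_TOL * max(ev[-1], 1.0)]).sum())
            penalties.append(
                _PenaltyBlock(tname, sl, basis.penalty, rank, logdet, width - rank)
            )
            pos += width

    re_levels: dict[str, list[str]] = {}
    for re_name in spec.random_effects:
        levels = _levels_of(data[re_name])
        re_levels[re_name] = levels
        vals = data[re_name].astype(str).to_numpy()
        block = np.column_stack([(vals == lev).astype(float) for lev in levels])
        sl = slice(pos, pos + len(levels))
        blocks.append(block)
        tname = f"re:{re_name}"
        term_slices[tname] = sl
        names += [f"{re_name}[{lev}]" for lev in levels]
        penalties.append(
            _PenaltyBlock(tname, sl, np.eye(len(levels)), len(levels), 0.0, 0)
        )
        pos += len(levels)

    X = np.hstack(blocks)
    return Design(
        spec=spec,
        X=X,
        y=y,
        factor_levels=factor_levels,
        re_levels=re_levels,
        smooth_terms=smooth_terms,
        penalties=penalties,
        term_slices=term_slices,
        column_names=names,
    )


# ---------------------------------------------------------------------------
# fitting


@dataclass
class PenalizedFit:
    beta: np.ndarray
    sigma2: float
    rss: float
    penalty: float
    edf_total: float
    edf_terms: dict[str, float]
    A: np.ndarray  # penalized normal-equation matrix X'X + sum lam_j S_j


def fit_penalized(design: Design, y: np.ndarray | None = None, lam: Sequence[float] = ()) -> PenalizedFit:
    """Penalized least squares at fixed smoothing parameters.

    Minimizes ``||y - X b||^2 + sum_j lam_j b' S_j b``; the scale estimate is
    ``RSS / (n - total EDF)``.
    """
    if y is None:
        y = design.y
        Xty, yty = design.Xty, design.yty
    else:
        y = np.asarray(y, dtype=float)
        Xty = design.X.T @ y
        yty = float(y @ y)
    A = design.penalized_matrix(lam)
    try:
        cf = linalg.cho_factor(A, lower=True)
    except linalg.LinAlgError as exc:
        raise FitError(f"penalized system not positive definite: {exc}") from exc
    beta = linalg.cho_solve(cf, Xty)
    H = linalg.cho_solve(cf, design.XtX)  # A^-1 X'X; trace = total EDF
    edf_total = float(np.trace(H))
    edf_terms: dict[str, float] = {}
    diag = np.diag(H)
    for name, sl in design.term_slices.items():
        edf_terms[name] = float(diag[sl].sum())
    rss = max(yty - 2.0 * beta @ Xty + beta @ design.XtX @ beta, 0.0)
    penalty = 0.0
    for b, l in zip(design.penalties, np.asarray(lam, dtype=float)):
        penalty += l * float(beta[b.sl] @ b.S @ beta[b.sl])
    denom = design.n - edf_total
    sigma2 = rss / denom if denom > 0 else np.nan
    return PenalizedFit(beta, sigma2, rss, penalty, edf_total, edf_terms, A)


def reml_score(design: Design, y: np.ndarray | None = None, lam: Sequence[float] = ()) -> float:
    """Profiled Gaussian REML criterion (smaller is better).

    The scale is profiled out analytically; the score is, up to a constant,

        (n - Mp)/2 * [log(2 pi s2) + 1] + (log|X'X + S_lam| - log|S_lam|_+)/2

    with ``s2 = (RSS + penalty)/(n - Mp)`` and Mp the total-penalty null
    dimension.  Penalty blocks are disjoint, so ``log|S_lam|_+`` decomposes
    per block.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise FitError("reml_score needs strictly positive smoothing parameters")
    if y is None:
        y = design.y
    fit = fit_penalized(design, y, lam)
    n = design.n
    mp = design.null_space_total
    s2 = (fit.rss + fit.penalty) / (n - mp)
    if s2 <= 0:
        s2 = np.finfo(float).tiny
    cf = linalg.cho_factor(fit.A, lower=True)
    logdet_A = 2.0 * float(np.log(np.diag(cf[0])).sum())
    logdet_S = sum(
        b.rank * np.log(l) + b.logdet_pos for b, l in zip(design.penalties, lam)
    )
    return float(
        0.5 * (n - mp) * (np.log(2.0 * np.pi * s2) + 1.0) + 0.5 * (logdet_A - logdet_S)
    )


@dataclass
class KCheckResult:
    term: str
    k_prime: int
    edf: float
    k_index: float
    p_value: float


@dataclass
class GamFit:
    """Fitted GAM: coefficients, smoothing parameters, covariance, diagnostics."""

    spec: GamSpec
    design: Design
    lam: np.ndarray
    beta: np.ndarray
    scale: float
    cov: np.ndarray  # posterior covariance V_b
    edf_terms: dict[str, float]
    edf_total: float
    reml: float
    aic: float
    deviance_explained: float
    fitted: np.ndarray
    residuals: np.ndarray
    converged: bool
    data: pd.DataFrame

    @property
    def nobs(self) -> int:
        return self.design.n

    @property
    def residual_df(self) -> float:
        return self.nobs - self.edf_total

    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.maximum(np.diag(self.cov), 0.0))
        return pd.DataFrame(
            {"name": self.design.column_names, "estimate": self.beta, "se": se}
        )

    def linear_term_tests(self) -> pd.DataFrame:
        """Wald tests for the treatment-coded linear factor coefficients."""
        rows = []
        se_all = np.sqrt(np.maximum(np.diag(self.cov), 0.0))
        df = self.residual_df
        for f, levels in self.design.factor_levels.items():
            sl = self.design.term_slices[f"factor:{f}"]
            for idx, lev in enumerate(levels[1:]):
                j = sl.start + idx
                est, se = self.beta[j], se_all[j]
                t = est / se if se > 0 else np.nan
                p = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else np.nan
                rows.append(
                    {"factor": f, "level": lev, "estimate": est, "se": se, "t": t, "p": p}
                )
        return pd.DataFrame(rows)


def fit_reml(
    spec: GamSpec,
    data: pd.DataFrame,
    *,
    restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-6,
    maxiter: int = 400,
) -> GamFit:
    """Fit a GAM, selecting smoothing parameters by multi-start Nelder-Mead REML."""
    design = build_design(spec, data)
    nlam = design.n_penalties

    if nlam == 0:
        best_rho = np.array([])
        converged = True
    else:
        rng = np.random.default_rng(seed)

        def objective(rho: np.ndarray) -> float:
            rho = np.clip(rho, -30.0, 30.0)
            try:
                return reml_score(design, None, np.exp(rho))
            except FitError:
                return np.inf

        starts = [np.zeros(nlam), np.full(nlam, 4.0), np.full(nlam, -4.0)]
        while len(starts) < max(restarts, 1):
            starts.append(rng.uniform(-8.0, 8.0, size=nlam))
        best_rho, best_val, converged = None, np.inf, False
        for s in starts[: max(restarts, 1)]:
            res = optimize.minimize(
                objective,
                s,
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": tol, "maxiter": maxiter * nlam},
            )
            if res.fun < best_val:
                best_val, best_rho = res.fun, res.x
                converged = converged or bool(res.success)
        if best_rho is None or not np.isfinite(best_val):
            raise FitError("REML optimization failed from every start")

    lam = np.exp(np.clip(best_rho, -30.0, 30.0)) if nlam else np.array([])
    pf = fit_penalized(design, None, lam)
    cf = linalg.cho_factor(pf.A, lower=True)
    cov = linalg.cho_solve(cf, np.eye(design.p)) * pf.sigma2
    fitted = design.X @ pf.beta
    resid = design.y - fitted
    rss = float(resid @ resid)
    tss = float(((design.y - design.y.mean()) ** 2).sum())
    dev_expl = 1.0 - rss / tss if tss > 0 else np.nan
    n = design.n
    sigma2_ml = max(rss / n, np.finfo(float).tiny)
    aic = n * np.log(2.0 * np.pi * sigma2_ml) + n + 2.0 * (pf.edf_total + 1.0)
    reml = reml_score(design, None, lam) if nlam else np.nan
    return GamFit(
        spec=spec,
        design=design,
        lam=lam,
        beta=pf.beta,
        scale=pf.sigma2,
        cov=0.5 * (cov + cov.T),
        edf_terms=pf.edf_terms,
        edf_total=pf.edf_total,
        reml=reml,
        aic=aic,
        deviance_explained=dev_expl,
        fitted=fitted,
        residuals=resid,
        converged=converged,
        data=data,
    )


def _kcheck_stat(resid: np.ndarray) -> float:
    """Variance of first differences of ordered residuals over 2x residual variance."""
    v = resid.var()
    if v <= 0:
        return np.nan
    return float(np.mean(np.diff(resid) ** 2) / (2.0 * v))


def diagnostics(fit: GamFit, n_perm: int = 200, seed: int = 0) -> dict:
    """Model-adequacy heuristics: deviance explained, AIC, residuals, k-check.

    The k-check orders each smooth term's residuals by its covariate and
    compares the variance of their first differences against randomized
    orderings; unmodeled structure in the covariate direction yields small
    statistics and small p-values.
    """
    rng = np.random.default_rng(seed)
    kchecks: list[KCheckResult] = []
    data = fit.data
    for term in fit.design.smooth_terms:
        cov = data[term.spec.covariate].to_numpy(dtype=float)
        if term.level is None:
            active = np.ones(fit.nobs, dtype=bool)
        else:
            active = data[term.spec.by].astype(str).to_numpy() == term.level
        r = fit.residuals[active]
        order = np.argsort(cov[active], kind="stable")
        obs = _kcheck_stat(r[order])
        perm_le = 0
        for _ in range(n_perm):
            perm = rng.permutation(r)
            if _kcheck_stat(perm) <= obs:
                perm_le += 1
        p = (1.0 + perm_le) / (n_perm + 1.0)
        kchecks.append(
            KCheckResult(
                term=term.name,
                k_prime=term.basis.basis.shape[1],
                edf=fit.edf_terms[term.name],
                k_index=obs,
                p_value=p,
            )
        )
    r = fit.residuals
    return {
        "deviance_explained": fit.deviance_explained,
        "aic": fit.aic,
        "residual_summary": {
            "mean": float(r.mean()),
            "sd": float(r.std(ddof=1)) if r.size > 1 else np.nan,
            "min": float(r.min()),
            "max": float(r.max()),
        },
        "kcheck": kchecks,
    }


def predict_mean(
    fit: GamFit, newdata: pd.DataFrame, include_re: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Fitted mean and pointwise SE at new covariate/factor combinations.

    Random-effect columns are zeroed (population-level prediction) unless
    ``include_re``; times outside the fitted range are rejected.
    """
    X = fit.design.build_rows(newdata, include_re=include_re)
    mu = X @ fit.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, fit.cov, X), 0.0))
    return mu, se
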