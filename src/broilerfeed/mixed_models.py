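"""Random-intercept linear mixed models with sum-to-zero contrasts.

Fits y_ij = x_ij' beta + u_j + e_ij with u_j ~ N(0, var_id) per bird and
e_ij ~ N(0, var_resid) by restricted maximum likelihood, profiled down to a
one-dimensional optimization over the variance ratio var_id/var_resid
(fast enough for thousands of fits in simulation studies). Categorical
terms use sum-to-zero coding, fixed-effect tests are Type III single-df
F/t tests, backward elimination respects marginality, and explained
variance is reported as the marginal/conditional R-squared pair.

Degrees of freedom: residual-df t tests (df = n_obs - n_fixed_columns) are
used rather than a Satterthwaite approximation; the choice is recorded in
``LmmFit.df_method``.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

#: factor variables and their level order; the first level codes +1,
#: the second -1 (sum-to-zero)
FACTOR_LEVELS: dict[str, tuple[str, str]] = {
    "sex": ("female", "male"),
    "gait_class": ("GG", "SG"),
}

#: response shorthand -> descriptor-table column
RESPONSE_COLUMNS = {"nfv": "nfv", "mfbd": "mfbd_s", "ndf": "ndf"}

DEFAULT_MAIN_EFFECTS = ("age_days", "sex", "gait_class", "start_bw_g", "bw_gain_g_d")


def default_candidate_terms(
    mains: Sequence[str] = DEFAULT_MAIN_EFFECTS,
) -> tuple[str, ...]:
    """All main effects plus all two-way interactions."""
    inters = [":".join(pair) for pair in itertools.combinations(mains, 2)]
    return tuple(mains) + tuple(inters)


@dataclass(frozen=True)
class ModelSpec:
    """Response, candidate fixed effects and selection threshold.

    ``fixed_terms`` may contain interaction terms written ``"a:b"``; every
    component of an interaction must itself be present as a main effect
    (marginality).
    """

    response: str
    fixed_terms: tuple[str, ...] = field(default_factory=default_candidate_terms)
    alpha: float = 0.05
    group: str = "bird_id"

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        mains = {t for t in self.fixed_terms if ":" not in t}
        for term in self.fixed_terms:
            if ":" in term:
                for comp in term.split(":"):
                    if comp not in mains:
                        raise ValueError(
                            f"marginality violated: interaction {term!r} without main effect {comp!r}"
                        )

    @property
    def response_column(self) -> str:
        return RESPONSE_COLUMNS.get(self.response, self.response)


@dataclass
class LmmFit:
    """Fitted state of one random-intercept model (the shape of a results table)."""

    response: str
    terms: pd.DataFrame  # index Intercept+terms; columns estimate, se, F, p
    var_id: float
    var_resid: float
    var_fixed: float
    n_obs: int
    n_birds: int
    r2_marginal: float
    r2_conditional: float
    df_resid: float
    method: str = "REML"
    df_method: str = "residual"
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "fixed_effects": {
                name: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                for name, row in self.terms.to_dict(orient="index").items()
            },
            "random_effects": {"var_id": self.var_id, "var_resid": self.var_resid},
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "n_obs": self.n_obs,
            "n_birds": self.n_birds,
            "method": self.method,
            "df_method": self.df_method,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def contrast_matrix(levels: Sequence[str]) -> np.ndarray:
    """Sum-to-zero contrast matrix for a two-level factor (column sums 0)."""
    if len(levels) != 2:
        raise ValueError("only two-level factors are supported")
    return np.array([[1.0], [-1.0]])


def _variable_column(data: pd.DataFrame, var: str) -> np.ndarray:
    if var not in data.columns:
        raise KeyError(f"model variable {var!r} not in data")
    if var in FACTOR_LEVELS:
        levels = FACTOR_LEVELS[var]
        vals = data[var].astype(str).to_numpy()
        unknown = set(vals) - set(levels)
        if unknown:
            raise ValueError(f"unknown level(s) {sorted(unknown)} for factor {var!r}")
        codes = contrast_matrix(levels).ravel()
        return np.where(vals == levels[0], codes[0], codes[1]).astype(float)
    col = pd.to_numeric(data[var], errors="raise").to_numpy(dtype=float)
    return col


def build_design(data: pd.DataFrame, terms: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Design matrix with an intercept and one column per (single-df) term."""
    n = len(data)
    cols = [np.ones(n)]
    names = ["Intercept"]
    cache: dict[str, np.ndarray] = {}

    def var(v: str) -> np.ndarray:
        if v not in cache:
            cache[v] = _variable_column(data, v)
        return cache[v]

    for term in terms:
        parts = term.split(":")
        col = var(parts[0]).copy()
        for part in parts[1:]:
            col = col * var(part)
        cols.append(col)
        names.append(term)
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# profiled-REML engine
# ---------------------------------------------------------------------------


class _RandomInterceptEngine:
    """Sufficient statistics for fast repeated REML fits on column subsets.

    With V* = I + gamma * Z Z' and W = inv(V*), all of X'WX, X'Wy and y'Wy
    reduce to the raw cross-products corrected by per-group sums, so the
    profiled REML criterion costs O(g p^2) per evaluation.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, codes: np.ndarray, names: list[str]):
        self.names = names
        self.n, self.p_full = X.shape
        self.g = int(codes.max()) + 1
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        # per-group sums
        self.S = np.zeros((self.g, self.p_full))
        np.add.at(self.S, codes, X)
        self.h = np.bincount(codes, weights=y, minlength=self.g)
        self.n_i = np.bincount(codes, minlength=self.g).astype(float)
        self._X = X
        self._y = y
        self._codes = codes

    def _criterion_parts(self, gamma: float, idx: np.ndarray):
        c = gamma / (1.0 + self.n_i * gamma)  # shape (g,)
        S = self.S[:, idx]
        A = self.XtX[np.ix_(idx, idx)] - (S * c[:, None]).T @ S
        b = self.Xty[idx] - S.T @ (c * self.h)
        yWy = self.yty - float(c @ (self.h**2))
        try:
            L = np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            return None
        z = np.linalg.solve(L, b)
        q = yWy - float(z @ z)
        logdetA = 2.0 * float(np.log(np.diag(L)).sum())
        return A, b, q, logdetA, c

    def reml_criterion(self, gamma: float, idx: np.ndarray) -> float:
        parts = self._criterion_parts(gamma, idx)
        if parts is None:
            return np.inf
        _, _, q, logdetA, _ = parts
        if q <= 0:
            return np.inf
        p = len(idx)
        logdetV = float(np.log1p(self.n_i * gamma).sum())
        return logdetV + logdetA + (self.n - p) * math.log(q)

    def fit(self, idx: Sequence[int]) -> dict:
        idx = np.asarray(idx, dtype=int)
        p = len(idx)
        self._check_rank(idx)

        def obj(psi: float) -> float:
            return self.reml_criterion(math.exp(psi), idx)

        res = optimize.minimize_scalar(obj, bounds=(-14.0, 16.0), method="bounded",
                                       options={"xatol": 1e-10})
        gamma = math.exp(res.x)
        # the boundary var_id = 0 must be admissible
        if self.reml_criterion(0.0, idx) <= res.fun:
            gamma = 0.0
        A, b, q, _, _ = self._criterion_parts(gamma, idx)
        beta = np.linalg.solve(A, b)
        sigma2 = q / (self.n - p)
        tau2 = gamma * sigma2
        cov = sigma2 * np.linalg.inv(A)
        eta = self._X[:, idx] @ beta
        var_fixed = float(np.var(eta, ddof=1)) if self.n > 1 else 0.0
        return {
            "names": [self.names[i] for i in idx],
            "beta": beta,
            "cov": cov,
            "var_id": float(tau2),
            "var_resid": float(sigma2),
            "var_fixed": var_fixed,
            "gamma": float(gamma),
            "df_resid": float(self.n - p),
            "converged": bool(res.success),
        }

    def _check_rank(self, idx: np.ndarray) -> None:
        Xs = self._X[:, idx]
        # scale-invariant rank test: raw columns differ by orders of magnitude
        norms = np.linalg.norm(Xs, axis=0)
        norms[norms == 0] = 1.0
        Xs = Xs / norms
        rank = np.linalg.matrix_rank(Xs)
        if rank < len(idx):
            # name the dependent columns via pivoted QR
            from scipy.linalg import qr

            _, R, piv = qr(Xs, mode="economic", pivoting=True)
            diag = np.abs(np.diag(R))
            tol = diag.max() * max(Xs.shape) * np.finfo(float).eps
            bad = [self.names[idx[piv[k]]] for k in range(len(idx)) if k >= rank or diag[k] < tol]
            raise np.linalg.LinAlgError(
                f"singular fixed-effects design; collinear term(s): {sorted(set(bad))}"
            )


def _prepare(data: pd.DataFrame, spec: ModelSpec) -> tuple[_RandomInterceptEngine, pd.DataFrame]:
    ycol = spec.response_column
    if ycol not in data.columns:
        raise KeyError(f"response column {ycol!r} not in data")
    used_vars = sorted({v for t in spec.fixed_terms for v in t.split(":")})
    work = data.copy()
    n_missing = int(work[ycol].isna().sum())
    if n_missing:
        logger.info("dropping %d row(s) with missing response %s", n_missing, ycol)
        work = work[work[ycol].notna()]
    for v in used_vars + [spec.group]:
        if v not in work.columns:
            raise KeyError(f"model variable {v!r} not in data")
        if work[v].isna().any():
            raise ValueError(f"missing values in model variable {v!r}")
    codes, uniques = pd.factorize(work[spec.group], sort=True)
    counts = np.bincount(codes)
    if (counts >= 2).sum() < 2 or len(uniques) < 2:
        raise ValueError("need at least 2 birds with at least 2 observations each")
    X, names = build_design(work, spec.fixed_terms)
    y = work[ycol].to_numpy(dtype=float)
    engine = _RandomInterceptEngine(X, y, codes, names)
    engine.n_birds = len(uniques)  # type: ignore[attr-defined]
    return engine, work


def _fit_to_lmmfit(engine: _RandomInterceptEngine, raw: dict, spec: ModelSpec) -> LmmFit:
    beta = raw["beta"]
    se = np.sqrt(np.diag(raw["cov"]))
    df = raw["df_resid"]
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    fvals = tvals**2
    terms = pd.DataFrame(
        {"estimate": beta, "se": se, "F": fvals, "p": pvals},
        index=raw["names"],
    )
    r2m, r2c = r2_nakagawa(raw["var_fixed"], raw["var_id"], raw["var_resid"])
    return LmmFit(
        response=spec.response,
        terms=terms,
        var_id=raw["var_id"],
        var_resid=raw["var_resid"],
        var_fixed=raw["var_fixed"],
        n_obs=engine.n,
        n_birds=getattr(engine, "n_birds", engine.g),
        r2_marginal=r2m,
        r2_conditional=r2c,
        df_resid=df,
        converged=raw["converged"],
    )


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> LmmFit:
    """REML fit of the random-intercept model defined by ``spec``.

    Rows with a missing response are dropped (logged); missing values in
    used covariates are an error, as is a rank-deficient design (the
    offending collinear terms are named).
    """
    engine, _ = _prepare(data, spec)
    raw = engine.fit(np.arange(engine.p_full))
    return _fit_to_lmmfit(engine, raw, spec)


def r2_nakagawa(var_fixed: float, var_id: float, var_resid: float) -> tuple[float, float]:
    """Marginal and conditional R-squared from variance components.

    marginal = var_fixed / total, conditional = (var_fixed + var_id) / total
    with total = var_fixed + var_id + var_resid; degenerate all-zero
    components give (0, 0).
    """
    total = var_fixed + var_id + var_resid
    if total <= 0:
        return 0.0, 0.0
    return var_fixed / total, (var_fixed + var_id) / total


def r2_for_fit(fit: LmmFit) -> tuple[float, float]:
    """The R-squared pair of a fitted model (recomputed from its components)."""
    return r2_nakagawa(fit.var_fixed, fit.var_id, fit.var_resid)


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------


def _eligible(terms: list[str]) -> list[str]:
    """Terms removable without violating marginality."""
    inter_parts = {c for t in terms if ":" in t for c in t.split(":")}
    out = []
    for t in terms:
        if ":" in t:
            out.append(t)
        elif t not in inter_parts:
            out.append(t)
    return out


def backward_select(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[ModelSpec, LmmFit, pd.DataFrame]:
    """Backward elimination of non-significant terms at ``spec.alpha``.

    Repeatedly refit (REML) and remove the single least-significant
    eligible term with p > alpha; interactions are removed before the main
    effects they contain, and a main effect is eligible only once it
    appears in no retained interaction. Ties in p are broken by removing
    the higher-order term first, then alphabetically. Returns the final
    spec, its fit and the elimination log (step, term, p, n_terms_left).
    """
    engine, _ = _prepare(data, spec)
    name_to_col = {name: i for i, name in enumerate(engine.names)}
    current = list(spec.fixed_terms)
    log_rows = []
    step = 0
    while True:
        idx = [0] + [name_to_col[t] for t in current]
        raw = engine.fit(idx)
        pvals = dict(zip(raw["names"], 2.0 * stats.t.sf(
            np.abs(raw["beta"] / np.sqrt(np.diag(raw["cov"]))), raw["df_resid"])))
        candidates = [t for t in _eligible(current) if pvals[t] > spec.alpha]
        if not candidates:
            final_spec = ModelSpec(
                response=spec.response, fixed_terms=tuple(current),
                alpha=spec.alpha, group=spec.group,
            )
            fit = _fit_to_lmmfit(engine, raw, final_spec)
            log = pd.DataFrame(log_rows, columns=["step", "term", "p", "n_terms_left"])
            return final_spec, fit, log
        # max p; ties -> interactions first, then alphabetical
        candidates.sort(key=lambda t: (-pvals[t], 0 if ":" in t else 1, t))
        victim = candidates[0]
        step += 1
        current.remove(victim)
        log_rows.append({"step": step, "term": victim, "p": float(pvals[victim]),
                         "n_terms_left": len(current)})
        logger.info("backward selection step %d: removed %s (p=%.4g)",
                    step, victim, pvals[victim])


def build_model_table(descriptors: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Join bird-day descriptors with per-bird covariates for modelling."""
    return descriptors.merge(covariates, on="bird_id", how="inner")
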