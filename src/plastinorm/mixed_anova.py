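"""Mixed-model ANOVA for growth-rate tables.

Fits Gaussian variance-components models by REML and reports

* Type III Wald F-tests for fixed terms with Satterthwaite denominator
  degrees of freedom (all factors sum-to-zero coded, so the Type III test of
  a term is the test that its coefficients vanish),
* chi-square likelihood-ratio tests for random terms (full vs term-deleted
  REML fits),
* Holm-corrected pairwise mutant-vs-control interaction tests.

Two model shapes are provided: an overall model with environmental
parameter, setting nested within parameter, mechanism, their interactions,
and genotype-level random terms; and a per-parameter model with mechanism,
setting, their interaction, and genotype(-by-setting) random terms.

All random terms are crossed with the genotype grouping factor, so the
marginal covariance is block-diagonal by genotype; each random term
contributes one pooled variance component (no covariances).  The REML
criterion, its gradient, and the expected (Fisher) information are computed
analytically, which makes the Satterthwaite df exact on balanced designs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .synthetic_data import ValidationError

__all__ = [
    "MixedModelSpec",
    "MixedModelFit",
    "AnovaResult",
    "ConvergenceError",
    "overall_spec",
    "per_param_spec",
    "fit_mixed_model",
    "type3_tests",
    "lrt_random_effects",
    "anova_table",
    "pairwise_control_tests",
    "holm_adjust",
]

log = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class MixedModelSpec:
    """Model terms over a long-format growth-rate table.

    Fixed-term expressions: a column name, a nested term ``inner(outer)``,
    or an interaction joined with ``:``.  Random-term expressions: the
    grouping factor itself (a random intercept per group) or
    ``factor:group`` / ``inner(outer):group`` for a pooled
    variance-component interaction with the group.
    """

    fixed: tuple[str, ...]
    random: tuple[str, ...] = ()
    response: str = "rate_mm_per_hr"
    group: str = "genotype"


def overall_spec(extra_fixed: tuple[str, ...] = ()) -> MixedModelSpec:
    """All-data model: mechanism x parameter x setting-within-parameter."""
    return MixedModelSpec(
        fixed=(
            "mechanism",
            "env_param",
            "setting(env_param)",
            "mechanism:env_param",
            "mechanism:setting(env_param)",
        ) + tuple(extra_fixed),
        random=("genotype", "env_param:genotype", "setting(env_param):genotype"),
    )


def per_param_spec(extra_fixed: tuple[str, ...] = ()) -> MixedModelSpec:
    """Single-parameter model: mechanism x setting with genotype terms."""
    return MixedModelSpec(
        fixed=("mechanism", "setting", "mechanism:setting") + tuple(extra_fixed),
        random=("genotype", "setting:genotype"),
    )


# ---------------------------------------------------------------------------
# design-matrix construction (sum-to-zero coding throughout)
# ---------------------------------------------------------------------------

def _sum_code(values: pd.Series) -> np.ndarray:
    """Effect coding: L-1 columns, last level coded -1 everywhere."""
    levels = sorted(pd.unique(values))
    if len(levels) < 2:
        raise ValidationError(f"factor {values.name!r} has fewer than 2 levels")
    out = np.zeros((len(values), len(levels) - 1))
    arr = values.to_numpy()
    for j, lev in enumerate(levels[:-1]):
        out[:, j] = np.where(arr == lev, 1.0, 0.0)
    out[np.isin(arr, [levels[-1]])] = -1.0
    return out


def _nested_sum_code(df: pd.DataFrame, inner: str, outer: str) -> np.ndarray:
    """Sum-code ``inner`` separately within each level of ``outer``."""
    cols = []
    arr_outer = df[outer].to_numpy()
    for olev in sorted(pd.unique(df[outer])):
        mask = arr_outer == olev
        ilevels = sorted(pd.unique(df.loc[mask, inner]))
        if len(ilevels) < 2:
            continue
        iarr = df[inner].to_numpy()
        for ilev in ilevels[:-1]:
            col = np.zeros(len(df))
            col[mask & (iarr == ilev)] = 1.0
            col[mask & (iarr == ilevels[-1])] = -1.0
            cols.append(col)
    if not cols:
        raise ValidationError(f"nested term {inner}({outer}) produced no columns")
    return np.column_stack(cols)


def _component_matrix(df: pd.DataFrame, expr: str) -> np.ndarray:
    expr = expr.strip()
    if "(" in expr:
        inner, outer = expr[:-1].split("(")
        return _nested_sum_code(df, inner.strip(), outer.strip())
    if df[expr].dtype.kind in "fiu" and df[expr].nunique() > 12:
        # numeric covariate (e.g. growth-chamber-free continuous regressor)
        return df[expr].to_numpy(dtype=float)[:, None]
    return _sum_code(df[expr].astype(str).rename(expr))


def _term_matrix(df: pd.DataFrame, expr: str) -> np.ndarray:
    parts = [p for p in expr.split(":") if p.strip()]
    mat = _component_matrix(df, parts[0])
    for part in parts[1:]:
        other = _component_matrix(df, part)
        mat = np.einsum("ni,nj->nij", mat, other).reshape(len(df), -1)
    return mat


def _build_fixed(df: pd.DataFrame, spec: MixedModelSpec):
    pieces = [np.ones((len(df), 1))]
    slices: dict[str, slice] = {}
    start = 1
    for expr in spec.fixed:
        mat = _term_matrix(df, expr)
        pieces.append(mat)
        slices[expr] = slice(start, start + mat.shape[1])
        start += mat.shape[1]
    X = np.hstack(pieces)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # find the first term whose columns do not add full rank
        acc = pieces[0]
        for expr, mat in zip(spec.fixed, pieces[1:]):
            prev = np.linalg.matrix_rank(acc)
            acc = np.hstack([acc, mat])
            if np.linalg.matrix_rank(acc) < prev + mat.shape[1]:
                raise ValidationError(f"term {expr!r} is aliased with earlier terms")
        raise ValidationError("fixed-effects design is rank deficient")
    return X, slices


def _random_codes(df: pd.DataFrame, expr: str, group: str) -> np.ndarray | None:
    """Integer codes of the factor crossed with the group (None = intercept)."""
    expr = expr.strip()
    if expr == group:
        return None
    if not expr.endswith(f":{group}"):
        raise ValidationError(
            f"random term {expr!r} must be {group!r} or end with ':{group}'"
        )
    factor = expr[: -len(group) - 1].strip()
    if "(" in factor:
        inner, outer = factor[:-1].split("(")
        keys = list(zip(df[outer.strip()].astype(str), df[inner.strip()].astype(str)))
    else:
        keys = df[factor].astype(str).tolist()
    codes, _ = pd.factorize(pd.Series(keys), sort=True)
    return codes.astype(int)


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

@dataclass
class MixedModelFit:
    spec: MixedModelSpec
    data: pd.DataFrame
    y: np.ndarray
    X: np.ndarray
    term_slices: dict[str, slice]
    blocks: list[np.ndarray]               # row indices per group level
    rand_codes: list[np.ndarray | None]    # aligned with spec.random
    theta: np.ndarray                      # [sigma2_e, sigma2_r1, ...]
    beta: np.ndarray
    cov_beta: np.ndarray
    loglik: float                          # REML log-likelihood
    converged: bool
    n_obs: int = 0
    info: dict = field(default_factory=dict)

    @property
    def variance_components(self) -> dict[str, float]:
        out = {"residual": float(self.theta[0])}
        for name, th in zip(self.spec.random, self.theta[1:]):
            out[name] = float(th)
        return out


def _block_Z(codes: np.ndarray | None, rows: np.ndarray, n_levels: int) -> np.ndarray:
    if codes is None:
        return np.ones((rows.size, 1))
    c = codes[rows]
    levels = np.unique(c)
    return (c[:, None] == levels[None, :]).astype(float)


class _REMLProblem:
    def __init__(self, y, X, blocks, rand_codes):
        self.y = y
        self.X = X
        self.blocks = blocks
        self.n, self.p = X.shape
        self.k = 1 + len(rand_codes)  # error + components
        # pre-slice per block
        self.yb = [y[b] for b in blocks]
        self.Xb = [X[b] for b in blocks]
        self.Zb = [
            [_block_Z(codes, b, 0) for b in blocks] for codes in rand_codes
        ]

    def _assemble(self, theta):
        """Per-block factorizations and the profiled GLS quantities."""
        p = self.p
        XtViX = np.zeros((p, p))
        XtViy = np.zeros(p)
        ytViy = 0.0
        logdet = 0.0
        chos, Tbs, Viyb = [], [], []
        for ib in range(len(self.blocks)):
            m = self.yb[ib].size
            V = theta[0] * np.eye(m)
            for r in range(self.k - 1):
                Z = self.Zb[r][ib]
                V += theta[1 + r] * (Z @ Z.T)
            try:
                cho = cho_factor(V, lower=True)
            except np.linalg.LinAlgError:
                V = V + (1e-10 * np.trace(V) / m) * np.eye(m)
                cho = cho_factor(V, lower=True)
            logdet += 2.0 * np.sum(np.log(np.diag(cho[0])))
            T = cho_solve(cho, self.Xb[ib])
            vy = cho_solve(cho, self.yb[ib])
            XtViX += self.Xb[ib].T @ T
            XtViy += self.Xb[ib].T @ vy
            ytViy += self.yb[ib] @ vy
            chos.append(cho)
            Tbs.append(T)
            Viyb.append(vy)
        XtViX = 0.5 * (XtViX + XtViX.T)
        cho_C = cho_factor(XtViX)
        beta = cho_solve(cho_C, XtViy)
        quad = ytViy - beta @ XtViy
        sign, logdet_X = np.linalg.slogdet(XtViX)
        ll = -0.5 * ((self.n - p) * np.log(2 * np.pi) + logdet + logdet_X + quad)
        C = cho_solve(cho_C, np.eye(p))
        return {
            "ll": ll, "beta": beta, "C": C, "chos": chos, "Tb": Tbs,
            "Viy": Viyb, "XtViX": XtViX,
        }

    def loglik(self, theta):
        return self._assemble(theta)["ll"]

    def loglik_grad(self, theta):
        """REML log-likelihood and its gradient on the variance scale."""
        state = self._assemble(theta)
        C, beta = state["C"], state["beta"]
        grad = np.zeros(self.k)
        for i in range(self.k):
            tr_vinv_vi = 0.0
            M_i = np.zeros((self.p, self.p))
            quad_i = 0.0
            for ib in range(len(self.blocks)):
                cho, T = state["chos"][ib], state["Tb"][ib]
                resid_v = state["Viy"][ib] - T @ beta  # V^-1 r on this block
                if i == 0:
                    Vinv = cho_solve(cho, np.eye(T.shape[0]))
                    tr_vinv_vi += np.trace(Vinv)
                    M_i += T.T @ T
                    quad_i += resid_v @ resid_v
                else:
                    Z = self.Zb[i - 1][ib]
                    W = cho_solve(cho, Z)
                    tr_vinv_vi += np.sum(Z * W)
                    A = Z.T @ T
                    M_i += A.T @ A
                    zz = Z.T @ resid_v
                    quad_i += zz @ zz
            tr_P_Vi = tr_vinv_vi - np.sum(C * M_i)
            grad[i] = -0.5 * (tr_P_Vi - quad_i)
        return state["ll"], grad

    def expected_information(self, theta):
        """Fisher information I_ij = 0.5 tr(P V_i P V_j) at ``theta``."""
        state = self._assemble(theta)
        C = state["C"]
        nb = len(self.blocks)
        # per-block H_i = V^-1 V_i and V_i T
        term1 = np.zeros((self.k, self.k))
        M = [np.zeros((self.p, self.p)) for _ in range(self.k)]
        G = np.zeros((self.k, self.k))
        for ib in range(nb):
            cho, T = state["chos"][ib], state["Tb"][ib]
            m = T.shape[0]
            Vi_mats = [np.eye(m)] + [
                self.Zb[r][ib] @ self.Zb[r][ib].T for r in range(self.k - 1)
            ]
            H = [cho_solve(cho, Vi) for Vi in Vi_mats]
            U = [cho_solve(cho, Vi @ T) for Vi in Vi_mats]
            for i in range(self.k):
                M[i] += T.T @ (Vi_mats[i] @ T)
                for j in range(i, self.k):
                    term1[i, j] += np.sum(H[i] * H[j].T)
                for j in range(self.k):
                    # tr over blocks of T' V_j (V^-1 V_i T); contract with C later
                    G[i, j] += np.sum((T.T @ (Vi_mats[j] @ U[i])) * C)
        info = np.zeros((self.k, self.k))
        for i in range(self.k):
            for j in range(i, self.k):
                t3 = np.sum((C @ M[i]) * (M[j] @ C).T)
                val = 0.5 * (term1[i, j] - G[i, j] - G[j, i] + t3)
                info[i, j] = info[j, i] = val
        return info

    def contrast_variance_grad(self, state, l_vec):
        """d/d theta_i of l' C(theta) l, analytically, at an assembled state."""
        cl = state["C"] @ l_vec
        grad = np.zeros(self.k)
        for ib in range(len(self.blocks)):
            u = state["Tb"][ib] @ cl
            grad[0] += u @ u
            for r in range(self.k - 1):
                zu = self.Zb[r][ib].T @ u
                grad[1 + r] += zu @ zu
        return grad


def fit_mixed_model(table: pd.DataFrame, spec: MixedModelSpec) -> MixedModelFit:
    """REML fit of ``spec`` to the non-missing rows of ``table``."""
    df = table.copy()
    if "missing_flag" in df.columns:
        df = df[df["missing_flag"] == 0]
    df = df[df[spec.response].notna()].reset_index(drop=True)
    if len(df) == 0:
        raise ValidationError("no non-missing rows to fit")
    y = df[spec.response].to_numpy(dtype=float)
    X, slices = _build_fixed(df, spec)
    n, p = X.shape
    groups = df[spec.group].astype(str).to_numpy()
    blocks = [np.nonzero(groups == g)[0] for g in sorted(pd.unique(groups))]
    rand_codes = [_random_codes(df, expr, spec.group) for expr in spec.random]
    prob = _REMLProblem(y, X, blocks, rand_codes)

    if not spec.random:
        # OLS limit: closed-form REML
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        if n <= p:
            raise ValidationError("no residual degrees of freedom")
        s2 = rss / (n - p)
        state = prob._assemble(np.array([s2]))
        return MixedModelFit(
            spec=spec, data=df, y=y, X=X, term_slices=slices, blocks=blocks,
            rand_codes=rand_codes, theta=np.array([s2]), beta=state["beta"],
            cov_beta=state["C"], loglik=state["ll"], converged=True, n_obs=n,
        )

    vary = float(np.var(y)) or 1.0
    k = prob.k
    hi = np.log(vary * 1e6)
    # residual variance gets a higher floor: V degenerates when it vanishes
    bounds = [(np.log(vary * 1e-6), hi)] + [(np.log(vary * 1e-10), hi)] * (k - 1)

    def neg(lt):
        ll, g = prob.loglik_grad(np.exp(lt))
        return -ll, -g * np.exp(lt)

    best = None
    starts = [
        np.log(np.full(k, vary / k)),
        np.log(np.concatenate([[vary * 0.9], np.full(k - 1, vary * 0.01)])),
    ]
    for x0 in starts:
        res = optimize.minimize(
            neg, x0, jac=True, method="L-BFGS-B",
            bounds=bounds, options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError(f"REML optimization failed: {best}")
    if not best.success:
        # line-search breakdown at tight tolerances is routine; the gradient
        # check below is the real convergence criterion
        _, g = prob.loglik_grad(np.exp(best.x))
        if np.max(np.abs(g * np.exp(best.x))) > 1e-3:
            log.warning("REML optimizer message: %s", best.message)
    theta = np.exp(best.x)
    state = prob._assemble(theta)
    return MixedModelFit(
        spec=spec, data=df, y=y, X=X, term_slices=slices, blocks=blocks,
        rand_codes=rand_codes, theta=theta, beta=state["beta"],
        cov_beta=state["C"], loglik=state["ll"], converged=True, n_obs=n,
        info={"opt": {"fun": float(best.fun), "nit": int(best.nit)}},
    )


def _problem_of(fit: MixedModelFit) -> _REMLProblem:
    return _REMLProblem(fit.y, fit.X, fit.blocks, fit.rand_codes)


# ---------------------------------------------------------------------------
# Type III tests with Satterthwaite denominator df
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    fixed: pd.DataFrame                    # term, f_value, df_num, df_den, p_value
    random: pd.DataFrame | None = None     # term, chi2, df, p_value


def _satterthwaite_df(prob: _REMLProblem, state: dict, A: np.ndarray, L: np.ndarray) -> float:
    """Multi-df Satterthwaite denominator df for contrast rows ``L``.

    Follows the eigenvector decomposition of L C L': each 1-df eigencontrast
    gets a moment-matched df, and the per-contrast dfs are pooled into one
    denominator df for the F statistic.
    """
    q = L.shape[0]
    Mmat = L @ state["C"] @ L.T
    Mmat = 0.5 * (Mmat + Mmat.T)
    evals, evecs = np.linalg.eigh(Mmat)
    if np.min(evals) <= 0:
        raise np.linalg.LinAlgError("singular contrast covariance")
    nus = []
    for i in range(q):
        l_vec = L.T @ evecs[:, i]
        g = prob.contrast_variance_grad(state, l_vec)
        denom = float(g @ A @ g)
        d_i = float(evals[i])
        nu = 2.0 * d_i**2 / denom if denom > 0 else np.inf
        nus.append(nu)
    E = sum(nu / (nu - 2.0) for nu in nus if nu > 2.0)
    if E <= q:
        return float(prob.n - prob.p)  # degenerate; fall back to residual df
    return float(2.0 * E / (E - q))


def type3_tests(fit: MixedModelFit) -> AnovaResult:
    """Type III Wald F-tests with Satterthwaite denominator df."""
    prob = _problem_of(fit)
    state = prob._assemble(fit.theta)
    A = np.linalg.pinv(prob.expected_information(fit.theta))
    rows = []
    for term, sl in fit.term_slices.items():
        q = sl.stop - sl.start
        L = np.zeros((q, fit.X.shape[1]))
        L[np.arange(q), np.arange(sl.start, sl.stop)] = 1.0
        Mmat = L @ fit.cov_beta @ L.T
        Mmat = 0.5 * (Mmat + Mmat.T)
        try:
            Minv = np.linalg.inv(Mmat)
            lb = L @ fit.beta
            F = float(lb @ Minv @ lb) / q
            df_den = _satterthwaite_df(prob, state, A, L)
        except np.linalg.LinAlgError:
            warnings.warn(f"singular contrast for term {term!r}; skipped")
            continue
        p = float(stats.f.sf(F, q, df_den))
        rows.append({"term": term, "f_value": F, "df_num": q, "df_den": df_den, "p_value": p})
    return AnovaResult(fixed=pd.DataFrame(rows))


def lrt_random_effects(fit: MixedModelFit, term: str) -> dict:
    """Chi-square LRT for one random term (full vs term-deleted REML fit)."""
    if term not in fit.spec.random:
        raise ValidationError(f"{term!r} is not a random term of the model")
    reduced_spec = replace(
        fit.spec, random=tuple(t for t in fit.spec.random if t != term)
    )
    reduced = fit_mixed_model(fit.data, reduced_spec)
    chi2 = max(0.0, 2.0 * (fit.loglik - reduced.loglik))
    p = float(stats.chi2.sf(chi2, 1))
    return {"term": term, "chi2": chi2, "df": 1, "p": p}


def anova_table(fit: MixedModelFit) -> AnovaResult:
    """Full ANOVA: Type III fixed tests plus LRTs for every random term."""
    res = type3_tests(fit)
    rand_rows = [lrt_random_effects(fit, t) for t in fit.spec.random]
    res.random = pd.DataFrame(rand_rows) if rand_rows else None
    return res


# ---------------------------------------------------------------------------
# pairwise mutant-vs-control interaction tests
# ---------------------------------------------------------------------------

def pairwise_control_tests(
    table: pd.DataFrame, control: str, env_param: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Genotype-by-setting interaction tests, one mutant vs the control.

    Each mutant is compared with the control in a two-genotype fixed-effects
    model (genotype + setting + genotype:setting); the interaction p-values
    are Holm-adjusted across mutants within the environment.
    """
    sub = table[table["env_param"] == env_param]
    if control not in set(sub["genotype"]):
        raise ValidationError(f"control {control!r} absent from {env_param!r} data")
    mutants = sorted(g for g in sub["genotype"].unique() if g != control)
    if not mutants:
        raise ValidationError("no mutants to compare")
    spec = MixedModelSpec(fixed=("genotype", "setting", "genotype:setting"))
    rows = []
    for mutant in mutants:
        pair = sub[sub["genotype"].isin([control, mutant])]
        avail = pair[pair["genotype"] == mutant]
        n_settings = avail[avail["rate_mm_per_hr"].notna()]["setting"].nunique()
        if n_settings < 2:
            log.warning("mutant %s: <2 settings with data; skipped", mutant)
            continue
        res = type3_tests(fit_mixed_model(pair, spec))
        prow = res.fixed.set_index("term").loc["genotype:setting"]
        rows.append({"mutant": mutant, "p_raw": float(prow["p_value"])})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = holm_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_adjusted"] < alpha
    return out


def holm_adjust(pvals) -> np.ndarray:
    """Step-down Holm adjustment, returned in the original order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("pvals must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running = max(running, val)
        adj[idx] = running
    return adj
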