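"""Dirichlet regression of subgroup probabilities on covariates.

Each sample's K subgroup probabilities form a composition (they sum to
1), so per-predictor association models use Dirichlet regression in the
"common" parametrization: every subgroup k gets its own coefficient
vector gamma_k through a log link on the Dirichlet concentration
parameters,

    a_ik = exp(x_i' gamma_k),      y_i ~ Dirichlet(a_i1, ..., a_iK).

The log-likelihood, gradient and observed information are analytic; the
likelihood is maximized by quasi-Newton (L-BFGS-B) from a moment-based
start and Wald z-tests use standard errors from the inverse observed
information.  Continuous predictors are divided by their standard
deviation so estimates read "per SD".  Batteries of one-exposure-per-
model fits share a Bonferroni correction whose m is the number of
exposures tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, polygamma, psi

from .io_preprocess import CovariateTable

logger = logging.getLogger(__name__)

_BOUNDARY_EPS = 1e-12


def dirichlet_loglik(composition: np.ndarray, alpha_params: np.ndarray) -> float:
    """Dirichlet log-density summed over observations.

    ``sum_i [ lgamma(sum_k a_ik) - sum_k lgamma(a_ik)
              + sum_k (a_ik - 1) log y_ik ]``
    """
    y = np.asarray(composition, dtype=float)
    a = np.asarray(alpha_params, dtype=float)
    if y.ndim == 1:
        y = y[None, :]
        a = a[None, :]
    if (y <= 0).any() or (y >= 1).any():
        raise ValueError(
            "composition on the simplex boundary; apply squeeze_composition first"
        )
    if (a <= 0).any():
        raise ValueError("alpha parameters must be positive")
    return float(
        np.sum(gammaln(a.sum(axis=1)) - gammaln(a).sum(axis=1) + ((a - 1) * np.log(y)).sum(axis=1))
    )


def squeeze_composition(composition: np.ndarray) -> np.ndarray:
    """Shrink compositions off the simplex boundary.

    ``y' = (y (n - 1) + 1/K) / n`` with n the number of observations:
    rows still sum to 1, every entry lands in (0, 1), and interior rows
    move by at most 1/n.
    """
    y = np.asarray(composition, dtype=float)
    squeeze_1d = y.ndim == 1
    if squeeze_1d:
        y = y[None, :]
    n, K = y.shape
    out = (y * (n - 1) + 1.0 / K) / n
    return out[0] if squeeze_1d else out


def bonferroni_threshold(alpha: float, m_tests: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if m_tests < 1:
        raise ValueError(f"m_tests must be >= 1, got {m_tests}")
    return alpha / m_tests


def adjust_p(p: float | np.ndarray, m_tests: int) -> float | np.ndarray:
    """Bonferroni-adjusted p-value min(1, p * m)."""
    if m_tests < 1:
        raise ValueError(f"m_tests must be >= 1, got {m_tests}")
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.minimum(1.0, p * m_tests)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DirichletRegSpec:
    """One Dirichlet regression: outcome composition, exposure, adjustments."""

    outcome: np.ndarray
    exposure: str
    adjustments: tuple[str, ...] = ()
    standardize: bool = True

    def __post_init__(self) -> None:
        y = np.asarray(self.outcome, dtype=float)
        object.__setattr__(self, "outcome", y)
        if y.ndim != 2:
            raise ValueError("outcome must be an observations x K matrix")
        if not np.allclose(y.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("outcome rows must sum to 1")


@dataclass
class DirichletRegFit:
    """Coefficients, Wald inference and fit diagnostics.

    ``table`` is long-format with one row per (term, subgroup):
    columns term, subgroup, beta, se, z, p.
    """

    table: pd.DataFrame
    loglik: float
    converged: bool
    n_used: int
    n_dropped: int
    exposure: str
    exposure_terms: list[str] = field(default_factory=list)

    def exposure_table(self) -> pd.DataFrame:
        return self.table[self.table["term"].isin(self.exposure_terms)].reset_index(drop=True)


def _neg_loglik_grad(gamma_flat: np.ndarray, X: np.ndarray, logy: np.ndarray, K: int):
    p = X.shape[1]
    gamma = gamma_flat.reshape(p, K)
    eta = X @ gamma
    eta = np.clip(eta, -30, 30)  # guard overflow during line search
    a = np.exp(eta)
    S = a.sum(axis=1)
    ll = float(np.sum(gammaln(S) - gammaln(a).sum(axis=1) + ((a - 1) * logy).sum(axis=1)))
    g = a * (psi(S)[:, None] - psi(a) + logy)  # d ll / d eta_ik
    grad = X.T @ g  # p x K
    return -ll, -grad.ravel()


def _observed_information(gamma_flat: np.ndarray, X: np.ndarray, logy: np.ndarray, K: int):
    """Negative Hessian of the log-likelihood in the flattened (p*K) layout."""
    n, p = X.shape
    gamma = gamma_flat.reshape(p, K)
    a = np.exp(np.clip(X @ gamma, -30, 30))
    S = a.sum(axis=1)
    g = a * (psi(S)[:, None] - psi(a) + logy)          # n x K
    trig_S = polygamma(1, S)                            # n
    trig_a = polygamma(1, a)                            # n x K
    H = np.zeros((p * K, p * K))
    # d2 ll / d eta_ik d eta_im = delta_km (g_ik - a_ik^2 psi1(a_ik)) + a_ik a_im psi1(S_i)
    for k in range(K):
        for m_ in range(k, K):
            if k == m_:
                w = g[:, k] - a[:, k] ** 2 * trig_a[:, k] + a[:, k] ** 2 * trig_S
            else:
                w = a[:, k] * a[:, m_] * trig_S
            block = X.T @ (w[:, None] * X)
            H[k * p:(k + 1) * p, m_ * p:(m_ + 1) * p] = block
            if m_ != k:
                H[m_ * p:(m_ + 1) * p, k * p:(k + 1) * p] = block.T
    return -H  # observed information


def _flat_index(p: int, K: int):
    """Map (term j, subgroup k) to the flat index used by the optimizer."""
    # optimizer layout is gamma.reshape(p, K).ravel() = row-major over terms;
    # the Hessian above uses subgroup-major blocks, so build a permutation
    perm = np.empty(p * K, dtype=int)
    for j in range(p):
        for k in range(K):
            perm[j * K + k] = k * p + j
    return perm


def build_design(
    covariates: CovariateTable,
    variables: list[str],
    standardize: bool = True,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Build an intercept + dummy/per-SD design matrix.

    Returns the design (rows with missing values dropped) and a map
    variable -> list of design term names (one per dummy level for
    categoricals, the variable name itself for continuous).
    """
    df = covariates.data
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise KeyError(f"variables not in covariate table: {', '.join(missing)}")
    used = df[variables].dropna()
    cols = {"Intercept": np.ones(len(used))}
    term_map: dict[str, list[str]] = {}
    for v in variables:
        if covariates.kind_of(v) == "continuous":
            x = used[v].to_numpy(dtype=float)
            sd = x.std(ddof=1)
            if sd == 0:
                raise ValueError(f"zero-variance predictor {v!r}")
            cols[v] = x / sd if standardize else x
            term_map[v] = [v]
        else:
            ref = covariates.reference_of(v)
            levels = sorted(used[v].astype(str).unique())
            if ref is None:
                ref = levels[0]
            ref = str(ref)
            if len(levels) < 2:
                raise ValueError(f"zero-variance predictor {v!r}")
            terms = []
            for lev in levels:
                if lev == ref:
                    continue
                name = f"{v}[{lev}]"
                cols[name] = (used[v].astype(str) == lev).to_numpy(dtype=float)
                terms.append(name)
            term_map[v] = terms
    design = pd.DataFrame(cols, index=used.index)
    return design, term_map


def fit_dirichlet_regression(
    spec: DirichletRegSpec,
    covariates: CovariateTable,
    sample_ids: list[str] | None = None,
) -> DirichletRegFit:
    """Maximum-likelihood Dirichlet regression with Wald inference.

    The outcome rows are matched to the covariate rows positionally
    unless ``sample_ids`` are given, in which case both are aligned on
    identifiers.  Rows with missing values in any used variable are
    dropped and counted.  Compositions touching the simplex boundary are
    squeezed automatically (with a log notice).
    """
    variables = [spec.exposure, *spec.adjustments]
    design, term_map = build_design(covariates, variables, spec.standardize)
    y = spec.outcome
    if sample_ids is not None:
        pos = {s: i for i, s in enumerate(sample_ids)}
        keep = [s for s in design.index.astype(str) if s in pos]
        design = design.loc[[s for s in design.index if str(s) in pos]]
        y = y[[pos[str(s)] for s in design.index]]
    else:
        if len(design) < y.shape[0]:
            y = y[df_positions(covariates.data, design.index)]
        elif len(design) != y.shape[0]:
            raise ValueError("outcome rows do not match covariate rows")
    n_dropped = len(covariates.data) - len(design)
    n, K = y.shape[0], y.shape[1]
    if (y <= _BOUNDARY_EPS).any() or (y >= 1 - _BOUNDARY_EPS).any():
        logger.info("composition touches the simplex boundary; applying squeeze")
        y = squeeze_composition(y)
    X = design.to_numpy(dtype=float)
    p = X.shape[1]
    logy = np.log(y)

    # moment start: intercept from the Dirichlet method-of-moments fit
    ybar = y.mean(axis=0)
    yvar = y.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s_k = ybar * (1 - ybar) / np.maximum(yvar, 1e-12) - 1
    s_k = s_k[np.isfinite(s_k) & (s_k > 0)]
    precision = float(np.exp(np.mean(np.log(s_k)))) if s_k.size else float(K)
    gamma0 = np.zeros((p, K))
    gamma0[0] = np.log(np.maximum(precision * ybar, 1e-8))
    ll_start = -_neg_loglik_grad(gamma0.ravel(), X, logy, K)[0]

    res = minimize(
        _neg_loglik_grad, gamma0.ravel(), args=(X, logy, K),
        jac=True, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    gamma_hat = res.x.reshape(p, K)
    loglik = -float(res.fun)
    converged = bool(res.success) and loglik >= ll_start - 1e-6
    if not converged:
        logger.warning("Dirichlet regression did not converge: %s", res.message)

    info = _observed_information(res.x, X, logy, K)
    perm = _flat_index(p, K)
    se_flat = np.full(p * K, np.nan)
    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
        if (diag <= 0).any():
            raise np.linalg.LinAlgError("non-positive variance")
        se_sub_major = np.sqrt(diag)
        se_flat = se_sub_major[perm]  # to term-major layout
    except np.linalg.LinAlgError:
        converged = False
        logger.warning("observed information not invertible; SEs unavailable")

    from scipy.stats import norm

    terms = list(design.columns)
    rows = []
    for j, term in enumerate(terms):
        for k in range(K):
            beta = gamma_hat[j, k]
            se = se_flat[j * K + k]
            z = beta / se if np.isfinite(se) and se > 0 else np.nan
            pval = 2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append(
                {"term": term, "subgroup": f"subgroup_{k + 1}",
                 "beta": beta, "se": se, "z": z, "p": pval}
            )
    exposure_terms = term_map[spec.exposure]
    return DirichletRegFit(
        table=pd.DataFrame(rows), loglik=loglik, converged=converged,
        n_used=n, n_dropped=n_dropped, exposure=spec.exposure,
        exposure_terms=exposure_terms,
    )


def df_positions(df: pd.DataFrame, index: pd.Index) -> np.ndarray:
    """Positional indices of ``index`` rows within ``df``'s index."""
    pos = {s: i for i, s in enumerate(df.index)}
    return np.array([pos[s] for s in index], dtype=int)


def predicted_composition(fit: DirichletRegFit, design: np.ndarray) -> np.ndarray:
    """Fitted expected compositions a / sum(a) for a design matrix."""
    terms = fit.table["term"].unique()
    K = fit.table["subgroup"].nunique()
    gamma = fit.table["beta"].to_numpy().reshape(len(terms), K)
    a = np.exp(np.asarray(design) @ gamma)
    return a / a.sum(axis=1, keepdims=True)


def run_association_battery(
    theta: np.ndarray,
    covariates: CovariateTable,
    exposures: list[str],
    adjustments: dict[str, list[str]] | list[str] | None = None,
    exclude_if: dict[str, str] | None = None,
    m_tests: int | None = None,
    alpha: float = 0.05,
    standardize: bool = True,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """One Dirichlet regression per exposure, Bonferroni-shared across all.

    ``adjustments`` is either one list shared by every exposure or a
    mapping exposure -> adjustment list.  ``exclude_if`` maps an
    exposure to the name of a boolean covariate column; samples where
    that column is true are excluded from that exposure's model (e.g.
    non-fasted samples for lipid models).  ``m_tests`` defaults to the
    number of exposures.  Returns a long-format table with one row per
    (exposure, term, subgroup) for the exposure terms only.
    """
    missing = [e for e in exposures if e not in covariates.data.columns]
    if missing:
        raise KeyError(f"exposures not in covariate table: {', '.join(missing)}")
    if m_tests is None:
        m_tests = len(exposures)
    threshold = bonferroni_threshold(alpha, m_tests)
    rows = []
    for exposure in exposures:
        adj = adjustments.get(exposure, []) if isinstance(adjustments, dict) else list(adjustments or [])
        cov, ids, y = covariates, sample_ids, theta
        if exclude_if and exposure in exclude_if:
            flag = exclude_if[exposure]
            mask = ~covariates.data[flag].astype(bool).to_numpy()
            cov = CovariateTable(covariates.data.loc[mask], covariates.kinds)
            y = theta[mask]
            if sample_ids is not None:
                ids = [s for s, keep in zip(sample_ids, mask) if keep]
        spec = DirichletRegSpec(
            outcome=y, exposure=exposure, adjustments=tuple(adj), standardize=standardize
        )
        fit = fit_dirichlet_regression(spec, cov, sample_ids=ids)
        sub = fit.exposure_table().copy()
        sub.insert(0, "exposure", exposure)
        sub["p_adj"] = adjust_p(np.nan_to_num(sub["p"].to_numpy(), nan=1.0), m_tests)
        sub["significant"] = sub["p"] < threshold
        sub["n"] = fit.n_used
        sub["converged"] = fit.converged
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)


def wide_matrix(battery: pd.DataFrame, value: str = "beta") -> pd.DataFrame:
    """Pivot a battery result to an (exposure term) x subgroup matrix."""
    b = battery.copy()
    b["row"] = np.where(
        b["term"] == b["exposure"], b["exposure"], b["exposure"] + ":" + b["term"]
    )
    return b.pivot(index="row", columns="subgroup", values=value)
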