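"""Enterotype-style clustering and multinomial logistic comparison arm.

As a conventional counterpart to the fractional-membership subgroup
model, samples are assigned to discrete community types: genus-level
profiles are compared by Jensen-Shannon distance and partitioned with
classic PAM (partitioning around medoids), typically at k = 3, the
clusters classically dominated by Bacteroides, Ruminococcus and
Prevotella.  Associations of cluster membership with the same exposures
then use multinomial logistic regression against a declared reference
cluster, reporting odds ratios per SD with Wald confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import jensenshannon
from scipy.stats import norm
from sklearn.metrics import silhouette_score

from .dirichlet_reg import adjust_p, build_design
from .io_preprocess import CovariateTable, OtuCountTable, TaxonomyMap, collapse_to_genus

logger = logging.getLogger(__name__)


def jsd_distance_matrix(profiles: np.ndarray, pseudocount: float = 1e-9) -> np.ndarray:
    """Pairwise Jensen-Shannon distances between probability profiles.

    A pseudocount is added (profiles contain zeros) and rows are
    renormalized before computing the distance (the square root of the
    Jensen-Shannon divergence, natural log base).
    """
    p = np.asarray(profiles, dtype=float) + pseudocount
    p = p / p.sum(axis=1, keepdims=True)
    n = p.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = jensenshannon(p[i], p[j])
            D[i, j] = D[j, i] = 0.0 if not np.isfinite(d) else d
    return D


def pam(D: np.ndarray, k: int, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Classic PAM (BUILD + SWAP) on a precomputed distance matrix.

    Returns (medoid indices, cluster index per sample).  Deterministic:
    BUILD greedily picks the medoid minimizing total distance, SWAP
    accepts the best-improving (medoid, non-medoid) exchange until no
    swap improves the total cost.
    """
    n = D.shape[0]
    if k > n:
        raise ValueError(f"k ({k}) exceeds the number of samples ({n})")
    medoids = [int(np.argmin(D.sum(axis=0)))]
    while len(medoids) < k:
        dist_to_nearest = D[:, medoids].min(axis=1)
        gains = np.array([
            np.sum(np.maximum(dist_to_nearest - D[:, c], 0)) if c not in medoids else -np.inf
            for c in range(n)
        ])
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)

    def cost(meds):
        return D[:, meds].min(axis=1).sum()

    current = cost(medoids)
    for _ in range(max_iter):
        best_swap, best_cost = None, current
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids[:mi] + [h] + medoids[mi + 1:]
                c = cost(trial)
                if c < best_cost - 1e-12:
                    best_cost, best_swap = c, (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
        medoids = sorted(medoids)
        current = best_cost
    meds = np.array(medoids)
    assign = np.argmin(D[:, meds], axis=1)
    return meds, assign


@dataclass(frozen=True)
class EnterotypeAssignment:
    """Per-sample cluster labels plus diagnostics."""

    sample_ids: list[str]
    labels: list[str]                 # e.g. "C1", mutually exclusive
    dominant_genus: dict[str, str]    # cluster label -> top mean-abundance genus
    sizes: dict[str, int]
    medoid_samples: list[str]
    silhouette: float

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("one label per sample required")
        if sum(self.sizes.values()) != len(self.sample_ids):
            raise ValueError("cluster sizes must sum to n")


def assign_enterotypes(
    table: OtuCountTable,
    tax: TaxonomyMap,
    k: int = 3,
    pseudocount: float = 1e-9,
) -> EnterotypeAssignment:
    """Cluster samples into k community types at genus level.

    Collapses the normalized table to genus profiles, computes pairwise
    Jensen-Shannon distances and runs PAM.  Clusters are named C1..Ck in
    decreasing size order and annotated with their highest
    mean-abundance genus.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if table.n_samples < k:
        raise ValueError(f"fewer samples ({table.n_samples}) than clusters ({k})")
    if not table.normalized:
        raise ValueError("assign_enterotypes requires a normalized table")
    genus = collapse_to_genus(table, tax)
    profiles = genus.to_numpy()
    D = jsd_distance_matrix(profiles, pseudocount)
    meds, assign = pam(D, k)
    order = sorted(
        range(k), key=lambda c: (-(assign == c).sum(), meds[c])
    )
    rank_of = {c: r for r, c in enumerate(order)}
    labels = [f"C{rank_of[c] + 1}" for c in assign]
    dominant, sizes = {}, {}
    for c in range(k):
        name = f"C{rank_of[c] + 1}"
        members = assign == c
        sizes[name] = int(members.sum())
        mean_prof = profiles[members].mean(axis=0)
        dominant[name] = str(genus.columns[int(np.argmax(mean_prof))])
    sil = float(silhouette_score(D, assign, metric="precomputed")) if k < table.n_samples else float("nan")
    return EnterotypeAssignment(
        sample_ids=list(table.sample_ids),
        labels=labels,
        dominant_genus=dominant,
        sizes=dict(sorted(sizes.items())),
        medoid_samples=[table.sample_ids[m] for m in meds],
        silhouette=sil,
    )


def fit_multinomial_logit(
    labels: EnterotypeAssignment | list[str],
    covariates: CovariateTable,
    exposure: str,
    adjustments: list[str] | None = None,
    reference_cluster: str = "C2",
    standardize: bool = True,
    m_tests: int | None = None,
) -> pd.DataFrame:
    """Multinomial logit of cluster membership on an exposure.

    Continuous predictors are divided by their SD (as in the Dirichlet
    regression battery) so odds ratios read per SD.  Returns one row per
    (non-reference cluster, term) with OR, Wald 95% CI and p-value; the
    reference cluster's OR is identically 1 and not reported.  Fits with
    non-finite coefficient drift (separation) are flagged via the
    ``converged`` column.
    """
    lab = labels.labels if isinstance(labels, EnterotypeAssignment) else list(labels)
    lab = pd.Series([str(x) for x in lab], index=covariates.data.index)
    levels = sorted(lab.unique())
    if reference_cluster not in levels:
        raise ValueError(f"reference cluster {reference_cluster!r} not among {levels}")
    design, term_map = build_design(
        covariates, [exposure, *(adjustments or [])], standardize=standardize
    )
    lab = lab.loc[design.index]
    # statsmodels MNLogit takes the first category as the base outcome
    ordered = [reference_cluster] + [l for l in levels if l != reference_cluster]
    endog = pd.Categorical(lab, categories=ordered).codes
    model = sm.MNLogit(endog, design.to_numpy())
    try:
        res = model.fit(method="newton", maxiter=200, disp=False)
        converged = bool(res.mle_retvals.get("converged", True))
    except (np.linalg.LinAlgError, Exception) as exc:  # separation, singular Hessian
        logger.warning("multinomial logit failed: %s", exc)
        raise
    params = np.asarray(res.params)        # p x (n_levels - 1)
    bse = np.asarray(res.bse)
    if not np.all(np.isfinite(params)):
        converged = False
    zcrit = norm.ppf(0.975)
    rows = []
    terms = list(design.columns)
    for ci, cluster in enumerate(ordered[1:]):
        for j, term in enumerate(terms):
            beta, se = params[j, ci], bse[j, ci]
            z = beta / se if se > 0 else np.nan
            p = 2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append(
                {"cluster": cluster, "term": term, "log_or": beta, "se": se,
                 "or": np.exp(beta), "or_ci_low": np.exp(beta - zcrit * se),
                 "or_ci_high": np.exp(beta + zcrit * se), "z": z, "p": p,
                 "converged": converged}
            )
    out = pd.DataFrame(rows)
    out["is_exposure_term"] = out["term"].isin(term_map[exposure])
    if m_tests is not None:
        out["p_adj"] = adjust_p(np.nan_to_num(out["p"].to_numpy(), nan=1.0), m_tests)
    return out
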