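"""Latent Dirichlet allocation of OTU count tables by collapsed Gibbs sampling.

The generative model treats each sample as a "document" whose reads are
"words" (OTUs): per-sample subgroup proportions theta_i ~ Dir(alpha),
per-subgroup OTU distributions phi_k ~ Dir(beta), and each read drawn by
first sampling its subgroup k ~ Multinomial(theta_i) and then the OTU
q ~ Multinomial(phi_k).  Inference integrates theta and phi out and
resamples per-read subgroup labels from the standard collapsed
conditional

    p(z = k | rest)  propto  (n_dk + alpha) * (m_kw + beta) / (m_k + V beta)

Point estimates are posterior means over retained (thinned) sweeps:

    theta[d, k] = (n_dk + alpha) / (N_d + K alpha)
    phi[k, v]   = (m_kv + beta) / (m_k + V beta)

The number of subgroups K is chosen by k-fold cross-validation on
held-out perplexity, with held-out theta re-estimated by folding in
(Gibbs with phi fixed).  Subgroup labels are arbitrary; recovery tests
must match subgroups by maximum-weight bipartite matching.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .io_preprocess import DegenerateSampleError, OtuCountTable

logger = logging.getLogger(__name__)

_SEED_MASK = 0x7FFFFFFF


@dataclass(frozen=True)
class LdaHyperparams:
    """Hyperparameters of the Gibbs sampler.

    alpha defaults to the Griffiths-Steyvers heuristic 50/K when left
    ``None``; beta defaults to 0.1.  ``thin`` keeps every thin-th sweep
    after burn-in for the posterior-mean estimates.
    """

    K: int
    alpha: float | None = None
    beta: float = 0.1
    n_sweeps: int = 2000
    n_burnin: int = 1000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0 <= self.n_burnin < self.n_sweeps:
            raise ValueError("need 0 <= n_burnin < n_sweeps")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def alpha_value(self) -> float:
        return 50.0 / self.K if self.alpha is None else self.alpha


@dataclass(frozen=True)
class LdaModel:
    """A fitted subgroup model.

    theta is samples x K (subgroup probabilities per sample, rows sum to
    1), phi is K x V (OTU probabilities per subgroup, rows sum to 1);
    both are strictly positive thanks to Dirichlet smoothing.
    ``assignments`` holds the final sweep's per-read subgroup labels.
    """

    theta: np.ndarray
    phi: np.ndarray
    hyperparams: LdaHyperparams
    sample_ids: list[str] = field(default_factory=list)
    otu_ids: list[str] = field(default_factory=list)
    assignments: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name, mat in (("theta", self.theta), ("phi", self.phi)):
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError(f"{name} rows must sum to 1")
            if (mat <= 0).any():
                raise ValueError(f"{name} must be strictly positive")

    @property
    def K(self) -> int:
        return self.phi.shape[0]

    def save(self, directory: str | Path) -> None:
        """Serialize theta/phi as TSV plus a JSON hyperparameter sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        k_labels = [f"subgroup_{k + 1}" for k in range(self.K)]
        samples = self.sample_ids or [str(i) for i in range(self.theta.shape[0])]
        otus = self.otu_ids or [str(v) for v in range(self.phi.shape[1])]
        pd.DataFrame(self.theta, index=samples, columns=k_labels).to_csv(
            directory / "theta.tsv", sep="\t", index_label="sample_id"
        )
        pd.DataFrame(self.phi, index=k_labels, columns=otus).to_csv(
            directory / "phi.tsv", sep="\t", index_label="subgroup"
        )
        hp = self.hyperparams
        with open(directory / "model.json", "w") as fh:
            json.dump(
                {
                    "K": hp.K,
                    "alpha": hp.alpha_value,
                    "beta": hp.beta,
                    "n_sweeps": hp.n_sweeps,
                    "n_burnin": hp.n_burnin,
                    "thin": hp.thin,
                    "seed": hp.seed,
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, directory: str | Path) -> "LdaModel":
        directory = Path(directory)
        theta = pd.read_csv(directory / "theta.tsv", sep="\t", index_col=0)
        phi = pd.read_csv(directory / "phi.tsv", sep="\t", index_col=0)
        with open(directory / "model.json") as fh:
            meta = json.load(fh)
        hp = LdaHyperparams(
            K=meta["K"], alpha=meta["alpha"], beta=meta["beta"],
            n_sweeps=meta["n_sweeps"], n_burnin=meta["n_burnin"],
            thin=meta["thin"], seed=meta["seed"],
        )
        return cls(
            theta=theta.to_numpy(), phi=phi.to_numpy(), hyperparams=hp,
            sample_ids=[str(s) for s in theta.index],
            otu_ids=[str(o) for o in phi.columns],
        )


@njit(cache=True)
def _gibbs_kernel(doc, word, n_docs, V, K, alpha, beta,
                  n_sweeps, n_burnin, thin, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    N = doc.shape[0]
    z = np.empty(N, np.int64)
    ndk = np.zeros((n_docs, K), np.int64)
    nkw = np.zeros((K, V), np.int64)
    nk = np.zeros(K, np.int64)
    nd = np.zeros(n_docs, np.int64)
    for t in range(N):
        k = np.random.randint(0, K)
        z[t] = k
        ndk[doc[t], k] += 1
        nkw[k, word[t]] += 1
        nk[k] += 1
        nd[doc[t]] += 1
    theta_sum = np.zeros((n_docs, K))
    phi_sum = np.zeros((K, V))
    n_ret = 0
    p = np.empty(K)
    for sweep in range(n_sweeps):
        for t in range(N):
            d = doc[t]
            w = word[t]
            k = z[t]
            ndk[d, k] -= 1
            nkw[k, w] -= 1
            nk[k] -= 1
            tot = 0.0
            for kk in range(K):
                p[kk] = (ndk[d, kk] + alpha) * (nkw[kk, w] + beta) / (nk[kk] + V * beta)
                tot += p[kk]
            u = np.random.random() * tot
            acc = 0.0
            knew = K - 1
            for kk in range(K):
                acc += p[kk]
                if u < acc:
                    knew = kk
                    break
            z[t] = knew
            ndk[d, knew] += 1
            nkw[knew, w] += 1
            nk[knew] += 1
        if sweep >= n_burnin and (sweep - n_burnin) % thin == 0:
            n_ret += 1
            for d in range(n_docs):
                for kk in range(K):
                    theta_sum[d, kk] += (ndk[d, kk] + alpha) / (nd[d] + K * alpha)
            for kk in range(K):
                denom = nk[kk] + V * beta
                for w2 in range(V):
                    phi_sum[kk, w2] += (nkw[kk, w2] + beta) / denom
    return theta_sum / n_ret, phi_sum / n_ret, z


@njit(cache=True)
def _fold_in_kernel(doc, word, n_docs, phi, K, alpha,
                    n_sweeps, n_burnin, thin, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    N = doc.shape[0]
    z = np.empty(N, np.int64)
    ndk = np.zeros((n_docs, K), np.int64)
    nd = np.zeros(n_docs, np.int64)
    for t in range(N):
        k = np.random.randint(0, K)
        z[t] = k
        ndk[doc[t], k] += 1
        nd[doc[t]] += 1
    theta_sum = np.zeros((n_docs, K))
    n_ret = 0
    p = np.empty(K)
    for sweep in range(n_sweeps):
        for t in range(N):
            d = doc[t]
            w = word[t]
            k = z[t]
            ndk[d, k] -= 1
            tot = 0.0
            for kk in range(K):
                p[kk] = (ndk[d, kk] + alpha) * phi[kk, w]
                tot += p[kk]
            u = np.random.random() * tot
            acc = 0.0
            knew = K - 1
            for kk in range(K):
                acc += p[kk]
                if u < acc:
                    knew = kk
                    break
            z[t] = knew
            ndk[d, knew] += 1
        if sweep >= n_burnin and (sweep - n_burnin) % thin == 0:
            n_ret += 1
            for d in range(n_docs):
                for kk in range(K):
                    theta_sum[d, kk] += (ndk[d, kk] + alpha) / (nd[d] + K * alpha)
    return theta_sum / n_ret


def _tokenize(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand an integer count matrix into per-read (doc, word) arrays."""
    counts = np.asarray(counts)
    docs, words = np.nonzero(counts)
    reps = counts[docs, words].astype(np.int64)
    return np.repeat(docs, reps).astype(np.int64), np.repeat(words, reps).astype(np.int64)


def _check_integer_counts(table: OtuCountTable) -> np.ndarray:
    values = table.values
    if not np.allclose(values, np.round(values)):
        raise ValueError("LDA requires integer counts; run rescale_to_counts first")
    counts = np.round(values).astype(np.int64)
    totals = counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = ", ".join(table.sample_ids[i] for i in zero[:5])
        raise DegenerateSampleError(f"sample(s) with zero reads: {names}")
    return counts


def fit_lda_gibbs(counts: OtuCountTable, hp: LdaHyperparams) -> LdaModel:
    """Fit the subgroup model by collapsed Gibbs sampling.

    Reproducible given ``hp.seed``.  K larger than the number of
    distinct OTUs is allowed but logged as a warning.
    """
    mat = _check_integer_counts(counts)
    if hp.K > counts.n_otus:
        warnings.warn(
            f"K={hp.K} exceeds the number of OTUs ({counts.n_otus})", stacklevel=2
        )
    doc, word = _tokenize(mat)
    theta, phi, z = _gibbs_kernel(
        doc, word, counts.n_samples, counts.n_otus, hp.K,
        float(hp.alpha_value), float(hp.beta),
        hp.n_sweeps, hp.n_burnin, hp.thin, hp.seed & _SEED_MASK,
    )
    return LdaModel(
        theta=theta, phi=phi, hyperparams=hp,
        sample_ids=list(counts.sample_ids), otu_ids=list(counts.otu_ids),
        assignments=z,
    )


def fold_in_theta(
    phi: np.ndarray,
    counts: OtuCountTable,
    alpha: float,
    n_sweeps: int = 200,
    n_burnin: int = 100,
    thin: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Estimate theta for held-out samples with phi held fixed."""
    mat = _check_integer_counts(counts)
    phi = np.ascontiguousarray(phi, dtype=float)
    if phi.shape[1] != counts.n_otus:
        raise ValueError(
            f"phi has {phi.shape[1]} OTUs but counts have {counts.n_otus}"
        )
    doc, word = _tokenize(mat)
    return _fold_in_kernel(
        doc, word, counts.n_samples, phi, phi.shape[0], float(alpha),
        n_sweeps, n_burnin, thin, seed & _SEED_MASK,
    )


def log_likelihood(
    model: LdaModel, counts: OtuCountTable, theta: np.ndarray | None = None
) -> float:
    """Multinomial-mixture log-likelihood sum_i sum_v c_iv log(theta_i . phi_.v).

    For held-out samples pass a folded-in ``theta`` (see
    :func:`fold_in_theta`); by default the model's own theta is used and
    must match the table's sample axis.
    """
    if counts.n_otus != model.phi.shape[1]:
        raise ValueError(
            f"OTU-axis mismatch: counts have {counts.n_otus}, model has {model.phi.shape[1]}"
        )
    if theta is None:
        theta = model.theta
    if theta.shape[0] != counts.n_samples:
        raise ValueError("theta rows must match the table's samples")
    mix = theta @ model.phi
    mask = counts.values > 0
    return float(np.sum(counts.values[mask] * np.log(mix[mask])))


def perplexity(
    model: LdaModel, counts: OtuCountTable, theta: np.ndarray | None = None
) -> float:
    """exp(-log_likelihood / total reads); lower is better, always >= 1."""
    total = counts.values.sum()
    if total <= 0:
        raise ValueError("perplexity undefined for zero total reads")
    return float(np.exp(-log_likelihood(model, counts, theta) / total))


def _subset(table: OtuCountTable, idx: np.ndarray) -> OtuCountTable:
    return OtuCountTable(
        sample_ids=[table.sample_ids[i] for i in idx],
        otu_ids=list(table.otu_ids),
        values=table.values[idx],
        normalized=False,
    )


def select_k_cv(
    counts: OtuCountTable,
    k_grid: list[int],
    folds: int = 5,
    hp_template: LdaHyperparams | None = None,
    fold_in_sweeps: int = 200,
    fold_in_burnin: int = 100,
    select: bool = False,
) -> pd.DataFrame:
    """Cross-validated held-out perplexity over a grid of subgroup numbers.

    Samples are partitioned into ``folds`` folds (seeded from the
    template's seed); for each K and fold the model is fitted on the
    training samples, theta for the held-out samples is folded in, and
    held-out perplexity/log-likelihood recorded.  Returns the per-K mean
    curve.  No K is selected automatically (the curve typically improves
    without a clear optimum and is meant to be inspected for jumps); the
    ``select`` flag adds a ``selected`` column marking the K with the
    largest relative perplexity improvement over its predecessor.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > counts.n_samples:
        raise ValueError(
            f"folds ({folds}) exceed the sample count ({counts.n_samples})"
        )
    if any(k < 1 for k in k_grid):
        raise ValueError("every K in the grid must be >= 1")
    hp_template = hp_template or LdaHyperparams(K=1)
    rng = np.random.default_rng(hp_template.seed)
    perm = rng.permutation(counts.n_samples)
    fold_of = np.empty(counts.n_samples, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, folds)):
        fold_of[chunk] = f
    rows = []
    for K in k_grid:
        perps, lls = [], []
        for f in range(folds):
            train = np.flatnonzero(fold_of != f)
            test = np.flatnonzero(fold_of == f)
            hp = replace(hp_template, K=K, alpha=hp_template.alpha)
            model = fit_lda_gibbs(_subset(counts, train), hp)
            held = _subset(counts, test)
            theta = fold_in_theta(
                model.phi, held, hp.alpha_value,
                n_sweeps=fold_in_sweeps, n_burnin=fold_in_burnin,
                seed=(hp.seed + 7919 * f) & _SEED_MASK,
            )
            lls.append(log_likelihood(model, held, theta))
            perps.append(perplexity(model, held, theta))
        rows.append(
            {"K": K, "mean_heldout_perplexity": float(np.mean(perps)),
             "mean_heldout_loglik": float(np.mean(lls))}
        )
        logger.info("CV K=%d: perplexity %.2f", K, rows[-1]["mean_heldout_perplexity"])
    curve = pd.DataFrame(rows)
    if select and len(curve) > 1:
        perp = curve["mean_heldout_perplexity"].to_numpy()
        improvement = np.zeros(len(perp))
        improvement[1:] = (perp[:-1] - perp[1:]) / perp[:-1]
        curve["selected"] = False
        curve.loc[int(np.argmax(improvement)), "selected"] = True
    return curve


def refit_best_of_m(
    counts: OtuCountTable, hp: LdaHyperparams, m: int = 5
) -> tuple[LdaModel, list[float]]:
    """Fit ``m`` models from distinct derived seeds; keep the best.

    The winner is the fit with the highest training log-likelihood (the
    only comparable criterion without a validation split).  Returns the
    winning model and all ``m`` scores.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    seeds = np.random.SeedSequence(hp.seed).generate_state(m) & _SEED_MASK
    best_model, best_score, scores = None, -np.inf, []
    for s in seeds:
        model = fit_lda_gibbs(counts, replace(hp, seed=int(s)))
        score = log_likelihood(model, counts)
        scores.append(score)
        if score > best_score:
            best_model, best_score = model, score
    logger.info("best-of-%d training log-likelihoods: %s", m, scores)
    return best_model, scores
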