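"""Descriptive characterization of fitted subgroups.

Covers the standard post-fit summaries: top genera per subgroup (after
collapsing the subgroup-OTU matrix phi to genus level), distribution
summaries of the subgroup probabilities theta (medians, IQRs, per-sample
maxima, counts of subgroups above probability thresholds), Ward
hierarchical clustering of the subgroups on the log-transformed full
K x V matrix, and summed subgroup probability over named OTU sets (e.g.
OTUs that lose circadian rhythmicity in metabolic disease).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree

from .io_preprocess import UNKNOWN_GENUS, MappingError, TaxonomyMap, collapse_to_genus


def top_genera(
    phi: np.ndarray,
    otu_ids: list[str],
    tax: TaxonomyMap,
    n_top: int = 5,
) -> list[dict]:
    """Ranked top genera per subgroup with their summed probabilities.

    phi is collapsed to genus level first.  Ties are broken
    lexicographically by genus label.  The unknown-genus sentinel is
    excluded from the ranked list but its percentage is always reported.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    collapsed = collapse_to_genus(np.asarray(phi, dtype=float), tax, otu_ids=otu_ids)
    out = []
    named = [g for g in collapsed.columns if g != UNKNOWN_GENUS]
    for k in range(collapsed.shape[0]):
        row = collapsed.iloc[k]
        ranked = sorted(
            ((g, float(row[g])) for g in named), key=lambda t: (-t[1], t[0])
        )[:n_top]
        na_pct = float(row.get(UNKNOWN_GENUS, 0.0)) * 100.0
        out.append(
            {"subgroup": f"subgroup_{k + 1}",
             "top": ranked,
             "unknown_genus_percent": na_pct}
        )
    return out


@dataclass(frozen=True)
class SubgroupSummary:
    """Distribution summaries of theta across samples."""

    median: np.ndarray            # per-subgroup median probability
    iqr: np.ndarray               # per-subgroup (q75 - q25)
    max_per_sample: np.ndarray    # per-sample maximum probability
    thresholds: tuple[float, ...]
    counts_above: np.ndarray      # samples x thresholds, strict ">"
    mean_counts: np.ndarray       # mean count per threshold
    sd_counts: np.ndarray         # SD of count per threshold


def summarize_subgroups(
    theta: np.ndarray, thresholds: tuple[float, ...] = (0.01, 0.10, 0.25)
) -> SubgroupSummary:
    """Medians/IQRs per subgroup, per-sample maxima, above-threshold counts.

    Counts use a strict "probability over t" convention.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size == 0:
        raise ValueError("empty theta")
    if not np.allclose(theta.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("theta rows must sum to 1")
    q25, q50, q75 = np.percentile(theta, [25, 50, 75], axis=0)
    thresholds = tuple(thresholds)
    counts = np.stack([(theta > t).sum(axis=1) for t in thresholds], axis=1)
    return SubgroupSummary(
        median=q50,
        iqr=q75 - q25,
        max_per_sample=theta.max(axis=1),
        thresholds=thresholds,
        counts_above=counts,
        mean_counts=counts.mean(axis=0),
        sd_counts=counts.std(axis=0, ddof=1) if theta.shape[0] > 1 else np.zeros(len(thresholds)),
    )


def _newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _newick(node.left, labels)
    right = _newick(node.right, labels)
    dl = node.dist - node.left.dist
    dr = node.dist - node.right.dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_subgroups(
    phi: np.ndarray,
    n_clusters: int = 8,
    pseudocount: float = 1e-6,
    labels: list[str] | None = None,
) -> dict:
    """Ward hierarchical clustering of subgroups on log(phi + pseudocount).

    The full K x V matrix is used (not the genus collapse), so
    species-level differences between subgroups sharing dominant genera
    can separate them.  Returns the scipy linkage matrix, a flat
    ``n_clusters`` cut (labels 1..n_clusters), and a newick export of
    the dendrogram.
    """
    phi = np.asarray(phi, dtype=float)
    K = phi.shape[0]
    if n_clusters > K:
        raise ValueError(f"n_clusters ({n_clusters}) exceeds the number of subgroups ({K})")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logphi = np.log(phi + pseudocount)
    Z = linkage(logphi, method="ward")
    flat = fcluster(Z, t=n_clusters, criterion="maxclust")
    labels = labels or [f"subgroup_{k + 1}" for k in range(K)]
    newick = _newick(to_tree(Z), labels) + ";"
    return {"linkage": Z, "clusters": flat, "newick": newick, "labels": labels}


def arrhythmic_fraction(
    phi: np.ndarray,
    otu_ids: list[str],
    otu_sets: dict[str, list[str]],
    on_unknown: str = "error",
) -> pd.DataFrame:
    """Summed subgroup probability over named OTU sets, as percentages.

    For each subgroup k and set S: ``100 * sum_{v in S} phi[k, v]``.
    Unknown OTU ids raise a :class:`MappingError` listing them unless
    ``on_unknown="warn"``, in which case they are reported and skipped.
    """
    if on_unknown not in ("error", "warn"):
        raise ValueError("on_unknown must be 'error' or 'warn'")
    phi = np.asarray(phi, dtype=float)
    col = {o: j for j, o in enumerate(otu_ids)}
    out = {}
    for name, members in otu_sets.items():
        unknown = [o for o in members if o not in col]
        if unknown:
            shown = ", ".join(unknown[:10])
            if on_unknown == "error":
                raise MappingError(f"set {name!r} lists unknown OTU ids: {shown}")
            import warnings

            warnings.warn(f"set {name!r}: skipping unknown OTU ids: {shown}", stacklevel=2)
        idx = [col[o] for o in members if o in col]
        out[name] = 100.0 * phi[:, idx].sum(axis=1) if idx else np.zeros(phi.shape[0])
    return pd.DataFrame(out, index=[f"subgroup_{k + 1}" for k in range(phi.shape[0])])
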