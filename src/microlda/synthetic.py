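"""Synthetic fixtures with known ground truth.

The real cohort data this kind of analysis targets are access-restricted,
so every recovery test runs on synthetic data generated from the same
models the pipeline assumes: an LDA corpus (per-sample subgroup
proportions theta ~ Dir(alpha); per-subgroup OTU distributions phi with
controllable vocabulary overlap; reads drawn subgroup-then-OTU),
optionally with subgroup proportions linked to covariates through a
log-linear Dirichlet model, plus taxonomy maps with an unknown-genus
fraction, disjoint "arrhythmic" OTU sets, and 5-level disease-like
categorical covariates.

Desk-scale defaults (300 samples x 120 OTUs, K=5, 1000 reads/sample)
keep the suite fast; ``FULL_SCALE`` mirrors a cohort-scale table
(2000 x 1713, K=20) and is provided for completeness, not used in tests.

Every generator records its planted truth in a :class:`SyntheticTruth`;
recovery tests must read the truth from this record only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .io_preprocess import (
    UNKNOWN_GENUS,
    CovariateTable,
    OtuCountTable,
    TaxonomyMap,
    write_otu_table,
    write_taxonomy,
)

#: Cohort-scale preset mirroring a large 16S study.
FULL_SCALE = {"n_samples": 2000, "n_otus": 1713, "K": 20, "reads_per_sample": 1000}

#: Desk-scale defaults used throughout the test suite.
DESK_SCALE = {"n_samples": 300, "n_otus": 120, "K": 5, "reads_per_sample": 1000}

#: Default 5-level categorical prevalences for disease-like covariates,
#: patterned on typical population-cohort glucose-tolerance and
#: blood-pressure distributions.
DIABETES_PREVALENCES = {
    "normal glucose tolerance": 0.48,
    "prediabetes": 0.34,
    "undiagnosed diabetes": 0.04,
    "type 2 diabetes": 0.10,
    "unknown": 0.04,
}
HYPERTENSION_PREVALENCES = {
    "normal blood pressure": 0.60,
    "controlled hypertension": 0.27,
    "uncontrolled hypertension": 0.07,
    "untreated hypertension": 0.04,
    "undiagnosed hypertension": 0.02,
}


@dataclass
class SyntheticTruth:
    """Planted parameters recorded alongside every fixture."""

    phi: np.ndarray | None = None              # K x V planted subgroup-OTU matrix
    theta: np.ndarray | None = None            # n x K planted per-sample proportions
    gamma: np.ndarray | None = None            # covariate -> subgroup coefficients
    gamma_terms: list[str] = field(default_factory=list)
    archetypes: np.ndarray | None = None       # enterotype genus archetypes
    cluster_labels: np.ndarray | None = None
    seed: int = 0
    params: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def conv(x):
            return None if x is None else np.asarray(x).tolist()

        with open(path, "w") as fh:
            json.dump(
                {
                    "phi": conv(self.phi),
                    "theta": conv(self.theta),
                    "gamma": conv(self.gamma),
                    "gamma_terms": self.gamma_terms,
                    "archetypes": conv(self.archetypes),
                    "cluster_labels": conv(self.cluster_labels),
                    "seed": self.seed,
                    "params": self.params,
                },
                fh,
            )


def _planted_phi(rng: np.random.Generator, K: int, V: int, separation: float) -> np.ndarray:
    """Topic-OTU matrix with controllable vocabulary overlap.

    The vocabulary is split into K blocks; topic k places mass
    ``separation`` inside its own block (Dirichlet(1)-distributed) and
    spreads the remainder uniformly over the other blocks.  At
    separation = 1 the vocabularies are disjoint.
    """
    if not 0 <= separation <= 1:
        raise ValueError("separation must lie in [0, 1]")
    blocks = np.array_split(np.arange(V), K)
    phi = np.zeros((K, V))
    for k, block in enumerate(blocks):
        inside = rng.dirichlet(np.ones(len(block)))
        phi[k, block] = separation * inside
        others = np.setdiff1d(np.arange(V), block)
        if separation < 1 and others.size:
            phi[k, others] = (1 - separation) / others.size
        elif separation == 1:
            pass
    # separation < 1 rows already sum to 1; separation == 1 rows sum to 1 * 1
    if separation == 1:
        phi /= phi.sum(axis=1, keepdims=True)
    return phi


def _draw_counts(
    rng: np.random.Generator,
    theta: np.ndarray,
    phi: np.ndarray,
    reads_per_sample: int,
) -> np.ndarray:
    """Sample reads subgroup-then-OTU; exact per-sample read totals."""
    n, K = theta.shape
    V = phi.shape[1]
    counts = np.zeros((n, V), dtype=int)
    for i in range(n):
        z_counts = rng.multinomial(reads_per_sample, theta[i])
        for k in range(K):
            if z_counts[k]:
                counts[i] += rng.multinomial(z_counts[k], phi[k])
    return counts


def generate_lda_corpus(
    n_samples: int = DESK_SCALE["n_samples"],
    n_otus: int = DESK_SCALE["n_otus"],
    K: int = DESK_SCALE["K"],
    alpha: float = 0.5,
    reads_per_sample: int = DESK_SCALE["reads_per_sample"],
    seed: int = 0,
    separation: float = 1.0,
    theta: np.ndarray | None = None,
) -> tuple[OtuCountTable, SyntheticTruth]:
    """Generate an OTU count table from the LDA generative process.

    theta_i ~ Dir(alpha) unless per-sample proportions are supplied
    (e.g. from :func:`generate_covariate_linked_thetas`); each read
    draws a subgroup from theta_i and then an OTU from that subgroup's
    planted distribution.
    """
    if min(n_samples, n_otus, K, reads_per_sample) < 1:
        raise ValueError("all sizes must be >= 1")
    rng = np.random.default_rng(seed)
    phi = _planted_phi(rng, K, n_otus, separation)
    if theta is None:
        theta = rng.dirichlet(np.full(K, alpha), size=n_samples)
    else:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (n_samples, K):
            raise ValueError("supplied theta must be n_samples x K")
    counts = _draw_counts(rng, theta, phi, reads_per_sample)
    table = OtuCountTable(
        sample_ids=[f"S{i + 1:04d}" for i in range(n_samples)],
        otu_ids=[f"OTU_{v + 1:04d}" for v in range(n_otus)],
        values=counts.astype(float),
        normalized=False,
    )
    truth = SyntheticTruth(
        phi=phi, theta=theta, seed=seed,
        params={
            "n_samples": n_samples, "n_otus": n_otus, "K": K, "alpha": alpha,
            "reads_per_sample": reads_per_sample, "separation": separation,
        },
    )
    return table, truth


def generate_covariate_linked_thetas(
    n_samples: int = 500,
    K: int = 5,
    covariate_specs: list[dict] | None = None,
    gamma: np.ndarray | None = None,
    precision: float = 10.0,
    seed: int = 0,
    correlation: np.ndarray | None = None,
) -> tuple[CovariateTable, np.ndarray, SyntheticTruth]:
    """Draw covariates and Dirichlet compositions linked through a log link.

    Concentrations follow ``a_ik = precision * exp(x_i' gamma_k)`` and
    theta_i ~ Dir(a_i).  ``covariate_specs`` is a list of dicts:
    continuous ``{"name", "kind": "continuous", "mean", "sd", "units"}``
    or categorical ``{"name", "kind": "categorical", "levels": {level:
    freq}, "reference"}``.  Continuous covariates may be drawn jointly
    with a declared ``correlation`` matrix (moderate positive
    correlation among co-consumed diet items is the realistic regime).
    ``gamma`` has one row per continuous covariate / categorical
    non-reference level, K columns.  The returned thetas can be fed to
    :func:`generate_lda_corpus` for an end-to-end corpus.
    """
    if precision <= 0:
        raise ValueError("precision must be positive")
    rng = np.random.default_rng(seed)
    if covariate_specs is None:
        covariate_specs = [
            {"name": "exposure", "kind": "continuous", "mean": 0.0, "sd": 1.0}
        ]
    cont = [s for s in covariate_specs if s["kind"] == "continuous"]
    cat = [s for s in covariate_specs if s["kind"] == "categorical"]
    data: dict[str, Any] = {}
    terms: list[str] = []
    design_cols: list[np.ndarray] = []
    if cont:
        means = np.array([s.get("mean", 0.0) for s in cont])
        sds = np.array([s.get("sd", 1.0) for s in cont])
        if correlation is None:
            X = rng.standard_normal((n_samples, len(cont)))
        else:
            correlation = np.asarray(correlation, dtype=float)
            L = np.linalg.cholesky(correlation)
            X = rng.standard_normal((n_samples, len(cont))) @ L.T
        X = means + sds * X
        for j, s in enumerate(cont):
            data[s["name"]] = X[:, j]
            terms.append(s["name"])
            design_cols.append(X[:, j])
    for s in cat:
        levels = list(s["levels"])
        probs = np.array([s["levels"][l] for l in levels], dtype=float)
        probs /= probs.sum()
        draws = rng.choice(len(levels), size=n_samples, p=probs)
        labels = np.array(levels, dtype=object)[draws]
        data[s["name"]] = labels
        ref = str(s.get("reference", levels[0]))
        for lev in sorted(levels, key=str):  # match the model design builder's order
            if str(lev) == ref:
                continue
            terms.append(f"{s['name']}[{lev}]")
            design_cols.append((labels == lev).astype(float))
    design = np.column_stack(design_cols) if design_cols else np.zeros((n_samples, 0))
    if gamma is None:
        gamma = np.zeros((design.shape[1], K))
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape != (design.shape[1], K):
        raise ValueError(
            f"gamma must be {design.shape[1]} terms x {K} subgroups, got {gamma.shape}"
        )
    a = precision * np.exp(design @ gamma)
    theta = np.empty((n_samples, K))
    for i in range(n_samples):
        theta[i] = rng.dirichlet(a[i])
    kinds = {}
    for s in cont:
        kinds[s["name"]] = {"kind": "continuous", "units": s.get("units", "")}
    for s in cat:
        kinds[s["name"]] = {
            "kind": "categorical",
            "reference": str(s.get("reference", list(s["levels"])[0])),
        }
    covariates = CovariateTable(
        pd.DataFrame(data, index=[f"S{i + 1:04d}" for i in range(n_samples)]), kinds
    )
    truth = SyntheticTruth(
        theta=theta, gamma=gamma, gamma_terms=terms, seed=seed,
        params={"n_samples": n_samples, "K": K, "precision": precision},
    )
    return covariates, theta, truth


def generate_ancillary(
    n_otus: int = DESK_SCALE["n_otus"],
    genus_pool_size: int = 20,
    unknown_genus_fraction: float = 0.2,
    arrhythmic_set_sizes: dict[str, int] | None = None,
    seed: int = 0,
    disease_prevalences: dict[str, dict[str, float]] | None = None,
    n_samples: int = 0,
) -> dict:
    """Taxonomy map, disjoint OTU sets, and disease-like labels.

    Returns a dict with keys ``taxonomy`` (:class:`TaxonomyMap`),
    ``otu_sets`` (name -> list of OTU ids, mutually disjoint),
    ``otu_ids`` and, when ``n_samples`` > 0, ``disease_labels`` (a
    DataFrame of 5-level categorical columns drawn at the stated
    prevalences).
    """
    if not 0 <= unknown_genus_fraction <= 1:
        raise ValueError("unknown_genus_fraction must lie in [0, 1]")
    arrhythmic_set_sizes = arrhythmic_set_sizes or {"all_arrhythmic": 20, "obesity": 12, "t2dm": 4}
    if sum(arrhythmic_set_sizes.values()) > n_otus:
        raise ValueError("requested OTU-set sizes exceed the number of OTUs")
    rng = np.random.default_rng(seed)
    otu_ids = [f"OTU_{v + 1:04d}" for v in range(n_otus)]
    genera = [f"Genus_{g + 1:02d}" for g in range(genus_pool_size)]
    assignment = {}
    for o in otu_ids:
        if rng.random() < unknown_genus_fraction:
            assignment[o] = UNKNOWN_GENUS
        else:
            assignment[o] = genera[rng.integers(genus_pool_size)]
    tax = TaxonomyMap(assignment)
    pool = rng.permutation(n_otus)
    otu_sets, start = {}, 0
    for name, size in arrhythmic_set_sizes.items():
        otu_sets[name] = [otu_ids[i] for i in pool[start:start + size]]
        start += size
    out: dict[str, Any] = {"taxonomy": tax, "otu_sets": otu_sets, "otu_ids": otu_ids}
    if n_samples:
        disease_prevalences = disease_prevalences or {
            "diabetes_status": DIABETES_PREVALENCES,
            "hypertension_status": HYPERTENSION_PREVALENCES,
        }
        cols = {}
        for var, prev in disease_prevalences.items():
            levels = list(prev)
            probs = np.array([prev[l] for l in levels], dtype=float)
            probs /= probs.sum()
            draws = rng.choice(len(levels), size=n_samples, p=probs)
            cols[var] = np.array(levels, dtype=object)[draws]
        out["disease_labels"] = pd.DataFrame(
            cols, index=[f"S{i + 1:04d}" for i in range(n_samples)]
        )
    return out


def write_fixture(
    directory: str | Path,
    table: OtuCountTable,
    truth: SyntheticTruth,
    taxonomy: TaxonomyMap | None = None,
    covariates: CovariateTable | None = None,
    otu_sets: dict[str, list[str]] | None = None,
) -> None:
    """Emit a full fixture directory (TSVs, sidecar JSON, truth JSON)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_otu_table(table, directory / "otu_table.tsv")
    truth.to_json(directory / "truth.json")
    if taxonomy is not None:
        write_taxonomy(taxonomy, directory / "taxonomy.tsv")
    if covariates is not None:
        covariates.data.to_csv(directory / "covariates.tsv", sep="\t", index_label="sample_id")
        with open(directory / "covariates.json", "w") as fh:
            json.dump(covariates.kinds, fh, indent=2)
    for name, members in (otu_sets or {}).items():
        with open(directory / f"otu_set_{name}.txt", "w") as fh:
            fh.write("\n".join(members) + "\n")
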