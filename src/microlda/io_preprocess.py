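"""Reading, normalization and filtering of OTU count tables.

The analysis consumes a finished OTU table (samples x OTUs), a taxonomy
map (OTU -> genus, with an ``NA`` sentinel for OTUs unresolved at genus
level) and a per-sample covariate table.  Internally samples are always
in rows; orientation is handled at read time.

The preprocessing pipeline mirrors common 16S practice: total-count
normalization per sample, a joint abundance/prevalence filter (an OTU is
kept if its within-sample relative abundance exceeds the abundance
threshold in at least a prevalence-threshold fraction of samples), and
an integer rescale (multiply by a factor, default 1000, and round) so
the matrix can be treated as count data by the topic model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: Sentinel genus label for OTUs that could not be classified to genus level.
UNKNOWN_GENUS = "NA"

_ROW_SUM_TOL = 1e-8


class FormatError(ValueError):
    """Malformed input table (duplicates, empty body, non-numeric)."""


class DegenerateSampleError(ValueError):
    """A sample with zero total count where a positive total is required."""


class MappingError(KeyError):
    """OTU identifiers missing from a taxonomy map or OTU axis."""


@dataclass(frozen=True)
class OtuCountTable:
    """A samples x OTUs matrix of non-negative counts or relative abundances.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers (row labels).
    otu_ids : list of str
        Unique OTU identifiers (column labels).
    values : ndarray of shape (n_samples, n_otus)
        Non-negative matrix.
    normalized : bool
        True when every row sums to 1 (relative abundances).
    """

    sample_ids: list[str]
    otu_ids: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise FormatError("values must be a 2-D samples x OTUs matrix")
        if values.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise FormatError(
                f"shape {values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample identifiers")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise FormatError("duplicate OTU identifiers")
        if len(self.sample_ids) == 0:
            raise FormatError("empty table")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite entries in OTU table")
        if (values < 0).any():
            raise ValueError("negative entries in OTU table")
        if self.normalized:
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=_ROW_SUM_TOL):
                raise ValueError("normalized flag set but rows do not sum to 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.otu_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, normalized: bool | None = None) -> "OtuCountTable":
        values = df.to_numpy(dtype=float)
        if normalized is None:
            normalized = bool(
                values.size and np.allclose(values.sum(axis=1), 1.0, atol=_ROW_SUM_TOL)
            )
        return cls(
            sample_ids=[str(s) for s in df.index],
            otu_ids=[str(o) for o in df.columns],
            values=values,
            normalized=normalized,
        )


def read_otu_table(path: str | Path, orientation: str = "samples-in-rows") -> OtuCountTable:
    """Read a TSV OTU table and return it in samples x OTUs orientation.

    The file must have a header row and a first column of identifiers.
    ``orientation`` declares what the file's rows mean:
    ``"samples-in-rows"`` (rows = samples) or ``"samples-in-columns"``
    (rows = OTUs, as in classic OTU tables exported with one column per
    sample).  The ``normalized`` flag is set by checking row sums.
    """
    if orientation not in ("samples-in-rows", "samples-in-columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        raise FormatError(f"duplicate identifiers in header of {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"empty table in {path}")
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError(f"duplicate identifiers in {path}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric body in {path}: {exc}") from exc
    if orientation == "samples-in-columns":
        df = df.T
    return OtuCountTable.from_dataframe(df)


def write_otu_table(table: OtuCountTable, path: str | Path) -> None:
    """Write a table as TSV, samples in rows."""
    table.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


@dataclass(frozen=True)
class TaxonomyMap:
    """OTU -> genus label map; unresolved OTUs carry the ``NA`` sentinel."""

    genus_of: Mapping[str, str]

    def __getitem__(self, otu_id: str) -> str:
        return self.genus_of[otu_id]

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.genus_of

    def genera(self) -> list[str]:
        """Sorted named genera present in the map (sentinel excluded)."""
        return sorted({g for g in self.genus_of.values() if g != UNKNOWN_GENUS})


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a two-column (otu_id, genus) TSV; literal ``NA`` is the sentinel."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["otu_id", "genus"],
        dtype=str, keep_default_na=False,
    )
    if df["otu_id"].duplicated().any():
        raise FormatError(f"duplicate OTU ids in taxonomy {path}")
    return TaxonomyMap(dict(zip(df["otu_id"], df["genus"])))


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for otu, genus in tax.genus_of.items():
            fh.write(f"{otu}\t{genus}\n")


@dataclass(frozen=True)
class CovariateTable:
    """Per-sample predictors with declared kinds.

    ``kinds`` maps each variable to ``{"kind": "continuous"|"categorical",
    "units": ..., "reference": ...}``; the reference level of a
    categorical variable must exist among its observed levels.
    """

    data: pd.DataFrame
    kinds: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, meta in self.kinds.items():
            if name not in self.data.columns:
                raise KeyError(f"declared variable {name!r} not in table")
            if meta.get("kind") == "categorical":
                ref = meta.get("reference")
                levels = set(self.data[name].dropna().astype(str))
                if ref is not None and str(ref) not in levels:
                    raise ValueError(
                        f"reference level {ref!r} of {name!r} not among observed levels"
                    )
            elif meta.get("kind") == "continuous":
                col = pd.to_numeric(self.data[name], errors="coerce")
                observed = self.data[name].notna()
                if not np.isfinite(col[observed]).all():
                    raise ValueError(f"non-finite values in continuous variable {name!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def kind_of(self, name: str) -> str:
        meta = self.kinds.get(name, {})
        if "kind" in meta:
            return meta["kind"]
        # undeclared numeric columns default to continuous
        return "continuous" if pd.api.types.is_numeric_dtype(self.data[name]) else "categorical"

    def reference_of(self, name: str) -> str | None:
        return self.kinds.get(name, {}).get("reference")


def read_covariates(path: str | Path, sidecar: str | Path | None = None) -> CovariateTable:
    """Read a covariate TSV plus an optional JSON sidecar of declared kinds."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    kinds: dict[str, dict] = {}
    if sidecar is not None:
        with open(sidecar) as fh:
            kinds = json.load(fh)
    return CovariateTable(df, kinds)


def normalize_total_count(table: OtuCountTable) -> OtuCountTable:
    """Divide each sample row by its total so rows sum to 1.

    Raises
    ------
    DegenerateSampleError
        If any sample has zero total count.
    """
    totals = table.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = ", ".join(table.sample_ids[i] for i in zero[:5])
        raise DegenerateSampleError(f"sample(s) with zero total count: {names}")
    return replace(table, values=table.values / totals[:, None], normalized=True)


def filter_otus(
    table: OtuCountTable,
    abundance_threshold: float = 0.001,
    prevalence_threshold: float = 0.01,
) -> OtuCountTable:
    """Keep OTUs exceeding an abundance threshold in enough samples.

    An OTU survives when its relative abundance strictly exceeds
    ``abundance_threshold`` in at least
    ``ceil(prevalence_threshold * n_samples)`` samples.  Column order is
    preserved and rows are *not* renormalized; call
    :func:`normalize_total_count` again before :func:`rescale_to_counts`.
    """
    for name, t in (("abundance", abundance_threshold), ("prevalence", prevalence_threshold)):
        if not 0 <= t < 1:
            raise ValueError(f"{name}_threshold must lie in [0, 1), got {t}")
    if not table.normalized:
        raise ValueError("filter_otus requires a normalized table")
    n_required = max(math.ceil(prevalence_threshold * table.n_samples), 1)
    qualifying = (table.values > abundance_threshold).sum(axis=0)
    keep = qualifying >= n_required
    return OtuCountTable(
        sample_ids=table.sample_ids,
        otu_ids=[o for o, k in zip(table.otu_ids, keep) if k],
        values=table.values[:, keep],
        normalized=False,
    )


def rescale_to_counts(table: OtuCountTable, factor: int = 1000) -> OtuCountTable:
    """Multiply by ``factor`` and round half-away-from-zero to integers."""
    if factor < 1:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    if not np.all(np.isfinite(table.values)):
        raise ValueError("non-finite entries")
    scaled = table.values * factor
    # np.round is banker's rounding; entries are non-negative so
    # half-away-from-zero is floor(x + 0.5); the 1e-9 guard keeps decimal
    # halves (e.g. 0.0005 * 1000) from falling just below .5 in binary
    rounded = np.floor(scaled + 0.5 + 1e-9)
    return replace(table, values=rounded, normalized=False)


def collapse_to_genus(
    matrix: OtuCountTable | np.ndarray,
    tax: TaxonomyMap,
    otu_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Sum columns sharing a genus label; unknown OTUs fall into ``NA``.

    Accepts either an :class:`OtuCountTable` or a bare rows x OTUs array
    (e.g. the topic-OTU matrix phi) plus its ``otu_ids``.  Row totals
    are preserved exactly.  Columns are ordered with named genera first
    (sorted) and the ``NA`` sentinel last, when present.
    """
    if isinstance(matrix, OtuCountTable):
        values = matrix.values
        ids = matrix.otu_ids
        index = matrix.sample_ids
    else:
        values = np.asarray(matrix, dtype=float)
        if otu_ids is None:
            raise ValueError("otu_ids required when passing a bare matrix")
        ids = list(otu_ids)
        index = list(range(values.shape[0]))
    missing = [o for o in ids if o not in tax]
    if missing:
        shown = ", ".join(missing[:10])
        raise MappingError(f"OTUs missing from taxonomy map: {shown}")
    genera = [tax[o] for o in ids]
    named = sorted({g for g in genera if g != UNKNOWN_GENUS})
    order = named + ([UNKNOWN_GENUS] if UNKNOWN_GENUS in genera else [])
    col_of = {g: i for i, g in enumerate(order)}
    out = np.zeros((values.shape[0], len(order)))
    for j, g in enumerate(genera):
        out[:, col_of[g]] += values[:, j]
    return pd.DataFrame(out, index=index, columns=order)
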