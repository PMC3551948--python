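"""Core domain types and tab-delimited I/O.

The universal exchange object is :class:`EnrichmentMatrix`: a gene x replicate
table of log2 enrichment values (IP-channel over total-RNA reference, or the
log2 output of the sequencing bin pipeline) together with a per-replicate
condition label, either ``"IP"`` (the specific immunoprecipitation) or
``"Mock"`` (the same procedure without the specific antibody/tag, measuring
non-specific background).

All downstream arithmetic is additive, so values are assumed to be already
log-transformed.  Condition labels live in a sidecar mapping rather than in
column names, because exported matrices from public repositories encode the
design in too many different ways to parse reliably.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Recognized condition labels.
IP = "IP"
MOCK = "Mock"

_CONDITION_ALIASES = {"ip": IP, "mock": MOCK}

#: Floating point format used when writing matrices (6 significant digits).
FLOAT_FORMAT = "%.6g"


def _normalize_condition(label: str) -> str:
    try:
        return _CONDITION_ALIASES[str(label).strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown condition label {label!r}; expected 'IP' or 'Mock'"
        ) from None


@dataclass
class EnrichmentMatrix:
    """Gene x replicate log2 enrichment values with IP/Mock labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per replicate.  All
        entries must be finite.
    conditions
        Series mapping each replicate id (= column of ``values``) to
        ``"IP"`` or ``"Mock"``.
    n_dropped
        Number of rows removed during loading because they contained
        missing or non-numeric entries (informational).
    """

    values: pd.DataFrame
    conditions: pd.Series
    n_dropped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        values = self.values
        if not values.index.is_unique:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if not values.columns.is_unique:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate replicate ids: {dups}")
        conditions = pd.Series(self.conditions)
        missing = [c for c in values.columns if c not in conditions.index]
        if missing:
            raise ValueError(f"replicates without a condition label: {missing}")
        conditions = conditions.reindex(values.columns).map(_normalize_condition)
        object.__setattr__(self, "conditions", conditions)
        arr = values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("EnrichmentMatrix values must be finite")

    # ------------------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def replicate_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    @property
    def ip_ids(self) -> list:
        return [r for r in self.values.columns if self.conditions[r] == IP]

    @property
    def mock_ids(self) -> list:
        return [r for r in self.values.columns if self.conditions[r] == MOCK]

    def ip_values(self) -> pd.DataFrame:
        return self.values[self.ip_ids]

    def mock_values(self) -> pd.DataFrame:
        return self.values[self.mock_ids]

    def with_values(self, values: pd.DataFrame) -> "EnrichmentMatrix":
        """Return a copy of this matrix with ``values`` replaced."""
        return EnrichmentMatrix(values=values, conditions=self.conditions.copy())


@dataclass
class Config:
    """Tunable parameters shared by the CLI and the library entry points.

    ``estimator`` selects how the per-replicate constant is computed from the
    background set (see :func:`adnorm.core.normalization_constant`); ``k`` is
    either a fixed background-set size or ``"auto"`` to invoke the
    piecewise-linearity scan of :func:`adnorm.kselect.select_k`;
    ``min_segment`` encodes the minimum knot separation (in ranks) of that
    scan; ``reference`` chooses how IP replicates are referenced to the Mocks
    (``"matched"`` or ``"pooled"``, see :mod:`adnorm.core`).
    """

    estimator: str = "set-median"
    k: int | str = "auto"
    k_min: int | None = None
    k_max: int | float | None = None
    min_segment: int = 500
    r2_min: float = 0.995
    reference: str = "matched"
    n_permutations: int = 1000
    fdr_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.estimator not in ("set-median", "set-mean", "orderstat-mean"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.reference not in ("matched", "pooled"):
            raise ValueError(f"unknown reference policy {self.reference!r}")
        if self.k != "auto":
            self.k = int(self.k)
            if self.k < 1:
                raise ValueError("k must be positive or 'auto'")
        if self.min_segment < 2:
            raise ValueError("min_segment must be >= 2")
        if not (0.0 < self.r2_min < 1.0):
            raise ValueError("r2_min must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if (
            self.k_min is not None
            and self.k_max is not None
            and not (self.k_min < self.k_max)
        ):
            raise ValueError("k_min must be smaller than k_max")


def load_config(path: str | Path) -> Config:
    """Read a flat YAML key-value document into a :class:`Config`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(Config)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return Config(**raw)


# ----------------------------------------------------------------------
# Tab-delimited matrix I/O


def read_matrix(
    path: str | Path, condition_map: Mapping[str, str]
) -> EnrichmentMatrix:
    """Load a gene x replicate TSV into an :class:`EnrichmentMatrix`.

    The file must be tab-delimited with the gene id in the first column and a
    header row of replicate ids.  Rows containing missing or non-numeric
    entries are dropped (complete-case deletion) and the count is logged.
    Row and column order are preserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not df.index.is_unique:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups}")
    missing = [c for c in df.columns if c not in condition_map]
    if missing:
        raise ValueError(
            f"replicates in {path} without a condition label: {missing}"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    keep = np.isfinite(numeric.to_numpy()).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "dropped %d of %d rows with missing or non-numeric entries from %s",
            n_dropped, len(df), path,
        )
    numeric = numeric.loc[keep]
    conditions = pd.Series({c: condition_map[c] for c in df.columns})
    return EnrichmentMatrix(
        values=numeric, conditions=conditions, n_dropped=n_dropped
    )


def write_matrix(matrix: EnrichmentMatrix, path: str | Path) -> None:
    """Write the matrix values as UTF-8 TSV, gene ids under a ``gene`` header.

    Values are written with 6 significant digits; ``read_matrix`` of the
    written file reproduces the values to that precision.
    """
    df = matrix.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_conditions(path: str | Path) -> dict[str, str]:
    """Read a two-column (replicate, condition) TSV sidecar into a dict."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (replicate, condition)")
    rep, cond = df.columns[:2]
    return {
        str(r): _normalize_condition(c) for r, c in zip(df[rep], df[cond])
    }


def write_conditions(conditions: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"replicate": list(conditions), "condition": list(conditions.values())}
    ).to_csv(path, sep="\t", index=False)
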