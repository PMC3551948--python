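"""Synthetic IP/Mock enrichment data with known ground truth.

The generative model mirrors the additive enrichment model the normalization
is built on: per gene, log2 enrichment = background draw + non-negative
target signal + noise, and every replicate carries an unknown additive
offset (the constant the normalization must recover).  Three generators are
provided: the idealized IP experiment (background genes N(0, 1), targets
N(3, 1), 6,000 genes by default), an all-background null with known offsets
for bias studies, and a Mock-vs-Mock split in which both "conditions" are
background so every called target is a false positive.

Also here: the sequencing-data preprocessor that turns per-bin read counts
into a log2 matrix ready for normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import IP, MOCK, EnrichmentMatrix

logger = logging.getLogger(__name__)

BACKGROUND = "background"
TARGET = "target"


@dataclass
class SimulationSpec:
    """Parameters of the idealized IP experiment.

    Defaults follow the validation setup: 6,000 genes, background log2
    enrichment drawn N(0, 1) and targets N(3, 1), three replicates per
    condition, and per-replicate offsets drawn Uniform(-2, 2) so constant
    recovery is non-trivial.  ``replicate_offsets`` may fix the offsets
    explicitly (IP replicates first, then Mocks).
    """

    n_genes: int = 6000
    target_fraction: float = 0.1
    background_mean: float = 0.0
    target_mean: float = 3.0
    sd: float = 1.0
    n_ip: int = 3
    n_mock: int = 3
    offset_range: tuple[float, float] = (-2.0, 2.0)
    replicate_offsets: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not (0.0 <= self.target_fraction <= 1.0):
            raise ValueError("target_fraction must lie in [0, 1]")
        if self.n_ip < 1 or self.n_mock < 1:
            raise ValueError("need at least one replicate per condition")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.replicate_offsets is not None:
            offs = np.asarray(self.replicate_offsets, dtype=float)
            if offs.shape != (self.n_ip + self.n_mock,):
                raise ValueError(
                    "replicate_offsets must have one entry per replicate "
                    f"({self.n_ip + self.n_mock})"
                )
            object.__setattr__(self, "replicate_offsets", offs)


@dataclass
class SimulatedDataset:
    """An EnrichmentMatrix plus the ground truth used to generate it."""

    matrix: EnrichmentMatrix
    truth: pd.Series = field(repr=False)  # per gene: "background" | "target"
    true_shift: float
    true_offsets: pd.Series = field(repr=False)  # per replicate

    @property
    def target_genes(self) -> pd.Index:
        return self.truth.index[self.truth == TARGET]

    @property
    def background_genes(self) -> pd.Index:
        return self.truth.index[self.truth == BACKGROUND]


def _gene_index(n: int) -> pd.Index:
    return pd.Index([f"g{i + 1}" for i in range(n)], name="gene")


def simulate_ip_experiment(spec: SimulationSpec) -> SimulatedDataset:
    """Generate the idealized IP experiment with known targets and offsets."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    genes = _gene_index(n)
    n_targets = round(spec.target_fraction * n)
    is_target = np.zeros(n, dtype=bool)
    if n_targets:
        is_target[rng.choice(n, size=n_targets, replace=False)] = True

    rep_ids = [f"ip{i + 1}" for i in range(spec.n_ip)] + [
        f"mock{i + 1}" for i in range(spec.n_mock)
    ]
    conditions = pd.Series(
        [IP] * spec.n_ip + [MOCK] * spec.n_mock, index=rep_ids
    )
    if spec.replicate_offsets is not None:
        offsets = np.asarray(spec.replicate_offsets, dtype=float)
    else:
        lo, hi = spec.offset_range
        offsets = rng.uniform(lo, hi, size=spec.n_ip + spec.n_mock)

    values = np.empty((n, spec.n_ip + spec.n_mock))
    for j in range(spec.n_ip):
        col = rng.normal(spec.background_mean, spec.sd, size=n)
        col[is_target] = rng.normal(spec.target_mean, spec.sd, size=n_targets)
        values[:, j] = col + offsets[j]
    for j in range(spec.n_mock):
        values[:, spec.n_ip + j] = (
            rng.normal(spec.background_mean, spec.sd, size=n)
            + offsets[spec.n_ip + j]
        )

    matrix = EnrichmentMatrix(
        values=pd.DataFrame(values, index=genes, columns=rep_ids),
        conditions=conditions,
    )
    truth = pd.Series(
        np.where(is_target, TARGET, BACKGROUND), index=genes, name="truth"
    )
    return SimulatedDataset(
        matrix=matrix,
        truth=truth,
        true_shift=spec.target_mean - spec.background_mean,
        true_offsets=pd.Series(offsets, index=rep_ids, name="offset"),
    )


def simulate_null_experiment(spec: SimulationSpec) -> SimulatedDataset:
    """All-background experiment (target_fraction forced to zero)."""
    return simulate_ip_experiment(replace(spec, target_fraction=0.0))


def simulate_mock_mock(
    n_mocks: int = 6,
    group_sizes: tuple[int, int] = (3, 3),
    n_genes: int = 6000,
    sd: float = 1.0,
    gene_level_sd: float = 1.0,
    offset_range: tuple[float, float] = (-2.0, 2.0),
    seed: int = 0,
) -> SimulatedDataset:
    """Split biological Mock replicates into two sham conditions.

    All replicates are draws from the same background process; replicates
    share a per-gene random level (sd ``gene_level_sd``) so they are
    correlated like biological replicates of one underlying sample, on top of
    independent noise (sd ``sd``) and a per-replicate offset.  Group A
    (first ``group_sizes[0]`` replicates) is labeled Mock and group B is
    labeled IP, so every gene called enriched downstream is an empirically
    false target.
    """
    if sum(group_sizes) != n_mocks:
        raise ValueError(
            f"group sizes {group_sizes} must sum to n_mocks={n_mocks}"
        )
    if min(group_sizes) < 1:
        raise ValueError("both groups need at least one replicate")
    rng = np.random.default_rng(seed)
    genes = _gene_index(n_genes)
    n_a, n_b = group_sizes
    rep_ids = [f"mockA{i + 1}" for i in range(n_a)] + [
        f"mockB{i + 1}" for i in range(n_b)
    ]
    conditions = pd.Series([MOCK] * n_a + [IP] * n_b, index=rep_ids)
    level = rng.normal(0.0, gene_level_sd, size=n_genes)
    offsets = rng.uniform(*offset_range, size=n_mocks)
    values = (
        level[:, None]
        + rng.normal(0.0, sd, size=(n_genes, n_mocks))
        + offsets[None, :]
    )
    matrix = EnrichmentMatrix(
        values=pd.DataFrame(values, index=genes, columns=rep_ids),
        conditions=conditions,
    )
    truth = pd.Series(BACKGROUND, index=genes, name="truth")
    return SimulatedDataset(
        matrix=matrix,
        truth=truth,
        true_shift=0.0,
        true_offsets=pd.Series(offsets, index=rep_ids, name="offset"),
    )


def counts_to_logmatrix(
    ip_counts: pd.Series,
    mock_counts: pd.Series,
    reference_counts: pd.Series | None = None,
    pseudocount_policy: str = "drop-zeros",
) -> pd.DataFrame:
    """Turn per-bin read counts into a log2 table ready for normalization.

    Bins with a zero count in either the IP or the Mock are removed (only
    bins observed in both carry usable enrichment information); when a
    total-RNA ``reference_counts`` is supplied, IP and Mock counts are
    divided by it (reference-zero bins are removed too) to absorb sequencing
    bias.  Remaining values are log2-transformed.  Zeros are handled by bin
    removal only — no pseudocounts are added.
    """
    if pseudocount_policy != "drop-zeros":
        raise ValueError(
            f"unknown pseudocount policy {pseudocount_policy!r}; "
            "only 'drop-zeros' is supported"
        )
    ip_counts = pd.Series(ip_counts)
    mock_counts = pd.Series(mock_counts)
    if not ip_counts.index.equals(mock_counts.index):
        raise ValueError("IP and Mock counts must cover the same bins")
    if reference_counts is not None:
        reference_counts = pd.Series(reference_counts)
        if not reference_counts.index.equals(ip_counts.index):
            raise ValueError("reference counts must cover the same bins")
    for name, s in (("IP", ip_counts), ("Mock", mock_counts)):
        arr = s.to_numpy()
        if (arr < 0).any():
            raise ValueError(f"{name} counts must be non-negative")
    keep = (ip_counts > 0) & (mock_counts > 0)
    if reference_counts is not None:
        keep &= reference_counts > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d bins with zero counts", n_dropped)
    ip = ip_counts[keep].astype(float)
    mock = mock_counts[keep].astype(float)
    if reference_counts is not None:
        ref = reference_counts[keep].astype(float)
        ip = ip / ref
        mock = mock / ref
    if keep.sum() == 0:
        logger.warning("no bins left after zero-count removal")
    return pd.DataFrame({"IP": np.log2(ip), "Mock": np.log2(mock)})
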