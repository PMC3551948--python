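"""Mock background model: centered replicates and leave-one-out averages.

The Mock arrays measure non-specific background enrichment.  Each Mock
replicate is median-centered (its column median subtracted) so that the
background distribution is anchored at zero; the per-gene average of the
centered Mocks (``mock_bar``) is the pooled background estimate, and for each
Mock replicate j the leave-one-out average over the other replicates
(``loo_bars[j]``) serves as an independent reference so the Mock itself can
be run through the normalization machinery exactly as if it were an IP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each column's median so every column has median zero."""
    if matrix.shape[0] == 0:
        raise ValueError("cannot median-center an empty matrix")
    centered = matrix - matrix.median(axis=0)
    logger.debug(
        "median_center: column medians before %s",
        matrix.median(axis=0).to_dict(),
    )
    return centered


@dataclass
class MockModel:
    """Centered Mock replicates, their average, and leave-one-out averages.

    Invariants (tested): each column of ``centered_mocks`` has median 0;
    ``mock_bar`` is the row-wise mean of ``centered_mocks``; and for every
    replicate j, ``n_mock * mock_bar == (n_mock - 1) * loo_bars[j] +
    centered_mocks[:, j]`` exactly.  ``loo_bars`` is ``None`` when only one
    Mock replicate is available.
    """

    centered_mocks: pd.DataFrame
    mock_bar: pd.Series
    loo_bars: pd.DataFrame | None
    n_mock: int

    def require_loo(self) -> pd.DataFrame:
        if self.loo_bars is None:
            raise ValueError(
                "leave-one-out Mock averages require at least 2 Mock replicates"
            )
        return self.loo_bars


def build_mock_model(mocks: pd.DataFrame) -> MockModel:
    """Median-center the Mock replicates and assemble the background model.

    With ``n_mock == 1`` the model is still built (``mock_bar`` is the single
    centered column) but leave-one-out averages are unavailable.
    """
    n_mock = mocks.shape[1]
    if n_mock == 0:
        raise ValueError("at least one Mock replicate is required")
    centered = median_center(mocks)
    mock_bar = centered.mean(axis=1)
    if n_mock >= 2:
        total = centered.sum(axis=1)
        loo = (total.to_numpy()[:, None] - centered.to_numpy()) / (n_mock - 1)
        loo_bars = pd.DataFrame(loo, index=centered.index, columns=centered.columns)
    else:
        loo_bars = None
    return MockModel(
        centered_mocks=centered, mock_bar=mock_bar, loo_bars=loo_bars, n_mock=n_mock
    )
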