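"""Automatic choice of the background-set size k.

The descending Mock-IP difference curve (value vs rank) has a steep,
nonlinear head formed by the extreme order statistics of the background
distribution, followed by a region that is well approximated by a piecewise
linear function with widely separated knots.  Genes in the head are the ones
most enriched in the Mock relative to the IP and are the safest background
anchors; k is placed where the curve first becomes locally linear, so the
background set covers the head plus the onset of the linear region.

Operationally, a linear fit is evaluated on every sliding window of
``min_segment`` ranks.  A candidate rank k qualifies when every window
starting within ``min_segment`` ranks of it reaches the goodness-of-fit
threshold ``r2_min``; the selected k is the smallest qualifying candidate.
``min_segment`` defaults to 500 ranks, the minimum knot separation observed
to hold on genome-scale IP data.  Because R-squared is invariant to shifting
and positive scaling of the curve, so is the selected k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_FLAT_TOL = 1e-12


def _as_sorted_diffs(profile) -> np.ndarray:
    """Accept a DifferenceProfile or a raw array of descending values."""
    y = getattr(profile, "sorted_diffs", profile)
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("expected a one-dimensional profile")
    if np.any(np.diff(y) > 1e-9):
        raise ValueError("profile values must be sorted in descending order")
    return y


def rolling_window_r2(y: np.ndarray, window: int) -> np.ndarray:
    """R^2 of the rank-vs-value linear fit on every window of ``window`` ranks.

    Returns one value per window start (length ``len(y) - window + 1``).
    A perfectly flat window has zero variance; it is linear by any standard,
    so its R^2 is reported as 1.
    """
    n = len(y)
    if window < 2 or n < window:
        raise ValueError("window must satisfy 2 <= window <= len(y)")
    cy = np.concatenate(([0.0], np.cumsum(y)))
    cy2 = np.concatenate(([0.0], np.cumsum(y * y)))
    x = np.arange(n, dtype=float)
    cxy = np.concatenate(([0.0], np.cumsum(x * y)))
    r = np.arange(n - window + 1)
    sum_y = cy[r + window] - cy[r]
    sum_y2 = cy2[r + window] - cy2[r]
    sum_xy = cxy[r + window] - cxy[r] - r * sum_y  # local x = 0..window-1
    xbar = (window - 1) / 2.0
    sxy = sum_xy - xbar * sum_y
    syy = sum_y2 - sum_y * sum_y / window
    sxx = window * (window * window - 1) / 12.0
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(syy > _FLAT_TOL, sxy * sxy / (sxx * np.maximum(syy, _FLAT_TOL)), 1.0)
    return np.clip(r2, 0.0, 1.0)


@dataclass
class KSelection:
    """Outcome of the k scan.

    ``r2_profile[i]`` is the worst (minimum) window R^2 among the windows a
    candidate ``candidates[i]`` must satisfy; ``accepted`` records whether any
    candidate met ``r2_min`` (otherwise k falls back to the best available
    candidate and a warning is logged); ``accepted_region`` is the contiguous
    run of qualifying candidates starting at k.
    """

    k: int
    candidates: np.ndarray = field(repr=False)
    r2_profile: np.ndarray = field(repr=False)
    window: int
    r2_min: float
    accepted: bool
    accepted_region: tuple[int, int] | None
    diagnostics: dict = field(default_factory=dict, repr=False)


def select_k(
    profile,
    *,
    min_segment: int = 500,
    r2_min: float = 0.995,
    k_min: int | None = None,
    k_max: int | float | None = None,
) -> KSelection:
    """Locate where the descending difference curve becomes piecewise linear.

    Parameters
    ----------
    profile
        A :class:`adnorm.core.DifferenceProfile` or an array of values sorted
        in descending order.
    min_segment
        Width (in ranks) of the sliding linear window, and the span of window
        starts each candidate must satisfy.  For small panels
        (``n < 2 * min_segment``) the window is scaled down to ``n // 4``
        with a warning; the 500-rank default assumes genome-scale data.
    r2_min
        Goodness-of-fit threshold each window must reach.
    k_min, k_max
        Candidate range.  Defaults: ``k_min = min_segment`` (after scaling)
        and ``k_max = floor(0.9 * n)``, which keeps a tail of candidate
        targets out of the normalization set.  A fractional ``k_max`` in
        (0, 1] is interpreted as a fraction of the gene count.
    """
    y = _as_sorted_diffs(profile)
    n = len(y)
    window = int(min_segment)
    if n < 2 * window:
        scaled = max(2, n // 4)
        logger.warning(
            "profile has %d genes < 2*min_segment=%d; scaling window down to %d",
            n, 2 * window, scaled,
        )
        window = scaled
    if k_min is None:
        k_min = window
    k_min = max(1, int(k_min))
    if k_max is None:
        k_max = int(0.9 * n)
    elif isinstance(k_max, float) and 0 < k_max <= 1:
        k_max = int(k_max * n)
    k_max = int(k_max)
    if k_max > n:
        raise ValueError(f"k_max={k_max} exceeds the number of genes ({n})")
    if k_min > k_max:
        raise ValueError(f"k_min={k_min} > k_max={k_max}")
    if n < k_min + window:
        raise ValueError(
            f"too few genes ({n}) for k_min={k_min} with window {window}"
        )

    r2 = rolling_window_r2(y, window)
    n_starts = len(r2)

    candidates = np.arange(k_min, k_max + 1)
    lo = candidates - 1  # 0-based first window start per candidate
    # min window R^2 over starts [lo, lo + window), truncated at the last
    # fittable window (the +inf padding drops truncated positions from the
    # min); candidates beyond the last window have nothing to test and are
    # excluded from selection and fallback alike
    padded = np.concatenate([r2, np.full(window - 1, np.inf)])
    sw_min = np.lib.stride_tricks.sliding_window_view(padded, window).min(axis=1)
    testable = lo < n_starts
    min_r2 = np.where(testable, sw_min[np.minimum(lo, n_starts - 1)], -np.inf)
    qualifies = testable & (min_r2 >= r2_min)

    if qualifies.any():
        idx = int(np.argmax(qualifies))
        k = int(candidates[idx])
        run_end = idx
        while run_end + 1 < len(candidates) and qualifies[run_end + 1]:
            run_end += 1
        region = (k, int(candidates[run_end]))
        accepted = True
    else:
        idx = int(np.argmax(min_r2))
        k = int(candidates[idx])
        region = None
        accepted = False
        logger.warning(
            "no candidate k in [%d, %d] reached window R^2 >= %.4f "
            "(best %.4f at k=%d); using the best candidate",
            k_min, k_max, r2_min, float(min_r2[idx]), k,
        )
    return KSelection(
        k=k,
        candidates=candidates,
        r2_profile=min_r2,
        window=window,
        r2_min=r2_min,
        accepted=accepted,
        accepted_region=region,
        diagnostics={"n_genes": n, "window_r2": r2},
    )


def rank_plot(
    profile,
    selection: KSelection | None = None,
    annotations=None,
    path=None,
    title: str | None = None,
):
    """Plot Mock-IP difference values against their rank.

    Background genes appear on the left; a vertical line marks the selected
    k.  ``annotations`` may be a boolean mask (aligned to the profile's gene
    order) highlighting e.g. known targets or motif-containing genes.
    Returns the matplotlib Figure, or ``path`` when a file is written.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    y = _as_sorted_diffs(profile)
    n = len(y)
    ranks = np.arange(1, n + 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(ranks, y, s=3, c="black", label="all genes", rasterized=True)
    if annotations is not None:
        mask = np.asarray(annotations, dtype=bool)
        order = getattr(profile, "order", None)
        if order is not None and len(mask) == n:
            mask = mask[order]
        ax.scatter(
            ranks[mask], y[mask], s=5, c="orange", label="annotated", zorder=3
        )
    if selection is not None:
        ax.axvline(selection.k, color="steelblue", ls="--",
                   label=f"k = {selection.k}")
    ax.set_xlabel("rank of Mock − IP difference")
    ax.set_ylabel("Mock − IP (log2)")
    ax.set_xlim(1, n)
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path
    return fig
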