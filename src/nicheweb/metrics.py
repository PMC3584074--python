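"""Structural metrics for networks and fitted niche models.

Covers the nestedness score NODF restricted to consumer pairs (with
equal-degree pairs excluded rather than scored zero), its continuous
analogue on fitted niche intervals, connectance estimators, the expected
fraction of observed links reproduced by a model (f_L), the
specialist-to-generalist ordering correlation, and the dispersion of
consumer niche centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import BPNMParams, ProbabilityMatrix
from .network import BipartiteNetwork, sort_by_marginals, connectance_empirical

__all__ = [
    "MetricsReport", "paired_overlap", "nodf_consumers", "r_interval",
    "continuous_overlap", "fraction_links_predicted",
    "connectance_from_probabilities", "degree_r_rank_correlation",
    "c_dispersion", "metrics_report",
]


@dataclass(frozen=True)
class MetricsReport:
    """One network / one fit's structural summary; None marks undefined values."""

    nodf_c: float | None
    overlap_r: float | None
    connectance_emp: float
    connectance_prob: float | None
    connectance_sim_mean: float | None
    f_l: float | None
    degree_r_spearman: float | None
    c_sd: float | None
    n_pairs_used: int


def paired_overlap(diet_wide: set, diet_narrow: set) -> float | None:
    """Fraction of the narrower consumer's resources shared with the wider one.

    Returns None (undefined) for an empty narrow diet.
    """
    if len(diet_narrow) == 0:
        return None
    if len(diet_wide) < len(diet_narrow):
        raise ValueError("first diet must be at least as large as the second")
    return len(diet_wide & diet_narrow) / len(diet_narrow)


def nodf_consumers(net: BipartiteNetwork, score_equal_degrees_zero: bool = False
                   ) -> tuple[float | None, int]:
    """Consumer NODF on the 0-100 scale; 100 is perfect nestedness.

    The matrix is first sorted in descending order by row and column
    marginal totals.  Every ordered column pair (wider degree first)
    scores ``100 * |shared resources| / narrower degree`` when the wider
    degree strictly exceeds the narrower; pairs with equal degrees are
    excluded from the average (set ``score_equal_degrees_zero`` to recover
    the original algorithm's zero-scoring), as are pairs whose narrower
    column is empty.  Returns ``(score, pairs_used)``; score is None when
    every pair is excluded.
    """
    if net.s_c < 2:
        raise ValueError("consumer NODF needs at least two consumers")
    sorted_net = sort_by_marginals(net)
    a = sorted_net.adjacency
    deg = a.sum(axis=0)
    scores = []
    for i in range(len(deg)):
        for j in range(i + 1, len(deg)):
            if deg[j] == 0:
                continue
            if deg[i] == deg[j]:
                if score_equal_degrees_zero:
                    scores.append(0.0)
                continue
            shared = int((a[:, i] & a[:, j]).sum())
            scores.append(100.0 * shared / deg[j])
    if not scores:
        return None, 0
    return float(np.mean(scores)), len(scores)


def r_interval(c_i: float, r_i: float) -> tuple[float, float]:
    """Dietary-range interval [c - r/2, c + r/2] on the niche axis.

    Not clipped to [0, 1]: a wide niche near the axis edge extends beyond it.
    """
    if r_i <= 0:
        raise ValueError("niche width must be positive")
    return (c_i - r_i / 2.0, c_i + r_i / 2.0)


def continuous_overlap(params: BPNMParams) -> tuple[float | None, int]:
    """Continuous niche overlap of consumer dietary ranges, 0-100 scale.

    The continuous analogue of consumer NODF: consumers are sorted by
    decreasing niche width and every ordered pair (wider i, narrower j)
    scores ``100 * |interval_i ∩ interval_j| / r_j`` when ``r_i > r_j``;
    equal-width pairs are excluded.  100 means every narrower range is
    contained in every wider one.
    """
    if params.s_c < 2:
        raise ValueError("continuous overlap needs at least two consumers")
    order = np.argsort(-params.r, kind="stable")
    c, r = params.c[order], params.r[order]
    scores = []
    for i in range(len(r)):
        lo_i, hi_i = r_interval(c[i], r[i])
        for j in range(i + 1, len(r)):
            if r[i] == r[j]:
                continue
            lo_j, hi_j = r_interval(c[j], r[j])
            inter = max(0.0, min(hi_i, hi_j) - max(lo_i, lo_j))
            scores.append(100.0 * inter / r[j])
    if not scores:
        return None, 0
    return float(np.mean(scores)), len(scores)


def fraction_links_predicted(net: BipartiteNetwork, matrix: ProbabilityMatrix,
                             threshold: float | None = None) -> float:
    """Expected fraction of observed links realized by the model (f_L).

    The mean model probability over cells where a link was observed.
    Valid as a performance measure only when the model's expected link
    count is close to the observed count; a warning is emitted when they
    differ by more than 5%.  Passing ``threshold`` switches to the count
    variant: the fraction of observed links with ``p_ij >= threshold``.
    """
    a = net.adjacency
    if a.shape != matrix.p.shape:
        raise ValueError("network and probability matrix shapes differ")
    l_total = net.n_links
    if l_total == 0:
        raise ValueError("f_L undefined on a linkless network")
    if abs(matrix.expected_links - l_total) / l_total > 0.05:
        warnings.warn(
            f"model expects {matrix.expected_links:.1f} links vs {l_total} observed; "
            "f_L may be a misleading performance measure", stacklevel=2)
    on_links = matrix.p[a == 1]
    if threshold is not None:
        return float((on_links >= threshold).mean())
    return float(on_links.sum() / l_total)


def connectance_from_probabilities(matrix: ProbabilityMatrix) -> float:
    """Model connectance without simulation: sum of p_ij over matrix size."""
    return matrix.expected_links / (matrix.s_c * matrix.s_r)


def degree_r_rank_correlation(net: BipartiteNetwork, params: BPNMParams) -> float | None:
    """Spearman rank correlation of empirical consumer degree vs fitted width r.

    The specialist-to-generalist ordering check: consumers taking more
    resources should carry wider fitted niches.  Average ranks on ties;
    None when either ranking has zero variance.
    """
    if net.s_c < 3:
        raise ValueError("rank correlation needs at least three consumers")
    deg = net.consumer_degrees
    if len(np.unique(deg)) < 2 or len(np.unique(params.r)) < 2:
        return None
    rho = stats.spearmanr(deg, params.r).statistic
    return float(rho)


def c_dispersion(params: BPNMParams) -> float:
    """Sample standard deviation (n-1 denominator) of consumer niche centers."""
    if params.s_c < 2:
        raise ValueError("dispersion needs at least two consumers")
    return float(np.std(params.c, ddof=1))


def metrics_report(net: BipartiteNetwork, params: BPNMParams | None = None,
                   matrix: ProbabilityMatrix | None = None,
                   ensemble_mean_connectance: float | None = None) -> MetricsReport:
    """Assemble the full structural summary for one network and optional fit."""
    nodf, pairs = nodf_consumers(net) if net.s_c >= 2 else (None, 0)
    overlap = conn_prob = f_l = rho = c_sd = None
    if params is not None:
        overlap, _ = continuous_overlap(params)
        c_sd = c_dispersion(params)
        if net.s_c >= 3:
            rho = degree_r_rank_correlation(net, params)
    if matrix is not None:
        conn_prob = connectance_from_probabilities(matrix)
        f_l = fraction_links_predicted(net, matrix)
    return MetricsReport(
        nodf_c=nodf, overlap_r=overlap,
        connectance_emp=connectance_empirical(net),
        connectance_prob=conn_prob,
        connectance_sim_mean=ensemble_mean_connectance,
        f_l=f_l, degree_r_spearman=rho, c_sd=c_sd, n_pairs_used=pairs,
    )
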