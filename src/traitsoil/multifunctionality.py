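"""Threshold-and-weighting soil multifunctionality score.

Per time point, soil functions are clustered on the distance 1 - |rho|
(Spearman correlation across subplots, average linkage, dendrogram cut at a
configurable height) so that redundant, strongly correlated functions are
down-weighted.  Each function in a cluster of size m receives the global
weight 1/(m*K) for K clusters — within a cluster the weights sum to 1/K and
over all functions to exactly 1.  A subplot scores the function's weight if
its value is in the top 50% (value >= the across-subplot median; ties pass)
and zero otherwise; the weighted sum is the multifunctionality score, with
a maximum of one when a subplot clears every threshold.

Because the threshold depends only on the rank of a subplot among subplots,
the score is invariant to monotone increasing transforms of any single
function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

PANEL_COLUMNS = ["subplot_id", "time_point", "function_name", "value"]

#: default dendrogram cut height on the 1 - |rho| scale
DEFAULT_CUT = 0.7
#: default threshold: top 50% of the observed distribution
DEFAULT_THRESHOLD = 0.5
#: minimum subplots per time point for a meaningful threshold
MIN_SUBPLOTS = 4


def _panel_matrix(panel: pd.DataFrame, time_point: str) -> pd.DataFrame:
    sub = panel[panel["time_point"] == time_point]
    if sub.empty:
        raise ValueError(f"no panel rows at time point {time_point!r}")
    if sub.duplicated(["subplot_id", "function_name"]).any():
        raise ValueError("panel has duplicate (subplot, function) values")
    return sub.pivot(index="subplot_id", columns="function_name", values="value")


def cluster_functions(panel: pd.DataFrame, time_point: str,
                      cut: float = DEFAULT_CUT) -> dict[str, int]:
    """Group soil functions by rank correlation across subplots.

    Returns a map function_name -> cluster id (1..K).
    """
    mat = _panel_matrix(panel, time_point)
    counts = mat.notna().sum()
    if (counts < MIN_SUBPLOTS).any():
        short = counts[counts < MIN_SUBPLOTS].index.tolist()
        raise ValueError(f"functions with < {MIN_SUBPLOTS} subplot values: {short}")
    constant = [f for f in mat.columns if mat[f].nunique(dropna=True) <= 1]
    if constant:
        raise ValueError(f"zero-variance function: {constant}")
    funcs = list(mat.columns)
    if len(funcs) == 1:
        return {funcs[0]: 1}
    rho = spearmanr(mat.to_numpy(), nan_policy="omit").statistic
    rho = np.atleast_2d(rho)
    dist = 1.0 - np.abs(rho)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)  # enforce exact symmetry
    labels = fcluster(linkage(squareform(dist, checks=False), method="average"),
                      t=cut, criterion="distance")
    return dict(zip(funcs, (int(c) for c in labels)))


def function_weights(cluster_of: dict[str, int]) -> dict[str, float]:
    """Global function weights 1/(m*K): equal within a cluster, summing to 1."""
    if not cluster_of:
        raise ValueError("empty clustering")
    sizes = pd.Series(cluster_of).value_counts()
    n_clusters = len(sizes)
    return {f: 1.0 / (sizes[c] * n_clusters) for f, c in cluster_of.items()}


@dataclass
class MultifunctionalityScore:
    scores: pd.DataFrame  # subplot_id, time_point, score
    weights: dict[str, float]
    cluster_of: dict[str, int]
    threshold: float


def multifunctionality_score(panel: pd.DataFrame, time_point: str,
                             weights: dict[str, float] | None = None,
                             threshold: float = DEFAULT_THRESHOLD,
                             cut: float = DEFAULT_CUT) -> MultifunctionalityScore:
    """Weighted threshold score per subplot at one time point.

    ``weights`` may be precomputed; by default functions are clustered and
    weighted here.  A subplot passes a function when its value is >= the
    (1 - threshold) quantile across subplots at this time point (median for
    the default 50% threshold); ties pass.  Missing values contribute zero
    without weight renormalization, so a subplot with gaps scores
    conservatively low (logged).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    mat = _panel_matrix(panel, time_point)
    if len(mat) < MIN_SUBPLOTS:
        raise ValueError(f"need >= {MIN_SUBPLOTS} subplots for thresholding")
    if weights is None:
        cluster_of = cluster_functions(panel, time_point, cut=cut)
        weights = function_weights(cluster_of)
    else:
        cluster_of = {}  # caller supplied weights; clustering not recomputed
    missing = set(mat.columns) - set(weights)
    if missing:
        raise ValueError(f"weights do not cover functions: {sorted(missing)}")
    cutoffs = mat.quantile(1.0 - threshold)
    passed = mat.ge(cutoffs, axis=1)
    if mat.isna().any().any():
        logger.warning("panel at %s has missing values: affected subplots are "
                       "scored without weight renormalization", time_point)
        passed = passed & mat.notna()
    w = pd.Series(weights).reindex(mat.columns)
    scores = passed.to_numpy(dtype=float) @ w.to_numpy()
    out = pd.DataFrame({
        "subplot_id": mat.index,
        "time_point": time_point,
        "score": scores,
    }).reset_index(drop=True)
    return MultifunctionalityScore(scores=out, weights=dict(weights),
                                   cluster_of=cluster_of, threshold=threshold)
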