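"""Drought resistance and resilience of soil functions (Orwin-Wardle indices).

For a soil function measured in a plot, let C0 and P0 be the unroofed
control and the droughted values at the end of the drought (July), and Cx,
Px the same pair after the recovery period (September).  With the initial
impact D0 = P0 - C0 and the remaining displacement Dx = Px - Cx:

    resistance  RS = 1 - 2|D0| / (C0 + |D0|)
    resilience  RL = 2|D0| / (|D0| + |Dx|) - 1

Both indices live in [-1, 1]: RS = 1 means no change under drought, RS = 0
a 100% change, and negative RS an overshoot beyond a full loss; RL = 1
means full return to the control, RL = 0 no recovery (|Dx| = |D0|) and
negative RL further divergence.  RS requires C0 > 0; RL requires a nonzero
initial impact.

An alternative reading in which D0 is the raw droughted value rather than
the control difference is available as ``d0_convention="value"`` for
reproduction attempts; it breaks the stated bounds and warns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_1samp

logger = logging.getLogger(__name__)

PAIRS_COLUMNS = ["plot_id", "function_name", "control_july", "drought_july",
                 "control_september", "drought_september"]


def _d0(c0, p0, convention: str):
    if convention == "difference":
        return np.asarray(p0, dtype=float) - np.asarray(c0, dtype=float)
    if convention == "value":
        logger.warning("d0_convention='value' follows the literal prose reading; "
                       "the indices are no longer bounded by [-1, 1]")
        return np.asarray(p0, dtype=float)
    raise ValueError(f"unknown d0 convention {convention!r}")


def resistance(c0, p0, d0_convention: str = "difference"):
    """RS = 1 - 2|D0|/(C0 + |D0|); scalar in (-1, 1] for C0 > 0."""
    c0_a = np.asarray(c0, dtype=float)
    if np.any(c0_a <= 0):
        raise ValueError("resistance undefined for non-positive control")
    d0 = np.abs(_d0(c0_a, p0, d0_convention))
    out = 1.0 - 2.0 * d0 / (c0_a + d0)
    return float(out) if out.ndim == 0 else out


def resilience(c0, p0, cx, px, d0_convention: str = "difference"):
    """RL = 2|D0|/(|D0| + |Dx|) - 1; requires |D0| > 0."""
    d0 = np.abs(_d0(c0, p0, d0_convention))
    if np.any(d0 == 0):
        raise ValueError("resilience undefined when initial impact is zero")
    dx = np.abs(np.asarray(px, dtype=float) - np.asarray(cx, dtype=float))
    out = 2.0 * d0 / (d0 + dx) - 1.0
    return float(out) if out.ndim == 0 else out


def compute_stability(pairs: pd.DataFrame,
                      d0_convention: str = "difference") -> pd.DataFrame:
    """Per (plot, function) D0, Dx, resistance and resilience.

    Rows with non-positive July control get NaN resistance and rows with
    zero initial impact NaN resilience; both are flagged, not dropped.
    """
    missing = [c for c in PAIRS_COLUMNS if c not in pairs.columns]
    if missing:
        raise ValueError(f"pairs table missing columns: {missing}")
    out = pairs[PAIRS_COLUMNS].copy()
    c0 = out["control_july"].to_numpy(dtype=float)
    p0 = out["drought_july"].to_numpy(dtype=float)
    cx = out["control_september"].to_numpy(dtype=float)
    px = out["drought_september"].to_numpy(dtype=float)
    if not np.all(np.isfinite(np.stack([c0, p0, cx, px]))):
        raise ValueError("stability inputs must be finite")
    d0 = _d0(c0, p0, d0_convention)
    dx = px - cx
    out["d0"], out["dx"] = d0, dx
    rs = np.full(len(out), np.nan)
    ok = c0 > 0
    if not ok.all():
        logger.warning("%d rows with non-positive July control: resistance flagged",
                       (~ok).sum())
    rs[ok] = 1.0 - 2.0 * np.abs(d0[ok]) / (c0[ok] + np.abs(d0[ok]))
    rl = np.full(len(out), np.nan)
    hit = np.abs(d0) > 0
    if not hit.all():
        logger.warning("%d rows with zero initial impact: resilience flagged",
                       (~hit).sum())
    rl[hit] = 2.0 * np.abs(d0[hit]) / (np.abs(d0[hit]) + np.abs(dx[hit])) - 1.0
    out["resistance"], out["resilience"] = rs, rl
    out["flag_nonpositive_control"] = ~ok
    out["flag_zero_impact"] = ~hit
    return out


def mean_stability(results: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean resistance/resilience across functions per plot.

    Functions with flagged (NaN) values simply lower n; nothing is imputed.
    """
    return (results.groupby("plot_id")[["resistance", "resilience"]]
            .mean().reset_index())


@dataclass
class OneSampleTest:
    group: object
    reference: float
    n: int
    mean: float
    t_statistic: float
    df: int
    p_value: float
    note: str = ""


def stability_tests(values: pd.Series | np.ndarray, reference: float,
                    groups: pd.Series | None = None) -> list[OneSampleTest]:
    """One-sample t-tests of stability indices against a reference (0 or 1).

    Run per group when a grouping factor is supplied.  Degenerate,
    zero-variance samples are reported exactly rather than tested.
    """
    v = pd.Series(np.asarray(values, dtype=float)).dropna()
    if groups is None:
        grouping = pd.Series("all", index=v.index)
    else:
        grouping = pd.Series(groups).reindex(v.index)
    out = []
    for g, idx in grouping.groupby(grouping).groups.items():
        sample = v.loc[idx].to_numpy()
        if len(sample) < 3:
            raise ValueError(f"group {g!r}: need >= 3 values per group")
        if np.ptp(sample) == 0:
            if sample[0] == reference:
                out.append(OneSampleTest(g, reference, len(sample), float(sample[0]),
                                         0.0, len(sample) - 1, 1.0,
                                         note="all values equal reference"))
            else:
                out.append(OneSampleTest(g, reference, len(sample), float(sample[0]),
                                         np.inf, len(sample) - 1, 0.0,
                                         note="all values equal non-reference constant"))
            continue
        t, p = ttest_1samp(sample, reference)
        out.append(OneSampleTest(g, reference, len(sample), float(sample.mean()),
                                 float(t), len(sample) - 1, float(p)))
    return out
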