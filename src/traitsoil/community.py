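"""Community trait summaries from percent-cover surveys.

For every subplot the community-weighted mean (CWM) and the functional
divergence (FDvar) of each trait are computed from visually estimated
percent cover, with cover converted to relative abundance within the
subplot.  FDvar follows the Mason et al. (2003) definition: the
abundance-weighted variance V of log trait values mapped onto [0, 1) by
(2/pi)*arctan(5V), so 0 means every present species shares the trait value
and values approach 1 as abundance-weighted log-trait spread grows.

Ordinal traits (perenniality, root architectural class, rooting depth
class, mycorrhizal affinity) enter as their numeric codes.  Species present
in a survey but missing from the trait table (or missing that trait) are
dropped from that trait's summary with a warning; the retained fraction of
total cover is reported, and subplots retaining < 80% of cover are flagged.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .grouping import TRAIT_NAMES

logger = logging.getLogger(__name__)

#: subplot summaries retaining less than this share of cover are flagged
MIN_COVER_RETAINED = 0.80

SURVEY_COLUMNS = ["subplot_id", "survey_month", "species_id", "cover_pct"]


_KEYS = ["subplot_id", "survey_month"]


def _weighted_table(survey: pd.DataFrame, traits: pd.DataFrame,
                    trait_name: str) -> tuple[pd.DataFrame, pd.Series]:
    """Present species joined to trait values, with relative weights.

    Vectorized core shared by cwm and fdvar: rows are species with positive
    cover; ``weight`` is cover normalized within (subplot, month) over the
    species that have the trait; ``cover_retained`` is the retained share.
    """
    tvals = pd.to_numeric(traits.set_index("species_id")[trait_name],
                          errors="coerce")
    present = survey[survey["cover_pct"] > 0].copy()
    totals = survey.groupby(_KEYS)["cover_pct"].sum()
    empty = totals[totals <= 0]
    if len(empty):
        raise ValueError(
            f"empty community: no positive cover in {empty.index.tolist()[:3]}")
    present["trait_value"] = tvals.reindex(present["species_id"]).to_numpy()
    has = present[present["trait_value"].notna()].copy()
    kept = has.groupby(_KEYS)["cover_pct"].sum()
    retained = (kept / totals).rename("cover_retained")
    n_dropped = len(present) - len(has)
    if n_dropped:
        logger.warning("trait %s: dropped %d survey records without trait "
                       "data (min cover retained %.0f%%)",
                       trait_name, n_dropped, 100 * retained.min())
    if retained.isna().any() or (retained == 0).any():
        bad = retained.index[retained.fillna(0) == 0].tolist()[:3]
        raise ValueError(
            f"empty community: no species with {trait_name!r} data in {bad}")
    has["weight"] = has["cover_pct"] / kept.reindex(
        pd.MultiIndex.from_frame(has[_KEYS])).to_numpy()
    return has, retained


def _finish(per_group: pd.Series, retained: pd.Series, trait_name: str,
            value_name: str) -> pd.DataFrame:
    out = per_group.rename(value_name).reset_index()
    out["trait_name"] = trait_name
    out = out.merge(retained.reset_index(), on=_KEYS)
    out["flagged"] = out["cover_retained"] < MIN_COVER_RETAINED
    cols = [*_KEYS, "trait_name", value_name, "cover_retained", "flagged"]
    return out[cols]


def cwm(survey: pd.DataFrame, traits: pd.DataFrame, trait_name: str) -> pd.DataFrame:
    """Community-weighted mean of a trait per (subplot, survey month).

    cwm = sum_i p_i * t_i with p_i the relative cover of species i; the
    result is bounded by the trait range of the present species.
    """
    has, retained = _weighted_table(survey, traits, trait_name)
    has["wt"] = has["weight"] * has["trait_value"]
    return _finish(has.groupby(_KEYS)["wt"].sum(), retained, trait_name, "cwm")


def fdvar(survey: pd.DataFrame, traits: pd.DataFrame, trait_name: str) -> pd.DataFrame:
    """Functional divergence of a trait per (subplot, survey month).

    With p_i the relative covers: ln xbar = sum p_i ln t_i,
    V = sum p_i (ln t_i - ln xbar)^2 and FDvar = (2/pi) arctan(5 V).
    Requires strictly positive trait values (the log is taken).
    """
    has, retained = _weighted_table(survey, traits, trait_name)
    if (has["trait_value"] <= 0).any():
        raise ValueError("FDvar requires positive traits")
    has["log_t"] = np.log(has["trait_value"])
    has["w_log"] = has["weight"] * has["log_t"]
    log_mean = has.groupby(_KEYS)["w_log"].sum()
    centred = has["log_t"] - log_mean.reindex(
        pd.MultiIndex.from_frame(has[_KEYS])).to_numpy()
    has["w_sq"] = has["weight"] * centred ** 2
    v = has.groupby(_KEYS)["w_sq"].sum()
    fd = (2.0 / math.pi) * np.arctan(5.0 * v)
    return _finish(fd, retained, trait_name, "fdvar")


def logit_transform(x, eps: float = 0.001):
    """Logit with clipping: ln(x'/(1-x')) where x' = clip(x, eps, 1-eps).

    Used on FDvar values before they enter linear models.
    """
    if not 0 < eps < 0.5:
        raise ValueError("eps must lie in (0, 0.5)")
    arr = np.asarray(x, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("logit_transform requires values in [0, 1]")
    clipped = np.clip(arr, eps, 1 - eps)
    out = np.log(clipped / (1 - clipped))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def flux_partition(nee, reco):
    """Photosynthetic rate estimate: P_syn = NEE - R_eco.

    Sign convention: positive fluxes point to the atmosphere, so P_syn is
    typically negative for net photosynthetic uptake.
    """
    nee_a, reco_a = np.asarray(nee, dtype=float), np.asarray(reco, dtype=float)
    if not (np.all(np.isfinite(nee_a)) and np.all(np.isfinite(reco_a))):
        raise ValueError("flux_partition requires finite NEE and R_eco")
    out = nee_a - reco_a
    return float(out) if out.ndim == 0 else out


def community_summary(survey: pd.DataFrame, traits: pd.DataFrame,
                      trait_names: list[str] | None = None,
                      eps: float = 0.001) -> pd.DataFrame:
    """Long table of CWM, FDvar and logit(FDvar) for every trait and subplot."""
    names = trait_names if trait_names is not None else TRAIT_NAMES
    parts = []
    for name in names:
        a = cwm(survey, traits, name)
        b = fdvar(survey, traits, name)[["subplot_id", "survey_month", "trait_name", "fdvar"]]
        merged = a.merge(b, on=["subplot_id", "survey_month", "trait_name"])
        merged["fdvar_logit"] = logit_transform(merged["fdvar"].to_numpy(), eps)
        parts.append(merged)
    cols = ["subplot_id", "survey_month", "trait_name", "cwm", "fdvar",
            "fdvar_logit", "cover_retained", "flagged"]
    return pd.concat(parts, ignore_index=True)[cols]
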