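"""Synthetic grassland-restoration drought experiment with known truth.

Generates every input the analysis pipeline consumes — a species x trait
database, the randomized block design, percent-cover surveys, subplot x
month soil-function panels and paired control/drought values — from one
seeded generator, so each stage can be tested against the generating
parameters without any field data.

The emulated design matches the field layout: 6 blocks x 7 treatments (all
non-empty combinations of three sown functional groups) = 42 plots, each
with 3 roof subplots (unroofed control, perforated roofed control, full
rain shelter) = 126 subplots, each treatment appearing exactly once per
block in a randomized position.

Three contrasting trait syndromes are generated: a tall, deep-rooted,
simple tap-rooted pool with varied lifespans (group 1); a short,
long-lived, shallow tap-rooted pool (group 2); and a shallow pool with
complex fibrous root architecture and low specific leaf area (group 3).
Within-group trait noise defaults to 10% of the between-group spread of
each trait, giving cleanly separable syndromes.

Soil-function values follow a linear model in the standardized community
trait summaries (CWM/FDvar), with month effects (July depressed), block and
plot random intercepts, Gaussian noise, and a drought effect applied to
rain-sheltered subplots whose magnitude shrinks with the functional
divergence of rooting depth (communities mixing rooting depths resist the
drought better).  The drought multiplies July soil moisture by
(1 - drought_smc_fraction), default 0.34, under the shelters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .community import community_summary
from .grouping import TRAIT_NAMES

ROOF_LEVELS = ["unroofed_control", "roofed_control", "drought"]
ROOF_SUFFIX = {"unroofed_control": "C", "roofed_control": "R", "drought": "D"}
MONTHS = ["May", "July", "September"]

TREATMENTS = ["FG1", "FG2", "FG3", "FG1+FG2", "FG1+FG3", "FG2+FG3",
              "FG1+FG2+FG3"]

FUNCTIONS = ["NH4-N", "NO3-N", "DOC", "PO4-P", "mineralization",
             "nitrification", "decomposition", "microbial_C", "microbial_N",
             "NEE", "R_eco"]

#: trait syndrome centers per functional group (group -> trait -> center)
SYNDROME_CENTERS: dict[int, dict[str, float]] = {
    1: {"height": 0.50, "perenniality": 3.0, "sla": 20.0,
        "root_architecture": 6.5, "root_depth": 2.7, "mycorrhizal_affinity": 2.0},
    2: {"height": 0.15, "perenniality": 4.5, "sla": 20.0,
        "root_architecture": 6.5, "root_depth": 1.2, "mycorrhizal_affinity": 2.5},
    3: {"height": 0.40, "perenniality": 4.5, "sla": 13.0,
        "root_architecture": 2.0, "root_depth": 1.2, "mycorrhizal_affinity": 1.5},
}

#: per-(group, trait) multipliers on the within-group noise SD; group 1 has a
#: wide range of lifespans and rooting architectures, and every group carries
#: some rooting-depth variation so communities can diverge in depth
SYNDROME_SD_SCALE: dict[tuple[int, str], float] = {
    (1, "perenniality"): 6.7,
    (1, "root_architecture"): 2.5,
    (1, "root_depth"): 2.3,
    (2, "root_depth"): 2.0,
    (3, "root_depth"): 2.0,
}

ORDINAL_BOUNDS = {"perenniality": (1, 5), "root_architecture": (1, 8),
                  "root_depth": (1, 3), "mycorrhizal_affinity": (1, 3)}

#: default trait -> function effects on the standardized predictor scale,
#: encoding the directions the pipeline should recover (taller communities
#: depress N cycling; high-SLA communities raise NO3 and P availability;
#: mycorrhizal communities raise NH4 and respiration)
DEFAULT_BETAS: dict[str, dict[tuple[str, str], float]] = {
    "mineralization": {("cwm", "height"): -0.5},
    "nitrification": {("cwm", "height"): -0.5},
    "NO3-N": {("cwm", "height"): -0.5, ("cwm", "sla"): 0.5},
    "PO4-P": {("cwm", "sla"): 0.5},
    "NH4-N": {("cwm", "mycorrhizal_affinity"): 0.5},
    "R_eco": {("cwm", "mycorrhizal_affinity"): 0.5,
              ("fdvar", "perenniality"): -0.3},
    "DOC": {("fdvar", "height"): 0.3},
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic experiment; defaults are the study conditions."""

    seed: int = 1
    species_per_group: int = 20
    trait_noise_frac: float = 0.10     # within-group SD as fraction of spread
    syndrome_sd_scale: dict = field(default_factory=lambda: dict(SYNDROME_SD_SCALE))
    total_cover_pct: float = 80.0
    cover_concentration: float = 1.0   # Dirichlet concentration per species
    betas: dict = field(default_factory=lambda: {
        f: dict(v) for f, v in DEFAULT_BETAS.items()})
    function_intercept: float = 10.0
    month_effects: dict = field(default_factory=lambda: {
        "May": 0.5, "July": -0.5, "September": 0.3})
    drought_effect: dict = field(default_factory=lambda: {
        "July": -3.0, "September": -1.5})
    resistance_link: float = 0.4       # FDvar root-depth damping of the impact
    drought_smc_fraction: float = 0.34
    smc_base: dict = field(default_factory=lambda: {
        "May": 24.0, "July": 26.0, "September": 22.0})
    noise_sd: float = 0.5
    block_sd: float = 0.3
    plot_sd: float = 0.3


@dataclass
class SimulatedExperiment:
    config: GeneratorConfig
    traits: pd.DataFrame          # TraitTable CSV schema
    true_groups: pd.Series        # species_id -> generating group label
    layout: pd.DataFrame          # DesignLayout
    survey: pd.DataFrame          # CoverSurvey (long)
    panel: pd.DataFrame           # FunctionPanel (long, incl. soil_moisture)
    pairs: pd.DataFrame           # StabilityInput (wide per plot x function)
    predictors: pd.DataFrame      # subplot-level standardized CWM/FDvar terms


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def build_design(config: GeneratorConfig) -> pd.DataFrame:
    """Randomized block layout: 6 blocks x 7 treatments x 3 roof subplots."""
    rng = _rngs(config.seed, 4)[0]
    rows = []
    for block in range(1, 7):
        order = list(TREATMENTS)
        rng.shuffle(order)
        for pos, treatment in enumerate(order, start=1):
            plot_id = f"B{block}P{pos}"
            for roof in ROOF_LEVELS:
                rows.append({
                    "block": block,
                    "plot_id": plot_id,
                    "treatment": treatment,
                    "subplot_id": f"{plot_id}-{ROOF_SUFFIX[roof]}",
                    "roof": roof,
                })
    return pd.DataFrame(rows)


def generate_traits(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Trait table with three syndromes plus the generating group labels."""
    rng = _rngs(config.seed, 4)[1]
    spread = {
        t: max(c[t] for c in SYNDROME_CENTERS.values())
        - min(c[t] for c in SYNDROME_CENTERS.values())
        for t in TRAIT_NAMES
    }
    rows, labels = [], {}
    for group in (1, 2, 3):
        centers = SYNDROME_CENTERS[group]
        for i in range(config.species_per_group):
            sp = f"sp_g{group}_{i:02d}"
            row = {"species_id": sp}
            for t in TRAIT_NAMES:
                sd = (config.trait_noise_frac * spread[t]
                      * config.syndrome_sd_scale.get((group, t), 1.0))
                val = centers[t] + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                if t in ORDINAL_BOUNDS:
                    lo, hi = ORDINAL_BOUNDS[t]
                    val = int(np.clip(round(val), lo, hi))
                else:
                    val = float(max(val, 0.01))
                row[t] = val
            rows.append(row)
            labels[sp] = group
    traits = pd.DataFrame(rows)
    return traits, pd.Series(labels, name="group")


def _zscore(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=0)
    return (s - s.mean()) / sd if sd > 0 else s * 0.0


def generate_observations(layout: pd.DataFrame, traits: pd.DataFrame,
                          labels: pd.Series, config: GeneratorConfig
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                                     pd.DataFrame]:
    """Cover surveys, soil-function panel, stability pairs and predictors."""
    rng = _rngs(config.seed, 4)[2]
    species_of_group = {g: sorted(labels.index[labels == g]) for g in (1, 2, 3)}

    # --- percent cover: one composition per subplot, stable across months
    subplots = layout.drop_duplicates("subplot_id").sort_values("subplot_id")
    sub_chunks, sp_chunks, cov_chunks = [], [], []
    for _, sub in subplots.iterrows():
        groups = [int(t[2]) for t in sub["treatment"].split("+")]
        pool = [sp for g in groups for sp in species_of_group[g]]
        w = rng.dirichlet(np.full(len(pool), config.cover_concentration))
        sub_chunks.append(np.repeat(sub["subplot_id"], len(pool)))
        sp_chunks.append(np.asarray(pool))
        cov_chunks.append(w * config.total_cover_pct)
    one_month = pd.DataFrame({
        "subplot_id": np.concatenate(sub_chunks),
        "species_id": np.concatenate(sp_chunks),
        "cover_pct": np.concatenate(cov_chunks),
    })
    survey = pd.concat(
        [one_month.assign(survey_month=m) for m in MONTHS], ignore_index=True
    )[["subplot_id", "survey_month", "species_id", "cover_pct"]]

    # --- standardized community trait summaries (composition is stable, so
    #     compute once on the May survey and reuse across months)
    summary = community_summary(survey[survey["survey_month"] == "May"], traits)
    wide = summary.pivot(index="subplot_id", columns="trait_name")
    predictors = pd.DataFrame(index=wide.index)
    for trait in TRAIT_NAMES:
        predictors[f"cwm_{trait}"] = _zscore(wide[("cwm", trait)])
        predictors[f"fdvar_{trait}"] = _zscore(wide[("fdvar", trait)])
    predictors = predictors.sort_index()

    # --- random intercepts
    blocks = sorted(layout["block"].unique())
    plots = sorted(layout["plot_id"].unique())
    b_re = dict(zip(blocks, rng.normal(0.0, config.block_sd, len(blocks))
                    if config.block_sd > 0 else np.zeros(len(blocks))))
    p_re = dict(zip(plots, rng.normal(0.0, config.plot_sd, len(plots))
                    if config.plot_sd > 0 else np.zeros(len(plots))))

    sub_ids = predictors.index.to_numpy()
    n = len(sub_ids)
    meta = subplots.set_index("subplot_id").loc[sub_ids]
    damping = np.exp(-config.resistance_link
                     * predictors["fdvar_root_depth"].to_numpy())
    re = (np.array([b_re[b] for b in meta["block"]])
          + np.array([p_re[p] for p in meta["plot_id"]]))
    is_drought = (meta["roof"] == "drought").to_numpy()

    # per-function trait effects, shared across months
    effects = {fn: np.zeros(n) for fn in FUNCTIONS}
    for fn, bmap in config.betas.items():
        for (kind, trait), beta in bmap.items():
            effects[fn] = effects[fn] + beta * predictors[
                f"{kind}_{trait}"].to_numpy()

    frames = []
    for month in MONTHS:
        if config.noise_sd > 0:
            noise = rng.normal(0.0, config.noise_sd, (n, len(FUNCTIONS) + 1))
        else:
            noise = np.zeros((n, len(FUNCTIONS) + 1))
        drought_shift = config.drought_effect.get(month, 0.0)
        for j, fn in enumerate(FUNCTIONS):
            val = (config.function_intercept + config.month_effects[month]
                   + effects[fn] + re + noise[:, j])
            if drought_shift:
                val = val + drought_shift * damping * is_drought
            frames.append(pd.DataFrame({
                "subplot_id": sub_ids, "time_point": month,
                "function_name": fn, "value": val}))
        # soil moisture: multiplicative drought reduction under shelters
        smc = config.smc_base[month] + re + noise[:, -1]
        mult = np.ones(n)
        if month == "July":
            mult[is_drought] = 1.0 - config.drought_smc_fraction
        elif month == "September":
            mult[is_drought] = 1.0 - 0.3 * config.drought_smc_fraction
        frames.append(pd.DataFrame({
            "subplot_id": sub_ids, "time_point": month,
            "function_name": "soil_moisture", "value": smc * mult}))
    panel = pd.concat(frames, ignore_index=True)

    # --- paired control/drought values per plot for the stability indices
    keyed = panel.merge(layout[["subplot_id", "plot_id", "roof"]],
                        on="subplot_id")
    wide_p = keyed.pivot_table(index=["plot_id", "function_name"],
                               columns=["roof", "time_point"], values="value",
                               aggfunc="first")
    pairs = pd.DataFrame({
        "control_july": wide_p[("unroofed_control", "July")],
        "drought_july": wide_p[("drought", "July")],
        "control_september": wide_p[("unroofed_control", "September")],
        "drought_september": wide_p[("drought", "September")],
    }).reset_index().sort_values(["plot_id", "function_name"]
                                 ).reset_index(drop=True)
    pairs = pairs[["plot_id", "function_name", "control_july", "drought_july",
                   "control_september", "drought_september"]]
    return survey, panel, pairs, predictors


def simulate_experiment(config: GeneratorConfig | None = None,
                        seed: int | None = None) -> SimulatedExperiment:
    """Run the full generator; same seed gives byte-identical outputs."""
    cfg = config if config is not None else GeneratorConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    layout = build_design(cfg)
    traits, labels = generate_traits(cfg)
    survey, panel, pairs, predictors = generate_observations(layout, traits,
                                                             labels, cfg)
    return SimulatedExperiment(config=cfg, traits=traits, true_groups=labels,
                               layout=layout, survey=survey, panel=panel,
                               pairs=pairs, predictors=predictors)


def generate_rainfall(seed: int = 1, years: range = range(2004, 2014),
                      wet_prob: float = 0.45, mean_wet_mm: float = 4.0
                      ) -> pd.DataFrame:
    """Synthetic daily rainfall series for exercising the drought design.

    A simple independent wet/dry day model over whole calendar years; it is
    a stand-in for a real station record, not a calibrated climate model.
    """
    rng = np.random.default_rng(seed)
    dates = pd.date_range(f"{years.start}-01-01", f"{years.stop - 1}-12-31",
                          freq="D")
    wet = rng.random(len(dates)) < wet_prob
    amounts = np.where(wet, rng.exponential(mean_wet_mm, len(dates)), 0.0)
    return pd.DataFrame({"date": dates, "rain_mm": amounts})
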