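"""Trait-based functional group assembly.

Species are classified into k functional groups from a six-trait database
table (canopy height, perenniality, specific leaf area, root architectural
class, rooting depth class, mycorrhizal affinity) by hierarchical clustering
on standardized traits, and the classification is verified by linear
discriminant analysis (LDA).  One-way ANOVA contrasts of single traits
between groups characterise the resulting trait syndromes.

Continuous traits are z-scored; ordinal traits enter as their numeric codes
and are z-scored the same way, so that Ward's criterion operates in a
Euclidean trait space.  Group labels are renumbered by descending group size
(ties broken by the lexicographically smallest member species id), which
makes partitions comparable across runs and row orders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

logger = logging.getLogger(__name__)

#: trait name -> (scale type, (lower, upper) bounds for ordinals or None)
TRAIT_SCHEMA: dict[str, tuple[str, tuple[int, int] | None]] = {
    "height": ("continuous", None),
    "perenniality": ("ordinal", (1, 5)),
    "sla": ("continuous", None),
    "root_architecture": ("ordinal", (1, 8)),
    "root_depth": ("ordinal", (1, 3)),
    "mycorrhizal_affinity": ("ordinal", (1, 3)),
}

TRAIT_NAMES = list(TRAIT_SCHEMA)

#: a trait with more than this fraction of missing values cannot be imputed
MAX_MISSING_FRACTION = 0.30


@dataclass
class GroupAssignment:
    """Species-to-group mapping, optionally with the LDA verification."""

    table: pd.DataFrame  # columns: species_id, group [, lda_predicted_group]
    k: int
    agreement_pct: float | None = None
    method: str = "ward"

    @property
    def groups(self) -> pd.Series:
        return self.table.set_index("species_id")["group"]

    def group_sizes(self) -> dict[int, int]:
        return self.table["group"].value_counts().sort_index().to_dict()


def validate_trait_table(traits: pd.DataFrame) -> pd.DataFrame:
    """Check structural invariants of a species x trait table.

    Raises ``ValueError`` on duplicate species ids, out-of-bounds ordinal
    codes or non-positive continuous traits.  Missing values are allowed
    here and handled by :func:`standardize_traits`.
    """
    missing_cols = [c for c in ["species_id", *TRAIT_NAMES] if c not in traits.columns]
    if missing_cols:
        raise ValueError(f"trait table missing columns: {missing_cols}")
    if traits["species_id"].duplicated().any():
        dups = traits.loc[traits["species_id"].duplicated(), "species_id"].tolist()
        raise ValueError(f"duplicate species_id: {dups}")
    for name, (scale, bounds) in TRAIT_SCHEMA.items():
        col = pd.to_numeric(traits[name], errors="coerce")
        observed = col.dropna()
        if scale == "continuous" and (observed <= 0).any():
            raise ValueError(f"continuous trait {name!r} must be strictly positive")
        if scale == "ordinal" and bounds is not None:
            lo, hi = bounds
            if ((observed < lo) | (observed > hi)).any():
                raise ValueError(f"ordinal trait {name!r} outside bounds {bounds}")
    return traits


def standardize_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Return the z-scored trait matrix indexed by species_id.

    Missing values are imputed by the across-species median of the trait
    (logged); a trait missing for more than 30% of species is an error.
    Rows are sorted by species_id so every downstream computation is
    independent of input row order.
    """
    validate_trait_table(traits)
    mat = (
        traits.set_index("species_id")[TRAIT_NAMES]
        .apply(pd.to_numeric, errors="coerce")
        .sort_index()
    )
    for name in TRAIT_NAMES:
        frac = mat[name].isna().mean()
        if frac > MAX_MISSING_FRACTION:
            raise ValueError(
                f"trait {name!r} is missing for {frac:.0%} of species "
                f"(> {MAX_MISSING_FRACTION:.0%}); cannot impute"
            )
        if frac > 0:
            med = mat[name].median()
            logger.info("imputing %d missing %s values with median %.4g",
                        mat[name].isna().sum(), name, med)
            mat[name] = mat[name].fillna(med)
    sd = mat.std(ddof=0)
    sd = sd.where(sd > 0, 1.0)  # constant trait carries no information
    return (mat - mat.mean()) / sd


def _relabel_by_size(species: pd.Index, raw_labels: np.ndarray) -> pd.Series:
    """Renumber cluster labels 1..k by descending size, ties by smallest member."""
    labels = pd.Series(raw_labels, index=species)
    order = sorted(
        labels.unique(),
        key=lambda lab: (-(labels == lab).sum(), min(labels.index[labels == lab])),
    )
    mapping = {lab: i + 1 for i, lab in enumerate(order)}
    return labels.map(mapping)


def _diana_labels(X: np.ndarray, k: int) -> np.ndarray:
    """Divisive (DIANA-style) hierarchical clustering into k clusters.

    Repeatedly splits the cluster with the largest diameter by seeding a
    splinter group with the most dissimilar member and migrating points
    that sit closer (on average) to the splinter than to the remainder.
    """
    n = X.shape[0]
    d = squareform(pdist(X))
    clusters: list[list[int]] = [list(range(n))]
    while len(clusters) < k:
        diam = [d[np.ix_(c, c)].max() if len(c) > 1 else 0.0 for c in clusters]
        target = int(np.argmax(diam))
        c = clusters.pop(target)
        sub = d[np.ix_(c, c)]
        seed = int(np.argmax(sub.mean(axis=1)))
        splinter, remainder = [c[seed]], [m for i, m in enumerate(c) if i != seed]
        moved = True
        while moved and len(remainder) > 1:
            moved = False
            gains = []
            for m in remainder:
                to_rest = np.mean([d[m, r] for r in remainder if r != m])
                to_split = np.mean([d[m, s] for s in splinter])
                gains.append(to_rest - to_split)
            best = int(np.argmax(gains))
            if gains[best] > 0:
                splinter.append(remainder.pop(best))
                moved = True
        clusters.extend([splinter, remainder])
    labels = np.empty(n, dtype=int)
    for i, c in enumerate(clusters):
        labels[c] = i
    return labels


def cluster_species(traits: pd.DataFrame, k: int, method: str = "ward",
                    seed: int = 1) -> GroupAssignment:
    """Partition species into ``k`` trait-based functional groups.

    Parameters
    ----------
    traits
        Species x trait table (see :data:`TRAIT_SCHEMA`).
    k
        Number of groups (the field protocol uses k=3).
    method
        ``"ward"`` (default): agglomerative clustering with Ward linkage on
        the standardized trait matrix.  ``"diana"``: divisive alternative.
    seed
        Accepted for interface uniformity; both linkage methods are
        deterministic on the sorted trait matrix.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    Z = standardize_traits(traits)
    n = len(Z)
    if n < k:
        raise ValueError(f"insufficient species: {n} < k={k}")
    if k == 1:
        labels = pd.Series(1, index=Z.index)
        table = labels.rename("group").reset_index()
        return GroupAssignment(table=table, k=1, method=method)
    if (Z.nunique() <= 1).all():
        raise ValueError("degenerate trait matrix: all trait rows identical")
    X = Z.to_numpy()
    if method == "ward":
        raw = fcluster(linkage(X, method="ward"), t=k, criterion="maxclust")
    elif method == "diana":
        raw = _diana_labels(X, k)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    labels = _relabel_by_size(Z.index, raw)
    table = labels.rename("group").reset_index().rename(columns={"index": "species_id"})
    table.columns = ["species_id", "group"]
    return GroupAssignment(table=table, k=k, method=method)


def verify_lda(traits: pd.DataFrame, assignment: GroupAssignment,
               cross_validate: bool = False) -> GroupAssignment:
    """Verify a cluster assignment with linear discriminant analysis.

    The LDA is fitted on the same standardized trait matrix used for
    clustering, with the cluster labels as the response; the resubstitution
    (or, optionally, leave-one-out) predictions are compared with the
    cluster labels and the percent agreement reported.
    """
    Z = standardize_traits(traits)
    groups = assignment.groups.reindex(Z.index)
    if groups.isna().any():
        raise ValueError("assignment does not cover all species in the trait table")
    if assignment.k < 2:
        raise ValueError("LDA verification requires k >= 2 groups")
    sizes = groups.value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"group too small for LDA: {small}")
    X, y = Z.to_numpy(), groups.to_numpy(dtype=int)
    # lsqr solves the discriminant via least squares, which stays stable when
    # an ordinal trait is constant within a group (singular within-class cov)
    make = lambda: LinearDiscriminantAnalysis(solver="lsqr")
    if cross_validate:
        pred = np.empty_like(y)
        for i in range(len(y)):
            mask = np.arange(len(y)) != i
            pred[i] = make().fit(X[mask], y[mask]).predict(X[i:i + 1])[0]
    else:
        pred = make().fit(X, y).predict(X)
    agreement = 100.0 * float(np.mean(pred == y))
    table = pd.DataFrame({
        "species_id": Z.index,
        "group": y,
        "lda_predicted_group": pred,
    })
    return GroupAssignment(table=table, k=assignment.k,
                           agreement_pct=agreement, method=assignment.method)


@dataclass
class AnovaSummary:
    trait_name: str
    f_statistic: float
    df1: int
    df2: int
    p_value: float


def group_trait_contrast(traits: pd.DataFrame, assignment: GroupAssignment,
                         trait_name: str) -> AnovaSummary:
    """One-way ANOVA of a single trait between functional groups.

    The trait values of each species are the response; the group label is
    the factor.  Degrees of freedom are (k-1, n-k).
    """
    if trait_name not in TRAIT_SCHEMA:
        raise ValueError(f"unknown trait {trait_name!r}")
    validate_trait_table(traits)
    values = pd.to_numeric(
        traits.set_index("species_id")[trait_name], errors="coerce"
    ).dropna()
    groups = assignment.groups.reindex(values.index).dropna()
    values = values.loc[groups.index]
    samples = [values[groups == g].to_numpy() for g in sorted(groups.unique())]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 members each")
    if all(np.ptp(s) == 0 for s in samples):
        means = {float(s[0]) for s in samples}
        if len(means) > 1:
            raise ValueError("no residual variance: groups are internally constant")
        # identical constant everywhere: no between- or within-group variance
        raise ValueError("no residual variance")
    k, n = len(samples), len(values)
    f_stat, p = f_oneway(*samples)
    return AnovaSummary(trait_name=trait_name, f_statistic=float(f_stat),
                        df1=k - 1, df2=n - k, p_value=float(p))
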