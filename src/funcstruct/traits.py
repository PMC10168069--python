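"""Trait derivation, species-level aggregation, pruning, and standardization.

Per-leaf measurements yield seven continuous traits: leaf thickness (LT, mm),
plant height (PH, mm), leaf shape (LS = length/width), leaf area (LA, mm2),
leaf perimeter (LP, mm), specific leaf area (SLA = area/dry mass, mm2/mg) and
leaf dry matter content (LDMC = dry mass/water-saturated mass, mg/mg). Highly
inter-correlated traits (|Pearson r| above 0.70 — in the study system this
removes LP) are pruned before analysis, and the survivors are centered and
scaled over the whole species pool.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import TraitTable

log = logging.getLogger(__name__)

LEAF_COLUMNS = (
    "species",
    "plot",
    "leaf_index",
    "saturated_mass_mg",
    "dry_mass_mg",
    "area_mm2",
    "perimeter_mm",
    "length_mm",
    "width_mm",
    "thickness_mm",
    "plant_height_mm",
)

DERIVED_TRAITS = ("LT", "PH", "LS", "LA", "LP", "SLA", "LDMC")


def derive_leaf_traits(records: pd.DataFrame) -> pd.DataFrame:
    """Per-leaf trait values from raw leaf measurements.

    SLA = area / dry mass; LDMC = dry mass / saturated mass; LS = length /
    width; LT, PH, LA, LP pass through. Records with a non-positive dry mass,
    saturated mass, or width cannot yield the ratios and are rejected with a
    logged reason; a dry mass exceeding the saturated mass is physically
    impossible and rejected likewise.
    """
    df = pd.DataFrame(records)
    missing = [c for c in LEAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"leaf records lack columns: {missing}")

    reasons = pd.Series("", index=df.index, dtype=object)
    reasons[df["dry_mass_mg"] <= 0] = "non-positive dry mass"
    reasons[df["saturated_mass_mg"] <= 0] = "non-positive saturated mass"
    reasons[df["width_mm"] <= 0] = "non-positive width"
    ok_mass = (df["dry_mass_mg"] > 0) & (df["saturated_mass_mg"] > 0)
    reasons[ok_mass & (df["dry_mass_mg"] > df["saturated_mass_mg"])] = (
        "dry mass exceeds saturated mass"
    )
    bad = reasons != ""
    for idx, reason in reasons[bad].items():
        log.warning(
            "rejecting leaf record %s (species=%s plot=%s): %s",
            idx, df.at[idx, "species"], df.at[idx, "plot"], reason,
        )
    df = df[~bad]

    out = pd.DataFrame(
        {
            "species": df["species"].astype(str),
            "plot": df["plot"].astype(str),
            "LT": df["thickness_mm"].astype(float),
            "PH": df["plant_height_mm"].astype(float),
            "LS": df["length_mm"].astype(float) / df["width_mm"].astype(float),
            "LA": df["area_mm2"].astype(float),
            "LP": df["perimeter_mm"].astype(float),
            "SLA": df["area_mm2"].astype(float) / df["dry_mass_mg"].astype(float),
            "LDMC": df["dry_mass_mg"].astype(float) / df["saturated_mass_mg"].astype(float),
        }
    )
    return out.reset_index(drop=True)


def aggregate_species_traits(leaf_traits: pd.DataFrame, level: str = "species"):
    """Average per-leaf traits to species x plot means, then (optionally) to
    species level as the unweighted mean of the species' plot means.

    Returns a :class:`TraitTable` at ``level='species'``; at
    ``level='species_plot'`` returns a DataFrame indexed by (species, plot)
    for descriptive use.
    """
    traits = [t for t in DERIVED_TRAITS if t in leaf_traits.columns]
    if not traits:
        raise ValueError("no trait columns found in leaf trait records")
    by_plot = leaf_traits.groupby(["species", "plot"], sort=True)[traits].mean()
    if level == "species_plot":
        return by_plot
    if level != "species":
        raise ValueError(f"unknown aggregation level {level!r}")
    species_means = by_plot.groupby(level="species", sort=True).mean()
    return TraitTable(species_means, standardized=False)


def iterative_correlation_prune(
    df: pd.DataFrame, threshold: float = 0.70
) -> tuple[list[str], list[tuple[str, str]]]:
    """Iteratively drop one column of every pair with |Pearson r| > threshold.

    Of an offending pair, the member with the larger mean absolute correlation
    to all remaining columns is removed. Constant columns (undefined
    correlation) are removed first. Returns (kept, [(dropped, reason), ...]).
    """
    kept = list(df.columns)
    dropped: list[tuple[str, str]] = []
    for col in list(kept):
        if df[col].nunique() <= 1:
            kept.remove(col)
            dropped.append((col, "constant column (undefined correlation)"))
            log.warning("dropping constant column %s before correlation pruning", col)
    while len(kept) >= 2:
        corr = df[kept].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        max_r = corr.to_numpy().max()
        if max_r <= threshold:
            break
        i, j = np.unravel_index(corr.to_numpy().argmax(), corr.shape)
        a, b = corr.columns[i], corr.columns[j]
        mean_r = corr.mean()
        victim = a if mean_r[a] >= mean_r[b] else b
        other = b if victim == a else a
        kept.remove(victim)
        dropped.append((victim, f"|r|={max_r:.3f} with {other}"))
    return kept, dropped


class CorrelationPruner(BaseEstimator, TransformerMixin):
    """Feature selector dropping one member of each over-correlated pair.

    Parameters
    ----------
    threshold : float, default 0.70
        Maximum tolerated absolute pairwise Pearson correlation.
    """

    def __init__(self, threshold: float = 0.70):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if X.shape[1] < 2 or X.shape[0] < 3:
            raise ValueError("correlation pruning needs >=2 columns and >=3 rows")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.kept_, self.dropped_ = iterative_correlation_prune(X, self.threshold)
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        return X[self.kept_]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.kept_, dtype=object)


class TraitStandardizer(BaseEstimator, TransformerMixin):
    """Center and scale columns to mean 0, SD 1 (sample SD, n-1 denominator).

    Unlike :class:`sklearn.preprocessing.StandardScaler` this uses the sample
    standard deviation, the convention of the R ``scale`` function, and fails
    loudly on constant columns instead of leaving them unscaled.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if X.shape[0] < 2:
            raise ValueError("standardization needs at least 2 rows")
        sd = X.std(ddof=self.ddof)
        constant = sd.index[(sd == 0) | ~np.isfinite(sd)].tolist()
        if constant:
            raise ValueError(f"cannot standardize constant trait(s): {constant}")
        self.mean_ = X.mean()
        self.scale_ = sd
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        return (X[self.mean_.index] - self.mean_) / self.scale_

    def inverse_transform(self, X):
        X = pd.DataFrame(X)
        return X * self.scale_ + self.mean_


def prune_correlated_traits(tt: TraitTable, threshold: float = 0.70) -> TraitTable:
    """Drop over-correlated traits (|r| > threshold) from a trait table."""
    pruner = CorrelationPruner(threshold=threshold).fit(tt.values)
    meta = dict(tt.meta)
    meta["pruned"] = list(pruner.dropped_)
    for victim, reason in pruner.dropped_:
        log.info("pruned trait %s: %s", victim, reason)
    return TraitTable(tt.values[pruner.kept_], tt.standardized, meta)


def standardize_traits(tt: TraitTable) -> TraitTable:
    """Center and scale every trait over the full species pool (sample SD)."""
    scaler = TraitStandardizer().fit(tt.values)
    meta = dict(tt.meta)
    meta["sd_convention"] = "sample (n-1)"
    return TraitTable(scaler.transform(tt.values), standardized=True, meta=meta)
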