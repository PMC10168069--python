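"""Core data containers for community, trait, and soil tables.

All containers wrap pandas objects and validate their ecological invariants on
construction. Identifiers (plot, site, species, trait, variable names) are
opaque strings matched exactly and case-sensitively.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: the seven continuous leaf/plant traits handled by the pipeline
KNOWN_TRAITS = ("LT", "PH", "LS", "LA", "LP", "SLA", "LDMC")

#: units per trait when raw (unstandardized)
TRAIT_UNITS = {
    "LT": "mm",
    "PH": "mm",
    "LS": "ratio",
    "LA": "mm2",
    "LP": "mm",
    "SLA": "mm2/mg",
    "LDMC": "mg/mg",
}


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated {what} identifiers: {dups}")


@dataclass
class CommunityMatrix:
    """Plot x species abundance (percent cover) with a plot -> site map.

    A species absent from a plot is stored as abundance 0; the cover data make
    no distinction between "not recorded" and "recorded as zero".
    """

    abundance: pd.DataFrame
    site_of: pd.Series

    def __post_init__(self) -> None:
        ab = self.abundance
        if not isinstance(ab, pd.DataFrame):
            raise TypeError("abundance must be a DataFrame (plots x species)")
        _check_unique(ab.index, "plot")
        _check_unique(ab.columns, "species")
        values = ab.to_numpy(dtype=float, copy=False)
        if not np.isfinite(values).all():
            raise ValueError("abundance contains non-finite values")
        if (values < 0).any():
            raise ValueError("abundance must be non-negative")
        self.abundance = ab.astype(float)
        site = pd.Series(self.site_of)
        missing = ab.index.difference(site.index)
        if len(missing):
            raise ValueError(f"plots without a site: {missing.tolist()}")
        self.site_of = site.reindex(ab.index).astype(str)

    # -- basic accessors -------------------------------------------------
    @property
    def plot_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def n_plots(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_species(self) -> int:
        return self.abundance.shape[1]

    def richness(self) -> pd.Series:
        """Species count per plot (number of positive-cover entries)."""
        return (self.abundance > 0).sum(axis=1)

    def presence(self) -> pd.DataFrame:
        return self.abundance > 0

    def with_abundance(self, values: np.ndarray) -> "CommunityMatrix":
        """Same plots/species/sites with a replaced abundance array."""
        ab = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=self.abundance.index,
            columns=self.abundance.columns,
        )
        return CommunityMatrix(ab, self.site_of.copy())

    def drop_unobserved_species(self) -> tuple["CommunityMatrix", list[str]]:
        """Remove all-zero species columns; returns (matrix, dropped names)."""
        observed = self.abundance.columns[(self.abundance > 0).any(axis=0)]
        dropped = [s for s in self.abundance.columns if s not in set(observed)]
        return CommunityMatrix(self.abundance[observed], self.site_of.copy()), dropped

    def equals(self, other: "CommunityMatrix", tol: float = 1e-12) -> bool:
        return (
            self.plot_ids == other.plot_ids
            and self.species_ids == other.species_ids
            and self.site_of.tolist() == other.site_of.tolist()
            and np.allclose(self.abundance.to_numpy(), other.abundance.to_numpy(), atol=tol, rtol=0)
        )


@dataclass
class TraitTable:
    """Species x trait values, raw (field units) or standardized (z-scores)."""

    values: pd.DataFrame
    standardized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.values
        if not isinstance(df, pd.DataFrame):
            raise TypeError("values must be a DataFrame (species x traits)")
        _check_unique(df.index, "species")
        _check_unique(df.columns, "trait")
        arr = df.to_numpy(dtype=float, copy=False)
        if np.isnan(arr).any():
            bad = df.index[np.isnan(arr).any(axis=1)].tolist()
            raise ValueError(f"missing trait values for species: {bad}")
        self.values = df.astype(float)
        if not self.standardized:
            self._check_raw_ranges()

    def _check_raw_ranges(self) -> None:
        for trait in ("LT", "PH", "LA", "LP", "SLA"):
            if trait in self.values.columns and (self.values[trait] <= 0).any():
                raise ValueError(f"raw trait {trait} must be strictly positive")
        if "LDMC" in self.values.columns:
            col = self.values["LDMC"]
            if ((col <= 0) | (col > 1)).any():
                raise ValueError("raw LDMC must lie in (0, 1]")

    @property
    def species_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, traits: list[str]) -> "TraitTable":
        missing = [t for t in traits if t not in self.values.columns]
        if missing:
            raise KeyError(f"traits not present: {missing}")
        return TraitTable(self.values[traits], self.standardized, dict(self.meta))

    def equals(self, other: "TraitTable", tol: float = 1e-12) -> bool:
        return (
            self.species_ids == other.species_ids
            and self.trait_names == other.trait_names
            and np.allclose(self.values.to_numpy(), other.values.to_numpy(), atol=tol, rtol=0)
        )


@dataclass
class SoilTable:
    """Plot x soil-variable table with per-variable unit labels."""

    values: pd.DataFrame
    units: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.values
        if not isinstance(df, pd.DataFrame):
            raise TypeError("values must be a DataFrame (plots x variables)")
        _check_unique(df.index, "plot")
        _check_unique(df.columns, "variable")
        self.values = df.astype(float)
        self.units = dict(self.units)
        # range checks only apply on the measurement scale, not after log
        def _is_log(v: str) -> bool:
            return "log" in str(self.units.get(v, "")).lower()

        if "pH" in df.columns and not _is_log("pH"):
            col = self.values["pH"]
            if ((col <= 0) | (col >= 14)).any():
                raise ValueError("pH must lie in (0, 14)")
        if "EC" in df.columns and not _is_log("EC"):
            if (self.values["EC"] < 0).any():
                raise ValueError("EC must be non-negative")

    @property
    def plot_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def variable_names(self) -> list[str]:
        return list(self.values.columns)

    def equals(self, other: "SoilTable", tol: float = 1e-12) -> bool:
        return (
            self.plot_ids == other.plot_ids
            and self.variable_names == other.variable_names
            and np.allclose(self.values.to_numpy(), other.values.to_numpy(), atol=tol, rtol=0)
        )


@dataclass
class ValidationReport:
    """Cross-table alignment report; empty missing lists mean analysis-ready."""

    missing_trait_species: list = field(default_factory=list)
    extra_trait_species: list = field(default_factory=list)
    missing_soil_plots: list = field(default_factory=list)
    extra_soil_plots: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @property
    def is_ready(self) -> bool:
        return not (self.missing_trait_species or self.missing_soil_plots)

    @property
    def n_issues(self) -> int:
        return (
            len(self.missing_trait_species)
            + len(self.extra_trait_species)
            + len(self.missing_soil_plots)
            + len(self.extra_soil_plots)
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class DistanceMatrix:
    """Symmetric species x species Gower distance matrix in [0, 1]."""

    species_ids: list
    values: np.ndarray
    trait_subset: tuple = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.species_ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match species list")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("Gower distances must lie in [0, 1]")
        self.values = v
        self.species_ids = list(self.species_ids)
        self.trait_subset = tuple(self.trait_subset)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species_ids, columns=self.species_ids)


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
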