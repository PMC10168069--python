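"""Readers and writers for the three delimited input tables.

Formats (CSV or TSV, UTF-8, header row required, ``#`` comment lines ignored):

* wide community layout — first column plot id, remaining columns species;
* long community layout — columns ``plot, site, species, cover``;
* trait layout — first column species, one column per trait;
* soil layout — first column plot, one column per variable.

Writers prepend a comment line carrying the pipeline version and RNG seed so
result tables are self-describing.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CommunityMatrix, SoilTable, TraitTable, ValidationReport

log = logging.getLogger(__name__)

LONG_COLUMNS = ("plot", "site", "species", "cover")


def _read_table(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep, comment="#", **kwargs)
    except Exception as exc:  # pragma: no cover - message path
        raise ValueError(f"could not parse {path}: {exc}") from exc
    return df


def _read_site_map(site_map) -> pd.Series:
    """Plot -> site map from a two-column file or an existing Series/dict."""
    if isinstance(site_map, pd.Series):
        return site_map.astype(str)
    if isinstance(site_map, dict):
        return pd.Series(site_map, dtype=str)
    df = _read_table(site_map)
    if df.shape[1] < 2:
        raise ValueError("site map file needs two columns: plot, site")
    return pd.Series(df.iloc[:, 1].astype(str).values, index=df.iloc[:, 0].astype(str))


def read_community(path, layout: str = "wide", site_map=None) -> CommunityMatrix:
    """Read a community (plot x species percent-cover) table.

    ``layout='long'`` expects plot/site/species/cover records and pivots them;
    duplicate (plot, species) records are an error, never summed. For the wide
    layout a ``site_map`` (file path, dict, or Series) is required unless the
    file itself carries a reserved ``site`` column.
    """
    if layout == "long":
        df = _read_table(path, dtype={0: str})
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"long layout requires columns {LONG_COLUMNS}, missing {missing}")
        df["plot"] = df["plot"].astype(str)
        df["species"] = df["species"].astype(str)
        dup = df.duplicated(subset=["plot", "species"])
        if dup.any():
            pairs = df.loc[dup, ["plot", "species"]].to_records(index=False).tolist()
            raise ValueError(f"duplicate (plot, species) records in long layout: {pairs}")
        cover = pd.to_numeric(df["cover"], errors="raise")
        wide = (
            df.assign(cover=cover)
            .pivot(index="plot", columns="species", values="cover")
            .fillna(0.0)
        )
        # preserve first-appearance order of plots and species
        wide = wide.loc[df["plot"].drop_duplicates(), df["species"].drop_duplicates()]
        sites = df.drop_duplicates("plot").set_index("plot")["site"].astype(str)
        return CommunityMatrix(wide, sites)
    if layout != "wide":
        raise ValueError(f"unknown layout {layout!r}; use 'wide' or 'long'")

    df = _read_table(path)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    sites = None
    if "site" in df.columns:
        sites = df.pop("site").astype(str)
    if site_map is not None:
        sites = _read_site_map(site_map)
    if sites is None:
        raise ValueError("wide layout needs a site map (file, dict, or 'site' column)")
    values = df.apply(pd.to_numeric, errors="raise")
    return CommunityMatrix(values, sites)


def read_traits(path, standardized: bool = False) -> TraitTable:
    df = _read_table(path)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return TraitTable(df.apply(pd.to_numeric, errors="raise"), standardized=standardized)


def read_soil(path, units: dict | None = None) -> SoilTable:
    df = _read_table(path)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return SoilTable(df.apply(pd.to_numeric, errors="raise"), units=units or {})


def read_dataset(
    community_path,
    trait_path,
    soil_path,
    site_map=None,
    layout: str = "wide",
) -> tuple[CommunityMatrix, TraitTable, SoilTable]:
    """Read and align the three tables.

    Soil rows are reordered to the community plot order and trait rows to the
    community species order (shared identifiers first); anything unmatched is
    kept at the end and surfaces in :func:`validate_dataset`.
    """
    cm = read_community(community_path, layout=layout, site_map=site_map)
    tt = read_traits(trait_path)
    st = read_soil(soil_path)

    trait_order = [s for s in cm.species_ids if s in set(tt.species_ids)]
    trait_order += [s for s in tt.species_ids if s not in set(cm.species_ids)]
    tt = TraitTable(tt.values.loc[trait_order], tt.standardized, dict(tt.meta))

    soil_order = [p for p in cm.plot_ids if p in set(st.plot_ids)]
    soil_order += [p for p in st.plot_ids if p not in set(cm.plot_ids)]
    st = SoilTable(st.values.loc[soil_order], dict(st.units))
    return cm, tt, st


def validate_dataset(cm: CommunityMatrix, tt: TraitTable, st: SoilTable) -> ValidationReport:
    """Report every cross-table misalignment; never mutates the inputs."""
    observed = set(np.asarray(cm.species_ids)[(cm.abundance.to_numpy() > 0).any(axis=0)])
    trait_species = set(tt.species_ids)
    soil_plots = set(st.plot_ids)
    plots = set(cm.plot_ids)

    report = ValidationReport(
        missing_trait_species=sorted(observed - trait_species),
        extra_trait_species=sorted(trait_species - set(cm.species_ids)),
        missing_soil_plots=sorted(plots - soil_plots),
        extra_soil_plots=sorted(soil_plots - plots),
        counts={
            "n_plots": cm.n_plots,
            "n_species": cm.n_species,
            "n_observed_species": len(observed),
            "n_trait_species": len(trait_species),
            "n_soil_plots": len(soil_plots),
        },
    )
    empty_plots = [p for p, r in cm.richness().items() if r == 0]
    if empty_plots:
        report.warnings.append(f"plots with no positive cover: {empty_plots}")
    return report


def dataset_summary(cm: CommunityMatrix) -> dict:
    """Descriptive summary of a community matrix.

    Mean cover is reported under two averaging units because the field
    convention is ambiguous: per species-record (mean of all positive cover
    values) and per plot (mean over plots of the plot's mean positive cover).
    """
    ab = cm.abundance.to_numpy()
    positive = ab > 0
    richness = positive.sum(axis=1)
    per_plot_mean = np.divide(
        ab.sum(axis=1), richness, out=np.full(len(richness), np.nan), where=richness > 0
    )
    return {
        "n_plots": cm.n_plots,
        "n_species_observed": int(positive.any(axis=0).sum()),
        "mean_richness": float(richness.mean()),
        "mean_cover_per_record": float(ab[positive].mean()) if positive.any() else float("nan"),
        "mean_cover_per_plot": float(np.nanmean(per_plot_mean)),
    }


# ---------------------------------------------------------------------------
# writers


def _header_comment(seed=None) -> str:
    from . import __version__

    seed_part = f" seed={seed}" if seed is not None else ""
    return f"# funcstruct v{__version__}{seed_part}\n"


def write_table(df: pd.DataFrame, path, seed=None, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment(seed))
        df.to_csv(fh, index=index)


def write_community(cm: CommunityMatrix, path, site_path=None, seed=None) -> None:
    """Write the wide community layout; the site map goes to ``site_path``
    (defaults to ``<path stem>.sites.csv``)."""
    path = Path(path)
    df = cm.abundance.copy()
    df.index.name = "plot"
    write_table(df, path, seed=seed, index=True)
    if site_path is None:
        site_path = path.with_suffix(".sites.csv")
    sites = cm.site_of.rename("site").rename_axis("plot").reset_index()
    write_table(sites, site_path, seed=seed)


def write_traits(tt: TraitTable, path, seed=None) -> None:
    df = tt.values.copy()
    df.index.name = "species"
    write_table(df, path, seed=seed, index=True)


def write_soil(st: SoilTable, path, seed=None) -> None:
    df = st.values.copy()
    df.index.name = "plot"
    write_table(df, path, seed=seed, index=True)
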