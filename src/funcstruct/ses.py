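"""Plot filtering and standardized effect sizes against null ensembles.

For every (plot, trait, metric) the observed MPD or CWM is compared with its
distribution over randomized communities:

    SES = (Obs - mean_null) / SD_null

with the sample-SD (n-1) convention and the observed value excluded from the
null distribution. Trait values stay fixed to species throughout — only the
abundance matrix is randomized. SES values that cannot be computed (zero null
SD, undefined observed metric) are retained as explicit rows with a reason
code so downstream model fits can report exclusions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import CommunityMatrix, TraitTable
from .metrics import cwm_by_plot, gower_distance, mpd_by_plot
from .nullmodels import NullEnsemble, generate_null_ensemble

log = logging.getLogger(__name__)

SES_COLUMNS = (
    "plot",
    "site",
    "trait",
    "metric",
    "obs",
    "null_mean",
    "null_sd",
    "ses",
    "n_rep_effective",
    "reason",
)


def filter_plots(cm: CommunityMatrix, min_richness: int = 3) -> CommunityMatrix:
    """Keep plots holding at least ``min_richness`` species.

    The default of 3 retains plots with *more than two* species. Species never
    observed in a retained plot are dropped from the matrix (logged), so null
    randomizations draw only on the realized species pool.
    """
    richness = cm.richness()
    keep = richness[richness >= min_richness].index
    if len(keep) == 0:
        raise ValueError(
            f"no plot has >= {min_richness} species; lower min_richness or check the data"
        )
    n_dropped = cm.n_plots - len(keep)
    if n_dropped:
        log.info("filtered out %d of %d plots below richness %d", n_dropped, cm.n_plots, min_richness)
    filtered = CommunityMatrix(cm.abundance.loc[keep], cm.site_of.loc[keep])
    filtered, dropped_species = filtered.drop_unobserved_species()
    if dropped_species:
        log.info("dropped %d species unobserved in retained plots: %s", len(dropped_species), dropped_species)
    return filtered


def _species_distance(tt: TraitTable, traits, species_order) -> np.ndarray:
    dm = gower_distance(tt, traits)
    idx = [dm.species_ids.index(s) for s in species_order]
    return dm.values[np.ix_(idx, idx)]


def compute_ses(
    cm: CommunityMatrix,
    tt: TraitTable,
    ensemble: NullEnsemble,
    traits=None,
    metrics=("MPD", "CWM"),
    abundance_weighted: bool = False,
    include_combined: bool = False,
) -> pd.DataFrame:
    """Standardized effect sizes of MPD and/or CWM per plot and trait.

    The same ensemble serves every trait and both metrics; per-trait Gower
    distances and trait vectors are evaluated on the observed matrix and on
    every replicate. ``include_combined`` adds an all-traits Gower MPD row
    labelled with the joined trait names.
    """
    traits = list(traits) if traits is not None else tt.trait_names
    unknown = set(metrics) - {"MPD", "CWM"}
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    if not tt.standardized:
        log.warning("trait table is not standardized; SES is conventionally computed on z-scored traits")
    if ensemble.plot_ids != cm.plot_ids or ensemble.species_ids != cm.species_ids:
        raise ValueError("ensemble was generated from a different community matrix")
    missing = [s for s in cm.species_ids if s not in set(tt.species_ids)]
    if missing:
        raise ValueError(f"species without trait values: {missing}")

    A = cm.abundance.to_numpy()
    richness = (A > 0).sum(axis=1)
    tvals = tt.values.loc[cm.species_ids]
    n_rep = ensemble.n_rep

    # assemble the evaluation tasks: (label, metric, D or trait vector)
    tasks: list[tuple[str, str, object]] = []
    for trait in traits:
        if "MPD" in metrics:
            tasks.append((trait, "MPD", _species_distance(tt, [trait], cm.species_ids)))
        if "CWM" in metrics:
            tasks.append((trait, "CWM", tvals[trait].to_numpy()))
    if include_combined and "MPD" in metrics and len(traits) > 1:
        tasks.append(("+".join(traits), "MPD", _species_distance(tt, traits, cm.species_ids)))

    def evaluate(a: np.ndarray, metric: str, payload) -> np.ndarray:
        if metric == "MPD":
            return mpd_by_plot(a, payload, abundance_weighted=abundance_weighted)
        return cwm_by_plot(a, payload)

    obs = {(label, metric): evaluate(A, metric, payload) for label, metric, payload in tasks}
    nulls = {
        (label, metric): np.empty((n_rep, cm.n_plots)) for label, metric, _ in tasks
    }
    for r, rep in enumerate(ensemble.replicates):
        for label, metric, payload in tasks:
            nulls[(label, metric)][r] = evaluate(rep, metric, payload)

    rows = []
    for label, metric, _ in tasks:
        o = obs[(label, metric)]
        null = nulls[(label, metric)]
        with np.errstate(invalid="ignore"):
            null_mean = np.nanmean(null, axis=0)
            null_sd = np.nanstd(null, axis=0, ddof=1)
        n_eff = np.isfinite(null).sum(axis=0)
        for k, plot in enumerate(cm.plot_ids):
            reason = ""
            ses = np.nan
            if not np.isfinite(o[k]):
                reason = "undefined_obs" if richness[k] < 2 else "non_finite_obs"
            elif n_eff[k] < 2:
                reason = "too_few_null_values"
            elif null_sd[k] <= 1e-10 * max(1.0, abs(null_mean[k])):
                # a degenerate null distribution; SDs at float-epsilon scale
                # are summation-order noise, not real variation
                reason = "zero_null_sd"
            else:
                ses = (o[k] - null_mean[k]) / null_sd[k]
            rows.append(
                (
                    plot,
                    cm.site_of.iloc[k],
                    label,
                    metric,
                    o[k] if np.isfinite(o[k]) else np.nan,
                    null_mean[k] if n_eff[k] else np.nan,
                    null_sd[k] if n_eff[k] else np.nan,
                    ses,
                    int(n_eff[k]),
                    reason,
                )
            )
    return pd.DataFrame(rows, columns=list(SES_COLUMNS))


def null_model_comparison(
    cm: CommunityMatrix,
    tt: TraitTable,
    traits=None,
    algorithms=("independent_swap", "frequency", "richness"),
    n_rep: int = 999,
    seed: int | None = None,
    metrics=("MPD", "CWM"),
    abundance_weighted: bool = False,
) -> tuple[dict, pd.DataFrame]:
    """SES tables per algorithm plus their pairwise Pearson correlations.

    All algorithms share the same root seed policy, so listing an algorithm
    twice reproduces its SES table exactly. Correlations are computed over the
    (plot, trait, metric) cells finite in both tables.
    """
    algorithms = list(algorithms)
    tables = {}
    for i, algorithm in enumerate(algorithms):
        ensemble = generate_null_ensemble(cm, algorithm=algorithm, n_rep=n_rep, seed=seed)
        key = algorithm if algorithm not in tables else f"{algorithm}#{i}"
        tables[key] = compute_ses(
            cm, tt, ensemble, traits=traits, metrics=metrics,
            abundance_weighted=abundance_weighted,
        )
    keys = list(tables)
    corr = pd.DataFrame(np.eye(len(keys)), index=keys, columns=keys)
    for i, ki in enumerate(keys):
        si = tables[ki].set_index(["plot", "trait", "metric"])["ses"]
        for kj in keys[i + 1 :]:
            sj = tables[kj].set_index(["plot", "trait", "metric"])["ses"]
            both = pd.concat([si, sj], axis=1, keys=["a", "b"]).dropna()
            r = both["a"].corr(both["b"]) if len(both) > 2 else np.nan
            corr.loc[ki, kj] = corr.loc[kj, ki] = r
    return tables, corr
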