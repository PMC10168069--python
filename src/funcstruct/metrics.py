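"""Gower trait distances, mean pairwise distance (MPD) and community-weighted
mean (CWM) trait values.

For a single continuous trait the Gower distance between species i and j is
|t_i - t_j| / range, with the range taken over the global species pool so
distances are comparable across plots and null replicates; a multi-trait
distance is the unweighted mean of the per-trait distances. MPD is the mean of
the pairwise distances over all distinct species present in a plot (optionally
weighted by relative-abundance products), and CWM is the relative-cover
weighted mean trait value.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import CommunityMatrix, DistanceMatrix, TraitTable

log = logging.getLogger(__name__)


def gower_distance(tt: TraitTable, traits=None) -> DistanceMatrix:
    """Range-normalized (Gower) distance matrix over a trait subset.

    The normalizing range per trait is max - min over *all* species in the
    table (the global pool). A constant trait has zero range and no defined
    Gower distance, which is an error naming the trait.
    """
    traits = list(traits) if traits is not None else tt.trait_names
    if len(tt.species_ids) < 2:
        raise ValueError("Gower distance needs at least 2 species")
    values = tt.subset(traits).values.to_numpy()
    ranges = values.max(axis=0) - values.min(axis=0)
    constant = [t for t, r in zip(traits, ranges) if r == 0]
    if constant:
        raise ValueError(f"zero trait range (constant over pool): {constant}")
    scaled = values / ranges
    # mean over traits of |x_ik - x_jk| / range_k
    diff = np.abs(scaled[:, None, :] - scaled[None, :, :])
    return DistanceMatrix(tt.species_ids, diff.mean(axis=2), trait_subset=tuple(traits))


def _align_abundance(abundances, species_ids) -> np.ndarray:
    if isinstance(abundances, pd.Series):
        missing = [s for s in species_ids if s not in abundances.index]
        if missing:
            raise ValueError(f"abundance vector lacks species: {missing}")
        return abundances.reindex(species_ids).to_numpy(dtype=float)
    a = np.asarray(abundances, dtype=float)
    if a.shape != (len(species_ids),):
        raise ValueError("abundance vector does not match species list")
    return a


def mpd(abundances, dm: DistanceMatrix, abundance_weighted: bool = False) -> float:
    """Mean pairwise trait distance among species present in one plot.

    Unweighted (default): mean of d_ij over all unordered pairs of distinct
    present species. Weighted: sum over distinct pairs of p_i p_j d_ij divided
    by the summed pair weights, with p the relative abundances.
    """
    a = _align_abundance(abundances, dm.species_ids)
    present = a > 0
    n = int(present.sum())
    if n < 2:
        raise ValueError(f"MPD undefined: only {n} species present (need >= 2)")
    d = dm.values[np.ix_(present, present)]
    if not abundance_weighted:
        return float(d.sum() / (n * (n - 1)))
    p = a[present] / a[present].sum()
    pair_w = np.outer(p, p)
    np.fill_diagonal(pair_w, 0.0)
    return float((pair_w * d).sum() / pair_w.sum())


def cwm(abundances, trait_values) -> float:
    """Community-weighted mean: relative-abundance weighted mean trait value."""
    if isinstance(trait_values, pd.Series):
        species = list(trait_values.index)
        a = _align_abundance(abundances, species)
        t = trait_values.to_numpy(dtype=float)
    else:
        t = np.asarray(trait_values, dtype=float)
        a = np.asarray(abundances, dtype=float)
        if a.shape != t.shape:
            raise ValueError("abundance and trait vectors differ in length")
    total = a.sum()
    if total <= 0:
        raise ValueError("CWM undefined: total abundance is zero")
    if np.isnan(t[a > 0]).any():
        raise ValueError("missing trait values for present species")
    return float((a / total) @ t)


# ---------------------------------------------------------------------------
# vectorized kernels shared with the null-model SES machinery


def mpd_by_plot(A: np.ndarray, D: np.ndarray, abundance_weighted: bool = False) -> np.ndarray:
    """MPD for every row of a plot x species abundance array (NaN when n<2)."""
    if abundance_weighted:
        totals = A.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            W = np.where(totals > 0, A / np.where(totals == 0, 1.0, totals), 0.0)
        num = ((W @ D) * W).sum(axis=1)
        denom = 1.0 - (W**2).sum(axis=1)
    else:
        P = (A > 0).astype(float)
        n = P.sum(axis=1)
        num = ((P @ D) * P).sum(axis=1)
        denom = n * (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, num / np.where(denom == 0, 1.0, denom), np.nan)
    return out


def cwm_by_plot(A: np.ndarray, t: np.ndarray) -> np.ndarray:
    """CWM for every row of a plot x species abundance array (NaN when empty)."""
    totals = A.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(totals > 0, (A @ t) / np.where(totals == 0, 1.0, totals), np.nan)


def community_metrics(
    cm: CommunityMatrix,
    tt: TraitTable,
    traits=None,
    abundance_weighted: bool = False,
) -> pd.DataFrame:
    """Per-plot, per-trait MPD and CWM table.

    One CWM row per (plot, trait) and one MPD row per (plot, trait) for plots
    holding at least two species; plots below that have no defined MPD and the
    skip is logged rather than emitted as a zero.
    """
    traits = list(traits) if traits is not None else tt.trait_names
    missing = [s for s in cm.species_ids if s not in set(tt.species_ids)]
    if missing:
        raise ValueError(f"species without trait values: {missing}")
    tvals = tt.values.loc[cm.species_ids]
    A = cm.abundance.to_numpy()
    richness = (A > 0).sum(axis=1)

    rows = []
    for trait in traits:
        dm = gower_distance(tt, [trait])
        order = [dm.species_ids.index(s) for s in cm.species_ids]
        D = dm.values[np.ix_(order, order)]
        mpd_vals = mpd_by_plot(A, D, abundance_weighted=abundance_weighted)
        cwm_vals = cwm_by_plot(A, tvals[trait].to_numpy())
        for k, plot in enumerate(cm.plot_ids):
            site = cm.site_of.iloc[k]
            if richness[k] >= 2:
                rows.append((plot, site, trait, "MPD", mpd_vals[k], int(richness[k])))
            else:
                log.info("plot %s has %d species; MPD skipped", plot, richness[k])
            if richness[k] >= 1:
                rows.append((plot, site, trait, "CWM", cwm_vals[k], int(richness[k])))
            else:
                log.info("plot %s is empty; CWM skipped", plot)
    return pd.DataFrame(
        rows, columns=["plot", "site", "trait", "metric", "value", "n_species"]
    )
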