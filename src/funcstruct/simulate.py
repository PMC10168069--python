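"""Synthetic multi-site community / trait / soil datasets with known assembly.

The generator emulates the structure of a salt-marsh survey: sites holding a
few plots each, log-scale soil gradients that vary mostly between sites and
are collinear within a salinity block (Na, EC, Mg, K), a species pool whose
seven leaf traits are drawn with realistic inter-trait correlation (leaf
perimeter tracks leaf area strongly, so the correlation-pruning stage has the
expected victim), and plot communities assembled under one of three regimes:

``neutral``
    species drawn uniformly without replacement;
``filtering``
    species drawn with probability proportional to a Gaussian niche weight
    exp(-(z_s - mu_p)^2 * strength^2 / 2), where z_s is the species' latent
    (standardized) value of the coupled trait and the plot optimum mu_p is
    linear in the plot's standardized log value of the coupled soil variable;
``divergence``
    sequential draws penalizing trait similarity to already-chosen species (a
    greedy caricature of limiting similarity).

Positive covers are log-normal. ``filtering_strength = 0`` collapses both
non-neutral modes to neutral. Everything is reproducible bitwise from the
seed, and each dataset carries a truth record sufficient to re-generate it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CommunityMatrix, SoilTable, TraitTable

TRAIT_NAMES = ("LT", "PH", "LS", "LA", "LP", "SLA", "LDMC")

#: latent-scale correlations among traits in the species pool. LA-LP is set
#: high (0.85) because a leaf's perimeter scales tightly with its area; SLA
#: trades off against LDMC and thickness (succulent leaves are thick with low
#: dry matter content).
_TRAIT_CORR = {
    ("LT", "PH"): 0.10, ("LT", "LS"): -0.20, ("LT", "LA"): 0.00,
    ("LT", "LP"): -0.10, ("LT", "SLA"): -0.50, ("LT", "LDMC"): -0.35,
    ("PH", "LS"): 0.00, ("PH", "LA"): 0.30, ("PH", "LP"): 0.30,
    ("PH", "SLA"): -0.10, ("PH", "LDMC"): 0.20,
    ("LS", "LA"): 0.00, ("LS", "LP"): 0.40, ("LS", "SLA"): 0.10,
    ("LS", "LDMC"): 0.00,
    # 0.92 on the latent log scale yields ~0.85 on the field scale after the
    # lognormal transform's correlation attenuation
    ("LA", "LP"): 0.92, ("LA", "SLA"): 0.20, ("LA", "LDMC"): -0.10,
    ("LP", "SLA"): 0.20, ("LP", "LDMC"): -0.10,
    ("SLA", "LDMC"): -0.60,
}

#: (log-mean, log-sd) of each trait on its field scale; LDMC is mapped through
#: a logistic onto (0, 1) instead.
_TRAIT_SCALE = {
    "LT": (np.log(0.5), 0.5),
    "PH": (np.log(300.0), 0.7),
    "LS": (np.log(3.0), 0.6),
    "LA": (np.log(400.0), 1.0),
    "LP": (np.log(90.0), 0.7),
    "SLA": (np.log(12.0), 0.5),
    "LDMC": (-0.8, 0.5),
}

SOIL_VARIABLES = ("Na", "K", "Mg", "N", "EC", "pH", "OM", "As", "P", "Si")

#: log-scale medians per soil variable (mg/kg except EC dS/m, OM %, pH units)
_SOIL_MEDIAN = {
    "Na": 5000.0, "K": 800.0, "Mg": 1500.0, "N": 1000.0, "EC": 5.0,
    "pH": 7.8, "OM": 2.0, "As": 5.0, "P": 300.0, "Si": 200.0,
}

#: log-scale correlations: a collinear salinity block (Na, EC, Mg, K) plus a
#: fertility pair (N, OM), emulating the multicollinearity that motivates the
#: predictor screen.
_SOIL_CORR = {
    ("Na", "EC"): 0.90, ("Na", "Mg"): 0.70, ("Na", "K"): 0.60,
    ("K", "Mg"): 0.60, ("Mg", "EC"): 0.60, ("K", "EC"): 0.50,
    ("N", "OM"): 0.70, ("Na", "N"): 0.10, ("Na", "pH"): 0.20,
    ("P", "N"): 0.30,
}


def _corr_matrix(names, pairs) -> np.ndarray:
    """Assemble a valid correlation matrix, clipping eigenvalues if needed."""
    n = len(names)
    C = np.eye(n)
    idx = {name: i for i, name in enumerate(names)}
    for (a, b), r in pairs.items():
        C[idx[a], idx[b]] = C[idx[b], idx[a]] = r
    w, V = np.linalg.eigh(C)
    if w.min() < 1e-8:
        w = np.clip(w, 1e-8, None)
        C = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
    return C


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic dataset (the stated world of a run)."""

    n_sites: int = 16
    plots_per_site: int = 3
    n_plots_total: int | None = None  # overrides n_sites*plots_per_site, spread evenly
    n_species: int = 60
    trait_names: tuple = TRAIT_NAMES
    soil_variables: tuple = SOIL_VARIABLES
    soil_site_sd: float = 1.0  # between-site log-scale SD multiplier
    soil_plot_sd: float = 0.3  # within-site log-scale SD multiplier
    assembly_mode: str = "neutral"  # neutral | filtering | divergence
    filtering_strength: float = 0.0  # inverse niche width; 0 = neutral
    coupled_trait: str = "LT"
    coupled_soil: str = "Na"
    coupling_slope: float = 1.0  # optimum shift per SD of log coupled soil
    richness_min: int = 4
    richness_max: int = 12
    cover_meanlog: float = float(np.log(5.0))  # mean positive cover ~ 8.2 %
    cover_sdlog: float = 1.0
    seed: int | None = None

    def validate(self) -> None:
        if min(self.n_sites, self.n_species, self.richness_min) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_plots_total is None and self.plots_per_site < 1:
            raise ValueError("plots_per_site must be >= 1")
        if self.richness_max < self.richness_min:
            raise ValueError("richness_max must be >= richness_min")
        if self.richness_max > self.n_species:
            raise ValueError("richness_max cannot exceed the species pool size")
        if self.assembly_mode not in {"neutral", "filtering", "divergence"}:
            raise ValueError(f"unknown assembly mode {self.assembly_mode!r}")
        if self.filtering_strength < 0:
            raise ValueError("filtering_strength must be >= 0")
        if self.coupled_trait not in self.trait_names:
            raise ValueError("coupled_trait not in trait_names")
        if self.coupled_soil not in self.soil_variables:
            raise ValueError("coupled_soil not in soil_variables")


@dataclass
class SyntheticDataset:
    """Aligned community/trait/soil tables plus the generating truth record."""

    community: CommunityMatrix
    traits: TraitTable
    soil: SoilTable
    truth: dict = field(default_factory=dict)

    @property
    def site_of(self):
        return self.community.site_of


def _plot_layout(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    """(plot ids, site ids); total plots spread round-robin over sites."""
    sites = [f"S{i + 1:02d}" for i in range(config.n_sites)]
    total = config.n_plots_total or config.n_sites * config.plots_per_site
    plot_sites = [sites[i % config.n_sites] for i in range(total)]
    plot_sites.sort(key=sites.index)
    counters: dict[str, int] = {}
    plots = []
    for s in plot_sites:
        counters[s] = counters.get(s, 0) + 1
        plots.append(f"{s}P{counters[s]}")
    return plots, plot_sites


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset under the configured assembly regime."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    traits = list(config.trait_names)
    soil_vars = list(config.soil_variables)

    # --- species pool traits: correlated latent normals -> field scales
    Ct = _corr_matrix(traits, {k: v for k, v in _TRAIT_CORR.items()
                               if k[0] in traits and k[1] in traits})
    Lt = np.linalg.cholesky(Ct)
    latent = rng.standard_normal((config.n_species, len(traits))) @ Lt.T
    species = [f"sp{i + 1:03d}" for i in range(config.n_species)]
    trait_values = {}
    for k, name in enumerate(traits):
        mu, sd = _TRAIT_SCALE.get(name, (0.0, 1.0))
        z = latent[:, k]
        if name == "LDMC":
            trait_values[name] = 1.0 / (1.0 + np.exp(-(mu + sd * z)))
        else:
            trait_values[name] = np.exp(mu + sd * z)
    trait_table = TraitTable(pd.DataFrame(trait_values, index=species), standardized=False)

    # --- soil: correlated site- and plot-level normals on the log scale
    plots, plot_sites = _plot_layout(config)
    sites = sorted(set(plot_sites), key=plot_sites.index)
    Cs = _corr_matrix(soil_vars, {k: v for k, v in _SOIL_CORR.items()
                                  if k[0] in soil_vars and k[1] in soil_vars})
    Ls = np.linalg.cholesky(Cs)
    z_site = rng.standard_normal((len(sites), len(soil_vars))) @ Ls.T
    z_plot = rng.standard_normal((len(plots), len(soil_vars))) @ Ls.T
    site_idx = np.array([sites.index(s) for s in plot_sites])
    combined = config.soil_site_sd * z_site[site_idx] + config.soil_plot_sd * z_plot
    soil_values = {}
    units = {}
    for k, var in enumerate(soil_vars):
        med = _SOIL_MEDIAN.get(var, 100.0)
        if var == "pH":
            soil_values[var] = med + 0.3 * combined[:, k]
            units[var] = "pH"
        else:
            soil_values[var] = med * np.exp(combined[:, k])
            units[var] = "dS/m" if var == "EC" else ("%" if var == "OM" else "mg/kg")
    soil = SoilTable(pd.DataFrame(soil_values, index=plots), units)

    # --- community assembly
    coupled_log = np.log(soil.values[config.coupled_soil].to_numpy())
    zsoil = (coupled_log - coupled_log.mean()) / coupled_log.std(ddof=1)
    z_coupled = latent[:, traits.index(config.coupled_trait)]
    strength = config.filtering_strength

    abundance = np.zeros((len(plots), config.n_species))
    richness = rng.integers(config.richness_min, config.richness_max + 1, size=len(plots))
    for p in range(len(plots)):
        n = int(richness[p])
        if config.assembly_mode == "filtering" and strength > 0:
            mu_p = config.coupling_slope * zsoil[p]
            w = np.exp(-0.5 * (strength * (z_coupled - mu_p)) ** 2)
            w = np.maximum(w, 1e-300)
            chosen = rng.choice(config.n_species, size=n, replace=False, p=w / w.sum())
        elif config.assembly_mode == "divergence" and strength > 0:
            chosen = [int(rng.integers(config.n_species))]
            for _ in range(n - 1):
                # greedy limiting similarity over all latent traits
                d = np.min(
                    np.abs(latent[:, None, :] - latent[None, chosen, :]).mean(axis=2), axis=1
                )
                w = d**strength
                w[chosen] = 0.0
                if w.sum() == 0:  # pathological ties: fall back to uniform
                    w = np.ones(config.n_species)
                    w[chosen] = 0.0
                chosen.append(int(rng.choice(config.n_species, p=w / w.sum())))
            chosen = np.asarray(chosen)
        else:
            chosen = rng.choice(config.n_species, size=n, replace=False)
        covers = np.exp(rng.normal(config.cover_meanlog, config.cover_sdlog, size=n))
        abundance[p, chosen] = covers

    community = CommunityMatrix(
        pd.DataFrame(abundance, index=plots, columns=species),
        pd.Series(plot_sites, index=plots),
    )
    truth = {
        "config": dataclasses.asdict(config),
        "latent_coupled_trait": z_coupled.tolist(),
        "zsoil_coupled": zsoil.tolist(),
    }
    return SyntheticDataset(community, trait_table, soil, truth)


# ---------------------------------------------------------------------------
# named presets


def _tiny_dataset() -> SyntheticDataset:
    """Hand-checkable 4-plot x 6-species fixture.

    The expected MPD/CWM values in the truth record were produced by the
    independent brute-force script ``scripts/tiny_truth.py`` and frozen here;
    the analysis code never feeds them.
    """
    plots = ["P1", "P2", "P3", "P4"]
    species = [f"sp{i}" for i in range(1, 7)]
    abundance = pd.DataFrame(
        [
            [4.0, 2.0, 0.0, 0.0, 1.0, 0.0],
            [0.0, 3.0, 3.0, 0.0, 0.0, 2.0],
            [1.0, 0.0, 2.0, 4.0, 2.0, 1.0],
            [0.0, 0.0, 0.0, 5.0, 0.0, 5.0],
        ],
        index=plots,
        columns=species,
    )
    sites = pd.Series(["A", "A", "B", "B"], index=plots)
    traits = pd.DataFrame(
        {
            "LT": [0.2, 0.4, 0.6, 0.8, 1.0, 1.2],
            "SLA": [20.0, 16.0, 12.0, 10.0, 8.0, 6.0],
        },
        index=species,
    )
    soil = pd.DataFrame(
        {"Na": [1000.0, 2000.0, 4000.0, 8000.0], "K": [500.0, 400.0, 800.0, 600.0],
         "pH": [7.5, 7.8, 8.0, 8.2]},
        index=plots,
    )
    truth = {
        "expected": {
            # frozen output of scripts/tiny_truth.py (brute-force, raw traits)
            "MPD": {
                "LT": {"P1": 0.5333333333333333, "P2": 0.5333333333333333,
                       "P3": 0.4800000000000001, "P4": 0.3999999999999999},
                "SLA": {"P1": 0.5714285714285713, "P2": 0.4761904761904761,
                        "P3": 0.4571428571428573, "P4": 0.2857142857142857},
            },
            "CWM": {
                "LT": {"P1": 0.37142857142857144, "P2": 0.675, "P3": 0.78, "P4": 1.0},
                "SLA": {"P1": 17.142857142857142, "P2": 12.0, "P3": 10.6, "P4": 8.0},
            },
        }
    }
    return SyntheticDataset(
        CommunityMatrix(abundance, sites),
        TraitTable(traits, standardized=False),
        SoilTable(soil, {"Na": "mg/kg", "K": "mg/kg", "pH": "pH"}),
        truth,
    )


PRESETS = {
    "tiny": None,  # hand-coded, see _tiny_dataset
    "neutral_calibration": SyntheticConfig(
        n_sites=16, n_plots_total=60, n_species=60,
        richness_min=4, richness_max=12, assembly_mode="neutral", seed=101,
    ),
    "filtering_recovery": SyntheticConfig(
        n_sites=16, plots_per_site=3, n_species=60,
        richness_min=4, richness_max=12, assembly_mode="filtering",
        filtering_strength=2.0, coupled_trait="LT", coupled_soil="Na",
        coupling_slope=1.0, seed=202,
    ),
    "divergence_demo": SyntheticConfig(
        n_sites=16, plots_per_site=3, n_species=60,
        richness_min=4, richness_max=12, assembly_mode="divergence",
        filtering_strength=2.0, seed=303,
    ),
}


def make_fixture(name: str, seed: int | None = None) -> SyntheticDataset:
    """Deterministic named preset used by the test suite and the docs.

    ``seed`` overrides the preset default (ignored by ``tiny``, which is
    hand-coded, not drawn).
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    if name == "tiny":
        return _tiny_dataset()
    config = dataclasses.replace(PRESETS[name])
    if seed is not None:
        config.seed = seed
    return generate_dataset(config)
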