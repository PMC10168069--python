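"""Community randomization algorithms for null-model inference.

Three algorithms are offered:

``independent_swap``
    Repeated checkerboard swaps: two plots and two species whose 2x2 abundance
    submatrix holds exactly two positive cells on a diagonal have those values
    exchanged across columns within their rows. Every plot's species richness
    and every species' occurrence frequency are preserved exactly; because the
    positive cover values travel with their rows, each plot also keeps its
    total cover and its multiset of cover values.
``frequency``
    Each species' abundance vector is permuted independently across plots,
    preserving species occurrence frequencies but destroying plot richness.
``richness``
    Each plot's abundance vector is permuted independently across species,
    preserving plot richness but destroying species frequencies.

Reproducibility contract: replicate ``r`` of an ensemble draws from a
dedicated generator seeded by ``(seed, r)``, so ensembles are identical
whether replicates are evaluated serially or in parallel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .datatypes import CommunityMatrix

log = logging.getLogger(__name__)

ALGORITHMS = ("independent_swap", "frequency", "richness")


def default_swap_effort(a: np.ndarray) -> int:
    """Attempted swaps per replicate: max(1000, 10 x positive cells)."""
    return max(1000, 10 * int((a > 0).sum()))


def _swap_core(a: np.ndarray, rng: np.random.Generator, n_attempts: int) -> tuple[np.ndarray, int]:
    """Attempt ``n_attempts`` checkerboard swaps on a copy of ``a``."""
    a = a.copy()
    n_plots, n_species = a.shape
    rows = rng.integers(0, n_plots, size=(2, n_attempts))
    cols = rng.integers(0, n_species, size=(2, n_attempts))
    ii, jj = rows[0].tolist(), rows[1].tolist()
    cc, dd = cols[0].tolist(), cols[1].tolist()
    swapped = 0
    for k in range(n_attempts):
        i = ii[k]
        j = jj[k]
        if i == j:
            continue
        c = cc[k]
        d = dd[k]
        if c == d:
            continue
        w = a[i, c]
        z = a[j, d]
        if w > 0 and z > 0:
            if a[i, d] == 0 and a[j, c] == 0:
                a[i, c] = 0.0
                a[i, d] = w
                a[j, d] = 0.0
                a[j, c] = z
                swapped += 1
        else:
            x = a[i, d]
            y = a[j, c]
            if x > 0 and y > 0 and w == 0 and z == 0:
                a[i, d] = 0.0
                a[i, c] = x
                a[j, c] = 0.0
                a[j, d] = y
                swapped += 1
    return a, swapped


def has_checkerboard(a: np.ndarray) -> bool:
    """True if any 2x2 submatrix forms a swappable checkerboard."""
    pres = a > 0
    n_species = pres.shape[1]
    for c in range(n_species - 1):
        col = pres[:, c]
        rest = pres[:, c + 1 :]
        only_c = col[:, None] & ~rest
        only_d = ~col[:, None] & rest
        if (only_c.any(axis=0) & only_d.any(axis=0)).any():
            return True
    return False


def _randomize_array(
    a: np.ndarray, algorithm: str, rng: np.random.Generator, n_swaps=None
) -> np.ndarray:
    if algorithm == "independent_swap":
        attempts = n_swaps if n_swaps is not None else default_swap_effort(a)
        out, swapped = _swap_core(a, rng, attempts)
        if swapped == 0:
            if has_checkerboard(a):
                log.warning(
                    "independent_swap made no swap in %d attempts despite an "
                    "existing checkerboard; increase the swap effort",
                    attempts,
                )
            else:
                log.warning("matrix holds no checkerboard; returning it unchanged")
        return out
    if algorithm == "frequency":
        out = a.copy()
        for s in range(a.shape[1]):
            out[:, s] = out[rng.permutation(a.shape[0]), s]
        return out
    if algorithm == "richness":
        out = a.copy()
        for p in range(a.shape[0]):
            out[p, :] = out[p, rng.permutation(a.shape[1])]
        return out
    raise ValueError(f"unknown null-model algorithm {algorithm!r}; use one of {ALGORITHMS}")


def randomize_matrix(
    cm: CommunityMatrix,
    algorithm: str = "independent_swap",
    n_swaps: int | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> CommunityMatrix:
    """One randomized community under the chosen algorithm."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return cm.with_abundance(_randomize_array(cm.abundance.to_numpy(), algorithm, rng, n_swaps))


@dataclass
class NullEnsemble:
    """A reproducible set of randomized community matrices."""

    algorithm: str
    n_rep: int
    seed: int | None
    plot_ids: list
    species_ids: list
    site_of: object
    replicates: list = field(default_factory=list)
    n_swaps: int | None = None

    def matrices(self) -> Iterator[CommunityMatrix]:
        import pandas as pd

        for rep in self.replicates:
            yield CommunityMatrix(
                pd.DataFrame(rep, index=self.plot_ids, columns=self.species_ids),
                pd.Series(self.site_of, index=self.plot_ids),
            )


def replicate_rng(seed: int | None, r: int) -> np.random.Generator:
    """Deterministic per-replicate stream derived from (root seed, index)."""
    root = 0 if seed is None else int(seed)
    return np.random.default_rng([root & 0x7FFFFFFF, r])


def generate_null_ensemble(
    cm: CommunityMatrix,
    algorithm: str = "independent_swap",
    n_rep: int = 999,
    seed: int | None = None,
    n_swaps: int | None = None,
) -> NullEnsemble:
    """``n_rep`` independent randomizations of the observed matrix.

    Every independent-swap replicate restarts from the observed matrix with a
    fresh burn-in of attempted swaps, rather than thinning one long chain.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown null-model algorithm {algorithm!r}; use one of {ALGORITHMS}")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    a = cm.abundance.to_numpy()
    reps = [_randomize_array(a, algorithm, replicate_rng(seed, r), n_swaps) for r in range(n_rep)]
    return NullEnsemble(
        algorithm=algorithm,
        n_rep=n_rep,
        seed=seed,
        plot_ids=cm.plot_ids,
        species_ids=cm.species_ids,
        site_of=cm.site_of.to_numpy(),
        replicates=reps,
        n_swaps=n_swaps,
    )


def dump_ensemble(ensemble: NullEnsemble, outdir) -> None:
    """Write one CSV per replicate plus a JSON manifest."""
    import json
    from pathlib import Path

    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    width = len(str(ensemble.n_rep - 1))
    for r, rep in enumerate(ensemble.replicates):
        df = pd.DataFrame(rep, index=ensemble.plot_ids, columns=ensemble.species_ids)
        df.index.name = "plot"
        df.to_csv(outdir / f"replicate_{r:0{width}d}.csv")
    manifest = {
        "algorithm": ensemble.algorithm,
        "seed": ensemble.seed,
        "n_rep": ensemble.n_rep,
        "n_swaps": ensemble.n_swaps,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
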