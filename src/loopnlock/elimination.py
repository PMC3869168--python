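"""Residue-elimination analysis of the TCD <-> ln k_f correlation.

Residues are ranked per protein by hydrophobicity, connectivity, or
their product (both factors min-max scaled to [0, 1] per protein);
increasing percentages of the lowest-ranked residues are removed, every
contact touching a removed residue is dropped, and the correlation
between the remaining-contact TCD and ln k_f is recomputed.  Ties at the
removal boundary are resolved by averaging over random tie-breaking
draws.  A Monte Carlo envelope -- percentiles of r^2 under uniformly
random removals of the same per-protein counts -- says how much of the
correlation survives *because* of the ranking rather than the mere
contact count.  The chain length L in the TCD denominator is kept fixed
(subset-of-contacts semantics); removal changes the contact set only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import _r2_vector, _rates_frame
from .structure import ContactMap, ResidueProperties, minmax_scale

__all__ = ["EliminationCurve", "rank_and_remove", "elimination_curve",
           "PERCENTILES", "ranking_values"]

PERCENTILES = (1, 5, 50, 95, 99)


@dataclass
class EliminationCurve:
    property_name: str
    grid: np.ndarray                      # percent removed
    mean_r2: np.ndarray                   # ranked removal, mean over tie draws
    envelope: dict[int, np.ndarray]       # percentile -> r^2 per grid point

    def to_frame(self) -> pd.DataFrame:
        data = {"percent": self.grid, "mean_r2": self.mean_r2}
        for p in sorted(self.envelope):
            data[f"p{p}"] = self.envelope[p]
        return pd.DataFrame(data)


def ranking_values(properties: ResidueProperties, property: str) -> np.ndarray:
    """Per-residue ranking vector for a named property."""
    if property == "hydrophobicity":
        return np.asarray(properties.hydrophobicity, dtype=float)
    if property == "connectivity":
        return np.asarray(properties.connectivity, dtype=float)
    if property == "product":
        return (minmax_scale(properties.connectivity.astype(float))
                * minmax_scale(properties.hydrophobicity))
    raise ValueError(f"unknown ranking property {property!r}")


def rank_and_remove(values, percent: float, tie_reps: int = 1000,
                    rng=None) -> list[np.ndarray]:
    """Removed-residue index sets (1-based) for a ranked removal.

    Removes ``floor(percent * L / 100)`` lowest-valued residues.
    Residues strictly below the boundary value are always removed; when
    several residues tie at the boundary, ``tie_reps`` independent
    uniform draws decide which of them fill the remaining slots.  With
    no boundary tie a single deterministic set is returned.
    """
    if not (0 <= percent < 100):
        raise ValueError("percent must be in [0, 100)")
    values = np.asarray(values, dtype=float)
    L = len(values)
    m = int(np.floor(percent * L / 100))
    if m >= L:
        raise ValueError("removal would eliminate every residue")
    if m == 0:
        return [np.zeros(0, dtype=int)]
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    order = np.sort(values)
    boundary = order[m - 1]
    below = np.flatnonzero(values < boundary)
    ties = np.flatnonzero(values == boundary)
    need = m - len(below)
    if need == len(ties):
        return [np.sort(np.concatenate([below, ties])) + 1]
    sets = []
    for _ in range(tie_reps):
        pick = rng.choice(ties, size=need, replace=False)
        sets.append(np.sort(np.concatenate([below, pick])) + 1)
    return sets


def _removal_masks_ranked(values: np.ndarray, m: int, tie_reps: int,
                          rng: np.random.Generator) -> np.ndarray:
    """(n_sets, L) boolean removal masks for a ranked removal of m."""
    L = len(values)
    if m == 0:
        return np.zeros((1, L), dtype=bool)
    order = np.sort(values)
    boundary = order[m - 1]
    below = values < boundary
    ties = np.flatnonzero(values == boundary)
    need = m - int(below.sum())
    if need == len(ties):
        mask = below.copy()
        mask[ties] = True
        return mask[None]
    masks = np.repeat(below[None], tie_reps, axis=0)
    for r in range(tie_reps):
        masks[r, rng.choice(ties, size=need, replace=False)] = True
    return masks


def _random_masks(L: int, m: int, reps: int,
                  rng: np.random.Generator) -> np.ndarray:
    if m == 0:
        return np.zeros((reps, L), dtype=bool)
    masks = np.zeros((reps, L), dtype=bool)
    scores = rng.random((reps, L))
    idx = np.argpartition(scores, m - 1, axis=1)[:, :m]
    np.put_along_axis(masks, idx, True, axis=1)
    return masks


def _tcd_under_masks(masks: np.ndarray, pair_idx: np.ndarray,
                     seps: np.ndarray, L: int) -> np.ndarray:
    """(n_sets,) TCD after dropping contacts touching removed residues."""
    if len(seps) == 0:
        return np.zeros(masks.shape[0])
    kept = ~(masks[:, pair_idx[:, 0]] | masks[:, pair_idx[:, 1]])
    return kept @ seps.astype(float) / L ** 2


def elimination_curve(proteins: dict, rates, property: str = "hydrophobicity",
                      grid=range(0, 81), tie_reps: int = 50,
                      rand_reps: int = 1000, seed=None) -> EliminationCurve:
    """Ranked-removal r^2 curve with a random-removal percentile envelope.

    ``proteins`` maps protein_id -> (ContactMap, ResidueProperties).
    At each grid percentage the same fraction of residues is removed
    from every protein; ``tie_reps`` caps the tie-breaking draws for the
    ranked removal and ``rand_reps`` sets the Monte Carlo envelope size.
    Sub-streams are derived per (grid point, protein) from ``seed`` so
    curves are reproducible point by point.
    """
    grid = np.asarray(list(grid), dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted")
    if np.any(grid < 0) or np.any(grid >= 100):
        raise ValueError("grid percentages must lie in [0, 100)")
    ids = sorted(proteins)
    rf = _rates_frame(rates).drop_duplicates("protein_id").set_index("protein_id")
    ids = [p for p in ids if p in rf.index]
    if len(ids) < 3:
        raise ValueError("need >= 3 proteins matched to rates")
    y = rf.ln_kf.loc[ids].to_numpy(dtype=float)
    prep = {}
    for p in ids:
        cmap, props = proteins[p]
        arr = cmap.pair_array()
        prep[p] = (arr - 1, cmap.separations(), cmap.n_residues,
                   ranking_values(props, property))
    root = np.random.SeedSequence(seed)
    mean_r2 = np.empty(len(grid))
    env = {q: np.empty(len(grid)) for q in PERCENTILES}
    for gi, pct in enumerate(grid):
        ss_grid = np.random.SeedSequence(root.entropy, spawn_key=(gi,))
        children = ss_grid.spawn(len(ids))
        ranked_cols, rand_cols = [], []
        for ci, p in enumerate(ids):
            pair_idx, seps, L, vals = prep[p]
            m = int(np.floor(pct * L / 100))
            if m >= L:
                raise ValueError(f"{p}: removing {pct}% eliminates all residues")
            rng = np.random.default_rng(children[ci])
            rmask = _removal_masks_ranked(vals, m, tie_reps, rng)
            ranked_cols.append(_tcd_under_masks(rmask, pair_idx, seps, L))
            nmask = _random_masks(L, m, rand_reps, rng)
            rand_cols.append(_tcd_under_masks(nmask, pair_idx, seps, L))
        n_sets = max(len(c) for c in ranked_cols)
        ranked = np.stack([np.resize(c, n_sets) for c in ranked_cols], axis=1)
        mean_r2[gi] = float(np.mean(_r2_vector(ranked, y)))
        null_r2 = _r2_vector(np.stack(rand_cols, axis=1), y)
        for q in PERCENTILES:
            env[q][gi] = float(np.percentile(null_r2, q))
    return EliminationCurve(property, grid, mean_r2, env)
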