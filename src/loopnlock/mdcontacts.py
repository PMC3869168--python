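"""Contact persistence in trajectory snapshots.

For every residue pair the fraction of frames in which it is in contact
is compared with the mean fraction over all pairs at the same sequence
separation; the log ratio of the two flags pairs that form contacts
more often than their chain distance alone would predict.  The overlap
of the flagged pairs with the locks-plus-neighbours core is scored with
a hypergeometric test.

The enrichment flag defaults to log ratio > +threshold ("enrichment"
convention); the mirrored "depletion" convention (log ratio below
-threshold) is available behind the ``convention`` switch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .loops import CoreSet
from .structure import ContactMap, ProteinStructure, compute_contacts

__all__ = ["contact_fractions", "separation_baseline", "contact_log_ratio",
           "core_overlap_significance"]


def contact_fractions(trajectory: ProteinStructure, cutoff: float = 6.0,
                      min_separation: int = 3):
    """Fraction of frames each residue pair is in contact.

    ``trajectory`` is a multi-model structure with >= 20 frames.
    Returns ``(fractions, n_frames, L)`` where ``fractions`` maps each
    pair observed in contact in at least one frame to its fraction.
    """
    if trajectory.n_models < 20:
        raise ValueError(f"need >= 20 frames, got {trajectory.n_models}")
    counts: dict[tuple[int, int], int] = {}
    for m in range(trajectory.n_models):
        cmap = compute_contacts(trajectory.model_structure(m), cutoff,
                                min_separation)
        for pair in cmap.pairs:
            counts[pair] = counts.get(pair, 0) + 1
    fractions = {p: c / trajectory.n_models for p, c in counts.items()}
    return fractions, trajectory.n_models, trajectory.length


def separation_baseline(fractions: dict, L: int,
                        min_separation: int = 3) -> dict[int, float]:
    """Expected contact fraction per sequence separation |i - j|.

    The mean is over *all* pairs at that separation within the chain
    (pairs never seen in contact contribute zero), so the baseline
    reflects how likely a contact is given chain distance alone.
    """
    if not fractions:
        raise ValueError("no contact fractions given")
    sums: dict[int, float] = {}
    for (i, j), f in fractions.items():
        sums[j - i] = sums.get(j - i, 0.0) + f
    return {sep: total / (L - sep) for sep, total in sums.items()}


def contact_log_ratio(fractions: dict, baseline: dict[int, float],
                      flag_threshold: float = 0.3,
                      convention: str = "enrichment") -> pd.DataFrame:
    """Log ratio ln(fraction / baseline) per pair, with enrichment flags.

    ``convention='enrichment'`` flags log ratio > +threshold;
    ``'depletion'`` flags log ratio < -threshold.
    """
    if convention not in ("enrichment", "depletion"):
        raise ValueError(f"unknown convention {convention!r}")
    rows = []
    for (i, j), f in sorted(fractions.items()):
        sep = j - i
        b = baseline.get(sep, 0.0)
        if b <= 0:
            raise ValueError(f"baseline at separation {sep} is zero")
        lr = float(np.log(f / b))
        flagged = lr > flag_threshold if convention == "enrichment" \
            else lr < -flag_threshold
        rows.append({"i": i, "j": j, "separation": sep, "fraction": f,
                     "baseline": b, "log_ratio": lr, "flagged": flagged})
    return pd.DataFrame(rows)


def core_overlap_significance(flagged_pairs, core: CoreSet,
                              full_map: ContactMap):
    """Overlap of flagged pairs with the core contacts, and its
    hypergeometric p-value.

    p is the upper tail of drawing ``len(flagged)`` contacts from the
    ``len(full_map)`` universe containing ``len(core_contacts)``
    successes, i.e. the chance of at least the observed overlap at
    random.  Returns ``(overlap_fraction, p)``.
    """
    flagged = {(min(i, j), max(i, j)) for (i, j) in flagged_pairs}
    if not flagged:
        raise ValueError("no flagged pairs")
    universe = set(full_map.pairs)
    if not flagged <= universe:
        raise ValueError("flagged pairs must come from the full contact map")
    core_contacts = set(core.core_contacts) & universe
    k = len(flagged & core_contacts)
    M, K, N = len(universe), len(core_contacts), len(flagged)
    p = float(stats.hypergeom.sf(k - 1, M, K, N))
    return k / N, p
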