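"""Closed-loop (loop-n-lock) detection.

A closed loop is a contiguous chain segment of 12-50 residues whose two
ends come into heavy-atom contact (<= 6 A).  The residues clustering at
the two ends that hold the loop shut are the *locks* (2-8 residues per
end).  Loops are scored by the connectivity, hydrophobicity and
conservation of their end regions, selected greedily with bounded
overlap, optionally refined against an NMR ensemble (only persistent
lock residues are kept), and reduced to a *minimal pair* of one residue
per end.  The minimal pairs plus every residue contacting them form the
locks-plus-neighbours core used for restricted contact metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .structure import (ContactMap, ProteinStructure, ResidueProperties,
                        compute_contacts, compute_properties)

__all__ = [
    "LoopCandidate",
    "LockRegion",
    "ClosedLoop",
    "CoreSet",
    "enumerate_closed_loops",
    "score_lock_region",
    "select_loops",
    "grow_lock_regions",
    "refine_locks_nmr",
    "minimal_lock_pair",
    "build_core",
    "find_loops_and_core",
]


@dataclass(frozen=True)
class LoopCandidate:
    """A contact pair whose inclusive segment length is in the loop band."""

    start: int
    end: int
    lock_score: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def interior(self) -> set[int]:
        return set(range(self.start + 1, self.end))


@dataclass
class LockRegion:
    """Residues clustered at one loop end that contact the opposite end."""

    residues: tuple[int, ...]
    loop_end: int
    persistent: bool | None = None   # set by NMR refinement

    def __post_init__(self):
        self.residues = tuple(sorted(self.residues))
        if not (1 <= len(self.residues) <= 8):
            raise ValueError("a lock region holds 1-8 residues before "
                             "validity checks; got "
                             f"{len(self.residues)}")


@dataclass
class ClosedLoop:
    start: int
    end: int
    score: float
    lock_a: LockRegion | None = None
    lock_b: LockRegion | None = None
    minimal_pair: tuple[int, int] | None = None
    degenerate: bool = False          # lock fell below 2 residues on refinement

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CoreSet:
    """Minimal lock pairs plus every residue/contact touching them."""

    protein_id: str
    minimal_pair_residues: frozenset[int]
    core_residues: frozenset[int]
    core_contacts: frozenset[tuple[int, int]]

    def __post_init__(self):
        if not self.minimal_pair_residues <= self.core_residues:
            raise ValueError("minimal pairs must be contained in the core")


# ---------------------------------------------------------------------------

def enumerate_closed_loops(contacts: ContactMap, min_len: int = 12,
                           max_len: int = 50) -> list[LoopCandidate]:
    """One candidate per contact pair with inclusive length in
    [min_len, max_len]."""
    out = [LoopCandidate(i, j) for (i, j) in sorted(contacts.pairs)
           if min_len <= j - i + 1 <= max_len]
    return out


def _window_indices(center: int, window: int, L: int) -> np.ndarray:
    half = window // 2
    lo, hi = max(1, center - half), min(L, center + half)
    return np.arange(lo, hi + 1)


def score_lock_region(candidate: LoopCandidate,
                      properties: ResidueProperties,
                      window: int = 3) -> float:
    """Lock score of a loop candidate.

    For each loop end, the scaled connectivity, scaled hydrophobicity and
    conservation are averaged over a centered window of 1, 3 or 5
    residues (truncated at the termini) and multiplied; the score is the
    mean over the two ends.  Deterministic.
    """
    if window not in (1, 3, 5):
        raise ValueError("window must be 1, 3 or 5")
    L = len(properties.connectivity)
    if not (1 <= candidate.start <= L and 1 <= candidate.end <= L):
        raise ValueError("candidate ends outside the property vectors")
    end_scores = []
    for center in (candidate.start, candidate.end):
        idx = _window_indices(center, window, L) - 1
        conn = properties.scaled_connectivity[idx].mean()
        hydro = properties.scaled_hydrophobicity[idx].mean()
        cons = properties.conservation[idx].mean()
        end_scores.append(conn * hydro * cons)
    return float(np.mean(end_scores))


def select_loops(candidates: list[LoopCandidate],
                 max_overlap: int = 5) -> list[LoopCandidate]:
    """Greedy selection by descending score.

    A candidate is accepted iff its interior (residues strictly between
    its ends) overlaps every accepted loop's interior by at most
    ``max_overlap`` residues; sharing lock endpoints is always allowed.
    Ties are broken by shorter length, then smaller start index.
    """
    scored = [c for c in candidates if c.lock_score is not None]
    if len(scored) != len(candidates):
        raise ValueError("all candidates must be scored before selection")
    order = sorted(candidates,
                   key=lambda c: (-c.lock_score, c.length, c.start))
    accepted: list[LoopCandidate] = []
    interiors: list[set[int]] = []
    for cand in order:
        interior = cand.interior()
        if all(len(interior & other) <= max_overlap for other in interiors):
            accepted.append(cand)
            interiors.append(interior)
    return sorted(accepted, key=lambda c: c.start)


# ---------------------------------------------------------------------------
# Lock regions
# ---------------------------------------------------------------------------

def _contacts_window(contacts: ContactMap, r: int, window_idx) -> bool:
    return any((min(r, o), max(r, o)) in contacts.pairs
               for o in window_idx if o != r)


def grow_lock_regions(loop: LoopCandidate, contacts: ContactMap,
                      max_size: int = 8, opposite_window: int = 2) -> tuple[LockRegion, LockRegion]:
    """Grow a lock region at each loop end.

    Each region is the maximal contiguous run (at most ``max_size``
    residues) centered on the loop end, every member of which contacts
    the opposite end's +/- ``opposite_window`` neighbourhood.  If growth
    leaves a single residue, the chain neighbour toward the loop interior
    is added so that a region always has at least two residues.
    """
    L = contacts.n_residues

    def grow(end: int, opp: int, inward: int) -> LockRegion:
        opp_idx = [o for o in range(opp - opposite_window,
                                    opp + opposite_window + 1) if 1 <= o <= L]
        members = [end]
        lo = hi = end
        while len(members) < max_size:
            extended = False
            for r in (lo - 1, hi + 1):
                if len(members) >= max_size or not (1 <= r <= L):
                    continue
                if _contacts_window(contacts, r, opp_idx):
                    members.append(r)
                    lo, hi = min(lo, r), max(hi, r)
                    extended = True
            if not extended:
                break
        if len(members) < 2:
            neighbour = end + inward if 1 <= end + inward <= L else end - inward
            members.append(neighbour)
        return LockRegion(tuple(members), loop_end=end)

    return (grow(loop.start, loop.end, inward=+1),
            grow(loop.end, loop.start, inward=-1))


def refine_locks_nmr(loops: list[ClosedLoop], ensemble: ProteinStructure,
                     persistence_threshold: float = 0.5,
                     cutoff: float = 6.0) -> list[ClosedLoop]:
    """Keep only lock residues with persistent cross-lock contacts.

    A lock residue is retained iff it contacts the opposite lock region
    (heavy-atom distance <= cutoff) in at least ``persistence_threshold``
    of the ensemble models.  Loops whose locks shrink below two residues
    are flagged ``degenerate``.
    """
    if ensemble.n_models < 2:
        raise ValueError(
            "NMR refinement needs an ensemble with >= 2 models; "
            "use the unrefined locks for single-model structures")
    model_maps = [compute_contacts(ensemble.model_structure(m), cutoff,
                                   min_separation=1)
                  for m in range(ensemble.n_models)]

    def persistence(r: int, opposite: tuple[int, ...]) -> float:
        hits = sum(
            any((min(r, o), max(r, o)) in cmap.pairs for o in opposite if o != r)
            for cmap in model_maps)
        return hits / ensemble.n_models

    refined = []
    for loop in loops:
        if loop.lock_a is None or loop.lock_b is None:
            raise ValueError("loops must carry lock regions before refinement")
        keep_a = tuple(r for r in loop.lock_a.residues
                       if persistence(r, loop.lock_b.residues)
                       >= persistence_threshold)
        keep_b = tuple(r for r in loop.lock_b.residues
                       if persistence(r, loop.lock_a.residues)
                       >= persistence_threshold)
        degenerate = len(keep_a) < 2 or len(keep_b) < 2
        lock_a = LockRegion(keep_a or loop.lock_a.residues,
                            loop.lock_a.loop_end, persistent=bool(keep_a))
        lock_b = LockRegion(keep_b or loop.lock_b.residues,
                            loop.lock_b.loop_end, persistent=bool(keep_b))
        refined.append(replace(loop, lock_a=lock_a, lock_b=lock_b,
                               degenerate=degenerate))
    return refined


def minimal_lock_pair(lock_a: LockRegion, lock_b: LockRegion,
                      contacts: ContactMap,
                      connectivity: np.ndarray) -> tuple[int, int]:
    """Reduce two lock regions to one residue per end.

    Among all cross-end residue pairs that are in contact, the pair with
    the largest summed connectivity wins; ties go to the smallest
    contact distance, then to the lowest indices.  Deterministic.
    """
    best = None
    for a in lock_a.residues:
        for b in lock_b.residues:
            key = (min(a, b), max(a, b))
            if key not in contacts.pairs:
                continue
            score = (-(connectivity[a - 1] + connectivity[b - 1]),
                     contacts.pairs[key], key)
            if best is None or score < best[0]:
                best = (score, key)
    if best is None:
        raise ValueError(
            f"no cross-end contact between lock regions {lock_a.residues} "
            f"and {lock_b.residues}: lock is invalid")
    return best[1]


def build_core(minimal_pairs, contacts: ContactMap) -> CoreSet:
    """Locks-plus-neighbours core.

    ``core_contacts`` are all contact pairs with at least one endpoint in
    the minimal-pair residue set; ``core_residues`` are the minimal-pair
    residues plus every endpoint of a core contact.
    """
    mp = frozenset(int(r) for r in minimal_pairs)
    if not mp:
        raise ValueError("minimal pair set is empty")
    core_contacts = frozenset(p for p in contacts.pairs
                              if p[0] in mp or p[1] in mp)
    core_residues = frozenset(mp | {r for p in core_contacts for r in p})
    return CoreSet(contacts.protein_id, mp, core_residues, core_contacts)


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------

def find_loops_and_core(structure: ProteinStructure,
                        properties: ResidueProperties | None = None,
                        cutoff: float = 6.0,
                        min_len: int = 12, max_len: int = 50,
                        window: int = 3, max_overlap: int = 5,
                        ensemble: ProteinStructure | None = None,
                        persistence_threshold: float = 0.5,
                        metric_min_separation: int = 3):
    """Full loop-n-lock pipeline for one protein.

    Returns ``(loops, core)`` where ``loops`` is the selected list of
    :class:`ClosedLoop` (with lock regions and minimal pairs) and
    ``core`` the resulting :class:`CoreSet` (None when no valid loop was
    found).  When ``ensemble`` is given, locks are refined against it.
    """
    contacts = compute_contacts(structure, cutoff, min_separation=3)
    if properties is None:
        properties = compute_properties(structure, cutoff=cutoff)
    candidates = enumerate_closed_loops(contacts, min_len, max_len)
    scored = [replace(c, lock_score=score_lock_region(c, properties, window))
              for c in candidates]
    selected = select_loops(scored, max_overlap)
    loops = []
    for cand in selected:
        lock_a, lock_b = grow_lock_regions(cand, contacts)
        loops.append(ClosedLoop(cand.start, cand.end, cand.lock_score,
                                lock_a, lock_b))
    if ensemble is not None:
        loops = refine_locks_nmr(loops, ensemble, persistence_threshold,
                                 cutoff)
    metric_map = (contacts if metric_min_separation == 3 else
                  compute_contacts(structure, cutoff, metric_min_separation))
    conn = properties.connectivity
    pair_residues: set[int] = set()
    for loop in loops:
        try:
            pair = minimal_lock_pair(loop.lock_a, loop.lock_b, contacts, conn)
        except ValueError:
            loop.degenerate = True
            continue
        loop.minimal_pair = pair
        pair_residues.update(pair)
    core = build_core(pair_residues, metric_map) if pair_residues else None
    return loops, core
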