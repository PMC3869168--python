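"""Reference synthetic cohorts: the study conditions used by the test
suite and the reproduction script.

Two cohorts cover the two headline analyses:

* :func:`core_rate_cohort` -- 43 loop-planted chain proteins whose
  ln k_f is generated from the locks-plus-neighbours core TCD (slope
  -60, intercept 12, Gaussian noise sd 0.8, chosen so the all-contacts
  correlation lands near r^2 = 0.6); the core-restricted correlation
  should then beat the all-contacts one.
* :func:`hydrophobic_core_cohort` -- 30 degree-neutral ring proteins
  whose ln k_f comes only from contacts among the most hydrophobic 40%
  of residues, so hydrophobicity-ranked elimination retains the signal
  while connectivity-ranked elimination cannot.
"""

from __future__ import annotations

import numpy as np

from .loops import find_loops_and_core
from .metrics import total_contact_distance
from .pipeline import synthetic_cohort
from .structure import compute_contacts, compute_properties
from .synthetic import make_rate_table, make_ring_protein

__all__ = ["core_rate_cohort", "hydrophobic_core_cohort"]

CORE_RATE_SLOPE = -60.0
CORE_RATE_INTERCEPT = 12.0
CORE_RATE_NOISE_SD = 0.8

HYDRO_CORE_NOISE_SD = 0.2
HYDRO_TOP_FRACTION = 0.4


def core_rate_cohort(n_proteins: int = 43, seed=0):
    """Loop-planted cohort with core-driven folding rates.

    Runs the loop finder on every structure, generates ln k_f from each
    protein's core TCD, and returns
    ``(structures, cores, rates, all_values, core_values)`` where the
    value dicts map protein_id to the all-contacts and core-restricted
    TCD.
    """
    structures, _ = synthetic_cohort(n_proteins, seed=seed,
                                     min_loops=1, max_loops=2)
    cores = {}
    for s in structures:
        _, core = find_loops_and_core(s)
        if core is not None and core.core_contacts:
            cores[s.id] = core
    usable = [s for s in structures if s.id in cores]
    subsets = {pid: set(c.core_contacts) for pid, c in cores.items()}
    rates, _ = make_rate_table(usable, CORE_RATE_SLOPE, CORE_RATE_INTERCEPT,
                               CORE_RATE_NOISE_SD, seed=seed + 10_000,
                               contact_subsets=subsets)
    all_values = {s.id: total_contact_distance(compute_contacts(s).pairs,
                                               s.length) for s in usable}
    core_values = {s.id: total_contact_distance(subsets[s.id], s.length)
                   for s in usable}
    return usable, cores, rates, all_values, core_values


def hydrophobic_core_cohort(n_proteins: int = 30, length: int = 80, seed=0):
    """Degree-neutral cohort whose rates come from hydrophobic contacts.

    Every residue has exactly two spatial neighbours (ring geometry with
    a random chain order), so connectivity carries no signal; ln k_f is
    generated from the TCD over contacts whose two endpoints are both in
    the top 40% of the hydrophobicity scale.  Returns
    ``(proteins, rates)`` with ``proteins`` mapping protein_id to
    ``(ContactMap, ResidueProperties)`` as the elimination analysis
    expects.
    """
    proteins, structures, subsets = {}, [], {}
    root = np.random.SeedSequence(seed)
    for k in range(n_proteins):
        s, _ = make_ring_protein(
            length, seed=np.random.SeedSequence(root.entropy, spawn_key=(k,)),
            protein_id=f"ring{k:03d}")
        cmap = compute_contacts(s)
        props = compute_properties(s)
        cut = np.quantile(props.hydrophobicity, 1.0 - HYDRO_TOP_FRACTION)
        top = {r + 1 for r in np.flatnonzero(props.hydrophobicity >= cut)}
        subsets[s.id] = {p for p in cmap.pairs
                         if p[0] in top and p[1] in top}
        proteins[s.id] = (cmap, props)
        structures.append(s)
    rates, _ = make_rate_table(structures, CORE_RATE_SLOPE, 10.0,
                               HYDRO_CORE_NOISE_SD, seed=seed + 20_000,
                               contact_subsets=subsets)
    return proteins, rates
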