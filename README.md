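# loopnlock

Closed-loop ("loop-n-lock") analysis of protein structures.

The closed-loop picture of protein folding holds that chains organize
into loops of roughly 25 residues whose two ends — the *locks*, small
clusters of buried hydrophobic residues — come into spatial contact
(≤ 6 Å between heavy atoms) and pin the loop shut.  This package
implements the full analysis pipeline around that idea for structural
bioinformaticians working on folding kinetics:

* detect closed loops (12–50 residues) and their lock residues in PDB
  or mmCIF structures, refine locks against NMR ensembles, and build
  the **locks-plus-neighbours core** — the minimal lock pairs plus
  every residue contacting them;
* compute contact-topology metrics over any contact subset:
  contact order **CO = Σ|i−j| / (L·N)**, total contact distance
  **TCD = Σ|i−j| / L²**, and their length-absolute variants
  ACO = CO·L, ATCD = TCD·L;
* correlate metrics with the log folding rate ln *k*_f of two-state
  proteins, with Monte Carlo random-contact controls and
  sequence-separation scans;
* rank-and-remove residues by hydrophobicity / connectivity / product
  and compare the surviving correlation against random-removal
  percentile envelopes;
* run coarse-grain elastic-network Brownian dynamics, derive
  per-residue force constants (rigidity profiles), and test the
  ~24-residue spacing of rigid residues by permutation;
* measure per-pair contact persistence in MD-style snapshot
  trajectories and test the enriched pairs' overlap with the core
  (hypergeometric);
* generate all of the above synthetically with known ground truth.

A transcription of the published 43-protein folding-rate / core-size
table ships with the package (`loopnlock.pipeline.load_table2`).

## Worked example

Plant two closed loops in a synthetic 80-residue bead chain, recover
them, and compare the all-contacts TCD with the core-restricted TCD:

```python
from loopnlock.synthetic import make_loop_protein
from loopnlock.loops import find_loops_and_core
from loopnlock.structure import compute_contacts
from loopnlock.metrics import total_contact_distance

structure, truth = make_loop_protein(80, [(10, 35, 5.0), (45, 70, 5.0)],
                                     seed=11)
loops, core = find_loops_and_core(structure)
for lp in loops:
    print(lp.start, lp.end, round(lp.score, 3), lp.minimal_pair)
cmap = compute_contacts(structure)
print("contacts:", cmap.n_contacts,
      "core:", len(core.core_residues), "residues,",
      len(core.core_contacts), "contacts")
print("TCD all:", round(total_contact_distance(cmap.pairs, 80), 4),
      "TCD core:", round(total_contact_distance(core.core_contacts, 80), 4))
```

prints

```
10 35 0.807 (9, 37)
45 70 0.843 (44, 71)
contacts: 28 core: 12 residues, 10 contacts
TCD all: 0.1109 TCD core: 0.043
```

Both planted loops are recovered exactly (scored 0.81 and 0.84 by the
lock criterion — connectivity × hydrophobicity at the loop ends), each
reduced to a minimal lock pair one residue off the planted ends; the
core of 12 residues carries 10 of the 28 contacts, and its TCD is the
quantity that, across a cohort, correlates with ln *k*_f.

The shipped rate table summarizes to:

```python
from loopnlock.pipeline import load_table2, summarize_core_stats
stats = summarize_core_stats(load_table2())
```

giving mean core sizes of 101.0 contacts and 29.9 residues per protein
(37.8% of all contacts, 42.6% of all residues; per-protein proportion
41.2 ± 10.6%, ranging from 24.1% for 2jwt to 64.5% for 1wiu).

## Command line

```sh
loopnlock loops structure.pdb --window 3         # loops, locks, core
loopnlock metrics *.pdb --rates rates.tsv --subset core
loopnlock eliminate *.pdb --rates rates.tsv --property hydrophobicity
loopnlock rigidity *.pdb --shuffles 9999 --seed 11
loopnlock loopsurvey *.pdb --sites sites.tsv
loopnlock mdcontacts trajectory.pdb --threshold 0.3
loopnlock synth --n-residues 80 --loop 10:35:5.0 --seed 0
loopnlock report                                  # shipped-table summary
loopnlock run --seed 5 --outdir demo              # synthetic end-to-end
```

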