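# Methods

## Scope and model

`loopnlock` analyses protein structures under the closed-loop
("loop-n-lock") picture of folding: contiguous chain segments of
roughly 12–50 residues whose two ends are brought into spatial contact
(minimum heavy-atom distance ≤ 6 Å), held shut by small clusters of
*lock* residues at the two ends.  The package covers five analysis
arms:

1. **Loop/lock detection** — enumerate candidate loops from the contact
   map, score and greedily select them, optionally refine the locks
   against an NMR ensemble, reduce each lock to a minimal residue pair,
   and assemble the *locks-plus-neighbours core* (minimal pairs plus
   every residue in contact with them).
2. **Contact-topology metrics** — contact order CO = Σ|i−j|/(L·N),
   total contact distance TCD = Σ|i−j|/L², and the length-absolute
   variants ACO = CO·L, ATCD = TCD·L, evaluated over the full contact
   set or any subset, correlated against ln k_f by ordinary least
   squares, with Monte Carlo random-contact controls and
   sequence-separation scans.
3. **Residue elimination** — remove increasing percentages of residues
   ranked by hydrophobicity, connectivity, or their product, and track
   the TCD ↔ ln k_f correlation against percentile envelopes from
   random removals.
4. **Elastic-network rigidity** — coarse-grain Brownian dynamics on a
   uniform-spring network; per-residue force constants from distance
   fluctuations; autocorrelation of clipped Z-scored profiles with a
   permutation significance test for the ≈24-residue spacing of rigid
   residues.
5. **MD contact persistence** — per-pair contact fractions over
   trajectory snapshots compared with a sequence-separation baseline;
   enriched pairs tested for overlap with the core by a hypergeometric
   test.

## Contact definitions

A contact is a residue pair whose minimum distance over all heavy-atom
pairs is within the cutoff.  Defaults: 6 Å cutoff; |i−j| ≥ 3 for the
metric map (the 1,2 and 1,3 contacts are excluded); |i−j| ≥ 2 for
per-residue connectivity; 9 Å for elastic-network springs.  The lock
criterion and the metric criterion use the same heavy-atom set (all
non-hydrogen atoms, highest-occupancy altloc).  Residues are renumbered
1..L over observed residues, with author numbering kept for reporting;
missing residues therefore compress |i−j|, which is logged rather than
repaired.

## TCD normalization

The package uses TCD = Σ|i−j|/L².  The L² normalization (rather than
L·N) is what makes TCD insensitive to whether near neighbours are
included and makes subset values additive:
TCD(A ∪ B)·L² = TCD(A)·L² + TCD(B)·L² for disjoint subsets.  ACO and
ATCD are exact identities (CO·L, TCD·L) and inherit these properties.

## Loop scoring and selection

Candidates are contact pairs with inclusive length end−start+1 in
[12, 50].  Each candidate is scored per loop end as the product of
window-averaged scaled connectivity, scaled hydrophobicity, and
conservation (window 1, 3 or 5; truncated at the termini), and the two
end scores are averaged.  The multiplicative combination was a design
choice: it demands that an end be *simultaneously* packed and
hydrophobic, which is the property the lock concept describes; an
additive score would let one strong factor mask the other.
Hydrophobicity is scaled against the embedded octanol–water
(Fauchère–Pliska) table bounds so that tryptophan always maps to 1.0;
connectivity is min-max scaled per protein; conservation defaults to a
constant 1.0 when no per-residue input is given.  Selection is greedy
by descending score; a candidate is accepted when its interior overlaps
every accepted loop by at most 5 residues (shared lock endpoints are
always allowed); ties break by shorter length, then smaller start.

Lock regions grow as the maximal contiguous run (≤ 8 residues) centred
on a loop end whose members all contact the opposite end's ±2 window;
a region always keeps at least two residues.  NMR refinement keeps a
lock residue when it contacts the opposite region in at least a
fraction (default 0.5) of ensemble models.  The minimal pair maximizes
summed connectivity over cross-end contacting pairs, breaking ties by
contact distance and then index — fully deterministic.

## Monte Carlo machinery

* Random-contact controls draw residues uniformly without replacement
  until the induced contact count reaches the core's count, recompute
  TCD, and report the one-sided empirical p with add-one smoothing:
  p = (1 + #{null r² ≥ observed}) / (n_reps + 1).
* Elimination envelopes remove the same per-protein counts uniformly at
  random (default 1000 replicates; the shipped tests use 200) and report
  the 1/5/50/95/99 percentiles of r².  Boundary ties in ranked removal
  are resolved by uniform draws (default cap 1000; tests use 10–50) and
  the mean r² over draws is reported.  Sub-streams are derived per
  (grid point, protein) from one seed, so single points are reproducible
  in isolation.  L stays fixed in the TCD denominator when residues are
  removed (subset-of-contacts semantics); the alternative — shrinking L
  — would mix chain-length effects into what is meant to be a contact
  subset comparison.
* The rigidity permutation test shuffles k′ within each protein;
  the statistic is mean C over lags 22–27 divided by mean C over
  15–20 ∪ 30–35, with the same add-one p.  Autocorrelation pools lag
  products across proteins and divides by the pooled pair count
  (C(L) = Σ_p Σ_i k′_i k′_{i+L} / Σ_p (L_p − L)); a per-protein-average
  alternative would weight short proteins up and is not what the
  normalization "by the number of residues at distance L apart in each
  protein" describes.  Shuffled autocorrelations are computed in FFT
  batches, which is what makes 9,999–99,999 shuffles cheap.

## Brownian dynamics

Overdamped Langevin updates
x ← x − (dt/ζ)∇U + √(2 k_B T dt/ζ)·η with U = Σ (γ/2)(|d|−d₀)²,
γ = 0.6 kcal mol⁻¹ Å⁻², spring cutoff 9 Å, rest lengths from the build
structure.  Defaults T = 300 K, ζ = 1 (reduced units), dt = 0.05 with
save stride 10; the single-spring stability parameter γ·dt/ζ is 0.03,
far below the Euler stability limit, and the integrator is validated
against the stationary bond-length variance of an isolated pair.  Note
that the exact stationary variance of a *radial* coordinate is slightly
below k_BT/γ (the d² Jacobian term contributes −2k_BT/(γd₀²)
relative); at rest length 10 Å this is a 2% effect, inside the 5%
validation band.  Force constants use the rigidity-profile convention
k_i = 3k_BT / Var(d_i), where d_i is the mean distance of residue i's
Cα bead to all other residues' Cα beads; per protein, k is re-expressed
as Z-scores and clipped below zero (k′).  Beads: Cα, plus one
side-chain centroid for residues with more than one side-chain heavy
atom and a second for the large side chains (Trp/Tyr/Phe/Arg), i.e.
one to three pseudo-atoms per residue.

## MD contact statistics

The separation baseline at |i−j| = s is the mean fraction over **all**
L−s pairs at that separation (pairs never seen in contact contribute
zero), so it estimates how likely a contact is from chain distance
alone.  A pair is flagged when ln(fraction/baseline) exceeds +0.3; the
mirrored convention (below −0.3) is available behind a switch, because
the flag is used for pairs *more* likely to form contacts and the sign
in circulation is ambiguous.  Core overlap uses the upper
hypergeometric tail of drawing the flagged count from the contact
universe with the core contacts as successes.

## Synthetic data: what it emulates, and what it does not

* `make_loop_protein` plants closed loops in a bead chain (one heavy
  atom per residue, ≈3.8 Å virtual bonds).  Each loop is a two-strand
  zigzag stem whose end pair sits at exactly `lock_gap` Å — the partner
  strand is phase-shifted by one zigzag level so the cross-diagonal
  pairs also fall inside 6 Å, giving lock residues ≥ 4 neighbours
  within 6 Å — closed by a circular-arc return whose radius is solved
  so every virtual bond stays at 3.8 Å.  Lock ends get hydrophobic
  names (Trp/Ile/Phe/Leu), the background polar ones.
* `make_globule_protein` dart-throws residues into a ball
  (R = 3.1·L^⅓ Å, ≥ 3.6 Å separation) with a random chain order: a
  dense contact map with a broad separation spectrum for metric
  statistics.
* `make_ring_protein` places residues on a circle with a random chain
  order: every residue has (almost) exactly two spatial neighbours, so
  packing carries no information.  This degree-neutral geometry is the
  control for the elimination analysis: on globules, *any* deterministic
  removal that spares high-degree residues retains signal contacts at a
  higher-than-random rate and can sit above the random envelope even
  when residue names are geometry-independent, so the discriminating
  test of "which property carries the signal" is run on rings.
* `make_ensemble` and `make_trajectory` plant per-contact persistence
  exactly (chosen models/frames); a displaced partner is parked along
  the out-of-plane normal at residue i so it clears i's chain
  neighbours.
* `make_rigidity_profiles` places amplitude spikes every `period`
  residues (random phase per protein) plus zero-clipped Gaussian noise.

None of these are physical decoys: no secondary structure, no
excluded-volume chain dynamics, no real energetics.  Passing tests
demonstrate that the *statistical machinery* — detection, metrics,
controls, significance — behaves as designed on data with known ground
truth, not that the biological claims hold for real proteins, which
requires the PDB-scale inputs the pipeline also accepts.

## Reference study conditions

The reproduction script and the end-to-end tests use two frozen
cohorts (`loopnlock.cohorts`):

* **Core-driven rates**: 43 loop-planted proteins (1–2 loops of 15–40
  residues each), ln k_f = −60·TCD(core) + 12 + N(0, 0.8²), where the
  core comes from running the loop finder itself.  The noise level was
  set so the all-contacts correlation lands near r² ≈ 0.6, after which
  the core-restricted correlation is expected to be higher (it wins in
  ≈97% of replicates).
* **Hydrophobic-core rates**: 30 ring proteins of 80 residues,
  ln k_f generated only from contacts whose two endpoints are both in
  the top 40% of the hydrophobicity scale (noise sd 0.2).
  Hydrophobicity-ranked elimination then retains the signal through
  60% removal while connectivity-ranked elimination cannot beat the
  random envelope.

Problem sizes throughout (20 replicate cohorts, 200-replicate
envelopes, 9,999 shuffles, 300-frame trajectories, 3·10⁵-step BD runs)
were chosen as the smallest that leave comfortable statistical margins
for the properties being demonstrated.

## Known limitations

* Single-chain analysis only; no inter-chain contacts, no hydrogen
  placement or structure repair.
* The lock-region growth rule and the multiplicative score are design
  choices where the underlying method description is silent; both are
  config-exposed.
* Conservation is consumed as an optional input column, never computed
  from alignments.
* The elimination analysis keeps L fixed; shrinking L per removal is a
  documented alternative, not implemented.
* Reproducing the published 43-protein correlations (r² = 0.65 all
  contacts, 0.76 core) needs the corresponding PDB/NMR entries, which
  are not shipped; the pipeline runs on them unchanged once downloaded.
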