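"""Synthetic structures and datasets with known ground truth.

Every pipeline stage can be exercised without downloading anything:

* :func:`make_loop_protein` -- a bead chain (one heavy atom per residue,
  ~3.8 A virtual bonds) with planted closed loops: each loop is built as
  a two-stranded stem whose end residues sit ``lock_gap`` apart, closed
  by a circular-arc return.  Planted lock residues acquire elevated
  local packing (>= 4 neighbours within 6 A) and hydrophobic residue
  names, so the loop finder can recover them.
* :func:`make_globule_protein` -- residues dart-thrown into a ball with
  a random chain order: a dense, loopless contact map for metric and
  elimination statistics.  Deliberately not a physical decoy.
* :func:`make_ensemble` -- NMR-like model sets with controlled
  per-contact persistence.
* :func:`make_rate_table` -- ln k_f as a linear function of a contact
  metric plus Gaussian noise.
* :func:`make_trajectory` -- MD-snapshot-like frames with planted
  persistent contacts.
* :func:`make_rigidity_profiles` -- non-negative reduced force-constant
  profiles with planted sequence periodicity.

All generators are deterministic under a fixed seed and return a
``(object, manifest)`` pair; the manifest (JSON-serializable) records the
ground truth needed to score recovery.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .metrics import RateRecord, compute_metric
from .structure import (ContactMap, ProteinStructure, Residue,
                        compute_contacts, write_structure)

__all__ = [
    "make_loop_protein",
    "make_globule_protein",
    "make_ring_protein",
    "make_ensemble",
    "make_rate_table",
    "make_trajectory",
    "make_rigidity_profiles",
    "save_dataset",
]

BOND = 3.8               # Calpha-Calpha virtual bond, Angstrom
_RISE = 2.75             # zigzag rise per residue (gives |i,i+2| = 5.5 A)
_SWING = 0.5 * np.sqrt(BOND ** 2 - _RISE ** 2)   # lateral alternation (+/-)

_HYDROPHOBIC = ("TRP", "ILE", "PHE", "LEU")
_BACKGROUND = ("GLY", "SER", "ALA", "THR", "ASN", "GLN", "ASP", "LYS")
_ALL_NAMES = ("ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
              "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
              "TYR", "VAL")


def _seed_repr(seed):
    if seed is None:
        return None
    try:
        return int(seed)
    except (TypeError, ValueError):
        return str(seed)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_perp(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        r = rng.normal(size=3)
        r -= r @ v * v
        if np.linalg.norm(r) > 1e-6:
            return _unit(r)


def _arc_radius(n_steps: int, chord: float, step: float = BOND) -> float:
    """Radius of the circle on which ``n_steps`` bonds of length ``step``
    return to a point ``chord`` away (single full wrap)."""
    from scipy.optimize import brentq

    def gap_angle(R):
        return (n_steps * 2 * np.arcsin(min(1.0, step / (2 * R)))
                + 2 * np.arcsin(min(1.0, chord / (2 * R))) - 2 * np.pi)

    lo = max(step, chord) / 2 + 1e-9
    hi = n_steps * step  # generous upper bound; gap_angle(hi) < 0
    return brentq(gap_angle, lo * (1 + 1e-9), hi)


def _arc_points(start: np.ndarray, stop: np.ndarray, n_interior: int,
                bulge: np.ndarray) -> np.ndarray:
    """``n_interior`` points along the long way round a circle through
    ``start`` and ``stop``, bulging toward ``bulge``."""
    m = n_interior + 1                       # number of bonds along the arc
    chord_vec = stop - start
    chord = np.linalg.norm(chord_vec)
    R = _arc_radius(m, chord)
    e_c = _unit(chord_vec)
    b = bulge - (bulge @ e_c) * e_c
    e_b = _unit(b)
    mid = 0.5 * (start + stop)
    d = np.sqrt(max(R ** 2 - (chord / 2) ** 2, 0.0))
    best = None
    for sign in (+1.0, -1.0):
        center = mid + sign * d * e_b
        e1 = _unit(start - center)
        e2_raw = stop - center - ((stop - center) @ e1) * e1
        if np.linalg.norm(e2_raw) < 1e-9:
            continue
        e2 = _unit(e2_raw)
        psi = np.arctan2((stop - center) @ e2, (stop - center) @ e1) % (2 * np.pi)
        # two ways round the circle: counter-clockwise covers psi,
        # clockwise covers 2*pi - psi; keep whichever gives ~BOND steps
        for sweep, orient in ((psi, +1.0), (2 * np.pi - psi, -1.0)):
            delta = sweep / m
            step_len = 2 * R * np.sin(delta / 2)
            err = abs(step_len - BOND)
            if best is None or err < best[0]:
                ang = orient * np.arange(1, m) * delta
                pts = (center[None] + R * (np.cos(ang)[:, None] * e1[None]
                                           + np.sin(ang)[:, None] * e2[None]))
                best = (err, pts)
    return best[1]


def make_loop_protein(n_residues: int, loops, seed=None,
                      protein_id: str | None = None,
                      lock_window: int = 1,
                      max_retries: int = 60):
    """Bead-chain protein with planted closed loops.

    ``loops`` is a list of ``(start, end, lock_gap)`` with 1-based
    residue indices, non-overlapping segments, and lock_gap < 6 A.
    Returns ``(structure, manifest)``.
    """
    loops = sorted(tuple(lp) for lp in loops)
    cursor = 1
    for (s, e, gap) in loops:
        if not (1 <= s < e <= n_residues):
            raise ValueError(f"loop ({s}, {e}) outside the chain")
        if e - s + 1 < 10:
            raise ValueError(f"loop ({s}, {e}) too short to plant (need >= 10)")
        if not (2 * _SWING < gap < 6):
            raise ValueError(f"lock_gap must be in ({2 * _SWING:.2f}, 6) A")
        if s < cursor:
            raise ValueError("planted loops must not overlap")
        cursor = e + 1

    ss = np.random.SeedSequence(seed)
    last_err = None
    for attempt, child in enumerate(ss.spawn(max_retries)):
        rng = np.random.default_rng(child)
        try:
            coords = _build_loop_chain(n_residues, loops, rng)
        except (ValueError, RuntimeError) as exc:
            last_err = exc
            continue
        if _self_avoiding(coords):
            break
    else:
        raise RuntimeError(
            f"could not build a feasible geometry in {max_retries} attempts"
            + (f" (last error: {last_err})" if last_err else ""))

    names = _assign_names(n_residues, loops, lock_window, rng)
    pid = protein_id or f"synth{n_residues}"
    model = [Residue(k + 1, names[k], coords[k][None], ("CA",))
             for k in range(n_residues)]
    structure = ProteinStructure(pid, [model])
    lock_residues = sorted({r for (s, e, _) in loops
                            for r in (*range(max(1, s - lock_window),
                                             min(n_residues, s + lock_window) + 1),
                                      *range(max(1, e - lock_window),
                                             min(n_residues, e + lock_window) + 1))})
    manifest = {
        "protein_id": pid,
        "n_residues": n_residues,
        "loops": [{"start": s, "end": e, "lock_gap": g} for (s, e, g) in loops],
        "lock_residues": lock_residues,
        "seed": _seed_repr(seed),
    }
    return structure, manifest


def _build_loop_chain(n: int, loops, rng: np.random.Generator) -> np.ndarray:
    coords = np.zeros((n, 3))
    u = np.array([1.0, 0.0, 0.0])
    nv = np.array([0.0, 1.0, 0.0])
    drift = 0.06 if loops else 0.0
    center = np.zeros(3)
    parity = 1
    pos_index = 0

    def place_coil(count, with_drift=True):
        nonlocal center, parity, pos_index, u, nv
        for _ in range(count):
            coords[pos_index] = center + parity * _SWING * nv
            pos_index += 1
            parity = -parity
            center = center + _RISE * u
            if drift and with_drift:
                axis = _unit(rng.normal(size=3))
                ang = rng.normal(0.0, drift)
                u_new = _rotate(u, axis, ang)
                nv_new = _rotate(nv, axis, ang)
                nv_new -= (nv_new @ u_new) * u_new
                u, nv = _unit(u_new), _unit(nv_new)

    h = 3  # stem length per strand
    for idx, (s, e, gap) in enumerate(loops):
        place_coil(s - 1 - pos_index)     # residues before the loop
        # Hairpin: strand A (s .. s+h-1) continues the incoming zigzag
        # straight on; strand B (e .. e-h+1) is strand A translated by
        # `gap` perpendicular to the chain plane, so the planted end
        # pairs (s+k, e-k) sit exactly `gap` apart; a circular arc links
        # the stem tops through the remaining interior residues.
        u0, nv0, parity0 = u.copy(), nv.copy(), parity
        base_center = center.copy()
        g = np.cross(u0, nv0) * rng.choice((-1.0, 1.0))
        # strand B is strand A translated by gap' and zigzag-phase
        # shifted one level, so that |s - e| = lock_gap exactly while the
        # cross-diagonal pairs also fall inside the 6 A criterion
        gap_t = np.sqrt(gap ** 2 - (2 * _SWING) ** 2)
        place_coil(h, with_drift=False)   # strand A
        for k in range(h):
            sign_k = parity0 * (1 if k % 2 == 0 else -1)
            coords[e - 1 - k] = (coords[s - 1 + k]
                                 - 2 * sign_k * _SWING * nv0 + gap_t * g)
        top_a = coords[s - 1 + h - 1]
        top_b = coords[e - 1 - h + 1]
        n_interior = (e - s + 1) - 2 * h
        tilt = _unit(u0 + 0.3 * rng.normal(size=3))
        coords[s - 1 + h: e - 1 - h + 1] = _arc_points(top_a, top_b,
                                                       n_interior, tilt)
        # Exit: continue strand B's zigzag downward past the hairpin base
        # (packs e against e+2), then veer sideways away from the body.
        next_start = loops[idx + 1][0] if idx + 1 < len(loops) else n + 1
        ext = max(0, min(2, n - e, next_start - 1 - e))
        for t in range(1, ext + 1):
            sign = -parity0 * (1 if t % 2 == 0 else -1)
            coords[e - 1 + t] = (base_center - t * _RISE * u0
                                 + sign * _SWING * nv0 + gap_t * g)
        pos_index = e + ext
        parity = parity0 * (1 if (ext + 1) % 2 == 0 else -1)
        u = _unit(g + 0.35 * _random_perp(g, rng))
        nv = _random_perp(u, rng)
        center = coords[pos_index - 1] + _RISE * u
    place_coil(n - pos_index)
    return coords


def _rotate(v, axis, angle):
    # Rodrigues rotation
    return (v * np.cos(angle) + np.cross(axis, v) * np.sin(angle)
            + axis * (axis @ v) * (1 - np.cos(angle)))


def _self_avoiding(coords: np.ndarray, min_dist: float = 3.3) -> bool:
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    for i, j in tree.query_pairs(min_dist):
        if abs(i - j) >= 2:
            return False
    return True


def _assign_names(n, loops, lock_window, rng) -> list[str]:
    names = [str(x) for x in rng.choice(_BACKGROUND, size=n)]
    for (s, e, _) in loops:
        for end in (s, e):
            for off in range(-lock_window, lock_window + 1):
                r = end + off
                if 1 <= r <= n:
                    names[r - 1] = "TRP" if off == 0 else str(
                        rng.choice(_HYDROPHOBIC[1:]))
    return names


# ---------------------------------------------------------------------------

def make_globule_protein(n_residues: int, seed=None,
                         protein_id: str | None = None,
                         radius: float | None = None,
                         min_dist: float = 3.6,
                         names: str = "all"):
    """Residues dart-thrown into a ball, chain order randomized.

    Yields a dense, realistic-density contact map with a broad
    separation spectrum -- the workhorse input for metric and
    residue-elimination statistics.  Not a physical chain model.
    """
    rng = np.random.default_rng(seed)
    R = radius if radius is not None else 3.1 * n_residues ** (1 / 3)
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n_residues:
        p = rng.uniform(-R, R, size=3)
        if np.linalg.norm(p) > R:
            continue
        tries += 1
        if tries > 200 * n_residues:
            raise RuntimeError("could not pack the requested residue count; "
                               "increase radius")
        if all(np.linalg.norm(p - q) >= min_dist for q in pts):
            pts.append(p)
    order = rng.permutation(n_residues)
    coords = np.array(pts)[order]
    pool = _ALL_NAMES if names == "all" else _BACKGROUND
    res_names = [str(x) for x in rng.choice(pool, size=n_residues)]
    pid = protein_id or f"glob{n_residues}"
    model = [Residue(k + 1, res_names[k], coords[k][None], ("CA",))
             for k in range(n_residues)]
    manifest = {"protein_id": pid, "n_residues": n_residues,
                "radius": float(R), "seed": _seed_repr(seed)}
    return ProteinStructure(pid, [model]), manifest


def make_ring_protein(n_residues: int, seed=None,
                      protein_id: str | None = None,
                      jitter: float = 0.25):
    """Residues on a circle with a random chain order: a degree-neutral
    contact cohort.

    Every residue touches exactly its two spatial neighbours, so
    connectivity carries no information and ranking by it degenerates to
    random removal; sequence properties (residue names are random) are
    the only informative per-residue signal.  Used as the control
    geometry for the residue-elimination analysis.
    """
    rng = np.random.default_rng(seed)
    R = n_residues * BOND / (2 * np.pi)
    theta = 2 * np.pi * np.arange(n_residues) / n_residues
    pts = np.stack([R * np.cos(theta), R * np.sin(theta),
                    np.zeros(n_residues)], axis=1)
    pts += rng.normal(0.0, jitter, pts.shape)
    order = rng.permutation(n_residues)
    coords = pts[np.argsort(order)]  # chain index k sits at ring slot
    res_names = [str(x) for x in rng.choice(_ALL_NAMES, size=n_residues)]
    pid = protein_id or f"ring{n_residues}"
    model = [Residue(k + 1, res_names[k], coords[k][None], ("CA",))
             for k in range(n_residues)]
    manifest = {"protein_id": pid, "n_residues": n_residues,
                "radius": float(R),
                "seed": _seed_repr(seed)}
    return ProteinStructure(pid, [model]), manifest


# ---------------------------------------------------------------------------

def _clearance_direction(model, i: int, k: int) -> np.ndarray:
    """Unit vector out of the local chain plane at residue i (sign
    alternating with the pair index k): a residue parked along it clears
    i's chain neighbours by the largest possible margin."""
    pos = lambda r: model[r - 1].heavy_atoms.mean(axis=0)
    v1 = pos(min(i + 1, len(model))) - pos(i)
    v2 = pos(max(i - 1, 1)) - pos(i)
    c = np.cross(v1, v2)
    if np.linalg.norm(c) < 1e-6:         # collinear neighbourhood
        ref = np.array([0.23, 0.57, 0.79])
        c = np.cross(v1 if np.linalg.norm(v1) > 1e-9 else ref, ref)
    return _unit(c) * (1.0 if k % 2 == 0 else -1.0)


def make_ensemble(structure: ProteinStructure, n_models: int,
                  jitter: float = 0.2, persistence=None, seed=None):
    """NMR-like ensemble: jittered copies of model 1 with selected
    contacts broken in exactly ``ceil((1 - p) * n_models)`` models.

    ``persistence`` maps contact pairs (i, j) to their target fraction of
    models in contact; pairs must be disjoint in their second residue.
    """
    if n_models < 2:
        raise ValueError("an ensemble needs >= 2 models")
    persistence = dict(persistence or {})
    for pair, p in persistence.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"persistence for {pair} outside [0, 1]")
    movers = [j for (_, j) in persistence]
    if len(set(movers)) != len(movers):
        raise ValueError("persistence pairs must have distinct second residues")
    rng = np.random.default_rng(seed)
    base = structure.models[0]
    broken_in: dict[tuple[int, int], set[int]] = {}
    for pair, p in persistence.items():
        # round first: 1 - 0.7 is 0.30000000000000004 in binary floats
        n_break = int(np.ceil(round((1.0 - p) * n_models, 9)))
        broken_in[pair] = set(rng.choice(n_models, size=n_break,
                                         replace=False).tolist())
    models = []
    for m in range(n_models):
        model = []
        for res in base:
            coords = res.heavy_atoms + rng.normal(0.0, jitter,
                                                  res.heavy_atoms.shape)
            model.append(Residue(res.chain_index, res.residue_name, coords,
                                 res.atom_names))
        for k, ((i, j), broken) in enumerate(broken_in.items()):
            pi = model[i - 1].heavy_atoms.mean(axis=0)
            pj = model[j - 1].heavy_atoms.mean(axis=0)
            vec = pj - pi
            dist = np.linalg.norm(vec)
            res_j = model[j - 1]
            if m in broken:
                # lift j clear of the chain, beyond the 6 A criterion
                target_pos = pi + 9.0 * _clearance_direction(base, i, k)
                shift = target_pos - pj
            else:
                base_d = np.linalg.norm(
                    base[j - 1].heavy_atoms.mean(axis=0)
                    - base[i - 1].heavy_atoms.mean(axis=0))
                shift = (min(base_d, 5.5) / dist - 1.0) * vec
            model[j - 1] = Residue(res_j.chain_index, res_j.residue_name,
                                   res_j.heavy_atoms + shift, res_j.atom_names)
        models.append(model)
    ensemble = ProteinStructure(structure.id, models,
                                structure.author_numbering)
    manifest = {
        "protein_id": structure.id, "n_models": n_models,
        "jitter": float(jitter),
        "persistence": [{"i": i, "j": j, "fraction": float(p),
                         "broken_models": sorted(broken_in[(i, j)])}
                        for (i, j), p in persistence.items()],
        "seed": _seed_repr(seed),
    }
    return ensemble, manifest


# ---------------------------------------------------------------------------

def make_rate_table(structures, slope: float, intercept: float,
                    noise_sd: float, metric: str = "tcd", seed=None,
                    cutoff: float = 6.0, min_separation: int = 3,
                    contact_subsets=None):
    """ln k_f = slope * metric + intercept + N(0, noise_sd^2).

    ``contact_subsets`` optionally maps protein_id to the contact pairs
    from which the metric is computed (defaults to the full map).
    Returns ``(records, manifest)``.
    """
    rng = np.random.default_rng(seed)
    records, truth = [], []
    for structure in structures:
        cmap = compute_contacts(structure, cutoff, min_separation)
        pairs = (contact_subsets[structure.id] if contact_subsets is not None
                 else cmap.pairs)
        value = compute_metric(pairs, structure.length, metric)
        ln_kf = slope * value + intercept + rng.normal(0.0, noise_sd)
        records.append(RateRecord(structure.id, structure.length,
                                  float(ln_kf)))
        truth.append({"protein_id": structure.id, "metric_value": value})
    manifest = {"slope": slope, "intercept": intercept, "noise_sd": noise_sd,
                "metric": metric, "per_protein": truth,
                "seed": _seed_repr(seed)}
    return records, manifest


# ---------------------------------------------------------------------------

def make_trajectory(structure: ProteinStructure, persistent_pairs,
                    n_frames: int, seed=None, jitter: float = 0.10):
    """Trajectory-like multi-model structure with planted contact
    persistence.

    ``persistent_pairs`` maps (i, j) to the fraction of frames in which
    the pair is in contact; the pair is parked at 5.5 A (out of the chain plane) in exactly
    ``round(fraction * n_frames)`` frames and left at its native
    position otherwise.  Pairs
    must be disjoint in their second residue.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    persistent_pairs = dict(persistent_pairs)
    movers = [j for (_, j) in persistent_pairs]
    if len(set(movers)) != len(movers):
        raise ValueError("persistent pairs must have distinct second residues")
    rng = np.random.default_rng(seed)
    base = structure.models[0]
    contact_frames = {}
    for pair, f in persistent_pairs.items():
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"fraction for {pair} outside [0, 1]")
        k = int(round(f * n_frames))
        contact_frames[pair] = set(rng.choice(n_frames, size=k,
                                              replace=False).tolist())
    offsets = {pair: _clearance_direction(base, pair[0], k)
               for k, pair in enumerate(contact_frames)}
    models = []
    for t in range(n_frames):
        model = []
        for res in base:
            coords = res.heavy_atoms + rng.normal(0.0, jitter,
                                                  res.heavy_atoms.shape)
            model.append(Residue(res.chain_index, res.residue_name, coords,
                                 res.atom_names))
        for (i, j), frames in contact_frames.items():
            if t not in frames:
                continue        # leave j at its (distant) native position
            pi = model[i - 1].heavy_atoms.mean(axis=0)
            res_j = model[j - 1]
            target = pi + 5.5 * offsets[(i, j)]
            shift = target - res_j.heavy_atoms.mean(axis=0)
            model[j - 1] = Residue(res_j.chain_index, res_j.residue_name,
                                   res_j.heavy_atoms + shift, res_j.atom_names)
        models.append(model)
    traj = ProteinStructure(structure.id, models, structure.author_numbering)
    manifest = {
        "protein_id": structure.id, "n_frames": n_frames,
        "jitter": float(jitter),
        "planted": [{"i": i, "j": j, "fraction": float(f),
                     "n_contact_frames": len(contact_frames[(i, j)])}
                    for (i, j), f in persistent_pairs.items()],
        "seed": _seed_repr(seed),
    }
    return traj, manifest


# ---------------------------------------------------------------------------

def make_rigidity_profiles(n_proteins: int = 50, length: int = 150,
                           period: int = 24, amplitude: float = 3.0,
                           noise_sd: float = 0.3, seed=None):
    """Non-negative reduced force-constant profiles with rigidity peaks
    every ``period`` residues (random phase per protein) plus clipped
    Gaussian noise.  Returns ``(profiles, manifest)``."""
    if n_proteins < 1 or length < 2:
        raise ValueError("need n_proteins >= 1 and length >= 2")
    rng = np.random.default_rng(seed)
    profiles, phases = [], []
    for _ in range(n_proteins):
        phase = int(rng.integers(0, period))
        k = np.zeros(length)
        k[phase::period] = amplitude
        k = np.clip(k + rng.normal(0.0, noise_sd, size=length), 0.0, None)
        profiles.append(k)
        phases.append(phase)
    manifest = {"n_proteins": n_proteins, "length": length, "period": period,
                "amplitude": amplitude, "noise_sd": noise_sd,
                "phases": phases,
                "seed": _seed_repr(seed)}
    return profiles, manifest


# ---------------------------------------------------------------------------

def save_dataset(outdir, structures=None, manifest=None, rates=None):
    """Write structures (PDB), a rate table (TSV) and a manifest (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if structures:
        for s in structures:
            write_structure(s, outdir / f"{s.id}.pdb")
    if rates is not None:
        import pandas as pd

        pd.DataFrame([{"protein_id": r.protein_id, "L": r.L,
                       "ln_kf": r.ln_kf} for r in rates]).to_csv(
            outdir / "rates.tsv", sep="\t", index=False)
    if manifest is not None:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
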