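"""Coarse-grain elastic network Brownian dynamics and rigidity profiles.

The protein is reduced to one to three pseudo-atoms per residue (Calpha,
plus side-chain centroids for larger residues).  All bead pairs closer
than 9 A are linked by identical Hookean springs (gamma = 0.6 kcal
mol^-1 A^-2, rest length = build-time distance), and the network is
propagated with overdamped Langevin (Brownian) dynamics:

    x <- x - (dt / zeta) * grad U + sqrt(2 kB T dt / zeta) * eta

Per-residue force constants follow the rigidity-profile convention:
d_i(t) is the mean distance of residue i's Calpha bead from all other
residues' Calpha beads, and k_i = 3 kB T / Var(d_i) -- a stiff, buried
residue fluctuates little and gets a large k.  Per protein, profiles are
re-expressed as Z-scores k_z and clipped below zero (k' = max(k_z, 0)).
The autocorrelation of k' over sequence offsets L, pooled across
proteins and normalized by the number of index pairs at each offset,
exposes the characteristic ~24-residue spacing of rigid residues; its
significance is assessed by randomizing k' within each protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import ProteinStructure

__all__ = [
    "ElasticNetwork",
    "RigidityProfile",
    "build_network",
    "brownian_dynamics",
    "force_constants",
    "rigidity_autocorrelation",
    "randomization_test",
    "KB_KCAL",
]

KB_KCAL = 0.0019872041          # Boltzmann constant, kcal mol^-1 K^-1

_BACKBONE = {"N", "CA", "C", "O", "OXT"}
_LARGE_AROMATIC = {"TRP", "TYR", "PHE", "ARG"}


@dataclass
class ElasticNetwork:
    """Beads, springs and a common force constant gamma."""

    coords: np.ndarray              # (n_beads, 3) build-time positions
    residue_index: np.ndarray       # (n_beads,) 1-based residue of each bead
    ca_beads: np.ndarray            # (L,) bead id of each residue's Calpha
    springs: np.ndarray             # (n_springs, 2) bead index pairs
    rest_lengths: np.ndarray        # (n_springs,)
    gamma: float                    # kcal mol^-1 A^-2
    cutoff: float

    @property
    def n_beads(self) -> int:
        return len(self.coords)


@dataclass
class RigidityProfile:
    """Per-residue force constants with per-protein Z-scores."""

    protein_id: str
    k: np.ndarray

    def __post_init__(self):
        self.k = np.asarray(self.k, dtype=float)
        sd = self.k.std()
        if sd == 0:
            raise ValueError(f"{self.protein_id}: flat force-constant profile")
        self.k_z = (self.k - self.k.mean()) / sd
        self.k_prime = np.clip(self.k_z, 0.0, None)


def build_network(structure: ProteinStructure, cutoff: float = 9.0,
                  gamma: float = 0.6,
                  representation: str = "ca_plus_sidechain") -> ElasticNetwork:
    """Place beads and connect all pairs closer than ``cutoff``.

    ``ca_only`` keeps one bead per residue (the Calpha, or the first
    heavy atom); ``ca_plus_sidechain`` adds one side-chain centroid for
    residues with more than one side-chain heavy atom and a second
    (distal) centroid for the large side chains.
    """
    if structure.n_models != 1:
        raise ValueError("build the network from a single model")
    if representation not in ("ca_only", "ca_plus_sidechain"):
        raise ValueError(f"unknown representation {representation!r}")
    beads, res_idx, ca_beads = [], [], []
    for res in structure.models[0]:
        ca_beads.append(len(beads))
        beads.append(res.ca_coord)
        res_idx.append(res.chain_index)
        if representation == "ca_plus_sidechain" and res.atom_names:
            side = [res.heavy_atoms[k] for k, nm in enumerate(res.atom_names)
                    if nm not in _BACKBONE]
            if len(side) > 1:
                side = np.asarray(side)
                if res.residue_name in _LARGE_AROMATIC and len(side) >= 4:
                    half = len(side) // 2
                    beads.append(side[:half].mean(axis=0))
                    res_idx.append(res.chain_index)
                    beads.append(side[half:].mean(axis=0))
                    res_idx.append(res.chain_index)
                else:
                    beads.append(side.mean(axis=0))
                    res_idx.append(res.chain_index)
    coords = np.asarray(beads)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    # strict "< cutoff" per the network definition
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    keep = d < cutoff
    return ElasticNetwork(coords=coords,
                          residue_index=np.asarray(res_idx, dtype=int),
                          ca_beads=np.asarray(ca_beads, dtype=int),
                          springs=pairs[keep], rest_lengths=d[keep],
                          gamma=gamma, cutoff=cutoff)


def _spring_gradient(x: np.ndarray, springs: np.ndarray,
                     rest: np.ndarray, gamma: float) -> np.ndarray:
    a, b = springs[:, 0], springs[:, 1]
    dvec = x[a] - x[b]
    d = np.linalg.norm(dvec, axis=1)
    f = gamma * (d - rest) / np.maximum(d, 1e-12)   # dU/dd per unit vector
    grad = np.zeros_like(x)
    contrib = f[:, None] * dvec
    np.add.at(grad, a, contrib)
    np.add.at(grad, b, -contrib)
    return grad


def brownian_dynamics(network: ElasticNetwork, n_steps: int = 20000,
                      dt: float = 0.05, temperature: float = 300.0,
                      friction: float = 1.0, seed=None,
                      save_stride: int = 10) -> np.ndarray:
    """Overdamped Langevin trajectory of the network.

    ``dt`` and ``friction`` are in the reduced unit system where the
    mobility dt/friction multiplies a kcal mol^-1 A^-1 gradient; the
    stability bound for a single spring is dt * gamma / friction << 1
    (defaults give 0.03).  Returns the saved frames
    (n_saved, n_beads, 3); bitwise reproducible under a fixed seed.
    """
    if dt <= 0 or friction <= 0 or n_steps < 1:
        raise ValueError("dt, friction and n_steps must be positive")
    rng = np.random.default_rng(seed)
    x = network.coords.copy()
    mob = dt / friction
    noise_sd = np.sqrt(2.0 * KB_KCAL * temperature * dt / friction)
    span = np.ptp(network.coords) + 10.0
    frames = []
    for step in range(1, n_steps + 1):
        grad = _spring_gradient(x, network.springs, network.rest_lengths,
                                network.gamma)
        x = x - mob * grad
        if temperature > 0:
            x = x + noise_sd * rng.standard_normal(x.shape)
        if step % save_stride == 0:
            if not np.all(np.isfinite(x)) or np.ptp(x) > 50 * span:
                raise RuntimeError(
                    f"Brownian dynamics diverged at step {step}: reduce dt "
                    f"(dt*gamma/friction = {dt * network.gamma / friction:.3g})")
            frames.append(x.copy())
    return np.asarray(frames)


def force_constants(trajectory: np.ndarray, network: ElasticNetwork,
                    temperature: float = 300.0,
                    equilibration: float = 0.25,
                    protein_id: str = "protein") -> RigidityProfile:
    """Per-residue force constants from distance fluctuations.

    For residue i, d_i(frame) is the mean distance from its Calpha bead
    to all other residues' Calpha beads; k_i = 3 kB T / Var(d_i).  The
    first ``equilibration`` fraction of frames is discarded; at least
    100 frames must remain.
    """
    frames = np.asarray(trajectory)[int(len(trajectory) * equilibration):]
    if len(frames) < 100:
        raise ValueError(f"need >= 100 frames after equilibration, "
                         f"got {len(frames)}")
    ca = frames[:, network.ca_beads]          # (F, L, 3)
    L = ca.shape[1]
    d_mean = np.empty((len(ca), L))
    for f in range(len(ca)):                  # frame-wise to bound memory
        diff = ca[f, :, None, :] - ca[f, None, :, :]
        d_mean[f] = np.linalg.norm(diff, axis=-1).sum(axis=1) / (L - 1)
    var = d_mean.var(axis=0)
    if np.all(var == 0):
        raise ValueError("frozen trajectory: all distance variances are zero")
    with np.errstate(divide="ignore"):
        k = np.where(var > 0, 3.0 * KB_KCAL * temperature / var, np.inf)
    return RigidityProfile(protein_id, k)


# ---------------------------------------------------------------------------
# Autocorrelation of reduced force constants
# ---------------------------------------------------------------------------

def _lag_products(x: np.ndarray, max_lag: int) -> np.ndarray:
    """sum_i x[..., i] * x[..., i+L] for L = 0..max_lag via FFT.

    Works on a batch (last axis = sequence); returns (..., max_lag+1).
    """
    n = x.shape[-1]
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    f = np.fft.rfft(x, n=nfft, axis=-1)
    acf = np.fft.irfft(f * np.conj(f), n=nfft, axis=-1)
    return acf[..., :max_lag + 1]


def rigidity_autocorrelation(profiles, max_lag: int = 60) -> np.ndarray:
    """Pooled autocorrelation C(L) of clipped reduced force constants.

    C(L) = sum_p sum_i k'_i k'_{i+L} / sum_p #(pairs at offset L); index
    0 of the returned array is the L=0 term; invariant to the order of
    the profiles.  Offsets no protein can support are NaN.
    """
    arrs = [np.asarray(p.k_prime if isinstance(p, RigidityProfile) else p,
                       dtype=float) for p in profiles]
    if not arrs:
        raise ValueError("no profiles")
    if max_lag >= max(len(a) for a in arrs):
        raise ValueError("max_lag exceeds every profile length")
    num = np.zeros(max_lag + 1)
    den = np.zeros(max_lag + 1)
    for a in arrs:
        lags = min(max_lag, len(a) - 1)
        num[:lags + 1] += _lag_products(a, lags)
        den[:lags + 1] += len(a) - np.arange(lags + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _mean_over(C: np.ndarray, lo: int, hi: int) -> float:
    return float(np.nanmean(C[lo:hi + 1]))


def peak_flank_ratio(C: np.ndarray, peak=(22, 27),
                     flanks=((15, 20), (30, 35))) -> float:
    """Mean C over the peak range divided by mean C over the flanks."""
    flank_vals = np.concatenate([C[lo:hi + 1] for lo, hi in flanks])
    flank_mean = np.nanmean(flank_vals)
    if flank_mean == 0:
        raise ValueError("flank mean is zero; ratio undefined")
    return _mean_over(C, *peak) / float(flank_mean)


def randomization_test(profiles, n_shuffles: int = 9999,
                       peak=(22, 27), flanks=((15, 20), (30, 35)),
                       seed=None, batch: int = 500):
    """Permutation significance of the autocorrelation peak.

    The statistic is the mean C over ``peak`` divided by the mean C over
    the combined ``flanks``; the null permutes k' within each protein
    independently.  Returns ``(ratio, p)`` with
    p = (1 + #{shuffled ratio >= observed}) / (n_shuffles + 1).
    """
    arrs = [np.asarray(p.k_prime if isinstance(p, RigidityProfile) else p,
                       dtype=float) for p in profiles]
    max_lag = max(max(hi for _, hi in flanks), peak[1])
    if max_lag >= max(len(a) for a in arrs):
        raise ValueError("peak/flank ranges exceed every profile length")
    C_obs = rigidity_autocorrelation(arrs, max_lag)
    observed = peak_flank_ratio(C_obs, peak, flanks)

    rng = np.random.default_rng(seed)
    den = np.zeros(max_lag + 1)
    for a in arrs:
        lags = min(max_lag, len(a) - 1)
        den[:lags + 1] += len(a) - np.arange(lags + 1)
    exceed = 0
    done = 0
    while done < n_shuffles:
        b = min(batch, n_shuffles - done)
        num = np.zeros((b, max_lag + 1))
        for a in arrs:
            lags = min(max_lag, len(a) - 1)
            idx = np.argsort(rng.random((b, len(a))), axis=1)
            num[:, :lags + 1] += _lag_products(a[idx], lags)
        with np.errstate(invalid="ignore", divide="ignore"):
            Cs = np.where(den > 0, num / den, np.nan)
        flank_vals = np.concatenate(
            [Cs[:, lo:hi + 1] for lo, hi in flanks], axis=1)
        ratios = (np.nanmean(Cs[:, peak[0]:peak[1] + 1], axis=1)
                  / np.nanmean(flank_vals, axis=1))
        exceed += int(np.sum(ratios >= observed))
        done += b
    p = (1 + exceed) / (n_shuffles + 1)
    return observed, p
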