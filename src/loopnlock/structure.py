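"""Protein structure model: I/O, contact maps and per-residue properties.

Residues are renumbered 1..L in order of appearance along the selected
chain; author numbering is preserved in a lookup for reporting.  Only
heavy (non-hydrogen) atoms are kept.  Contacts are defined by the minimum
heavy-atom distance between two residues falling below a cutoff (default
6 A) at a minimum sequence separation (default |i - j| >= 3, i.e. the
1,2 and 1,3 contacts are excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Residue",
    "ProteinStructure",
    "ContactMap",
    "ResidueProperties",
    "StructureError",
    "read_structure",
    "write_structure",
    "compute_contacts",
    "residue_connectivity",
    "residue_hydrophobicity",
    "compute_properties",
    "FAUCHERE_PLISKA",
    "minmax_scale",
]


class StructureError(ValueError):
    """Raised for unreadable or internally inconsistent structures."""


@dataclass(frozen=True)
class Residue:
    """One amino-acid residue: index along the chain, name, heavy atoms."""

    chain_index: int                 # 1-based position along the polypeptide
    residue_name: str                # 3-letter code
    heavy_atoms: np.ndarray          # (n_atoms, 3) coordinates in Angstrom
    atom_names: tuple[str, ...] = ()

    def __post_init__(self):
        coords = np.asarray(self.heavy_atoms, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
            raise StructureError(
                f"residue {self.chain_index}: heavy_atoms must be a non-empty (n, 3) array"
            )
        object.__setattr__(self, "heavy_atoms", coords)
        if self.chain_index < 1:
            raise StructureError("chain_index must be >= 1")

    @property
    def ca_coord(self) -> np.ndarray:
        """C-alpha coordinate; falls back to the first heavy atom."""
        if "CA" in self.atom_names:
            return self.heavy_atoms[self.atom_names.index("CA")]
        return self.heavy_atoms[0]


class ProteinStructure:
    """A single chain, possibly with several models (e.g. an NMR ensemble).

    All models share an identical residue sequence; ``models[m][i]`` is
    residue ``i + 1`` of model ``m``.
    """

    def __init__(self, id: str, models: list[list[Residue]],
                 author_numbering: dict[int, str] | None = None):
        if not models or not models[0]:
            raise StructureError(f"{id}: structure has no residues")
        names0 = [r.residue_name for r in models[0]]
        for m, model in enumerate(models):
            if [r.residue_name for r in model] != names0:
                raise StructureError(
                    f"{id}: model 1 and model {m + 1} differ in residue "
                    f"count or names ({len(names0)} vs {len(model)} residues)"
                )
            for k, res in enumerate(model):
                if res.chain_index != k + 1:
                    raise StructureError(
                        f"{id}: model {m + 1} residue indices are not 1..L"
                    )
        if len(names0) < 3:
            raise StructureError(f"{id}: need at least 3 residues, got {len(names0)}")
        self.id = id
        self.models = models
        self.author_numbering = author_numbering or {}

    @property
    def length(self) -> int:
        return len(self.models[0])

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def residue_names(self) -> list[str]:
        return [r.residue_name for r in self.models[0]]

    def ca_coords(self, model: int = 0) -> np.ndarray:
        """(L, 3) array of C-alpha (or first-atom) coordinates."""
        return np.array([r.ca_coord for r in self.models[model]])

    def model_structure(self, model: int) -> "ProteinStructure":
        return ProteinStructure(self.id, [self.models[model]],
                                self.author_numbering)

    def __repr__(self):
        return (f"ProteinStructure(id={self.id!r}, L={self.length}, "
                f"models={self.n_models})")


@dataclass
class ContactMap:
    """Residue contacts of one protein: pairs (i, j), i < j, with the
    minimum heavy-atom distance per pair."""

    protein_id: str
    pairs: dict[tuple[int, int], float]
    cutoff: float
    min_separation: int
    n_residues: int

    def __post_init__(self):
        for (i, j) in self.pairs:
            if not (1 <= i < j <= self.n_residues):
                raise ValueError(f"invalid pair ({i}, {j})")
            if j - i < self.min_separation:
                raise ValueError(f"pair ({i}, {j}) below min_separation")

    @property
    def n_contacts(self) -> int:
        return len(self.pairs)

    def pair_array(self) -> np.ndarray:
        """(N, 2) int array of contact pairs, sorted."""
        if not self.pairs:
            return np.zeros((0, 2), dtype=int)
        return np.array(sorted(self.pairs), dtype=int)

    def separations(self) -> np.ndarray:
        arr = self.pair_array()
        return arr[:, 1] - arr[:, 0] if len(arr) else np.zeros(0, dtype=int)

    def __contains__(self, pair):
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs

    def subset(self, pairs) -> "ContactMap":
        """Restrict to the given pairs (must be present)."""
        keep = {}
        for p in pairs:
            key = (min(p), max(p))
            keep[key] = self.pairs[key]
        return ContactMap(self.protein_id, keep, self.cutoff,
                          self.min_separation, self.n_residues)

    def to_dataframe(self):
        import pandas as pd

        arr = self.pair_array()
        return pd.DataFrame({
            "protein_id": self.protein_id,
            "i": arr[:, 0] if len(arr) else [],
            "j": arr[:, 1] if len(arr) else [],
            "min_distance": [self.pairs[tuple(p)] for p in arr],
        })


# ---------------------------------------------------------------------------
# Structure I/O (biotite backend)
# ---------------------------------------------------------------------------

def _structure_from_atom_array(stack, id: str, chain: str | None) -> ProteinStructure:
    import biotite.structure as struc

    if stack.array_length() == 0:
        raise StructureError(f"{id}: no atoms")
    aa_mask = struc.filter_amino_acids(stack)
    heavy = ~np.isin(stack.element, ("H", "D"))
    mask = aa_mask & heavy
    if not mask.any():
        raise StructureError(f"{id}: no protein chain present")
    sub = stack[..., mask] if sub_is_stack(stack) else stack[mask]
    chains = sub.chain_id[np.sort(np.unique(sub.chain_id, return_index=True)[1])]
    target = chain if chain is not None else chains[0]
    if target not in chains:
        raise StructureError(f"{id}: chain {target!r} not found (have {list(chains)})")
    cmask = sub.chain_id == target
    sub = sub[..., cmask] if sub_is_stack(sub) else sub[cmask]

    starts = struc.get_residue_starts(sub, add_exclusive_stop=True)
    n_models = sub.stack_depth() if sub_is_stack(sub) else 1
    coords = sub.coord if sub_is_stack(sub) else sub.coord[None]
    models: list[list[Residue]] = [[] for _ in range(n_models)]
    author = {}
    for k in range(len(starts) - 1):
        lo, hi = starts[k], starts[k + 1]
        name = str(sub.res_name[lo])
        atom_names = tuple(str(a) for a in sub.atom_name[lo:hi])
        author[k + 1] = f"{sub.res_id[lo]}{str(getattr(sub, 'ins_code', [''] * len(sub.res_id))[lo]).strip()}"
        for m in range(n_models):
            models[m].append(Residue(k + 1, name, coords[m, lo:hi], atom_names))
    return ProteinStructure(id, models, author)


def sub_is_stack(arr) -> bool:
    import biotite.structure as struc

    return isinstance(arr, struc.AtomArrayStack)


def read_structure(path, format: str | None = None,
                   chain: str | None = None) -> ProteinStructure:
    """Read a PDB or mmCIF file into a :class:`ProteinStructure`.

    All models are kept; hydrogens are dropped; one chain is selected
    (default: the first protein chain); the highest-occupancy altloc is
    used.  ``format`` is inferred from the suffix when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"file not found: {path}")
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if format == "pdb":
            from biotite.structure.io.pdb import PDBFile

            f = PDBFile.read(str(path))
            stack = f.get_structure(model=None, altloc="occupancy")
        elif format == "mmcif":
            from biotite.structure.io.pdbx import CIFFile, get_structure

            f = CIFFile.read(str(path))
            stack = get_structure(f, model=None, altloc="occupancy")
        else:
            raise StructureError(f"unknown format {format!r}")
    except StructureError:
        raise
    except Exception as exc:  # biotite raises InvalidFileError for ragged models
        raise StructureError(
            f"could not parse {path} as {format}: models are inconsistent "
            f"or the file is unreadable ({exc})"
        ) from exc
    return _structure_from_atom_array(stack, path.stem, chain)


def write_structure(structure: ProteinStructure, path) -> None:
    """Write a (possibly multi-model) structure as a PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_atoms = sum(len(r.heavy_atoms) for r in structure.models[0])
    stack = struc.AtomArrayStack(structure.n_models, n_atoms)
    pos = 0
    for res in structure.models[0]:
        n = len(res.heavy_atoms)
        names = res.atom_names or tuple(
            "CA" if k == 0 else f"C{k}" for k in range(n))
        for k in range(n):
            stack.chain_id[pos + k] = "A"
            stack.res_id[pos + k] = res.chain_index
            stack.res_name[pos + k] = res.residue_name
            stack.atom_name[pos + k] = names[k]
            stack.element[pos + k] = names[k][0]
            stack.hetero[pos + k] = False
        pos += n
    for m in range(structure.n_models):
        pos = 0
        for res in structure.models[m]:
            n = len(res.heavy_atoms)
            stack.coord[m, pos:pos + n] = res.heavy_atoms
            pos += n
    f = PDBFile()
    f.set_structure(stack)
    f.write(str(path))


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------

def _model_contact_distances(model: list[Residue], cutoff: float,
                             min_separation: int) -> dict[tuple[int, int], float]:
    coords = np.concatenate([r.heavy_atoms for r in model])
    res_idx = np.concatenate([
        np.full(len(r.heavy_atoms), r.chain_index) for r in model
    ]).astype(int)
    tree = cKDTree(coords)
    atom_pairs = tree.query_pairs(cutoff, output_type="ndarray")
    out: dict[tuple[int, int], float] = {}
    if len(atom_pairs) == 0:
        return out
    ri = res_idx[atom_pairs[:, 0]]
    rj = res_idx[atom_pairs[:, 1]]
    lo, hi = np.minimum(ri, rj), np.maximum(ri, rj)
    sep_ok = (hi - lo) >= min_separation
    d = np.linalg.norm(coords[atom_pairs[:, 0]] - coords[atom_pairs[:, 1]], axis=1)
    for a, b, dist in zip(lo[sep_ok], hi[sep_ok], d[sep_ok]):
        key = (int(a), int(b))
        if dist < out.get(key, np.inf):
            out[key] = float(dist)
    return out


def compute_contacts(structure: ProteinStructure, cutoff: float = 6.0,
                     min_separation: int = 3,
                     model_policy: str = "first") -> ContactMap:
    """Contact map at a heavy-atom distance cutoff.

    A pair (i, j) is in contact when the minimum distance over all
    heavy-atom pairs is <= ``cutoff`` and j - i >= ``min_separation``.
    ``model_policy``: 'first' uses model 1 only; 'all_models_any' keeps
    pairs present in at least one model (best distance); 'all_models_all'
    keeps pairs present in every model (worst-case distance).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    if model_policy == "first":
        per_model = [_model_contact_distances(structure.models[0], cutoff,
                                              min_separation)]
    elif model_policy in ("all_models_any", "all_models_all"):
        per_model = [_model_contact_distances(m, cutoff, min_separation)
                     for m in structure.models]
    else:
        raise ValueError(f"unknown model_policy {model_policy!r}")

    if model_policy == "all_models_all":
        keys = set(per_model[0])
        for d in per_model[1:]:
            keys &= set(d)
        pairs = {k: max(d[k] for d in per_model) for k in keys}
    else:
        pairs: dict[tuple[int, int], float] = {}
        for d in per_model:
            for k, v in d.items():
                if v < pairs.get(k, np.inf):
                    pairs[k] = v
    return ContactMap(structure.id, pairs, cutoff, min_separation,
                      structure.length)


def residue_connectivity(structure: ProteinStructure, cutoff: float = 6.0,
                         min_separation: int = 2, model: int = 0) -> np.ndarray:
    """Neighbour count per residue: partners with |i - j| >= min_separation
    within the heavy-atom cutoff (each partner counted on both residues)."""
    target = structure if model == 0 else structure.model_structure(model)
    cmap = compute_contacts(target, cutoff, min_separation, "first")
    counts = np.zeros(structure.length, dtype=int)
    for (i, j) in cmap.pairs:
        counts[i - 1] += 1
        counts[j - 1] += 1
    return counts


# ---------------------------------------------------------------------------
# Hydrophobicity
# ---------------------------------------------------------------------------

# Octanol-water partition based side-chain hydrophobicity scale
# (Fauchere & Pliska pi values, kcal/mol).
FAUCHERE_PLISKA: dict[str, float] = {
    "ALA": 0.31, "ARG": -1.01, "ASN": -0.60, "ASP": -0.77, "CYS": 1.54,
    "GLN": -0.22, "GLU": -0.64, "GLY": 0.00, "HIS": 0.13, "ILE": 1.80,
    "LEU": 1.70, "LYS": -0.99, "MET": 1.23, "PHE": 1.79, "PRO": 0.72,
    "SER": -0.04, "THR": 0.26, "TRP": 2.25, "TYR": 0.96, "VAL": 1.22,
}

_SCALES = {"fauchere_pliska": FAUCHERE_PLISKA, "octanol": FAUCHERE_PLISKA}


def load_hydrophobicity_scale(path) -> dict[str, float]:
    """Load an alternative scale from a two-column text file
    (3-letter residue name, value)."""
    scale = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, value = line.split()[:2]
        scale[name.upper()] = float(value)
    return scale


def minmax_scale(values, lo: float | None = None, hi: float | None = None) -> np.ndarray:
    """Rescale to [0, 1]; a constant vector maps to all ones."""
    values = np.asarray(values, dtype=float)
    lo = float(np.min(values)) if lo is None else lo
    hi = float(np.max(values)) if hi is None else hi
    if hi == lo:
        return np.ones_like(values)
    return np.clip((values - lo) / (hi - lo), 0.0, 1.0)


def _window_average(values: np.ndarray, window: int) -> np.ndarray:
    if window == 1:
        return values.copy()
    half = window // 2
    out = np.empty_like(values, dtype=float)
    for k in range(len(values)):
        lo, hi = max(0, k - half), min(len(values), k + half + 1)
        out[k] = values[lo:hi].mean()      # truncated window at the edges
    return out


def residue_hydrophobicity(sequence, scale="fauchere_pliska",
                           window: int = 1):
    """Per-residue hydrophobicity from a named (or dict) scale.

    Returns ``(raw, scaled)``: the (optionally window-averaged) raw scale
    values and the same values rescaled to [0, 1] against the scale's own
    bounds (so the scale's most hydrophobic residue maps to 1.0).
    """
    if isinstance(scale, str):
        try:
            table = _SCALES[scale]
        except KeyError:
            raise ValueError(f"unknown hydrophobicity scale {scale!r}") from None
    else:
        table = dict(scale)
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be a positive odd integer")
    names = [r.residue_name if isinstance(r, Residue) else str(r).upper()
             for r in sequence]
    unknown = sorted({n for n in names if n not in table})
    if unknown:
        raise ValueError(f"residue name(s) not in scale: {', '.join(unknown)}")
    raw = _window_average(np.array([table[n] for n in names], dtype=float),
                          window)
    scaled = minmax_scale(raw, lo=min(table.values()), hi=max(table.values()))
    return raw, scaled


@dataclass
class ResidueProperties:
    """Per-residue property vectors used for lock scoring and ranking."""

    hydrophobicity: np.ndarray           # raw scale values
    connectivity: np.ndarray             # integer neighbour counts
    conservation: np.ndarray             # in [0, 1]; 1.0 when unknown
    scaled_hydrophobicity: np.ndarray    # [0, 1] against the scale bounds
    scaled_connectivity: np.ndarray      # [0, 1] per protein (min-max)

    def __post_init__(self):
        n = len(self.hydrophobicity)
        for name in ("connectivity", "conservation", "scaled_hydrophobicity",
                     "scaled_connectivity"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if np.any(self.conservation < 0) or np.any(self.conservation > 1):
            raise ValueError("conservation must lie in [0, 1]")

    @property
    def product(self) -> np.ndarray:
        """Scaled connectivity x scaled hydrophobicity (both in [0, 1])."""
        return self.scaled_connectivity * self.scaled_hydrophobicity


def compute_properties(structure: ProteinStructure,
                       conservation=None,
                       scale="fauchere_pliska",
                       cutoff: float = 6.0,
                       connectivity_min_separation: int = 2) -> ResidueProperties:
    """Convenience bundle: hydrophobicity, connectivity, conservation."""
    raw, scaled = residue_hydrophobicity(structure.residue_names, scale)
    conn = residue_connectivity(structure, cutoff, connectivity_min_separation)
    if conservation is None:
        cons = np.ones(structure.length)
    else:
        cons = np.asarray(conservation, dtype=float)
        if len(cons) != structure.length:
            raise ValueError("conservation length does not match structure")
    return ResidueProperties(
        hydrophobicity=raw,
        connectivity=conn,
        conservation=cons,
        scaled_hydrophobicity=scaled,
        scaled_connectivity=minmax_scale(conn.astype(float)),
    )
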