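import numpy as np
import pytest

from loopnlock.structure import ProteinStructure, Residue
from loopnlock.synthetic import make_globule_protein, make_loop_protein


def bead_structure(coords, names=None, pid="toy"):
    """Single-bead-per-residue structure from an (L, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    names = names or ["GLY"] * len(coords)
    model = [Residue(k + 1, names[k], coords[k][None], ("CA",))
             for k in range(len(coords))]
    return ProteinStructure(pid, [model])


def brute_force_contacts(structure, cutoff=6.0, min_separation=3, model=0):
    """All-pairs reference contact computation (no spatial index)."""
    res = structure.models[model]
    pairs = {}
    for a in range(len(res)):
        for b in range(a + 1, len(res)):
            if res[b].chain_index - res[a].chain_index < min_separation:
                continue
            d = np.linalg.norm(res[a].heavy_atoms[:, None, :]
                               - res[b].heavy_atoms[None, :, :], axis=-1).min()
            if d <= cutoff:
                pairs[(res[a].chain_index, res[b].chain_index)] = float(d)
    return pairs


@pytest.fixture(scope="session")
def loop_protein():
    structure, manifest = make_loop_protein(
        80, [(10, 35, 5.0), (45, 70, 5.0)], seed=11)
    return structure, manifest


@pytest.fixture(scope="session")
def globule_cohort():
    structures = [make_globule_protein(50 + 4 * k, seed=100 + k)[0]
                  for k in range(8)]
    return structures
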