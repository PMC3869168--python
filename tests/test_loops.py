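import numpy as np
import pytest
from dataclasses import replace

from loopnlock.loops import (LoopCandidate, LockRegion, build_core,
                             enumerate_closed_loops, find_loops_and_core,
                             minimal_lock_pair, refine_locks_nmr,
                             score_lock_region, select_loops)
from loopnlock.structure import (ContactMap, ResidueProperties,
                                 compute_contacts, compute_properties)
from loopnlock.synthetic import make_ensemble, make_loop_protein


def _cmap(pairs, L, pid="toy", min_sep=3):
    return ContactMap(pid, {p: 5.0 for p in pairs}, 6.0, min_sep, L)


def _props(L, conn=None, hydro=None, cons=None):
    conn = np.asarray(conn if conn is not None else np.ones(L))
    hydro = np.asarray(hydro if hydro is not None else np.ones(L))
    cons = np.asarray(cons if cons is not None else np.ones(L))
    return ResidueProperties(hydro, conn, cons, hydro,
                             conn / max(conn.max(), 1))


def test_enumerate_length_band():
    cmap = _cmap([(10, 35), (5, 9), (1, 60)], L=80, min_sep=3)
    cands = enumerate_closed_loops(cmap)
    assert [(c.start, c.end) for c in cands] == [(10, 35)]
    assert cands[0].length == 26


def test_enumerate_matches_brute_filter(loop_protein):
    s, _ = loop_protein
    cmap = compute_contacts(s)
    cands = enumerate_closed_loops(cmap, 12, 50)
    expected = sorted((i, j) for (i, j) in cmap.pairs
                      if 12 <= j - i + 1 <= 50)
    assert [(c.start, c.end) for c in cands] == expected


def test_score_uniform_properties_ranked_by_connectivity():
    L = 60
    conn = np.ones(L)
    conn[[9, 34]] = 8          # engineered high-connectivity ends
    props = _props(L, conn=conn)
    a = LoopCandidate(10, 35)
    b = LoopCandidate(20, 45)
    assert score_lock_region(a, props, 1) > score_lock_region(b, props, 1)


def test_score_window1_is_product_of_end_values():
    L = 50
    conn = np.arange(1, L + 1, dtype=float)
    props = _props(L, conn=conn)
    c = LoopCandidate(10, 30)
    sc = score_lock_region(c, props, 1)
    expected = 0.5 * (props.scaled_connectivity[9]
                      + props.scaled_connectivity[29])
    assert sc == pytest.approx(expected)


def test_select_single_candidate():
    c = LoopCandidate(10, 35, lock_score=1.0)
    assert select_loops([c]) == [c]


def test_select_rejects_heavy_overlap():
    hi = LoopCandidate(10, 40, lock_score=2.0)
    lo = LoopCandidate(12, 42, lock_score=1.0)   # shares ~27 interior residues
    assert select_loops([hi, lo]) == [hi]


def test_select_allows_shared_lock_endpoint():
    a = LoopCandidate(10, 35, lock_score=2.0)
    b = LoopCandidate(35, 60, lock_score=1.0)
    assert select_loops([a, b]) == [a, b]


def test_select_tie_break_prefers_shorter():
    # equal scores, heavy mutual overlap: the shorter candidate wins
    a = LoopCandidate(10, 45, lock_score=1.0)
    b = LoopCandidate(12, 42, lock_score=1.0)
    assert select_loops([a, b]) == [b]


def test_selected_loops_respect_overlap_invariant(loop_protein):
    s, _ = loop_protein
    cmap = compute_contacts(s)
    props = compute_properties(s)
    cands = [replace(c, lock_score=score_lock_region(c, props, 3))
             for c in enumerate_closed_loops(cmap)]
    sel = select_loops(cands, max_overlap=5)
    for x in sel:
        for y in sel:
            if x is not y:
                assert len(x.interior() & y.interior()) <= 5


def test_refine_locks_requires_ensemble(loop_protein):
    s, _ = loop_protein
    loops, _ = find_loops_and_core(s)
    with pytest.raises(ValueError, match="unrefined"):
        refine_locks_nmr(loops, s)


def _single_contact_structure():
    """Extended chain with exactly one cross contact, (10, 35) at 5 A."""
    from conftest import bead_structure

    coords = np.array([[3.8 * k, 0.0, 0.0] for k in range(40)])
    coords[34] = coords[9] + np.array([0.0, 5.0, 0.0])
    return bead_structure(coords, pid="onelock")


@pytest.mark.parametrize("planted,threshold,kept", [
    (1.0, 0.5, True),    # contact in 10/10 models -> retained
    (0.2, 0.5, False),   # contact in 2/10 models -> eliminated
    (0.7, 0.5, True),
    (0.7, 0.8, False),
])
def test_refine_locks_persistence(planted, threshold, kept):
    from loopnlock.loops import ClosedLoop

    base = _single_contact_structure()
    loop = ClosedLoop(10, 35, 1.0, LockRegion((10, 11), 10),
                      LockRegion((35, 36), 35))
    ens, _ = make_ensemble(base, 10, jitter=0.02,
                           persistence={(10, 35): planted}, seed=22)
    (refined,) = refine_locks_nmr([loop], ens,
                                  persistence_threshold=threshold)
    if kept:
        assert refined.lock_a.persistent
        assert refined.lock_a.residues == (10,)
        assert refined.lock_b.residues == (35,)
    else:
        assert not refined.lock_a.persistent
    # residues without any persistent cross contact never survive
    assert refined.degenerate


def test_minimal_pair_single_residue_locks():
    cmap = _cmap([(5, 30)], L=40)
    pair = minimal_lock_pair(LockRegion((5,), 5), LockRegion((30,), 30),
                             cmap, np.ones(40))
    assert pair == (5, 30)


def test_minimal_pair_maximizes_connectivity_sum():
    pairs = [(5, 30), (5, 31), (6, 30), (6, 31)]
    cmap = _cmap(pairs, L=40)
    conn = np.ones(40)
    conn[5] = 7   # residue 6
    conn[30] = 7  # residue 31
    pair = minimal_lock_pair(LockRegion((5, 6), 5), LockRegion((30, 31), 30),
                             cmap, conn)
    assert pair == (6, 31)
    # exhaustive oracle
    best = max(pairs, key=lambda p: (conn[p[0] - 1] + conn[p[1] - 1],
                                     -p[0], -p[1]))
    assert pair == best


def test_minimal_pair_no_cross_contact_errors():
    cmap = _cmap([(1, 20)], L=40)
    with pytest.raises(ValueError, match="invalid"):
        minimal_lock_pair(LockRegion((5, 6), 5), LockRegion((30, 31), 30),
                          cmap, np.ones(40))


def test_build_core_example():
    # pair {a, b} with a~{c, d} and b~{c}
    a, b, c, d = 5, 30, 12, 20
    pairs = [(a, b), (a, c), (a, d), (c, b)]
    cmap = _cmap(pairs + [(14, 25)], L=40)
    core = build_core({a, b}, cmap)
    assert core.core_residues == {a, b, c, d}
    assert core.core_contacts == set(pairs)
    assert (14, 25) not in core.core_contacts


def test_build_core_monotone():
    pairs = [(5, 30), (5, 12), (12, 30), (8, 22), (8, 35), (14, 25)]
    cmap = _cmap(pairs, L=40)
    small = build_core({5, 30}, cmap)
    big = build_core({5, 30, 8}, cmap)
    assert small.core_residues <= big.core_residues
    assert small.core_contacts <= big.core_contacts


def test_lock_regions_within_size_band(loop_protein):
    s, _ = loop_protein
    loops, _ = find_loops_and_core(s)
    for lp in loops:
        assert 2 <= len(lp.lock_a.residues) <= 8
        assert 2 <= len(lp.lock_b.residues) <= 8


@pytest.mark.parametrize("seed", range(6))
def test_planted_loop_recovery(seed):
    rng = np.random.default_rng(1000 + seed)
    length = int(rng.integers(15, 41))
    s0 = int(rng.integers(5, 15))
    e0 = s0 + length - 1
    n = e0 + int(rng.integers(5, 20))
    structure, _ = make_loop_protein(n, [(s0, e0, 5.0)], seed=seed)
    loops, core = find_loops_and_core(structure)
    assert any(abs(l.start - s0) <= 1 and abs(l.end - e0) <= 1 for l in loops)
    assert core is not None
    assert core.minimal_pair_residues <= core.core_residues
    full = compute_contacts(structure)
    assert core.core_contacts <= set(full.pairs)
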