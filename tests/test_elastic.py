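import numpy as np
import pytest

from loopnlock.elastic import (KB_KCAL, brownian_dynamics, build_network,
                               force_constants, peak_flank_ratio,
                               randomization_test, rigidity_autocorrelation,
                               RigidityProfile)
from loopnlock.synthetic import make_globule_protein, make_rigidity_profiles

from conftest import bead_structure


def _pair_structure(dist, extra=None):
    coords = [[0.0, 0.0, 0.0], [dist, 0.0, 0.0],
              extra or [200.0, 0.0, 0.0]]
    return bead_structure(np.array(coords))


def test_network_single_spring():
    net = build_network(_pair_structure(5.0), cutoff=9.0)
    assert len(net.springs) == 1
    assert net.rest_lengths[0] == pytest.approx(5.0)
    assert net.gamma == 0.6


def test_network_beyond_cutoff_no_spring():
    net = build_network(_pair_structure(10.0), cutoff=9.0)
    assert len(net.springs) == 0


def test_network_matches_brute_force_on_globule():
    s, _ = make_globule_protein(40, seed=1)
    net = build_network(s, cutoff=9.0, representation="ca_only")
    coords = s.ca_coords()
    expected = sum(np.linalg.norm(coords[a] - coords[b]) < 9.0
                   for a in range(40) for b in range(a + 1, 40))
    assert len(net.springs) == expected


def test_bd_zero_temperature_stays_at_equilibrium():
    net = build_network(_pair_structure(5.0), cutoff=9.0)
    traj = brownian_dynamics(net, n_steps=500, dt=0.05, temperature=0.0,
                             seed=0)
    np.testing.assert_allclose(traj[-1], net.coords, atol=1e-10)


def test_bd_seed_reproducible():
    net = build_network(_pair_structure(5.0), cutoff=9.0)
    t1 = brownian_dynamics(net, n_steps=400, seed=3)
    t2 = brownian_dynamics(net, n_steps=400, seed=3)
    np.testing.assert_array_equal(t1, t2)


def test_bd_divergence_detected():
    net = build_network(_pair_structure(5.0), cutoff=9.0)
    with pytest.raises(RuntimeError, match="diverged|dt"):
        brownian_dynamics(net, n_steps=2000, dt=50.0, seed=1)


def test_single_spring_equipartition():
    """Stationary bond-length variance of an isolated pair ~ kBT/gamma."""
    net = build_network(_pair_structure(10.0, extra=[300.0, 0, 0]),
                        cutoff=11.0)
    assert len(net.springs) == 1
    samples = []
    for seed in (7, 17):
        traj = brownian_dynamics(net, n_steps=300000, dt=0.02, seed=seed,
                                 save_stride=10)
        a, b = net.springs[0]
        d = np.linalg.norm(traj[:, a] - traj[:, b], axis=1)
        samples.append(d[len(d) // 5:])
    var = np.var(np.concatenate(samples))
    expected = KB_KCAL * 300.0 / net.gamma
    assert var == pytest.approx(expected, rel=0.05)


def test_force_constant_buried_vs_terminal():
    """A densely connected central bead is stiffer than a chain end."""
    s, _ = make_globule_protein(30, seed=5)
    net = build_network(s, representation="ca_only")
    ks = []
    for seed in (0, 1, 2):
        traj = brownian_dynamics(net, n_steps=6000, dt=0.05, seed=seed)
        ks.append(force_constants(traj, net, protein_id=s.id).k)
    k = np.mean(ks, axis=0)
    degree = np.zeros(30)
    for a, b in net.springs:
        ra, rb = net.residue_index[a] - 1, net.residue_index[b] - 1
        degree[ra] += 1
        degree[rb] += 1
    assert k[np.argmax(degree)] > k[np.argmin(degree)]


def test_force_constant_scales_with_gamma():
    s, _ = make_globule_protein(25, seed=6)
    k_by_gamma = {}
    for gamma in (0.6, 1.2):
        net = build_network(s, gamma=gamma, representation="ca_only")
        traj = brownian_dynamics(net, n_steps=40000, dt=0.02, seed=8)
        k_by_gamma[gamma] = force_constants(traj, net).k
    ratio = np.median(k_by_gamma[1.2] / k_by_gamma[0.6])
    assert ratio == pytest.approx(2.0, rel=0.15)


def test_force_constants_need_enough_frames():
    net = build_network(_pair_structure(5.0), cutoff=9.0)
    traj = brownian_dynamics(net, n_steps=100, dt=0.05, seed=1)
    with pytest.raises(ValueError, match="frames"):
        force_constants(traj, net)


def test_zscore_profile_normalization():
    prof = RigidityProfile("p", np.array([1.0, 2.0, 3.0, 10.0]))
    assert prof.k_z.mean() == pytest.approx(0.0, abs=1e-12)
    assert prof.k_z.std() == pytest.approx(1.0, rel=1e-12)
    assert np.all(prof.k_prime >= 0)


def test_autocorrelation_alternating_profile():
    C = rigidity_autocorrelation([np.array([1.0, 0, 1, 0, 1, 0, 1, 0])],
                                 max_lag=3)
    assert C[1] == 0.0
    assert C[2] > C[1]


def test_autocorrelation_zero_profiles():
    C = rigidity_autocorrelation([np.zeros(20), np.zeros(15)], max_lag=10)
    np.testing.assert_allclose(C, 0.0)


def test_autocorrelation_order_invariant():
    profs, _ = make_rigidity_profiles(6, 80, seed=3)
    C1 = rigidity_autocorrelation(profs, 30)
    C2 = rigidity_autocorrelation(profs[::-1], 30)
    np.testing.assert_allclose(C1, C2, rtol=1e-10)


def test_autocorrelation_matches_direct_sum():
    profs, _ = make_rigidity_profiles(3, 60, seed=4)
    C = rigidity_autocorrelation(profs, 20)
    for L in (1, 7, 20):
        num = sum(float(np.dot(p[:-L], p[L:])) for p in profs)
        den = sum(len(p) - L for p in profs)
        assert C[L] == pytest.approx(num / den, rel=1e-9)


def test_planted_period_peak():
    profs, _ = make_rigidity_profiles(50, 150, period=24, seed=5)
    C = rigidity_autocorrelation(profs, 40)
    argmax = 10 + int(np.nanargmax(C[10:41]))
    assert 22 <= argmax <= 26


def test_randomization_planted_vs_null():
    profs, _ = make_rigidity_profiles(50, 150, period=24, seed=6)
    ratio, p = randomization_test(profs, n_shuffles=999, seed=7)
    assert ratio > 1.2
    assert p <= 2 / 1000
    flat, _ = make_rigidity_profiles(20, 100, amplitude=0.0, noise_sd=1.0,
                                     seed=8)
    ratio0, p0 = randomization_test(flat, n_shuffles=199, seed=9)
    assert ratio0 == pytest.approx(1.0, abs=0.25)
    assert p0 > 0.01


def test_null_pvalues_uniform():
    """Permutation p-values under a true null are uniform (KS check)."""
    from scipy import stats

    rng = np.random.default_rng(10)
    pvals = []
    for rep in range(60):
        profs = [np.clip(rng.normal(0, 1, size=100), 0, None)
                 for _ in range(8)]
        _, p = randomization_test(profs, n_shuffles=199,
                                  seed=int(rng.integers(2 ** 31)))
        pvals.append(p)
    ks = stats.ks_1samp(pvals, stats.uniform.cdf)
    assert ks.pvalue > 0.01
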