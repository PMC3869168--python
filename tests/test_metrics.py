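import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from loopnlock.metrics import (RateRecord, absolute_contact_order,
                               absolute_total_contact_distance,
                               contact_order, correlate_lnkf,
                               load_rate_table, random_contact_control,
                               separation_scan, total_contact_distance)
from loopnlock.structure import ContactMap, compute_contacts
from loopnlock.synthetic import make_globule_protein, make_rate_table


def oracle_sum(pairs):
    return sum(abs(i - j) for (i, j) in set(pairs))


def test_contact_order_examples():
    assert contact_order({(1, 8)}, 10) == pytest.approx(0.7)
    assert contact_order({(1, 4), (1, 9)}, 10) == pytest.approx(0.55)


def test_tcd_examples():
    assert total_contact_distance({(1, 8)}, 10) == pytest.approx(0.07)
    # identity TCD = CO * N / L
    pairs = {(1, 4), (1, 9)}
    assert total_contact_distance(pairs, 10) == pytest.approx(
        contact_order(pairs, 10) * len(pairs) / 10)


def test_empty_subset_errors():
    with pytest.raises(ValueError):
        contact_order(set(), 10)
    with pytest.raises(ValueError):
        total_contact_distance(set(), 10)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.integers(10, 80), st.data())
def test_metric_identities_and_oracle(L, data):
    n = data.draw(st.integers(1, 40))
    pairs = set()
    idx = data.draw(st.lists(st.tuples(st.integers(1, L), st.integers(1, L)),
                             min_size=n, max_size=n))
    for a, b in idx:
        if a != b:
            pairs.add((min(a, b), max(a, b)))
    if not pairs:
        pairs = {(1, L)}
    co = contact_order(pairs, L)
    tcd = total_contact_distance(pairs, L)
    s = oracle_sum(pairs)
    assert co == pytest.approx(s / (L * len(pairs)), rel=1e-12)
    assert tcd == pytest.approx(s / L ** 2, rel=1e-12)
    assert absolute_contact_order(pairs, L) == pytest.approx(co * L, rel=1e-12)
    assert absolute_total_contact_distance(pairs, L) == pytest.approx(
        tcd * L, rel=1e-12)


def test_tcd_additive_over_disjoint_subsets():
    L = 50
    a = {(1, 10), (5, 30)}
    b = {(2, 20), (7, 44)}
    total = total_contact_distance(a | b, L) * L ** 2
    assert total == pytest.approx(total_contact_distance(a, L) * L ** 2
                                  + total_contact_distance(b, L) * L ** 2)


def test_metrics_ignore_duplicates_and_order():
    L = 30
    assert total_contact_distance([(5, 1), (1, 5), (2, 9)], L) == \
        total_contact_distance([(2, 9), (1, 5)], L)


def test_tcd_less_sensitive_than_co_to_near_neighbours():
    # compact globule: toggling min_separation 1 -> 3 changes CO more
    s, _ = make_globule_protein(60, seed=42)
    loose = compute_contacts(s, min_separation=1)
    strict = compute_contacts(s, min_separation=3)
    rel = lambda f: abs(f(loose.pairs, 60) - f(strict.pairs, 60)) / f(strict.pairs, 60)
    assert rel(total_contact_distance) < rel(contact_order)


def test_correlation_exact_line():
    values = {f"p{k}": 0.05 + 0.01 * k for k in range(6)}
    rates = [RateRecord(f"p{k}", 50, -50 * values[f"p{k}"] + 10)
             for k in range(6)]
    res = correlate_lnkf(values, rates)
    assert res.r2 == pytest.approx(1.0)
    assert res.slope == pytest.approx(-50.0)
    assert res.intercept == pytest.approx(10.0)


def test_correlation_constant_metric_errors():
    values = {f"p{k}": 0.3 for k in range(5)}
    rates = [RateRecord(f"p{k}", 50, float(k)) for k in range(5)]
    with pytest.raises(ValueError, match="constant"):
        correlate_lnkf(values, rates)


def test_correlation_needs_three_proteins():
    values = {"a": 0.1, "b": 0.2}
    rates = [RateRecord("a", 50, 1.0), RateRecord("b", 50, 2.0)]
    with pytest.raises(ValueError):
        correlate_lnkf(values, rates)


def test_r2_matches_closed_form_at_n200():
    # ln k_f = a*x + b + noise: E[r^2] ~ var(a x)/(var(a x) + sigma^2)
    rng = np.random.default_rng(7)
    a, sigma = -60.0, 1.0
    x = rng.uniform(0.05, 0.25, size=200)
    values = {f"p{k}": float(x[k]) for k in range(200)}
    rates = [RateRecord(f"p{k}", 50,
                        float(a * x[k] + 5 + rng.normal(0, sigma)))
             for k in range(200)]
    res = correlate_lnkf(values, rates)
    expected = np.var(a * x) / (np.var(a * x) + sigma ** 2)
    assert res.r2 == pytest.approx(expected, abs=0.05)


def test_rate_generator_noise_free_gives_r2_one(globule_cohort):
    rates, _ = make_rate_table(globule_cohort, -60, 10, 0.0, seed=1)
    values = {s.id: total_contact_distance(compute_contacts(s).pairs,
                                           s.length)
              for s in globule_cohort}
    assert correlate_lnkf(values, rates).r2 == pytest.approx(1.0)


class TestRandomContactControl:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        maps, values, rates = {}, {}, []
        for k in range(8):
            s, _ = make_globule_protein(45 + 3 * k, seed=300 + k)
            cmap = compute_contacts(s)
            maps[s.id] = cmap
            values[s.id] = total_contact_distance(cmap.pairs, s.length)
            rates.append(RateRecord(s.id, s.length,
                                    float(-60 * values[s.id] + 10
                                          + rng.normal(0, 0.3))))
        return maps, values, rates

    def test_add_one_rule_and_bounds(self):
        maps, values, rates = self._setup()
        obs = correlate_lnkf(values, rates).r2
        k = {p: min(20, maps[p].n_contacts) for p in maps}
        null, p = random_contact_control(maps, k, rates, obs,
                                         n_reps=49, seed=5)
        assert len(null) == 49
        assert np.all((null >= 0) & (null <= 1))
        expected = (1 + int((null >= obs).sum())) / 50
        assert p == expected
        assert p >= 1 / 50

    def test_seed_reproducibility(self):
        maps, values, rates = self._setup()
        k = {p: 15 for p in maps}
        n1, p1 = random_contact_control(maps, k, rates, 0.5, 30, seed=9)
        n2, p2 = random_contact_control(maps, k, rates, 0.5, 30, seed=9)
        assert np.array_equal(n1, n2) and p1 == p2

    def test_unreachable_k_errors(self):
        maps, values, rates = self._setup()
        k = {p: maps[p].n_contacts + 10 for p in maps}
        with pytest.raises(ValueError):
            random_contact_control(maps, k, rates, 0.5, 5, seed=1)


def test_separation_scan_reproduces_base_and_grid_size(globule_cohort):
    maps = {s.id: compute_contacts(s) for s in globule_cohort}
    rates, _ = make_rate_table(globule_cohort, -60, 10, 0.4, seed=2)
    scan = separation_scan(maps, rates, min_sep_grid=range(2, 55))
    assert len(scan) == 53
    base_vals = {pid: total_contact_distance(m.pairs, m.n_residues)
                 for pid, m in maps.items()}
    base = correlate_lnkf(base_vals, rates)
    at3 = scan[scan.min_sep == 3].iloc[0]
    assert at3.r2 == pytest.approx(base.r2)


def test_separation_scan_band_knockout():
    # rates generated only from the 25 <= |i-j| <= 40 band: excluding the
    # band collapses the correlation
    structures = [make_globule_protein(70, seed=500 + k,
                                       protein_id=f"bk{k}")[0]
                  for k in range(30)]
    maps = {s.id: compute_contacts(s) for s in structures}
    subsets = {}
    for s in structures:
        arr = maps[s.id].pair_array()
        seps = arr[:, 1] - arr[:, 0]
        keep = (seps >= 25) & (seps <= 40)
        subsets[s.id] = {tuple(p) for p in arr[keep]}
    rates, _ = make_rate_table(structures, -60, 10, 0.1, seed=3,
                               contact_subsets=subsets)
    band = separation_scan(maps, rates, min_sep_grid=[25],
                           max_sep=40).iloc[0].r2
    excluded = separation_scan(maps, rates, min_sep_grid=[41]).iloc[0].r2
    assert band > 0.8
    assert excluded < 0.1


def test_rate_table_loader_roundtrip(tmp_path, globule_cohort):
    rates, _ = make_rate_table(globule_cohort[:3], -60, 10, 0.2, seed=4)
    from loopnlock.synthetic import save_dataset

    save_dataset(tmp_path, rates=rates)
    df = load_rate_table(tmp_path / "rates.tsv")
    assert set(df.protein_id) == {s.id for s in globule_cohort[:3]}
    with pytest.raises(ValueError):
        bad = tmp_path / "bad.tsv"
        bad.write_text("a\tb\n1\t2\n")
        load_rate_table(bad)
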