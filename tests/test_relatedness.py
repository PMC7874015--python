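"""Method-of-moments IBD, expected IBS and Mendelian-error engines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import grapekin as gk
import oracles
from conftest import tiny_panel


class TestIBSCounts:
    @pytest.mark.parametrize(
        "d1, d2, state",
        [(0, 2, 0), (1, 1, 2), (0, 1, 1), (2, 1, 1), (2, 2, 2)],
    )
    def test_state_table(self, d1, d2, state):
        panel = tiny_panel([[d1], [d2]])
        c = gk.ibs_counts(panel, "s1", "s2")
        assert getattr(c, f"n{state}") == 1 and c.n_valid == 1

    def test_identical_individuals_all_ibs2(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, 40).astype(np.int8)
        panel = tiny_panel(np.vstack([d, d]))
        c = gk.ibs_counts(panel, "s1", "s2")
        assert c.n2 == c.n_valid == 40

    def test_matches_loop_oracle_with_missing(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, (2, 200)).astype(np.int8)
        d[rng.random(d.shape) < 0.15] = gk.MISSING
        panel = tiny_panel(d)
        c = gk.ibs_counts(panel, "s1", "s2")
        assert (c.n0, c.n1, c.n2) == oracles.ibs_counts_loop(d[0], d[1])


class TestExpectedIBS:
    def test_half_frequency_closed_values(self):
        """p = 0.5: E[.|IBD0] = (0.125, 0.5, 0.375), E[.|IBD1] = (0, 0.5, 0.5)."""
        e = gk.expected_ibs(np.array([0.5]))
        assert e.e00 == pytest.approx(0.125)
        assert e.e10 == pytest.approx(0.5)
        assert e.e20 == pytest.approx(0.375)
        assert e.e11 == pytest.approx(0.5)
        assert e.e21 == pytest.approx(0.5)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(p=st.floats(0.01, 0.99))
    def test_columns_normalize_and_match_enumeration(self, p):
        e = gk.expected_ibs(np.array([p]))
        assert e.e00 + e.e10 + e.e20 == pytest.approx(1.0, abs=1e-12)
        table = oracles.ibs_given_ibd(p)
        assert e.e00 == pytest.approx(table[0, 0], abs=1e-12)
        assert e.e10 == pytest.approx(table[1, 0], abs=1e-12)
        assert e.e20 == pytest.approx(table[2, 0], abs=1e-12)
        assert e.e11 == pytest.approx(table[1, 1], abs=1e-12)
        assert e.e21 == pytest.approx(table[2, 1], abs=1e-12)

    def test_monomorphic_markers_excluded(self):
        e = gk.expected_ibs(np.array([0.0, 0.5, 1.0, np.nan]))
        assert e.n_valid == 1 and e.n_excluded == 3

    def test_near_monomorphic_limit(self):
        e = gk.expected_ibs(np.array([1e-9]))
        assert e.e20 == pytest.approx(1.0, abs=1e-6)


class TestMomIBD:
    def test_clone_estimate_is_001(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, 300).astype(np.int8)
        panel = tiny_panel(np.vstack([d, d]))
        p = gk.allele_frequencies(panel)
        est = gk.mom_ibd(gk.ibs_counts(panel, "s1", "s2"), gk.expected_ibs(p))
        assert (est.k0, est.k1, est.k2) == (0.0, 0.0, 1.0)
        assert est.kinship == 0.5

    def test_po_pair_k1_near_one(self):
        cfg = gk.SimulationConfig(
            n_markers=2000, n_founders=20, seed=17,
            events=[gk.Cross(f"F{2 * i + 1:02d}", f"F{2 * i + 2:02d}", f"C{i}")
                    for i in range(10)],
        )
        founders, p = gk.simulate_founders(cfg)
        panel, _ = gk.gene_drop(founders, cfg)
        exp = gk.expected_ibs(p)
        k1s = [
            gk.mom_ibd(gk.ibs_counts(panel, f"C{i}", f"F{2 * i + 1:02d}"), exp).k1
            for i in range(10)
        ]
        assert np.mean(k1s) == pytest.approx(1.0, abs=0.03)
        assert all(
            gk.mom_ibd(gk.ibs_counts(panel, f"C{i}", f"F{2 * i + 1:02d}"), exp).k0
            < 0.03
            for i in range(10)
        )

    def test_simplex_invariant_on_random_counts(self):
        """After truncation, k0 + k1 + k2 = 1 exactly and phi in [0, 0.5]."""
        rng = np.random.default_rng(2)
        p = rng.uniform(0.05, 0.95, 60)
        exp = gk.expected_ibs(p)
        for _ in range(200):
            n = rng.multinomial(60, rng.dirichlet([1, 1, 1]))
            est = gk.mom_ibd(
                gk.IBSCounts("a", "b", int(n[0]), int(n[1]), int(n[2])), exp
            )
            assert est.k0 + est.k1 + est.k2 == pytest.approx(1.0, abs=1e-12)
            assert 0.0 <= est.kinship <= 0.5

    def test_constrained_estimator_boundary_bias_is_inward(self):
        """Truncating to the simplex pulls boundary classes inward: for
        unrelated pairs the constrained mean k0 sits a few percent below 1
        while the raw solution stays mean-calibrated.  This is the price of
        the simplex guarantee, not an implementation defect."""
        panel, freqs, pairs = gk.calibration_experiment(seed=55, n_pairs=30)
        exp = gk.expected_ibs(freqs)
        raw, con = [], []
        for a, b in pairs["UNREL"]:
            c = gk.ibs_counts(panel, a, b)
            raw.append(gk.mom_ibd(c, exp, constrain=False).k0)
            con.append(gk.mom_ibd(c, exp).k0)
        assert np.mean(raw) == pytest.approx(1.0, abs=0.06)
        assert 0.85 < np.mean(con) < np.mean(raw)

    def test_degenerate_inputs_raise(self):
        exp = gk.expected_ibs(np.array([0.5]))
        with pytest.raises(ValueError, match="no valid markers"):
            gk.mom_ibd(gk.IBSCounts("a", "b", 0, 0, 0), exp)
        with pytest.raises(ValueError, match="monomorphic"):
            gk.mom_ibd(
                gk.IBSCounts("a", "b", 1, 1, 1),
                gk.ExpectedIBS(0.0, 0.0, 1.0, 0.5, 0.5, 1),
            )

    def test_error_on_one_clone_copy_cannot_raise_ibs2(self):
        """Corrupting one member of a clone pair can only move markers out
        of IBS state 2."""
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, 500).astype(np.int8)
        panel = tiny_panel(np.vstack([d, d]))
        clean = gk.ibs_counts(panel, "s1", "s2")
        noisy_panel = panel.copy()
        err = rng.random(500) < 0.05
        noisy_panel.dosages[1, err] = (noisy_panel.dosages[1, err] + 1) % 3
        noisy = gk.ibs_counts(noisy_panel, "s1", "s2")
        assert noisy.n2 <= clean.n2
        assert noisy.n0 + noisy.n1 >= clean.n0 + clean.n1

    def test_pairwise_table_matches_per_pair_path(self):
        """The vectorized all-pairs table equals the scalar mom_ibd route."""
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, (6, 300)).astype(np.int8)
        d[rng.random(d.shape) < 0.05] = gk.MISSING
        panel = tiny_panel(d)
        freqs = gk.allele_frequencies(panel)
        table = gk.pairwise_ibd(panel, freqs=freqs)
        poly = np.isfinite(freqs) & (freqs > 0) & (freqs < 1)
        for row in table.itertuples():
            counts = gk.ibs_counts(panel, row.id1, row.id2, marker_mask=poly)
            d1 = panel.dosages[panel.sample_index(row.id1)]
            d2 = panel.dosages[panel.sample_index(row.id2)]
            pair_ok = poly & (d1 != gk.MISSING) & (d2 != gk.MISSING)
            exp = gk.expected_ibs(freqs[pair_ok])
            est = gk.mom_ibd(counts, exp)
            assert (row.k0, row.k1, row.k2) == pytest.approx(
                (est.k0, est.k1, est.k2), abs=1e-9
            )


class TestMendelErrors:
    def test_duo_single_marker_opposite_hom(self):
        panel = tiny_panel([[0], [2]])
        assert gk.mendel_errors_duo(panel, "s1", "s2").mendelian_errors == 1

    def test_duo_matches_loop_oracle(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, (2, 300)).astype(np.int8)
        d[rng.random(d.shape) < 0.1] = gk.MISSING
        panel = tiny_panel(d)
        assert gk.mendel_errors_duo(panel, "s1", "s2").mendelian_errors == (
            oracles.duo_errors_loop(d[0], d[1])
        )

    def test_unrelated_duo_error_expectation(self):
        """Unrelated HWE pair at p = 0.5: 2 p^2 q^2 = 12.5% of markers."""
        cfg = gk.SimulationConfig(
            n_markers=1000, n_founders=2, maf_range=(0.5, 0.5), seed=23
        )
        panel, _ = gk.simulate_founders(cfg)
        res = gk.mendel_errors_duo(panel, "F01", "F02")
        expect, sd = 125.0, np.sqrt(1000 * 0.125 * 0.875)
        assert abs(res.mendelian_errors - expect) < 3 * sd

    @pytest.mark.parametrize(
        "p1, p2, off, is_error",
        [
            (0, 0, 1, True),    # no B allele available
            (0, 2, 1, False),   # forced heterozygote
            (0, 2, 0, True),
            (0, 2, 2, True),
            (1, 1, 0, False),
            (2, 2, 1, True),
            (0, 1, 2, True),
            (1, 2, 2, False),
        ],
    )
    def test_trio_rule_table(self, p1, p2, off, is_error):
        panel = tiny_panel([[off], [p1], [p2]], samples=["o", "p1", "p2"])
        res = gk.mendel_errors_trio(panel, "o", "p1", "p2")
        assert res.mendelian_errors == int(is_error)

    def test_trio_matches_gamete_enumeration(self):
        rng = np.random.default_rng(7)
        d = rng.integers(0, 3, (3, 400)).astype(np.int8)
        d[rng.random(d.shape) < 0.1] = gk.MISSING
        panel = tiny_panel(d, samples=["o", "p1", "p2"])
        assert gk.mendel_errors_trio(panel, "o", "p1", "p2").mendelian_errors == (
            oracles.trio_errors_loop(d[0], d[1], d[2])
        )

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 9999))
    def test_trio_errors_dominate_duo_errors(self, seed):
        """A marker with a duo error against either parent is always a trio
        error, so trio errors >= each duo's errors on the shared markers."""
        rng = np.random.default_rng(seed)
        d = rng.integers(0, 3, (3, 120)).astype(np.int8)
        d[rng.random(d.shape) < 0.1] = gk.MISSING
        panel = tiny_panel(d, samples=["o", "p1", "p2"])
        all_called = (d != gk.MISSING).all(axis=0)
        trio = gk.mendel_errors_trio(panel, "o", "p1", "p2")
        for parent in ("p1", "p2"):
            duo = gk.mendel_errors_duo(panel, "o", parent, marker_mask=all_called)
            assert trio.mendelian_errors >= duo.mendelian_errors

    def test_true_trio_vs_false_trio_gap(self, chain):
        """True trios sit orders of magnitude below swapped-parent trios."""
        panel = chain.panel_parentage
        t = chain.trios_accepted[0]
        truth = chain.scenario.truth
        true_rate = t.error_rate
        # replace one parent by an unrelated individual
        unrel = next(
            s for s in panel.samples
            if truth.relationship(t.offspring, s) == "UNREL"
            and s not in (t.parent1, t.parent2)
        )
        wrong = gk.mendel_errors_trio(panel, t.offspring, t.parent1, unrel)
        assert true_rate <= 0.002
        assert wrong.error_rate > 10 * max(true_rate, 1e-4)
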