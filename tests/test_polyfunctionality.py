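import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scbc import AnalytePanel, compute_psi, polyfunction_histogram, psi_by_analyte
from scbc.calling import EmptyTableError

from conftest import make_call_table

P3 = AnalytePanel(("A", "B", "C"))


def brute_force_psi(calls, rates):
    """Independent oracle: literal per-stratum definition with plain loops."""
    calls = np.asarray(calls, dtype=bool)
    rates = np.asarray(rates, dtype=float)
    n, p = calls.shape
    per_k = {}
    for i in range(n):
        k = int(sum(calls[i]))
        total = sum(rates[i][j] for j in range(p) if calls[i][j])
        per_k.setdefault(k, []).append(total)
    psi = {}
    for k, totals in per_k.items():
        psi[k] = (len(totals) / n) * (sum(totals) / len(totals))
    return sum(v for k, v in psi.items() if k >= 1), psi


class TestHistogram:
    def test_counts_and_fractions(self):
        # call counts 0,0,1,2,2,3
        calls = [
            [0, 0, 0],
            [0, 0, 0],
            [1, 0, 0],
            [1, 1, 0],
            [0, 1, 1],
            [1, 1, 1],
        ]
        t = make_call_table(calls, np.ones((6, 3)), P3)
        counts, fractions = polyfunction_histogram(t)
        assert counts.tolist() == [2, 1, 2, 1]
        assert fractions.tolist() == pytest.approx([1 / 3, 1 / 6, 1 / 3, 1 / 6])

    def test_all_negative_cells_fill_k0(self):
        t = make_call_table(np.zeros((7, 3)), np.zeros((7, 3)), P3)
        counts, _ = polyfunction_histogram(t)
        assert counts[0] == 7 and counts[1:].sum() == 0

    def test_total_conserved_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            calls = rng.random((20, 3)) < 0.5
            t = make_call_table(calls, rng.random((20, 3)), P3)
            counts, fractions = polyfunction_histogram(t)
            assert counts.sum() == 20
            assert fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_table_raises(self):
        t = make_call_table(np.zeros((0, 3)), np.zeros((0, 3)), P3)
        with pytest.raises(EmptyTableError):
            polyfunction_histogram(t)


class TestComputePsi:
    def test_single_cell_two_analytes(self):
        t = make_call_table([[1, 1, 0]], [[10.0, 30.0, 99.0]], P3)
        prof = compute_psi(t)
        assert prof.fraction_k[2] == 1.0
        assert prof.psi_k[2] == pytest.approx(40.0)
        assert prof.psi_total == pytest.approx(40.0)

    def test_two_cell_hand_example(self):
        # A: k=1 total 10; B: k=2 total 40 (15 + 25)
        t = make_call_table(
            [[1, 0, 0], [0, 1, 1]], [[10.0, 0.0, 0.0], [0.0, 15.0, 25.0]], P3
        )
        prof = compute_psi(t)
        assert prof.psi_k[1] == pytest.approx(5.0)
        assert prof.psi_k[2] == pytest.approx(20.0)
        assert prof.psi_total == pytest.approx(25.0)
        contrib = psi_by_analyte(t)
        assert contrib == pytest.approx({"A": 5.0, "B": 7.5, "C": 12.5})
        assert sum(contrib.values()) == pytest.approx(prof.psi_total, abs=1e-9)

    def test_no_calls_gives_zero_psi(self):
        t = make_call_table(np.zeros((4, 3)), np.ones((4, 3)), P3)
        assert compute_psi(t).psi_total == 0.0
        assert compute_psi(t).psi_k[0] == 0.0

    def test_single_analyte_panel_decomposition(self):
        p1 = AnalytePanel(("A",))
        t = make_call_table([[1], [0]], [[8.0], [0.0]], p1)
        prof = compute_psi(t)
        assert psi_by_analyte(t)["A"] == pytest.approx(prof.psi_total)

    def test_permuting_analytes_permutes_decomposition(self):
        rng = np.random.default_rng(3)
        calls = rng.random((10, 3)) < 0.5
        rates = rng.random((10, 3)) * 10
        contrib = psi_by_analyte(make_call_table(calls, rates, P3))
        perm = [2, 0, 1]
        panel_p = AnalytePanel(tuple(P3.names[j] for j in perm))
        contrib_p = psi_by_analyte(
            make_call_table(calls[:, perm], rates[:, perm], panel_p)
        )
        assert contrib_p == pytest.approx(contrib)

    def test_exhaustive_small_tables_match_oracle(self):
        """All call patterns for <= 3 cells x 3 analytes over a fixed rate grid."""
        rate_grid = np.array(
            [[1.0, 2.0, 4.0], [8.0, 16.0, 32.0], [5.0, 0.5, 64.0]]
        )
        patterns = list(itertools.product([0, 1], repeat=3))
        for n in (1, 2, 3):
            for combo in itertools.product(patterns, repeat=n):
                calls = np.array(combo)
                rates = rate_grid[:n]
                t = make_call_table(calls, rates, P3)
                expected_total, expected_per_k = brute_force_psi(calls, rates)
                prof = compute_psi(t)
                assert prof.psi_total == pytest.approx(expected_total, abs=1e-9)
                for k, v in expected_per_k.items():
                    if k >= 1:
                        assert prof.psi_k[k] == pytest.approx(v, abs=1e-9)

    def test_random_larger_tables_match_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = rng.integers(4, 6)
            calls = rng.random((n, 3)) < 0.5
            rates = rng.integers(0, 8, (n, 3)).astype(float)
            t = make_call_table(calls, rates, P3)
            expected_total, _ = brute_force_psi(calls, rates)
            assert compute_psi(t).psi_total == pytest.approx(expected_total, abs=1e-9)


class TestInvariants:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1), st.integers(1, 30))
    def test_conservation(self, seed, n_cells):
        rng = np.random.default_rng(seed)
        calls = rng.random((n_cells, 3)) < 0.5
        rates = rng.gamma(2.0, 5.0, (n_cells, 3))
        prof = compute_psi(make_call_table(calls, rates, P3))
        assert prof.n_k.sum() == n_cells
        assert prof.fraction_k.sum() == pytest.approx(1.0, abs=1e-9)
        assert prof.psi_k[1:].sum() == pytest.approx(prof.psi_total, abs=1e-9)
        assert prof.per_analyte_psi.sum() == pytest.approx(prof.psi_total, abs=1e-9)

    def test_scaling_rates_scales_psi_linearly(self):
        rng = np.random.default_rng(4)
        calls = rng.random((25, 3)) < 0.4
        rates = rng.gamma(2.0, 5.0, (25, 3))
        base = compute_psi(make_call_table(calls, rates, P3)).psi_total
        scaled = compute_psi(make_call_table(calls, rates * 3.0, P3)).psi_total
        assert scaled == pytest.approx(3.0 * base, rel=1e-12)

    def test_new_positive_call_never_decreases_psi(self):
        rng = np.random.default_rng(5)
        calls = rng.random((15, 3)) < 0.4
        rates = rng.gamma(2.0, 5.0, (15, 3))
        base = compute_psi(make_call_table(calls, rates, P3)).psi_total
        i, j = next(
            (i, j) for i in range(15) for j in range(3) if not calls[i, j]
        )
        calls2 = calls.copy()
        calls2[i, j] = True
        bumped = compute_psi(make_call_table(calls2, rates, P3)).psi_total
        assert bumped >= base - 1e-12
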