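import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from hybridexpr.diffexpr import (
    bh_adjust,
    call_de,
    call_directions,
    exact_count_test,
    log2_fold_change,
)
from conftest import make_table


def ac_tail_oracle(x, n1, y, n2):
    """Independent log-space summation of the conditional pmf tails."""
    r = n2 / n1
    upper = int(max(x, y) + 50 * np.sqrt(max(x, y) + 1) + 200)
    yy = np.arange(0, upper + 1, dtype=np.float64)
    logpmf = (
        yy * np.log(r)
        + gammaln(x + yy + 1.0)
        - gammaln(x + 1.0)
        - gammaln(yy + 1.0)
        - (x + yy + 1.0) * np.log1p(r)
    )
    pmf = np.exp(logpmf)
    p_low = pmf[: int(y) + 1].sum()
    p_high = pmf[int(y):].sum()
    return min(1.0, 2.0 * min(p_low, p_high))


def bh_oracle(p):
    """Brute-force BH by definition: q_(i) = min_{j>=i} p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_i in range(m):
        q[order[rank_i]] = min(
            min(p[order[j]] * m / (j + 1) for j in range(rank_i, m)), 1.0
        )
    return q


class TestExactCountTest:
    def test_symmetric_equal_counts_give_one(self):
        assert exact_count_test(3, 10**6, 3, 10**6) == 1.0

    def test_geometric_series_closed_form(self):
        # x=0, y=10, n1=n2: one tail = 2^-10, two-sided = 2^-9
        assert exact_count_test(0, 10**6, 10, 10**6) == pytest.approx(
            2.0**-9, rel=1e-12
        )

    def test_closed_form_at_y_zero(self):
        # x=5, y=0, n1=n2: P_low = 2^-6, two-sided = 0.03125
        assert exact_count_test(5, 10**6, 0, 10**6) == pytest.approx(
            0.03125, rel=1e-12
        )

    @pytest.mark.parametrize(
        "x,n1,y,n2",
        [
            (0, 1e6, 10, 1e6),
            (5, 1e6, 0, 1e6),
            (12, 1e6, 40, 2e6),
            (100, 5e6, 180, 4e6),
            (1000, 1e7, 700, 1e7),
            (3, 1e5, 3, 3e5),
        ],
    )
    def test_matches_log_space_oracle(self, x, n1, y, n2):
        assert exact_count_test(x, n1, y, n2) == pytest.approx(
            ac_tail_oracle(x, n1, y, n2), rel=1e-9
        )

    @given(
        x=st.integers(min_value=0, max_value=500),
        y=st.integers(min_value=0, max_value=500),
        ratio=st.floats(min_value=0.2, max_value=5.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_p_in_unit_interval_and_oracle_agreement_under_swap(self, x, y, ratio):
        # The conditional construction is NOT exactly symmetric under
        # (x, n1) <-> (y, n2) (it conditions on the first count); both
        # orientations must still be valid p-values and match the
        # independent log-space oracle.
        n1, n2 = 1e6, ratio * 1e6
        a = exact_count_test(x, n1, y, n2)
        b = exact_count_test(y, n2, x, n1)
        assert 0.0 < a <= 1.0
        assert 0.0 < b <= 1.0
        oracle = ac_tail_oracle(y, n2, x, n1)
        if oracle > 1e-100:
            assert b == pytest.approx(oracle, rel=1e-9)
        else:
            # far below any decision threshold; relative precision of the
            # incomplete-beta tail degrades but the order holds
            assert b < 1e-90

    def test_identity_swap_is_symmetric(self):
        for x, n in ((0, 1e6), (7, 2e6), (400, 1e7)):
            assert exact_count_test(x, n, x, n) == pytest.approx(1.0, abs=1e-12)

    def test_pmf_sums_to_one(self):
        for x in (0, 3, 50, 400):
            for r in (0.5, 1.0, 2.3):
                n1 = 1e6
                n2 = r * n1
                upper = int(x + 50 * np.sqrt(x + 1) + 50)
                yy = np.arange(0, upper + 1, dtype=float)
                logpmf = (
                    yy * np.log(n2 / n1)
                    + gammaln(x + yy + 1.0)
                    - gammaln(x + 1.0)
                    - gammaln(yy + 1.0)
                    - (x + yy + 1.0) * np.log1p(n2 / n1)
                )
                assert np.exp(logpmf).sum() >= 1 - 1e-10

    def test_null_type_one_error_controlled(self):
        # small-scale version of the acceptance check
        rng = np.random.default_rng(0)
        lam = rng.lognormal(3, 1, size=2000)
        x = rng.poisson(lam)
        y = rng.poisson(lam)
        p = exact_count_test(x, 1e6, y, 1e6)
        frac = np.mean(p <= 0.05)
        se = np.sqrt(0.05 * 0.95 / len(p))
        assert frac <= 0.05 + 3 * se

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            exact_count_test(np.nan, 1e6, 1, 1e6)
        with pytest.raises(ValueError):
            exact_count_test(1, 0, 1, 1e6)
        with pytest.raises(ValueError):
            exact_count_test(-1, 1e6, 1, 1e6)


class TestBhAdjust:
    def test_single_p(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_hand_case(self):
        # 0.01*3/1, 0.02*3/2, 0.03*3/3 -> cumulative min from the largest
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            m = rng.integers(1, 40)
            p = rng.random(m)
            assert bh_adjust(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.random(500)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert bh_adjust(p) == pytest.approx(q_sm, abs=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_p_rank(self, p):
        p = np.array(p)
        q = bh_adjust(p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all((q >= 0) & (q <= 1))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])


class TestLog2FoldChange:
    def test_identity(self):
        assert log2_fold_change(5, 5) == 0.0

    def test_hand_arithmetic(self):
        assert log2_fold_change(31, 7, 1.0) == pytest.approx(2.0)

    def test_antisymmetry(self):
        assert log2_fold_change(13, 4) == pytest.approx(-log2_fold_change(4, 13))

    def test_requires_positive_pseudocount(self):
        with pytest.raises(ValueError):
            log2_fold_change(1, 2, 0.0)


class TestCallDe:
    def test_equal_counts_ns(self):
        t = make_table([[50, 50, 50, 50]], library_sizes=[10**6] * 4)
        calls = call_de(t, ("P1", "P2"), alpha=0.001, fc_threshold=2.0)
        assert list(calls["direction"]) == ["NS"]

    def test_single_spiked_gene_up_rest_ns(self):
        rows = [[20, 20, 20, 20]] * 99 + [[1000, 10, 10, 10]]
        t = make_table(rows, library_sizes=[10**6] * 4)
        calls = call_de(t, ("P1", "P2"), alpha=0.001, fc_threshold=2.0)
        # oracle: exact test + brute-force BH over the same 100 genes
        p_oracle = np.array(
            [ac_tail_oracle(r[0], 1e6, r[1], 1e6) for r in rows]
        )
        q_oracle = bh_oracle(p_oracle)
        assert calls["q"].to_numpy() == pytest.approx(q_oracle, rel=1e-9)
        assert calls["direction"].iloc[-1] == "UP"
        assert (calls["direction"].iloc[:-1] == "NS").all()

    def test_fold_gate_is_strict(self):
        # huge counts at exactly 2-fold: q tiny but |log2fc| == 1 -> NS
        x, y = 2**20 - 1, 2**19 - 1
        t = make_table(
            [[x, y, y, y]], library_sizes=[10**8] * 4
        )
        calls = call_de(t, ("P1", "P2"), alpha=0.001, fc_threshold=2.0)
        assert calls["q"].iloc[0] < 1e-10
        assert calls["log2fc"].iloc[0] == 1.0
        assert calls["direction"].iloc[0] == "NS"

    def test_empty_table(self):
        t = make_table(np.zeros((0, 4), dtype=int))
        calls = call_de(t, ("P1", "P2"), alpha=0.001, fc_threshold=2.0)
        assert len(calls) == 0

    def test_strict_alpha_boundary(self):
        # q exactly at alpha: significant under <=, not under <
        assert call_directions([3.0], [0.05], 0.05, 2.0, strict_alpha=True)[0] == "NS"
        assert call_directions([3.0], [0.05], 0.05, 2.0, strict_alpha=False)[0] == "UP"
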