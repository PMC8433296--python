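import math

import pytest
from hypothesis import given, settings, strategies as st

from dnastore import (
    METHOD_1_1CS,
    METHOD_1_MCI,
    METHOD_M_1CI,
    SystemParameters,
    breakeven_S_o,
    compression_efficiency,
    sb,
    sd,
    storage_density,
    sweep,
)
from dnastore.errors import CapacityError

FIG_PARAMS = SystemParameters()  # S_h=10, S_T=2010, L_p=20, a=1/1.6,
#                                  S_D=100000, r_c=0.34


class TestCompressionEfficiency:
    def test_ideal_case_is_one_minus_rc(self):
        assert compression_efficiency(0.34, 10 ** 6, 0) == \
            pytest.approx(0.66)

    def test_zero_at_breakeven_boundary(self):
        assert compression_efficiency(0.5, 100, 50) == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        # 1 - 0.34 - 1646592/4194304, computed independently
        expected = 1 - 0.34 - 1_646_592 / 4_194_304
        assert compression_efficiency(0.34, 4_194_304, 1_646_592) == \
            pytest.approx(expected)
        assert expected == pytest.approx(0.2674, abs=1e-4)

    def test_zero_original_size_is_domain_error(self):
        with pytest.raises(ValueError):
            compression_efficiency(0.5, 0, 10)


class TestBreakeven:
    def test_boundary_inversion(self):
        assert breakeven_S_o(0.5, 50) == pytest.approx(100)

    def test_direct_arithmetic(self):
        assert breakeven_S_o(0.34, 1_646_592) == \
            pytest.approx(1_646_592 / 0.66)

    def test_no_breakeven_when_incompressible(self):
        with pytest.raises(ValueError):
            breakeven_S_o(1.0, 100)

    @given(r_c=st.floats(0.01, 0.99), S_T=st.floats(1, 10 ** 7))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_efficiency_vanishes_at_breakeven(self, r_c, S_T):
        S_o = breakeven_S_o(r_c, S_T)
        assert compression_efficiency(r_c, S_o, S_T) == \
            pytest.approx(0.0, abs=1e-9)


class TestStoredBits:
    def test_hand_arithmetic(self):
        assert sb(METHOD_1_1CS, FIG_PARAMS) == pytest.approx(108_060)
        assert sb(METHOD_M_1CI, FIG_PARAMS) == pytest.approx(104_160)
        assert sb(METHOD_1_MCI, FIG_PARAMS) == pytest.approx(104_040)

    def test_empty_corpus_limit(self):
        p = SystemParameters(n=0, S_D=None, S_Di=())
        assert sb(METHOD_1_1CS, p) == 0
        assert sb(METHOD_M_1CI, p) == p.S_T
        assert sb(METHOD_1_MCI, p) == p.S_T

    def test_heterogeneous_sizes_sum(self):
        p = SystemParameters(n=2, S_D=None, S_Di=(50_000.0, 150_000.0))
        q = SystemParameters(n=2, S_D=100_000.0)
        assert sb(METHOD_1_MCI, p) == pytest.approx(sb(METHOD_1_MCI, q))

    @given(n=st.integers(1, 40), S_D=st.floats(1e3, 1e7),
           S_T=st.floats(0, 1e7), r_c=st.floats(0.01, 0.99),
           S_h=st.floats(0, 100))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_chain_indexing_never_stores_more(self, n, S_D, S_T, r_c,
                                              S_h):
        p = SystemParameters(n=n, S_D=S_D, S_T=S_T, r_c=r_c, S_h=S_h)
        assert sb(METHOD_1_MCI, p) <= sb(METHOD_M_1CI, p) + 1e-9
        assert sb(METHOD_1_MCI, p) <= sb(METHOD_1_1CS, p) + 1e-9
        # the structural difference: (n-1) tool copies / 2 n L_p pointers
        scale = 1e-9 * sb(METHOD_1_1CS, p)  # cancellation of large sums
        assert sb(METHOD_1_1CS, p) - sb(METHOD_1_MCI, p) == \
            pytest.approx((n - 1) * S_T, abs=max(1e-9, scale))
        assert sb(METHOD_M_1CI, p) - sb(METHOD_1_MCI, p) == \
            pytest.approx(2 * n * p.L_p, abs=max(1e-9, scale))


class TestStoredBases:
    def test_hand_arithmetic_continuous(self):
        want = (1 / 1.6) * 108_060 * (1 + 40 / 180)
        assert sd(METHOD_1_1CS, FIG_PARAMS) == pytest.approx(want)
        assert want == pytest.approx(82_545.833, abs=0.01)

    def test_term_by_term_one_to_many(self):
        p = FIG_PARAMS
        a = p.a
        term1 = a * sb(METHOD_1_MCI, p)
        term2 = (0.34 * 300_000 + 3 * 10) * a / 220 * 40
        term3 = 2010 * a / (220 - 4 * 20) * 4 * 20
        assert sd(METHOD_1_MCI, p) == pytest.approx(term1 + term2 + term3)
        assert sd(METHOD_1_MCI, p) == pytest.approx(77_337.175, abs=0.01)

    def test_zero_primer_limit_collapses(self):
        p = SystemParameters(L_p=0.0001)  # L_p -> 0 limit
        assert sd(METHOD_1_1CS, p) == \
            pytest.approx(p.a * sb(METHOD_1_1CS, p), rel=1e-4)

    def test_factor_identity_two_term_form(self):
        # a*Sb + a*Sb/(L_s-2L_p) * 2L_p  ==  a*Sb*(1 + 2L_p/(L_s-2L_p))
        p = FIG_PARAMS
        two_term = (p.a * sb(METHOD_M_1CI, p)
                    + p.a * sb(METHOD_M_1CI, p) / (p.L_s - 2 * p.L_p)
                    * 2 * p.L_p)
        assert sd(METHOD_M_1CI, p) == pytest.approx(two_term)

    def test_capacity_error_when_tool_fragment_full(self):
        with pytest.raises(CapacityError):
            sd(METHOD_1_MCI, SystemParameters(n=10))


class TestStorageDensity:
    def test_bare_stream_density_is_inverse_base_factor(self):
        assert storage_density(1600, 1600 * (1 / 1.6)) == pytest.approx(1.6)

    def test_simple_ratio(self):
        assert storage_density(2.0, 1.0) == 2.0

    def test_zero_bases_domain_error(self):
        with pytest.raises(ValueError):
            storage_density(100, 0)


class TestSweep:
    def test_single_point_matches_direct_calls(self):
        table = sweep(FIG_PARAMS, {"n": [3]})
        assert len(table) == 1
        assert table.loc[0, "Sd_1-1CS"] == \
            pytest.approx(sd(METHOD_1_1CS, FIG_PARAMS))

    def test_reference_sweep_ordering_every_row(self):
        table = sweep(FIG_PARAMS, {"L_s": range(100, 401, 20)})
        assert (table["Sd_1-MCI"] <= table["Sd_M-1CI"] + 1e-9).all()
        assert (table["Sd_M-1CI"] <= table["Sd_1-1CS"] + 1e-9).all()

    def test_sd_decreasing_in_ls_lp_ratio(self):
        table = sweep(FIG_PARAMS, {"L_s": range(100, 401, 20)})
        for col in ("Sd_1-1CS", "Sd_M-1CI", "Sd_1-MCI"):
            assert table[col].is_monotonic_decreasing

    def test_sd_linear_in_n(self):
        table = sweep(SystemParameters(), {"n": range(1, 9)})
        diffs = table["Sd_1-1CS"].diff().dropna()
        assert diffs.max() == pytest.approx(diffs.min())

    def test_efficiency_monotone_in_original_size(self):
        sizes = [10 ** k for k in range(4, 9)]
        vals = [compression_efficiency(0.34, s, 2010) for s in sizes]
        assert vals == sorted(vals)
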