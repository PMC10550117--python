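import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lucflow.errors import (
    ContractError,
    DegenerateSpikeError,
    DegenerateSplitError,
    DegenerateSpreadError,
    ReferenceBackgroundError,
    UndefinedCorrelationError,
)
from lucflow.fcs_io import ReplicateRecord
from lucflow.gating import GateConfig
from lucflow.quantify import (
    analyze_tube,
    coefficient_of_variation,
    compare_to_bulk,
    fold_change_scheme_A,
    fold_change_scheme_B,
    median_fluorescence,
    percentile_84,
    precision_report,
    separation_index,
)
from lucflow.simulate import SyntheticTubeSpec, simulate_tube


# --- independent oracles (sort/enumeration based, no numpy shortcuts) ------

def oracle_median(values):
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def oracle_percentile(values, q):
    s = sorted(values)
    rank = (len(s) - 1) * q / 100.0
    lo = math.floor(rank)
    frac = rank - lo
    if lo + 1 < len(s):
        return s[lo] + frac * (s[lo + 1] - s[lo])
    return s[lo]


def oracle_cv(values):
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return 100.0 * math.sqrt(var) / mean


def oracle_r_squared(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov * cov / (vx * vy)


finite_values = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False)


class TestMedian:
    def test_constant(self):
        assert median_fluorescence([5, 5, 5]) == 5

    def test_even_count(self):
        assert median_fluorescence([1, 2, 3, 10]) == 2.5

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 1e4, size=10_001)
        assert median_fluorescence(values) == oracle_median(values.tolist())

    def test_empty_is_contract_error(self):
        with pytest.raises(ContractError):
            median_fluorescence([])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(finite_values, min_size=1, max_size=50))
    def test_matches_oracle(self, values):
        assert median_fluorescence(values) == pytest.approx(
            oracle_median(values), rel=1e-12, abs=1e-9
        )


class TestPercentile84:
    def test_constant_vector(self):
        assert percentile_84([7.0] * 9) == 7.0

    def test_two_point_interpolation(self):
        assert percentile_84([0, 100]) == pytest.approx(84.0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        values = rng.normal(100, 15, size=5_000)
        assert percentile_84(values) == pytest.approx(
            oracle_percentile(values.tolist(), 84), rel=1e-12
        )

    def test_single_value_is_contract_error(self):
        with pytest.raises(ContractError):
            percentile_84([3.0])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(finite_values, min_size=2, max_size=50))
    def test_matches_oracle(self, values):
        assert percentile_84(values) == pytest.approx(
            oracle_percentile(values, 84), rel=1e-9, abs=1e-6
        )


class TestSeparationIndex:
    def test_zero_numerator(self):
        assert separation_index(100, 100, 200) == 0

    def test_hand_value(self):
        # 0.995 * (1000 - 100) / (200 - 100)
        assert separation_index(1000, 100, 200) == pytest.approx(8.955)

    def test_scale_invariance(self):
        a = separation_index(1000, 100, 200)
        b = separation_index(10_000, 1000, 2000)
        assert a == pytest.approx(b)

    def test_degenerate_spread(self):
        with pytest.raises(DegenerateSpreadError):
            separation_index(500, 100, 100)

    @settings(max_examples=200, deadline=None)
    @given(
        mu_s=st.floats(0, 1e5),
        mu_p=st.floats(1, 1e4),
        spread=st.floats(1e-3, 1e4),
        c=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance_property(self, mu_s, mu_p, spread, c):
        base = separation_index(mu_s, mu_p, mu_p + spread)
        scaled = separation_index(c * mu_s, c * mu_p, c * (mu_p + spread))
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)

    def test_zero_iff_equal_medians(self):
        assert separation_index(42.0, 42.0, 50.0) == 0.0
        assert separation_index(42.1, 42.0, 50.0) != 0.0


class TestSchemeA:
    def test_self_reference(self):
        assert fold_change_scheme_A(500, 100, 500, 100).L_sample == 1.0

    def test_no_signal_above_spike(self):
        assert fold_change_scheme_A(500, 100, 250, 250).L_sample == 0.0

    def test_hand_value(self):
        fc = fold_change_scheme_A(500, 100, 900, 100)
        assert fc.L_sample == pytest.approx(2.0)
        assert fc.scheme == "A_puer_spike"
        assert fc.b_sample is None

    def test_reference_background_error(self):
        with pytest.raises(ReferenceBackgroundError):
            fold_change_scheme_A(100, 100, 900, 100)

    def test_negative_signal_flagged_not_clipped(self):
        with pytest.warns(UserWarning, match="negative"):
            fc = fold_change_scheme_A(500, 100, 50, 100)
        assert fc.negative_signal
        assert fc.L_sample == pytest.approx(-0.125)

    @settings(max_examples=200, deadline=None)
    @given(
        f_s1=st.floats(10, 1e5),
        gap1=st.floats(1, 1e4),
        f_s2=st.floats(10, 1e5),
        gap2=st.floats(0, 1e4),
        d=st.floats(0, 1e4),
    )
    def test_additive_shift_invariance(self, f_s1, gap1, f_s2, gap2, d):
        f_c1, f_c2 = f_s1 - gap1, f_s2 - gap2
        base = fold_change_scheme_A(f_s1, f_c1, f_s2, f_c2).L_sample
        shifted = fold_change_scheme_A(f_s1, f_c1, f_s2 + d, f_c2 + d).L_sample
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-12)


class TestSchemeB:
    def test_sample_identical_to_spike(self):
        fc = fold_change_scheme_B(400, 400, 100, 400)
        assert fc.b_sample == pytest.approx(100.0)
        assert fc.L_sample == pytest.approx(1.0)

    def test_hand_value(self):
        # b = 100 * 800 / 400 = 200; L = (1600 - 200) / (800 - 200) = 7/3
        fc = fold_change_scheme_B(1600, 800, 100, 400)
        assert fc.b_sample == pytest.approx(200.0)
        assert fc.L_sample == pytest.approx(7 / 3)
        assert fc.scheme == "B_promoter_spike"

    def test_degenerate_spike(self):
        with pytest.raises(DegenerateSpikeError):
            fold_change_scheme_B(400, 100, 100, 100)

    def test_nonpositive_spike_reference(self):
        with pytest.raises(ContractError):
            fold_change_scheme_B(400, 400, 100, 0)

    @settings(max_examples=200, deadline=None)
    @given(
        f_sample=st.floats(10, 1e5),
        f_spike=st.floats(10, 1e5),
        f_puer=st.floats(1, 1e3),
        f_puer_s=st.floats(1e3, 1e5),
        c=st.floats(1e-2, 1e2),
    )
    def test_multiplicative_invariance(self, f_sample, f_spike, f_puer,
                                       f_puer_s, c):
        b = f_puer * f_spike / f_puer_s
        if f_spike <= b * 1.001:
            return  # degenerate region excluded by the operation's contract
        base = fold_change_scheme_B(f_sample, f_spike, f_puer, f_puer_s).L_sample
        scaled = fold_change_scheme_B(
            c * f_sample, c * f_spike, f_puer, f_puer_s
        ).L_sample
        assert scaled == pytest.approx(base, rel=1e-6, abs=1e-9)


class TestCV:
    def test_no_variation(self):
        assert coefficient_of_variation([2, 2, 2]) == 0.0

    def test_hand_value(self):
        assert coefficient_of_variation([1, 2, 3]) == pytest.approx(50.0)

    def test_scale_invariance(self):
        values = [3.0, 4.5, 5.25, 2.75]
        assert coefficient_of_variation([7 * v for v in values]) == pytest.approx(
            coefficient_of_variation(values)
        )

    def test_contract_errors(self):
        with pytest.raises(ContractError):
            coefficient_of_variation([1.0])
        with pytest.raises(ContractError):
            coefficient_of_variation([-1.0, 1.0])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0.1, 1e5), min_size=2, max_size=30))
    def test_matches_oracle(self, values):
        assert coefficient_of_variation(values) == pytest.approx(
            oracle_cv(values), rel=1e-9
        )


class TestAnalyzeTube:
    def test_recovers_log_median(self):
        m = np.log(5_000.0)
        spec = SyntheticTubeSpec(n_events=20_000, expression_level=np.exp(m),
                                 seed=77)
        table, _ = simulate_tube(spec)
        summary = analyze_tube(table, GateConfig())
        assert abs(summary.f_sample / np.exp(m) - 1) < 0.02

    def test_zero_spike_propagates_degenerate_split(self):
        spec = SyntheticTubeSpec(
            n_events=5_000,
            fractions={"debris": 0.05, "doublet": 0.05, "dead": 0.1, "spike": 0.0},
            seed=5,
        )
        table, _ = simulate_tube(spec)
        with pytest.raises(DegenerateSplitError):
            analyze_tube(table, GateConfig())

    def test_counts_partition_live_singlets(self, simulated_tube):
        table, _, _ = simulated_tube
        from lucflow.gating import apply_gates

        result = apply_gates(table, GateConfig())
        summary = analyze_tube(table, GateConfig(), gating=result)
        live_singlets = table.n_events - sum(
            result.counts[lab] for lab in ("debris", "doublet", "dead")
        )
        assert summary.n_sample + summary.n_control == live_singlets

    def test_low_count_warning(self):
        spec = SyntheticTubeSpec(
            n_events=400,
            fractions={"debris": 0.0, "doublet": 0.0, "dead": 0.0, "spike": 0.2},
            seed=3,
        )
        table, _ = simulate_tube(spec)
        with pytest.warns(UserWarning, match="control"):
            summary = analyze_tube(table, GateConfig(), min_count=100)
        assert any("control" in w for w in summary.warnings)

    def test_p84_at_least_median(self, simulated_tube):
        table, _, _ = simulated_tube
        summary = analyze_tube(table, GateConfig())
        assert summary.p84_sample >= summary.f_sample
        assert summary.p84_control >= summary.f_control


class TestPrecisionReport:
    def test_hand_computed_cvs(self):
        records = [
            ReplicateRecord("A", i + 1, {"fold_change": v})
            for i, v in enumerate([1.0, 1.1, 0.9])
        ] + [
            ReplicateRecord("B", i + 1, {"fold_change": v})
            for i, v in enumerate([2.0, 2.2, 1.8])
        ]
        report = precision_report(records, statistics=("fold_change",))
        assert report.per_construct["fold_change"]["A"]["cv"] == pytest.approx(10.0)
        assert report.per_construct["fold_change"]["B"]["cv"] == pytest.approx(10.0)
        assert report.cv_range("fold_change") == (
            pytest.approx(10.0), pytest.approx(10.0)
        )

    def test_single_replicate_group_skipped_with_warning(self):
        records = [ReplicateRecord("A", 1, {"mfi": 5.0})]
        with pytest.warns(UserWarning, match="skipped"):
            report = precision_report(records, statistics=("mfi",))
        assert ("A", "mfi") in report.skipped
        assert report.per_construct["mfi"] == {}

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        base = rng.uniform(1, 10, size=6)
        records = [
            ReplicateRecord("A", i + 1, {"mfi": float(v)})
            for i, v in enumerate(base)
        ]
        scaled = [
            ReplicateRecord("A", i + 1, {"mfi": float(3.7 * v)})
            for i, v in enumerate(base)
        ]
        a = precision_report(records, ("mfi",)).per_construct["mfi"]["A"]["cv"]
        b = precision_report(scaled, ("mfi",)).per_construct["mfi"]["A"]["cv"]
        assert a == pytest.approx(b)


class TestCompareToBulk:
    def test_perfect_linear_relation(self):
        bulk = {("c", float(t)): float(v) for t, v in enumerate([1, 2, 3, 4, 5])}
        flow = {k: 2 * v for k, v in bulk.items()}
        assert compare_to_bulk(bulk, flow) == pytest.approx(1.0)

    def test_constant_bulk_vector(self):
        bulk = {("c", float(t)): 1.0 for t in range(5)}
        flow = {("c", float(t)): float(t) for t in range(5)}
        with pytest.raises(UndefinedCorrelationError):
            compare_to_bulk(bulk, flow)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(9)
        x, y = rng.uniform(0, 10, 10), rng.uniform(0, 10, 10)
        bulk = {("c", float(t)): float(v) for t, v in enumerate(x)}
        flow = {("c", float(t)): float(v) for t, v in enumerate(y)}
        assert compare_to_bulk(bulk, flow) == pytest.approx(
            oracle_r_squared(x.tolist(), y.tolist())
        )

    def test_too_few_matched_points(self):
        bulk = {("c", 0.0): 1.0, ("c", 1.0): 2.0}
        flow = {("c", 0.0): 1.0, ("c", 1.0): 2.0, ("d", 0.0): 3.0}
        with pytest.raises(ContractError):
            compare_to_bulk(bulk, flow)
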