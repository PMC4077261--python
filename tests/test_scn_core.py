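import numpy as np
import pandas as pd
import pytest

from spikenorm.baseline_norm import median_normalize
from spikenorm.exceptions import ConfigurationError
from spikenorm.io_formats import summarize_probesets
from spikenorm.scn_core import (
    SpikeInMatrix,
    apply_correction,
    build_correction_function,
    check_assumption_a1,
    check_assumption_a2,
    check_assumption_a3,
    compute_spikein_corrections,
    extract_spikein,
    scn_normalize,
)
from spikenorm.synthetic_data import SimulationConfig, simulate_experiment

from conftest import make_pld, make_psd


def make_spike_matrix(values, probe_level=None, index=None, columns=None):
    values = np.asarray(values, dtype=float)
    idx = pd.Index(index or [f"sp{i + 1}" for i in range(values.shape[0])])
    cols = columns or [f"a{i + 1}" for i in range(values.shape[1])]
    frame = pd.DataFrame(values, index=idx, columns=cols)
    if probe_level is None:
        probe_level = frame.copy()
        probe_level.index = pd.Index([f"{s}_p1" for s in idx])
        probe_set_of = pd.Series(list(idx), index=probe_level.index)
    else:
        probe_set_of = probe_level[1]
        probe_level = probe_level[0]
    return SpikeInMatrix(
        values=frame,
        row_means=frame.mean(axis=1),
        probe_level=probe_level,
        probe_set_of=probe_set_of,
    )


class TestExtractSpikein:
    def test_extracts_spike_subset(self, sim_small):
        pld, _, truth = sim_small
        psd = summarize_probesets(pld)
        sm = extract_spikein(psd, pld)
        assert sm.values.shape == (10, 16)
        assert set(sm.set_ids) == set(truth.spike_levels)

    def test_row_means_of_constant_rows(self):
        psd = make_psd(
            [[5.0, 5.0, 5.0], [9.0, 9.0, 9.0]],
            set_classes="spikein",
            index=["spa", "spb"],
        )
        pld = make_pld(
            {"spa_p1": [5.0, 5.0, 5.0], "spb_p1": [9.0, 9.0, 9.0]},
            annotation={
                "spa_p1": ["spa", "spikein"],
                "spb_p1": ["spb", "spikein"],
            },
        )
        sm = extract_spikein(psd, pld)
        assert sm.row_means.tolist() == [5.0, 9.0]

    def test_single_spike_set_rejected(self):
        psd = make_psd([[5.0, 5.0]], set_classes="spikein", index=["spa"])
        pld = make_pld(
            {"spa_p1": [5.0, 5.0], "x": [1.0, 2.0]},
            annotation={"spa_p1": ["spa", "spikein"], "x": ["x", "mirna"]},
        )
        with pytest.raises(ConfigurationError, match="2 spike-in"):
            extract_spikein(psd, pld)


class TestAssumptionA1:
    def test_affine_copies_pass(self):
        base = np.array([1.0, 3.0, 2.0, 5.0])
        sm = make_spike_matrix([base, 2 * base + 1, 0.5 * base - 3])
        check = check_assumption_a1(sm)
        assert check.passed
        assert check.stats["median_offdiagonal"] == pytest.approx(1.0)

    def test_anticorrelated_fail(self):
        base = np.array([1.0, 2.0, 3.0])
        sm = make_spike_matrix([base, -base])
        check = check_assumption_a1(sm)
        assert not check.passed
        assert check.stats["median_offdiagonal"] == pytest.approx(-1.0)

    def test_snr10_passes_with_high_median(self):
        rng = np.random.default_rng(1)
        common = rng.normal(0, 1, size=16)
        rows = np.array([8 + j + common + rng.normal(0, 0.1, 16) for j in range(6)])
        sm = make_spike_matrix(rows)
        check = check_assumption_a1(sm)
        assert check.passed
        assert check.stats["median_offdiagonal"] >= 0.9
        # oracle: direct pairwise np.corrcoef
        expected = []
        for i in range(6):
            for j in range(i + 1, 6):
                expected.append(np.corrcoef(rows[i], rows[j])[0, 1])
        assert check.stats["median_offdiagonal"] == pytest.approx(
            np.median(expected)
        )

    def test_needs_three_arrays(self):
        sm = make_spike_matrix([[1.0, 2.0], [2.0, 4.0]])
        with pytest.raises(ConfigurationError):
            check_assumption_a1(sm)


class TestAssumptionA2:
    def _sm_with_probe_sd(self, means, sd, n_probes=4, n_arrays=3, seed=0):
        rng = np.random.default_rng(seed)
        rows, ids = [], []
        probe_set_of = {}
        for i, m in enumerate(means):
            for p in range(n_probes):
                pid = f"sp{i}_p{p}"
                rows.append(m + sd * rng.standard_normal(n_arrays))
                ids.append(pid)
                probe_set_of[pid] = f"sp{i}"
        probe_level = pd.DataFrame(
            rows, index=ids, columns=[f"a{k}" for k in range(n_arrays)]
        )
        values = probe_level.groupby(pd.Series(probe_set_of)).median()
        return SpikeInMatrix(
            values=values,
            row_means=values.mean(axis=1),
            probe_level=probe_level,
            probe_set_of=pd.Series(probe_set_of),
        )

    def test_small_sd_passes(self):
        sm = self._sm_with_probe_sd([4.0, 8.0, 12.0], sd=0.1)
        assert check_assumption_a2(sm).passed

    def test_equal_means_fail(self):
        sm = self._sm_with_probe_sd([6.0, 6.0, 12.0], sd=0.1)
        check = check_assumption_a2(sm)
        assert not check.passed
        assert check.stats["min_between_set_gap"] < 0.1

    def test_sd_exceeding_gap_fails(self):
        # direct-evaluation oracle: pooled SD 1.2 vs min gap 1.0
        sm = self._sm_with_probe_sd([4.0, 5.0, 12.0], sd=0.0)
        block = sm.probe_level.copy()
        # give set sp0 a deterministic within-array spread with sample SD 1.2
        base = np.array([-1.2, -0.4, 0.4, 1.2])
        spread = base * (1.2 / base.std(ddof=1))
        for k in block.columns:
            block.loc[[f"sp0_p{p}" for p in range(4)], k] = 4.0 + spread
        sm.probe_level = block
        check = check_assumption_a2(sm)
        sd0 = check.stats["within_set_sd"]["sp0"]
        assert sd0 == pytest.approx(1.2, rel=1e-6)
        assert not check.passed


class TestAssumptionA3:
    def _full(self, lo, hi, n=200):
        rng = np.random.default_rng(2)
        values = rng.uniform(lo, hi, size=(n, 4))
        # force the percentile band to sit essentially at (lo, hi)
        values[0] = lo
        values[1] = hi
        return make_psd(values)

    def test_full_coverage_passes(self):
        sm = make_spike_matrix(np.linspace(4, 14, 10)[:, None] * [1, 1, 1])
        full = self._full(5.0, 13.0)
        assert check_assumption_a3(sm, full).passed

    def test_short_spike_range_fails(self):
        sm = make_spike_matrix(np.linspace(4, 8, 5)[:, None] * [1, 1, 1])
        full = self._full(5.0, 13.0)
        assert not check_assumption_a3(sm, full, max_extrapolation=2.0).passed

    def test_boundary_overhang_exactly_allowed(self):
        # band top exceeds spike max by exactly the allowed overhang
        sm = make_spike_matrix(np.array([[4.0], [8.0]]) * [[1, 1, 1]])
        full = make_psd(np.linspace(4.0, 10.0, 100)[:, None] * [1, 1, 1])
        check = check_assumption_a3(sm, full, max_extrapolation=2.0, band=(0, 100))
        assert check.stats["mirna_band"][1] == pytest.approx(10.0)
        assert check.passed


class TestFirstStep:
    def test_constant_rows_give_zero_corrections(self):
        sm = make_spike_matrix([[5.0, 5.0, 5.0], [9.0, 9.0, 9.0]])
        sc = compute_spikein_corrections(sm)
        assert np.allclose(sc.delta_S.to_numpy(), 0.0)
        assert np.allclose(sc.residuals.to_numpy(), 0.0)

    def test_hand_worked_two_by_two(self):
        # row1 = (1, 3), row2 = (2, 6): centered (-1, 1), (-2, 2);
        # norms sqrt(2), 2 sqrt(2); U rows both (-1/sqrt2, 1/sqrt2);
        # delta row1 (-1, 1), row2 (-2, 2); residuals zero
        sm = make_spike_matrix([[1.0, 3.0], [2.0, 6.0]])
        sc = compute_spikein_corrections(sm)
        s = 1 / np.sqrt(2)
        np.testing.assert_allclose(sc.U.to_numpy(), [[-s, s], [-s, s]])
        np.testing.assert_allclose(sc.U_mean.to_numpy(), [-s, s])
        np.testing.assert_allclose(sc.row_norms.to_numpy(), [np.sqrt(2), 2 * np.sqrt(2)])
        np.testing.assert_allclose(sc.delta_S.to_numpy(), [[-1, 1], [-2, 2]])
        np.testing.assert_allclose(sc.residuals.to_numpy(), 0.0, atol=1e-12)

    def test_rank1_plus_noise_reduces_residual(self):
        rng = np.random.default_rng(3)
        u = rng.normal(size=8)
        u -= u.mean()
        a = rng.uniform(0.5, 2.0, size=6)
        deviations = np.outer(a, u) + rng.normal(0, 0.05, size=(6, 8))
        values = 8.0 + deviations
        sm = make_spike_matrix(values)
        sc = compute_spikein_corrections(sm)
        centered = values - values.mean(axis=1, keepdims=True)
        assert (
            np.linalg.norm(sc.residuals.to_numpy())
            < np.linalg.norm(centered)
        )
        # direct recomputation oracle
        norms = np.linalg.norm(centered, axis=1)
        U = centered / norms[:, None]
        delta = np.outer(norms, U.mean(axis=0))
        np.testing.assert_allclose(sc.delta_S.to_numpy(), delta, atol=1e-12)

    def test_rank1_and_zero_sum_invariants(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            values = rng.normal(8, 2, size=(7, 9))
            sc = compute_spikein_corrections(make_spike_matrix(values))
            delta = sc.delta_S.to_numpy()
            svals = np.linalg.svd(delta, compute_uv=False)
            if svals[0] > 0:
                assert svals[1] <= 1e-8 * svals[0]
            np.testing.assert_allclose(delta.sum(axis=1), 0.0, atol=1e-10)
            np.testing.assert_allclose(sc.U_mean.sum(), 0.0, atol=1e-10)
            norms = np.linalg.norm(sc.U.to_numpy(), axis=1)
            np.testing.assert_allclose(norms[norms > 0], 1.0, atol=1e-10)


class TestCorrectionFunction:
    def _sm_sc(self, x, delta_row):
        """Spike matrix + corrections with delta_S = delta_row on array a1
        and -delta_row on a2 (built directly, not via the first step)."""
        from spikenorm.scn_core import SpikeInCorrections

        x = np.asarray(x, dtype=float)
        delta_row = np.asarray(delta_row, dtype=float)
        sm = make_spike_matrix(np.column_stack([x + delta_row, x - delta_row]))
        sm.row_means = pd.Series(x, index=sm.set_ids)
        delta = pd.DataFrame(
            np.column_stack([delta_row, -delta_row]),
            index=sm.set_ids,
            columns=sm.array_labels,
        )
        zeros = delta * 0.0
        sc = SpikeInCorrections(
            U=zeros, U_mean=delta.iloc[0] * 0.0, row_norms=sm.row_means * 0.0,
            delta_S=delta, residuals=zeros,
            corr=pd.DataFrame(np.eye(len(x)), index=sm.set_ids, columns=sm.set_ids),
        )
        return sm, sc

    def test_constant_correction_stays_constant(self):
        sm, sc = self._sm_sc([4.0, 6.0, 8.0, 10.0, 12.0], [0.3] * 5)
        full = make_pld(np.array([[2.0, 2.0], [14.0, 14.0]]))
        cf = build_correction_function(sc, sm, full)
        xs = np.linspace(2, 14, 25)
        np.testing.assert_allclose(cf.evaluate(xs, "a1"), 0.3, atol=1e-9)
        np.testing.assert_allclose(cf.evaluate(xs, "a2"), -0.3, atol=1e-9)

    def test_high_extrapolation_line(self):
        # two highest spike knots (10, 0.2), (12, 0.4); max(E) = 14
        # pre-smoothing extrapolated knot at x=14 must be 0.6
        sm, sc = self._sm_sc([4.0, 6.0, 8.0, 10.0, 12.0], [0.1, 0.1, 0.1, 0.2, 0.4])
        full = make_pld(np.array([[5.0, 5.0], [14.0, 14.0]]))
        cf = build_correction_function(sc, sm, full)
        knots = cf.knots["a1"]
        extra = knots[knots["provenance"] == "extrapolation"]
        assert extra["x"].tolist() == [13.0, 14.0]
        np.testing.assert_allclose(extra["delta_raw"].to_numpy(), [0.5, 0.6])

    def test_low_stabilization_knot(self):
        sm, sc = self._sm_sc([4.0, 6.0, 8.0], [-0.1, 0.2, 0.3])
        full = make_pld(np.array([[2.0, 2.0], [8.0, 8.0]]))
        cf = build_correction_function(sc, sm, full)
        knots = cf.knots["a1"]
        first = knots.iloc[0]
        assert first["provenance"] == "stabilization"
        assert first["x"] == 2.0
        assert first["delta_raw"] == pytest.approx(-0.1)

    def test_knot_range_spans_data(self, sim_small):
        pld, _, _ = sim_small
        psd = summarize_probesets(pld)
        sm = extract_spikein(psd, pld)
        sc = compute_spikein_corrections(sm)
        cf = build_correction_function(sc, sm, pld)
        lo = pld.intensities.to_numpy().min()
        hi = pld.intensities.to_numpy().max()
        for k, table in cf.knots.items():
            x = table["x"].to_numpy()
            assert np.all(np.diff(x) > 0)
            assert x[0] <= lo + 1e-9 and x[-1] >= hi - 1e-9


class TestApplyCorrection:
    def test_zero_correction_is_identity(self):
        sm, _ = None, None
        data = make_psd(np.random.default_rng(0).normal(8, 1, (5, 3)))
        from spikenorm.scn_core import CorrectionFunction

        knots = {
            k: pd.DataFrame(
                {"x": [0.0, 20.0], "delta": [0.0, 0.0], "delta_raw": [0.0, 0.0],
                 "provenance": ["spike", "spike"]}
            )
            for k in data.array_labels
        }
        cf = CorrectionFunction(knots=knots)
        out = apply_correction(data, cf)
        np.testing.assert_allclose(
            out.intensities.to_numpy(), data.intensities.to_numpy()
        )

    def test_constant_correction_shifts(self):
        from spikenorm.scn_core import CorrectionFunction

        data = make_psd([[5.0, 5.0], [9.0, 9.0]])
        knots = {
            "a1": pd.DataFrame({"x": [0.0, 20.0], "delta": [1.0, 1.0],
                                "delta_raw": [1.0, 1.0],
                                "provenance": ["spike", "spike"]}),
            "a2": pd.DataFrame({"x": [0.0, 20.0], "delta": [-2.0, -2.0],
                                "delta_raw": [-2.0, -2.0],
                                "provenance": ["spike", "spike"]}),
        }
        out = apply_correction(data, CorrectionFunction(knots=knots))
        np.testing.assert_allclose(
            out.intensities.to_numpy(), [[4.0, 7.0], [8.0, 11.0]]
        )

    def test_entrywise_interpolation_oracle(self):
        from spikenorm.scn_core import CorrectionFunction

        rng = np.random.default_rng(4)
        data = make_psd(rng.normal(8, 2, size=(50, 4)))
        knots = {}
        for k in data.array_labels:
            x = np.sort(rng.uniform(2, 14, size=6))
            d = rng.normal(0, 0.5, size=6)
            knots[k] = pd.DataFrame(
                {"x": x, "delta": d, "delta_raw": d, "provenance": "spike"}
            )
        cf = CorrectionFunction(knots=knots)
        out = apply_correction(data, cf)
        for k in data.array_labels:
            expected = data.intensities[k].to_numpy() - np.interp(
                data.intensities[k].to_numpy(),
                knots[k]["x"].to_numpy(),
                knots[k]["delta"].to_numpy(),
            )
            np.testing.assert_allclose(out.intensities[k].to_numpy(), expected)

    def test_missing_array_label_errors(self):
        from spikenorm.scn_core import CorrectionFunction

        data = make_psd([[5.0, 5.0]])
        knots = {
            "a1": pd.DataFrame({"x": [0.0, 20.0], "delta": [0.0, 0.0],
                                "delta_raw": [0.0, 0.0], "provenance": "spike"})
        }
        with pytest.raises(ConfigurationError, match="a2"):
            apply_correction(data, CorrectionFunction(knots=knots))


class TestScnNormalize:
    def test_constant_offsets_equal_median(self):
        cfg = SimulationConfig(
            seed=5, n_mirna_sets=60, bias_model="constant",
            bias_amplitude=0.4, probe_noise_sd=0.0,
        )
        pld, design, _ = simulate_experiment(cfg)
        result = scn_normalize(pld, design)
        assert not result.report.fallback_used
        med = median_normalize(summarize_probesets(pld))
        np.testing.assert_allclose(
            result.data.intensities.to_numpy(),
            med.intensities.to_numpy(),
            atol=1e-6,
        )

    def test_uncorrelated_deviations_fall_back(self):
        cfg = SimulationConfig(
            seed=6, n_mirna_sets=60, bias_amplitude=0.0, probe_noise_sd=0.3
        )
        pld, design, _ = simulate_experiment(cfg)
        result = scn_normalize(pld, design)
        assert result.report.fallback_used
        med = median_normalize(summarize_probesets(pld))
        assert np.array_equal(
            result.data.intensities.to_numpy(), med.intensities.to_numpy()
        )

    def test_smooth_bias_reduces_spike_variance(self, sim_small):
        pld, design, _ = sim_small
        result = scn_normalize(pld, design)
        assert not result.report.fallback_used
        psd = summarize_probesets(pld)
        sm = extract_spikein(psd, pld)
        raw_var = sm.values.to_numpy().var(axis=1, ddof=1)
        corrected = result.data.intensities.loc[sm.set_ids].to_numpy()
        corr_var = corrected.var(axis=1, ddof=1)
        # all sets above the lowest spike level
        assert np.all(corr_var[1:] <= 0.3 * raw_var[1:])

    def test_no_spikes_falls_back_with_warning(self):
        pld = make_pld(np.random.default_rng(7).normal(8, 1, (10, 4)))
        with pytest.warns(UserWarning, match="MEDIAN"):
            result = scn_normalize(pld)
        assert result.report.fallback_used
        assert result.correction is None

    def test_exact_idempotence_constant_bias(self):
        # with a constant (intensity-independent) correction the first pass
        # removes the bias exactly, so a second pass must be the identity
        cfg = SimulationConfig(
            seed=8, n_mirna_sets=60, bias_model="constant",
            bias_amplitude=0.4, probe_noise_sd=0.0,
        )
        pld, design, _ = simulate_experiment(cfg)
        first = scn_normalize(pld, design)
        second = scn_normalize(first.probe_level, design)
        np.testing.assert_allclose(
            second.data.intensities.to_numpy(),
            summarize_probesets(first.probe_level).intensities.to_numpy(),
            atol=1e-8,
        )

    def test_second_pass_smaller_than_first(self):
        # intensity-dependent case: the second correction is much smaller
        # than the first (idempotence up to evaluation-point error)
        cfg = SimulationConfig(
            seed=8, n_mirna_sets=60, bias_amplitude=0.4, probe_noise_sd=0.0
        )
        pld, design, _ = simulate_experiment(cfg)
        first = scn_normalize(pld, design)
        second = scn_normalize(first.probe_level, design)
        first_change = np.abs(
            first.data.intensities.to_numpy()
            - summarize_probesets(pld).intensities.to_numpy()
        ).max()
        second_change = np.abs(
            second.data.intensities.to_numpy()
            - summarize_probesets(first.probe_level).intensities.to_numpy()
        ).max()
        assert second_change < 0.2 * first_change
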