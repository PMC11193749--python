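import numpy as np
import pytest

from polfx.burst_analysis import (
    BurstSegment,
    PauseThresholds,
    classify_rate,
    detect_pauses,
    extract_segments,
    flanking_states,
    independence_null,
    memory_configuration_counts,
    segment_type_from_labels,
    simplify_label,
    single_type_fraction,
)
from polfx.step_detection import BinaryTrace

from conftest import matched


def make_binary(state, dt=0.1):
    state = np.asarray(state, dtype=int)
    return BinaryTrace(
        time=(np.arange(state.size) + 0.5) * dt,
        state=state,
        threshold_used=0.0,
        k_sigma=4.0,
    )


class TestClassifyRate:
    def test_exo_at_high_force(self):
        # measured mean exo rate at 50 pN is ~ -62 bp/s
        assert classify_rate(-62.0, 50.0) == "exo"

    def test_pause_below_high_force_cutoff(self):
        assert classify_rate(5.0, 50.0) == "pause"

    def test_pol_at_low_force(self):
        # measured mean pol rate at 20 pN is ~ +32 bp/s
        assert classify_rate(32.0, 20.0) == "pol"

    def test_middle_band_unclassified(self):
        assert classify_rate(-62.0, 30.0) == "unclassified"

    @pytest.mark.parametrize("rate", [15.0, 50.0, 150.0])
    def test_sign_antisymmetry(self, rate):
        assert classify_rate(rate, 50.0) in ("pol", "pause")
        up, down = classify_rate(rate, 50.0), classify_rate(-rate, 50.0)
        if up == "pause":
            assert down == "pause"
        else:
            assert (up, down) == ("pol", "exo")

    def test_simplification(self):
        assert simplify_label("exo") == "E"
        assert simplify_label("pol") == "E"
        assert simplify_label("pause") == "P"
        with pytest.raises(ValueError):
            simplify_label("unclassified")

    def test_thresholds_validate(self):
        with pytest.raises(ValueError):
            PauseThresholds(high_force_cutoff=0.0)


class TestDetectPauses:
    def test_monotone_ramp_no_pauses(self):
        n = 600
        time = (np.arange(n) + 0.5) * 0.1
        bp = 8000 - 100.0 * time
        force = np.full(n, 50.0)
        assert detect_pauses(bp, time, force) == []

    def test_single_plateau_found(self):
        n = 600
        time = (np.arange(n) + 0.5) * 0.1
        bp = np.where(time < 20, 8000 - 100 * time, 6000.0)
        bp = np.where(time >= 40, 6000 - 100 * (time - 40), bp)
        force = np.full(n, 50.0)
        pauses = detect_pauses(bp, time, force)
        assert len(pauses) == 1
        t0, t1 = pauses[0]
        assert t0 == pytest.approx(20.0, abs=1.0)
        assert t1 == pytest.approx(40.0, abs=1.0)

    def test_simulator_precision_recall(self, detector_sim):
        from polfx.polymer_models import reconstruct_junction

        cfg, truth, trace, kymo, traj = detector_sim
        bp = traj.basepairs_ds.astype(float)
        detected = detect_pauses(
            bp, truth.time, truth.force, min_pause_duration=2.0
        )
        true_pauses = truth.pause_intervals(min_duration=2.0)
        precision = np.mean([matched(p, true_pauses) for p in detected])
        recall = np.mean([matched(t, detected) for t in true_pauses])
        assert precision >= 0.9
        assert recall >= 0.9


class TestExtractSegments:
    def _scene(self, rates_by_interval, fluor_intervals, force=50.0, n=600, dt=0.1):
        time = (np.arange(n) + 0.5) * dt
        rate = np.zeros(n)
        for (t0, t1), r in rates_by_interval:
            rate[(time >= t0) & (time < t1)] = r
        bp = 7000 + np.cumsum(rate) * dt
        state = np.zeros(n, dtype=int)
        for t0, t1 in fluor_intervals:
            state[(time >= t0) & (time < t1)] = 1
        return make_binary(state, dt), bp, time, np.full(n, force)

    def test_single_exo_segment(self):
        fluor, bp, time, force = self._scene(
            [((10.0, 20.0), -100.0)], [(10.0, 20.0)]
        )
        segs = extract_segments(fluor, bp, time, force)
        assert len(segs) == 1
        assert segs[0].segment_type == "single"
        assert segs[0].labels == ["exo"]
        assert segs[0].mean_rate == pytest.approx(-100.0, abs=10.0)

    def test_transitional_exo_then_pause(self):
        fluor, bp, time, force = self._scene(
            [((10.0, 20.0), -100.0)], [(10.0, 30.0)]
        )
        segs = extract_segments(fluor, bp, time, force)
        assert len(segs) == 1
        assert segs[0].segment_type == "transitional"
        assert segs[0].labels == ["exo", "pause"]

    def test_no_fluorescence_no_segments(self):
        fluor, bp, time, force = self._scene([((0.0, 60.0), -100.0)], [])
        assert extract_segments(fluor, bp, time, force) == []

    def test_single_fraction_close_to_truth(self, detector_sim):
        from polfx.kymo_registration import extract_junction_intensity, refine_offsets
        from polfx.step_detection import binarize, min_run_filter

        cfg, truth, trace, kymo, traj = detector_sim
        off = refine_offsets(kymo, traj)
        inten = extract_junction_intensity(kymo, traj, off)
        fluor = min_run_filter(
            binarize(np.nan_to_num(inten.counts), time=inten.time, k_sigma=4.0), 3
        )
        bp = traj.basepairs_ds.astype(float)
        segs = extract_segments(fluor, bp, truth.time, truth.force)
        assert len(segs) >= 10
        got = single_type_fraction(segs)
        # ground truth: fraction of visible binding events with one class
        vis = [ev for ev in truth.events if ev.labeled]
        truth_frac = np.mean([len(set(ev.classes)) == 1 for ev in vis])
        assert abs(got - truth_frac) <= 0.15

    def test_segment_type_counts_partition(self, detector_sim):
        from polfx.kymo_registration import extract_junction_intensity
        from polfx.step_detection import binarize, min_run_filter

        cfg, truth, trace, kymo, traj = detector_sim
        inten = extract_junction_intensity(kymo, traj)
        fluor = min_run_filter(
            binarize(np.nan_to_num(inten.counts), time=inten.time, k_sigma=4.0), 3
        )
        bp = traj.basepairs_ds.astype(float)
        segs = extract_segments(fluor, bp, truth.time, truth.force)
        n_single = sum(1 for s in segs if s.segment_type == "single")
        n_trans = sum(1 for s in segs if s.segment_type == "transitional")
        assert n_single + n_trans == len(segs)


class TestFlankingStates:
    def _scene_with_segment(self, pre_rate, post_rate):
        n, dt = 600, 0.1
        time = (np.arange(n) + 0.5) * dt
        rate = np.zeros(n)
        rate[(time >= 5) & (time < 25)] = pre_rate
        rate[(time >= 25) & (time < 35)] = -100.0  # during
        rate[(time >= 35) & (time < 55)] = post_rate
        bp = 7000 + np.cumsum(rate) * dt
        force = np.full(n, 50.0)
        state = ((time >= 25) & (time < 35)).astype(int)
        fluor = make_binary(state, dt)
        segs = extract_segments(fluor, bp, time, force)
        assert len(segs) == 1
        return segs[0], bp, time, force

    def test_active_flanks(self):
        seg, bp, time, force = self._scene_with_segment(-100.0, -100.0)
        assert flanking_states(seg, bp, time, force) == ("E", "E")

    def test_paused_flanks(self):
        seg, bp, time, force = self._scene_with_segment(0.0, 0.0)
        assert flanking_states(seg, bp, time, force) == ("P", "P")

    def test_boundary_segment_unavailable(self):
        n, dt = 300, 0.1
        time = (np.arange(n) + 0.5) * dt
        bp = 7000 - 100.0 * time
        force = np.full(n, 50.0)
        state = np.zeros(n, dtype=int)
        state[:30] = 1  # starts at the trace edge
        segs = extract_segments(make_binary(state, dt), bp, time, force)
        pre, post = flanking_states(segs[0], bp, time, force)
        assert pre is None
        assert post == "E"


class TestMemoryConfigurations:
    @staticmethod
    def _segment(pre, during, post):
        label = "exo" if during == "E" else "pause"
        return BurstSegment(
            t_start=0.0,
            t_end=1.0,
            sub_intervals=[(0.0, 1.0, -100.0 if during == "E" else 0.0, label)],
            mean_rate=0.0,
            segment_type="single",
            pre_state=pre,
            post_state=post,
        )

    def test_all_E_stream(self):
        segs = [self._segment("E", "E", "E") for _ in range(10)]
        counts = memory_configuration_counts(segs)
        assert counts.fraction(("E", "E", "E")) == 1.0
        assert counts.n_total == 10

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        segs = [
            self._segment(*(rng.choice(["E", "P"]) for _ in range(3)))
            for _ in range(200)
        ]
        counts = memory_configuration_counts(segs)
        assert sum(counts.fractions().values()) == pytest.approx(1.0)
        assert sum(counts.counts.values()) == counts.n_total

    def test_transitional_and_missing_flanks_excluded(self):
        seg = self._segment("E", "E", "E")
        seg.segment_type = "transitional"
        missing = self._segment("E", "E", "E")
        missing.pre_state = None
        counts = memory_configuration_counts([seg, missing])
        assert counts.n_total == 0

    def test_sqrt_error_bars(self):
        segs = [self._segment("E", "E", "E") for _ in range(9)]
        segs += [self._segment("P", "P", "P") for _ in range(16)]
        counts = memory_configuration_counts(segs)
        assert counts.errors()[("E", "E", "E")] == pytest.approx(3 / 25)
        assert counts.errors()[("P", "P", "P")] == pytest.approx(4 / 25)

    def _simulated_triplets(self, memory_strength, n_segments=2000, seed=123):
        """Independent (pre, during, post) triplets from simulated kinetics.

        Stride-3 over the event stream so consecutive triplets share no
        events and the chi-squared independence test is valid.
        """
        from polfx.exchange_simulator import SimulationConfig, simulate_kinetics

        cfg = SimulationConfig(
            seed=seed,
            duration=3.0 * n_segments * 0.7,
            k_on=5.0,
            tau_off=0.5,
            p_pause_given_bind=0.4,
            memory_strength=memory_strength,
            bp_init=4000,
            rate_exo=-10.0,  # keep bp away from template limits
        )
        truth = simulate_kinetics(cfg)
        classes = [simplify_label(ev.classes[0]) for ev in truth.events]
        segs = []
        for i in range(1, len(classes) - 1, 3):
            segs.append(self._segment(classes[i - 1], classes[i], classes[i + 1]))
        return segs[:n_segments]

    def test_no_memory_consistent_with_independence(self):
        segs = self._simulated_triplets(0.0)
        counts = memory_configuration_counts(segs)
        assert counts.n_total >= 1500
        _chi2, p, _exp = independence_null(counts)
        assert p > 0.01
        # E→E→E fraction within binomial CI of the factorized null
        pE = sum(c for t, c in counts.counts.items() if t[1] == "E") / counts.n_total
        null = pE**3
        se = np.sqrt(null * (1 - null) / counts.n_total)
        assert abs(counts.fraction(("E", "E", "E")) - null) < 3.5 * se

    def test_strong_memory_rejects_independence(self):
        segs = self._simulated_triplets(0.8)
        counts = memory_configuration_counts(segs)
        chi2, p, expected = independence_null(counts)
        assert p < 0.01
        # matched-configuration excess > 3 SD above the null
        obs = counts.counts[("E", "E", "E")] + counts.counts[("P", "P", "P")]
        exp = expected[0] + expected[-1]  # ordering: EEE first, PPP last
        assert (obs - exp) / np.sqrt(exp) > 3.0


class TestSegmentTypeHelpers:
    def test_type_from_labels(self):
        assert segment_type_from_labels(["exo"]) == "single"
        assert segment_type_from_labels(["exo", "exo"]) == "single"
        assert segment_type_from_labels(["exo", "pause"]) == "transitional"
        assert segment_type_from_labels(["pol", "unclassified"]) == "single"

    def test_single_type_fraction_empty_rejected(self):
        with pytest.raises(ValueError):
            single_type_fraction([])
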