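"""Single-cell event classification, doubling times, phases, and life curves."""

import numpy as np
import pytest

from coldlife import singlecell as sc
from coldlife import synthetic
from coldlife.errors import InsufficientDataError, InvalidInputError


def make_track(cell_id="c0", t=None, size=None, ros=100.0, buds=(), born=None,
               death=None, censored=True):
    t = np.arange(0.0, 240.0, 12.0) if t is None else np.asarray(t, float)
    size = 20.0 + 0.1 * t if size is None else size
    return sc.CellTrack(cell_id=cell_id, time_h=t, size_au=size, ros_au=ros,
                        bud_times=np.asarray(buds, float), born_at=born,
                        death_time=death, censored=censored)


class TestClassifyEvents:
    def test_bud_separation_begins_life(self):
        track = make_track(born=48.0)
        assert sc.classify_events(track) == "begins_life"

    def test_growth_without_bud_or_death(self):
        assert sc.classify_events(make_track()) == "grows"

    def test_death_dominates(self):
        track = make_track(buds=(24.0,), death=228.0, censored=False)
        assert sc.classify_events(track) == "dies"

    def test_budding_after_birth_duplicates(self):
        track = make_track(born=12.0, buds=(120.0,))
        assert sc.classify_events(track) == "duplicates"

    def test_generator_labels_recovered_exactly(self, low_gsh):
        df, manifest = synthetic.gen_cell_tracks(low_gsh, 80, seed=4, noise_cv=0.0)
        truth = {c["cell_id"]: c["label"] for c in manifest["cells"]}
        tracks = sc.tracks_from_table(df)
        labels = {tr.cell_id: sc.classify_events(tr) for tr in tracks}
        assert labels == truth

    def test_disjoint_window_rejected(self):
        with pytest.raises(InvalidInputError):
            sc.classify_events(make_track(), window=(1000.0, 2000.0))


class TestBudToBudDoublingTimes:
    def test_consecutive_buds_subtract(self):
        out = sc.bud_to_bud_doubling_times([make_track(buds=(24.0, 180.0), censored=False)])
        done = out[~out.censored]
        assert list(done.duration_h) == [156.0]

    def test_unfinished_division_censored_at_movie_end(self):
        track = make_track(t=np.arange(0.0, 492.0, 12.0), buds=(24.0,))
        out = sc.bud_to_bud_doubling_times([track], movie_end=480.0)
        row = out.iloc[-1]
        assert row.censored and row.duration_h == pytest.approx(456.0)

    def test_invariant_under_time_axis_offset(self):
        base = make_track(buds=(24.0, 180.0, 300.0), censored=False)
        shifted = make_track(t=base.time_h + 500.0, buds=(524.0, 680.0, 800.0), censored=False)
        a = sc.bud_to_bud_doubling_times([base], movie_end=240.0)
        b = sc.bud_to_bud_doubling_times([shifted], movie_end=740.0)
        assert np.allclose(a.duration_h, b.duration_h)

    def test_censored_durations_never_exceed_movie_span(self, low_gsh):
        df, _ = synthetic.gen_cell_tracks(low_gsh, 60, seed=9)
        out = sc.bud_to_bud_doubling_times(sc.tracks_from_table(df))
        span = df["time_h"].max() - df["time_h"].min()
        assert (out.duration_h <= span + 1e-9).all()

    def test_recovered_mean_matches_generator_truth(self, low_gsh):
        df, manifest = synthetic.gen_cell_tracks(low_gsh, 150, seed=5)
        out = sc.bud_to_bud_doubling_times(sc.tracks_from_table(df))
        est = out.loc[~out.censored, "duration_h"].to_numpy()
        # completed bud-to-bud intervals correspond to the generator's
        # second-and-later gaps (the first gap runs from birth to first bud)
        truth = np.concatenate(
            [c["true_bud_intervals_h"][1:] for c in manifest["cells"]]
        ) if any(len(c["true_bud_intervals_h"]) > 1 for c in manifest["cells"]) else np.array([])
        se = truth.std(ddof=1) / np.sqrt(truth.size)
        assert est.size == truth.size
        assert abs(est.mean() - truth.mean()) <= 2 * se + low_gsh.frame_h / 2

    def test_km_mean_defined_and_below_naive_maximum(self):
        tracks = [make_track(buds=(24.0, 180.0)), make_track(cell_id="c1", buds=(12.0,))]
        out = sc.bud_to_bud_doubling_times(tracks, movie_end=240.0)
        km = sc.mean_doubling_time(out, method="km")
        assert 0 < km <= out.duration_h.max()


class TestEventProbabilities:
    def test_probabilities_partition_to_one(self, low_gsh):
        df, _ = synthetic.gen_cell_tracks(low_gsh, 200, seed=6)
        curve = sc.event_probabilities(sc.tracks_from_table(df), "ros", bins=6, n_boot=100, seed=1)
        total = curve.table[[f"p_{e}" for e in sc.EVENTS]].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-9)
        for e in sc.EVENTS:
            assert ((curve.prob(e) >= 0) & (curve.prob(e) <= 1)).all()

    def test_pure_divider_bin_has_probability_one_and_zero_sem(self):
        tracks = [make_track(cell_id=f"c{i}", ros=100.0 * (1 + 0.01 * i), buds=(24.0, 96.0))
                  for i in range(12)]
        curve = sc.event_probabilities(tracks, "ros", bins=1, n_boot=50, seed=0, min_count=5)
        row = curve.table.iloc[0]
        assert row.p_duplicates == 1.0 and row.sem_duplicates == 0.0

    def test_logistic_generator_recovered_within_bootstrap_interval(self):
        rng = np.random.default_rng(12)
        tracks = []
        for i in range(800):
            ros = float(rng.lognormal(7.0, 1.0))
            p = 1.0 / (1.0 + np.exp(2.0 * (np.log(ros) - 7.5)))
            buds = (24.0, 96.0) if rng.random() < p else ()
            tracks.append(make_track(cell_id=f"c{i}", ros=ros, buds=buds))
        curve = sc.event_probabilities(tracks, "ros", bins=8, n_boot=300, seed=3)
        centers = 0.5 * (curve.table.bin_lo + curve.table.bin_hi)
        expected = 1.0 / (1.0 + np.exp(2.0 * (np.log(centers) - 7.5)))
        within = (
            np.abs(curve.table.p_duplicates - expected)
            <= 2.5 * np.maximum(curve.table.sem_duplicates, 1e-3) + 0.05
        )
        assert within.mean() >= 0.9

    def test_unknown_covariate_rejected(self):
        with pytest.raises(InvalidInputError):
            sc.event_probabilities([make_track()], "volume")


class TestExtractPhases:
    def test_noiseless_boundaries_within_one_frame(self, low_gsh):
        df, manifest = synthetic.gen_cycle_traces(low_gsh, 30, seed=3, noise_cv=0.0)
        truth = {c["cell_id"]: c for c in manifest["cells"]}
        frame = low_gsh.frame_h
        checked = 0
        for trace in sc.traces_from_table(df):
            got = sc.extract_phases(trace)
            want = truth[trace.cell_id]
            if not (got.complete and want["complete"]):
                continue
            checked += 1
            # boundary errors: S start (= G1 exit) and S end, each to a frame
            assert abs(got.g1_h - want["g1_h"]) <= frame
            assert abs((got.g1_h + got.s_h) - (want["g1_h"] + want["s_h"])) <= frame
            assert abs(got.replicative_h - (want["s_h"] + want["g2_h"] + want["m_h"])) <= 2 * frame
        assert checked >= 10

    def test_whi5_stuck_in_nucleus_reports_censored_g1(self, low_gsh):
        df, manifest = synthetic.gen_cycle_traces(low_gsh, 40, seed=8)
        truth = {c["cell_id"]: c for c in manifest["cells"]}
        for trace in sc.traces_from_table(df):
            if not truth[trace.cell_id]["divider"]:
                got = sc.extract_phases(trace)
                assert got.g1_censored
                assert got.g1_h == pytest.approx(trace.time_h[-1] - trace.time_h[0])

    def test_constant_dna_copy_reports_no_s_phase(self):
        t = np.arange(0.0, 120.0, 12.0)
        whi5 = np.where(t < 48.0, 2.5, 0.8)
        trace = sc.CycleTrace("c0", t, whi5, np.ones_like(t))
        got = sc.extract_phases(trace)
        assert np.isnan(got.s_h) and not got.complete

    def test_too_short_trace_rejected(self):
        trace = sc.CycleTrace("c0", [0.0, 12.0], [2.5, 2.5], [1.0, 1.0])
        with pytest.raises(InsufficientDataError):
            sc.extract_phases(trace)


class TestPhaseSummary:
    def test_identical_traces_have_zero_sem(self, low_gsh):
        df, _ = synthetic.gen_cycle_traces(low_gsh, 1, seed=2, noise_cv=0.0)
        trace = sc.traces_from_table(df)[0]
        one = sc.extract_phases(trace)
        if not one.complete:  # draw another seed deterministically
            df, _ = synthetic.gen_cycle_traces(low_gsh, 1, seed=5, noise_cv=0.0)
            one = sc.extract_phases(sc.traces_from_table(df)[0])
        summary = sc.phase_summary([one, one, one])
        assert (summary.table["sem_h"] <= 1e-9).all()

    def test_censored_cells_reported_separately(self, low_gsh):
        df, manifest = synthetic.gen_cycle_traces(low_gsh, 60, seed=1)
        phases = [sc.extract_phases(tr) for tr in sc.traces_from_table(df)]
        summary = sc.phase_summary(phases)
        n_nondiv = sum(not c["divider"] for c in manifest["cells"])
        assert summary.n_g1_censored >= max(n_nondiv - 2, 0)
        assert summary.g1_censored_lower_bound_h is not None
        assert summary.n_complete + summary.n_g1_censored <= 60

    def test_requires_two_completed_cycles(self):
        with pytest.raises(InsufficientDataError):
            sc.phase_summary([sc.PhaseDurations("c0", g1_h=10.0)])


class TestLifeCurve:
    @staticmethod
    def _linear_tracks(rate, burst=120.0, n=12, seed=0):
        rng = np.random.default_rng(seed)
        tracks = []
        for i in range(n):
            s0 = 20.0 + rng.normal(0.0, 0.5)
            death = (burst - s0) / rate
            t = np.arange(0.0, death + 12.0, 12.0)
            t = t[t <= death]
            tracks.append(sc.CellTrack(
                cell_id=f"c{i}", time_h=t, size_au=s0 + rate * t, ros_au=100.0,
                born_at=0.0, death_time=float(t[-1]), censored=False))
        return tracks

    def test_linear_growth_closed_form_lifespan(self):
        rate = 0.2
        curve = sc.reconstruct_life_curve(self._linear_tracks(rate))
        expected_days = (120.0 - 20.0) / rate / 24.0
        assert curve.lifespan_d == pytest.approx(expected_days, rel=0.15)

    def test_mean_size_nondecreasing(self, low_gsh):
        df, _ = synthetic.gen_cell_tracks(low_gsh, 80, seed=10)
        curve = sc.reconstruct_life_curve(sc.tracks_from_table(df))
        finite = curve.mean_size[np.isfinite(curve.mean_size)]
        assert (np.diff(finite) >= -1e-9).all()

    def test_faster_growth_shortens_lifespan(self):
        slow = sc.reconstruct_life_curve(self._linear_tracks(0.15, seed=3))
        fast = sc.reconstruct_life_curve(self._linear_tracks(0.30, seed=3))
        assert fast.lifespan_d < slow.lifespan_d

    def test_no_dying_cells_leaves_lifespan_undefined(self):
        tracks = [make_track(cell_id=f"c{i}", born=0.0) for i in range(4)]
        curve = sc.reconstruct_life_curve(tracks)
        assert curve.burst_size is None and curve.lifespan_d is None


class TestReplicativeLifespan:
    def _curve(self, rate=0.2):
        return sc.reconstruct_life_curve(TestLifeCurve._linear_tracks(rate))

    def test_zero_probability_means_zero_divisions(self):
        assert sc.replicative_lifespan(self._curve(), lambda s: 0.0, 48.0) == 0.0

    def test_certain_division_counts_cycle_windows(self):
        curve = self._curve()
        k = 4
        cycle = curve.lifespan_d * 24.0 / k
        assert sc.replicative_lifespan(curve, lambda s: 1.0, cycle) == pytest.approx(k)

    def test_lower_ros_population_divides_more(self, low_gsh, high_gsh):
        # the high-antioxidant population keeps dividing at larger sizes
        curve = self._curve()
        p_low = lambda s: max(0.0, 0.6 - 0.005 * (s - 20.0))
        p_high = lambda s: max(0.1, 0.9 - 0.003 * (s - 20.0))
        cycle = 120.0
        assert sc.replicative_lifespan(curve, p_high, cycle) > sc.replicative_lifespan(
            curve, p_low, cycle
        )
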