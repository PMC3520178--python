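"""Session protocol: screening, probing, I/O selection, robot runs."""

import numpy as np
import pandas as pd
import pytest

from hybrot import (
    CodingParams,
    DecodingParams,
    IOAssignment,
    ProtocolError,
    SessionConfig,
    SpikeData,
    build_arena,
    calibrate_decoding,
    navigation_metrics,
    probe_and_map,
    run_session,
    screen_inputs,
    select_io,
)


class TestScreenInputs:
    def test_silent_culture_aborts(self, layout):
        silent = SpikeData({}, 0.0, 300.0)
        with pytest.raises(ProtocolError):
            screen_inputs(silent, layout)

    def test_low_rate_electrodes_excluded(self, layout):
        rng = np.random.default_rng(0)
        trains = {}
        for k, e in enumerate(layout.electrode_ids[:12]):
            trains[int(e)] = np.sort(rng.uniform(0, 300, 90))  # 0.3 spikes/s
        trains[int(layout.electrode_ids[20])] = np.array([1.0, 2.0])  # 0.0067 /s
        sd = SpikeData(trains, 0.0, 300.0)
        cands = screen_inputs(sd, layout)
        assert int(layout.electrode_ids[20]) not in cands
        assert len(cands) == 8

    def test_short_recording_rejected(self, layout):
        sd = SpikeData({12: np.arange(0, 60, 0.5)}, 0.0, 60.0)
        with pytest.raises(ValueError):
            screen_inputs(sd, layout)

    def test_ranking_is_deterministic(self, spont_modular, layout):
        a = screen_inputs(spont_modular, layout)
        b = screen_inputs(spont_modular, layout)
        assert a == b
        assert 8 <= len(a) <= 10

    def test_least_synchronized_sites_rank_first(self, layout):
        rng = np.random.default_rng(1)
        common = np.sort(rng.uniform(0, 300, 150))
        trains = {}
        # ten electrodes locked to a shared burst train, one independent
        for e in layout.electrode_ids[:10]:
            trains[int(e)] = np.sort(common + rng.normal(0, 0.002, common.size))
        indep = int(layout.electrode_ids[30])
        trains[indep] = np.sort(rng.uniform(0, 300, 150))
        cands = screen_inputs(SpikeData(trains, 0.0, 300.0), layout)
        assert cands[0] == indep


class TestProbeAndMap:
    def test_probe_arithmetic_and_map_shape(self, make_culture, layout):
        culture = make_culture(seed=4)
        pm = probe_and_map(culture, [44, 45], n_stimuli=6, isi_s=0.7)
        assert len(pm.stim_log) == 12
        assert len(pm.psths) == 2 * 59
        assert all(len(v) == 6 for v in pm.stim_times.values())
        areas = pm.areas()
        assert areas.shape == (59, 2)
        assert (areas.values >= 0).all()

    def test_empty_candidate_list_rejected(self, make_culture):
        with pytest.raises(ValueError):
            probe_and_map(make_culture(seed=4), [])


class TestSelectIO:
    @staticmethod
    def synthetic_areas(selective=True):
        recs = list(range(30))
        a_vals, b_vals = [], []
        for r in recs:
            if not selective:
                a_vals.append(4.0)
                b_vals.append(4.0)
            elif r < 15:
                a_vals.append(5.0 + 0.1 * r)
                b_vals.append(0.5)
            else:
                a_vals.append(0.5)
                b_vals.append(5.0 + 0.1 * r)
        return pd.DataFrame({101: a_vals, 102: b_vals}, index=recs)

    def test_on_bisector_degenerate_aborts(self):
        with pytest.raises(ProtocolError):
            select_io(self.synthetic_areas(selective=False))

    def test_bisector_distance_formula(self):
        from hybrot.protocol import bisector_distance

        assert bisector_distance(4.0, 0.0) == pytest.approx(4.0 / np.sqrt(2.0))

    def test_selective_map_yields_disjoint_areas(self):
        io = select_io(self.synthetic_areas())
        assert io.input_left == 101 and io.input_right == 102
        assert len(io.output_left) == 8 and len(io.output_right) == 8
        assert set(io.output_left).isdisjoint(io.output_right)
        # most selective electrodes (largest index per side) chosen first
        assert 14 in io.output_left and 29 in io.output_right

    def test_io_assignment_invariants_enforced(self):
        with pytest.raises(ValueError):
            IOAssignment(input_left=1, input_right=2,
                         output_left=(1, 3, 4, 5, 6, 7, 8, 9),
                         output_right=(10, 11, 12, 13, 14, 15, 16, 17))
        with pytest.raises(ValueError):
            IOAssignment(input_left=1, input_right=2,
                         output_left=(3, 4, 5, 6, 7, 8, 9, 10),
                         output_right=(10, 11, 12, 13, 14, 15, 16, 17))


class TestCalibration:
    def test_fmax_reflects_spontaneous_quantile(self, spont_modular, layout):
        els = [int(e) for e in layout.electrode_ids]
        io = IOAssignment(input_left=els[0], input_right=els[1],
                         output_left=tuple(els[2:10]), output_right=tuple(els[10:18]))
        left, right = calibrate_decoding(spont_modular, io)
        assert left.f_max >= 0.5 and right.f_max >= 0.5
        assert left.electrodes == io.output_left
        assert left.omega_min == 20.0 and left.omega_max == 40.0


def _manual_io(layout):
    top = [int(e) for e in layout.electrode_ids if layout.compartment_of(int(e)) == "top"]
    bot = [int(e) for e in layout.electrode_ids if layout.compartment_of(int(e)) == "bottom"]
    return IOAssignment(input_left=top[0], input_right=bot[0],
                        output_left=tuple(top[1:9]), output_right=tuple(bot[1:9]))


class TestRunSession:
    def test_closed_run_produces_consistent_log(self, make_culture, layout):
        culture = make_culture(seed=6)
        io = _manual_io(layout)
        cfg = SessionConfig(mode="closed", duration_s=20.0, seed=1,
                            coding_left=CodingParams(electrode=io.input_left),
                            coding_right=CodingParams(electrode=io.input_right))
        log = run_session(cfg, culture, build_arena(seed=2), io)
        assert len(log.windows) == 200
        assert log.trajectory.shape == (201, 4)
        assert np.all(np.isfinite(log.windows.to_numpy()))
        assert len(log.relocations) == len(log.collisions)
        # wheel speeds bounded by the decoder range
        w = log.windows
        assert w.omega_left.between(20.0, 40.0).all()
        assert (w.s_left >= 0.2).all() and (w.s_left <= 2.0).all()

    def test_open_mode_never_stimulates(self, make_culture, layout):
        culture = make_culture(seed=6)
        io = _manual_io(layout)
        cfg = SessionConfig(mode="open", duration_s=10.0, seed=1,
                            coding_left=CodingParams(electrode=io.input_left),
                            coding_right=CodingParams(electrode=io.input_right))
        log = run_session(cfg, culture, build_arena(seed=2), io)
        assert (log.windows.s_left == 0).all() and (log.windows.s_right == 0).all()

    def test_empty_mode_runs_straight(self):
        cfg = SessionConfig(mode="empty", duration_s=60.0, seed=3)
        log = run_session(cfg, None, build_arena(seed=2), None)
        headings = np.unwrap(log.trajectory[:, 3])
        assert np.rad2deg(headings.std()) < 1.0

    def test_byte_for_byte_determinism(self, layout):
        from hybrot import CultureConfig, build_culture, simulate_window

        def one():
            st = build_culture(CultureConfig(seed=8, topology="modular"), layout)
            simulate_window(st, 5.0)
            io = _manual_io(layout)
            cfg = SessionConfig(mode="closed", duration_s=15.0, seed=2,
                                coding_left=CodingParams(electrode=io.input_left),
                                coding_right=CodingParams(electrode=io.input_right))
            return run_session(cfg, st, build_arena(seed=2), io)

        a, b = one(), one()
        assert np.array_equal(a.trajectory, b.trajectory)
        pd.testing.assert_frame_equal(a.windows, b.windows)

    def test_plasticity_triggers_tetanus_and_freeze(self, make_culture, layout):
        culture = make_culture(seed=6)
        io = _manual_io(layout)
        cfg = SessionConfig(mode="closed", duration_s=60.0, seed=1, plasticity=True,
                            coding_left=CodingParams(electrode=io.input_left),
                            coding_right=CodingParams(electrode=io.input_right))
        log = run_session(cfg, culture, build_arena(seed=2), io)
        if log.collisions:  # a 60 s run virtually always collides
            assert log.tetani
            first = log.tetani[0]
            assert first.electrode in (io.input_left, io.input_right)
            # robot is held during the 2 s tetanus: pose constant
            t0 = first.time
            idx = np.searchsorted(log.trajectory[:, 0], t0)
            frozen = log.trajectory[idx:idx + 20, 1:3]
            assert np.allclose(frozen, frozen[0])

    def test_missing_io_rejected_outside_empty_mode(self):
        with pytest.raises(ValueError):
            run_session(SessionConfig(mode="closed", duration_s=1.0, seed=0),
                        None, build_arena(seed=1), None)

    def test_runlog_saves_text_artifacts(self, tmp_path):
        cfg = SessionConfig(mode="empty", duration_s=10.0, seed=3)
        log = run_session(cfg, None, build_arena(seed=2), None)
        log.save(tmp_path)
        for name in ("windows.tsv", "trajectory.tsv", "events.tsv", "spikes.tsv"):
            assert (tmp_path / name).exists()
        m = navigation_metrics(log)
        assert m.total_path_px > 0
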