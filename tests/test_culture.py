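"""Surrogate culture: layout, construction, simulation, tetanus."""

import numpy as np
import pytest

from hybrot import (
    CultureConfig,
    ElectrodeLayout,
    SpikeData,
    StimPulse,
    apply_tetanus,
    build_culture,
    potentiate,
    simulate_window,
)


class TestElectrodeLayout:
    def test_has_59_sites_on_200um_grid(self, layout):
        assert len(layout.electrode_ids) == 59
        assert len(set(layout.electrode_ids.tolist())) == 59
        # axis-aligned distances are multiples of the 200 um pitch
        offsets = layout.positions % 200.0
        assert np.allclose(offsets, 0.0)

    def test_corners_and_reference_excluded(self, layout):
        for eid in (11, 18, 81, 88, 15):
            assert eid not in layout.electrode_ids

    def test_modular_labels_partition_all_sites(self, layout):
        comps = set(layout.compartment)
        assert comps == {"top", "bottom"}
        n_top = sum(c == "top" for c in layout.compartment)
        assert n_top + sum(c == "bottom" for c in layout.compartment) == 59

    def test_plain_layout_has_no_compartments(self):
        lay = ElectrodeLayout.mea_8x8()
        assert lay.compartment is None
        with pytest.raises(ValueError):
            lay.compartment_of(12)


class TestBuildCulture:
    def test_excitatory_inhibitory_split_is_exact(self, layout):
        state = build_culture(CultureConfig(seed=0, n_neurons=400, excitatory_fraction=0.75), layout)
        assert int(state.is_excitatory.sum()) == 300
        assert int((~state.is_excitatory).sum()) == 100

    def test_no_bridges_means_block_diagonal_connectivity(self, layout):
        cfg = CultureConfig(seed=1, topology="modular", n_bridges=0)
        state = build_culture(cfg, layout)
        y = state.neuron_pos[:, 1]
        midline = 0.5 * (cfg.extent[2] + cfg.extent[3])
        top = y < midline
        cross = state.weights[np.ix_(top, ~top)], state.weights[np.ix_(~top, top)]
        assert not cross[0].any() and not cross[1].any()

    def test_bridges_connect_compartments(self, layout):
        cfg = CultureConfig(seed=1, topology="modular", n_bridges=20)
        state = build_culture(cfg, layout)
        y = state.neuron_pos[:, 1]
        top = y < 0.5 * (cfg.extent[2] + cfg.extent[3])
        n_cross = np.count_nonzero(state.weights[np.ix_(top, ~top)]) + np.count_nonzero(
            state.weights[np.ix_(~top, top)]
        )
        assert n_cross == 20

    def test_same_seed_same_weights(self, layout):
        cfg = CultureConfig(seed=7)
        w1 = build_culture(cfg, layout).weights
        w2 = build_culture(cfg, layout).weights
        assert np.array_equal(w1, w2)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CultureConfig(excitatory_fraction=1.5)
        with pytest.raises(ValueError):
            CultureConfig(topology="lattice")
        with pytest.raises(ValueError):
            CultureConfig(tau_m=-1.0)

    def test_modular_needs_compartment_labels(self):
        plain = ElectrodeLayout.mea_8x8()
        with pytest.raises(ValueError):
            build_culture(CultureConfig(seed=0, topology="modular"), plain)


class TestSimulateWindow:
    def test_zero_duration_returns_empty_and_keeps_clock(self, make_culture):
        st = make_culture(seed=11)
        t = st.time
        sd = simulate_window(st, 0.0)
        assert sd.n_spikes() == 0
        assert st.time == t

    def test_clock_advances_by_duration(self, make_culture):
        st = make_culture(seed=11)
        t = st.time
        simulate_window(st, 2.5)
        assert st.time == pytest.approx(t + 2.5, abs=1e-9)

    def test_pulse_outside_window_rejected(self, make_culture):
        st = make_culture(seed=11)
        bad = StimPulse(electrode=44, time=st.time + 99.0)
        with pytest.raises(ValueError):
            simulate_window(st, 1.0, [bad])

    def test_seeded_reproducibility_of_spike_data(self, layout):
        def run():
            st = build_culture(CultureConfig(seed=5, topology="modular"), layout)
            pulses = [StimPulse(electrode=44, time=3.0 + k) for k in range(3)]
            return simulate_window(st, 10.0, pulses)

        a, b = run(), run()
        assert a.electrodes() == b.electrodes()
        for e in a.electrodes():
            assert np.array_equal(a.train(e), b.train(e))

    def test_spontaneous_rates_mostly_in_plausible_band(self, spont_modular, layout):
        """>=80% of electrodes fire between 0.1 and 10 spikes/s."""
        rates = np.array([len(spont_modular.train(int(e))) / spont_modular.duration
                          for e in layout.electrode_ids])
        assert np.mean((rates >= 0.1) & (rates <= 10.0)) >= 0.8

    def test_stimulation_evokes_local_response(self, make_culture, layout):
        st = make_culture(topology="modular", seed=9)
        quiet = simulate_window(st, 5.0)
        pulses = [StimPulse(electrode=44, time=st.time + 0.5 + k) for k in range(10)]
        sd = simulate_window(st, 12.0, pulses)
        same = [int(e) for e in layout.electrode_ids
                if layout.compartment_of(int(e)) == layout.compartment_of(44)]
        evoked = sum(sd.count_in(same, p.time, p.time + 0.1) for p in pulses)
        base_rate = sum(len(quiet.train(e)) for e in same) / quiet.duration
        assert evoked > base_rate * 0.1 * len(pulses)

    def test_no_nans_and_weights_bounded_over_long_run(self, make_culture):
        st = make_culture(seed=2)
        simulate_window(st, 120.0)
        assert np.all(np.isfinite(st.v))
        w = st.effective_weights()
        assert w.max() <= st.config.w_ceiling + 1e-12
        assert np.all(st.depression >= 0.0) and np.all(st.depression <= 1.0)


class TestTetanus:
    def test_schedule_is_40_pulses_at_50ms(self, make_culture):
        st = make_culture(seed=1)
        pulses = apply_tetanus(st, electrode=44, rate=20.0, duration=2.0)
        assert len(pulses) == 40
        gaps = np.diff([p.time for p in pulses])
        assert np.allclose(gaps, 0.05)
        assert all(p.kind == "tetanus" for p in pulses)

    def test_zero_eta_leaves_weights_unchanged(self, make_culture):
        st = make_culture(seed=1)
        before = st.effective_weights().copy()
        potentiate(st, electrode=44, eta=0.0)
        assert np.array_equal(before, st.effective_weights())

    def test_potentiation_scales_outgoing_excitatory_weights(self, make_culture):
        st = make_culture(seed=1)
        area = st.neurons_near(44, st.config.stim_radius_um)
        area = area[st.is_excitatory[area]]
        before = st.effective_weights()[area].copy()
        potentiate(st, electrode=44)
        after = st.effective_weights()[area]
        unclipped = before < st.config.w_ceiling / (1 + st.config.eta)
        assert np.allclose(after[unclipped], before[unclipped] * 1.2)
        assert after.max() <= st.config.w_ceiling + 1e-12

    def test_unknown_electrode_rejected(self, make_culture):
        st = make_culture(seed=1)
        with pytest.raises(KeyError):
            apply_tetanus(st, electrode=999)

    def test_psth_area_not_reduced_after_tetanus(self, layout):
        """Early-response area of the stimulated compartment grows (or holds)
        after one default tetanus, averaged over seeds."""
        from hybrot import compute_psth

        ratios = []
        for seed in (20, 21, 22):
            st = build_culture(CultureConfig(seed=seed, topology="modular"), layout)
            simulate_window(st, 10.0)
            same = [int(e) for e in layout.electrode_ids
                    if e != 42 and layout.compartment_of(int(e)) == layout.compartment_of(42)]

            def probe_area():
                pulses = [StimPulse(electrode=42, time=st.time + 0.5 + k) for k in range(40)]
                sd = simulate_window(st, 41.2, pulses)
                ts = np.array([p.time for p in pulses])
                return sum(compute_psth(sd.train(e), ts, window_s=0.1).area for e in same)

            before = probe_area()
            train = apply_tetanus(st, electrode=42)
            simulate_window(st, 2.5, train)
            potentiate(st, electrode=42)
            simulate_window(st, 10.0)
            ratios.append(probe_area() / before)
        assert np.mean(ratios) >= 1.0
        assert sum(r >= 0.95 for r in ratios) >= 2


class TestSpikeDataIO:
    def test_tsv_round_trip(self, tmp_path):
        sd = SpikeData({12: np.array([0.5, 1.25]), 87: np.array([0.75])}, 0.0, 2.0)
        path = tmp_path / "spikes.tsv"
        sd.to_tsv(path)
        back = SpikeData.from_tsv(path)
        assert back.t_start == 0.0 and back.t_stop == 2.0
        assert np.allclose(back.train(12), [0.5, 1.25])
        assert np.allclose(back.train(87), [0.75])

    def test_npz_round_trip(self, tmp_path):
        sd = SpikeData({12: np.array([0.5, 1.25])}, 0.0, 2.0)
        path = tmp_path / "spikes.npz"
        sd.to_npz(path)
        back = SpikeData.from_npz(path)
        assert np.allclose(back.train(12), sd.train(12))

    def test_count_in_is_half_open(self):
        sd = SpikeData({1: np.array([0.1, 0.2, 0.3])}, 0.0, 1.0)
        assert sd.count_in([1], 0.1, 0.3) == 2  # 0.3 falls in the next window

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = CultureConfig(seed=9, topology="modular", n_bridges=7)
        path = tmp_path / "culture.yaml"
        cfg.to_yaml(path)
        assert CultureConfig.from_yaml(path) == cfg
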