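import numpy as np
import pytest
from scipy.stats import spearmanr

from impedimap.demodulation import (
    current_to_impedance,
    demodulate_trace,
)
from impedimap.image_features import (
    FeatureConfig,
    compute_cell_mask,
    compute_epoxy_mask,
    detect_domes,
    extract_timeseries,
    masked_median,
)
from impedimap.plate_model import MAP_KEYS, default_field_config
from impedimap.synthetic_data import (
    ARCHETYPES,
    COMPOUND_LIBRARY,
    CellTypeArchetype,
    SimulationConfig,
    default_screen_platemap,
    simulate_coculture,
    simulate_plate,
    simulate_raw_scan,
    simulate_well,
)


def logistic_closed_form(n0, r, t):
    return n0 * np.exp(r * t) / (1 + n0 * (np.exp(r * t) - 1))


class TestDeterminism:
    @pytest.mark.parametrize("noiseless", [True, False])
    def test_same_seed_bit_identical(self, noiseless):
        cfg = SimulationConfig(seed=0, duration_h=3.0, scan_interval_h=1.0)
        if noiseless:
            cfg = cfg.noiseless()
        a = simulate_well(ARCHETYPES["MDCK-like"], 1.0, cfg, seed=11)
        b = simulate_well(ARCHETYPES["MDCK-like"], 1.0, cfg, seed=11)
        for sa, sb in zip(a.stacks, b.stacks):
            for k in MAP_KEYS:
                np.testing.assert_array_equal(sa[k], sb[k])

    def test_plate_independent_of_wellmap_insertion_order(self):
        cfg = SimulationConfig(seed=5, duration_h=1.0, scan_interval_h=0.5)
        meta = default_screen_platemap(n_dmso=1)
        sub = {w: meta.wells[w] for w in ("B2", "A2", "A3")}
        from impedimap.plate_model import PlateMetadata

        m1 = PlateMetadata("p", dict(sorted(sub.items())), 24.0)
        m2 = PlateMetadata("p", dict(sorted(sub.items(), reverse=True)), 24.0)
        s1 = simulate_plate(m1, cfg)
        s2 = simulate_plate(m2, cfg)
        for w in sub:
            np.testing.assert_array_equal(
                s1[w].stacks[0][("VF", "mag@4000")], s2[w].stacks[0][("VF", "mag@4000")]
            )


class TestGrowth:
    def test_initial_occupancy_matches_seeding_density(self, noiseless_cfg):
        sw = simulate_well(
            ARCHETYPES["A549-like"], 1.0, noiseless_cfg, seed=1, density=14_800.0
        )
        n_avail = (~sw.epoxy_mask).sum()
        expect = 14_800.0 / 40_000.0
        got = sw.total_occupancy[0]
        assert abs(got * n_avail - expect * n_avail) <= 1.0

    def test_noiseless_occupancy_tracks_logistic_closed_form(self):
        cfg = SimulationConfig(seed=2, duration_h=48.0, scan_interval_h=2.0).noiseless()
        arch = ARCHETYPES["A549-like"]
        sw = simulate_well(arch, 1.0, cfg, seed=3, density=10_000.0)
        t = sw.times_h
        expect = logistic_closed_form(0.25, arch.growth_rate, t)
        np.testing.assert_allclose(sw.total_occupancy, expect, rtol=0.02, atol=0.001)


class TestCoculture:
    def test_ratio_zero_is_pure_first_archetype(self, noiseless_cfg):
        sw = simulate_coculture(
            ARCHETYPES["MCF7-like"], ARCHETYPES["MDA-MB-231-like"], 0.0,
            cfg=noiseless_cfg, seed=4,
        )
        assert list(sw.occupancy_fraction) == ["MCF7-like"]

    def test_equal_growth_rates_keep_fraction_constant(self):
        cfg = SimulationConfig(seed=0, duration_h=24.0, scan_interval_h=4.0).noiseless()
        a = ARCHETYPES["MCF7-like"]
        b = CellTypeArchetype(name="twin", growth_rate=a.growth_rate, motility_amplitude=0.3)
        sw = simulate_well([a, b], [0.5, 0.5], cfg, seed=5, density=10_000.0)
        fa = sw.occupancy_fraction["MCF7-like"]
        fb = sw.occupancy_fraction["twin"]
        frac = fb / (fa + fb)
        np.testing.assert_allclose(frac, 0.5, atol=0.01)

    def test_growth_advantage_makes_fraction_increase(self):
        cfg = SimulationConfig(seed=0, duration_h=48.0, scan_interval_h=4.0).noiseless()
        sw = simulate_coculture(
            ARCHETYPES["MCF7-like"], ARCHETYPES["MDA-MB-231-like"], 0.5,
            growth_advantage=1.5, cfg=cfg, seed=6, density=10_000.0,
        )
        fa = sw.occupancy_fraction["MCF7-like"]
        fb = sw.occupancy_fraction["MDA-MB-231-like"]
        frac = fb / (fa + fb)
        growing = (fa + fb)[:-1] < 0.9  # strict increase while growth outpaces quantization
        assert np.all(np.diff(frac)[growing] > 0)
        assert np.all(np.diff(frac) > -2.0 / 4096)  # pixel quantization near capacity
        assert frac[-1] > frac[0] + 0.2


class TestRawTraces:
    def make_z(self, seed=0):
        rng = np.random.default_rng(seed)
        return {
            f: 10 ** rng.uniform(5.5, 7.5, (64, 64))
            for f in (250.0, 1000.0, 4000.0, 16000.0)
        }

    def test_noiseless_round_trip_recovers_impedance(self):
        cfg = SimulationConfig(sample_rate_hz=250_000.0).noiseless()
        config = default_field_config("LF")
        z = self.make_z(1)
        traces = simulate_raw_scan(z, config, cfg)
        rng = np.random.default_rng(2)
        idx = rng.integers(0, 64, size=(50, 2))
        for r, c in idx:
            res = demodulate_trace(traces[r, c], cfg.sample_rate_hz)
            for i, (f, a) in enumerate(zip(config.frequencies_hz, config.amplitudes_v)):
                z_rec = current_to_impedance(res.magnitudes[i], a, config.tia_gain_ohm)
                assert z_rec == pytest.approx(z[f][r, c], rel=1e-6)

    def test_doubling_impedance_halves_output(self):
        cfg = SimulationConfig(sample_rate_hz=250_000.0).noiseless()
        config = default_field_config("VF")
        z = self.make_z(3)
        t1 = simulate_raw_scan(z, config, cfg)
        t2 = simulate_raw_scan({f: 2 * v for f, v in z.items()}, config, cfg)
        np.testing.assert_allclose(t2, t1 / 2, rtol=1e-12)

    def test_dc_offset_passes_through(self):
        cfg = SimulationConfig(sample_rate_hz=250_000.0).noiseless()
        config = default_field_config("LF")
        z = {f: np.full((64, 64), 1e12) for f in config.frequencies_hz}
        traces = simulate_raw_scan(z, config, cfg, dc_v=0.31)
        res = demodulate_trace(traces[0, 0], cfg.sample_rate_hz)
        assert res.dc == pytest.approx(0.31, rel=1e-6)
        assert np.all(res.magnitudes < 1e-4)


class TestLatentToMeasurement:
    def test_higher_motility_raises_measured_rms(self):
        cfg = SimulationConfig(seed=0, duration_h=2.0, scan_interval_h=0.5)
        levels = [0.03, 0.1, 0.3]
        means = []
        for m in levels:
            arch = CellTypeArchetype(name=f"m{m}", motility_amplitude=m)
            vals = []
            for seed in range(10):
                sw = simulate_well(arch, 1.0, cfg, seed=100 + seed, density=20_000.0)
                ts = extract_timeseries(sw.stacks, sw.reference)
                vals.append(np.nanmean(ts.values["rms"]))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_latent_attachment_recovered_up_to_monotone_transform(self):
        cfg = SimulationConfig(seed=0, duration_h=48.0, scan_interval_h=2.0).noiseless()
        arch = ARCHETYPES["MDCK-like"]
        sw = simulate_well(arch, 1.0, cfg, seed=9, density=20_000.0)
        fc = FeatureConfig()
        epoxy = compute_epoxy_mask(sw.reference, fc)
        med = []
        for st in sw.stacks:
            mask = compute_cell_mask(st, sw.reference, fc, epoxy_mask=epoxy)
            med.append(masked_median(st[("LF", "mag@16000")], mask))
        rho = spearmanr(sw.latents["MDCK-like"]["attachment"], med).statistic
        assert rho >= 0.9

    def test_dome_events_are_detectable_at_truth_locations(self):
        cfg = SimulationConfig(seed=0, duration_h=40.0, scan_interval_h=1.0).noiseless()
        sw = simulate_well(ARCHETYPES["MDCK-like"], 1.0, cfg, seed=12, density=30_000.0)
        assert sw.dome_log, "expected at least one doming event at this rate"
        fc = FeatureConfig()
        epoxy = compute_epoxy_mask(sw.reference, fc)
        hits = 0
        for d in sw.dome_log:
            mid = 0.5 * (d["t_start_h"] + min(d["t_end_h"], sw.times_h[-1]))
            k = int(np.argmin(np.abs(sw.times_h - mid)))
            if not (d["t_start_h"] <= sw.times_h[k] < d["t_end_h"]):
                continue
            stack = sw.stacks[k]
            mask = compute_cell_mask(stack, sw.reference, fc, epoxy_mask=epoxy)
            found = detect_domes(stack[("LF", "mag@16000")], mask, fc)
            if any(
                np.hypot(f["center"][0] - d["center"][0], f["center"][1] - d["center"][1]) < 3
                for f in found
            ):
                hits += 1
        assert hits >= 1


class TestPlateSimulation:
    def test_screen_platemap_layout(self):
        meta = default_screen_platemap(n_dmso=6)
        assert len(meta.wells) == 96
        assert len(meta.excluded_wells()) == 16  # columns 1 and 12
        assert len(meta.wells_with_role("positive_control")) == 5
        assert len(meta.wells_with_role("negative_control")) >= 6

    def test_plate_contains_all_requested_scans(self):
        cfg = SimulationConfig(seed=1, duration_h=1.0, scan_interval_h=0.25)
        meta = default_screen_platemap(n_dmso=1)
        from impedimap.plate_model import PlateMetadata

        sub = PlateMetadata(
            "p", {w: meta.wells[w] for w in ("A2", "A3", "B2")}, 24.0
        )
        sim = simulate_plate(sub, cfg)
        assert set(sim) == {"A2", "A3", "B2"}
        assert all(len(s.stacks) == 5 for s in sim.values())

    def test_duplicate_invalid_ratio_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_well(
                [ARCHETYPES["MCF7-like"], ARCHETYPES["MDA-MB-231-like"]], [0.5, 0.6]
            )

    def test_positive_control_moves_its_target_parameter(self):
        t_add = 4.0
        cfg = SimulationConfig(seed=0, duration_h=12.0, scan_interval_h=1.0).noiseless()
        arch = ARCHETYPES["A549-like"]
        kw = dict(cfg=cfg, density=20_000.0, t_compound_h=t_add)
        ctrl = simulate_well(arch, 1.0, seed=13, compound=COMPOUND_LIBRARY["DMSO"], **kw)
        drug = simulate_well(
            arch, 1.0, seed=13, compound=COMPOUND_LIBRARY["cytoskeletal"], **kw
        )
        # flatness kernel is positive: VF 16 kHz should rise above the DMSO well
        late = slice(-4, None)
        f_ctrl = ctrl.latents["A549-like"]["flatness"][late]
        f_drug = drug.latents["A549-like"]["flatness"][late]
        assert np.all(f_drug > f_ctrl)
        ts_c = extract_timeseries(ctrl.stacks, ctrl.reference)
        ts_d = extract_timeseries(drug.stacks, drug.reference)
        assert (
            np.nanmean(ts_d.values["VF:mag@16000"][late])
            > np.nanmean(ts_c.values["VF:mag@16000"][late])
        )
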