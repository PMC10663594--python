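import numpy as np
import pytest

from impedimap.plate_model import WellTimeSeries
from impedimap.profiling import (
    BIOBASIS_NAMES,
    BaselineError,
    GridAlignmentError,
    NormalizedProfile,
    biobasis,
    cluster_compounds,
    dmso_gate,
    functional_indices,
    log_time_grid,
    mean_profile,
    normalize_profile,
    phenoactivity,
    profile_matrix,
    train_classifier,
)

T_ADD = 24.0


def make_series(values_fn, t_end=72.25, dt=0.25, well="A2"):
    t = np.arange(0.0, t_end, dt)
    return WellTimeSeries(
        well,
        t,
        {
            "VF:mag@250": values_fn(t, 0),
            "VF:mag@16000": values_fn(t, 1),
            "LF:mag@16000": values_fn(t, 2),
            "rms": values_fn(t, 3),
            "confluence": values_fn(t, 4),
        },
    )


def flat_series(level=2.0, **kw):
    return make_series(lambda t, i: np.full(len(t), level), **kw)


def make_profile(values, well="A2", compound="x", grid=None):
    grid = log_time_grid(T_ADD) if grid is None else grid
    return NormalizedProfile(
        compound=compound,
        well_id=well,
        times_h=grid,
        values={k: np.asarray(v, dtype=float) for k, v in values.items()},
    )


class TestLogGrid:
    def test_endpoints(self):
        g = log_time_grid(T_ADD, 16)
        assert g[0] > T_ADD
        assert g[0] == pytest.approx(T_ADD + 0.25)
        assert g[-1] == pytest.approx(T_ADD + 48.0)
        assert len(g) == 16
        # logarithmic: ratios of offsets are constant
        off = g - T_ADD
        np.testing.assert_allclose(np.diff(np.log(off)), np.diff(np.log(off))[0])


class TestNormalizeProfile:
    def test_constant_trace_gives_all_ones(self):
        p = normalize_profile(flat_series(3.0), T_ADD)
        for k, v in p.values.items():
            np.testing.assert_allclose(v, 1.0)

    def test_relative_change_arithmetic(self):
        def fn(t, i):
            v = np.full(len(t), 2.0)
            v[t > T_ADD] = 3.0
            return v

        p = normalize_profile(make_series(fn), T_ADD)
        np.testing.assert_allclose(p.values["rms"], 1.5)

    def test_nonpositive_baseline_flags_well(self):
        with pytest.raises(BaselineError, match="baseline"):
            normalize_profile(flat_series(0.0), T_ADD)

    def test_no_scan_near_baseline_flags_well(self):
        s = flat_series(2.0, dt=0.25, t_end=30.0)
        trimmed = WellTimeSeries(
            s.well_id,
            s.times_h[s.times_h > T_ADD],
            {k: v[-len(s.times_h[s.times_h > T_ADD]) :] for k, v in s.values.items()},
        )
        with pytest.raises(BaselineError, match="scan"):
            normalize_profile(trimmed, T_ADD)

    def test_raw_confluence_kept_alongside(self):
        p = normalize_profile(flat_series(50.0), T_ADD)
        np.testing.assert_allclose(p.values["confluence"], 1.0)
        np.testing.assert_allclose(p.raw_values["confluence"], 50.0)


class TestPhenoactivity:
    def grid_ones(self, n=16):
        return {k: np.ones(n) for k in ("VF:mag@250", "rms")}

    def test_zero_against_matching_dmso(self):
        dmso = [make_profile(self.grid_ones(), well=f"D{i}") for i in range(3)]
        assert phenoactivity(make_profile(self.grid_ones()), dmso) == 0.0

    def test_single_parameter_offset_closed_form(self):
        dmso = [make_profile(self.grid_ones(), well=f"D{i}") for i in range(3)]
        vals = self.grid_ones()
        delta = 0.7
        vals["rms"] = vals["rms"] + delta
        p = make_profile(vals)
        # brute force: sum of squares over 2 params x 16 points
        expect = np.sqrt((16 * delta**2) / (2 * 16))
        assert phenoactivity(p, dmso) == pytest.approx(expect, rel=1e-12)
        assert phenoactivity(p, dmso) == pytest.approx(abs(delta) / np.sqrt(2))

    def test_monotone_in_single_residual(self):
        dmso = [make_profile(self.grid_ones(), well=f"D{i}") for i in range(3)]
        scores = []
        for delta in (0.1, 0.2, 0.5):
            vals = self.grid_ones()
            vals["rms"] = vals["rms"].copy()
            vals["rms"][3] += delta
            scores.append(phenoactivity(make_profile(vals), dmso))
        assert scores[0] < scores[1] < scores[2]

    def test_grid_mismatch_rejected(self):
        dmso = [make_profile(self.grid_ones(), well=f"D{i}") for i in range(2)]
        other = make_profile(self.grid_ones(), grid=log_time_grid(T_ADD + 1))
        with pytest.raises(GridAlignmentError):
            phenoactivity(other, dmso)


class TestDmsoGate:
    def test_three_sigma_is_active_mean_is_not(self):
        rng = np.random.default_rng(0)
        dmso = rng.normal(1.0, 0.1, 20)
        m, s = dmso.mean(), dmso.std(ddof=1)
        out = dmso_gate(np.array([m + 3 * s, m]), dmso)
        assert out.tolist() == [True, False]

    def test_dict_interface(self):
        dmso = np.array([1.0, 1.1, 0.9, 1.05])
        out = dmso_gate({"a": 10.0, "b": 1.0}, dmso)
        assert out == {"a": True, "b": False}

    def test_degenerate_sd_warns(self):
        with pytest.warns(UserWarning):
            out = dmso_gate(np.array([1.5]), np.array([1.0, 1.0, 1.0]))
        assert out.tolist() == [True]


class TestBioBasis:
    def all_params(self, n=16):
        return {
            k: np.ones(n)
            for k in ("VF:mag@250", "VF:mag@16000", "LF:mag@16000", "rms", "confluence")
        }

    def test_matching_dmso_gives_zero_vector(self):
        p = make_profile(self.all_params())
        d = make_profile(self.all_params())
        bb = biobasis(p, d)
        assert np.all(bb.to_array() == 0.0)

    def test_positive_excursion_matches_trapezoid_oracle(self):
        grid = log_time_grid(T_ADD)
        vals = self.all_params()
        excess = np.where(grid - T_ADD <= 10.0, 0.5, 0.0)
        vals["LF:mag@16000"] = 1.0 + excess
        p = make_profile(vals, grid=grid)
        d = make_profile(self.all_params(), grid=grid)
        bb = biobasis(p, d)
        assert bb.attachment_up == pytest.approx(np.trapezoid(excess, grid), rel=1e-12)
        assert bb.detachment_down == 0.0

    def test_up_down_split_is_disjoint(self):
        grid = log_time_grid(T_ADD)
        vals = self.all_params()
        diff = np.where(grid - T_ADD <= 5.0, 0.4, -0.3)
        vals["rms"] = 1.0 + diff
        p = make_profile(vals, grid=grid)
        d = make_profile(self.all_params(), grid=grid)
        bb = biobasis(p, d)
        up = np.trapezoid(np.clip(diff, 0, None), grid)
        down = -np.trapezoid(np.clip(diff, None, 0), grid)
        assert bb.dynamicity_up == pytest.approx(up, rel=1e-12)
        assert bb.staticity_down == pytest.approx(down, rel=1e-12)
        assert bb.dynamicity_up > 0 and bb.staticity_down > 0

    def test_cell_death_and_death_rate_from_confluence(self):
        t = T_ADD + np.linspace(0.25, 48.0, 192)
        conf = np.where(t - T_ADD <= 12.0, 100.0 - 5.0 * (t - T_ADD), 40.0)
        vals = self.all_params(len(t))
        p = make_profile(vals, grid=t)
        d = make_profile(self.all_params(len(t)), grid=t)
        bb = biobasis(p, d, confluence_trace=conf, dmso_confluence=np.full(len(t), 100.0))
        assert bb.cell_death == pytest.approx(60.0, rel=1e-9)
        assert bb.death_rate == pytest.approx(5.0, rel=1e-6)

    def test_biobasis_vector_ordering(self):
        bb = biobasis(make_profile(self.all_params()), make_profile(self.all_params()))
        assert len(bb.to_array()) == len(BIOBASIS_NAMES) == 11


class TestFunctionalIndices:
    def panel_series(self, scale, well="A2"):
        t = np.arange(0.0, 48.25, 0.25)
        conf = np.clip(2.0 * scale * t, 0, 100)  # growth slope 2*scale %/h, unclipped through 12 h
        vals = {
            "confluence": conf,
            "VF:mag@250": np.full(len(t), 1.0 * scale),
            "VF:mag@1000": np.full(len(t), 2.0 * scale),
            "VF:mag@16000": np.full(len(t), 3.0 * scale),
            "LF:mag@16000": np.full(len(t), 4.0 * scale),
            "rms": np.full(len(t), 0.1 * scale),
            "rms_long": np.full(len(t), 0.2 * scale),
        }
        return WellTimeSeries(well, t, vals)

    def test_minmax_anchors_and_midpoint(self):
        panel = {
            "lo": self.panel_series(1.0),
            "mid": self.panel_series(1.5),
            "hi": self.panel_series(2.0),
        }
        fi = functional_indices(panel)
        for name in fi.indices["lo"]:
            assert fi.indices["lo"][name] == 0.0
            assert fi.indices["hi"][name] == 1.0
            assert fi.indices["mid"][name] == pytest.approx(0.5, abs=0.02)

    def test_growth_rate_is_regression_slope(self):
        panel = {"a": self.panel_series(1.0), "b": self.panel_series(0.5)}
        fi = functional_indices(panel)
        assert fi.raw["a"]["growth_rate"] == pytest.approx(2.0, rel=1e-6)
        assert fi.raw["b"]["growth_rate"] == pytest.approx(1.0, rel=1e-6)

    def test_single_cell_type_rejected(self):
        with pytest.raises(ValueError, match="2 cell types"):
            functional_indices({"only": self.panel_series(1.0)})


def blob_features(rng, n_classes, n_per, sep=10.0, sd=1.0, n_feat=40):
    """Dense random class signatures (inter-centroid distance sep x sd), the
    correlated-feature regime of real multi-parameter response profiles."""
    centers = rng.standard_normal((n_classes, n_feat))
    centers *= sep / np.linalg.norm(centers, axis=1, keepdims=True)
    X, y = [], []
    for i in range(n_classes):
        X.append(centers[i] + sd * rng.standard_normal((n_per, n_feat)))
        y += [i] * n_per
    return np.vstack(X), np.array(y)


class TestClustering:
    def test_separated_archetypes_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(0)
        X, y = blob_features(rng, 3, 20)
        labels, _ = cluster_compounds(X, n_components=20)
        assert adjusted_rand_score(y, labels) == 1.0

    def test_duplicated_dataset_same_labeling(self):
        rng = np.random.default_rng(1)
        X, _ = blob_features(rng, 3, 10)
        l1, _ = cluster_compounds(X, n_components=10, n_clusters=3)
        l2, _ = cluster_compounds(np.vstack([X, X]), n_components=10, n_clusters=3)
        # duplicated rows land in the same cluster as their originals
        assert np.array_equal(l2[: len(X)], l2[len(X) :])

    def test_identical_profiles_form_single_cluster(self):
        X = np.ones((30, 8))
        labels, _ = cluster_compounds(X, n_components=5)
        assert len(set(labels)) == 1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="components"):
            cluster_compounds(np.ones((5, 8)), n_components=20)


class TestClassifier:
    def test_separable_controls_reach_precision_one(self):
        rng = np.random.default_rng(2)
        X, y = blob_features(rng, 6, 13, sep=10.0)
        m = train_classifier(X, y, split=0.8, seed=0)
        assert m.precision_macro == 1.0
        assert set(m.precision_per_class.values()) == {1.0}
        assert len(m.test_idx) == round(0.2 * len(y))

    def test_randomized_labels_fall_to_chance(self):
        rng = np.random.default_rng(3)
        X, y = blob_features(rng, 6, 13, sep=10.0)
        precisions = []
        for seed in range(50):
            perm = np.random.default_rng(seed).permutation(y)
            m = train_classifier(X, perm, split=0.8, seed=seed)
            precisions.append(m.precision_macro)
        assert np.mean(precisions) <= 2.0 / 6.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            train_classifier(np.ones((10, 4)), np.zeros(10))

    def test_sample_order_permutation_invariance(self):
        rng = np.random.default_rng(4)
        X, y = blob_features(rng, 3, 10, sep=10.0)
        m1 = train_classifier(X, y, seed=1)
        perm = rng.permutation(len(y))
        m2 = train_classifier(X[perm], y[perm], seed=1)
        assert m1.precision_macro == m2.precision_macro


class TestProfileMatrix:
    def test_shape_and_alignment_check(self):
        profs = [
            make_profile({"a": np.ones(16), "b": np.zeros(16)}, well=f"W{i}")
            for i in range(3)
        ]
        X = profile_matrix(profs)
        assert X.shape == (3, 32)
        bad = make_profile({"a": np.ones(16), "b": np.zeros(16)}, grid=log_time_grid(1.0))
        with pytest.raises(GridAlignmentError):
            profile_matrix(profs + [bad])

    def test_mean_profile_averages_parameterwise(self):
        p1 = make_profile({"a": np.full(16, 1.0)})
        p2 = make_profile({"a": np.full(16, 3.0)})
        np.testing.assert_allclose(mean_profile([p1, p2]).values["a"], 2.0)
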