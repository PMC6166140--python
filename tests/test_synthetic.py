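import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from exosite import (
    ConditionSpec,
    NoiseModel,
    PlateLayout,
    constant_rate,
    ring_prob_constant,
    ring_prob_logistic,
    simulate_field,
    simulate_fusion_events,
    simulate_plate,
    simulate_strings,
    simulate_timecourse,
)
from exosite.synthetic import CELLS_PER_FIELD_DEFAULT, field_seed

from .oracles import gaussian_halfmax_area_px


class TestConditionSpec:
    def test_mode_calibration_enforced(self):
        """Modes straddling the 2 um^2 boundary with < 0.99 probability are
        rejected at construction."""
        with pytest.raises(ValueError, match="small mode"):
            ConditionSpec("bad", small_mode=(np.log(1.8), 0.5))
        with pytest.raises(ValueError, match="large mode"):
            ConditionSpec("bad", large_mode=(np.log(2.2), 0.5))

    def test_default_modes_calibrated_by_sampling(self):
        """Sampled small-mode areas are <= 2 um^2 and large-mode areas
        > 2 um^2 with probability >= 0.99 each."""
        rng = np.random.default_rng(0)
        cond = ConditionSpec("c")
        small = np.exp(rng.normal(*cond.small_mode, 20000))
        large = np.exp(rng.normal(*cond.large_mode, 20000))
        assert np.mean(small <= 2.0) >= 0.99
        assert np.mean(large > 2.0) >= 0.99

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"site_rate_per_cell": -1},
            {"large_fraction": 1.5},
            {"kinetics": "bursty"},
            {"tau_min": 0.0},
        ],
    )
    def test_invalid_specs(self, kwargs):
        with pytest.raises(ValueError):
            ConditionSpec("c", **kwargs)


class TestPlateLayout:
    def test_duplicate_wells_rejected(self):
        cond = ConditionSpec("c")
        with pytest.raises(ValueError, match="duplicate"):
            PlateLayout(wells=(("A1", cond), ("A1", cond)))

    def test_default_cells_per_field_matches_dataset_scale(self):
        """864 fields at the default density hold ~10 000 cells."""
        assert CELLS_PER_FIELD_DEFAULT * 864 == pytest.approx(10000)

    def test_default_geometry(self):
        layout = PlateLayout(wells=(("A1", ConditionSpec("c")),))
        assert layout.fields_per_well == 9
        assert layout.field_shape == (512, 688)


class TestSimulateField:
    def test_zero_rate_no_sites(self, quiet_noise):
        cond = ConditionSpec("c", site_rate_per_cell=0.0)
        layout = PlateLayout(wells=(("A1", cond),), field_shape=(128, 128), cells_per_field=4)
        fi, gt = simulate_field(cond, layout, quiet_noise, seed=0)
        assert len(gt.sites) == 0
        assert fi.channels["vwf"].max() == 0  # background + noise only (both zero)

    def test_determinism(self, default_noise, small_layout):
        cond = small_layout.wells[0][1]
        f1, g1 = simulate_field(cond, small_layout, default_noise, seed=42)
        f2, g2 = simulate_field(cond, small_layout, default_noise, seed=42)
        for chan in f1.channels:
            assert np.array_equal(f1.channels[chan], f2.channels[chan])
        pd.testing.assert_frame_equal(g1.sites, g2.sites)
        pd.testing.assert_frame_equal(g1.nuclei, g2.nuclei)

    def test_halfmax_thresholding_recovers_true_area(self, quiet_noise):
        """With zero noise, pixels above half-max of a rendered site cover
        its true area within 15% (analytic Gaussian half-max oracle)."""
        cond = ConditionSpec("c", site_rate_per_cell=1.0, large_fraction=1.0)
        layout = PlateLayout(
            wells=(("A1", cond),), cells_per_field=1.0, field_shape=(256, 256)
        )
        checked = 0
        for seed in range(120):
            if checked >= 10:
                break
            fi, gt = simulate_field(cond, layout, quiet_noise, seed=seed)
            if len(gt.sites) != 1:
                continue
            img = fi.channels["vwf"].astype(float)
            area_px = (img > img.max() / 2.0).sum()
            true_area_px = gt.sites.loc[0, "area_um2"] / layout.pixel_size_um**2
            # oracle cross-check: half-max ellipse area from the drawn axes
            sa = gt.sites.loc[0, "axis_major_um"] / layout.pixel_size_um / np.sqrt(2 * np.log(2))
            sb = gt.sites.loc[0, "axis_minor_um"] / layout.pixel_size_um / np.sqrt(2 * np.log(2))
            assert gaussian_halfmax_area_px(sa, sb) == pytest.approx(true_area_px, rel=1e-9)
            assert area_px == pytest.approx(true_area_px, rel=0.15)
            checked += 1
        assert checked >= 10

    def test_noiseless_maximum_at_center_pixel(self, quiet_noise):
        """Every rendered site's intensity maximum sits at its ground-truth
        centre pixel."""
        cond = ConditionSpec("c", site_rate_per_cell=2.0)
        layout = PlateLayout(
            wells=(("A1", cond),), cells_per_field=4.0, field_shape=(256, 344)
        )
        fi, gt = simulate_field(cond, layout, quiet_noise, seed=3)
        img = fi.channels["vwf"]
        for _, site in gt.sites.iterrows():
            r, c = int(site["row"]), int(site["col"])
            patch = img[max(r - 6, 0): r + 7, max(c - 6, 0): c + 7]
            assert img[r, c] == patch.max()

    def test_sites_inside_bounds(self, default_noise, small_layout):
        cond = small_layout.wells[0][1]
        _, gt = simulate_field(cond, small_layout, default_noise, seed=8)
        assert (gt.sites["row"] >= 0).all() and (gt.sites["row"] < 256).all()
        assert (gt.sites["col"] >= 0).all() and (gt.sites["col"] < 344).all()

    def test_invalid_geometry(self, default_noise):
        cond = ConditionSpec("c")
        with pytest.raises(ValueError):
            PlateLayout(wells=(("A1", cond),), field_shape=(0, 10))
        with pytest.raises(ValueError):
            PlateLayout(wells=(("A1", cond),), pixel_size_um=0.0)


class TestSimulatePlate:
    def test_field_count_bookkeeping(self, default_noise):
        cond = ConditionSpec("c", site_rate_per_cell=1.0)
        layout = PlateLayout(
            wells=(("A1", cond), ("B1", cond)),
            fields_per_well=9,
            cells_per_field=2.0,
            field_shape=(96, 96),
        )
        fields, gt = simulate_plate(layout, default_noise, seed=1)
        assert len(fields) == 18
        keys = {(f.well, f.field) for f in fields}
        assert len(keys) == 18
        assert set(gt.nuclei["well"]) <= {"A1", "B1"}

    def test_plate_determinism(self, default_noise):
        cond = ConditionSpec("c", site_rate_per_cell=1.5)
        layout = PlateLayout(
            wells=(("A1", cond),), fields_per_well=2, cells_per_field=3.0, field_shape=(96, 96)
        )
        _, g1 = simulate_plate(layout, default_noise, seed=7)
        _, g2 = simulate_plate(layout, default_noise, seed=7)
        pd.testing.assert_frame_equal(g1.sites, g2.sites)

    def test_subseeds_differ_between_fields(self):
        s1 = field_seed(1, "A1", 0).generate_state(2)
        s2 = field_seed(1, "A1", 1).generate_state(2)
        s3 = field_seed(1, "A2", 0).generate_state(2)
        assert not np.array_equal(s1, s2)
        assert not np.array_equal(s1, s3)

    def test_total_sites_poisson_oracle(self, quiet_noise):
        """With rate 5 sites/cell and ~1000 cells the realized total site
        count lies within 4 sd of 5 x (realized cells), conditioning on the
        cell draw (Poisson-sum oracle)."""
        cond = ConditionSpec("c", site_rate_per_cell=5.0)
        layout = PlateLayout(
            wells=(("A1", cond),),
            fields_per_well=9,
            cells_per_field=116.0,
            field_shape=(512, 688),
        )
        _, gt = simulate_plate(layout, quiet_noise, seed=13)
        n_cells = len(gt.nuclei)
        n_sites = len(gt.sites)
        expected = 5.0 * n_cells
        assert abs(n_sites - expected) <= 4 * np.sqrt(expected)

    def test_calibration_ground_truth_fraction(self, quiet_noise):
        """The ground-truth fraction of sites > 2 um^2 matches
        large_fraction within 3 binomial sd over >= 1000 sites."""
        cond = ConditionSpec("c", site_rate_per_cell=5.0, large_fraction=0.4)
        layout = PlateLayout(
            wells=(("A1", cond),), fields_per_well=2, cells_per_field=120.0,
            field_shape=(512, 688),
        )
        _, gt = simulate_plate(layout, quiet_noise, seed=21)
        n = len(gt.sites)
        assert n >= 1000
        frac = (gt.sites["area_um2"] > 2.0).mean()
        assert abs(frac - 0.4) <= 3 * np.sqrt(0.4 * 0.6 / n)

    def test_dose_response_monotone_counts_stable_areas(self, quiet_noise):
        """Raising site_rate_per_cell increases sites per field but leaves
        the area distribution unchanged (two-sample KS below the 5%
        critical value)."""
        counts = {}
        areas = {}
        for rate in (1.0, 3.0, 6.0):
            cond = ConditionSpec("c", site_rate_per_cell=rate)
            layout = PlateLayout(
                wells=(("A1", cond),), fields_per_well=4, cells_per_field=60.0,
                field_shape=(512, 688),
            )
            _, gt = simulate_plate(layout, quiet_noise, seed=31)
            counts[rate] = len(gt.sites) / 4
            areas[rate] = gt.sites["area_um2"].to_numpy()
        assert counts[1.0] < counts[3.0] < counts[6.0]
        n, m = len(areas[1.0]), len(areas[6.0])
        d_crit = 1.358 * np.sqrt((n + m) / (n * m))
        assert ks_2samp(areas[1.0], areas[6.0]).statistic < d_crit


class TestTimecourse:
    def test_linear_counts_double(self, quiet_noise):
        """Linear kinetics: expected cumulative counts at 20 min are twice
        those at 10 min, within Poisson error."""
        cond = ConditionSpec("c", site_rate_per_cell=4.0, kinetics="linear")
        layout = PlateLayout(
            wells=(("A1", cond),), fields_per_well=4, cells_per_field=80.0,
            field_shape=(512, 688),
        )
        tc = simulate_timecourse(cond, [10.0, 20.0], layout, quiet_noise, seed=2, render=False)
        n10 = len(tc[10.0][1].sites)
        n20 = len(tc[20.0][1].sites)
        assert n20 > 0
        assert n10 / n20 == pytest.approx(0.5, abs=4 * np.sqrt(n10) / n20)

    def test_fast_saturating_near_plateau_at_10min(self, quiet_noise):
        """tau = 3 min: 1 - exp(-10/3) = 0.964 of the plateau by 10 min."""
        cond = ConditionSpec("c", site_rate_per_cell=4.0, kinetics="fast_saturating", tau_min=3.0)
        layout = PlateLayout(
            wells=(("A1", cond),), fields_per_well=4, cells_per_field=80.0,
            field_shape=(512, 688),
        )
        tc = simulate_timecourse(cond, [10.0, 20.0], layout, quiet_noise, seed=2, render=False)
        n10 = len(tc[10.0][1].sites)
        n20 = len(tc[20.0][1].sites)
        assert n10 >= 0.90 * n20

    def test_sites_persist(self, quiet_noise):
        """Sites present at an early timepoint are still present later."""
        cond = ConditionSpec("c", site_rate_per_cell=3.0)
        layout = PlateLayout(
            wells=(("A1", cond),), fields_per_well=1, cells_per_field=20.0,
            field_shape=(256, 344),
        )
        tc = simulate_timecourse(cond, [5.0, 15.0], layout, quiet_noise, seed=6, render=False)
        early = tc[5.0][1].sites
        late = tc[15.0][1].sites
        merged = early.merge(late, on=["well", "field", "row", "col", "area_um2"])
        assert len(merged) == len(early)

    def test_rendered_matches_ground_truth_layout(self, quiet_noise):
        cond = ConditionSpec("c", site_rate_per_cell=2.0)
        layout = PlateLayout(
            wells=(("A1", cond),), fields_per_well=1, cells_per_field=5.0,
            field_shape=(128, 172),
        )
        tc = simulate_timecourse(cond, [20.0], layout, quiet_noise, seed=6)
        images, gt = tc[20.0]
        assert len(images) == 1
        img = images[0].channels["vwf"]
        for _, site in gt.sites.iterrows():
            assert img[int(site["row"]), int(site["col"])] > 0

    @pytest.mark.parametrize("tps", [[], [5.0, 5.0], [5.0, 3.0], [-1.0, 5.0], [5.0, 25.0]])
    def test_bad_timepoints(self, tps, quiet_noise, small_layout):
        cond = small_layout.wells[0][1]
        with pytest.raises(ValueError):
            simulate_timecourse(cond, tps, small_layout, quiet_noise, seed=0, render=False)


class TestFusionEvents:
    def test_all_positive_at_probability_one(self):
        ev = simulate_fusion_events(constant_rate(500), ring_prob_constant(1.0), seed=0)
        assert len(ev) > 0
        assert ev["ring_positive"].all()

    def test_constant_probability_binomial(self):
        """10 000 events at p = 0.65 give a positive fraction within 3
        binomial sd of 0.65."""
        ev = simulate_fusion_events(constant_rate(10000), ring_prob_constant(0.65), seed=1)
        n = len(ev)
        frac = ev["ring_positive"].mean()
        assert abs(frac - 0.65) <= 3 * np.sqrt(0.65 * 0.35 / n)

    def test_logistic_low_early_high_late(self):
        """With a logistic recruitment probability the early (0-50 s)
        positive fraction is below the late (100-600 s) fraction."""
        ev = simulate_fusion_events(
            constant_rate(20000), ring_prob_logistic(0.05, 0.8), seed=2
        )
        early = ev.loc[ev["time_s"] < 50, "ring_positive"].mean()
        late = ev.loc[ev["time_s"] >= 100, "ring_positive"].mean()
        assert early < late

    def test_times_on_frame_grid(self):
        ev = simulate_fusion_events(constant_rate(300), ring_prob_constant(0.5), seed=3)
        assert (ev["time_s"] % 5 == 0).all()
        assert ev["time_s"].max() < 600

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            simulate_fusion_events(constant_rate(10), ring_prob_constant(0.5), frame_s=7.0)
        with pytest.raises(ValueError):
            simulate_fusion_events(constant_rate(10), lambda t: 1.2, seed=0)
        with pytest.raises(ValueError):
            ring_prob_logistic(0.8, 0.2)


class TestStrings:
    def test_explicit_lengths_recorded(self):
        rec, polys, masks = simulate_strings(1, [30.0], seed=0)
        assert rec.loc[0, "length_um"] == 30.0
        poly_len = np.sum(np.hypot(*np.diff(polys[0], axis=0).T))
        assert poly_len == pytest.approx(30.0)

    def test_empty(self):
        rec, polys, masks = simulate_strings(0, seed=0)
        assert len(rec) == 0 and polys == [] and masks == []

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            simulate_strings(1, [30.0], pixel_size_um=0.0)
        with pytest.raises(ValueError):
            simulate_strings(2, [30.0, -1.0], seed=0)
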