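import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from rgcdegen import preprocess as pp, synthetic_cohort as sc


class TestTypeLibrary:
    def test_abundances_sum_to_one(self, library):
        assert sum(t.baseline_abundance for t in library) == pytest.approx(1.0, abs=1e-12)

    def test_templates_mutually_distinguishable(self, library):
        C = np.stack([t.chirp_template for t in library])
        R = np.corrcoef(C)
        np.fill_diagonal(R, 0.0)
        assert R.max() < 0.95

    def test_off_templates_respond_at_light_offset(self, library, cohort_stimuli):
        fs = 7.8125
        on = cohort_stimuli.chirp.segments["step_on"]
        off = cohort_stimuli.chirp.segments["step_off"]
        for tpl in library:
            if tpl.super_group != "Off":
                continue
            resp = tpl.chirp_template
            on_peak = resp[int(on[0] * fs):int(on[1] * fs)].max()
            off_peak = resp[int(off[0] * fs):int(off[1] * fs)].max()
            assert off_peak > on_peak

    def test_seed_determinism(self):
        a = sc.make_type_library(seed=3)
        b = sc.make_type_library(seed=3)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.chirp_template, tb.chirp_template)
            assert ta.baseline_abundance == tb.baseline_abundance

    def test_library_covers_selectivity_and_lag_ranges(self, library):
        assert any(t.ds_flag for t in library)
        assert any(t.os_flag for t in library)
        for t in library:
            assert 0.0 < t.temporal_peak_lag_s < 0.3
            assert t.chirp_template.max() == pytest.approx(1.0)


class TestSimulateCell:
    def test_noiseless_cell_perfectly_repeatable(self, library, cohort_stimuli):
        cell = sc.simulate_cell(library[10], cohort_stimuli, noise_scale=0.0, seed=5)
        snips = pp.snippet(
            cell.traces["chirp"], cell.triggers["chirp"],
            int(np.floor(cohort_stimuli.chirp.rep_duration_s * 7.8125)),
        )
        assert pp.quality_index(snips) > 0.999

    def test_ds_cell_preferred_vs_null_amplitude(self, library, cohort_stimuli):
        tpl = next(t for t in library if t.ds_flag)
        pref = tpl.tuning_gain(tpl.preferred_angle_deg)
        null = tpl.tuning_gain(tpl.preferred_angle_deg + 180.0)
        assert pref / (null + 1e-12) > 5

    def test_seed_determinism(self, library, cohort_stimuli):
        a = sc.simulate_cell(library[2], cohort_stimuli, seed=77)
        b = sc.simulate_cell(library[2], cohort_stimuli, seed=77)
        assert np.array_equal(a.traces["chirp"], b.traces["chirp"])
        assert a.soma_size_um2 == b.soma_size_um2

    def test_nonresponsive_cell_has_no_signal(self, library, cohort_stimuli):
        cell = sc.simulate_cell(library[2], cohort_stimuli, seed=3, responsive=False,
                                noise_scale=0.0)
        assert not cell.traces["chirp"].any()


class TestSchedules:
    def test_wildtype_schedule_is_unity(self):
        sched = sc.wildtype_schedule()
        for sg in ("Off", "On-Off", "Fast On", "Slow On", "Uncertain"):
            for age in ("P30", "P45", "P90", "P180"):
                assert sched.multiplier(sg, age) == 1.0

    def test_rd10_multipliers_nonincreasing_with_age(self):
        sched = sc.default_rd10_schedule()
        ages = ("P30", "P45", "P90", "P180")
        for sg in ("Off", "On-Off", "Fast On", "Slow On", "Uncertain"):
            vals = [sched.multiplier(sg, a) for a in ages]
            assert all(x >= y for x, y in zip(vals, vals[1:]))

    def test_rd10_encodes_resilience_order(self):
        sched = sc.default_rd10_schedule()
        order = ["Uncertain", "Fast On", "Slow On", "On-Off", "Off"]
        means = [
            np.mean([np.log2(sched.multiplier(sg, a)) for a in ("P30", "P45", "P90")])
            for sg in order
        ]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_unknown_cohort_raises(self):
        with pytest.raises(ValueError):
            sc.simulate_cohort("wt", "P60", n_fields=1, seed=0)
        with pytest.raises(ValueError):
            sc.simulate_cohort("het", "P30", n_fields=1, seed=0)


class TestSimulateCohort:
    def test_field_sizes_and_ground_truth_responsiveness(self, library, cohort_stimuli):
        cells = sc.simulate_cohort("wt", "P30", n_fields=4, seed=11,
                                   library=library, stimuli=cohort_stimuli)
        by_field = {}
        for c in cells:
            by_field.setdefault(c.field_id, []).append(c)
        assert len(by_field) == 4
        for members in by_field.values():
            assert 100 <= len(members) <= 120
        frac = np.mean([c.ground_truth["responsive"] for c in cells])
        assert frac == pytest.approx(0.60, abs=0.06)

    def test_rd10_p180_nearly_silent(self, library, cohort_stimuli):
        cells = sc.simulate_cohort("rd10", "P180", n_fields=4, seed=12,
                                   library=library, stimuli=cohort_stimuli)
        frac = np.mean([c.ground_truth["responsive"] for c in cells])
        assert frac < 0.02

    def test_type_draws_follow_baseline_abundance(self, library, cohort_stimuli):
        cells = sc.simulate_cohort("wt", "P45", n_fields=10, seed=13,
                                   library=library, stimuli=cohort_stimuli)
        counts = np.zeros(32)
        for c in cells:
            counts[c.ground_truth["group_id"] - 1] += 1
        expected = np.array([t.baseline_abundance for t in library]) * counts.sum()
        _, p = sps.chisquare(counts, expected)
        assert p > 0.01

    def test_degeneration_monotonic_in_measured_ground_truth(self, library, cohort_stimuli):
        fracs = []
        for age in ("P30", "P45", "P90", "P180"):
            cells = sc.simulate_cohort("rd10", age, n_fields=3, seed=14,
                                       library=library, stimuli=cohort_stimuli)
            fracs.append(np.mean([c.ground_truth["responsive"] for c in cells]))
        # allow sampling error of a few percentage points between stages
        assert all(a >= b - 0.04 for a, b in zip(fracs, fracs[1:]))
        assert fracs[0] > fracs[-1]


class TestPlantedAbundanceRecovery:
    def test_halved_off_responsiveness_measured_through_pipeline(self, library):
        """Halving Off responsiveness (others untouched) shifts the measured
        Off relative abundance to log2(0.5) plus the renormalisation offset
        -log2(1 - 0.5 * f_Off) ~ +0.2, i.e. about -0.8."""
        from rgcdegen import pipeline
        base = sc.wildtype_schedule()
        resp = dict(base.responsiveness)
        for age in ("P30", "P45", "P90", "P180"):
            resp[("Off", age)] = 0.5
        sched = sc.DegenerationSchedule(
            resp, base.rf_size_scale, base.kinetics_scale, base.noise_scale
        )
        res = pipeline.run_cohort_analysis(
            seed=9, ages=("P30",), n_fields=6, schedule_rd10=sched, n_perm=100
        )
        table = res.abundance_by_age["P30"]
        from rgcdegen.classify import supergroup
        vals = [
            row["relative_abundance"]
            for g, row in table.iterrows()
            if supergroup(g) == "Off" and np.isfinite(row["relative_abundance"])
        ]
        assert np.mean(vals) == pytest.approx(-1.0, abs=0.3)


class TestRFGroundTruthRecovery:
    def test_rf_size_recovered_within_tolerance(self, library, noise_stimuli):
        from rgcdegen import receptive_fields as rf
        basis = rf.SplineBasis.make()
        tpl = dataclasses.replace(
            library[16], rf_sigma_um=(25.0, 25.0), temporal_peak_lag_s=0.12, rf_polarity=1
        )
        cell = sc.simulate_cell(tpl, noise_stimuli, noise_scale=1.0, seed=21, amplitude=1.0)
        det = pp.detrend(cell.traces["noise"])
        model = rf.estimate_rf(det, noise_stimuli.noise_fine,
                               trigger_s=cell.triggers["noise"][0], basis=basis)
        assert model.passes_quality
        _, d_true = rf.rf_size(25.0, 25.0)
        assert abs(model.rf_diameter_um - d_true) / d_true < 0.2
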