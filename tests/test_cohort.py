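import dataclasses

import numpy as np
import pandas as pd
import pytest

from ieegnet.cohort import (
    CohortPatient,
    CohortResult,
    coverage_scan,
    cross_validated_auc,
    from_synthetic,
    group_auc,
    load_cohort,
    multi_segment_analysis,
    patient_pipeline,
    run_cohort,
    segment_length_analysis,
    subsample_contacts,
)
from ieegnet.io import ContactTable, Recording
from ieegnet.simulate import SynthConfig, make_cohort, make_patient
from ieegnet.spatial import BaselineFit


def result_table(rows):
    df = pd.DataFrame(
        rows, columns=["patient_id", "ilae_class", "n_removed", "n_spared", "drs"]
    )
    df["drs_unnormalized"] = df["drs"]
    return df


class TestRunCohort:
    def test_good_patients_have_low_drs(self, tiny_cohort):
        res = run_cohort(from_synthetic(tiny_cohort))
        good = res.table[res.table.ilae_class == 1].drs
        poor = res.table[res.table.ilae_class != 1].drs
        assert good.mean() < 0.5 < poor.mean()

    def test_patient_without_removed_contacts_excluded(self, tiny_cohort):
        patients = from_synthetic(tiny_cohort)
        broken = patients[0]
        tab = broken.contacts
        patients[0] = CohortPatient(
            broken.patient_id,
            broken.recording,
            ContactTable(tab.contact_ids, tab.coords, np.zeros(len(tab), bool), tab.artifact),
            broken.ilae_class,
        )
        res = run_cohort(patients)
        assert (broken.patient_id, "no removed contacts") in res.exclusions
        assert broken.patient_id not in set(res.table.patient_id)

    def test_deterministic_given_inputs(self, tiny_cohort):
        a = run_cohort(from_synthetic(tiny_cohort))
        b = run_cohort(from_synthetic(tiny_cohort))
        assert a.table.to_csv() == b.table.to_csv()

    def test_precomputed_baseline_reused(self, tiny_cohort):
        fit = BaselineFit(0.0, 1.0, 10.0, 10, 0.0, (5.0, 100.0))
        res = run_cohort(from_synthetic(tiny_cohort), baseline=fit)
        assert res.baseline == fit

    def test_leave_one_out_baseline_variant_runs(self, tiny_cohort):
        res = run_cohort(from_synthetic(tiny_cohort), baseline_exclude_self=True)
        assert len(res.table) == 6


class TestPatientPipeline:
    def test_good_patient_drs_below_half(self, tiny_cohort):
        cohort = from_synthetic(tiny_cohort)
        fit = run_cohort(cohort).baseline
        res = patient_pipeline(cohort[0], fit)
        assert res.drs < 0.5
        assert res.n_removed >= 1 and res.n_spared >= 1

    def test_null_effect_carries_no_outcome_information(self, tiny_cfg):
        # with no planted epileptogenic effect, D_RS cannot distinguish the
        # outcome groups: their means agree and the group AUC sits near 0.5.
        # (Each patient's D_RS carries a small common offset from the
        # contiguity of the resection cluster; it cancels between groups.)
        null_cfg = dataclasses.replace(tiny_cfg, epi_effect=0.0)
        patients, _ = make_cohort(12, 12, null_cfg, seed=303, duration_s=12.0)
        res = run_cohort(from_synthetic(patients))
        good = res.table[res.table.ilae_class == 1].drs.to_numpy()
        poor = res.table[res.table.ilae_class != 1].drs.to_numpy()
        se = np.sqrt(good.var(ddof=1) / good.size + poor.var(ddof=1) / poor.size)
        assert abs(good.mean() - poor.mean()) < 3 * se + 0.02
        v, i = res.drs_values(True)
        assert 0.2 < group_auc(v, i).auc < 0.8


class TestGroupAuc:
    def test_separated_groups(self):
        g = group_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 3, 3])
        assert g.auc == 1.0 and g.n_good == 2 and g.n_poor == 2

    def test_identical_distributions(self):
        g = group_auc([0.4, 0.6, 0.4, 0.6], [1, 1, 2, 2])
        assert g.auc == 0.5

    def test_matches_pair_counting_oracle(self):
        vals = [0.2, 0.5, 0.7, 0.4, 0.9]
        ilae = [1, 1, 1, 2, 3]
        poor = [v for v, c in zip(vals, ilae) if c >= 2]
        good = [v for v, c in zip(vals, ilae) if c == 1]
        brute = np.mean([1.0 if p > g else 0.5 if p == g else 0.0 for p in poor for g in good])
        assert group_auc(vals, ilae).auc == pytest.approx(brute)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            group_auc([0.1, 0.2], [1, 1])


class TestCoverageScan:
    def test_retention_semantics(self):
        table = result_table(
            [("a", 1, 5, 30, 0.2), ("b", 2, 25, 25, 0.8), ("c", 1, 40, 10, 0.4)]
        )
        scan = coverage_scan(table, 1, 40)
        at20 = scan[scan.n_x == 20].iloc[0]
        assert at20.n_patients_retained == 1
        assert not at20.defined  # single patient: no two-group AUC
        at1 = scan[scan.n_x == 1].iloc[0]
        assert at1.n_patients_retained == 3 and at1.defined

    def test_retention_non_increasing(self, rng):
        rows = [
            (f"p{i}", int(rng.integers(1, 4)), int(rng.integers(1, 41)), int(rng.integers(1, 41)), float(rng.uniform()))
            for i in range(30)
        ]
        scan = coverage_scan(result_table(rows), 1, 40)
        assert np.all(np.diff(scan.n_patients_retained) <= 0)

    def test_undefined_rows_still_written(self):
        table = result_table([("a", 1, 2, 2, 0.2), ("b", 3, 2, 2, 0.9)])
        scan = coverage_scan(table, 1, 10)
        assert len(scan) == 10
        assert scan[scan.n_x > 2].defined.sum() == 0


class TestSubsampleContacts:
    def test_budgets_respected(self, tiny_cohort, rng):
        p = from_synthetic(tiny_cohort)[0]
        sub = subsample_contacts(p, 3, 4, rng)
        assert sub.contacts.n_removed == 3 and sub.contacts.n_spared == 4
        assert sub.recording.channel_ids == sub.contacts.contact_ids

    def test_overdraw_rejected(self, tiny_cohort, rng):
        p = from_synthetic(tiny_cohort)[0]
        with pytest.raises(ValueError):
            subsample_contacts(p, 1000, 1, rng)


class TestSegmentLengthAnalysis:
    def test_segment_bookkeeping(self, tiny_cohort):
        df = segment_length_analysis(
            from_synthetic(tiny_cohort), lengths=(4.0, 6.0), max_segments_per_length=20
        )
        # 30 s recordings: 7 four-second and 5 six-second segments
        assert sorted(df[df.length_s == 4.0].segment_index) == list(range(7))
        assert sorted(df[df.length_s == 6.0].segment_index) == list(range(5))

    def test_max_segments_cap(self, tiny_cohort):
        df = segment_length_analysis(
            from_synthetic(tiny_cohort), lengths=(4.0,), max_segments_per_length=2
        )
        assert len(df) == 2

    def test_too_long_segment_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            segment_length_analysis(from_synthetic(tiny_cohort), lengths=(60.0,))


class TestMultiSegment:
    def test_identical_segments_similarity_one(self, tiny_cohort):
        cohort = from_synthetic(tiny_cohort)
        _, aucs, c = multi_segment_analysis([cohort, cohort])
        assert c == pytest.approx(1.0, abs=1e-12)
        assert len(aucs) == 2

    def test_independent_white_noise_similarity_near_zero(self):
        rng = np.random.default_rng(0)
        n = 100

        def white_cohort():
            out = []
            for k, ilae in ((0, 1), (1, 1), (2, 3), (3, 3)):
                data = rng.standard_normal((n, 256 * 12))
                ids = [f"E{i:03d}" for i in range(n)]
                coords = np.column_stack([np.arange(n) * 5.0, np.zeros(n), np.zeros(n)])
                removed = np.zeros(n, bool)
                removed[: n // 3] = True
                tab = ContactTable(ids, coords, removed, np.zeros(n, bool))
                out.append(
                    CohortPatient(f"P{k}", Recording(f"P{k}", ids, 256.0, data), tab, ilae)
                )
            return out

        _, _, c = multi_segment_analysis([white_cohort(), white_cohort()])
        assert abs(c) < 0.1

    def test_needs_two_segments(self, tiny_cohort):
        with pytest.raises(ValueError):
            multi_segment_analysis([from_synthetic(tiny_cohort)])


class TestCrossValidatedAuc:
    def test_perfect_separation(self):
        assert cross_validated_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 3, 3]) == 1.0

    def test_matches_plain_auc_on_separated_toy(self):
        vals = [0.1, 0.2, 0.8, 0.9]
        ilae = [1, 1, 3, 3]
        assert cross_validated_auc(vals, ilae) == group_auc(vals, ilae).auc

    def test_permutation_null_centers_on_half(self, rng):
        vals = rng.uniform(size=16)
        aucs = []
        for _ in range(100):
            ilae = np.where(rng.permutation(16) < 8, 1, 3)
            aucs.append(cross_validated_auc(vals, ilae))
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se + 0.02

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            cross_validated_auc([0.1, 0.9], [1, 3])


class TestDiskRoundTrip:
    def test_manifest_cohort_matches_in_memory(self, tmp_path, tiny_cfg):
        patients, manifest = make_cohort(2, 1, tiny_cfg, seed=21, out_dir=tmp_path, duration_s=4.0)
        loaded = load_cohort(tmp_path / "manifest.json")
        assert [p.patient_id for p in loaded] == [p.recording.patient_id for p in patients]
        res_mem = run_cohort(from_synthetic(patients))
        res_disk = run_cohort(loaded)
        # EDF quantization perturbs signals by <1e-4 relative; D_RS is rank
        # based and the cohort is tiny, so values agree closely
        np.testing.assert_allclose(
            res_disk.table.drs.to_numpy(), res_mem.table.drs.to_numpy(), atol=0.1
        )
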