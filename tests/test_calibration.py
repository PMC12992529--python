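"""Likelihood-ratio estimation, ACMG/AMP evidence mapping, cohort reports."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrdevidence import calibration as cal
from hrdevidence.calibration import (
    EvidenceConfig,
    LRResult,
    TwoGroupCategoryCounts,
    category_counts,
    compute_lr,
    lr_to_evidence,
    sensitivity_reanalysis,
    vus_evidence_report,
)
from hrdevidence.curation import BRCA1_POS, BRCA2_POS


def counts(x_case, n_case, x_ctrl, n_ctrl, category="HRD"):
    return TwoGroupCategoryCounts(category, x_case, n_case, x_ctrl, n_ctrl)


class TestComputeLR:
    # the published reference-table rows, frozen at their printed precision
    @pytest.mark.parametrize(
        "c,lr,lo,hi",
        [
            ((27, 27, 35, 232), 6.63, 4.88, 9.00),
            ((0, 27, 197, 232), 0.02, 0.00, 0.33),
            ((27, 27, 17, 232), 13.65, 8.64, 21.57),
            ((0, 27, 15, 232), 0.27, 0.02, 4.37),
            ((19, 21, 35, 232), 6.00, 4.29, 8.39),
            ((2, 21, 197, 232), 0.11, 0.03, 0.42),
            ((2, 21, 17, 232), 1.30, 0.32, 5.25),
            ((17, 21, 15, 232), 12.52, 7.36, 21.31),
            ((5, 10, 5, 10), 1.00, None, None),
        ],
    )
    def test_reference_values_at_2dp(self, c, lr, lo, hi):
        res = compute_lr(counts(*c))
        assert round(res.lr, 2) == lr
        if lo is not None:
            assert round(res.ci_low, 2) == lo
            assert round(res.ci_high, 2) == hi

    def test_correction_active_exactly_on_zero_cells(self):
        assert compute_lr(counts(0, 10, 5, 20)).correction_c == 0.5
        assert compute_lr(counts(3, 10, 0, 20)).correction_c == 0.5
        res = compute_lr(counts(3, 10, 5, 20))
        assert res.correction_c == 0.0
        assert res.lr == pytest.approx((3 / 10) / (5 / 20))

    def test_point_estimate_inside_its_interval(self):
        for c in [(1, 5, 4, 9), (0, 8, 3, 11), (7, 7, 1, 30)]:
            res = compute_lr(counts(*c))
            assert res.ci_low <= res.lr <= res.ci_high

    def test_empty_group_rejected(self):
        with pytest.raises(cal.CalibrationError):
            counts(0, 0, 5, 10)

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(1, 30), st.integers(1, 30), st.integers(1, 300), st.integers(1, 300))
    def test_swapping_groups_inverts_the_lr(self, x1, extra1, x2, extra2):
        n1, n2 = x1 + extra1, x2 + extra2
        fwd = compute_lr(counts(x1, n1, x2, n2))
        rev = compute_lr(counts(x2, n2, x1, n1))
        assert fwd.lr == pytest.approx(1.0 / rev.lr)
        assert fwd.ci_low == pytest.approx(1.0 / rev.ci_high)

    def test_katz_interval_close_to_parametric_bootstrap(self):
        # small-count check: 10,000-replicate parametric bootstrap of the
        # two proportions; Katz endpoints within 0.25 on the log scale
        rng = np.random.default_rng(11)
        x_case, n_case, x_ctrl, n_ctrl = 5, 30, 10, 100
        res = compute_lr(counts(x_case, n_case, x_ctrl, n_ctrl))
        bc = rng.binomial(n_case, x_case / n_case, 10_000)
        bk = rng.binomial(n_ctrl, x_ctrl / n_ctrl, 10_000)
        reps = ((bc + 0.5) / (n_case + 1)) / ((bk + 0.5) / (n_ctrl + 1))
        lo, hi = np.quantile(reps, [0.025, 0.975])
        assert abs(math.log(res.ci_low) - math.log(lo)) < 0.25
        assert abs(math.log(res.ci_high) - math.log(hi)) < 0.25


class TestEvidenceMapping:
    def _res(self, lr, lo=None, hi=None):
        lo = lr / 2 if lo is None else lo
        hi = lr * 2 if hi is None else hi
        return LRResult(lr, lo, hi, 0.0, 1.96, 0.5, 0.5)

    @pytest.mark.parametrize(
        "lr,lo,hi,label,points",
        [
            (6.63, 4.88, 9.00, "Pathogenic Moderate", 2),
            (0.02, 0.001, 0.33, "Benign Strong", -4),
            (0.27, 0.02, 4.37, "Not significant", 0),  # CI spans 1
            (1.30, 0.32, 5.25, "Indeterminate", 0),  # point estimate in the gap
            (1.00, 0.9, 1.1, "Indeterminate", 0),
            (400.0, 300.0, 500.0, "Pathogenic Very Strong", 8),
            (0.002, 0.001, 0.01, "Benign Very Strong", -8),
            (3.0, 2.0, 4.0, "Pathogenic Supporting", 1),
            (0.3, 0.2, 0.45, "Benign Supporting", -1),
        ],
    )
    def test_tiering_and_gating(self, lr, lo, hi, label, points):
        ev = lr_to_evidence(self._res(lr, lo, hi))
        assert (ev.strength_label, ev.points) == (label, points)

    def test_boundary_inclusive_on_the_extreme_side(self):
        lr = 350 ** 0.25
        ev = lr_to_evidence(self._res(lr, lr * 0.8, lr * 1.2))
        assert (ev.strength_label, ev.points) == ("Pathogenic Moderate", 2)

    def test_gate_can_be_disabled(self):
        ev = lr_to_evidence(self._res(6.0, 0.9, 40.0), EvidenceConfig(ci_gate=False))
        assert ev.points == 2

    def test_nonpositive_lr_rejected(self):
        with pytest.raises(cal.CalibrationError):
            lr_to_evidence(self._res(0.0, 0.0, 1.0))

    @settings(max_examples=300, derandomize=True)
    @given(st.floats(1e-4, 1e4), st.floats(1.01, 3.0))
    def test_reciprocity_of_labels_and_points(self, lr, spread):
        fwd = lr_to_evidence(self._res(lr, lr / spread, lr * spread))
        rev = lr_to_evidence(self._res(1 / lr, 1 / (lr * spread), 1 / (lr / spread)))
        assert fwd.points == -rev.points
        if fwd.strength_label.startswith("Pathogenic"):
            assert rev.strength_label == fwd.strength_label.replace("Pathogenic", "Benign")


class TestCategoryCounts:
    def test_dichotomous_counts_from_fixture(self, groups, calls):
        c = category_counts(groups, calls, BRCA1_POS, "HRD")
        assert (c.x_case, c.n_case, c.x_ctrl, c.n_ctrl) == (27, 27, 35, 232)

    def test_subtype_counts_keep_undetermined_in_denominator(self, groups, calls):
        c = category_counts(groups, calls, BRCA2_POS, "HRD_BRCA2_subtype")
        assert (c.x_case, c.n_case, c.x_ctrl, c.n_ctrl) == (17, 21, 15, 232)
        b1 = category_counts(groups, calls, BRCA2_POS, "HRD_BRCA1_subtype")
        hrd = category_counts(groups, calls, BRCA2_POS, "HRD")
        # BRCA1 + BRCA2 subtype + undetermined = all HRD (3 undetermined controls)
        assert b1.x_ctrl + c.x_ctrl == hrd.x_ctrl - 3

    def test_dichotomous_conservation(self, groups, calls):
        for group in (BRCA1_POS, BRCA2_POS):
            hrp = category_counts(groups, calls, group, "HRP")
            hrd = category_counts(groups, calls, group, "HRD")
            assert hrp.x_case + hrd.x_case == hrp.n_case
            assert hrp.x_ctrl + hrd.x_ctrl == hrp.n_ctrl


class TestCoverage:
    def test_katz_ci_covers_known_ratio(self):
        # simulated two-group tables with a known true proportion ratio
        rng = np.random.default_rng(5)
        p_case, p_ctrl = 0.6, 0.2
        truth = p_case / p_ctrl
        n = 1000
        covered = 0
        for _ in range(n):
            x1 = rng.binomial(40, p_case)
            x2 = rng.binomial(120, p_ctrl)
            res = compute_lr(counts(int(x1), 40, int(x2), 120))
            covered += res.ci_low <= truth <= res.ci_high
        assert covered / n >= 0.90


class TestCohortReports:
    def test_all_hrp_tool_degenerates_gracefully(self, groups, cohort):
        from hrdevidence.hrcalls import call_cohort, ThresholdConfig

        all_hrp = call_cohort(cohort.scores, "CHORD", ThresholdConfig(chord_cut=1.0))
        table = cal.build_calibration_table(groups, all_hrp, stratified=False)
        hrd_rows = table[table["category"] == "HRD"]
        assert (hrd_rows["correction"] == 0.5).all()
        assert (hrd_rows["points"] == 0).all()

    def test_sensitivity_augments_case_groups(self, cohort, calls):
        out = sensitivity_reanalysis(cohort.variants, cohort.samples, calls)
        sens = out["sensitivity"]
        assert sens.loc[(sens.gene == "BRCA1") & (sens.category == "HRD"), "n_case"].iloc[0] == 29
        assert sens.loc[(sens.gene == "BRCA2") & (sens.category == "HRD"), "n_case"].iloc[0] == 24
        # evidence categories survive the reanalysis
        assert not out["delta"]["points_changed"].any()

    def test_sensitivity_noop_without_excluded_patients(self, cohort, calls, groups):
        keep = groups.loc[groups["group"] != "excluded", "patient_id"]
        samples = cohort.samples[cohort.samples["patient_id"].isin(keep)]
        variants = cohort.variants[cohort.variants["patient_id"].isin(keep)]
        out = sensitivity_reanalysis(variants, samples, calls)
        pd.testing.assert_frame_equal(out["baseline"], out["sensitivity"])

    def test_vus_report_rows(self, groups, cohort, calls, calibration_table):
        report = vus_evidence_report(groups, cohort.variants, calls, calibration_table)
        assert len(report) == 8
        b1_hrd = report[(report.gene == "BRCA1") & (report.status == "HRD")]
        assert len(b1_hrd) == 5
        assert (b1_hrd["subtype_concordant"]).all()
        assert (b1_hrd["points"] == 2).all()  # matches the BRCA1 subtype row
        hrp = report[report.status == "HRP"]
        assert len(hrp) == 2
        assert (hrp["points"] == -4).all()  # benign-direction evidence

    def test_vus_discordant_subtype_contributes_nothing(self, groups, cohort, calls, calibration_table):
        # rewire the single BRCA2 VUS carrier's tumour to a BRCA1-type profile
        vus_b2 = cohort.variants[
            (cohort.variants.gene == "BRCA2") & (cohort.variants.clinvar_class == "VUS")
        ]["patient_id"].iloc[0]
        flipped = calls.copy()
        sel = (flipped.patient_id == vus_b2) & (flipped.tool == "CHORD")
        flipped.loc[sel, "subtype"] = "BRCA1_type"
        report = vus_evidence_report(groups, cohort.variants, flipped, calibration_table)
        row = report[report.patient_id == vus_b2].iloc[0]
        assert row.subtype_concordant == False  # noqa: E712
        assert row.points == 0
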