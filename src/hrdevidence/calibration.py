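"""Likelihood-ratio calibration of tumour HR status as ACMG/AMP evidence.

For a germline case group (BRCA1-positive or BRCA2-positive patients) and
the BRCA1/2-negative control group, the likelihood ratio towards
pathogenicity associated with an HR category (HRP, HRD, or a CHORD HRD
gene subtype) is the ratio of the category's proportion in cases to its
proportion in controls:

    LR = p_case / p_ctrl,   p = (x + c) / (n + 2c)

with a Haldane continuity correction c = 0.5 applied to all cells whenever
either category count is zero.  The 95% confidence interval is the Katz
log-scale Wald interval

    exp( ln LR  +/-  z * sqrt((1-p_case)/((n_case+2c) p_case)
                            + (1-p_ctrl)/((n_ctrl+2c) p_ctrl)) ).

LRs are converted to ACMG/AMP evidence strengths under the Bayesian
points framework: with odds-of-pathogenicity 350 for Very Strong, the
tier boundaries are 350^(1/8) (Supporting, +/-1), 350^(1/4) (Moderate,
+/-2), 350^(1/2) (Strong, +/-4) and 350 (Very Strong, +/-8), mirrored
with reciprocals on the benign side.  An LR whose 95% CI includes 1
contributes no evidence: it is labelled "Not significant" when the point
estimate would otherwise reach a tier, and "Indeterminate" when the point
estimate itself falls between the innermost boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import pandas as pd

from . import curation, hrcalls
from .curation import BRCA1_POS, BRCA2_POS, NEGATIVE
from .hrcalls import BRCA1_TYPE, BRCA2_TYPE, HRD, HRP, UNDETERMINED

# categories a calibration row can describe
CAT_HRP = "HRP"
CAT_HRD = "HRD"
CAT_HRD_BRCA1 = "HRD_BRCA1_subtype"
CAT_HRD_BRCA2 = "HRD_BRCA2_subtype"
CATEGORIES = (CAT_HRP, CAT_HRD, CAT_HRD_BRCA1, CAT_HRD_BRCA2)


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class TwoGroupCategoryCounts:
    category: str
    x_case: int
    n_case: int
    x_ctrl: int
    n_ctrl: int

    def __post_init__(self) -> None:
        for x, n, side in ((self.x_case, self.n_case, "case"), (self.x_ctrl, self.n_ctrl, "control")):
            if n <= 0:
                raise CalibrationError(f"{side} group is empty")
            if not 0 <= x <= n:
                raise CalibrationError(f"{side} count {x} outside [0, {n}]")


@dataclass(frozen=True)
class LRResult:
    lr: float
    ci_low: float
    ci_high: float
    correction_c: float
    z: float
    p_case: float
    p_ctrl: float


@dataclass(frozen=True)
class EvidenceConfig:
    """Bayesian points framework parameters."""

    odds_very_strong: float = 350.0
    exponents: tuple[float, ...] = (1.0, 0.5, 0.25, 0.125)  # VS, St, Mo, Su
    points: tuple[int, ...] = (8, 4, 2, 1)
    labels: tuple[str, ...] = ("Very Strong", "Strong", "Moderate", "Supporting")
    ci_gate: bool = True

    def __post_init__(self) -> None:
        if self.odds_very_strong <= 1:
            raise CalibrationError("odds_very_strong must exceed 1")

    @property
    def thresholds(self) -> tuple[float, ...]:
        return tuple(self.odds_very_strong**e for e in self.exponents)


@dataclass(frozen=True)
class EvidenceAssignment:
    strength_label: str
    points: int


def category_counts(
    groups: pd.DataFrame,
    calls: pd.DataFrame,
    case_group: str,
    category: str,
    tool: str = hrcalls.CHORD,
) -> TwoGroupCategoryCounts:
    """Tabulate one HR category for a case group against the negative group.

    Excluded and BRCA1/2-VUS patients never enter; in subtype categories
    the undetermined-subtype HRD patients stay in the denominators but in
    no subtype numerator.
    """
    if category not in CATEGORIES:
        raise CalibrationError(f"unknown category {category!r}")
    if case_group not in (BRCA1_POS, BRCA2_POS):
        raise CalibrationError(f"case group must be a BRCA-positive group, got {case_group!r}")
    tool_calls = calls[calls["tool"] == tool]
    merged = groups.merge(tool_calls, on="patient_id", how="inner")

    def tab(group: str) -> tuple[int, int]:
        sub = merged[merged["group"] == group]
        n = len(sub)
        if category == CAT_HRP:
            x = int((sub["status"] == HRP).sum())
        elif category == CAT_HRD:
            x = int((sub["status"] == HRD).sum())
        else:
            subtype = BRCA1_TYPE if category == CAT_HRD_BRCA1 else BRCA2_TYPE
            x = int(((sub["status"] == HRD) & (sub["subtype"] == subtype)).sum())
        return x, n

    x_case, n_case = tab(case_group)
    x_ctrl, n_ctrl = tab(NEGATIVE)
    if n_case == 0:
        raise CalibrationError(f"no called patients in case group {case_group!r}")
    if n_ctrl == 0:
        raise CalibrationError("no called patients in the negative control group")
    return TwoGroupCategoryCounts(category, x_case, n_case, x_ctrl, n_ctrl)


def compute_lr(counts: TwoGroupCategoryCounts, z: float = 1.96) -> LRResult:
    """Point estimate and Katz log-scale Wald CI for the proportion ratio."""
    c = 0.5 if (counts.x_case == 0 or counts.x_ctrl == 0) else 0.0
    n_case = counts.n_case + 2 * c
    n_ctrl = counts.n_ctrl + 2 * c
    p_case = (counts.x_case + c) / n_case
    p_ctrl = (counts.x_ctrl + c) / n_ctrl
    lr = p_case / p_ctrl
    se = math.sqrt((1 - p_case) / (n_case * p_case) + (1 - p_ctrl) / (n_ctrl * p_ctrl))
    return LRResult(
        lr=lr,
        ci_low=lr * math.exp(-z * se),
        ci_high=lr * math.exp(z * se),
        correction_c=c,
        z=z,
        p_case=p_case,
        p_ctrl=p_ctrl,
    )


def _tier(lr: float, config: EvidenceConfig) -> tuple[str, int]:
    """Raw tier from the point estimate alone: (label, signed points)."""
    for t, pts, lab in zip(config.thresholds, config.points, config.labels):
        if lr >= t:
            return f"Pathogenic {lab}", pts
        if lr <= 1.0 / t:
            return f"Benign {lab}", -pts
    return "Indeterminate", 0


def lr_to_evidence(result: LRResult, config: EvidenceConfig | None = None) -> EvidenceAssignment:
    """Map an LR (with CI) to an ACMG/AMP strength label and signed points."""
    cfg = config or EvidenceConfig()
    if result.lr <= 0:
        raise CalibrationError("likelihood ratio must be positive")
    label, pts = _tier(result.lr, cfg)
    if cfg.ci_gate and result.ci_low <= 1.0 <= result.ci_high and pts != 0:
        return EvidenceAssignment("Not significant", 0)
    return EvidenceAssignment(label, pts)


def _row(gene, section, counts, z, ev_cfg, flags=()):
    res = compute_lr(counts, z)
    ev = lr_to_evidence(res, ev_cfg)
    return {
        "gene": gene,
        "section": section,
        "category": counts.category,
        "x_ctrl": counts.x_ctrl,
        "n_ctrl": counts.n_ctrl,
        "p_ctrl": round(counts.x_ctrl / counts.n_ctrl, 2),  # raw, uncorrected
        "x_case": counts.x_case,
        "n_case": counts.n_case,
        "p_case": round(counts.x_case / counts.n_case, 2),
        "lr": round(res.lr, 2),
        "ci_low": round(res.ci_low, 2),
        "ci_high": round(res.ci_high, 2),
        "correction": res.correction_c,
        "strength": ev.strength_label,
        "points": ev.points,
        "flags": ";".join(flags),
    }


def build_calibration_table(
    groups: pd.DataFrame,
    calls: pd.DataFrame,
    tool: str = hrcalls.CHORD,
    stratified: bool = True,
    z: float = 1.96,
    evidence_config: EvidenceConfig | None = None,
) -> pd.DataFrame:
    """The full calibration report: dichotomous rows per gene, plus, for
    CHORD, the subtype-stratified rows.  Display values rounded to 2 dp;
    the underlying computation is full precision."""
    ev_cfg = evidence_config or EvidenceConfig()
    rows = []
    for gene, case_group in (("BRCA1", BRCA1_POS), ("BRCA2", BRCA2_POS)):
        for cat in (CAT_HRP, CAT_HRD):
            counts = category_counts(groups, calls, case_group, cat, tool)
            rows.append(_row(gene, "dichotomous", counts, z, ev_cfg))
        if stratified and tool == hrcalls.CHORD:
            counts = category_counts(groups, calls, case_group, CAT_HRP, tool)
            rows.append(_row(gene, "stratified", counts, z, ev_cfg))
            for cat in (CAT_HRD_BRCA1, CAT_HRD_BRCA2):
                counts = category_counts(groups, calls, case_group, cat, tool)
                rows.append(_row(gene, "stratified", counts, z, ev_cfg))
    return pd.DataFrame(rows)


def sensitivity_reanalysis(
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    calls: pd.DataFrame,
    tool: str = hrcalls.CHORD,
    stratified: bool = True,
    include_excluded_in_control: bool = False,
    thresholds: curation.CurationThresholds | None = None,
    z: float = 1.96,
    evidence_config: EvidenceConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Re-run the calibration with the Excluded rules bypassed.

    Category-A carriers inside the Excluded group rejoin their positive
    case group; remaining Excluded patients stay out of the analysis
    unless include_excluded_in_control is set, in which case they join the
    negative controls.  Returns the baseline table, the sensitivity table
    and a per-row delta of the LR and points.
    """
    base_groups, _ = curation.partition_cohort(variants, samples, thresholds)
    sens_groups, _ = curation.partition_cohort(variants, samples, thresholds, sensitivity=True)
    if include_excluded_in_control:
        sens_groups = sens_groups.copy()
        sens_groups.loc[sens_groups["group"] == curation.EXCLUDED, "group"] = NEGATIVE
    kw = dict(tool=tool, stratified=stratified, z=z, evidence_config=evidence_config)
    baseline = build_calibration_table(base_groups, calls, **kw)
    reanalysis = build_calibration_table(sens_groups, calls, **kw)
    delta = baseline[["gene", "section", "category", "lr", "points"]].merge(
        reanalysis[["gene", "section", "category", "lr", "points"]],
        on=["gene", "section", "category"],
        suffixes=("_base", "_sens"),
    )
    delta["lr_change"] = delta["lr_sens"] - delta["lr_base"]
    delta["points_changed"] = delta["points_sens"] != delta["points_base"]
    return {"baseline": baseline, "sensitivity": reanalysis, "delta": delta}


def vus_evidence_report(
    groups: pd.DataFrame,
    variants: pd.DataFrame,
    calls: pd.DataFrame,
    calibration_table: pd.DataFrame,
    tool: str = hrcalls.CHORD,
    thresholds: curation.CurationThresholds | None = None,
) -> pd.DataFrame:
    """Per-variant evidence report for BRCA1/2 VUS carriers.

    Each category-C variant receives the evidence its carrier's tumour HR
    profile would contribute under the cohort calibration: the stratified
    subtype row when the CHORD subtype matches the VUS gene, the
    dichotomous HRD row for an undetermined subtype, the HRP row for a
    proficient tumour — and zero evidence when the subtype names the
    *other* gene (an HRD profile of the opposite subtype says nothing
    about this variant's pathogenicity).
    """
    curated = curation.curate_variants(variants, thresholds)
    vus_patients = set(groups.loc[groups["group"] == curation.BRCA12_VUS, "patient_id"])
    c_rows = curated[(curated["category"] == "C") & curated["patient_id"].isin(vus_patients)]
    tool_calls = calls[calls["tool"] == tool].set_index("patient_id")
    cal = calibration_table.set_index(["gene", "section", "category"])

    def lookup(gene, section, category):
        try:
            r = cal.loc[(gene, section, category)]
        except KeyError:
            return None
        return r

    out = []
    for _, v in c_rows.iterrows():
        pid, gene = str(v["patient_id"]), str(v["gene"])
        if pid not in tool_calls.index:
            continue
        call = tool_calls.loc[pid]
        status, subtype = call["status"], call["subtype"]
        own_cat = CAT_HRD_BRCA1 if gene == "BRCA1" else CAT_HRD_BRCA2
        concordant = None
        if status == HRP:
            src = lookup(gene, "stratified", CAT_HRP) if tool == hrcalls.CHORD else None
            if src is None:
                src = lookup(gene, "dichotomous", CAT_HRP)
            label, pts = src["strength"], int(src["points"])
        elif subtype == UNDETERMINED or tool != hrcalls.CHORD:
            src = lookup(gene, "dichotomous", CAT_HRD)
            label, pts = src["strength"], int(src["points"])
            concordant = subtype != UNDETERMINED
        else:
            expected = BRCA1_TYPE if gene == "BRCA1" else BRCA2_TYPE
            concordant = subtype == expected
            if concordant:
                src = lookup(gene, "stratified", own_cat)
                label, pts = src["strength"], int(src["points"])
            else:
                label, pts = "Discordant subtype", 0
        out.append(
            {
                "patient_id": pid,
                "gene": gene,
                "variant_id": v["variant_id"],
                "status": status,
                "subtype": subtype,
                "subtype_concordant": concordant,
                "strength": label,
                "points": pts,
            }
        )
    return pd.DataFrame(
        out,
        columns=[
            "patient_id",
            "gene",
            "variant_id",
            "status",
            "subtype",
            "subtype_concordant",
            "strength",
            "points",
        ],
    )
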