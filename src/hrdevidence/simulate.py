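"""Synthetic cohorts and copy-number profiles for end-to-end testing.

Two generation modes:

* **fixture** — a deterministic 350-patient cohort whose germline-group
  partition (27 BRCA1-positive, 21 BRCA2-positive, 232 negative, 62
  excluded, 8 BRCA1/2-VUS carriers) and group x HR-status cross-tabulation
  exactly match the published study cohort, so the downstream calibration
  reproduces the reference table cell for cell.  No sampling is involved;
  the same tables are emitted for any seed.
* **stochastic** — per-patient sampling of HR status, CHORD subtype,
  scores and pathology markers conditional on the germline group, with
  the fixture's empirical frequencies as defaults.

Scores are threshold-consistent draws (uniform strictly above or below
each tool's decision cutoff) rather than imitations of real score
distributions: the calibration consumes only the dichotomised calls.

``simulate_segments`` builds allele-specific copy-number profiles whose
scar events are placed so that HRD-labelled genomes exceed the HRDsum
cutoff of 42 in expectation and HRP-labelled genomes stay far below it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .curation import BRCA1_POS, BRCA2_POS, BRCA12_VUS, EXCLUDED, GROUPS, NEGATIVE
from .genome import MB, GenomeAnnotation
from .hrcalls import BRCA1_TYPE, BRCA2_TYPE, HRD, HRP, NOT_APPLICABLE, UNDETERMINED


class ConfigError(ValueError):
    pass


DEFAULT_GROUP_SIZES: dict[str, int] = {
    BRCA1_POS: 27,
    BRCA2_POS: 21,
    NEGATIVE: 232,
    EXCLUDED: 62,
    BRCA12_VUS: 8,
}

# P(HRD | germline group): fixture cross-tabulation frequencies
DEFAULT_HR_GIVEN_GROUP: dict[str, float] = {
    BRCA1_POS: 1.0,
    BRCA2_POS: 19 / 21,
    NEGATIVE: 35 / 232,
    EXCLUDED: 13 / 62,
    BRCA12_VUS: 6 / 8,
}

# (BRCA1-type, BRCA2-type, undetermined) given HRD
DEFAULT_SUBTYPE_GIVEN_GROUP_HRD: dict[str, tuple[float, float, float]] = {
    BRCA1_POS: (1.0, 0.0, 0.0),
    BRCA2_POS: (2 / 19, 17 / 19, 0.0),
    NEGATIVE: (17 / 35, 15 / 35, 3 / 35),
    EXCLUDED: (0.5, 0.5, 0.0),
    BRCA12_VUS: (5 / 6, 1 / 6, 0.0),
}

# marker frequencies (grade3, ER-, PR-, HER2-); ER- and grade-3 follow the
# published per-group proportions, PR-/HER2- are plausible defaults
DEFAULT_PATHOLOGY_GIVEN_GROUP: dict[str, dict[str, float]] = {
    BRCA1_POS: {"grade3": 19 / 27, "er_neg": 24 / 27, "pr_neg": 20 / 27, "her2_neg": 24 / 27},
    BRCA2_POS: {"grade3": 12 / 21, "er_neg": 2 / 21, "pr_neg": 6 / 21, "her2_neg": 17 / 21},
    NEGATIVE: {"grade3": 66 / 232, "er_neg": 73 / 232, "pr_neg": 80 / 232, "her2_neg": 180 / 232},
    EXCLUDED: {"grade3": 0.35, "er_neg": 0.35, "pr_neg": 0.35, "her2_neg": 0.80},
    BRCA12_VUS: {"grade3": 0.50, "er_neg": 0.50, "pr_neg": 0.50, "her2_neg": 0.80},
}

MEAN_PURITY = 0.58

# deterministic fixture score constants (one value per side of each cutoff)
_FIX = {
    "chord_hrd": 0.96,
    "chord_hrp": 0.04,
    "b_main": 0.88,
    "b_other": 0.05,
    "b_und": 0.43,
    "b_hrp": 0.01,
    "hrdetect_hrd": 0.95,
    "hrdetect_hrp": 0.10,
    "hrdsum_hrd": 62,
    "hrdsum_hrp": 18,
}


@dataclass(frozen=True)
class CohortConfig:
    """Generation parameters; defaults reproduce the fixture conditions."""

    mode: str = "fixture"
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    hr_given_group: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HR_GIVEN_GROUP))
    subtype_given_group_hrd: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_GIVEN_GROUP_HRD)
    )
    pathology_given_group: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_PATHOLOGY_GIVEN_GROUP.items()}
    )
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("fixture", "stochastic"):
            raise ConfigError(f"mode must be fixture or stochastic, got {self.mode!r}")
        if sum(self.group_sizes.values()) <= 0:
            raise ConfigError("total cohort size must be positive")
        for g, n in self.group_sizes.items():
            if n < 0:
                raise ConfigError(f"negative group size for {g!r}")
        for g, p in self.hr_given_group.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"P(HRD | {g}) = {p} outside [0, 1]")
        for g, probs in self.subtype_given_group_hrd.items():
            if any(p < 0 or p > 1 for p in probs):
                raise ConfigError(f"subtype probability outside [0, 1] for group {g!r}")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(f"subtype probabilities for {g!r} must sum to 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigError("missing_rate must lie in [0, 1]")


@dataclass
class SimulatedCohort:
    """Container for the emitted tables.

    ``truth`` records the per-patient generating state (group, HR status,
    subtype) so tests can check recovery without re-deriving it.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    scores: pd.DataFrame
    truth: pd.DataFrame


def _scores_for(hr: str, subtype: str) -> dict[str, float]:
    if hr == HRP:
        return {
            "chord_prob": _FIX["chord_hrp"],
            "chord_brca1_prob": _FIX["b_hrp"],
            "chord_brca2_prob": _FIX["b_hrp"],
            "hrdetect_prob": _FIX["hrdetect_hrp"],
            "hrdsum_score": _FIX["hrdsum_hrp"],
        }
    if subtype == BRCA1_TYPE:
        b1, b2 = _FIX["b_main"], _FIX["b_other"]
    elif subtype == BRCA2_TYPE:
        b1, b2 = _FIX["b_other"], _FIX["b_main"]
    else:
        b1 = b2 = _FIX["b_und"]
    return {
        "chord_prob": _FIX["chord_hrd"],
        "chord_brca1_prob": b1,
        "chord_brca2_prob": b2,
        "hrdetect_prob": _FIX["hrdetect_hrd"],
        "hrdsum_score": _FIX["hrdsum_hrd"],
    }


def _pathology_counts(n: int, freqs: dict[str, float]) -> dict[str, int]:
    """Exact marker counts for fixture mode (round half away from harm:
    plain rounding of n * frequency, clipped to [0, n])."""
    return {k: int(min(n, max(0, round(n * f)))) for k, f in freqs.items()}


def _fixture_patients() -> list[dict]:
    """The deterministic 350-patient roster with HR truth and variants."""
    patients: list[dict] = []

    def add(group, hr, subtype, variants):
        patients.append(
            {"group": group, "hr": hr, "subtype": subtype, "variants": variants}
        )

    def var(gene, clinvar=None, vtype="SNV", faf=None, suspicious=False, bayesdel=None, idx=0):
        return {
            "gene": gene,
            "variant_id": f"{gene}:c.{101 + 17 * idx}{'del' if vtype == 'indel' else 'A>T'}",
            "variant_type": vtype,
            "clinvar_class": clinvar,
            "gnomad_faf": faf,
            "bayesdel": bayesdel,
            "spliceai_max": None,
            "cadd": None,
            "suspicious_vus": suspicious,
            "class3": None,
        }

    # BRCA1 positive: 27, all HRD BRCA1-type; three carried as SV rows
    for i in range(27):
        vtype = "SV" if i < 3 else ("indel" if i % 3 == 0 else "SNV")
        add(BRCA1_POS, HRD, BRCA1_TYPE, [var("BRCA1", "P" if i % 2 else "LP", vtype, idx=i)])
    # BRCA2 positive: 21 (2 HRP, 2 HRD BRCA1-type, 17 HRD BRCA2-type)
    for i in range(21):
        if i < 2:
            hr, st = HRP, NOT_APPLICABLE
        elif i < 4:
            hr, st = HRD, BRCA1_TYPE
        else:
            hr, st = HRD, BRCA2_TYPE
        vtype = "SV" if i < 3 else "SNV"
        add(BRCA2_POS, hr, st, [var("BRCA2", "P" if i % 2 else "LP", vtype, idx=i)])
    # negative: 232 (197 HRP; 17 B1-type, 15 B2-type, 3 undetermined HRD)
    for i in range(232):
        if i < 197:
            hr, st = HRP, NOT_APPLICABLE
        elif i < 214:
            hr, st = HRD, BRCA1_TYPE
        elif i < 229:
            hr, st = HRD, BRCA2_TYPE
        else:
            hr, st = HRD, UNDETERMINED
        if i < 40:  # benign BRCA variant (category E)
            vs = [var("BRCA1" if i % 2 else "BRCA2", "B", idx=i)]
        elif i < 80:  # common non-BRCA variant collapsed to B/LB by FAF (category F)
            vs = [var("CHEK2", None, faf=0.002, idx=i)]
        else:
            vs = []
        add(NEGATIVE, hr, st, vs)
    # excluded: 62 = 36 with P/LP (category B) in other genes + 26 VUS-only (D)
    for i in range(62):
        if i < 2:  # BRCA1 P/LP co-occurring with PALB2 P/LP
            vs = [var("BRCA1", "P", idx=100 + i), var("PALB2", "LP", "SV" if i == 0 else "SNV", idx=i)]
            hr, st = HRD, BRCA1_TYPE
        elif i < 5:  # BRCA2 P/LP co-occurring with ATM P/LP
            vs = [var("BRCA2", "P", idx=100 + i), var("ATM", "P", idx=i)]
            hr, st = HRD, BRCA2_TYPE
        elif i < 9:  # suspicious VUS in other genes, conservatively category B
            gene = ("PALB2", "RAD51C", "BRIP1", "RAD51D")[i - 5]
            vs = [var(gene, "VUS", suspicious=True, idx=i)]
            hr, st = (HRD, BRCA1_TYPE) if i % 2 else (HRD, BRCA2_TYPE)
        elif i < 36:  # plain P/LP in other genes; 4 more HRD for 13 total
            gene = ("ATM", "CHEK2", "PALB2", "TP53", "PTEN", "BARD1")[i % 6]
            vtype = "SV" if i == 9 else "SNV"  # one RAD51C-style SV carrier
            gene = "RAD51C" if i == 9 else gene
            vs = [var(gene, "P" if i % 2 else "LP", vtype, idx=i)]
            hr, st = ((HRD, BRCA1_TYPE) if i % 2 else (HRD, BRCA2_TYPE)) if i < 13 else (HRP, NOT_APPLICABLE)
        else:  # only VUS in other genes
            gene = ("ATM", "CHEK2", "BRIP1", "BARD1")[i % 4]
            vs = [var(gene, "VUS", idx=i)]
            hr, st = HRP, NOT_APPLICABLE
        add(EXCLUDED, hr, st, vs)
    # BRCA1/2 VUS: 7 BRCA1 (5 HRD BRCA1-type, 2 HRP) + 1 BRCA2 (HRD BRCA2-type)
    for i in range(8):
        gene = "BRCA2" if i == 7 else "BRCA1"
        if i < 5:
            hr, st = HRD, BRCA1_TYPE
        elif i < 7:
            hr, st = HRP, NOT_APPLICABLE
        else:
            hr, st = HRD, BRCA2_TYPE
        # one VUS classified via the score fallback rather than ClinVar
        v = var(gene, None, bayesdel=0.21, idx=200 + i) if i == 4 else var(gene, "VUS", idx=200 + i)
        add(BRCA12_VUS, hr, st, [v])
    return patients


def _assemble(patients, config: CohortConfig, rng: np.random.Generator | None) -> SimulatedCohort:
    """Shared table assembly for both modes.

    rng=None means fixture mode: pathology markers are assigned as exact
    deterministic counts, purity is the cohort mean, nothing is missing.
    """
    sample_rows, variant_rows, score_rows, truth_rows = [], [], [], []
    # index patients within group for deterministic pathology assignment
    group_seen: dict[str, int] = {g: 0 for g in GROUPS}
    group_total: dict[str, int] = {}
    for p in patients:
        group_total[p["group"]] = group_total.get(p["group"], 0) + 1
    path_counts = {
        g: _pathology_counts(n, config.pathology_given_group.get(g, DEFAULT_PATHOLOGY_GIVEN_GROUP[g]))
        for g, n in group_total.items()
    }
    for idx, p in enumerate(patients):
        pid = f"S{idx + 1:04d}"
        g = p["group"]
        j = group_seen[g]
        group_seen[g] += 1
        freqs = config.pathology_given_group.get(g, DEFAULT_PATHOLOGY_GIVEN_GROUP[g])
        if rng is None:
            cnt = path_counts[g]
            grade = 3 if j < cnt["grade3"] else (2 if j % 2 else 1)
            er = "neg" if j < cnt["er_neg"] else "pos"
            pr = "neg" if j < cnt["pr_neg"] else "pos"
            her2 = "neg" if j < cnt["her2_neg"] else "pos"
            purity = MEAN_PURITY
        else:
            grade = 3 if rng.random() < freqs["grade3"] else int(rng.integers(1, 3))
            er = "neg" if rng.random() < freqs["er_neg"] else "pos"
            pr = "neg" if rng.random() < freqs["pr_neg"] else "pos"
            her2 = "neg" if rng.random() < freqs["her2_neg"] else "pos"
            purity = float(np.clip(rng.normal(MEAN_PURITY, 0.12), 0.1, 1.0))
            if config.missing_rate:
                grade = "missing" if rng.random() < config.missing_rate else grade
                er = "missing" if rng.random() < config.missing_rate else er
                pr = "missing" if rng.random() < config.missing_rate else pr
                her2 = "missing" if rng.random() < config.missing_rate else her2
        sample_rows.append(
            {
                "patient_id": pid,
                "cohort": "synthetic",
                "sex": "F",
                "purity": round(purity, 3),
                "grade": grade,
                "ER": er,
                "PR": pr,
                "HER2": her2,
            }
        )
        for v in p["variants"]:
            variant_rows.append({"patient_id": pid, **v})
        if rng is None:
            sc = _scores_for(p["hr"], p["subtype"])
        else:
            sc = _draw_scores(p["hr"], p["subtype"], rng)
        score_rows.append({"patient_id": pid, **sc})
        truth_rows.append(
            {"patient_id": pid, "group": g, "hr_status": p["hr"], "subtype": p["subtype"]}
        )
    from .curation import VARIANT_COLUMNS

    variants = pd.DataFrame(variant_rows, columns=["patient_id"] + VARIANT_COLUMNS[1:])
    return SimulatedCohort(
        samples=pd.DataFrame(sample_rows),
        variants=variants,
        scores=pd.DataFrame(score_rows),
        truth=pd.DataFrame(truth_rows),
    )


def _draw_scores(hr: str, subtype: str, rng: np.random.Generator) -> dict[str, float]:
    """Threshold-consistent random scores for one patient."""
    if hr == HRP:
        chord = rng.uniform(0.0, 0.45)
        b1 = b2 = 0.2 * chord
        return {
            "chord_prob": round(chord, 4),
            "chord_brca1_prob": round(b1, 4),
            "chord_brca2_prob": round(b2, 4),
            "hrdetect_prob": round(rng.uniform(0.0, 0.65), 4),
            "hrdsum_score": int(rng.integers(0, 40)),
        }
    if subtype == UNDETERMINED:
        chord = rng.uniform(0.55, 1.0)
        b1 = b2 = 0.43 * chord
    else:
        chord = rng.uniform(0.6, 1.0)
        main, other = 0.9 * chord, 0.05 * chord
        b1, b2 = (main, other) if subtype == BRCA1_TYPE else (other, main)
    return {
        "chord_prob": round(chord, 4),
        "chord_brca1_prob": round(b1, 4),
        "chord_brca2_prob": round(b2, 4),
        "hrdetect_prob": round(rng.uniform(0.75, 1.0), 4),
        "hrdsum_score": int(rng.integers(43, 90)),
    }


def _stochastic_patients(config: CohortConfig, rng: np.random.Generator) -> list[dict]:
    fixture = _fixture_patients()
    # reuse the fixture's variant constructions as per-group templates
    templates: dict[str, list[list[dict]]] = {g: [] for g in GROUPS}
    for p in fixture:
        templates[p["group"]].append(p["variants"])
    patients = []
    for g in GROUPS:
        n = config.group_sizes.get(g, 0)
        p_hrd = config.hr_given_group.get(g, DEFAULT_HR_GIVEN_GROUP[g])
        sub_p = config.subtype_given_group_hrd.get(g, DEFAULT_SUBTYPE_GIVEN_GROUP_HRD[g])
        for i in range(n):
            hr = HRD if rng.random() < p_hrd else HRP
            if hr == HRD:
                k = rng.choice(3, p=np.asarray(sub_p) / sum(sub_p))
                subtype = (BRCA1_TYPE, BRCA2_TYPE, UNDETERMINED)[int(k)]
            else:
                subtype = NOT_APPLICABLE
            variants = templates[g][i % len(templates[g])] if templates[g] else []
            patients.append({"group": g, "hr": hr, "subtype": subtype, "variants": variants})
    return patients


def simulate_cohort(config: CohortConfig | None = None) -> SimulatedCohort:
    """Generate sample sheet, variant table, HR score table and truth table."""
    cfg = config or CohortConfig()
    if cfg.mode == "fixture":
        return _assemble(_fixture_patients(), cfg, rng=None)
    rng = np.random.default_rng(cfg.seed)
    return _assemble(_stochastic_patients(cfg, rng), cfg, rng=rng)


def fixture_cohort() -> SimulatedCohort:
    """The deterministic reference cohort (shorthand for fixture mode)."""
    return simulate_cohort(CohortConfig(mode="fixture"))


# ---------------------------------------------------------------------------
# allele-specific copy-number profile simulation


@dataclass(frozen=True)
class SegmentSimConfig:
    """Per-chromosome event rates for the copy-number profile generator.

    An HRD chromosome receives a long interstitial q-arm LOH block (1 LOH
    + 2 LSTs) with probability hrd_loh_rate and a p-telomeric imbalance
    (1 NtAI + 1 LST) with probability hrd_tai_rate; with 22 chromosomes
    the expected HRDsum is ~86, comfortably above the cutoff of 42.  HRP
    chromosomes receive only sub-threshold events (short LOH or short
    telomeric AI) at hrp_event_rate, which score zero.
    """

    hrd_loh_rate: float = 0.9
    hrd_tai_rate: float = 0.6
    hrp_event_rate: float = 0.1


def simulate_segments(
    hr_status: str,
    genome: GenomeAnnotation,
    seed: int,
    config: SegmentSimConfig | None = None,
) -> pd.DataFrame:
    """One whole-genome ASCN tiling consistent with the requested HR label."""
    if hr_status not in (HRD, HRP):
        raise ConfigError(f"hr_status must be HRD or HRP, got {hr_status!r}")
    cfg = config or SegmentSimConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in genome.names():
        info = genome[chrom]
        segs: list[tuple[int, int, int, int]] = []
        pos = 0
        if hr_status == HRD:
            # telomeric allelic imbalance on the p arm
            if rng.random() < cfg.hrd_tai_rate and info.cen_start - 1 * MB > 12 * MB:
                tai_end = int(rng.integers(12 * MB, info.cen_start - 1 * MB))
                segs.append((0, tai_end, 2, 1))
                pos = tai_end
            # long interstitial LOH on the q arm, 10 Mb flanks each side
            q_len = info.length - info.cen_end
            max_len = min(28 * MB, q_len - 21 * MB)
            if rng.random() < cfg.hrd_loh_rate and max_len >= 16 * MB:
                loh_len = int(rng.integers(16 * MB, max_len + 1))
                loh_start = int(
                    rng.integers(info.cen_end + 10 * MB, info.length - loh_len - 10 * MB + 1)
                )
                segs.append((pos, loh_start, 1, 1))
                segs.append((loh_start, loh_start + loh_len, 1, 0))
                segs.append((loh_start + loh_len, info.length, 1, 1))
            else:
                segs.append((pos, info.length, 1, 1))
        else:
            if cfg.hrp_event_rate > 0 and rng.random() < cfg.hrp_event_rate:
                if rng.random() < 0.5:  # short interstitial LOH, below every cutoff
                    s = info.cen_end + 5 * MB
                    segs = [(0, s, 1, 1), (s, s + 5 * MB, 1, 0), (s + 5 * MB, info.length, 1, 1)]
                else:  # short telomeric imbalance, below the NtAI length cutoff
                    segs = [(0, 6 * MB, 2, 1), (6 * MB, info.length, 1, 1)]
            else:
                segs = [(0, info.length, 1, 1)]
        for start, end, major, minor in segs:
            rows.append({"chrom": chrom, "start": start, "end": end, "major": major, "minor": minor})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "major", "minor"])


def simulate_cohort_segments(
    truth: pd.DataFrame, genome: GenomeAnnotation, seed: int, config: SegmentSimConfig | None = None
) -> pd.DataFrame:
    """Per-patient segment tables keyed by patient_id, seeded per patient."""
    frames = []
    for i, row in enumerate(truth.itertuples(index=False)):
        hr = row.hr_status
        segs = simulate_segments(hr, genome, seed=(seed + i) % (2**31), config=config)
        segs.insert(0, "patient_id", row.patient_id)
        frames.append(segs)
    return pd.concat(frames, ignore_index=True)
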