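"""Germline variant curation: three-class collapse, categories A-F, groups.

The analysis panel covers eleven breast-cancer predisposition genes.  Each
germline variant is collapsed into one of three classes — pathogenic/likely
pathogenic (P/LP), variant of uncertain significance (VUS) or benign/likely
benign (B/LB) — then bucketed into a category crossing class with gene set:

    A: P/LP in BRCA1/2        B: P/LP in another panel gene
                                 (suspicious VUS conservatively included)
    C: VUS in BRCA1/2         D: VUS in another panel gene
    E: B/LB in BRCA1/2        F: B/LB in another panel gene

Patients are then partitioned into five mutually exclusive groups: BRCA1
positive, BRCA2 positive, BRCA1/2 negative, Excluded (P/LP or only VUS in
the non-BRCA genes, to avoid confounding) and BRCA1/2 VUS carriers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
import logging

import pandas as pd

log = logging.getLogger(__name__)

BRCA_GENES = ("BRCA1", "BRCA2")
OTHER_GENES = (
    "ATM",
    "BARD1",
    "BRIP1",
    "CHEK2",
    "PALB2",
    "PTEN",
    "RAD51C",
    "RAD51D",
    "TP53",
)
PANEL_GENES = BRCA_GENES + OTHER_GENES

# collapsed classes
PLP, VUS, BLB = "P/LP", "VUS", "B/LB"

# patient groups
BRCA1_POS = "BRCA1_positive"
BRCA2_POS = "BRCA2_positive"
NEGATIVE = "negative"
EXCLUDED = "excluded"
BRCA12_VUS = "BRCA12_VUS"
GROUPS = (BRCA1_POS, BRCA2_POS, NEGATIVE, EXCLUDED, BRCA12_VUS)

_CLINVAR_TO_CLASS = {
    "P": PLP,
    "LP": PLP,
    "P/LP": PLP,
    "B": BLB,
    "LB": BLB,
    "B/LB": BLB,
    "VUS": VUS,
    "conflicting": VUS,
}

VARIANT_COLUMNS = [
    "patient_id",
    "gene",
    "variant_id",
    "variant_type",
    "clinvar_class",
    "gnomad_faf",
    "bayesdel",
    "spliceai_max",
    "cadd",
    "suspicious_vus",
    "class3",
]


class CurationError(ValueError):
    pass


@dataclass(frozen=True)
class CurationThresholds:
    """Cutoffs controlling the class collapse.

    faf_max: gnomAD filtering allele frequency at or above which a variant
        is treated as too common to be a high-penetrance pathogenic allele
        and collapsed to B/LB.
    bayesdel_suspicious / spliceai_suspicious: optional score cutoffs used
        to *derive* the suspicious-VUS flag when it is not supplied; no
        defaults are asserted.
    """

    faf_max: float = 1e-4
    bayesdel_suspicious: float | None = None
    spliceai_suspicious: float | None = None


def _present(value) -> bool:
    return value is not None and not pd.isna(value)


def collapse_classification(variant, thresholds: CurationThresholds | None = None) -> str:
    """Collapse one variant's annotations into P/LP, VUS or B/LB.

    Precedence: a precomputed class3 overrides everything; a gnomAD FAF at
    or above faf_max forces B/LB; otherwise ClinVar P/LP and B/LB are taken
    as-is; anything else with at least one usable annotation is a VUS.
    Bioinformatic scores (BayesDel, SpliceAI, CADD) never set the class —
    they only feed the suspicious-VUS flag.
    """
    th = thresholds or CurationThresholds()
    class3 = variant.get("class3") if hasattr(variant, "get") else getattr(variant, "class3", None)

    def g(name):
        return variant.get(name) if hasattr(variant, "get") else getattr(variant, name, None)

    if _present(class3) and str(class3) in (PLP, VUS, BLB):
        return str(class3)
    faf = g("gnomad_faf")
    if _present(faf):
        faf = float(faf)
        if not 0.0 <= faf <= 1.0:
            raise CurationError(f"gnomad_faf {faf} outside [0, 1]")
        if faf >= th.faf_max:
            return BLB
    clinvar = g("clinvar_class")
    if _present(clinvar) and str(clinvar) not in ("absent", ""):
        mapped = _CLINVAR_TO_CLASS.get(str(clinvar))
        if mapped is None:
            raise CurationError(f"unrecognised ClinVar class {clinvar!r}")
        return mapped
    usable = _present(faf) or any(_present(g(k)) for k in ("bayesdel", "spliceai_max"))
    if not usable:
        vid = g("variant_id")
        raise CurationError(
            f"variant {vid!r}: no usable annotation (ClinVar absent, no FAF, "
            "no interpretable score)"
        )
    return VUS


def derive_suspicious(variant, thresholds: CurationThresholds) -> bool:
    """Optional suspicious-VUS derivation from score cutoffs (off by default)."""

    def g(name):
        return variant.get(name) if hasattr(variant, "get") else getattr(variant, name, None)

    flag = g("suspicious_vus")
    if _present(flag):
        return bool(flag)
    hits = []
    if thresholds.bayesdel_suspicious is not None and _present(g("bayesdel")):
        hits.append(float(g("bayesdel")) >= thresholds.bayesdel_suspicious)
    if thresholds.spliceai_suspicious is not None and _present(g("spliceai_max")):
        hits.append(float(g("spliceai_max")) >= thresholds.spliceai_suspicious)
    return any(hits)


def assign_category(gene: str, class3: str, suspicious_vus: bool = False) -> str:
    """Map (gene, class, suspicious flag) to category A-F."""
    if gene not in PANEL_GENES:
        raise CurationError(f"gene {gene!r} outside the {len(PANEL_GENES)}-gene panel")
    in_brca = gene in BRCA_GENES
    if class3 == PLP:
        return "A" if in_brca else "B"
    if class3 == VUS:
        if in_brca:
            return "C"
        # a suspicious VUS in a non-BRCA gene is conservatively treated as P/LP-like
        return "B" if suspicious_vus else "D"
    if class3 == BLB:
        return "E" if in_brca else "F"
    raise CurationError(f"unknown collapsed class {class3!r}")


def assign_group(categories, sensitivity: bool = False) -> str:
    """Assign one patient's group from their (category, gene) multiset.

    Normal precedence: any B -> Excluded; only-D (no A, no C) -> Excluded;
    any A in BRCA1 -> BRCA1 positive (wins over BRCA2 when both, logged);
    any A in BRCA2 -> BRCA2 positive; any C -> BRCA1/2 VUS; else negative.

    With sensitivity=True the Excluded rules are bypassed for category-A
    carriers, who become positive irrespective of co-occurring non-BRCA
    variants; everyone else is grouped by the normal rules.
    """
    cats = [(c, g) for c, g in categories]
    has = Counter(c for c, _ in cats)
    a_genes = {g for c, g in cats if c == "A"}

    if sensitivity and a_genes:
        if "BRCA1" in a_genes and "BRCA2" in a_genes:
            log.warning("patient carries P/LP in both BRCA1 and BRCA2; BRCA1 group wins")
        return BRCA1_POS if "BRCA1" in a_genes else BRCA2_POS

    if has["B"]:
        return EXCLUDED
    if has["D"] and not has["A"] and not has["C"]:
        return EXCLUDED
    if "BRCA1" in a_genes:
        if "BRCA2" in a_genes:
            log.warning("patient carries P/LP in both BRCA1 and BRCA2; BRCA1 group wins")
        return BRCA1_POS
    if "BRCA2" in a_genes:
        return BRCA2_POS
    if has["C"]:
        return BRCA12_VUS
    return NEGATIVE


def curate_variants(
    variants: pd.DataFrame, thresholds: CurationThresholds | None = None
) -> pd.DataFrame:
    """Add class3 / suspicious_vus / category columns to a variant table."""
    th = thresholds or CurationThresholds()
    df = variants.copy()
    class3, suspicious, category = [], [], []
    for _, row in df.iterrows():
        c3 = collapse_classification(row, th)
        susp = derive_suspicious(row, th)
        class3.append(c3)
        suspicious.append(susp)
        category.append(assign_category(str(row["gene"]), c3, susp))
    df["class3"] = class3
    df["suspicious_vus"] = suspicious
    df["category"] = category
    return df


def partition_cohort(
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    thresholds: CurationThresholds | None = None,
    sensitivity: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assign every sample-sheet patient to exactly one germline group.

    Returns (group table with columns patient_id/group, per-group counts).
    Patients with no variant rows are negative; a variant row whose
    patient_id is missing from the sample sheet is a referential error.
    """
    sample_ids = list(samples["patient_id"].astype(str))
    if len(set(sample_ids)) != len(sample_ids):
        raise CurationError("duplicate patient_id in sample sheet")
    known = set(sample_ids)
    if len(variants):
        orphans = set(variants["patient_id"].astype(str)) - known
        if orphans:
            raise CurationError(
                f"variant rows reference unknown patients: {sorted(orphans)[:5]}"
            )
        curated = curate_variants(variants, thresholds)
        per_patient = {
            str(pid): list(zip(chunk["category"], chunk["gene"]))
            for pid, chunk in curated.groupby(curated["patient_id"].astype(str))
        }
    else:
        per_patient = {}
    groups = [
        assign_group(per_patient.get(pid, []), sensitivity=sensitivity) for pid in sample_ids
    ]
    table = pd.DataFrame({"patient_id": sample_ids, "group": groups})
    counts = table["group"].value_counts().reindex(GROUPS, fill_value=0)
    counts.name = "n"
    return table, counts
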