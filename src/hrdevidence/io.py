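"""Tab-delimited readers/writers for the exchange tables, plus a minimal
VCF ingestion path for germline variants.

All tables are plain TSV with a header row.  Segment coordinates are
0-based half-open by default; files written 1-based inclusive can be
declared as such and are converted on read.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .curation import VARIANT_COLUMNS
from .genome import GenomeAnnotation
from .scars import SEGMENT_COLUMNS


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise ValueError(f"{path}: sample sheet requires a patient_id column")
    return df


def read_variants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "variant_id": str})
    missing = {"patient_id", "gene"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: variant table missing columns {sorted(missing)}")
    for col in VARIANT_COLUMNS:
        if col not in df.columns:
            df[col] = None
    if "suspicious_vus" in df.columns:
        df["suspicious_vus"] = df["suspicious_vus"].fillna(False).astype(bool)
    return df[VARIANT_COLUMNS]


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise ValueError(f"{path}: score table requires a patient_id column")
    return df


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"patient_id": str})


def read_groups(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"patient_id": str})


def read_segments(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: segment table missing columns {sorted(missing)}")
    if one_based:
        df = df.copy()
        df["start"] = df["start"].astype(int) - 1  # 1-based inclusive -> 0-based half-open
    return df


def read_genome(path: str | Path) -> GenomeAnnotation:
    return GenomeAnnotation.from_frame(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def read_variants_vcf(path: str | Path) -> pd.DataFrame:
    """Minimal VCF ingestion: CHROM/POS/REF/ALT plus INFO keys GENE, CLASS3,
    FAF and the sample name as patient_id (one sample per file, or the
    PATIENT INFO key).  Requires cyvcf2."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF ingestion requires the cyvcf2 package") from exc
    rows = []
    vcf = VCF(str(path))
    default_patient = vcf.samples[0] if vcf.samples else None
    for rec in vcf:
        gene = rec.INFO.get("GENE")
        if gene is None:
            continue
        patient = rec.INFO.get("PATIENT", default_patient)
        if patient is None:
            raise ValueError(f"{path}: no sample column and no PATIENT INFO key")
        alt = rec.ALT[0] if rec.ALT else "."
        rows.append(
            {
                "patient_id": str(patient),
                "gene": str(gene),
                "variant_id": f"{rec.CHROM}:{rec.POS}{rec.REF}>{alt}",
                "variant_type": "indel" if len(rec.REF) != len(alt) else "SNV",
                "clinvar_class": rec.INFO.get("CLINVAR"),
                "gnomad_faf": rec.INFO.get("FAF"),
                "bayesdel": rec.INFO.get("BAYESDEL"),
                "spliceai_max": rec.INFO.get("SPLICEAI"),
                "cadd": rec.INFO.get("CADD"),
                "suspicious_vus": bool(rec.INFO.get("SUSPICIOUS", False)),
                "class3": rec.INFO.get("CLASS3"),
            }
        )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)
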