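"""Genomic scar scores from allele-specific copy number.

The HRD summary score ("HRDsum") used as a clinical biomarker of homologous
recombination deficiency is the sum of three counts derived from a tumour's
allele-specific copy-number (ASCN) profile:

* **HRD-LOH** — interstitial loss-of-heterozygosity segments at least 15 Mb
  long that do not span a whole chromosome;
* **LST** (large-scale state transitions) — copy-number breakpoints between
  two long (>= 10 Mb) segments after smoothing away fragments shorter than
  3 Mb, not counting breakpoints at the centromere;
* **NtAI** (telomeric allelic imbalance) — allelic-imbalance runs
  (major != minor) that reach a chromosome end, do not cross the centromere,
  do not span the whole chromosome, and are at least 11 Mb long.

A tumour with HRDsum >= 42 is called HR-deficient (HRD), the FDA-recognised
cutoff; otherwise HR-proficient (HRP).  All lengths and the cutoff are
configurable.  Coordinates are 0-based half-open throughout; allelic
imbalance is taken as major != minor without ploidy normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome import GenomeAnnotation

SEGMENT_COLUMNS = ["chrom", "start", "end", "major", "minor"]


class SegmentError(ValueError):
    """Raised for malformed or inconsistent segment input."""


@dataclass(frozen=True)
class ScarConfig:
    """Tunable lengths (bp) and decision cutoff for the three counters."""

    loh_min_len: int = 15_000_000
    lst_smooth_len: int = 3_000_000
    lst_min_flank: int = 10_000_000
    ntai_min_len: int = 11_000_000
    hrdsum_cut: int = 42


@dataclass(frozen=True)
class ScarResult:
    loh: int
    lst: int
    ntai: int
    hrdsum: int
    status: str  # "HRD" or "HRP"


def _validate_chrom(chrom: str, segs: list[tuple[int, int, int, int]], genome: GenomeAnnotation) -> None:
    if chrom not in genome:
        raise SegmentError(f"chromosome {chrom!r} absent from genome annotation")
    length = genome[chrom].length
    prev_end = None
    for start, end, major, minor in segs:
        if start >= end:
            raise SegmentError(f"{chrom}:{start}-{end}: empty or inverted segment")
        if start < 0 or end > length:
            raise SegmentError(
                f"{chrom}:{start}-{end} extends beyond chromosome length {length}"
            )
        if major < 0 or minor < 0:
            raise SegmentError(f"{chrom}:{start}-{end}: negative copy count")
        if major < minor:
            raise SegmentError(
                f"{chrom}:{start}-{end}: major ({major}) < minor ({minor})"
            )
        if prev_end is not None and start < prev_end:
            raise SegmentError(
                f"overlapping segments on {chrom}: previous ends at {prev_end}, "
                f"next starts at {start}"
            )
        prev_end = end


def _merge_adjacent(segs: list[tuple[int, int, int, int]]) -> list[tuple[int, int, int, int]]:
    """Merge abutting segments with identical (major, minor)."""
    merged: list[list[int]] = []
    for start, end, major, minor in segs:
        if merged and merged[-1][1] == start and merged[-1][2] == major and merged[-1][3] == minor:
            merged[-1][1] = end
        else:
            merged.append([start, end, major, minor])
    return [tuple(s) for s in merged]  # type: ignore[return-value]


def preprocess_segments(segments: pd.DataFrame, genome: GenomeAnnotation) -> pd.DataFrame:
    """Sort, validate and merge a single profile's segments.

    Gaps between segments are tolerated (missing data); overlaps, inverted
    intervals, out-of-bounds coordinates and major < minor are rejected.
    Abutting segments with identical copy numbers are merged, so any
    refinement of a segment into equal-copy pieces scores identically.
    """
    missing = set(SEGMENT_COLUMNS) - set(segments.columns)
    if missing:
        raise SegmentError(f"segment table missing columns: {sorted(missing)}")
    out_rows = []
    df = segments[SEGMENT_COLUMNS].copy()
    for col in ("start", "end", "major", "minor"):
        df[col] = df[col].astype(int)
    for chrom, chunk in df.groupby("chrom", sort=True):
        segs = sorted(
            chunk[["start", "end", "major", "minor"]].itertuples(index=False, name=None)
        )
        _validate_chrom(str(chrom), segs, genome)
        for start, end, major, minor in _merge_adjacent(segs):
            out_rows.append((chrom, start, end, major, minor))
    return pd.DataFrame(out_rows, columns=SEGMENT_COLUMNS)


def _by_chrom(pre: pd.DataFrame):
    for chrom, chunk in pre.groupby("chrom", sort=True):
        yield str(chrom), list(
            chunk[["start", "end", "major", "minor"]].itertuples(index=False, name=None)
        )


def count_hrd_loh(pre: pd.DataFrame, genome: GenomeAnnotation, min_len: int = 15_000_000) -> int:
    """Count long interstitial LOH segments (minor allele lost)."""
    n = 0
    for chrom, segs in _by_chrom(pre):
        length = genome[chrom].length
        for start, end, _major, minor in segs:
            if minor != 0:
                continue
            if end - start < min_len:
                continue
            if start == 0 and end == length:  # whole-chromosome LOH is excluded
                continue
            n += 1
    return n


def _smooth(segs, smooth_len: int):
    """Drop fragments shorter than smooth_len, then re-merge equal-copy
    neighbours whose gap is below smooth_len."""
    kept = [s for s in segs if s[1] - s[0] >= smooth_len]
    merged: list[list[int]] = []
    for start, end, major, minor in kept:
        if (
            merged
            and merged[-1][2] == major
            and merged[-1][3] == minor
            and start - merged[-1][1] < smooth_len
        ):
            merged[-1][1] = end
        else:
            merged.append([start, end, major, minor])
    return [tuple(s) for s in merged]


def count_lst(
    pre: pd.DataFrame,
    genome: GenomeAnnotation,
    smooth_len: int = 3_000_000,
    min_flank: int = 10_000_000,
) -> int:
    """Count large-scale state transitions after 3 Mb smoothing.

    A transition is a breakpoint between two segments each >= min_flank long
    with an inter-segment gap < smooth_len; breakpoints falling on the
    centromere (the gap interval intersects it) are not counted.
    """
    n = 0
    for chrom, segs in _by_chrom(pre):
        info = genome[chrom]
        smoothed = _smooth(segs, smooth_len)
        for left, right in zip(smoothed, smoothed[1:]):
            if left[1] - left[0] < min_flank or right[1] - right[0] < min_flank:
                continue
            if right[0] - left[1] >= smooth_len:
                continue
            # skip transitions at the centromere: [left.end, right.start]
            # intersecting [cen_start, cen_end]
            if left[1] <= info.cen_end and right[0] >= info.cen_start:
                continue
            n += 1
    return n


def count_ntai(pre: pd.DataFrame, genome: GenomeAnnotation, min_len: int = 11_000_000) -> int:
    """Count telomeric allelic-imbalance regions.

    Maximal runs of contiguous imbalanced segments (major != minor) count
    when they touch a chromosome end, stay on one side of the centromere,
    do not span the whole chromosome, and are >= min_len long.
    """
    n = 0
    for chrom, segs in _by_chrom(pre):
        info = genome[chrom]
        runs: list[tuple[int, int]] = []
        cur: list[int] | None = None
        for start, end, major, minor in segs:
            if major != minor:
                if cur is not None and cur[1] == start:
                    cur[1] = end
                else:
                    if cur is not None:
                        runs.append((cur[0], cur[1]))
                    cur = [start, end]
            else:
                if cur is not None:
                    runs.append((cur[0], cur[1]))
                    cur = None
        if cur is not None:
            runs.append((cur[0], cur[1]))
        for start, end in runs:
            telomeric = start == 0 or end == info.length
            if not telomeric:
                continue
            if start == 0 and end == info.length:  # whole chromosome
                continue
            if start < info.cen_start and end > info.cen_end:  # crosses centromere
                continue
            if end - start < min_len:
                continue
            n += 1
    return n


def hrdsum_total(loh: int, lst: int, ntai: int, cut: int = 42) -> ScarResult:
    """Combine the three counters and apply the HRD decision (sum >= cut)."""
    for name, v in (("loh", loh), ("lst", lst), ("ntai", ntai)):
        if v < 0:
            raise SegmentError(f"{name} count must be non-negative, got {v}")
    total = loh + lst + ntai
    return ScarResult(loh, lst, ntai, total, "HRD" if total >= cut else "HRP")


def score_profile(
    segments: pd.DataFrame, genome: GenomeAnnotation, config: ScarConfig | None = None
) -> ScarResult:
    """Preprocess one patient's segments and compute the full scar result."""
    cfg = config or ScarConfig()
    pre = preprocess_segments(segments, genome)
    return hrdsum_total(
        count_hrd_loh(pre, genome, cfg.loh_min_len),
        count_lst(pre, genome, cfg.lst_smooth_len, cfg.lst_min_flank),
        count_ntai(pre, genome, cfg.ntai_min_len),
        cfg.hrdsum_cut,
    )


def score_cohort(
    segments: pd.DataFrame, genome: GenomeAnnotation, config: ScarConfig | None = None
) -> pd.DataFrame:
    """Score a multi-patient segment table (column patient_id) -> one row each."""
    if "patient_id" not in segments.columns:
        raise SegmentError("cohort segment table requires a patient_id column")
    rows = []
    for pid, chunk in segments.groupby("patient_id", sort=True):
        res = score_profile(chunk, genome, config)
        rows.append(
            {
                "patient_id": pid,
                "loh": res.loh,
                "lst": res.lst,
                "ntai": res.ntai,
                "hrdsum": res.hrdsum,
                "status": res.status,
            }
        )
    return pd.DataFrame(rows)
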