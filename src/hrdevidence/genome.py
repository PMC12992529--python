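"""Genome annotation: chromosome lengths and centromere intervals.

The scar counters only need to know how long each chromosome is and where
its centromere sits (telomeric-AI and LST rules are arm-aware).  A small
toy genome in real base-pair units is bundled for simulation and testing;
any annotation with the same three coordinates per chromosome can be
substituted, e.g. one derived from hg38 cytobands.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

MB = 1_000_000


class AnnotationError(ValueError):
    """Raised when a genome annotation is internally inconsistent."""


@dataclass(frozen=True)
class ChromInfo:
    length: int
    cen_start: int
    cen_end: int

    def __post_init__(self) -> None:
        if not (0 < self.cen_start < self.cen_end < self.length):
            raise AnnotationError(
                f"centromere [{self.cen_start}, {self.cen_end}) must lie strictly "
                f"inside the chromosome (length {self.length})"
            )


class GenomeAnnotation:
    """Mapping of chromosome name -> (length, centromere interval), 0-based bp."""

    def __init__(self, chroms: dict[str, ChromInfo]):
        if not chroms:
            raise AnnotationError("annotation must contain at least one chromosome")
        self.chroms = dict(chroms)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def __getitem__(self, chrom: str) -> ChromInfo:
        return self.chroms[chrom]

    def names(self) -> list[str]:
        return list(self.chroms)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenomeAnnotation":
        """Build from a table with columns chrom, length, cen_start, cen_end."""
        required = {"chrom", "length", "cen_start", "cen_end"}
        missing = required - set(df.columns)
        if missing:
            raise AnnotationError(f"annotation table missing columns: {sorted(missing)}")
        return cls(
            {
                str(r.chrom): ChromInfo(int(r.length), int(r.cen_start), int(r.cen_end))
                for r in df.itertuples(index=False)
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"chrom": c, "length": i.length, "cen_start": i.cen_start, "cen_end": i.cen_end}
                for c, i in self.chroms.items()
            ]
        )


def toy_genome(n_chrom: int = 22) -> GenomeAnnotation:
    """A deterministic 22-chromosome toy genome.

    Chromosome i has length 240 - 8*(i-1) Mb (so 240 Mb down to 72 Mb) with a
    3 Mb centromere starting at 40% of the length.  Arms are long enough for
    every scar event class used by the segment simulator.
    """
    if not 1 <= n_chrom <= 23:
        raise AnnotationError("toy genome supports 1-23 chromosomes")
    chroms = {}
    for i in range(1, n_chrom + 1):
        length = (240 - 8 * (i - 1)) * MB
        cen_start = int(0.4 * length)
        chroms[f"chr{i}"] = ChromInfo(length, cen_start, cen_start + 3 * MB)
    return GenomeAnnotation(chroms)
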