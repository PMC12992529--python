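import pandas as pd
import pytest

from hrdevidence import calibration, curation, fixture_cohort, hrcalls
from hrdevidence.genome import ChromInfo, GenomeAnnotation


@pytest.fixture(scope="session")
def cohort():
    return fixture_cohort()


@pytest.fixture(scope="session")
def groups(cohort):
    table, _ = curation.partition_cohort(cohort.variants, cohort.samples)
    return table


@pytest.fixture(scope="session")
def group_counts(cohort):
    _, counts = curation.partition_cohort(cohort.variants, cohort.samples)
    return counts


@pytest.fixture(scope="session")
def calls(cohort):
    return hrcalls.call_cohort(cohort.scores)


@pytest.fixture(scope="session")
def calibration_table(groups, calls):
    return calibration.build_calibration_table(groups, calls)


@pytest.fixture(scope="session")
def genome100():
    """One 100 Mb chromosome with a 40-50 Mb centromere."""
    return GenomeAnnotation({"chr1": ChromInfo(100_000_000, 40_000_000, 50_000_000)})


def make_segments(rows, chrom="chr1"):
    return pd.DataFrame(
        [{"chrom": chrom, "start": s, "end": e, "major": M, "minor": m} for s, e, M, m in rows]
    )
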