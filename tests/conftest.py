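import numpy as np
import pandas as pd
import pytest

from aplmeth import CpGSiteTable, SampleRecord, SampleSheet, Split, Subtype, Tissue


def make_table(records):
    """Build a CpGSiteTable from {sample: [(chrom, pos, meth, unmeth), ...]}."""
    frames = {
        sid: pd.DataFrame(rows, columns=["chrom", "pos", "meth", "unmeth"])
        for sid, rows in records.items()
    }
    return CpGSiteTable.from_sample_frames(frames)


def table_from_betas(betas, depth=20):
    """CpGSiteTable with given beta values (sites x samples DataFrame)."""
    meth = (betas * depth).round().astype(int)
    unmeth = depth - meth
    return CpGSiteTable(meth, unmeth)


@pytest.fixture(scope="session")
def paired_sheet():
    """Six paired patients across two subtypes."""
    records = []
    for s, n in ((Subtype.SSL, 3), (Subtype.TA, 3)):
        for i in range(n):
            pid = f"{s.value}_P{i}"
            records.append(SampleRecord(f"{pid}_T", pid, Tissue.tumor, s, Split.discovery))
            records.append(SampleRecord(f"{pid}_N", pid, Tissue.NAT, s, Split.discovery))
    return SampleSheet(records)


@pytest.fixture(scope="session")
def default_cohort():
    """One default planted cohort, shared across read-only tests."""
    from aplmeth import SimulationConfig, generate_cohort

    return generate_cohort(SimulationConfig(seed=11))
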