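import numpy as np
import pytest

from mrkit.harmonization import HarmonizedSet
from mrkit.instrument_selection import InstrumentRecord
from mrkit.summary_data import SummaryRecord, load_table1_fixture


def make_record(snp_id="rs1", ea="T", oa="C", beta=0.1, se=0.05, pvalue=1e-9,
                eaf=0.3, chrom=None, pos=None, n=None):
    return SummaryRecord(snp_id=snp_id, effect_allele=ea, other_allele=oa,
                         beta=beta, se=se, pvalue=pvalue, eaf=eaf, chrom=chrom,
                         pos=pos, n=n)


def make_hset(bx, sx, by, sy, binary=True, snp_ids=None):
    bx = np.asarray(bx, dtype=float)
    return HarmonizedSet(
        snp_ids=snp_ids or [f"rs{i + 1}" for i in range(len(bx))],
        beta_exp=bx,
        se_exp=np.asarray(sx, dtype=float),
        beta_out=np.asarray(by, dtype=float),
        se_out=np.asarray(sy, dtype=float),
        outcome_binary=binary,
    )


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table1_h(table1):
    from mrkit.harmonization import harmonize_set

    exposure, outcome = table1
    return harmonize_set([InstrumentRecord(record=r) for r in exposure], outcome)
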