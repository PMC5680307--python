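import numpy as np
import pytest

from urinpep.io import CleavageSiteEntry, PeptideRecord, SampleGroups


@pytest.fixture
def toy_sequences():
    return {
        "P00001": "MKWVTFISLLFLFSSAYSRGVFRRDAHKSEVAHRFKDLGEENFKALVLIA",
        "P00002": "GAPGPQGFQGPPGEPGEPGASGPMGPRGPPGPPGKNGDDGEAGKPGRPGE",
    }


@pytest.fixture
def toy_groups():
    return SampleGroups(case_ids=["c1", "c2", "c3"], control_ids=["n1", "n2", "n3"])


def make_peptide(pid, acc, start, stop, seq, case, control,
                 case_ids=("c1", "c2", "c3"), control_ids=("n1", "n2", "n3")):
    abundances = {s: float(v) for s, v in zip(case_ids, case)}
    abundances.update({s: float(v) for s, v in zip(control_ids, control)})
    return PeptideRecord(peptide_id=pid, sequence=seq, protein_accession=acc,
                         start=start, stop=stop, abundances=abundances)


@pytest.fixture
def toy_db():
    return [
        CleavageSiteEntry("MMP9", "P00002", 20, "observed"),
        CleavageSiteEntry("CTSD", "P00001", 18, "observed"),
        CleavageSiteEntry("CTSD", "P00001", 30, "observed"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
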