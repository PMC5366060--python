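import pytest

import matrilog as ml
from matrilog.synthetic import SimParams, populate_and_sample


@pytest.fixture(scope="session")
def default_sim():
    """One default-parameter simulated dataset (88 logs) with ground truth."""
    return populate_and_sample(SimParams(seed=11))


@pytest.fixture(scope="session")
def default_analysis(default_sim):
    """The simulated dataset pushed through haplotype collapse and classification."""
    aln, records, truth = default_sim
    table = ml.collapse_haplotypes(aln)
    assemblages = ml.build_assemblages(records, table)
    class_table = ml.classify_all(assemblages)
    return {
        "alignment": aln,
        "records": records,
        "truth": truth,
        "haplotype_table": table,
        "assemblages": assemblages,
        "class_table": class_table,
    }
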