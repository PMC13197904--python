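import numpy as np
import pandas as pd
import pytest

from leansift.cohort import CohortConfig, simulate_cohort, simulate_npx


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_subjects=120, npx_dropout=5, seed=3)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_npx(small_config, small_cohort):
    _, _, truth = small_cohort
    return simulate_npx(small_config, truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_npx_frame(values, lods, panels=None, samples=None, qc=None):
    """Small long-format NPX table from a dict {assay: [values...]}"""
    rows = []
    n = len(next(iter(values.values())))
    samples = samples or [f"X{i}" for i in range(n)]
    for assay, vals in values.items():
        panel = (panels or {}).get(assay, "P1")
        uniprot = assay.split("@")[0]
        for s, v in zip(samples, vals):
            rows.append({
                "SampleID": s, "SubjectID": s.split("_")[0],
                "Timepoint": "baseline", "OlinkID": assay, "Assay": uniprot,
                "UniProt": uniprot, "Panel": panel, "NPX": v,
                "LOD": lods[assay],
                "QC_Warning": (qc or {}).get((s, panel), "Pass"),
            })
    return pd.DataFrame(rows)
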