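import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_cascade_records():
    """Six annotated SNPs built so each cascade stage removes exactly one."""
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(6)],
            "gene": ["G"] * 6,
            # rs1 fails protein_changing, rs2 fails gene_set,
            # rs3 fails ortholog, rs4 fails artifact; rs5 fails significance
            "consequence": [
                "missense_deleterious",
                "synonymous",
                "nonsense",
                "splice",
                "start_loss",
                "missense_deleterious",
            ],
            "in_gene_set": [True, True, False, True, True, True],
            "ortholog_common_flag": [False, False, False, True, False, False],
            "artifact_flag": ["none", "none", "none", "none", "allele_calling_error", "none"],
            "n_assessed": [100] * 6,
            "rare_allele_count": [0] * 6,
            "carrier_count": [0] * 6,
            "ref_freq": [0.01] * 6,
            "ref_freq_kind": ["carrier"] * 6,
            "ref_cohort_size": [np.nan] * 6,
        }
    )


@pytest.fixture
def toy_cascade_results(toy_cascade_records):
    """Matching scan results: all significant except rs5."""
    q = [0.001, 0.001, 0.001, 0.001, 0.001, 0.9]
    return pd.DataFrame(
        {
            "snp_id": toy_cascade_records["snp_id"],
            "tested": True,
            "observed": 5.0,
            "expected": 1.0,
            "chi2": 10.0,
            "p": q,
            "p_bonferroni": q,
            "q_bh": q,
        }
    )
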