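import numpy as np
import pandas as pd
import pytest

from vdresponse import build_motif_library, load_fixture
from vdresponse.matrix import ExpressionMatrix


@pytest.fixture(scope="session")
def motif_library():
    """Known-VDRE half-site library plus the scanning motif set."""
    return build_motif_library(load_fixture("known_vdres"), load_fixture("motif_defs"))


def make_matrix(values: np.ndarray, subjects, doses, statuses, gene_ids=None):
    """Build an ExpressionMatrix with one baseline+followup pair per subject.

    ``values`` has one column per sample, ordered (s1_baseline,
    s1_followup, s2_baseline, ...).
    """
    sample_ids, rows = [], []
    for subj, dose, status in zip(subjects, doses, statuses):
        for visit in ("baseline", "followup"):
            sid = f"{subj}_{visit}"
            sample_ids.append(sid)
            rows.append(
                {"sample_id": sid, "subject": subj, "visit": visit,
                 "dose": dose, "status": status}
            )
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        pd.DataFrame(rows).set_index("sample_id"),
    )


@pytest.fixture
def tiny_paired_matrix():
    """4 genes x 4 subjects (2 per arm), balanced status groups."""
    rng = np.random.default_rng(0)
    values = rng.normal(8, 1, size=(4, 8))
    return make_matrix(
        values,
        subjects=["s1", "s2", "s3", "s4"],
        doses=[400, 400, 2000, 2000],
        statuses=[
            "deficient", "deficient",
            "insufficient_sufficient", "insufficient_sufficient",
        ],
    )
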