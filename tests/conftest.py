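import numpy as np
import pytest
from hypothesis import settings

from metasynopsis import AssociationDataset, StudyRecord

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def dataset_from_effects(thetas, ses, variant="rs1", outcome="disease X", **record_kw):
    """Build an additive log-odds dataset directly from (theta, se) pairs.

    ``record_kw`` values may be scalars (broadcast) or per-study sequences.
    """
    k = len(thetas)
    records = []
    for i in range(k):
        kw = {
            key: (val[i] if isinstance(val, (list, tuple, np.ndarray)) else val)
            for key, val in record_kw.items()
        }
        records.append(
            StudyRecord(
                study_id=f"s{i + 1}",
                variant_id=variant,
                outcome_name=outcome,
                effect_allele="C",
                other_allele="A",
                theta=float(thetas[i]),
                se=float(ses[i]),
                **kw,
            )
        )
    return AssociationDataset(variant, outcome, records)


@pytest.fixture
def make_dataset():
    return dataset_from_effects
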