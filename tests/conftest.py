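import numpy as np
import pandas as pd
import pytest

import marsha_screen as ms


@pytest.fixture(scope="session")
def study_cohort() -> pd.DataFrame:
    """Clean synthetic cohort at the default study condition (n=10000)."""
    return ms.generate_cohort(ms.study_config(n=10_000, seed=20240601))


@pytest.fixture(scope="session")
def study_item_frame(study_cohort) -> pd.DataFrame:
    cfg = ms.study_config(n=1, seed=0)
    return study_cohort[list(cfg.item_ids)]


@pytest.fixture(scope="session")
def reconstructed_table() -> ms.ConfusionTable:
    """Integer 2x2 table recovered from the published full-sample metrics."""
    return ms.reconstruct_confusion_table(
        n=224,
        n_reference_positive=117,
        sensitivity=0.838,
        specificity=0.907,
        ppv=0.907,
        npv=0.836,
        accuracy=0.871,
    )


@pytest.fixture(scope="session")
def recruitment_cohort() -> pd.DataFrame:
    """Synthetic cohort with the published recruitment-flow contamination."""
    return ms.generate_cohort(
        ms.study_config(n=224, seed=7, contamination=ms.STUDY_CONTAMINATION)
    )


def reference_and_screen(item_frame: pd.DataFrame):
    """Score a cohort: reference positivity and screener count score."""
    ref = item_frame.sum(axis=1) >= ms.REFERENCE_CUTPOINT
    scr = (item_frame[list(ms.SCREENER_ITEMS)] > 0).sum(axis=1)
    return np.asarray(ref), np.asarray(scr)
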