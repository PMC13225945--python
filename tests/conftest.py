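import numpy as np
import pytest

from vancopk import ehr_model, synthgen


@pytest.fixture(scope="session")
def small_cohort():
    """12-patient observable cohort with ground truth."""
    return synthgen.generate_cohort(synthgen.CohortSpec(n_patients=12, seed=7))


@pytest.fixture(scope="session")
def small_frames(small_cohort):
    """Preprocessed frames + splits for the 12-patient cohort."""
    timelines, gt = small_cohort
    view = ehr_model.training_view(timelines)
    tr, te, va = ehr_model.split_patients(view, ehr_model.SplitSpec(seed=1))
    frames, std = ehr_model.impute_and_standardize(view, tr)
    return {"view": view, "train": tr, "test": te, "val": va,
            "frames": frames, "std": std, "gt": gt}


@pytest.fixture(scope="session")
def recovery_small():
    """8-patient dense peak+trough noiseless recovery cohort."""
    return synthgen.generate_recovery_suite(8, "peak_trough", noise_sd=0.0, seed=4)


def frames_of(bundle, split):
    return [bundle["frames"][tl.encounter_id] for tl in bundle[split]]
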