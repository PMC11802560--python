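import numpy as np
import pytest

from sefcn.preprocess import preprocess_record, EpochSet
from sefcn.simulate import SeizureSpec, SimConfig, generate_cohort, generate_record
from sefcn.evaluate import lopo_splits, train_fold
from sefcn.model import ModelConfig


@pytest.fixture(scope="session")
def seizure_record():
    """60-s record with one gain-5 seizure on channels 3 and 7."""
    cfg = SimConfig(
        duration_s=60.0,
        seizures=(SeizureSpec(20.0, 30.0, (3, 7), amplitude_gain=5.0, rhythm_hz=3.0),),
        seed=1,
    )
    return generate_record(cfg, patient_id="p1")


@pytest.fixture(scope="session")
def tiny_model_config():
    """Narrow network for fast training in structural tests."""
    return ModelConfig(conv_filters=(4, 6, 8), se_reduction=2, seed=0)


@pytest.fixture(scope="session")
def trained_fold():
    """One LOPO fold trained on a separable 2-patient cohort (gain 8).

    Session-scoped: several tests reuse the trained model, its history
    and its held-out patient's epochs.
    """
    template = SimConfig(
        duration_s=120.0,
        seizures=(SeizureSpec(40.0, 70.0, (3, 7), amplitude_gain=8.0, rhythm_hz=3.0),),
        seed=0,
    )
    records = generate_cohort(2, template, seed=7)
    epochs = EpochSet.concatenate([preprocess_record(r) for r in records])
    folds = lopo_splits(sorted({str(p) for p in epochs.patient_ids}), seed=7)
    model, history, test = train_fold(folds[0], epochs, n_epochs=8)
    return {
        "model": model,
        "history": history,
        "test": test,
        "epochs": epochs,
        "records": records,
        "fold": folds[0],
    }
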