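import numpy as np
import pandas as pd
import pytest

from fscore_elm import SimConfig, extract_features, generate_dataset, preprocess_dataset


def make_feature_table(
    n_subjects: int = 10,
    per_subject: int = 20,
    n_informative: int = 3,
    n_noise: int = 28,
    effect: float = 1.0,
    subject_sd: float = 0.3,
    trial_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature-table analogue of the ERP simulator.

    Informative columns shift by ±effect between classes, with a per-subject
    offset and trial-level noise (the structure averaged P300 amplitudes
    have); the remaining columns are pure N(0, 1) noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for label, prefix in ((1, "G"), (-1, "I")):
        for s in range(n_subjects):
            sid = f"{prefix}{s + 1:02d}"
            offset = rng.normal(0.0, subject_sd, n_informative)
            for _ in range(per_subject):
                inf = label * effect + offset + rng.normal(0.0, trial_sd, n_informative)
                noise = rng.normal(0.0, 1.0, n_noise)
                rows.append([sid, label, *inf, *noise])
    cols = (
        ["subject_id", "label"]
        + [f"inf{i}" for i in range(n_informative)]
        + [f"noise{i}" for i in range(n_noise)]
    )
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture(scope="session")
def study_table() -> pd.DataFrame:
    """Feature table of a full simulated study at the default conditions:
    14 subjects per class, 105 trials each, 5-trial averaging (294 averaged
    responses per class)."""
    cfg = SimConfig(seed=42)
    averaged = preprocess_dataset(generate_dataset(cfg), group_size=cfg.avg_group_size)
    return extract_features(averaged)
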