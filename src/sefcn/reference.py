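"""Published CHB-MIT reference tables used in worked examples.

Two small tables are embedded as literals: the per-subject metadata of
the CHB-MIT scalp-EEG corpus (seizure counts, recording hours, ages)
and the per-patient results of a published SE-FCN benchmark evaluated
on that corpus with leave-one-patient-out cross-validation.  They serve
as ground truth for the metric arithmetic implemented in
:mod:`sefcn.evaluate` (e.g. recomputing a G-Mean column from printed
sensitivity/specificity pairs) and for dataset-summary bookkeeping;
they are inputs, never outputs, of this package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# Per-subject CHB-MIT metadata: (subject, sex, age, used seizures,
# total duration in hours, mean seizure duration in seconds).
# Age/sex of subject 24 are unknown.
CHBMIT_SUBJECTS = pd.DataFrame(
    [
        (1, "F", 11.0, 7, 40.55, 63.15),
        (2, "M", 11.0, 3, 35.27, 57.34),
        (3, "F", 14.0, 7, 38.00, 57.43),
        (4, "M", 22.0, 4, 156.07, 94.50),
        (5, "F", 7.0, 5, 39.00, 111.60),
        (6, "F", 1.5, 10, 66.74, 15.30),
        (7, "F", 14.5, 3, 67.05, 108.34),
        (8, "M", 3.5, 5, 20.01, 183.80),
        (9, "F", 10.0, 4, 67.87, 69.00),
        (10, "M", 3.0, 6, 50.02, 65.50),
        (11, "F", 12.0, 3, 34.79, 268.67),
        (12, "F", 2.0, 27, 20.69, 36.63),
        (13, "F", 3.0, 12, 33.00, 44.59),
        (14, "F", 9.0, 8, 26.00, 22.13),
        (15, "M", 16.0, 20, 40.01, 99.60),
        (16, "F", 7.0, 10, 19.00, 8.40),
        (17, "F", 12.0, 3, 21.01, 97.67),
        (18, "F", 18.0, 6, 35.63, 52.84),
        (19, "F", 19.0, 3, 29.93, 78.67),
        (20, "F", 6.0, 8, 27.60, 36.75),
        (21, "F", 13.0, 4, 32.83, 49.75),
        (22, "F", 9.0, 3, 31.00, 68.00),
        (23, "F", 6.0, 7, 26.56, 60.58),
        (24, None, np.nan, 16, 21.30, 31.94),
    ],
    columns=["subject", "sex", "age", "n_seizures", "total_h", "mean_seizure_s"],
)

# Per-patient results of a published SE-FCN CHB-MIT benchmark
# (sensitivity %, specificity %, G-Mean %, accuracy, AUC).
SE_BENCHMARK = pd.DataFrame(
    [
        ("chb01", 96.8, 93.6, 95.2, 0.94, 0.99),
        ("chb02", 80.8, 92.9, 86.7, 0.93, 0.96),
        ("chb03", 99.5, 79.9, 89.2, 0.90, 0.99),
        ("chb04", 77.2, 88.0, 82.4, 0.88, 0.89),
        ("chb05", 96.1, 82.7, 89.1, 0.83, 0.98),
        ("chb06", 56.5, 75.7, 65.4, 0.75, 0.51),
        ("chb07", 92.6, 87.8, 90.2, 0.88, 0.94),
        ("chb08", 64.5, 92.8, 77.4, 0.92, 0.86),
        ("chb09", 99.3, 61.3, 78.0, 0.62, 0.99),
        ("chb10", 95.7, 77.6, 86.2, 0.78, 0.97),
        ("chb11", 56.9, 96.0, 73.9, 0.95, 0.82),
        ("chb12", 53.6, 86.0, 67.9, 0.85, 0.89),
        ("chb13", 57.4, 92.3, 72.8, 0.91, 0.80),
        ("chb14", 55.7, 87.4, 69.8, 0.87, 0.73),
        ("chb15", 78.7, 94.2, 86.1, 0.92, 0.88),
        ("chb16", 66.0, 84.6, 74.7, 0.85, 0.79),
        ("chb17", 94.2, 82.3, 88.0, 0.82, 0.96),
        ("chb18", 72.0, 79.5, 75.7, 0.79, 0.88),
        ("chb19", 81.9, 88.1, 84.9, 0.88, 0.93),
        ("chb20", 76.2, 79.4, 77.8, 0.90, 0.84),
        ("chb21", 82.4, 89.7, 86.0, 0.90, 0.94),
        ("chb22", 98.5, 95.4, 97.0, 0.95, 1.00),
        ("chb23", 97.2, 91.7, 94.4, 0.92, 0.98),
    ],
    columns=["patient", "sen_pct", "spe_pct", "gmean_pct", "acc", "auc"],
)


def dataset_summary(subjects: pd.DataFrame | None = None) -> dict:
    """Recompute the summary row of a per-subject metadata table.

    Totals for seizure counts and recording hours; means for ages (over
    subjects with a known age only) and per-subject mean seizure
    durations.
    """
    df = CHBMIT_SUBJECTS if subjects is None else subjects
    return {
        "n_subjects": int(len(df)),
        "total_seizures": int(df["n_seizures"].sum()),
        "total_hours": float(df["total_h"].sum()),
        "mean_age": float(df["age"].mean()),  # pandas skips NaN ages
        "mean_seizure_duration_s": float(df["mean_seizure_s"].mean()),
    }
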