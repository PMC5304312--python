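"""Bundled reference tables from a 10-subject healthy-cohort tonometry study.

Three small CSVs ship with the package; they are the printed per-measurement
and per-subject results of an air-puff tonometry study of 10 healthy adults
(6 measurements per subject, one eye each, measurements spread over the
cardiac cycle):

* ``reference_subject1_features`` — the six feature vectors (w1-w5) of one
  right eye;
* ``reference_cohort_feature_stats`` — per-subject mean +/- std of w1-w5;
* ``reference_scan_extrema`` — per-subject minimum/maximum IOP-phase
  correlation with the shifts at which they occur.

They serve as worked-example inputs and as reference values for the
aggregate checks in the test suite.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_subject1_features",
    "load_cohort_feature_stats",
    "load_scan_extrema",
]


def _load(name: str) -> pd.DataFrame:
    with resources.files("oculopulse.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_subject1_features() -> pd.DataFrame:
    """Six measurements of one right eye: columns measurement, w1_ms..w5_mmHg."""
    return _load("reference_subject1_features.csv")


def load_cohort_feature_stats() -> pd.DataFrame:
    """Per-subject feature means/stds: subject, eye, w1_mean, w1_std, ..."""
    return _load("reference_cohort_feature_stats.csv")


def load_scan_extrema() -> pd.DataFrame:
    """Per-subject IOP-phase correlation extrema and their shifts."""
    return _load("reference_scan_extrema.csv")
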