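"""Binary steatosis reference standards: ultrasound label and CAP threshold.

Two reference definitions of hepatic steatosis are supported:

* ``us``  — the radiologist's ultrasound diagnosis, consumed as a given
  boolean label (the sonographic criteria are image-level and outside
  this package's scope);
* ``cap`` — controlled attenuation parameter >= 248 dB/m (boundary
  inclusive), the transient-elastography definition.

Liver stiffness measurement (LSM) reliability is computed and reported
but does not gate the CAP analysis by default: exams with ten valid
measurements are kept regardless, with gating available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: CAP threshold (dB/m) defining hepatic steatosis; boundary inclusive.
CAP_STEATOSIS_THRESHOLD = 248.0

#: LSM reliability bounds: IQR/median < 0.3, or median < 7.1 kPa; and at
#: least 10 valid measurements.
LSM_IQR_MEDIAN_MAX = 0.3
LSM_MEDIAN_MAX_KPA = 7.1
LSM_MIN_VALID = 10


class EmptyLabelError(ValueError):
    """No subject carries the requested reference label."""


@dataclass
class ReferenceLabels:
    """A reference-standard label vector aligned to a subset of the cohort."""

    reference: str
    index: pd.Index            # cohort rows that carry the label
    labels: np.ndarray         # boolean, aligned with `index`
    n_dropped: int             # subjects lacking the reference

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def prevalence(self) -> float:
        return float(np.mean(self.labels))

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "n_labeled": self.n,
            "n_dropped": self.n_dropped,
            "prevalence": self.prevalence,
        }


def classify_cap_steatosis(cap, threshold: float = CAP_STEATOSIS_THRESHOLD):
    """Steatosis by CAP: ``cap >= threshold``. NaN CAP yields NaN.

    Scalars return bool (or ``None`` for missing); arrays return a float
    array of {0.0, 1.0, NaN}.
    """
    if np.isscalar(cap) or cap is None:
        if cap is None or (isinstance(cap, float) and np.isnan(cap)):
            return None
        return bool(cap >= threshold)
    cap = np.asarray(cap, dtype=float)
    out = np.where(np.isnan(cap), np.nan, (cap >= threshold).astype(float))
    return out


def lsm_reliable(lsm_n_valid, lsm_iqr_over_median, lsm_median):
    """Reliability of a liver-stiffness exam.

    Reliable iff at least :data:`LSM_MIN_VALID` valid shots AND
    (IQR/median < 0.3 OR median < 7.1 kPa). Missing inputs give
    ``None`` (scalar) / NaN (array).
    """
    scalar = np.isscalar(lsm_n_valid) or lsm_n_valid is None
    n = np.asarray(lsm_n_valid, dtype=float)
    ratio = np.asarray(lsm_iqr_over_median, dtype=float)
    med = np.asarray(lsm_median, dtype=float)
    ok = (n >= LSM_MIN_VALID) & (
        (ratio < LSM_IQR_MEDIAN_MAX) | (med < LSM_MEDIAN_MAX_KPA)
    )
    any_missing = np.isnan(n) | np.isnan(ratio) | np.isnan(med)
    if scalar:
        return None if bool(any_missing) else bool(ok)
    return np.where(any_missing, np.nan, ok.astype(float))


def build_reference_labels(
    cohort: pd.DataFrame,
    reference: str = "us",
    cap_threshold: float = CAP_STEATOSIS_THRESHOLD,
) -> ReferenceLabels:
    """Build the boolean steatosis label vector for one reference standard.

    Subjects lacking the reference (missing ultrasound label, or missing
    CAP) are dropped and counted; the returned index records which rows
    remain so scores can be aligned.

    Raises
    ------
    EmptyLabelError
        If no subject carries the reference.
    """
    if reference == "us":
        col = cohort["us_steatosis"]
        have = col.notna()
        labels = col[have].astype(bool).to_numpy()
    elif reference == "cap":
        cap = cohort["cap"]
        have = cap.notna()
        labels = (cap[have] >= cap_threshold).to_numpy()
    else:
        raise ValueError(f"unknown reference {reference!r} (use 'us' or 'cap')")
    if not have.any():
        raise EmptyLabelError(f"no subject carries the {reference!r} reference")
    return ReferenceLabels(
        reference=reference,
        index=cohort.index[have],
        labels=labels,
        n_dropped=int((~have).sum()),
    )
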