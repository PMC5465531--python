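"""Cardiac output from raw echo and thermodilution measurements.

Transthoracic echocardiography (TTE) estimates cardiac output from the left
ventricular outflow tract (LVOT): the LVOT is assumed circular, its area is
computed from the average of repeated diameter measurements, stroke volume
is area x velocity-time integral (VTI), and CO = SV x HR / 1000. The
pulmonary artery catheter (PAC) reference value is the mean of repeated
cold-saline bolus thermodilution readings.

Replicate-based precision follows the hemodynamic-monitoring convention

    precision% = 100 * k * CV_pooled / sqrt(n),

with k = 2 by default (k = 1.96 available), CV pooled across subjects as a
root mean square, and n the replicate count averaged into one reported
value. The least significant change is precision * sqrt(2): the smallest
measured change distinguishable from measurement noise at the same
confidence level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .exceptions import InvalidInputError

logger = logging.getLogger(__name__)

#: Nominal replicate counts used in the study protocol.
NOMINAL_N_DIAMETERS = 3
NOMINAL_N_VTI = 5
NOMINAL_N_BOLUS = 5


def _check_positive(values: Sequence[float], what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidInputError(f"{what}: empty list")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise InvalidInputError(f"{what}: all values must be positive and finite, got {list(arr)}")
    return arr


@dataclass(frozen=True)
class EchoMeasurement:
    """Raw echo quantities for one patient at one timepoint.

    Parameters
    ----------
    patient_id : str
        Patient identifier.
    timepoint : int
        Ordinal timepoint (1 = baseline, 2 = follow-up).
    lvot_diameters : tuple of float
        Repeated LVOT diameter measurements, cm (nominally 3).
    vti_values : tuple of float
        Repeated velocity-time integrals, cm (nominally 5 consecutive beats).
    heart_rate : float
        Heart rate during VTI acquisition, beats/min.
    """

    patient_id: str
    timepoint: int
    lvot_diameters: tuple[float, ...]
    vti_values: tuple[float, ...]
    heart_rate: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "lvot_diameters", tuple(float(d) for d in self.lvot_diameters))
        object.__setattr__(self, "vti_values", tuple(float(v) for v in self.vti_values))
        _check_positive(self.lvot_diameters, "lvot_diameters")
        _check_positive(self.vti_values, "vti_values")
        if not (math.isfinite(self.heart_rate) and self.heart_rate > 0):
            raise InvalidInputError(f"heart_rate must be positive, got {self.heart_rate}")
        if len(self.lvot_diameters) != NOMINAL_N_DIAMETERS:
            logger.warning(
                "patient %s t%d: %d LVOT diameters (nominal %d)",
                self.patient_id, self.timepoint, len(self.lvot_diameters), NOMINAL_N_DIAMETERS,
            )
        if len(self.vti_values) != NOMINAL_N_VTI:
            logger.warning(
                "patient %s t%d: %d VTI traces (nominal %d)",
                self.patient_id, self.timepoint, len(self.vti_values), NOMINAL_N_VTI,
            )


@dataclass(frozen=True)
class ThermodilutionSeries:
    """Repeated thermodilution bolus CO readings for one patient-timepoint."""

    patient_id: str
    timepoint: int
    bolus_co: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bolus_co", tuple(float(v) for v in self.bolus_co))
        _check_positive(self.bolus_co, "bolus_co")
        if len(self.bolus_co) < 2:
            raise InvalidInputError(
                f"patient {self.patient_id} t{self.timepoint}: need >=2 bolus readings, "
                f"got {len(self.bolus_co)}"
            )
        if len(self.bolus_co) != NOMINAL_N_BOLUS:
            logger.warning(
                "patient %s t%d: %d bolus readings (nominal %d)",
                self.patient_id, self.timepoint, len(self.bolus_co), NOMINAL_N_BOLUS,
            )


@dataclass(frozen=True)
class PrecisionResult:
    """Replicate-based precision of one CO method."""

    method_label: str
    pooled_cv: float
    n_replicates: float
    precision_pct: float
    lsc_pct: float
    n_subjects: int = 0


def lvot_area(lvot_diameters: Sequence[float], *, pi_literal: float | None = None) -> float:
    """Cross-sectional LVOT area (cm^2) from repeated diameter measurements.

    The LVOT is modelled as a circle of radius mean(diameter)/2. ``pi_literal``
    substitutes a rounded constant (e.g. 3.14) for full-precision pi, for
    exact agreement with sources that print the rounded formula.
    """
    d = _check_positive(lvot_diameters, "lvot_diameters")
    pi = math.pi if pi_literal is None else float(pi_literal)
    return pi * (float(d.mean()) / 2.0) ** 2


def echo_cardiac_output(m: EchoMeasurement, *, pi_literal: float | None = None) -> dict[str, float]:
    """Stroke volume (ml) and cardiac output (L/min) from one echo record.

    SV = LVOT area x mean VTI (cm^3 = ml); CO = SV x HR / 1000.
    """
    area = lvot_area(m.lvot_diameters, pi_literal=pi_literal)
    sv_ml = area * float(np.mean(m.vti_values))
    co_lmin = sv_ml * m.heart_rate / 1000.0
    return {"sv_ml": sv_ml, "co_lmin": co_lmin}


def pac_cardiac_output(s: ThermodilutionSeries) -> float:
    """Reference CO (L/min): arithmetic mean of the bolus readings."""
    return float(np.mean(s.bolus_co))


class ReplicatePrecision(BaseEstimator):
    """Pooled replicate precision and least significant change of a method.

    Per subject, the coefficient of variation CV = sd/mean (sd with the n-1
    denominator) of the replicate readings is computed; subject CVs are
    pooled (root mean square by default, so the pooled CV^2 is the mean
    within-subject relative variance). The reported value is an average of n
    replicates, so its precision is ``100 * k * CV_pooled / sqrt(n)`` and the
    least significant change is ``precision * sqrt(2)``.

    Parameters
    ----------
    k : float, default=2.0
        Coverage multiplier of the precision convention (1.96 for the exact
        normal quantile).
    pooling : {"rms", "mean"}, default="rms"
        How subject CVs are pooled.

    Attributes
    ----------
    pooled_cv_ : float
        Pooled per-replicate coefficient of variation (fraction).
    n_replicates_ : float
        Mean replicate count per subject.
    precision_pct_ : float
        Precision of the n-replicate average, percent.
    lsc_pct_ : float
        Least significant change, percent.
    """

    def __init__(self, k: float = 2.0, pooling: str = "rms"):
        self.k = k
        self.pooling = pooling

    def fit(self, X: Sequence[Sequence[float]], y=None) -> "ReplicatePrecision":
        """Compute pooled precision from per-subject replicate lists.

        ``X`` is a list of per-subject replicate value lists (lengths may
        differ); every subject needs at least two positive replicates.
        """
        if self.pooling not in ("rms", "mean"):
            raise ValueError(f"pooling must be 'rms' or 'mean', got {self.pooling!r}")
        if len(X) == 0:
            raise InvalidInputError("precision: no subjects")
        cvs = []
        counts = []
        for i, reps in enumerate(X):
            arr = _check_positive(reps, f"subject {i} replicates")
            if arr.size < 2:
                raise InvalidInputError(f"subject {i}: need >=2 replicates, got {arr.size}")
            cvs.append(float(arr.std(ddof=1) / arr.mean()))
            counts.append(arr.size)
        cvs = np.asarray(cvs)
        if self.pooling == "rms":
            pooled = float(np.sqrt(np.mean(cvs**2)))
        else:
            pooled = float(np.mean(cvs))
        n_bar = float(np.mean(counts))
        self.subject_cvs_ = cvs
        self.n_subjects_ = len(cvs)
        self.pooled_cv_ = pooled
        self.n_replicates_ = n_bar
        self.precision_pct_ = 100.0 * self.k * pooled / math.sqrt(n_bar)
        self.lsc_pct_ = self.precision_pct_ * math.sqrt(2.0)
        return self

    def result(self, method_label: str = "") -> PrecisionResult:
        """Fitted attributes packaged as a :class:`PrecisionResult`."""
        return PrecisionResult(
            method_label=method_label,
            pooled_cv=self.pooled_cv_,
            n_replicates=self.n_replicates_,
            precision_pct=self.precision_pct_,
            lsc_pct=self.lsc_pct_,
            n_subjects=self.n_subjects_,
        )


def precision_stats(
    replicate_sets: Sequence[Sequence[float]],
    method_label: str,
    *,
    k: float = 2.0,
    pooling: str = "rms",
) -> PrecisionResult:
    """Pooled precision and LSC of a method from per-subject replicates."""
    return ReplicatePrecision(k=k, pooling=pooling).fit(replicate_sets).result(method_label)
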