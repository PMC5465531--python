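"""Agreement between two cardiac output methods.

Bland-Altman analysis summarises paired differences d_i = test - reference
by their central tendency (the bias) and the limits of agreement
bias +/- 1.96 * sd(d). The Critchley percentage error normalises the
half-width of the limits by the mean CO of the cohort,

    PE = 100 * 1.96 * sd(d) / mean of pairwise mean CO,

with <= 30% the conventional interchangeability cutoff. Pearson correlation
is reported alongside, as method-comparison studies conventionally do,
although correlation alone cannot establish agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import DegenerateDataError, InvalidInputError


@dataclass(frozen=True)
class PairedCO:
    """One simultaneous (reference, test) CO pair."""

    patient_id: str
    timepoint: int
    co_ref: float   # PAC, L/min
    co_test: float  # TTE, L/min

    def __post_init__(self) -> None:
        if not (self.co_ref > 0 and self.co_test > 0):
            raise InvalidInputError(
                f"patient {self.patient_id} t{self.timepoint}: CO values must be positive "
                f"(ref={self.co_ref}, test={self.co_test})"
            )


@dataclass(frozen=True)
class AgreementResult:
    n_pairs: int
    r: float
    p_value: float
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pe_pct: float

    def to_dict(self) -> dict:
        return asdict(self)


def _constant(x: np.ndarray) -> bool:
    return bool((x == x[0]).all())


def _pairs_to_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(pairs, "ndim"):  # array-like (n, 2)
        arr = np.asarray(pairs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise InvalidInputError(f"expected (n, 2) array of (ref, test), got shape {arr.shape}")
        return arr[:, 0], arr[:, 1]
    ref = np.array([p.co_ref for p in pairs], dtype=float)
    test = np.array([p.co_test for p in pairs], dtype=float)
    return ref, test


class BlandAltmanAgreement(BaseEstimator):
    """Bland-Altman agreement with Pearson correlation and percentage error.

    Parameters
    ----------
    central_tendency : {"mean", "median"}, default="mean"
        Statistic used for the bias line. The limits of agreement always use
        1.96 * sd about the *mean* construction; the option affects only the
        reported bias.
    loa_multiplier : float, default=1.96
        Half-width of the limits of agreement in sd units.
    pe_denominator : {"pair_means", "reference"}, default="pair_means"
        Percentage-error denominator: grand mean of the pairwise
        (ref + test)/2 means (Critchley convention) or the reference-method
        mean.

    Attributes
    ----------
    bias_, sd_diff_, loa_low_, loa_high_ : float
        Bias and limits of agreement, L/min.
    pe_pct_ : float
        Percentage error.
    r_, p_value_ : float
        Pearson correlation of the paired values and its two-sided p-value;
        NaN when either column is constant.
    """

    def __init__(
        self,
        central_tendency: str = "mean",
        loa_multiplier: float = 1.96,
        pe_denominator: str = "pair_means",
    ):
        self.central_tendency = central_tendency
        self.loa_multiplier = loa_multiplier
        self.pe_denominator = pe_denominator

    def fit(self, X, y=None) -> "BlandAltmanAgreement":
        """Fit on paired measurements.

        ``X`` is either an (n, 2) array with columns (reference, test) or a
        sequence of :class:`PairedCO`.
        """
        if self.central_tendency not in ("mean", "median"):
            raise ValueError(f"central_tendency must be 'mean' or 'median', got {self.central_tendency!r}")
        if self.pe_denominator not in ("pair_means", "reference"):
            raise ValueError(f"pe_denominator must be 'pair_means' or 'reference', got {self.pe_denominator!r}")
        ref, test = _pairs_to_arrays(X)
        if ref.size < 2:
            raise InvalidInputError(f"need >=2 pairs, got {ref.size}")
        d = test - ref
        self.n_pairs_ = int(ref.size)
        self.bias_ = float(np.mean(d)) if self.central_tendency == "mean" else float(np.median(d))
        self.sd_diff_ = float(np.std(d, ddof=1))
        center = float(np.mean(d))  # LOA always about the mean
        self.loa_low_ = center - self.loa_multiplier * self.sd_diff_
        self.loa_high_ = center + self.loa_multiplier * self.sd_diff_

        denom = float(np.mean((ref + test) / 2.0)) if self.pe_denominator == "pair_means" else float(np.mean(ref))
        if denom == 0:
            raise DegenerateDataError("percentage error undefined: zero mean CO")
        self.mean_co_ = denom
        self.pe_pct_ = 100.0 * self.loa_multiplier * self.sd_diff_ / denom

        if ref.size >= 3 and not _constant(ref) and not _constant(test):
            r, p = stats.pearsonr(ref, test)
            self.r_, self.p_value_ = float(r), float(p)
        else:
            self.r_ = self.p_value_ = float("nan")
        return self

    def result(self) -> AgreementResult:
        """Fitted attributes packaged as an :class:`AgreementResult`."""
        return AgreementResult(
            n_pairs=self.n_pairs_,
            r=self.r_,
            p_value=self.p_value_,
            bias=self.bias_,
            sd_diff=self.sd_diff_,
            loa_low=self.loa_low_,
            loa_high=self.loa_high_,
            pe_pct=self.pe_pct_,
        )


def correlate(pairs) -> dict[str, float]:
    """Pearson correlation of paired CO values with two-sided p-value.

    Requires n >= 3 and non-constant columns; a constant column makes the
    correlation undefined and raises :class:`DegenerateDataError`.
    """
    ref, test = _pairs_to_arrays(pairs)
    if ref.size < 3:
        raise InvalidInputError(f"correlation needs >=3 pairs, got {ref.size}")
    if _constant(ref) or _constant(test):
        raise DegenerateDataError("correlation undefined: constant column")
    r, p = stats.pearsonr(ref, test)
    return {"r": float(r), "p_value": float(p)}


def bland_altman(pairs, central_tendency: str = "mean", loa_multiplier: float = 1.96) -> AgreementResult:
    """Bland-Altman bias and limits of agreement (with correlation and PE)."""
    return BlandAltmanAgreement(
        central_tendency=central_tendency, loa_multiplier=loa_multiplier
    ).fit(pairs).result()


def percentage_error(pairs, agreement: AgreementResult, loa_multiplier: float = 1.96) -> float:
    """Critchley percentage error from a fitted agreement result.

    PE = 100 * multiplier * sd_diff / grand mean of pairwise mean CO.
    """
    ref, test = _pairs_to_arrays(pairs)
    denom = float(np.mean((ref + test) / 2.0))
    if denom == 0:
        raise DegenerateDataError("percentage error undefined: zero mean CO")
    return 100.0 * loa_multiplier * agreement.sd_diff / denom
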