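"""Trending analysis: can the test method track changes in cardiac output?

Paired changes (second minus first measurement, per method) are analysed two
ways. The four-quadrant plot scatters percentage change in the test method
against percentage change in the reference; pairs inside a central exclusion
square (both |%change| below the zone) are discarded as noise, and the
concordance rate is the fraction of remaining pairs in which both methods
agree on direction. The half-circle polar plot re-expresses each pair of
absolute changes as a radius (the mean change magnitude) and an angle (the
deviation of the change vector from the line of identity); pairs whose mean
change is negative are folded by 180 degrees so concordant decreases also
lie on the polar axis. The mean polar angle measures calibration of the
trend, the radial limits of agreement (mean +/- 1.96 sd of angles) its
scatter, and the polar concordance rate the fraction of included angles
within a +/-30 degree band.

Conventional good-trending criteria: four-quadrant concordance > 90%, mean
polar angle within +/-5 degrees, radial LOA within +/-30 degrees.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .exceptions import InvalidInputError, UndefinedResultError

logger = logging.getLogger(__name__)

GOOD_FQ_CONCORDANCE_PCT = 90.0
GOOD_MEAN_ANGLE_DEG = 5.0
GOOD_RADIAL_LOA_DEG = 30.0


@dataclass(frozen=True)
class DeltaPair:
    """Paired change in CO between two timepoints, both methods.

    ``d_*`` are absolute changes (L/min), ``pct_*`` percentage changes
    relative to each method's own first measurement.
    """

    patient_id: str
    d_ref: float
    d_test: float
    pct_ref: float
    pct_test: float


@dataclass(frozen=True)
class PolarPoint:
    """One change pair in half-circle polar coordinates."""

    radius: float      # |mean change|, L/min
    angle_deg: float   # deviation from the identity line, (-180, 180]
    included: bool


@dataclass(frozen=True)
class TrendingResult:
    n_total: int
    n_included_fq: int
    concordance_fq_pct: float
    good_trending_fq: bool
    n_included_polar: int
    mean_polar_angle_deg: float
    radial_loa_low_deg: float
    radial_loa_high_deg: float
    concordance_polar_pct: float
    good_trending_polar: bool

    def to_dict(self) -> dict:
        return asdict(self)


def compute_deltas(timepoint1_pairs, timepoint2_pairs) -> list[DeltaPair]:
    """Per-patient changes between two timepoints for both methods.

    Arguments are sequences of :class:`~hemotrend.agreement.PairedCO` at
    each timepoint; patients are matched on ``patient_id``. Unmatched
    patients are skipped with a warning, as are patients with a
    non-positive baseline in either method (their percentage change is
    undefined).
    """
    t1 = {p.patient_id: p for p in timepoint1_pairs}
    t2 = {p.patient_id: p for p in timepoint2_pairs}
    unmatched = set(t1) ^ set(t2)
    for pid in sorted(unmatched):
        logger.warning("patient %s present at only one timepoint; skipped from trending", pid)
    deltas = []
    for pid in sorted(set(t1) & set(t2)):
        a, b = t1[pid], t2[pid]
        if a.co_ref <= 0 or a.co_test <= 0:
            logger.warning("patient %s: non-positive baseline CO; excluded from trending", pid)
            continue
        d_ref = b.co_ref - a.co_ref
        d_test = b.co_test - a.co_test
        deltas.append(
            DeltaPair(
                patient_id=pid,
                d_ref=d_ref,
                d_test=d_test,
                pct_ref=100.0 * d_ref / a.co_ref,
                pct_test=100.0 * d_test / a.co_test,
            )
        )
    return deltas


def _deltas_to_pct(deltas) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(deltas, "ndim"):
        arr = np.asarray(deltas, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise InvalidInputError(f"expected (n, 2) array of pct changes, got shape {arr.shape}")
        return arr[:, 0], arr[:, 1]
    return (
        np.array([d.pct_ref for d in deltas], dtype=float),
        np.array([d.pct_test for d in deltas], dtype=float),
    )


class FourQuadrantConcordance(BaseEstimator):
    """Four-quadrant concordance rate with a central exclusion zone.

    A pair is excluded iff both percentage changes are strictly inside the
    central square (|pct| < zone on both axes); among included pairs the
    concordance rate is the percentage whose changes share a sign. A change
    of exactly zero in either method agrees with no direction and counts as
    discordant.

    Parameters
    ----------
    zone_pct : float, default=15.0
        Half-width of the central exclusion square, percent.

    Attributes
    ----------
    concordance_pct_ : float
    n_included_, n_excluded_ : int
    """

    def __init__(self, zone_pct: float = 15.0):
        self.zone_pct = zone_pct

    def fit(self, X, y=None) -> "FourQuadrantConcordance":
        """X: (n, 2) array of (pct_ref, pct_test) or sequence of DeltaPair."""
        pr, pt = _deltas_to_pct(X)
        if pr.size == 0:
            raise InvalidInputError("no change pairs")
        excluded = (np.abs(pr) < self.zone_pct) & (np.abs(pt) < self.zone_pct)
        inc_r, inc_t = pr[~excluded], pt[~excluded]
        self.n_total_ = int(pr.size)
        self.n_included_ = int(inc_r.size)
        self.n_excluded_ = int(excluded.sum())
        if self.n_included_ == 0:
            raise UndefinedResultError(
                f"four-quadrant concordance undefined: all {self.n_total_} pairs "
                f"inside the {self.zone_pct}% exclusion zone"
            )
        concordant = np.sign(inc_r) * np.sign(inc_t) > 0
        self.concordance_pct_ = 100.0 * float(concordant.sum()) / self.n_included_
        self.good_trending_ = bool(self.concordance_pct_ > GOOD_FQ_CONCORDANCE_PCT)
        return self


def four_quadrant(deltas, zone_pct: float = 15.0) -> dict:
    """Four-quadrant concordance rate; see :class:`FourQuadrantConcordance`."""
    est = FourQuadrantConcordance(zone_pct=zone_pct).fit(deltas)
    return {
        "concordance_pct": est.concordance_pct_,
        "n_included": est.n_included_,
        "n_excluded": est.n_excluded_,
        "good_trending": est.good_trending_,
    }


def _wrap_angle(deg: float) -> float:
    """Wrap an angle into (-180, 180]."""
    wrapped = math.fmod(deg + 180.0, 360.0)
    if wrapped <= 0:
        wrapped += 360.0
    return wrapped - 180.0


def polar_transform(d, zone_lmin: float = 0.5) -> PolarPoint:
    """Half-circle polar coordinates of one change pair.

    The change vector (d_ref, d_test) has angle phi from the reference axis;
    the polar angle is phi - 45 degrees, so the identity line maps to the
    polar axis. The radius is the magnitude of the mean change
    (d_ref + d_test)/2; when the mean change is negative the point is folded
    by 180 degrees into the half circle. Points with radius below the
    exclusion zone are flagged excluded (boundary included).

    Accepts a :class:`DeltaPair` or a (d_ref, d_test) tuple.
    """
    if isinstance(d, DeltaPair):
        d_ref, d_test = d.d_ref, d.d_test
    else:
        d_ref, d_test = float(d[0]), float(d[1])
    if not (math.isfinite(d_ref) and math.isfinite(d_test)):
        raise InvalidInputError(f"non-finite change pair ({d_ref}, {d_test})")
    mean_change = (d_ref + d_test) / 2.0
    theta = _wrap_angle(math.degrees(math.atan2(d_test, d_ref)) - 45.0)
    if mean_change < 0:
        theta = _wrap_angle(theta + 180.0)
    radius = abs(mean_change)
    return PolarPoint(radius=radius, angle_deg=theta, included=radius >= zone_lmin)


class PolarTrending(BaseEstimator):
    """Mean polar angle, radial limits of agreement and polar concordance.

    Parameters
    ----------
    zone_lmin : float, default=0.5
        Exclusion radius: pairs whose mean absolute change is below this are
        dropped (boundary points kept).
    band_deg : float, default=30.0
        Half-width of the concordance band about the polar axis.
    loa_multiplier : float, default=1.96
        Radial LOA half-width in sd units.
    radial_loa_method : {"parametric", "percentile"}, default="parametric"
        Mean +/- multiplier*sd of included angles, or empirical 2.5/97.5
        percentiles.

    Attributes
    ----------
    mean_angle_deg_, radial_loa_low_deg_, radial_loa_high_deg_ : float
    concordance_pct_ : float
    points_ : list of PolarPoint
    """

    def __init__(
        self,
        zone_lmin: float = 0.5,
        band_deg: float = 30.0,
        loa_multiplier: float = 1.96,
        radial_loa_method: str = "parametric",
    ):
        self.zone_lmin = zone_lmin
        self.band_deg = band_deg
        self.loa_multiplier = loa_multiplier
        self.radial_loa_method = radial_loa_method

    def fit(self, X, y=None) -> "PolarTrending":
        """X: sequence of DeltaPair or (n, 2) array of (d_ref, d_test) L/min."""
        if self.radial_loa_method not in ("parametric", "percentile"):
            raise ValueError(f"radial_loa_method must be 'parametric' or 'percentile', got {self.radial_loa_method!r}")
        if hasattr(X, "ndim"):
            arr = np.asarray(X, dtype=float)
            items: Sequence = [tuple(row) for row in arr]
        else:
            items = list(X)
        self.points_ = [polar_transform(d, zone_lmin=self.zone_lmin) for d in items]
        angles = np.array([p.angle_deg for p in self.points_ if p.included])
        self.n_total_ = len(self.points_)
        self.n_included_ = int(angles.size)
        if angles.size < 2:
            raise UndefinedResultError(
                f"polar statistics undefined: {angles.size} of {self.n_total_} pairs "
                f"outside the {self.zone_lmin} L/min exclusion zone (need >=2)"
            )
        self.mean_angle_deg_ = float(angles.mean())
        sd = float(angles.std(ddof=1))
        self.sd_angle_deg_ = sd
        if self.radial_loa_method == "parametric":
            self.radial_loa_low_deg_ = self.mean_angle_deg_ - self.loa_multiplier * sd
            self.radial_loa_high_deg_ = self.mean_angle_deg_ + self.loa_multiplier * sd
        else:
            lo, hi = np.percentile(angles, [2.5, 97.5])
            self.radial_loa_low_deg_, self.radial_loa_high_deg_ = float(lo), float(hi)
        self.concordance_pct_ = 100.0 * float(np.mean(np.abs(angles) <= self.band_deg))
        self.good_trending_ = bool(
            abs(self.mean_angle_deg_) < GOOD_MEAN_ANGLE_DEG
            and max(abs(self.radial_loa_low_deg_), abs(self.radial_loa_high_deg_)) < GOOD_RADIAL_LOA_DEG
        )
        return self


def polar_stats(
    deltas,
    zone_lmin: float = 0.5,
    concordance_band_deg: float = 30.0,
    loa_multiplier: float = 1.96,
) -> dict:
    """Polar trending statistics; see :class:`PolarTrending`."""
    est = PolarTrending(
        zone_lmin=zone_lmin, band_deg=concordance_band_deg, loa_multiplier=loa_multiplier
    ).fit(deltas)
    return {
        "n_included": est.n_included_,
        "mean_polar_angle_deg": est.mean_angle_deg_,
        "radial_loa_low_deg": est.radial_loa_low_deg_,
        "radial_loa_high_deg": est.radial_loa_high_deg_,
        "concordance_pct": est.concordance_pct_,
        "good_trending": est.good_trending_,
    }


def trending_analysis(
    deltas,
    fq_zone_pct: float = 15.0,
    polar_zone_lmin: float = 0.5,
    polar_band_deg: float = 30.0,
    loa_multiplier: float = 1.96,
) -> TrendingResult:
    """Combined four-quadrant and polar trending analysis of change pairs."""
    fq = FourQuadrantConcordance(zone_pct=fq_zone_pct).fit(deltas)
    po = PolarTrending(
        zone_lmin=polar_zone_lmin, band_deg=polar_band_deg, loa_multiplier=loa_multiplier
    ).fit(deltas)
    return TrendingResult(
        n_total=fq.n_total_,
        n_included_fq=fq.n_included_,
        concordance_fq_pct=fq.concordance_pct_,
        good_trending_fq=fq.good_trending_,
        n_included_polar=po.n_included_,
        mean_polar_angle_deg=po.mean_angle_deg_,
        radial_loa_low_deg=po.radial_loa_low_deg_,
        radial_loa_high_deg=po.radial_loa_high_deg_,
        concordance_polar_pct=po.concordance_pct_,
        good_trending_polar=po.good_trending_,
    )
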