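"""ROC analysis of test-method change as a detector of reference change.

Each change pair is labelled positive when the reference method's percentage
change exceeds a clinical threshold (default: ΔCO by thermodilution > 10%,
the usual cutoff for a hemodynamic response to volume expansion); the score
is the test method's percentage change. The AUC is the trapezoid area under
the empirical ROC curve, identical to the normalised Mann-Whitney count of
concordant (positive, negative) score pairs with ties counted half. The
confidence interval uses the DeLong structural-components estimator of the
AUC variance by default (stratified bootstrap available), and the p-value
tests AUC = 0.5 on the same variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_curve as _sk_roc_curve

from .exceptions import DegenerateDataError
from .trending import _deltas_to_pct


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_pos: int
    n_neg: int
    curve: tuple = field(default=(), repr=False)  # (threshold, sensitivity, specificity)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["curve"] = [list(row) for row in self.curve]
        return d


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from scores and binary labels.

    Structural components: V10_i = mean over negatives of the concordance
    indicator (ties half) for positive i, and symmetrically V01_j; the AUC
    variance is var(V10)/m + var(V01)/n.
    """
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n                 # P(neg < pos_i), ties half
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m           # P(neg_j < pos), ties half
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


class ChangeDetectionROC(BaseEstimator):
    """ROC of percentage test-method change against a reference change rule.

    Parameters
    ----------
    positive_pct : float, default=10.0
        Reference rule: a pair is positive when pct_ref > positive_pct
        (strict).
    operating_threshold_pct : float, default=8.0
        Threshold at which the operating-point sensitivity/specificity are
        reported (rule pct_test > threshold, strict).
    ci_method : {"delong", "bootstrap"}, default="delong"
        95% CI construction. Bootstrap is stratified within classes.
    n_boot : int, default=2000
    random_state : int or None
        Used by the bootstrap CI only.

    Attributes
    ----------
    auc_, ci_low_, ci_high_, p_value_ : float
    sensitivity_pct_, specificity_pct_ : float
        At the operating threshold.
    youden_threshold_ : float
        Score threshold maximising sensitivity + specificity (convenience).
    curve_ : list of (threshold, sensitivity, specificity)
    """

    def __init__(
        self,
        positive_pct: float = 10.0,
        operating_threshold_pct: float = 8.0,
        ci_method: str = "delong",
        n_boot: int = 2000,
        random_state: int | None = None,
    ):
        self.positive_pct = positive_pct
        self.operating_threshold_pct = operating_threshold_pct
        self.ci_method = ci_method
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X, y=None) -> "ChangeDetectionROC":
        """X: sequence of DeltaPair or (n, 2) array of (pct_ref, pct_test)."""
        if self.ci_method not in ("delong", "bootstrap"):
            raise ValueError(f"ci_method must be 'delong' or 'bootstrap', got {self.ci_method!r}")
        pct_ref, scores = _deltas_to_pct(X)
        labels = pct_ref > self.positive_pct
        n_pos, n_neg = int(labels.sum()), int((~labels).sum())
        if n_pos == 0 or n_neg == 0:
            raise DegenerateDataError(
                f"ROC undefined: single-class data (n_pos={n_pos}, n_neg={n_neg} "
                f"under rule pct_ref > {self.positive_pct})"
            )
        self.n_pos_, self.n_neg_ = n_pos, n_neg
        self.labels_, self.scores_ = labels, scores

        auc, var = delong_variance(scores, labels)
        self.auc_ = auc
        se = math.sqrt(var) if var > 0 else 0.0
        self.auc_se_ = se
        if self.ci_method == "delong":
            z = stats.norm.ppf(0.975)
            lo, hi = auc - z * se, auc + z * se
        else:
            rng = np.random.default_rng(self.random_state)
            pos, neg = scores[labels], scores[~labels]
            boots = np.empty(self.n_boot)
            for b in range(self.n_boot):
                bp = rng.choice(pos, size=n_pos, replace=True)
                bn = rng.choice(neg, size=n_neg, replace=True)
                bs = np.concatenate([bp, bn])
                bl = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
                boots[b], _ = delong_variance(bs, bl)
            lo, hi = np.percentile(boots, [2.5, 97.5])
        self.ci_low_ = float(np.clip(lo, 0.0, 1.0))
        self.ci_high_ = float(np.clip(hi, 0.0, 1.0))
        self.p_value_ = (
            float(2.0 * stats.norm.sf(abs(auc - 0.5) / se)) if se > 0
            else (0.0 if auc != 0.5 else 1.0)
        )

        fpr, tpr, thr = _sk_roc_curve(labels, scores)
        self.curve_ = [
            (float(t), 100.0 * float(s), 100.0 * float(1.0 - f))
            for t, s, f in zip(thr, tpr, fpr)
        ]
        j = np.argmax(tpr - fpr)
        self.youden_threshold_ = float(thr[j])

        op = self.operating_point(self.operating_threshold_pct)
        self.sensitivity_pct_ = op["sensitivity_pct"]
        self.specificity_pct_ = op["specificity_pct"]
        return self

    def operating_point(self, threshold: float) -> dict[str, float]:
        """Sensitivity/specificity (%) of the rule pct_test > threshold."""
        called_pos = self.scores_ > threshold
        sens = 100.0 * float((called_pos & self.labels_).sum()) / self.n_pos_
        spec = 100.0 * float((~called_pos & ~self.labels_).sum()) / self.n_neg_
        return {"sensitivity_pct": sens, "specificity_pct": spec}

    def result(self) -> ROCResult:
        """Fitted attributes packaged as a :class:`ROCResult`."""
        return ROCResult(
            auc=self.auc_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            p_value=self.p_value_,
            n_pos=self.n_pos_,
            n_neg=self.n_neg_,
            curve=tuple(self.curve_),
        )


def roc_analysis(
    deltas,
    positive_pct: float = 10.0,
    ci_method: str = "delong",
    random_state: int | None = None,
) -> ROCResult:
    """ROC of pct_test as a detector of pct_ref > positive_pct."""
    return ChangeDetectionROC(
        positive_pct=positive_pct, ci_method=ci_method, random_state=random_state
    ).fit(deltas).result()


def operating_point(deltas, positive_pct: float = 10.0, threshold: float = 8.0) -> dict[str, float]:
    """Sensitivity/specificity (%) of pct_test > threshold for pct_ref > positive_pct."""
    est = ChangeDetectionROC(positive_pct=positive_pct, operating_threshold_pct=threshold).fit(deltas)
    return {"sensitivity_pct": est.sensitivity_pct_, "specificity_pct": est.specificity_pct_}
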