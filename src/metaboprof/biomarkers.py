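"""S-plot construction and jack-knifed confidence intervals for biomarker ions.

The S-plot pairs, for every feature, its *modeled covariance* with the
first predictive OPLS-DA score t1 (magnitude, in intensity*score units)
against its *modeled correlation* with t1 (reliability, dimensionless).
Influential ions occupy the tails: high |covariance| AND high
|correlation|. Statistical reliability of a candidate is judged by a
jack-knifed confidence interval (JKCI) on its covariance, built from
delete-a-fold re-estimates over the cross-validation segments; ions
whose interval includes 0 are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chemometrics import _fit_oplsda_fixed, dummy_code, stratified_folds


@dataclass(frozen=True)
class SplotPoint:
    feature_id: str
    cov: float          # covariance of the feature with t1, (n-1) denominator
    pcorr: float        # correlation with t1; 0 (flagged) for constant features
    zero_variance: bool = False


@dataclass(frozen=True)
class JackknifeInterval:
    feature_id: str
    cov_estimate: float
    se: float
    lo: float
    hi: float

    @property
    def significant(self) -> bool:
        """True iff the interval excludes 0."""
        return self.lo > 0 or self.hi < 0


def splot(t1: np.ndarray, X: np.ndarray,
          feature_ids: list[str] | None = None) -> list[SplotPoint]:
    """Covariance and correlation of every feature with the first predictive score.

    cov_i = t1' x_i / (n-1); pcorr_i = cov_i / (s_t1 * s_xi) with sample
    (n-1) standard deviations. X is expected centered/Pareto-scaled, but
    both quantities are computed on centered columns regardless.
    """
    t1 = np.asarray(t1, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(t1)
    if X.shape[0] != n:
        raise ValueError("t1 length must match X rows")
    if feature_ids is None:
        feature_ids = [str(j) for j in range(X.shape[1])]
    tc = t1 - t1.mean()
    s_t = t1.std(ddof=1)
    if s_t == 0:
        raise ValueError("constant t1 score vector")
    Xc = X - X.mean(axis=0)
    cov = tc @ Xc / (n - 1)
    s_x = X.std(axis=0, ddof=1)
    points = []
    for j, fid in enumerate(feature_ids):
        if s_x[j] == 0:
            points.append(SplotPoint(fid, float(cov[j]), 0.0, zero_variance=True))
        else:
            points.append(SplotPoint(fid, float(cov[j]),
                                     float(cov[j] / (s_t * s_x[j]))))
    return points


def _first_score_cov(X: np.ndarray, Y01: np.ndarray, levels: list,
                     n_pred: int, n_orth: int) -> tuple[np.ndarray, np.ndarray]:
    """Fit OPLS-DA and return (t1, per-feature covariance with t1)."""
    model = _fit_oplsda_fixed(X, Y01, levels, n_pred, n_orth)
    t1 = model.Tp[:, 0]
    tc = t1 - t1.mean()
    Xc = X - X.mean(axis=0)
    return t1, tc @ Xc / (len(t1) - 1)


def jackknife_cov_ci(X: np.ndarray, y, k: int = 7, alpha: float = 0.05,
                     seed: int = 0, n_pred: int = 1, n_orth: int = 0,
                     feature_ids: list[str] | None = None,
                     class_levels: list | None = None
                     ) -> list[JackknifeInterval]:
    """Delete-a-fold jackknife CI on each feature's first-component covariance.

    The OPLS-DA model is refit on each of the k retained subsets; refit t1
    scores are sign-aligned to the full-model t1 by their correlation on
    the retained rows. The CI is the full-data estimate +/-
    ``t(1-alpha/2, k-1) * SE`` with the grouped-jackknife standard error
    ``sqrt((k-1)/k * sum((theta_f - theta_bar)^2))``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if feature_ids is None:
        feature_ids = [str(j) for j in range(X.shape[1])]
    Y01, levels = dummy_code(y, class_levels)
    t1_full, cov_full = _first_score_cov(X, Y01, levels, n_pred, n_orth)
    assign = stratified_folds(y, k, seed)

    cov_folds = np.empty((k, X.shape[1]))
    for fold in range(k):
        keep = assign != fold
        t1_f, cov_f = _first_score_cov(X[keep], Y01[keep], levels,
                                       n_pred, n_orth)
        r = np.corrcoef(t1_f, t1_full[keep])[0, 1]
        if not np.isfinite(r) or abs(r) < 1e-8:
            raise ValueError(
                f"cannot sign-align fold {fold}: refit first score is "
                "orthogonal to the full-model score")
        cov_folds[fold] = cov_f if r > 0 else -cov_f

    theta_bar = cov_folds.mean(axis=0)
    se = np.sqrt((k - 1) / k * ((cov_folds - theta_bar) ** 2).sum(axis=0))
    tcrit = stats.t.ppf(1 - alpha / 2, k - 1)
    out = []
    for j, fid in enumerate(feature_ids):
        est = float(cov_full[j])
        half = float(tcrit * se[j])
        out.append(JackknifeInterval(fid, est, float(se[j]),
                                     est - half, est + half))
    return out


def select_discriminatory(points: list[SplotPoint],
                          intervals: list[JackknifeInterval],
                          min_abs_cov: float | None = None,
                          min_abs_pcorr: float | None = None
                          ) -> list[SplotPoint]:
    """Threshold-and-significance surrogate for manual S-plot tail picking.

    Keeps features with |cov| >= min_abs_cov, |pcorr| >= min_abs_pcorr and
    a jackknife interval excluding 0; thresholds default to the 95th
    percentile of each statistic's absolute value. The result is sorted
    ascending by covariance, so ions elevated in the positive-scoring
    class appear last.
    """
    by_id = {iv.feature_id: iv for iv in intervals}
    missing = [p.feature_id for p in points if p.feature_id not in by_id]
    if missing:
        raise ValueError(f"no jackknife interval for features: {missing[:5]}")
    if min_abs_cov is None:
        min_abs_cov = float(np.percentile([abs(p.cov) for p in points], 95))
    if min_abs_pcorr is None:
        min_abs_pcorr = float(np.percentile([abs(p.pcorr) for p in points], 95))
    if min_abs_cov < 0 or min_abs_pcorr < 0:
        raise ValueError("thresholds must be nonnegative")
    chosen = [p for p in points
              if abs(p.cov) >= min_abs_cov
              and abs(p.pcorr) >= min_abs_pcorr
              and by_id[p.feature_id].significant]
    return sorted(chosen, key=lambda p: p.cov)
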