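"""PCA and OPLS-DA chemometrics with cross-validated fit statistics.

Principal components analysis summarizes the (scaled) intensity matrix X
as ``X = x_bar + T P' + E``. Orthogonal projections to latent structures
discriminant analysis (OPLS-DA) adds a rotation driven by the class
membership matrix Y (dummy-coded), partitioning the modelled X variation
into components *predictive* of class and components *orthogonal* to it:

    X = x_bar + Tp Pp' + To Po' + E,     Y = y_bar + Tp C' + F

Model quality is reported with the usual trinity: R2X(cum) (explained X
variation, split into R2Xp + R2Xo), R2Y(cum) (explained Y variation) and
Q2Y(cum) (Y variation predicted under k-fold cross-validation,
Q2 = 1 - PRESS/SS). Classification uses the predicted dummy-Y response,
normalized to pseudo-probabilities by a softmax; confusion tables are
summarized by their generalized-hypergeometric (Fisher exact) point
probability.

The orthogonal-filtering algorithm is the NIPALS O-PLS sequence:
each orthogonal component is the part of the dominant X loading that is
uncorrelated with Y; it is removed from X before the predictive
components are fitted, so predictive and orthogonal scores are exactly
orthogonal by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, softmax

logger = logging.getLogger(__name__)

_NIPALS_TOL = 1e-12
_NIPALS_MAXIT = 1000


# -- helpers ---------------------------------------------------------------

def _fix_sign(scores: np.ndarray, loadings: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """Fix each component's sign so its largest-magnitude loading is positive."""
    scores = scores.copy()
    loadings = loadings.copy()
    for a in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, a]))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    return scores, loadings


def dummy_code(y, class_levels: list | None = None
               ) -> tuple[np.ndarray, list]:
    """Dummy-code class labels as a 0/1 matrix with one column per class."""
    y = np.asarray(y, dtype=object)
    levels = list(class_levels) if class_levels is not None else list(pd.unique(y))
    unknown = set(y) - set(levels)
    if unknown:
        raise ValueError(f"labels not in class levels: {sorted(map(str, unknown))}")
    Y = np.zeros((len(y), len(levels)))
    for k, lev in enumerate(levels):
        Y[y == lev, k] = 1.0
    return Y, levels


# -- PCA -------------------------------------------------------------------

@dataclass
class PcaModel:
    """PCA fit: mean vector, loadings P, scores T, and explained-variance stats."""

    mean_vector: np.ndarray
    loadings: np.ndarray          # (n_features, A)
    scores: np.ndarray            # (n_obs, A)
    r2x_per_component: np.ndarray
    q2_cum: float | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def r2x_cum(self) -> float:
        return float(self.r2x_per_component.sum())

    def project(self, X_new: np.ndarray) -> np.ndarray:
        return (np.asarray(X_new, dtype=float) - self.mean_vector) @ self.loadings


def fit_pca(X: np.ndarray, n_components: int | str = "auto",
            q2_gain: float = 0.01, k_folds: int = 7, seed: int = 0) -> PcaModel:
    """Fit a PCA model by singular value decomposition of the centered matrix.

    ``n_components="auto"`` adds components while row-wise k-fold
    cross-validated Q2X improves by more than ``q2_gain``.
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    Xc = X - mean
    total_ss = float((Xc ** 2).sum())
    if total_ss == 0:
        raise ValueError("degenerate all-zero (constant) matrix")
    max_a = min(X.shape[0] - 1, X.shape[1])

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if n_components == "auto":
        A = _auto_pca_components(Xc, max_a, q2_gain, k_folds, seed)
    else:
        A = int(n_components)
        if A < 1 or A > max_a:
            raise ValueError(f"n_components must be in [1, {max_a}]")
    T = U[:, :A] * s[:A]
    P = Vt[:A].T
    T, P = _fix_sign(T, P)
    r2x = (s[:A] ** 2) / total_ss
    return PcaModel(mean_vector=mean, loadings=P, scores=T, r2x_per_component=r2x)


def _auto_pca_components(Xc: np.ndarray, max_a: int, q2_gain: float,
                         k: int, seed: int) -> int:
    """Row-held-out CV: rebuild held rows from loadings fit without them."""
    n = Xc.shape[0]
    k = min(k, n)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    ss = float((Xc ** 2).sum())
    best_a, best_q2 = 1, -np.inf
    for a in range(1, max_a + 1):
        press = 0.0
        for held in folds:
            train = np.setdiff1d(order, held)
            _, _, Vt = np.linalg.svd(Xc[train] - Xc[train].mean(0),
                                     full_matrices=False)
            P = Vt[: min(a, len(train) - 1)].T
            H = Xc[held]
            press += float(((H - H @ P @ P.T) ** 2).sum())
        q2 = 1 - press / ss
        if q2 > best_q2 + q2_gain:
            best_a, best_q2 = a, q2
        else:
            break
    return best_a


# -- Hotelling T2 ellipse --------------------------------------------------

@dataclass
class HotellingEllipse:
    semi_axes: tuple[float, float]
    t2_critical: float
    t2_values: np.ndarray
    outliers: np.ndarray       # boolean flags, T2 above critical

    @property
    def orientation(self) -> float:
        """Axis-aligned in score space by construction."""
        return 0.0


def hotelling_ellipse(T: np.ndarray, alpha: float = 0.05) -> HotellingEllipse:
    """95% (by default) Hotelling T-squared confidence ellipse for 2-D scores.

    Semi-axis i is ``s_i * sqrt(2 (n^2-1) / (n (n-2)) * F(1-alpha; 2, n-2))``
    where s_i is the component score standard deviation; observations with
    T2 above the critical value are flagged as potential outliers.
    """
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[1] != 2:
        raise ValueError("T must have exactly 2 score columns")
    n = T.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations")
    s = T.std(axis=0, ddof=1)
    fcrit = stats.f.ppf(1 - alpha, 2, n - 2)
    t2crit = 2 * (n ** 2 - 1) / (n * (n - 2)) * fcrit
    t2 = ((T - T.mean(0)) ** 2 / s ** 2).sum(axis=1)
    return HotellingEllipse(semi_axes=(float(s[0] * np.sqrt(t2crit)),
                                       float(s[1] * np.sqrt(t2crit))),
                            t2_critical=float(t2crit),
                            t2_values=t2, outliers=t2 > t2crit)


# -- PLS2 / OPLS-DA --------------------------------------------------------

def _nipals_pls_component(X: np.ndarray, Y: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One NIPALS PLS2 component: returns (w, t, p, c); w unit-norm."""
    # start u from the Y column with the largest variance
    u = Y[:, np.argmax(Y.var(axis=0))].copy()
    if not u.any():
        u = Y[:, 0].copy()
    t_old = None
    for _ in range(_NIPALS_MAXIT):
        w = X.T @ u / (u @ u)
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("degenerate X: zero weight vector")
        w /= nw
        t = X @ w
        c = Y.T @ t / (t @ t)
        u = Y @ c / (c @ c)
        if t_old is not None and np.linalg.norm(t - t_old) <= _NIPALS_TOL * np.linalg.norm(t):
            break
        t_old = t
    p = X.T @ t / (t @ t)
    return w, t, p, c


@dataclass
class OplsdaModel:
    """Fitted OPLS-DA model with predictive/orthogonal partition and statistics."""

    class_levels: list
    x_mean: np.ndarray
    y_mean: np.ndarray
    # predictive part
    Tp: np.ndarray
    Pp: np.ndarray
    Wp: np.ndarray                # weights on the orthogonal-deflated X
    C: np.ndarray                 # dummy-Y loadings (K, n_pred)
    # orthogonal part (possibly 0 columns)
    To: np.ndarray
    Po: np.ndarray
    Wo: np.ndarray
    # statistics
    r2x_p: float = 0.0
    r2x_o: float = 0.0
    r2y_cum: float = 0.0
    q2y_cum: float | None = None

    @property
    def n_pred(self) -> int:
        return self.Tp.shape[1]

    @property
    def n_orth(self) -> int:
        return self.To.shape[1]

    @property
    def r2x_cum(self) -> float:
        return self.r2x_p + self.r2x_o

    # -- projection -------------------------------------------------------
    def _remove_orthogonal(self, Xc: np.ndarray) -> np.ndarray:
        Xd = Xc.copy()
        for a in range(self.n_orth):
            t_o = Xd @ self.Wo[:, a]
            Xd -= np.outer(t_o, self.Po[:, a])
        return Xd

    def transform(self, X_new: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
        """Project new (already scaled) observations to (Tp, To) scores."""
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim != 2 or X_new.shape[1] != len(self.x_mean):
            raise ValueError("feature dimension mismatch with training table")
        Xc = X_new - self.x_mean
        To_new = np.empty((Xc.shape[0], self.n_orth))
        Xd = Xc.copy()
        for a in range(self.n_orth):
            t_o = Xd @ self.Wo[:, a]
            To_new[:, a] = t_o
            Xd -= np.outer(t_o, self.Po[:, a])
        Tp_new = np.empty((Xc.shape[0], self.n_pred))
        for a in range(self.n_pred):
            t = Xd @ self.Wp[:, a]
            Tp_new[:, a] = t
            Xd -= np.outer(t, self.Pp[:, a])
        return Tp_new, To_new

    def predict_response(self, X_new: np.ndarray) -> np.ndarray:
        """Predicted dummy-Y matrix (uncentered scale) for scaled X_new."""
        Tp_new, _ = self.transform(X_new)
        return Tp_new @ self.C.T + self.y_mean


def fit_oplsda(X: np.ndarray, y, n_pred: int | str = "auto",
               n_orth: int | str = "auto", k_folds: int = 7, seed: int = 0,
               q2_gain: float = 0.01, class_levels: list | None = None,
               _with_cv: bool = True) -> OplsdaModel:
    """Fit an OPLS-DA model on a scaled matrix X against class labels y.

    Y is dummy-coded (one column per class) and column-centered.
    Orthogonal components are extracted and deflated sequentially before
    the predictive components are fitted. With ``"auto"`` counts, the
    model grows while k-fold cross-validated Q2Y(cum) improves by more
    than ``q2_gain``; predictive components are capped at K - 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if X.shape[0] != len(y):
        raise ValueError("X rows must match y length")
    Y01, levels = dummy_code(y, class_levels)
    if len(levels) < 2:
        raise ValueError("need at least 2 classes")
    counts = Y01.sum(axis=0)
    if (counts < 2).any():
        small = [lev for lev, c in zip(levels, counts) if c < 2]
        raise ValueError(f"classes with fewer than 2 members: {small}")

    max_pred = len(levels) - 1
    if n_pred == "auto" or n_orth == "auto":
        n_pred, n_orth = _auto_components(X, y, levels, max_pred, k_folds,
                                          seed, q2_gain)
    n_pred, n_orth = int(n_pred), int(n_orth)
    if not 1 <= n_pred <= max_pred:
        raise ValueError(f"n_pred must be in [1, {max_pred}] for {len(levels)} classes")

    model = _fit_oplsda_fixed(X, Y01, levels, n_pred, n_orth)
    if _with_cv:
        cv = cross_validate(X, y, k=k_folds, seed=seed, n_pred=n_pred,
                            n_orth=n_orth, class_levels=levels)
        model.q2y_cum = cv.q2_cum
    return model


def _fit_oplsda_fixed(X: np.ndarray, Y01: np.ndarray, levels: list,
                      n_pred: int, n_orth: int) -> OplsdaModel:
    x_mean = X.mean(axis=0)
    y_mean = Y01.mean(axis=0)
    Xc = X - x_mean
    Yc = Y01 - y_mean
    ssx = float((Xc ** 2).sum())
    ssy = float((Yc ** 2).sum())
    if ssx == 0:
        raise ValueError("degenerate constant X")

    n, m = Xc.shape
    Wo = np.zeros((m, n_orth))
    Po = np.zeros((m, n_orth))
    To = np.zeros((n, n_orth))
    Xd = Xc.copy()
    for a in range(n_orth):
        w, t, p, c = _nipals_pls_component(Xd, Yc)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            # no Y-orthogonal variation left; stop extracting
            Wo, Po, To = Wo[:, :a], Po[:, :a], To[:, :a]
            break
        w_o /= norm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Wo[:, a], Po[:, a], To[:, a] = w_o, p_o, t_o
        Xd -= np.outer(t_o, p_o)
    n_orth = To.shape[1]

    Wp = np.zeros((m, n_pred))
    Pp = np.zeros((m, n_pred))
    Tp = np.zeros((n, n_pred))
    C = np.zeros((Yc.shape[1], n_pred))
    Xp = Xd.copy()
    Yd = Yc.copy()
    for a in range(n_pred):
        w, t, p, c = _nipals_pls_component(Xp, Yd)
        Wp[:, a], Pp[:, a], Tp[:, a], C[:, a] = w, p, t, c
        Xp -= np.outer(t, p)
        Yd -= np.outer(t, c)

    # sign convention: largest-magnitude predictive loading positive
    for a in range(n_pred):
        j = np.argmax(np.abs(Pp[:, a]))
        if Pp[j, a] < 0:
            Pp[:, a] *= -1
            Wp[:, a] *= -1
            Tp[:, a] *= -1
            C[:, a] *= -1
    for a in range(n_orth):
        j = np.argmax(np.abs(Po[:, a]))
        if Po[j, a] < 0:
            Po[:, a] *= -1
            Wo[:, a] *= -1
            To[:, a] *= -1

    r2x_p = float(sum((Tp[:, a] @ Tp[:, a]) * (Pp[:, a] @ Pp[:, a])
                      for a in range(n_pred))) / ssx
    r2x_o = float(sum((To[:, a] @ To[:, a]) * (Po[:, a] @ Po[:, a])
                      for a in range(n_orth))) / ssx
    Yhat = Tp @ C.T
    r2y = 1.0 - float(((Yc - Yhat) ** 2).sum()) / ssy

    return OplsdaModel(class_levels=levels, x_mean=x_mean, y_mean=y_mean,
                       Tp=Tp, Pp=Pp, Wp=Wp, C=C, To=To, Po=Po, Wo=Wo,
                       r2x_p=r2x_p, r2x_o=r2x_o, r2y_cum=r2y)


def _auto_components(X, y, levels, max_pred, k, seed, q2_gain,
                     max_orth: int = 5) -> tuple[int, int]:
    """Grow (n_pred, n_orth) greedily while CV Q2Y(cum) gains exceed q2_gain."""
    best = (1, 0)
    best_q2 = cross_validate(X, y, k=k, seed=seed, n_pred=1, n_orth=0,
                             class_levels=levels).q2_cum
    improved = True
    while improved:
        improved = False
        for cand in ((best[0] + 1, best[1]), (best[0], best[1] + 1)):
            if cand[0] > max_pred or cand[1] > max_orth:
                continue
            try:
                q2 = cross_validate(X, y, k=k, seed=seed, n_pred=cand[0],
                                    n_orth=cand[1], class_levels=levels).q2_cum
            except ValueError:
                continue
            if q2 > best_q2 + q2_gain:
                best, best_q2 = cand, q2
                improved = True
                break
    return best


# -- cross-validation ------------------------------------------------------

@dataclass
class CvResult:
    """k-fold cross-validation summary for an OPLS-DA model."""

    n_folds: int
    press_per_component: np.ndarray   # cumulative PRESS at 1..A pred components
    ss_y: float
    q2_per_component: np.ndarray
    q2_cum: float
    fold_assignment: np.ndarray
    seed: int


def stratified_folds(y, k: int, seed: int) -> np.ndarray:
    """Seeded stratified fold assignment; every class present in every train split."""
    y = np.asarray(y, dtype=object)
    if k < 2 or k > len(y):
        raise ValueError("folds must be in [2, n_obs]")
    rng = np.random.default_rng(seed)
    assign = np.empty(len(y), dtype=int)
    start = 0
    for lev in pd.unique(y):
        idx = np.flatnonzero(y == lev)
        if len(idx) < 2:
            raise ValueError(
                f"class {lev!r} has {len(idx)} member(s); needs >= 2 so every "
                "training split contains it — reduce folds or merge classes")
        idx = rng.permutation(idx)
        # round-robin with a rotating start keeps folds balanced even when a
        # class has fewer members than folds (it then spans min(size, k)
        # folds, so each training split of k-1 folds still contains it)
        assign[idx] = (start + np.arange(len(idx))) % k
        start += len(idx)
    return assign


def cross_validate(X: np.ndarray, y, k: int = 7, seed: int = 0,
                   n_pred: int = 1, n_orth: int = 0,
                   class_levels: list | None = None) -> CvResult:
    """Stratified k-fold CV of an OPLS-DA model: Q2Y(cum) = 1 - PRESS/SS.

    PRESS is accumulated over held-out centered dummy-Y predictions; SS is
    the total centered sum of squares of the dummy Y. Deterministic for a
    fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    Y01, levels = dummy_code(y, class_levels)
    y_mean = Y01.mean(axis=0)
    Yc = Y01 - y_mean
    ssy = float((Yc ** 2).sum())
    assign = stratified_folds(y, k, seed)

    press = np.zeros(n_pred)
    for fold in range(k):
        held = assign == fold
        train = ~held
        model = _fit_oplsda_fixed(X[train], Y01[train], levels, n_pred, n_orth)
        Tp_new, _ = model.transform(X[held])
        for a in range(1, n_pred + 1):
            Yhat = Tp_new[:, :a] @ model.C[:, :a].T + model.y_mean
            press[a - 1] += float(((Y01[held] - Yhat) ** 2).sum())
    q2 = 1.0 - press / ssy
    return CvResult(n_folds=k, press_per_component=press, ss_y=ssy,
                    q2_per_component=q2, q2_cum=float(q2[-1]),
                    fold_assignment=assign, seed=seed)


# -- classification & confusion tables -------------------------------------

def classify(model: OplsdaModel, X_new: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    """Assign classes to scaled observations from the predicted dummy response.

    Per-class scores are the softmax of the predicted dummy-Y vector
    ("modeled probability" surrogate); the predicted class is the argmax,
    ties broken by class order with a warning.
    """
    Yhat = model.predict_response(X_new)
    probs = softmax(Yhat, axis=1)
    pred_idx = np.argmax(probs, axis=1)
    ties = (probs == probs.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.warning("%d observation(s) had tied class scores; "
                       "ties broken by class order", int(ties.sum()))
    pred = np.array([model.class_levels[i] for i in pred_idx], dtype=object)
    return pred, probs


@dataclass
class ConfusionTable:
    """K x K counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_levels: list

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / float(self.counts.sum())

    @property
    def n_misclassified(self) -> int:
        return int(self.counts.sum() - np.trace(self.counts))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_levels,
                            columns=self.class_levels)


def misclassification_table(true, pred, class_levels: list | None = None
                            ) -> ConfusionTable:
    """Cross-tabulate true vs predicted labels."""
    true = np.asarray(true, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if len(true) != len(pred):
        raise ValueError("true and pred must have equal length")
    levels = list(class_levels) if class_levels is not None else list(pd.unique(true))
    unseen = set(pred) - set(levels)
    if unseen:
        raise ValueError(f"predicted labels unseen in truth: {sorted(map(str, unseen))}")
    K = len(levels)
    lut = {lev: i for i, lev in enumerate(levels)}
    counts = np.zeros((K, K), dtype=int)
    for t, p in zip(true, pred):
        counts[lut[t], lut[p]] += 1
    return ConfusionTable(counts=counts, class_levels=levels)


def fisher_exact_probability(table: ConfusionTable | np.ndarray) -> float:
    """Generalized hypergeometric point probability of a contingency table.

    With margins fixed, the probability of observing exactly this table is
    ``prod(row_sums!) * prod(col_sums!) / (N! * prod(cells!))``; computed
    in log space via lgamma so large tables cannot overflow. A 1x1 table
    has probability 1.
    """
    counts = table.counts if isinstance(table, ConfusionTable) else np.asarray(table)
    counts = np.asarray(counts)
    if counts.size == 0 or counts.sum() < 1:
        raise ValueError("table must contain at least one observation")
    if (counts < 0).any() or not np.issubdtype(counts.dtype, np.integer):
        counts_f = np.asarray(counts, dtype=float)
        if (counts_f < 0).any() or not np.allclose(counts_f, np.round(counts_f)):
            raise ValueError("table entries must be nonnegative integers")
        counts = np.round(counts_f).astype(int)
    n = counts.sum()
    logp = (gammaln(counts.sum(axis=1) + 1).sum()
            + gammaln(counts.sum(axis=0) + 1).sum()
            - gammaln(n + 1) - gammaln(counts + 1).sum())
    return float(np.exp(logp))


def model_summary_row(name: str, model: OplsdaModel,
                      n_misclassified: int) -> dict:
    """One row of the tab-separated model summary table."""
    return {
        "Model": name,
        "R2Xp": round(model.r2x_p, 4),
        "R2Xo": round(model.r2x_o, 4),
        "R2X(cum)": round(model.r2x_cum, 4),
        "R2Y(cum)": round(model.r2y_cum, 4),
        "Q2Y(cum)": None if model.q2y_cum is None else round(model.q2y_cum, 4),
        "Wheat Lines Misclassified": n_misclassified,
    }
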