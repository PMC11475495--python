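"""Survival statistics: Kaplan-Meier, log-rank, Harrell's C, AUC, stratification.

All estimators take raw ``(time, event)`` arrays (or a
:class:`~gatsurv.cohort.SurvivalOutcome`); censored subjects remain in the
risk set at their censoring time.  The per-time internals (n_i, d_i, O/E/V
columns) are exposed on the result objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score

from .cohort import MultiOmicsDataset, SurvivalOutcome
from .coxph import RidgeCoxResult, ridge_cox_fit
from .exceptions import ConfigurationError
from .screening import screen_features


def _as_time_event(outcome, event=None):
    if isinstance(outcome, SurvivalOutcome):
        return outcome.time, outcome.event
    return np.asarray(outcome, dtype=float), np.asarray(event, dtype=int)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""

    event_times: np.ndarray  # sorted distinct times with >= 1 event
    at_risk: np.ndarray  # n_i just before each event time
    events: np.ndarray  # d_i
    survival: np.ndarray  # S(t_i)

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation; S = 1 before the first event time."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.event_times.size == 0:  # no events observed anywhere
            return np.ones_like(t)
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_risk": self.at_risk,
                "n_event": self.events,
                "survival": self.survival,
            }
        )


def kaplan_meier(outcome, event=None) -> KMCurve:
    """Kaplan-Meier estimator; accepts a SurvivalOutcome or (time, event)."""
    time, ev = _as_time_event(outcome, event)
    if len(time) < 1:
        raise ConfigurationError("need at least one subject")
    if np.any(time < 0):
        raise ConfigurationError("negative survival times")
    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], ev[order]
    n = len(t_s)
    # distinct times with events; n_i counts everyone with t >= t_i
    uniq, first = np.unique(t_s, return_index=True)
    at_risk = n - first
    d = np.array([e_s[t_s == t].sum() for t in uniq])
    keep = d > 0
    uniq, at_risk, d = uniq[keep], at_risk[keep], d[keep]
    surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(uniq, at_risk, d, surv)


@dataclass(frozen=True)
class LogRankResult:
    """Log-rank chi-square: (sum(O_i1 - E_i1))^2 / sum(V_i1) for two groups."""

    statistic: float
    p_value: float
    df: int
    table: Optional[pd.DataFrame] = field(default=None, compare=False)


def log_rank_test(time, event, group) -> LogRankResult:
    """Log-rank test across two or more groups.

    For two groups the statistic is the classical
    ``(sum(O - E))^2 / sum(V)`` with hypergeometric expectations and
    variances per event time (the per-time O/E/V table is attached).  For
    more than two groups the standard k-sample quadratic form is used with
    df = k - 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) < 2:
        raise ConfigurationError("need at least two groups")
    for g in labels:
        if (group == g).sum() == 0:
            raise ConfigurationError(f"group {g!r} is empty")
    if event.sum() == 0:
        raise ConfigurationError("need at least one event overall")

    event_times = np.unique(time[event == 1])
    k = len(labels)
    O = np.zeros((len(event_times), k))
    E = np.zeros((len(event_times), k))
    n_at = np.zeros((len(event_times), k))
    V1 = np.zeros(len(event_times))  # variance of group-0 event count (2-group)
    cov = np.zeros((len(event_times), k, k))
    for i, t in enumerate(event_times):
        at_risk = time >= t
        N = at_risk.sum()
        d = int(((time == t) & (event == 1)).sum())
        for a, g in enumerate(labels):
            n_g = int((at_risk & (group == g)).sum())
            n_at[i, a] = n_g
            O[i, a] = int(((time == t) & (event == 1) & (group == g)).sum())
            E[i, a] = d * n_g / N
        if N > 1:
            hyper = d * (N - d) / (N - 1)
            for a in range(k):
                for b in range(k):
                    if a == b:
                        cov[i, a, b] = hyper * n_at[i, a] * (N - n_at[i, a]) / N**2
                    else:
                        cov[i, a, b] = -hyper * n_at[i, a] * n_at[i, b] / N**2
            V1[i] = cov[i, 0, 0]

    if k == 2:
        num = float((O[:, 0] - E[:, 0]).sum()) ** 2
        den = float(V1.sum())
        statistic = num / den if den > 0 else 0.0
        table = pd.DataFrame(
            {
                "time": event_times,
                "O1": O[:, 0],
                "E1": E[:, 0],
                "V1": V1,
            }
        )
    else:
        z = (O - E).sum(axis=0)[: k - 1]
        Sigma = cov.sum(axis=0)[: k - 1, : k - 1]
        statistic = float(z @ np.linalg.solve(Sigma, z))
        table = None
    df = k - 1
    return LogRankResult(statistic, float(sps.chi2.sf(statistic, df)), df, table)


def concordance_index(risk, outcome, event=None) -> float:
    """Harrell's C: fraction of comparable pairs ranked correctly by risk.

    A pair is comparable when the earlier time carries an event, or when the
    times are tied and exactly one subject has an event (the event subject
    should then have the higher risk — Harrell's convention).  Tied risks on
    comparable pairs count 0.5.
    """
    risk = np.asarray(risk, dtype=float)
    time, ev = _as_time_event(outcome, event)
    n = len(risk)
    ti = time[:, None]
    tj = time[None, :]
    ri = risk[:, None]
    rj = risk[None, :]
    ei = ev[:, None].astype(bool)
    ej = ev[None, :].astype(bool)
    # i is the earlier subject with an event
    comparable = ((ti < tj) & ei) | ((ti == tj) & ei & ~ej)
    concordant = (ri > rj) & comparable
    tied = (ri == rj) & comparable
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ConfigurationError("no comparable pairs under censoring")
    return float((concordant.sum() + 0.5 * tied.sum()) / n_comp)


def roc_auc(score, label) -> float:
    """Mann-Whitney AUC of a score against a binary label (ties at 0.5)."""
    label = np.asarray(label, dtype=int)
    if len(np.unique(label)) < 2:
        raise ConfigurationError("both labels must be present")
    return float(roc_auc_score(label, np.asarray(score, dtype=float)))


def accuracy_at_median(score, label) -> float:
    """Accuracy of the median-score threshold (score > median predicts 1)."""
    score = np.asarray(score, dtype=float)
    label = np.asarray(label, dtype=int)
    if len(np.unique(label)) < 2:
        raise ConfigurationError("both labels must be present")
    pred = (score > np.median(score)).astype(int)
    return float((pred == label).mean())


@dataclass(frozen=True)
class StratifyResult:
    """Median-risk stratification: per-group KM curves, log-rank, C-index."""

    km_high: KMCurve
    km_low: KMCurve
    log_rank: LogRankResult
    c_index: float
    risk_scores: np.ndarray
    high_mask: np.ndarray
    cox_model: RidgeCoxResult
    n_components: int
    n_selected: int


def _drop_correlated(X: np.ndarray, threshold: float = 0.9) -> np.ndarray:
    """Greedily drop one column of each pair with |r| > threshold; returns kept indices."""
    if X.shape[1] < 2:
        return np.arange(X.shape[1])
    corr = np.corrcoef(X, rowvar=False)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    keep: list[int] = []
    for j in range(X.shape[1]):
        if all(abs(corr[j, k]) <= threshold for k in keep):
            keep.append(j)
    return np.asarray(keep, dtype=int)


def stratify_km(
    dataset: MultiOmicsDataset,
    blocks=("mrna", "mirna", "meth"),
    screen: bool = True,
    alpha: float = 0.05,
    variance_retained: float = 0.95,
    corr_drop_threshold: float = 0.9,
    l2_penalty: float = 0.1,
) -> StratifyResult:
    """Exploratory risk stratification of a cohort.

    Pipeline: z-score -> PCA retaining ``variance_retained`` of the variance
    -> drop one of each component pair with |r| > ``corr_drop_threshold``
    (inert for exact PCA scores, kept as a guard for other reductions) ->
    optional chi-square screen of the components against vital status ->
    ridge Cox risk score -> median-risk split -> KM per group, log-rank test
    and the C-index of the risk score.  ``screen=False`` reproduces the
    before-selection comparison.
    """
    blocks = [b for b in blocks if b in dataset.blocks]
    cols = np.nonzero(np.isin(dataset.feature_block, blocks))[0]
    if cols.size == 0:
        raise ConfigurationError("no features in the requested blocks")
    X = dataset.X[:, cols]
    sd = X.std(axis=0)
    Xz = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    n_comp = min(Xz.shape[0] - 1, Xz.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=0)
    scores = pca.fit_transform(Xz)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, variance_retained) + 1)
    scores = scores[:, :n_keep]

    kept = _drop_correlated(scores, corr_drop_threshold)
    scores = scores[:, kept]

    n_selected = scores.shape[1]
    if screen:
        sel = screen_features(scores, dataset.outcome.event, alpha=alpha)
        if len(sel) == 0:
            import warnings

            warnings.warn("chi-square screen kept no components; using all")
        else:
            scores = scores[:, sel.indices]
            n_selected = len(sel)

    model = ridge_cox_fit(scores, dataset.outcome.time, dataset.outcome.event,
                          l2_penalty=l2_penalty)
    risk = model.risk_score(scores)
    high = risk > np.median(risk)
    km_high = kaplan_meier(dataset.outcome.time[high], dataset.outcome.event[high])
    km_low = kaplan_meier(dataset.outcome.time[~high], dataset.outcome.event[~high])
    lr = log_rank_test(dataset.outcome.time, dataset.outcome.event, high.astype(int))
    c = concordance_index(risk, dataset.outcome)
    return StratifyResult(
        km_high=km_high,
        km_low=km_low,
        log_rank=lr,
        c_index=c,
        risk_scores=risk,
        high_mask=high,
        cox_model=model,
        n_components=n_keep,
        n_selected=n_selected,
    )


def plot_km(result: StratifyResult, ax=None, time_unit: str = "days"):
    """Step plot of the high- vs low-risk Kaplan-Meier curves."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for curve, label, color in (
        (result.km_low, "low risk", "tab:blue"),
        (result.km_high, "high risk", "tab:red"),
    ):
        t = np.concatenate([[0.0], curve.event_times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=label, color=color)
    ax.set_xlabel(f"time ({time_unit})")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    ax.set_title(f"log-rank p = {result.log_rank.p_value:.2e}, C = {result.c_index:.3f}")
    return ax
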