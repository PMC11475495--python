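"""Chi-square screening of median-binarized features against vital status.

Each feature is binarized at its own median (strictly greater -> 1, ties -> 0),
cross-tabulated against the event indicator (Dead = 1 / Alive = 0), and tested
with the plain Pearson chi-square statistic

    chi2 = sum_i (O_i - E_i)^2 / E_i,     E_i = R_i * C_i / N,
    df = (r - 1)(c - 1),

without continuity correction.  Features with p strictly below ``alpha``
(default 0.05) are retained; tables with a zero row or column margin are
degenerate (expected counts undefined) and are never retained.  No
multiple-testing adjustment is applied by default, matching a raw per-feature
p < 0.05 screen; a Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MultiOmicsDataset
from .exceptions import ConfigurationError, DegenerateTableError


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c table of observed counts with its margins."""

    observed: np.ndarray

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, dtype=float)
        object.__setattr__(self, "observed", obs)
        if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
            raise ConfigurationError("contingency table must be at least 2 x 2")
        if np.any(obs < 0) or np.any(~np.isfinite(obs)):
            raise ConfigurationError("observed counts must be finite and non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.observed.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.observed.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.observed.sum())

    @property
    def expected(self) -> np.ndarray:
        return np.outer(self.row_totals, self.col_totals) / self.grand_total


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class SelectedFeatures:
    """Retained feature indices with their p-values and the screening threshold."""

    indices: np.ndarray
    p_values: np.ndarray
    alpha: float
    statistics: np.ndarray
    all_p_values: np.ndarray  # NaN where the table was degenerate

    def __len__(self) -> int:
        return len(self.indices)

    def summary(self, feature_block: np.ndarray | None = None) -> pd.DataFrame:
        """Per-block screen summary: tested / selected counts and the min/max
        p-value among the selected features (the shape of a screen report)."""
        blocks = (
            feature_block[self.indices]
            if feature_block is not None
            else np.array(["all"] * len(self.indices))
        )
        all_blocks = feature_block if feature_block is not None else np.array(
            ["all"] * len(self.all_p_values)
        )
        rows = []
        for b in pd.unique(all_blocks):
            tested = int(np.isfinite(self.all_p_values[all_blocks == b]).sum())
            if tested == 0:  # block was outside the screen (or all degenerate)
                continue
            sel_p = self.p_values[blocks == b]
            rows.append(
                {
                    "block": b,
                    "n_tested": tested,
                    "n_selected": len(sel_p),
                    "min_p": float(sel_p.min()) if len(sel_p) else np.nan,
                    "max_p": float(sel_p.max()) if len(sel_p) else np.nan,
                }
            )
        return pd.DataFrame(rows)


def median_binarize(values: np.ndarray) -> np.ndarray:
    """1 where the value strictly exceeds the vector's median, else 0."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ConfigurationError("cannot binarize an empty vector")
    if not np.all(np.isfinite(values)):
        raise ConfigurationError("cannot binarize non-finite values")
    return (values > np.median(values)).astype(int)


def chi_square_test(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction."""
    if np.any(table.row_totals == 0) or np.any(table.col_totals == 0):
        raise DegenerateTableError("zero row or column margin: expected counts undefined")
    expected = table.expected
    statistic = float(((table.observed - expected) ** 2 / expected).sum())
    r, c = table.observed.shape
    df = (r - 1) * (c - 1)
    return ChiSquareResult(statistic, df, float(stats.chi2.sf(statistic, df)))


def _chi2_2xk_vectorized(binary: np.ndarray, labels: np.ndarray):
    """Per-column 2x2 chi-square of a 0/1 matrix against a 0/1 label vector.

    Returns (statistic, p, degenerate) arrays; degenerate columns get NaN.
    """
    n = binary.shape[0]
    n1 = float(labels.sum())
    n0 = n - n1
    a = binary.T @ labels  # feature=1 & label=1
    b = binary.sum(axis=0) - a  # feature=1 & label=0
    c = n1 - a
    d = n0 - b
    row1 = a + b
    row0 = c + d
    degenerate = (row1 == 0) | (row0 == 0) | (n1 == 0) | (n0 == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (a * d - b * c) ** 2 / (row1 * row0 * n1 * n0)
    stat = np.where(degenerate, np.nan, stat)
    p = np.where(degenerate, np.nan, stats.chi2.sf(stat, 1))
    return stat, p, degenerate


def screen_features(
    dataset: MultiOmicsDataset | np.ndarray,
    event: np.ndarray | None = None,
    alpha: float = 0.05,
    blocks=None,
    sample_mask: np.ndarray | None = None,
    adjust: str = "none",
) -> SelectedFeatures:
    """Screen every feature against the vital-status label.

    Parameters
    ----------
    dataset : MultiOmicsDataset or 2-d array
        When a dataset is given the event labels come from its outcome.
    event : array, optional
        Binary labels (required when ``dataset`` is a bare matrix).
    alpha : float
        Strict selection threshold (p < alpha).
    blocks : iterable, optional
        Restrict the screen to these blocks (dataset input only); indices
        returned still refer to the full matrix.
    sample_mask : boolean array, optional
        Screen on a subset of samples (e.g. the training fold) only.
    adjust : {"none", "bh"}
        Optional Benjamini-Hochberg adjustment before thresholding.
    """
    if isinstance(dataset, MultiOmicsDataset):
        X = dataset.X
        event = dataset.outcome.event if event is None else np.asarray(event)
        col_pool = (
            np.nonzero(np.isin(dataset.feature_block, list(blocks)))[0]
            if blocks is not None
            else np.arange(X.shape[1])
        )
    else:
        X = np.asarray(dataset, dtype=float)
        if event is None:
            raise ConfigurationError("event labels are required with a bare matrix")
        event = np.asarray(event)
        col_pool = np.arange(X.shape[1])
    if sample_mask is not None:
        X = X[sample_mask]
        event = event[sample_mask]
    if not np.isin(event, (0, 1)).all():
        raise ConfigurationError("event labels must be binary")
    if min((event == 0).sum(), (event == 1).sum()) < 2:
        raise ConfigurationError("need at least 2 samples per vital-status label")

    sub = X[:, col_pool]
    binary = (sub > np.median(sub, axis=0, keepdims=True)).astype(float)
    stat, p, degenerate = _chi2_2xk_vectorized(binary, event.astype(float))

    p_for_threshold = p.copy()
    if adjust == "bh":
        ok = ~degenerate
        m = int(ok.sum())
        if m:
            order = np.argsort(p[ok])
            ranked = p[ok][order] * m / (np.arange(m) + 1)
            adj = np.minimum.accumulate(ranked[::-1])[::-1]
            tmp = np.full(m, np.nan)
            tmp[order] = np.minimum(adj, 1.0)
            p_for_threshold[ok] = tmp
    elif adjust != "none":
        raise ConfigurationError(f"unknown adjustment {adjust!r}")

    with np.errstate(invalid="ignore"):
        keep = ~degenerate & (p_for_threshold < alpha)
    if degenerate.all():
        warnings.warn("all features produced degenerate tables; nothing selected")

    all_p = np.full(X.shape[1], np.nan)
    all_p[col_pool] = p
    all_stat = np.full(X.shape[1], np.nan)
    all_stat[col_pool] = stat
    sel = col_pool[keep]
    return SelectedFeatures(
        indices=sel,
        p_values=all_p[sel],
        alpha=alpha,
        statistics=all_stat[sel],
        all_p_values=all_p,
    )
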