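"""Synthetic multi-omics survival cohorts with known ground truth.

The generator emulates the *output* of a preprocessed TCGA-style NSCLC cohort:
block-structured feature matrices (non-negative expression-like values for the
mRNA/miRNA blocks, [0, 1] beta values for the methylation block, 11 mixed-type
clinical covariates), a proportional-hazards survival time driven by a small
set of informative features, independent right censoring calibrated to a
target fraction, class imbalance between deceased and alive patients, and
correlated sample clusters so that a 0.7 correlation threshold yields a
non-trivial patient graph.

Informative features within each omics block load, with mixed signs, on a
shared per-block latent risk factor (co-regulated "risk module"); their raw
values are monotone transforms of a latent Gaussian field, and the hazard's
linear predictor is defined on the z-scored feature matrix, so the stored
ground-truth coefficients refer to the columns downstream code actually sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy import stats
from scipy.special import ndtr

from .exceptions import ConfigurationError

#: canonical block order; generation and column layout never depend on dict order
BLOCK_ORDER = ("mrna", "mirna", "meth", "clinical")
OMICS_BLOCKS = ("mrna", "mirna", "meth")

#: names of the 11 clinical covariates (numeric-coded; see pipeline.encode_clinical)
CLINICAL_FEATURES = (
    "gender",
    "age",
    "prior_malignancy",
    "synchronous_malignancy",
    "prior_treatment",
    "primary_diagnosis",
    "t_stage",
    "n_stage",
    "m_stage",
    "tissue_organ",
    "pack_years",
)


@dataclass(frozen=True)
class SurvivalOutcome:
    """Right-censored survival outcome: observed time and event indicator.

    ``event == 1`` means the death was observed; ``event == 0`` means the
    subject was censored at ``time``.  The time unit is abstract (label
    ``days`` by default); every downstream computation is unit-agnostic.
    """

    time: np.ndarray
    event: np.ndarray
    time_unit: str = "days"

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", np.asarray(event, dtype=int))
        if time.ndim != 1 or event.ndim != 1 or time.shape != event.shape:
            raise ConfigurationError("time and event must be 1-d arrays of equal length")
        if np.any(~np.isfinite(time)) or np.any(time < 0):
            raise ConfigurationError("survival times must be finite and non-negative")
        if not np.isin(self.event, (0, 1)).all():
            raise ConfigurationError("event indicator must be 0 (censored) or 1 (death)")

    def __len__(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx) -> "SurvivalOutcome":
        return SurvivalOutcome(self.time[idx], self.event[idx], self.time_unit)


@dataclass(frozen=True)
class GroundTruth:
    """Indices (into the merged matrix) and z-scale coefficients of informative features."""

    indices: np.ndarray
    beta: np.ndarray

    def block_indices(self, feature_block: np.ndarray, block: str) -> np.ndarray:
        mask = feature_block[self.indices] == block
        return self.indices[mask]


@dataclass
class MultiOmicsDataset:
    """Merged samples x features matrix with block labels and survival outcome."""

    sample_ids: np.ndarray
    feature_ids: np.ndarray
    feature_block: np.ndarray
    X: np.ndarray
    outcome: SurvivalOutcome
    truth: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        self.feature_ids = np.asarray(self.feature_ids, dtype=str)
        self.feature_block = np.asarray(self.feature_block, dtype=str)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ConfigurationError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if self.feature_block.shape != self.feature_ids.shape:
            raise ConfigurationError("feature_block must align with feature_ids")
        if len(np.unique(self.sample_ids)) != len(self.sample_ids):
            raise ConfigurationError("duplicate sample_ids")
        if len(np.unique(self.feature_ids)) != len(self.feature_ids):
            raise ConfigurationError("duplicate feature_ids")
        if not np.all(np.isfinite(self.X)):
            raise ConfigurationError("feature matrix contains non-finite entries")
        if len(self.outcome) != len(self.sample_ids):
            raise ConfigurationError("outcome length does not match sample count")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def blocks(self) -> tuple:
        present = set(self.feature_block)
        return tuple(b for b in BLOCK_ORDER if b in present)

    def block_columns(self, block: str) -> np.ndarray:
        """Column indices of one block, in matrix order."""
        return np.nonzero(self.feature_block == block)[0]

    def subset_blocks(self, blocks) -> "MultiOmicsDataset":
        """Dataset restricted to a subset of blocks (canonical column order kept)."""
        blocks = set(blocks)
        unknown = blocks - set(BLOCK_ORDER)
        if unknown:
            raise ConfigurationError(f"unknown blocks: {sorted(unknown)}")
        cols = np.nonzero(np.isin(self.feature_block, list(blocks)))[0]
        truth = None
        if self.truth is not None:
            keep = np.isin(self.truth.indices, cols)
            remap = {c: i for i, c in enumerate(cols)}
            truth = GroundTruth(
                indices=np.array([remap[c] for c in self.truth.indices[keep]], dtype=int),
                beta=self.truth.beta[keep],
            )
        return MultiOmicsDataset(
            sample_ids=self.sample_ids,
            feature_ids=self.feature_ids[cols],
            feature_block=self.feature_block[cols],
            X=self.X[:, cols],
            outcome=self.outcome,
            truth=truth,
        )


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the package's reference design: n = 600 patients,
    2,000 features across four blocks, 50 informative omics features with
    |beta| in [0.5, 1], a baseline hazard of 0.01 events per day and ~30%
    right censoring, six correlated patient clusters.
    """

    n_samples: int = 600
    block_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"mrna": 1000, "mirna": 200, "meth": 789, "clinical": 11}
    )
    n_informative: Mapping[str, int] = field(
        default_factory=lambda: {"mrna": 20, "mirna": 10, "meth": 20}
    )
    effect_sizes: tuple = (0.5, 1.0)
    baseline_hazard: float = 0.01
    censoring_fraction_target: float = 0.3
    n_clusters: int = 6
    within_cluster_corr: float = 0.85
    informative_corr: float = 0.6
    clinical_effect: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be at least 2")
        blocks = dict(self.block_sizes)
        unknown = set(blocks) - set(BLOCK_ORDER)
        if unknown:
            raise ConfigurationError(f"unknown blocks in block_sizes: {sorted(unknown)}")
        if not blocks:
            raise ConfigurationError("block_sizes must name at least one block")
        for b, p in blocks.items():
            if p < 1:
                raise ConfigurationError(f"block {b!r} must have at least one feature")
        if "clinical" in blocks and blocks["clinical"] != len(CLINICAL_FEATURES):
            raise ConfigurationError(
                f"clinical block must have exactly {len(CLINICAL_FEATURES)} features"
            )
        n_inf = self.informative_counts()
        for b, k in n_inf.items():
            if b not in blocks:
                raise ConfigurationError(f"n_informative names absent block {b!r}")
            if b == "clinical":
                raise ConfigurationError(
                    "clinical informativeness is controlled by clinical_effect"
                )
            if k < 0 or k > blocks[b]:
                raise ConfigurationError(
                    f"n_informative[{b!r}] = {k} exceeds block size {blocks[b]}"
                )
        lo, hi = self.effect_sizes
        if lo < 0 or hi < lo:
            raise ConfigurationError("effect_sizes must be a non-negative interval (lo, hi)")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        if not 0 <= self.censoring_fraction_target < 1:
            raise ConfigurationError("censoring_fraction_target must lie in [0, 1)")
        if self.n_clusters < 1 or self.n_clusters > self.n_samples:
            raise ConfigurationError("n_clusters must be in [1, n_samples]")
        if not 0 <= self.within_cluster_corr < 1:
            raise ConfigurationError("within_cluster_corr must lie in [0, 1)")
        if not 0 <= self.informative_corr < 1:
            raise ConfigurationError("informative_corr must lie in [0, 1)")

    def informative_counts(self) -> dict:
        """Per-block informative feature count, with int broadcast to omics blocks."""
        if isinstance(self.n_informative, int):
            return {b: self.n_informative for b in OMICS_BLOCKS if b in self.block_sizes}
        return dict(self.n_informative)


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


# per-feature Beta shape menu for the methylation block: hypo-, hyper- and
# intermediately methylated CpG-like marginals
_METH_SHAPES = np.array([[2.0, 5.0], [5.0, 2.0], [2.0, 2.0], [0.8, 0.8]])


def _calibrate_censoring(log_t: np.ndarray, log_neg_log_u: np.ndarray, target: float) -> np.ndarray:
    """Bisection on the log exponential-censoring rate to hit the target fraction.

    The censoring quantiles ``log C = log(-log U_c) - log(rate)`` are fixed
    draws, so the realized fraction ``mean(log C < log T)`` is monotone
    non-decreasing in the rate and the calibration is deterministic.
    """
    lo, hi = -80.0, 80.0

    def frac(log_rate: float) -> float:
        return float(np.mean(log_neg_log_u - log_rate < log_t))

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    best = min((lo, hi), key=lambda r: abs(frac(r) - target))
    return log_neg_log_u - best


def generate_cohort(config: CohortConfig) -> MultiOmicsDataset:
    """Draw one synthetic multi-omics cohort under a proportional-hazards model.

    Survival times follow ``T = -log(U) / (h0 * exp(x beta))`` where ``x`` is
    the z-scored merged feature matrix and ``beta`` is nonzero only on the
    informative features (plus weak age / pack-years effects when the clinical
    block is present).  Identical configs (including the seed) produce
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    blocks = {b: config.block_sizes[b] for b in BLOCK_ORDER if b in config.block_sizes}
    n_inf = config.informative_counts()
    rho = config.within_cluster_corr
    tau = config.informative_corr

    # ~equal-size correlated sample clusters
    cluster = np.repeat(np.arange(config.n_clusters), int(np.ceil(n / config.n_clusters)))[:n]
    cluster = rng.permuted(cluster)

    columns, col_blocks, col_ids = [], [], []
    informative_cols: list[int] = []
    beta_vals: list[float] = []
    offset = 0

    for block in OMICS_BLOCKS:
        if block not in blocks:
            continue
        p = blocks[block]
        k = n_inf.get(block, 0)
        G = rng.standard_normal((config.n_clusters, p))
        eps = rng.standard_normal((n, p))
        # block risk-module activity: cluster-level (molecular subtype) plus
        # individual variation, sharing the within-cluster correlation rho
        factor_cluster = rng.standard_normal(config.n_clusters)
        factor_indiv = rng.standard_normal(n)
        risk_factor = (
            np.sqrt(rho) * factor_cluster[cluster] + np.sqrt(1.0 - rho) * factor_indiv
        )
        inf_idx = np.sort(rng.choice(p, size=k, replace=False)) if k else np.array([], int)
        signs = rng.choice((-1.0, 1.0), size=k)
        L = np.sqrt(rho) * G[cluster] + np.sqrt(1.0 - rho) * eps
        if k:
            L[:, inf_idx] = (
                np.sqrt(tau) * np.outer(risk_factor, signs)
                + np.sqrt(1.0 - tau) * L[:, inf_idx]
            )

        if block in ("mrna", "mirna"):
            base = 2.0 if block == "mrna" else 1.0
            mu = rng.normal(base, 1.0, size=p)
            Xb = np.exp(mu + L)  # log-normal expression, strictly positive
        else:
            shapes = _METH_SHAPES[rng.integers(0, len(_METH_SHAPES), size=p)]
            # monotone map of the latent Gaussian onto per-CpG Beta marginals
            Xb = stats.beta.ppf(np.clip(ndtr(L), 1e-12, 1 - 1e-12), shapes[:, 0], shapes[:, 1])
            Xb = np.clip(Xb, 0.0, 1.0)

        columns.append(Xb)
        col_blocks.extend([block] * p)
        col_ids.extend(f"{block}_{j:05d}" for j in range(p))
        informative_cols.extend(offset + inf_idx)
        mags = rng.uniform(config.effect_sizes[0], config.effect_sizes[1], size=k)
        beta_vals.extend(signs * mags)
        offset += p

    if "clinical" in blocks:
        clin = np.empty((n, len(CLINICAL_FEATURES)))
        clin[:, 0] = rng.random(n) < 0.593  # gender: 1 = male
        clin[:, 1] = np.clip(rng.normal(66.19, 9.32, n), 39, 88)  # age
        clin[:, 2] = rng.random(n) < 0.138  # prior malignancy
        clin[:, 3] = rng.random(n) < 0.0224  # synchronous malignancy
        clin[:, 4] = rng.random(n) < 0.0048  # prior treatment
        clin[:, 5] = rng.random(n) < 0.5577  # diagnosis: 1 = adenocarcinoma
        clin[:, 6] = rng.choice(4, n, p=[0.345, 0.515, 0.125, 0.015]) + 1  # T stage
        clin[:, 7] = rng.choice(4, n, p=[0.70, 0.205, 0.082, 0.013])  # N stage
        clin[:, 8] = rng.random(n) < 0.027  # M stage
        clin[:, 9] = rng.choice(6, n, p=[0.58, 0.343, 0.034, 0.022, 0.012, 0.009])  # organ
        clin[:, 10] = np.clip(rng.normal(47.09, 28.43, n), 0, None)  # pack-years
        columns.append(clin)
        col_blocks.extend(["clinical"] * len(CLINICAL_FEATURES))
        col_ids.extend(CLINICAL_FEATURES)
        if config.clinical_effect:
            informative_cols.extend([offset + 1, offset + 10])  # age, pack-years
            beta_vals.extend([config.clinical_effect, config.clinical_effect])
        offset += len(CLINICAL_FEATURES)

    X = np.concatenate(columns, axis=1)
    inf_cols = np.asarray(informative_cols, dtype=int)
    beta = np.asarray(beta_vals, dtype=float)

    eta = np.zeros(n)
    if inf_cols.size:
        eta = _zscore(X)[:, inf_cols] @ beta

    u = rng.random(n)
    log_t = np.log(-np.log(u)) - np.log(config.baseline_hazard) - eta
    if config.censoring_fraction_target > 0:
        u_c = rng.random(n)
        log_c = _calibrate_censoring(log_t, np.log(-np.log(u_c)), config.censoring_fraction_target)
        event = (log_t <= log_c).astype(int)
        time = np.exp(np.minimum(log_t, log_c))
    else:
        event = np.ones(n, dtype=int)
        time = np.exp(log_t)

    return MultiOmicsDataset(
        sample_ids=np.array([f"S{i:04d}" for i in range(n)]),
        feature_ids=np.array(col_ids),
        feature_block=np.array(col_blocks),
        X=X,
        outcome=SurvivalOutcome(time, event),
        truth=GroundTruth(indices=inf_cols, beta=beta),
    )
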