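"""Cross-validated training protocol over omics-block combinations.

The protocol per fold: chi-square screen of the omics features on the
training samples only (clinical covariates always bypass the screen), SMOTE
balancing of the training fold's vital-status classes, construction of the
patient-correlation graph over all nodes (training, synthetic and held-out),
transductive GAT-Cox training with the loss restricted to training nodes,
and Harrell's C on the held-out nodes.  Folds are stratified by the event
indicator so every fold contains deaths.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cohort import BLOCK_ORDER, MultiOmicsDataset, SurvivalOutcome
from .exceptions import ConfigurationError, ParseError
from .gat import GATConfig, GATCoxSurvival, TrainConfig
from .graphs import build_sample_graph
from .sampling import SmoteConfig, balance_training_set
from .screening import screen_features
from .survival import concordance_index

_BLOCK_LABELS = {"mrna": "mRNA", "mirna": "miRNA", "meth": "Meth", "clinical": "ClinicInfo"}


@dataclass(frozen=True)
class CombinationSpec:
    """A non-empty subset of omics/clinical blocks with its canonical name."""

    blocks: frozenset

    def __post_init__(self) -> None:
        blocks = frozenset(self.blocks)
        object.__setattr__(self, "blocks", blocks)
        if not blocks:
            raise ConfigurationError("a combination needs at least one block")
        unknown = blocks - set(BLOCK_ORDER)
        if unknown:
            raise ConfigurationError(f"unknown blocks: {sorted(unknown)}")

    @property
    def name(self) -> str:
        return "-".join(_BLOCK_LABELS[b] for b in BLOCK_ORDER if b in self.blocks)

    @property
    def ordered_blocks(self) -> tuple:
        return tuple(b for b in BLOCK_ORDER if b in self.blocks)


def all_combinations(blocks=BLOCK_ORDER) -> list:
    """All non-empty block subsets (15 for the full four-block set)."""
    blocks = [b for b in BLOCK_ORDER if b in blocks]
    out = []
    for r in range(1, len(blocks) + 1):
        for combo in itertools.combinations(blocks, r):
            out.append(CombinationSpec(frozenset(combo)))
    return out


@dataclass(frozen=True)
class CVResult:
    """Per-fold and aggregate C-index for one block combination."""

    combination: str
    fold_c_indices: tuple
    n_features: tuple  # features used per fold (post-screen)
    seed: int
    config: dict = field(compare=False, default_factory=dict)

    @property
    def mean_c_index(self) -> float:
        return float(np.mean(self.fold_c_indices))

    @property
    def std_c_index(self) -> float:
        if len(self.fold_c_indices) < 2:
            return 0.0
        return float(np.std(self.fold_c_indices, ddof=1))


# --- clinical covariate coding -------------------------------------------------

#: documented category -> code maps for the 11 clinical characteristics
CLINICAL_CODES = {
    "gender": {"female": 0, "male": 1},
    "prior_malignancy": {"no": 0, "yes": 1},
    "synchronous_malignancy": {"no": 0, "yes": 1},
    "prior_treatment": {"no": 0, "yes": 1},
    "primary_diagnosis": {"squamous cell carcinoma": 0, "adenocarcinoma": 1},
    "tissue_organ": {
        "upper lobe, lung": 0,
        "lower lobe, lung": 1,
        "middle lobe, lung": 2,
        "lung, nos": 3,
        "overlapping lesion of lung": 4,
        "main bronchus": 5,
    },
}
_STAGE_PREFIX = {"t_stage": "T", "n_stage": "N", "m_stage": "M"}
CLINICAL_NUMERIC = ("age", "pack_years")


def _encode_stage(value: str, prefix: str) -> float:
    """T/N/M stage string -> ordinal integer; the X sub-stage codes missing."""
    token = str(value).strip().upper()
    if not token.startswith(prefix):
        raise ParseError(f"unknown {prefix}-stage value {value!r}")
    token = token[len(prefix):]
    if token.startswith("X"):
        return np.nan
    digits = "".join(ch for ch in token if ch.isdigit())
    if not digits:
        raise ParseError(f"unknown {prefix}-stage value {value!r}")
    return float(int(digits))


def encode_clinical(table: pd.DataFrame, train_mask: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Encode the 11 clinical characteristics to a numeric matrix.

    Binary categories map to {0, 1}; T/N/M stages to ordinal integers with
    the X sub-stage treated as missing; tissue organ to integer codes; age
    and pack-years stay numeric.  Missing values are imputed with the
    training-subset median (numeric/ordinal) or mode (binary/categorical);
    unknown category tokens raise a :class:`ParseError` naming the value.
    """
    expected = list(CLINICAL_CODES) + list(_STAGE_PREFIX) + list(CLINICAL_NUMERIC)
    missing = [c for c in expected if c not in table.columns]
    if missing:
        raise ParseError(f"clinical table missing column(s) {missing}")
    n = len(table)
    train_mask = (
        np.ones(n, dtype=bool) if train_mask is None else np.asarray(train_mask, bool)
    )
    out = {}
    for col, codes in CLINICAL_CODES.items():
        vals = table[col]
        enc = np.full(n, np.nan)
        for i, v in enumerate(vals):
            if pd.isna(v):
                continue
            key = str(v).strip().lower()
            if key not in codes:
                raise ParseError(f"unknown category {v!r} in column {col!r}")
            enc[i] = codes[key]
        out[col] = enc
    for col, prefix in _STAGE_PREFIX.items():
        out[col] = np.array(
            [np.nan if pd.isna(v) else _encode_stage(v, prefix) for v in table[col]]
        )
    for col in CLINICAL_NUMERIC:
        out[col] = pd.to_numeric(table[col], errors="raise").to_numpy(dtype=float)

    df = pd.DataFrame(out, index=table.index)
    for col in df.columns:
        nan = df[col].isna().to_numpy()
        if nan.any():
            train_vals = df[col].to_numpy()[train_mask & ~nan]
            if train_vals.size == 0:
                raise ParseError(f"column {col!r} has no observed training values")
            if col in CLINICAL_NUMERIC or col in _STAGE_PREFIX:
                fill = float(np.median(train_vals))
            else:  # mode of the coded categories
                vals, counts = np.unique(train_vals, return_counts=True)
                fill = float(vals[np.argmax(counts)])
            df.loc[nan, col] = fill
    # fixed column order matching the generator's clinical block
    order = [
        "gender", "age", "prior_malignancy", "synchronous_malignancy",
        "prior_treatment", "primary_diagnosis", "t_stage", "n_stage",
        "m_stage", "tissue_organ", "pack_years",
    ]
    return df[order]


def decode_clinical(encoded: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`encode_clinical` for the categorical columns."""
    out = {}
    for col, codes in CLINICAL_CODES.items():
        inverse = {v: k for k, v in codes.items()}
        out[col] = [inverse[int(v)] for v in encoded[col]]
    for col, prefix in _STAGE_PREFIX.items():
        out[col] = [f"{prefix}{int(v)}" for v in encoded[col]]
    for col in CLINICAL_NUMERIC:
        out[col] = encoded[col].to_numpy(dtype=float)
    return pd.DataFrame(out, index=encoded.index)[list(encoded.columns)]


# --- cross-validated training --------------------------------------------------

def _fold_features(
    dataset: MultiOmicsDataset,
    combination: CombinationSpec,
    train_rows: np.ndarray,
    alpha: float,
    screen_global: bool,
):
    """Select this fold's feature columns: screened omics + all clinical."""
    omics = [b for b in combination.ordered_blocks if b != "clinical"]
    cols = []
    if omics:
        sel = screen_features(
            dataset,
            alpha=alpha,
            blocks=omics,
            sample_mask=None if screen_global else train_rows,
        )
        cols.extend(sel.indices.tolist())
    if "clinical" in combination.blocks:
        cols.extend(dataset.block_columns("clinical").tolist())
    if not cols:
        warnings.warn(
            f"{combination.name}: screen kept no features; falling back to all "
            "block features"
        )
        cols = np.nonzero(np.isin(dataset.feature_block,
                                  list(combination.ordered_blocks)))[0].tolist()
    return np.asarray(sorted(cols), dtype=int)


def run_fold(
    dataset: MultiOmicsDataset,
    combination: CombinationSpec,
    train_rows: np.ndarray,
    gat_config: GATConfig = GATConfig(),
    train_config: TrainConfig = TrainConfig(),
    alpha: float = 0.05,
    smote: Optional[SmoteConfig] = SmoteConfig(),
    graph_threshold: float = 0.7,
    screen_global: bool = False,
):
    """Train one transductive fold; returns (risk_scores_per_sample, n_features).

    Every training-dependent step (screen, standardization, SMOTE, loss) uses
    the ``train_rows`` samples only; held-out samples contribute features and
    graph edges but never outcomes.
    """
    n = dataset.n_samples
    event = dataset.outcome.event
    time = dataset.outcome.time
    train_bool = np.zeros(n, dtype=bool)
    train_bool[np.asarray(train_rows)] = True
    cols = _fold_features(dataset, combination, train_bool, alpha, screen_global)
    X = dataset.X[:, cols]
    # standardize on training-fold statistics only
    mu = X[train_bool].mean(axis=0)
    sd = X[train_bool].std(axis=0)
    Xz = (X - mu) / np.where(sd > 0, sd, 1.0)

    if smote is not None:
        X_syn, t_syn, e_syn, _, _ = balance_training_set(
            Xz[train_bool], time[train_bool], event[train_bool], smote
        )
        X_all = np.vstack([Xz, X_syn])
        t_all = np.concatenate([time, t_syn])
        e_all = np.concatenate([event, e_syn])
        mask_all = np.concatenate([train_bool, np.ones(len(X_syn), dtype=bool)])
    else:
        X_all, t_all, e_all, mask_all = Xz, time, event, train_bool

    graph = build_sample_graph(X_all, threshold=graph_threshold, standardize=False)
    model = GATCoxSurvival(
        X_all,
        SurvivalOutcome(t_all, e_all),
        graph=graph,
        config=gat_config,
        standardize=False,
    )
    results = model.fit(mask_all, train_config)
    return results.risk_scores[:n], len(cols)


def run_cv(
    dataset: MultiOmicsDataset,
    combination: CombinationSpec | Sequence[str],
    gat_config: GATConfig = GATConfig(),
    train_config: TrainConfig = TrainConfig(),
    k_folds: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
    smote: Optional[SmoteConfig] = SmoteConfig(),
    graph_threshold: float = 0.7,
    screen_global: bool = False,
) -> CVResult:
    """Stratified k-fold transductive evaluation of one block combination.

    Per fold: training-only chi-square screen -> optional SMOTE balancing of
    the training nodes -> correlation graph over all nodes -> GAT-Cox
    training on the training nodes -> C-index on held-out nodes.  Folds with
    fewer than 2 events are skipped with a warning.
    """
    if not isinstance(combination, CombinationSpec):
        combination = CombinationSpec(frozenset(combination))
    if k_folds < 2:
        raise ConfigurationError("k_folds must be >= 2")
    missing = combination.blocks - set(dataset.blocks)
    if missing:
        raise ConfigurationError(f"dataset lacks block(s) {sorted(missing)}")

    n = dataset.n_samples
    event = dataset.outcome.event
    splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_cs, fold_nfeat = [], []
    for fold, (train_rows, test_rows) in enumerate(splitter.split(np.zeros(n), event)):
        if event[train_rows].sum() < 2:
            warnings.warn(f"fold {fold}: fewer than 2 training events; skipped")
            continue
        fold_train_config = TrainConfig(
            learning_rate=train_config.learning_rate,
            weight_decay=train_config.weight_decay,
            max_epochs=train_config.max_epochs,
            grad_clip_norm=train_config.grad_clip_norm,
            patience=train_config.patience,
            val_fraction=train_config.val_fraction,
            seed=train_config.seed + fold,
        )
        risk, n_feat = run_fold(
            dataset,
            combination,
            train_rows,
            gat_config=gat_config,
            train_config=fold_train_config,
            alpha=alpha,
            smote=smote,
            graph_threshold=graph_threshold,
            screen_global=screen_global,
        )
        fold_cs.append(
            concordance_index(risk[test_rows], dataset.outcome.subset(test_rows))
        )
        fold_nfeat.append(n_feat)
    if not fold_cs:
        raise ConfigurationError("every fold was skipped (too few events)")
    return CVResult(
        combination=combination.name,
        fold_c_indices=tuple(fold_cs),
        n_features=tuple(fold_nfeat),
        seed=seed,
        config={
            "gat": vars(gat_config).copy() if hasattr(gat_config, "__dict__")
            else gat_config.__dict__,
            "train": train_config.__dict__,
            "k_folds": k_folds,
            "alpha": alpha,
            "smote": None if smote is None else smote.__dict__,
            "graph_threshold": graph_threshold,
            "screen_global": screen_global,
        },
    )


def run_combination_matrix(
    dataset: MultiOmicsDataset,
    combinations: Optional[Sequence[CombinationSpec]] = None,
    **cv_kwargs,
) -> pd.DataFrame:
    """One cross-validated row per block combination (the run-matrix report)."""
    if combinations is None:
        combinations = all_combinations(dataset.blocks)
    rows = []
    for combo in combinations:
        res = run_cv(dataset, combo, **cv_kwargs)
        rows.append(
            {
                "combination": res.combination,
                "n_features": int(np.round(np.mean(res.n_features))),
                "mean_c_index": res.mean_c_index,
                "std_c_index": res.std_c_index,
                "fold_c_indices": list(res.fold_c_indices),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GridSpec:
    """Candidate hyperparameter lists for the exhaustive grid search."""

    hidden_dim: tuple = (32, 64)
    num_heads: tuple = (2, 4)
    learning_rate: tuple = (1e-3,)
    weight_decay: tuple = (1e-5,)

    def validate(self) -> None:
        for name in ("hidden_dim", "num_heads", "learning_rate", "weight_decay"):
            if not getattr(self, name):
                raise ConfigurationError(f"grid list {name!r} is empty")


def grid_search(
    dataset: MultiOmicsDataset,
    grid: GridSpec,
    combination=("mrna", "mirna"),
    base_gat: GATConfig = GATConfig(),
    **cv_kwargs,
):
    """Exhaustive grid search by mean cross-validated C-index.

    Ties are broken deterministically toward the smaller hidden_dim, then
    fewer heads.  Returns ``(best_config, leaderboard)``.
    """
    grid.validate()
    base_train = cv_kwargs.pop("train_config", TrainConfig())
    rows = []
    for hd, nh, lr, wd in itertools.product(
        grid.hidden_dim, grid.num_heads, grid.learning_rate, grid.weight_decay
    ):
        gat_config = GATConfig(
            hidden_dim=hd,
            num_heads=nh,
            dropout=base_gat.dropout,
            head_merge_hidden=base_gat.head_merge_hidden,
            activation=base_gat.activation,
            leaky_slope=base_gat.leaky_slope,
            batch_norm=base_gat.batch_norm,
        )
        train_config = TrainConfig(
            learning_rate=lr,
            weight_decay=wd,
            max_epochs=base_train.max_epochs,
            grad_clip_norm=base_train.grad_clip_norm,
            patience=base_train.patience,
            val_fraction=base_train.val_fraction,
            seed=base_train.seed,
        )
        res = run_cv(dataset, combination, gat_config=gat_config,
                     train_config=train_config, **cv_kwargs)
        rows.append(
            {
                "hidden_dim": hd,
                "num_heads": nh,
                "learning_rate": lr,
                "weight_decay": wd,
                "mean_c_index": res.mean_c_index,
                "std_c_index": res.std_c_index,
            }
        )
    board = pd.DataFrame(rows)
    # deterministic ordering: C-index desc, then smaller width, fewer heads
    board = board.sort_values(
        ["hidden_dim", "num_heads"], kind="stable"
    ).sort_values("mean_c_index", ascending=False, kind="stable")
    board = board.reset_index(drop=True)
    top = board.iloc[0]
    best = GATConfig(
        hidden_dim=int(top["hidden_dim"]),
        num_heads=int(top["num_heads"]),
        dropout=base_gat.dropout,
        head_merge_hidden=base_gat.head_merge_hidden,
        activation=base_gat.activation,
        leaky_slope=base_gat.leaky_slope,
        batch_norm=base_gat.batch_norm,
    ), {"learning_rate": float(top["learning_rate"]),
        "weight_decay": float(top["weight_decay"])}
    return best, board


def report(
    matrix: pd.DataFrame,
    outdir,
    screen_summary: Optional[pd.DataFrame] = None,
    manifest: Optional[dict] = None,
) -> Path:
    """Write the run-matrix table, per-fold values and a manifest JSON."""
    if matrix.empty:
        raise ConfigurationError("nothing to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.drop(columns=["fold_c_indices"], errors="ignore").to_csv(
        outdir / "combinations.tsv", sep="\t", index=False
    )
    if "fold_c_indices" in matrix.columns:
        folds = matrix[["combination", "fold_c_indices"]].explode("fold_c_indices")
        folds["fold"] = folds.groupby("combination").cumcount()
        folds.rename(columns={"fold_c_indices": "c_index"}).to_csv(
            outdir / "folds.tsv", sep="\t", index=False
        )
    if screen_summary is not None:
        screen_summary.to_csv(outdir / "screen_summary.tsv", sep="\t", index=False)
    payload = {
        "combinations": matrix.drop(columns=["fold_c_indices"], errors="ignore")
        .to_dict(orient="records"),
    }
    if "fold_c_indices" in matrix.columns:
        payload["folds"] = {
            r["combination"]: list(map(float, r["fold_c_indices"]))
            for _, r in matrix.iterrows()
        }
    if manifest:
        payload["manifest"] = manifest
    (outdir / "report.json").write_text(json.dumps(payload, indent=2, default=float))
    return outdir
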