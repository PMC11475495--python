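"""Plain-text (TSV / YAML / JSON) persistence for multi-omics datasets.

Layout of a dataset directory::

    features.tsv   sample_id + one column per feature (all blocks, merged)
    blocks.tsv     feature_id -> block label
    outcome.tsv    sample_id, time, event
    truth.json     optional ground-truth indices / coefficients
    config.yaml    optional generating configuration

Floats are written with 17 significant digits so a write/read round trip is
bit-exact for float64.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig, GroundTruth, MultiOmicsDataset, SurvivalOutcome
from .exceptions import ParseError

_FLOAT_FMT = "%.17g"


def write_dataset(dataset: MultiOmicsDataset, path) -> Path:
    """Write a dataset to a directory of TSV files; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    feats = pd.DataFrame(dataset.X, index=dataset.sample_ids, columns=dataset.feature_ids)
    feats.index.name = "sample_id"
    feats.to_csv(path / "features.tsv", sep="\t", float_format=_FLOAT_FMT)
    pd.DataFrame(
        {"feature_id": dataset.feature_ids, "block": dataset.feature_block}
    ).to_csv(path / "blocks.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "sample_id": dataset.sample_ids,
            "time": dataset.outcome.time,
            "event": dataset.outcome.event,
        }
    ).to_csv(path / "outcome.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    if dataset.truth is not None:
        (path / "truth.json").write_text(
            json.dumps(
                {
                    "indices": dataset.truth.indices.tolist(),
                    "beta": dataset.truth.beta.tolist(),
                }
            )
        )
    return path


def _require_columns(df: pd.DataFrame, cols, fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{fname}: missing required column(s) {missing}")


def _numeric_or_raise(df: pd.DataFrame, fname: str) -> np.ndarray:
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ParseError(
            f"{fname}: non-numeric value {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    if coerced.isna().any().any():
        r, c = np.argwhere(coerced.isna().values)[0]
        raise ParseError(
            f"{fname}: missing value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return coerced.to_numpy(dtype=float)


def read_dataset(path) -> MultiOmicsDataset:
    """Read a dataset directory written by :func:`write_dataset`.

    Raises :class:`~gatsurv.exceptions.ParseError` naming the offending
    row/column for duplicate IDs, missing survival columns or non-numeric
    cells.
    """
    path = Path(path)
    feats = pd.read_csv(path / "features.tsv", sep="\t", dtype={"sample_id": str},
                        float_precision="round_trip")
    _require_columns(feats, ["sample_id"], "features.tsv")
    sample_ids = feats["sample_id"].to_numpy(dtype=str)
    dup = pd.Series(sample_ids).duplicated()
    if dup.any():
        raise ParseError(f"features.tsv: duplicate sample_id {sample_ids[dup.argmax()]!r}")
    feature_ids = np.array([c for c in feats.columns if c != "sample_id"], dtype=str)
    if pd.Series(feature_ids).duplicated().any():
        raise ParseError("features.tsv: duplicate feature column names")
    X = _numeric_or_raise(feats[list(feature_ids)], "features.tsv")

    blocks = pd.read_csv(path / "blocks.tsv", sep="\t", dtype=str)
    _require_columns(blocks, ["feature_id", "block"], "blocks.tsv")
    block_map = dict(zip(blocks["feature_id"], blocks["block"]))
    unmapped = [f for f in feature_ids if f not in block_map]
    if unmapped:
        raise ParseError(f"blocks.tsv: no block label for feature {unmapped[0]!r}")
    feature_block = np.array([block_map[f] for f in feature_ids], dtype=str)

    outcome_df = pd.read_csv(path / "outcome.tsv", sep="\t", dtype={"sample_id": str},
                             float_precision="round_trip")
    _require_columns(outcome_df, ["sample_id", "time", "event"], "outcome.tsv")
    outcome_df = outcome_df.set_index("sample_id")
    missing = [s for s in sample_ids if s not in outcome_df.index]
    if missing:
        raise ParseError(f"outcome.tsv: no outcome row for sample {missing[0]!r}")
    outcome_df = outcome_df.loc[list(sample_ids)]
    vals = _numeric_or_raise(outcome_df[["time", "event"]], "outcome.tsv")
    outcome = SurvivalOutcome(vals[:, 0], vals[:, 1].astype(int))

    truth = None
    truth_path = path / "truth.json"
    if truth_path.exists():
        raw = json.loads(truth_path.read_text())
        truth = GroundTruth(
            indices=np.asarray(raw["indices"], dtype=int),
            beta=np.asarray(raw["beta"], dtype=float),
        )
    return MultiOmicsDataset(
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        feature_block=feature_block,
        X=X,
        outcome=outcome,
        truth=truth,
    )


def write_config(config: CohortConfig, path) -> Path:
    path = Path(path)
    payload = dataclasses.asdict(config)
    payload["block_sizes"] = dict(payload["block_sizes"])
    payload["n_informative"] = (
        payload["n_informative"]
        if isinstance(payload["n_informative"], int)
        else dict(payload["n_informative"])
    )
    payload["effect_sizes"] = list(payload["effect_sizes"])
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def read_config(path) -> CohortConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: expected a mapping of cohort-config fields")
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ParseError(f"{path}: unknown config field(s) {sorted(unknown)}")
    if "effect_sizes" in raw:
        raw["effect_sizes"] = tuple(raw["effect_sizes"])
    config = CohortConfig(**raw)
    config.validate()
    return config
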