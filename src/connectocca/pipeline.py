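"""End-to-end orchestration: config, table IO, staged analysis, manifest.

The pipeline runs the full workflow on CSV/TSV tables: (optional)
connectome construction from time series, confound residualization,
MAD edge selection, standardization, penalty tuning, rCCA fit,
permutation inference with FDR, loading-based network interpretation,
and nested-CV prediction of each selected mode's score. Every stage's
outputs are written before the next begins, and a run manifest records
the config hash, seeds and produced files so a run can be reproduced
exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import CommunityAssignment, EdgeIndex, assign_edge_communities
from .inference import evaluate_modes, mode_overlap
from .prediction import (
    PredictionConfig,
    label_permutation_test,
    mode_target_scores,
    nested_cv_predict,
)
from .prep import ConfoundRegressor, Standardizer, mad_select
from .rcca import RCCA

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "read_table", "load_config"]


class ConfigError(ValueError):
    """Invalid configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Invalid input data (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    """Paths and per-stage settings for a full run."""

    edge_features: str = ""
    behaviors: str = ""
    covariates: str = ""
    communities: str = ""
    out_dir: str = "connectocca_out"
    seed: int = 0
    # feature_prep
    mad_fraction: float = 0.05
    confounds: tuple = ("age", "sex", "mean_fd")
    residualize_behavior: bool = False
    mad_before_residualize: bool = False
    # rcca tuning
    lambda_grid: dict = field(
        default_factory=lambda: {"min": 0.01, "max": 0.99, "length": 20}
    )
    tuning_folds: int = 5
    # inference
    n_perms: int = 5000
    alpha: float = 0.05
    cov_threshold: float = 0.05
    loading_threshold: float = 0.2
    # prediction
    run_prediction: bool = True
    prediction: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


load_config = PipelineConfig.from_yaml


@dataclass
class RunManifest:
    """What a run produced and how to reproduce it."""

    config_hash: str
    version: str
    seed: int
    timings: dict
    outputs: list

    def write(self, path) -> None:
        tmp = Path(str(path) + ".tmp")
        with open(tmp, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
        tmp.replace(path)  # atomic on POSIX


def read_table(path, kind: str = "table") -> pd.DataFrame:
    """Read a CSV/TSV with a `subject_id` column; validate and index by it."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"{kind} file not found: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise DataError(f"{kind} table {path} is empty")
    if "subject_id" not in df.columns:
        raise DataError(f"{kind} table {path} lacks a subject_id column")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise DataError(
            f"duplicate subject_id in {kind} table: {sorted(set(dup))}"
        )
    df = df.set_index("subject_id")
    non_numeric = [
        c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])
    ]
    if non_numeric:
        raise DataError(
            f"non-numeric column(s) in {kind} table: {non_numeric}"
        )
    if df.isna().any().any():
        raise DataError(f"missing values in {kind} table {path}")
    return df


def _align(tables: dict) -> dict:
    ids = None
    for name, df in tables.items():
        s = set(df.index)
        ids = s if ids is None else ids & s
    for name, df in tables.items():
        extra = set(df.index) - ids
        if extra:
            raise DataError(
                f"subject ids {sorted(extra)[:5]} in {name} are missing from "
                "other tables"
            )
    order = sorted(ids)
    return {name: df.loc[order] for name, df in tables.items()}


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute the staged analysis described in the module docstring."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict = {}
    outputs: list = []
    t0 = time.perf_counter()

    def _stage_done(name):
        timings[name] = round(time.perf_counter() - t0 - sum(timings.values()), 4)

    # --- load & align -----------------------------------------------------
    edges_df = read_table(cfg.edge_features, "edge_features")
    beh_df = read_table(cfg.behaviors, "behaviors")
    cov_df = read_table(cfg.covariates, "covariates")
    tables = _align(
        {"edge_features": edges_df, "behaviors": beh_df, "covariates": cov_df}
    )
    edges_df, beh_df, cov_df = (
        tables["edge_features"],
        tables["behaviors"],
        tables["covariates"],
    )
    communities = (
        CommunityAssignment.from_tsv(cfg.communities) if cfg.communities else None
    )
    _stage_done("load")

    # --- feature prep -----------------------------------------------------
    seeds = np.random.SeedSequence(cfg.seed).spawn(3)  # tuning, perms, prediction
    X_raw = edges_df.to_numpy(dtype=float)
    Y_raw = beh_df.to_numpy(dtype=float)
    resid = ConfoundRegressor(columns=tuple(cfg.confounds))
    if cfg.mad_before_residualize:
        sel, mad_thr = mad_select(X_raw, cfg.mad_fraction)
        X_res = resid.fit_transform(X_raw[:, sel], cov_df)
    else:
        X_all = resid.fit_transform(X_raw, cov_df)
        sel, mad_thr = mad_select(X_all, cfg.mad_fraction)
        X_res = X_all[:, sel]
    if cfg.residualize_behavior:
        Y_raw = ConfoundRegressor(columns=tuple(cfg.confounds)).fit_transform(
            Y_raw, cov_df
        )
    X = Standardizer().fit_transform(X_res)
    Y = Standardizer().fit_transform(Y_raw)
    selected_names = [edges_df.columns[i] for i in sel]
    pd.DataFrame({"edge": selected_names, "edge_id": sel}).to_csv(
        out / "selected_edges.csv", index=False
    )
    outputs.append("selected_edges.csv")
    _stage_done("feature_prep")

    # --- tune + fit -------------------------------------------------------
    model = RCCA(X, Y, feature_names=selected_names, behavior_names=list(beh_df.columns))
    tuning = model.tune(
        grid_min=cfg.lambda_grid.get("min", 0.01),
        grid_max=cfg.lambda_grid.get("max", 0.99),
        grid_len=cfg.lambda_grid.get("length", 20),
        n_folds=cfg.tuning_folds,
        seed=seeds[0],
    )
    res = model.fit(*tuning.best_pair)
    res.to_json(out / "rcca_model.json")
    outputs.append("rcca_model.json")
    _stage_done("rcca")

    # --- inference & interpretation --------------------------------------
    edge_index = None
    if communities is not None:
        n_nodes = communities.n_nodes
        full_index = assign_edge_communities(
            EdgeIndex.from_n_nodes(n_nodes), communities
        )
        edge_index = EdgeIndex(
            n_nodes=n_nodes,
            node_i=full_index.node_i[sel],
            node_j=full_index.node_j[sel],
            community_pair=[full_index.community_pair[i] for i in sel],
        )
    modes = evaluate_modes(
        res,
        edge_index=edge_index,
        n_perms=cfg.n_perms,
        seed=seeds[1],
        alpha=cfg.alpha,
        cov_threshold=cfg.cov_threshold,
        loading_threshold=cfg.loading_threshold,
    )
    mode_payload = [m.to_dict() for m in modes]
    selected_ids = [m.mode_id for m in modes if m.selected]
    with open(out / "modes.json", "w") as fh:
        json.dump(
            {
                "lambda_x": res.lambda_x,
                "lambda_y": res.lambda_y,
                "selected_modes": selected_ids,
                "modes": mode_payload,
            },
            fh,
            indent=2,
        )
    outputs.append("modes.json")
    if edge_index is not None:
        loading_rows = []
        strength_rows = []
        node_rows = []
        for m in modes:
            if not m.selected:
                continue
            for local_e in m.contributing_edges:
                loading_rows.append(
                    {
                        "mode_id": m.mode_id,
                        "edge": selected_names[local_e],
                        "node_i": int(edge_index.node_i[local_e]),
                        "node_j": int(edge_index.node_j[local_e]),
                        "community_pair": "-".join(
                            edge_index.community_pair[local_e]
                        ),
                        "loading": float(m.loadings_brain[local_e]),
                    }
                )
            if m.network_summary is not None:
                for (a, b), s in m.network_summary.pair_strength.items():
                    strength_rows.append(
                        {"mode_id": m.mode_id, "community_pair": f"{a}-{b}", "strength": s}
                    )
                for v, s in m.network_summary.node_strength.items():
                    node_rows.append(
                        {"mode_id": m.mode_id, "node_id": v, "strength": s}
                    )
        pd.DataFrame(loading_rows).to_csv(out / "edge_loadings.csv", index=False)
        pd.DataFrame(strength_rows).to_csv(out / "network_strengths.csv", index=False)
        pd.DataFrame(node_rows).to_csv(out / "node_strengths.csv", index=False)
        outputs += ["edge_loadings.csv", "network_strengths.csv", "node_strengths.csv"]
        if len(selected_ids) >= 2:
            a, b = (modes[selected_ids[0]], modes[selected_ids[1]])
            shared, shared_summary = mode_overlap(a, b, edge_index)
            with open(out / "mode_overlap.json", "w") as fh:
                json.dump(
                    {
                        "shared_edges": [selected_names[i] for i in shared],
                        "mean_pair_strength": (
                            {
                                "-".join(p): s
                                for p, s in shared_summary.pair_strength.items()
                            }
                            if shared_summary
                            else {}
                        ),
                    },
                    fh,
                    indent=2,
                )
            outputs.append("mode_overlap.json")
    _stage_done("inference")

    # --- prediction -------------------------------------------------------
    if cfg.run_prediction and selected_ids:
        pred_cfg = PredictionConfig(
            seed=int(seeds[2].generate_state(1)[0] % (2**31 - 1)),
            **cfg.prediction,
        )
        report = {}
        for m in modes:
            if not m.selected or m.contributing_behaviors.size == 0:
                continue
            target = mode_target_scores(Y_raw, m.contributing_behaviors)
            obs = nested_cv_predict(
                X_raw[:, sel][:, m.contributing_edges]
                if m.contributing_edges.size
                else X_raw[:, sel],
                target,
                cov_df,
                pred_cfg,
            )
            p = label_permutation_test(
                X_raw[:, sel][:, m.contributing_edges]
                if m.contributing_edges.size
                else X_raw[:, sel],
                target,
                cov_df,
                pred_cfg,
                observed=obs,
                n_perms=pred_cfg.n_label_perms,
                seed=pred_cfg.seed + 1,
            )
            report[f"mode_{m.mode_id}"] = {
                "r_pred_obs": obs.r_pred_obs,
                "mae": obs.mae,
                "perm_p": p,
                "per_repeat": obs.per_repeat,
            }
            pd.DataFrame(
                {"subject_id": edges_df.index, "observed": target, "predicted": obs.predictions}
            ).to_csv(out / f"predictions_mode_{m.mode_id}.csv", index=False)
            outputs.append(f"predictions_mode_{m.mode_id}.csv")
        with open(out / "prediction_metrics.json", "w") as fh:
            json.dump(report, fh, indent=2)
        outputs.append("prediction_metrics.json")
    _stage_done("prediction")

    manifest = RunManifest(
        config_hash=cfg.digest(),
        version=__version__,
        seed=cfg.seed,
        timings=timings,
        outputs=outputs,
    )
    manifest.write(out / "manifest.json")
    return manifest
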