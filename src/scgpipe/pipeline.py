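"""End-to-end orchestration: simulate -> preprocess -> segment -> cluster ->
features -> train/eval, with file outputs and provenance.

Each stage writes its output under the run directory so stages are
independently inspectable; re-running with an identical config reproduces
identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import BeatDistanceCache, BeatKMedoids
from .errors import MissingDependencyError, ScgPipeError
from .features import FEATURE_COLUMNS, session_features
from .modeling import EvalResult, ReadmissionClassifier, loocv, rf_select
from .preprocess import preprocess_session
from .segmentation import segment_session
from .synth import SessionRecording, SyntheticConfig, generate_cohort, read_session_csv

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "segment", "cluster", "features", "train_eval")


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    input_dir: str | None = None  # read sessions from here instead of simulating
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    target_fs: float = 1000.0
    filter_low_hz: float = 0.5
    filter_high_hz: float = 100.0
    filter_order: int = 4
    model_kind: str = "knn"
    decision_threshold: float = 0.7
    threshold_on: str = "negative"
    select_k: int = 11
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = SyntheticConfig(**raw.pop("synthetic", {}))
        stages = {s: True for s in STAGES}
        stages.update(raw.pop("stages", {}))
        return cls(synthetic=syn, stages=stages, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def analyze_session(
    session: SessionRecording,
    target_fs: float | None = None,
    filter_low_hz: float = 0.5,
    filter_high_hz: float = 100.0,
    filter_order: int = 4,
) -> dict:
    """Run one session through preprocess/segment/cluster/features.

    Returns a dict with the intermediate artifacts and the feature row.
    """
    pre = preprocess_session(
        session,
        # only downsampling is meaningful; never upsample a low-rate session
        target_fs=min(target_fs, session.fs_hz) if target_fs else None,
        low=filter_low_hz,
        high=filter_high_hz,
        order=filter_order,
    )
    beats = segment_session(pre)
    km = BeatKMedoids().fit(beats)
    row = session_features(pre, beats, km.result_, km.cache_)
    return {
        "pre": pre,
        "beats": beats,
        "cluster": km.result_,
        "cache": km.cache_,
        "row": row,
    }


def extract_cohort_features(
    sessions: list[SessionRecording],
    target_fs: float | None = None,
    **kw,
) -> pd.DataFrame:
    """Feature table (one row per session) for a list of sessions."""
    rows = []
    for sess in sessions:
        art = analyze_session(sess, target_fs=target_fs, **kw)
        rows.append(art["row"])
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages in order; return the run directory."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.stages

    provenance = {"package_version": __version__, "config": config.to_dict()}
    (out / "provenance.yaml").write_text(yaml.safe_dump(provenance, sort_keys=True))

    sessions: list[SessionRecording] = []
    manifest: pd.DataFrame | None = None
    if stages.get("simulate", True):
        cfg = dataclasses.replace(config.synthetic, seed=config.seed)
        sessions, manifest = generate_cohort(cfg)
        manifest.to_csv(out / "manifest.csv", index=False)
    elif config.input_dir:
        in_dir = Path(config.input_dir)
        manifest = pd.read_csv(in_dir / "manifest.csv")
        sessions = [read_session_csv(in_dir / f"{sid}.csv") for sid in manifest["session_id"]]
    else:
        raise MissingDependencyError("no input: enable the simulate stage or set input_dir")

    needed = ("preprocess", "segment", "cluster")
    if stages.get("features", True):
        missing = [s for s in needed if not stages.get(s, True)]
        if missing:
            raise MissingDependencyError(
                f"features stage requires stages {missing} to be enabled"
            )

    features_df: pd.DataFrame | None = None
    if stages.get("features", True):
        rows = []
        cluster_audit = {}
        for sess in sessions:
            try:
                art = analyze_session(
                    sess,
                    target_fs=config.target_fs,
                    filter_low_hz=config.filter_low_hz,
                    filter_high_hz=config.filter_high_hz,
                    filter_order=config.filter_order,
                )
            except ScgPipeError as exc:
                log.warning("session %s failed: %s", sess.session_id, exc)
                continue
            rows.append(art["row"])
            res = art["cluster"]
            cluster_audit[sess.session_id] = {
                "init_basis": res.init_basis,
                "init_metric": res.init_metric,
                "n_iterations": res.n_iterations,
                "converged": bool(res.converged),
                "labels": res.labels.tolist(),
                "medoids": [int(res.medoid_1), int(res.medoid_2)],
                "wv_intra_audit": {k: (None if np.isnan(v) else v) for k, v in res.audit.items()},
            }
        features_df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
        features_df.to_csv(out / "features.csv", index=False)
        (out / "clusters.json").write_text(json.dumps(cluster_audit, indent=1))

    if stages.get("train_eval", True):
        if features_df is None:
            raise MissingDependencyError("train_eval stage requires the features stage")
        mask = features_df["label"].isin(["readmitted", "non_readmitted"])
        patients = features_df[mask].reset_index(drop=True)
        y = (patients["label"] == "readmitted").to_numpy().astype(int)
        from .features import FEATURE_NAMES

        selected, importances = rf_select(
            patients[FEATURE_NAMES], y, k=min(config.select_k, len(FEATURE_NAMES)),
            seed=config.seed,
        )
        importances.rename("gini_importance").to_csv(out / "importances.csv")
        model = ReadmissionClassifier(
            kind=config.model_kind,
            decision_threshold=config.decision_threshold,
            threshold_on=config.threshold_on,
            seed=config.seed,
        )
        result: EvalResult = loocv(patients, model, feature_names=selected)
        result.predictions.to_csv(out / "predictions.csv", index=False)
        result.roc.to_csv(out / "roc.csv", index=False)
        (out / "metrics.json").write_text(json.dumps(result.metrics, indent=1))
    return out
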