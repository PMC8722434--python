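"""End-to-end experiment orchestration on synthetic cohorts.

``run_experiment`` executes simulate -> preprocess -> connectivity ->
identification (intra-session CV + cross-session permanence) -> connection
weights, and writes a run directory with feature tables, a JSON master
report and the resolved configuration.  Everything is a pure function of
the config's master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import SESSION_DAYS, SessionSpec, make_cohort
from .connectivity import connectivity_dataset, save_features_tsv
from .identify import cross_session_eval, intra_session_cv
from .preprocess import preprocess_recording
from .weights import edge_table, feature_weights, major_connections

__all__ = ["PipelineConfig", "run_experiment", "CI_PROFILE", "PAPER_PROFILE"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved parameters for a full run; round-trips losslessly via YAML."""

    # cohort
    n_subjects: int = 15
    session_ids: tuple = ("A", "B", "C", "D", "E", "F")
    session_days: dict = field(default_factory=lambda: dict(SESSION_DAYS))
    drift_coeff: float = 0.06
    fs: float = 250.0
    duration_s: float = 240.0
    var_order: int = 2
    base_coupling: float = 0.1
    n_planted: int = 12
    planted_strength: float = 0.35
    noise_scale: float = 0.2
    seed: int = 42
    # preprocessing
    low: float = 1.0
    high: float = 40.0
    notch: float | None = 50.0
    laplacian: str = "hjorth"
    seg_len_s: float = 2.0
    # connectivity
    indices: tuple = ("GC", "MI")
    gc_order: int = 15
    mi_bins: int = 16
    # identification
    folds: int = 10
    svm_c: float = 1.0
    grid_search: bool = False
    train_session: str = "A"
    # weights
    weight_method: str = "linear-ovo-aggregate"
    top_frac: float = 0.10

    def validate(self) -> None:
        unknown = [s for s in self.session_ids if s not in self.session_days]
        if unknown:
            raise ValueError(f"unknown session label(s) {unknown}")
        if self.train_session not in self.session_ids:
            raise ValueError(
                f"train_session {self.train_session!r} not among {self.session_ids}"
            )
        if not set(self.indices) <= {"GC", "MI"}:
            raise ValueError(f"indices must be among GC/MI, got {self.indices}")
        if self.laplacian not in ("hjorth", "none"):
            raise ValueError(f"unknown laplacian mode {self.laplacian!r}")
        days = [self.session_days[s] for s in self.session_ids]
        if sorted(days) != days:
            raise ValueError("session_ids must be in nominal-day order")

    def sessions(self) -> list:
        return [
            SessionSpec(s, self.session_days[s],
                        self.drift_coeff * math.log(self.session_days[s]))
            for s in self.session_ids
        ]

    def to_yaml(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        payload["session_ids"] = list(payload["session_ids"])
        payload["indices"] = list(payload["indices"])
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            source = Path(source).read_text()
        payload = yaml.safe_load(source)
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(payload) - known
        if extra:
            raise ValueError(f"unknown config key(s) {sorted(extra)}")
        for key in ("session_ids", "indices"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


#: Desk-scale profile for quick runs and CI-sized checks.
CI_PROFILE = dict(
    n_subjects=5, session_ids=("A", "B"), fs=125.0, duration_s=80.0,
    gc_order=8, folds=5,
)
#: The full-protocol profile (15 subjects, 6 sessions, 120 epochs each).
PAPER_PROFILE = dict()


def run_experiment(config: PipelineConfig, out_dir) -> dict:
    """Run the whole experiment; returns the report dict (also written as
    ``report.json`` in ``out_dir`` along with feature tables and the resolved
    config)."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")

    log.info("simulating cohort (%d subjects x %d sessions)",
             config.n_subjects, len(config.session_ids))
    recordings = make_cohort(
        n_subjects=config.n_subjects,
        sessions=config.sessions(),
        duration_s=config.duration_s,
        fs=config.fs,
        seed=config.seed,
        order=config.var_order,
        base_coupling=config.base_coupling,
        n_planted=config.n_planted,
        planted_strength=config.planted_strength,
        noise_scale=config.noise_scale,
    )

    log.info("preprocessing (%g-%g Hz, notch %s, laplacian=%s, %g s epochs)",
             config.low, config.high, config.notch, config.laplacian,
             config.seg_len_s)
    epochs_by_session = {s: [] for s in config.session_ids}
    for rec in recordings:
        epochs_by_session[rec.session_id].extend(
            preprocess_recording(
                rec, low=config.low, high=config.high, notch=config.notch,
                laplacian=config.laplacian, seg_len_s=config.seg_len_s,
            )
        )

    report = {
        "eegfp_version": __version__,
        "python": sys.version.split()[0],
        "config": yaml.safe_load(config.to_yaml()),
        "indices": {},
    }
    features_by_kind = {}
    for kind in config.indices:
        log.info("computing %s features", kind)
        by_session = {}
        for sess, eps in epochs_by_session.items():
            by_session[sess] = connectivity_dataset(
                eps, kind, order=config.gc_order, n_bins=config.mi_bins
            )
            save_features_tsv(
                by_session[sess], out_dir / f"features_{kind.lower()}_{sess}.tsv"
            )
        features_by_kind[kind] = by_session

        intra = {
            sess: intra_session_cv(
                feats, config.folds, c=config.svm_c,
                grid_search=config.grid_search, seed=config.seed,
            )
            for sess, feats in by_session.items()
        }
        entry = {"intra_session_accuracy": intra}
        if len(config.session_ids) > 1:
            tests = {
                s: by_session[s] for s in config.session_ids
                if s != config.train_session
            }
            perm = cross_session_eval(
                by_session[config.train_session], tests,
                session_days=config.session_days, c=config.svm_c,
                grid_search=config.grid_search, seed=config.seed,
            )
            entry["cross_session_accuracy"] = perm.per_session_accuracy
        report["indices"][kind] = entry

    if "GC" in features_by_kind:
        log.info("ranking connections (%s)", config.weight_method)
        wmap = feature_weights(
            features_by_kind["GC"][config.train_session],
            method=config.weight_method, seed=config.seed,
        )
        summary = major_connections(wmap, config.top_frac)
        edge_table(wmap, config.top_frac).to_csv(
            out_dir / "edge_weights.tsv", sep="\t", index=False
        )
        summary.counts.to_csv(out_dir / "region_counts.tsv", sep="\t")
        report["major_connections"] = {
            "method": wmap.method,
            "top_frac": config.top_frac,
            "n_major": len(summary.major_pairs),
            "intra_frontal_fraction": summary.intra_frontal_fraction,
            "region_counts": {
                r: summary.counts.loc[r].to_dict() for r in summary.counts.index
            },
        }

    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
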