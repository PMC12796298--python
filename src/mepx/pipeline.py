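"""End-to-end orchestration: simulate -> clean -> metrics -> reports.

A :class:`RunConfig` fully determines a run; executing the same config twice
produces byte-identical CSV/JSON artifacts.  Every stage writes its output
to ``output_dir`` so any later stage can be re-run in isolation from the
intermediate files, and real data in the stimulation CSV schema can replace
the simulated table without code changes.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import CohortConfig, generate_cohort, write_stimulation_csv
from .preprocess import build_feature_table
from .diststats import distribution_report
from .glmm import run_pc_glmm
from .classify import attribution, run_feature_set_comparison

logger = logging.getLogger("mepx")

ARTIFACTS = [
    "stimulations.csv",
    "features.csv",
    "cleaning_report.json",
    "distribution_report.csv",
    "glmm_summary.json",
    "comparison_report.json",
    "fold_metrics.csv",
    "gini_importance.csv",
    "manifest.json",
]


@dataclass
class RunConfig:
    """Everything that determines a pipeline run (all seeds included)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    iqr_k: float = 1.5
    iqr_scope: str = "global"
    cv_k: int = 10
    cv_seed: int = 0
    positive_class: str = "MDD"
    output_dir: str = "mepx_run"
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        if isinstance(cohort, dict):
            from .simulate import GroupEffectSpec, ProtocolSpec

            kwargs = dict(cohort)
            if "protocol" in kwargs and isinstance(kwargs["protocol"], dict):
                proto = dict(kwargs["protocol"])
                proto["isis_ms"] = tuple(int(i) for i in proto.get("isis_ms", ()))
                kwargs["protocol"] = ProtocolSpec(**proto)
            for key in ("effects_hc", "effects_mdd"):
                if key in kwargs and isinstance(kwargs[key], dict):
                    eff = dict(kwargs[key])
                    # JSON/YAML mapping keys arrive as strings
                    eff["isi_modulation"] = {
                        int(k): float(v) for k, v in eff.get("isi_modulation", {}).items()
                    }
                    kwargs[key] = GroupEffectSpec(**eff)
            cohort = CohortConfig(**kwargs)
        return cls(cohort=cohort, **d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["protocol"]["isis_ms"] = list(self.cohort.protocol.isis_ms)
        for key in ("effects_hc", "effects_mdd"):
            d["cohort"][key]["isi_modulation"] = {
                str(k): v for k, v in d["cohort"][key]["isi_modulation"].items()
            }
        return d


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all artifacts; returns them in memory."""
    logging.basicConfig(stream=sys.stderr, level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    probe = out_dir / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    current = {"stage": "init"}

    def stage(name):
        current["stage"] = name
        logger.info("stage: %s", name)

    try:
        stage("simulate")
        stim = generate_cohort(config.cohort)
        write_stimulation_csv(stim, out_dir / "stimulations.csv")

        stage("preprocess")
        features, cleaning = build_feature_table(stim, k=config.iqr_k, scope=config.iqr_scope)
        features.to_csv(out_dir / "features.csv", index=False)
        _write_json(out_dir / "cleaning_report.json", cleaning.to_dict())

        stage("distfit")
        dist = distribution_report(features)
        dist.to_csv(out_dir / "distribution_report.csv", index=False)

        stage("glmm")
        pc, agg, glmm_res = run_pc_glmm(features)
        agg.to_csv(out_dir / "aggregated_pc1.csv", index=False)
        _write_json(
            out_dir / "glmm_summary.json",
            {
                "pc1_loadings": dict(zip(["amplitude_uv", "delta", "rho"], pc.loadings.tolist())),
                "pc1_variance_explained": pc.variance_explained,
                "n_aggregated": len(agg),
                **glmm_res.to_dict(),
            },
        )

        stage("classify")
        report, artifacts = run_feature_set_comparison(
            features, k=config.cv_k, seed=config.cv_seed, positive_class=config.positive_class
        )
        _write_json(out_dir / "comparison_report.json", report.to_dict())
        fold_rows = []
        for name, df in report.fold_metrics.items():
            df = df.copy()
            df.insert(0, "fold", range(len(df)))
            df.insert(0, "model", name)
            fold_rows.append(df)
        pd.concat(fold_rows, ignore_index=True).to_csv(out_dir / "fold_metrics.csv", index=False)

        stage("attribution")
        attr = attribution(artifacts)
        attr.gini.to_csv(out_dir / "gini_importance.csv")
        _write_json(out_dir / "attribution_report.json", attr.to_dict())

        stage("manifest")
        # the output path is location metadata, not run configuration: keep it
        # out of the manifest so runs into different directories hash equal
        manifest_config = {k: v for k, v in config.to_dict().items() if k != "output_dir"}
        _write_json(
            out_dir / "manifest.json",
            {
                "package": "mepx",
                "version": __version__,
                "config": manifest_config,
                "stages": ["simulate", "preprocess", "distfit", "glmm", "classify", "attribution"],
                "n_stimulations": len(stim),
                "n_features": len(features),
                "fold_hash": report.fold_hash,
                "lib_versions": {
                    "numpy": np.__version__,
                    "pandas": pd.__version__,
                },
            },
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{current['stage']}': {exc}") from exc

    return {
        "stimulations": stim,
        "features": features,
        "cleaning": cleaning,
        "distribution": dist,
        "pc": pc,
        "aggregated": agg,
        "glmm": glmm_res,
        "comparison": report,
        "attribution": attr,
    }
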