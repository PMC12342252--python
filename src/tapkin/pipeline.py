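"""End-to-end run orchestration: simulate -> extract -> features -> evaluate.

A :class:`RunConfig` fully determines a run; the config is serialized into
the output directory so a re-run from the serialized config reproduces all
numerical artifacts. Plots are advisory; CSV/JSON outputs are the contract.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .features import FEATURE_COLUMNS, build_feature_table
from .model_eval import FAMILIES, CVConfig, ModelReport, nested_cv
from .signal import DEFAULT_PROMINENCE, signals_to_csv
from .synthetic import CohortSpec, generate_cohort

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce a full pipeline run."""

    seed: int = 7
    n_control: int = 47
    n_pd: int = 53
    fps: float = 30.0
    duration_s: float = 10.0
    prominence: float = DEFAULT_PROMINENCE
    families: Sequence[str] = field(default_factory=lambda: list(FAMILIES))
    outer_folds: int = 5
    inner_folds: int = 3
    make_plots: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["families"] = list(self.families)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def feature_matrix(features) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split a feature table into X, y (bradykinesia = 1) and column names."""
    X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    y = (features["label"] == "bradykinesia").to_numpy(dtype=int)
    return X, y, list(FEATURE_COLUMNS)


def run_all(config: RunConfig, out_dir) -> dict[str, ModelReport]:
    """Execute the full pipeline and write all artifacts to ``out_dir``.

    Writes: config.yaml, manifest.csv (commanded parameters), signals.csv,
    features.csv, report.json, and (optionally) ROC and importance plots.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    log.info("simulating cohort: %d control + %d pd, seed %d",
             config.n_control, config.n_pd, config.seed)
    spec = CohortSpec(
        n_control=config.n_control, n_pd=config.n_pd, seed=config.seed,
        fps=config.fps, duration_s=config.duration_s,
    )
    cohort = generate_cohort(spec)
    cohort.manifest().to_csv(out / "manifest.csv", index=False)
    signals_to_csv(cohort.signals(), out / "signals.csv")

    log.info("extracting features (prominence %.2f)", config.prominence)
    features = build_feature_table(cohort, prominence=config.prominence)
    features.to_csv(out / "features.csv", index=False)

    X, y, names = feature_matrix(features)
    reports: dict[str, ModelReport] = {}
    for fam in config.families:
        log.info("nested CV: %s", fam)
        reports[fam] = nested_cv(
            X, y,
            CVConfig(
                model_family=fam, seed=config.seed,
                outer_folds=config.outer_folds, inner_folds=config.inner_folds,
            ),
            feature_names=names,
        )
    with open(out / "report.json", "w") as fh:
        json.dump({fam: r.to_dict() for fam, r in reports.items()}, fh, indent=1)

    if config.make_plots:
        _plots(reports, out)
    return reports


def _plots(reports: dict[str, ModelReport], out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for fam, rep in reports.items():
        s = rep.summaries["auc"]
        for i, f in enumerate(rep.folds):
            if f.roc is not None:
                ax.plot(*f.roc, alpha=0.35, lw=1,
                        label=f"{fam} (AUC {s.mean:.2f}±{s.sd:.2f})" if i == 0 else None)
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="chance")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "roc.png", dpi=120)
    plt.close(fig)

    fam, rep = next(iter(reports.items()))
    if rep.feature_importances:
        names, vals = zip(*rep.feature_importances)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.barh(range(len(names)), vals)
        ax.set_yticks(range(len(names)), names)
        ax.invert_yaxis()
        ax.set_xlabel("mean |Shapley attribution|")
        ax.set_title(f"feature influence ({fam})")
        fig.tight_layout()
        fig.savefig(out / "importances.png", dpi=120)
        plt.close(fig)
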