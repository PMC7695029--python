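"""End-to-end orchestration: simulate -> rank -> select -> embed -> bench
-> summarize, from one config, with a reproducibility manifest.

Stage seeds are derived by hashing (master seed, stage name), so changing
one stage's options never perturbs another stage's randomness, and the
whole bundle is a deterministic function of the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .classification_bench import (ClassifierSpec, EvaluationReport, FAMILIES,
                                   ValidationScheme, evaluate_holdout,
                                   prefix_evaluator)
from .data_model import LabeledDataset, write_dataset
from .embedding import TsneConfig, pca_project, tsne_feature_stage, tsne_map
from .feature_ranking import RankedFeatureList, rank_features
from .feature_selection import SelectionResult, minimal_feature_search
from .summary_stats import GroupSummary, summarize_groups
from .synthetic_data import GeneratorConfig, default_parameters, generate_dataset


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.blake2s(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run depends on."""

    master_seed: int = 0
    generator: dict = field(default_factory=dict)   # GeneratorConfig overrides
    selection_threshold: float = 0.99
    selection_model: str = "knn"
    tsne_top_k: int = 3
    tsne: dict = field(default_factory=dict)        # TsneConfig overrides
    models: tuple[str, ...] = FAMILIES
    test_fraction: float = 0.2
    output_dir: str | None = None
    write_figures: bool = False
    samples_per_group: dict[int, int] | None = None  # None = study design

    def __post_init__(self):
        unknown = set(self.models) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown model name(s): {sorted(unknown)}")
        if self.selection_model not in FAMILIES:
            raise ValueError(f"unknown selection model {self.selection_model!r}")
        object.__setattr__(self, "models", tuple(self.models))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        if "samples_per_group" in raw and raw["samples_per_group"] is not None:
            raw["samples_per_group"] = {int(k): int(v)
                                        for k, v in raw["samples_per_group"].items()}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All stage outputs of one run, plus the manifest."""

    dataset: LabeledDataset
    ranking: RankedFeatureList
    selection: SelectionResult
    pca: Any
    tsne_viz: Any
    tsne_dataset: LabeledDataset
    evaluations: dict[str, dict[str, EvaluationReport]]  # regime -> model -> report
    summary: GroupSummary
    manifest: dict

    def report_dict(self) -> dict:
        """Deterministic (timing-free) machine-readable report."""
        return {
            "manifest": self.manifest,
            "ranking": self.ranking.to_records(),
            "selection": {
                "k": self.selection.k,
                "selected": list(self.selection.selected),
                "threshold": self.selection.threshold,
                "used_all_features": self.selection.used_all_features,
                "prefix_accuracies": {str(k): round(v, 6) for k, v in
                                      sorted(self.selection.prefix_accuracies.items())},
            },
            "pca_explained_variance": [round(v, 6)
                                       for v in self.pca.explained_variance],
            "evaluations": {
                regime: {model: rep.to_dict() for model, rep in sorted(reps.items())}
                for regime, reps in sorted(self.evaluations.items())
            },
        }


REGIMES = ("all_features", "selected", "tsne_mapped")


def run_pipeline(config: PipelineConfig | None = None) -> ReportBundle:
    """Run every stage in order; see module docstring for seeding scheme.

    Classifier evaluations cover three feature regimes: all 17 features,
    the selected minimal prefix, and the 2-D t-SNE mapping of the
    ``tsne_top_k`` top-ranked features.  One shared holdout split (same
    split seed) is used across models within a regime.
    """
    config = config or PipelineConfig()
    timings: dict[str, float] = {}

    def timed(stage):
        t0 = time.perf_counter()
        def done():
            timings[stage] = round(time.perf_counter() - t0, 3)
        return done

    # -- simulate ---------------------------------------------------------
    end = timed("simulate")
    params = default_parameters()
    if config.samples_per_group is not None:
        params = dataclasses.replace(params,
                                     samples_per_group=dict(config.samples_per_group))
    gen = GeneratorConfig(**{"seed": stage_seed(config.master_seed, "generate"),
                             **config.generator})
    dataset = generate_dataset(params, gen)
    end()

    # -- rank -------------------------------------------------------------
    end = timed("rank")
    ranking = rank_features(dataset)
    end()

    # -- select -----------------------------------------------------------
    end = timed("select")
    sel_spec = ClassifierSpec(config.selection_model,
                              seed=stage_seed(config.master_seed, "select"))
    selection = minimal_feature_search(
        ranking, prefix_evaluator(dataset, ranking, sel_spec),
        threshold=config.selection_threshold)
    end()

    # -- embed ------------------------------------------------------------
    end = timed("embed")
    pca = pca_project(dataset)
    tsne_cfg = TsneConfig(**{"seed": stage_seed(config.master_seed, "tsne"),
                             **config.tsne})
    tsne_viz = tsne_map(dataset, config=tsne_cfg)
    tsne_ds = tsne_feature_stage(dataset, ranking.top(config.tsne_top_k),
                                 config=tsne_cfg)
    end()

    # -- bench ------------------------------------------------------------
    end = timed("bench")
    scheme = ValidationScheme(kind="holdout", test_fraction=config.test_fraction,
                              seed=stage_seed(config.master_seed, "split"))
    model_seed = stage_seed(config.master_seed, "models")
    regimes = {
        "all_features": (dataset, None),
        "selected": (dataset, list(selection.selected)),
        "tsne_mapped": (tsne_ds, None),
    }
    evaluations: dict[str, dict[str, EvaluationReport]] = {}
    for regime, (ds, feats) in regimes.items():
        evaluations[regime] = {}
        for model in config.models:
            spec = ClassifierSpec(model, seed=model_seed)
            evaluations[regime][model] = evaluate_holdout(ds, spec, scheme,
                                                          features=feats)
    end()

    # -- summarize --------------------------------------------------------
    end = timed("summarize")
    summary = summarize_groups(dataset)
    end()

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "stage_seeds": {s: stage_seed(config.master_seed, s)
                        for s in ("generate", "select", "tsne", "split", "models")},
        "n_instances": dataset.n_instances,
        "n_samples": dataset.n_samples,
    }
    bundle = ReportBundle(dataset, ranking, selection, pca, tsne_viz, tsne_ds,
                          evaluations, summary, manifest)
    if config.output_dir:
        _write_artifacts(bundle, Path(config.output_dir), timings,
                         figures=config.write_figures)
    return bundle


def _write_artifacts(bundle: ReportBundle, outdir: Path, timings: dict,
                     figures: bool = False):
    outdir.mkdir(parents=True, exist_ok=True)
    write_dataset(bundle.dataset, outdir / "data.csv")
    with open(outdir / "report.json", "w") as fh:
        json.dump(bundle.report_dict(), fh, indent=2, sort_keys=True)
    with open(outdir / "timings.json", "w") as fh:  # wall clock: logged only
        json.dump(timings, fh, indent=2)
    bundle.summary.table.to_csv(outdir / "group_summary.csv")
    bundle.summary.formatted().to_csv(outdir / "group_summary_formatted.csv")
    _write_text_tables(bundle, outdir / "tables.txt")
    if figures:
        _write_figures(bundle, outdir)


def _write_text_tables(bundle: ReportBundle, path: Path):
    lines = ["Feature ranking (gain ratio)", "-" * 34]
    for rec in bundle.ranking.to_records():
        lines.append(f"{rec['feature']:<18} {rec['gain_ratio']:.3f}")
    lines.append("")
    lines.append(f"Selected features (k={bundle.selection.k}): "
                 + ", ".join(bundle.selection.selected))
    ev = bundle.pca.explained_variance
    lines.append(f"PCA: PC1+PC2 explained variance = {100 * (ev[0] + ev[1]):.1f}%")
    for regime, reps in bundle.evaluations.items():
        lines += ["", f"Classifier performance ({regime})", "-" * 34,
                  f"{'Model':<16}{'CA':>8}{'F1':>8}"]
        for model, rep in sorted(reps.items(), key=lambda kv: -kv[1].accuracy):
            lines.append(f"{model:<16}{rep.accuracy:>8.3f}{rep.f1:>8.3f}")
    path.write_text("\n".join(lines) + "\n")


def _write_figures(bundle: ReportBundle, outdir: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .embedding import plot_embedding

    y = bundle.dataset.y
    for name, emb in (("pca", bundle.pca), ("tsne", bundle.tsne_viz)):
        ax = plot_embedding(emb, y, title=name.upper())
        ax.figure.savefig(outdir / f"{name}.png", dpi=150,
                          bbox_inches="tight")
        plt.close(ax.figure)
    # confusion heatmap of the best and worst model in the t-SNE regime
    reps = bundle.evaluations.get("tsne_mapped", {})
    if reps:
        ordered = sorted(reps.items(), key=lambda kv: kv[1].accuracy)
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, (model, rep) in zip(axes, (ordered[0], ordered[-1])):
            im = ax.imshow(rep.confusion_proportions, cmap="Blues",
                           vmin=0, vmax=1)
            ax.set_title(f"{model} (CA={rep.accuracy:.3f})")
            ax.set_xlabel("predicted")
            ax.set_ylabel("actual")
            fig.colorbar(im, ax=ax, fraction=0.046)
        fig.savefig(outdir / "confusion.png", dpi=150, bbox_inches="tight")
        plt.close(fig)
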