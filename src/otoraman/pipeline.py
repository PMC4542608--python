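"""End-to-end orchestration: generate/ingest -> despike -> screen -> PCA
-> RadViz -> PLS-DA evaluation, as one seeded, logged, reproducible run.

A single global seed deterministically derives one sub-seed per stage
(SHA-256 of ``"{seed}:{stage}"``, reduced below 2**31), so any stage can
be replayed in isolation and a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from .datatypes import SpectralDataset
from .decomposition import pca_fit, per_class_pca
from .evaluation import ResamplingPlan, balanced_resample_evaluate, binary_task, negative_control
from .io import load_dataset
from .preprocess import despike_dataset
from .radviz import radviz_embed, select_anchor_pcs
from .screen import assigned_labels, assignments_frame, screen_dataset
from .synthetic import SimulationConfig, generate_dataset

log = logging.getLogger("otoraman")

MINERALIZED = "mineralized_myringosclerosis"
CHOLESTEATOMA = "cholesteatoma"
NONMINERALIZED = "nonmineralized_myringosclerosis"


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source: ``generator`` (synthetic cohort settings,
    a :class:`SimulationConfig` or kwargs dict) or ``manifest`` (path to a
    measured-spectra manifest TSV). ``rng_seed`` is mandatory and derives
    every stage-level seed.
    """

    rng_seed: int
    output_dir: str = "otoraman-run"
    generator: Optional[Any] = None
    manifest: Optional[str] = None
    despike: dict = field(default_factory=lambda: {"window": 7, "threshold": 8.0})
    screen: dict = field(
        default_factory=lambda: {"band_center": 960.0, "band_width": 20.0, "snr_threshold": 5.0}
    )
    pca: dict = field(default_factory=lambda: {"n_components": 7})
    radviz: dict = field(default_factory=lambda: {"k_select": 7})
    plsda: dict = field(
        default_factory=lambda: {
            "n_iterations": 100,
            "train_fraction": 0.6,
            "n_components": None,
        }
    )

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.manifest is None):
            raise ValueError("configure exactly one input source: generator or manifest")
        if self.rng_seed is None:
            raise ValueError("rng_seed is mandatory")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(self.generator, SimulationConfig):
            d["generator"] = {
                k: v for k, v in dataclasses.asdict(self.generator).items() if k != "phenotypes"
            }
        return d


def _build_dataset(cfg: RunConfig) -> SpectralDataset:
    if cfg.generator is not None:
        gen = cfg.generator
        if not isinstance(gen, SimulationConfig):
            gen = SimulationConfig(**dict(gen))
        gen = dataclasses.replace(gen, rng_seed=stage_seed(cfg.rng_seed, "generate"))
        log.info("generate: %d phenotypes, seed %d", len(gen.phenotypes), gen.rng_seed)
        return generate_dataset(gen)
    return load_dataset(cfg.manifest)


def run_pipeline(cfg: RunConfig, write: bool = True) -> dict:
    """Execute the full chain; returns the machine-readable summary.

    With ``write=True`` stage outputs land under ``cfg.output_dir``:
    screen assignments TSV, pooled PCA loadings/scores TSV, RadViz
    embedding TSV, ROC points TSV, and ``summary.json``.
    """
    outdir = Path(cfg.output_dir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)

    dataset = _build_dataset(cfg)
    log.info("dataset: %d spectra x %d channels", dataset.n_spectra, dataset.n_channels)

    dataset, spike_report = despike_dataset(dataset, **cfg.despike)
    log.info("despike: spikes removed in %d spectra", len(spike_report))

    assignments = screen_dataset(dataset, **cfg.screen)
    labels = assigned_labels(assignments, dataset)
    counts = {str(c): int(n) for c, n in zip(*np.unique(labels, return_counts=True))}
    log.info("screen: class counts %s", counts)

    pooled = pca_fit(dataset, **cfg.pca)
    class_models = per_class_pca(dataset, labels, **cfg.pca)

    anchor_idx = select_anchor_pcs(pooled, labels, **cfg.radviz)
    embedding = radviz_embed(
        pooled.scores_[:, anchor_idx], [f"PC{j + 1}" for j in anchor_idx]
    )

    plan = ResamplingPlan(
        n_iterations=cfg.plsda["n_iterations"],
        train_fraction=cfg.plsda["train_fraction"],
        rng_seed=stage_seed(cfg.rng_seed, "plsda"),
    )
    n_comp = cfg.plsda.get("n_components")
    three_class = balanced_resample_evaluate(dataset, labels, plan, n_components=n_comp)
    control = negative_control(dataset, labels, plan, n_components=n_comp or 3)

    bin_ds, bin_labels = binary_task(dataset, labels, MINERALIZED, CHOLESTEATOMA)
    bin_cm = balanced_resample_evaluate(
        bin_ds, bin_labels, plan, n_components=n_comp, positive_class=MINERALIZED
    )
    rest_ds, rest_labels = binary_task(
        dataset, labels, MINERALIZED, [CHOLESTEATOMA, NONMINERALIZED]
    )
    bin_rest = balanced_resample_evaluate(
        rest_ds, rest_labels, plan, n_components=n_comp, positive_class=MINERALIZED
    )

    summary = {
        "n_spectra": dataset.n_spectra,
        "n_channels": dataset.n_channels,
        "despiked_spectra": len(spike_report),
        "class_counts": counts,
        "three_class": {
            "mean_correct_rate_percent": {
                k: round(100.0 * v, 2) for k, v in three_class.mean_class_rates.items()
            },
            "overall_percent": round(100.0 * three_class.overall_rate, 2),
            "n_latent": three_class.n_components_used,
        },
        "negative_control": {
            "overall_percent": round(100.0 * control.overall_rate, 2),
            "chance_level_percent": round(100.0 / len(control.class_order), 2),
        },
        "binary_mineralized_vs_cholesteatoma": {
            **bin_cm.binary.as_percent(),
            "AUC": round(bin_cm.auc, 4),
        },
        "binary_mineralized_vs_rest": {
            **bin_rest.binary.as_percent(),
            "AUC": round(bin_rest.auc, 4),
        },
        "config": cfg.resolved(),
    }
    if "true_label" in dataset.meta.columns:
        truth = dataset.meta["true_label"].to_numpy()
        summary["screen_agreement_with_truth_percent"] = round(
            100.0 * float(np.mean(labels == truth)), 2
        )

    if write:
        assignments_frame(assignments).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
        pd.DataFrame(
            pooled.loadings_.T,
            index=dataset.wavenumbers,
            columns=[f"PC{j + 1}" for j in range(pooled.loadings_.shape[0])],
        ).to_csv(outdir / "pca_loadings.tsv", sep="\t", index_label="wavenumber_cm-1")
        pd.DataFrame(
            {
                "site_id": dataset.site_ids,
                "x": embedding.points[:, 0],
                "y": embedding.points[:, 1],
                "assigned_class": labels,
            }
        ).to_csv(outdir / "radviz.tsv", sep="\t", index=False)
        pd.DataFrame(bin_cm.roc_points, columns=["fpr", "tpr"]).to_csv(
            outdir / "roc_mineralized_vs_cholesteatoma.tsv", sep="\t", index=False
        )
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
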