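"""End-to-end orchestration: calling -> scoring -> selection stats ->
constraint analysis -> landscapes, driven by a declarative run config."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calling import (
    CallingConfig,
    MutantCountMatrix,
    SampleInfo,
    apply_count_filter,
    call_fastq,
    call_sam,
    collapse_to_aa,
)
from .constraints import (
    assign_subsets,
    cluster_correlations,
    cross_env_correlation_resample,
    feature_fitness_correlations,
    subset_significance,
    subsetwise_selection,
)
from .landscape import build_grid_from_table, render
from .scoring import classify, neutrality_thresholds, score_environment, write_fitness_table
from .selection import compare_environments
from .structure import load_feature_table

log = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised before any compute when a run config is inconsistent."""


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class SampleInput:
    environment: str
    pool: str
    replicate: int
    fastq: str | None = None
    sam: str | None = None
    counts: str | None = None

    @property
    def info(self) -> SampleInfo:
        return SampleInfo(self.environment, self.pool, self.replicate)


@dataclass
class RunConfig:
    reference_environment: str
    samples: list[SampleInput]
    reference_fasta: str | None = None
    features: str | None = None
    seed: int = 0
    outdir: str = "dmsenv_out"
    n_draws: int = 1000
    n_boot: int = 1000
    subset_band: float = 10.0
    landscape_resolution: int = 100
    render_landscapes: bool = True
    calling: CallingConfig = field(default_factory=CallingConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        samples = [SampleInput(**s) for s in raw.pop("samples", [])]
        calling = CallingConfig(**raw.pop("calling", {}))
        return cls(samples=samples, calling=calling, **raw)

    def validate(self) -> None:
        if not self.samples:
            raise ValidationError("no samples configured")
        envs = {s.environment for s in self.samples}
        if self.reference_environment not in envs:
            raise ValidationError(
                f"reference environment {self.reference_environment!r} has no samples"
            )
        keys = {(s.environment, s.pool, s.replicate) for s in self.samples}
        if len(keys) != len(self.samples):
            raise ValidationError("duplicate (environment, pool, replicate) sample entries")
        for s in self.samples:
            if s.pool == "selected" and (s.environment, "unselected", s.replicate) not in keys:
                raise ValidationError(
                    f"selected pool {s.environment}/rep{s.replicate} has no matching unselected pool"
                )
            if not (s.fastq or s.sam or s.counts):
                raise ValidationError(f"sample {s.info.name} has no input (fastq/sam/counts)")
            if (s.fastq or s.sam) and not self.reference_fasta:
                raise ValidationError("reference_fasta required when calling from reads")


def score_simulation(config, min_reads: int = 3):
    """Convenience: simulate counts in memory and score every environment.

    Returns (truth, features, tables) where features holds the true
    ddG/dist_active of non-synonymous mutants keyed like the fitness tables.
    The per-variant count filter is applied to the simulated matrices,
    mirroring the calling stage.
    """
    from .calling import apply_count_filter
    from .simulate import assign_true_features, generate_library, ground_truth, random_reference
    from .simulate import simulate_counts as _simulate_counts

    reference = random_reference(config)
    catalogue = generate_library(reference, config)
    truth = ground_truth(assign_true_features(catalogue, config), config)
    counts = {k: apply_count_filter(m, min_reads) for k, m in _simulate_counts(truth, config).items()}
    tables: dict[str, pd.DataFrame] = {}
    for env in config.environments:
        reps = range(1, config.n_replicates + 1)
        pairs = [(counts[(env.name, "selected", r)], counts[(env.name, "unselected", r)]) for r in reps]
        tables[env.name] = score_environment(pairs, environment=env.name)
    features = truth.rename(columns={"wt_codon": "wt", "mut_codon": "mut"})
    features = features.loc[~features["synonymous"], ["position", "wt", "mut", "ddG", "dist_active"]]
    return truth, features, tables


def _read_fasta(path: str | Path) -> str:
    lines = Path(path).read_text().splitlines()
    seq = "".join(line.strip() for line in lines if not line.startswith(">"))
    if not seq:
        raise ValidationError(f"empty FASTA: {path}")
    return seq.upper()


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) a machine-readable report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "reference_environment": config.reference_environment,
        "manifest": {"samples": [s.__dict__ | {} for s in config.samples]},
    }

    # ---- stage: variant calling ------------------------------------------
    try:
        reference = _read_fasta(config.reference_fasta) if config.reference_fasta else None
        matrices: dict[tuple[str, str, int], MutantCountMatrix] = {}
        for s in config.samples:
            if s.counts:
                # externally supplied counts get the same per-variant cutoff
                m = apply_count_filter(
                    MutantCountMatrix.from_tsv(s.counts, level="codon", sample=s.info),
                    config.calling.min_reads_per_variant,
                )
            elif s.sam:
                m = call_sam(s.sam, reference, config.calling, sample=s.info)
            else:
                m = call_fastq(s.fastq, reference, config.calling, sample=s.info)
            matrices[(s.environment, s.pool, s.replicate)] = collapse_to_aa(m)
    except ValidationError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("calling", str(exc)) from exc

    # ---- stage: fitness scoring ------------------------------------------
    try:
        envs = sorted({e for e, _, _ in matrices})
        tables: dict[str, pd.DataFrame] = {}
        for env in envs:
            reps = sorted({r for e, p, r in matrices if e == env and p == "selected"})
            pairs = [
                (matrices[(env, "selected", r)], matrices[(env, "unselected", r)]) for r in reps
            ]
            tables[env] = score_environment(pairs, environment=env)
        ref_unselected = [
            matrices[k] for k in sorted(matrices) if k[0] == config.reference_environment and k[1] == "unselected"
        ]
        thresholds = None
        if len(ref_unselected) >= 2:
            thresholds = neutrality_thresholds(ref_unselected)
            tables = {env: classify(t, thresholds) for env, t in tables.items()}
            report["neutrality_thresholds"] = {
                "lower": thresholds.lower, "upper": thresholds.upper,
                "mu0": thresholds.mu0, "sigma0": thresholds.sigma0,
            }
        scores_dir = outdir / "fitness"
        scores_dir.mkdir(exist_ok=True)
        for env, t in tables.items():
            write_fitness_table(t, scores_dir / f"{env}.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("scoring", str(exc)) from exc

    # ---- stage: selection statistics -------------------------------------
    try:
        summary, _ = compare_environments(
            tables, config.reference_environment, n_draws=config.n_draws, seed=config.seed
        )
        summary.to_csv(outdir / "environment_summary.tsv", sep="\t", index=False)
        report["environments"] = summary.replace([np.inf], "inf").fillna("").to_dict("records")
    except Exception as exc:  # noqa: BLE001
        raise StageError("selection_stats", str(exc)) from exc

    # ---- stage: constraint analysis + landscapes -------------------------
    if config.features:
        try:
            features = load_feature_table(config.features)
            corr = cluster_correlations(feature_fitness_correlations(tables, features))
            corr.r.to_csv(outdir / "feature_correlations.tsv", sep="\t")
            corr.p.to_csv(outdir / "feature_correlation_pvalues.tsv", sep="\t")
            assignment = assign_subsets(features, band=config.subset_band)
            feat_out = features.copy()
            feat_out["subset"] = assignment.labels
            feat_out.to_csv(outdir / "subset_assignment.tsv", sep="\t", index=False)
            subset_s, _ = subsetwise_selection(
                tables, features, assignment, n_draws=config.n_draws, seed=config.seed
            )
            subset_s.to_csv(outdir / "subset_selection.tsv", sep="\t", index=False)
            report["subset_selection"] = subset_s.fillna("").to_dict("records")
            if subset_s["environment"].nunique() >= 4:
                sig = subset_significance(subset_s)
                sig.to_csv(outdir / "subset_significance.tsv", sep="\t", index=False)
            cross_rows = []
            for env in tables:
                if env == config.reference_environment:
                    continue
                res = cross_env_correlation_resample(
                    tables[env], tables[config.reference_environment],
                    features, assignment, n_boot=config.n_boot, seed=config.seed,
                )
                s = res.summary.copy()
                s.insert(0, "environment", env)
                cross_rows.append(s)
            if cross_rows:
                pd.concat(cross_rows).to_csv(outdir / "cross_env_correlations.tsv", sep="\t", index=False)
        except Exception as exc:  # noqa: BLE001
            raise StageError("constraint_analysis", str(exc)) from exc

        try:
            grids = {}
            for env, t in tables.items():
                try:
                    grids[env] = build_grid_from_table(t, features, resolution=config.landscape_resolution)
                except ValueError as err:
                    log.warning("no landscape for %s: %s", env, err)
            land_dir = outdir / "landscapes"
            land_dir.mkdir(exist_ok=True)
            for env, grid in grids.items():
                grid.to_tsv(land_dir / f"{env}.tsv")
            if grids and config.render_landscapes:
                render(grids, land_dir)
            report["landscapes"] = sorted(grids)
        except Exception as exc:  # noqa: BLE001
            raise StageError("landscape", str(exc)) from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    return report
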