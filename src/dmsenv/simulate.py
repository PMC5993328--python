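"""Synthetic single-site mutant library with environment-dependent selection.

Ground-truth fitness follows a folding x binding double-sigmoid: a folding
cliff on the stability axis (default 2 kcal/mol, shiftable per environment)
and a binding cliff on the distance-to-active-site axis (default 15 A).
Counts are drawn as multinomial samples of a single multiplicative selection
round; reads are emitted as full-length amplicons with two-point base
qualities so the downstream quality filters can be exercised.
"""

from __future__ import annotations

import gzip
import io
import zlib
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .calling import MutantCountMatrix, SampleInfo
from .genetic_code import CODON_TO_AA, NNK_CODONS, translate_codon

ELIMINATED = -np.inf  # fitness marker for fully eliminated mutants

CATALOGUE_COLUMNS = ["position", "wt_codon", "mut_codon", "wt_aa", "mut_aa", "synonymous"]


@dataclass(frozen=True)
class EnvironmentSpec:
    """Selection regime of one environment.

    ``folding_shift`` (kcal/mol) is added to every mutant's effective ddG:
    positive under folding stress (heat), negative under chemical chaperones.
    ``binding_cliff`` (A) is the distance below which binding is compromised;
    it grows with antibiotic dose.  Mutants with true fitness below
    ``elimination_floor`` are removed from the selected pool entirely.
    """

    name: str
    folding_shift: float = 0.0
    binding_cliff: float = 15.0
    elimination_floor: float = -7.0

    def __post_init__(self) -> None:
        if self.binding_cliff < 0:
            raise ValueError("binding_cliff must be >= 0")


@dataclass(frozen=True)
class FitnessModel:
    """Parameters of the folding x binding fitness surface."""

    folding_cliff: float = 2.0  # kcal/mol
    folding_scale: float = 0.5  # kcal/mol, sigmoid softness on the folding axis
    binding_scale: float = 2.0  # A, sigmoid softness on the binding axis
    f_min: float = -8.0  # log2 fitness of a fully compromised mutant

    def __post_init__(self) -> None:
        if self.folding_scale <= 0 or self.binding_scale <= 0:
            raise ValueError("sigmoid scales must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    gene_length_codons: int = 177
    library_spec: str = "all_single_codon_NNK"  # or "random_subset"
    subset_size: int = 2000
    depth_per_sample: int = 100_000
    n_replicates: int = 2
    environments: tuple[EnvironmentSpec, ...] = (EnvironmentSpec("reference"),)
    seed: int = 0
    read_length: int | None = None  # default: full amplicon (3 x gene length)
    q_high: int = 40
    q_low: int = 20
    low_q_fraction: float = 0.0
    error_rate: float = 0.0
    model: FitnessModel = field(default_factory=FitnessModel)
    # ddG ~ loc + Gamma(shape, scale); right-skewed, support >= loc
    ddg_shape: float = 2.0
    ddg_scale: float = 1.5
    ddg_loc: float = -1.0
    dist_range: tuple[float, float] = (3.0, 40.0)

    def __post_init__(self) -> None:
        if self.gene_length_codons < 1:
            raise ValueError("gene_length_codons must be positive")
        if self.depth_per_sample < 1:
            raise ValueError("depth_per_sample must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if not 0.0 <= self.error_rate <= 0.01:
            raise ValueError("error_rate must be in [0, 0.01]")
        if self.library_spec not in ("all_single_codon_NNK", "random_subset"):
            raise ValueError(f"unknown library_spec {self.library_spec!r}")

    @property
    def amplicon_length(self) -> int:
        return 3 * self.gene_length_codons

    @property
    def effective_read_length(self) -> int:
        return self.read_length if self.read_length is not None else self.amplicon_length

    def environment(self, name: str) -> EnvironmentSpec:
        for env in self.environments:
            if env.name == name:
                return env
        raise KeyError(name)


def ddg_mean(config: SimulationConfig) -> float:
    """Mean of the configured ddG distribution (shifted gamma)."""
    return config.ddg_loc + config.ddg_shape * config.ddg_scale


def graded_stress_config(
    seed: int = 0,
    gene_length_codons: int = 70,
    depth_per_sample: int = 100_000,
    folding_shift: float = 1.25,
) -> SimulationConfig:
    """Reference + folding-stressed environment pair with graded elimination.

    Sigmoid scales are softened and the fitness floor deepened so that
    elimination is driven by sampling depth rather than the hard floor; the
    survival gradient then resolves the folding x binding subset ordering.
    """
    model = FitnessModel(folding_cliff=2.0, folding_scale=1.0, binding_scale=3.5, f_min=-10.0)
    return SimulationConfig(
        gene_length_codons=gene_length_codons,
        depth_per_sample=depth_per_sample,
        seed=seed,
        environments=(
            EnvironmentSpec("reference", elimination_floor=-30.0),
            EnvironmentSpec("stressed", folding_shift=folding_shift, elimination_floor=-30.0),
        ),
        model=model,
    )


# ---------------------------------------------------------------------------
# reference and library


def random_reference(config: SimulationConfig) -> str:
    """Random stop-free coding sequence starting with ATG, seed-determined."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    sense_codons = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
    codons = ["ATG"]
    idx = rng.integers(0, len(sense_codons), size=config.gene_length_codons - 1)
    codons.extend(sense_codons[i] for i in idx)
    return "".join(codons)


def _check_reference(reference: str) -> str:
    reference = reference.upper()
    if set(reference) - set("ACGT"):
        bad = sorted(set(reference) - set("ACGT"))
        raise ValueError(f"reference contains non-ACGT symbols: {bad}")
    if len(reference) % 3:
        raise ValueError("reference length not divisible by 3")
    return reference


def enumerate_nnk(reference: str) -> pd.DataFrame:
    """All position x NNK-codon combinations, including wild-type codons."""
    reference = _check_reference(reference)
    rows = []
    for pos in range(1, len(reference) // 3 + 1):
        wt_codon = reference[(pos - 1) * 3 : pos * 3]
        wt_aa = translate_codon(wt_codon)
        for mut_codon in NNK_CODONS:
            rows.append(
                {
                    "position": pos,
                    "wt_codon": wt_codon,
                    "mut_codon": mut_codon,
                    "wt_aa": wt_aa,
                    "mut_aa": translate_codon(mut_codon),
                }
            )
    df = pd.DataFrame(rows)
    df["synonymous"] = df["wt_aa"] == df["mut_aa"]
    return df


def generate_library(reference: str, config: SimulationConfig) -> pd.DataFrame:
    """Single-site mutant catalogue; every entry differs from the reference
    in exactly one codon (wild-type codons are dropped after enumeration)."""
    catalogue = enumerate_nnk(reference)
    catalogue = catalogue[catalogue["mut_codon"] != catalogue["wt_codon"]].reset_index(drop=True)
    if config.library_spec == "random_subset":
        if config.subset_size > len(catalogue):
            raise ValueError("subset_size exceeds catalogue size")
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        keep = np.sort(rng.choice(len(catalogue), size=config.subset_size, replace=False))
        catalogue = catalogue.iloc[keep].reset_index(drop=True)
    return catalogue[CATALOGUE_COLUMNS]


# ---------------------------------------------------------------------------
# ground truth


def assign_true_features(catalogue: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Attach true ddG and distance-to-active-site to a mutant catalogue.

    ddG is drawn per non-synonymous substitution from a right-skewed shifted
    gamma; distance is drawn once per position (uniform) and shared by every
    substitution at that position; synonymous entries get ddG = 0.
    """
    if catalogue.empty:
        raise ValueError("empty catalogue")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    out = catalogue.copy()
    positions = np.sort(out["position"].unique())
    lo, hi = config.dist_range
    dist_by_pos = pd.Series(rng.uniform(lo, hi, size=len(positions)), index=positions)
    out["dist_active"] = out["position"].map(dist_by_pos)
    ddg = config.ddg_loc + rng.gamma(config.ddg_shape, config.ddg_scale, size=len(out))
    ddg[out["synonymous"].to_numpy()] = 0.0
    out["ddG"] = ddg
    return out


def true_fitness(
    ddg: np.ndarray | float,
    dist: np.ndarray | float,
    env: EnvironmentSpec,
    model: FitnessModel | None = None,
) -> np.ndarray | float:
    """Folding x binding double-sigmoid fitness, in log2 units.

    F = f_min + (0 - f_min) * w_fold * w_bind with
    w_fold = 1 / (1 + exp((ddG + shift - G0) / k_G)) and
    w_bind = 1 / (1 + exp((D0 - dist) / k_D)).
    """
    model = model or FitnessModel()
    ddg = np.asarray(ddg, dtype=float)
    dist = np.asarray(dist, dtype=float)
    w_fold = 1.0 / (1.0 + np.exp((ddg + env.folding_shift - model.folding_cliff) / model.folding_scale))
    w_bind = 1.0 / (1.0 + np.exp((env.binding_cliff - dist) / model.binding_scale))
    f = model.f_min + (0.0 - model.f_min) * w_fold * w_bind
    return f if f.ndim else float(f)


def ground_truth(truth_features: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Per-environment true fitness and survival columns.

    Synonymous mutants are neutral by construction (F_true = 0 everywhere).
    Adds ``F_true_{env}`` and ``survives_{env}`` columns.
    """
    out = truth_features.copy()
    syn = out["synonymous"].to_numpy()
    for env in config.environments:
        f = np.asarray(
            true_fitness(out["ddG"].to_numpy(), out["dist_active"].to_numpy(), env, config.model)
        )
        f[syn] = 0.0
        survives = f >= env.elimination_floor
        out[f"F_true_{env.name}"] = np.where(survives, f, ELIMINATED)
        out[f"survives_{env.name}"] = survives
    return out


# ---------------------------------------------------------------------------
# sampling


def _stable_hash(text: str) -> int:
    """Process-independent 32-bit hash (Python's str hash is salted)."""
    return zlib.crc32(text.encode())


def _sample_rng(config: SimulationConfig, env: str, pool: str, rep: int) -> np.random.Generator:
    key = [config.seed, 3, _stable_hash(env), 0 if pool == "unselected" else 1, rep]
    return np.random.default_rng(np.random.SeedSequence(key))


def simulate_counts(
    truth: pd.DataFrame, config: SimulationConfig
) -> dict[tuple[str, str, int], MutantCountMatrix]:
    """Draw unselected/selected count matrices for every environment/replicate.

    Unselected counts are multinomial over uniform library proportions.
    Selected proportions are uniform * 2**F_true after zeroing eliminated
    mutants (single multiplicative selection round).
    """
    n = len(truth)
    n_positions = int(truth["position"].max())
    depth = config.depth_per_sample
    uniform = np.full(n, 1.0 / n)
    out: dict[tuple[str, str, int], MutantCountMatrix] = {}
    for env in config.environments:
        f_true = truth[f"F_true_{env.name}"].to_numpy()
        weights = np.where(np.isfinite(f_true), np.exp2(np.where(np.isfinite(f_true), f_true, 0.0)), 0.0)
        selected_p = uniform * weights
        total = selected_p.sum()
        if total <= 0:
            raise ValueError(f"all mutants eliminated in environment {env.name!r}")
        selected_p /= total
        for rep in range(1, config.n_replicates + 1):
            for pool, p in (("unselected", uniform), ("selected", selected_p)):
                rng = _sample_rng(config, env.name, pool, rep)
                counts = rng.multinomial(depth, p)
                out[(env.name, pool, rep)] = _counts_to_matrix(
                    truth, counts, n_positions, depth, SampleInfo(env.name, pool, rep)
                )
    return out


def _counts_to_matrix(
    truth: pd.DataFrame,
    counts: np.ndarray,
    n_positions: int,
    depth: int,
    sample: SampleInfo,
) -> MutantCountMatrix:
    df = pd.DataFrame(
        {
            "position": truth["position"].to_numpy(),
            "wt": truth["wt_codon"].to_numpy(),
            "mut": truth["mut_codon"].to_numpy(),
            "count": counts,
            "synonymous": truth["synonymous"].to_numpy(),
            "stop": (truth["mut_aa"] == "*").to_numpy(),
        }
    )
    # full-length amplicons: every read covers every position
    depth_s = pd.Series(
        np.full(n_positions, depth, dtype=np.int64),
        index=pd.RangeIndex(1, n_positions + 1, name="position"),
    )
    return MutantCountMatrix(level="codon", counts=df, depth=depth_s, sample=sample)


# ---------------------------------------------------------------------------
# reads


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def emit_reads(
    matrix: MutantCountMatrix,
    reference: str,
    config: SimulationConfig,
    path: str | Path,
    compress: bool = False,
) -> Path:
    """Write one FASTQ of full-length amplicon reads for a count matrix.

    Each variant contributes exactly ``count`` reads.  A ``low_q_fraction``
    of reads (chosen deterministically from the sample seed) carries uniform
    quality ``q_low`` (mean below the Q30 filter); the rest carry ``q_high``.
    Substitution errors are applied at ``error_rate`` per base.
    """
    reference = _check_reference(reference)
    if config.effective_read_length < 3 * config.gene_length_codons:
        raise ValueError("read_length must cover the full amplicon in default mode")
    sample = matrix.sample or SampleInfo("na", "unselected", 0)
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [config.seed, 4, _stable_hash(sample.environment),
             0 if sample.pool == "unselected" else 1, sample.replicate]
        )
    )
    path = Path(path)
    buf = io.StringIO()
    q_high_str = chr(config.q_high + 33) * len(reference)
    q_low_str = chr(config.q_low + 33) * len(reference)
    read_no = 0
    for row in matrix.counts.itertuples(index=False):
        start = (row.position - 1) * 3
        seq = reference[:start] + row.mut + reference[start + 3 :]
        for _ in range(int(row.count)):
            read_no += 1
            out_seq = seq
            if config.error_rate > 0:
                arr = np.frombuffer(out_seq.encode(), dtype=np.uint8).copy()
                hits = np.nonzero(rng.random(len(arr)) < config.error_rate)[0]
                for i in hits:
                    choices = _BASES[_BASES != arr[i]]
                    arr[i] = rng.choice(choices)
                out_seq = arr.tobytes().decode()
            qual = q_low_str if rng.random() < config.low_q_fraction else q_high_str
            buf.write(f"@{sample.name}:{read_no}\n{out_seq}\n+\n{qual}\n")
    data = buf.getvalue()
    if compress:
        path = path if path.suffix == ".gz" else path.with_suffix(path.suffix + ".gz")
        with gzip.open(path, "wt") as fh:
            fh.write(data)
    else:
        path.write_text(data)
    return path


# ---------------------------------------------------------------------------
# dataset on disk


def write_dataset(config: SimulationConfig, outdir: str | Path, reads: bool = True,
                  reference: str | None = None) -> dict:
    """Generate a complete synthetic experiment under ``outdir``.

    Writes reference.fasta, catalogue.tsv, ground_truth.tsv, per-sample count
    TSVs and (optionally) FASTQ files.  Returns a manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = _check_reference(reference) if reference else random_reference(config)
    catalogue = generate_library(ref, config)
    truth = ground_truth(assign_true_features(catalogue, config), config)
    counts = simulate_counts(truth, config)

    (outdir / "reference.fasta").write_text(f">reference\n{ref}\n")
    catalogue.to_csv(outdir / "catalogue.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    manifest: dict = {"reference": "reference.fasta", "samples": [], "seed": config.seed}
    counts_dir = outdir / "counts"
    counts_dir.mkdir(exist_ok=True)
    reads_dir = outdir / "reads"
    if reads:
        reads_dir.mkdir(exist_ok=True)
    for (env, pool, rep), matrix in counts.items():
        name = f"{env}_{pool}_{rep}"
        matrix.to_tsv(counts_dir / f"{name}.tsv")
        entry = {
            "environment": env,
            "pool": pool,
            "replicate": rep,
            "counts": f"counts/{name}.tsv",
        }
        if reads:
            fq = emit_reads(matrix, ref, config, reads_dir / f"{name}.fastq")
            entry["fastq"] = f"reads/{fq.name}"
        manifest["samples"].append(entry)
    return manifest
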