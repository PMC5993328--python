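"""Codon-level variant calling from amplicon reads.

Reads are placed on the reference by an exact-match anchor (or taken from an
externally produced SAM), compared codon-by-codon in frame, filtered on mean
read/codon quality, and accumulated into a single-site mutant count matrix
which can be collapsed to amino-acid level.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .genetic_code import translate_codon

log = logging.getLogger(__name__)

CODON_COLUMNS = ["position", "wt", "mut", "count"]


@dataclass(frozen=True)
class CallingConfig:
    """Quality and count filters applied during variant calling.

    ``min_read_mean_q`` / ``min_codon_mean_q`` are strict lower bounds: a read
    (or mutated codon) whose mean Phred quality is <= the threshold is
    rejected.  ``min_reads_per_variant`` is inclusive: a variant seen exactly
    that many times is retained.
    """

    min_read_mean_q: float = 30.0
    min_codon_mean_q: float = 30.0
    min_reads_per_variant: int = 3
    anchor_length: int = 20
    max_mutated_codons_per_read: int = 1

    def __post_init__(self) -> None:
        for name in (
            "min_read_mean_q",
            "min_codon_mean_q",
            "min_reads_per_variant",
            "anchor_length",
            "max_mutated_codons_per_read",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class SampleInfo:
    environment: str
    pool: str  # "selected" | "unselected"
    replicate: int

    def __post_init__(self) -> None:
        if self.pool not in ("selected", "unselected"):
            raise ValueError(f"pool must be selected/unselected, got {self.pool!r}")

    @property
    def name(self) -> str:
        return f"{self.environment}_{self.pool}_{self.replicate}"


@dataclass
class MutantCountMatrix:
    """Counts of single-site variants plus per-position retained-read depth.

    ``counts`` columns: position (1-based codon index), wt, mut, count and —
    at amino-acid level — synonymous/stop flags.  ``depth`` maps codon
    position -> number of retained reads covering it (wild-type reads count
    toward depth only).
    """

    level: str  # "codon" | "aa"
    counts: pd.DataFrame
    depth: pd.Series
    sample: SampleInfo | None = None
    n_wt_reads: int = 0
    n_rejected: int = 0
    n_variant_reads: int = 0  # quality-retained variant reads, before count filter

    def __post_init__(self) -> None:
        if self.level not in ("codon", "aa"):
            raise ValueError(f"level must be codon/aa, got {self.level!r}")
        if (self.counts["count"] < 0).any():
            raise ValueError("negative counts")

    def total_variant_reads(self) -> int:
        return int(self.counts["count"].sum())

    def to_tsv(self, path: str | Path) -> None:
        df = self.counts.copy()
        df["depth"] = df["position"].map(self.depth).astype("Int64")
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, level: str = "codon", sample: SampleInfo | None = None
    ) -> "MutantCountMatrix":
        df = pd.read_csv(path, sep="\t")
        depth = df.groupby("position")["depth"].first()
        counts = df.drop(columns=["depth"])
        return cls(level=level, counts=counts, depth=depth, sample=sample)


# ---------------------------------------------------------------------------
# read placement and calling


def _unique_match(ref: str, anchor: str) -> int | None:
    first = ref.find(anchor)
    if first < 0 or ref.find(anchor, first + 1) >= 0:
        return None  # absent or ambiguous
    return first


def align_read(seq: str, reference: str, config: CallingConfig) -> int | None:
    """Locate a read on the reference by exact anchor match.

    The read's leading ``anchor_length`` nt are matched exactly against the
    reference; if that fails (e.g. the single mutated codon falls inside the
    head anchor) the trailing anchor is tried.  Returns the 0-based reference
    offset, or None when no unique anchor placement keeps the read fully
    within the reference.
    """
    if len(reference) % 3:
        raise ValueError("reference length not divisible by 3")
    k = config.anchor_length
    if len(seq) < k:
        return None
    seq = seq.upper()
    ref = reference.upper()
    head = _unique_match(ref, seq[:k])
    if head is not None and head + len(seq) <= len(ref):
        return head
    tail = _unique_match(ref, seq[-k:])
    if tail is not None:
        offset = tail + k - len(seq)
        if offset >= 0 and offset + len(seq) <= len(ref):
            return offset
    return None


@dataclass(frozen=True)
class VariantCall:
    position: int  # 1-based codon index
    wt: str
    mut: str


def call_read(
    seq: str,
    quals: Sequence[int],
    offset: int,
    reference: str,
    config: CallingConfig,
) -> VariantCall | str:
    """Compare an aligned read against the reference codon-by-codon.

    Returns a :class:`VariantCall`, the sentinel ``"wt"`` for a read identical
    to the reference over its span, or ``"rejected"``.
    """
    if offset % 3:
        return "rejected"  # out of frame
    if len(quals) != len(seq):
        raise ValueError("quality/sequence length mismatch")
    quals_arr = np.asarray(quals, dtype=float)
    if quals_arr.mean() <= config.min_read_mean_q:
        return "rejected"
    seq = seq.upper()
    ref = reference.upper()
    n_codons = len(seq) // 3  # trailing partial codon ignored
    mutated: list[tuple[int, str, str, float]] = []
    for c in range(n_codons):
        i = c * 3
        read_codon = seq[i : i + 3]
        ref_codon = ref[offset + i : offset + i + 3]
        if read_codon != ref_codon:
            codon_q = quals_arr[i : i + 3].mean()
            position = (offset + i) // 3 + 1
            mutated.append((position, ref_codon, read_codon, codon_q))
    if not mutated:
        return "wt"
    if len(mutated) > config.max_mutated_codons_per_read:
        return "rejected"
    for _, _, _, codon_q in mutated:
        if codon_q <= config.min_codon_mean_q:
            return "rejected"
    position, wt, mut, _ = mutated[0]
    return VariantCall(position=position, wt=wt, mut=mut)


def _covered_positions(offset: int, read_len: int) -> range:
    """1-based codon positions fully covered by a frame-aligned read."""
    first = offset // 3 + 1
    n_codons = read_len // 3
    return range(first, first + n_codons)


def build_count_matrix(
    calls: Iterable[VariantCall | str],
    coverage: Iterable[range],
    config: CallingConfig,
    n_positions: int,
    sample: SampleInfo | None = None,
) -> MutantCountMatrix:
    """Accumulate per-read calls from one sample into a codon count matrix.

    ``calls`` and ``coverage`` are parallel: coverage holds the codon
    positions each retained (wt or variant) read spans.  Variants with count
    < ``min_reads_per_variant`` are zeroed; their reads still contribute to
    depth (the read itself passed all quality filters).
    """
    tallies: dict[tuple[int, str, str], int] = {}
    depth = np.zeros(n_positions + 1, dtype=np.int64)  # 1-based
    n_wt = 0
    n_rejected = 0
    for call, cov in zip(calls, coverage):
        if call == "rejected":
            n_rejected += 1
            continue
        for p in cov:
            depth[p] += 1
        if call == "wt":
            n_wt += 1
            continue
        assert isinstance(call, VariantCall)
        key = (call.position, call.wt, call.mut)
        tallies[key] = tallies.get(key, 0) + 1

    n_variant = sum(tallies.values())
    rows = []
    for (pos, wt, mut), count in sorted(tallies.items()):
        if count < config.min_reads_per_variant:
            count = 0
        rows.append({"position": pos, "wt": wt, "mut": mut, "count": count})
    counts = pd.DataFrame(rows, columns=CODON_COLUMNS)
    depth_s = pd.Series(depth[1:], index=pd.RangeIndex(1, n_positions + 1, name="position"))
    return MutantCountMatrix(
        level="codon",
        counts=counts,
        depth=depth_s,
        sample=sample,
        n_wt_reads=n_wt,
        n_rejected=n_rejected,
        n_variant_reads=n_variant,
    )


def call_sample(
    reads: Iterable[tuple[str, Sequence[int]]],
    reference: str,
    config: CallingConfig | None = None,
    sample: SampleInfo | None = None,
) -> MutantCountMatrix:
    """Full per-sample pipeline: anchor placement -> calling -> count matrix."""
    config = config or CallingConfig()
    calls: list[VariantCall | str] = []
    coverage: list[range] = []
    for seq, quals in reads:
        offset = align_read(seq, reference, config)
        if offset is None:
            calls.append("rejected")
            coverage.append(range(0))
            continue
        call = call_read(seq, quals, offset, reference, config)
        calls.append(call)
        coverage.append(_covered_positions(offset, len(seq)) if call != "rejected" else range(0))
    return build_count_matrix(calls, coverage, config, len(reference) // 3, sample=sample)


def apply_count_filter(matrix: MutantCountMatrix, min_reads: int = 3) -> MutantCountMatrix:
    """Zero out variants below the per-variant read cutoff (count < min_reads).

    Used for count matrices that did not pass through :func:`build_count_matrix`
    (e.g. simulated or externally supplied counts).
    """
    df = matrix.counts.copy()
    df.loc[df["count"] < min_reads, "count"] = 0
    return MutantCountMatrix(
        level=matrix.level,
        counts=df,
        depth=matrix.depth.copy(),
        sample=matrix.sample,
        n_wt_reads=matrix.n_wt_reads,
        n_rejected=matrix.n_rejected,
        n_variant_reads=matrix.n_variant_reads,
    )


# ---------------------------------------------------------------------------
# input formats


def iter_fastq(path: str | Path) -> Iterator[tuple[str, list[int]]]:
    """Yield (sequence, qualities) from a Sanger Phred+33 FASTQ(.gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()  # +
            qual = fh.readline().strip()
            if not header.startswith("@") or len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record in {path}")
            yield seq, [ord(c) - 33 for c in qual]


def call_fastq(
    path: str | Path,
    reference: str,
    config: CallingConfig | None = None,
    sample: SampleInfo | None = None,
) -> MutantCountMatrix:
    return call_sample(iter_fastq(path), reference, config, sample=sample)


def call_sam(
    path: str | Path,
    reference: str,
    config: CallingConfig | None = None,
    sample: SampleInfo | None = None,
) -> MutantCountMatrix:
    """Call variants from externally aligned reads (SAM/BAM).

    Only ungapped, fully-matching alignments (CIGAR of a single M/= block)
    are considered; everything else is rejected.  The aligner's position
    replaces the internal anchor search; the same quality filters apply.
    """
    import pysam

    config = config or CallingConfig()
    calls: list[VariantCall | str] = []
    coverage: list[range] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if (
                rec.is_unmapped
                or rec.query_sequence is None
                or rec.cigartuples is None
                or len(rec.cigartuples) != 1
                or rec.cigartuples[0][0] not in (0, 7)  # M or =
            ):
                calls.append("rejected")
                coverage.append(range(0))
                continue
            seq = rec.query_sequence
            quals = list(rec.query_qualities) if rec.query_qualities is not None else [40] * len(seq)
            offset = rec.reference_start
            if offset + len(seq) > len(reference):
                calls.append("rejected")
                coverage.append(range(0))
                continue
            call = call_read(seq, quals, offset, reference, config)
            calls.append(call)
            coverage.append(_covered_positions(offset, len(seq)) if call != "rejected" else range(0))
    return build_count_matrix(calls, coverage, config, len(reference) // 3, sample=sample)


# ---------------------------------------------------------------------------
# codon -> amino acid


def collapse_to_aa(matrix: MutantCountMatrix) -> MutantCountMatrix:
    """Sum codon variants encoding the same amino-acid substitution.

    Substitutions whose mutant amino acid equals the wild type are flagged
    synonymous; stop-codon variants are retained with ``stop=True``.  Codon
    entries containing ambiguous bases are excluded (count logged).
    """
    if matrix.level != "codon":
        raise ValueError("expected a codon-level matrix")
    df = matrix.counts
    has_n = ~df["wt"].str.fullmatch("[ACGT]{3}") | ~df["mut"].str.fullmatch("[ACGT]{3}")
    n_excluded = int(has_n.sum())
    if n_excluded:
        log.warning("excluded %d codon entries containing ambiguous bases", n_excluded)
    df = df[~has_n].copy()
    df["wt_aa"] = df["wt"].map(translate_codon)
    df["mut_aa"] = df["mut"].map(translate_codon)
    grouped = (
        df.groupby(["position", "wt_aa", "mut_aa"], as_index=False)["count"]
        .sum()
        .rename(columns={"wt_aa": "wt", "mut_aa": "mut"})
    )
    grouped["synonymous"] = grouped["wt"] == grouped["mut"]
    grouped["stop"] = grouped["mut"] == "*"
    return MutantCountMatrix(
        level="aa",
        counts=grouped,
        depth=matrix.depth.copy(),
        sample=matrix.sample,
        n_wt_reads=matrix.n_wt_reads,
        n_rejected=matrix.n_rejected,
        n_variant_reads=matrix.n_variant_reads,
    )
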