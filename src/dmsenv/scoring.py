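"""Per-mutant fitness scores as depth-normalised log2 preferential enrichments.

A mutant's score in one environment is the log2 ratio of its depth-normalised
frequency in the selected pool over the unselected pool, averaged across
replicates.  Mutants absent from every selected replicate (after the count
filter) are *eliminated*: they carry no numeric score.  Neutrality thresholds
come from the spread of unselected-vs-unselected enrichments (mean +/- 2 SD).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import MutantCountMatrix

log = logging.getLogger(__name__)

CLASS_ENRICHED = "enriched"
CLASS_NEUTRAL = "neutral"
CLASS_DEPLETED = "depleted"
CLASS_ELIMINATED = "eliminated"

_KEY = ["position", "wt", "mut"]


@dataclass(frozen=True)
class NeutralityThresholds:
    """Closed neutrality interval [lower, upper] = mu0 +/- 2*sigma0."""

    lower: float
    upper: float
    mu0: float
    sigma0: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower threshold exceeds upper")


def normalize_counts(matrix: MutantCountMatrix) -> pd.DataFrame:
    """Per-entry frequency = count / depth at the entry's position."""
    df = matrix.counts.copy()
    depth = df["position"].map(matrix.depth)
    bad = (depth <= 0) & (df["count"] > 0)
    if bad.any():
        pos = df.loc[bad, "position"].tolist()
        raise ValueError(f"zero depth at positions with nonzero counts: {pos}")
    with np.errstate(invalid="ignore", divide="ignore"):
        df["frequency"] = np.where(depth > 0, df["count"] / depth, 0.0)
    return df


def _freq_series(matrix: MutantCountMatrix) -> pd.Series:
    df = normalize_counts(matrix)
    return df.set_index(_KEY)["frequency"]


def preferential_enrichment(
    selected: MutantCountMatrix,
    unselected: MutantCountMatrix,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Single-replicate log2 enrichment of selected over unselected frequency.

    Mutants with zero unselected frequency cannot be scored and are dropped
    (logged).  Zero selected frequency yields NaN (eliminated in this
    replicate).  ``pseudocount`` (off by default) is added to both counts
    before normalisation when nonzero.
    """
    if pseudocount:
        selected = _with_pseudocount(selected, pseudocount)
        unselected = _with_pseudocount(unselected, pseudocount)
    sel = _freq_series(selected)
    unsel = _freq_series(unselected)
    idx = unsel.index.union(sel.index)
    sel = sel.reindex(idx, fill_value=0.0)
    unsel = unsel.reindex(idx, fill_value=0.0)
    unscorable = unsel == 0
    n_dropped = int(unscorable.sum())
    if n_dropped:
        log.warning("dropping %d mutants absent from the unselected pool", n_dropped)
    sel, unsel = sel[~unscorable], unsel[~unscorable]
    with np.errstate(divide="ignore"):
        f = np.log2(sel / unsel)
    f[sel == 0] = np.nan
    out = f.rename("F").reset_index()
    return out


def _with_pseudocount(matrix: MutantCountMatrix, pc: float) -> MutantCountMatrix:
    df = matrix.counts.copy()
    df["count"] = df["count"] + pc
    return MutantCountMatrix(
        level=matrix.level, counts=df, depth=matrix.depth + pc, sample=matrix.sample
    )


def score_environment(
    replicate_pairs: list[tuple[MutantCountMatrix, MutantCountMatrix]],
    environment: str = "",
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """FitnessTable for one environment from (selected, unselected) replicate pairs.

    Columns: position, wt, mut [, synonymous, stop], F_rep{i}.., F (mean over
    replicates with a numeric value), survived.  A mutant survives iff it has
    a nonzero selected count in at least one replicate; otherwise F is NaN
    and the class (after :func:`classify`) is "eliminated".
    """
    if not replicate_pairs:
        raise ValueError("no replicate pairs")
    per_rep = []
    for i, (sel, unsel) in enumerate(replicate_pairs, start=1):
        f = preferential_enrichment(sel, unsel, pseudocount=pseudocount)
        per_rep.append(f.set_index(_KEY)["F"].rename(f"F_rep{i}"))
    table = pd.concat(per_rep, axis=1)
    rep_cols = [c for c in table.columns if c.startswith("F_rep")]
    table["F"] = table[rep_cols].mean(axis=1)
    table["survived"] = table[rep_cols].notna().any(axis=1)
    table.loc[~table["survived"], "F"] = np.nan
    table = table.reset_index()
    # carry variant annotation (synonymous/stop flags): every scored variant is
    # present in at least one matrix, so pool annotation across all of them
    ann_frames = [
        m.counts for pair in replicate_pairs for m in pair
        if {"synonymous", "stop"} & set(m.counts.columns)
    ]
    if ann_frames:
        ann = pd.concat(ann_frames, ignore_index=True)
        cols = [c for c in ("synonymous", "stop") if c in ann.columns]
        table = table.merge(ann[_KEY + cols].drop_duplicates(_KEY), on=_KEY, how="left")
    table.attrs["environment"] = environment
    return table


def neutrality_thresholds(
    unselected_replicates: list[MutantCountMatrix],
) -> NeutralityThresholds:
    """Thresholds from enrichment between unselected replicate pairs.

    For every ordered pair (A earlier, B later) the per-mutant enrichment
    log2(freq_A / freq_B) is computed over mutants present in both; mu0 and
    sigma0 are the pooled mean and SD, thresholds are mu0 +/- 2*sigma0.
    """
    if len(unselected_replicates) < 2:
        raise ValueError("need >= 2 unselected replicates")
    values: list[np.ndarray] = []
    for a, b in itertools.combinations(unselected_replicates, 2):
        fa = _freq_series(a)
        fb = _freq_series(b)
        idx = fa.index.intersection(fb.index)
        fa, fb = fa.loc[idx], fb.loc[idx]
        ok = (fa > 0) & (fb > 0)
        values.append(np.log2(fa[ok] / fb[ok]).to_numpy())
    pooled = np.concatenate(values)
    if pooled.size == 0:
        raise ValueError("no mutants shared between unselected replicates")
    mu0 = float(pooled.mean())
    sigma0 = float(pooled.std(ddof=0))
    return NeutralityThresholds(lower=mu0 - 2 * sigma0, upper=mu0 + 2 * sigma0, mu0=mu0, sigma0=sigma0)


def classify(table: pd.DataFrame, thresholds: NeutralityThresholds) -> pd.DataFrame:
    """Label each mutant enriched / neutral / depleted / eliminated.

    The neutrality interval is closed: F exactly at a threshold is neutral.
    """
    out = table.copy()
    f = out["F"]
    cls = np.select(
        [~out["survived"], f > thresholds.upper, f < thresholds.lower],
        [CLASS_ELIMINATED, CLASS_ENRICHED, CLASS_DEPLETED],
        default=CLASS_NEUTRAL,
    )
    out["class"] = cls
    return out


def write_fitness_table(table: pd.DataFrame, path: str | Path) -> None:
    df = table.copy()
    df.insert(0, "mutant", df["wt"].astype(str) + df["position"].astype(str) + df["mut"].astype(str))
    df.to_csv(path, sep="\t", index=False)


def read_fitness_table(path: str | Path, environment: str = "") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "mutant" in df.columns:
        df = df.drop(columns=["mutant"])
    df.attrs["environment"] = environment
    return df
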