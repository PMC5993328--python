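"""Recompute environment summaries from a deposited per-mutant fitness table.

Accepts the published per-environment fitness scores (e.g. a supplementary
spreadsheet exported to TSV/CSV, or the XLSX itself) and recomputes the
selection coefficient s, delta-F and rho for every environment against a
reference environment.  A mutant counts as eliminated in an environment when
its fitness cell is empty/NaN.

Accepted layouts
----------------
wide
    one row per mutant with a ``mutant`` column (or position/wt/mut columns),
    a ``synonymous`` column (or wt == mut inference), and one fitness column
    per environment.
long
    columns ``environment``, ``mutant`` (or position/wt/mut), ``F`` and
    optionally ``synonymous``.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .selection import (
    SurvivalData,
    robustness_rho,
    s_point_estimate,
    survival_posterior,
)

_MUTANT_RE = re.compile(r"^([A-Z\*])(\d+)([A-Z\*])$")

_META_COLUMNS = {"mutant", "position", "wt", "mut", "synonymous", "stop"}


def _split_mutant_ids(df: pd.DataFrame) -> pd.DataFrame:
    """Derive position/wt/mut columns from compact mutant ids like L5P."""
    out = df.copy()
    if {"position", "wt", "mut"} <= set(out.columns):
        return out
    if "mutant" not in out.columns:
        raise ValueError("table needs either a 'mutant' column or position/wt/mut columns")
    parsed = out["mutant"].astype(str).str.extract(_MUTANT_RE)
    if parsed.isna().any(axis=None):
        bad = out.loc[parsed.isna().any(axis=1), "mutant"].head().tolist()
        raise ValueError(f"unparseable mutant ids (expected e.g. L5P): {bad}")
    out["wt"] = parsed[0]
    out["position"] = parsed[1].astype(int)
    out["mut"] = parsed[2]
    return out


def load_supplementary_fitness(path: str | Path) -> pd.DataFrame:
    """Load a deposited fitness table into the wide per-mutant layout.

    Returns a dataframe with position/wt/mut/synonymous plus one numeric
    fitness column per environment (NaN = eliminated).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep)
    df.columns = [str(c).strip() for c in df.columns]
    lower = {c.lower(): c for c in df.columns}
    df = df.rename(columns={lower[k]: k for k in
                            ("mutant", "position", "wt", "mut", "synonymous", "environment", "f")
                            if k in lower})
    if "environment" in df.columns:  # long layout -> pivot wide
        df = _split_mutant_ids(df)
        value_col = "F" if "F" in df.columns else "f"
        keep = [c for c in ("position", "wt", "mut", "synonymous") if c in df.columns]
        df = df.pivot_table(index=keep, columns="environment", values=value_col,
                            aggfunc="first").reset_index()
        df.columns.name = None
    df = _split_mutant_ids(df)
    if "synonymous" not in df.columns:
        df["synonymous"] = df["wt"] == df["mut"]
    df["synonymous"] = df["synonymous"].astype(bool)
    env_cols = [c for c in df.columns if c not in _META_COLUMNS]
    if not env_cols:
        raise ValueError("no environment fitness columns found")
    df[env_cols] = df[env_cols].apply(pd.to_numeric, errors="coerce")
    return df


def environment_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _META_COLUMNS]


#: normalised aliases for the study's environment columns
ENVIRONMENT_ALIASES: dict[str, set[str]] = {
    "reference": {"reference", "ref", "37c", "37", "gm125", "37c125", "125"},
    "gm25": {"gm25", "25", "37c25", "gm25ugml"},
    "30C": {"30c", "30"},
    "42C": {"42c", "42"},
    "TMAO": {"tmao", "tmao37c", "37ctmao"},
    "glycerol": {"glycerol", "gly", "glycerol37c", "37cglycerol"},
    "42C_TMAO": {"42ctmao", "tmao42c", "42tmao"},
    "42C_glycerol": {"42cglycerol", "glycerol42c", "42glycerol", "42gly"},
}


def _normalise_name(name: str) -> str:
    norm = re.sub(r"[^a-z0-9]", "", name.lower())
    return norm.replace("ugml", "")


def match_environment_columns(table: pd.DataFrame, wanted) -> dict[str, str]:
    """Map canonical environment keys to this table's column names.

    Matching is on normalised names via :data:`ENVIRONMENT_ALIASES`; columns
    that match nothing are ignored, keys without a column are absent from the
    result.
    """
    cols = {_normalise_name(c): c for c in environment_columns(table)}
    out: dict[str, str] = {}
    for key in wanted:
        aliases = ENVIRONMENT_ALIASES.get(key, {_normalise_name(key)})
        for alias in aliases | {_normalise_name(key)}:
            if alias in cols:
                out[key] = cols[alias]
                break
    return out


def _as_fitness_table(table: pd.DataFrame, env: str) -> pd.DataFrame:
    out = table[["position", "wt", "mut", "synonymous"]].copy()
    out["F"] = table[env]
    out["survived"] = out["F"].notna()
    if "stop" not in out.columns:
        out["stop"] = out["mut"] == "*"
    out.attrs["environment"] = env
    return out


def recompute_summaries(
    table: pd.DataFrame,
    reference: str,
    n_draws: int = 1000,
    seed: int = 0,
    exclude_stops: bool = True,
) -> pd.DataFrame:
    """Per-environment s (point + posterior mean), delta-F and rho vs reference.

    s uses the table's own class totals as library sizes; delta-F averages
    surviving non-synonymous mutants per environment; rho is the Spearman
    correlation over mutants surviving in both environments.
    """
    envs = environment_columns(table)
    if reference not in envs:
        raise KeyError(f"reference environment {reference!r} not among {envs}")
    work = table
    if exclude_stops:
        work = table[table["mut"] != "*"]
    syn = work["synonymous"]
    n_non, n_syn = int((~syn).sum()), int(syn.sum())
    rng = np.random.default_rng(seed)
    ref_ft = _as_fitness_table(work, reference)
    rows = []
    for env in envs:
        surv = work[env].notna()
        data = SurvivalData(
            k_non=int((surv & ~syn).sum()), n_non=n_non,
            k_syn=int((surv & syn).sum()), n_syn=n_syn,
        )
        post = survival_posterior(data, n_draws=n_draws, seed=rng)
        ft = _as_fitness_table(work, env)
        if env == reference:
            d_f, rho = 0.0, 1.0
        else:
            non = ~syn
            d_f = float(work.loc[surv & non, env].mean() - work.loc[work[reference].notna() & non, reference].mean())
            rho = robustness_rho(ft, ref_ft)
        rows.append({
            "environment": env,
            "n_non_survived": data.k_non, "n_syn_survived": data.k_syn,
            "v_non": data.k_non / n_non, "v_syn": data.k_syn / n_syn,
            "s_point": s_point_estimate(data),
            "s_posterior_mean": post.s_mean,
            "s_lo": post.s_ci[0], "s_hi": post.s_ci[1],
            "delta_F": d_f, "rho": rho,
        })
    return pd.DataFrame(rows)
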