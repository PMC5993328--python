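"""Biophysical-constraint analysis of fitness scores.

Correlates fitness with per-substitution features across environments,
clusters the correlation matrix, partitions mutants into folding x binding
subsets around the feature medians, and computes subset-wise selection
coefficients and bootstrap cross-environment correlations.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from ._util import bool_flag
from .selection import SelectionPosterior, SurvivalData, survival_posterior, pmcmc

log = logging.getLogger(__name__)

SUBSETS = ("FB", "cFB", "FcB", "cFcB")
EXCLUDED = "excluded"
_KEY = ["position", "wt", "mut"]

DEFAULT_FEATURES = [
    "ddG", "dist_active", "dist_interface", "depth",
    "conservation", "flexibility", "dlogP", "dSASA", "dpI",
]


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame  # features x environments, Spearman r_s
    p: pd.DataFrame
    n: pd.DataFrame
    row_order: list[str] = field(default_factory=list)
    col_order: list[str] = field(default_factory=list)


def _join_features(table: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    surv = table[table["survived"].astype(bool)]
    if "synonymous" in surv.columns:
        surv = surv[~bool_flag(surv["synonymous"])]
    if "stop" in surv.columns:
        surv = surv[~bool_flag(surv["stop"])]
    return surv[_KEY + ["F"]].merge(features, on=_KEY, how="inner")


def feature_fitness_correlations(
    tables: dict[str, pd.DataFrame],
    features: pd.DataFrame,
    feature_cols: list[str] | None = None,
    min_n: int = 10,
) -> CorrelationMatrix:
    """Spearman r_s between fitness and each feature, per environment.

    Uses surviving non-synonymous mutants; missing feature values are dropped
    pairwise.  Cells with < ``min_n`` pairs or a constant feature are NA.
    """
    feature_cols = feature_cols or [c for c in DEFAULT_FEATURES if c in features.columns]
    envs = list(tables)
    r = pd.DataFrame(index=feature_cols, columns=envs, dtype=float)
    p = pd.DataFrame(index=feature_cols, columns=envs, dtype=float)
    n = pd.DataFrame(0, index=feature_cols, columns=envs, dtype=int)
    for env, table in tables.items():
        joined = _join_features(table, features)
        for feat in feature_cols:
            pair = joined[["F", feat]].dropna()
            n.loc[feat, env] = len(pair)
            if len(pair) < min_n or pair[feat].nunique() < 2 or pair["F"].nunique() < 2:
                continue
            rs, pv = stats.spearmanr(pair["F"], pair[feat])
            r.loc[feat, env] = rs
            p.loc[feat, env] = pv
    return CorrelationMatrix(r=r, p=p, n=n)


def cluster_correlations(matrix: CorrelationMatrix) -> CorrelationMatrix:
    """Order rows and columns by average-linkage Euclidean clustering.

    Distances are computed on the correlation vectors (NA as 0); leaf order
    is deterministic, ties broken by input order.
    """
    filled = matrix.r.astype(float).fillna(0.0)
    if filled.isna().all(axis=None):
        raise ValueError("all-NA correlation matrix")

    def _order(df: pd.DataFrame) -> list[str]:
        if len(df) < 3:
            return list(df.index)
        link = average(pdist(df.to_numpy(), metric="euclidean"))
        return [df.index[i] for i in leaves_list(link)]

    matrix.row_order = _order(filled)
    matrix.col_order = _order(filled.T)
    return matrix


# ---------------------------------------------------------------------------
# folding x binding subsets


@dataclass
class SubsetAssignment:
    labels: pd.Series  # index-aligned with the feature table rows
    m_g: float  # ddG median cutoff
    m_d: float  # distance median cutoff
    band: float  # excluded percentile half-band around the median, per side

    def members(self, subset: str) -> pd.Index:
        return self.labels.index[self.labels == subset]


def _percentile_ranks(values: np.ndarray) -> np.ndarray:
    """Average-rank percentiles in (0, 100]."""
    return 100.0 * stats.rankdata(values, method="average") / len(values)


def assign_subsets(features: pd.DataFrame, band: float = 10.0) -> SubsetAssignment:
    """Partition mutants into FB / cFB / FcB / cFcB around feature medians.

    F (proper folding) means ddG <= median; B (proper binding) means distance
    from active site >= median.  Mutants whose percentile rank on either axis
    falls within ``band`` points of the 50th percentile (open interval) are
    excluded to buffer feature uncertainty.
    """
    needed = {"ddG", "dist_active"}
    if needed - set(features.columns):
        raise ValueError(f"features must contain {sorted(needed)}")
    df = features.dropna(subset=["ddG", "dist_active"])
    if df.empty:
        raise ValueError("no mutants with both ddG and dist_active")
    ddg = df["ddG"].to_numpy(dtype=float)
    dist = df["dist_active"].to_numpy(dtype=float)
    if np.ptp(ddg) == 0 or np.ptp(dist) == 0:
        raise ValueError("degenerate feature distribution: median split undefined")
    m_g = float(np.median(ddg))
    m_d = float(np.median(dist))
    pct_g = _percentile_ranks(ddg)
    pct_d = _percentile_ranks(dist)
    in_band = ((pct_g > 50 - band) & (pct_g < 50 + band)) | (
        (pct_d > 50 - band) & (pct_d < 50 + band)
    )
    folding_ok = ddg <= m_g
    binding_ok = dist >= m_d
    labels = np.where(
        in_band,
        EXCLUDED,
        np.where(
            folding_ok,
            np.where(binding_ok, "FB", "FcB"),
            np.where(binding_ok, "cFB", "cFcB"),
        ),
    )
    out = pd.Series(EXCLUDED, index=features.index, dtype=object, name="subset")
    out.loc[df.index] = labels
    return SubsetAssignment(labels=out, m_g=m_g, m_d=m_d, band=band)


def subsetwise_selection(
    tables: dict[str, pd.DataFrame],
    features: pd.DataFrame,
    assignment: SubsetAssignment,
    n_draws: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], SelectionPosterior]]:
    """Per-subset, per-environment s posterior (synonymous class unrestricted).

    The non-synonymous survival counts are restricted to the subset's
    mutants; the synonymous comparator is the full synonymous class of each
    environment's table.  Empty subsets yield NA rows.
    """
    feat = features.copy()
    feat["subset"] = assignment.labels
    rng = np.random.default_rng(seed)
    rows = []
    posteriors: dict[tuple[str, str], SelectionPosterior] = {}
    for env, table in tables.items():
        syn = table[bool_flag(table.get("synonymous"), index=table.index)]
        k_syn, n_syn = int(syn["survived"].astype(bool).sum()), len(syn)
        merged = table.merge(feat[_KEY + ["subset"]], on=_KEY, how="inner")
        for subset in SUBSETS:
            sub = merged[merged["subset"] == subset]
            if sub.empty or k_syn == 0:
                rows.append({"environment": env, "subset": subset, "n": 0, "s": np.nan,
                             "s_lo": np.nan, "s_hi": np.nan})
                continue
            data = SurvivalData(
                k_non=int(sub["survived"].astype(bool).sum()),
                n_non=len(sub),
                k_syn=k_syn,
                n_syn=n_syn,
            )
            post = survival_posterior(data, n_draws=n_draws, seed=rng)
            posteriors[(env, subset)] = post
            rows.append({
                "environment": env, "subset": subset, "n": len(sub),
                "s": post.s_mean, "s_lo": post.s_ci[0], "s_hi": post.s_ci[1],
            })
    return pd.DataFrame(rows), posteriors


# ---------------------------------------------------------------------------
# exact Mann-Whitney U (one-sided, mid-p for ties)


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for y relative to x; ties contribute 1/2."""
    x = np.asarray(x, dtype=float)[:, None]
    y = np.asarray(y, dtype=float)[None, :]
    return float((y > x).sum() + 0.5 * (y == x).sum())


def subset_significance_test(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 12
) -> tuple[float, float]:
    """One-sided test that y is stochastically greater than x.

    Exact enumeration of all group assignments for small samples (mid-p so
    identical vectors give exactly 0.5); tie-corrected normal approximation
    beyond ``exact_max_n`` per group.  Returns (U, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    u_obs = mann_whitney_u(x, y)
    n, m = len(x), len(y)
    if max(n, m) <= exact_max_n:
        pooled = np.concatenate([x, y])
        idx = range(n + m)
        greater = equal = total = 0
        for comb in itertools.combinations(idx, m):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(comb)] = True
            u = mann_whitney_u(pooled[~mask], pooled[mask])
            total += 1
            if u > u_obs:
                greater += 1
            elif u == u_obs:
                equal += 1
        p = (greater + 0.5 * equal) / total
        return u_obs, float(p)
    # normal approximation with tie correction, mid-p (no continuity shift)
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    nm = n + m
    tie_term = ((counts**3 - counts).sum()) / (nm * (nm - 1)) if nm > 1 else 0.0
    mu = n * m / 2.0
    sigma2 = n * m / 12.0 * (nm + 1 - tie_term)
    if sigma2 <= 0:
        return u_obs, 0.5
    z = (u_obs - mu) / math.sqrt(sigma2)
    return u_obs, float(stats.norm.sf(z))


def subset_significance(subset_s: pd.DataFrame, baseline: str = "FB") -> pd.DataFrame:
    """One-sided Mann-Whitney tests of each subset's per-environment s against FB.

    Each environment contributes one observation (the s point estimate) per
    subset; the alternative is 'other subset > FB'.
    """
    wide = subset_s.pivot(index="environment", columns="subset", values="s")
    if len(wide) < 4:
        raise ValueError("need >= 4 environments for subset significance")
    base = wide[baseline].dropna().to_numpy()
    rows = []
    for subset in SUBSETS:
        if subset == baseline:
            continue
        other = wide[subset].dropna().to_numpy()
        u, p = subset_significance_test(base, other)
        rows.append({"subset": subset, "baseline": baseline, "U": u, "p_one_sided": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bootstrap cross-environment correlations per subset


def _spearman_bootstrap(
    a: np.ndarray, b: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Spearman correlation of (a, b) under n_boot joint resamples (vectorised)."""
    n = len(a)
    idx = rng.integers(0, n, size=(n_boot, n))
    ra = stats.rankdata(a[idx], axis=1)
    rb = stats.rankdata(b[idx], axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    num = (ra * rb).sum(axis=1)
    den = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = num / den
    return rho


@dataclass
class SubsetCrossEnvResult:
    env_pair: tuple[str, str]
    draws: dict[str, np.ndarray]  # subset -> bootstrap correlation draws
    summary: pd.DataFrame  # subset, n, median, q25, q75, q2.5, q97.5
    contrasts: pd.DataFrame  # subset_a, subset_b, p_mcmc


def cross_env_correlation_resample(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    features: pd.DataFrame,
    assignment: SubsetAssignment,
    n_boot: int = 1000,
    seed: int = 0,
    min_n: int = 5,
) -> SubsetCrossEnvResult:
    """Bootstrap Spearman correlations between two environments per subset.

    Resamples each subset's common survivors with replacement; subset
    contrasts are two-sided tail probabilities of the paired bootstrap
    difference (floored at 1/n_boot).
    """
    feat = features.copy()
    feat["subset"] = assignment.labels
    a = table_a[table_a["survived"].astype(bool)][_KEY + ["F"]]
    b = table_b[table_b["survived"].astype(bool)][_KEY + ["F"]]
    merged = (
        a.merge(b, on=_KEY, suffixes=("_a", "_b"))
        .merge(feat[_KEY + ["subset"]], on=_KEY)
        .dropna(subset=["F_a", "F_b"])
    )
    rng = np.random.default_rng(seed)
    draws: dict[str, np.ndarray] = {}
    rows = []
    for subset in SUBSETS:
        sub = merged[merged["subset"] == subset]
        if len(sub) < min_n:
            log.warning("subset %s below minimum size (%d < %d)", subset, len(sub), min_n)
            rows.append({"subset": subset, "n": len(sub), "median": np.nan,
                         "q25": np.nan, "q75": np.nan, "q025": np.nan, "q975": np.nan})
            continue
        rho = _spearman_bootstrap(
            sub["F_a"].to_numpy(), sub["F_b"].to_numpy(), n_boot, rng
        )
        draws[subset] = rho
        q25, q75, q025, q975 = np.nanquantile(rho, [0.25, 0.75, 0.025, 0.975])
        rows.append({"subset": subset, "n": len(sub), "median": float(np.nanmedian(rho)),
                     "q25": q25, "q75": q75, "q025": q025, "q975": q975})
    contrasts = []
    for sa, sb in itertools.combinations([s for s in SUBSETS if s in draws], 2):
        contrasts.append({
            "subset_a": sa, "subset_b": sb,
            "p_mcmc": pmcmc(draws[sa] - draws[sb], floor=1.0 / n_boot),
        })
    env_a = table_a.attrs.get("environment", "a")
    env_b = table_b.attrs.get("environment", "b")
    return SubsetCrossEnvResult(
        env_pair=(env_a, env_b),
        draws=draws,
        summary=pd.DataFrame(rows),
        contrasts=pd.DataFrame(contrasts, columns=["subset_a", "subset_b", "p_mcmc"]),
    )
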