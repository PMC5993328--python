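"""Environment-level selection statistics.

Four quantities characterise an environment: the mean viability selection
coefficient s = 1 - v_non/v_syn with Bayesian posterior uncertainty from a
conjugate Beta-Bernoulli survival model, the change in average fitness dF
relative to a reference environment, the mutational robustness rho (Spearman
rank correlation of fitness scores), and the ratio n_pos/n_neg of mutants
moved beyond replicate-noise thresholds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import bool_flag


@dataclass(frozen=True)
class SurvivalData:
    """Survival counts of the non-synonymous and synonymous library classes."""

    k_non: int
    n_non: int
    k_syn: int
    n_syn: int

    def __post_init__(self) -> None:
        for k, n in ((self.k_non, self.n_non), (self.k_syn, self.n_syn)):
            if n <= 0:
                raise ValueError("class totals must be positive")
            if not 0 <= k <= n:
                raise ValueError("survivor count outside [0, n]")


@dataclass
class SelectionPosterior:
    """Paired posterior draws of (v_non, v_syn, s) plus point summaries."""

    v_non: np.ndarray
    v_syn: np.ndarray
    s: np.ndarray
    s_mean: float
    s_ci: tuple[float, float]  # central 95% credible interval

    @property
    def n_draws(self) -> int:
        return len(self.s)


def survival_from_fitness_table(
    table: pd.DataFrame, n_non: int | None = None, n_syn: int | None = None
) -> SurvivalData:
    """Survival counts from a FitnessTable with synonymous/survived columns.

    Stop-codon variants are excluded from both classes when flagged.  Library
    totals default to the table's row counts but can be overridden when the
    table omits never-observed mutants.
    """
    df = table
    if "stop" in df.columns:
        df = df[~bool_flag(df["stop"])]
    syn = bool_flag(df["synonymous"])
    surv = df["survived"].astype(bool)
    return SurvivalData(
        k_non=int((surv & ~syn).sum()),
        n_non=int(n_non if n_non is not None else (~syn).sum()),
        k_syn=int((surv & syn).sum()),
        n_syn=int(n_syn if n_syn is not None else syn.sum()),
    )


def survival_posterior(
    data: SurvivalData,
    n_draws: int = 1000,
    seed: int | np.random.Generator = 0,
) -> SelectionPosterior:
    """Conjugate Beta(1,1) posterior of class survival and of s = 1 - v_non/v_syn.

    v_non ~ Beta(k_non+1, n_non-k_non+1) and v_syn ~ Beta(k_syn+1,
    n_syn-k_syn+1), drawn independently; each paired draw gives one s draw.
    """
    if data.k_syn == 0:
        raise ValueError("synonymous class extinct: s is undefined")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v_non = rng.beta(data.k_non + 1, data.n_non - data.k_non + 1, size=n_draws)
    v_syn = rng.beta(data.k_syn + 1, data.n_syn - data.k_syn + 1, size=n_draws)
    s = 1.0 - v_non / v_syn
    lo, hi = np.quantile(s, [0.025, 0.975])
    return SelectionPosterior(
        v_non=v_non, v_syn=v_syn, s=s, s_mean=float(s.mean()), s_ci=(float(lo), float(hi))
    )


def s_point_estimate(data: SurvivalData) -> float:
    """Plug-in point estimate 1 - (k_non/n_non)/(k_syn/n_syn)."""
    if data.k_syn == 0:
        raise ValueError("synonymous class extinct: s is undefined")
    return 1.0 - (data.k_non / data.n_non) / (data.k_syn / data.n_syn)


def pmcmc(delta: np.ndarray, floor: float | None = None) -> float:
    """Two-sided Bayesian tail probability of a posterior contrast.

    2 * min(Pr(delta >= 0), Pr(delta <= 0)), capped at 1 and floored at
    1/n_draws (ties count toward both tails, so an all-zero contrast gives 1).
    """
    delta = np.asarray(delta, dtype=float)
    n = len(delta)
    if floor is None:
        floor = 1.0 / n
    p = 2.0 * min((delta >= 0).mean(), (delta <= 0).mean())
    return float(min(1.0, max(floor, p)))


def contrast_s(a: SelectionPosterior, b: SelectionPosterior) -> float:
    """pMCMC for the draw-paired contrast s_A - s_B."""
    if a.n_draws != b.n_draws:
        raise ValueError("posteriors must have equal draw counts")
    return pmcmc(a.s - b.s)


# ---------------------------------------------------------------------------
# relative parameters


def _surviving_nonsyn(table: pd.DataFrame) -> pd.DataFrame:
    df = table[table["survived"].astype(bool)]
    if "stop" in df.columns:
        df = df[~bool_flag(df["stop"])]
    if "synonymous" in df.columns:
        df = df[~bool_flag(df["synonymous"])]
    return df


def delta_F(test: pd.DataFrame, reference: pd.DataFrame) -> float:
    """Mean F of survivors in test minus mean F of survivors in reference.

    Survivor sets are per-environment (not intersected): complete elimination
    of deleterious mutants in one environment legitimately shifts its mean.
    Non-synonymous mutants only.
    """
    t = _surviving_nonsyn(test)
    r = _surviving_nonsyn(reference)
    if t.empty or r.empty:
        raise ValueError("no surviving non-synonymous mutants in one of the environments")
    return float(t["F"].mean() - r["F"].mean())


def robustness_rho(
    test: pd.DataFrame,
    reference: pd.DataFrame,
    include_synonymous: bool = False,
) -> float:
    """Spearman rank correlation of F over mutants surviving in both environments."""
    key = ["position", "wt", "mut"]
    t = test[test["survived"].astype(bool)]
    r = reference[reference["survived"].astype(bool)]
    if not include_synonymous:
        t, r = _surviving_nonsyn(test), _surviving_nonsyn(reference)
    merged = t[key + ["F"]].merge(r[key + ["F"]], on=key, suffixes=("_t", "_r")).dropna()
    if len(merged) < 3:
        raise ValueError("fewer than 3 common survivors")
    rho, _ = stats.spearmanr(merged["F_t"], merged["F_r"])
    return float(rho)


# ---------------------------------------------------------------------------
# n_pos / n_neg with replicate-noise thresholds


def _rep_cols(table: pd.DataFrame) -> list[str]:
    cols = sorted(
        (c for c in table.columns if c.startswith("F_rep")),
        key=lambda c: int(c.removeprefix("F_rep")),
    )
    if len(cols) < 2:
        raise ValueError("need >= 2 replicate fitness columns")
    return cols


def _within_replicate_changes(table: pd.DataFrame) -> np.ndarray:
    """Per-mutant within-replicate fitness changes, fixed replicate order.

    With two replicates this is F_rep1 - F_rep2; with more, all ordered pairs
    (i < j) pool together.
    """
    cols = _rep_cols(table)
    df = _surviving_nonsyn(table)
    changes = []
    for a, b in itertools.combinations(cols, 2):
        d = (df[a] - df[b]).dropna().to_numpy()
        changes.append(d)
    return np.concatenate(changes)


@dataclass(frozen=True)
class PosNegResult:
    n_pos: int
    n_neg: int
    t_plus: float
    t_minus: float

    @property
    def ratio(self) -> float:
        if self.n_neg == 0:
            return float("inf")
        return self.n_pos / self.n_neg


def noise_thresholds(
    mu_test: float, sigma_test: float, mu_ref: float, sigma_ref: float
) -> tuple[float, float]:
    """T+/- = (mu_t + mu_r)/2 +/- 2*sqrt((sigma_t^2 + sigma_r^2)/2)."""
    centre = (mu_test + mu_ref) / 2.0
    half_width = 2.0 * np.sqrt((sigma_test**2 + sigma_ref**2) / 2.0)
    return centre + half_width, centre - half_width


def pos_neg_ratio(test: pd.DataFrame, reference: pd.DataFrame) -> PosNegResult:
    """Mutants with between-environment fitness change beyond replicate noise.

    Replicate noise is summarised per environment by the mean/SD of
    within-replicate changes; a mutant counts as positive when
    F_test - F_ref > T_plus and negative when < T_minus.
    """
    d_test = _within_replicate_changes(test)
    d_ref = _within_replicate_changes(reference)
    t_plus, t_minus = noise_thresholds(
        float(d_test.mean()), float(d_test.std(ddof=0)),
        float(d_ref.mean()), float(d_ref.std(ddof=0)),
    )
    key = ["position", "wt", "mut"]
    t = _surviving_nonsyn(test)
    r = _surviving_nonsyn(reference)
    merged = t[key + ["F"]].merge(r[key + ["F"]], on=key, suffixes=("_t", "_r")).dropna()
    change = merged["F_t"] - merged["F_r"]
    return PosNegResult(
        n_pos=int((change > t_plus).sum()),
        n_neg=int((change < t_minus).sum()),
        t_plus=t_plus,
        t_minus=t_minus,
    )


# ---------------------------------------------------------------------------
# per-environment summary


@dataclass
class EnvironmentComparison:
    environment: str
    reference: str
    s_mean: float
    s_ci: tuple[float, float]
    p_mcmc_vs_reference: float
    delta_f: float
    rho: float
    n_pos: int
    n_neg: int
    t_plus: float
    t_minus: float

    @property
    def pos_neg(self) -> float:
        return float("inf") if self.n_neg == 0 else self.n_pos / self.n_neg


def compare_environments(
    tables: dict[str, pd.DataFrame],
    reference: str,
    n_non: int | None = None,
    n_syn: int | None = None,
    n_draws: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, SelectionPosterior]]:
    """S1-Table-style summary of every environment against the reference.

    Returns (summary dataframe, posterior per environment).  All posteriors
    share a seed stream so cross-environment contrasts are draw-paired.
    """
    if reference not in tables:
        raise KeyError(f"reference environment {reference!r} not in tables")
    rng = np.random.default_rng(seed)
    posteriors: dict[str, SelectionPosterior] = {}
    surv: dict[str, SurvivalData] = {}
    for env in tables:
        surv[env] = survival_from_fitness_table(tables[env], n_non=n_non, n_syn=n_syn)
        posteriors[env] = survival_posterior(surv[env], n_draws=n_draws, seed=rng)
    rows = []
    for env, table in tables.items():
        post = posteriors[env]
        if env == reference:
            p_ref, df_, rho_, pn = 1.0, 0.0, 1.0, None
        else:
            p_ref = contrast_s(post, posteriors[reference])
            df_ = delta_F(table, tables[reference])
            rho_ = robustness_rho(table, tables[reference])
            pn = pos_neg_ratio(table, tables[reference])
        d = surv[env]
        rows.append(
            {
                "environment": env,
                "n_non_survived": d.k_non,
                "n_syn_survived": d.k_syn,
                "v_non": d.k_non / d.n_non,
                "v_syn": d.k_syn / d.n_syn,
                "s": post.s_mean,
                "s_lo": post.s_ci[0],
                "s_hi": post.s_ci[1],
                "p_mcmc_vs_reference": p_ref,
                "delta_F": df_,
                "rho": rho_,
                "n_pos": pn.n_pos if pn else np.nan,
                "n_neg": pn.n_neg if pn else np.nan,
                "pos_neg_ratio": pn.ratio if pn else np.nan,
            }
        )
    return pd.DataFrame(rows), posteriors
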