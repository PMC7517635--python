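"""Per-exchange mitonuclear epistasis tests and clade-scope comparisons.

Each mtDNA exchange between parental strains i and j defines a 2x2 genotype
set: the two original pairings (n_i/mt_i, n_j/mt_j) and the two synthetic
cybrids (n_i/mt_j, n_j/mt_i).  Epistasis is the mt x n interaction of a
fixed-effect two-way ANOVA on those four genotypes; its effect size is

    delta_delta = |(y_ij - y_ii) - (y_jj - y_ji)|

the absolute difference between the two nuclear backgrounds' fitness changes
upon receiving the foreign mtDNA — identically the magnitude of the 2x2
interaction contrast.  Within- vs between-clade exchanges are compared by a
chi-square test on significance frequencies and by a rank test on the
delta_delta effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .design import ExchangePair


class ExchangeError(ValueError):
    pass


@dataclass
class ExchangeTest:
    pair: ExchangePair
    environment_id: str
    y_ii: float  # nuclear i with its own mtDNA
    y_ij: float  # nuclear i with mtDNA j
    y_ji: float  # nuclear j with mtDNA i
    y_jj: float  # nuclear j with its own mtDNA
    f_interaction: float
    p_interaction: float
    delta_delta: float
    interaction_sign: int  # sign of the contrast before |.|
    significant: bool
    n_obs: int
    skipped: bool = False
    skip_reason: str = ""


@dataclass
class CladeComparison:
    environment_id: str
    counts: pd.DataFrame  # index scope, columns significant / ns
    frequency_statistic: float
    frequency_p: float
    frequency_method: str  # "chi2" | "fisher"
    effect_statistic: float | None
    effect_p: float | None
    median_dd_within: float | None
    median_dd_between: float | None


def delta_delta(y_ii: float, y_ij: float, y_ji: float, y_jj: float) -> float:
    """|change in nuclear i's fitness - change in nuclear j's fitness| on exchange."""
    vals = np.array([y_ii, y_ij, y_ji, y_jj], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("delta_delta requires four finite cell means")
    return abs((y_ij - y_ii) - (y_jj - y_ji))


def exchange_anova(
    fitness: pd.DataFrame,
    pair: ExchangePair,
    environment_id: str,
    alpha: float = 0.05,
    min_reps: int = 2,
) -> ExchangeTest:
    """Fixed-effect two-way ANOVA on the four genotypes of one mtDNA exchange."""
    i, j = pair.strain_i, pair.strain_j
    sub = fitness[
        (fitness["environment_id"] == environment_id)
        & fitness["nuclear_id"].isin([i, j])
        & fitness["mitotype_id"].isin([i, j])
    ].copy()

    counts = sub.groupby(["nuclear_id", "mitotype_id"]).size()
    cells = {(n, m) for n in (i, j) for m in (i, j)}
    missing = sorted(cells - set(counts.index))
    short = sorted(k for k, c in counts.items() if c < min_reps)
    if missing or short:
        reason = f"missing genotypes {missing}" if missing else f"<{min_reps} replicates in {short}"
        return ExchangeTest(
            pair, environment_id, *(float("nan"),) * 4, float("nan"), float("nan"),
            float("nan"), 0, False, int(len(sub)), skipped=True, skip_reason=reason,
        )

    model = smf.ols("fitness ~ C(mitotype_id) * C(nuclear_id)", data=sub).fit()
    table = sm.stats.anova_lm(model, typ=2)
    inter = table.loc["C(mitotype_id):C(nuclear_id)"]
    f_val, p_val = float(inter["F"]), float(inter["PR(>F)"])

    cm = counts.index.to_frame(index=False)
    means = sub.groupby(["nuclear_id", "mitotype_id"])["fitness"].mean()
    y_ii, y_ij = float(means[(i, i)]), float(means[(i, j)])
    y_ji, y_jj = float(means[(j, i)]), float(means[(j, j)])
    contrast = (y_ij - y_ii) - (y_jj - y_ji)
    return ExchangeTest(
        pair, environment_id, y_ii, y_ij, y_ji, y_jj,
        f_val, p_val, abs(contrast), int(np.sign(contrast)),
        bool(p_val < alpha), int(len(sub)),
    )


def run_exchange_tests(
    fitness: pd.DataFrame,
    pairs: list[ExchangePair],
    environments: list[str] | None = None,
    alpha: float = 0.05,
) -> list[ExchangeTest]:
    envs = environments or sorted(fitness["environment_id"].unique())
    return [exchange_anova(fitness, p, e, alpha=alpha) for e in envs for p in pairs]


def clade_frequency_test(tests: list[ExchangeTest], environment_id: str) -> CladeComparison:
    """2x2 test of significance frequency vs exchange scope (within/between).

    Uses a chi-square test without continuity correction; switches to
    Fisher's exact test when any expected count drops below 5.
    """
    usable = [t for t in tests if t.environment_id == environment_id and not t.skipped]
    rows = pd.DataFrame(
        {
            "scope": [t.pair.scope for t in usable],
            "significant": [t.significant for t in usable],
        }
    )
    if rows.empty or rows["scope"].nunique() < 2:
        raise ExchangeError("need tested exchanges in both scopes")
    table = (
        rows.groupby("scope")["significant"]
        .agg(significant="sum", ns=lambda s: int((~s).sum()))
        .loc[["within_clade", "between_clade"]]
    )
    obs = table.to_numpy(dtype=float)
    expected = stats.contingency.expected_freq(obs)
    if (expected < 5).any():
        odds, p = stats.fisher_exact(obs)
        stat, method = float(odds), "fisher"
    else:
        stat, p, _, _ = stats.chi2_contingency(obs, correction=False)
        method = "chi2"

    dd_w = [t.delta_delta for t in usable if t.pair.scope == "within_clade"]
    dd_b = [t.delta_delta for t in usable if t.pair.scope == "between_clade"]
    eff_stat = eff_p = med_w = med_b = None
    if len(dd_w) >= 3 and len(dd_b) >= 3:
        res = effect_size_comparison(tests, environment_id)
        eff_stat, eff_p = res["statistic"], res["p_value"]
        med_w, med_b = res["median_within"], res["median_between"]
    return CladeComparison(
        environment_id, table, float(stat), float(p), method,
        eff_stat, eff_p, med_w, med_b,
    )


def effect_size_comparison(tests: list[ExchangeTest], environment_id: str) -> dict:
    """Two-sided Mann-Whitney comparison of delta_delta by exchange scope."""
    usable = [t for t in tests if t.environment_id == environment_id and not t.skipped]
    dd_w = np.array([t.delta_delta for t in usable if t.pair.scope == "within_clade"])
    dd_b = np.array([t.delta_delta for t in usable if t.pair.scope == "between_clade"])
    if len(dd_w) < 3 or len(dd_b) < 3:
        return {
            "statistic": None, "p_value": None, "skipped": True,
            "reason": f"need >=3 effect sizes per scope (got {len(dd_w)} within, {len(dd_b)} between)",
            "median_within": None, "median_between": None,
        }
    if np.all(dd_w == dd_w[0]) and np.all(dd_b == dd_w[0]):
        stat, p = float(len(dd_w) * len(dd_b) / 2), 1.0  # all tied
    else:
        res = stats.mannwhitneyu(dd_w, dd_b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    return {
        "statistic": stat, "p_value": p, "skipped": False, "reason": "",
        "median_within": float(np.median(dd_w)), "median_between": float(np.median(dd_b)),
    }


def tests_to_frame(tests: list[ExchangeTest]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                t.pair.strain_i, t.pair.strain_j, t.pair.scope, t.environment_id,
                t.y_ii, t.y_ij, t.y_ji, t.y_jj, t.f_interaction, t.p_interaction,
                t.delta_delta, t.interaction_sign, t.significant, t.n_obs,
                t.skipped, t.skip_reason,
            )
            for t in tests
        ],
        columns=[
            "strain_i", "strain_j", "scope", "environment_id",
            "y_ii", "y_ij", "y_ji", "y_jj", "F_interaction", "p_interaction",
            "delta_delta", "interaction_sign", "significant", "n_obs",
            "skipped", "skip_reason",
        ],
    )
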