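"""Mitonuclear coadaptation profiling.

For a nuclear background tested in the environment matching its isolation
niche, the original (coadapted) genotype is compared against each
foreign-mtDNA cybrid: a one-way ANOVA across the k mitotypes gives the
omnibus test, and each original-vs-foreign contrast is tested with the
pooled within-group error term.  A contrast is an *advantage* when the
original genotype's mean fitness is significantly higher than the cybrid's,
a *disadvantage* when significantly lower.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class ProfileError(ValueError):
    pass


@dataclass
class CoadaptationResult:
    nuclear_id: str
    environment_id: str
    omnibus_f: float
    omnibus_p: float
    contrasts: pd.DataFrame  # mitotype_id, relative_fitness, mean_diff, p, class
    n_advantage: int
    n_disadvantage: int
    n_ns: int

    @property
    def preference(self) -> str:
        """'preferred own mtDNA' | 'avoided own mtDNA' | 'mixed' | 'no preference'."""
        n_foreign = int((self.contrasts["class"] != "original").sum())
        if self.n_advantage == n_foreign and n_foreign > 0:
            return "preferred own mtDNA"
        if self.n_disadvantage == n_foreign and n_foreign > 0:
            return "avoided own mtDNA"
        if self.n_advantage == 0 and self.n_disadvantage == 0:
            return "no preference"
        if self.n_advantage > self.n_disadvantage:
            return "majority advantage"
        if self.n_disadvantage > self.n_advantage:
            return "majority disadvantage"
        return "mixed"


def coadaptation_profile(
    fitness: pd.DataFrame,
    nuclear_id: str,
    environment_id: str,
    alpha: float = 0.05,
) -> CoadaptationResult:
    """Compare the original genotype with each foreign-mtDNA cybrid.

    Contrasts use the pooled mean-squared error of the one-way ANOVA over all
    mitotypes within the background (t on N - k df); per-comparison alpha,
    no family-wise correction.  Reported relative fitness is each cybrid's
    mean divided by the original genotype's mean, so the original's own row
    carries relative fitness 1.0 (class "original").
    """
    sub = fitness[
        (fitness["nuclear_id"] == nuclear_id) & (fitness["environment_id"] == environment_id)
    ]
    groups = {m: g["fitness"].to_numpy(dtype=float) for m, g in sub.groupby("mitotype_id")}
    if nuclear_id not in groups:
        raise ProfileError(
            f"original genotype {nuclear_id}/{nuclear_id} absent in {environment_id}"
        )
    if len(groups) < 2:
        raise ProfileError("need at least one foreign mitotype")
    if any(len(v) < 2 for v in groups.values()):
        raise ProfileError("every genotype needs >=2 replicates")

    arrays = list(groups.values())
    f_stat, omnibus_p = stats.f_oneway(*arrays)

    n_total = sum(len(v) for v in arrays)
    k = len(arrays)
    mse = sum(np.sum((v - v.mean()) ** 2) for v in arrays) / (n_total - k)
    df_err = n_total - k

    orig = groups[nuclear_id]
    orig_mean = float(orig.mean())
    rows = [(nuclear_id, 1.0, 0.0, np.nan, "original")]
    for m, v in sorted(groups.items()):
        if m == nuclear_id:
            continue
        diff = orig_mean - float(v.mean())
        if mse <= 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            t = diff / np.sqrt(mse * (1.0 / len(orig) + 1.0 / len(v)))
            p = 2.0 * float(stats.t.sf(abs(t), df_err))
        if p >= alpha:
            cls = "ns"
        else:
            cls = "advantage" if diff > 0 else "disadvantage"
        rel = float(v.mean()) / orig_mean if orig_mean != 0 else np.nan
        rows.append((m, rel, diff, p, cls))
    contrasts = pd.DataFrame(rows, columns=["mitotype_id", "relative_fitness", "mean_diff", "p", "class"])
    return CoadaptationResult(
        nuclear_id, environment_id,
        float(f_stat), float(omnibus_p), contrasts,
        int((contrasts["class"] == "advantage").sum()),
        int((contrasts["class"] == "disadvantage").sum()),
        int((contrasts["class"] == "ns").sum()),
    )


def count_preferences(results: list[CoadaptationResult]) -> pd.DataFrame:
    """Per-background summary of whether the original mtDNA was preferred."""
    if not results:
        raise ProfileError("no coadaptation results to summarize")
    rows = [
        (
            r.nuclear_id, r.environment_id, r.omnibus_p,
            r.n_advantage, r.n_disadvantage, r.n_ns, r.preference,
        )
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "nuclear_id", "environment_id", "omnibus_p",
            "n_advantage", "n_disadvantage", "n_ns", "preference",
        ],
    )


def profile_niche_map(
    fitness: pd.DataFrame,
    niche_map: dict[str, str],
    alpha: float = 0.05,
) -> list[CoadaptationResult]:
    """Run coadaptation profiles for a {nuclear_id: environment_id} mapping."""
    return [
        coadaptation_profile(fitness, nuc, env, alpha=alpha)
        for nuc, env in sorted(niche_map.items())
    ]
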