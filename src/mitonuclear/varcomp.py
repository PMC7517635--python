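"""Crossed random-effects variance decomposition for mitonuclear fitness data.

Within one environment the model is

    y_ijr = mu + mt_i + n_j + (mt x n)_ij + eps_ijr

with every genetic term an independent zero-mean normal random effect.
Across environments the model extends with e and its interactions
(mt x e, n x e, mt x n x e).  Two estimators are provided:

* ``ems_varcomp`` — method-of-moments from expected mean squares, exact for a
  balanced a x b x r design;
* ``reml_varcomp`` — restricted maximum likelihood with variance components
  constrained non-negative.  Balanced two-factor data use a closed-form
  spectral (strata) representation of the restricted likelihood; anything
  else (unbalanced data, environment terms) goes through a general
  mixed-model likelihood evaluated with the Woodbury identity.

``lrt_term`` compares full vs reduced REML fits.  Because the null value of
a variance component sits on the boundary of its parameter space, the
default reference distribution is the 50:50 mixture of a point mass at zero
and chi-square with 1 df; a plain chi-square(1) mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.stats import chi2

GENETIC_TERMS = ("mt", "n", "mt:n")
ALL_TERMS = ("mt", "n", "e", "mt:n", "mt:e", "n:e", "mt:n:e")

_TERM_FACTORS = {
    "mt": ("mitotype_id",),
    "n": ("nuclear_id",),
    "e": ("environment_id",),
    "mt:n": ("mitotype_id", "nuclear_id"),
    "mt:e": ("mitotype_id", "environment_id"),
    "n:e": ("nuclear_id", "environment_id"),
    "mt:n:e": ("mitotype_id", "nuclear_id", "environment_id"),
}


class ModelError(ValueError):
    pass


@dataclass
class VarianceDecomposition:
    components: dict  # term -> sigma^2 (includes "resid")
    proportions: dict  # term -> share of total phenotypic variance
    method: str  # "EMS" | "REML"
    loglik: float | None = None
    converged: bool = True
    clipped: tuple = ()

    def __getitem__(self, term):
        return self.components[term]


@dataclass
class LRTResult:
    term: str
    statistic: float
    df: int
    p_value: float
    boundary_corrected: bool
    loglik_full: float
    loglik_reduced: float


def _check_hierarchy(terms) -> None:
    terms = set(terms)
    unknown = terms - set(ALL_TERMS)
    if unknown:
        raise ModelError(f"unknown model terms: {sorted(unknown)}")


def _proportions(components: dict) -> dict:
    total = sum(components.values())
    if total <= 0:
        return {k: (1.0 if k == "resid" else 0.0) for k in components}
    return {k: v / total for k, v in components.items()}


# ---------------------------------------------------------------------------
# EMS (expected mean squares) estimator, balanced two-way design
# ---------------------------------------------------------------------------

def _balanced_layout(fitness: pd.DataFrame):
    """Return (y, a, b, r, strata) for a balanced mt x n x r table or raise."""
    if fitness["environment_id"].nunique() > 1:
        raise ModelError("per-environment estimator: pass a single environment's slice")
    counts = fitness.groupby(["mitotype_id", "nuclear_id"]).size()
    a = fitness["mitotype_id"].nunique()
    b = fitness["nuclear_id"].nunique()
    if len(counts) != a * b or counts.nunique() != 1:
        raise ModelError(
            "design is unbalanced or incomplete; run balance_replicates first "
            "or use reml_varcomp"
        )
    r = int(counts.iloc[0])
    return a, b, r


def _strata_ss(fitness: pd.DataFrame):
    """Sums of squares and df for the four strata of a balanced a x b x r design."""
    a, b, r = _balanced_layout(fitness)
    y = fitness["fitness"].to_numpy(dtype=float)
    grand = y.mean()
    cell = fitness.groupby(["mitotype_id", "nuclear_id"])["fitness"].mean().unstack()  # a x b
    mt_mean = cell.mean(axis=1).to_numpy()
    n_mean = cell.mean(axis=0).to_numpy()
    resid_cell = cell.to_numpy() - mt_mean[:, None] - n_mean[None, :] + grand

    ss = {
        "mt": r * b * float(np.sum((mt_mean - grand) ** 2)),
        "n": r * a * float(np.sum((n_mean - grand) ** 2)),
        "mt:n": r * float(np.sum(resid_cell**2)),
    }
    cell_of_obs = fitness.groupby(["mitotype_id", "nuclear_id"])["fitness"].transform("mean").to_numpy()
    ss["resid"] = float(np.sum((y - cell_of_obs) ** 2))
    df = {"mt": a - 1, "n": b - 1, "mt:n": (a - 1) * (b - 1), "resid": a * b * (r - 1)}
    return ss, df, a, b, r


def ems_varcomp(fitness: pd.DataFrame) -> VarianceDecomposition:
    """Method-of-moments components from expected mean squares.

    For the balanced a x b x r crossed random model:
        sigma2_resid = MS_E
        sigma2_mtn   = (MS_mtn - MS_E) / r
        sigma2_mt    = (MS_mt - MS_mtn) / (r b)
        sigma2_n     = (MS_n  - MS_mtn) / (r a)
    Negative solutions are clipped to zero and flagged.
    """
    ss, df, a, b, r = _strata_ss(fitness)
    if r < 2:
        raise ModelError("EMS estimator needs at least 2 replicates per cell")
    ms = {k: ss[k] / df[k] for k in ss}
    raw = {
        "resid": ms["resid"],
        "mt:n": (ms["mt:n"] - ms["resid"]) / r,
        "mt": (ms["mt"] - ms["mt:n"]) / (r * b),
        "n": (ms["n"] - ms["mt:n"]) / (r * a),
    }
    clipped = tuple(k for k, v in raw.items() if v < 0)
    comps = {k: max(v, 0.0) for k, v in raw.items()}
    comps = {k: comps[k] for k in ("mt", "n", "mt:n", "resid")}
    return VarianceDecomposition(comps, _proportions(comps), method="EMS", clipped=clipped)


# ---------------------------------------------------------------------------
# REML, balanced two-factor fast path (spectral strata representation)
# ---------------------------------------------------------------------------

def _strata_lambdas(sig, terms, a, b, r):
    """Stratum eigenvalues as functions of the variance components."""
    se = sig["resid"]
    sg = sig.get("mt:n", 0.0) if "mt:n" in terms else 0.0
    smt = sig.get("mt", 0.0) if "mt" in terms else 0.0
    sn = sig.get("n", 0.0) if "n" in terms else 0.0
    return {
        "mt": se + r * sg + r * b * smt,
        "n": se + r * sg + r * a * sn,
        "mt:n": se + r * sg,
        "resid": se,
    }


def _strata_loglik(sig, terms, ss, df, a, b, r, n_obs):
    lam = _strata_lambdas(sig, terms, a, b, r)
    ll = 0.0
    for s in ss:
        if df[s] == 0:
            continue
        if lam[s] <= 0:
            return -np.inf
        ll += df[s] * np.log(lam[s]) + ss[s] / lam[s]
    return -0.5 * (ll + np.log(n_obs) + (n_obs - 1) * np.log(2 * np.pi))


def _reml_balanced(fitness: pd.DataFrame, terms) -> VarianceDecomposition:
    ss, df, a, b, r = _strata_ss(fitness)
    n_obs = a * b * r
    terms = tuple(t for t in ("mt", "n", "mt:n") if t in terms)
    ms = {k: (ss[k] / df[k] if df[k] > 0 else 0.0) for k in ss}

    # interior candidate: ANOVA estimators solve the REML equations for the
    # full and the main-effects models when all components are positive
    candidate = None
    if df["resid"] > 0:
        if set(terms) == {"mt", "n", "mt:n"}:
            candidate = {
                "resid": ms["resid"],
                "mt:n": (ms["mt:n"] - ms["resid"]) / r,
                "mt": (ms["mt"] - ms["mt:n"]) / (r * b),
                "n": (ms["n"] - ms["mt:n"]) / (r * a),
            }
        elif set(terms) == {"mt", "n"}:
            pooled = (ss["mt:n"] + ss["resid"]) / (df["mt:n"] + df["resid"])
            candidate = {
                "resid": pooled,
                "mt": (ms["mt"] - pooled) / (r * b),
                "n": (ms["n"] - pooled) / (r * a),
            }
    if candidate is not None and all(v > 0 for v in candidate.values()):
        sig = {k: candidate.get(k, 0.0) for k in ("mt", "n", "mt:n")}
        sig["resid"] = candidate["resid"]
        ll = _strata_loglik(sig, terms, ss, df, a, b, r, n_obs)
        comps = {t: sig[t] for t in terms}
        comps["resid"] = sig["resid"]
        ordered = {t: comps.get(t, 0.0) for t in ("mt", "n", "mt:n") if t in terms}
        ordered["resid"] = comps["resid"]
        return VarianceDecomposition(ordered, _proportions(ordered), "REML", loglik=ll)

    # boundary or degenerate case: bounded quasi-Newton on the strata likelihood
    names = list(terms) + ["resid"]
    tot = float(np.var(fitness["fitness"].to_numpy(), ddof=1)) or 1.0
    x0 = np.full(len(names), tot / len(names))
    if candidate is not None:
        x0 = np.array([max(candidate.get(k, tot / len(names)), 1e-8 * tot) for k in names])

    def neg(x):
        sig = dict(zip(names, x))
        return -_strata_loglik(sig, terms, ss, df, a, b, r, n_obs)

    bounds = [(0.0, None)] * len(terms) + [(1e-12 * tot, None)]
    res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
    sig = dict(zip(names, res.x))
    comps = {t: float(sig[t]) for t in terms}
    comps["resid"] = float(sig["resid"])
    clipped = tuple(t for t in terms if comps[t] < 1e-10 * tot)
    return VarianceDecomposition(
        comps, _proportions(comps), "REML",
        loglik=-float(res.fun), converged=bool(res.success), clipped=clipped,
    )


# ---------------------------------------------------------------------------
# REML, general path (unbalanced data, environment terms)
# ---------------------------------------------------------------------------

def _design_matrices(fitness: pd.DataFrame, terms):
    Zs = []
    for t in terms:
        key = fitness[list(_TERM_FACTORS[t])].astype(str).agg("|".join, axis=1)
        codes, _ = pd.factorize(key, sort=True)
        q = codes.max() + 1
        Z = np.zeros((len(codes), q))
        Z[np.arange(len(codes)), codes] = 1.0
        Zs.append(Z)
    return Zs


def _profiled_neg_reml(gamma, y, Zs):
    """-2x profiled restricted log-likelihood over gamma_k = sigma2_k/sigma2_e."""
    n = len(y)
    p = 1  # intercept only
    U = np.hstack([Z * np.sqrt(g) for Z, g in zip(Zs, gamma)]) if Zs else np.zeros((n, 0))
    q = U.shape[1]
    A = np.eye(q) + U.T @ U
    try:
        cA = linalg.cho_factor(A, lower=True)
    except linalg.LinAlgError:  # pragma: no cover
        return np.inf, None
    logdetA = 2.0 * float(np.sum(np.log(np.diag(cA[0]))))

    X = np.ones((n, 1))
    M = np.column_stack([X, y])
    HiM = M - U @ linalg.cho_solve(cA, U.T @ M)
    XtHiX = float(X[:, 0] @ HiM[:, 0])
    XtHiy = float(X[:, 0] @ HiM[:, 1])
    ytHiy = float(y @ HiM[:, 1])
    beta = XtHiy / XtHiX
    Q = max(ytHiy - XtHiy * beta, 1e-300)
    sigma2e = Q / (n - p)
    neg2 = (
        (n - p) * np.log(sigma2e) + logdetA + np.log(XtHiX)
        + (n - p) + (n - p) * np.log(2 * np.pi)
    )
    return 0.5 * neg2, sigma2e


def _reml_general(fitness: pd.DataFrame, terms) -> VarianceDecomposition:
    y = fitness["fitness"].to_numpy(dtype=float)
    terms = tuple(t for t in ALL_TERMS if t in terms)
    Zs = _design_matrices(fitness, terms)
    tot = float(np.var(y, ddof=1)) or 1.0

    def neg(g):
        val, _ = _profiled_neg_reml(g, y, Zs)
        return val

    best = None
    for start in (np.full(len(terms), 0.5), np.full(len(terms), 0.05)):
        res = optimize.minimize(
            neg, start, method="L-BFGS-B",
            bounds=[(0.0, 1e7)] * len(terms),
        )
        if best is None or res.fun < best.fun:
            best = res
    _, sigma2e = _profiled_neg_reml(best.x, y, Zs)
    comps = {t: float(g * sigma2e) for t, g in zip(terms, best.x)}
    comps["resid"] = float(sigma2e)
    clipped = tuple(t for t in terms if comps[t] < 1e-10 * tot)
    return VarianceDecomposition(
        comps, _proportions(comps), "REML",
        loglik=-float(best.fun), converged=bool(best.success), clipped=clipped,
    )


def _is_balanced_two_way(fitness: pd.DataFrame, terms) -> bool:
    if not set(terms) <= {"mt", "n", "mt:n"}:
        return False
    if fitness["environment_id"].nunique() > 1:
        return False
    counts = fitness.groupby(["mitotype_id", "nuclear_id"]).size()
    a = fitness["mitotype_id"].nunique()
    b = fitness["nuclear_id"].nunique()
    return len(counts) == a * b and counts.nunique() == 1


def reml_varcomp(fitness: pd.DataFrame, terms=GENETIC_TERMS) -> VarianceDecomposition:
    """Non-negative REML estimates of the variance components in `terms`.

    Balanced single-environment two-factor data are fitted through the exact
    spectral representation of the restricted likelihood; unbalanced data and
    models with environment terms use the general mixed-model likelihood.
    """
    _check_hierarchy(terms)
    if any("environment_id" in _TERM_FACTORS[t] for t in terms):
        if fitness["environment_id"].nunique() < 2:
            raise ModelError("environment terms need more than one environment in the data")
    if _is_balanced_two_way(fitness, terms):
        return _reml_balanced(fitness, terms)
    return _reml_general(fitness, terms)


def lrt_term(
    fitness: pd.DataFrame,
    term: str,
    terms=GENETIC_TERMS,
    boundary_correction: bool = True,
) -> LRTResult:
    """REML likelihood-ratio test of one variance component.

    Fits the model with all of `terms` and the model lacking `term`; the
    statistic is 2(l_full - l_reduced), floored at zero.  With the boundary
    correction the p-value is 0.5 * P(chi2_1 > LRT) (a point mass at zero
    covers the other half); without it, plain chi-square(1).
    """
    _check_hierarchy(terms)
    if term not in terms:
        raise ModelError(f"term {term!r} not in the full model {terms}")
    reduced = tuple(t for t in terms if t != term)
    # note: unlike fixed-effect ANOVA, variance-component models need no
    # marginality constraint — a main-effect variance may be tested while the
    # interaction variance stays in the model
    use_balanced = _is_balanced_two_way(fitness, terms)
    fit = _reml_balanced if use_balanced else _reml_general
    full = fit(fitness, terms)
    red = fit(fitness, reduced)
    stat = max(0.0, 2.0 * (full.loglik - red.loglik))
    if boundary_corrected := boundary_correction:
        p = 0.5 * float(chi2.sf(stat, 1)) if stat > 0 else 1.0
    else:
        p = float(chi2.sf(stat, 1))
    return LRTResult(term, stat, 1, p, boundary_corrected, full.loglik, red.loglik)


def decompose_by_environment(fitness: pd.DataFrame, method: str = "REML") -> pd.DataFrame:
    """Per-environment variance decomposition (one row per term per environment)."""
    rows = []
    for env, sub in fitness.groupby("environment_id", sort=True):
        vd = ems_varcomp(sub) if method.upper() == "EMS" else reml_varcomp(sub)
        for term, s2 in vd.components.items():
            rows.append((env, term, s2, vd.proportions[term], vd.method))
    return pd.DataFrame(rows, columns=["environment_id", "term", "sigma2", "proportion", "method"])
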