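"""Colony time-series to normalized fitness.

The pipeline mirrors standard high-density colony-array practice:

1. drop spots failing circularity QC and spots in the outermost plate rings
   (edge colonies grow large from reduced competition);
2. fit a four-parameter logistic growth curve per spot; the fitted asymptote
   difference y_max - y_min is the spot's raw fitness proxy;
3. flag outlier fits within each genotype x environment group
   (median +/- k*MAD, plus non-converged fits);
4. normalize raw spans to the median span of reference-strain control spots
   on the same plate, removing plate-to-plate scale effects;
5. subsample technical replicates so each biological replicate of a genotype
   contributes equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


class QCError(ValueError):
    pass


class FitError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


@dataclass
class QCParams:
    edge_rings: int = 2
    require_circularity: bool = True
    outlier_mad_k: float = 4.0
    min_group_size: int = 3


@dataclass
class QCReport:
    n_spots_in: int = 0
    n_removed_circularity: int = 0
    n_removed_edge: int = 0
    n_flagged_outlier: int = 0
    n_unconverged: int = 0
    n_spots_out: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class GrowthCurveFit:
    y_min: float
    y_max: float
    rate: float
    t_mid: float
    rss: float
    converged: bool

    @property
    def span(self) -> float:
        return self.y_max - self.y_min


def _logistic(t, y_min, span, rate, t_mid):
    return y_min + span / (1.0 + np.exp(-rate * (t - t_mid)))


def filter_spots(table: pd.DataFrame, qc: QCParams | None = None) -> tuple[pd.DataFrame, QCReport]:
    """Remove circularity-failed spots and the outermost `edge_rings` rings.

    Plate dimensions are taken as the max row/col seen per plate (the array
    format is fixed within a run).
    """
    qc = qc or QCParams()
    report = QCReport()
    spot_cols = ["plate_id", "row", "col"]
    report.n_spots_in = table[spot_cols].drop_duplicates().shape[0]

    keep = pd.Series(True, index=table.index)
    if qc.require_circularity:
        keep &= table["circularity_ok"].astype(bool)
        removed = table.loc[~keep, spot_cols].drop_duplicates().shape[0]
        report.n_removed_circularity = removed

    if qc.edge_rings > 0:
        edge_mask = pd.Series(False, index=table.index)
        for plate_id, sub in table.groupby("plate_id"):
            nrow, ncol = int(sub["row"].max()), int(sub["col"].max())
            if nrow < 2 * qc.edge_rings + 1 or ncol < 2 * qc.edge_rings + 1:
                raise QCError(
                    f"plate {plate_id!r} ({nrow}x{ncol}) too small for edge_rings={qc.edge_rings}"
                )
            e = qc.edge_rings
            m = (sub["row"] <= e) | (sub["row"] > nrow - e) | (sub["col"] <= e) | (sub["col"] > ncol - e)
            edge_mask.loc[sub.index] = m
        report.n_removed_edge = (
            table.loc[edge_mask & keep, spot_cols].drop_duplicates().shape[0]
        )
        keep &= ~edge_mask

    out = table.loc[keep].copy()
    report.n_spots_out = out[spot_cols].drop_duplicates().shape[0]
    return out, report


def fit_logistic(timepoints, sizes) -> GrowthCurveFit:
    """Least-squares logistic fit; returns the fitted curve parameters.

    Parametrized as (y_min, span, rate, t_mid) with span >= 0 so the upper
    asymptote can never fall below the lower.  A flat series short-circuits
    to span 0.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(sizes, dtype=float)
    if len(t) < 5:
        raise FitError("need at least 5 timepoints to fit a growth curve")
    if np.any(np.diff(t) <= 0):
        raise FitError("timepoints must be strictly increasing")

    rng_y = float(y.max() - y.min())
    if rng_y <= 1e-12 * max(1.0, abs(float(y.max()))):
        v = float(y.mean())
        return GrowthCurveFit(v, v, 0.0, float(t.mean()), float(np.sum((y - v) ** 2)), True)

    # heuristics: half-range crossing for t_mid, 10-90% rise time for the rate
    y_lo0, y_hi0 = float(y[0]), float(y[-1])
    half = y.min() + 0.5 * rng_y
    above = np.nonzero(y >= half)[0]
    t_mid0 = float(t[above[0]]) if len(above) else float(t.mean())
    q10, q90 = y.min() + 0.1 * rng_y, y.min() + 0.9 * rng_y
    i10 = np.nonzero(y >= q10)[0]
    i90 = np.nonzero(y >= q90)[0]
    rise = float(t[i90[0]] - t[i10[0]]) if len(i10) and len(i90) and t[i90[0]] > t[i10[0]] else float(t[-1] - t[0]) / 4
    r0 = 4.0 / max(rise, 1e-6)

    x0 = np.array([max(y_lo0, 0.0), max(y_hi0 - y_lo0, 1e-6), r0, t_mid0])
    lo = np.array([0.0, 0.0, 0.0, t[0] - (t[-1] - t[0])])
    hi = np.array([np.inf, np.inf, 10.0, t[-1] + (t[-1] - t[0])])
    x0 = np.clip(x0, lo, hi)

    def resid(p):
        return _logistic(t, *p) - y

    try:
        sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12)
        converged = bool(sol.success)
        y_min_f, span_f, rate_f, t_mid_f = sol.x
        rss = float(np.sum(sol.fun**2))
    except Exception:
        return GrowthCurveFit(float(y.min()), float(y.max()), 0.0, t_mid0, float("inf"), False)

    # degenerate fits: midpoint far outside the observation window
    if not (lo[3] < t_mid_f < hi[3]) or not np.isfinite(rss):
        converged = False
    return GrowthCurveFit(float(y_min_f), float(y_min_f + span_f), float(rate_f), float(t_mid_f), rss, converged)


def fit_spots(table: pd.DataFrame) -> pd.DataFrame:
    """Fit one logistic curve per spot; returns a per-spot table with raw spans."""
    meta_cols = [
        "plate_id", "row", "col", "nuclear_id", "mitotype_id",
        "bio_rep", "tech_rep", "environment_id",
    ]
    rows = []
    for key, sub in table.groupby(["plate_id", "row", "col"], sort=True):
        sub = sub.sort_values("timepoint_h")
        fit = fit_logistic(sub["timepoint_h"].to_numpy(), sub["colony_size"].to_numpy())
        meta = sub.iloc[0]
        rows.append([meta[c] for c in meta_cols] + [fit.y_min, fit.y_max, fit.rate, fit.t_mid, fit.span, fit.converged])
    return pd.DataFrame(rows, columns=meta_cols + ["y_min", "y_max", "rate", "t_mid", "raw_span", "converged"])


def flag_fit_outliers(fits: pd.DataFrame, qc: QCParams | None = None) -> pd.Series:
    """Flag spans deviating > k*MAD from their genotype x environment median.

    Non-converged fits are always flagged.  Groups smaller than
    ``min_group_size`` get no MAD flags (too few points to define a centre).
    """
    qc = qc or QCParams()
    flags = ~fits["converged"].astype(bool)
    for _, sub in fits.groupby(["nuclear_id", "mitotype_id", "environment_id"], sort=False):
        if len(sub) < qc.min_group_size:
            continue
        med = sub["raw_span"].median()
        mad = float((sub["raw_span"] - med).abs().median())
        dev = (sub["raw_span"] - med).abs()
        flags.loc[sub.index] |= dev > qc.outlier_mad_k * mad
    return flags


def normalize_to_reference(
    fits: pd.DataFrame, reference_strain_id: str
) -> pd.DataFrame:
    """Divide each spot's raw span by the median reference span on its plate."""
    is_ref = (fits["nuclear_id"] == reference_strain_id) & (fits["mitotype_id"] == reference_strain_id)
    med = fits.loc[is_ref].groupby("plate_id")["raw_span"].median()
    out = fits.copy()
    missing = sorted(set(out["plate_id"]) - set(med.index))
    if missing:
        raise NormalizationError(f"no surviving reference spots on plate(s): {missing}")
    out["fitness"] = out["raw_span"] / out["plate_id"].map(med)
    return out


def balance_replicates(fitness: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Equalize technical replicates across biological replicates.

    Within each genotype x environment, every biological replicate is
    subsampled (without replacement, seeded) down to the smallest technical
    replicate count among that genotype's biological replicates.
    """
    rng = np.random.default_rng(seed)
    keep_idx = []
    group_cols = ["nuclear_id", "mitotype_id", "environment_id"]
    for _, sub in fitness.sort_values(group_cols + ["bio_rep", "tech_rep"]).groupby(group_cols, sort=True):
        counts = sub.groupby("bio_rep").size()
        m = int(counts.min())
        for _, bio_sub in sub.groupby("bio_rep", sort=True):
            idx = bio_sub.index.to_numpy()
            if len(idx) > m:
                idx = rng.choice(idx, size=m, replace=False)
            keep_idx.extend(idx.tolist())
    return fitness.loc[sorted(keep_idx)].copy()


def fitness_from_timeseries(
    table: pd.DataFrame,
    reference_strain_id: str,
    qc: QCParams | None = None,
    seed: int = 0,
    drop_reference: bool = True,
) -> tuple[pd.DataFrame, QCReport]:
    """Full time-series -> FitnessTable pipeline.

    Filters, fits, outlier-flags, normalizes and replicate-balances; returns
    the fitness table (reference spots dropped by default) and the QC report.
    """
    qc = qc or QCParams()
    filtered, report = filter_spots(table, qc)
    fits = fit_spots(filtered)
    flags = flag_fit_outliers(fits, qc)
    report.n_unconverged = int((~fits["converged"]).sum())
    report.n_flagged_outlier = int(flags.sum())
    fits = fits.loc[~flags]
    fits = normalize_to_reference(fits, reference_strain_id)
    if drop_reference:
        is_ref = (fits["nuclear_id"] == reference_strain_id) & (fits["mitotype_id"] == reference_strain_id)
        fits = fits.loc[~is_ref]
    cols = ["nuclear_id", "mitotype_id", "environment_id", "bio_rep", "tech_rep", "fitness"]
    balanced = balance_replicates(fits[cols].reset_index(drop=True), seed=seed)
    report.n_spots_out = len(balanced)
    return balanced.reset_index(drop=True), report
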