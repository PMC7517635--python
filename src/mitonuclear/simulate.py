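"""Seeded simulation of a mitonuclear colony-array experiment.

Generates data at two levels:

* ``simulate_true_fitness`` draws the genotype-by-environment fitness surface
  from the crossed random-effects model

      f_ijk = mu + m_i + n_j + g_ij + e_k + (me)_ik + (ne)_jk + (ge)_ijk

  with each effect an independent zero-mean normal with its configured
  variance.  ``m`` is the mitotype effect, ``n`` the nuclear background,
  ``g`` the mitonuclear interaction and ``e`` the environment; three-letter
  terms are the corresponding environment interactions.

* ``simulate_colony_timeseries`` lays genotypes out on high-density colony
  arrays (reference-strain border and interior control spots included),
  grows each spot along a logistic curve whose span encodes the spot's
  fitness, and adds measurement noise plus quality-control failures, so the
  whole image-to-fitness pipeline downstream can be exercised.

Fitness is carried on a log scale internally: a spot's asymptotic colony-size
span is ``exp(f) * reference_span``, which keeps sizes positive and makes the
reference-normalized fitness ratio well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import StrainPanel, enumerate_genotypes, example_panel

REFERENCE_BIO_REP = 0  # bio_rep code reserved for reference-strain spots


class SimulationError(ValueError):
    pass


def default_environments(media=("CSM", "CSMEG", "MSy", "SGM", "SOE"), temperatures=(20, 30, 37)):
    """Environment labels as media@temperature, e.g. 'SGM@30'."""
    return [f"{m}@{t}" for m in media for t in temperatures]


@dataclass
class SimulationParams:
    """Study conditions for the synthetic collection.

    Variances are on the (log-scale) fitness axis; the defaults put the
    phenotypic variance split within one environment at roughly
    nuclear 0.40, mitonuclear 0.20, residual 0.40 with no marginal mtDNA
    effect, which is the regime the factorial design is built to detect.
    """

    media: tuple = ("CSM", "CSMEG", "MSy", "SGM", "SOE")
    temperatures: tuple = (20, 30, 37)
    grand_mean: float = 1.0
    var_mt: float = 0.0
    var_n: float = 0.016
    var_mtn: float = 0.008
    var_env: float = 0.01
    var_mt_env: float = 0.0
    var_n_env: float = 0.0
    var_mtn_env: float = 0.0
    var_resid: float = 0.016
    bio_reps: int = 2
    tech_reps_range: tuple = (2, 3)
    plate_rows: int = 32
    plate_cols: int = 48
    timepoints: tuple = tuple(np.linspace(0.0, 96.0, 18))
    logistic_rate_mean: float = 0.15  # per hour
    logistic_rate_sd: float = 0.015
    t_mid_mean: float = 36.0  # hours
    t_mid_sd: float = 4.0
    reference_span: float = 100.0  # colony-size units at the reference fitness
    baseline_size: float = 10.0  # y_min: printed-spot size before growth
    size_noise_cv: float = 0.03  # multiplicative log-normal on colony size
    size_noise_sd: float = 1.0  # additive measurement noise, size units
    circularity_fail_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name in (
            "var_mt", "var_n", "var_mtn", "var_env",
            "var_mt_env", "var_n_env", "var_mtn_env", "var_resid",
        ):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be non-negative")
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.ndim != 1 or len(tp) < 2 or np.any(np.diff(tp) <= 0):
            raise SimulationError("timepoints must be strictly increasing")
        if self.plate_rows < 5 or self.plate_cols < 5:
            raise SimulationError("plate dimensions must be at least 5x5")
        if not (0 <= self.circularity_fail_rate < 1):
            raise SimulationError("circularity_fail_rate must be in [0, 1)")
        lo, hi = self.tech_reps_range
        if lo < 1 or hi < lo:
            raise SimulationError("tech_reps_range must satisfy 1 <= min <= max")

    @property
    def environments(self) -> list[str]:
        return default_environments(self.media, self.temperatures)

    def with_variance_proportions(self, mt, n, mtn, resid, total=0.04) -> "SimulationParams":
        """Convenience: set within-environment variances from target proportions."""
        if not np.isclose(mt + n + mtn + resid, 1.0):
            raise SimulationError("proportions must sum to 1")
        return replace(
            self,
            var_mt=mt * total, var_n=n * total, var_mtn=mtn * total,
            var_resid=resid * total,
            var_mt_env=0.0, var_n_env=0.0, var_mtn_env=0.0,
        )


@dataclass
class TrueFitnessTable:
    """Genotype x environment fitness surface plus the drawn random effects."""

    table: pd.DataFrame  # nuclear_id, mitotype_id, environment_id, true_fitness
    effects: dict  # term -> drawn effect array/frame


def simulate_true_fitness(params: SimulationParams, panel: StrainPanel | None = None) -> TrueFitnessTable:
    """Draw the genotype-by-environment fitness surface for the panel."""
    panel = panel if panel is not None else example_panel()
    rng = np.random.default_rng(params.seed)
    ids = panel.strain_ids
    k = len(ids)
    envs = params.environments
    ne = len(envs)

    sd = np.sqrt
    m = rng.normal(0.0, sd(params.var_mt), size=k)
    n = rng.normal(0.0, sd(params.var_n), size=k)
    g = rng.normal(0.0, sd(params.var_mtn), size=(k, k))  # [nuclear, mitotype]
    e = rng.normal(0.0, sd(params.var_env), size=ne)
    me = rng.normal(0.0, sd(params.var_mt_env), size=(k, ne))
    nee = rng.normal(0.0, sd(params.var_n_env), size=(k, ne))
    ge = rng.normal(0.0, sd(params.var_mtn_env), size=(k, k, ne))

    rows = []
    for j, nuc in enumerate(ids):  # j indexes nuclear background
        for i, mito in enumerate(ids):  # i indexes mitotype
            for kk, env in enumerate(envs):
                f = (
                    params.grand_mean
                    + m[i] + n[j] + g[j, i]
                    + e[kk] + me[i, kk] + nee[j, kk] + ge[j, i, kk]
                )
                rows.append((nuc, mito, env, f))
    table = pd.DataFrame(rows, columns=["nuclear_id", "mitotype_id", "environment_id", "true_fitness"])
    effects = {"mt": m, "n": n, "mtn": g, "e": e, "mt_e": me, "n_e": nee, "mtn_e": ge,
               "strain_ids": ids, "environments": envs}
    return TrueFitnessTable(table=table, effects=effects)


def simulate_fitness_observations(
    truth: TrueFitnessTable,
    params: SimulationParams,
    reps: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Replicate-level fitness: truth plus N(0, var_resid) per observation.

    Bypasses the colony-array layer; used wherever only the statistical layer
    is under study.  `reps` defaults to bio_reps * min tech reps.
    """
    if reps is None:
        reps = params.bio_reps * params.tech_reps_range[0]
    rng = np.random.default_rng(params.seed if seed is None else seed)
    t = truth.table
    base = np.repeat(t["true_fitness"].to_numpy(), reps)
    noise = rng.normal(0.0, np.sqrt(params.var_resid), size=len(base))
    out = t.loc[t.index.repeat(reps), ["nuclear_id", "mitotype_id", "environment_id"]].reset_index(drop=True)
    bio_pattern = 1 + (np.arange(reps) * params.bio_reps) // reps  # split reps across bio reps
    out["bio_rep"] = np.tile(bio_pattern, len(t))
    out["tech_rep"] = np.tile(np.arange(1, reps + 1), len(t))
    out["fitness"] = base + noise
    return out


# ---------------------------------------------------------------------------
# Colony-array layout and growth
# ---------------------------------------------------------------------------

def _interior_reference_positions(rows: int, cols: int, edge: int = 2):
    """Reference control spots: four corners of the interior region + centre."""
    r0, r1 = edge + 1, rows - edge
    c0, c1 = edge + 1, cols - edge
    return [(r0, c0), (r0, c1), (r1, c0), (r1, c1), ((r0 + r1) // 2, (c0 + c1) // 2)]


def _plate_positions(rows: int, cols: int, edge: int = 2):
    """(border positions, interior reference positions, free interior positions)."""
    border, interior = [], []
    ref = set(_interior_reference_positions(rows, cols, edge))
    for r in range(1, rows + 1):
        for c in range(1, cols + 1):
            on_border = r <= edge or r > rows - edge or c <= edge or c > cols - edge
            if on_border:
                border.append((r, c))
            elif (r, c) not in ref:
                interior.append((r, c))
    return border, sorted(ref), interior


def simulate_colony_timeseries(
    truth: TrueFitnessTable,
    params: SimulationParams,
    panel: StrainPanel | None = None,
    environments: list[str] | None = None,
) -> pd.DataFrame:
    """Grow the collection on simulated high-density arrays.

    Each spot's colony size follows
    ``y(t) = y_min + span / (1 + exp(-r (t - t_mid)))`` with multiplicative
    log-normal size noise and additive measurement noise; ``span`` encodes the
    spot's fitness as ``exp(f) * reference_span``.  Spot-level fitness is the
    genotype's true fitness plus a N(0, var_resid) biological deviation per
    spot.  The two outermost rings of every plate carry reference-strain
    border colonies; a fixed set of interior positions carries reference
    control spots used for normalization.  A configured fraction of spots is
    flagged as failing colony-circularity QC.

    Returns a long table: one row per spot per timepoint.
    """
    panel = panel if panel is not None else example_panel()
    envs = environments if environments is not None else params.environments
    known = set(zip(truth.table.nuclear_id, truth.table.mitotype_id))
    need = {(g.nuclear_id, g.mitotype_id) for g in enumerate_genotypes(panel)}
    if not need <= known:
        raise SimulationError("truth table does not cover the panel's factorial")

    tp = np.asarray(params.timepoints, dtype=float)
    border, ref_interior, free = _plate_positions(params.plate_rows, params.plate_cols)
    capacity = len(free)
    if capacity < 1:
        raise SimulationError("plate layout has no free interior positions")

    fit_lookup = truth.table.set_index(["nuclear_id", "mitotype_id", "environment_id"])["true_fitness"]
    ref_id = panel.reference_strain_id

    root = np.random.SeedSequence(params.seed)
    env_seeds = root.spawn(len(envs))

    records = []
    for env, env_seed in zip(envs, env_seeds):
        rng = np.random.default_rng(env_seed)
        # queue of experimental spots for this environment
        queue = []
        for g in enumerate_genotypes(panel):
            for bio in range(1, params.bio_reps + 1):
                ntech = int(rng.integers(params.tech_reps_range[0], params.tech_reps_range[1] + 1))
                for tech in range(1, ntech + 1):
                    queue.append((g.nuclear_id, g.mitotype_id, bio, tech))
        n_plates = int(np.ceil(len(queue) / capacity))
        pos = 0
        for plate_idx in range(n_plates):
            plate_id = f"{env}:p{plate_idx + 1}"
            spots = []  # (row, col, nuclear, mitotype, bio, tech, is_reference)
            for r, c in border:
                spots.append((r, c, ref_id, ref_id, REFERENCE_BIO_REP, 0, True))
            for r, c in ref_interior:
                spots.append((r, c, ref_id, ref_id, REFERENCE_BIO_REP, 0, True))
            for r, c in free:
                if pos >= len(queue):
                    break
                nuc, mito, bio, tech = queue[pos]
                pos += 1
                spots.append((r, c, nuc, mito, bio, tech, False))

            for r, c, nuc, mito, bio, tech, is_ref in spots:
                if is_ref:
                    f_spot = params.grand_mean
                else:
                    f_spot = float(fit_lookup[(nuc, mito, env)])
                f_spot = f_spot + rng.normal(0.0, np.sqrt(params.var_resid))
                span = np.exp(f_spot - params.grand_mean) * params.reference_span
                rate = max(1e-3, rng.normal(params.logistic_rate_mean, params.logistic_rate_sd))
                t_mid = rng.normal(params.t_mid_mean, params.t_mid_sd)
                y = params.baseline_size + span / (1.0 + np.exp(-rate * (tp - t_mid)))
                if params.size_noise_cv > 0:
                    y = y * rng.lognormal(0.0, params.size_noise_cv, size=len(tp))
                if params.size_noise_sd > 0:
                    y = y + rng.normal(0.0, params.size_noise_sd, size=len(tp))
                y = np.maximum(y, 0.0)
                circ_ok = bool(rng.random() >= params.circularity_fail_rate)
                for t_h, size in zip(tp, y):
                    records.append(
                        (plate_id, r, c, nuc, mito, bio, tech, env, t_h, size, circ_ok)
                    )
        if pos < len(queue):  # pragma: no cover - capacity always sized above
            raise SimulationError("layout capacity smaller than required spots")

    return pd.DataFrame(
        records,
        columns=[
            "plate_id", "row", "col", "nuclear_id", "mitotype_id",
            "bio_rep", "tech_rep", "environment_id", "timepoint_h",
            "colony_size", "circularity_ok",
        ],
    )


# ---------------------------------------------------------------------------
# Mitochondrial coding-sequence alignments
# ---------------------------------------------------------------------------

def simulate_alignment(
    panel: StrainPanel | None = None,
    n_sites: int = 8400,
    n_snps: int = 198,
    gap_columns: int = 6,
    seed: int = 0,
) -> dict[str, str]:
    """Synthetic gapped alignment of mitochondrial coding sequence per mitotype.

    Defaults emulate a concatenation of the major mitochondrially encoded
    genes (~8.4 kb) segregating 198 SNPs across a 15-strain panel, which puts
    nucleotide diversity near 0.01 — the level typical of S. cerevisiae
    mitochondrial coding sequence.  Polymorphic columns are biallelic with
    the minor allele carried by 2-7 strains; a few columns carry gaps so gap
    policies are exercised.  Returns {mitotype_id: sequence}.
    """
    panel = panel if panel is not None else example_panel()
    rng = np.random.default_rng(seed)
    ids = panel.strain_ids
    k = len(ids)
    if n_snps + gap_columns > n_sites:
        raise SimulationError("more variable/gap columns than sites")
    bases = np.array(list("ACGT"))
    cons = rng.choice(4, size=n_sites)
    aln = np.repeat(bases[cons][None, :], k, axis=0)
    variable = rng.choice(n_sites, size=n_snps + gap_columns, replace=False)
    snp_cols, gap_cols = variable[:n_snps], variable[n_snps:]
    for col in snp_cols:
        alt = (cons[col] + int(rng.integers(1, 4))) % 4
        n_carriers = int(rng.integers(2, min(8, k - 1)))
        carriers = rng.choice(k, size=n_carriers, replace=False)
        aln[carriers, col] = bases[alt]
    for col in gap_cols:
        gapped = rng.choice(k, size=int(rng.integers(1, 3)), replace=False)
        aln[gapped, col] = "-"
    return {sid: "".join(row) for sid, row in zip(ids, aln)}
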