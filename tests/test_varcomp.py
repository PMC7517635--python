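import numpy as np
import pandas as pd
import pytest

import mitonuclear.varcomp as vc
from mitonuclear import ems_varcomp, lrt_term, reml_varcomp
from mitonuclear.varcomp import ModelError

from conftest import fitness_frame, simulated_fitness


def balanced_table(cells, reps_axis=-1, env="E"):
    """Build a FitnessTable from an (a, b, r) array: mitotype x nuclear x rep."""
    cells = np.asarray(cells, dtype=float)
    a, b, r = cells.shape
    rows = []
    for i in range(a):
        for j in range(b):
            for k in range(r):
                rows.append((f"N{j}", f"M{i}", env, 1, k + 1, cells[i, j, k]))
    return fitness_frame(rows)


def brute_force_ems(cells):
    """Independent oracle: EMS components from the raw sums-of-squares definitions.

    Loops over the textbook definitions of SS_mt, SS_n, SS_mtn and SS_E for a
    balanced a x b x r layout — no shared code with the implementation.
    """
    y = np.asarray(cells, dtype=float)
    a, b, r = y.shape
    grand = y.mean()
    ss_mt = sum(r * b * (y[i].mean() - grand) ** 2 for i in range(a))
    ss_n = sum(r * a * (y[:, j].mean() - grand) ** 2 for j in range(b))
    ss_int = 0.0
    for i in range(a):
        for j in range(b):
            ss_int += r * (y[i, j].mean() - y[i].mean() - y[:, j].mean() + grand) ** 2
    ss_e = sum(
        (y[i, j, k] - y[i, j].mean()) ** 2
        for i in range(a) for j in range(b) for k in range(r)
    )
    ms_mt, ms_n = ss_mt / (a - 1), ss_n / (b - 1)
    ms_int = ss_int / ((a - 1) * (b - 1))
    ms_e = ss_e / (a * b * (r - 1))
    return {
        "resid": ms_e,
        "mt:n": max((ms_int - ms_e) / r, 0.0),
        "mt": max((ms_mt - ms_int) / (r * b), 0.0),
        "n": max((ms_n - ms_int) / (r * a), 0.0),
    }


# a printed 3x3x2 toy table (mitotype x nuclear x replicate)
TOY_3x3x2 = [
    [[1.2, 1.4], [0.9, 1.1], [1.6, 1.5]],
    [[1.0, 0.8], [1.3, 1.2], [1.1, 0.9]],
    [[1.5, 1.7], [1.0, 1.2], [0.8, 0.7]],
]


class TestEMS:
    def test_noiseless_additive_data_has_zero_interaction_and_error(self):
        mt = np.array([0.0, 0.5, -0.5])
        n = np.array([1.0, 2.0, 3.0])
        cells = (mt[:, None] + n[None, :])[:, :, None].repeat(2, axis=2)
        vd = ems_varcomp(balanced_table(cells))
        assert vd["mt:n"] == pytest.approx(0.0, abs=1e-12)
        assert vd["resid"] == pytest.approx(0.0, abs=1e-12)
        assert vd["mt"] > 0 and vd["n"] > 0

    def test_matches_brute_force_oracle_on_toy_table(self):
        vd = ems_varcomp(balanced_table(TOY_3x3x2))
        oracle = brute_force_ems(TOY_3x3x2)
        for term, expected in oracle.items():
            assert vd[term] == pytest.approx(expected, abs=1e-12)

    def test_unbalanced_input_rejected_with_guidance(self):
        df = balanced_table(TOY_3x3x2)
        with pytest.raises(ModelError, match="balance_replicates"):
            ems_varcomp(df.iloc[:-1])

    def test_single_replicate_rejected(self):
        cells = np.asarray(TOY_3x3x2)[:, :, :1]
        with pytest.raises(ModelError):
            ems_varcomp(balanced_table(cells))

    def test_negative_components_clipped_and_flagged(self):
        rng = np.random.default_rng(0)
        cells = rng.normal(0, 1, (3, 3, 2))  # pure noise: genetic terms often negative
        vd = ems_varcomp(balanced_table(cells))
        assert all(v >= 0 for v in vd.components.values())
        assert set(vd.clipped) <= {"mt", "n", "mt:n"}


class TestREML:
    def test_agrees_with_ems_on_balanced_interior_data(self, small_fitness):
        ems = ems_varcomp(small_fitness)
        reml = reml_varcomp(small_fitness)
        assert not ems.clipped
        for term in ("mt", "n", "mt:n", "resid"):
            assert reml[term] == pytest.approx(ems[term], rel=1e-3)

    def test_balanced_and_general_engines_agree(self, small_fitness):
        fast = vc._reml_balanced(small_fitness, ("mt", "n", "mt:n"))
        slow = vc._reml_general(small_fitness, ("mt", "n", "mt:n"))
        assert slow.loglik == pytest.approx(fast.loglik, abs=1e-3)
        for term in ("mt", "n", "mt:n", "resid"):
            assert slow.proportions[term] == pytest.approx(fast.proportions[term], abs=1e-3)

    def test_pure_noise_puts_genetic_terms_at_boundary(self):
        rng = np.random.default_rng(3)
        cells = rng.normal(5, 1, (4, 4, 3))
        vd = reml_varcomp(balanced_table(cells))
        assert vd["mt:n"] + vd["mt"] + vd["n"] < 0.2 * vd["resid"]

    def test_duplicating_observations_preserves_proportions(self):
        # replication consistency: with a reasonable replicate depth, doubling
        # every observation leaves the estimated variance shares essentially
        # unchanged (the within-cell df correction vanishes as r grows)
        _, obs = simulated_fitness(seed=42, reps=20)
        doubled = pd.concat([obs, obs.assign(tech_rep=obs.tech_rep + 100)], ignore_index=True)
        base = reml_varcomp(obs)
        dup = reml_varcomp(doubled)
        for term in ("mt", "n", "mt:n", "resid"):
            assert dup.proportions[term] == pytest.approx(base.proportions[term], abs=0.02)

    def test_unbalanced_data_accepted(self, small_fitness):
        vd = reml_varcomp(small_fitness.iloc[:-5])
        assert vd.converged
        assert sum(vd.proportions.values()) == pytest.approx(1.0)

    def test_environment_terms_need_multiple_environments(self, small_fitness):
        with pytest.raises(ModelError):
            reml_varcomp(small_fitness, terms=("mt", "n", "e"))

    def test_three_way_environment_model_recovers_gxgxe(self):
        from mitonuclear import SimulationParams, simulate_fitness_observations, simulate_true_fitness
        from conftest import make_panel

        params = SimulationParams(
            media=("A", "B"), temperatures=(30, 37), seed=5,
            var_mt=0.0, var_n=0.01, var_mtn=0.0, var_env=0.02,
            var_mt_env=0.0, var_n_env=0.0, var_mtn_env=0.02, var_resid=0.01,
        )
        truth = simulate_true_fitness(params, make_panel({"A": 6}))
        obs = simulate_fitness_observations(truth, params, reps=3, seed=6)
        vd = reml_varcomp(obs, terms=("mt", "n", "e", "mt:n", "mt:n:e"))
        assert vd["mt:n:e"] > vd["mt:n"]
        assert vd["mt:n:e"] == pytest.approx(0.02, abs=0.015)


class TestAgainstLme4:
    def test_reml_matches_lmer_on_crossed_design(self, small_fitness, tmp_path):
        """Independent oracle: R's lme4 (lmer, REML) on the same crossed data."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        df = small_fitness.copy()
        df["mtn"] = df.mitotype_id + ":" + df.nuclear_id
        csv = tmp_path / "fitness.csv"
        df.to_csv(csv, index=False)
        script = f"""
suppressMessages(library(lme4))
d <- read.csv("{csv}")
fit <- lmer(fitness ~ 1 + (1|mitotype_id) + (1|nuclear_id) + (1|mtn), data=d, REML=TRUE)
vc <- as.data.frame(VarCorr(fit))
for (i in seq_len(nrow(vc))) cat(vc$grp[i], vc$vcov[i], "\\n")
cat("logLik", as.numeric(logLik(fit)), "\\n")
"""
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        if out.returncode != 0:
            pytest.skip(f"lme4 unavailable: {out.stderr[-200:]}")
        lme4 = {}
        for line in out.stdout.strip().splitlines():
            parts = line.split()
            lme4[parts[0]] = float(parts[1])
        vd = reml_varcomp(small_fitness)
        assert vd["mt"] == pytest.approx(lme4["mitotype_id"], rel=1e-3)
        assert vd["n"] == pytest.approx(lme4["nuclear_id"], rel=1e-3)
        assert vd["mt:n"] == pytest.approx(lme4["mtn"], rel=1e-3)
        assert vd["resid"] == pytest.approx(lme4["Residual"], rel=1e-3)
        assert vd.loglik == pytest.approx(lme4["logLik"], abs=1e-2)


class TestInvariances:
    def test_proportions_sum_to_one_and_lie_in_unit_interval(self, small_fitness):
        for vd in (ems_varcomp(small_fitness), reml_varcomp(small_fitness)):
            assert sum(vd.proportions.values()) == pytest.approx(1.0)
            assert all(0 <= p <= 1 for p in vd.proportions.values())

    def test_shift_invariance_and_scale_equivariance(self, small_fitness):
        base = ems_varcomp(small_fitness)
        shifted = small_fitness.assign(fitness=small_fitness.fitness + 7.0)
        scaled = small_fitness.assign(fitness=small_fitness.fitness * 3.0)
        vd_shift = ems_varcomp(shifted)
        vd_scale = ems_varcomp(scaled)
        for term in base.components:
            assert vd_shift[term] == pytest.approx(base[term], rel=1e-9, abs=1e-12)
            assert vd_scale[term] == pytest.approx(9.0 * base[term], rel=1e-9, abs=1e-12)
            assert vd_scale.proportions[term] == pytest.approx(base.proportions[term], abs=1e-9)


class TestLRT:
    def test_statistic_nonnegative_and_interaction_detected(self, small_fitness):
        res = lrt_term(small_fitness, "mt:n")
        assert res.statistic >= 0
        assert res.p_value < 1e-6

    def test_absent_mt_effect_gives_large_p(self, small_fitness):
        res = lrt_term(small_fitness, "mt")
        assert res.p_value > 0.05

    def test_plain_chisq_mode_doubles_boundary_p(self, small_fitness):
        corrected = lrt_term(small_fitness, "mt", boundary_correction=True)
        plain = lrt_term(small_fitness, "mt", boundary_correction=False)
        if corrected.statistic > 0:
            assert plain.p_value == pytest.approx(2 * corrected.p_value, rel=1e-9)

    def test_mt_pvalues_super_uniform_under_null(self):
        # sigma2_mt = 0 in the generator: P(p < alpha) should not exceed alpha
        rej = 0
        n_rep = 60
        for seed in range(n_rep):
            _, obs = simulated_fitness(seed=300 + seed, proportions=(0.0, 0.4, 0.2, 0.4), reps=2)
            rej += lrt_term(obs, "mt").p_value < 0.05
        # binomial(60, 0.05) 3-sigma upper bound
        assert rej <= 0.05 * n_rep + 3 * np.sqrt(n_rep * 0.05 * 0.95)

    def test_strong_interaction_has_high_power(self):
        hits = 0
        for seed in range(20):
            _, obs = simulated_fitness(seed=600 + seed, proportions=(0.0, 0.2, 0.4, 0.4), reps=2)
            hits += lrt_term(obs, "mt:n").p_value < 0.05
        assert hits == 20

    def test_unknown_term_rejected(self, small_fitness):
        with pytest.raises(ModelError):
            lrt_term(small_fitness, "mt:q")
        with pytest.raises(ModelError):
            lrt_term(small_fitness, "e")  # not in the default two-factor model
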