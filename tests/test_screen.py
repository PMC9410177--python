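"""The multi-stage candidate screen and its kinetic-concordance rule."""

import math

import numpy as np
import pandas as pd
import pytest

from lignanscreen.census import Orthogroup
from lignanscreen.errors import ValidationError
from lignanscreen.screen import (
    ExpressionMatrix,
    KineticProfile,
    PanelSpec,
    ScreenConfig,
    core_membership_filter,
    early_expression_filter,
    final_candidates,
    kinetic_concordance,
    log_transform,
    run_screen,
    seed_preference_filter,
    seedcolor_filter,
)
from lignanscreen.simulate import (
    SimConfig,
    default_panels,
    simulate_expression,
    simulate_pangenome,
    simulate_pinoresinol_profile,
)


def matrix(gene_rows, samples):
    """gene_rows: gene -> list of fpkm; samples: list of (variety, tissue, stage)."""
    ids = [f"{v}_{t}_{s}" for v, t, s in samples]
    sample_df = pd.DataFrame(
        [(i, v, t, s, 1) for i, (v, t, s) in zip(ids, samples)],
        columns=["sample_id", "variety", "tissue", "stage", "replicate"],
    ).set_index("sample_id")
    fpkm = pd.DataFrame(gene_rows, index=ids).T
    return ExpressionMatrix(fpkm, sample_df)


ORGAN_SAMPLES = [("v1", t, s) for t in ("seed", "root", "leaf")
                 for s in (10, 20, 30)]


class TestLogTransform:
    def test_exact_values(self):
        df = pd.DataFrame({"s": [0.0, 1.0, 3.0]}, index=["a", "b", "c"])
        out = log_transform(df, 1.0)
        assert out.loc["a", "s"] == 0.0
        assert out.loc["b", "s"] == 1.0
        assert out.loc["c", "s"] == 2.0

    def test_order_preserving(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.uniform(0, 100, size=(30, 4)))
        out = log_transform(df, 1.0)
        flat_in, flat_out = df.to_numpy().ravel(), out.to_numpy().ravel()
        order = np.argsort(flat_in)
        assert (np.diff(flat_out[order]) >= 0).all()

    def test_negative_fpkm_errors(self):
        with pytest.raises(ValidationError):
            log_transform(pd.DataFrame({"s": [-1.0]}))


class TestSeedPreference:
    def test_seed_only_expression_passes_with_infinite_fold(self):
        expr = matrix({"g": [10, 10, 10, 0, 0, 0, 0, 0, 0]}, ORGAN_SAMPLES)
        passed, fold = seed_preference_filter(expr, ScreenConfig())
        assert passed["g"]
        assert fold["g"] == math.inf

    def test_root_dominant_gene_fails(self):
        expr = matrix({"g": [0, 0, 0, 5, 5, 5, 0, 0, 0]}, ORGAN_SAMPLES)
        passed, _ = seed_preference_filter(expr, ScreenConfig())
        assert not passed["g"]

    def test_exact_fold_boundary_is_inclusive(self):
        expr = matrix({"g": [4, 4, 4, 2, 2, 2, 1, 1, 1]}, ORGAN_SAMPLES)
        passed, fold = seed_preference_filter(expr, ScreenConfig(seed_fold=2.0))
        assert passed["g"]
        assert fold["g"] == pytest.approx(2.0)

    def test_missing_seed_tissue_errors(self):
        expr = matrix({"g": [1, 1]}, [("v1", "root", 10), ("v1", "leaf", 10)])
        with pytest.raises(ValidationError, match="seed"):
            seed_preference_filter(expr, ScreenConfig())


OIL_SAMPLES = [(v, "seed", s) for v in ("v2", "v3", "v4") for s in (10, 20, 30)]


class TestEarlyExpression:
    def test_expressed_early_everywhere_passes(self):
        expr = matrix({"g": [5, 9, 9] * 3}, OIL_SAMPLES)
        assert early_expression_filter(expr, ScreenConfig())["g"]

    def test_silent_at_one_varietys_earliest_stage_fails(self):
        expr = matrix({"g": [5, 9, 9, 0, 9, 9, 5, 9, 9]}, OIL_SAMPLES)
        assert not early_expression_filter(expr, ScreenConfig())["g"]


COLOR_SAMPLES = [(v, "seed", s) for v in ("white", "black")
                 for s in (5, 8, 20, 30)]


class TestSeedColor:
    def test_present_early_in_white_passes(self):
        expr = matrix({"g": [4, 4, 9, 9, 0, 0, 0, 0]}, COLOR_SAMPLES)
        assert seedcolor_filter(expr, ScreenConfig(), "white")["g"]

    def test_silent_early_in_white_fails(self):
        expr = matrix({"g": [0, 0, 9, 9, 9, 9, 9, 9]}, COLOR_SAMPLES)
        assert not seedcolor_filter(expr, ScreenConfig(), "white")["g"]

    def test_black_dominance_does_not_matter(self):
        # higher in black early, but present in white early: presence wins
        expr = matrix({"g": [2, 2, 9, 9, 20, 20, 9, 9]}, COLOR_SAMPLES)
        assert seedcolor_filter(expr, ScreenConfig(), "white")["g"]

    def test_missing_white_variety_errors(self):
        expr = matrix({"g": [1] * 8}, COLOR_SAMPLES)
        with pytest.raises(ValidationError, match="absent"):
            seedcolor_filter(expr, ScreenConfig(), "ivory")


def pearson_oracle(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


class TestKinetic:
    STAGES = [5, 10, 15, 20, 23, 25, 30]

    def profile(self):
        return simulate_pinoresinol_profile(self.STAGES)

    def test_monotone_rise_through_final_stage_fails(self):
        traj = pd.Series([1, 2, 4, 8, 16, 32, 64], index=self.STAGES, dtype=float)
        ok, peak, _, _ = kinetic_concordance(traj, self.profile(), ScreenConfig())
        assert not ok
        assert peak == 30

    def test_constant_trajectory_fails_flatness_rule(self):
        traj = pd.Series([7.0] * 7, index=self.STAGES)
        ok, *_ = kinetic_concordance(traj, self.profile(), ScreenConfig())
        assert not ok

    def test_rise_fall_passes_and_correlation_matches_oracle(self):
        values = [1.0, 4.0, 20.0, 50.0, 40.0, 25.0, 8.0]
        traj = pd.Series(values, index=self.STAGES)
        ok, peak, decline, corr = kinetic_concordance(
            traj, self.profile(), ScreenConfig())
        assert ok
        assert peak == 20
        assert decline == pytest.approx((40 + 25 + 8) / 3 / 50)
        prof = self.profile().as_series().loc[self.STAGES].tolist()
        assert corr == pytest.approx(pearson_oracle(values, prof), abs=1e-12)

    def test_too_few_stages_error(self):
        traj = pd.Series([1.0, 2.0, 1.0], index=[10, 20, 30])
        with pytest.raises(ValidationError):
            kinetic_concordance(traj, self.profile(), ScreenConfig())


class TestCoreMembership:
    def groups(self):
        core = Orthogroup("OG1", {"v1": ["a"], "v2": ["a2"]}, cls="core")
        spec = Orthogroup("OG2", {"v1": ["b"]}, cls="specific")
        return [core, spec]

    def test_core_kept_specific_and_unknown_dropped(self):
        passed = core_membership_filter(["a", "b", "zz"], self.groups())
        assert passed.to_dict() == {"a": True, "b": False, "zz": False}


class TestRunScreen:
    def test_planted_candidates_recovered_exactly(self, default_cfg, dataset,
                                                  expression, kinetic_profile):
        from lignanscreen.census import classify_orthogroups, cluster_orthogroups
        gene_variety = {g: g.split("_", 1)[0]
                        for g in dataset.truth.gene_orthogroup}
        groups = cluster_orthogroups(dataset.edges, gene_variety, 50.0)
        groups, _ = classify_orthogroups(groups, default_cfg.varieties)
        report = run_screen(expression, kinetic_profile, groups,
                            default_panels(default_cfg))
        assert set(final_candidates(report)) == dataset.truth.candidate_genes
        # the constitutively expressed confounder survives the first three
        # filters and dies only on the kinetic rule
        flat = dataset.truth.flat_confounder
        row = report.loc[flat]
        assert row["stage1_seed_pref"] and row["stage2_early_oil"] \
            and row["stage3_color"]
        assert not row["kinetic_pass"]

    def test_empty_matrix_gives_empty_report(self, kinetic_profile):
        expr = matrix({}, ORGAN_SAMPLES)
        panels = PanelSpec(("v1",), ("v1",), "v1", "v1")
        report = run_screen(expr, kinetic_profile, [], panels)
        assert report.empty

    def test_unreachable_floor_empties_final_set_with_audit(
            self, default_cfg, expression, kinetic_profile):
        cfg = ScreenConfig(min_expr=1e9)
        report = run_screen(expression, kinetic_profile, [],
                            default_panels(default_cfg), cfg)
        assert final_candidates(report) == []
        assert not report["stage1_seed_pref"].any()

    def test_audit_trail_is_complete(self, default_cfg, expression,
                                     kinetic_profile):
        report = run_screen(expression, kinetic_profile, [],
                            default_panels(default_cfg))
        assert list(report.index) == list(expression.genes)
        for col in ("stage1_seed_pref", "stage2_early_oil", "stage3_color",
                    "kinetic_pass", "core_member", "final"):
            assert report[col].notna().all()

    def test_sample_and_gene_order_invariance(self, default_cfg, dataset,
                                              expression, kinetic_profile):
        rng = np.random.default_rng(3)
        perm_genes = expression.fpkm.index[rng.permutation(len(expression.genes))]
        perm_samples = expression.fpkm.columns[
            rng.permutation(expression.fpkm.shape[1])]
        shuffled = ExpressionMatrix(
            expression.fpkm.loc[perm_genes, perm_samples],
            expression.samples.loc[perm_samples])
        a = run_screen(expression, kinetic_profile, [],
                       default_panels(default_cfg))
        b = run_screen(shuffled, kinetic_profile, [],
                       default_panels(default_cfg))
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_tightening_thresholds_never_enlarges_final_set(
            self, default_cfg, dataset, expression, kinetic_profile):
        from lignanscreen.census import classify_orthogroups, cluster_orthogroups
        gene_variety = {g: g.split("_", 1)[0]
                        for g in dataset.truth.gene_orthogroup}
        groups = cluster_orthogroups(dataset.edges, gene_variety, 50.0)
        groups, _ = classify_orthogroups(groups, default_cfg.varieties)
        panels = default_panels(default_cfg)
        rng = np.random.default_rng(8)
        for _ in range(15):
            base = ScreenConfig(
                min_expr=float(rng.uniform(0.2, 3.0)),
                seed_fold=float(rng.uniform(1.2, 3.0)),
                decline_ratio=float(rng.uniform(0.4, 0.9)),
                flat_cv=float(rng.uniform(0.05, 0.5)))
            loose = set(final_candidates(
                run_screen(expression, kinetic_profile, groups, panels, base)))
            tighter = ScreenConfig(
                min_expr=base.min_expr * 1.5, seed_fold=base.seed_fold * 1.5,
                decline_ratio=base.decline_ratio * 0.7,
                flat_cv=base.flat_cv * 1.5)
            tight = set(final_candidates(
                run_screen(expression, kinetic_profile, groups, panels, tighter)))
            assert tight <= loose

    def test_recovery_degrades_gracefully_at_high_noise(self):
        """At noise_sd = 0.4 sensitivity stays >= 0.9 over repeated seeds."""
        hits = total = 0
        for seed in range(8):
            cfg = SimConfig(rng_seed=seed, noise_sd=0.4)
            ds = simulate_pangenome(cfg)
            expr = simulate_expression(cfg, ds.truth)
            profile = simulate_pinoresinol_profile(list(cfg.stages))
            from lignanscreen.census import (classify_orthogroups,
                                             cluster_orthogroups)
            gene_variety = {g: g.split("_", 1)[0]
                            for g in ds.truth.gene_orthogroup}
            groups = cluster_orthogroups(ds.edges, gene_variety, 50.0)
            groups, _ = classify_orthogroups(groups, cfg.varieties)
            report = run_screen(expr, profile, groups, default_panels(cfg))
            found = set(final_candidates(report))
            hits += len(found & ds.truth.candidate_genes)
            total += len(ds.truth.candidate_genes)
        assert hits / total >= 0.9
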