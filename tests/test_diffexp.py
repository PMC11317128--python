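"""Differential-expression engines and the grid runner."""

import numpy as np
import pandas as pd
import pytest

from crosspipe import (
    fit_moderated_lm,
    log_cpm,
    nb_ql_engine,
    nb_wald_engine,
    run_pipeline_grid,
    simulate_bulk_counts,
    tmm_factors,
)
from crosspipe.core import ContrastSpec, PipelineID, SampleSheet
from crosspipe.diffexp import (
    ModerationParams,
    _nb_irls,
    build_contrast_design,
    squeeze_variances,
)
from crosspipe.errors import ValidationError

from conftest import make_counts


def _two_group_design(n_a, n_b):
    n = n_a + n_b
    design = np.column_stack([np.ones(n), np.r_[np.ones(n_a), np.zeros(n_b)]])
    cvec = np.array([0.0, 1.0])
    return design, cvec


class TestModeratedLM:
    def test_shrinkage_formula_hand_example(self):
        # d0=4, s0^2=1, d_g=4, s_g^2=2 -> posterior variance 1.5;
        # lfc=1 with unscaled contrast variance 0.5 -> t = 1/sqrt(0.75)
        s2_post = squeeze_variances(np.array([2.0]), 4, ModerationParams(4.0, 1.0))
        assert s2_post[0] == pytest.approx(1.5)
        stat = 1.0 / np.sqrt(s2_post[0] * 0.5)
        assert stat == pytest.approx(1.1547, abs=1e-4)

    def test_equal_variances_reduce_to_ordinary_t(self):
        # genes share one residual pattern (hence one variance): the
        # empirical-Bayes step must leave the ordinary t untouched
        resid = np.array([0.3, -0.1, -0.2, 0.25, -0.15, -0.1])
        design, cvec = _two_group_design(3, 3)
        rows = [resid + design[:, 1] * shift for shift in (0.0, 0.5, 2.0, -1.0)]
        x = pd.DataFrame(rows, index=list("abcd"), columns=[f"s{i}" for i in range(6)])
        res = fit_moderated_lm(x, design, cvec)
        beta = np.linalg.lstsq(design, x.to_numpy().T, rcond=None)[0].T
        fitted = beta @ design.T
        s2 = ((x.to_numpy() - fitted) ** 2).sum(axis=1) / 4
        v_c = cvec @ np.linalg.inv(design.T @ design) @ cvec
        ordinary_t = beta[:, 1] / np.sqrt(s2 * v_c)
        assert np.allclose(res["stat"].to_numpy(), ordinary_t, atol=1e-10)

    def test_lfc_is_group_mean_difference(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.normal(size=(20, 6)))
        design, cvec = _two_group_design(3, 3)
        res = fit_moderated_lm(x, design, cvec)
        diff = x.iloc[:, :3].mean(axis=1) - x.iloc[:, 3:].mean(axis=1)
        assert np.allclose(res["lfc"].to_numpy(), diff.to_numpy(), atol=1e-12)

    def test_constant_gene_flagged_not_nan(self):
        x = pd.DataFrame(
            [[1.0] * 6, [0.1, 0.4, 0.2, 0.9, 1.2, 1.1]], index=["const", "var"]
        )
        design, cvec = _two_group_design(3, 3)
        res = fit_moderated_lm(x, design, cvec)
        assert res.loc["const", "stat"] == 0.0
        assert res.loc["const", "p"] == 1.0
        assert not res["stat"].isna().any()

    def test_sign_of_stat_matches_sign_of_lfc(self, nb_dataset):
        m, s, _ = nb_dataset
        _, design, cvec = build_contrast_design(s, ContrastSpec("A", "B"))
        res = fit_moderated_lm(log_cpm(m, tmm_factors(m)), design, cvec)
        nz = res["lfc"] != 0
        assert (np.sign(res.loc[nz, "stat"]) == np.sign(res.loc[nz, "lfc"])).all()


class TestNBEngines:
    def test_identical_group_columns_give_null_stats(self):
        rng = np.random.default_rng(4)
        block = rng.integers(0, 300, size=(60, 3))
        m = make_counts(np.hstack([block, block]))
        s = SampleSheet(pd.DataFrame({
            "sample_id": m.sample_ids, "group": ["A"] * 3 + ["B"] * 3,
        }))
        for engine in (nb_wald_engine, nb_ql_engine):
            res = engine(m, s, ContrastSpec("A", "B"))
            assert np.allclose(res["lfc"], 0.0, atol=1e-6)
            assert np.allclose(res["stat"], 0.0, atol=1e-5)

    def test_swapping_groups_negates_effects(self, nb_dataset):
        m, s, _ = nb_dataset
        for engine in (nb_wald_engine, nb_ql_engine):
            ab = engine(m, s, ContrastSpec("A", "B"))
            ba = engine(m, s, ContrastSpec("B", "A"))
            # genes expressed on one side only sit at the clipped boundary of
            # the GLM; their huge lfc magnitudes may differ in the last digits
            assert np.allclose(ab["lfc"], -ba["lfc"], atol=0.02)
            assert np.allclose(ab["stat"], -ba["stat"], atol=1e-4)

    def test_wald_matches_independent_glm_fit_at_fixed_dispersion(self):
        # oracle: statsmodels' IRLS NB GLM at the same known dispersion
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        y = rng.negative_binomial(5, 5 / (5 + 100), size=(10, 8)).astype(float)
        design, cvec = _two_group_design(4, 4)
        offset = np.zeros(8)
        alpha = np.full(10, 0.2)
        beta, cov, _ = _nb_irls(y, design, offset, alpha)
        for g in range(10):
            fit = sm.GLM(
                y[g], design, family=sm.families.NegativeBinomial(alpha=0.2)
            ).fit()
            assert beta[g, 1] == pytest.approx(fit.params[1], abs=1e-6)
            se = np.sqrt(cov[g, 1, 1])
            assert se == pytest.approx(fit.bse[1] / np.sqrt(fit.scale), rel=1e-4)

    def test_ql_stat_is_signed_root_of_f(self, nb_dataset):
        # |stat| ranking must equal the F ranking, and p must be monotone in F
        m, s, _ = nb_dataset
        res = nb_ql_engine(m, s, ContrastSpec("A", "B"))
        f = res["stat"].to_numpy() ** 2
        order_f = np.argsort(-f)
        order_stat = np.argsort(-np.abs(res["stat"].to_numpy()))
        assert np.array_equal(order_f, order_stat)
        nz = res["lfc"] != 0
        assert (np.sign(res.loc[nz, "stat"]) == np.sign(res.loc[nz, "lfc"])).all()

    def test_all_zero_gene_reported_with_unit_p(self):
        counts = np.vstack([np.zeros(6, dtype=int), [[30, 40, 35, 60, 70, 65]]])
        m = make_counts(counts, genes=["dead", "alive"])
        s = SampleSheet(pd.DataFrame({
            "sample_id": m.sample_ids, "group": ["A"] * 3 + ["B"] * 3,
        }))
        res = nb_wald_engine(m, s, ContrastSpec("A", "B"))
        assert res.loc["dead", "p"] == 1.0
        assert res.loc["dead", "stat"] == 0.0
        assert res.loc["dead", "flagged"]


class TestPipelineGrid:
    def test_full_grid_emits_twelve_pipeline_blocks(self, nb_dataset):
        m, s, _ = nb_dataset
        de = run_pipeline_grid(m, s, [ContrastSpec("A", "B")])
        assert de["pipeline"].nunique() == 12
        assert not de.attrs["failures"]

    def test_single_pipeline_row_cardinality(self, nb_dataset):
        m, s, _ = nb_dataset
        de = run_pipeline_grid(
            m, s, [ContrastSpec("A", "B")],
            pipelines=[PipelineID("unfiltered", "tmm-limma")],
        )
        assert len(de) == m.shape[0]

    def test_filtered_rows_are_subset_of_unfiltered(self, nb_dataset):
        m, s, _ = nb_dataset
        de = run_pipeline_grid(
            m, s, [ContrastSpec("A", "B")],
            pipelines=[PipelineID("filtered", "tmm-limma"),
                       PipelineID("unfiltered", "tmm-limma")],
        )
        filtered_genes = set(de.loc[de["pipeline"] == "filtered-tmm-limma", "gene"])
        unfiltered_genes = set(de.loc[de["pipeline"] == "unfiltered-tmm-limma", "gene"])
        assert filtered_genes < unfiltered_genes

    def test_bh_adjustment_monotone_and_bounded(self, nb_dataset):
        m, s, _ = nb_dataset
        de = run_pipeline_grid(
            m, s, [ContrastSpec("A", "B")],
            pipelines=[PipelineID("unfiltered", "deseq2")],
        )
        assert (de["padj"] >= de["p"] - 1e-12).all()
        assert (de["padj"] <= 1.0).all()
        block = de.sort_values("p")
        assert np.all(np.diff(block["padj"].to_numpy()) >= -1e-12)

    def test_gene_order_invariance(self, nb_dataset):
        m, s, _ = nb_dataset
        pipe = [PipelineID("unfiltered", "log2quant-limma")]
        de1 = run_pipeline_grid(m, s, [ContrastSpec("A", "B")], pipelines=pipe)
        order = list(reversed(m.gene_ids))
        m2 = make_counts(m.counts.loc[order].to_numpy(), genes=order,
                         samples=m.sample_ids)
        de2 = run_pipeline_grid(m2, s, [ContrastSpec("A", "B")], pipelines=pipe)
        a = de1.set_index("gene")["stat"]
        b = de2.set_index("gene")["stat"]
        assert np.allclose(a.loc[order].to_numpy(), b.loc[order].to_numpy())

    def test_empty_pipeline_list_is_error(self, nb_dataset):
        m, s, _ = nb_dataset
        with pytest.raises(ValidationError):
            run_pipeline_grid(m, s, [ContrastSpec("A", "B")], pipelines=[])


class TestCalibrationAndPower:
    def test_null_pvalues_approximately_uniform(self):
        """Under a global null, each engine's p < 0.05 fraction is ~5%."""
        from crosspipe.diffexp import fit_moderated_lm

        fracs = {"modlm": [], "wald": [], "ql": []}
        for rep in range(12):
            m, s, _ = simulate_bulk_counts(
                2000, {"A": 5, "B": 5}, low_count_fraction=0.0, seed=900 + rep
            )
            c = ContrastSpec("A", "B")
            _, design, cvec = build_contrast_design(s, c)
            x = log_cpm(m, tmm_factors(m))
            fracs["modlm"].append((fit_moderated_lm(x, design, cvec)["p"] < 0.05).mean())
            fracs["wald"].append((nb_wald_engine(m, s, c)["p"] < 0.05).mean())
            fracs["ql"].append((nb_ql_engine(m, s, c)["p"] < 0.05).mean())
        for name, values in fracs.items():
            assert 0.03 <= np.mean(values) <= 0.08, (name, np.mean(values))

    def test_planted_genes_rank_highly_in_every_engine(self):
        planted = {f"g{i + 1:04d}": 2.0 for i in range(100)}
        m, s, _ = simulate_bulk_counts(
            1000, {"A": 5, "B": 5}, lfc_map=planted,
            low_count_fraction=0.0, seed=77,
        )
        de = run_pipeline_grid(
            m, s, [ContrastSpec("A", "B")],
            pipelines=[PipelineID("unfiltered", meth) for meth in
                       ("tmm-limma", "vsn-limma", "voom-limma",
                        "log2quant-limma", "edger", "deseq2")],
        )
        for pipeline, block in de.groupby("pipeline"):
            top200 = set(
                block.reindex(block["stat"].abs().sort_values(ascending=False).index)
                .head(200)["gene"]
            )
            recovered = len(top200 & set(planted)) / len(planted)
            assert recovered >= 0.9, (pipeline, recovered)
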