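import shutil
import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from matchsym import (
    SimulationParams,
    design_from_records,
    dispersion_homogeneity_shape,
    gpa,
    levene_size,
    procrustes_anova,
    replicate_residuals,
    residual_normality,
    simulate_dataset,
    size_anova,
    size_anova_from_aligned,
    submodel_anova_shape,
    submodel_anova_size,
    tangent_project,
)


def naive_two_factor_ss(y, ind, side, rep):
    """Independent oracle: per-coordinate balanced two-factor SS by direct
    group-by means, summed over coordinates."""
    df = pd.DataFrame(y)
    cols = list(df.columns)
    df["ind"], df["side"] = ind, side
    grand = df[cols].mean()
    m_i = df.groupby("ind")[cols].mean()
    m_s = df.groupby("side")[cols].mean()
    m_c = df.groupby(["ind", "side"])[cols].mean()
    n_rep = len(df) // len(m_c)
    ss_ind = 2 * n_rep * ((m_i - grand) ** 2).to_numpy().sum()
    ss_side = len(m_i) * n_rep * ((m_s - grand) ** 2).to_numpy().sum()
    inter = m_c.copy()
    for (i, s) in inter.index:
        inter.loc[(i, s)] = (
            m_c.loc[(i, s)] - m_i.loc[i] - m_s.loc[s] + grand
        )
    ss_int = n_rep * (inter**2).to_numpy().sum()
    resid = df[cols].to_numpy() - m_c.loc[
        list(zip(df["ind"], df["side"]))
    ].to_numpy()
    ss_rep = (resid**2).sum()
    return ss_ind, ss_side, ss_int, ss_rep


class TestProcrustesAnova:
    @pytest.mark.parametrize(
        "n,expected",
        [(25, (1824, 76, 1824, 3800)), (30, (2204, 76, 2204, 4560))],
    )
    def test_shape_df_ladder(self, n, expected):
        ds = simulate_dataset(SimulationParams(n_individuals=n, seed=1))
        tab = procrustes_anova(gpa(ds.records, reflect_side="left"))
        assert tuple(r.df for r in tab.rows) == expected

    def test_f_denominator_structure(self, study_aligned):
        tab = procrustes_anova(study_aligned)
        ms = {r.effect: r.MS for r in tab.rows}
        assert tab["individual"].F == pytest.approx(ms["individual"] / ms["interaction"])
        assert tab["side"].F == pytest.approx(ms["side"] / ms["interaction"])
        assert tab["interaction"].F == pytest.approx(ms["interaction"] / ms["replicate"])
        assert tab["individual"].denominator == "interaction"
        assert tab["interaction"].denominator == "replicate"
        assert tab["replicate"].F is None

    def test_ss_additivity_and_pct(self, study_aligned):
        tab = procrustes_anova(study_aligned)
        y = tangent_project(study_aligned)
        total = ((y - y.mean(axis=0)) ** 2).sum()
        assert sum(r.SS for r in tab.rows) == pytest.approx(total, abs=1e-8)
        assert sum(r.pct_SS for r in tab.rows) == pytest.approx(100, abs=0.2)
        for r in tab.rows:
            assert r.MS * r.df == pytest.approx(r.SS, abs=1e-9)

    def test_matches_naive_oracle(self):
        for seed in range(5):
            p = SimulationParams(
                n_individuals=int(np.random.default_rng(seed).integers(3, 8)),
                template=_small_template(),
                seed=seed,
            )
            aligned = gpa(simulate_dataset(p).records, reflect_side="left")
            design = design_from_records(aligned.records)
            tab = procrustes_anova(aligned, design)
            y = tangent_project(aligned)
            ind = [r.individual_id for r in aligned.records]
            side = [r.side for r in aligned.records]
            rep = [r.replicate for r in aligned.records]
            expected = naive_two_factor_ss(y, ind, side, rep)
            for row, ss in zip(tab.rows, expected):
                assert row.SS == pytest.approx(ss, abs=1e-8)

    def test_unbalanced_is_an_error(self, small_dataset):
        recs = small_dataset.records[:-1]
        aligned = gpa(recs, reflect_side="left")
        with pytest.raises(ValueError, match="filter_complete_pairs"):
            procrustes_anova(aligned)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(2, 40), st.integers(2, 4), st.integers(3, 50))
    def test_df_identities(self, n, r, lm):
        """df(ind)=(N-1)d, df(side)=d, df(int)=(N-1)d, df(rep)=2N(R-1)d."""
        from matchsym.anova import _assemble_table, Design

        design = Design(
            individuals=[f"i{k}" for k in range(n)],
            ind_idx=np.repeat(np.arange(n), 2 * r),
            side_idx=np.tile(np.repeat([0, 1], r), n),
            rep_idx=np.tile(np.arange(r), 2 * n),
            n_replicates=r,
        )
        d = 2 * lm - 4
        tab = _assemble_table((1.0, 1.0, 1.0, 1.0), d, design, "shape", None, lm)
        assert [row.df for row in tab.rows] == [
            (n - 1) * d, d, (n - 1) * d, n * 2 * (r - 1) * d
        ]


class TestSizeAnova:
    @pytest.mark.parametrize("n,expected", [(25, (24, 1, 24, 50)), (30, (29, 1, 29, 60))])
    def test_size_df_ladder(self, n, expected):
        ds = simulate_dataset(SimulationParams(n_individuals=n, seed=1))
        tab = size_anova_from_aligned(gpa(ds.records, reflect_side="left"))
        assert tuple(r.df for r in tab.rows) == expected

    def test_constant_sizes_reported_na(self, small_aligned):
        design = design_from_records(small_aligned.records)
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            tab = size_anova(np.ones(len(small_aligned.records)), design)
        assert any("identical" in str(x.message) for x in w)
        assert all(r.F is None and r.p is None for r in tab.rows)
        assert all(r.SS == 0 for r in tab.rows)

    def test_strong_fa_detected(self):
        """cs_sd_fa >> cs_sd_error makes the interaction test reject."""
        hits = 0
        runs = 30
        for seed in range(runs):
            p = SimulationParams(
                n_individuals=15, seed=seed, template=_small_template(),
                cs_sd_fa=5.0, cs_sd_error=0.2,
            )
            tab = size_anova_from_aligned(
                gpa(simulate_dataset(p).records, reflect_side="left")
            )
            if tab["interaction"].p < 0.001:
                hits += 1
        assert hits >= int(0.95 * runs)


class TestSubmodels:
    def test_sequential_ss_equals_full_model_under_balance(self, small_aligned):
        full = procrustes_anova(small_aligned)
        sub = submodel_anova_shape(small_aligned, n_perm=19, seed=0)
        assert sub["individual"].SS == pytest.approx(full["individual"].SS, rel=1e-10)
        assert sub["side"].SS == pytest.approx(full["side"].SS, rel=1e-10)
        assert sub["residual"].SS == pytest.approx(
            full["interaction"].SS + full["replicate"].SS, rel=1e-10
        )

    def test_permutation_p_deterministic(self, small_aligned):
        a = submodel_anova_shape(small_aligned, n_perm=99, seed=5)
        b = submodel_anova_shape(small_aligned, n_perm=99, seed=5)
        assert a["individual"].p == b["individual"].p
        assert a["side"].p == b["side"].p

    def test_individual_effect_detected(self):
        hits = 0
        runs = 20
        for seed in range(runs):
            p = SimulationParams(
                n_individuals=12, seed=seed, template=_small_template(),
                sd_individual=0.01,
            )
            aligned = gpa(simulate_dataset(p).records, reflect_side="left")
            sub = submodel_anova_shape(aligned, n_perm=199, seed=seed)
            if sub["individual"].p <= 0.005:
                hits += 1
        assert hits >= int(0.95 * runs)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_pseudo_f_matches_vegan_adonis(self, tmp_path):
        """Independent oracle: vegan::adonis2 sequential pseudo-F."""
        p = SimulationParams(n_individuals=6, seed=7, template=_small_template())
        aligned = gpa(simulate_dataset(p).records, reflect_side="left")
        sub = submodel_anova_shape(aligned, n_perm=19, seed=1)
        y = tangent_project(aligned)
        np.savetxt(tmp_path / "y.csv", y, delimiter=",")
        pd.DataFrame(
            {
                "ind": [r.individual_id for r in aligned.records],
                "side": [r.side for r in aligned.records],
            }
        ).to_csv(tmp_path / "meta.csv", index=False)
        script = (
            'suppressMessages(library(vegan));'
            f'y <- as.matrix(read.csv("{tmp_path}/y.csv", header=FALSE));'
            f'm <- read.csv("{tmp_path}/meta.csv");'
            'res <- adonis2(y ~ ind + side, data=m, method="euclidean",'
            '               permutations=19, by="terms");'
            'cat(res$F[1], res$F[2], res$SumOfSqs[1], res$SumOfSqs[2], "\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        f_ind, f_side, ss_ind, ss_side = map(float, out.stdout.split())
        assert sub["individual"].F == pytest.approx(f_ind, rel=1e-5)
        assert sub["side"].F == pytest.approx(f_side, rel=1e-5)
        assert sub["individual"].SS == pytest.approx(ss_ind, rel=1e-5)
        assert sub["side"].SS == pytest.approx(ss_side, rel=1e-5)

    def test_size_submodel_additivity_and_full_model_match(self, small_aligned):
        design = design_from_records(small_aligned.records)
        sizes = small_aligned.centroid_sizes
        sub = submodel_anova_size(sizes, design)
        full = size_anova(sizes, design)
        total = ((sizes - sizes.mean()) ** 2).sum()
        assert sum(r.SS for r in sub.rows) == pytest.approx(total, abs=1e-9)
        assert sub["individual"].SS == pytest.approx(full["individual"].SS, rel=1e-10)
        assert sub["side"].SS == pytest.approx(full["side"].SS, rel=1e-10)

    def test_size_submodel_zero_variance(self, small_aligned):
        design = design_from_records(small_aligned.records)
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            sub = submodel_anova_size(np.full(len(small_aligned.records), 3.0), design)
        assert any("identical" in str(x.message) for x in w)
        assert all(r.F is None for r in sub.rows)


class TestDiagnostics:
    def test_normality_calibrated_on_gaussian(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            residual_normality(rng.normal(size=100))[1] < 0.05 for _ in range(200)
        )
        assert 2 <= rejections <= 22  # ~5% of 200 within binomial slack

    def test_normality_rejects_heavy_tails(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            residual_normality(stats.t.rvs(2, size=100, random_state=rng))[1] < 0.05
            for _ in range(100)
        )
        assert rejections > 50

    def test_normality_degenerate_input(self):
        with pytest.raises(ValueError):
            residual_normality(np.ones(20))
        with pytest.raises(ValueError):
            residual_normality(np.array([1.0, 2.0]))

    def test_replicate_residuals_center_on_cells(self, small_aligned):
        design = design_from_records(small_aligned.records)
        res = replicate_residuals(small_aligned.centroid_sizes, design)
        # residuals sum to zero within each individual x side cell
        for i in range(design.n_individuals):
            for s in (0, 1):
                mask = (design.ind_idx == i) & (design.side_idx == s)
                assert abs(res[mask].sum()) < 1e-9

    def test_dispersion_homogeneity_calibrated(self, small_aligned):
        f, p = dispersion_homogeneity_shape(small_aligned, n_perm=199, seed=3)
        assert np.isfinite(f) and 0 < p <= 1

    def test_dispersion_detects_side_heteroscedasticity(self):
        """Doubling the right side's spread should be detected."""
        from dataclasses import replace
        from matchsym import LandmarkConfiguration

        p = SimulationParams(n_individuals=30, seed=8, template=_small_template())
        ds = simulate_dataset(p)
        noise_rng = np.random.default_rng(99)
        recs = []
        for rec in ds.records:
            pts = rec.config.points
            if rec.side == "right":
                c = pts.mean(axis=0)
                cs = np.sqrt(((pts - c) ** 2).sum())
                pts = pts + noise_rng.normal(0, 0.02 * cs, pts.shape)
            recs.append(replace(rec, config=LandmarkConfiguration(pts)))
        aligned = gpa(recs, reflect_side="left")
        f, pval = dispersion_homogeneity_shape(aligned, n_perm=199, seed=0)
        assert pval < 0.05

    def test_levene_equal_and_unequal_variances(self, rng):
        from matchsym.anova import Design

        n = 40
        design = Design(
            individuals=[f"i{k}" for k in range(n // 4)],
            ind_idx=np.repeat(np.arange(n // 4), 4),
            side_idx=np.tile([0, 0, 1, 1], n // 4),
            rep_idx=np.tile([0, 1, 0, 1], n // 4),
            n_replicates=2,
        )
        equal = rng.normal(size=n)
        f, p = levene_size(equal, design)
        assert p > 0.01
        unequal = np.where(design.side_idx == 1, equal * 4, equal)
        f2, p2 = levene_size(unequal, design)
        assert p2 < 0.05

    def test_levene_single_group_error(self):
        from matchsym.anova import Design

        design = Design(["a"], np.zeros(2, int), np.array([0, 1]),
                        np.zeros(2, int), 1)
        with pytest.raises(ValueError):
            levene_size(np.array([1.0, 2.0]), design)


def _small_template():
    from matchsym import make_anchor_template

    return make_anchor_template((3,) * 8)
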