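import numpy as np
import pandas as pd
import pytest

from phyllo3d.quantgen import (AssociationConfig, GenotypeMatrix,
                               HeritabilityModel, bonferroni_threshold,
                               heritability, iqr_outlier_flag,
                               iteration_threshold, ld_r2, marker_qc, read_vcf,
                               rmip, scan, summary_metrics, write_vcf)
from phyllo3d.synthetic_plant import make_population


def phenotable(rows):
    return pd.DataFrame(rows, columns=["plant_id", "genotype_id", "timepoint",
                                       "angle_index", "value"])


class TestSummaryMetrics:
    def test_median_of_four_angles(self):
        t = phenotable([("p1", "g1", 1, i, v)
                        for i, v in enumerate([10, 20, 30, 40], start=1)])
        out = summary_metrics(t, ["median_all"])
        assert out.loc[0, "median_all"] == 25.0

    def test_perfect_alternation_gives_zero_everywhere(self):
        t = phenotable([("p1", "g1", tp, i, 0.0)
                        for tp in (1, 2, 3) for i in (1, 2, 3, 4)])
        out = summary_metrics(t)
        metrics = out.drop(columns=["plant_id", "genotype_id"])
        assert (metrics.fillna(0.0) == 0.0).all().all()

    def test_single_angle_metric_equals_value(self):
        t = phenotable([("p1", "g1", 1, 2, 33.0)])
        out = summary_metrics(t, ["angle2_median", "median_all"])
        assert out.loc[0, "angle2_median"] == 33.0
        assert out.loc[0, "median_all"] == 33.0

    def test_empty_selection_rejected(self):
        t = phenotable([("p1", "g1", 1, 1, 1.0)])
        with pytest.raises(ValueError):
            summary_metrics(t, [])
        with pytest.raises(KeyError):
            summary_metrics(t, ["no_such_metric"])


class TestIqrFlag:
    def test_central_value_not_flagged(self):
        v = np.arange(1, 101, dtype=float)
        assert not iqr_outlier_flag(v)[49]

    def test_extreme_value_flagged(self):
        v = np.concatenate([np.arange(1, 101, dtype=float), [10000.0]])
        flags = iqr_outlier_flag(v)
        assert flags[-1]
        assert flags.sum() == 1

    def test_constant_values_only_equal_unflagged(self):
        v = np.array([5.0] * 10 + [5.1])
        flags = iqr_outlier_flag(v)
        assert not flags[:10].any()
        assert flags[10]

    def test_needs_four_values(self):
        with pytest.raises(ValueError):
            iqr_outlier_flag([1.0, 2.0, 3.0])


class TestHeritability:
    def test_plugin_formula(self):
        m = HeritabilityModel(mu=0, sigma2_g=1.0, sigma2_r=1.0, n=2,
                              n_genotypes=10, n_records=20, method="mom")
        assert m.H == pytest.approx(2 / 3)

    def test_h_bounds_and_monotone_in_n(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            sg, sr = rng.uniform(0, 5, 2)
            hs = [HeritabilityModel(0, sg, sr, n, 2, 4, "mom").H
                  for n in (1, 2, 4, 8)]
            assert all(0 <= h <= 1 for h in hs)
            assert all(b >= a - 1e-12 for a, b in zip(hs, hs[1:]))

    def test_parameter_recovery_h05(self):
        from phyllo3d.synthetic_plant import h2_for_target_H

        hits = 0
        for seed in range(100):
            pop = make_population(n_geno=200, reps=2, n_markers=10,
                                  h2_target=h2_for_target_H(0.5), seed=seed)
            est = heritability(pop.phenotypes, n=2).H
            hits += abs(est - 0.5) <= 0.10
        # sampling sd of H-hat is ~0.07 at this design, so ~85% of draws
        # land within +-0.10 of truth
        assert hits >= 80

    def test_pure_noise_phenotype_low_heritability(self):
        # at the zero boundary roughly half the estimates collapse to zero
        # and the positive half is small; the median sits well below 0.1
        ests = []
        for seed in range(100):
            pop = make_population(n_geno=200, reps=2, n_markers=10,
                                  h2_target=0.0, seed=seed)
            ests.append(heritability(pop.phenotypes, n=2).H)
        ests = np.array(ests)
        assert np.median(ests) < 0.1
        assert np.mean(ests < 0.1) >= 0.6

    def test_unreplicated_panel_unidentifiable(self):
        df = pd.DataFrame({"genotype_id": list("abcd"), "value": [1., 2., 3., 4.]})
        with pytest.raises(ValueError, match="unreplicated"):
            heritability(df)

    def test_needs_two_genotypes(self):
        df = pd.DataFrame({"genotype_id": ["a"] * 4, "value": [1., 2., 3., 4.]})
        with pytest.raises(ValueError):
            heritability(df)

    def test_replicate_cap_is_seeded_subsample(self):
        rng = np.random.default_rng(0)
        rows = [{"genotype_id": "check", "value": v}
                for v in rng.normal(10, 1, 8)]
        rows += [{"genotype_id": f"g{i}", "value": v}
                 for i in range(20) for v in rng.normal(0, 1, 2)]
        df = pd.DataFrame(rows)
        m1 = heritability(df, max_reps=2, seed=3)
        m2 = heritability(df, max_reps=2, seed=3)
        assert m1.n_records == 2 + 40
        assert m1.H == m2.H

    def test_reml_close_to_mom_on_unbalanced_data(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(60):
            g = rng.normal(0, 1)
            for _ in range(int(rng.integers(1, 4))):
                rows.append({"genotype_id": f"g{i}", "value": g + rng.normal(0, 1)})
        df = pd.DataFrame(rows)
        h_reml = heritability(df, method="reml").H
        h_mom = heritability(df, method="mom").H
        assert abs(h_reml - h_mom) < 0.15


def toy_matrix(dosages, **meta):
    d = np.asarray(dosages, dtype=float)
    m = d.shape[0]
    defaults = dict(
        chrom=np.array(["1"] * m), pos=np.arange(1, m + 1),
        ids=np.array([f"m{i}" for i in range(m)]),
        ref=np.array(["A"] * m), alt=np.array(["T"] * m),
        samples=[f"s{i}" for i in range(d.shape[1])])
    defaults.update(meta)
    return GenotypeMatrix(dosages=d, **defaults)


class TestMarkerQc:
    def test_multiallelic_excluded(self):
        gm = toy_matrix(np.tile([0, 1, 2, 0, 2, 0, 2, 0, 2, 0] + [0, 2] * 5, (2, 1)),
                        alt=np.array(["T", "T,G"]))
        qc = marker_qc(gm)
        assert qc.kept.tolist() == [True, False]
        assert qc.exclusion_counts["not_biallelic"] == 1

    def test_indel_excluded(self):
        gm = toy_matrix(np.tile([0, 1, 2, 0, 2, 0, 2, 0, 2, 0] + [0, 2] * 5, (2, 1)),
                        ref=np.array(["A", "AT"]))
        assert qc_kept(gm) == [True, False]

    def test_het_fraction_boundary(self):
        # 6 ref-hom, 3 het, 1 alt-hom: het fraction 0.30 >= 0.10 -> excluded
        gm = toy_matrix([[0, 0, 0, 0, 0, 0, 1, 1, 1, 2]])
        assert qc_kept(gm) == [False]

    def test_maf_boundary_kept(self):
        # one alt-hom among ten: MAF = 0.10 >= 0.05 -> kept
        gm = toy_matrix([[0, 0, 0, 0, 0, 0, 0, 0, 0, 2]])
        assert qc_kept(gm) == [True]

    def test_maf_below_threshold_excluded(self):
        gm = toy_matrix([[0] * 24 + [1]])  # MAF = 0.02
        assert qc_kept(gm) == [False]

    def test_missingness_over_all_individuals(self):
        row = [0, 2, 0, 2, 0, 2, np.nan, np.nan, np.nan, np.nan]
        gm = toy_matrix([row])          # 40 % missing
        assert qc_kept(gm) == [False]

    def test_filters_are_order_independent(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, size=(50, 30)).astype(float)
        d[rng.random((50, 30)) < 0.2] = np.nan
        gm = toy_matrix(d)
        kept = marker_qc(gm).kept
        perm = rng.permutation(50)
        kept_perm = marker_qc(gm.subset(marker_mask=perm)).kept
        assert np.array_equal(kept[perm], kept_perm)


def qc_kept(gm):
    return marker_qc(gm).kept.tolist()


class TestThresholds:
    def test_bonferroni_from_effective_markers(self):
        # printed constants of the study population
        thr = bonferroni_threshold(0.05, 1_088_251.19)
        assert thr == pytest.approx(4.59e-8, rel=5e-3)

    def test_bonferroni_trivial_cases(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.05, 2) == 0.025
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    def test_iteration_threshold_from_marker_ratio(self):
        thr = iteration_threshold(0.05, 1_088_251.19, 4_693_810)
        assert thr == pytest.approx(0.21, abs=0.01)

    def test_iteration_threshold_trivial_cases(self):
        assert iteration_threshold(0.05, 10, 10) == pytest.approx(0.05)
        assert iteration_threshold(0.05, 1, 2) == pytest.approx(0.10)


class TestScan:
    def test_perfect_signal(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(5, 50)).astype(float)
        y = 2.0 * d[3]
        p = scan(d, y)
        assert p[3] < 1e-30
        assert np.argmin(p) == 3

    def test_constant_phenotype_warns(self):
        d = np.array([[0.0, 1.0, 2.0, 1.0]])
        with pytest.warns(UserWarning, match="constant"):
            p = scan(d, np.ones(4))
        assert p[0] == 1.0

    def test_missing_dosages_dropped_per_marker(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(3, 60)).astype(float)
        y = d[0] + rng.normal(0, 0.5, 60)
        d_missing = d.copy()
        d_missing[0, :30] = np.nan
        p_full = scan(d, y)
        p_miss = scan(d_missing, y)
        assert p_miss[0] > p_full[0]  # fewer samples, weaker evidence
        assert p_miss[1] == pytest.approx(p_full[1])

    def test_matches_scipy_linregress(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(10, 80)).astype(float)
        y = rng.normal(size=80)
        p = scan(d, y)
        for m in range(10):
            assert p[m] == pytest.approx(stats.linregress(d[m], y).pvalue,
                                         rel=1e-9)

    def test_covariates_absorb_confounder(self):
        rng = np.random.default_rng(3)
        n = 200
        confounder = rng.normal(size=n)
        d = (confounder > 0).astype(float)[None, :] * 2
        y = confounder + rng.normal(0, 0.3, n)
        p_marginal = scan(d, y)
        p_adjusted = scan(d, y, covariates=confounder[:, None])
        assert p_marginal[0] < 1e-6
        assert p_adjusted[0] > 1e-3


class TestRmip:
    def _pop(self, seed=0):
        return make_population(n_geno=60, reps=1, n_markers=30,
                               h2_target=0.0, seed=seed)

    def test_always_significant_engine(self):
        pop = self._pop()
        y = np.arange(60, dtype=float)
        cfg = AssociationConfig(me=30, n_iter=20, seed=1)

        def engine(d, yy):
            return np.zeros(d.shape[0])

        t = rmip(pop.genotypes, y, cfg, engine=engine).table
        assert (t["rmip"] == 1.0).all()

    def test_never_significant_engine(self):
        pop = self._pop()
        y = np.arange(60, dtype=float)
        cfg = AssociationConfig(me=30, n_iter=20, seed=1)
        t = rmip(pop.genotypes, y, cfg,
                 engine=lambda d, yy: np.ones(d.shape[0])).table
        assert (t["rmip"] == 0.0).all()

    def test_rmip_values_are_multiples_of_iteration_count(self):
        pop = make_population(n_geno=100, reps=1, n_markers=50,
                              causal=[(10, 0.4)], h2_target=0.4, seed=2)
        y = (pop.phenotypes.groupby("genotype_id")["value"].mean()
             .reindex(pop.genotypes.samples).to_numpy())
        cfg = AssociationConfig(me=50, n_iter=25, seed=2)
        t = rmip(pop.genotypes, y, cfg).table
        assert np.allclose(np.mod(t["rmip"] * 25, 1.0), 0.0)
        assert t.loc[10, "rmip"] >= 0.9

    def test_marker_order_invariance(self):
        pop = make_population(n_geno=100, reps=1, n_markers=40,
                              causal=[(5, 0.3)], h2_target=0.3, seed=3)
        y = (pop.phenotypes.groupby("genotype_id")["value"].mean()
             .reindex(pop.genotypes.samples).to_numpy())
        cfg = AssociationConfig(me=40, n_iter=15, seed=3)
        t1 = rmip(pop.genotypes, y, cfg).table
        perm = np.random.default_rng(0).permutation(40)
        t2 = rmip(pop.genotypes.subset(marker_mask=perm), y, cfg).table
        assert np.array_equal(t1["rmip"].to_numpy()[perm], t2["rmip"].to_numpy())

    def test_masking_too_many_records_rejected(self):
        pop = self._pop()
        cfg = AssociationConfig(me=30, n_iter=5, mask_frac=0.9, seed=0)
        with pytest.raises(ValueError, match="fewer than 10"):
            rmip(pop.genotypes, np.arange(60, dtype=float), cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AssociationConfig(mask_frac=0.0)
        with pytest.raises(ValueError):
            AssociationConfig(me=10, m=5)


class TestLd:
    def test_identical_markers_r2_one(self):
        gm = toy_matrix(np.tile([0, 1, 2, 0, 1, 2, 0, 1], (2, 1)))
        assert ld_r2(gm, 0, 1) == pytest.approx(1.0)

    def test_complement_coding_invariance(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 3, 50).astype(float)
        b = rng.integers(0, 3, 50).astype(float)
        gm = toy_matrix(np.stack([a, b, 2 - b]))
        assert ld_r2(gm, 0, 1) == pytest.approx(ld_r2(gm, 0, 2))

    def test_independent_markers_low_r2(self):
        pop = make_population(n_geno=500, reps=1, n_markers=40,
                              h2_target=0.0, seed=6)
        vals = [ld_r2(pop.genotypes, i, i + 1) for i in range(0, 38, 2)]
        assert np.mean(vals) < 0.05

    def test_degenerate_cases_are_nan(self):
        gm = toy_matrix(np.array([[1, 1, 1, 1], [0, 1, 2, 0]], dtype=float))
        assert np.isnan(ld_r2(gm, 0, 1))
        sparse = toy_matrix(np.array([[0, np.nan, np.nan, np.nan],
                                      [1, 0, 2, 1]]))
        assert np.isnan(ld_r2(sparse, 0, 1))


class TestVcfIO:
    def test_roundtrip_through_vcf(self, tmp_path):
        pop = make_population(n_geno=12, reps=1, n_markers=8,
                              h2_target=0.0, seed=7)
        gm = pop.genotypes
        gm.dosages[2, 3] = np.nan
        path = tmp_path / "geno.vcf"
        write_vcf(gm, path)
        back = read_vcf(path)
        assert back.samples == gm.samples
        assert np.array_equal(np.isnan(back.dosages), np.isnan(gm.dosages))
        m = ~np.isnan(gm.dosages)
        assert np.array_equal(back.dosages[m], gm.dosages[m])
        assert np.array_equal(back.pos, gm.pos)

    def test_reads_multiallelic_and_indel_flags(self, tmp_path):
        text = "\n".join([
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "##contig=<ID=1>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\ts2",
            "1\t100\tsnp\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1",
            "1\t200\tmulti\tA\tT,G\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1",
            "1\t300\tindel\tAT\tA\t.\tPASS\t.\tGT\t0/0\t./.\t1/1",
        ]) + "\n"
        path = tmp_path / "mixed.vcf"
        path.write_text(text)
        gm = read_vcf(path)
        assert gm.is_biallelic().tolist() == [True, False, True]
        assert gm.is_indel().tolist() == [False, False, True]
        assert np.isnan(gm.dosages[2, 1])
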