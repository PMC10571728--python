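import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikequant import quantify as q
from spikequant.quantify import FilterThresholds, QuantError

from conftest import make_transitions


class TestPairTransitions:
    def test_fully_paired(self):
        rec = make_transitions([
            {"fragment": "y4", "label": "light", "area": 100},
            {"fragment": "y5", "label": "light", "area": 200},
            {"fragment": "y4", "label": "heavy", "area": 50},
            {"fragment": "y5", "label": "heavy", "area": 100},
        ])
        paired, dropped = q.pair_transitions(rec)
        assert len(paired) == 2 and len(dropped) == 0

    def test_non_paired_dropped(self):
        rec = make_transitions([
            {"fragment": "y4", "label": "light", "area": 100},
            {"fragment": "y4", "label": "heavy", "area": 100},
            {"fragment": "y6", "label": "heavy", "area": 50},
        ])
        paired, dropped = q.pair_transitions(rec)
        assert set(paired.fragment) == {"y4"}
        assert list(dropped.fragment) == ["y6"]
        assert list(dropped.drop_reason) == ["unpaired"]

    def test_zero_pairs(self):
        rec = make_transitions([{"fragment": "y4", "label": "light", "area": 100}])
        paired, dropped = q.pair_transitions(rec)
        assert len(paired) == 0 and len(dropped) == 1

    def test_zero_area_not_paired(self):
        rec = make_transitions([
            {"fragment": "y4", "label": "light", "area": 100},
            {"fragment": "y4", "label": "heavy", "area": 0.0},
        ])
        paired, dropped = q.pair_transitions(rec)
        assert len(paired) == 0
        assert set(dropped.drop_reason) == {"unpaired", "zero_area"}

    def test_conservation_counts(self, small_sim):
        paired, dropped = q.pair_transitions(small_sim.report)
        assert 2 * len(paired) + len(dropped) == len(small_sim.report)


class TestComputeRatio:
    def test_arithmetic(self):
        L, H, r = q.compute_ratio([100, 200], [50, 100])
        assert (L, H, r) == (300.0, 150.0, 2.0)

    def test_identity(self):
        assert q.compute_ratio([100], [100])[2] == 1.0

    def test_zero_heavy_error(self):
        with pytest.raises(QuantError):
            q.compute_ratio([100], [0])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.tuples(
        st.floats(0.01, 1e6), st.floats(0.01, 1e6)), min_size=1, max_size=12))
    def test_fuzz_against_sum_oracle(self, pairs):
        light = [p[0] for p in pairs]
        heavy = [p[1] for p in pairs]
        # independent oracle: plain Python summation
        oL, oH = sum(light), sum(heavy)
        L, H, r = q.compute_ratio(light, heavy)
        assert L == pytest.approx(oL) and H == pytest.approx(oH)
        assert r == pytest.approx(oL / oH)


class TestComputeRdotp:
    def test_collinear(self):
        assert q.compute_rdotp([100, 200], [50, 100]) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert q.compute_rdotp([1, 0], [0, 1]) == 0.0

    def test_three_four(self):
        assert q.compute_rdotp([3, 4], [4, 3]) == pytest.approx(24 / 25)

    def test_zero_vector(self):
        assert q.compute_rdotp([0, 0], [1, 2]) == 0.0


def _quant_row(rdotp=0.9, dotp=0.9, ratio=1.0, n_pairs=3):
    return pd.DataFrame([{
        "sample_id": "S1", "protein": "P", "peptide": "PEPK",
        "n_pairs": n_pairs, "light_sum": 1.0, "heavy_sum": 1.0,
        "rdotp": rdotp, "ratio": ratio, "dotp": dotp,
    }])


class TestFilterPeptides:
    def test_just_inside_thresholds(self):
        out = q.filter_peptides(_quant_row(rdotp=0.71, dotp=0.51, ratio=1.0))
        assert out.status.iloc[0] == "quantified"

    def test_boundary_rdotp_strict(self):
        out = q.filter_peptides(_quant_row(rdotp=0.7))
        assert out.status.iloc[0] == "rejected"
        assert out.reasons.iloc[0] == "low_rdotp"

    def test_boundary_ratio_strict(self):
        out = q.filter_peptides(_quant_row(ratio=1000.0))
        assert out.reasons.iloc[0] == "ratio_out_of_bounds"

    def test_no_pairs_reason(self):
        out = q.filter_peptides(_quant_row(n_pairs=0, ratio=np.nan))
        assert "no_pairs" in out.reasons.iloc[0]

    def test_multiple_reasons(self):
        out = q.filter_peptides(_quant_row(rdotp=0.1, dotp=0.1, ratio=2000.0))
        assert out.reasons.iloc[0] == "low_rdotp;low_dotp;ratio_out_of_bounds"

    def test_fuzz_against_predicate_oracle(self):
        rng = np.random.default_rng(42)
        n = 10_000
        df = pd.DataFrame({
            "sample_id": "S1", "protein": "P",
            "peptide": [f"PEP{i}" for i in range(n)],
            "n_pairs": rng.integers(0, 5, n),
            "light_sum": 1.0, "heavy_sum": 1.0,
            "rdotp": rng.choice([0.7, 0.69, 0.71, 0.5, 0.95], n),
            "ratio": rng.choice([0.01, 0.009, 0.011, 1.0, 999.0, 1000.0, 1001.0], n),
            "dotp": rng.choice([0.5, 0.49, 0.51, 0.9, np.nan], n),
        })
        df.loc[df.n_pairs == 0, "ratio"] = np.nan
        out = q.filter_peptides(df)
        for row in out.itertuples():
            ok = (row.n_pairs > 0 and not np.isnan(row.ratio)
                  and row.rdotp > 0.7
                  and not np.isnan(row.dotp) and row.dotp > 0.5
                  and 0.01 < row.ratio < 1000.0)
            assert (row.status == "quantified") == ok


class TestIrtRegression:
    def test_exact_line(self):
        rec = make_transitions([
            {"peptide": f"A{i}K", "fragment": "y1", "irt_ref": x,
             "rt_min": 0.5 * x + 10.0}
            for i, x in enumerate([0.0, 20.0, 40.0, 60.0])
        ])
        fits = q.fit_irt_regression(rec)
        row = fits.iloc[0]
        assert row.slope == pytest.approx(0.5)
        assert row.intercept == pytest.approx(10.0)
        assert row.r2 == pytest.approx(1.0)
        assert row.n_anchors == 4

    def test_scrambled_rt_low_r2(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 100, 12)
        y = 0.5 * x + 10
        rec = make_transitions([
            {"peptide": f"A{i}K", "fragment": "y1", "irt_ref": xi, "rt_min": yi}
            for i, (xi, yi) in enumerate(zip(x, rng.permutation(y)))
        ])
        fits = q.fit_irt_regression(rec)
        assert fits.r2.iloc[0] < 0.5

    def test_single_anchor_undefined(self):
        rec = make_transitions([
            {"peptide": "A1K", "fragment": "y1", "irt_ref": 10.0, "rt_min": 15.0}])
        fits = q.fit_irt_regression(rec)
        assert np.isnan(fits.r2.iloc[0])
        assert fits.n_anchors.iloc[0] == 1


class TestQcSamples:
    def _quants(self, n_proteins, sample="S1"):
        return pd.DataFrame({
            "sample_id": sample,
            "protein": [f"P{i}" for i in range(n_proteins)],
            "peptide": [f"PEP{i}" for i in range(n_proteins)],
            "status": "quantified",
        })

    def _manifest(self, sample="S1"):
        return pd.DataFrame({
            "sample_id": [sample], "plate": ["P01"], "well": ["A01"],
            "sample_type": ["patient"], "cancer": ["MM"], "sex": ["male"]})

    def test_119_proteins_excluded(self):
        out = q.qc_samples(self._quants(119), self._manifest(),
                           pd.DataFrame(), min_proteins=120)
        assert not out.passed.iloc[0]
        assert "too_few_proteins" in out.reasons.iloc[0]

    def test_120_proteins_retained(self):
        out = q.qc_samples(self._quants(120), self._manifest(),
                           pd.DataFrame(), min_proteins=120)
        assert out.passed.iloc[0]

    def test_poor_irt_fit_fails(self):
        fits = pd.DataFrame([{"sample_id": "S1", "slope": 1.0,
                              "intercept": 0.0, "r2": 0.5, "n_anchors": 12}])
        out = q.qc_samples(self._quants(150), self._manifest(), fits)
        assert not out.passed.iloc[0]
        assert "irt_poor_fit" in out.reasons.iloc[0]

    def test_too_few_anchors_fails(self):
        fits = pd.DataFrame([{"sample_id": "S1", "slope": 1.0,
                              "intercept": 0.0, "r2": 1.0, "n_anchors": 3}])
        out = q.qc_samples(self._quants(150), self._manifest(), fits)
        assert "irt_too_few_anchors" in out.reasons.iloc[0]


class TestQuantRateFilter:
    def _matrix(self, n_present, n_total=100):
        col = [1.0] * n_present + [np.nan] * (n_total - n_present)
        return pd.DataFrame({"PEP1": col},
                            index=[f"S{i}" for i in range(n_total)])

    def test_exactly_half_kept(self):
        assert "PEP1" in q.filter_by_quant_rate(self._matrix(50)).columns

    def test_just_below_half_dropped(self):
        assert "PEP1" not in q.filter_by_quant_rate(self._matrix(49)).columns

    def test_all_missing_dropped(self):
        assert q.filter_by_quant_rate(self._matrix(0)).shape[1] == 0

    def test_fuzz_against_rate_oracle(self):
        rng = np.random.default_rng(7)
        mat = pd.DataFrame(
            np.where(rng.random((40, 50)) < rng.random(50), 1.0, np.nan),
            index=[f"S{i}" for i in range(40)],
            columns=[f"PEP{j}" for j in range(50)])
        kept = set(q.filter_by_quant_rate(mat, 0.5).columns)
        for col in mat.columns:
            rate = sum(not np.isnan(v) for v in mat[col]) / len(mat)
            assert (col in kept) == (rate >= 0.5)


class TestToAbsolute:
    def _quants(self, ratio):
        return pd.DataFrame([{
            "sample_id": "S1", "protein": "P", "peptide": "PEPK",
            "n_pairs": 2, "light_sum": 1.0, "heavy_sum": 1.0,
            "rdotp": 0.99, "ratio": ratio, "dotp": 0.9,
            "status": "quantified", "reasons": ""}])

    def _panel(self, spike=0.5):
        return pd.DataFrame([{"protein": "P", "peptide": "PEPK",
                              "standard_id": "STD1",
                              "spike_conc_pmol_per_ul": spike}])

    def test_arithmetic(self):
        mat, _ = q.to_absolute(self._quants(2.0), self._panel(0.5))
        assert mat.loc["S1", "PEPK"] == pytest.approx(1.0)

    def test_equimolar_identity(self):
        mat, _ = q.to_absolute(self._quants(1.0), self._panel(0.5))
        assert mat.loc["S1", "PEPK"] == pytest.approx(0.5)

    def test_unknown_peptide_error(self):
        panel = self._panel().assign(peptide=["OTHERK"])
        with pytest.raises(QuantError, match="absent from the spike panel"):
            q.to_absolute(self._quants(1.0), panel)


def _two_plate_matrix():
    samples = ["POOL-A-1", "POOL-A-2", "SA1", "POOL-B-1", "POOL-B-2", "SB1"]
    manifest = pd.DataFrame({
        "sample_id": samples,
        "plate": ["PA"] * 3 + ["PB"] * 3,
        "well": ["A01"] * 6,
        "sample_type": ["pool", "pool", "patient"] * 2,
        "cancer": ["", "", "MM"] * 2,
        "sex": ["", "", "male"] * 2,
    })
    matrix = pd.DataFrame(
        {"PEP1": [1.0, 1.2, 1.1, 2.0, 2.4, 2.2]}, index=samples)
    return matrix, manifest


class TestMedianNormalize:
    def test_single_plate_identity(self):
        matrix, manifest = _two_plate_matrix()
        one = matrix.iloc[:3]
        out, factors = q.median_normalize(one, manifest, return_factors=True)
        pd.testing.assert_frame_equal(out, one)
        assert np.allclose(factors.to_numpy(), 1.0)

    def test_two_plate_exactness(self):
        matrix, manifest = _two_plate_matrix()
        out = q.median_normalize(matrix, manifest)
        pools_a = out.loc[["POOL-A-1", "POOL-A-2"], "PEP1"].median()
        pools_b = out.loc[["POOL-B-1", "POOL-B-2"], "PEP1"].median()
        assert pools_a == pytest.approx(pools_b)
        global_med = matrix.loc[
            ["POOL-A-1", "POOL-A-2", "POOL-B-1", "POOL-B-2"], "PEP1"].median()
        assert pools_a == pytest.approx(global_med)

    def test_idempotence(self):
        matrix, manifest = _two_plate_matrix()
        once = q.median_normalize(matrix, manifest)
        twice = q.median_normalize(once, manifest)
        pd.testing.assert_frame_equal(once, twice)

    def test_no_pools_error(self):
        matrix, manifest = _two_plate_matrix()
        patients_only = matrix.loc[["SA1", "SB1"]]
        with pytest.raises(QuantError, match="pool"):
            q.median_normalize(patients_only, manifest)

    def test_plate_effect_variance_reduction(self):
        # planted plate effect -> normalization shrinks between-plate pool
        # variance for nearly all peptides
        from spikequant import synthetic
        from spikequant.config import CohortConfig
        cfg = CohortConfig(cancer_counts={"CRC": 30}, n_plates=4,
                           n_proteins=20, sigma_plate=0.4, seed=21,
                           qc_fail_fraction=0.0)
        sim = synthetic.simulate(cfg)
        res = q.run_quantification(
            sim.report, sim.panel, sim.manifest,
            q.QuantParams(min_proteins=10, normalize=False))
        raw = res.peptide_matrix
        normed = q.median_normalize(raw, sim.manifest)
        pool_ids = sim.manifest.loc[sim.manifest.sample_type == "pool",
                                    "sample_id"]
        plates = sim.manifest.set_index("sample_id").loc[pool_ids, "plate"]
        improved = 0
        total = 0
        for pep in raw.columns:
            before = np.log(raw.loc[pool_ids, pep]).groupby(plates).mean().var()
            after = np.log(normed.loc[pool_ids, pep]).groupby(plates).mean().var()
            if np.isfinite(before) and np.isfinite(after):
                total += 1
                improved += after < before
        assert improved / total >= 0.95


class TestRollup:
    def test_single_peptide_identity(self):
        mat = pd.DataFrame({"PEP1": [2.0]}, index=["S1"])
        out = q.rollup_protein(mat, pd.Series({"PEP1": "P"}))
        assert out.loc["S1", "P"] == 2.0

    def test_median_of_three(self):
        mat = pd.DataFrame({"A": [1.0], "B": [2.0], "C": [9.0]}, index=["S1"])
        out = q.rollup_protein(mat, pd.Series({"A": "P", "B": "P", "C": "P"}))
        assert out.loc["S1", "P"] == 2.0

    def test_even_count_mean_of_middle(self):
        mat = pd.DataFrame({"A": [1.0], "B": [3.0]}, index=["S1"])
        out = q.rollup_protein(mat, pd.Series({"A": "P", "B": "P"}))
        assert out.loc["S1", "P"] == 2.0


class TestPipelineProperties:
    def test_ordering_insensitivity(self, small_sim):
        params = q.QuantParams(min_proteins=8)
        res1 = q.run_quantification(
            small_sim.report, small_sim.panel, small_sim.manifest, params)
        shuffled = small_sim.report.sample(
            frac=1.0, random_state=5).reset_index(drop=True)
        res2 = q.run_quantification(
            shuffled, small_sim.panel, small_sim.manifest, params)
        pd.testing.assert_frame_equal(
            res1.peptide_matrix.sort_index(axis=1),
            res2.peptide_matrix.sort_index(axis=1))

    def test_provenance_additive(self, small_result):
        p = small_result.provenance
        assert p["n_quantified"] + p["n_rejected"] == p["n_peptide_observations"]
        assert p["n_samples_passed"] + p["n_samples_failed"] == p["n_samples_in"]
        assert (p["n_transitions_paired"] + p["n_transitions_dropped"]
                == p["n_transitions_in"])

    def test_values_positive_where_present(self, small_result):
        vals = small_result.peptide_matrix.to_numpy()
        assert np.all(vals[np.isfinite(vals)] > 0)

    def test_parameter_recovery(self):
        # sigma_intra = 0.1: per-peptide group median within 5% of truth
        # for >= 95% of peptides
        from spikequant import synthetic
        from spikequant.config import CohortConfig
        cfg = CohortConfig(cancer_counts={"CRC": 150, "MM": 150}, n_plates=4,
                           n_proteins=20, sigma_intra=0.1, sigma_plate=0.0,
                           qc_fail_fraction=0.0, corrupted_fraction=0.0,
                           seed=31)
        sim = synthetic.simulate(cfg)
        # normalization off: at 3 pools/plate its factors add ~5% plate-level
        # sampling noise of their own, which is not what this bound measures
        res = q.run_quantification(sim.report, sim.panel, sim.manifest,
                                   q.QuantParams(min_proteins=10, normalize=False))
        truth = sim.truth.peptide_truth()
        mani = sim.manifest.set_index("sample_id")
        est = res.peptide_matrix
        patients = [s for s in est.index if mani.loc[s, "sample_type"] == "patient"]
        cancers = mani.loc[patients, "cancer"]
        ok = 0
        total = 0
        for pep in est.columns:
            for grp in ("CRC", "MM"):
                ids = [s for s in patients if cancers[s] == grp]
                est_med = est.loc[ids, pep].median()
                true_med = truth.loc[ids, pep].median()
                total += 1
                ok += abs(est_med / true_med - 1) < 0.05
        assert ok / total >= 0.95
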