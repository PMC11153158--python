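"""SILAC turnover fits, filtering/imputation, quantile norm, contexts."""

import math

import numpy as np
import pandas as pd
import pytest

from dosagecomp.datatypes import Karyotype, RelativeMatrix, ValidationError, \
    validate_annotation
from dosagecomp.simulate import simulate_silac
from dosagecomp.turnover import (
    attenuation_turnover_correlation,
    context_turnover,
    deletion_collection_contrast,
    expression_turnover_correlation,
    filter_impute_turnover,
    fit_turnover,
    quantile_normalize,
    turnover_matrix,
)


def silac_frame(rows):
    return pd.DataFrame(rows, columns=["strain_id", "protein_id", "time_min",
                                       "hl_ratio"])


class TestFitTurnover:
    def test_literal_exact_line(self):
        # ln(H/L) = (0.9, 1.35, 1.8) at t = (90, 135, 180) -> kdp = 0.01/min
        rows = [("A", "P", t, math.exp(0.01 * t)) for t in (90, 135, 180)]
        rec = fit_turnover(silac_frame(rows), "literal").iloc[0]
        assert rec["kdp"] == pytest.approx(0.01, abs=1e-12)
        assert rec["half_life"] == pytest.approx(math.log(2) / 0.01, rel=1e-12)
        assert rec["fit_r2"] == pytest.approx(1.0)

    def test_kinetic_inverts_generator(self):
        silac = simulate_silac({("A", "P"): 0.005}, model="kinetic", noise_cv=0.0)
        rec = fit_turnover(silac, "kinetic").iloc[0]
        assert rec["kdp"] == pytest.approx(0.005, abs=1e-12)

    def test_half_life_identity(self):
        rng = np.random.default_rng(2)
        rates = {("A", f"P{i}"): k for i, k in
                 enumerate(rng.uniform(0.001, 0.02, 20))}
        silac = simulate_silac(rates, noise_cv=0.05, seed=5)
        rec = fit_turnover(silac, "literal")
        valid = rec[rec["valid"]]
        assert np.allclose(valid["half_life"] * valid["kdp"], math.log(2))

    def test_single_point_series_skipped(self):
        rec = fit_turnover(silac_frame([("A", "P", 90, 2.0)]))
        assert len(rec) == 0

    def test_negative_slope_flagged_invalid(self):
        rows = [("A", "P", 90, 3.0), ("A", "P", 180, 1.5)]
        rec = fit_turnover(silac_frame(rows)).iloc[0]
        assert not rec["valid"]
        assert np.isnan(rec["half_life"])

    def test_literal_on_kinetic_data_overestimates(self):
        """ln(H/L) on first-order data has slope k e^{kt}/(e^{kt}-1) > k,
        so the literal fit overestimates k — most strongly at early times."""
        silac = simulate_silac({("A", "P"): 0.005}, model="kinetic", noise_cv=0.0)
        rec = fit_turnover(silac, "literal").iloc[0]
        assert rec["kdp"] > 0.005
        early = simulate_silac({("A", "P"): 0.005}, times=(30.0, 60.0, 90.0),
                               model="kinetic", noise_cv=0.0)
        rec_early = fit_turnover(early, "literal").iloc[0]
        assert rec_early["kdp"] > rec["kdp"]


class TestFilterImpute:
    def matrix(self, n_proteins, n_strains, missing=()):
        rng = np.random.default_rng(0)
        data = rng.uniform(0.002, 0.02, (n_proteins, n_strains))
        df = pd.DataFrame(data, index=[f"P{i}" for i in range(n_proteins)],
                          columns=[f"S{j}" for j in range(n_strains)])
        for i, j in missing:
            df.iat[i, j] = np.nan
        return df

    def test_80_percent_boundary(self):
        # 55 strains: 44 present (exactly 80%) retained, 43 dropped
        df = self.matrix(2, 55, missing=[(0, j) for j in range(11)]
                         + [(1, j) for j in range(12)])
        out = filter_impute_turnover(df)
        assert list(out.index) == ["P0"]
        assert not out.isna().any().any()

    def test_complete_matrix_unchanged(self):
        df = self.matrix(4, 10)
        pd.testing.assert_frame_equal(filter_impute_turnover(df), df)

    def test_no_survivor_rejected(self):
        df = self.matrix(1, 10, missing=[(0, j) for j in range(5)])
        with pytest.raises(ValidationError):
            filter_impute_turnover(df)


class TestQuantileNormalize:
    def test_textbook_case(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(df)
        expected = [2.5, 3.5, 4.5]
        assert out["a"].tolist() == pytest.approx(expected)
        assert out["b"].tolist() == pytest.approx(expected)

    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(df), df)

    def test_idempotent_and_rank_preserving(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.uniform(0.001, 0.03, (20, 5)))
        once = quantile_normalize(df)
        pd.testing.assert_frame_equal(quantile_normalize(once), once)
        for col in df.columns:
            assert (df[col].rank() == once[col].rank()).all()

    def test_column_multisets_identical(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(30, 4)))
        out = quantile_normalize(df)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for j in range(1, 4):
            assert np.allclose(np.sort(out.iloc[:, j].to_numpy()), ref)


class TestContexts:
    def setup_contexts(self):
        karyos = (
            [Karyotype(f"A{i}", 2, {"chr1": 3, "chr2": 2}) for i in range(3)]
            + [Karyotype(f"B{i}", 2, {"chr1": 2, "chr2": 3}) for i in range(3)]
            + [Karyotype(f"E{i}", 2, {"chr1": 2, "chr2": 2}) for i in range(3)]
        )
        ann = validate_annotation(pd.DataFrame(
            {"chromosome": ["chr1"], "position_index": [0]},
            index=pd.Index(["P"], name="gene_id")))
        # P on chr1: aneuploid in A*, euploid-of-aneuploid in B*, euploid in E*
        values = {f"A{i}": 0.9 + 0.1 * i for i in range(3)}
        values.update({f"B{i}": 0.55 + 0.05 * i for i in range(3)})
        values.update({f"E{i}": 0.5 + 0.1 * i for i in range(3)})
        qnorm = pd.DataFrame(values, index=ann.index)
        return qnorm, karyos, ann

    def test_aneuploid_context_higher(self):
        qnorm, karyos, ann = self.setup_contexts()
        table, summary = context_turnover(qnorm, karyos, ann)
        assert summary["n_proteins"] == 1
        assert summary["aneuploid_higher_than_euploid_of_euploid"] == 1
        assert table.at["P", "median_aneuploid"] == pytest.approx(1.0)
        assert table.at["P", "median_euploid_of_euploid"] == pytest.approx(0.6)

    def test_insufficient_occurrences_excluded(self):
        qnorm, karyos, ann = self.setup_contexts()
        qnorm = qnorm.drop(columns=["A2"])  # only 2 aneuploid-context rates
        table, summary = context_turnover(qnorm, karyos[:2] + karyos[3:], ann)
        assert summary["n_proteins"] == 0


class TestCorrelations:
    def test_attenuation_turnover_line(self):
        idx = [f"s{i}" for i in range(6)]
        turn = pd.Series([1.0, 1.2, 1.4, 1.6, 1.8, 2.0], index=idx)
        att = pd.Series(10 + 20 * turn.to_numpy(), index=idx)
        out = attenuation_turnover_correlation(turn, att)
        assert out["r"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(20.0)
        # sign flip negates r
        flipped = attenuation_turnover_correlation(turn, -att)
        assert flipped["r"] == pytest.approx(-1.0)

    def test_permuted_pairing_decorrelates(self):
        rng = np.random.default_rng(6)
        idx = [f"s{i}" for i in range(200)]
        turn = pd.Series(rng.normal(1, 0.2, 200), index=idx)
        att = pd.Series(30 + 50 * (turn.to_numpy() - 1), index=idx)
        out = attenuation_turnover_correlation(turn, att)
        assert out["r"] > 0.99
        permuted = pd.Series(rng.permutation(att.to_numpy()), index=idx)
        out_p = attenuation_turnover_correlation(turn, permuted)
        assert abs(out_p["r"]) < 0.2

    def test_expression_turnover_contexts(self):
        karyos = (
            [Karyotype(f"A{i}", 2, {"chr1": 3}) for i in range(4)]
            + [Karyotype(f"E{i}", 2, {"chr1": 2}) for i in range(4)]
        )
        ann = validate_annotation(pd.DataFrame(
            {"chromosome": ["chr1"], "position_index": [0],
             "complex_member": [True]},
            index=pd.Index(["P"], name="gene_id")))
        strains = [k.strain_id for k in karyos]
        turnover = pd.Series(np.linspace(1.0, 2.0, 8), index=strains)
        # aneuploid-context expression decreases with turnover (attenuation)
        expr = [1.0 - 0.5 * turnover[s] for s in strains[:4]]
        expr += [0.1, -0.1, 0.05, -0.05]
        rel = RelativeMatrix("protein", pd.DataFrame(
            [expr], index=ann.index, columns=strains))
        out = expression_turnover_correlation(rel, turnover, karyos, ann)
        by_ctx = out.set_index("context")["r"]
        assert by_ctx["aneuploid_chromosome"] == pytest.approx(-1.0)
        assert "euploid_chromosome_of_euploid_strain" in by_ctx.index
        assert out["complex_member"].all()

    def test_two_qualifying_strains_no_r(self):
        karyos = [Karyotype(f"A{i}", 2, {"chr1": 3}) for i in range(2)]
        ann = validate_annotation(pd.DataFrame(
            {"chromosome": ["chr1"], "position_index": [0]},
            index=pd.Index(["P"], name="gene_id")))
        rel = RelativeMatrix("protein", pd.DataFrame(
            [[0.5, 0.6]], index=ann.index, columns=["A0", "A1"]))
        turnover = pd.Series([1.0, 1.5], index=["A0", "A1"])
        out = expression_turnover_correlation(rel, turnover, karyos, ann)
        assert len(out) == 0


class TestDeletionContrast:
    def build(self):
        rng = np.random.default_rng(7)
        n_prot = 40
        proteins = [f"P{i}" for i in range(n_prot)]
        ann = validate_annotation(pd.DataFrame(
            {"chromosome": ["chr1"] * 20 + ["chr2"] * 20,
             "position_index": list(range(20)) * 2},
            index=pd.Index(proteins, name="gene_id")))
        half_lives = pd.Series(rng.uniform(5.0, 300.0, n_prot), index=proteins)
        base = pd.DataFrame(
            2.0 ** rng.normal(10, 0.05, (n_prot, 12)), index=proteins,
            columns=[f"S{j}" for j in range(12)])
        # strains S0, S1 duplicate chr1; short-half-life proteins get
        # smaller fold changes (better buffered) than long-half-life ones
        on_chr1 = ann["chromosome"] == "chr1"
        for s in ("S0", "S1"):
            factor = np.where(half_lives[proteins] < half_lives.median(),
                              1.8, 2.1)
            base.loc[on_chr1.to_numpy(), s] *= factor[on_chr1.to_numpy()]
        return base, ann, half_lives

    def test_duplication_calls_and_halflife_contrast(self):
        base, ann, half_lives = self.build()
        out = deletion_collection_contrast(base, ann, half_lives)
        calls = out["calls"]
        assert set(zip(calls["strain_id"], calls["chromosome"])) == {
            ("S0", "chr1"), ("S1", "chr1")}
        assert out["mean_short"] < out["mean_long"]
        assert out["p_value"] < 0.05

    def test_threshold_boundary(self):
        base, ann, half_lives = self.build()
        # 0.9 median log2 fc -> duplicated at 0.8; not at 0.95
        out_hi = deletion_collection_contrast(
            base, ann, half_lives, duplication_log2_threshold=1.2)
        assert len(out_hi["calls"]) == 0
        assert np.isnan(out_hi["t_stat"])
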