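"""Strain-level attenuation: pseudomedian Wilcoxon tests, reversion, load."""

import math

import numpy as np
import pandas as pd
import pytest

from dosagecomp.datatypes import Karyotype, RelativeMatrix, ValidationError, \
    validate_annotation
from dosagecomp.integrate import build_integrated_cohort, relative_cn_table
from dosagecomp.simulate import CohortSpec, simulate_cohort
from dosagecomp.strains import (
    aneuploid_protein_load,
    detect_reverted,
    fit_dosage_response,
    strain_wilcoxon,
    summarize_distributions,
)

D15 = math.log2(1.5)


def one_strain_setup(ratios, cn=3, ploidy=2, n_chrom=2):
    """Strain trisomic for chr1; `ratios` live on chr1 genes."""
    chroms = {f"chr{i + 1}": ploidy for i in range(n_chrom)}
    chroms["chr1"] = cn
    kary = Karyotype("tri", ploidy, chroms)
    genes = [f"g{i}" for i in range(len(ratios))]
    ann = validate_annotation(pd.DataFrame(
        {"chromosome": ["chr1"] * len(ratios),
         "position_index": range(len(ratios))},
        index=pd.Index(genes, name="gene_id"),
    ))
    rel = RelativeMatrix("protein", pd.DataFrame(
        {"tri": ratios}, index=ann.index))
    return rel, kary, ann


class TestStrainWilcoxon:
    def test_ratios_equal_to_cn_class_give_zero_attenuation(self):
        rel, kary, ann = one_strain_setup([D15] * 8)
        out = strain_wilcoxon(rel, [kary], ann)
        row = out.iloc[0]
        assert row["pseudomedian"] == pytest.approx(D15, abs=1e-12)
        assert row["attenuation_pct"] == pytest.approx(0.0, abs=1e-6)

    def test_walsh_average_worked_example(self):
        # {0.1, 0.2, 0.3}: Walsh averages {.1,.15,.2,.2,.25,.3} -> pm 0.2;
        # exact two-sided p vs 0.585 is 0.25 (all three differences negative)
        rel, kary, ann = one_strain_setup([0.1, 0.2, 0.3])
        out = strain_wilcoxon(rel, [kary], ann, min_genes=3)
        row = out.iloc[0]
        assert row["pseudomedian"] == pytest.approx(0.2, abs=1e-12)
        assert row["attenuation_pct"] == pytest.approx(
            100 * (1 - 0.2 / D15), abs=1e-6
        )
        assert row["p_raw"] == pytest.approx(0.25)
        assert row["test_method"] == "exact"

    def test_symmetric_ratios_full_compensation(self):
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 0.05, 20)
        ratios = np.concatenate([noise, -noise])  # exactly symmetric about 0
        rel, kary, ann = one_strain_setup(list(ratios))
        out = strain_wilcoxon(rel, [kary], ann)
        row = out.iloc[0]
        assert abs(row["pseudomedian"]) < 1e-9
        assert row["attenuation_pct"] == pytest.approx(100.0, abs=1e-6)

    def test_small_class_skipped(self):
        rel, kary, ann = one_strain_setup([0.1, 0.2, 0.3])
        out = strain_wilcoxon(rel, [kary], ann, min_genes=5)
        assert len(out) == 0

    def test_multi_class_strain_has_no_attenuation_pct(self):
        kary = Karyotype("cx", 2, {"chr1": 3, "chr2": 1, "chr3": 2})
        genes = [f"g{i}" for i in range(12)]
        ann = validate_annotation(pd.DataFrame(
            {"chromosome": ["chr1"] * 6 + ["chr2"] * 6,
             "position_index": list(range(6)) * 2},
            index=pd.Index(genes, name="gene_id"),
        ))
        rel = RelativeMatrix("protein", pd.DataFrame(
            {"cx": [0.5] * 6 + [-0.5] * 6}, index=ann.index))
        out = strain_wilcoxon(rel, [kary], ann)
        assert len(out) == 2
        assert out["attenuation_pct"].isna().all()

    def test_bh_within_layer(self):
        specs = [one_strain_setup([0.1 * i + 0.05 * j for j in range(6)])
                 for i in range(3)]
        # merge three strains into one matrix
        ann = specs[0][2]
        values = pd.concat(
            [s[0].values.rename(columns={"tri": f"tri{i}"})
             for i, s in enumerate(specs)], axis=1,
        )
        karyos = [Karyotype(f"tri{i}", 2, dict(specs[i][1].chrom_cn))
                  for i in range(3)]
        out = strain_wilcoxon(RelativeMatrix("protein", values), karyos, ann)
        assert (out["p_adj"] >= out["p_raw"] - 1e-12).all()


class TestDetectReverted:
    def frame(self, pm):
        return pd.DataFrame(
            {"strain_id": ["tri"], "pseudomedian": [pm], "cn_class": [D15]}
        )

    @pytest.mark.parametrize("pm,expected", [
        (0.05, True),    # inside the open band
        (0.3, False),
        (0.1, False),    # exact endpoint counts as not reverted
        (-0.1, False),
    ])
    def test_band_membership(self, pm, expected):
        kary = Karyotype("tri", 2, {"chr1": 3, "chr2": 2})
        reverted = detect_reverted(self.frame(pm), [kary])
        assert (reverted == ["tri"]) is expected
        assert kary.reverted is expected

    def test_planted_reverted_trisome_in_cohort(self):
        """A trisome whose *protein* expression matches euploid is caught.

        The transcriptome still follows the annotated karyotype, so the
        CN-mRNA mismatch filter stays quiet and the protein-pseudomedian
        reversion rule is exercised in isolation; no clean strain is flagged.
        """
        spec = CohortSpec(
            n_strains=40, n_chromosomes=6, genes_per_chromosome=40,
            ploidy_weights={2: 1.0}, aneuploidy_rate=0.3, gain_fraction=1.0,
            complex_aneuploidy_rate=0.0, seed=21,
            protein_slope_mixture=((1.0, 0.7, 0.1),),
            trans_proteasome_shift=0.0,
        )
        c = simulate_cohort(spec)
        victim = next(k for k in c.karyotypes if not k.is_euploid)
        # rewrite the victim's protein column with slope-0 (euploid-like) values
        eu = [k.strain_id for k in c.karyotypes if k.is_euploid]
        base = c.protein.values[eu].median(axis=1)
        rng = np.random.default_rng(1)
        c.protein.values[victim.strain_id] = base * 2 ** rng.normal(
            0, 0.05, len(base)
        )
        cohort = build_integrated_cohort(
            {"mRNA": c.mrna, "protein": c.protein}, c.karyotypes, c.annotation
        )
        assert victim.strain_id in cohort.cn.index
        tests = strain_wilcoxon(cohort.layers["protein"], cohort.karyotypes,
                                c.annotation)
        reverted = detect_reverted(tests, cohort.karyotypes)
        assert reverted == [victim.strain_id]


class TestDistributionsAndDosageResponse:
    def test_gain_and_loss_cutoffs(self):
        # a gain class with 250 pooled genes is flagged (250 < 300); a loss
        # class with 190 is retained (190 >= 50)
        kary_g = Karyotype("g", 2, {"chr1": 3, "chr2": 2})
        kary_l = Karyotype("l", 2, {"chr1": 1, "chr2": 2})
        genes = [f"g{i}" for i in range(250)]
        ann = validate_annotation(pd.DataFrame(
            {"chromosome": ["chr1"] * 250, "position_index": range(250)},
            index=pd.Index(genes, name="gene_id")))
        values = pd.DataFrame({"g": [0.5] * 250, "l": [-0.5] * 190 + [np.nan] * 60},
                              index=ann.index)
        rel = RelativeMatrix("protein", values)
        cn = relative_cn_table([kary_g, kary_l])
        out = summarize_distributions(rel, cn, ann)
        gain = out[np.isclose(out["cn_class"], math.log2(1.5))].iloc[0]
        assert gain["n_points"] == 250 and bool(gain["excluded_from_visualization"])
        loss = out[np.isclose(out["cn_class"], -1.0)].iloc[0]
        assert loss["n_points"] == 190 and not bool(loss["excluded_from_visualization"])

    def test_dosage_response_exact_line(self):
        summary = pd.DataFrame({
            "cn_class": [0.32, 0.585, 1.0],
            "median": [0.75 * 0.32, 0.75 * 0.585, 0.75],
        })
        fit = fit_dosage_response(summary)
        assert fit["slope"] == pytest.approx(0.75, abs=1e-12)
        assert fit["r_squared"] == pytest.approx(1.0)
        assert fit["average_attenuation_pct"] == pytest.approx(25.0)

    def test_identity_slope_means_no_compensation(self):
        summary = pd.DataFrame({"cn_class": [0.5, 1.0], "median": [0.5, 1.0]})
        assert fit_dosage_response(summary)["slope"] == pytest.approx(1.0)

    def test_single_class_rejected(self):
        summary = pd.DataFrame({"cn_class": [0.585], "median": [0.4]})
        with pytest.raises(ValidationError):
            fit_dosage_response(summary)

    def test_noise_free_pooled_medians_follow_uniform_slope(self):
        spec = CohortSpec(
            n_strains=30, n_chromosomes=4, genes_per_chromosome=30,
            ploidy_weights={2: 1.0}, aneuploidy_rate=0.4, gain_fraction=1.0,
            complex_aneuploidy_rate=0.0, mrna_slope_sd=0.0,
            protein_slope_mixture=((1.0, 0.6, 0.0),), mrna_noise_sd=0.0,
            protein_noise_sd=0.0, missing_rate=0.0,
            trans_proteasome_shift=0.0, seed=2,
        )
        c = simulate_cohort(spec)
        cohort = build_integrated_cohort(
            {"mRNA": c.mrna, "protein": c.protein}, c.karyotypes, c.annotation)
        out = summarize_distributions(cohort.layers["protein"], cohort.cn,
                                      c.annotation)
        gains = out[out["cn_class"] > 0]
        assert len(gains) >= 1
        for _, row in gains.iterrows():
            assert row["median"] == pytest.approx(0.6 * row["cn_class"], abs=1e-9)


class TestProteinLoad:
    def annotation(self, copies):
        genes = [f"g{i}" for i in range(len(copies))]
        return validate_annotation(pd.DataFrame(
            {"chromosome": ["chr1"] * len(copies),
             "position_index": range(len(copies)),
             "copies_per_cell": copies},
            index=pd.Index(genes, name="gene_id")))

    def test_trisomy_surplus(self):
        kary = Karyotype("t", 2, {"chr1": 3})
        load, _ = aneuploid_protein_load(kary, self.annotation([1000.0, 2000.0]))
        assert load == pytest.approx(1500.0)

    def test_euploid_zero(self):
        kary = Karyotype("e", 2, {"chr1": 2})
        load, _ = aneuploid_protein_load(kary, self.annotation([1000.0]))
        assert load == 0.0

    def test_monosomy_deficit(self):
        kary = Karyotype("m", 2, {"chr1": 1})
        load, _ = aneuploid_protein_load(kary, self.annotation([1000.0]))
        assert load == pytest.approx(500.0)

    def test_dosage_variant(self):
        kary = Karyotype("t", 2, {"chr1": 3})
        load, _ = aneuploid_protein_load(kary, self.annotation([1000.0]),
                                         method="dosage")
        assert load == pytest.approx(1500.0)  # 1000 * 3/2
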