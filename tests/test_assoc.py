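import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stabilityqtl as sq
from stabilityqtl.assoc import add_bh_q, genotype_pcs, hwe_pvalue
from stabilityqtl.errors import ValidationError
from stabilityqtl.simdata import GeneAnnotation, GenotypeMatrix


def make_genotypes(dosage, positions=None, ref="A", alt="G"):
    dosage = np.asarray(dosage, dtype=float)
    n_samples, n_variants = dosage.shape
    positions = positions or list(range(1000, 1000 + 10 * n_variants, 10))
    sample_ids = [f"s{i}" for i in range(n_samples)]
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": positions,
            "id": [f"v{j}" for j in range(n_variants)],
            "ref": ref,
            "alt": alt,
            "maf": 0.0,
            "pass_qc": True,
        }
    )
    sex = pd.Series(["male", "female"] * (n_samples // 2 + 1), name="sex")[:n_samples]
    sex.index = sample_ids
    age = pd.Series(50.0, index=sample_ids, name="age")
    return GenotypeMatrix(sample_ids, variants, dosage, sex, age)


class TestVariantQc:
    def test_hwe_exact_fit_p_one(self):
        # genotype counts (81, 18, 1): expected counts match exactly
        assert hwe_pvalue(81, 18, 1) == pytest.approx(1.0)

    def test_hwe_extreme_violation(self):
        assert hwe_pvalue(50, 0, 50) < 1e-6

    def test_monomorphic_removed(self):
        dosage = np.zeros((100, 1))
        filtered = sq.variant_qc(make_genotypes(dosage))
        assert filtered.n_variants == 0

    def test_retains_hwe_consistent_variant(self):
        dosage = np.array([0] * 81 + [1] * 18 + [2] * 1, dtype=float)[:, None]
        filtered = sq.variant_qc(make_genotypes(dosage))
        assert filtered.n_variants == 1
        assert filtered.variants["maf"].iloc[0] == pytest.approx(0.10)

    def test_removes_hwe_violating_variant(self):
        dosage = np.array([0] * 50 + [2] * 50, dtype=float)[:, None]
        filtered = sq.variant_qc(make_genotypes(dosage))
        assert filtered.n_variants == 0

    def test_missing_dosage_mean_imputed_and_flagged(self):
        dosage = np.array([0, 0, 1, 1, 2, 2, np.nan, np.nan], dtype=float)[:, None]
        filtered = sq.variant_qc(make_genotypes(dosage))
        assert filtered.variants["imputed"].iloc[0]
        imputed = filtered.dosage[6:, 0]
        np.testing.assert_allclose(imputed, 1.0)


class TestCisPairs:
    def gene(self, strand="+", tss=200_000, tts=210_000):
        if strand == "+":
            segs = [(tss, tss + 99, "5'UTR"), (tss + 100, tts - 100, "CDS"),
                    (tts - 99, tts, "3'UTR")]
            return GeneAnnotation("g", "1", "+", tss, tts, segs)
        segs = [(tss - 99, tss, "5'UTR"), (tts + 100, tss - 100, "CDS"),
                (tts, tts + 99, "3'UTR")]
        return GeneAnnotation("g", "1", "-", tss, tts, segs)

    def pairs_for(self, gene, positions):
        dosage = np.tile([0.0, 1.0, 2.0], (len(positions), 1)).T
        geno = make_genotypes(dosage, positions=list(positions))
        return sq.cis_pairs([gene], geno)

    def test_boundary_inclusive_upstream(self):
        gene = self.gene("+")
        pairs = self.pairs_for(gene, [100_000])  # exactly TSS - 100000
        assert len(pairs) == 1
        assert pairs["dist_tss"].iloc[0] == -100_000

    def test_one_bp_outside_excluded(self):
        gene = self.gene("+")
        pairs = self.pairs_for(gene, [99_999])
        assert len(pairs) == 0

    def test_minus_strand_upstream_at_higher_coordinates(self):
        # minus-strand gene with TSS at 500,000: genomic 599,999 is upstream
        gene = self.gene("-", tss=500_000, tts=490_000)
        pairs = self.pairs_for(gene, [599_999])
        assert len(pairs) == 1
        assert pairs["dist_tss"].iloc[0] == -99_999  # upstream in orientation

    def test_downstream_boundary_minus_strand(self):
        gene = self.gene("-", tss=500_000, tts=490_000)
        assert len(self.pairs_for(gene, [390_000])) == 1
        assert len(self.pairs_for(gene, [389_999])) == 0


class TestAssociateLinear:
    def test_closed_form_example(self):
        dosage = np.array([0, 0, 1, 1, 2, 2], dtype=float)[:, None]
        geno = make_genotypes(dosage)
        trait = pd.DataFrame(
            [[0.1, -0.1, 1.1, 0.9, 2.1, 1.9]], index=["g"], columns=geno.sample_ids
        )
        pairs = pd.DataFrame({"variant_id": ["v0"], "gene_id": ["g"]})
        out = sq.associate_linear(trait, geno, None, pairs)
        row = out.iloc[0]
        assert row["beta"] == pytest.approx(1.0, abs=1e-12)
        # SSE 0.06, df 4, Sxx 4 => se = sqrt(0.06/4/4), t = 1/se
        assert row["se"] == pytest.approx(np.sqrt(0.06 / 4 / 4), abs=1e-12)
        assert row["t"] == pytest.approx(16.3299, abs=1e-4)

    def test_matches_statsmodels_with_covariates(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 80
        dosage = rng.integers(0, 3, (n, 3)).astype(float)
        geno = make_genotypes(dosage)
        cov = pd.DataFrame(
            {"age": rng.uniform(20, 70, n), "pc1": rng.normal(size=n)},
            index=geno.sample_ids,
        )
        trait = pd.DataFrame(
            rng.normal(size=(2, n)), index=["gA", "gB"], columns=geno.sample_ids
        )
        pairs = pd.DataFrame(
            [(v, g) for v in ["v0", "v1", "v2"] for g in ["gA", "gB"]],
            columns=["variant_id", "gene_id"],
        )
        out = sq.associate_linear(trait, geno, cov, pairs)
        for _, row in out.iterrows():
            j = int(row["variant_id"][1:])
            x = sm.add_constant(
                np.column_stack([dosage[:, j], cov["age"], cov["pc1"]])
            )
            fit = sm.OLS(trait.loc[row["gene_id"]].to_numpy(), x).fit()
            assert row["beta"] == pytest.approx(fit.params[1], rel=1e-9)
            assert row["se"] == pytest.approx(fit.bse[1], rel=1e-9)
            assert row["p"] == pytest.approx(fit.pvalues[1], rel=1e-9)

    def test_constant_trait_reports_p_one(self):
        dosage = np.array([0, 1, 2, 0, 1, 2], dtype=float)[:, None]
        geno = make_genotypes(dosage)
        trait = pd.DataFrame(
            [[3.0] * 6], index=["g"], columns=geno.sample_ids
        )
        pairs = pd.DataFrame({"variant_id": ["v0"], "gene_id": ["g"]})
        out = sq.associate_linear(trait, geno, None, pairs)
        assert out["beta"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0

    def test_duplicated_covariate_rejected(self):
        dosage = np.array([0, 1, 2, 0, 1, 2], dtype=float)[:, None]
        geno = make_genotypes(dosage)
        cov = pd.DataFrame(
            {"age": [1.0, 2, 3, 4, 5, 6], "age_copy": [1.0, 2, 3, 4, 5, 6]},
            index=geno.sample_ids,
        )
        trait = pd.DataFrame(
            [[0.1, 0.2, 0.3, 0.4, 0.5, 0.6]], index=["g"], columns=geno.sample_ids
        )
        pairs = pd.DataFrame({"variant_id": ["v0"], "gene_id": ["g"]})
        with pytest.raises(ValidationError, match="age_copy"):
            sq.associate_linear(trait, geno, cov, pairs)


class TestBhFdr:
    def test_all_equal(self):
        np.testing.assert_allclose(sq.bh_fdr([0.3, 0.3, 0.3]), 0.3)

    def test_step_up_hand_example(self):
        q = sq.bh_fdr([0.01, 0.02, 0.04, 0.8])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.8], rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            sq.bh_fdr([0.1, 1.5])
        with pytest.raises(ValidationError):
            sq.bh_fdr([-0.1])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1,
                 max_size=60)
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_p_and_matches_statsmodels(self, p):
        from statsmodels.stats.multitest import multipletests

        q = sq.bh_fdr(p)
        assert (q >= np.asarray(p) - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_ref, rtol=1e-12, atol=1e-15)


class TestSexSpecific:
    def _simulate_sex_specific(self, seed):
        config = sq.SimConfig(
            n_samples=300, n_variants=400, n_genes=40, seed=seed,
            dispersion=0.0, p_male=0.6,
            prop_transcription_qtl=0.0, prop_stability_qtl=0.2,
            prop_sex_specific=1.0,
            effect_size_grid=(-0.6,),
        )
        return sq.simulate_dataset(config)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_recovers_male_specific_decay_effect(self, seed):
        data = self._simulate_sex_specific(seed)
        male_rows = data.truth[data.truth["sex_restricted"] == "male"]
        if male_rows.empty:
            pytest.skip("no male-restricted effects drawn for this seed")
        geno = sq.variant_qc(data.genotypes)
        pairs = sq.cis_pairs(data.annotation, geno)
        stab = sq.infer_stability(data.counts)
        lengths = pd.Series(
            {g.gene_id: g.exonic_length for g in data.annotation}
        )
        expression = sq.transform_expression(
            sq.compute_tpm(data.counts.exon, lengths)
        )
        result = sq.sex_specific_stqtls(
            stab.values, geno, data.covariates[["age"]],
            data.covariates["sex"], expression, pairs,
        )
        calls = result.calls
        truth_keys = set(zip(male_rows["variant_id"], male_rows["gene_id"]))
        for method in ("stratified", "interaction"):
            sub = calls[(calls["method"] == method) & (calls["class"] == "male_specific")]
            found = set(zip(sub["variant_id"], sub["gene_id"])) & truth_keys
            # power property: most planted male-only effects are recovered
            assert len(found) >= 0.5 * len(truth_keys), method

    def test_definition_boundaries(self):
        # male q < 0.05 with female p > 0.1 is male-specific; female p <= 0.1 is not
        from stabilityqtl.assoc import sex_specific_stqtls  # noqa: F401 (API surface)

        # exercised via the classification rule on a crafted dataset
        data = self._simulate_sex_specific(1)
        geno = sq.variant_qc(data.genotypes)
        pairs = sq.cis_pairs(data.annotation, geno)
        stab = sq.infer_stability(data.counts)
        lengths = pd.Series({g.gene_id: g.exonic_length for g in data.annotation})
        expression = sq.transform_expression(sq.compute_tpm(data.counts.exon, lengths))
        result = sq.sex_specific_stqtls(
            stab.values, geno, data.covariates[["age"]],
            data.covariates["sex"], expression, pairs,
        )
        strat = result.calls[result.calls["method"] == "stratified"]
        for _, row in strat.iterrows():
            if row["class"] == "male_specific":
                assert row["male_q"] < 0.05 and row["female_p"] > 0.1
            elif row["class"] == "female_specific":
                assert row["female_q"] < 0.05 and row["male_p"] > 0.1


def test_genotype_pcs_shape_and_ambiguous_removed(small_dataset):
    geno = sq.variant_qc(small_dataset.genotypes)
    pcs = genotype_pcs(geno, n_components=3, thin_step=2)
    assert pcs.shape == (geno.n_samples, 3)
    # A/T variants are strand-ambiguous and must not influence the PCs
    var_at = geno.variants.copy()
    var_at["alt"] = "T"  # ref is A => every variant ambiguous
    ambiguous = sq.simdata.GenotypeMatrix(
        geno.sample_ids, var_at, geno.dosage, geno.sex, geno.age
    )
    with pytest.raises(Exception):
        genotype_pcs(ambiguous)
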