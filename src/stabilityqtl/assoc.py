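"""Cis-QTL association: variant QC, pairing, linear dosage models, FDR.

The association statistic for each variant-gene pair is the two-sided t test
on the dosage coefficient of an ordinary least squares fit of the trait on
(intercept, dosage, covariates).  Fits are computed by residualizing both
trait and dosage on the covariate block (Frisch-Waugh-Lovell), which is
exact OLS and lets whole trait matrices be processed with vectorized numpy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from stabilityqtl.errors import ValidationError
from stabilityqtl.simdata import FLANK_BP, GeneAnnotation, GenotypeMatrix

logger = logging.getLogger(__name__)

ASSOC_COLUMNS = ["variant_id", "gene_id", "trait", "n_used", "beta", "se", "t", "p", "q"]


def hwe_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-degree chi-square goodness-of-fit test for Hardy-Weinberg proportions."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    p_alt = (n_het + 2 * n_hom_alt) / (2 * n)
    expected = np.array(
        [n * (1 - p_alt) ** 2, 2 * n * p_alt * (1 - p_alt), n * p_alt**2]
    )
    observed = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if (expected == 0).any():
        # monomorphic: no deviation from HWE is expressible
        return 1.0
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def variant_qc(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-6,
) -> GenotypeMatrix:
    """Drop variants with MAF below ``maf_min`` or HWE p below ``hwe_alpha``.

    Missing genotypes are mean-imputed to dosage (and flagged in the variant
    table) before downstream association; MAF and HWE use the observed hard
    calls only.
    """
    dosage = genotypes.dosage.copy()
    n_variants = dosage.shape[1]
    keep = np.zeros(n_variants, dtype=bool)
    maf_out = np.zeros(n_variants)
    hwe_out = np.ones(n_variants)
    imputed = np.zeros(n_variants, dtype=bool)

    for j in range(n_variants):
        col = dosage[:, j]
        observed = col[~np.isnan(col)]
        if observed.size == 0:
            continue
        hard = np.round(observed).astype(int)
        counts = np.bincount(hard, minlength=3)
        af = (counts[1] + 2 * counts[2]) / (2 * counts.sum())
        maf = min(af, 1 - af)
        hwe_p = hwe_pvalue(counts[0], counts[1], counts[2])
        maf_out[j] = maf
        hwe_out[j] = hwe_p
        keep[j] = (maf >= maf_min) and (hwe_p >= hwe_alpha)
        if np.isnan(col).any():
            imputed[j] = True
            col[np.isnan(col)] = observed.mean()
            dosage[:, j] = col

    variants = genotypes.variants.copy()
    variants["maf"] = maf_out
    variants["hwe_p"] = hwe_out
    variants["imputed"] = imputed
    variants["pass_qc"] = keep
    filtered = GenotypeMatrix(
        sample_ids=list(genotypes.sample_ids),
        variants=variants.loc[keep].reset_index(drop=True),
        dosage=dosage[:, keep],
        sex=genotypes.sex,
        age=genotypes.age,
    )
    if filtered.n_variants == 0:
        logger.warning("variant QC removed every variant (MAF >= %s, HWE p >= %s)",
                       maf_min, hwe_alpha)
    return filtered


def cis_pairs(
    annotation: Sequence[GeneAnnotation],
    genotypes: GenotypeMatrix,
    window: int = FLANK_BP,
) -> pd.DataFrame:
    """All variant-gene pairs within the cis window (boundary-inclusive).

    The window runs from ``window`` bp upstream of the TSS to ``window`` bp
    downstream of the TTS in transcription orientation; signed distances are
    positive downstream of the anchor along the direction of transcription.
    """
    var = genotypes.variants
    rows = []
    for gene in annotation:
        on_chrom = var["chrom"] == gene.chrom
        lo, hi = gene.body_start - window, gene.body_end + window
        inside = on_chrom & (var["pos"] >= lo) & (var["pos"] <= hi)
        sign = 1 if gene.strand == "+" else -1
        for _, v in var.loc[inside].iterrows():
            rows.append(
                {
                    "variant_id": v["id"],
                    "gene_id": gene.gene_id,
                    "dist_tss": sign * (int(v["pos"]) - gene.tss),
                    "dist_tts": sign * (int(v["pos"]) - gene.tts),
                }
            )
    return pd.DataFrame(rows, columns=["variant_id", "gene_id", "dist_tss", "dist_tts"])


def _covariate_design(
    covariates: Optional[pd.DataFrame], sample_ids: Sequence[str]
) -> np.ndarray:
    """Intercept plus numeric covariates; raises on rank deficiency."""
    n = len(sample_ids)
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((n, 1))
    cov = covariates.loc[list(sample_ids)]
    numeric = pd.get_dummies(cov, drop_first=True).astype(float)
    design = np.column_stack([np.ones(n), numeric.to_numpy()])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        offenders = []
        base = np.ones((n, 1))
        for name, col in zip(numeric.columns, numeric.to_numpy().T):
            trial = np.column_stack([base, col])
            if np.linalg.matrix_rank(trial) == base.shape[1]:
                offenders.append(str(name))
            else:
                base = trial
        raise ValidationError(
            "covariate design is rank deficient; collinear columns: "
            + ", ".join(offenders)
        )
    return design


def _residualize(design: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Project out the column span of ``design`` (via thin QR)."""
    q, _ = np.linalg.qr(design)
    return values - q @ (q.T @ values)


def associate_linear(
    trait: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: Optional[pd.DataFrame],
    pairs: pd.DataFrame,
    trait_name: str = "trait",
) -> pd.DataFrame:
    """OLS association of each pair's dosage with the gene's trait values.

    Returns one row per pair with the dosage coefficient, its standard
    error, t statistic and two-sided p (n - k residual df).  Zero-variance
    traits or dosages are reported with beta 0 and p 1 rather than dropped,
    so the pair universe stays aligned across traits.  ``q`` is left NaN;
    apply :func:`bh_fdr` over the desired adjustment batch.
    """
    sample_ids = [s for s in genotypes.sample_ids if s in trait.columns]
    if len(sample_ids) < 3:
        raise ValidationError("need >= 3 samples shared between trait and genotypes")
    trait = trait[sample_ids]

    missing = set(pairs["gene_id"]) - set(trait.index)
    pairs = pairs[pairs["gene_id"].isin(trait.index)].reset_index(drop=True)
    if missing:
        logger.info("skipping %d pairs for genes absent from trait matrix", len(missing))

    design = _covariate_design(covariates, sample_ids)
    n, k0 = design.shape
    df_resid = n - (k0 + 1)
    if df_resid <= 0:
        raise ValidationError(
            f"zero residual degrees of freedom (n={n}, covariates={k0 - 1})"
        )

    sample_pos = {s: i for i, s in enumerate(genotypes.sample_ids)}
    take = np.array([sample_pos[s] for s in sample_ids])
    dosage = genotypes.dosage[take]

    trait_resid = pd.DataFrame(
        _residualize(design, trait.to_numpy().T).T,
        index=trait.index,
        columns=sample_ids,
    )
    variant_col = {v: j for j, v in enumerate(genotypes.variants["id"])}
    unknown = set(pairs["variant_id"]) - variant_col.keys()
    if unknown:
        raise ValidationError(
            f"pairs reference variants absent from genotypes: {sorted(unknown)[:5]}"
        )
    dosage_resid = _residualize(design, dosage)

    records = []
    for row in pairs.itertuples(index=False):
        g = dosage_resid[:, variant_col[row.variant_id]]
        y = trait_resid.loc[row.gene_id].to_numpy()
        sxx = float(g @ g)
        syy = float(y @ y)
        if sxx <= 1e-12 or syy <= 1e-12:
            records.append((row.variant_id, row.gene_id, trait_name, n, 0.0,
                            np.nan, 0.0, 1.0))
            continue
        beta = float(g @ y) / sxx
        rss = max(syy - beta * beta * sxx, 0.0)
        sigma2 = rss / df_resid
        se = float(np.sqrt(sigma2 / sxx))
        if se == 0.0:
            t_stat, p = np.inf, 0.0
        else:
            t_stat = beta / se
            p = float(2.0 * stats.t.sf(abs(t_stat), df_resid))
        records.append((row.variant_id, row.gene_id, trait_name, n, beta, se, t_stat, p))

    out = pd.DataFrame(
        records,
        columns=["variant_id", "gene_id", "trait", "n_used", "beta", "se", "t", "p"],
    )
    out["q"] = np.nan
    return out


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``q_(i) = min_{j >= i} p_(j) * n / j`` over the sorted p-values, clipped
    to 1.  Declaring ``q < alpha`` is the standard FDR-alpha discovery rule.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def add_bh_q(table: pd.DataFrame) -> pd.DataFrame:
    """Attach BH q-values adjusted over all rows of one association table."""
    out = table.copy()
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


@dataclass
class SexSpecificResult:
    calls: pd.DataFrame  # SexSpecificCall rows
    male_table: pd.DataFrame
    female_table: pd.DataFrame
    interaction_table: pd.DataFrame
    genes_tested: list[str]  # genes surviving the sex-DE filter


def _sex_de_filter(
    expression: pd.DataFrame, sex: pd.Series, alpha: float = 0.05
) -> list[str]:
    """Genes NOT differentially expressed between sexes (Welch t, BH q > alpha)."""
    male_cols = [s for s in expression.columns if sex.loc[s] == "male"]
    female_cols = [s for s in expression.columns if sex.loc[s] == "female"]
    male = expression[male_cols].to_numpy()
    female = expression[female_cols].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(male, female, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    q = bh_fdr(p)
    return expression.index[q > alpha].tolist()


def _interaction_scan(
    trait: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: Optional[pd.DataFrame],
    sex: pd.Series,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Per pair, t test on the dosage-by-sex coefficient in the full model."""
    sample_ids = [s for s in genotypes.sample_ids if s in trait.columns]
    male = (sex.loc[sample_ids] == "male").to_numpy(dtype=float)
    base = _covariate_design(covariates, sample_ids)
    design0 = np.column_stack([base, male])

    sample_pos = {s: i for i, s in enumerate(genotypes.sample_ids)}
    take = np.array([sample_pos[s] for s in sample_ids])
    dosage = genotypes.dosage[take]
    variant_col = {v: j for j, v in enumerate(genotypes.variants["id"])}

    n = len(sample_ids)
    df_resid = n - (design0.shape[1] + 2)
    if df_resid <= 0:
        raise ValidationError("not enough samples for the interaction model")

    records = []
    trait = trait[sample_ids]
    for row in pairs.itertuples(index=False):
        g = dosage[:, variant_col[row.variant_id]]
        x = np.column_stack([design0, g, g * male])
        y = trait.loc[row.gene_id].to_numpy()
        xtx = x.T @ x
        try:
            xtx_inv = np.linalg.inv(xtx)
        except np.linalg.LinAlgError:
            records.append((row.variant_id, row.gene_id, 0.0, 1.0))
            continue
        coef = xtx_inv @ (x.T @ y)
        resid = y - x @ coef
        sigma2 = float(resid @ resid) / df_resid
        se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
        if se == 0.0 or not np.isfinite(se):
            records.append((row.variant_id, row.gene_id, float(coef[-1]), 1.0))
            continue
        t_stat = float(coef[-1]) / se
        p = float(2.0 * stats.t.sf(abs(t_stat), df_resid))
        records.append((row.variant_id, row.gene_id, float(coef[-1]), p))
    out = pd.DataFrame(records, columns=["variant_id", "gene_id", "beta_gxs", "p"])
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else np.nan
    return out


def sex_specific_stqtls(
    stability: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: Optional[pd.DataFrame],
    sex: pd.Series,
    expression: pd.DataFrame,
    pairs: pd.DataFrame,
    fdr: float = 0.05,
    nonsig_p: float = 0.1,
    interaction_fdr: float = 0.25,
) -> SexSpecificResult:
    """Classify sex-specific stability QTLs by two complementary rules.

    Genes differentially expressed between sexes are removed first (Welch t
    test on expression, BH q <= 0.05 excluded).  The *stratified* rule runs
    the association separately per sex: a pair is male-specific when the
    male q < ``fdr`` while the female p > ``nonsig_p`` (and symmetrically).
    The *interaction* rule keeps pairs whose genotype-by-sex term passes BH
    q <= ``interaction_fdr``, then classifies them by the per-sex stratified
    q at ``fdr`` (significant in both sexes => sex_biased_both).
    """
    if covariates is not None and "sex" in covariates.columns:
        covariates = covariates.drop(columns=["sex"])

    genes_ok = _sex_de_filter(expression, sex)
    stability = stability.loc[stability.index.intersection(genes_ok)]
    pairs = pairs[pairs["gene_id"].isin(stability.index)].reset_index(drop=True)

    per_sex_tables = {}
    for label in ("male", "female"):
        cols = [s for s in stability.columns if sex.loc[s] == label]
        if len(cols) < 3:
            raise ValidationError(f"too few {label} samples for stratified model")
        sub_cov = covariates.loc[cols] if covariates is not None else None
        table = associate_linear(
            stability[cols], genotypes, sub_cov, pairs, trait_name="stability"
        )
        per_sex_tables[label] = add_bh_q(table)

    male_t = per_sex_tables["male"].set_index(["variant_id", "gene_id"])
    female_t = per_sex_tables["female"].set_index(["variant_id", "gene_id"])

    interaction = _interaction_scan(stability, genotypes, covariates, sex, pairs)
    inter_idx = interaction.set_index(["variant_id", "gene_id"])

    calls = []
    for key in male_t.index:
        m, f = male_t.loc[key], female_t.loc[key]
        record = {
            "variant_id": key[0],
            "gene_id": key[1],
            "male_p": m["p"],
            "male_q": m["q"],
            "female_p": f["p"],
            "female_q": f["q"],
            "interaction_p": inter_idx.loc[key, "p"],
            "interaction_q": inter_idx.loc[key, "q"],
        }
        # stratified rule
        if m["q"] < fdr and f["p"] > nonsig_p:
            calls.append({**record, "class": "male_specific", "method": "stratified"})
        elif f["q"] < fdr and m["p"] > nonsig_p:
            calls.append({**record, "class": "female_specific", "method": "stratified"})
        # interaction rule
        if record["interaction_q"] <= interaction_fdr:
            m_sig, f_sig = m["q"] < fdr, f["q"] < fdr
            if m_sig and f_sig:
                cls = "sex_biased_both"
            elif m_sig:
                cls = "male_specific"
            elif f_sig:
                cls = "female_specific"
            else:
                cls = None
            if cls is not None:
                calls.append({**record, "class": cls, "method": "interaction"})

    columns = [
        "variant_id", "gene_id", "class", "male_p", "male_q",
        "female_p", "female_q", "interaction_p", "interaction_q", "method",
    ]
    calls_df = pd.DataFrame(calls, columns=columns)
    return SexSpecificResult(
        calls=calls_df,
        male_table=per_sex_tables["male"],
        female_table=per_sex_tables["female"],
        interaction_table=interaction,
        genes_tested=genes_ok,
    )


def genotype_pcs(
    genotypes: GenotypeMatrix,
    n_components: int = 3,
    thin_step: int = 10,
) -> pd.DataFrame:
    """Principal components of the standardized dosage matrix.

    Strand-ambiguous variants (A/T, C/G) are removed; LD pruning is
    simplified to fixed-step thinning (every ``thin_step``-th variant).
    """
    var = genotypes.variants
    ambiguous = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
    keep = ~var.apply(lambda r: (r["ref"], r["alt"]) in ambiguous, axis=1)
    idx = np.flatnonzero(keep.to_numpy())[::thin_step]
    if idx.size == 0:
        raise ValidationError(
            "no variants left for PCA after removing strand-ambiguous sites"
        )
    x = genotypes.dosage[:, idx]
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    ok = sd > 0
    z = (x[:, ok] - mean[ok]) / sd[ok]
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    k = min(n_components, len(s))
    pcs = u[:, :k] * s[:k]
    return pd.DataFrame(
        pcs,
        index=genotypes.sample_ids,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
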