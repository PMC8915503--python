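"""Synthetic genotypes, gene models, and exon/intron read counts.

The generative model is a steady-state transcription/decay kinetic model:
per gene g and sample s a transcription rate alpha and a decay rate beta are
drawn on the log2 scale, with planted allelic effects on log2(alpha)
(transcription QTLs) or log2(beta) (decay / stability QTLs, where relative
stability is defined as -log2 beta).  Intronic reads are proportional to
pre-mRNA abundance (alpha); exonic reads to mature abundance (alpha / beta).
Counts are negative-binomial around those means (Poisson when dispersion=0).

Genotypes come from a founder-haplotype copying scheme: each gamete copies
one of ``n_haplotypes`` founders independently per genomic segment of
``ld_segment_bp``, which yields Hardy-Weinberg proportions (random union of
gametes) together with block-structured linkage disequilibrium.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from stabilityqtl.errors import ConfigError, ValidationError

FLANK_BP = 100_000
GENE_GAP_BP = 1_000

REGION_LABELS = ("upstream", "5'UTR", "CDS", "intron", "3'UTR", "downstream")


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset.

    All kinetic constants are artifact choices for exercising the pipeline;
    they are not estimates of any real-tissue quantity.
    """

    n_samples: int = 300
    n_variants: int = 2000
    n_genes: int = 200
    n_haplotypes: int = 16
    maf_min: float = 0.01
    genome_length: Optional[int] = None  # None => auto-sized to fit all genes
    ld_segment_bp: int = 40_000

    # gene-structure mean lengths (bp)
    utr5_mean: int = 300
    cds_exon_mean: int = 400
    intron_mean: int = 2_000
    utr3_mean: int = 400
    max_introns: int = 3

    # kinetic baselines (log2 scale)
    alpha_log2_mean: float = 0.0
    alpha_log2_sd: float = 1.0
    beta_log2_mean: float = 0.0
    beta_log2_sd: float = 0.5

    # per-gene-sample lognormal rate noise (log2 sd)
    alpha_noise_sd: float = 0.10
    beta_noise_sd: float = 0.10

    # planted QTLs
    effect_size_grid: Sequence[float] = (-1.0, -0.5, 0.5, 1.0)
    prop_transcription_qtl: float = 0.15
    prop_stability_qtl: float = 0.15
    prop_sex_specific: float = 0.0

    # counting model
    dispersion: float = 0.05  # NB dispersion; 0 => Poisson
    intron_capture: float = 0.10  # kappa
    library_size_mean: float = 2.0e6
    library_size_cv: float = 0.2

    # cohort
    p_male: float = 0.5
    founder_freq_range: tuple[float, float] = (0.1, 0.5)

    seed: int = 0

    def validate(self) -> None:
        fractions = {
            "maf_min": self.maf_min,
            "prop_transcription_qtl": self.prop_transcription_qtl,
            "prop_stability_qtl": self.prop_stability_qtl,
            "prop_sex_specific": self.prop_sex_specific,
            "intron_capture": self.intron_capture,
            "p_male": self.p_male,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value} must lie in [0, 1]")
        if self.n_haplotypes < 2:
            raise ConfigError(
                f"n_haplotypes={self.n_haplotypes}: at least 2 founder "
                "haplotypes are required for polymorphism"
            )
        for name in ("n_samples", "n_variants", "n_genes"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.genome_length is not None and self.genome_length < self.min_genome_length():
            raise ConfigError(
                f"genome_length={self.genome_length} too small to place "
                f"{self.n_genes} genes with {FLANK_BP} bp flanks "
                f"(need >= {self.min_genome_length()})"
            )

    def expected_gene_slot(self) -> int:
        """Conservative per-gene span: body upper bound plus flanks and gap."""
        body = (
            3 * self.utr5_mean
            + (self.max_introns + 1) * 3 * self.cds_exon_mean
            + self.max_introns * 3 * self.intron_mean
            + 3 * self.utr3_mean
        )
        return body + 2 * FLANK_BP + GENE_GAP_BP

    def min_genome_length(self) -> int:
        return self.n_genes * self.expected_gene_slot() + 2 * FLANK_BP

    def resolved_genome_length(self) -> int:
        if self.genome_length is not None:
            return self.genome_length
        return self.min_genome_length()

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GenotypeMatrix:
    """Dosage matrix with variant metadata and per-sample sex/age."""

    sample_ids: list[str]
    variants: pd.DataFrame  # columns: chrom, pos, id, ref, alt, maf, pass_qc
    dosage: np.ndarray  # (n_samples, n_variants), values in [0, 2]
    sex: pd.Series  # 'male' / 'female', indexed by sample id
    age: pd.Series

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        if self.dosage.shape != (len(self.sample_ids), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        pos = self.variants["pos"].to_numpy()
        for chrom in self.variants["chrom"].unique():
            p = pos[self.variants["chrom"].to_numpy() == chrom]
            if not np.all(np.diff(p) > 0):
                raise ValidationError(f"positions not strictly increasing on {chrom}")
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValidationError("dosage values must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosage, index=self.sample_ids, columns=self.variants["id"].tolist()
        )

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=self.variants.loc[mask].reset_index(drop=True),
            dosage=self.dosage[:, np.asarray(mask)],
            sex=self.sex,
            age=self.age,
        )


@dataclass
class GeneAnnotation:
    """A gene model with disjoint labeled segments.

    Segments are stored in transcription order as (start, end, label) with
    1-based inclusive genomic coordinates.  In transcription order the labels
    read 5'UTR, then alternating CDS / intron, then 3'UTR.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    tss: int
    tts: int
    segments: list[tuple[int, int, str]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        lo, hi = min(self.tss, self.tts), max(self.tss, self.tts)
        spans = sorted((s, e) for s, e, _ in self.segments)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValidationError(f"{self.gene_id}: overlapping segments")
        for s, e, _ in self.segments:
            if s < lo or e > hi:
                raise ValidationError(f"{self.gene_id}: segment outside gene body")

    @property
    def body_start(self) -> int:
        return min(self.tss, self.tts)

    @property
    def body_end(self) -> int:
        return max(self.tss, self.tts)

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e, lab in self.segments if lab != "intron")

    @property
    def intronic_length(self) -> int:
        return sum(e - s + 1 for s, e, lab in self.segments if lab == "intron")

    def cis_window(self, flank: int = FLANK_BP) -> tuple[int, int]:
        """Genomic interval [TSS - flank, TTS + flank] in transcription orientation."""
        return (self.body_start - flank, self.body_end + flank)


@dataclass
class CountMatrixPair:
    """Paired exonic/intronic count matrices (genes x samples)."""

    exon: pd.DataFrame
    intron: pd.DataFrame
    exon_library_size: Optional[pd.Series] = None
    intron_library_size: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if not self.exon.index.equals(self.intron.index):
            raise ValidationError("exon and intron matrices have different gene order")
        if not self.exon.columns.equals(self.intron.columns):
            raise ValidationError("exon and intron matrices have different sample order")
        if (self.exon.to_numpy() < 0).any() or (self.intron.to_numpy() < 0).any():
            raise ValidationError("counts must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return self.exon.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.exon.columns.tolist()


@dataclass
class SimulatedDataset:
    """Bundle of every simulated component plus generative diagnostics."""

    config: SimConfig
    genotypes: GenotypeMatrix
    annotation: list[GeneAnnotation]
    truth: pd.DataFrame
    counts: CountMatrixPair
    covariates: pd.DataFrame
    log2_alpha: pd.DataFrame  # genes x samples, realized (incl. noise)
    log2_beta: pd.DataFrame
    mu_exon: pd.DataFrame  # closed-form NB means
    mu_intron: pd.DataFrame


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per simulation stage
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _draw_positions(rng: np.random.Generator, n: int, genome_length: int) -> np.ndarray:
    """n distinct sorted positions in [1, genome_length]."""
    seen: set[int] = set()
    while len(seen) < n:
        draw = rng.integers(1, genome_length + 1, size=n - len(seen))
        seen.update(int(v) for v in draw)
    return np.array(sorted(seen)[:n], dtype=np.int64)


def simulate_genotypes(
    config: SimConfig, founders: Optional[np.ndarray] = None
) -> GenotypeMatrix:
    """Draw LD-structured biallelic genotypes from a founder pool.

    Each gamete copies one founder haplotype per ``ld_segment_bp`` genomic
    segment, independently and uniformly; the two gametes of a sample are
    independent, so genotype frequencies follow Hardy-Weinberg proportions.
    ``founders`` optionally overrides the random founder allele matrix
    (shape ``(n_haplotypes, n_variants)``, values in {0, 1}).

    Variants with realized folded allele frequency below ``maf_min`` are
    flagged via ``pass_qc=False`` but kept in the matrix.
    """
    config.validate()
    rng = _rng(config, 1)
    genome_length = config.resolved_genome_length()

    pos = _draw_positions(rng, config.n_variants, genome_length)

    if founders is None:
        lo, hi = config.founder_freq_range
        pool_freq = rng.uniform(lo, hi, size=config.n_variants)
        founders = (
            rng.random((config.n_haplotypes, config.n_variants)) < pool_freq
        ).astype(np.int8)
    else:
        founders = np.asarray(founders, dtype=np.int8)
        if founders.shape != (config.n_haplotypes, config.n_variants):
            raise ConfigError(
                f"founders shape {founders.shape} != "
                f"({config.n_haplotypes}, {config.n_variants})"
            )

    segment = pos // config.ld_segment_bp
    seg_ids, seg_index = np.unique(segment, return_inverse=True)
    n_gametes = 2 * config.n_samples
    # founder choice per gamete per segment
    choice = rng.integers(0, config.n_haplotypes, size=(n_gametes, len(seg_ids)))
    gametes = founders[choice[:, seg_index], np.arange(config.n_variants)]
    dosage = (gametes[0::2] + gametes[1::2]).astype(np.float64)

    af = dosage.mean(axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "id": [f"snp_{i:06d}" for i in range(config.n_variants)],
            "ref": "A",
            "alt": "G",
            "maf": maf,
            "pass_qc": maf >= config.maf_min,
        }
    )

    sample_ids = [f"sample_{i:04d}" for i in range(config.n_samples)]
    sex = pd.Series(
        np.where(rng.random(config.n_samples) < config.p_male, "male", "female"),
        index=sample_ids,
        name="sex",
    )
    age = pd.Series(
        rng.integers(20, 71, size=config.n_samples).astype(float),
        index=sample_ids,
        name="age",
    )
    return GenotypeMatrix(sample_ids, variants, dosage, sex, age)


def _segment_lengths(rng: np.random.Generator, mean: int) -> int:
    # uniform around the mean, floor keeps segments non-degenerate
    return int(max(20, rng.integers(mean // 2, mean + mean // 2 + 1)))


def simulate_annotation(config: SimConfig) -> list[GeneAnnotation]:
    """Place non-overlapping gene models (with 100 kb flanks) along one chromosome.

    Strands alternate so about half the genes are on each strand; each gene
    body reads 5'UTR, alternating CDS/intron, 3'UTR in transcription order.
    """
    config.validate()
    rng = _rng(config, 2)
    genome_length = config.resolved_genome_length()

    strands = np.array(["+", "-"])[
        rng.permutation(np.arange(config.n_genes) % 2)
    ]
    genes: list[GeneAnnotation] = []
    cursor = 1 + FLANK_BP
    for i in range(config.n_genes):
        n_introns = int(rng.integers(1, config.max_introns + 1))
        lengths = [(_segment_lengths(rng, config.utr5_mean), "5'UTR")]
        for j in range(n_introns):
            lengths.append((_segment_lengths(rng, config.cds_exon_mean), "CDS"))
            lengths.append((_segment_lengths(rng, config.intron_mean), "intron"))
        lengths.append((_segment_lengths(rng, config.cds_exon_mean), "CDS"))
        lengths.append((_segment_lengths(rng, config.utr3_mean), "3'UTR"))

        body_len = sum(n for n, _ in lengths)
        start, end = cursor, cursor + body_len - 1
        if end + FLANK_BP > genome_length:
            raise ConfigError(
                f"cannot place gene {i} within genome_length={genome_length}"
            )
        strand = strands[i]
        if strand == "+":
            tss, tts = start, end
            walk = start
            segments = []
            for n, lab in lengths:
                segments.append((walk, walk + n - 1, lab))
                walk += n
        else:
            tss, tts = end, start
            walk = end
            segments = []
            for n, lab in lengths:
                segments.append((walk - n + 1, walk, lab))
                walk -= n
        genes.append(
            GeneAnnotation(
                gene_id=f"gene_{i:04d}",
                chrom="1",
                strand=strand,
                tss=tss,
                tts=tts,
                segments=segments,
            )
        )
        cursor = end + 2 * FLANK_BP + GENE_GAP_BP
    return genes


TRUTH_COLUMNS = ["variant_id", "gene_id", "target", "effect", "sex_restricted"]


def make_truth_table(
    genotypes: GenotypeMatrix,
    annotation: list[GeneAnnotation],
    config: SimConfig,
    transcription_regions: Optional[Sequence[str]] = None,
    stability_regions: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Plant QTL effects on randomly chosen cis variant-gene pairs.

    ``transcription_regions`` / ``stability_regions`` optionally restrict the
    genic regions (e.g. ``["upstream"]`` or ``["CDS", "3'UTR"]``) from which
    causal variants are drawn; the default is anywhere in the cis window.
    Effects are on the log2 scale per alternate allele: positive effects on
    the decay target mean faster decay, i.e. lower stability (-log2 beta).
    """
    from stabilityqtl.enrich import assign_genic_region  # local: avoid cycle

    config.validate()
    rng = _rng(config, 4)
    var = genotypes.variants
    pos = var["pos"].to_numpy()
    usable = var["pass_qc"].to_numpy()

    def candidates(gene: GeneAnnotation, regions: Optional[Sequence[str]]) -> np.ndarray:
        lo, hi = gene.cis_window()
        mask = usable & (pos >= lo) & (pos <= hi)
        idx = np.flatnonzero(mask)
        if regions is not None:
            keep = [
                j
                for j in idx
                if assign_genic_region(int(pos[j]), gene) in set(regions)
            ]
            idx = np.array(keep, dtype=int)
        return idx

    rows = []
    grid = np.asarray(config.effect_size_grid, dtype=float)

    def plant(target: str, prop: float, regions: Optional[Sequence[str]]) -> None:
        n_qtl = int(round(prop * config.n_genes))
        if n_qtl == 0:
            return
        order = rng.permutation(len(annotation))
        planted = 0
        for gi in order:
            if planted >= n_qtl:
                break
            gene = annotation[gi]
            idx = candidates(gene, regions)
            if idx.size == 0:
                continue
            j = int(rng.choice(idx))
            effect = float(rng.choice(grid))
            sex = "none"
            if target == "decay" and rng.random() < config.prop_sex_specific:
                sex = "male" if rng.random() < 0.5 else "female"
            rows.append(
                {
                    "variant_id": var["id"].iloc[j],
                    "gene_id": gene.gene_id,
                    "target": target,
                    "effect": effect,
                    "sex_restricted": sex,
                }
            )
            planted += 1

    plant("transcription", config.prop_transcription_qtl, transcription_regions)
    plant("decay", config.prop_stability_qtl, stability_regions)
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth = truth[truth["effect"] != 0.0].reset_index(drop=True)
    return truth


def validate_truth(
    truth: pd.DataFrame,
    genotypes: GenotypeMatrix,
    annotation: list[GeneAnnotation],
) -> None:
    known_variants = set(genotypes.variants["id"])
    known_genes = {g.gene_id for g in annotation}
    bad_v = set(truth["variant_id"]) - known_variants
    bad_g = set(truth["gene_id"]) - known_genes
    if bad_v or bad_g:
        raise ValidationError(
            f"truth table references unknown ids: variants={sorted(bad_v)[:5]} "
            f"genes={sorted(bad_g)[:5]}"
        )
    dup = truth.duplicated(subset=["variant_id", "gene_id", "target"])
    if dup.any():
        raise ValidationError("duplicate (variant, gene, target) rows in truth table")


def _library_sizes(
    rng: np.random.Generator, config: SimConfig, sample_ids: list[str], name: str
) -> pd.Series:
    cv = config.library_size_cv
    if cv <= 0:
        vals = np.full(len(sample_ids), config.library_size_mean)
    else:
        sigma2 = np.log1p(cv**2)
        mu = np.log(config.library_size_mean) - sigma2 / 2.0
        vals = rng.lognormal(mu, np.sqrt(sigma2), size=len(sample_ids))
    return pd.Series(vals, index=sample_ids, name=name)


def expected_counts(
    log2_alpha: np.ndarray,
    log2_beta: np.ndarray,
    exonic_lengths: np.ndarray,
    intronic_lengths: np.ndarray,
    exon_libsize: np.ndarray,
    intron_libsize: np.ndarray,
    kappa: float,
    normalizer: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form NB means: mature abundance alpha/beta, pre-mRNA alpha."""
    alpha = np.exp2(log2_alpha)
    beta = np.exp2(log2_beta)
    mu_exon = (
        exon_libsize[np.newaxis, :]
        * (alpha / beta)
        * exonic_lengths[:, np.newaxis]
        * normalizer
    )
    mu_intron = (
        intron_libsize[np.newaxis, :]
        * kappa
        * alpha
        * intronic_lengths[:, np.newaxis]
        * normalizer
    )
    return mu_exon, mu_intron


def simulate_counts(
    genotypes: GenotypeMatrix,
    annotation: list[GeneAnnotation],
    truth: pd.DataFrame,
    config: SimConfig,
) -> SimulatedDataset:
    """Draw exon/intron count matrices from the kinetic model.

    Planted effects enter additively on log2(alpha) (transcription target) or
    log2(beta) (decay target), scaled by dosage; sex-restricted decay effects
    apply only to samples of the recorded sex.  The global normalizer is
    chosen so the expected per-sample exonic total approximately matches the
    library size at baseline rates.
    """
    config.validate()
    validate_truth(truth, genotypes, annotation)
    rng = _rng(config, 3)

    gene_ids = [g.gene_id for g in annotation]
    sample_ids = genotypes.sample_ids
    n_g, n_s = len(gene_ids), len(sample_ids)

    a0 = rng.normal(config.alpha_log2_mean, config.alpha_log2_sd, size=n_g)
    b0 = rng.normal(config.beta_log2_mean, config.beta_log2_sd, size=n_g)

    log2_alpha = np.repeat(a0[:, np.newaxis], n_s, axis=1)
    log2_beta = np.repeat(b0[:, np.newaxis], n_s, axis=1)
    if config.alpha_noise_sd > 0:
        log2_alpha = log2_alpha + rng.normal(0, config.alpha_noise_sd, size=(n_g, n_s))
    if config.beta_noise_sd > 0:
        log2_beta = log2_beta + rng.normal(0, config.beta_noise_sd, size=(n_g, n_s))

    gene_index = {g: i for i, g in enumerate(gene_ids)}
    variant_index = {v: j for j, v in enumerate(genotypes.variants["id"])}
    male = (genotypes.sex.loc[sample_ids] == "male").to_numpy()
    for row in truth.itertuples(index=False):
        gi = gene_index[row.gene_id]
        vj = variant_index[row.variant_id]
        dose = genotypes.dosage[:, vj]
        if row.sex_restricted in ("male", "female"):
            # center dosage within the affected sex so the planted
            # genotype-by-sex effect carries no sex main effect (otherwise
            # the downstream sex-DE filter would exclude every planted gene)
            active = male if row.sex_restricted == "male" else ~male
            centered = dose - dose[active].mean()
            contribution = row.effect * centered * active
        else:
            contribution = row.effect * dose
        if row.target == "transcription":
            log2_alpha[gi] += contribution
        elif row.target == "decay":
            log2_beta[gi] += contribution
        else:
            raise ValidationError(f"unknown truth target {row.target!r}")

    exon_len = np.array([g.exonic_length for g in annotation], dtype=float)
    intron_len = np.array([g.intronic_length for g in annotation], dtype=float)
    exon_lib = _library_sizes(rng, config, sample_ids, "exon_library_size")
    intron_lib = _library_sizes(rng, config, sample_ids, "intron_library_size")

    normalizer = 1.0 / float(np.sum(np.exp2(a0 - b0) * exon_len))
    mu_exon, mu_intron = expected_counts(
        log2_alpha,
        log2_beta,
        exon_len,
        intron_len,
        exon_lib.to_numpy(),
        intron_lib.to_numpy(),
        config.intron_capture,
        normalizer,
    )

    if config.dispersion == 0:
        exon_counts = rng.poisson(mu_exon)
        intron_counts = rng.poisson(mu_intron)
    else:
        size = 1.0 / config.dispersion
        exon_counts = rng.negative_binomial(size, size / (size + mu_exon))
        intron_counts = rng.negative_binomial(size, size / (size + mu_intron))

    counts = CountMatrixPair(
        exon=pd.DataFrame(exon_counts, index=gene_ids, columns=sample_ids),
        intron=pd.DataFrame(intron_counts, index=gene_ids, columns=sample_ids),
        exon_library_size=exon_lib,
        intron_library_size=intron_lib,
    )
    covariates = pd.DataFrame(
        {"sex": genotypes.sex.loc[sample_ids], "age": genotypes.age.loc[sample_ids]}
    )
    return SimulatedDataset(
        config=config,
        genotypes=genotypes,
        annotation=annotation,
        truth=truth,
        counts=counts,
        covariates=covariates,
        log2_alpha=pd.DataFrame(log2_alpha, index=gene_ids, columns=sample_ids),
        log2_beta=pd.DataFrame(log2_beta, index=gene_ids, columns=sample_ids),
        mu_exon=pd.DataFrame(mu_exon, index=gene_ids, columns=sample_ids),
        mu_intron=pd.DataFrame(mu_intron, index=gene_ids, columns=sample_ids),
    )


def simulate_dataset(
    config: SimConfig,
    transcription_regions: Optional[Sequence[str]] = None,
    stability_regions: Optional[Sequence[str]] = None,
) -> SimulatedDataset:
    """End-to-end simulation: genotypes, annotation, truth table, counts."""
    genotypes = simulate_genotypes(config)
    annotation = simulate_annotation(config)
    truth = make_truth_table(
        genotypes, annotation, config, transcription_regions, stability_regions
    )
    return simulate_counts(genotypes, annotation, truth, config)
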