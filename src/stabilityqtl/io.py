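"""Readers and writers for the on-disk formats used by the pipeline.

Genotypes travel as minimal VCF 4.2 (GT-only), annotation as GTF (1-based,
inclusive) with a companion segment BED (0-based, half-open), everything
else as headered TSV.  Coordinate conversion between the 1-based inclusive
convention (VCF/GTF, internal) and 0-based half-open (BED) happens only
here and in :func:`bed_interval`.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd

from stabilityqtl.errors import ValidationError
from stabilityqtl.simdata import CountMatrixPair, GeneAnnotation, GenotypeMatrix


def bed_interval(start_1based: int, end_1based: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return start_1based - 1, end_1based


def write_vcf(genotypes: GenotypeMatrix, path: str) -> None:
    """Write hard-called genotypes as minimal VCF 4.2 with GT fields only."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
        dosage = genotypes.dosage
        for j, row in genotypes.variants.iterrows():
            calls = []
            for value in dosage[:, j]:
                if np.isnan(value):
                    calls.append("./.")
                else:
                    calls.append(gt_strings[int(round(value))])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(
    path: str,
    sex: Optional[pd.Series] = None,
    age: Optional[pd.Series] = None,
) -> GenotypeMatrix:
    """Read biallelic GT calls from a VCF into a dosage matrix.

    Uses cyvcf2 when available, falling back to a plain-text reader (the
    writer above emits only the minimal subset either path understands).
    Missing genotypes become NaN dosage; sex/age default to unknown
    placeholders unless provided.
    """
    try:
        records, samples = _read_vcf_cyvcf2(path)
    except ImportError:
        records, samples = _read_vcf_text(path)

    if records:
        dosage = np.array([r[5] for r in records], dtype=float).T
    else:
        dosage = np.zeros((len(samples), 0))
    variants = pd.DataFrame(
        [(r[0], r[1], r[2], r[3], r[4]) for r in records],
        columns=["chrom", "pos", "id", "ref", "alt"],
    )
    if len(records):
        with np.errstate(invalid="ignore"):
            af = np.nanmean(dosage, axis=0) / 2.0
        maf = np.minimum(af, 1.0 - af)
    else:
        maf = np.array([])
    variants["maf"] = maf
    variants["pass_qc"] = True

    if sex is None:
        sex = pd.Series("female", index=samples, name="sex")
    if age is None:
        age = pd.Series(np.nan, index=samples, name="age")
    return GenotypeMatrix(list(samples), variants, dosage, sex, age)


def _read_vcf_cyvcf2(path: str):
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    records = []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        gt = v.gt_types.astype(float)  # 0/1/2 with 3 == unknown under gts012
        gt[gt == 3] = np.nan
        records.append((v.CHROM, v.POS, v.ID or f"{v.CHROM}:{v.POS}", v.REF, v.ALT[0], gt))
    return records, samples


def _read_vcf_text(path: str):
    samples: list[str] = []
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            chrom, pos, vid, ref, alt = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
            if "," in alt:
                continue
            gt = []
            for call in fields[9:]:
                alleles = call.split(":")[0].replace("|", "/").split("/")
                if "." in alleles:
                    gt.append(np.nan)
                else:
                    gt.append(float(sum(int(a) > 0 for a in alleles)))
            records.append((chrom, pos, vid, ref, alt, np.array(gt)))
    return records, samples


def write_gtf(annotation: list[GeneAnnotation], path: str) -> None:
    """Write gene models as GTF (1-based inclusive), one feature per segment."""
    feature_names = {
        "5'UTR": "five_prime_utr",
        "CDS": "CDS",
        "intron": "intron",
        "3'UTR": "three_prime_utr",
    }
    with open(path, "w") as fh:
        for gene in annotation:
            attrs = f'gene_id "{gene.gene_id}";'
            fh.write(
                f"{gene.chrom}\tstabilityqtl\tgene\t{gene.body_start}\t"
                f"{gene.body_end}\t.\t{gene.strand}\t.\t{attrs}\n"
            )
            for start, end, label in gene.segments:
                fh.write(
                    f"{gene.chrom}\tstabilityqtl\t{feature_names[label]}\t"
                    f"{start}\t{end}\t.\t{gene.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str) -> list[GeneAnnotation]:
    """Read gene models written by :func:`write_gtf`."""
    label_by_feature = {
        "five_prime_utr": "5'UTR",
        "CDS": "CDS",
        "intron": "intron",
        "three_prime_utr": "3'UTR",
    }
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _, feature, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            gene_id = attrs.split('gene_id "')[1].split('"')[0]
            if gene_id not in genes:
                genes[gene_id] = {"chrom": chrom, "strand": strand, "segments": []}
                order.append(gene_id)
            rec = genes[gene_id]
            if feature == "gene":
                rec["start"], rec["end"] = int(start), int(end)
            elif feature in label_by_feature:
                rec["segments"].append((int(start), int(end), label_by_feature[feature]))
    out = []
    for gene_id in order:
        rec = genes[gene_id]
        if "start" not in rec:
            raise ValidationError(f"{gene_id}: missing gene feature line")
        # transcription order: genomic order on '+', reversed on '-'
        segments = sorted(rec["segments"], key=lambda s: s[0], reverse=rec["strand"] == "-")
        if rec["strand"] == "+":
            tss, tts = rec["start"], rec["end"]
        else:
            tss, tts = rec["end"], rec["start"]
        out.append(
            GeneAnnotation(
                gene_id=gene_id,
                chrom=rec["chrom"],
                strand=rec["strand"],
                tss=tss,
                tts=tts,
                segments=segments,
            )
        )
    return out


def write_segment_bed(annotation: list[GeneAnnotation], path: str) -> None:
    """Companion BED (0-based half-open) of all labeled gene segments."""
    with open(path, "w") as fh:
        for gene in annotation:
            for start, end, label in sorted(gene.segments):
                b_start, b_end = bed_interval(start, end)
                fh.write(
                    f"{gene.chrom}\t{b_start}\t{b_end}\t"
                    f"{gene.gene_id}:{label}\t.\t{gene.strand}\n"
                )


def read_bed_sites(path: str) -> pd.DataFrame:
    """Read binding-site intervals from BED: chrom, start, end, factor[, type].

    Coordinates stay 0-based half-open.  Unsorted input is sorted with a
    warning; the fifth column (when present) labels the factor type
    (RBP / miRNA), defaulting to RBP.
    """
    import warnings

    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValidationError("binding-site BED needs >= 4 columns (factor name)")
    df = df.iloc[:, :5] if df.shape[1] >= 5 else df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "factor"][: df.shape[1]] + (
        ["type"] if df.shape[1] == 5 else []
    )
    if "type" not in df.columns:
        df["type"] = "RBP"
    df["chrom"] = df["chrom"].astype(str)
    if (df["start"] >= df["end"]).any():
        raise ValidationError("binding-site BED has intervals with start >= end")
    if (df["factor"].astype(str).str.len() == 0).any():
        raise ValidationError("binding-site BED has empty factor names")
    sorted_df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    if not sorted_df.index.equals(df.index):
        warnings.warn("binding-site BED was not coordinate-sorted; sorting")
    return sorted_df.reset_index(drop=True)


def write_counts_tsv(counts: CountMatrixPair, exon_path: str, intron_path: str) -> None:
    counts.exon.to_csv(exon_path, sep="\t", index_label="gene_id")
    counts.intron.to_csv(intron_path, sep="\t", index_label="gene_id")


def read_counts_tsv(exon_path: str, intron_path: str) -> CountMatrixPair:
    exon = pd.read_csv(exon_path, sep="\t", index_col="gene_id")
    intron = pd.read_csv(intron_path, sep="\t", index_col="gene_id")
    return CountMatrixPair(exon=exon, intron=intron)


def write_tsv(df: pd.DataFrame, path: str, index_label: Optional[str] = None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def read_covariates_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
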