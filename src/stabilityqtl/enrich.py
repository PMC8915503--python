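"""Genic-region assignment, enrichment tests, and binding-site overlap.

Enrichment ratio (ER) for a category is the QTL set's proportion in the
category divided by the background proportion of all tested variant-gene
pairs in it; significance comes from a two-sided Fisher exact test on the
corresponding 2x2 table (with an upper-tail hypergeometric p reported
alongside).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from stabilityqtl.errors import ValidationError
from stabilityqtl.assoc import bh_fdr
from stabilityqtl.simdata import FLANK_BP, REGION_LABELS, GeneAnnotation

logger = logging.getLogger(__name__)

MATURE_MRNA_REGIONS = ("5'UTR", "CDS", "3'UTR")


def overlap_proportion_pct(k: int, n: int, ndigits: int = 2) -> float:
    """Share ``k``/``n`` as a percentage, round-half-even to ``ndigits``."""
    if n == 0:
        raise ZeroDivisionError("proportion with zero denominator")
    value = Decimal(k) * 100 / Decimal(n)
    return float(value.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_EVEN))


def assign_genic_region(
    pos: int, gene: GeneAnnotation, flank: int = FLANK_BP
) -> str:
    """Label a position relative to a gene: segment label, upstream, or downstream.

    Flanks follow transcription orientation: for a minus-strand gene the
    upstream flank sits at genomic coordinates above the TSS.  Positions
    outside ``[TSS - flank, TTS + flank]`` (oriented) raise.
    """
    sign = 1 if gene.strand == "+" else -1
    d_tss = sign * (pos - gene.tss)
    d_tts = sign * (pos - gene.tts)
    if -flank <= d_tss < 0:
        return "upstream"
    if 0 < d_tts <= flank:
        return "downstream"
    if d_tss < -flank or d_tts > flank:
        raise ValidationError(
            f"position {pos} outside the cis window of {gene.gene_id}"
        )
    for start, end, label in gene.segments:
        if start <= pos <= end:
            return label
    raise ValidationError(
        f"position {pos} in gene body of {gene.gene_id} but in no segment"
    )


@dataclass
class RegionCounts:
    """Per-region totals of background pairs (N_k) and QTL pairs (Q_k)."""

    n_k: dict[str, int]
    q_k: dict[str, int]

    def __post_init__(self) -> None:
        for region, q in self.q_k.items():
            if q > self.n_k.get(region, 0):
                raise ValidationError(f"{region}: QTL count exceeds background count")

    @property
    def n_total(self) -> int:
        return sum(self.n_k.values())

    @property
    def q_total(self) -> int:
        return sum(self.q_k.values())


def count_regions(regions: pd.Series, is_qtl: pd.Series) -> RegionCounts:
    """Tally background and QTL pairs per genic region."""
    n_k = regions.value_counts().to_dict()
    q_k = regions[is_qtl.to_numpy()].value_counts().to_dict()
    n_k = {r: int(n_k.get(r, 0)) for r in REGION_LABELS}
    q_k = {r: int(q_k.get(r, 0)) for r in REGION_LABELS}
    return RegionCounts(n_k=n_k, q_k=q_k)


def region_percentages(counts: RegionCounts, ndigits: int = 2) -> dict[str, float]:
    """Share of the QTL total falling in each region, as rounded percentages."""
    q = counts.q_total
    if q == 0:
        raise ValidationError("no QTLs to summarize")
    return {
        region: overlap_proportion_pct(counts.q_k[region], q, ndigits)
        for region in REGION_LABELS
        if counts.n_k[region] > 0
    }


def region_enrichment(counts: RegionCounts) -> pd.DataFrame:
    """ER, Fisher p and hypergeometric p per region, with BH q across regions.

    The 2x2 table for region k is (Q_k, Q - Q_k; N_k - Q_k, (N - N_k) -
    (Q - Q_k)): QTLs vs non-QTL background pairs, inside vs outside k.
    """
    n, q = counts.n_total, counts.q_total
    rows = []
    for region in REGION_LABELS:
        n_k, q_k = counts.n_k[region], counts.q_k[region]
        if n_k == 0:
            logger.info("region %s has no background pairs; skipped", region)
            continue
        table = np.array(
            [[q_k, q - q_k], [n_k - q_k, (n - n_k) - (q - q_k)]]
        )
        _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
        hyper_p = float(stats.hypergeom.sf(q_k - 1, n, n_k, q))
        er = (q_k / q) / (n_k / n) if q > 0 else np.nan
        odds = (
            (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
            if table[0, 1] > 0 and table[1, 0] > 0
            else np.inf
        )
        rows.append(
            {
                "region": region,
                "n_background": n_k,
                "n_qtl": q_k,
                "qtl_pct": overlap_proportion_pct(q_k, q, 2) if q else np.nan,
                "er": er,
                "odds_ratio": odds,
                "fisher_p": float(fisher_p),
                "hypergeom_p": hyper_p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["fisher_p"].to_numpy())
    return out


def positional_profile(
    qtl_distances: np.ndarray,
    all_distances: np.ndarray,
    bin_bp: int = 2000,
    step_bp: int = 50,
) -> pd.DataFrame:
    """Sliding-window ER along signed distance from an anchor.

    Window i covers ``[d_min + i*step, d_min + i*step + bin)`` (half-open,
    so a distance at a window's right edge belongs to the next window).
    Windows with no background variants report NaN.
    """
    if bin_bp <= 0 or step_bp <= 0:
        raise ValidationError("bin and step must be positive")
    all_distances = np.asarray(all_distances, dtype=float)
    qtl_distances = np.asarray(qtl_distances, dtype=float)
    if all_distances.size == 0:
        return pd.DataFrame(columns=["window_start", "window_end", "n_all", "n_qtl", "er"])
    d_min, d_max = all_distances.min(), all_distances.max()
    n, q = all_distances.size, qtl_distances.size
    starts = np.arange(d_min, d_max + 1, step_bp)
    rows = []
    for start in starts:
        end = start + bin_bp
        n_i = int(((all_distances >= start) & (all_distances < end)).sum())
        q_i = int(((qtl_distances >= start) & (qtl_distances < end)).sum())
        if n_i == 0 or q == 0:
            er = np.nan
        else:
            er = (q_i / q) / (n_i / n)
        rows.append(
            {"window_start": start, "window_end": end, "n_all": n_i, "n_qtl": q_i, "er": er}
        )
    return pd.DataFrame(rows)


def _positions_in_sites(
    chrom: pd.Series, pos_1based: pd.Series, sites: pd.DataFrame
) -> np.ndarray:
    """Boolean overlap of 1-based positions with 0-based half-open intervals.

    A variant overlaps iff ``start <= pos - 1 < end`` for some interval on
    its chromosome; implemented with a sweep over merged sorted intervals.
    """
    out = np.zeros(len(pos_1based), dtype=bool)
    pos0 = pos_1based.to_numpy() - 1
    chrom_arr = chrom.to_numpy()
    for c, group in sites.groupby("chrom"):
        mask = chrom_arr == c
        if not mask.any():
            continue
        starts = group["start"].to_numpy()
        ends = group["end"].to_numpy()
        # merge overlapping intervals so searchsorted gives a clean parity test
        sort = np.argsort(starts, kind="mergesort")
        starts, ends = starts[sort], ends[sort]
        merged_s, merged_e = [], []
        for s, e in zip(starts, ends):
            if merged_e and s <= merged_e[-1]:
                merged_e[-1] = max(merged_e[-1], e)
            else:
                merged_s.append(s)
                merged_e.append(e)
        ms = np.asarray(merged_s)
        me = np.asarray(merged_e)
        p = pos0[mask]
        idx = np.searchsorted(ms, p, side="right") - 1
        hit = (idx >= 0) & (p < me[np.clip(idx, 0, len(me) - 1)])
        out[mask] = hit
    return out


@dataclass
class BindingOverlapResult:
    n_qtl: int
    n_qtl_overlap: int
    qtl_overlap_pct: float
    n_background: int
    n_background_overlap: int
    background_overlap_pct: float
    vs_background_p: float
    per_factor: pd.DataFrame


def binding_site_enrichment(
    pairs: pd.DataFrame,
    sites: pd.DataFrame,
    qtl_flag: str = "is_qtl",
    scope: Sequence[str] = MATURE_MRNA_REGIONS,
) -> BindingOverlapResult:
    """Overlap of mature-mRNA QTLs with binding-site intervals.

    ``pairs`` needs columns chrom, pos (1-based), region, and a boolean QTL
    flag; only pairs whose region falls in ``scope`` are considered.
    Reports the fraction of QTLs overlapping >= 1 site, a Fisher test
    against the non-QTL background, and a per-factor table (2x2 of
    QTL/background x in/out of that factor's sites) with ER, Fisher p and
    BH q across factors.
    """
    required = {"chrom", "pos", "region", qtl_flag}
    if not required.issubset(pairs.columns):
        raise ValidationError(f"pairs table needs columns {sorted(required)}")
    mature = pairs[pairs["region"].isin(set(scope))].reset_index(drop=True)
    is_qtl = mature[qtl_flag].to_numpy(dtype=bool)
    n_qtl = int(is_qtl.sum())
    n_bg = len(mature)

    if len(sites) == 0:
        empty = pd.DataFrame(
            columns=["factor", "n_qtl_in", "n_qtl_out", "n_bg_in", "n_bg_out",
                     "er", "fisher_p", "q"]
        )
        return BindingOverlapResult(
            n_qtl=n_qtl, n_qtl_overlap=0,
            qtl_overlap_pct=overlap_proportion_pct(0, n_qtl, 2) if n_qtl else np.nan,
            n_background=n_bg, n_background_overlap=0,
            background_overlap_pct=overlap_proportion_pct(0, n_bg, 2) if n_bg else np.nan,
            vs_background_p=1.0, per_factor=empty,
        )

    any_hit = _positions_in_sites(mature["chrom"], mature["pos"], sites)
    n_qtl_overlap = int(any_hit[is_qtl].sum())
    n_bg_overlap = int(any_hit.sum())

    nonqtl = ~is_qtl
    table = np.array(
        [
            [n_qtl_overlap, n_qtl - n_qtl_overlap],
            [int(any_hit[nonqtl].sum()), int((~any_hit[nonqtl]).sum())],
        ]
    )
    _, vs_bg_p = stats.fisher_exact(table, alternative="two-sided")

    factor_rows = []
    for factor, group in sites.groupby("factor", sort=True):
        hit = _positions_in_sites(mature["chrom"], mature["pos"], group)
        q_in = int(hit[is_qtl].sum())
        bg_in = int(hit.sum())
        q_out = n_qtl - q_in
        bg_out = n_bg - bg_in
        f_table = np.array(
            [[q_in, q_out], [int(hit[nonqtl].sum()), int((~hit[nonqtl]).sum())]]
        )
        _, p = stats.fisher_exact(f_table, alternative="two-sided")
        er = (
            (q_in / n_qtl) / (bg_in / n_bg)
            if n_qtl > 0 and bg_in > 0
            else np.nan
        )
        factor_rows.append(
            {
                "factor": factor,
                "n_qtl_in": q_in,
                "n_qtl_out": q_out,
                "n_bg_in": bg_in,
                "n_bg_out": bg_out,
                "er": er,
                "fisher_p": float(p),
            }
        )
    per_factor = pd.DataFrame(factor_rows)
    if len(per_factor):
        per_factor["q"] = bh_fdr(per_factor["fisher_p"].to_numpy())

    return BindingOverlapResult(
        n_qtl=n_qtl,
        n_qtl_overlap=n_qtl_overlap,
        qtl_overlap_pct=overlap_proportion_pct(n_qtl_overlap, n_qtl, 2) if n_qtl else np.nan,
        n_background=n_bg,
        n_background_overlap=n_bg_overlap,
        background_overlap_pct=overlap_proportion_pct(n_bg_overlap, n_bg, 2) if n_bg else np.nan,
        vs_background_p=float(vs_bg_p),
        per_factor=per_factor,
    )


def compare_overlap_proportions(
    k1: int, n1: int, k2: int, n2: int
) -> float:
    """Two-sided Fisher p comparing overlap fractions of two QTL sets."""
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)


def annotate_pairs_with_regions(
    pairs: pd.DataFrame,
    annotation: Sequence[GeneAnnotation],
    genotypes,
    flank: int = FLANK_BP,
) -> pd.DataFrame:
    """Attach chrom, pos, and genic-region labels to a cis-pair table."""
    gene_by_id = {g.gene_id: g for g in annotation}
    var = genotypes.variants.set_index("id")
    out = pairs.copy()
    out["chrom"] = var.loc[out["variant_id"], "chrom"].to_numpy()
    out["pos"] = var.loc[out["variant_id"], "pos"].to_numpy()
    out["region"] = [
        assign_genic_region(int(p), gene_by_id[g], flank)
        for p, g in zip(out["pos"], out["gene_id"])
    ]
    return out
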