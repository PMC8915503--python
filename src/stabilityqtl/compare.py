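"""Cross-classification of eQTLs vs stQTLs and LD-block filtering."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Optional

import numpy as np
import pandas as pd

from stabilityqtl.errors import ValidationError
from stabilityqtl.simdata import GenotypeMatrix

logger = logging.getLogger(__name__)


def pct(numerator: int, denominator: int, ndigits: int) -> float:
    """Exact percentage with round-half-even at ``ndigits`` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    value = Decimal(numerator) * 100 / Decimal(denominator)
    quantum = Decimal(1).scaleb(-ndigits)
    return float(value.quantize(quantum, rounding=ROUND_HALF_EVEN))


def overlap_summary(
    n_shared: int,
    n_concordant_up: int,
    n_concordant_down: int,
    n_stqtl: int,
    n_eqtl: int,
) -> dict:
    """Concordance and overlap percentages from cross-classification counts.

    ``n_shared`` pairs are significant for both traits; of those,
    ``n_concordant_up`` have both effects positive and ``n_concordant_down``
    both negative.  Concordance and the per-direction shares are reported to
    one decimal; the share of each QTL set that overlaps the other to the
    nearest integer.  With an empty overlap the concordance fields are None
    and ``concordance_defined`` is False.
    """
    if n_concordant_up + n_concordant_down > n_shared:
        raise ValidationError("concordant counts exceed the shared total")
    summary = {
        "n_shared": n_shared,
        "n_concordant_up": n_concordant_up,
        "n_concordant_down": n_concordant_down,
        "n_discordant": n_shared - n_concordant_up - n_concordant_down,
        "n_stqtl": n_stqtl,
        "n_eqtl": n_eqtl,
        "concordance_defined": n_shared > 0,
    }
    if n_shared > 0:
        summary["concordance_pct"] = pct(
            n_concordant_up + n_concordant_down, n_shared, 1
        )
        summary["concordant_up_pct"] = pct(n_concordant_up, n_shared, 1)
        summary["concordant_down_pct"] = pct(n_concordant_down, n_shared, 1)
        summary["discordant_pct"] = pct(summary["n_discordant"], n_shared, 1)
    else:
        summary["concordance_pct"] = None
        summary["concordant_up_pct"] = None
        summary["concordant_down_pct"] = None
        summary["discordant_pct"] = None
    summary["stqtl_overlap_pct"] = pct(n_shared, n_stqtl, 0) if n_stqtl else None
    summary["eqtl_overlap_pct"] = pct(n_shared, n_eqtl, 0) if n_eqtl else None
    return summary


@dataclass
class QtlCrossTable:
    table: pd.DataFrame  # per-pair classification
    summary: dict


def cross_classify(
    eqtl_table: pd.DataFrame,
    stqtl_table: pd.DataFrame,
    fdr: float = 0.05,
) -> QtlCrossTable:
    """Cross-classify variant-gene pairs by eQTL / stQTL significance.

    Both tables must cover the same pair universe.  A pair is an eQTL
    (stQTL) iff its q-value is below ``fdr`` in the respective table;
    shared pairs are concordant when the two betas share a sign.
    """
    e = eqtl_table.set_index(["variant_id", "gene_id"])
    s = stqtl_table.set_index(["variant_id", "gene_id"])
    if not e.index.sort_values().equals(s.index.sort_values()):
        only_e = e.index.difference(s.index)[:3].tolist()
        only_s = s.index.difference(e.index)[:3].tolist()
        raise ValidationError(
            f"pair universes differ; e.g. only in eQTL table: {only_e}, "
            f"only in stQTL table: {only_s}"
        )
    s = s.loc[e.index]

    table = pd.DataFrame(
        {
            "is_eqtl": e["q"] < fdr,
            "is_stqtl": s["q"] < fdr,
            "beta_expression": e["beta"],
            "beta_stability": s["beta"],
        }
    )
    category = np.select(
        [
            table["is_eqtl"] & table["is_stqtl"],
            table["is_eqtl"],
            table["is_stqtl"],
        ],
        ["both", "eqtl_only", "stqtl_only"],
        default="neither",
    )
    table["category"] = category
    both = table[table["category"] == "both"]
    up = int(((both["beta_expression"] > 0) & (both["beta_stability"] > 0)).sum())
    down = int(((both["beta_expression"] < 0) & (both["beta_stability"] < 0)).sum())

    summary = overlap_summary(
        n_shared=len(both),
        n_concordant_up=up,
        n_concordant_down=down,
        n_stqtl=int(table["is_stqtl"].sum()),
        n_eqtl=int(table["is_eqtl"].sum()),
    )
    summary["category_counts"] = table["category"].value_counts().to_dict()
    return QtlCrossTable(table=table.reset_index(), summary=summary)


@dataclass
class LdBlockSet:
    """Greedy partition of position-sorted variants into high-r2 blocks."""

    blocks: list[list[str]]
    r2_min: float
    window_bp: int
    window_count: int
    block_of: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.block_of = {
            v: i for i, block in enumerate(self.blocks) for v in block
        }


def _dosage_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD)."""
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        logger.warning("zero-variance dosage vector; treating r2 as 0")
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


def ld_blocks_and_filter(
    genotypes: GenotypeMatrix,
    qtls: pd.DataFrame,
    r2_min: float = 0.9,
    window_bp: int = 100_000_000,
    window_count: int = 50,
) -> tuple[LdBlockSet, pd.DataFrame]:
    """Build greedy LD blocks and keep one representative QTL per block-gene.

    Variants are scanned in position order; a variant joins the open block
    iff its dosage r2 exceeds ``r2_min`` with *every* current member and it
    is within ``window_bp`` / ``window_count`` of each of them, else it
    opens a new block (a greedy approximation of clique partitioning; the
    result depends on the position order, which is part of the contract).
    Within each block, per gene, the QTL row with the smallest q (ties:
    smallest p, then smallest position) is the representative.
    """
    var = genotypes.variants.sort_values(["chrom", "pos"], kind="mergesort")
    order = var.index.to_numpy()
    ids = var["id"].to_numpy()
    pos = var["pos"].to_numpy()
    chrom = var["chrom"].to_numpy()
    dosage = genotypes.dosage

    missing = set(qtls["variant_id"]) - set(ids)
    if missing:
        raise ValidationError(
            f"QTL table references variants without dosages: {sorted(missing)[:5]}"
        )

    blocks: list[list[int]] = []
    current: list[int] = []
    for i in range(len(ids)):
        joins = bool(current)
        for j in current:
            same_chrom = chrom[i] == chrom[j]
            near = (
                same_chrom
                and abs(int(pos[i]) - int(pos[j])) <= window_bp
                and abs(i - j) <= window_count
            )
            if not near or _dosage_r2(
                dosage[:, order[i]], dosage[:, order[j]]
            ) <= r2_min:
                joins = False
                break
        if joins:
            current.append(i)
        else:
            if current:
                blocks.append(current)
            current = [i]
    if current:
        blocks.append(current)

    block_set = LdBlockSet(
        blocks=[[ids[i] for i in block] for block in blocks],
        r2_min=r2_min,
        window_bp=window_bp,
        window_count=window_count,
    )

    pos_of = dict(zip(ids, pos))
    qtl = qtls.copy()
    qtl["_block"] = qtl["variant_id"].map(block_set.block_of)
    qtl["_pos"] = qtl["variant_id"].map(pos_of)
    qtl = qtl.sort_values(["q", "p", "_pos"], kind="mergesort")
    representatives = (
        qtl.groupby(["_block", "gene_id"], sort=False)
        .head(1)
        .drop(columns=["_block", "_pos"])
        .reset_index(drop=True)
    )
    return block_set, representatives
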