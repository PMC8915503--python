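"""Relative mRNA stability from exon/intron counts, plus expression traits.

Stability is the per-gene, per-sample difference between exonic and intronic
log2 abundance deviations (delta-exon minus delta-intron), optionally
corrected for an expression-dependent bias by per-sample linear regression
on gene-mean log2 exonic CPM, and re-centered so each gene's row averages
zero.  Values are therefore *relative* to the cohort mean, never absolute
half-lives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from stabilityqtl.errors import ValidationError
from stabilityqtl.simdata import CountMatrixPair

logger = logging.getLogger(__name__)

# stringency grid: 11 values mirroring a 0.01..0.99 sweep
STRINGENCY_GRID = (0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.99)


@dataclass
class StabilityMatrix:
    """Per-gene, per-sample relative stability (log2 units).

    ``values`` rows are centered to mean zero.  ``max_stringency`` records
    the largest grid stringency at which each gene's minimum read count
    clears the corresponding threshold (0.0 when it never does);
    ``passed`` flags genes clearing the analysis stringency.
    """

    values: pd.DataFrame
    max_stringency: pd.Series
    passed: pd.Series
    dropped: pd.DataFrame  # gene_id, reason


def _log2_cpm(counts: pd.DataFrame, libsize: pd.Series, pseudocount: float) -> pd.DataFrame:
    # pseudocount on the CPM scale keeps the result exactly invariant to
    # joint rescaling of one sample's counts and library size
    return np.log2(counts.div(libsize, axis=1) * 1.0e6 + pseudocount)


def infer_stability(
    counts: CountMatrixPair,
    pseudocount: float = 0.5,
    bias_method: str = "linear",
    stringency: float = 0.01,
    exon_library_size: Optional[pd.Series] = None,
    intron_library_size: Optional[pd.Series] = None,
) -> StabilityMatrix:
    """Compute relative stability per gene per sample.

    Steps: (1) log2 CPM of exon and intron counts with ``pseudocount``;
    (2) center each gene's log2 CPM across samples (delta-exon, delta-intron);
    (3) take the difference; (4) with ``bias_method='linear'``, regress each
    sample's column on the gene-mean log2 exonic CPM and subtract the fit;
    (5) re-center rows.  The output is invariant to per-sample rescaling of
    the raw counts (library sizes cancel in the centering).

    Genes with zero intronic counts in every sample carry no stability
    signal and are excluded (recorded in ``dropped``).
    """
    if bias_method not in ("linear", "none"):
        raise ValueError(f"bias_method must be 'linear' or 'none', got {bias_method!r}")
    if counts.exon.shape[1] < 2:
        raise ValidationError("stability inference requires >= 2 samples")

    exon = counts.exon.astype(float)
    intron = counts.intron.astype(float)
    if exon_library_size is None:
        exon_library_size = counts.exon_library_size
    if intron_library_size is None:
        intron_library_size = counts.intron_library_size
    if exon_library_size is None:
        exon_library_size = exon.sum(axis=0)
    if intron_library_size is None:
        intron_library_size = intron.sum(axis=0)

    all_zero_intron = (intron.sum(axis=1) == 0)
    dropped = pd.DataFrame(
        {
            "gene_id": exon.index[all_zero_intron],
            "reason": "zero intronic counts in all samples",
        }
    )
    if all_zero_intron.any():
        logger.info(
            "excluding %d genes with no intronic reads in any sample",
            int(all_zero_intron.sum()),
        )
    exon = exon.loc[~all_zero_intron]
    intron = intron.loc[~all_zero_intron]

    x = _log2_cpm(exon, exon_library_size, pseudocount)
    y = _log2_cpm(intron, intron_library_size, pseudocount)
    delta_exon = x.sub(x.mean(axis=1), axis=0)
    delta_intron = y.sub(y.mean(axis=1), axis=0)
    delta = delta_exon - delta_intron

    if bias_method == "linear":
        delta = _linear_bias_correct(delta, x.mean(axis=1))

    delta = delta.sub(delta.mean(axis=1), axis=0)

    sub_counts = CountMatrixPair(
        exon=exon,
        intron=intron,
        exon_library_size=exon_library_size,
        intron_library_size=intron_library_size,
    )
    pass_genes, max_stringency = stringency_filter(sub_counts, stringency)
    passed = pd.Series(delta.index.isin(pass_genes), index=delta.index, name="passed")
    return StabilityMatrix(
        values=delta,
        max_stringency=max_stringency.loc[delta.index],
        passed=passed,
        dropped=dropped,
    )


def _linear_bias_correct(delta: pd.DataFrame, mean_expression: pd.Series) -> pd.DataFrame:
    """Per sample, remove the OLS fit of delta on gene-mean log2 exonic CPM."""
    xbar = mean_expression.to_numpy()
    design = np.column_stack([np.ones_like(xbar), xbar])
    coef, *_ = np.linalg.lstsq(design, delta.to_numpy(), rcond=None)
    fitted = design @ coef
    return pd.DataFrame(
        delta.to_numpy() - fitted, index=delta.index, columns=delta.columns
    )


def stringency_filter(
    counts: CountMatrixPair, sigma: float
) -> tuple[list[str], pd.Series]:
    """Select genes whose minimum exon/intron count clears the sigma-quantile.

    Per gene, ``m_g`` is the smallest count over samples and over the two
    matrices; the threshold ``T(sigma)`` is the sigma-quantile (lower
    interpolation, so thresholds are attained values) of ``{m_g : m_g > 0}``.
    A gene passes iff ``m_g >= T(sigma)``.  Returns the pass list and each
    gene's largest passing grid stringency (0.0 when even the lowest grid
    value fails, e.g. ``m_g = 0``).
    """
    if not 0.0 < sigma <= 1.0:
        raise ValueError(f"stringency must lie in (0, 1], got {sigma}")
    m = np.minimum(counts.exon.min(axis=1), counts.intron.min(axis=1)).astype(float)
    positive = m[m > 0]
    if positive.empty:
        return [], pd.Series(0.0, index=m.index, name="max_stringency")

    def threshold(s: float) -> float:
        return float(np.quantile(positive.to_numpy(), s, method="lower"))

    pass_genes = m.index[m >= threshold(sigma)].tolist()
    max_stringency = pd.Series(0.0, index=m.index, name="max_stringency")
    for s in STRINGENCY_GRID:
        max_stringency[m >= threshold(s)] = s
    return pass_genes, max_stringency


def compute_tpm(exon_counts: pd.DataFrame, exonic_lengths: pd.Series) -> pd.DataFrame:
    """Length-normalized expression: per-sample TPM over the gene universe.

    ``rate = count / (length_kb)``; TPM rescales rates to sum to 1e6 in each
    sample.  A sample with zero counts everywhere has no defined TPM.
    """
    lengths = exonic_lengths.loc[exon_counts.index]
    if (lengths <= 0).any():
        raise ValidationError("exonic lengths must be positive")
    rate = exon_counts.div(lengths / 1000.0, axis=0)
    totals = rate.sum(axis=0)
    zero = totals[totals == 0]
    if not zero.empty:
        raise ValidationError(
            f"TPM undefined for all-zero sample(s): {', '.join(map(str, zero.index[:5]))}"
        )
    return rate.div(totals, axis=1) * 1.0e6


def transform_expression(tpm):
    """Expression trait transform: log10(100 * TPM + 1); maps 0 to 0."""
    arr = np.asarray(tpm, dtype=float)
    if (arr < 0).any():
        raise ValidationError("TPM must be nonnegative")
    out = np.log10(100.0 * arr + 1.0)
    if isinstance(tpm, pd.DataFrame):
        return pd.DataFrame(out, index=tpm.index, columns=tpm.columns)
    if isinstance(tpm, pd.Series):
        return pd.Series(out, index=tpm.index, name=tpm.name)
    if np.isscalar(tpm):
        return float(out)
    return out
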