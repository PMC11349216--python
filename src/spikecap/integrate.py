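"""Cell-level QC, normalization, and target-expression grouping.

Implements the downstream steps applied to the merged matrix: strict
threshold QC (total UMIs, detected genes, mitochondrial fraction),
log-normalization followed by a per-feature z-transform, quantile grouping
of target expression with zero-inflation handling, and a Wilcoxon rank-sum
comparison between groups.  No clustering or embedding is performed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from spikecap.quant import GEXMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "LogNormResult",
    "qc_filter",
    "lognorm_z",
    "quantile_groups",
    "rank_sum_compare",
]


@dataclass(frozen=True)
class QCThresholds:
    """Strict-inequality QC cutoffs: keep cells with
    total > ``min_umi_count`` AND genes > ``min_genes`` AND
    mito% < ``max_mito_pct``."""

    min_umi_count: int = 2000
    min_genes: int = 200
    max_mito_pct: float = 15.0

    def __post_init__(self) -> None:
        if self.min_umi_count < 0 or self.min_genes < 0:
            raise ValueError("QC thresholds must be non-negative")
        if not 0.0 <= self.max_mito_pct <= 100.0:
            raise ValueError("max_mito_pct must be in [0, 100]")


@dataclass
class QCReport:
    cells_in: int
    cells_retained: int
    failed_umi_count: int
    failed_gene_count: int
    failed_mito_pct: int
    mito_criterion_applied: bool

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def qc_filter(
    gex: GEXMatrix, thr: QCThresholds = QCThresholds(), mito_prefix: str = "MT-"
) -> tuple[GEXMatrix, QCReport]:
    """Drop low-quality cells; inequalities are strict on every criterion.

    If no feature carries ``mito_prefix`` the mitochondrial criterion is
    vacuously passed and a warning is issued.
    """
    totals = gex.cell_totals()
    genes = gex.genes_per_cell()
    mito = gex.mito_fraction(mito_prefix)
    pass_umi = totals > thr.min_umi_count
    pass_genes = genes > thr.min_genes
    if mito is None:
        warnings.warn(
            f"no features with prefix {mito_prefix!r}; "
            "mitochondrial criterion vacuously passed",
            stacklevel=2,
        )
        pass_mito = np.ones(len(gex.barcodes), dtype=bool)
    else:
        pass_mito = 100.0 * mito < thr.max_mito_pct
    keep = pass_umi & pass_genes & pass_mito
    report = QCReport(
        cells_in=len(gex.barcodes),
        cells_retained=int(keep.sum()),
        failed_umi_count=int((~pass_umi).sum()),
        failed_gene_count=int((~pass_genes).sum()),
        failed_mito_pct=int((~pass_mito).sum()),
        mito_criterion_applied=mito is not None,
    )
    return gex.subset_cells(keep), report


@dataclass
class LogNormResult:
    """Per-feature z-scored log-normalized expression over retained cells.

    ``z`` is a features x cells frame; features with zero variance are
    returned as all-zero rows and listed in ``degenerate_features``.
    Zero-total cells are excluded (with a warning) before normalization.
    """

    z: pd.DataFrame
    lognorm: pd.DataFrame
    degenerate_features: tuple[str, ...]
    excluded_barcodes: tuple[str, ...]

    def feature(self, name: str) -> np.ndarray:
        return self.z.loc[name].to_numpy()


def lognorm_z(gex: GEXMatrix, scale_factor: float = 1e4) -> LogNormResult:
    """``log1p(count / cell_total * scale_factor)`` then per-feature z-score.

    The z-transform uses the population (n) standard deviation.  Requires at
    least two retained cells.
    """
    totals = gex.cell_totals().astype(float)
    nonzero = totals > 0
    if (~nonzero).any():
        warnings.warn(
            f"excluding {int((~nonzero).sum())} zero-total cell(s) "
            "from normalization",
            stacklevel=2,
        )
    kept = gex.subset_cells(nonzero)
    totals = totals[nonzero]
    if len(kept.barcodes) < 2:
        raise ValueError("lognorm_z needs at least 2 cells with nonzero totals")

    dense = np.asarray(kept.matrix.todense(), dtype=float)
    lognorm = np.log1p(dense / totals[np.newaxis, :] * scale_factor)
    mean = lognorm.mean(axis=1, keepdims=True)
    sd = lognorm.std(axis=1, keepdims=True)  # population sd
    degenerate = sd.ravel() == 0.0
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    z = (lognorm - mean) / safe_sd
    z[degenerate, :] = 0.0
    return LogNormResult(
        z=pd.DataFrame(z, index=list(kept.features), columns=list(kept.barcodes)),
        lognorm=pd.DataFrame(
            lognorm, index=list(kept.features), columns=list(kept.barcodes)
        ),
        degenerate_features=tuple(np.array(kept.features)[degenerate]),
        excluded_barcodes=tuple(np.array(gex.barcodes)[~nonzero]),
    )


def quantile_groups(expr: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Label cells 1..``n_bins`` by quantile bin of target expression.

    Zero-inflation rule: cells at exactly zero go to bin 1 outright; the
    remaining cells are quantiled among themselves.  Values tied with a bin
    edge fall into the lower bin.  All-equal expression yields a single bin
    with a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    expr = np.asarray(expr, dtype=float)
    labels = np.ones(expr.size, dtype=np.int64)
    nonzero = expr != 0.0
    values = expr[nonzero]
    if values.size == 0 or np.ptp(expr) == 0.0:
        warnings.warn("expression is constant; a single bin was assigned", stacklevel=2)
        return labels
    if np.ptp(values) == 0.0:
        # all nonzero cells identical: they form the top bin above the zeros
        labels[nonzero] = n_bins
        return labels
    edges = np.quantile(values, np.arange(1, n_bins) / n_bins)
    labels[nonzero] = np.searchsorted(edges, values, side="left") + 1
    return labels


def rank_sum_compare(
    group_a: np.ndarray, group_b: np.ndarray, mode: str = "normal"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) between two cell groups.

    ``mode="normal"`` uses the tie-corrected normal approximation;
    ``mode="exact"`` enumerates the exact null distribution (small groups,
    no ties).  Returns ``(U_statistic_of_group_a, p_value)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    if np.ptp(np.concatenate([a, b])) == 0.0:
        raise ValueError("degenerate comparison: all values identical")
    if mode == "normal":
        result = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    elif mode == "exact":
        result = mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(result.statistic), float(result.pvalue)
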