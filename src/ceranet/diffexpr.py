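"""Count normalization and negative-binomial differential expression.

Normalization uses median-of-ratios size factors. The per-contrast test is
a Wald test on the log2 fold change of group means of normalized counts,
with a per-gene method-of-moments NB dispersion pooled across the two
groups and a delta-method standard error. Genes are called differentially
expressed at raw p < alpha (default 0.05), with a Benjamini-Hochberg
adjusted column reported alongside.

Also provides 2^-ddCt relative quantification for qPCR validation tables.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ceranet.core import ExpressionMatrix, SegmentDesign

_DISP_FLOOR = 1e-8
_PSEUDOCOUNT = 0.5

CONTRASTS = (("S1", "S2"), ("S1", "S3"), ("S2", "S3"))


def size_factors(matrix: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios library-size factors, one per sample.

    Each gene with all-positive counts contributes its ratio to the
    per-gene geometric mean; a sample's factor is the median ratio.
    """
    arr = matrix.values.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "prefilter all-zero-containing genes before normalization"
        )
    sub = arr[positive]
    log_geo = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geo[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=matrix.values.columns, name="size_factor")


def _mom_dispersion(pooled: np.ndarray) -> np.ndarray:
    """Classical method-of-moments NB dispersion on pooled normalized counts
    (biased second moment), floored at a small positive value."""
    m = pooled.mean(axis=1)
    s2 = pooled.var(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (s2 - m) / np.where(m > 0, m, 1.0) ** 2
    return np.clip(np.where(m > 0, disp, 0.0), _DISP_FLOOR, None)


def de_test(
    matrix: ExpressionMatrix,
    design: SegmentDesign,
    contrast: tuple[str, str],
    alpha: float = 0.05,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """NB Wald test between two segments; one row per gene.

    ``contrast = (A, B)`` tests B relative to A: log2FC > 0 means higher in
    B. ``factors`` may supply size factors computed on a larger matrix (the
    pipeline shares one set across contrasts); by default they are computed
    from this matrix. All-zero genes are reported with p = 1, not dropped.
    """
    seg_a, seg_b = contrast
    if seg_a == seg_b:
        raise ValueError(f"degenerate contrast {contrast!r}")
    samples_a = [s for s in matrix.samples if design.segment_of(s) == seg_a]
    samples_b = [s for s in matrix.samples if design.segment_of(s) == seg_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"contrast {contrast!r} needs >= 2 samples per segment "
            f"(got {len(samples_a)} and {len(samples_b)})"
        )
    if factors is None:
        factors = size_factors(matrix)
    norm = matrix.values / factors.reindex(matrix.values.columns)
    a = norm[samples_a].to_numpy(dtype=float)
    b = norm[samples_b].to_numpy(dtype=float)

    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    disp = _mom_dispersion(np.hstack([a, b]))
    c0 = _PSEUDOCOUNT
    lfc = np.log2((mu_b + c0) / (mu_a + c0))
    var_a = (mu_a + disp * mu_a**2) / a.shape[1] / (mu_a + c0) ** 2
    var_b = (mu_b + disp * mu_b**2) / b.shape[1] / (mu_b + c0) ** 2
    se = np.sqrt(var_a + var_b) / math.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    pvalue = 2 * stats.norm.sf(np.abs(stat))

    allzero = (a.sum(axis=1) == 0) & (b.sum(axis=1) == 0)
    lfc = np.where(allzero, 0.0, lfc)
    stat = np.where(allzero, 0.0, stat)
    pvalue = np.where(allzero, 1.0, pvalue)

    padj = multipletests(pvalue, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene": matrix.genes,
            "contrast": f"{seg_a}_vs_{seg_b}",
            "log2FC": lfc,
            "SE": se,
            "stat": stat,
            "pvalue": pvalue,
            "padj": padj,
            "direction": np.where(lfc >= 0, "up", "down"),
            "de_flag": (pvalue < alpha) & ~allzero,
        }
    )
    return out


def relative_quantification(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """2^-ddCt relative expression of a target gene.

    dCt = Ct(target) - Ct(reference) in each condition; ddCt is the test
    condition's dCt minus the calibrator's; the relative quantity is
    2**(-ddCt), so ddCt = 0 gives 1 and each extra cycle halves it.
    """
    vals = (ct_target_test, ct_ref_test, ct_target_calibrator, ct_ref_calibrator)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError(f"non-finite cycle threshold among {vals!r}")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_calibrator - ct_ref_calibrator)
    return 2.0 ** (-ddct)
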