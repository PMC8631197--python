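"""Normalization and negative-binomial Wald differential expression.

Per-class normalizations follow the conventions of whole-transcriptome
studies: FPKM for mRNA/lncRNA (fragments per kilobase per million mapped),
TPM for miRNA (with length 1, i.e. reads per million), and SRPBM for
circRNA (back-splice-junction reads per billion mapped reads).

The DE test models counts as NB(mu, alpha) with variance mu + alpha*mu^2.
Library size is removed with median-of-ratios size factors; the log2 fold
change between the two groups is tested against its delta-method standard
error with a standard-normal reference (a Wald test), and p-values are
Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, ExprMatrix

LOG2 = np.log(2.0)


def fpkm(counts: CountMatrix) -> ExprMatrix:
    """Fragments per kilobase of transcript per million mapped reads.

    value = count / ((length/1e3) * (column_total/1e6)).
    """
    if counts.n_features == 0:
        raise ValueError("empty count matrix")
    if counts.lengths is None or counts.lengths.isna().any():
        raise ValueError("FPKM requires a length for every feature")
    if (counts.lengths <= 0).any():
        raise ValueError("feature lengths must be > 0")
    totals = counts.values.sum(axis=0).astype(float)
    if (totals == 0).any():
        raise ValueError("all-zero sample column")
    kb = counts.lengths.astype(float) / 1e3
    vals = counts.values.div(totals / 1e6, axis=1).div(kb, axis=0)
    return ExprMatrix(vals, counts.feature_class, "FPKM")


def tpm(counts: CountMatrix) -> ExprMatrix:
    """Transcripts per million: length-rate renormalized to 1e6 per sample.

    For miRNA matrices (or when lengths are absent) the length is taken as
    1, which reduces to the reads-per-million convention.
    """
    if counts.n_features == 0:
        raise ValueError("empty count matrix")
    if counts.lengths is None or counts.lengths.isna().any():
        lengths = pd.Series(1.0, index=counts.values.index)
    else:
        if (counts.lengths <= 0).any():
            raise ValueError("feature lengths must be > 0")
        lengths = counts.lengths.astype(float)
    rates = counts.values.div(lengths, axis=0)
    denom = rates.sum(axis=0)
    if (denom == 0).any():
        raise ValueError("all-zero sample column")
    vals = rates.div(denom, axis=1) * 1e6
    return ExprMatrix(vals, counts.feature_class, "TPM")


def srpbm(bsj_counts: CountMatrix, mapped_reads: pd.Series) -> ExprMatrix:
    """Spliced (back-splice junction) reads per billion mapped reads."""
    mapped = mapped_reads.reindex(bsj_counts.values.columns)
    if mapped.isna().any() or (mapped <= 0).any():
        raise ValueError("mapped_reads must be > 0 for every sample")
    vals = bsj_counts.values.div(mapped.astype(float) / 1e9, axis=1)
    return ExprMatrix(vals, bsj_counts.feature_class, "SRPBM")


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq convention).

    Each sample's factor is the median, over features positive in every
    sample, of the ratio of its count to the feature's geometric mean.
    """
    df = counts.values if isinstance(counts, CountMatrix) else counts
    vals = df.to_numpy(dtype=float)
    pos = (vals > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no feature is positive in all samples")
    logv = np.log(vals[pos])
    log_geo = logv.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logv - log_geo, axis=0))
    return pd.Series(sf, index=df.columns, name="size_factor")


def size_factors_from_totals(mapped_reads: pd.Series) -> pd.Series:
    """Size factors proportional to mapped-read totals, geometric mean 1.

    Used for circRNA back-splice counts, whose library size is the total
    mapped reads of the parent library rather than the BSJ count sum.
    """
    m = mapped_reads.astype(float)
    if (m <= 0).any():
        raise ValueError("mapped_reads must be > 0")
    return m / np.exp(np.log(m).mean())


def _dispersion_mom(q: np.ndarray, masks: list[np.ndarray],
                    floor: float, shrink: float) -> np.ndarray:
    """Per-feature method-of-moments NB dispersion, pooled within groups.

    alpha solves var = mu + alpha*mu^2 per group; group estimates are
    averaged with df weights, floored at ``floor`` and shrunk toward the
    across-feature mean (weight ``shrink``).  The mean, not the median, is
    the shrink target: per-feature moment estimates are strongly
    right-skewed at small n, so the median sits below the true dispersion
    and would make the Wald test anticonservative.
    """
    num = np.zeros(q.shape[0])
    den = np.zeros(q.shape[0])
    for mask in masks:
        sub = q[:, mask]
        n = sub.shape[1]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mu > 0, (var - mu) / np.maximum(mu, 1e-12) ** 2, 0.0)
        num += (n - 1) * a
        den += n - 1
    alpha = np.maximum(num / den, floor)
    if shrink > 0 and alpha.size > 1:
        alpha = (1.0 - shrink) * alpha + shrink * alpha.mean()
    return np.maximum(alpha, floor)


def nb_wald_test(counts: CountMatrix, groups: pd.Series, *,
                 reference: str | None = None,
                 sf: pd.Series | None = None,
                 pseudocount: float = 0.5,
                 dispersion_floor: float = 1e-8,
                 dispersion_shrink: float = 0.9) -> pd.DataFrame:
    """Two-group negative-binomial Wald test, one row per feature.

    log2FC = log2((mean_B + c) / (mean_A + c)) on size-factor-normalized
    counts (pseudocount ``c``), A being the ``reference`` group.  The
    standard error comes from the delta method under var = mu + alpha*mu^2
    with a method-of-moments dispersion shrunk toward the per-matrix
    mean; the Wald statistic log2FC/SE is referred to N(0, 1).

    Returns columns: feature_id (index), base_mean, log2FC, se, stat, p.
    """
    groups = groups.reindex(counts.values.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"unknown reference group {reference!r}")
    other = levels[1] if levels[0] == reference else levels[0]
    mask_a = (groups == reference).to_numpy()
    mask_b = (groups == other).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs >= 2 samples")

    if sf is None:
        sf = size_factors(counts)
    q = counts.values.to_numpy(dtype=float) / sf.to_numpy()

    mu_a = q[:, mask_a].mean(axis=1)
    mu_b = q[:, mask_b].mean(axis=1)
    c = pseudocount
    log2fc = np.log2(mu_b + c) - np.log2(mu_a + c)

    alpha = _dispersion_mom(q, [mask_a, mask_b],
                            dispersion_floor, dispersion_shrink)
    # delta method: Var(log2(mean_g + c)) ~= Var(mean_g)/((mean_g+c)*ln2)^2
    var_ma = (mu_a + alpha * mu_a ** 2) / mask_a.sum()
    var_mb = (mu_b + alpha * mu_b ** 2) / mask_b.sum()
    se = np.sqrt(var_ma / ((mu_a + c) * LOG2) ** 2
                 + var_mb / ((mu_b + c) * LOG2) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, log2fc / np.maximum(se, 1e-300), 0.0)
    p = np.clip(2.0 * stats.norm.sf(np.abs(stat)), 1e-300, 1.0)

    return pd.DataFrame(
        {"base_mean": q.mean(axis=1), "log2FC": log2fc, "se": se,
         "stat": stat, "p": p},
        index=pd.Index(counts.values.index, name="feature_id"))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(records: pd.DataFrame, lfc_cut: float = 1.0,
            padj_cut: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Adjust p-values and classify each feature as up / down / ns.

    up: log2FC >= lfc_cut and padj < padj_cut; down: log2FC <= -lfc_cut
    and padj < padj_cut; otherwise ns.  Returns the annotated table and a
    ``{"total": ..., "up": ..., "down": ...}`` summary.
    """
    if lfc_cut < 0 or not 0.0 <= padj_cut <= 1.0:
        raise ValueError("invalid cutoffs")
    out = records.copy()
    if "padj" not in out.columns:
        out["padj"] = bh_adjust(out["p"].to_numpy())
    sig = out["padj"] < padj_cut
    out["direction"] = np.where(
        sig & (out["log2FC"] >= lfc_cut), "up",
        np.where(sig & (out["log2FC"] <= -lfc_cut), "down", "ns"))
    up = int((out["direction"] == "up").sum())
    down = int((out["direction"] == "down").sum())
    return out, {"total": up + down, "up": up, "down": down}
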