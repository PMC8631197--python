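"""Bench-side quantification formulas: IHC H-score and qPCR 2^-ddCT.

The H-score summarizes immunohistochemical staining as
H = sum(percent of cells at intensity x intensity) over the weak (1),
moderate (2) and strong (3) bins, giving a value in [0, 300].

Relative expression by the ddCT method compares a target gene's qPCR
cycle threshold (CT) to an internal reference within each condition, then
between conditions: dCT = CT_target - CT_reference, ddCT = dCT_sample -
dCT_control, fold change = 2^-ddCT.
"""

from __future__ import annotations

import pandas as pd


def h_score(negative: float, weak: float, moderate: float, strong: float,
            percent: bool = True) -> float:
    """H = 1*%weak + 2*%moderate + 3*%strong, in [0, 300].

    Fractions are percentages (0-100) by default; pass ``percent=False``
    for proportions in [0, 1] (the result is then scaled to the same
    0-300 range).  Fractions must be non-negative and sum to <= 100%.
    """
    scale = 1.0 if percent else 100.0
    vals = [v * scale for v in (negative, weak, moderate, strong)]
    if any(v < 0 for v in vals):
        raise ValueError("intensity fractions must be non-negative")
    if sum(vals) > 100.0 + 1e-9:
        raise ValueError("intensity fractions must sum to <= 100%")
    return 1.0 * vals[1] + 2.0 * vals[2] + 3.0 * vals[3]


def relative_expression(ct_target_sample: float, ct_ref_sample: float,
                        ct_target_control: float,
                        ct_ref_control: float) -> float:
    """Fold change 2^-ddCT of the sample relative to the control."""
    cts = (ct_target_sample, ct_ref_sample, ct_target_control,
           ct_ref_control)
    for ct in cts:
        if not (ct == ct and abs(ct) != float("inf")):
            raise ValueError("CT values must be finite")
        if ct <= 0:
            raise ValueError("CT values must be positive cycle counts")
    dct_sample = ct_target_sample - ct_ref_sample
    dct_control = ct_target_control - ct_ref_control
    return 2.0 ** (-(dct_sample - dct_control))


def h_score_table(df: pd.DataFrame, percent: bool = True) -> pd.DataFrame:
    """Vectorized H-score over a table with columns negative/weak/moderate/strong."""
    out = df.copy()
    out["h_score"] = [
        h_score(r.negative, r.weak, r.moderate, r.strong, percent=percent)
        for r in df.itertuples()]
    return out


def ddct_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized 2^-ddCT over columns ct_target_sample/ct_ref_sample/
    ct_target_control/ct_ref_control."""
    out = df.copy()
    out["fold_change"] = [
        relative_expression(r.ct_target_sample, r.ct_ref_sample,
                            r.ct_target_control, r.ct_ref_control)
        for r in df.itertuples()]
    return out
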