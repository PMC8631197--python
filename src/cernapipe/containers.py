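"""Core in-memory containers shared across the pipeline.

Counts live in a :class:`CountMatrix` (features x samples, non-negative
integers, one RNA class per matrix).  Normalized expression lives in an
:class:`ExprMatrix` tagged with its unit (FPKM, TPM or SRPBM).  Both wrap a
:class:`pandas.DataFrame` so downstream code can use ordinary pandas
indexing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RNA_CLASSES = ("mRNA", "lncRNA", "circRNA", "miRNA")

EXPR_UNITS = ("FPKM", "TPM", "SRPBM")


@dataclass
class CountMatrix:
    """Raw counts for one RNA class.

    Parameters
    ----------
    values
        Integer DataFrame, index = feature ids, columns = sample ids.
    feature_class
        One of ``mRNA``, ``lncRNA``, ``circRNA``, ``miRNA``.
    lengths
        Effective feature length in nt, indexed like ``values``.  May be
        ``None`` for circRNA back-splice-junction counts, which are
        normalized per mapped read rather than per kilobase.
    """

    values: pd.DataFrame
    feature_class: str
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.feature_class not in RNA_CLASSES:
            raise ValueError(f"unknown RNA class {self.feature_class!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dups)[:5]}")
        vals = self.values.to_numpy()
        if vals.size and not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                bad = self.values.index[
                    ~np.isclose(vals, np.round(vals)).all(axis=1)
                ][0]
                raise ValueError(f"non-integer count in row {bad!r}")
            self.values = self.values.round().astype(np.int64)
            vals = self.values.to_numpy()
        if vals.size and vals.min() < 0:
            bad = self.values.index[(vals < 0).any(axis=1)][0]
            raise ValueError(f"negative count in row {bad!r}")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class ExprMatrix:
    """Normalized expression with its unit.

    TPM columns sum to 1e6 (checked at construction); all values finite.
    """

    values: pd.DataFrame
    feature_class: str
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in EXPR_UNITS:
            raise ValueError(f"unknown expression unit {self.unit!r}")
        vals = self.values.to_numpy(dtype=float)
        if vals.size and not np.isfinite(vals).all():
            raise ValueError("non-finite expression value")
        if self.unit == "TPM" and vals.size:
            sums = vals.sum(axis=0)
            if not np.allclose(sums, 1e6, rtol=1e-6):
                raise ValueError("TPM columns must sum to 1e6")
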