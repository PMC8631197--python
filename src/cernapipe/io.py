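"""Readers and writers for the pipeline's plain-text formats.

Counts travel as TSV with three metadata columns (feature_id,
feature_class, length) followed by one column per sample; sequences as
FASTA; gene sets as GMT (name, description, members, tab-separated).
All coordinates in site tables are 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import RNA_CLASSES, CountMatrix
from .enrich import GeneSet

META_COLS = ("feature_id", "feature_class", "length")


def read_count_matrix(path: str | Path,
                      feature_class: str | None = None) -> CountMatrix:
    """Parse a counts TSV into a validated :class:`CountMatrix`.

    Raises ``ValueError`` naming the offending row for negative or
    non-integer counts and for duplicated feature ids.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in META_COLS[:2] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    classes = df["feature_class"].unique()
    if len(classes) != 1:
        raise ValueError(f"{path}: one RNA class per matrix, got {classes}")
    cls = feature_class or classes[0]
    if cls not in RNA_CLASSES:
        raise ValueError(f"{path}: unknown RNA class {cls!r}")
    if df["feature_id"].duplicated().any():
        dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    sample_cols = [c for c in df.columns if c not in META_COLS]
    values = df[sample_cols].copy()
    values.index = pd.Index(df["feature_id"], name="feature_id")
    for col in sample_cols:
        v = pd.to_numeric(values[col], errors="coerce")
        bad = values.index[v.isna() | (v < 0) | (v != v.round())]
        if len(bad):
            raise ValueError(
                f"{path}: invalid count for feature {bad[0]!r}, sample {col!r}")
        values[col] = v.astype(np.int64)
    lengths = None
    if "length" in df.columns and not df["length"].isna().all():
        lengths = pd.Series(df["length"].to_numpy(), index=values.index,
                            name="length")
    return CountMatrix(values, cls, lengths)


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    df = cm.values.copy()
    df.insert(0, "feature_class", cm.feature_class)
    if cm.lengths is not None:
        df.insert(1, "length", cm.lengths)
    else:
        df.insert(1, "length", np.nan)
    df.rename_axis("feature_id").reset_index().to_csv(path, sep="\t",
                                                      index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: sequence}; wrapped lines are concatenated."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path,
                width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """GMT -> list of GeneSet; rejects rows with fewer than 3 fields.

    The stock GMT readers floating around drop the description column and
    silently accept truncated rows, so this one is explicit.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: GMT row needs >= 3 fields")
            name, desc, members = fields[0], fields[1], [f for f in fields[2:]
                                                         if f]
            if not members:
                raise ValueError(f"{path}:{ln}: gene set {name!r} is empty")
            if name in seen:
                raise ValueError(f"{path}:{ln}: duplicate set name {name!r}")
            seen.add(name)
            sets.append(GeneSet(name, desc, members))
    return sets


def write_gmt(sets: list[tuple[str, str, list[str]] | GeneSet],
              path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            if isinstance(s, GeneSet):
                name, desc, members = s.name, s.description, s.members
            else:
                name, desc, members = s
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_sites_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_pairs_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("feature_id")


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df.rename_axis("feature_id").reset_index().to_csv(path, sep="\t",
                                                      index=False,
                                                      float_format="%.10g")
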