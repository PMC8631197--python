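"""miRNA response element (MRE) prediction by canonical seed matching.

A miRNA's seed is nucleotides 2-7 (1-based, from the 5' end).  A target
site is the reverse complement of the seed on the transcript's sense
strand, optionally extended by pairing to miRNA nucleotide 8 (the "m8"
anchor) and/or an adenosine opposite miRNA position 1 (the "A1" anchor):

========  =========================================  ======
class     target pattern (5'->3')                    length
========  =========================================  ======
6mer      revcomp(miRNA nt 2-7)                      6
7mer-A1   revcomp(nt 2-7) + A                        7
7mer-m8   revcomp(nt 2-8)                            7
8mer      revcomp(nt 2-8) + A                        8
========  =========================================  ======

Site strength is ordered 8mer > 7mer-m8 > 7mer-A1 > 6mer.  Each seed-match
occurrence is reported once, classified as the strongest class supported by
its flanking nucleotides.  An optional miRanda-style duplex score (local
anti-parallel alignment with complementarity scoring) can annotate pairs.

Coordinates are 0-based half-open on the target sense strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

SITE_CLASSES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
CLASS_RANK = {c: i for i, c in enumerate(SITE_CLASSES)}

_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_VALID = frozenset("ACGU")


def _as_rna(seq: str, what: str = "sequence") -> str:
    """Uppercase, map T->U, and validate the alphabet."""
    s = seq.upper().replace("T", "U")
    if not set(s) <= _VALID:
        bad = sorted(set(s) - _VALID)
        raise ValueError(f"invalid {what} alphabet: {bad}")
    return s


def revcomp(seq: str) -> str:
    return _as_rna(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MRESite:
    """One predicted binding site; interval is 0-based half-open."""

    mirna_id: str
    target_id: str
    start: int
    end: int
    site_class: str
    duplex_score: float | None = None


def seed_patterns(mirna_seq: str) -> dict[str, str]:
    """Target-strand patterns for each canonical seed class.

    Raises ``ValueError`` for miRNAs shorter than 8 nt (no m8 position).
    """
    m = _as_rna(mirna_seq, "miRNA")
    if len(m) < 8:
        raise ValueError("miRNA must be >= 8 nt for seed classes")
    p6 = revcomp(m[1:7])
    p7m8 = revcomp(m[1:8])
    return {"6mer": p6, "7mer-A1": p6 + "A",
            "7mer-m8": p7m8, "8mer": p7m8 + "A"}


def scan_sites(mirna_seq: str, target_seq: str,
               mirna_id: str = "miRNA", target_id: str = "target") -> list[MRESite]:
    """All seed-match sites of one miRNA on one target.

    Every 6mer seed-match occurrence is reported exactly once, upgraded to
    the strongest class its flanks support (m8 pairing upstream, A1
    adenosine downstream).  DNA input (T) is accepted and treated as RNA.
    """
    m = _as_rna(mirna_seq, "miRNA")
    t = _as_rna(target_seq, "target")
    if not t:
        raise ValueError("empty target sequence")
    pats = seed_patterns(m)
    p6 = pats["6mer"]
    m8_char = pats["7mer-m8"][0]  # complement of miRNA nt 8 on the target
    sites: list[MRESite] = []
    i = t.find(p6)
    while i != -1:
        has_m8 = i > 0 and t[i - 1] == m8_char
        has_a1 = i + 6 < len(t) and t[i + 6] == "A"
        if has_m8 and has_a1:
            cls, start, end = "8mer", i - 1, i + 7
        elif has_m8:
            cls, start, end = "7mer-m8", i - 1, i + 6
        elif has_a1:
            cls, start, end = "7mer-A1", i, i + 7
        else:
            cls, start, end = "6mer", i, i + 6
        sites.append(MRESite(mirna_id, target_id, start, end, cls))
        i = t.find(p6, i + 1)
    return sites


@lru_cache(maxsize=8)
def _aligner(match: float, wobble: float, mismatch: float,
             gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    alpha = "ACGU"
    mat = substitution_matrices.Array(alpha, dims=2)
    pairs = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    wobbles = {("G", "U"), ("U", "G")}
    for a in alpha:
        for b in alpha:
            if (a, b) in pairs:
                mat[a, b] = match
            elif (a, b) in wobbles:
                mat[a, b] = wobble
            else:
                mat[a, b] = mismatch
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = mat
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def duplex_score(mirna_seq: str, target_window: str, *,
                 match: float = 5.0, wobble: float = 1.0,
                 mismatch: float = -3.0, gap_open: float = -8.0,
                 gap_extend: float = -2.0) -> float:
    """Best local anti-parallel duplex score of miRNA vs. a target window.

    The miRNA (5'->3') is aligned against the reversed target window so
    that aligned columns are potential base pairs; Watson-Crick pairs score
    ``match``, G:U wobbles ``wobble``, everything else ``mismatch``; gaps
    are affine (first gap position ``gap_open``, each further ``gap_extend``).
    Local alignment floors the score at 0.
    """
    m = _as_rna(mirna_seq, "miRNA")
    w = _as_rna(target_window, "target window")
    if not m or not w:
        raise ValueError("empty sequence")
    al = _aligner(match, wobble, mismatch, gap_open, gap_extend)
    return float(al.score(m, w[::-1]))


def sites_to_frame(sites: list[MRESite]) -> pd.DataFrame:
    cols = ["mirna_id", "target_id", "start", "end", "site_class",
            "duplex_score"]
    if not sites:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([s.__dict__ for s in sites])[cols]


def build_target_table(mirna_seqs: dict[str, str],
                       target_seqs: dict[str, str],
                       min_class: str = "7mer-A1",
                       min_score: float | None = None,
                       score_flank: int = 25) -> pd.DataFrame:
    """Aggregate per-pair binding evidence over all miRNA x target scans.

    A pair is retained iff its strongest site class is at least
    ``min_class`` and, when ``min_score`` is set, its best duplex score
    (computed over each site extended by ``score_flank`` nt on both sides)
    reaches it.  Columns: mirna_id, target_id, n_sites, best_class,
    best_score.
    """
    if min_class not in CLASS_RANK:
        raise ValueError(f"unknown site class {min_class!r}")
    rows = []
    for mid, mseq in mirna_seqs.items():
        for tid, tseq in target_seqs.items():
            sites = scan_sites(mseq, tseq, mid, tid)
            if not sites:
                continue
            best = max(sites, key=lambda s: CLASS_RANK[s.site_class])
            if CLASS_RANK[best.site_class] < CLASS_RANK[min_class]:
                continue
            best_score = None
            if min_score is not None:
                t = _as_rna(tseq)
                best_score = max(
                    duplex_score(mseq,
                                 t[max(0, s.start - score_flank):
                                   s.end + score_flank])
                    for s in sites)
                if best_score < min_score:
                    continue
            rows.append({"mirna_id": mid, "target_id": tid,
                         "n_sites": len(sites),
                         "best_class": best.site_class,
                         "best_score": best_score})
    cols = ["mirna_id", "target_id", "n_sites", "best_class", "best_score"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]
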