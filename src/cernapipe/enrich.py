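"""Gene-set enrichment: hypergeometric over-representation and GSEA.

ORA asks whether a study list (e.g. the DE mRNAs) contains more members of
a gene set than expected when drawing the same number of genes from the
population; its p-value is the same inclusive upper-tail hypergeometric
used by the sponge test.

GSEA walks a ranked gene list and accumulates a running sum that rises by
|score|^weight (normalized over the set's members) at every set hit and
falls by 1/(N - set size) at every miss; the enrichment score ES is the
signed extremum of that walk.  Significance comes from a gene-label
permutation null: random same-size sets yield a null ES distribution, the
normalized score NES divides ES by the mean |null ES| of matching sign,
and the permutation p and FDR are computed within the matching sign class.
At weight 0 the statistic reduces to the two-sample Kolmogorov-Smirnov
distance between hit and miss rank distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cerna import hypergeom_sponge_test
from .expression import bh_adjust


@dataclass
class GeneSet:
    name: str
    description: str
    members: list[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            self.members = list(dict.fromkeys(self.members))


@dataclass
class ORARecord:
    set_name: str
    N: int
    K: int
    n: int
    k: int
    p: float
    padj: float | None = None


def ora_test(study: list[str], population: list[str],
             gene_set: GeneSet) -> ORARecord:
    """Hypergeometric over-representation p-value for one gene set.

    N = |population|, K = |set in population|, n = |study|, k = |set in
    study|; p = P(X >= k).  ``study`` must be a subset of ``population``.
    """
    pop = set(population)
    stu = set(study)
    if not stu <= pop:
        raise ValueError("study list must be contained in the population")
    members = set(gene_set.members) & pop
    k = len(members & stu)
    return ORARecord(gene_set.name, N=len(pop), K=len(members), n=len(stu),
                     k=k, p=hypergeom_sponge_test(len(pop), len(members),
                                                  len(stu), k))


def ora_batch(study: list[str], population: list[str],
              gene_sets: list[GeneSet]) -> pd.DataFrame:
    """ORA over a GMT collection with BH adjustment, sorted by p."""
    if not gene_sets:
        raise ValueError("empty gene-set collection")
    recs = [ora_test(study, population, gs) for gs in gene_sets]
    df = pd.DataFrame([r.__dict__ for r in recs])
    df["padj"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values(["p", "set_name"]).reset_index(drop=True)


def rank_features(de_table: pd.DataFrame) -> pd.DataFrame:
    """Rank features by signed Wald statistic, descending.

    Ties break lexicographically on the feature id so the ranking is a
    pure function of the table contents.  Returns columns feature_id,
    score.
    """
    if "stat" not in de_table.columns:
        raise ValueError("de_table needs a 'stat' column")
    stats_ = de_table["stat"]
    if not np.isfinite(stats_.to_numpy(dtype=float)).all():
        raise ValueError("non-finite ranking statistic")
    out = de_table.reset_index().rename(columns={de_table.index.name
                                                 or "index": "feature_id"})
    out = out[["feature_id", "stat"]].rename(columns={"stat": "score"})
    return out.sort_values(["score", "feature_id"],
                           ascending=[False, True]).reset_index(drop=True)


@dataclass
class GSEARecord:
    set_name: str
    ES: float
    running_sum: np.ndarray = field(repr=False)
    NES: float | None = None
    p_perm: float | None = None
    FDR: float | None = None
    n_hits: int = 0


def gsea_es(ranked_ids: list[str], scores, gene_set: GeneSet,
            weight: float = 1.0) -> GSEARecord:
    """Running-sum enrichment score of one set against a ranked list.

    Hits increment by |score|^weight / sum over hits; misses decrement by
    1/(N - n_hits).  ES is the running sum's largest signed deviation from
    zero; the walk returns to 0 at the end by construction.
    """
    ids = np.asarray(ranked_ids)
    scores = np.asarray(scores, dtype=float)
    hit = np.isin(ids, list(gene_set.members))
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no ranked members")
    rs = _running_sum(hit, scores, weight)
    es = float(rs[np.argmax(np.abs(rs))])
    return GSEARecord(gene_set.name, ES=es, running_sum=rs, n_hits=n_hits)


def _running_sum(hit: np.ndarray, scores: np.ndarray,
                 weight: float) -> np.ndarray:
    n = hit.size
    n_hits = int(hit.sum())
    if n_hits == n:
        raise ValueError("gene set covers the whole ranked list")
    w = np.abs(scores) ** weight
    steps = np.where(hit, 0.0, -1.0 / (n - n_hits))
    denom = w[hit].sum()
    if denom == 0:
        # all-zero hit scores: fall back to the unweighted step
        steps[hit] = 1.0 / n_hits
    else:
        steps[hit] = w[hit] / denom
    return np.cumsum(steps)


def _null_es(hit_count: int, scores: np.ndarray, weight: float,
             n_perm: int, rng: np.random.Generator) -> np.ndarray:
    n = scores.size
    out = np.empty(n_perm)
    for i in range(n_perm):
        hit = np.zeros(n, dtype=bool)
        hit[rng.choice(n, size=hit_count, replace=False)] = True
        rs = _running_sum(hit, scores, weight)
        out[i] = rs[np.argmax(np.abs(rs))]
    return out


def _nes_p(es: float, null: np.ndarray) -> tuple[float, float]:
    same = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same.size == 0:
        return np.nan, 1.0
    nes = es / np.abs(same).mean()
    p = (1.0 + (np.abs(same) >= abs(es)).sum()) / (1.0 + same.size)
    return float(nes), float(p)


def gsea_permutation(ranked_ids: list[str], scores, gene_set: GeneSet,
                     n_perm: int = 1000, seed: int = 0,
                     weight: float = 1.0) -> GSEARecord:
    """Gene-label permutation test for one set: NES, p_perm and FDR.

    The null re-draws ``n_hits`` random positions ``n_perm`` times.  p_perm
    uses the add-one estimator within the sign class of the observed ES;
    with a single query set the positive/negative-ratio FDR reduces to the
    fraction of same-sign null NES at least as extreme.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rec = gsea_es(ranked_ids, scores, gene_set, weight)
    rng = np.random.default_rng(seed)
    scores = np.asarray(scores, dtype=float)
    null = _null_es(rec.n_hits, scores, weight, n_perm, rng)
    nes, p = _nes_p(rec.ES, null)
    same = null[np.sign(null) == np.sign(rec.ES)] if rec.ES != 0 else null
    if same.size and np.isfinite(nes):
        null_nes = same / np.abs(same).mean()
        fdr = min(1.0, float((np.abs(null_nes) >= abs(nes)).mean()))
    else:
        fdr = 1.0
    rec.NES, rec.p_perm, rec.FDR = nes, p, fdr
    return rec


def gsea_batch(de_table: pd.DataFrame, gene_sets: list[GeneSet],
               n_perm: int = 1000, seed: int = 0,
               weight: float = 1.0) -> pd.DataFrame:
    """GSEA over a collection: one row per set with ES/NES/p_perm/FDR."""
    ranked = rank_features(de_table)
    ids = ranked["feature_id"].tolist()
    scores = ranked["score"].to_numpy()
    rows = []
    for i, gs in enumerate(gene_sets):
        try:
            rec = gsea_permutation(ids, scores, gs, n_perm=n_perm,
                                   seed=seed + i, weight=weight)
        except ValueError:
            continue
        rows.append({"set_name": rec.set_name, "n_hits": rec.n_hits,
                     "ES": rec.ES, "NES": rec.NES, "p_perm": rec.p_perm,
                     "FDR": rec.FDR})
    cols = ["set_name", "n_hits", "ES", "NES", "p_perm", "FDR"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols].sort_values("p_perm").reset_index(drop=True)
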