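"""ceRNA network construction: correlation filters + hypergeometric sponge test.

A sponge candidate is a DE lncRNA or circRNA paired with a DE mRNA such
that, among DE miRNAs with binding evidence, at least ``min_shared``
miRNAs target both partners and each of those miRNA-target relationships
is strongly anti-correlated (Pearson r < r_max, p < p_max) while the
sponge and the mRNA are positively co-expressed (r > r_min, p < p_max).
The shared-miRNA overlap is then tested against a hypergeometric null:
with N miRNAs in play, K targeting the sponge and n targeting the mRNA,
the probability of sharing >= k by chance is the upper tail
P(X >= k), X ~ Hypergeom(N, K, n).  Pairs with p_hyper below the cutoff
form the network, together with their miRNA-sponge and miRNA-mRNA edges.

The two networks built this way - a lncRNA-based and a circRNA-based one -
can be intersected on their mRNA nodes to nominate hub genes supported by
both sponge classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .config import Thresholds

EDGE_TYPES = ("miRNA-mRNA", "miRNA-ce", "ce-mRNA")


@dataclass(frozen=True)
class CorrEdge:
    """A Pearson correlation between two expression profiles."""

    id_a: str
    id_b: str
    r: float
    p: float
    n_samples: int


def pearson_edge(x, y, id_a: str = "a", id_b: str = "b") -> CorrEdge:
    """Sample Pearson r with the two-sided t-transform p-value.

    p derives from t = r*sqrt((n-2)/(1-r^2)) on n-2 df; |r| = 1 yields the
    distribution's limit p = 0.  Constant input is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return CorrEdge(id_a, id_b, float(res.statistic), float(res.pvalue), n)


def _corr_and_p(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r and two-sided p between two feature blocks.

    ``a`` (ka x n) vs ``b`` (kb x n) -> (ka x kb) matrices.  Matches the
    scalar t-transform of :func:`pearson_edge`.
    """
    n = a.shape[1]
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((az ** 2).sum(axis=1))
    sb = np.sqrt((bz ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (az @ bz.T) / np.outer(sa, sb)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    return r, p


def _expr_rows(expr: pd.DataFrame, ids: list[str], log2: bool) -> np.ndarray:
    missing = [i for i in ids if i not in expr.index]
    if missing:
        raise KeyError(f"features missing from expression matrix: {missing[:5]}")
    vals = expr.loc[ids].to_numpy(dtype=float)
    return np.log2(vals + 1.0) if log2 else vals


def filter_mirna_target(pairs: pd.DataFrame, expr_mirna: pd.DataFrame,
                        expr_target: pd.DataFrame, r_max: float = -0.9,
                        p_max: float = 0.05, log2: bool = True) -> pd.DataFrame:
    """Keep binding-evidence pairs whose expression anti-correlates.

    Retains rows with Pearson r < ``r_max`` and p < ``p_max``; annotates
    ``r`` and ``p``.  ``pairs`` needs columns mirna_id / target_id.
    """
    if pairs.empty:
        return pairs.assign(r=pd.Series(dtype=float), p=pd.Series(dtype=float))
    mids = list(pd.unique(pairs["mirna_id"]))
    tids = list(pd.unique(pairs["target_id"]))
    a = _expr_rows(expr_mirna, mids, log2)
    b = _expr_rows(expr_target, tids, log2)
    r, p = _corr_and_p(a, b)
    mi = {m: i for i, m in enumerate(mids)}
    ti = {t: i for i, t in enumerate(tids)}
    ridx = pairs["mirna_id"].map(mi).to_numpy()
    cidx = pairs["target_id"].map(ti).to_numpy()
    out = pairs.copy()
    out["r"] = r[ridx, cidx]
    out["p"] = p[ridx, cidx]
    return out[(out["r"] < r_max) & (out["p"] < p_max)].reset_index(drop=True)


def filter_coexpression(ce_ids: list[str], mrna_ids: list[str],
                        expr_ce: pd.DataFrame, expr_mrna: pd.DataFrame,
                        r_min: float = 0.8, p_max: float = 0.05,
                        log2: bool = True) -> pd.DataFrame:
    """All positively co-expressed sponge-mRNA pairs (r > r_min, p < p_max)."""
    if not ce_ids or not mrna_ids:
        return pd.DataFrame(columns=["ce_id", "mrna_id", "r", "p"])
    a = _expr_rows(expr_ce, list(ce_ids), log2)
    b = _expr_rows(expr_mrna, list(mrna_ids), log2)
    r, p = _corr_and_p(a, b)
    keep = (r > r_min) & (p < p_max)
    ii, jj = np.nonzero(keep)
    return pd.DataFrame({"ce_id": np.asarray(ce_ids)[ii],
                         "mrna_id": np.asarray(mrna_ids)[jj],
                         "r": r[ii, jj], "p": p[ii, jj]})


def hypergeom_sponge_test(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail (inclusive) hypergeometric probability P(X >= k).

    X counts the overlap when ``n`` draws are taken without replacement
    from ``N`` items of which ``K`` are marked.
    """
    if not (0 <= k <= min(K, n) and max(K, n) <= N and min(K, n) >= 0):
        raise ValueError(f"inconsistent counts N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class CandidatePair:
    """One sponge-mRNA candidate with its shared-miRNA evidence."""

    ce_id: str
    mrna_id: str
    shared_mirnas: list[str]
    K: int
    n: int
    N: int
    r: float
    p: float
    p_hyper: float

    @property
    def k(self) -> int:
        return len(self.shared_mirnas)


def assemble_network(de_tables: dict[str, pd.DataFrame],
                     target_pairs: pd.DataFrame,
                     expr: dict[str, pd.DataFrame],
                     ce_class: str,
                     thresholds: Thresholds | None = None) -> nx.Graph:
    """Build the ceRNA network for one sponge class (lncRNA or circRNA).

    Pipeline: restrict to DE features -> anti-correlation filter on
    miRNA-target binding evidence -> positive co-expression filter on
    sponge-mRNA pairs -> require >= min_shared_mirnas miRNAs retained
    against both partners -> hypergeometric sponge test -> emit nodes
    (typed, with DE direction) and the three edge types of every surviving
    candidate.  Empty DE sets yield an empty, valid graph.

    ``de_tables`` maps RNA class to a DE table with a ``direction`` column;
    ``expr`` maps class to an expression DataFrame over the same samples.
    N for the sponge test is the number of distinct DE miRNAs that retain
    at least one anti-correlated target among the DE sponges and mRNAs.
    """
    if ce_class not in ("lncRNA", "circRNA"):
        raise ValueError("ce_class must be lncRNA or circRNA")
    th = thresholds or Thresholds()

    def de_set(cls: str) -> pd.DataFrame:
        t = de_tables.get(cls)
        if t is None:
            return pd.DataFrame(columns=["direction"])
        return t[t["direction"].isin(("up", "down"))]

    de_mirna = de_set("miRNA")
    de_mrna = de_set("mRNA")
    de_ce = de_set(ce_class)
    direction = pd.concat([de_mirna, de_mrna, de_ce])["direction"]

    net = nx.Graph(ce_class=ce_class)
    if de_mirna.empty or de_mrna.empty or de_ce.empty or target_pairs.empty:
        return net

    tp = target_pairs[target_pairs["mirna_id"].isin(de_mirna.index)]
    tp_mrna = tp[tp["target_id"].isin(de_mrna.index)]
    tp_ce = tp[tp["target_id"].isin(de_ce.index)]

    kept_mrna = filter_mirna_target(tp_mrna, expr["miRNA"], expr["mRNA"],
                                    th.r_max, th.p_max, th.log_expression)
    kept_ce = filter_mirna_target(tp_ce, expr["miRNA"], expr[ce_class],
                                  th.r_max, th.p_max, th.log_expression)
    if kept_mrna.empty or kept_ce.empty:
        return net

    mirnas_of_mrna = kept_mrna.groupby("target_id")["mirna_id"].agg(set)
    mirnas_of_ce = kept_ce.groupby("target_id")["mirna_id"].agg(set)
    N = len(set(kept_mrna["mirna_id"]) | set(kept_ce["mirna_id"]))

    coexpr = filter_coexpression(list(mirnas_of_ce.index),
                                 list(mirnas_of_mrna.index),
                                 expr[ce_class], expr["mRNA"],
                                 th.r_min, th.p_max, th.log_expression)

    corr_mrna = {(r.mirna_id, r.target_id): (r.r, r.p)
                 for r in kept_mrna.itertuples()}
    corr_ce = {(r.mirna_id, r.target_id): (r.r, r.p)
               for r in kept_ce.itertuples()}

    for row in coexpr.itertuples():
        shared = sorted(mirnas_of_ce[row.ce_id] & mirnas_of_mrna[row.mrna_id])
        if len(shared) < th.min_shared_mirnas:
            continue
        K = len(mirnas_of_ce[row.ce_id])
        n = len(mirnas_of_mrna[row.mrna_id])
        cand = CandidatePair(
            ce_id=row.ce_id, mrna_id=row.mrna_id, shared_mirnas=shared,
            K=K, n=n, N=N, r=float(row.r), p=float(row.p),
            p_hyper=hypergeom_sponge_test(N, K, n, len(shared)))
        if cand.p_hyper >= th.p_hyper_cut:
            continue
        net.add_node(cand.ce_id, rna_type=ce_class,
                     direction=direction[cand.ce_id])
        net.add_node(cand.mrna_id, rna_type="mRNA",
                     direction=direction[cand.mrna_id])
        net.add_edge(cand.ce_id, cand.mrna_id, edge_type="ce-mRNA",
                     r=cand.r, p=cand.p, p_hyper=cand.p_hyper,
                     k=cand.k, K=cand.K, n=cand.n, N=cand.N)
        for m in shared:
            net.add_node(m, rna_type="miRNA", direction=direction[m])
            r_c, p_c = corr_ce[(m, cand.ce_id)]
            net.add_edge(m, cand.ce_id, edge_type="miRNA-ce",
                         r=float(r_c), p=float(p_c))
            r_m, p_m = corr_mrna[(m, cand.mrna_id)]
            net.add_edge(m, cand.mrna_id, edge_type="miRNA-mRNA",
                         r=float(r_m), p=float(p_m))
    return net


def network_summary(net: nx.Graph) -> dict:
    """Node counts by RNA type x DE direction, and edge counts by type."""
    nodes: dict[str, dict[str, int]] = {}
    for _, d in net.nodes(data=True):
        t = d["rna_type"]
        nodes.setdefault(t, {"total": 0, "up": 0, "down": 0})
        nodes[t]["total"] += 1
        nodes[t][d["direction"]] += 1
    edges: dict[str, int] = {t: 0 for t in EDGE_TYPES}
    for _, _, d in net.edges(data=True):
        edges[d["edge_type"]] += 1
    return {"n_nodes": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
            "nodes_by_type": nodes, "edges_by_type": edges}


def intersect_hub_mrnas(net_lnc: nx.Graph, net_circ: nx.Graph) -> list[str]:
    """Sorted mRNA identifiers present in both networks."""
    def mrnas(net: nx.Graph) -> set[str]:
        return {n for n, d in net.nodes(data=True) if d["rna_type"] == "mRNA"}
    return sorted(mrnas(net_lnc) & mrnas(net_circ))


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

_EDGE_COLS = ["id_a", "id_b", "edge_type", "r", "p", "p_hyper", "k", "K",
              "n", "N"]
_NODE_COLS = ["node_id", "rna_type", "direction"]


def export_network(net: nx.Graph, path, fmt: str) -> None:
    """Write the network as SIF, GraphML, or a nodes+edges TSV pair.

    ``fmt='tsv'`` writes ``<path>.edges.tsv`` and ``<path>.nodes.tsv``;
    this pair round-trips through :func:`import_network_tsv`.
    """
    from pathlib import Path
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as fh:
            for a, b, d in sorted(net.edges(data=True)):
                fh.write(f"{a}\t{d['edge_type']}\t{b}\n")
    elif fmt == "graphml":
        g = nx.Graph(**{k: v for k, v in net.graph.items() if v is not None})
        for n, d in net.nodes(data=True):
            g.add_node(n, **{k: v for k, v in d.items() if v is not None})
        for a, b, d in net.edges(data=True):
            g.add_edge(a, b, **{k: v for k, v in d.items() if v is not None})
        nx.write_graphml(g, path)
    elif fmt == "tsv":
        erows = [{"id_a": min(a, b), "id_b": max(a, b), **d}
                 for a, b, d in net.edges(data=True)]
        edf = pd.DataFrame(erows, columns=_EDGE_COLS).sort_values(
            ["id_a", "id_b"]) if erows else pd.DataFrame(columns=_EDGE_COLS)
        edf.to_csv(f"{path}.edges.tsv", sep="\t", index=False)
        nrows = [{"node_id": n, **d} for n, d in sorted(net.nodes(data=True))]
        ndf = pd.DataFrame(nrows, columns=_NODE_COLS) if nrows else \
            pd.DataFrame(columns=_NODE_COLS)
        ndf.to_csv(f"{path}.nodes.tsv", sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_network_tsv(path) -> nx.Graph:
    """Rebuild a network from the TSV pair written by :func:`export_network`."""
    edf = pd.read_csv(f"{path}.edges.tsv", sep="\t")
    ndf = pd.read_csv(f"{path}.nodes.tsv", sep="\t")
    net = nx.Graph()
    for row in ndf.itertuples(index=False):
        net.add_node(row.node_id, rna_type=row.rna_type,
                     direction=row.direction)
    for row in edf.itertuples(index=False):
        attrs = {c: getattr(row, c) for c in _EDGE_COLS[2:]}
        attrs = {c: v for c, v in attrs.items() if pd.notna(v)}
        for c in ("k", "K", "n", "N"):
            if c in attrs:
                attrs[c] = int(attrs[c])
        net.add_edge(row.id_a, row.id_b, **attrs)
    return net
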