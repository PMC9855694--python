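"""ceRNA network construction from correlation-filtered target pairs.

Competing-endogenous-RNA triplets couple an mRNA and an lncRNA that are
both targeted by the same miRNA: the miRNA correlates negatively with each
(rho <= -0.7, p < 0.05) and the mRNA and lncRNA correlate positively
(rho >= 0.7, p < 0.05), Spearman across the nine samples. Triplet edges are
assembled into a typed tripartite graph whose connected components are
labeled by the regulation direction of their mRNAs, with maximal-degree
nodes reported as hubs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from math import isnan

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ceranet.core import ExpressionMatrix
from ceranet.patterns import PatternCall
from ceranet.targets import TargetSite

EDGE_TYPES = ("miRNA-mRNA", "miRNA-lncRNA", "mRNA-lncRNA")


@dataclass(frozen=True)
class CorrEdge:
    """A typed, signed Spearman-correlation edge."""

    node_a: str
    type_a: str
    node_b: str
    type_b: str
    edge_type: str
    rho: float
    p: float


@dataclass(frozen=True)
class CeRNATriplet:
    mrna: str
    mirna: str
    lncrna: str
    edges: tuple[CorrEdge, CorrEdge, CorrEdge]  # miR-mRNA, miR-lncRNA, mRNA-lncRNA


@dataclass
class CeRNANetwork:
    graph: nx.Graph
    triplets: list[CeRNATriplet]
    components: list[set[str]] = field(default_factory=list)
    component_labels: list[str] = field(default_factory=list)
    hubs: list[list[str]] = field(default_factory=list)

    def node_counts(self) -> dict[str, int]:
        counts = {"mRNA": 0, "lncRNA": 0, "miRNA": 0}
        for _, d in self.graph.nodes(data=True):
            counts[d["rna_class"]] += 1
        return counts


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def _t_pvalue(rho: float, n: int) -> float:
    if abs(rho) >= 1.0 - 1e-15:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@lru_cache(maxsize=4)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.int16)


def spearman(x, y, method: str = "t") -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ranks use average ties; rho is the Pearson correlation of the rank
    vectors. ``method="t"`` (default) tests rho with the Student-t
    approximation on n-2 degrees of freedom; ``method="exact"`` enumerates
    all permutations of one vector (n <= 9) and reports the exact two-sided
    tail probability of |rho|. Constant input is undefined: (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    xr, yr = _rank(x), _rank(y)
    xc, yc = xr - xr.mean(), yr - yr.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    rho = float((xc * yc).sum() / denom)
    rho = max(-1.0, min(1.0, rho))
    if method == "t":
        return rho, _t_pvalue(rho, n)
    if method == "exact":
        if n > 9:
            raise ValueError("exact permutation p-value supported for n <= 9 only")
        perms = _perm_matrix(n)
        null = (yr[perms] - yr.mean()) @ xc / denom
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
        return rho, p
    raise ValueError(f"unknown method {method!r}")


def _rank_corr_matrix(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman rho and t-approximation p between two matrices
    sharing columns. Constant rows yield nan."""
    n = A.shape[1]
    Ar = np.apply_along_axis(_rank, 1, A) if len(A) else A
    Br = np.apply_along_axis(_rank, 1, B) if len(B) else B
    Ac = Ar - Ar.mean(axis=1, keepdims=True)
    Bc = Br - Br.mean(axis=1, keepdims=True)
    na = np.sqrt((Ac**2).sum(axis=1))
    nb = np.sqrt((Bc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Ac @ Bc.T) / np.outer(na, nb)
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = R * np.sqrt((n - 2) / (1.0 - R * R))
    P = 2.0 * stats.t.sf(np.abs(T), df=n - 2)
    P[np.abs(R) >= 1.0 - 1e-15] = 0.0
    return R, P


def _check_same_samples(exprs: dict[str, ExpressionMatrix]) -> list[str]:
    samples = None
    for cls, m in exprs.items():
        cur = set(m.samples)
        if samples is None:
            ref_cls, samples = cls, cur
        elif cur != samples:
            raise ValueError(
                f"sample sets differ between {ref_cls} and {cls} matrices"
            )
    first = next(iter(exprs.values()))
    return list(first.samples)


def build_edges(
    exprs: dict[str, ExpressionMatrix],
    targets: list[TargetSite],
    rho_neg: float = -0.7,
    rho_pos: float = 0.7,
    alpha: float = 0.05,
) -> list[CorrEdge]:
    """Correlation-filtered candidate edges of the ceRNA network.

    ``exprs`` maps RNA class to its normalized expression matrix, already
    restricted to the gene sets of interest (growth-associated sets in the
    default pipeline). miRNA-mRNA and miRNA-lncRNA candidates are the
    predicted target pairs; mRNA-lncRNA candidates are pairs sharing at
    least one common targeting miRNA. Edges are kept when Spearman rho
    passes the signed threshold (<= rho_neg for miRNA edges, >= rho_pos for
    the mRNA-lncRNA edge) with p < alpha.
    """
    samples = _check_same_samples(exprs)
    mats = {cls: m.values[samples] for cls, m in exprs.items()}

    mrna_targets: dict[str, set[str]] = {}
    lnc_targets: dict[str, set[str]] = {}
    for site in targets:
        if site.mirna_id not in mats["miRNA"].index:
            continue
        if site.transcript_id in mats["mRNA"].index:
            mrna_targets.setdefault(site.mirna_id, set()).add(site.transcript_id)
        elif site.transcript_id in mats["lncRNA"].index:
            lnc_targets.setdefault(site.mirna_id, set()).add(site.transcript_id)

    edges: list[CorrEdge] = []

    def corr(cls_a, gid_a, cls_b, gid_b):
        return spearman(
            mats[cls_a].loc[gid_a].to_numpy(), mats[cls_b].loc[gid_b].to_numpy()
        )

    for mir in sorted(set(mrna_targets) | set(lnc_targets)):
        for cls, pool, etype in (
            ("mRNA", mrna_targets, "miRNA-mRNA"),
            ("lncRNA", lnc_targets, "miRNA-lncRNA"),
        ):
            for gid in sorted(pool.get(mir, ())):
                rho, p = corr("miRNA", mir, cls, gid)
                if not isnan(rho) and rho <= rho_neg and p < alpha:
                    edges.append(CorrEdge(mir, "miRNA", gid, cls, etype, rho, p))

    pair_mirnas: dict[tuple[str, str], set[str]] = {}
    for mir in sorted(set(mrna_targets) & set(lnc_targets)):
        for m_id in mrna_targets[mir]:
            for l_id in lnc_targets[mir]:
                pair_mirnas.setdefault((m_id, l_id), set()).add(mir)
    for (m_id, l_id) in sorted(pair_mirnas):
        rho, p = corr("mRNA", m_id, "lncRNA", l_id)
        if not isnan(rho) and rho >= rho_pos and p < alpha:
            edges.append(CorrEdge(m_id, "mRNA", l_id, "lncRNA", "mRNA-lncRNA", rho, p))
    return edges


def assemble_network(
    edges: list[CorrEdge], patterns: list[PatternCall]
) -> CeRNANetwork:
    """Enumerate ceRNA triplets and assemble the component-labeled network.

    A triplet (mRNA, miRNA, lncRNA) requires all three of its edges. The
    network is the union of triplet edges; each connected component is
    labeled upregulated / downregulated / mixed from the regulation
    directions of its mRNAs, and its maximal-degree nodes (all ties) are
    reported as hubs.
    """
    direction = {(c.rna_class, c.gene): c.direction for c in patterns}

    mir_m: dict[str, set[str]] = {}
    mir_l: dict[str, set[str]] = {}
    ml: dict[tuple[str, str], CorrEdge] = {}
    by_pair: dict[tuple[str, str], CorrEdge] = {}
    for e in edges:
        by_pair[(e.node_a, e.node_b)] = e
        if e.edge_type == "miRNA-mRNA":
            mir_m.setdefault(e.node_a, set()).add(e.node_b)
        elif e.edge_type == "miRNA-lncRNA":
            mir_l.setdefault(e.node_a, set()).add(e.node_b)
        elif e.edge_type == "mRNA-lncRNA":
            ml[(e.node_a, e.node_b)] = e

    triplets: list[CeRNATriplet] = []
    graph = nx.Graph()
    for mir in sorted(set(mir_m) & set(mir_l)):
        for m_id in sorted(mir_m[mir]):
            for l_id in sorted(mir_l[mir]):
                if (m_id, l_id) not in ml:
                    continue
                trip = CeRNATriplet(
                    m_id,
                    mir,
                    l_id,
                    (by_pair[(mir, m_id)], by_pair[(mir, l_id)], ml[(m_id, l_id)]),
                )
                triplets.append(trip)
                for node, cls in ((m_id, "mRNA"), (mir, "miRNA"), (l_id, "lncRNA")):
                    if (cls, node) not in direction:
                        raise ValueError(
                            f"no regulation direction known for {cls} node {node!r}"
                        )
                    graph.add_node(node, rna_class=cls, direction=direction[(cls, node)])
                for e in trip.edges:
                    graph.add_edge(
                        e.node_a, e.node_b, edge_type=e.edge_type, rho=e.rho, p=e.p
                    )

    net = CeRNANetwork(graph=graph, triplets=triplets)
    for comp in sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0]):
        dirs = {
            graph.nodes[v]["direction"]
            for v in comp
            if graph.nodes[v]["rna_class"] == "mRNA"
        }
        if dirs == {"up"}:
            label = "upregulated"
        elif dirs == {"down"}:
            label = "downregulated"
        else:
            label = "mixed"
        degmax = max(graph.degree(v) for v in comp)
        hubs = sorted(v for v in comp if graph.degree(v) == degmax)
        net.components.append(set(comp))
        net.component_labels.append(label)
        net.hubs.append(hubs)
    return net


def correlation_target_sets(
    exprs: dict[str, ExpressionMatrix],
    targets: list[TargetSite],
    rho_min: float = 0.7,
    alpha: float = 0.05,
    mirna_mode: str = "absolute",
) -> dict[str, dict[str, set[str]]]:
    """Correlation-defined target gene sets for miRNA/lncRNA enrichment.

    A miRNA's set holds mRNAs with at least one predicted binding site whose
    expression correlation passes ``mirna_mode``: "positive" (rho >=
    rho_min), "negative" (rho <= -rho_min) or "absolute" (|rho| >= rho_min),
    always with p < alpha. An lncRNA's set holds all mRNAs with rho >=
    rho_min and p < alpha; no targeting relationship is required.
    """
    if mirna_mode not in ("positive", "negative", "absolute"):
        raise ValueError(f"unknown mirna_mode {mirna_mode!r}")
    samples = _check_same_samples(exprs)
    m_mat = exprs["mRNA"].values[samples]
    mrna_ids = list(m_mat.index)

    out: dict[str, dict[str, set[str]]] = {"miRNA": {}, "lncRNA": {}}

    mir_mat = exprs["miRNA"].values[samples]
    R, P = _rank_corr_matrix(mir_mat.to_numpy(float), m_mat.to_numpy(float))
    targeted: dict[str, set[str]] = {}
    for site in targets:
        if site.mirna_id in mir_mat.index and site.transcript_id in m_mat.index:
            targeted.setdefault(site.mirna_id, set()).add(site.transcript_id)
    mcol = {g: i for i, g in enumerate(mrna_ids)}
    for i, mir in enumerate(mir_mat.index):
        hits = set()
        for g in targeted.get(mir, ()):
            rho, p = R[i, mcol[g]], P[i, mcol[g]]
            if np.isnan(rho) or p >= alpha:
                continue
            ok = (
                rho >= rho_min
                if mirna_mode == "positive"
                else rho <= -rho_min
                if mirna_mode == "negative"
                else abs(rho) >= rho_min
            )
            if ok:
                hits.add(g)
        out["miRNA"][mir] = hits

    lnc_mat = exprs["lncRNA"].values[samples]
    R, P = _rank_corr_matrix(lnc_mat.to_numpy(float), m_mat.to_numpy(float))
    keep = (~np.isnan(R)) & (R >= rho_min) & (P < alpha)
    for i, lnc in enumerate(lnc_mat.index):
        out["lncRNA"][lnc] = {mrna_ids[j] for j in np.nonzero(keep[i])[0]}
    return out


def filter_ppi(
    interactions: pd.DataFrame,
    min_score: float = 0.4,
    genes=None,
) -> pd.DataFrame:
    """Keep protein-interaction rows with combined score strictly above
    ``min_score``, optionally restricted to a gene set (both endpoints)."""
    required = {"gene_a", "gene_b", "combined_score"}
    missing = required - set(interactions.columns)
    if missing:
        raise ValueError(f"interaction table missing column(s) {sorted(missing)}")
    scores = interactions["combined_score"].to_numpy(dtype=float)
    if len(scores) and (np.nanmin(scores) < 0 or np.nanmax(scores) > 1):
        raise ValueError("combined_score values must lie in [0, 1]")
    kept = interactions[scores > min_score]
    if genes is not None:
        gset = set(genes)
        kept = kept[kept["gene_a"].isin(gset) & kept["gene_b"].isin(gset)]
    return kept.reset_index(drop=True)


def edges_to_frame(edges: list[CorrEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "node_a": e.node_a,
                "type_a": e.type_a,
                "node_b": e.node_b,
                "type_b": e.type_b,
                "edge_type": e.edge_type,
                "rho": e.rho,
                "p": e.p,
            }
            for e in edges
        ],
        columns=["node_a", "type_a", "node_b", "type_b", "edge_type", "rho", "p"],
    )


def triplets_to_frame(triplets: list[CeRNATriplet]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mRNA": t.mrna,
                "miRNA": t.mirna,
                "lncRNA": t.lncrna,
                "rho_mir_mrna": t.edges[0].rho,
                "rho_mir_lncrna": t.edges[1].rho,
                "rho_mrna_lncrna": t.edges[2].rho,
            }
            for t in triplets
        ],
        columns=[
            "mRNA",
            "miRNA",
            "lncRNA",
            "rho_mir_mrna",
            "rho_mir_lncrna",
            "rho_mrna_lncrna",
        ],
    )
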