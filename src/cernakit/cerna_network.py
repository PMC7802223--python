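"""Correlation screening, the shared-sponge hypergeometric test, and
assembly of the tripartite ceRNA network.

The three retained-edge kinds are:

* circRNA-miRNA and miRNA-mRNA: targeting pairs whose Spearman rank
  correlation across all samples is strictly below ``scc_threshold``;
* circRNA-mRNA: pairs sharing >= 1 such miRNA, with Pearson correlation
  strictly above ``pcc_threshold`` and a significant upper-tail
  hypergeometric test on the overlap of their miRNA-regulator sets.

A triad is any (circRNA, miRNA, mRNA) triple whose three supporting edges
are all retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence  # noqa: F401

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .de_analysis import DERecord, bh_fdr
from .errors import ConstantVectorError, InputError
from .target_prediction import TargetEdge

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationEdge",
    "SpongeTestResult",
    "CeRNATriad",
    "CeRNANetwork",
    "spearman_scc",
    "pearson_pcc",
    "negative_pairs",
    "coexpressed_pairs",
    "hypergeom_sf",
    "sponge_test",
    "build_network",
    "extract_subnetwork",
]


@dataclass(frozen=True)
class CorrelationEdge:
    """A feature pair with its correlation statistic."""

    id_a: str
    id_b: str
    class_a: str
    class_b: str
    method: str
    coefficient: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise InputError("self-correlation edge")
        if self.method not in ("spearman", "pearson"):
            raise InputError(f"unknown correlation method {self.method!r}")
        if not -1.0 <= self.coefficient <= 1.0:
            raise InputError("correlation outside [-1, 1]")
        if self.n_samples < 3:
            raise InputError("correlation needs >= 3 samples")


@dataclass(frozen=True)
class SpongeTestResult:
    """Hypergeometric upper-tail test of shared miRNA regulators."""

    circ_id: str
    mrna_id: str
    shared_mirnas: frozenset[str]
    k: int
    K: int
    n: int
    N: int
    p_value: float

    def __post_init__(self) -> None:
        if self.k != len(self.shared_mirnas):
            raise InputError("k must equal |shared_mirnas|")
        if self.k > min(self.K, self.n) or max(self.K, self.n) > self.N:
            raise InputError("hypergeometric parameters out of range")


@dataclass(frozen=True)
class CeRNATriad:
    """A fully supported circRNA-miRNA-mRNA triple."""

    circ_id: str
    mirna_id: str
    mrna_id: str
    scc_circ_mirna: float
    scc_mirna_mrna: float
    pcc_circ_mrna: float
    sponge_p: float

    def __post_init__(self) -> None:
        if not (self.scc_circ_mirna < -0.7 and self.scc_mirna_mrna < -0.7):
            raise InputError("triad SCC support out of contract")
        if not self.pcc_circ_mrna > 0.9:
            raise InputError("triad PCC support out of contract")
        if not self.sponge_p < 0.05:
            raise InputError("triad sponge support out of contract")


@dataclass
class CeRNANetwork:
    """Typed tripartite graph plus its fully supported triads.

    Node attributes: ``rna_class``, ``log2fc``, ``direction``.
    Edge attributes: ``kind`` in {``circ-miRNA``, ``miRNA-mRNA``,
    ``circ-mRNA``}, ``coefficient`` (correlation edges), ``sponge_p``
    (circ-mRNA edges).
    """

    graph: nx.Graph
    triads: list[CeRNATriad] = field(default_factory=list)

    def node_ids(self, rna_class: str | None = None) -> list[str]:
        return sorted(
            n
            for n, d in self.graph.nodes(data=True)
            if rna_class is None or d["rna_class"] == rna_class
        )


def _check_vectors(x, y) -> tuple[np.ndarray, np.ndarray]:
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.ndim != 1 or yv.ndim != 1 or xv.size != yv.size:
        raise InputError("correlation needs two equal-length 1-D vectors")
    if xv.size < 3:
        raise InputError("correlation needs length >= 3")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    return xv, yv


def spearman_scc(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    xv, yv = _check_vectors(x, y)
    rx = stats.rankdata(xv, method="average")
    ry = stats.rankdata(yv, method="average")
    return float(np.clip(np.corrcoef(rx, ry)[0, 1], -1.0, 1.0))


def pearson_pcc(x, y) -> float:
    """Standard product-moment correlation."""
    xv, yv = _check_vectors(x, y)
    return float(np.clip(np.corrcoef(xv, yv)[0, 1], -1.0, 1.0))


def negative_pairs(
    log_expr: pd.DataFrame,
    target_edges: Sequence[TargetEdge],
    scc_threshold: float = -0.7,
    de_ids: Iterable[str] | None = None,
) -> list[CorrelationEdge]:
    """Targeting pairs with SCC strictly below ``scc_threshold``.

    ``log_expr`` holds log-scale expression for every referenced feature
    (rows) across the same samples (columns). Pairs with an undefined
    (constant-vector) correlation are excluded and counted in the log.
    """
    allowed = set(de_ids) if de_ids is not None else None
    kept: list[CorrelationEdge] = []
    n_excluded = 0
    for edge in sorted(target_edges, key=lambda e: (e.mirna_id, e.target_id)):
        for fid in (edge.mirna_id, edge.target_id):
            if fid not in log_expr.index:
                raise InputError(f"feature {fid!r} missing from expression matrix")
        if allowed is not None and (
            edge.mirna_id not in allowed or edge.target_id not in allowed
        ):
            continue
        x = log_expr.loc[edge.mirna_id].to_numpy()
        y = log_expr.loc[edge.target_id].to_numpy()
        try:
            scc = spearman_scc(x, y)
        except ConstantVectorError:
            n_excluded += 1
            continue
        if scc < scc_threshold:
            kept.append(
                CorrelationEdge(
                    id_a=edge.mirna_id,
                    id_b=edge.target_id,
                    class_a="miRNA",
                    class_b=edge.target_class,
                    method="spearman",
                    coefficient=scc,
                    n_samples=x.size,
                )
            )
    if n_excluded:
        logger.info("negative_pairs: %d pairs excluded (zero variance)", n_excluded)
    return kept


def _partners_by_mirna(
    negative_edges: Sequence[CorrelationEdge],
) -> dict[str, dict[str, set[str]]]:
    """miRNA id -> {'circRNA': partner ids, 'mRNA': partner ids}."""
    out: dict[str, dict[str, set[str]]] = {}
    for e in negative_edges:
        out.setdefault(e.id_a, {"circRNA": set(), "mRNA": set()})[e.class_b].add(
            e.id_b
        )
    return out


def coexpressed_pairs(
    log_expr: pd.DataFrame,
    negative_edges: Sequence[CorrelationEdge],
    pcc_threshold: float = 0.9,
) -> list[CorrelationEdge]:
    """circRNA-mRNA pairs sharing a negatively coexpressed miRNA, with PCC
    strictly above ``pcc_threshold``."""
    partners = _partners_by_mirna(negative_edges)
    candidates: set[tuple[str, str]] = set()
    for sets in partners.values():
        for c in sets["circRNA"]:
            for m in sets["mRNA"]:
                candidates.add((c, m))
    kept: list[CorrelationEdge] = []
    n_excluded = 0
    for circ_id, mrna_id in sorted(candidates):
        for fid in (circ_id, mrna_id):
            if fid not in log_expr.index:
                raise InputError(f"feature {fid!r} missing from expression matrix")
        x = log_expr.loc[circ_id].to_numpy()
        y = log_expr.loc[mrna_id].to_numpy()
        try:
            pcc = pearson_pcc(x, y)
        except ConstantVectorError:
            n_excluded += 1
            continue
        if pcc > pcc_threshold:
            kept.append(
                CorrelationEdge(
                    id_a=circ_id,
                    id_b=mrna_id,
                    class_a="circRNA",
                    class_b="mRNA",
                    method="pearson",
                    coefficient=pcc,
                    n_samples=x.size,
                )
            )
    if n_excluded:
        logger.info(
            "coexpressed_pairs: %d pairs excluded (zero variance)", n_excluded
        )
    return kept


def hypergeom_sf(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the overlap when ``n`` items are drawn without replacement from
    a universe of ``N`` containing ``K`` marked items. Evaluated via the
    log-space survival function of the hypergeometric distribution; exact to
    floating precision for small arguments. k = 0 returns exactly 1.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v:
            raise InputError(f"{name} must be an integer")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if N < 0 or K < 0 or n < 0 or K > N or n > N:
        raise InputError("require 0 <= K, n <= N")
    if k < 0 or k > min(K, n):
        raise InputError("require 0 <= k <= min(K, n)")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def sponge_test(
    circ_id: str,
    mrna_id: str,
    mirnas_targeting_circ: Iterable[str],
    mirnas_targeting_mrna: Iterable[str],
    universe: Iterable[str],
) -> SpongeTestResult:
    """Shared-regulator significance for one circRNA-mRNA pair."""
    set_c = frozenset(mirnas_targeting_circ)
    set_m = frozenset(mirnas_targeting_mrna)
    uni = frozenset(universe)
    if not set_c <= uni or not set_m <= uni:
        raise InputError("target sets must be subsets of the universe")
    shared = set_c & set_m
    k, K, n, N = len(shared), len(set_c), len(set_m), len(uni)
    return SpongeTestResult(
        circ_id=circ_id,
        mrna_id=mrna_id,
        shared_mirnas=shared,
        k=k,
        K=K,
        n=n,
        N=N,
        p_value=hypergeom_sf(k, K, n, N),
    )


def build_network(
    negative_edges: Sequence[CorrelationEdge],
    coexpressed_edges: Sequence[CorrelationEdge],
    sponge_results: Sequence[SpongeTestResult],
    de_records: Mapping[str, DERecord],
    sponge_p_cutoff: float = 0.05,
    sponge_bh: bool = False,
) -> CeRNANetwork:
    """Assemble the tripartite network and enumerate its triads.

    circRNA-mRNA edges are retained only when their sponge test (optionally
    BH-adjusted across all tested pairs) is strictly below the cutoff.
    Nodes are exactly the endpoints of retained edges; ordering of all
    outputs is lexicographic.
    """
    sponge_p = {(r.circ_id, r.mrna_id): r.p_value for r in sponge_results}
    if sponge_bh and sponge_results:
        pairs = sorted(sponge_p)
        adjusted = bh_fdr([sponge_p[pr] for pr in pairs])
        sponge_p = {pr: float(q) for pr, q in zip(pairs, adjusted)}

    g = nx.Graph()
    scc_lookup: dict[tuple[str, str], float] = {}
    retained_edges: list[tuple[str, str, dict]] = []
    for e in negative_edges:
        kind = "circ-miRNA" if e.class_b == "circRNA" else "miRNA-mRNA"
        scc_lookup[(e.id_a, e.id_b)] = e.coefficient
        retained_edges.append(
            (e.id_a, e.id_b, {"kind": kind, "coefficient": e.coefficient})
        )
    pcc_lookup: dict[tuple[str, str], float] = {}
    retained_pairs: set[tuple[str, str]] = set()
    for e in coexpressed_edges:
        key = (e.id_a, e.id_b)
        if key not in sponge_p:
            raise InputError(f"no sponge test for pair {key}")
        p = sponge_p[key]
        if p < sponge_p_cutoff:
            pcc_lookup[key] = e.coefficient
            retained_pairs.add(key)
            retained_edges.append(
                (
                    e.id_a,
                    e.id_b,
                    {"kind": "circ-mRNA", "coefficient": e.coefficient, "sponge_p": p},
                )
            )

    node_ids = sorted({u for u, _, _ in retained_edges} | {v for _, v, _ in retained_edges})
    for nid in node_ids:
        if nid not in de_records:
            raise InputError(f"node {nid!r} missing from DE records")
        rec = de_records[nid]
        g.add_node(
            nid, rna_class=rec.rna_class, log2fc=rec.log2fc, direction=rec.direction
        )
    for u, v, attrs in sorted(retained_edges, key=lambda t: (t[0], t[1])):
        g.add_edge(u, v, **attrs)

    partners = _partners_by_mirna(list(negative_edges))
    triads: list[CeRNATriad] = []
    for circ_id, mrna_id in sorted(retained_pairs):
        for mirna_id in sorted(
            {
                m
                for m, sets in partners.items()
                if circ_id in sets["circRNA"] and mrna_id in sets["mRNA"]
            }
        ):
            triads.append(
                CeRNATriad(
                    circ_id=circ_id,
                    mirna_id=mirna_id,
                    mrna_id=mrna_id,
                    scc_circ_mirna=scc_lookup[(mirna_id, circ_id)],
                    scc_mirna_mrna=scc_lookup[(mirna_id, mrna_id)],
                    pcc_circ_mrna=pcc_lookup[(circ_id, mrna_id)],
                    sponge_p=sponge_p[(circ_id, mrna_id)],
                )
            )
    triads.sort(key=lambda t: (t.circ_id, t.mirna_id, t.mrna_id))
    return CeRNANetwork(graph=g, triads=triads)


def extract_subnetwork(
    network: CeRNANetwork, focal_id: str, radius: int = 1
) -> CeRNANetwork:
    """Induced subgraph within graph distance ``radius`` of ``focal_id``,
    keeping only triads fully contained in it."""
    if focal_id not in network.graph:
        raise KeyError(f"unknown focal id {focal_id!r}")
    if radius < 0:
        raise InputError("radius must be non-negative")
    sub = nx.ego_graph(network.graph, focal_id, radius=radius)
    kept_nodes = set(sub.nodes)
    triads = [
        t
        for t in network.triads
        if {t.circ_id, t.mirna_id, t.mrna_id} <= kept_nodes
    ]
    return CeRNANetwork(graph=nx.Graph(sub), triads=triads)
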