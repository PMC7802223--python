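"""Over-representation analysis of a feature list against gene sets."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .cerna_network import hypergeom_sf
from .de_analysis import bh_fdr
from .errors import InputError

__all__ = ["GeneSet", "GeneSetCollection", "EnrichmentRecord", "over_representation"]


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise InputError(f"gene set {self.term_id!r} is empty")


@dataclass
class GeneSetCollection:
    """A keyed collection of gene sets (e.g. parsed from a GMT file)."""

    sets: dict[str, GeneSet]
    source: str = ""

    def __post_init__(self) -> None:
        for term_id, gs in self.sets.items():
            if term_id != gs.term_id:
                raise InputError(f"key {term_id!r} does not match set id {gs.term_id!r}")

    @classmethod
    def from_items(
        cls, items: Iterable[tuple[str, str, Iterable[str]]], source: str = ""
    ) -> "GeneSetCollection":
        sets: dict[str, GeneSet] = {}
        for term_id, name, members in items:
            if term_id in sets:
                raise InputError(f"duplicate term id {term_id!r}")
            sets[term_id] = GeneSet(term_id, name, frozenset(members))
        return cls(sets=sets, source=source)


@dataclass(frozen=True)
class EnrichmentRecord:
    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise InputError("hits exceed term or query size")


def over_representation(
    query: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
) -> list[EnrichmentRecord]:
    """Hypergeometric upper-tail enrichment of ``query`` against each term.

    Term membership is intersected with the universe before testing; BH
    adjustment runs across all tested terms. Records are sorted by
    (p, term id).
    """
    query_set = frozenset(query)
    uni = frozenset(universe)
    if not uni:
        raise InputError("universe must be non-empty")
    if not query_set <= uni:
        stray = sorted(query_set - uni)[0]
        raise InputError(f"query id {stray!r} not in universe")
    n, N = len(query_set), len(uni)
    rows = []
    for term_id in sorted(collection.sets):
        gs = collection.sets[term_id]
        members = gs.members & uni
        k = len(members & query_set)
        K = len(members)
        p = hypergeom_sf(k, K, n, N)
        rows.append((term_id, gs.term_name, k, K, p))
    if not rows:
        return []
    qvals = bh_fdr([r[4] for r in rows])
    records = [
        EnrichmentRecord(
            term_id=tid, term_name=name, k=k, K=K, n=n, N=N,
            p_value=float(p), q_value=float(q),
        )
        for (tid, name, k, K, p), q in zip(rows, qvals)
    ]
    records.sort(key=lambda r: (r.p_value, r.term_id))
    return records


def enrichment_table(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in records],
            "term_name": [r.term_name for r in records],
            "k": [r.k for r in records],
            "K": [r.K for r in records],
            "n": [r.n for r in records],
            "N": [r.N for r in records],
            "pvalue": [r.p_value for r in records],
            "qvalue": [r.q_value for r in records],
        }
    )
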