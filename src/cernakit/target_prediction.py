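"""Canonical seed-match assignment of miRNA -> target edges.

Site classes follow the standard seed taxonomy. Writing the target 5'->3',
a site is anchored on a perfect Watson-Crick match to the reverse
complement of miRNA nucleotides 2-7 (the 6mer core). Supplementing the core
with a match to nucleotide 8 on its 5' side and/or an adenosine opposite
nucleotide 1 on its 3' side upgrades it:

    6mer      core only                              length 6
    7mer-A1   core + A opposite position 1           length 7
    7mer-m8   core + match to position 8             length 7
    8mer      both extensions                        length 8
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import InputError

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
SITE_RANK: Mapping[str, int] = {t: i for i, t in enumerate(SITE_TYPES)}
SITE_LENGTH: Mapping[str, int] = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}

_RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

__all__ = [
    "SITE_TYPES",
    "SITE_RANK",
    "SITE_LENGTH",
    "SeqRecord",
    "TargetSite",
    "TargetEdge",
    "normalize_rna",
    "reverse_complement",
    "site_string",
    "find_seed_sites",
    "predict_targets",
]


def normalize_rna(sequence: str) -> str:
    """Upper-case, DNA 'T' rewritten to 'U'; rejects other characters."""
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - _RNA_ALPHABET
    if bad:
        raise InputError(f"illegal characters in sequence: {sorted(bad)}")
    return seq


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class SeqRecord:
    """An RNA sequence with an id and an RNA-class tag."""

    id: str
    rna_class: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.rna_class not in ("miRNA", "circRNA", "mRNA"):
            raise InputError(f"unknown rna_class {self.rna_class!r}")
        self.sequence = normalize_rna(self.sequence)
        if not self.sequence:
            raise InputError(f"record {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class TargetSite:
    """One seed-match locus on a target, 0-based half-open coordinates."""

    mirna_id: str
    target_id: str
    site_type: str
    start: int
    length: int

    def __post_init__(self) -> None:
        if self.site_type not in SITE_RANK:
            raise InputError(f"unknown site type {self.site_type!r}")
        if self.length != SITE_LENGTH[self.site_type]:
            raise InputError("site length inconsistent with its type")
        if self.start < 0:
            raise InputError("site start must be non-negative")

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class TargetEdge:
    """A miRNA -> target relationship supported by >= 1 seed site."""

    mirna_id: str
    target_id: str
    target_class: str
    best_site_type: str
    n_sites: int

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise InputError("an edge needs at least one site")
        if self.best_site_type not in SITE_RANK:
            raise InputError(f"unknown site type {self.best_site_type!r}")


def site_string(mirna_seq: str, site_type: str) -> str:
    """The exact target-strand string a site of the given type occupies."""
    m = normalize_rna(mirna_seq)
    if len(m) < 8:
        raise InputError("miRNA must be at least 8 nt")
    core = reverse_complement(m[1:7])
    m8 = m[7].translate(_COMPLEMENT)
    if site_type == "6mer":
        return core
    if site_type == "7mer-A1":
        return core + "A"
    if site_type == "7mer-m8":
        return m8 + core
    if site_type == "8mer":
        return m8 + core + "A"
    raise InputError(f"unknown site type {site_type!r}")


def find_seed_sites(mirna: SeqRecord, target: SeqRecord) -> list[TargetSite]:
    """All seed-match sites of ``mirna`` on ``target``.

    Each 6mer-core locus yields exactly one site, classified as the maximal
    type its flanks support. Coordinates are on the target as given; no
    strand logic is applied.
    """
    m = mirna.sequence
    if len(m) < 8:
        raise InputError(f"miRNA {mirna.id!r} is shorter than 8 nt")
    t = target.sequence
    core = reverse_complement(m[1:7])
    m8 = m[7].translate(_COMPLEMENT)
    sites: list[TargetSite] = []
    i = t.find(core)
    while i != -1:
        has_m8 = i >= 1 and t[i - 1] == m8
        has_a1 = i + 6 < len(t) and t[i + 6] == "A"
        if has_m8 and has_a1:
            stype, start = "8mer", i - 1
        elif has_m8:
            stype, start = "7mer-m8", i - 1
        elif has_a1:
            stype, start = "7mer-A1", i
        else:
            stype, start = "6mer", i
        sites.append(
            TargetSite(
                mirna_id=mirna.id,
                target_id=target.id,
                site_type=stype,
                start=start,
                length=SITE_LENGTH[stype],
            )
        )
        i = t.find(core, i + 1)
    return sites


def _circularized(record: SeqRecord) -> SeqRecord:
    """Append the first 7 nt so back-splice-spanning sites become visible."""
    return SeqRecord(
        id=record.id,
        rna_class=record.rna_class,
        sequence=record.sequence + record.sequence[:7],
        description=record.description,
    )


def predict_targets(
    mirnas: Sequence[SeqRecord],
    targets: Sequence[SeqRecord],
    min_site_type: str = "7mer-A1",
    restrict_to: Iterable[str] | None = None,
    circular_scan: bool = False,
) -> tuple[list[TargetEdge], list[TargetSite]]:
    """Edges for every (miRNA, target) pair with >= 1 site of sufficient type.

    ``restrict_to`` limits both miRNAs and targets to the given id set (the
    differential-expression gate). ``circular_scan`` additionally scans
    circRNA sequences across the back-splice junction. Returns the edge list
    plus all qualifying sites, both in deterministic lexicographic order.
    """
    if min_site_type not in SITE_RANK:
        raise InputError(f"unknown site type {min_site_type!r}")
    ids = [r.id for r in mirnas] + [r.id for r in targets]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        for x in ids:
            if x in seen:
                raise InputError(f"duplicate id across inputs: {x!r}")
            seen.add(x)
    allowed = set(restrict_to) if restrict_to is not None else None
    min_rank = SITE_RANK[min_site_type]
    edges: list[TargetEdge] = []
    all_sites: list[TargetSite] = []
    for mi in sorted(mirnas, key=lambda r: r.id):
        if allowed is not None and mi.id not in allowed:
            continue
        for tg in sorted(targets, key=lambda r: r.id):
            if allowed is not None and tg.id not in allowed:
                continue
            scan_tg = tg
            if circular_scan and tg.rna_class == "circRNA":
                scan_tg = _circularized(tg)
            sites = [
                s
                for s in find_seed_sites(mi, scan_tg)
                if SITE_RANK[s.site_type] >= min_rank
            ]
            if not sites:
                continue
            best = max(sites, key=lambda s: SITE_RANK[s.site_type])
            edges.append(
                TargetEdge(
                    mirna_id=mi.id,
                    target_id=tg.id,
                    target_class=tg.rna_class,
                    best_site_type=best.site_type,
                    n_sites=len(sites),
                )
            )
            all_sites.extend(sites)
    return edges, all_sites
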