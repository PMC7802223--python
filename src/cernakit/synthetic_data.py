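"""Synthetic two-group count data with planted sponge triads.

The generator emits negative-binomial count matrices for the three RNA
classes, mature-miRNA and target sequences, and the ground truth needed to
verify the whole inference pipeline at desk scale:

* planted differentially expressed features in every class (a pure group
  shift on the mean);
* planted triads driven by a latent per-sample "stress" factor: the triad's
  circRNA and mRNA move with the factor and its miRNA moves against it (or
  the mirror image), so on log expression SCC(miRNA, circRNA) and
  SCC(miRNA, mRNA) approach -1 and PCC(circRNA, mRNA) approaches +1 as
  coupling grows and dispersion shrinks;
* planted seed-complementary sites realizing every ground-truth
  miRNA -> target edge, including decoy edges between same-direction DE
  features, which pass the targeting stage but must be rejected by the
  negative-correlation filter;
* optional scrubbing of accidental seed matches so that the realized
  targeting relation equals the ground truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .de_analysis import CountMatrix
from .errors import ConfigurationError, InputError
from .target_prediction import (
    SITE_LENGTH,
    SITE_TYPES,
    SeqRecord,
    normalize_rna,
    predict_targets,
    site_string,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_dataset",
    "plant_seed_sites",
    "write_fixture",
    "read_fixture",
]

_BASES = np.array(list("ACGU"))


@dataclass
class SimulationConfig:
    """All knobs of the generator; identical configs give identical data."""

    n_per_group: int = 3
    n_circ: int = 200
    n_mirna: int = 100
    n_mrna: int = 500
    baseline_mean_range: tuple[float, float] = (2000.0, 8000.0)
    nb_dispersion: float = 0.002
    n_de_per_class: int = 40
    de_log2fc: float = 3.0
    n_triads: int = 10
    triad_coupling: float = 1.0
    n_decoys: int = 25
    latent_sd: float = 0.08
    mirna_length_range: tuple[int, int] = (20, 24)
    target_length_range: tuple[int, int] = (200, 400)
    planted_site_type: str = "8mer"
    scrub_background: bool = True
    seed: int = 0
    group_labels: tuple[str, str] = ("CG", "HS")

    def __post_init__(self) -> None:
        def fail(fieldname: str, why: str) -> None:
            raise ConfigurationError(f"{fieldname}: {why}")

        if self.n_per_group < 2:
            fail("n_per_group", "need at least 2 samples per group")
        for name in ("n_circ", "n_mirna", "n_mrna"):
            if getattr(self, name) < 1:
                fail(name, "must be positive")
        lo, hi = self.baseline_mean_range
        if not (0 < lo <= hi):
            fail("baseline_mean_range", "need 0 < low <= high")
        if self.nb_dispersion < 0:
            fail("nb_dispersion", "must be non-negative")
        n_min = min(self.n_circ, self.n_mirna, self.n_mrna)
        if not 0 <= self.n_de_per_class <= n_min:
            fail("n_de_per_class", "must lie in [0, min class size]")
        if self.de_log2fc <= 0:
            fail("de_log2fc", "must be positive")
        if not 0 <= self.n_triads <= n_min:
            fail("n_triads", "must lie in [0, min class size]")
        if self.n_triads > self.n_de_per_class:
            fail("n_triads", "planted triad members must be differentially expressed")
        if not 0 < self.triad_coupling <= 1:
            fail("triad_coupling", "must lie in (0, 1]")
        if self.n_decoys < 0:
            fail("n_decoys", "must be non-negative")
        if self.n_decoys > self.n_de_per_class - self.n_triads:
            fail("n_decoys", "not enough non-triad DE miRNAs for distinct decoys")
        if self.n_decoys > 2 * (self.n_de_per_class - self.n_triads):
            fail("n_decoys", "not enough non-triad DE targets")
        if self.latent_sd < 0:
            fail("latent_sd", "must be non-negative")
        if self.mirna_length_range[0] < 8:
            fail("mirna_length_range", "miRNAs must be at least 8 nt")
        if self.mirna_length_range[0] > self.mirna_length_range[1]:
            fail("mirna_length_range", "low must not exceed high")
        if self.target_length_range[0] < 30:
            fail("target_length_range", "targets must be at least 30 nt")
        if self.target_length_range[0] > self.target_length_range[1]:
            fail("target_length_range", "low must not exceed high")
        if self.planted_site_type not in SITE_TYPES:
            fail("planted_site_type", f"must be one of {SITE_TYPES}")
        if len(set(self.group_labels)) != 2 or not all(self.group_labels):
            fail("group_labels", "need two distinct non-empty labels")


@dataclass
class GroundTruth:
    """What the pipeline is supposed to rediscover."""

    de_features: dict[str, list[tuple[str, str]]]
    target_edges: list[tuple[str, str, str]]
    triads: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        de_ids = {
            cls: {fid for fid, _ in feats} for cls, feats in self.de_features.items()
        }
        edge_pairs = {(m, t) for m, t, _ in self.target_edges}
        for circ, mirna, mrna in self.triads:
            if (
                circ not in de_ids.get("circRNA", set())
                or mirna not in de_ids.get("miRNA", set())
                or mrna not in de_ids.get("mRNA", set())
            ):
                raise InputError(f"triad ({circ},{mirna},{mrna}) not fully DE")
            if (mirna, circ) not in edge_pairs or (mirna, mrna) not in edge_pairs:
                raise InputError(
                    f"triad ({circ},{mirna},{mrna}) missing its target edges"
                )


@dataclass
class SyntheticDataset:
    counts_circ: CountMatrix
    counts_mirna: CountMatrix
    counts_mrna: CountMatrix
    mirna_seqs: list[SeqRecord]
    target_seqs: list[SeqRecord]
    truth: GroundTruth
    config: SimulationConfig

    def __post_init__(self) -> None:
        mats = (self.counts_circ, self.counts_mirna, self.counts_mrna)
        sample_sets = {tuple(m.sample_ids) for m in mats}
        if len(sample_sets) != 1:
            raise InputError("sample ids differ across count matrices")
        group_maps = {tuple(sorted(m.group_of.items())) for m in mats}
        if len(group_maps) != 1:
            raise InputError("group labels differ across count matrices")
        seq_of = {r.id: r.sequence for r in self.target_seqs}
        mir_of = {r.id: r.sequence for r in self.mirna_seqs}
        for mirna_id, target_id, _ in self.truth.target_edges:
            core = site_string(mir_of[mirna_id], "6mer")
            if core not in seq_of[target_id]:
                raise InputError(
                    f"edge ({mirna_id},{target_id}) has no seed site in the target"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts_circ.sample_ids)


def plant_seed_sites(
    mirna_seq: str, target_seq: str, site_type: str, position: int
) -> str:
    """Overwrite ``target_seq`` at ``position`` with the exact site string a
    seed match of ``site_type`` requires; everything else is unchanged."""
    site = site_string(mirna_seq, site_type)
    target = normalize_rna(target_seq)
    if position < 0 or position + len(site) > len(target):
        raise InputError(
            f"site of length {len(site)} does not fit at position {position} "
            f"in a target of length {len(target)}"
        )
    return target[:position] + site + target[position + len(site):]


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson draw: variance = mean + dispersion * mean**2."""
    if dispersion < 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _draw_mirnas(
    rng: np.random.Generator, ids: list[str], length_range: tuple[int, int]
) -> dict[str, str]:
    """Random miRNA sequences with pairwise-distinct 6mer seed cores."""
    seqs: dict[str, str] = {}
    cores: set[str] = set()
    for mid in ids:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        for _ in range(1000):
            seq = _random_rna(rng, length)
            core = site_string(seq, "6mer")
            if core not in cores:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw a miRNA with a unique seed core")
        cores.add(core)
        seqs[mid] = seq
    return seqs


def _realize_sequences(
    rng: np.random.Generator,
    mirna_seqs: dict[str, str],
    target_lengths: dict[str, int],
    plan: Mapping[str, list[tuple[str, str]]],
    scrub: bool,
    max_iter: int = 400,
) -> tuple[dict[str, str], dict[str, str]]:
    """Random target sequences carrying exactly the planned seed sites.

    ``plan`` maps target id -> [(mirna id, site type)]. When ``scrub`` is
    set, every accidental seed-core match of any miRNA in any target is
    mutated away (or, when an accidental core sits inside a planted site,
    the offending miRNA is redrawn), so the realized targeting relation over
    the full sequence set equals the plan exactly.
    """
    targets: dict[str, list[str]] = {
        tid: list(_random_rna(rng, ln)) for tid, ln in sorted(target_lengths.items())
    }
    # choose pairwise-disjoint site positions per target
    placements: dict[str, list[tuple[str, str, int]]] = {}
    spans: dict[str, list[tuple[int, int]]] = {tid: [] for tid in target_lengths}
    for tid in sorted(plan):
        placements[tid] = []
        for mid, stype in plan[tid]:
            ln = SITE_LENGTH[stype]
            for _ in range(500):
                start = int(rng.integers(0, target_lengths[tid] - ln + 1))
                if all(
                    start + ln <= a or start >= a + la for a, la in spans[tid]
                ):
                    break
            else:  # pragma: no cover
                raise RuntimeError(f"could not place sites in target {tid!r}")
            spans[tid].append((start, ln))
            placements[tid].append((mid, stype, start))

    def write_sites_of(mid_filter: str | None = None) -> None:
        for tid, entries in placements.items():
            for mid, stype, start in entries:
                if mid_filter is not None and mid != mid_filter:
                    continue
                site = site_string(mirna_seqs[mid], stype)
                targets[tid][start : start + len(site)] = list(site)

    write_sites_of()
    truth_pairs = {
        (mid, tid) for tid, entries in plan.items() for mid, _ in entries
    }

    if scrub:
        core_of = {mid: site_string(seq, "6mer") for mid, seq in mirna_seqs.items()}
        for _ in range(max_iter):
            mirnas_of_core: dict[str, list[str]] = {}
            for mid in sorted(core_of):
                mirnas_of_core.setdefault(core_of[mid], []).append(mid)
            offending: list[tuple[str, str, int]] = []
            for tid in sorted(targets):
                seq = "".join(targets[tid])
                for i in range(len(seq) - 5):
                    for mid in mirnas_of_core.get(seq[i : i + 6], ()):
                        if (mid, tid) not in truth_pairs:
                            offending.append((mid, tid, i))
            if not offending:
                break
            for mid, tid, i in offending:
                window = "".join(targets[tid][i : i + 6])
                if window != core_of.get(mid):  # already fixed this round
                    continue
                mutable = [
                    pos
                    for pos in range(i, i + 6)
                    if all(pos < a or pos >= a + la for a, la in spans[tid])
                ]
                if mutable:
                    pos = int(rng.choice(mutable))
                    old = targets[tid][pos]
                    targets[tid][pos] = str(
                        rng.choice([b for b in "ACGU" if b != old])
                    )
                else:
                    # accidental core buried inside another miRNA's planted
                    # site: redraw the offending miRNA and replant its sites
                    length = len(mirna_seqs[mid])
                    taken = set(core_of.values()) - {core_of[mid]}
                    for _ in range(1000):
                        seq_new = _random_rna(rng, length)
                        core_new = site_string(seq_new, "6mer")
                        if core_new not in taken:
                            break
                    else:  # pragma: no cover
                        raise RuntimeError("could not redraw a unique miRNA core")
                    mirna_seqs[mid] = seq_new
                    core_of[mid] = core_new
                    write_sites_of(mid)
        else:  # pragma: no cover
            raise RuntimeError("background scrubbing did not converge")

    return mirna_seqs, {tid: "".join(chars) for tid, chars in targets.items()}


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate counts, sequences and ground truth from ``config``."""
    rng = np.random.default_rng(config.seed)
    g1, g2 = config.group_labels
    n = config.n_per_group
    sample_ids = [f"{g1}_{i + 1}" for i in range(n)] + [
        f"{g2}_{i + 1}" for i in range(n)
    ]
    group_of = {s: (g1 if s.startswith(f"{g1}_") else g2) for s in sample_ids}

    ids = {
        "circRNA": [f"circ_{i + 1:04d}" for i in range(config.n_circ)],
        "miRNA": [f"mir_{i + 1:04d}" for i in range(config.n_mirna)],
        "mRNA": [f"gene_{i + 1:04d}" for i in range(config.n_mrna)],
    }

    # --- plant differential expression and triads -------------------------
    de_choice: dict[str, list[str]] = {}
    direction: dict[str, str] = {}
    for cls in ("circRNA", "miRNA", "mRNA"):
        chosen = rng.choice(len(ids[cls]), size=config.n_de_per_class, replace=False)
        de_choice[cls] = [ids[cls][int(i)] for i in np.sort(chosen)]
        for fid in de_choice[cls]:
            direction[fid] = "up" if rng.random() < 0.5 else "down"

    triads: list[tuple[str, str, str]] = []
    triad_members: set[str] = set()
    for t in range(config.n_triads):
        circ = de_choice["circRNA"][t]
        mirna = de_choice["miRNA"][t]
        mrna = de_choice["mRNA"][t]
        sign_up = bool(rng.random() < 0.5)
        direction[circ] = "up" if sign_up else "down"
        direction[mrna] = "up" if sign_up else "down"
        direction[mirna] = "down" if sign_up else "up"
        triads.append((circ, mirna, mrna))
        triad_members.update((circ, mirna, mrna))

    target_edges: list[tuple[str, str, str]] = []
    for circ, mirna, mrna in triads:
        target_edges.append((mirna, circ, "circRNA"))
        target_edges.append((mirna, mrna, "mRNA"))

    # decoy edges: distinct non-triad DE miRNAs paired with same-direction
    # non-triad DE targets, so targeting succeeds but anticorrelation fails
    decoy_mirna_pool = [m for m in de_choice["miRNA"] if m not in triad_members]
    decoy_target_pool = [
        (fid, cls)
        for cls in ("circRNA", "mRNA")
        for fid in de_choice[cls]
        if fid not in triad_members
    ]
    decoy_mirnas = [
        decoy_mirna_pool[int(i)]
        for i in rng.choice(len(decoy_mirna_pool), size=config.n_decoys, replace=False)
    ] if config.n_decoys else []
    decoy_targets = [
        decoy_target_pool[int(i)]
        for i in rng.choice(
            len(decoy_target_pool), size=config.n_decoys, replace=False
        )
    ] if config.n_decoys else []
    for mirna, (tid, cls) in zip(decoy_mirnas, decoy_targets):
        direction[tid] = direction[mirna]
        target_edges.append((mirna, tid, cls))
    target_edges.sort()

    de_features = {
        cls: [(fid, direction[fid]) for fid in de_choice[cls]]
        for cls in ("circRNA", "miRNA", "mRNA")
    }

    # --- expression means -------------------------------------------------
    # latent per-sample stress factor: ~0 in group 1, ~1 in group 2, with a
    # deterministic evenly spaced within-group spread so that sample ranks
    # along the factor are well separated (count noise stays stochastic)
    spread = np.linspace(-1.0, 1.0, n)
    z = np.array([0.0] * n + [1.0] * n) + config.latent_sd * np.concatenate(
        [spread, spread]
    )
    group_ind = np.array([0.0] * n + [1.0] * n)
    lo, hi = config.baseline_mean_range

    counts: dict[str, CountMatrix] = {}
    for cls in ("circRNA", "miRNA", "mRNA"):
        base = rng.uniform(lo, hi, size=len(ids[cls]))
        mu = np.tile(base[:, None], (1, 2 * n))
        for r, fid in enumerate(ids[cls]):
            if fid not in direction:
                continue
            sign = 1.0 if direction[fid] == "up" else -1.0
            if fid in triad_members:
                effect = sign * config.de_log2fc * config.triad_coupling * (z - 0.5)
            else:
                effect = sign * config.de_log2fc * (group_ind - 0.5)
            mu[r] = base[r] * 2.0 ** effect
        counts[cls] = CountMatrix(
            feature_ids=ids[cls],
            sample_ids=sample_ids,
            group_of=group_of,
            values=_nb_counts(rng, mu, config.nb_dispersion),
            rna_class=cls,
        )

    # --- sequences --------------------------------------------------------
    mirna_seqs = _draw_mirnas(rng, ids["miRNA"], config.mirna_length_range)
    t_lo, t_hi = config.target_length_range
    target_ids = ids["circRNA"] + ids["mRNA"]
    target_lengths = {
        tid: int(rng.integers(t_lo, t_hi + 1)) for tid in target_ids
    }
    plan: dict[str, list[tuple[str, str]]] = {}
    for mirna, tid, _ in target_edges:
        plan.setdefault(tid, []).append((mirna, config.planted_site_type))
    mirna_seqs, target_strs = _realize_sequences(
        rng, mirna_seqs, target_lengths, plan, scrub=config.scrub_background
    )

    class_of_target = {tid: "circRNA" for tid in ids["circRNA"]}
    class_of_target.update({tid: "mRNA" for tid in ids["mRNA"]})
    mirna_records = [
        SeqRecord(id=mid, rna_class="miRNA", sequence=mirna_seqs[mid])
        for mid in ids["miRNA"]
    ]
    target_records = [
        SeqRecord(id=tid, rna_class=class_of_target[tid], sequence=target_strs[tid])
        for tid in target_ids
    ]

    truth = GroundTruth(
        de_features=de_features, target_edges=target_edges, triads=sorted(triads)
    )
    return SyntheticDataset(
        counts_circ=counts["circRNA"],
        counts_mirna=counts["miRNA"],
        counts_mrna=counts["mRNA"],
        mirna_seqs=mirna_records,
        target_seqs=target_records,
        truth=truth,
        config=config,
    )


FIXTURE_FILES = (
    "counts_circRNA.tsv",
    "counts_miRNA.tsv",
    "counts_mRNA.tsv",
    "samples.tsv",
    "mirna.fasta",
    "targets.fasta",
    "ground_truth.tsv",
)


def write_fixture(dataset: SyntheticDataset, directory) -> list[Path]:
    """Write the dataset as plain-text files; returns the file manifest."""
    from . import pipeline_io as pio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: list[Path] = []
    for name, mat in (
        ("counts_circRNA.tsv", dataset.counts_circ),
        ("counts_miRNA.tsv", dataset.counts_mirna),
        ("counts_mRNA.tsv", dataset.counts_mrna),
    ):
        path = directory / name
        pio.write_count_table(mat, path)
        out.append(path)
    path = directory / "samples.tsv"
    pio.write_sample_table(
        dataset.counts_circ.sample_ids, dataset.counts_circ.group_of, path
    )
    out.append(path)
    path = directory / "mirna.fasta"
    pio.write_fasta(dataset.mirna_seqs, path)
    out.append(path)
    path = directory / "targets.fasta"
    pio.write_fasta(dataset.target_seqs, path)
    out.append(path)
    path = directory / "ground_truth.tsv"
    pio.write_ground_truth(dataset.truth, path)
    out.append(path)
    return out


def read_fixture(directory, config: SimulationConfig | None = None) -> SyntheticDataset:
    """Re-read a written fixture; inverse of :func:`write_fixture`."""
    from . import pipeline_io as pio

    directory = Path(directory)
    group_of = pio.read_sample_table(directory / "samples.tsv")
    mats = {
        cls: pio.read_count_table(
            directory / f"counts_{cls}.tsv", group_of, rna_class=cls
        )
        for cls in ("circRNA", "miRNA", "mRNA")
    }
    mirna_seqs = pio.read_fasta(directory / "mirna.fasta", rna_class="miRNA")
    target_seqs = pio.read_fasta(directory / "targets.fasta")
    truth = pio.read_ground_truth(directory / "ground_truth.tsv")
    return SyntheticDataset(
        counts_circ=mats["circRNA"],
        counts_mirna=mats["miRNA"],
        counts_mrna=mats["mRNA"],
        mirna_seqs=mirna_seqs,
        target_seqs=target_seqs,
        truth=truth,
        config=config if config is not None else SimulationConfig(),
    )
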