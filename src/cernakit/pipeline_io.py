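"""File formats, configuration and end-to-end pipeline orchestration.

All on-disk formats are plain text: TSV tables, FASTA, GMT, GraphML, YAML
config and a JSON run manifest. Every writer here has a paired reader that
accepts its output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from . import cerna_network as net
from . import de_analysis as de
from . import enrichment as enr
from . import target_prediction as tp
from .errors import CernakitError, ConfigurationError, FormatError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "read_count_table",
    "write_count_table",
    "read_sample_table",
    "write_sample_table",
    "read_fasta",
    "write_fasta",
    "read_gmt",
    "read_ground_truth",
    "write_ground_truth",
    "read_de_table",
    "write_network",
    "read_network",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# tabular formats
# ---------------------------------------------------------------------------

def read_count_table(path, group_of: Mapping[str, str], rna_class: str) -> de.CountMatrix:
    """Parse a TSV count table (feature id column + one column per sample)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty count table")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: line 1: header needs id column + samples")
    sample_ids = header[1:]
    feature_ids: list[str] = []
    seen: set[str] = set()
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise FormatError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(parts)}"
            )
        fid = parts[0]
        if fid in seen:
            raise FormatError(f"{path}: line {lineno}: duplicate feature id {fid!r}")
        seen.add(fid)
        values: list[int] = []
        for cell in parts[1:]:
            try:
                v = int(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer count {cell!r}"
                ) from None
            if v < 0:
                raise FormatError(f"{path}: line {lineno}: negative count {v}")
            values.append(v)
        feature_ids.append(fid)
        rows.append(values)
    import numpy as np

    return de.CountMatrix(
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        group_of={s: group_of[s] for s in sample_ids},
        values=np.asarray(rows, dtype=np.int64),
        rna_class=rna_class,
    )


def write_count_table(counts: de.CountMatrix, path) -> None:
    frame = counts.to_frame()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t")


def read_sample_table(path) -> dict[str, str]:
    """TSV of (sample_id, group) -> mapping, preserving file order."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if frame["sample_id"].duplicated().any():
        dup = frame["sample_id"][frame["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    return dict(zip(frame["sample_id"], frame["group"]))


def write_sample_table(sample_ids: Sequence[str], group_of: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"sample_id": list(sample_ids), "group": [group_of[s] for s in sample_ids]}
    ).to_csv(path, sep="\t", index=False)


def read_fasta(path, rna_class: str | None = None) -> list[tp.SeqRecord]:
    """Parse FASTA; 'T' is normalized to 'U'. A ``class=<rna_class>`` token in
    the description overrides the ``rna_class`` argument per record."""
    path = Path(path)
    records: list[tp.SeqRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        description = rec.description[len(rec.id):].strip()
        cls = rna_class
        for token in description.split():
            if token.startswith("class="):
                cls = token[len("class="):]
        if cls is None:
            raise FormatError(
                f"{path}: record {rec.id!r} has no RNA class annotation"
            )
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        try:
            records.append(
                tp.SeqRecord(
                    id=rec.id,
                    rna_class=cls,
                    sequence=str(rec.seq),
                    description=description,
                )
            )
        except InputError as exc:
            raise FormatError(f"{path}: record {rec.id!r}: {exc}") from exc
    if not records:
        logger.warning("read_fasta: %s contains no records", path)
    return records


def write_fasta(records: Sequence[tp.SeqRecord], path) -> None:
    bio = [
        BioSeqRecord(
            Seq(r.sequence), id=r.id, description=f"class={r.rna_class}"
        )
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


def read_gmt(path) -> enr.GeneSetCollection:
    """Standard GMT: term <tab> description <tab> member ids."""
    path = Path(path)
    items: list[tuple[str, str, list[str]]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(
                f"{path}: line {lineno}: GMT rows need term, description, members"
            )
        items.append((parts[0], parts[1], [m for m in parts[2:] if m]))
    try:
        return enr.GeneSetCollection.from_items(items, source=str(path))
    except InputError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_ground_truth(truth, path) -> None:
    rows = []
    for cls in sorted(truth.de_features):
        for fid, direction in truth.de_features[cls]:
            rows.append(("de", cls, fid, direction))
    for mirna, target, cls in truth.target_edges:
        rows.append(("edge", mirna, target, cls))
    for circ, mirna, mrna in truth.triads:
        rows.append(("triad", circ, mirna, mrna))
    pd.DataFrame(rows, columns=["kind", "v1", "v2", "v3"]).to_csv(
        path, sep="\t", index=False
    )


def read_ground_truth(path):
    from .synthetic_data import GroundTruth

    frame = pd.read_csv(path, sep="\t", dtype=str)
    de_features: dict[str, list[tuple[str, str]]] = {
        "circRNA": [], "miRNA": [], "mRNA": []
    }
    target_edges: list[tuple[str, str, str]] = []
    triads: list[tuple[str, str, str]] = []
    for row in frame.itertuples(index=False):
        if row.kind == "de":
            de_features[row.v1].append((row.v2, row.v3))
        elif row.kind == "edge":
            target_edges.append((row.v1, row.v2, row.v3))
        elif row.kind == "triad":
            triads.append((row.v1, row.v2, row.v3))
        else:
            raise FormatError(f"{path}: unknown ground-truth row kind {row.kind!r}")
    return GroundTruth(
        de_features=de_features, target_edges=target_edges, triads=triads
    )


def read_de_table(path) -> tuple[list[de.DERecord], tuple[str, str]]:
    """Inverse of :func:`cernakit.de_analysis.de_table`."""
    frame = pd.read_csv(path, sep="\t")
    mean_cols = [c for c in frame.columns if c.startswith("mean_")]
    if len(mean_cols) != 2:
        raise FormatError(f"{path}: expected two mean_<group> columns")
    g1, g2 = (c[len("mean_"):] for c in mean_cols)
    records = [
        de.DERecord(
            feature_id=str(row["feature_id"]),
            rna_class=str(row["class"]),
            mean_expr_g1=float(row[mean_cols[0]]),
            mean_expr_g2=float(row[mean_cols[1]]),
            log2fc=float(row["log2FC"]),
            p_value=float(row["pvalue"]),
            q_value=float(row["qvalue"]),
            direction=str(row["direction"]),
            significant=bool(row["significant"]),
        )
        for _, row in frame.iterrows()
    ]
    return records, (g1, g2)


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

def write_network(network: net.CeRNANetwork, graphml_path, edges_path=None, triads_path=None) -> None:
    """GraphML with fixed attribute names (``rna_class``, ``log2fc``,
    ``direction`` on nodes; ``kind``, ``coefficient``, ``sponge_p`` on
    edges), plus optional flat TSV edge and triad tables."""
    nx.write_graphml(network.graph, graphml_path, named_key_ids=True)
    if edges_path is not None:
        rows = []
        for u, v, data in sorted(network.graph.edges(data=True)):
            rows.append(
                (
                    u,
                    v,
                    data["kind"],
                    data.get("coefficient", ""),
                    data.get("sponge_p", ""),
                )
            )
        pd.DataFrame(
            rows, columns=["source", "target", "kind", "coefficient", "sponge_p"]
        ).to_csv(edges_path, sep="\t", index=False)
    if triads_path is not None:
        pd.DataFrame(
            [
                (
                    t.circ_id,
                    t.mirna_id,
                    t.mrna_id,
                    t.scc_circ_mirna,
                    t.scc_mirna_mrna,
                    t.pcc_circ_mrna,
                    t.sponge_p,
                )
                for t in network.triads
            ],
            columns=[
                "circ_id",
                "mirna_id",
                "mrna_id",
                "scc_circ_mirna",
                "scc_mirna_mrna",
                "pcc_circ_mrna",
                "sponge_p",
            ],
        ).to_csv(triads_path, sep="\t", index=False)


def read_network(graphml_path, triads_path=None) -> net.CeRNANetwork:
    graph = nx.read_graphml(graphml_path)
    triads: list[net.CeRNATriad] = []
    if triads_path is not None:
        frame = pd.read_csv(triads_path, sep="\t")
        triads = [
            net.CeRNATriad(
                circ_id=str(r["circ_id"]),
                mirna_id=str(r["mirna_id"]),
                mrna_id=str(r["mrna_id"]),
                scc_circ_mirna=float(r["scc_circ_mirna"]),
                scc_mirna_mrna=float(r["scc_mirna_mrna"]),
                pcc_circ_mrna=float(r["pcc_circ_mrna"]),
                sponge_p=float(r["sponge_p"]),
            )
            for _, r in frame.iterrows()
        ]
    return net.CeRNANetwork(graph=graph, triads=triads)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Single source of truth for an end-to-end run."""

    counts_circ: str
    counts_mirna: str
    counts_mrna: str
    samples: str
    mirna_fasta: str
    target_fasta: str
    out_dir: str
    gmt: str | None = None
    de_method: str = "welch_t"
    min_fold_change: float = 2.0
    p_cutoff_circ: float = 0.05
    p_cutoff_mirna: float = 0.05
    p_cutoff_mrna: float = 0.05
    use_fdr_circ: bool = False
    use_fdr_mirna: bool = False
    use_fdr_mrna: bool = True
    pseudocount: float = 1.0
    min_site_type: str = "7mer-A1"
    circular_scan: bool = False
    scc_threshold: float = -0.7
    pcc_threshold: float = 0.9
    sponge_p_cutoff: float = 0.05
    sponge_bh: bool = False
    universe_policy: str = "targeting_de"
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1 <= self.scc_threshold <= 0:
            raise ConfigurationError("scc_threshold: must lie in [-1, 0]")
        if not 0 <= self.pcc_threshold <= 1:
            raise ConfigurationError("pcc_threshold: must lie in [0, 1]")
        if not 0 <= self.sponge_p_cutoff <= 1:
            raise ConfigurationError("sponge_p_cutoff: must lie in [0, 1]")
        if self.min_site_type not in tp.SITE_RANK:
            raise ConfigurationError(
                f"min_site_type: must be one of {tp.SITE_TYPES}"
            )
        if self.universe_policy not in ("targeting_de", "all_de_mirna"):
            raise ConfigurationError(
                "universe_policy: must be 'targeting_de' or 'all_de_mirna'"
            )
        if self.de_method not in ("welch_t", "permutation"):
            raise ConfigurationError("de_method: must be 'welch_t' or 'permutation'")

    def thresholds(self, rna_class: str) -> de.DEThresholds:
        key = {"circRNA": "circ", "miRNA": "mirna", "mRNA": "mrna"}[rna_class]
        return de.DEThresholds(
            min_fold_change=self.min_fold_change,
            p_cutoff=getattr(self, f"p_cutoff_{key}"),
            use_fdr=getattr(self, f"use_fdr_{key}"),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


class PipelineError(CernakitError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """DE -> targeting -> correlation filters -> sponge test -> network
    (-> enrichment), writing all stage outputs plus a JSON manifest.

    Returns the manifest as a dict. Identical config and inputs yield
    byte-identical outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "parameters": config.to_dict(),
        "inputs": {},
        "stages": {},
        "outputs": {},
        "status": "running",
    }
    written: list[Path] = []

    def record_output(path: Path) -> None:
        written.append(path)

    def finish(status: str, failed_stage: str | None = None, error: str | None = None) -> dict:
        manifest["status"] = status
        if failed_stage is not None:
            manifest["failed_stage"] = failed_stage
            manifest["error"] = error
        manifest["outputs"] = {p.name: _sha256(p) for p in sorted(set(written))}
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest

    stage = "read_inputs"
    try:
        input_paths = {
            "counts_circ": config.counts_circ,
            "counts_mirna": config.counts_mirna,
            "counts_mrna": config.counts_mrna,
            "samples": config.samples,
            "mirna_fasta": config.mirna_fasta,
            "target_fasta": config.target_fasta,
        }
        if config.gmt:
            input_paths["gmt"] = config.gmt
        manifest["inputs"] = {
            key: {"path": str(p), "sha256": _sha256(Path(p))}
            for key, p in input_paths.items()
        }
        group_of = read_sample_table(config.samples)
        counts = {
            "circRNA": read_count_table(config.counts_circ, group_of, "circRNA"),
            "miRNA": read_count_table(config.counts_mirna, group_of, "miRNA"),
            "mRNA": read_count_table(config.counts_mrna, group_of, "mRNA"),
        }
        mirna_seqs = read_fasta(config.mirna_fasta, rna_class="miRNA")
        target_seqs = read_fasta(config.target_fasta)
        group_labels = counts["circRNA"].groups
        manifest["stages"]["read_inputs"] = {
            "n_features": {cls: len(m.feature_ids) for cls, m in counts.items()},
            "n_samples": len(counts["circRNA"].sample_ids),
        }

        # ---- differential expression ------------------------------------
        stage = "de"
        de_records: dict[str, list[de.DERecord]] = {}
        for cls in ("circRNA", "miRNA", "mRNA"):
            de_records[cls] = de.run_de(
                counts[cls],
                config.thresholds(cls),
                method=config.de_method,
                pseudocount=config.pseudocount,
            )
            path = out_dir / f"de_{cls}.tsv"
            de.de_table(de_records[cls], group_labels).to_csv(
                path, sep="\t", index=False
            )
            record_output(path)
        all_records = {
            r.feature_id: r for recs in de_records.values() for r in recs
        }
        de_sig = {
            cls: sorted(r.feature_id for r in de_records[cls] if r.significant)
            for cls in de_records
        }
        manifest["stages"]["de"] = {
            "n_significant": {cls: len(v) for cls, v in de_sig.items()},
            "n_up": {
                cls: sum(1 for r in de_records[cls] if r.direction == "up")
                for cls in de_records
            },
            "n_down": {
                cls: sum(1 for r in de_records[cls] if r.direction == "down")
                for cls in de_records
            },
        }
        de_sig_all = set().union(*de_sig.values())

        # ---- target prediction (restricted to DE features) ----------------
        stage = "targets"
        edges, sites = tp.predict_targets(
            mirna_seqs,
            target_seqs,
            min_site_type=config.min_site_type,
            restrict_to=de_sig_all,
            circular_scan=config.circular_scan,
        )
        path = out_dir / "target_edges.tsv"
        pd.DataFrame(
            [
                (e.mirna_id, e.target_id, e.target_class, e.best_site_type, e.n_sites)
                for e in edges
            ],
            columns=["mirna_id", "target_id", "target_class", "best_site_type", "n_sites"],
        ).to_csv(path, sep="\t", index=False)
        record_output(path)
        path = out_dir / "target_sites.tsv"
        pd.DataFrame(
            [
                (s.mirna_id, s.target_id, s.site_type, s.start, s.length)
                for s in sites
            ],
            columns=["mirna_id", "target_id", "site_type", "start", "length"],
        ).to_csv(path, sep="\t", index=False)
        record_output(path)
        manifest["stages"]["targets"] = {"n_edges": len(edges), "n_sites": len(sites)}

        # ---- correlation filters -----------------------------------------
        stage = "negative_pairs"
        log_expr = pd.concat(
            [
                de.log_expression(counts[cls], config.pseudocount)
                for cls in ("circRNA", "miRNA", "mRNA")
            ]
        )
        if log_expr.index.duplicated().any():
            raise InputError("feature ids are not unique across RNA classes")
        neg = net.negative_pairs(
            log_expr,
            edges,
            scc_threshold=config.scc_threshold,
            de_ids=de_sig_all,
        )
        path = out_dir / "negative_pairs.tsv"
        _write_correlation_edges(neg, path)
        record_output(path)
        manifest["stages"]["negative_pairs"] = {
            "n_screened": len(edges),
            "n_retained": len(neg),
        }

        stage = "coexpressed_pairs"
        coexpr = net.coexpressed_pairs(
            log_expr, neg, pcc_threshold=config.pcc_threshold
        )
        path = out_dir / "coexpressed_pairs.tsv"
        _write_correlation_edges(coexpr, path)
        record_output(path)
        manifest["stages"]["coexpressed_pairs"] = {"n_retained": len(coexpr)}

        # ---- sponge tests --------------------------------------------------
        stage = "sponge_test"
        targeting: dict[str, set[str]] = {}
        for e in edges:
            if e.mirna_id in de_sig["miRNA"] and e.target_id in de_sig_all:
                targeting.setdefault(e.target_id, set()).add(e.mirna_id)
        if config.universe_policy == "targeting_de":
            universe = sorted(set().union(*targeting.values())) if targeting else []
        else:
            universe = de_sig["miRNA"]
        sponge_results = [
            net.sponge_test(
                c.id_a,
                c.id_b,
                targeting.get(c.id_a, set()),
                targeting.get(c.id_b, set()),
                universe,
            )
            for c in coexpr
        ]
        path = out_dir / "sponge_tests.tsv"
        pd.DataFrame(
            [
                (
                    r.circ_id,
                    r.mrna_id,
                    r.k,
                    r.K,
                    r.n,
                    r.N,
                    r.p_value,
                    ",".join(sorted(r.shared_mirnas)),
                )
                for r in sponge_results
            ],
            columns=["circ_id", "mrna_id", "k", "K", "n", "N", "pvalue", "shared_mirnas"],
        ).to_csv(path, sep="\t", index=False)
        record_output(path)
        manifest["stages"]["sponge_test"] = {
            "n_tested": len(sponge_results),
            "n_universe": len(universe),
            "n_passing": sum(
                1 for r in sponge_results if r.p_value < config.sponge_p_cutoff
            ),
        }

        # ---- network assembly ---------------------------------------------
        stage = "network"
        network = net.build_network(
            neg,
            coexpr,
            sponge_results,
            all_records,
            sponge_p_cutoff=config.sponge_p_cutoff,
            sponge_bh=config.sponge_bh,
        )
        graphml = out_dir / "network.graphml"
        edges_tsv = out_dir / "network_edges.tsv"
        triads_tsv = out_dir / "triads.tsv"
        write_network(network, graphml, edges_tsv, triads_tsv)
        record_output(graphml)
        record_output(edges_tsv)
        record_output(triads_tsv)
        path = out_dir / "network_nodes.tsv"
        pd.DataFrame(
            [
                (
                    nid,
                    network.graph.nodes[nid]["rna_class"],
                    network.graph.nodes[nid]["log2fc"],
                    network.graph.nodes[nid]["direction"],
                )
                for nid in sorted(network.graph.nodes)
            ],
            columns=["feature_id", "rna_class", "log2FC", "direction"],
        ).to_csv(path, sep="\t", index=False)
        record_output(path)
        manifest["stages"]["network"] = {
            "n_nodes": {
                cls: len(network.node_ids(cls))
                for cls in ("circRNA", "miRNA", "mRNA")
            },
            "n_edges": {
                kind: sum(
                    1
                    for _, _, d in network.graph.edges(data=True)
                    if d["kind"] == kind
                )
                for kind in ("circ-miRNA", "miRNA-mRNA", "circ-mRNA")
            },
            "n_triads": len(network.triads),
        }

        # ---- enrichment -----------------------------------------------------
        if config.gmt:
            stage = "enrichment"
            collection = read_gmt(config.gmt)
            records = enr.over_representation(
                query=de_sig["mRNA"],
                universe=counts["mRNA"].feature_ids,
                collection=collection,
            )
            path = out_dir / "enrichment.tsv"
            enr.enrichment_table(records).to_csv(path, sep="\t", index=False)
            record_output(path)
            manifest["stages"]["enrichment"] = {
                "n_terms": len(records),
                "n_significant": sum(1 for r in records if r.q_value < 0.05),
            }
    except Exception as exc:
        finish("failed", failed_stage=stage, error=str(exc))
        raise PipelineError(stage, exc) from exc

    return finish("complete")


def _write_correlation_edges(edges: Sequence[net.CorrelationEdge], path) -> None:
    pd.DataFrame(
        [
            (e.id_a, e.id_b, e.class_a, e.class_b, e.method, e.coefficient, e.n_samples)
            for e in edges
        ],
        columns=["id_a", "id_b", "class_a", "class_b", "method", "coefficient", "n_samples"],
    ).to_csv(path, sep="\t", index=False)


def read_correlation_edges(path) -> list[net.CorrelationEdge]:
    frame = pd.read_csv(path, sep="\t")
    return [
        net.CorrelationEdge(
            id_a=str(r["id_a"]),
            id_b=str(r["id_b"]),
            class_a=str(r["class_a"]),
            class_b=str(r["class_b"]),
            method=str(r["method"]),
            coefficient=float(r["coefficient"]),
            n_samples=int(r["n_samples"]),
        )
        for _, r in frame.iterrows()
    ]
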