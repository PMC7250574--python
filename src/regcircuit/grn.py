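"""Temporal gene-regulatory-circuit inference.

The integration joins, per regeneration stage, the peaks gaining
accessibility at that stage with their nearest genes and the
transcription-factor (TF) motifs found inside them; vets both the TF
gene and the candidate target against bulk expression at the stage; and
chains TF -> target links across successive stages, where each link's
target must encode the TF of the next link.

The earliest stage table serves as entry evidence rather than
contributing edges of its own: a TF may open a chain at the second stage
only if its motif also occurs in a peak gaining accessibility at the
first stage (the early-stage "activity" linkage).  Circuits are finally
filtered against single-cell differential expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .intervals import PeakAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "TFRecord",
    "GRNEdge",
    "Circuit",
    "build_tf_map",
    "build_regulator_table",
    "filter_expressed",
    "chain_circuits",
    "filter_by_sc_de",
    "target_overlap",
    "export_network",
]

REGULATOR_COLUMNS = [
    "peak", "nearest_gene", "distance", "da_direction", "contrast",
    "motif_id", "tf_name", "tf_gene", "hit_score", "da_fdr",
]


@dataclass(frozen=True)
class TFRecord:
    """A transcription factor: its gene, its motif, and bulk expression flags."""

    tf_name: str
    gene_id: str
    motif_id: str
    expressed_at: Mapping[str, bool] = field(default_factory=dict)


@dataclass(frozen=True)
class GRNEdge:
    """One TF -> target link supported by a stage-specific accessible peak."""

    tf_name: str
    tf_gene: str
    target_gene: str
    peak: str
    stage: str
    motif_id: str
    hit_score: float
    da_fdr: float
    bulk_expressed: bool = True
    sc_de: bool = False
    self_loop: bool = False


@dataclass(frozen=True)
class Circuit:
    """A chain of edges across strictly increasing stages."""

    edges: tuple[GRNEdge, ...]

    def __post_init__(self) -> None:
        stages = [e.stage for e in self.edges]
        if len(set(stages)) != len(stages):
            raise ValueError("circuit stages must be distinct")

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for e in self.edges:
            out.add(e.tf_gene)
            out.add(e.target_gene)
        return out

    def __len__(self) -> int:
        return len(self.edges)


def build_tf_map(
    library: Sequence,
    tf_genes: Mapping[str, str],
    bulk: Optional[pd.DataFrame] = None,
    min_expr: float = 1.0,
) -> dict[str, TFRecord]:
    """TF records from a motif library (PWMs) plus a TF-name -> gene map.

    ``bulk`` is a genes-x-stages expression table (CPM); a TF is flagged
    expressed at a stage when its gene meets ``min_expr`` there.
    """
    out: dict[str, TFRecord] = {}
    for pwm in library:
        gene = tf_genes.get(pwm.tf_name, pwm.tf_name)
        flags: dict[str, bool] = {}
        if bulk is not None:
            for stage in bulk.columns:
                flags[stage] = bool(
                    gene in bulk.index and bulk.loc[gene, stage] >= min_expr
                )
        out[pwm.tf_name] = TFRecord(pwm.tf_name, gene, pwm.motif_id, flags)
    return out


def build_regulator_table(
    da: pd.DataFrame,
    hits: pd.DataFrame,
    annotations: Iterable[PeakAnnotation],
    tf_map: Mapping[str, TFRecord],
    stage: str,
    up_direction: str = "up_in_2",
) -> pd.DataFrame:
    """Join DA peaks up at ``stage`` with their motif hits and nearest genes.

    One row per (peak, motif); the motif's TF and the peak's nearest gene
    are carried along.  A hit in a DA-up peak lacking an annotation is an
    error: annotation must cover the peak universe.
    """
    ann_by_peak = {a.peak: a for a in annotations}
    up = da[da["direction"] == up_direction]
    contrast = da.attrs.get("contrast", ("?", "?"))
    contrast_label = f"{contrast[0]}|{contrast[1]}"
    fdr_by_peak = dict(zip(up["feature"], up["fdr"]))
    motif_tf = {rec.motif_id: rec for rec in tf_map.values()}
    rows = []
    up_set = set(up["feature"])
    for hit in hits.itertuples(index=False):
        if hit.peak not in up_set:
            continue
        if hit.peak not in ann_by_peak:
            raise ValueError(f"peak {hit.peak} has motif hits but no annotation")
        rec = motif_tf.get(hit.motif_id)
        if rec is None:
            continue
        a = ann_by_peak[hit.peak]
        rows.append(
            (
                hit.peak, a.gene_id, a.distance, up_direction, contrast_label,
                hit.motif_id, rec.tf_name, rec.gene_id, hit.score,
                fdr_by_peak[hit.peak],
            )
        )
    out = pd.DataFrame(rows, columns=REGULATOR_COLUMNS)
    out.attrs["stage"] = stage
    return out.sort_values(["peak", "motif_id"], kind="stable").reset_index(drop=True)


def filter_expressed(
    table: pd.DataFrame,
    bulk: pd.DataFrame,
    stage: str,
    min_expr: float = 1.0,
) -> pd.DataFrame:
    """Retain rows whose TF gene and nearest gene are bulk-expressed at stage.

    Genes missing from the bulk table count as not expressed (logged).
    """
    if stage not in bulk.columns:
        raise ValueError(f"bulk expression table does not cover stage {stage!r}")
    expr = bulk[stage]

    def _ok(gene: Optional[str]) -> bool:
        if gene is None or gene not in expr.index:
            if gene is not None:
                logger.info("gene %s absent from bulk table; treated as unexpressed", gene)
            return False
        return bool(expr.loc[gene] >= min_expr)

    keep = table.apply(
        lambda r: _ok(r["tf_gene"]) and _ok(r["nearest_gene"]), axis=1
    ) if len(table) else pd.Series(dtype=bool)
    out = table[keep] if len(table) else table.copy()
    out.attrs["stage"] = table.attrs.get("stage", stage)
    return out.reset_index(drop=True)


def _edges_from_table(table: pd.DataFrame, stage: str) -> list[GRNEdge]:
    edges: dict[tuple, GRNEdge] = {}
    for r in table.itertuples(index=False):
        key = (r.tf_name, r.nearest_gene, r.peak)
        if key not in edges:
            edges[key] = GRNEdge(
                tf_name=r.tf_name,
                tf_gene=r.tf_gene,
                target_gene=r.nearest_gene,
                peak=r.peak,
                stage=stage,
                motif_id=r.motif_id,
                hit_score=float(r.hit_score),
                da_fdr=float(r.da_fdr),
                bulk_expressed=True,
                self_loop=r.tf_gene == r.nearest_gene,
            )
    return sorted(
        edges.values(), key=lambda e: (e.tf_name, e.target_gene, e.peak)
    )


def chain_circuits(
    tables: Mapping[str, pd.DataFrame],
    tf_map: Mapping[str, TFRecord],
) -> list[Circuit]:
    """Chain stage tables into maximal regulatory circuits.

    ``tables`` maps stages, in temporal order, to regulator tables that
    already passed expression vetting.  The first stage contributes entry
    evidence only: an edge at the second stage is admitted iff its TF's
    motif occurs somewhere in the first-stage table.  From the second
    stage on, an edge at stage k+1 extends a chain whose stage-k target
    encodes the TF.  Every maximal chain (not extendable left or right)
    is emitted; self-loops are flagged and never revisit a stage.
    """
    stages = list(tables)
    if len(stages) < 2:
        raise ValueError("need at least two consecutive stages")
    linkage_motifs = set(tables[stages[0]]["motif_id"]) if len(tables[stages[0]]) else set()
    edge_stages = stages[1:]
    per_stage: list[list[GRNEdge]] = []
    for si, stage in enumerate(edge_stages):
        edges = _edges_from_table(tables[stage], stage)
        if si == 0:
            edges = [e for e in edges if tf_map[e.tf_name].motif_id in linkage_motifs]
        per_stage.append(edges)

    tf_gene_of = {rec.gene_id for rec in tf_map.values()}

    def successors(edge: GRNEdge, si: int) -> list[GRNEdge]:
        if si + 1 >= len(per_stage) or edge.target_gene not in tf_gene_of:
            return []
        return [e for e in per_stage[si + 1] if e.tf_gene == edge.target_gene]

    has_pred: list[set[int]] = [set() for _ in per_stage]
    for si in range(len(per_stage) - 1):
        for e in per_stage[si]:
            for nxt in successors(e, si):
                has_pred[si + 1].add(id(nxt))

    circuits: list[Circuit] = []

    def extend(path: list[GRNEdge], si: int) -> None:
        nxt = successors(path[-1], si)
        if not nxt:
            circuits.append(Circuit(tuple(path)))
            return
        for e in nxt:
            extend(path + [e], si + 1)

    for si, edges in enumerate(per_stage):
        for e in edges:
            if id(e) not in has_pred[si]:
                extend([e], si)
    circuits.sort(
        key=lambda c: tuple(
            (e.stage, e.tf_name, e.target_gene, e.peak) for e in c.edges
        )
    )
    return circuits


def filter_by_sc_de(
    circuits: Sequence[Circuit],
    de_table: pd.DataFrame,
    sc_genes: Iterable[str],
    alpha: float = 0.05,
    strict: bool = False,
) -> list[Circuit]:
    """Vet circuits against single-cell differential expression.

    Every edge's TF gene and target must be measured in the single-cell
    data, and at least one node of the circuit must be DE at adjusted
    p <= alpha (``strict`` demands every node).  Per-edge ``sc_de`` flags
    mark targets that pass the DE filter.  ``alpha=1`` keeps everything
    measured.
    """
    sc_genes = set(sc_genes)
    de_genes = set(de_table.loc[de_table["p_adjusted"] <= alpha, "gene"])
    kept: list[Circuit] = []
    for c in circuits:
        if not c.nodes <= sc_genes:
            continue
        flags = [n in de_genes for n in sorted(c.nodes)]
        if strict:
            ok = all(flags)
        else:
            ok = any(flags) or alpha >= 1.0
        if not ok:
            continue
        new_edges = tuple(
            replace(e, sc_de=e.target_gene in de_genes) for e in c.edges
        )
        kept.append(Circuit(new_edges))
    return kept


def target_overlap(
    tf_a: str,
    tf_b: str,
    tables: Iterable[pd.DataFrame],
    tf_map: Mapping[str, TFRecord],
) -> tuple[int, int, int]:
    """Region counts hit by A's motif only, by both, and by B's only.

    Counted over the union of stage-specific accessible regions across
    all supplied regulator tables.
    """
    for tf in (tf_a, tf_b):
        if tf not in tf_map:
            raise ValueError(f"unknown TF {tf!r}")
    motif_a = tf_map[tf_a].motif_id
    motif_b = tf_map[tf_b].motif_id
    region_motifs: dict[str, set[str]] = {}
    for table in tables:
        for r in table.itertuples(index=False):
            region_motifs.setdefault(r.peak, set()).add(r.motif_id)
    only_a = both = only_b = 0
    for motifs in region_motifs.values():
        a, b = motif_a in motifs, motif_b in motifs
        if motif_a == motif_b:
            both += a
        elif a and b:
            both += 1
        elif a:
            only_a += 1
        elif b:
            only_b += 1
    return only_a, both, only_b


def export_network(
    circuits: Sequence[Circuit],
    tsv_path: str | Path,
    dot_path: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Write the circuit edge list as TSV (and optionally DOT).

    Rows are unique edges ordered by (stage, tf, target, peak); the DOT
    file contains one node per gene and one labelled edge per link, in
    the same deterministic order.
    """
    rows = []
    seen = set()
    for ci, c in enumerate(circuits):
        for e in c.edges:
            key = (e.stage, e.tf_name, e.target_gene, e.peak)
            if key in seen:
                continue
            seen.add(key)
            rows.append(
                {
                    "tf": e.tf_name,
                    "target": e.target_gene,
                    "stage": e.stage,
                    "peak": e.peak,
                    "motif_id": e.motif_id,
                    "hit_score": e.hit_score,
                    "da_fdr": e.da_fdr,
                    "bulk_expressed": e.bulk_expressed,
                    "sc_de": e.sc_de,
                    "self_loop": e.self_loop,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "tf", "target", "stage", "peak", "motif_id", "hit_score",
            "da_fdr", "bulk_expressed", "sc_de", "self_loop",
        ],
    )
    if len(df):
        df = df.sort_values(["stage", "tf", "target", "peak"], kind="stable")
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    if dot_path is not None:
        nodes = sorted(set(df["tf"]) | set(df["target"])) if len(df) else []
        lines = ["digraph regulatory_circuits {"]
        for n in nodes:
            lines.append(f'  "{n}";')
        for r in df.itertuples(index=False):
            lines.append(f'  "{r.tf}" -> "{r.target}" [label="{r.stage}"];')
        lines.append("}")
        Path(dot_path).write_text("\n".join(lines) + "\n")
    return df.reset_index(drop=True)
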