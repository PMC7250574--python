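"""End-to-end orchestration over an on-disk dataset.

Reads the file layout emitted by :mod:`regcircuit.synthetic` (or any
dataset using the same formats), runs differential accessibility per
consecutive timepoint contrast, annotates peaks, scans motifs, builds
per-stage regulator tables vetted by bulk expression, chains circuits
across stages, and filters them against single-cell differential
expression.  All outputs are numeric tables written with deterministic
ordering, so repeated runs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import diffacc, grn, intervals, motifs, sc, synthetic

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    da_tables: dict[str, pd.DataFrame]  # keyed "g1|g2"
    annotations: list[intervals.PeakAnnotation]
    hits: pd.DataFrame
    stage_tables: dict[str, pd.DataFrame]
    circuits_all: list[grn.Circuit]
    circuits: list[grn.Circuit]  # after the single-cell DE filter
    de_table: pd.DataFrame
    edge_list: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_pipeline(
    dataset_dir: str | Path,
    timepoints: Sequence[str] = ("uninjured", "6hpa", "24hpa", "72hpa"),
    stages: Sequence[str] = ("6hpa", "24hpa", "72hpa"),
    sc_contrast: tuple[str, str] = ("uninjured", "24hpa"),
    alpha: float = 0.05,
    min_expr: float = 1.0,
    frac_of_max: float = 0.8,
    min_pct: float = 0.3,
    strict_de: bool = False,
    out_dir: Optional[str | Path] = None,
) -> PipelineResult:
    """Run the integrative analysis on a dataset directory.

    ``stages`` are the regeneration timepoints whose accessibility gains
    feed the regulator tables; the first entry provides entry-linkage
    evidence only.  When ``out_dir`` is given, every table is also
    written there as TSV (plus a DOT file for the final circuits).
    """
    d = Path(dataset_dir)
    paths = synthetic.dataset_paths(d, timepoints)

    counts = diffacc.read_counts_tsv(paths["counts"])
    sheet = diffacc.read_sample_sheet(paths["sheet"])
    peaks = intervals.read_bed(paths["consensus_bed"])
    tss = intervals.extract_tss(paths["gff"])
    annotations = intervals.annotate_peaks(peaks, tss)
    library = motifs.read_meme(paths["meme"])
    seqs = motifs.read_fasta(paths["fasta"])
    hits = motifs.scan_peakset(seqs, library, frac_of_max=frac_of_max)
    bulk = synthetic.load_bulk_expression(d, timepoints)
    tf_map = grn.build_tf_map(
        library, {p.tf_name: p.tf_name for p in library}, bulk, min_expr
    )

    da_tables: dict[str, pd.DataFrame] = {}
    tps = list(timepoints)
    for g1, g2 in zip(tps, tps[1:]):
        da_tables[f"{g1}|{g2}"] = diffacc.da_table(counts, sheet, (g1, g2), alpha=alpha)

    stage_tables: dict[str, pd.DataFrame] = {}
    for stage in stages:
        prev = tps[tps.index(stage) - 1]
        da = da_tables[f"{prev}|{stage}"]
        table = grn.build_regulator_table(
            da, hits, annotations, tf_map, stage, up_direction="up_in_2"
        )
        stage_tables[stage] = grn.filter_expressed(table, bulk, stage, min_expr)

    circuits_all = grn.chain_circuits(stage_tables, tf_map)

    adata = sc.read_sc_dataset(paths["mtx"], paths["sc_genes"], paths["sc_meta"])
    adata = sc.lognormalize(adata)
    de_table = sc.rank_sum_markers(
        adata, "timepoint", sc_contrast[0], sc_contrast[1], min_pct=min_pct
    )
    circuits = grn.filter_by_sc_de(
        circuits_all, de_table, adata.var_names, alpha=alpha, strict=strict_de
    )

    result = PipelineResult(
        da_tables=da_tables,
        annotations=annotations,
        hits=hits,
        stage_tables=stage_tables,
        circuits_all=circuits_all,
        circuits=circuits,
        de_table=de_table,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key, da in da_tables.items():
            safe = key.replace("|", "_vs_")
            da.to_csv(out / f"da_{safe}.tsv", sep="\t", index=False, float_format="%.6g")
        motifs.write_hit_table(hits, out / "motif_hits.tsv")
        intervals.write_annotation_table(annotations, out / "peak_annotation.tsv")
        for stage, table in stage_tables.items():
            table.to_csv(
                out / f"regulators_{stage}.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
        de_table.to_csv(out / "sc_de.tsv", sep="\t", index=False, float_format="%.6g")
        result.edge_list = grn.export_network(
            circuits, out / "circuit_edges.tsv", out / "circuits.dot"
        )
    else:
        import tempfile

        with tempfile.TemporaryDirectory() as tmp:
            result.edge_list = grn.export_network(
                circuits, Path(tmp) / "edges.tsv", None
            )
    return result
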