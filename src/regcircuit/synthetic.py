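"""Seed-reproducible synthetic regeneration study with planted ground truth.

The generator emits a complete miniature study of the kind the pipeline
consumes: a two-chromosome genome annotation, a consensus ATAC peak set
with per-timepoint calls, peak sequences with planted motif instances,
negative-binomial fragment counts with planted stage-specific
accessibility gains, per-stage bulk expression, a clustered single-cell
count matrix with planted markers, a timepoint expression shift and
cell-cycle signatures, a motif library, a small term ontology, and a
truth ledger recording every planted item.

Planted regulatory circuits are constructed to be exactly recoverable:
each edge (TF, target, stage) implies a peak gaining accessibility at
that stage whose nearest TSS is the target and which carries the TF's
motif, with the TF expressed in bulk at the stage and the target
differentially expressed in the single-cell contrast.  Decoy genes each
violate exactly one of those criteria, so end-to-end recovery is a sharp
precision/recall test.

Fragment counts are modelled at the peak level (no read simulation):
counts are NB with Var = mu + phi * mu^2.  Peak sequences are i.i.d.
uniform background with motif instances planted by substitution at
recorded offsets, which makes scanner ground truth exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmwrite

from .diffacc import CountMatrix
from .intervals import GenomicInterval, write_bed
from .motifs import PWM, revcomp, write_fasta, write_meme
from .enrich import Ontology, write_ontology_tsv, write_gene2term_tsv
from .sc import write_gene_list

__all__ = [
    "SyntheticConfig",
    "TruthLedger",
    "generate_dataset",
    "sample_nb_counts",
    "simulate_contrast_counts",
    "dataset_paths",
    "load_bulk_expression",
]

FILES = {
    "gff": "genes.gff3",
    "consensus_bed": "peaks_consensus.bed",
    "fasta": "peaks.fasta",
    "counts": "atac_counts.tsv",
    "sheet": "sample_sheet.tsv",
    "mtx": "sc_counts.mtx",
    "sc_genes": "sc_genes.tsv",
    "sc_meta": "sc_cells.tsv",
    "meme": "motifs.meme",
    "ontology": "ontology_edges.tsv",
    "gene2term": "gene2term.tsv",
    "s_genes": "s_genes.txt",
    "g2m_genes": "g2m_genes.txt",
    "ledger": "truth.json",
}


def dataset_paths(out_dir: str | Path, timepoints: Sequence[str] = ()) -> dict[str, Path]:
    out = {k: Path(out_dir) / v for k, v in FILES.items()}
    for tp in timepoints:
        out[f"bed_{tp}"] = Path(out_dir) / f"peaks_{tp}.bed"
        out[f"bulk_{tp}"] = Path(out_dir) / f"bulk_{tp}.tsv"
    return out


_DEFAULT_CIRCUIT = (
    ("tf1", "tf2", "24hpa"),
    ("tf1", "g0005", "24hpa"),
    ("tf2", "g0006", "72hpa"),
    ("tf2", "g0007", "72hpa"),
)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic regeneration dataset."""

    seed: int = 0
    genome_length: int = 2_010_000  # bp per chromosome
    n_chroms: int = 2
    n_genes: int = 1000
    n_tfs: int = 4
    gene_spacing: int = 4000
    timepoints: tuple[str, ...] = ("uninjured", "6hpa", "24hpa", "72hpa")
    n_replicates: int = 3
    n_peaks: int = 400
    peak_width: int = 200
    baseline_mean: float = 100.0
    dispersion: float = 0.1
    da_fraction: float = 0.1
    da_log2fc: float = 2.0
    # single-cell conditions
    sc_timepoints: tuple[str, ...] = ("uninjured", "24hpa")
    n_cells: int = 600  # per single-cell timepoint
    n_clusters: int = 4
    n_markers_per_cluster: int = 5
    marker_log2fc: float = 2.0
    cycle_log2fc: float = 4.5
    sc_dispersion: float = 0.4
    cycle_fractions: dict = field(
        default_factory=lambda: {
            "uninjured": (0.30, 0.16, 0.54),
            "24hpa": (0.17, 0.07, 0.76),
        }
    )
    cluster_fractions: dict = field(
        default_factory=lambda: {
            "uninjured": (0.38, 0.20, 0.22, 0.20),
            "24hpa": (0.25, 0.10, 0.40, 0.25),
        }
    )
    # ground-truth structure
    n_decoys: int = 200
    n_signature_genes: int = 40
    n_peaks_per_edge: int = 2  # accessible elements supporting each circuit edge
    n_shared_motif_peaks: int = 6  # regions carrying both circuit TF motifs
    motif_width: int = 14
    planted_circuit: tuple[tuple[str, str, str], ...] = _DEFAULT_CIRCUIT

    def __post_init__(self) -> None:
        if not 0.0 <= self.da_fraction <= 1.0:
            raise ValueError("da_fraction must lie in [0, 1]")
        if self.dispersion < 0 or self.sc_dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        for tp, fr in self.cycle_fractions.items():
            if any(not 0 <= f <= 1 for f in fr) or abs(sum(fr) - 1) > 1e-9:
                raise ValueError(f"cycle_fractions[{tp!r}] must be proportions summing to 1")
        for tp, fr in self.cluster_fractions.items():
            if len(fr) != self.n_clusters or abs(sum(fr) - 1) > 1e-9:
                raise ValueError(
                    f"cluster_fractions[{tp!r}] needs {self.n_clusters} proportions summing to 1"
                )
        genes = set(self.gene_ids())
        for tf, target, stage in self.planted_circuit:
            for g in (tf, target):
                if g not in genes:
                    raise ValueError(f"planted_circuit references unknown gene {g!r}")
            if stage not in self.timepoints:
                raise ValueError(f"planted_circuit references unknown stage {stage!r}")
            if tf not in self.tf_names():
                raise ValueError(f"planted_circuit TF {tf!r} is not a declared TF gene")
        per_chrom = (self.n_genes + self.n_chroms - 1) // self.n_chroms
        if 2 * 2000 + per_chrom * self.gene_spacing > self.genome_length:
            raise ValueError("genome_length too small for the requested gene count")

    def tf_names(self) -> list[str]:
        return [f"tf{i+1}" for i in range(self.n_tfs)]

    def gene_ids(self) -> list[str]:
        return self.tf_names() + [
            f"g{i+1:04d}" for i in range(self.n_tfs, self.n_genes)
        ]

    def cluster_names(self) -> list[str]:
        return [f"c{i+1}" for i in range(self.n_clusters)]


@dataclass
class TruthLedger:
    """Every planted item, as emitted into the data files."""

    da_truth: list = field(default_factory=list)
    motif_truth: list = field(default_factory=list)
    marker_truth: list = field(default_factory=list)
    de_truth: list = field(default_factory=list)
    circuit_truth: list = field(default_factory=list)
    phase_truth: list = field(default_factory=list)
    decoy_truth: list = field(default_factory=list)
    signature_genes: dict = field(default_factory=dict)
    tf_genes: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, sort_keys=True, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "TruthLedger":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Count sampling


def sample_nb_counts(
    mean: float | np.ndarray,
    dispersion: float,
    n: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Negative-binomial draws with E = mean and Var = mean + phi * mean^2.

    ``dispersion`` (phi) of zero gives the Poisson limit.  ``mean`` may be
    an array, in which case ``n`` is ignored and one draw per element is
    returned.
    """
    rng = rng if rng is not None else np.random.default_rng()
    mean = np.asarray(mean, dtype=float)
    if (mean <= 0).any():
        raise ValueError("mean must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if mean.shape == ():
        if n is None:
            raise ValueError("n is required for a scalar mean")
        mean = np.full(n, float(mean))
    shape = mean.shape
    if dispersion == 0:
        return rng.poisson(mean, size=shape)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=shape)


def simulate_contrast_counts(
    n_features: int,
    n_per_group: int = 3,
    baseline_mean: float = 100.0,
    dispersion: float = 0.1,
    da_fraction: float = 0.0,
    da_log2fc: float = 2.0,
    seed: int = 0,
    group_names: tuple[str, str] = ("g1", "g2"),
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Two-group NB count matrix with a planted fraction of true effects.

    Per-feature abundances vary log-normally around ``baseline_mean``;
    a ``da_fraction`` of features get their group-2 mean shifted by
    ``da_log2fc`` (up or down with equal probability).  Returns the count
    matrix, a sample sheet, and a truth table (feature, planted,
    direction).
    """
    rng = np.random.default_rng(seed)
    rel = rng.lognormal(0.0, 0.4, n_features)
    mean1 = baseline_mean * rel
    mean2 = mean1.copy()
    n_da = int(round(da_fraction * n_features))
    planted = rng.choice(n_features, size=n_da, replace=False)
    up = rng.random(n_da) < 0.5
    mean2[planted[up]] *= 2.0 ** da_log2fc
    mean2[planted[~up]] /= 2.0 ** da_log2fc
    cols = {}
    samples = []
    for gi, (g, means) in enumerate(zip(group_names, (mean1, mean2))):
        for r in range(n_per_group):
            name = f"{g}_r{r+1}"
            cols[name] = sample_nb_counts(means, dispersion, rng=rng)
            samples.append((name, g, "pax6", r + 1))
    features = [f"peak{i+1:05d}" for i in range(n_features)]
    counts = CountMatrix(pd.DataFrame(cols, index=pd.Index(features, name="feature")))
    sheet = pd.DataFrame(samples, columns=["sample", "timepoint", "condition", "replicate"])
    direction = np.array([""] * n_features, dtype=object)
    direction[planted[up]] = "up_in_2"
    direction[planted[~up]] = "up_in_1"
    truth = pd.DataFrame(
        {
            "feature": features,
            "planted": np.isin(np.arange(n_features), planted),
            "direction": direction,
        }
    )
    return counts, sheet, truth


# ---------------------------------------------------------------------------
# Dataset generation


def _gene_positions(cfg: SyntheticConfig) -> pd.DataFrame:
    ids = cfg.gene_ids()
    rows = []
    for i, gid in enumerate(ids):
        chrom = f"chr{i % cfg.n_chroms + 1}"
        slot = i // cfg.n_chroms
        tss0 = 2000 + slot * cfg.gene_spacing
        strand = "+" if slot % 2 == 0 else "-"
        rows.append((gid, chrom, tss0, strand))
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss0", "strand"])


def _write_gff(genes: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genes.itertuples(index=False):
            if r.strand == "+":
                start1, end1 = r.tss0 + 1, r.tss0 + 1500
            else:
                start1, end1 = r.tss0 - 1500 + 1, r.tss0 + 1
            fh.write(
                f"{r.chrom}\tregcircuit\tgene\t{start1}\t{end1}\t.\t{r.strand}\t.\t"
                f"ID={r.gene};Name={r.gene}\n"
            )


def _make_pwms(cfg: SyntheticConfig, rng: np.random.Generator) -> list[PWM]:
    """Sharp, mutually distant PWMs so planted consensus hits are unambiguous."""
    bases = "ACGT"
    consensi: list[str] = []
    while len(consensi) < cfg.n_tfs:
        cand = "".join(bases[i] for i in rng.integers(0, 4, cfg.motif_width))
        ok = all(
            sum(a != b for a, b in zip(cand, c)) >= 6
            and sum(a != b for a, b in zip(cand, revcomp(c))) >= 6
            for c in consensi
        )
        if ok:
            consensi.append(cand)
    pwms = []
    for name, cons in zip(cfg.tf_names(), consensi):
        mat = np.full((cfg.motif_width, 4), 0.005)
        for i, b in enumerate(cons):
            mat[i, bases.index(b)] = 0.985
        pwms.append(PWM(f"M_{name}", name, mat))
    return pwms


@dataclass
class _Peak:
    name: str
    chrom: str
    start: int
    end: int
    stage: Optional[str]  # timepoint of planted accessibility gain, or None
    motifs: tuple[str, ...] = ()  # motif_ids planted inside
    rel_abundance: float = 1.0


def generate_dataset(config: SyntheticConfig, out_dir: str | Path) -> TruthLedger:
    """Write the full synthetic study into ``out_dir``; return the truth ledger."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = dataset_paths(out, config.timepoints)
    ss = np.random.SeedSequence(config.seed)
    (
        rng_motif, rng_peaks, rng_seq, rng_counts, rng_bulk, rng_sc, rng_ont
    ) = [np.random.default_rng(s) for s in ss.spawn(7)]
    ledger = TruthLedger()

    genes = _gene_positions(config)
    gene_pos = genes.set_index("gene")
    _write_gff(genes, paths["gff"])

    layout = _gene_layout(config)
    ledger.signature_genes = {"S": layout["s_genes"], "G2M": layout["g2m_genes"]}
    ledger.tf_genes = {tf: tf for tf in config.tf_names()}

    pwms = _make_pwms(config, rng_motif)
    write_meme(pwms, paths["meme"])
    motif_of = {p.tf_name: p for p in pwms}

    peaks = _plan_peaks(config, layout, gene_pos, rng_peaks, ledger)
    _write_peak_files(config, peaks, paths)
    _write_sequences(config, peaks, motif_of, rng_seq, paths["fasta"], ledger)
    _write_atac_counts(config, peaks, rng_counts, paths)
    _write_bulk(config, layout, rng_bulk, paths)
    _write_single_cell(config, layout, rng_sc, paths, ledger)
    _write_ontology(config, rng_ont, paths)
    ledger.circuit_truth = [
        {"tf": tf, "target": target, "stage": stage}
        for tf, target, stage in config.planted_circuit
    ]
    ledger.save(paths["ledger"])
    return ledger


def _gene_layout(cfg: SyntheticConfig) -> dict:
    """Deterministic assignment of gene indices to planted roles."""
    ids = cfg.gene_ids()
    tf = cfg.tf_names()
    circuit_targets = sorted(
        {t for _, t, _ in cfg.planted_circuit if t not in tf}
    )
    pool = [g for g in ids[cfg.n_tfs :] if g not in circuit_targets]
    need = cfg.n_decoys + 2 * cfg.n_signature_genes + 2 + cfg.n_shared_motif_peaks + (
        cfg.n_clusters * cfg.n_markers_per_cluster
    )
    if need > len(pool):
        raise ValueError(
            f"n_genes={cfg.n_genes} too small for the planted structure "
            f"(needs at least {cfg.n_tfs + len(circuit_targets) + need})"
        )
    cursor = 0
    decoys = pool[cursor : cursor + cfg.n_decoys]
    cursor += cfg.n_decoys
    s_genes = pool[cursor : cursor + cfg.n_signature_genes]
    cursor += cfg.n_signature_genes
    g2m_genes = pool[cursor : cursor + cfg.n_signature_genes]
    cursor += cfg.n_signature_genes
    linkage = pool[cursor : cursor + 2]
    cursor += 2
    shared_targets = pool[cursor : cursor + cfg.n_shared_motif_peaks]
    cursor += cfg.n_shared_motif_peaks
    markers = {}
    for cl in cfg.cluster_names():
        markers[cl] = pool[cursor : cursor + cfg.n_markers_per_cluster]
        cursor += cfg.n_markers_per_cluster
    return {
        "tf": tf,
        "circuit_targets": circuit_targets,
        "decoys": list(decoys),
        "s_genes": list(s_genes),
        "g2m_genes": list(g2m_genes),
        "linkage": list(linkage),
        "shared_targets": list(shared_targets),
        "markers": markers,
    }


def _flanking_contrasts(cfg: SyntheticConfig, stage: str) -> list[tuple[str, str]]:
    tps = list(cfg.timepoints)
    i = tps.index(stage)
    out = []
    if i > 0:
        out.append((tps[i - 1], tps[i], "up_in_2"))
    if i + 1 < len(tps):
        out.append((tps[i], tps[i + 1], "up_in_1"))
    return out


def _plan_peaks(
    cfg: SyntheticConfig,
    layout: dict,
    gene_pos: pd.DataFrame,
    rng: np.random.Generator,
    ledger: TruthLedger,
) -> list[_Peak]:
    peaks: list[_Peak] = []
    counter = [0]

    def new_peak(
        near_gene: Optional[str],
        stage: Optional[str],
        motif_tf: Optional[str] | Sequence[str],
        shift: int = 0,
    ) -> _Peak:
        counter[0] += 1
        name = f"peak{counter[0]:05d}"
        if near_gene is not None:
            row = gene_pos.loc[near_gene]
            mid = int(row.tss0) + shift + int(rng.integers(-40, 41))
            chrom = row.chrom
        else:
            chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
            mid = int(rng.integers(cfg.peak_width, cfg.genome_length - cfg.peak_width))
        start = max(0, mid - cfg.peak_width // 2)
        if motif_tf is None:
            planted_motifs: tuple[str, ...] = ()
        elif isinstance(motif_tf, str):
            planted_motifs = (f"M_{motif_tf}",)
        else:
            planted_motifs = tuple(f"M_{t}" for t in motif_tf)
        p = _Peak(
            name, chrom, start, start + cfg.peak_width, stage,
            motifs=planted_motifs,
            rel_abundance=float(rng.lognormal(0.0, 0.4)),
        )
        peaks.append(p)
        if stage is not None:
            for g1, g2, direction in _flanking_contrasts(cfg, stage):
                ledger.da_truth.append(
                    {
                        "peak": name,
                        "contrast": f"{g1}|{g2}",
                        "direction": direction,
                        "stage": stage,
                    }
                )
        return p

    # circuit edges: DA peaks at the edge's stage, nearest the target, TF motif
    # inside; several supporting elements per edge, as for real regulatory links
    for tf, target, stage in cfg.planted_circuit:
        for j in range(cfg.n_peaks_per_edge):
            new_peak(target, stage, tf, shift=j * 300)
    # early-stage linkage evidence for entry TFs (and for the expressed decoy TF)
    entry_tfs = []
    first_edge_stage = min(
        (cfg.timepoints.index(s) for _, _, s in cfg.planted_circuit), default=None
    )
    if cfg.planted_circuit:
        linkage_stage = cfg.timepoints[max(1, first_edge_stage - 1)]
        entry_tfs.append(cfg.planted_circuit[0][0])
    else:
        linkage_stage = cfg.timepoints[1]
    if cfg.n_tfs >= 4:
        entry_tfs.append(cfg.tf_names()[3])  # the non-DE decoy TF needs entry too
    for tf, lg in zip(entry_tfs, layout["linkage"]):
        for j in range(cfg.n_peaks_per_edge):
            new_peak(lg, linkage_stage, tf, shift=j * 300)
    # decoy genes: each violates exactly one edge criterion
    da_stages = [tp for tp in cfg.timepoints[2:]] or [cfg.timepoints[-1]]
    categories = ["non_da_peak", "no_motif", "tf_unexpressed", "target_not_de"]
    tf_names = cfg.tf_names()
    for i, gene in enumerate(layout["decoys"]):
        cat = categories[i % len(categories)]
        stage = da_stages[(i // len(categories)) % len(da_stages)]
        if cat == "non_da_peak":
            p = new_peak(gene, None, tf_names[0])
        elif cat == "no_motif":
            p = new_peak(gene, stage, None)
        elif cat == "tf_unexpressed" and cfg.n_tfs >= 3:
            p = new_peak(gene, stage, tf_names[2])
        else:
            cat = "target_not_de"
            p = new_peak(gene, stage, tf_names[3] if cfg.n_tfs >= 4 else tf_names[0])
        ledger.decoy_truth.append(
            {"gene": gene, "category": cat, "stage": stage, "peak": p.name}
        )
    # regions carrying the motifs of both circuit TFs (co-regulated targets);
    # their candidate edges are blocked downstream (no entry linkage for the
    # second TF; non-DE targets for the first), so they only feed the
    # target-overlap summary
    if cfg.n_tfs >= 2 and len(cfg.timepoints) >= 3:
        pair = tf_names[:2]
        for gene in layout["shared_targets"]:
            new_peak(gene, cfg.timepoints[2], pair)
    # background peaks, a fraction with generic stage-specific gains
    n_background = cfg.n_peaks - len(peaks)
    n_bg_da = int(round(cfg.da_fraction * max(n_background, 0)))
    for j in range(max(n_background, 0)):
        stage = (
            cfg.timepoints[1 + int(rng.integers(0, len(cfg.timepoints) - 1))]
            if j < n_bg_da
            else None
        )
        new_peak(None, stage, None)
    return peaks


def _write_peak_files(cfg: SyntheticConfig, peaks: list[_Peak], paths: dict) -> None:
    consensus = [
        GenomicInterval(p.chrom, p.start, p.end, p.name, ".") for p in peaks
    ]
    write_bed(sorted(consensus, key=lambda iv: (iv.chrom, iv.start, iv.name)),
              paths["consensus_bed"])
    for tp in cfg.timepoints:
        called = [
            GenomicInterval(p.chrom, p.start, p.end, p.name, ".")
            for p in peaks
            if p.stage is None or p.stage == tp
        ]
        write_bed(sorted(called, key=lambda iv: (iv.chrom, iv.start, iv.name)),
                  paths[f"bed_{tp}"])


def _write_sequences(
    cfg: SyntheticConfig,
    peaks: list[_Peak],
    motif_of: dict[str, PWM],
    rng: np.random.Generator,
    path: Path,
    ledger: TruthLedger,
) -> None:
    bases = np.array(list("ACGT"))
    pwm_by_id = {p.motif_id: p for p in motif_of.values()}
    seqs: dict[str, str] = {}
    for p in peaks:
        seq = list(bases[rng.integers(0, 4, cfg.peak_width)])
        # plant each motif in its own disjoint window of the peak
        n_m = len(p.motifs)
        for mi, motif_id in enumerate(p.motifs):
            pwm = pwm_by_id[motif_id]
            w = pwm.width
            lo = 10 + mi * (cfg.peak_width - 20) // max(n_m, 1)
            hi = 10 + (mi + 1) * (cfg.peak_width - 20) // max(n_m, 1) - w
            offset = int(rng.integers(lo, hi))
            strand = "+" if rng.random() < 0.5 else "-"
            planted = pwm.consensus if strand == "+" else revcomp(pwm.consensus)
            seq[offset : offset + w] = list(planted)
            ledger.motif_truth.append(
                {"peak": p.name, "motif": motif_id, "offset": offset, "strand": strand}
            )
        seqs[p.name] = "".join(seq)
    write_fasta(seqs, path)


def _write_atac_counts(
    cfg: SyntheticConfig, peaks: list[_Peak], rng: np.random.Generator, paths: dict
) -> None:
    low = cfg.baseline_mean / (2.0 ** cfg.da_log2fc)
    sample_names, rows = [], []
    means = np.zeros((len(peaks), len(cfg.timepoints)))
    for pi, p in enumerate(peaks):
        for ti, tp in enumerate(cfg.timepoints):
            base = cfg.baseline_mean if (p.stage is None or p.stage == tp) else low
            means[pi, ti] = base * p.rel_abundance
    cols = {}
    for ti, tp in enumerate(cfg.timepoints):
        for r in range(cfg.n_replicates):
            name = f"{tp}_r{r+1}"
            cols[name] = sample_nb_counts(means[:, ti], cfg.dispersion, rng=rng)
            rows.append((name, tp, "pax6", r + 1))
            sample_names.append(name)
    counts = pd.DataFrame(cols, index=pd.Index([p.name for p in peaks], name="feature"))
    CountMatrix(counts).to_tsv(paths["counts"])
    pd.DataFrame(rows, columns=["sample", "timepoint", "condition", "replicate"]).to_csv(
        paths["sheet"], sep="\t", index=False
    )


def _write_bulk(
    cfg: SyntheticConfig, layout: dict, rng: np.random.Generator, paths: dict
) -> None:
    ids = cfg.gene_ids()
    unexpressed = {ids[2]} if cfg.n_tfs >= 3 else set()  # the "TF unexpressed" decoy TF
    base = np.clip(rng.lognormal(np.log(30.0), 0.5, len(ids)), 2.0, None)
    for tp in cfg.timepoints:
        wiggle = rng.lognormal(0.0, 0.1, len(ids))
        cpm = base * wiggle
        cpm[[ids.index(g) for g in unexpressed]] = 0.0
        pd.DataFrame({"gene": ids, "cpm": cpm}).to_csv(
            paths[f"bulk_{tp}"], sep="\t", index=False, float_format="%.6g"
        )


def load_bulk_expression(out_dir: str | Path, timepoints: Sequence[str]) -> pd.DataFrame:
    """Assemble the per-timepoint bulk tables into one genes x stages frame."""
    cols = {}
    for tp in timepoints:
        df = pd.read_csv(Path(out_dir) / f"bulk_{tp}.tsv", sep="\t")
        cols[tp] = df.set_index("gene")["cpm"]
    return pd.DataFrame(cols)


def _write_single_cell(
    cfg: SyntheticConfig,
    layout: dict,
    rng: np.random.Generator,
    paths: dict,
    ledger: TruthLedger,
) -> None:
    ids = cfg.gene_ids()
    n_genes = len(ids)
    gene_idx = {g: i for i, g in enumerate(ids)}
    base = rng.lognormal(np.log(0.8), 0.6, n_genes)
    for tf in layout["tf"]:
        base[gene_idx[tf]] = 1.0
    for g in layout["circuit_targets"]:
        base[gene_idx[g]] = 1.0
    # cycling-gene baselines spread over the expression range (like real
    # signature genes) so binned controls are ordinary genes, not the
    # opposite signature
    sig = layout["s_genes"] + layout["g2m_genes"]
    base[[gene_idx[g] for g in sig]] = rng.lognormal(np.log(0.25), 0.5, len(sig))
    for cl, genes in layout["markers"].items():
        for g in genes:
            base[gene_idx[g]] = 1.0

    de_genes = sorted(
        {t for _, t, _ in cfg.planted_circuit}
    )
    for g in de_genes:
        ledger.de_truth.append({"gene": g, "cluster": "all", "direction": "up_in_24hpa"})
    for cl, genes in layout["markers"].items():
        for g in genes:
            ledger.marker_truth.append({"gene": g, "cluster": cl})

    clusters = cfg.cluster_names()
    s_cols = [gene_idx[g] for g in layout["s_genes"]]
    g2m_cols = [gene_idx[g] for g in layout["g2m_genes"]]
    de_cols = [gene_idx[g] for g in de_genes]

    cells, rows = [], []
    mat = []
    for tp in cfg.sc_timepoints:
        cl_fr = np.asarray(cfg.cluster_fractions[tp])
        cy_fr = np.asarray(cfg.cycle_fractions[tp])
        cl_draw = rng.choice(len(clusters), size=cfg.n_cells, p=cl_fr)
        ph_draw = rng.choice(3, size=cfg.n_cells, p=cy_fr)  # 0=S 1=G2M 2=G1
        lib = rng.lognormal(0.0, 0.3, cfg.n_cells)
        for i in range(cfg.n_cells):
            cell = f"{tp}_cell{i+1:04d}"
            cl = clusters[cl_draw[i]]
            phase = ("S", "G2M", "G1")[ph_draw[i]]
            mean = base.copy()
            for g in layout["markers"][cl]:
                mean[gene_idx[g]] *= 2.0 ** cfg.marker_log2fc
            if phase == "S":
                mean[s_cols] *= 2.0 ** cfg.cycle_log2fc
            elif phase == "G2M":
                mean[g2m_cols] *= 2.0 ** cfg.cycle_log2fc
            if tp == "24hpa" and de_cols:
                mean[de_cols] *= 2.0 ** cfg.marker_log2fc
            mat.append(sample_nb_counts(mean * lib[i], cfg.sc_dispersion, rng=rng))
            cells.append(cell)
            rows.append((cell, tp, cl))
            ledger.phase_truth.append({"cell": cell, "phase": phase})
    x = np.vstack(mat)  # cells x genes
    mmwrite(str(paths["mtx"]), sp.coo_matrix(x.T.astype(np.int64)), field="integer")
    pd.Series(ids).to_csv(paths["sc_genes"], sep="\t", index=False, header=False)
    pd.DataFrame(rows, columns=["cell", "timepoint", "cluster"]).to_csv(
        paths["sc_meta"], sep="\t", index=False
    )
    write_gene_list(layout["s_genes"], paths["s_genes"])
    write_gene_list(layout["g2m_genes"], paths["g2m_genes"])


def _write_ontology(cfg: SyntheticConfig, rng: np.random.Generator, paths: dict) -> None:
    root = "T00"
    mids = [f"T{i:02d}" for i in range(1, 6)]
    leaves = [f"T{i:02d}" for i in range(6, 30)]
    edges = [(m, root) for m in mids]
    names = {root: "biological_process"}
    for i, leaf in enumerate(leaves):
        edges.append((leaf, mids[i % 5]))
        if i % 5 == 0:
            edges.append((leaf, mids[(i + 1) % 5]))
        names[leaf] = f"process_{leaf}"
    for m in mids:
        names[m] = f"family_{m}"
    ont = Ontology(edges, names)
    write_ontology_tsv(ont, paths["ontology"])
    ids = cfg.gene_ids()
    raw = {}
    for g in ids:
        k = 1 + int(rng.integers(0, 2))
        raw[g] = sorted(
            leaves[j] for j in rng.choice(len(leaves), size=k, replace=False)
        )
    write_gene2term_tsv(raw, paths["gene2term"])
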