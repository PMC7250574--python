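"""PWM log-odds scanning of peak sequences.

A PWM stores per-position nucleotide probabilities; scanning scores every
window of the sequence (both strands) with log2-odds against a background
model and reports placements above a threshold, given either in bits or
as a fraction of the motif's maximum attainable score.  Windows touching
an ambiguous base (N) are skipped, not imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PWM",
    "MotifHit",
    "log_odds",
    "revcomp",
    "scan",
    "scan_peakset",
    "read_fasta",
    "write_fasta",
    "read_meme",
    "write_meme",
    "read_homer",
    "estimate_background",
]

ALPHABET = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")
_ENCODE = {b: i for i, b in enumerate(ALPHABET)}
_ENCODE["N"] = 4
_NEG_INF = -1e9


@dataclass
class PWM:
    """Position probability matrix with a mononucleotide background."""

    motif_id: str
    tf_name: str
    matrix: np.ndarray  # width x 4, rows sum to 1
    background: np.ndarray = None  # length 4

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: matrix must be width x 4")
        if self.matrix.shape[0] < 4:
            raise ValueError(f"{self.motif_id}: motif width must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: probability rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def max_score(self, pseudocount: float = 0.01) -> float:
        return float(log_odds(self, pseudocount).max(axis=1).sum())


@dataclass(frozen=True)
class MotifHit:
    """A scored motif placement inside a peak sequence.

    ``offset`` is 0-based on the forward strand of the peak regardless of
    hit strand; ``score`` is in bits.
    """

    peak: str
    motif_id: str
    offset: int
    strand: str
    score: float


def log_odds(pwm: PWM, pseudocount: float = 0.01) -> np.ndarray:
    """log2((p + pc*bg) / ((1 + pc) * bg)) per position and base."""
    bg = pwm.background
    if (bg <= 0).any():
        raise ValueError("background probabilities must be positive")
    return np.log2((pwm.matrix + pseudocount * bg) / ((1.0 + pseudocount) * bg))


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _window_scores(seq: str, scores: np.ndarray) -> np.ndarray:
    """Score every window of ``seq``; windows containing N get -inf."""
    w = scores.shape[0]
    if len(seq) < w:
        return np.empty(0)
    idx = np.fromiter((_ENCODE.get(c, 4) for c in seq.upper()), dtype=np.int64)
    padded = np.hstack([scores, np.full((w, 1), _NEG_INF)])
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    vals = padded[np.arange(w)[None, :], windows].sum(axis=1)
    return np.where(vals < _NEG_INF / 2, -np.inf, vals)


def resolve_threshold(
    pwm: PWM,
    min_score: Optional[float] = None,
    frac_of_max: float = 0.8,
    pseudocount: float = 0.01,
) -> float:
    if min_score is not None:
        return float(min_score)
    return frac_of_max * pwm.max_score(pseudocount)


def scan(
    sequence: str,
    pwm: PWM,
    min_score: Optional[float] = None,
    frac_of_max: float = 0.8,
    pseudocount: float = 0.01,
    peak_name: str = "",
) -> list[MotifHit]:
    """Scan one sequence on both strands; report hits at score >= threshold.

    Minus-strand hits are produced by scanning the reverse complement and
    reporting the window start mapped back to forward-strand coordinates
    (offset' = L - width - offset).
    """
    thr = resolve_threshold(pwm, min_score, frac_of_max, pseudocount)
    sm = log_odds(pwm, pseudocount)
    w = pwm.width
    L = len(sequence)
    hits: list[MotifHit] = []
    fwd = _window_scores(sequence, sm)
    for off in np.flatnonzero(fwd >= thr - 1e-9):
        hits.append(MotifHit(peak_name, pwm.motif_id, int(off), "+", float(fwd[off])))
    rev = _window_scores(revcomp(sequence), sm)
    for off in np.flatnonzero(rev >= thr - 1e-9):
        hits.append(
            MotifHit(peak_name, pwm.motif_id, int(L - w - off), "-", float(rev[off]))
        )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_peakset(
    sequences: Mapping[str, str] | str | Path,
    library: Sequence[PWM],
    frac_of_max: float = 0.8,
    min_score: Optional[float] = None,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Scan every peak against every motif; one row per (peak, motif, offset, strand)."""
    if not isinstance(sequences, Mapping):
        sequences = read_fasta(sequences)
    rows = []
    tf_of = {p.motif_id: p.tf_name for p in library}
    for peak in sequences:
        seq = sequences[peak]
        for pwm in library:
            for h in scan(
                seq, pwm, min_score=min_score, frac_of_max=frac_of_max,
                pseudocount=pseudocount, peak_name=peak,
            ):
                rows.append(
                    (h.peak, h.motif_id, tf_of[h.motif_id], h.offset, h.strand, h.score)
                )
    return pd.DataFrame(
        rows, columns=["peak", "motif_id", "tf_name", "offset", "strand", "score"]
    )


def estimate_background(sequences: Mapping[str, str]) -> np.ndarray:
    """Mononucleotide frequencies pooled over a set of sequences (N ignored)."""
    counts = np.zeros(4)
    for seq in sequences.values():
        for c in seq.upper():
            i = _ENCODE.get(c, 4)
            if i < 4:
                counts[i] += 1
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate peak name in FASTA: {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_meme(path: str | Path) -> list[PWM]:
    """Parse MEME-minimal motif files."""
    pwms: list[PWM] = []
    background = np.full(4, 0.25)
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            toks = lines[i].split()
            freq = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = np.array([freq.get(b, 0.25) for b in ALPHABET])
        elif line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1]
            tf_name = parts[2] if len(parts) > 2 else motif_id
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                i += 1
            header = lines[i].strip()
            w = int(header.split("w=")[1].split()[0])
            rows = []
            for k in range(w):
                i += 1
                rows.append([float(x) for x in lines[i].split()])
            pwms.append(PWM(motif_id, tf_name, np.array(rows), background.copy()))
        i += 1
    return pwms


def write_meme(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {bg[i]:.6f}" for i, b in enumerate(ALPHABET)) + "\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.motif_id} {p.tf_name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in p.matrix:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_homer(path: str | Path) -> list[PWM]:
    """Convert HOMER ``.motif`` probability files (rows are A C G T)."""
    pwms: list[PWM] = []
    rows: list[list[float]] = []
    header: Optional[tuple[str, str]] = None

    def _flush() -> None:
        nonlocal rows, header
        if header is not None and rows:
            motif_id, tf_name = header
            mat = np.array(rows)
            mat = mat / mat.sum(axis=1, keepdims=True)
            pwms.append(PWM(motif_id, tf_name, mat))
        rows = []

    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            _flush()
            parts = line[1:].split("\t")
            name = parts[1] if len(parts) > 1 else parts[0]
            tf = name.split("(")[0].split("/")[0]
            header = (name, tf)
        elif line.strip():
            rows.append([float(x) for x in line.split()])
    _flush()
    return pwms


def write_hit_table(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_hit_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"peak": str, "motif_id": str, "tf_name": str})
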