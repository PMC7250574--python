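"""Single-cell statistics: normalisation, composition tables, cell-cycle
module scoring with phase assignment, and rank-sum marker tests.

Embedding and clustering are out of scope here; cluster labels arrive as
cell metadata.  Counts are held in an AnnData (cells x genes) whose
``lognorm`` layer stores ln(1 + scale * count / libsize).
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from scipy.stats import mannwhitneyu, rankdata

__all__ = [
    "read_sc_dataset",
    "write_sc_dataset",
    "read_gene_list",
    "write_gene_list",
    "lognormalize",
    "module_score",
    "assign_phase",
    "composition",
    "rank_sum_markers",
]


def read_sc_dataset(
    mtx_path: str | Path, genes_path: str | Path, meta_path: str | Path
) -> ad.AnnData:
    """Load a genes-x-cells MatrixMarket matrix into a cells-x-genes AnnData."""
    mat = sp.csr_matrix(mmread(str(mtx_path)).T)
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("cell")
    adata = ad.AnnData(X=mat, obs=meta, var=pd.DataFrame(index=genes))
    if adata.n_obs != len(meta):
        raise ValueError("cell metadata rows do not match matrix columns")
    return adata


def write_sc_dataset(
    adata: ad.AnnData,
    mtx_path: str | Path,
    genes_path: str | Path,
    meta_path: str | Path,
) -> None:
    x = sp.coo_matrix(adata.X).T.astype(np.int64)  # genes x cells
    mmwrite(str(mtx_path), x, field="integer")
    pd.Series(adata.var_names).to_csv(genes_path, sep="\t", index=False, header=False)
    meta = adata.obs.reset_index().rename(columns={"index": "cell"})
    meta.to_csv(meta_path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    return [
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    ]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


# ---------------------------------------------------------------------------
# Normalisation


def _dense_counts(adata: ad.AnnData) -> np.ndarray:
    x = adata.X
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x, dtype=float)


def lognormalize(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Store ln(1 + scale * count / libsize) in layer ``lognorm``.

    Cells with zero total counts are dropped with a warning.
    """
    counts = _dense_counts(adata)
    lib = counts.sum(axis=1)
    if (lib == 0).any():
        n_zero = int((lib == 0).sum())
        warnings.warn(f"dropping {n_zero} all-zero cells", stacklevel=2)
        adata = adata[lib > 0].copy()
        counts = counts[lib > 0]
        lib = lib[lib > 0]
    norm = np.log1p(scale * counts / lib[:, None])
    adata.layers["lognorm"] = norm
    return adata


# ---------------------------------------------------------------------------
# Cell-cycle scoring


def module_score(
    adata: ad.AnnData,
    gene_set: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    exclude_set: bool = True,
) -> np.ndarray:
    """Per-cell gene-set score against expression-matched controls.

    Genes are binned into ``n_bins`` equal-frequency bins by their mean
    normalised expression across cells.  For each set gene, ``n_ctrl``
    control genes are drawn (seeded, without replacement, capped at the
    pool size) from its bin, excluding the set itself.  The score is the
    mean set expression minus the mean control expression, per cell.
    """
    if "lognorm" not in adata.layers:
        raise ValueError("run lognormalize() first")
    genes = list(adata.var_names)
    present = sorted(set(gene_set) & set(genes))
    if not present:
        missing = sorted(set(gene_set))
        raise ValueError(f"no gene-set members found in data: {missing}")
    norm = np.asarray(adata.layers["lognorm"])
    avg = norm.mean(axis=0)
    # equal-frequency bins; ties broken by gene name for determinism
    order = sorted(range(len(genes)), key=lambda i: (avg[i], genes[i]))
    bin_of = np.empty(len(genes), dtype=int)
    for rank, gi in enumerate(order):
        bin_of[gi] = min(int(rank * n_bins / len(genes)), n_bins - 1)
    gene_idx = {g: i for i, g in enumerate(genes)}
    set_idx = {gene_idx[g] for g in present}
    rng = np.random.default_rng(seed)
    ctrl_idx: list[int] = []
    for g in present:
        gi = gene_idx[g]
        pool = [j for j in np.flatnonzero(bin_of == bin_of[gi])]
        if exclude_set:
            pruned = [j for j in pool if j not in set_idx]
            pool = pruned if pruned else pool
        pool = sorted(pool, key=lambda j: genes[j])
        take = min(n_ctrl, len(pool))
        ctrl_idx.extend(rng.choice(pool, size=take, replace=False).tolist())
    set_cols = sorted(set_idx)
    score = norm[:, set_cols].mean(axis=1) - norm[:, ctrl_idx].mean(axis=1)
    return np.asarray(score, dtype=float)


def assign_phase(s_score: np.ndarray, g2m_score: np.ndarray) -> np.ndarray:
    """G1 iff both scores <= 0; else the phase with the larger score."""
    s = np.asarray(s_score, dtype=float)
    g = np.asarray(g2m_score, dtype=float)
    if not (np.isfinite(s).all() and np.isfinite(g).all()):
        raise ValueError("phase scores must be finite")
    out = np.where((s <= 0) & (g <= 0), "G1", np.where(s > g, "S", "G2M"))
    return out


# ---------------------------------------------------------------------------
# Composition


def composition(
    meta: pd.DataFrame, by: str = "cluster", within: str = "timepoint"
) -> pd.DataFrame:
    """Per-``within`` fractions of cells per ``by`` category (rows sum to 1)."""
    if meta.empty:
        raise ValueError("empty cell metadata")
    for col in (by, within):
        if col not in meta.columns:
            raise ValueError(f"unknown metadata column {col!r}")
    tab = pd.crosstab(meta[within], meta[by])
    return tab.div(tab.sum(axis=1), axis=0)


# ---------------------------------------------------------------------------
# Marker / differential-expression tests


def _exact_ranksum_p(values: np.ndarray, n1: int) -> float:
    """Two-sided exact rank-sum p by full enumeration of group-1 index sets."""
    n = values.size
    ranks = rankdata(values)
    mu = n1 * (n + 1) / 2.0
    w_obs = ranks[:n1].sum()
    dev = abs(w_obs - mu) - 1e-9
    hits = 0
    total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= dev:
            hits += 1
    return hits / total


def rank_sum_markers(
    adata: ad.AnnData,
    groupby: str,
    group_1: str,
    group_2: Optional[str] = None,
    min_pct: float = 0.3,
    only_pos: bool = False,
    exact_limit: int = 1000,
) -> pd.DataFrame:
    """Wilcoxon rank-sum marker table between two cell groups.

    Genes detected (count > 0) in >= ``min_pct`` of either group are
    tested on the normalised layer; p-values use the tie-corrected normal
    approximation, or full permutation enumeration when the number of
    group splits is at most ``exact_limit``.  log2 fold change uses
    expm1 means with a pseudo-mean of 1; adjustment is Bonferroni over
    tested genes.  ``group_2=None`` means the complement of group 1.
    """
    if "lognorm" not in adata.layers:
        raise ValueError("run lognormalize() first")
    labels = adata.obs[groupby].astype(str)
    mask1 = (labels == group_1).to_numpy()
    mask2 = (
        ~mask1 if group_2 is None else (labels == group_2).to_numpy()
    )
    if mask1.sum() < 3 or mask2.sum() < 3:
        raise ValueError("each group needs at least three cells")
    counts = _dense_counts(adata)
    norm = np.asarray(adata.layers["lognorm"])
    x1, x2 = norm[mask1], norm[mask2]
    c1, c2 = counts[mask1], counts[mask2]
    pct1 = (c1 > 0).mean(axis=0)
    pct2 = (c2 > 0).mean(axis=0)
    tested = np.flatnonzero(np.maximum(pct1, pct2) >= min_pct)
    if tested.size == 0:
        return pd.DataFrame(
            columns=[
                "gene", "log2fc", "pct_1", "pct_2", "p_value", "p_adjusted",
            ]
        )
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    use_exact = math.comb(n1 + n2, n1) <= exact_limit
    if use_exact:
        pvals = np.array(
            [
                _exact_ranksum_p(
                    np.concatenate([x1[:, g], x2[:, g]]), n1
                )
                for g in tested
            ]
        )
    else:
        res = mannwhitneyu(
            x1[:, tested], x2[:, tested], alternative="two-sided",
            method="asymptotic", axis=0,
        )
        pvals = np.asarray(res.pvalue)
    m1 = np.expm1(x1[:, tested]).mean(axis=0)
    m2 = np.expm1(x2[:, tested]).mean(axis=0)
    log2fc = np.log2((m1 + 1.0) / (m2 + 1.0))
    out = pd.DataFrame(
        {
            "gene": adata.var_names[tested],
            "log2fc": log2fc,
            "pct_1": pct1[tested],
            "pct_2": pct2[tested],
            "p_value": pvals,
            "p_adjusted": np.minimum(pvals * tested.size, 1.0),
        }
    )
    if only_pos:
        out = out[out["log2fc"] > 0]
    return out.sort_values(["p_adjusted", "p_value", "gene"], kind="stable").reset_index(
        drop=True
    )
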