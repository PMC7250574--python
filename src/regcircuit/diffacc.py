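"""Differential chromatin accessibility from peak-count matrices.

The model is the classic pairwise negative-binomial (NB) workflow for
count matrices with few replicates:

1. filter peaks with >= ``min_cpm`` counts-per-million in at least
   ``n - 1`` of the samples entering the contrast,
2. trimmed-mean-of-M-values (TMM) normalisation factors,
3. counts linearly rescaled to the geometric-mean effective library size
   (round half to even), so samples are directly comparable,
4. a common NB dispersion estimated by maximising the conditional
   log-likelihood (conditioning on within-group totals),
5. a per-peak exact test conditional on the two-group total, with
   Benjamini-Hochberg FDR across peaks.

Counts are NB with Var = mu + phi * mu^2; phi = 0 is the Poisson limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "read_counts_tsv",
    "read_sample_sheet",
    "validate_sample_sheet",
    "cpm",
    "cpm_filter",
    "tmm_factors",
    "scale_to_common_libsize",
    "DispersionEstimate",
    "estimate_dispersion",
    "nb_exact_test",
    "da_table",
    "direction_counts",
    "timepoint_specific_peaks",
    "mds_embedding",
]


@dataclass
class CountMatrix:
    """Peak-by-sample integer counts with per-sample library sizes."""

    counts: pd.DataFrame  # features x samples, non-negative integers

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(samples)].copy())

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "feature", out.index)
        out.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df.index.name = "feature"
    return CountMatrix(df.astype(np.int64))


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    sheet["replicate"] = sheet["replicate"].astype(int)
    return sheet


def validate_sample_sheet(m: CountMatrix, sheet: pd.DataFrame) -> None:
    if set(sheet["sample"]) != set(m.samples) or len(sheet) != len(m.samples):
        raise ValueError("sample sheet rows are not bijective with count columns")


# ---------------------------------------------------------------------------
# Normalisation


def cpm(m: CountMatrix, log2: bool = False, prior: float = 1.0) -> pd.DataFrame:
    """Counts per million; optionally log2(CPM + prior)."""
    lib = m.lib_sizes
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for samples {bad}")
    vals = m.counts / lib * 1e6
    return np.log2(vals + prior) if log2 else vals


def cpm_filter(
    m: CountMatrix, min_cpm: float = 1.0, min_samples: Optional[int] = None
) -> CountMatrix:
    """Keep features with CPM >= min_cpm in at least min_samples samples.

    ``min_samples`` defaults to ``n_samples - 1`` (the "at least one count
    per million in n-1 samples" rule).  An empty result warns rather than
    raising.
    """
    if min_samples is None:
        min_samples = m.counts.shape[1] - 1
    keep = (cpm(m) >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("cpm_filter removed every feature", stacklevel=2)
    return CountMatrix(m.counts.loc[keep].copy())


def tmm_factors(
    m: CountMatrix,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalisation factors.

    The reference sample is the one whose 75th-percentile CPM is closest
    to the mean of those quantiles.  For every sample, M (log2 ratio to
    the reference, after library-size scaling) and A (mean log2 abundance)
    are computed over features positive in both samples; the most extreme
    30% of M on each side and 5% of A on each side are trimmed, and the
    remaining M are averaged with inverse-asymptotic-variance weights.
    Factors are rescaled to have geometric mean one.
    """
    counts = m.counts.to_numpy(dtype=float)
    lib = m.lib_sizes.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    if (lib <= 0).any():
        raise ValueError("sample with zero library size")
    q75 = np.array(
        [np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])]
    )
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        factors[j] = 2.0 ** _tmm_pair(
            counts[:, j], counts[:, ref], lib[j], lib[ref], logratio_trim, abs_trim
        )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.samples, name="tmm_factor")


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    abs_trim: float,
) -> float:
    """Weighted trimmed mean of M values for one sample against the reference."""
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos], ref[pos]
    if obs.size == 0:
        return 0.0
    p_obs = obs / n_obs
    p_ref = ref / n_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    # binomial asymptotic variance of M
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = M.size
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
    lo_a, hi_a = np.floor(n * abs_trim) + 1, n - np.floor(n * abs_trim)
    rank_m = _rank(M)
    rank_a = _rank(A)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    f = np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 0.0
    # a weighted mean of near-zero M values is numerically zero
    return 0.0 if abs(f) < 1e-10 else float(f)


def _rank(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based), matching R's rank() for trimming."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size, dtype=float)
    sx = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def scale_to_common_libsize(
    m: CountMatrix, factors: Optional[pd.Series] = None
) -> CountMatrix:
    """Rescale counts to the geometric-mean effective library size.

    Effective library size = raw library size x TMM factor.  Counts are
    multiplied by the per-sample ratio and rounded half to even so the
    matrix stays integral.
    """
    if factors is None:
        factors = tmm_factors(m)
    eff = m.lib_sizes.to_numpy(dtype=float) * factors.loc[m.samples].to_numpy()
    common = np.exp(np.mean(np.log(eff)))
    scaled = np.round(m.counts.to_numpy(dtype=float) * (common / eff))
    return CountMatrix(
        pd.DataFrame(scaled.astype(np.int64), index=m.features, columns=m.samples)
    )


# ---------------------------------------------------------------------------
# Dispersion


@dataclass
class DispersionEstimate:
    phi: float
    method: str = "conditional_likelihood"


def _cond_loglik(counts: np.ndarray, groups: np.ndarray, phi: float) -> float:
    """Summed per-feature conditional NB log-likelihood at dispersion phi.

    For each group with n replicates, conditions on the feature's group
    total z; data-only terms that do not involve phi are dropped.
    Features with zero group total carry no information and are skipped.
    """
    r = 1.0 / phi
    total = 0.0
    for g in np.unique(groups):
        y = counts[:, groups == g]
        n = y.shape[1]
        if n < 2:
            continue
        z = y.sum(axis=1)
        keep = z > 0
        if not keep.any():
            continue
        y = y[keep]
        z = z[keep]
        total += float(
            np.sum(gammaln(y + r))
            - y.shape[0] * n * gammaln(r)
            + y.shape[0] * gammaln(n * r)
            - np.sum(gammaln(z + n * r))
        )
    return total


def estimate_dispersion(
    m: CountMatrix,
    groups: Sequence[str],
    grid: Optional[np.ndarray] = None,
) -> DispersionEstimate:
    """Common NB dispersion by conditional maximum likelihood.

    Counts should already be scaled to a common effective library size.
    The likelihood is evaluated on a log-spaced grid over [1e-4, 10] and
    the maximum refined by bounded scalar optimisation.
    """
    groups = np.asarray(groups)
    counts = m.counts.to_numpy(dtype=float)
    sizes = [np.sum(groups == g) for g in np.unique(groups)]
    if max(sizes) < 2:
        raise ValueError(
            "no group has replication; supply a dispersion estimated elsewhere"
        )
    if grid is None:
        grid = np.logspace(-4, 1, 25)
    # constant counts within every group carry no dispersion information
    no_info = all(
        np.all(counts[:, groups == g].var(axis=1) == 0) for g in np.unique(groups)
    )
    ll = np.array([_cond_loglik(counts, groups, p) for p in grid])
    if no_info or np.allclose(ll, ll[0], atol=1e-9):
        warnings.warn(
            "counts carry no dispersion information; returning the grid minimum",
            stacklevel=2,
        )
        return DispersionEstimate(float(grid[0]), method="degenerate_grid_minimum")
    best = int(np.argmax(ll))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda lp: -_cond_loglik(counts, groups, float(np.exp(lp))),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return DispersionEstimate(float(np.exp(res.x)))


# ---------------------------------------------------------------------------
# Exact test


def _cond_logpmf(t: int, n_a: float, n_b: float, phi: float) -> np.ndarray:
    """log P(group-A sum = k | total = t) for k = 0..t.

    With per-replicate NB(mu, phi) counts at equal effective library
    sizes, group sums are NB with sizes n/phi and a success probability
    shared between groups, so the conditional law is the Dirichlet
    (beta-binomial-like) form depending only on n_a/phi and n_b/phi.
    phi = 0 reduces to Binomial(t, n_a/(n_a+n_b)).
    """
    k = np.arange(t + 1, dtype=float)
    if phi <= 0:
        p = n_a / (n_a + n_b)
        lp = (
            gammaln(t + 1)
            - gammaln(k + 1)
            - gammaln(t - k + 1)
            + k * np.log(p)
            + (t - k) * np.log1p(-p)
        )
    else:
        r_a = n_a / phi
        r_b = n_b / phi
        lp = (
            gammaln(k + r_a)
            - gammaln(k + 1)
            - gammaln(r_a)
            + gammaln(t - k + r_b)
            - gammaln(t - k + 1)
            - gammaln(r_b)
        )
    return lp - logsumexp(lp)


def nb_exact_test(
    a: Sequence[float], b: Sequence[float], phi: float, _rel_tol: float = 1e-7
) -> float:
    """Two-sided exact NB test on two groups of pre-scaled counts.

    Conditional on the total t, sums every outcome whose conditional
    probability is <= that of the observed split (small-p method).  A
    relative tolerance absorbs floating-point ties.  t = 0 returns 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    s_a = int(round(a.sum()))
    s_b = int(round(b.sum()))
    t = s_a + s_b
    if t == 0:
        return 1.0
    lp = _cond_logpmf(t, a.size, b.size, phi)
    prob = np.exp(lp)
    obs = prob[s_a]
    return float(min(1.0, prob[prob <= obs * (1.0 + _rel_tol)].sum()))


# ---------------------------------------------------------------------------
# Contrast tables


def da_table(
    m: CountMatrix,
    sheet: pd.DataFrame,
    contrast: tuple[str, str],
    alpha: float = 0.05,
    min_cpm: float = 1.0,
    group_col: str = "timepoint",
    phi: Optional[float] = None,
) -> pd.DataFrame:
    """Differential-accessibility table for one two-group contrast.

    Runs the full path (CPM filter at n-1 over the contrast samples, TMM,
    scaling to a common library size, common-dispersion estimation, exact
    test per peak, BH FDR).  ``log2fc`` is group2 over group1; direction
    labels ``up_in_2`` / ``up_in_1`` are set at FDR <= alpha.
    Attributes ``contrast`` and ``phi`` are attached to the result.
    """
    g1, g2 = contrast
    validate_sample_sheet(m, sheet)
    samples1 = list(sheet.loc[sheet[group_col] == g1, "sample"])
    samples2 = list(sheet.loc[sheet[group_col] == g2, "sample"])
    if not samples1 or not samples2:
        raise ValueError(f"contrast group without samples: {contrast}")
    sub = m.subset_samples(samples1 + samples2)
    sub = cpm_filter(sub, min_cpm=min_cpm)
    scaled = scale_to_common_libsize(sub)
    groups = np.array(["g1"] * len(samples1) + ["g2"] * len(samples2))
    if phi is None:
        phi = estimate_dispersion(scaled, groups).phi
    counts = scaled.counts.to_numpy(dtype=float)
    c1 = counts[:, : len(samples1)]
    c2 = counts[:, len(samples1) :]
    pvals = np.array(
        [nb_exact_test(c1[i], c2[i], phi) for i in range(counts.shape[0])]
    )
    mean1 = c1.mean(axis=1)
    mean2 = c2.mean(axis=1)
    log2fc = np.log2((mean2 + 0.5) / (mean1 + 0.5))
    common_lib = scaled.lib_sizes.mean()
    log_cpm = np.log2((mean1 + mean2) / 2 / common_lib * 1e6 + 0.5)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    direction = np.where(
        fdr <= alpha,
        np.where(log2fc > 0, "up_in_2", np.where(log2fc < 0, "up_in_1", "ns")),
        "ns",
    )
    out = pd.DataFrame(
        {
            "feature": scaled.features,
            "log2fc": log2fc,
            "log_cpm": log_cpm,
            "p_value": pvals,
            "fdr": fdr,
            "direction": direction,
        }
    ).reset_index(drop=True)
    out.attrs["contrast"] = contrast
    out.attrs["phi"] = phi
    out.attrs["alpha"] = alpha
    return out


def direction_counts(da: pd.DataFrame) -> pd.Series:
    """Counts (and implied percentages) of peaks per DA direction."""
    return da["direction"].value_counts().reindex(
        ["up_in_1", "up_in_2", "ns"], fill_value=0
    )


def timepoint_specific_peaks(
    da_prev: pd.DataFrame, da_next: pd.DataFrame
) -> tuple[set[str], set[str], set[str]]:
    """Partition peaks up at a timepoint t flanked by two contrasts.

    ``da_prev`` contrasts (earlier, t): up at t is ``up_in_2``.
    ``da_next`` contrasts (t, later): up at t is ``up_in_1``.
    Returns (unique to prev contrast, transient = up in both, unique to
    next contrast).
    """
    up_prev = set(da_prev.loc[da_prev["direction"] == "up_in_2", "feature"])
    up_next = set(da_next.loc[da_next["direction"] == "up_in_1", "feature"])
    return up_prev - up_next, up_prev & up_next, up_next - up_prev


# ---------------------------------------------------------------------------
# MDS


def mds_embedding(m: CountMatrix, top_n: int = 500, n_axes: int = 2) -> pd.DataFrame:
    """Classical metric MDS of samples on log2-CPM Euclidean distances.

    Profiles are restricted to the ``top_n`` most variable features.
    Negative eigenvalues (rank deficiency) contribute zero-padded axes.
    Axis signs are fixed so the largest-magnitude loading is positive.
    """
    if m.counts.shape[1] < 3:
        raise ValueError("MDS needs at least three samples")
    lc = cpm(m, log2=True).to_numpy(dtype=float)
    var = lc.var(axis=1)
    idx = np.argsort(-var, kind="stable")[: min(top_n, lc.shape[0])]
    x = lc[idx].T  # samples x features
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    n = sq.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ sq @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(-evals)
    coords = np.zeros((n, n_axes))
    for ax, ei in enumerate(order[:n_axes]):
        if evals[ei] > 1e-10:
            v = evecs[:, ei] * np.sqrt(evals[ei])
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            coords[:, ax] = v
    return pd.DataFrame(
        coords, index=m.samples, columns=[f"dim{i+1}" for i in range(n_axes)]
    )
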