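"""Double-PETH construction, PCA embedding and lab/region comparison tests.

Each cell is summarized by two concatenated peri-event time histograms
aligned to first-movement onset — one over fast-reaction-time trials
(< 0.15 s), one over slow trials — each baseline-normalized, giving an
N x 2T matrix (T = 100 bins of 20 ms spanning -0.5 to 1.5 s). PCA on this
matrix yields a low-dimensional embedding per cell; lab and region
differences are then probed with two-sample KS tests on the first PC, a
2D mean-distance permutation test, and a cell-number-controlled variant
that subsamples groups to equal size and combines p-values with Fisher's
method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PethMatrix",
    "Embedding",
    "FisherResult",
    "build_peth_matrix",
    "pca_embed",
    "ks_target_test",
    "ks_test_grid",
    "distance_permutation_test",
    "fisher_combine",
    "subsampled_ks_fisher",
]


@dataclass
class PethMatrix:
    """N cells x 2T normalized double-PETH matrix with per-cell metadata."""

    Y: np.ndarray
    cell_meta: pd.DataFrame       # columns: lab, region, session, unit_id
    bin_centers: np.ndarray       # seconds relative to movement onset (length T)
    rt_threshold: float
    baseline_window: tuple
    epsilon: float
    n_excluded: int


@dataclass
class Embedding:
    """Truncated-SVD embedding of the PETH matrix: scores U (N x k),
    temporal components V (k x 2T) and per-cell reconstruction R^2."""

    U: np.ndarray
    V: np.ndarray
    r2_per_cell: np.ndarray
    k: int
    column_mean: np.ndarray


@dataclass
class FisherResult:
    chi2: float
    p_value: float
    sample_p_values: np.ndarray


def _peth(
    spikes: np.ndarray, events: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    """Trial-averaged binned firing rate (spikes/s) around events."""
    rel = (spikes[None, :] - events[:, None]).ravel()
    rel = rel[(rel >= edges[0]) & (rel < edges[-1])]
    counts, _ = np.histogram(rel, bins=edges)
    bin_s = edges[1] - edges[0]
    return counts / (len(events) * bin_s)


def build_peth_matrix(
    sessions,
    rt_threshold: float = 0.15,
    bin_s: float = 0.02,
    window: tuple = (-0.5, 1.5),
    baseline: tuple = (-0.5, -0.2),
    epsilon: float = 0.5,
) -> PethMatrix:
    """Stack every cell's normalized fast/slow double PETH into a matrix.

    Each PETH is normalized as ``(PETH - b) / (b + epsilon)`` where ``b``
    is the cell's mean pre-movement baseline rate (over ``baseline``,
    pooled across trials) and ``epsilon`` a small positive offset that
    keeps very low-firing cells from amplifying noise. Cells lacking
    either a fast or a slow trial are excluded and counted.
    """
    n_bins = int(round((window[1] - window[0]) / bin_s))
    edges = window[0] + bin_s * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    base_mask = (centers >= baseline[0]) & (centers < baseline[1])

    rows, meta, n_excluded = [], [], 0
    for s in sessions:
        trials = s.trial_table
        if trials is None or len(trials) == 0:
            n_excluded += len(s.units)
            continue
        rt = trials["reaction_time"].to_numpy()
        moves = trials["first_move"].to_numpy()
        fast, slow = moves[rt < rt_threshold], moves[~(rt < rt_threshold)]
        if len(fast) == 0 or len(slow) == 0:
            n_excluded += len(s.units)
            continue
        for u in s.units:
            pf = _peth(u.spike_times, fast, edges)
            ps = _peth(u.spike_times, slow, edges)
            pall = _peth(u.spike_times, moves, edges)
            b = float(pall[base_mask].mean())
            rows.append(
                np.concatenate([(pf - b) / (b + epsilon), (ps - b) / (b + epsilon)])
            )
            meta.append(
                {
                    "lab": s.lab_id,
                    "region": u.region,
                    "session": s.session_id,
                    "unit_id": u.unit_id,
                }
            )
    Y = np.array(rows) if rows else np.empty((0, 2 * n_bins))
    return PethMatrix(
        Y=Y,
        cell_meta=pd.DataFrame(meta, columns=["lab", "region", "session", "unit_id"]),
        bin_centers=centers,
        rt_threshold=rt_threshold,
        baseline_window=baseline,
        epsilon=epsilon,
        n_excluded=n_excluded,
    )


def pca_embed(Y: np.ndarray, k: int = 2, center: bool = True) -> Embedding:
    """Rank-``k`` principal-component embedding of the PETH matrix.

    Column means are removed before the SVD (so PC1 captures variance; an
    uncentered SVD is available with ``center=False``). The per-cell
    goodness of fit is ``1 - ||row - reconstruction||^2 /
    ||row - column_mean||^2``.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < k:
        raise ValueError("need at least k rows")
    mean = Y.mean(axis=0) if center else np.zeros(Y.shape[1])
    Yc = Y - mean
    left, sv, vt = np.linalg.svd(Yc, full_matrices=False)
    U = left[:, :k] * sv[:k]
    V = vt[:k]
    resid = Yc - U @ V
    num = np.sum(resid**2, axis=1)
    den = np.sum(Yc**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - num / den
    r2[den == 0] = 1.0  # a row equal to the mean is reconstructed exactly
    return Embedding(U=U, V=V, r2_per_cell=r2, k=k, column_mean=mean)


def ks_target_test(pc1: np.ndarray, target_mask: np.ndarray) -> tuple[float, float]:
    """Two-sample KS test of a target subset's first-PC distribution
    against all remaining cells. Raises when either group is empty."""
    pc1 = np.asarray(pc1, dtype=float)
    target_mask = np.asarray(target_mask, dtype=bool)
    a, b = pc1[target_mask], pc1[~target_mask]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both the target subset and the remainder must be non-empty")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def ks_test_grid(
    pc1: np.ndarray,
    labs: np.ndarray,
    regions: np.ndarray,
    min_cells: int = 4,
) -> pd.DataFrame:
    """Region x lab grid of KS p-values (plus 'all' margins).

    Each cell tests the target lab's cells within one region against the
    remaining cells of that region; the margins target whole regions or
    whole labs against everything else. Pairs with fewer than
    ``min_cells`` cells on either side are NaN (undetermined).
    """
    pc1 = np.asarray(pc1, dtype=float)
    labs = np.asarray(labs)
    regions = np.asarray(regions)
    lab_names = list(np.unique(labs))
    region_names = list(np.unique(regions))
    grid = pd.DataFrame(
        np.nan, index=lab_names + ["all"], columns=region_names + ["all"]
    )

    def safe_p(vals, mask):
        if mask.sum() < min_cells or (~mask).sum() < min_cells:
            return np.nan
        return ks_target_test(vals, mask)[1]

    for region in region_names:
        rmask = regions == region
        for lab in lab_names:
            grid.loc[lab, region] = safe_p(pc1[rmask], labs[rmask] == lab)
        grid.loc["all", region] = safe_p(pc1, rmask)
    for lab in lab_names:
        grid.loc[lab, "all"] = safe_p(pc1, labs == lab)
    return grid


def distance_permutation_test(
    U2: np.ndarray,
    labels,
    n_perm: int = 10000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Per-group permutation test on 2D embedding mean distances.

    For each group, the observed statistic is the Euclidean distance
    between the group's mean embedded activity and the mean of all
    remaining cells; the null shuffles group labels. Returns a frame with
    the observed distance and add-one p-value per group.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    U2 = np.asarray(U2, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    n = len(U2)
    total = U2.sum(axis=0)
    out = []
    for g in np.unique(labels):
        mask = labels == g
        c = int(mask.sum())
        if c == 0 or c == n:
            out.append({"group": g, "distance": np.nan, "p_value": np.nan})
            continue
        mg = U2[mask].mean(axis=0)
        mr = (total - U2[mask].sum(axis=0)) / (n - c)
        observed = float(np.linalg.norm(mg - mr))
        null = np.empty(n_perm)
        for i in range(n_perm):
            idx = rng.choice(n, size=c, replace=False)
            sg = U2[idx].sum(axis=0)
            null[i] = np.linalg.norm(sg / c - (total - sg) / (n - c))
        p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
        out.append({"group": g, "distance": observed, "p_value": float(p)})
    return pd.DataFrame(out).set_index("group")


def fisher_combine(p_values) -> tuple[float, float]:
    """Fisher's method: ``X = -2 sum(ln p)`` against chi-square with
    ``2 * len(p)`` degrees of freedom. Returns ``(X, combined p)``."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0 or np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    X = float(-2.0 * np.sum(np.log(p)))
    return X, float(stats.chi2.sf(X, 2 * len(p)))


def subsampled_ks_fisher(
    pc1: np.ndarray,
    target_mask: np.ndarray,
    n_samplings: int = 100,
    seed: Optional[int] = None,
) -> FisherResult:
    """Cell-number-controlled KS test.

    Repeatedly draws the minimum group size from both the target subset
    and the remainder (without replacement), applies the KS test to each
    drawn pair, and combines the resulting p-values with Fisher's method
    (chi-square, ``2 * n_samplings`` df). The repeated subsamples overlap,
    so the combination is not exactly calibrated; see the methods note.
    Returns NaNs when the minimum group size is below 2 (undetermined).
    """
    pc1 = np.asarray(pc1, dtype=float)
    target_mask = np.asarray(target_mask, dtype=bool)
    a, b = pc1[target_mask], pc1[~target_mask]
    m = min(len(a), len(b))
    if m < 2:
        return FisherResult(np.nan, np.nan, np.empty(0))
    rng = np.random.default_rng(seed)
    ps = np.empty(n_samplings)
    for i in range(n_samplings):
        sa = rng.choice(a, size=m, replace=False)
        sb = rng.choice(b, size=m, replace=False)
        ps[i] = stats.ks_2samp(sa, sb).pvalue
    X, p = fisher_combine(np.clip(ps, 1e-300, 1.0))
    return FisherResult(chi2=X, p_value=p, sample_p_values=ps)
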