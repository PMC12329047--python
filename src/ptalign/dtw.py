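"""Alignment quality control by dynamic time warping and permutation.

A successful alignment places query cells so that binning them along the
aligned pseudotime reproduces the reference's expression dynamics: the
ref-bin x query-bin correlation matrix then shows a narrow, highly
correlated diagonal.  The traceback score along the maximal-correlation
monotone path is the test statistic; its null distribution comes from
rerunning the entire pipeline on expression-matched permuted gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from .align import (
    PseudotimePredictor,
    fit_predictor_fixed,
    normalize_profiles,
    predict_pseudotime,
    reference_self_profiles,
    similarity_profiles,
    train_predictor,
)
from .matrix import ExpressionMatrix
from .reference import BinnedReference, ReferenceLineage, TrajectoryGeneSet, bin_reference

__all__ = [
    "DtwResult",
    "PermutationResult",
    "dtw_matrix",
    "traceback_max_correlation",
    "permutation_pvalue",
    "pseudotime_coherence",
]


@dataclass
class DtwResult:
    matrix: np.ndarray
    path: list  # monotone (ref_bin, query_bin) pairs, 0-based
    path_length: int
    mean_corr: float
    diag_deviation: float


@dataclass
class PermutationResult:
    observed_score: float
    permuted_scores: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    observed: DtwResult | None = None


def _bin_means(
    lognorm: np.ndarray, pt: np.ndarray, n_bins: int, min_cells: int
) -> tuple[np.ndarray, np.ndarray]:
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(pt, edges) - 1, 0, n_bins - 1)
    means, centers = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() < min_cells:
            continue
        means.append(lognorm[mask].mean(axis=0))
        centers.append((edges[b] + edges[b + 1]) / 2.0)
    if not means:
        raise ValueError("no query bins survive the cell-count filter")
    return np.vstack(means), np.asarray(centers)


def dtw_matrix(
    binned_ref: BinnedReference,
    query: ExpressionMatrix,
    query_pt: np.ndarray,
    genes=None,
    n_bins: int | None = None,
    min_cells_per_bin: int = 3,
) -> np.ndarray:
    """Ref-bin x query-bin Pearson correlation matrix over shared genes.

    The query is binned along its aligned pseudotime with the same
    equal-width scheme as the reference (``n_bins`` defaults to the
    reference's).  At least 5 query bins must survive.
    """
    if query.lognorm is None:
        raise ValueError("query matrix must be log-normalized")
    gene_list = list(binned_ref.genes if genes is None else getattr(genes, "genes", genes))
    present = set(query.gene_ids)
    shared = [g for g in gene_list if g in present and g in set(binned_ref.genes)]
    if not shared:
        raise ValueError("empty shared gene set between reference bins and query")
    n_bins = binned_ref.n_bins if n_bins is None else n_bins

    pt = np.asarray(query_pt, dtype=float)
    ok = np.isfinite(pt)
    qmeans, _ = _bin_means(
        query.lognorm[ok][:, query.gene_indexer(shared)], pt[ok], n_bins, min_cells_per_bin
    )
    if qmeans.shape[0] < 5:
        raise ValueError(f"only {qmeans.shape[0]} query bins survive; need >= 5")
    ref_pos = [i for i, g in enumerate(binned_ref.genes) if g in set(shared)]
    rmeans = binned_ref.bin_means[:, ref_pos]

    def _std(a):
        c = a - a.mean(axis=1, keepdims=True)
        n = np.linalg.norm(c, axis=1, keepdims=True)
        n[n < 1e-12] = 1.0
        return c / n

    return _std(rmeans) @ _std(qmeans).T


def _max_sum_path(m: np.ndarray) -> list:
    """Max-sum monotone path from (0,0) to (R-1,C-1); ties prefer the diagonal."""
    R, C = m.shape
    score = np.full((R, C), -np.inf)
    move = np.zeros((R, C), dtype=np.int8)  # 0 start, 1 diag, 2 down, 3 right
    score[0, 0] = m[0, 0]
    for i in range(R):
        for j in range(C):
            if i == 0 and j == 0:
                continue
            best, mv = -np.inf, 0
            if i > 0 and j > 0 and score[i - 1, j - 1] >= best:
                best, mv = score[i - 1, j - 1], 1
            if i > 0 and score[i - 1, j] > best:
                best, mv = score[i - 1, j], 2
            if j > 0 and score[i, j - 1] > best:
                best, mv = score[i, j - 1], 3
            score[i, j] = best + m[i, j]
            move[i, j] = mv
    path = []
    i, j = R - 1, C - 1
    while True:
        path.append((i, j))
        mv = move[i, j]
        if mv == 0:
            break
        if mv == 1:
            i, j = i - 1, j - 1
        elif mv == 2:
            i -= 1
        else:
            j -= 1
    path.reverse()
    return path


def traceback_max_correlation(matrix: np.ndarray) -> DtwResult:
    """Monotone path of maximal *mean* correlation through the matrix.

    Moves are down, right, or diagonal from (0, 0) to (R-1, C-1).  Because
    paths differ in length, maximizing the summed correlation would favor
    long staircase paths whenever correlations are positive; the mean
    (sum / length) is the reported statistic, so the path maximizes it
    directly, solved by Dinkelbach's parametric method (repeated max-sum
    dynamic programming on ``m - lambda``).  Exact ties are broken
    preferring the diagonal move, so a constant matrix yields the plain
    diagonal.  ``diag_deviation`` is the mean |i/R - j/C| along the path
    (1-based indices).
    """
    m = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix must be finite")
    R, C = m.shape
    lam = float(np.mean(np.diag(m)))
    path = [(i, i) for i in range(min(R, C))]
    for _ in range(100):
        path = _max_sum_path(m - lam)
        mean = float(np.mean([m[i, j] for i, j in path]))
        if abs(mean - lam) <= 1e-13:
            break
        lam = mean
    vals = np.array([m[i, j] for i, j in path])
    dev = float(np.mean([abs((i + 1) / R - (j + 1) / C) for i, j in path]))
    return DtwResult(
        matrix=m,
        path=path,
        path_length=len(path),
        mean_corr=float(vals.mean()),
        diag_deviation=dev,
    )


def expression_matched_sample(
    ref_mean_expr: np.ndarray,
    traj_idx: np.ndarray,
    rng: np.random.Generator,
    n_deciles: int = 10,
) -> np.ndarray:
    """Sample a non-trajectory gene set matching the trajectory set's expression deciles."""
    n_genes = ref_mean_expr.size
    edges = np.quantile(ref_mean_expr, np.linspace(0, 1, n_deciles + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    decile = np.clip(np.digitize(ref_mean_expr, edges[1:-1]), 0, n_deciles - 1)
    is_traj = np.zeros(n_genes, dtype=bool)
    is_traj[traj_idx] = True
    picked = []
    deficient = []
    for d in range(n_deciles):
        need = int((decile[traj_idx] == d).sum())
        if need == 0:
            continue
        candidates = np.flatnonzero((decile == d) & ~is_traj)
        if candidates.size < need:
            deficient.append(d)
            continue
        picked.append(rng.choice(candidates, size=need, replace=False))
    if deficient:
        raise ValueError(
            f"insufficient non-trajectory genes to match expression deciles {deficient}"
        )
    return np.concatenate(picked)


def _pipeline_score(
    ref: ReferenceLineage,
    query: ExpressionMatrix,
    gene_list,
    n_bins: int,
    ref_min_cells: int,
    query_min_cells: int,
    params: dict,
    mlp_seed: int,
    max_iter: int,
) -> tuple[float, DtwResult | None]:
    """One full alignment + DTW scoring run for a given gene set.

    A run whose query binning collapses scores -1 (the correlation minimum),
    so degenerate permutations never inflate significance.
    """
    try:
        binned = bin_reference(ref, gene_list, n_bins=n_bins, min_cells_per_bin=ref_min_cells)
        profs, pt = reference_self_profiles(ref, binned)
        ok = ~profs.degenerate
        model = fit_predictor_fixed(
            profs.normalized[ok], pt[ok], params, seed=mlp_seed, max_iter=max_iter
        )
        qsim = normalize_profiles(similarity_profiles(query, binned))
        qpt = predict_pseudotime(model, qsim)
        m = dtw_matrix(binned, query, qpt, min_cells_per_bin=query_min_cells)
        res = traceback_max_correlation(m)
        return res.mean_corr, res
    except ValueError:
        return -1.0, None


def permutation_pvalue(
    query: ExpressionMatrix,
    ref: ReferenceLineage,
    binned: BinnedReference,
    genes: TrajectoryGeneSet,
    n_perm: int = 100,
    seed: int = 0,
    model: PseudotimePredictor | None = None,
    ref_min_cells: int = 10,
    query_min_cells: int = 3,
    max_iter: int = 150,
) -> PermutationResult:
    """Empirical alignment P-value from expression-matched gene permutations.

    The observed statistic is the mean correlation along the DTW traceback
    of the trajectory-gene alignment.  Each permutation draws a same-size,
    expression-decile-matched gene set from non-trajectory genes and reruns
    the entire pipeline (reference binning, self-masked profiles, perceptron
    retraining at the observed hyperparameters, query prediction, query
    binning, DTW).  The add-one rule gives
    p = (1 + #{permuted >= observed}) / (1 + n_perm).
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    if model is None:
        model = train_predictor(ref, binned, genes, seed=seed)
    rng = np.random.default_rng(seed)
    params = dict(model.best_params)

    obs_score, obs_res = _pipeline_score(
        ref, query, list(genes.genes), binned.n_bins, ref_min_cells, query_min_cells,
        params, int(rng.integers(2**31 - 1)), max_iter,
    )

    nc = ~ref.cycling
    mean_expr = ref.matrix.lognorm[nc].mean(axis=0)
    traj_idx = ref.matrix.gene_indexer(genes.genes)

    permuted = np.empty(n_perm)
    for k in range(n_perm):
        perm_idx = expression_matched_sample(mean_expr, traj_idx, rng)
        permuted[k], _ = _pipeline_score(
            ref, query, list(ref.matrix.gene_ids[perm_idx]), binned.n_bins,
            ref_min_cells, query_min_cells, params, int(rng.integers(2**31 - 1)), max_iter,
        )
    p = (1.0 + np.sum(permuted >= obs_score)) / (1.0 + n_perm)
    return PermutationResult(
        observed_score=float(obs_score),
        permuted_scores=permuted,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
        observed=obs_res,
    )


def pseudotime_coherence(
    matrix: ExpressionMatrix,
    pt: np.ndarray,
    n_components: int = 10,
) -> float:
    """Correlation between transcriptome distances and pseudotime rank distances.

    Pairwise Euclidean distances in a principal-component subspace are
    compared to pairwise pseudotime rank distances by Pearson correlation —
    a trajectory-algorithm-agnostic measure of how coherently a pseudotime
    orders the expression manifold (rank distances make it invariant to
    monotone reparametrization).
    """
    from sklearn.decomposition import PCA

    if matrix.lognorm is None:
        raise ValueError("matrix must be log-normalized")
    pt = np.asarray(pt, dtype=float)
    ok = np.isfinite(pt)
    if ok.sum() < 3:
        raise ValueError("need >= 3 cells with pseudotime")
    if np.unique(pt[ok]).size < 2:
        raise ValueError("constant pseudotime")
    X = matrix.lognorm[ok]
    k = min(n_components, min(X.shape) - 1)
    Z = PCA(n_components=k, random_state=0).fit_transform(X)
    d_expr = pdist(Z)
    ranks = rankdata(pt[ok])
    d_rank = pdist(ranks[:, None], metric="cityblock")
    return float(np.corrcoef(d_expr, d_rank)[0, 1])
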