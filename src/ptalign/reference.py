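"""Reference-side preparation for pseudotime alignment.

A reference lineage is a non-branching differentiation trajectory (the adult
v-SVZ neural stem cell lineage in the motivating application) with a
per-cell pseudotime in [0, 1].  This module covers everything needed to turn
such a lineage into an alignment target: cycling-cell flagging via G2M
scores, stage-boundary detection from the pseudotime density, derivation of
a stage-labeled trajectory gene set, and pseudotime binning.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.model_selection import cross_val_score, train_test_split

from .matrix import ExpressionMatrix

__all__ = [
    "StageBoundaries",
    "ReferenceLineage",
    "TrajectoryGeneSet",
    "BinnedReference",
    "score_cell_cycle",
    "flag_cycling",
    "detect_stage_boundaries",
    "derive_trajectory_genes",
    "bin_reference",
    "DEFAULT_BOUNDARIES",
    "G2M_CUTOFF",
]

#: G2M-score threshold above which a cell is considered actively cycling.
G2M_CUTOFF = 0.1

RIBOSOMAL_RE = re.compile(r"^RP[LS]", re.IGNORECASE)


@dataclass(frozen=True)
class StageBoundaries:
    """Pseudotime cutoffs separating lineage stages.

    ``[0, b_qa)`` is Quiescence (with ``[0, b_dormant)`` the dormant
    astrocytic sub-stage), ``[b_qa, b_ad]`` Activation, and ``(b_ad, 1]``
    Differentiation.
    """

    b_dormant: float = 0.141
    b_qa: float = 0.282
    b_ad: float = 0.676

    def __post_init__(self) -> None:
        if not (0 < self.b_dormant < self.b_qa < self.b_ad < 1):
            raise ValueError(
                "boundaries must satisfy 0 < b_dormant < b_qa < b_ad < 1, got "
                f"({self.b_dormant}, {self.b_qa}, {self.b_ad})"
            )


DEFAULT_BOUNDARIES = StageBoundaries()


@dataclass
class ReferenceLineage:
    """An expression matrix with per-cell pseudotime and cycling flags.

    ``pseudotime`` is NaN for cycling cells — they are excluded from
    pseudotime analysis to keep inference on the non-branching lineage.
    """

    matrix: ExpressionMatrix
    pseudotime: np.ndarray
    cycling: np.ndarray
    boundaries: StageBoundaries = field(default_factory=StageBoundaries)

    def __post_init__(self) -> None:
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        self.cycling = np.asarray(self.cycling, dtype=bool)
        n = self.matrix.n_cells
        if self.pseudotime.shape != (n,) or self.cycling.shape != (n,):
            raise ValueError("pseudotime and cycling must be per-cell arrays")
        pt = self.pseudotime[~self.cycling]
        if np.any(~np.isfinite(pt)):
            raise ValueError("non-cycling cells must carry finite pseudotime")
        if np.unique(pt).size < 2:
            raise ValueError("need >= 2 distinct pseudotime values")
        # rescale so the non-cycling lineage spans [0, 1] exactly
        lo, hi = pt.min(), pt.max()
        if not (lo == 0.0 and hi == 1.0):
            self.pseudotime = (self.pseudotime - lo) / (hi - lo)
        self.pseudotime[self.cycling] = np.nan

    @property
    def noncycling_pt(self) -> np.ndarray:
        return self.pseudotime[~self.cycling]


@dataclass
class TrajectoryGeneSet:
    """Stage-labeled pseudotime-predictive genes."""

    genes: np.ndarray
    stage: np.ndarray  # one of {"Q", "A", "D"} per gene
    importance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.stage = np.asarray(self.stage, dtype=object)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in trajectory set")
        bad = set(self.stage) - {"Q", "A", "D"}
        if bad:
            raise ValueError(f"unknown stage labels {bad}")
        ribo = [g for g in self.genes if RIBOSOMAL_RE.match(str(g))]
        if ribo:
            raise ValueError(f"ribosomal genes not allowed in trajectory set: {ribo[:5]}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class BinnedReference:
    """Mean trajectory-gene expression per pseudotime bin."""

    n_bins: int
    bin_centers: np.ndarray
    bin_means: np.ndarray  # retained bins x trajectory genes
    bin_counts: np.ndarray
    genes: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if self.bin_means.shape[0] != len(self.bin_centers):
            raise ValueError("bin_means rows must match retained bins")

    @property
    def n_retained(self) -> int:
        return len(self.bin_centers)


def score_cell_cycle(
    matrix: ExpressionMatrix,
    s_genes,
    g2m_genes,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Score S- and G2M-phase programs per cell.

    Follows the standard single-cell scoring scheme: the mean lognorm
    expression of the phase gene set minus the mean of control genes drawn
    from expression-matched bins.  Delegates to scanpy's ``score_genes``.
    """
    if matrix.lognorm is None:
        raise ValueError("matrix must be log-normalized first")
    present = set(matrix.gene_ids)
    s_genes = [g for g in s_genes if g in present]
    g2m_genes = [g for g in g2m_genes if g in present]
    if not s_genes or not g2m_genes:
        raise ValueError("phase gene lists have empty intersection with the matrix")

    import anndata as ad
    import scanpy as sc

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adata = ad.AnnData(
            X=matrix.lognorm.astype(np.float64),
            obs={"cell": list(map(str, matrix.cell_ids))},
            var={"gene": list(map(str, matrix.gene_ids))},
        )
        adata.var_names = list(map(str, matrix.gene_ids))
        for name, genes in (("S_score", s_genes), ("G2M_score", g2m_genes)):
            sc.tl.score_genes(
                adata,
                gene_list=genes,
                score_name=name,
                ctrl_size=n_ctrl,
                n_bins=n_bins,
                random_state=seed,
            )
    return (
        np.asarray(adata.obs["S_score"], dtype=float),
        np.asarray(adata.obs["G2M_score"], dtype=float),
    )


def flag_cycling(g2m_scores: np.ndarray, cutoff: float = G2M_CUTOFF) -> np.ndarray:
    """Cells with G2M score strictly above ``cutoff`` are cycling."""
    return np.asarray(g2m_scores, dtype=float) > cutoff


def detect_stage_boundaries(
    pseudotimes: np.ndarray,
    bandwidth: str | float = "scott",
    grid_size: int = 1001,
) -> StageBoundaries:
    """Locate Q/A/D stage boundaries from the pseudotime density.

    Fits a Gaussian KDE over the (non-cycling) pseudotimes, finds density
    peaks on a dense grid over [0, 1], and places boundaries at the density
    minima between the first three peaks.  The dormant sub-boundary is set
    halfway into the Q stage, mirroring the printed default ratio
    (0.141 = 0.282 / 2).

    Raises
    ------
    ValueError
        If fewer than three density modes are found; the error advises the
        printed default boundaries (0.141, 0.282, 0.676).
    """
    pts = np.asarray(pseudotimes, dtype=float)
    pts = pts[np.isfinite(pts)]
    if pts.size < 10:
        raise ValueError("need >= 10 pseudotime values for KDE boundary detection")
    kde = gaussian_kde(pts, bw_method=bandwidth)
    grid = np.linspace(0.0, 1.0, grid_size)
    dens = kde(grid)
    (maxima,) = argrelextrema(dens, np.greater)
    if len(maxima) < 3:
        raise ValueError(
            f"found {len(maxima)} density modes, need >= 3 for a Q/A/D split; "
            "consider the default boundaries (0.141, 0.282, 0.676)"
        )
    p1, p2, p3 = maxima[:3]
    b_qa = grid[p1 + np.argmin(dens[p1 : p2 + 1])]
    b_ad = grid[p2 + np.argmin(dens[p2 : p3 + 1])]
    return StageBoundaries(b_dormant=b_qa / 2.0, b_qa=float(b_qa), b_ad=float(b_ad))


def _prefilter_genes(
    lognorm: np.ndarray,
    stage_labels: np.ndarray,
    min_cells_frac: float,
    stage_fold: float,
) -> np.ndarray:
    """Boolean mask of genes passing global- and per-stage expression filters."""
    expressed_frac = (lognorm > 0).mean(axis=0)
    keep = expressed_frac >= min_cells_frac
    stages = ["Q", "A", "D"]
    stage_enriched = np.zeros(lognorm.shape[1], dtype=bool)
    for s in stages:
        in_s = stage_labels == s
        mean_in = lognorm[in_s].mean(axis=0)
        mean_out = lognorm[~in_s].mean(axis=0)
        stage_enriched |= mean_in >= stage_fold * np.maximum(mean_out, 1e-12)
    return keep & stage_enriched


def derive_trajectory_genes(
    ref: ReferenceLineage,
    stage_labels: np.ndarray,
    cv_folds: int = 3,
    test_size: float = 0.3,
    n_perm: int = 500,
    genes_per_perm: int = 500,
    top_per_stage: int = 100,
    rfe_target: int | None = None,
    min_cells_frac: float = 0.01,
    stage_fold: float = 1.5,
    n_estimators: int = 50,
    seed: int = 0,
) -> TrajectoryGeneSet:
    """Derive stage-predictive trajectory genes from a labeled reference.

    Pipeline: expression prefilter (global detection rate and per-stage
    enrichment) -> recursive feature elimination with a random-forest stage
    classifier on a 70/30 split, sanity-checked by ``cv_folds``-fold
    cross-validation -> repeated random-subset random-forest fits
    (``n_perm`` draws of ``genes_per_perm`` genes) with mean permutation
    importance per gene -> knee-point cutoff on the ranked importance curve
    -> ribosomal-gene removal -> per-stage cap of ``top_per_stage`` genes,
    with each gene assigned to the stage of its maximum mean expression.

    Deterministic given ``seed``.
    """
    from .dynamics import find_inflection  # local: avoids a module cycle

    if ref.matrix.lognorm is None:
        raise ValueError("reference matrix must be log-normalized")
    stage_labels = np.asarray(stage_labels, dtype=object)
    nc = ~ref.cycling
    X = ref.matrix.lognorm[nc]
    y = stage_labels[nc] if stage_labels.shape[0] == ref.matrix.n_cells else stage_labels
    if y.shape[0] != X.shape[0]:
        raise ValueError("stage_labels must cover all (or all non-cycling) cells")
    for s in ("Q", "A", "D"):
        if (y == s).sum() < 20:
            raise ValueError(f"stage {s} has fewer than 20 cells")

    rng = np.random.default_rng(seed)
    genes = ref.matrix.gene_ids
    keep = _prefilter_genes(X, y, min_cells_frac, stage_fold)
    pool = np.flatnonzero(keep)
    if pool.size < 3:
        raise ValueError("prefilter left fewer genes than stages")

    if rfe_target is None:
        rfe_target = max(3 * top_per_stage, pool.size // 2)
    if pool.size > rfe_target:
        Xp = X[:, pool]
        X_tr, X_te, y_tr, y_te = train_test_split(
            Xp, y, test_size=test_size, stratify=y, random_state=seed
        )
        rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
        cv_acc = cross_val_score(rf, X_tr, y_tr, cv=cv_folds).mean()
        rfe = RFE(rf, n_features_to_select=rfe_target, step=0.1)
        rfe.fit(X_tr, y_tr)
        pool = pool[rfe.support_]
        del cv_acc  # diagnostic only; selection is by RFE ranking

    # repeated random-subset importance ranking
    imp_sum = np.zeros(pool.size)
    imp_cnt = np.zeros(pool.size)
    k = min(genes_per_perm, pool.size)
    for _ in range(n_perm):
        sub = rng.choice(pool.size, size=k, replace=False)
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(X[:, pool[sub]], y)
        imp_sum[sub] += rf.feature_importances_
        imp_cnt[sub] += 1
    seen = imp_cnt > 0
    mean_imp = np.where(seen, imp_sum / np.maximum(imp_cnt, 1), 0.0)

    order = np.argsort(mean_imp)[::-1]
    ranked = mean_imp[order]
    # random-forest importances separate signal from noise multiplicatively;
    # the knee is found on the log curve so the signal/noise cliff dominates
    # the smooth decay within the informative genes
    log_ranked = np.log(np.maximum(ranked, ranked.max() * 1e-6))
    knee = find_inflection(log_ranked) if ranked.size >= 5 else None
    cut = knee if knee is not None else ranked.size
    selected = pool[order[: max(cut, 3)]]
    selected_imp = mean_imp[order[: max(cut, 3)]]

    # ribosomal removal
    not_ribo = np.array([not RIBOSOMAL_RE.match(str(genes[i])) for i in selected])
    selected, selected_imp = selected[not_ribo], selected_imp[not_ribo]
    if selected.size < 3:
        raise ValueError("fewer selected genes than stages after filtering")

    # stage by maximum mean expression, then per-stage cap by importance
    stage_means = np.vstack([X[y == s][:, selected].mean(axis=0) for s in ("Q", "A", "D")])
    assigned = np.array(["QAD"[i] for i in stage_means.argmax(axis=0)], dtype=object)
    keep_idx = []
    for s in ("Q", "A", "D"):
        in_s = np.flatnonzero(assigned == s)
        in_s = in_s[np.argsort(selected_imp[in_s])[::-1]][:top_per_stage]
        keep_idx.extend(in_s.tolist())
    keep_idx = sorted(keep_idx)
    return TrajectoryGeneSet(
        genes=genes[selected[keep_idx]],
        stage=assigned[keep_idx],
        importance=selected_imp[keep_idx],
    )


def bin_reference(
    ref: ReferenceLineage,
    genes,
    n_bins: int = 50,
    min_cells_per_bin: int = 10,
) -> BinnedReference:
    """Bin non-cycling reference cells into equal-width pseudotime bins.

    ``genes`` may be a :class:`TrajectoryGeneSet` or a plain gene list
    (permutation reruns bin over arbitrary matched gene sets).  Bins with
    fewer than ``min_cells_per_bin`` cells are dropped; a warning is emitted
    if more than 20% of bins are dropped, and fewer than five surviving bins
    is an error.
    """
    if n_bins < 5:
        raise ValueError("n_bins must be >= 5")
    if ref.matrix.lognorm is None:
        raise ValueError("reference matrix must be log-normalized")
    gene_list = list(getattr(genes, "genes", genes))
    gidx = ref.matrix.gene_indexer(gene_list)
    nc = ~ref.cycling
    pt = ref.pseudotime[nc]
    L = ref.matrix.lognorm[nc][:, gidx]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(pt, edges) - 1, 0, n_bins - 1)
    centers, means, counts = [], [], []
    for b in range(n_bins):
        mask = which == b
        n = int(mask.sum())
        if n < min_cells_per_bin:
            continue
        centers.append((edges[b] + edges[b + 1]) / 2.0)
        means.append(L[mask].mean(axis=0))
        counts.append(n)
    n_drop = n_bins - len(centers)
    if len(centers) < 5:
        raise ValueError(
            f"only {len(centers)} bins with >= {min_cells_per_bin} cells; need >= 5"
        )
    if n_drop > 0.2 * n_bins:
        warnings.warn(
            f"{n_drop}/{n_bins} pseudotime bins dropped (< {min_cells_per_bin} cells)",
            stacklevel=2,
        )
    return BinnedReference(
        n_bins=n_bins,
        bin_centers=np.asarray(centers),
        bin_means=np.vstack(means),
        bin_counts=np.asarray(counts, dtype=int),
        genes=np.asarray(gene_list, dtype=object),
    )
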