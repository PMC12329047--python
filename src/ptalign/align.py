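"""Query-to-reference pseudotime alignment.

Each query cell is summarized by its Pearson-correlation profile against the
pseudotime-binned reference (a "similarity profile").  A small multi-layer
perceptron, trained on the reference's own self-masked profiles, maps
profiles to pseudotime.  Cycling cells are flagged before alignment and never
aligned; heuristics flag out-of-distribution cells whose profile resembles
no reference position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neural_network import MLPRegressor

from .matrix import ExpressionMatrix
from .reference import (
    BinnedReference,
    ReferenceLineage,
    StageBoundaries,
    TrajectoryGeneSet,
)

__all__ = [
    "SimilarityMatrix",
    "PseudotimePredictor",
    "AlignmentResult",
    "similarity_profiles",
    "normalize_profiles",
    "train_predictor",
    "predict_pseudotime",
    "flag_out_of_distribution",
    "assign_stages",
    "stage_composition",
    "aitchison_distance",
    "align_query",
    "DEFAULT_PARAM_GRID",
]

#: Grid searched over by :func:`train_predictor` (5-fold CV, MSE).
DEFAULT_PARAM_GRID = {
    "hidden_layer_sizes": [(32, 16), (64, 32)],
    "alpha": [1e-3],
}


@dataclass
class SimilarityMatrix:
    """Per-cell correlation profiles against reference pseudotime bins."""

    cell_ids: np.ndarray
    raw: np.ndarray  # cells x bins, NaN rows for degenerate cells
    degenerate: np.ndarray
    normalized: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return self.raw.shape[1]


@dataclass
class PseudotimePredictor:
    """A fitted profile -> pseudotime regressor (3-layer perceptron)."""

    model: MLPRegressor
    n_bins: int
    best_params: dict
    training_loss: float
    cv_folds: int = 5
    seed: int = 0
    fitted: bool = True


@dataclass
class AlignmentResult:
    """Aligned pseudotimes, per-cell status, and stage calls for one query."""

    cell_ids: np.ndarray
    pseudotime: np.ndarray  # NaN unless status == "aligned"
    status: np.ndarray  # aligned | cycling | out_of_distribution | degenerate
    stage: np.ndarray  # Dormant | Q | A | D, None unless aligned
    boundaries: StageBoundaries = field(default_factory=StageBoundaries)


def _standardize_rows(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/normalize rows to unit L2 norm; returns (standardized, degenerate mask)."""
    c = a - a.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(c, axis=1)
    degen = norms < 1e-12
    c[~degen] /= norms[~degen, None]
    c[degen] = np.nan
    return c, degen


def _pearson_rows(x: np.ndarray, m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xs, degen = _standardize_rows(np.asarray(x, dtype=float))
    ms, mdegen = _standardize_rows(np.asarray(m, dtype=float))
    if mdegen.any():
        raise ValueError("reference bin mean vector with zero variance")
    return xs @ ms.T, degen


def similarity_profiles(
    query: ExpressionMatrix,
    binned: BinnedReference,
    genes: TrajectoryGeneSet | None = None,
) -> SimilarityMatrix:
    """Correlate each query cell with every reference pseudotime bin.

    Correlations are computed over the trajectory genes shared between the
    query gene space and the binned reference (>= 10 required).  Cells with
    zero variance over those genes are flagged degenerate and carry a NaN
    profile.
    """
    if query.lognorm is None:
        raise ValueError("query matrix must be log-normalized")
    ref_genes = list(binned.genes if genes is None else genes.genes)
    present = set(query.gene_ids)
    shared = [g for g in ref_genes if g in present]
    if len(shared) < 10:
        raise ValueError(
            f"only {len(shared)} trajectory genes present in query; need >= 10"
        )
    shared_pos_ref = [i for i, g in enumerate(binned.genes) if g in present]
    raw, degen = _pearson_rows(
        query.lognorm[:, query.gene_indexer(shared)],
        binned.bin_means[:, shared_pos_ref],
    )
    return SimilarityMatrix(cell_ids=query.cell_ids, raw=raw, degenerate=degen)


def normalize_profiles(sim: SimilarityMatrix) -> SimilarityMatrix:
    """Shape-normalize each profile to mean 0 and unit variance.

    An affine transform of a profile leaves the normalized profile unchanged,
    so downstream prediction sees only profile *shape*.  Constant profiles
    are flagged degenerate rather than normalized.
    """
    raw = sim.raw
    std = np.nanstd(raw, axis=1)
    degen = sim.degenerate | (std < 1e-12) | ~np.isfinite(std)
    normalized = np.full_like(raw, np.nan)
    ok = ~degen
    normalized[ok] = (raw[ok] - raw[ok].mean(axis=1, keepdims=True)) / raw[ok].std(
        axis=1, keepdims=True
    )
    return SimilarityMatrix(
        cell_ids=sim.cell_ids, raw=raw, degenerate=degen, normalized=normalized
    )


def reference_self_profiles(
    ref: ReferenceLineage,
    binned: BinnedReference,
) -> tuple[SimilarityMatrix, np.ndarray]:
    """Self-masked similarity profiles for the non-cycling reference cells.

    Each cell is excluded from its own bin's mean before correlating, so the
    training targets are not leaked through the profile.  Returns the
    normalized profiles and the matching pseudotimes.
    """
    if ref.matrix.lognorm is None:
        raise ValueError("reference matrix must be log-normalized")
    nc = ~ref.cycling
    pt = ref.pseudotime[nc]
    L = ref.matrix.lognorm[nc][:, ref.matrix.gene_indexer(binned.genes)]
    edges = np.linspace(0.0, 1.0, binned.n_bins + 1)
    which = np.clip(np.digitize(pt, edges) - 1, 0, binned.n_bins - 1)
    # map original bin index -> retained row in bin_means
    width = 1.0 / binned.n_bins
    retained = {int(round(c / width - 0.5)): r for r, c in enumerate(binned.bin_centers)}

    raw, degen = _pearson_rows(L, binned.bin_means)
    # correct each cell's own-bin correlation with the leave-one-out mean
    xs, _ = _standardize_rows(L.astype(float))
    sums = np.zeros_like(binned.bin_means)
    for i in range(L.shape[0]):
        r = retained.get(int(which[i]))
        if r is not None:
            sums[r] += L[i]
    for i in range(L.shape[0]):
        r = retained.get(int(which[i]))
        if r is None or degen[i]:
            continue
        n_b = binned.bin_counts[r]
        if n_b < 2:
            continue
        loo = (sums[r] - L[i]) / (n_b - 1)
        loo = loo - loo.mean()
        norm = np.linalg.norm(loo)
        if norm < 1e-12:
            continue
        raw[i, r] = xs[i] @ (loo / norm)
    sim = SimilarityMatrix(
        cell_ids=ref.matrix.cell_ids[nc], raw=raw, degenerate=degen
    )
    return normalize_profiles(sim), pt


def train_predictor(
    ref: ReferenceLineage,
    binned: BinnedReference,
    genes: TrajectoryGeneSet | None = None,
    seed: int = 0,
    param_grid: dict | None = None,
    max_iter: int = 400,
    min_cells: int = 200,
) -> PseudotimePredictor:
    """Grid-search and fit the profile -> pseudotime perceptron.

    Training profiles are the reference's own self-masked similarity
    profiles; hyperparameters are chosen by 5-fold cross-validated mean
    squared error and the winning model is refit on all profiles.
    Deterministic given ``seed``.
    """
    nc = int((~ref.cycling).sum())
    if nc < min_cells:
        raise ValueError(f"need >= {min_cells} non-cycling reference cells, got {nc}")
    sim, pt = reference_self_profiles(ref, binned)
    ok = ~sim.degenerate
    X, y = sim.normalized[ok], pt[ok]
    grid = DEFAULT_PARAM_GRID if param_grid is None else param_grid
    gs = GridSearchCV(
        MLPRegressor(solver="lbfgs", max_iter=max_iter, random_state=seed),
        grid,
        cv=KFold(n_splits=5, shuffle=True, random_state=seed),
        scoring="neg_mean_squared_error",
        error_score="raise",
    )
    try:
        gs.fit(X, y)
    except Exception as e:  # surface the failing grid point
        raise RuntimeError(f"cross-validation failure during grid search: {e}") from e
    if not np.isfinite(gs.best_score_):
        raise RuntimeError(f"non-finite CV loss at grid point {gs.best_params_}")
    model = gs.best_estimator_
    loss = float(np.mean((model.predict(X) - y) ** 2))
    return PseudotimePredictor(
        model=model,
        n_bins=binned.n_retained,
        best_params=dict(gs.best_params_),
        training_loss=loss,
        seed=seed,
    )


def fit_predictor_fixed(
    profiles: np.ndarray,
    pt: np.ndarray,
    params: dict,
    seed: int = 0,
    max_iter: int = 400,
) -> PseudotimePredictor:
    """Fit the perceptron at fixed hyperparameters (no grid search).

    Permutation reruns use a capped iteration budget; hitting the cap is
    expected and applies symmetrically to observed and permuted runs, so
    the convergence warning is suppressed.
    """
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    model = MLPRegressor(solver="lbfgs", max_iter=max_iter, random_state=seed, **params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(profiles, pt)
    loss = float(np.mean((model.predict(profiles) - pt) ** 2))
    return PseudotimePredictor(
        model=model,
        n_bins=profiles.shape[1],
        best_params=dict(params),
        training_loss=loss,
        seed=seed,
    )


def predict_pseudotime(model: PseudotimePredictor, sim: SimilarityMatrix) -> np.ndarray:
    """Predict pseudotime for each profile, clipped to [0, 1]; NaN for degenerate."""
    if not model.fitted:
        raise ValueError("predictor is not fitted")
    if sim.normalized is None:
        raise ValueError("similarity matrix must be normalized first")
    if sim.n_bins != model.n_bins:
        raise ValueError(
            f"bin-count mismatch: model expects {model.n_bins}, got {sim.n_bins}"
        )
    out = np.full(len(sim.cell_ids), np.nan)
    ok = ~sim.degenerate
    if ok.any():
        out[ok] = np.clip(model.model.predict(sim.normalized[ok]), 0.0, 1.0)
    return out


def flag_out_of_distribution(
    sim: SimilarityMatrix,
    c_min: float = 0.2,
    prominence_min: float = 0.05,
) -> np.ndarray:
    """Flag cells whose profile resembles no reference pseudotime position.

    A cell is out-of-distribution when its best raw correlation is below
    ``c_min`` or when the profile peak barely rises above the profile median
    (max - median < ``prominence_min``).  Degenerate cells are not flagged
    here; they carry their own status.
    """
    raw = sim.raw
    out = np.zeros(raw.shape[0], dtype=bool)
    ok = ~sim.degenerate
    mx = np.max(raw[ok], axis=1)
    med = np.median(raw[ok], axis=1)
    out[ok] = (mx < c_min) | ((mx - med) < prominence_min)
    return out


_STAGE_ORDER = ("Dormant", "Q", "A", "D")


def assign_stages(pt: np.ndarray, boundaries: StageBoundaries | None = None) -> np.ndarray:
    """Map pseudotimes to lineage stages under the printed cutoffs.

    ``pt < b_dormant`` -> Dormant (a sub-label of Q), ``pt < b_qa`` -> Q,
    ``b_qa <= pt <= b_ad`` -> A (closed interval), ``pt > b_ad`` -> D.
    """
    b = boundaries or StageBoundaries()
    pt = np.asarray(pt, dtype=float)
    if np.any(~np.isfinite(pt)) or np.any((pt < 0) | (pt > 1)):
        raise ValueError("pseudotime values must lie in [0, 1]")
    out = np.empty(pt.shape, dtype=object)
    out[pt < b.b_dormant] = "Dormant"
    out[(pt >= b.b_dormant) & (pt < b.b_qa)] = "Q"
    out[(pt >= b.b_qa) & (pt <= b.b_ad)] = "A"
    out[pt > b.b_ad] = "D"
    return out


def stage_composition(
    result: AlignmentResult, include_cycling: bool = False
) -> np.ndarray:
    """QAD(-cycling) stage fractions over aligned (and cycling) cells.

    Dormant cells count toward Q.  Out-of-distribution and degenerate cells
    are excluded from the denominator.  Returns fractions over (Q, A, D)
    or (Q, A, D, cycling), summing to 1.
    """
    aligned = result.status == "aligned"
    cyc = result.status == "cycling"
    denom = int(aligned.sum()) + (int(cyc.sum()) if include_cycling else 0)
    if denom == 0:
        raise ValueError("no aligned (or cycling) cells to build a composition from")
    stage = result.stage[aligned]
    counts = [
        int(((stage == "Q") | (stage == "Dormant")).sum()),
        int((stage == "A").sum()),
        int((stage == "D").sum()),
    ]
    if include_cycling:
        counts.append(int(cyc.sum()))
    return np.asarray(counts, dtype=float) / denom


def aitchison_distance(x, y, pseudofraction: float = 1e-3) -> float:
    """Aitchison distance between two compositions.

    Zero components are replaced by ``pseudofraction`` and the composition
    renormalized; the distance is the Euclidean norm of the difference of
    centered-log-ratio transforms.  Symmetric by construction.
    """
    from skbio.stats.composition import clr

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("compositions must have equal length >= 2")
    for v in (x, y):
        if np.any(v < 0):
            raise ValueError("compositions must be nonnegative")
        if not np.isclose(v.sum(), 1.0, atol=1e-6):
            raise ValueError("compositions must sum to 1")

    def _closed(v: np.ndarray) -> np.ndarray:
        v = np.where(v == 0, pseudofraction, v)
        return v / v.sum()

    return float(np.linalg.norm(clr(_closed(x)) - clr(_closed(y))))


def align_query(
    query: ExpressionMatrix,
    binned: BinnedReference,
    model: PseudotimePredictor,
    cycling: np.ndarray | None = None,
    boundaries: StageBoundaries | None = None,
    c_min: float = 0.2,
    prominence_min: float = 0.05,
) -> AlignmentResult:
    """Run the full alignment for one query sample.

    Cycling cells (precomputed flags) are excluded before alignment;
    degenerate and out-of-distribution cells receive no pseudotime.
    """
    b = boundaries or StageBoundaries()
    n = query.n_cells
    cycling = np.zeros(n, dtype=bool) if cycling is None else np.asarray(cycling, bool)
    sim = normalize_profiles(similarity_profiles(query, binned))
    pt = predict_pseudotime(model, sim)
    ood = flag_out_of_distribution(sim, c_min=c_min, prominence_min=prominence_min)

    status = np.full(n, "aligned", dtype=object)
    status[ood] = "out_of_distribution"
    status[sim.degenerate] = "degenerate"
    status[cycling] = "cycling"
    aligned = status == "aligned"

    pseudotime = np.full(n, np.nan)
    pseudotime[aligned] = pt[aligned]
    stage = np.full(n, None, dtype=object)
    stage[aligned] = assign_stages(pt[aligned], b)
    return AlignmentResult(
        cell_ids=query.cell_ids,
        pseudotime=pseudotime,
        status=status,
        stage=stage,
        boundaries=b,
    )
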