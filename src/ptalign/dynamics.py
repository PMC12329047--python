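"""Expression-dynamics curves over pseudotime and Earth Mover's Distance.

Per gene and sample, expression over aligned pseudotime is summarized by a
penalized 5-basis B-spline fit to bin means, clipped at zero and
area-normalized to a unit-area density on [0, 1].  Differences in dynamics
between a sample and the healthy reference are scored by the Wasserstein-1
distance between these densities; recurrently dysregulated genes are the
top tail of the ranked mean distance, cut at the kneedle inflection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import simpson
from scipy.interpolate import BSpline
from scipy.stats import wasserstein_distance

from .matrix import ExpressionMatrix
from .reference import StageBoundaries

__all__ = [
    "PseudotimeGrid",
    "ExpressionSpline",
    "EmdResult",
    "select_universal_genes",
    "fit_expression_spline",
    "emd",
    "mean_reference_curve",
    "find_inflection",
    "rank_dysregulated",
    "qd_bias",
    "group_emd_biomarkers",
    "area_difference_ratio",
]


@dataclass(frozen=True)
class PseudotimeGrid:
    """Uniform grid over [0, 1]; curves are evaluated at these points."""

    step: float = 0.05

    def __post_init__(self) -> None:
        n = round(1.0 / self.step)
        if not np.isclose(n * self.step, 1.0):
            raise ValueError("step must divide 1 evenly")

    @property
    def points(self) -> np.ndarray:
        n = round(1.0 / self.step)
        return np.linspace(0.0, 1.0, n + 1)

    @property
    def n_bins(self) -> int:
        return round(1.0 / self.step)


@dataclass
class ExpressionSpline:
    """An area-normalized expression curve over pseudotime."""

    grid: PseudotimeGrid
    values: np.ndarray  # >= 0, on grid points
    area: float
    normalized_values: np.ndarray | None
    expressed: bool
    n_basis: int = 5
    smoothing: float = 1.0


@dataclass
class EmdResult:
    """Ranked mean EMDs with the kneedle dysregulation cutoff."""

    table: pd.DataFrame  # gene, mean_emd, rank, dysregulated
    knee: int | None = None
    per_sample: pd.DataFrame | None = field(default=None, repr=False)


def select_universal_genes(
    samples: list[ExpressionMatrix],
    frac_cells: float = 0.01,
    frac_samples: float = 0.10,
    expr_threshold: float = 0.0,
) -> list:
    """Genes expressed above threshold in >= ``frac_cells`` of cells for
    >= ``frac_samples`` of samples."""
    if not samples:
        raise ValueError("need >= 1 sample")
    hits: dict = {}
    for s in samples:
        if s.lognorm is None:
            raise ValueError("samples must be log-normalized")
        frac = (s.lognorm > expr_threshold).mean(axis=0)
        for g in s.gene_ids[frac >= frac_cells]:
            hits[g] = hits.get(g, 0) + 1
    n = len(samples)
    return [g for g, k in sorted(hits.items(), key=lambda kv: str(kv[0])) if k / n >= frac_samples]


def _spline_basis(n_basis: int, degree: int = 3) -> tuple[np.ndarray, int]:
    """Open-uniform knot vector on [0, 1] yielding ``n_basis`` basis functions."""
    n_internal = n_basis - degree - 1
    internal = np.linspace(0, 1, n_internal + 2)[1:-1]
    t = np.concatenate([[0.0] * (degree + 1), internal, [1.0] * (degree + 1)])
    return t, degree


def _design_matrix(x: np.ndarray, t: np.ndarray, k: int, n_basis: int) -> np.ndarray:
    B = np.empty((x.size, n_basis))
    for j in range(n_basis):
        c = np.zeros(n_basis)
        c[j] = 1.0
        B[:, j] = BSpline(t, c, k, extrapolate=False)(x)
    return np.nan_to_num(B)


def _second_derivative_penalty(t: np.ndarray, k: int, n_basis: int) -> np.ndarray:
    """Gram matrix of second derivatives, integral over [0, 1] by Gauss-Legendre."""
    splines = []
    for j in range(n_basis):
        c = np.zeros(n_basis)
        c[j] = 1.0
        splines.append(BSpline(t, c, k, extrapolate=False).derivative(2))
    breaks = np.unique(t)
    nodes, weights = np.polynomial.legendre.leggauss(5)
    omega = np.zeros((n_basis, n_basis))
    for a, b in zip(breaks[:-1], breaks[1:]):
        x = 0.5 * (b - a) * nodes + 0.5 * (a + b)
        w = 0.5 * (b - a) * weights
        vals = np.vstack([np.nan_to_num(s(x)) for s in splines])
        omega += (vals * w) @ vals.T
    return omega


def fit_expression_spline(
    pt: np.ndarray,
    expr: np.ndarray,
    grid: PseudotimeGrid | None = None,
    min_cells_per_bin: int = 20,
    smoothing: float = 1.0,
    n_basis: int = 5,
) -> ExpressionSpline:
    """Fit a penalized B-spline expression curve over pseudotime.

    Cells are grouped into the grid's bins; bins with fewer than
    ``min_cells_per_bin`` cells are discarded (>= 3 must survive).  The fit
    minimizes squared error on the bin means plus ``smoothing`` times the
    integrated squared second derivative.  Negative values are clipped to 0
    and the Simpson-rule area defines the unit-area normalization.
    """
    grid = grid or PseudotimeGrid()
    pt = np.asarray(pt, dtype=float)
    expr = np.asarray(expr, dtype=float)
    ok = np.isfinite(pt) & np.isfinite(expr)
    pt, expr = pt[ok], expr[ok]

    edges = np.linspace(0.0, 1.0, grid.n_bins + 1)
    which = np.clip(np.digitize(pt, edges) - 1, 0, grid.n_bins - 1)
    centers, means = [], []
    for b in range(grid.n_bins):
        mask = which == b
        if mask.sum() < min_cells_per_bin:
            continue
        centers.append((edges[b] + edges[b + 1]) / 2.0)
        means.append(expr[mask].mean())
    if len(centers) < 3:
        raise ValueError(
            f"only {len(centers)} pseudotime bins with >= {min_cells_per_bin} cells; need >= 3"
        )
    x, y = np.asarray(centers), np.asarray(means)

    t, k = _spline_basis(n_basis)
    B = _design_matrix(x, t, k, n_basis)
    omega = _second_derivative_penalty(t, k, n_basis)
    lhs = B.T @ B + smoothing * omega
    coef, *_ = np.linalg.lstsq(lhs, B.T @ y, rcond=None)

    values = np.clip(_design_matrix(grid.points, t, k, n_basis) @ coef, 0.0, None)
    area = float(simpson(values, x=grid.points))
    expressed = area > 0
    normalized = values / area if expressed else None
    return ExpressionSpline(
        grid=grid,
        values=values,
        area=area,
        normalized_values=normalized,
        expressed=expressed,
        n_basis=n_basis,
        smoothing=smoothing,
    )


def unexpressed_spline(grid: PseudotimeGrid | None = None) -> ExpressionSpline:
    """The all-zero (unexpressed) curve."""
    grid = grid or PseudotimeGrid()
    z = np.zeros_like(grid.points)
    return ExpressionSpline(
        grid=grid, values=z, area=0.0, normalized_values=None, expressed=False
    )


def emd(a: ExpressionSpline, b: ExpressionSpline) -> float:
    """Wasserstein-1 distance between two unit-area curves on [0, 1].

    If either curve is unexpressed the distance is 1 (the diameter of the
    support) — lost expression is maximally dysregulated by convention.
    """
    if a.grid != b.grid:
        raise ValueError("splines must share the same pseudotime grid")
    if not (a.expressed and b.expressed):
        return 1.0
    x = a.grid.points
    return float(
        wasserstein_distance(x, x, u_weights=a.normalized_values, v_weights=b.normalized_values)
    )


def mean_reference_curve(splines: list[ExpressionSpline]) -> ExpressionSpline:
    """Average the unit-area curves of the expressed samples, then renormalize.

    Averaging normalized curves weights every expressed sample equally
    regardless of its absolute expression level.  All-unexpressed input
    yields the unexpressed curve.
    """
    if not splines:
        raise ValueError("need >= 1 sample spline")
    grid = splines[0].grid
    expressed = [s for s in splines if s.expressed]
    if not expressed:
        return unexpressed_spline(grid)
    for s in expressed:
        if s.grid != grid:
            raise ValueError("splines must share the same pseudotime grid")
    mean = np.mean([s.normalized_values for s in expressed], axis=0)
    area = float(simpson(mean, x=grid.points))
    return ExpressionSpline(
        grid=grid,
        values=mean,
        area=area,
        normalized_values=mean / area,
        expressed=True,
    )


def find_inflection(values: np.ndarray, tol: float = 1e-9) -> int | None:
    """Kneedle knee index of a descending curve; None when no knee exists.

    Both axes are normalized to [0, 1]; the knee is the point of maximal
    drop below the straight line from the first to the last value.  A
    strictly linear input has no knee.  Invariant to positive rescaling.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 5:
        raise ValueError("need >= 5 values for knee detection")
    rng = y.max() - y.min()
    if rng <= 0:
        return None
    x_n = np.linspace(0.0, 1.0, y.size)
    y_n = (y - y.min()) / rng
    diff = (1.0 - x_n) - y_n
    if diff.max() <= tol:
        return None
    return int(np.argmax(diff))


def rank_dysregulated(
    mean_emd: pd.Series,
    reference_area: pd.Series,
    lost_frac: pd.Series,
    trajectory_genes=(),
    area_quantile: float = 0.5,
    lost_max: float = 0.5,
) -> EmdResult:
    """Rank genes by mean EMD and call the dysregulated set at the knee.

    Filters applied before ranking: genes must sit in the upper
    ``1 - area_quantile`` of reference spline area (guards against
    area-normalization noise in lowly expressed genes), be lost (unexpressed)
    in <= ``lost_max`` of samples, and not belong to the trajectory gene set
    (those define the alignment and are dysregulated by construction of the
    comparison).  Dysregulated genes are those ranked above the kneedle
    inflection of the descending mean-EMD curve.
    """
    traj = set(trajectory_genes)
    genes = mean_emd.index
    keep = (
        (reference_area.reindex(genes) >= reference_area.reindex(genes).quantile(area_quantile))
        & (lost_frac.reindex(genes) <= lost_max)
        & ~genes.isin(traj)
    )
    sub = mean_emd[keep].sort_values(ascending=False)
    knee = find_inflection(sub.to_numpy()) if len(sub) >= 5 else None
    dys = np.zeros(len(sub), dtype=bool)
    if knee is None:
        warnings.warn("no knee found in the mean-EMD curve; no genes called dysregulated",
                      stacklevel=2)
    else:
        dys[:knee] = True
    table = pd.DataFrame(
        {
            "gene": sub.index,
            "mean_emd": sub.to_numpy(),
            "rank": np.arange(1, len(sub) + 1),
            "dysregulated": dys,
        }
    ).reset_index(drop=True)
    return EmdResult(table=table, knee=knee)


def _interval_area(spline_values: np.ndarray, grid: PseudotimeGrid, lo: float, hi: float,
                   n_fine: int = 1001) -> float:
    x = np.linspace(lo, hi, n_fine)
    y = np.interp(x, grid.points, spline_values)
    return float(simpson(y, x=x))


def qd_bias(spline: ExpressionSpline, boundaries: StageBoundaries | None = None) -> float | None:
    """Q-over-(Q+D) area bias of an expression curve.

    Area of the unit-area curve over the Q interval [0, b_qa] divided by the
    summed Q- and D-interval areas.  1 means fully quiescence-biased, 0
    fully differentiation-biased; None when both areas vanish.
    """
    if not spline.expressed:
        raise ValueError("qd_bias requires an expressed spline")
    b = boundaries or StageBoundaries()
    q = _interval_area(spline.normalized_values, spline.grid, 0.0, b.b_qa)
    d = _interval_area(spline.normalized_values, spline.grid, b.b_ad, 1.0)
    if q + d == 0:
        return None
    return q / (q + d)


def group_emd_biomarkers(
    group_a: dict[str, list[ExpressionSpline]],
    group_b: dict[str, list[ExpressionSpline]],
    within_max: float = 0.1,
) -> pd.DataFrame:
    """Between-group dynamics differences with within-group consistency control.

    Per gene, each group's member curves are compared (EMD) to the group
    mean curve; genes whose within-group mean EMD exceeds ``within_max`` in
    either group are discarded as inconsistent.  Survivors are ranked by the
    EMD between the two group mean curves.
    """
    rows = []
    for gene in sorted(set(group_a) & set(group_b), key=str):
        sa, sb = group_a[gene], group_b[gene]
        if len(sa) < 2 or len(sb) < 2:
            raise ValueError(f"each group needs >= 2 samples (gene {gene!r})")
        ma, mb = mean_reference_curve(sa), mean_reference_curve(sb)
        wa = float(np.mean([emd(s, ma) for s in sa]))
        wb = float(np.mean([emd(s, mb) for s in sb]))
        rows.append(
            {"gene": gene, "within_a": wa, "within_b": wb,
             "between": emd(ma, mb), "retained": wa <= within_max and wb <= within_max}
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["retained", "between"], ascending=[False, False]).reset_index(drop=True)
        ranks = np.full(len(df), np.nan)
        ranks[: int(df["retained"].sum())] = np.arange(1, int(df["retained"].sum()) + 1)
        df["rank"] = ranks
    return df


DEFAULT_INCREMENTS = ((0.0, 1.0 / 3.0), (1.0 / 3.0, 2.0 / 3.0), (2.0 / 3.0, 1.0))


def area_difference_ratio(
    healthy: ExpressionSpline,
    disease: ExpressionSpline,
    increments=DEFAULT_INCREMENTS,
) -> tuple[np.ndarray, float] | None:
    """Per-increment healthy-vs-disease divergence and its trend over pseudotime.

    For each pseudotime increment, the area under |healthy - disease|
    (raw curves) divided by the maximum value attained by either curve; the
    slope is the least-squares trend of the ratios across ordered increments
    (positive slope = divergence grows along pseudotime).  Returns None when
    both curves are identically zero.
    """
    if healthy.grid != disease.grid:
        raise ValueError("splines must share the same pseudotime grid")
    denom = max(healthy.values.max(), disease.values.max())
    if denom == 0:
        return None
    diff = np.abs(healthy.values - disease.values)
    ratios = np.array(
        [_interval_area(diff, healthy.grid, lo, hi) / denom for lo, hi in increments]
    )
    mids = np.array([(lo + hi) / 2.0 for lo, hi in increments])
    slope = float(np.polyfit(mids, ratios, 1)[0])
    return ratios, slope
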