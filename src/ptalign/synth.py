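"""Synthetic non-branching lineages and query samples with known ground truth.

The generator emulates the features of the alignment problem that matter at
desk scale: pseudotime-dependent gene programs (Gaussian bumps along the
trajectory), negative-binomial count noise with log-normal library-size
variation, cycling-cell contamination carrying an added G2M program,
stage-composition bias between samples, recurrently dysregulated genes with
shifted dynamics, and out-of-distribution cells drawn gene-independently
from the marginal.  Every dataset ships with a truth sidecar so tests never
re-derive ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, log_normalize
from .reference import ReferenceLineage, StageBoundaries, TrajectoryGeneSet

__all__ = ["SynthConfig", "SynthTruth", "make_reference", "make_query_sample", "make_cohort"]


@dataclass(frozen=True)
class SynthConfig:
    """Generative settings; defaults are the package's standard study conditions.

    2,000 reference cells over 300 genes with 150 trajectory genes mirror
    the scale the alignment is validated at; NB dispersion 10 and 0.3
    log-library-size sd give realistically sparse counts without drowning
    the programs.
    """

    n_cells: int = 2000
    n_genes: int = 300
    n_traj_genes: int = 150
    n_informative_genes: int | None = None  # defaults to n_traj_genes
    seed: int = 0
    pt_density: tuple | None = None  # (Q, A, D) stage weights; None = uniform pseudotime
    amplitude: float = 4.0
    baseline: float = 0.2
    noise_base: float = 3.0  # background baselines ~ U(0.05, noise_base)
    width_range: tuple = (0.08, 0.18)
    nb_theta: float = 10.0
    lib_sigma: float = 0.3
    cycling_fraction: float = 0.1
    ood_fraction: float = 0.0
    n_g2m_genes: int = 10
    g2m_boost: float = 6.0
    n_dysregulated: int = 0
    dysreg_center_shift: float = 0.3
    dysreg_amp_scale: float = 1.0
    boundaries: StageBoundaries = field(default_factory=StageBoundaries)

    def __post_init__(self) -> None:
        n_inf = self.n_informative_genes or self.n_traj_genes
        if not (self.n_traj_genes <= n_inf <= self.n_genes):
            raise ValueError("need n_traj_genes <= n_informative_genes <= n_genes")
        for f in (self.cycling_fraction, self.ood_fraction):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_dysregulated > n_inf - self.n_traj_genes:
            raise ValueError(
                "dysregulated genes are drawn from informative non-trajectory genes; "
                "increase n_informative_genes"
            )

    @property
    def n_informative(self) -> int:
        return self.n_informative_genes or self.n_traj_genes


@dataclass
class SynthTruth:
    """Ground truth for a generated dataset."""

    pseudotime: np.ndarray  # generative pseudotime, all cells (incl. cycling/OOD)
    cycling: np.ndarray
    ood: np.ndarray
    gene_informative: np.ndarray
    gene_trajectory: np.ndarray
    gene_dysregulated: np.ndarray
    programs: pd.DataFrame  # center, width, amplitude, baseline per gene
    g2m_genes: list
    s_genes: list

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(per-cell, per-gene) truth tables for sidecar serialization."""
        cells = pd.DataFrame(
            {"pseudotime": self.pseudotime, "cycling": self.cycling, "ood": self.ood}
        )
        genes = self.programs.copy()
        genes["informative"] = self.gene_informative
        genes["trajectory"] = self.gene_trajectory
        genes["dysregulated"] = self.gene_dysregulated
        return cells, genes


def _programs(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene response parameters; informative genes get pseudotime bumps."""
    n, n_inf = cfg.n_genes, cfg.n_informative
    center = np.full(n, np.nan)
    width = np.full(n, np.nan)
    amplitude = np.zeros(n)
    # background genes span the expression range of program genes so that
    # expression-matched permutation sets exist at every decile
    baseline = rng.uniform(0.05, cfg.noise_base, n)
    # spread bump centers evenly with jitter so every stage is covered
    center[:n_inf] = np.clip(
        np.linspace(0.02, 0.98, n_inf) + rng.normal(0, 0.02, n_inf), 0, 1
    )
    width[:n_inf] = rng.uniform(*cfg.width_range, n_inf)
    amplitude[:n_inf] = cfg.amplitude
    baseline[:n_inf] = cfg.baseline
    genes = [f"G{i:04d}" for i in range(n)]
    return pd.DataFrame(
        {"center": center, "width": width, "amplitude": amplitude, "baseline": baseline},
        index=genes,
    )


def _mean_expression(pt: np.ndarray, programs: pd.DataFrame) -> np.ndarray:
    c = programs["center"].to_numpy()
    w = programs["width"].to_numpy()
    a = programs["amplitude"].to_numpy()
    b = programs["baseline"].to_numpy()
    mu = np.tile(b, (pt.size, 1))
    inf = np.isfinite(c)
    mu[:, inf] += a[inf] * np.exp(
        -((pt[:, None] - c[inf][None, :]) ** 2) / (2.0 * w[inf][None, :] ** 2)
    )
    return mu


def _draw_counts(mu: np.ndarray, cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    lib = np.exp(rng.normal(0.0, cfg.lib_sigma, mu.shape[0]))
    mu = mu * lib[:, None]
    if cfg.nb_theta <= 0:  # noise-free limit
        counts = np.round(mu).astype(int)
    else:
        counts = rng.poisson(rng.gamma(cfg.nb_theta, mu / cfg.nb_theta))
    # guard: every cell must have a positive total for normalization
    empty = counts.sum(axis=1) == 0
    if empty.any():
        counts[empty, rng.integers(0, mu.shape[1], int(empty.sum()))] += 1
    return counts


def _sample_pt(n: int, density, boundaries: StageBoundaries, rng: np.random.Generator) -> np.ndarray:
    if density is None:
        return rng.uniform(0.0, 1.0, n)
    w = np.asarray(density, dtype=float)
    w = w / w.sum()
    edges = [0.0, boundaries.b_qa, boundaries.b_ad, 1.0]
    stage = rng.choice(3, size=n, p=w)
    return np.array([rng.uniform(edges[s], edges[s + 1]) for s in stage])


def _apply_cycling(
    mu: np.ndarray, cycling: np.ndarray, cfg: SynthConfig, truth_g2m: list, gene_index
) -> np.ndarray:
    pos = [list(gene_index).index(g) for g in truth_g2m]
    mu = mu.copy()
    mu[np.ix_(cycling, pos)] += cfg.g2m_boost
    return mu


def make_reference(config: SynthConfig) -> tuple[ReferenceLineage, SynthTruth]:
    """Generate a reference lineage with known pseudotime and cycling flags.

    Pseudotime is rescaled to span [0, 1] exactly; cycling cells carry the
    added G2M program and are masked from pseudotime.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    programs = _programs(config, rng)
    pt = _sample_pt(config.n_cells, config.pt_density, config.boundaries, rng)
    pt = (pt - pt.min()) / (pt.max() - pt.min())
    cycling = np.zeros(config.n_cells, dtype=bool)
    n_cyc = int(round(config.cycling_fraction * config.n_cells))
    if n_cyc:
        cycling[rng.choice(config.n_cells, n_cyc, replace=False)] = True

    n_inf = config.n_informative
    g2m_genes = [f"G{i:04d}" for i in range(config.n_genes - config.n_g2m_genes, config.n_genes)]
    s_genes = [
        f"G{i:04d}"
        for i in range(config.n_genes - 2 * config.n_g2m_genes, config.n_genes - config.n_g2m_genes)
    ]
    mu = _mean_expression(pt, programs)
    mu = _apply_cycling(mu, cycling, config, g2m_genes, programs.index)
    counts = _draw_counts(mu, config, rng)

    matrix = log_normalize(
        ExpressionMatrix(
            cell_ids=np.array([f"ref_{i}" for i in range(config.n_cells)], dtype=object),
            gene_ids=np.asarray(programs.index, dtype=object),
            counts=counts,
        )
    )
    lineage = ReferenceLineage(
        matrix=matrix, pseudotime=pt.copy(), cycling=cycling, boundaries=config.boundaries
    )
    gene_informative = np.zeros(config.n_genes, dtype=bool)
    gene_informative[:n_inf] = True
    gene_trajectory = np.zeros(config.n_genes, dtype=bool)
    gene_trajectory[: config.n_traj_genes] = True
    gene_dys = np.zeros(config.n_genes, dtype=bool)
    truth = SynthTruth(
        pseudotime=pt,
        cycling=cycling,
        ood=np.zeros(config.n_cells, dtype=bool),
        gene_informative=gene_informative,
        gene_trajectory=gene_trajectory,
        gene_dysregulated=gene_dys,
        programs=programs,
        g2m_genes=g2m_genes,
        s_genes=s_genes,
    )
    return lineage, truth


def true_trajectory_genes(truth: SynthTruth, boundaries: StageBoundaries | None = None) -> TrajectoryGeneSet:
    """The planted trajectory gene set, stage-labeled by bump center."""
    b = boundaries or StageBoundaries()
    idx = np.flatnonzero(truth.gene_trajectory)
    centers = truth.programs["center"].to_numpy()[idx]
    stage = np.where(centers < b.b_qa, "Q", np.where(centers <= b.b_ad, "A", "D"))
    return TrajectoryGeneSet(
        genes=np.asarray(truth.programs.index, dtype=object)[idx], stage=stage.astype(object)
    )


def make_query_sample(
    config: SynthConfig,
    composition=(1 / 3, 1 / 3, 1 / 3),
    shift: float = 1.0,
    ood_fraction: float | None = None,
    n_cells: int | None = None,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, SynthTruth]:
    """Generate a query sample from the same generative programs.

    Stage composition reweights the pseudotime density; ``shift`` scales all
    program means globally; dysregulated genes (``config.n_dysregulated``,
    always the same informative non-trajectory genes) use bump centers
    shifted by ``config.dysreg_center_shift``; OOD cells are resampled
    gene-independently from the in-distribution marginal.
    """
    comp = np.asarray(composition, dtype=float)
    if not np.isclose(comp.sum(), 1.0, atol=1e-6):
        raise ValueError("composition must sum to 1")
    n = n_cells if n_cells is not None else config.n_cells
    ood_frac = config.ood_fraction if ood_fraction is None else ood_fraction
    rng = np.random.default_rng(config.seed if seed is None else seed)
    # programs are regenerated from config.seed so reference and queries share them
    programs = _programs(config, np.random.default_rng(config.seed))

    pt = _sample_pt(n, comp, config.boundaries, rng)
    cycling = np.zeros(n, dtype=bool)
    n_cyc = int(round(config.cycling_fraction * n))
    if n_cyc:
        cycling[rng.choice(n, n_cyc, replace=False)] = True

    dys = np.zeros(config.n_genes, dtype=bool)
    if config.n_dysregulated:
        dys[config.n_traj_genes : config.n_traj_genes + config.n_dysregulated] = True
        programs = programs.copy()
        centers = programs["center"].to_numpy().copy()
        centers[dys] = np.clip(centers[dys] + config.dysreg_center_shift, 0.0, 1.0)
        programs["center"] = centers
        programs.loc[dys, "amplitude"] = (
            programs.loc[dys, "amplitude"] * config.dysreg_amp_scale
        )

    g2m_genes = [f"G{i:04d}" for i in range(config.n_genes - config.n_g2m_genes, config.n_genes)]
    s_genes = [
        f"G{i:04d}"
        for i in range(config.n_genes - 2 * config.n_g2m_genes, config.n_genes - config.n_g2m_genes)
    ]
    mu = _mean_expression(pt, programs) * shift
    mu = _apply_cycling(mu, cycling, config, g2m_genes, programs.index)
    counts = _draw_counts(mu, config, rng)

    ood = np.zeros(n, dtype=bool)
    n_ood = int(round(ood_frac * n))
    if n_ood:
        ood[rng.choice(np.flatnonzero(~cycling), n_ood, replace=False)] = True
        src = np.flatnonzero(~ood)
        for g in range(config.n_genes):
            donors = rng.choice(src, size=n_ood, replace=True)
            counts[ood, g] = counts[donors, g]

    matrix = log_normalize(
        ExpressionMatrix(
            cell_ids=np.array([f"query_{i}" for i in range(n)], dtype=object),
            gene_ids=np.asarray(programs.index, dtype=object),
            counts=counts,
        )
    )
    gene_informative = np.zeros(config.n_genes, dtype=bool)
    gene_informative[: config.n_informative] = True
    gene_trajectory = np.zeros(config.n_genes, dtype=bool)
    gene_trajectory[: config.n_traj_genes] = True
    truth = SynthTruth(
        pseudotime=pt,
        cycling=cycling,
        ood=ood,
        gene_informative=gene_informative,
        gene_trajectory=gene_trajectory,
        gene_dysregulated=dys,
        programs=programs,
        g2m_genes=g2m_genes,
        s_genes=s_genes,
    )
    return matrix, truth


def make_cohort(
    n_samples: int,
    config: SynthConfig,
    q_dominated=(0.7, 0.2, 0.1),
    d_dominated=(0.1, 0.2, 0.7),
    n_cells: int | None = None,
) -> list[tuple[ExpressionMatrix, SynthTruth, np.ndarray]]:
    """Samples spaced along a Q-dominated to D-dominated composition spectrum.

    Per-sample seeds derive from the master ``config.seed``; each element is
    (matrix, truth, composition).
    """
    if n_samples < 2:
        raise ValueError("need >= 2 samples")
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_samples)
    out = []
    for i in range(n_samples):
        frac = i / (n_samples - 1)
        comp = (1 - frac) * np.asarray(q_dominated) + frac * np.asarray(d_dominated)
        comp = comp / comp.sum()
        m, t = make_query_sample(
            config, composition=comp, n_cells=n_cells, seed=int(seeds[i])
        )
        out.append((m, t, comp))
    return out


def with_seed(config: SynthConfig, seed: int) -> SynthConfig:
    """A copy of ``config`` with a different seed (programs change with it)."""
    return replace(config, seed=seed)
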