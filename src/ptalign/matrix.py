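"""Expression-matrix container and per-cell log-normalization.

The container is deliberately small: cells x genes counts with an optional
derived ``lognorm`` layer, plus unique string ids on both axes.  Heavier
ecosystems (AnnData) are used where a third-party routine needs them, but the
alignment pipeline itself only requires dense arrays at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["ExpressionMatrix", "log_normalize"]


def _as_dense(a) -> np.ndarray:
    if sp.issparse(a):
        a = a.toarray()
    return np.asarray(a)


@dataclass
class ExpressionMatrix:
    """Cells x genes counts with an optional log-normalized layer.

    Parameters
    ----------
    cell_ids, gene_ids
        Unique string identifiers; gene ids are conventionally uppercase
        1:1-ortholog symbols so that mouse references and human queries share
        one symbol space.
    counts
        Nonnegative integer matrix, one row per cell.
    lognorm
        Derived layer from :func:`log_normalize`; ``None`` until computed.
    """

    cell_ids: np.ndarray
    gene_ids: np.ndarray
    counts: np.ndarray
    lognorm: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.counts = _as_dense(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        for name, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} ids")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_indexer(self, genes) -> np.ndarray:
        """Integer positions of ``genes`` (order preserved); missing genes error."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as e:  # pragma: no cover - message path
            raise KeyError(f"gene {e.args[0]!r} absent from matrix") from None

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = self.gene_indexer(genes)
        return ExpressionMatrix(
            cell_ids=self.cell_ids.copy(),
            gene_ids=self.gene_ids[idx].copy(),
            counts=self.counts[:, idx].copy(),
            lognorm=None if self.lognorm is None else self.lognorm[:, idx].copy(),
        )


def log_normalize(matrix: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Per-cell library-size normalization followed by log1p.

    Each entry becomes ``log1p(count * scale / cell_total)``.  The counts
    layer is untouched; a new matrix carrying the ``lognorm`` layer is
    returned.

    Raises
    ------
    ValueError
        If any cell has a zero total count (the cell id is named).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = matrix.counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cell(s) with all-zero counts cannot be normalized: "
            f"{list(matrix.cell_ids[zero[:5]])}"
        )
    lognorm = np.log1p(matrix.counts * (scale / totals[:, None]))
    return ExpressionMatrix(
        cell_ids=matrix.cell_ids,
        gene_ids=matrix.gene_ids,
        counts=matrix.counts,
        lognorm=lognorm,
    )
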