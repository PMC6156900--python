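"""Kinship / expected-relationship matrices.

The package stores the *relationship* matrix ``K = 2 * Phi`` (GRM
convention), where ``Phi`` is the matrix of kinship coefficients — the
probability that two alleles drawn at random, one from each individual, are
identical by descent.  Non-inbred individuals therefore have unit diagonal
(``Phi_self = 1/2``), full siblings share ``K = 0.5``, and members of
different families share 0.  The overall scale of K is absorbed by the
family variance component, so the choice of convention is free; it only has
to be used consistently, and it is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = ["KinshipMatrix", "kinship_from_pedigree", "exchangeable_family_matrix"]

#: tolerance on the smallest eigenvalue when checking positive semidefiniteness
PSD_TOL = 1e-10


@dataclass(frozen=True)
class KinshipMatrix:
    """Symmetric PSD expected-relationship matrix with row/column ids."""

    ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        ids = tuple(self.ids)
        object.__setattr__(self, "ids", ids)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(ids)
        if len(set(ids)) != n:
            raise ValueError("kinship ids must be unique")
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} does not match {n} ids")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("kinship matrix must be symmetric")
        if values.size and (values.min() < -1e-12 or values.max() > 2 + 1e-12):
            raise ValueError("kinship entries must lie in [0, 2]")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_psd(self, tol: float = PSD_TOL) -> bool:
        return float(np.linalg.eigvalsh(self.values)[0]) >= -tol

    def check_psd(self, tol: float = PSD_TOL) -> None:
        smallest = float(np.linalg.eigvalsh(self.values)[0])
        if smallest < -tol:
            raise ValueError(
                f"kinship matrix is not positive semidefinite "
                f"(smallest eigenvalue {smallest:.3e})"
            )

    @classmethod
    def identity(cls, ids: Sequence[str]) -> "KinshipMatrix":
        ids = tuple(ids)
        return cls(ids, np.eye(len(ids)))

    def subset(self, ids: Iterable[str]) -> "KinshipMatrix":
        """Submatrix on ``ids`` (kept in the order given)."""
        ids = tuple(ids)
        pos = {iid: i for i, iid in enumerate(self.ids)}
        try:
            idx = np.array([pos[iid] for iid in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not in kinship matrix") from None
        return KinshipMatrix(ids, self.values[np.ix_(idx, idx)])

    # -- text I/O: square TSV with a header row of ids -------------------
    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))
        df.to_csv(path, sep="\t", float_format="%.12g", index_label="id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = tuple(str(c) for c in df.columns)
        if tuple(str(i) for i in df.index) != ids:
            raise ValueError(f"{path}: row ids do not match column ids")
        return cls(ids, df.to_numpy(dtype=float))


def kinship_from_pedigree(ped: Pedigree) -> KinshipMatrix:
    """Relationship matrix K = 2*Phi from a pedigree by the recursive rule.

    Founders are non-inbred and mutually unrelated; then
    ``Phi_jj = (1 + Phi_{f,m}) / 2`` and ``Phi_ij = (Phi_{i,f} + Phi_{i,m}) / 2``
    where ``f``, ``m`` are the parents of the later-born of ``i, j`` and a
    missing parent contributes 0.  Processing individuals parents-first makes
    the recursion a single forward pass.
    """
    topo = ped.topological_order()
    pos = {iid: k for k, iid in enumerate(topo)}
    n = len(topo)
    phi = np.zeros((n, n))
    for j, iid in enumerate(topo):
        ind = ped[iid]
        fa = pos[ind.father_id] if ind.father_id is not None else None
        mo = pos[ind.mother_id] if ind.mother_id is not None else None
        parent_phi = phi[fa, mo] if fa is not None and mo is not None else 0.0
        phi[j, j] = 0.5 * (1.0 + parent_phi)
        for i in range(j):
            val = 0.0
            if fa is not None:
                val += phi[i, fa]
            if mo is not None:
                val += phi[i, mo]
            phi[i, j] = phi[j, i] = 0.5 * val
    # reindex from topological to family-major order
    order = np.array([pos[iid] for iid in ped.ids], dtype=int)
    k = 2.0 * phi[np.ix_(order, order)]
    return KinshipMatrix(ped.ids, k)


def exchangeable_family_matrix(
    n_families: int,
    family_size: int,
    within_value: float,
    ids: Optional[Sequence[str]] = None,
) -> KinshipMatrix:
    """Block-diagonal K with exchangeable within-family blocks.

    Each of the ``n_families`` blocks is ``family_size`` x ``family_size``
    with unit diagonal and off-diagonal ``within_value`` (0.5 reproduces
    full sibships); different families are unrelated.  ``within_value``
    must lie in [0, 1) so every block is positive definite.
    """
    if n_families < 1 or family_size < 1:
        raise ValueError("n_families and family_size must be positive")
    if not 0.0 <= within_value < 1.0:
        raise ValueError(
            f"within_value must be in [0, 1), got {within_value}"
        )
    s = family_size
    block = np.full((s, s), within_value)
    np.fill_diagonal(block, 1.0)
    values = np.kron(np.eye(n_families), block)
    if ids is None:
        ids = tuple(
            f"F{f:04d}-S{i:02d}"
            for f in range(1, n_families + 1)
            for i in range(1, s + 1)
        )
    else:
        ids = tuple(ids)
        if len(ids) != n_families * s:
            raise ValueError("ids length does not match n_families * family_size")
    return KinshipMatrix(ids, values)
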