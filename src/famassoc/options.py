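"""The three modeling options and their covariance specifications.

* ``representative`` — keep one randomly drawn member per family and treat
  the subsample as independent (identity covariance on the subset).
* ``kinship`` — model all individuals with family random-effect covariance
  proportional to the relationship matrix K.
* ``independence`` — model all individuals, ignoring family structure
  (identity covariance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .kinship import KinshipMatrix
from .pedigree import Pedigree

__all__ = [
    "OPTIONS",
    "CovarianceSpec",
    "select_representatives",
    "draw_one_per_family",
    "build_covariance_spec",
]

OPTIONS = ("representative", "kinship", "independence")


@dataclass(frozen=True)
class CovarianceSpec:
    """Covariance structure of one modeling option.

    ``universe`` is the full id set the data are aligned to; ``active_ids``
    the subset actually modeled (all ids except under the representative
    option, where it is one member per family); ``matrix`` is the covariance
    structure on ``active_ids``.
    """

    option: str
    matrix: KinshipMatrix
    active_ids: tuple[str, ...]
    universe: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.option not in OPTIONS:
            raise ValueError(
                f"unknown option {self.option!r}; expected one of {OPTIONS}"
            )
        object.__setattr__(self, "active_ids", tuple(self.active_ids))
        object.__setattr__(self, "universe", tuple(self.universe))
        if self.matrix.ids != self.active_ids:
            raise ValueError("matrix ids must equal active_ids")
        missing = set(self.active_ids) - set(self.universe)
        if missing:
            raise ValueError(f"active ids not in universe: {sorted(missing)[:3]}")
        if self.option in ("representative", "independence"):
            if not np.array_equal(self.matrix.values, np.eye(len(self.active_ids))):
                raise ValueError(f"{self.option} option requires identity covariance")
        if self.option in ("kinship", "independence") and len(self.active_ids) != len(
            self.universe
        ):
            raise ValueError(f"{self.option} option must keep all individuals")

    @property
    def n_active(self) -> int:
        return len(self.active_ids)

    def active_indices(self) -> np.ndarray:
        """Row indices of ``active_ids`` within ``universe``."""
        pos = {iid: i for i, iid in enumerate(self.universe)}
        return np.array([pos[iid] for iid in self.active_ids], dtype=int)


def draw_one_per_family(
    families: Mapping[str, Sequence[str]], seed: int
) -> tuple[str, ...]:
    """Uniformly draw one individual id per family; deterministic in seed.

    Families are visited in mapping order, so the returned tuple is
    family-ordered and reproducible.
    """
    rng = np.random.default_rng(seed)
    chosen = []
    for fam_id, members in families.items():
        if len(members) == 0:
            raise ValueError(f"family {fam_id!r} is empty")
        chosen.append(members[int(rng.integers(len(members)))])
    return tuple(chosen)


def select_representatives(ped: Pedigree, seed: int) -> tuple[str, ...]:
    """One uniformly drawn representative per family of the pedigree."""
    families = {
        fam: [ind.individual_id for ind in members]
        for fam, members in ped.families.items()
    }
    return draw_one_per_family(families, seed)


def build_covariance_spec(
    option: str,
    K: KinshipMatrix,
    representatives: Optional[Sequence[str]] = None,
) -> CovarianceSpec:
    """Assemble the :class:`CovarianceSpec` for one modeling option.

    The kinship option keeps ``K`` as-is; the independence option discards
    it for the identity; the representative option needs ``representatives``
    (one id per family, all present in ``K``) and uses the identity on that
    subset.
    """
    if option not in OPTIONS:
        raise ValueError(f"unknown option {option!r}; expected one of {OPTIONS}")
    universe = K.ids
    if option == "kinship":
        return CovarianceSpec("kinship", K, universe, universe)
    if option == "independence":
        return CovarianceSpec(
            "independence", KinshipMatrix.identity(universe), universe, universe
        )
    if representatives is None:
        raise ValueError("representative option requires a set of representatives")
    # keep universe order, not draw order, so rows subset cleanly
    rep_set = set(representatives)
    missing = rep_set - set(universe)
    if missing:
        raise ValueError(f"representatives not in kinship ids: {sorted(missing)[:3]}")
    reps = tuple(iid for iid in universe if iid in rep_set)
    return CovarianceSpec(
        "representative", KinshipMatrix.identity(reps), reps, universe
    )
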