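"""Pedigree representation and PLINK ``.fam`` input/output.

A :class:`Pedigree` is an ordered collection of :class:`Individual` records
partitioned into families.  Individuals are kept in *family-major* order
(families in order of first appearance, insertion order within a family);
every matrix and vector downstream shares this ordering.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

__all__ = ["Individual", "Pedigree", "PedigreeError", "sibship_pedigree"]

_SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
_SEX_TO_CODE = {"male": "1", "female": "2", "unknown": "0"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree, naming the offending individual."""

    def __init__(self, message: str, individual_id: Optional[str] = None):
        super().__init__(message)
        self.individual_id = individual_id


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id`` / ``mother_id`` are ``None`` for a founder (or an
    unobserved parent); ``sex`` is one of ``male``, ``female``, ``unknown``.
    """

    individual_id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.sex not in _SEX_TO_CODE:
            raise PedigreeError(
                f"invalid sex {self.sex!r} for individual {self.individual_id!r}",
                self.individual_id,
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """A validated set of individuals grouped into families.

    Validation checks id uniqueness, that every named parent resolves to a
    member of the pedigree, and that the parent graph is acyclic (so a
    topological order, parents before children, exists).
    """

    def __init__(self, individuals: Iterable[Individual]):
        members: "OrderedDict[str, Individual]" = OrderedDict()
        for ind in individuals:
            if ind.individual_id in members:
                raise PedigreeError(
                    f"duplicate individual id {ind.individual_id!r}",
                    ind.individual_id,
                )
            members[ind.individual_id] = ind
        if not members:
            raise PedigreeError("pedigree is empty")
        for ind in members.values():
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None and parent not in members:
                    raise PedigreeError(
                        f"individual {ind.individual_id!r} names missing parent "
                        f"{parent!r}",
                        ind.individual_id,
                    )
        self._members = members
        self._topo = self._topological_order()  # raises on cycles
        fams: "OrderedDict[str, list[Individual]]" = OrderedDict()
        for ind in members.values():
            fams.setdefault(ind.family_id, []).append(ind)
        self._families = fams

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._members

    def __getitem__(self, individual_id: str) -> Individual:
        return self._members[individual_id]

    @property
    def ids(self) -> tuple[str, ...]:
        """All individual ids in family-major order."""
        return tuple(
            ind.individual_id for fam in self._families.values() for ind in fam
        )

    @property
    def families(self) -> "OrderedDict[str, list[Individual]]":
        return self._families

    @property
    def family_ids(self) -> tuple[str, ...]:
        return tuple(self._families)

    def topological_order(self) -> tuple[str, ...]:
        """Ids ordered so that every parent precedes its children."""
        return self._topo

    def _topological_order(self) -> tuple[str, ...]:
        order: list[str] = []
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str, child: str) -> None:
            st = state.get(iid)
            if st == 1:
                return
            if st == 0:
                raise PedigreeError(
                    f"pedigree cycle detected at individual {iid!r}", iid
                )
            state[iid] = 0
            ind = self._members[iid]
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None:
                    visit(parent, iid)
            state[iid] = 1
            order.append(iid)

        for iid in self._members:
            visit(iid, iid)
        return tuple(order)

    # -- PLINK .fam dialect ----------------------------------------------
    @classmethod
    def read_fam(cls, path: str | Path) -> "Pedigree":
        """Read a whitespace-delimited FID IID PAT MAT SEX PHENO table.

        ``0`` denotes a missing parent; the phenotype column is ignored.
        """
        individuals = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise PedigreeError(
                    f"{path}:{lineno}: expected >=5 whitespace-delimited fields, "
                    f"got {len(fields)}"
                )
            fid, iid, pat, mat, sex = fields[:5]
            individuals.append(
                Individual(
                    individual_id=iid,
                    family_id=fid,
                    father_id=None if pat == "0" else pat,
                    mother_id=None if mat == "0" else mat,
                    sex=_SEX_CODES.get(sex, "unknown"),
                )
            )
        return cls(individuals)

    def write_fam(self, path: str | Path) -> None:
        lines = []
        for iid in self.ids:
            ind = self._members[iid]
            lines.append(
                " ".join(
                    [
                        ind.family_id,
                        ind.individual_id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_TO_CODE[ind.sex],
                        "-9",
                    ]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n")


def sibship_pedigree(
    n_families: int, family_size: int, include_parents: bool = True
) -> Pedigree:
    """Pedigree of ``n_families`` sibships of ``family_size`` full siblings.

    Each family has two founder parents; set ``include_parents=False`` to get
    sibling-only families (founders latent), the structure used throughout
    the simulations.
    """
    if n_families < 1 or family_size < 1:
        raise ValueError("n_families and family_size must be positive")
    individuals = []
    for f in range(1, n_families + 1):
        fam = f"F{f:04d}"
        father, mother = f"{fam}-P1", f"{fam}-P2"
        if include_parents:
            individuals.append(Individual(father, fam, sex="male"))
            individuals.append(Individual(mother, fam, sex="female"))
        for s in range(1, family_size + 1):
            individuals.append(
                Individual(
                    f"{fam}-S{s:02d}",
                    fam,
                    father_id=father if include_parents else None,
                    mother_id=mother if include_parents else None,
                )
            )
    return Pedigree(individuals)
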