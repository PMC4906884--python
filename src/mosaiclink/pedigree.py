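"""Pedigree container for half-sib families.

The structure of interest is a single sire mated to many dams, one offspring
per dam ("paternal half-sib family") — the classic cattle AI design in which a
dominant de novo mutation carried by a mosaic sire surfaces as a burst of
affected calves. The container itself is general: any acyclic pedigree with
resolvable parent links is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from .exceptions import InvalidDesignError

MALE = 1
FEMALE = 2


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``sire_id``/``dam_id`` are ``None`` for founders. ``affected`` is the
    binary disease phenotype (full penetrance is assumed by the downstream
    linkage and segregation logic, not enforced here).
    """

    id: str
    sire_id: Optional[str]
    dam_id: Optional[str]
    sex: int
    affected: bool


class Pedigree:
    """An ordered, validated collection of :class:`Individual`.

    Validation: ids unique, parent references resolve, parent sexes are
    consistent, and no individual is its own ancestor.
    """

    def __init__(self, individuals: Iterable[Individual]):
        members = list(individuals)
        by_id = {}
        for ind in members:
            if ind.id in by_id:
                raise InvalidDesignError(f"duplicate individual id {ind.id!r}")
            by_id[ind.id] = ind
        for ind in members:
            for pid, want_sex, label in (
                (ind.sire_id, MALE, "sire"),
                (ind.dam_id, FEMALE, "dam"),
            ):
                if pid is None:
                    continue
                if pid not in by_id:
                    raise InvalidDesignError(
                        f"{label} {pid!r} of {ind.id!r} is not in the pedigree"
                    )
                if by_id[pid].sex != want_sex:
                    raise InvalidDesignError(
                        f"{label} {pid!r} of {ind.id!r} has sex {by_id[pid].sex}"
                    )
        self._members = members
        self._by_id = by_id
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise InvalidDesignError(f"{iid!r} is its own ancestor")
            state[iid] = 0
            ind = self._by_id[iid]
            for pid in (ind.sire_id, ind.dam_id):
                if pid is not None:
                    visit(pid)
            state[iid] = 1

        for ind in self._members:
            visit(ind.id)

    # -- container protocol -------------------------------------------------
    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members)

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def __getitem__(self, iid: str) -> Individual:
        return self._by_id[iid]

    @property
    def members(self) -> list[Individual]:
        return list(self._members)

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self._members]

    # -- queries -------------------------------------------------------------
    def founders(self) -> list[Individual]:
        return [i for i in self._members if i.sire_id is None and i.dam_id is None]

    def offspring_of(self, parent_id: str) -> list[Individual]:
        return [
            i
            for i in self._members
            if parent_id in (i.sire_id, i.dam_id)
        ]

    def affected(self) -> list[Individual]:
        return [i for i in self._members if i.affected]

    def sires(self) -> list[str]:
        """Ids of individuals appearing as a sire, in pedigree order."""
        seen: list[str] = []
        for ind in self._members:
            if ind.sire_id is not None and ind.sire_id not in seen:
                seen.append(ind.sire_id)
        return seen

    def affected_half_sibs(self, sire_id: str) -> list[Individual]:
        """Affected offspring of ``sire_id`` — the case set for allele-sharing
        linkage."""
        return [i for i in self.offspring_of(sire_id) if i.affected]
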