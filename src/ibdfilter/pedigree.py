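"""Pedigree structures and LINKAGE-format PED input/output.

A pedigree file groups individuals into families.  Each individual either
has both parents inside the same family (non-founder) or neither
(founder); married-in spouses are founders.  The container validates
structure on construction: no duplicate ids, no dangling parent
references, parental sexes consistent, and no ancestry cycles.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

MISSING = "0"
MALE = 1
FEMALE = 2


class PedigreeError(ValueError):
    """Structurally invalid pedigree or malformed PED input."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member; ``father``/``mother`` are ``None`` for founders."""

    iid: str
    father: Optional[str]
    mother: Optional[str]
    sex: int
    family: str

    @property
    def is_founder(self) -> bool:
        return self.father is None


class Pedigree:
    """Immutable collection of :class:`Individual` with derived structure.

    Iteration yields individual ids in topological order (parents before
    children), which is also the deterministic processing order used by
    the gene-drop simulator and the kinship recursion.
    """

    def __init__(self, individuals: Iterable[Individual]):
        members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.iid in members:
                raise PedigreeError(f"duplicate individual id {ind.iid!r}")
            if (ind.father is None) != (ind.mother is None):
                raise PedigreeError(
                    f"individual {ind.iid!r} has exactly one parent; "
                    "both or neither are required"
                )
            if ind.sex not in (MALE, FEMALE):
                raise PedigreeError(f"individual {ind.iid!r} has invalid sex {ind.sex!r}")
            members[ind.iid] = ind
        children: dict[str, list[str]] = defaultdict(list)
        for ind in members.values():
            if ind.is_founder:
                continue
            for pid, want_sex, label in (
                (ind.father, MALE, "father"),
                (ind.mother, FEMALE, "mother"),
            ):
                if pid not in members:
                    raise PedigreeError(
                        f"individual {ind.iid!r} references unknown {label} {pid!r}"
                    )
                parent = members[pid]
                if parent.sex != want_sex:
                    raise PedigreeError(
                        f"{label} {pid!r} of {ind.iid!r} has sex {parent.sex}"
                    )
                if parent.family != ind.family:
                    raise PedigreeError(
                        f"parent {pid!r} of {ind.iid!r} is in a different family"
                    )
                children[pid].append(ind.iid)
        self._members = members
        self._children = {k: tuple(sorted(v)) for k, v in children.items()}
        self._order = self._toposort()
        self._rank = self._ranks()

    def _toposort(self) -> tuple[str, ...]:
        indeg = {iid: 0 for iid in self._members}
        for ind in self._members.values():
            if not ind.is_founder:
                indeg[ind.iid] = 2
        ready = sorted(iid for iid, d in indeg.items() if d == 0)
        order: list[str] = []
        queue = list(ready)
        while queue:
            iid = queue.pop(0)
            order.append(iid)
            newly = []
            for cid in self._children.get(iid, ()):
                indeg[cid] -= 1
                if indeg[cid] == 0:
                    newly.append(cid)
            queue.extend(sorted(newly))
        if len(order) != len(self._members):
            raise PedigreeError("pedigree contains an ancestry cycle")
        return tuple(order)

    def _ranks(self) -> dict[str, int]:
        rank: dict[str, int] = {}
        for iid in self._order:
            ind = self._members[iid]
            if ind.is_founder:
                rank[iid] = 0
            else:
                rank[iid] = max(rank[ind.father], rank[ind.mother]) + 1
        return rank

    # -- basic access ---------------------------------------------------

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self) -> Iterator[str]:
        return iter(self._order)

    def __contains__(self, iid: str) -> bool:
        return iid in self._members

    def individual(self, iid: str) -> Individual:
        try:
            return self._members[iid]
        except KeyError:
            raise PedigreeError(f"unknown individual id {iid!r}") from None

    @property
    def members(self) -> Mapping[str, Individual]:
        return self._members

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(sorted({ind.family for ind in self._members.values()}))

    def members_of(self, family: str) -> tuple[str, ...]:
        return tuple(
            iid for iid in self._order if self._members[iid].family == family
        )

    @property
    def founders(self) -> tuple[str, ...]:
        return tuple(iid for iid in self._order if self._members[iid].is_founder)

    def children_of(self, iid: str) -> tuple[str, ...]:
        self.individual(iid)
        return self._children.get(iid, ())

    def generation(self, iid: str) -> int:
        """Depth below the family's founders (founders are 0)."""
        self.individual(iid)
        return self._rank[iid]

    def couples(self) -> list[tuple[tuple[str, str], tuple[str, ...]]]:
        """All mated pairs ``(father, mother)`` with their children, sorted."""
        by_pair: dict[tuple[str, str], list[str]] = defaultdict(list)
        for ind in self._members.values():
            if not ind.is_founder:
                by_pair[(ind.father, ind.mother)].append(ind.iid)
        return sorted((pair, tuple(sorted(kids))) for pair, kids in by_pair.items())

    def pairs(self, family: Optional[str] = None) -> list[tuple[str, str]]:
        """All unordered within-family pairs, in canonical (sorted) order."""
        fams = [family] if family is not None else list(self.families)
        out: list[tuple[str, str]] = []
        for fam in fams:
            ids = sorted(self.members_of(fam))
            out.extend(itertools.combinations(ids, 2))
        return out


# -- LINKAGE PED input/output ------------------------------------------


def read_ped(path: str | Path) -> Pedigree:
    """Parse a whitespace-delimited 6+ column LINKAGE PED file.

    Columns: family, individual, father, mother, sex, phenotype.  Parent
    id ``0`` marks a founder; the phenotype column is ignored here
    (affection status lives in replicate phenotype files).
    """
    individuals: list[Individual] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(
                    f"{path}:{lineno}: expected >=6 columns, got {len(fields)}"
                )
            fam, iid, fa, mo, sex, _ = fields[:6]
            try:
                sex_code = int(sex)
            except ValueError:
                raise PedigreeError(f"{path}:{lineno}: bad sex code {sex!r}") from None
            individuals.append(
                Individual(
                    iid=iid,
                    father=None if fa == MISSING else fa,
                    mother=None if mo == MISSING else mo,
                    sex=sex_code,
                    family=fam,
                )
            )
    try:
        return Pedigree(individuals)
    except PedigreeError as exc:
        raise PedigreeError(f"{path}: {exc}") from None


def write_ped(
    pedigree: Pedigree,
    path: str | Path,
    affection: Optional[Mapping[str, bool]] = None,
    header: Sequence[str] = (),
) -> None:
    """Write a LINKAGE PED file (phenotype column: 2=affected, 1=not, 0=unknown)."""
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for iid in pedigree:
            ind = pedigree.individual(iid)
            if affection is None:
                phen = "0"
            else:
                phen = "2" if affection.get(iid, False) else "1"
            fh.write(
                f"{ind.family}\t{ind.iid}\t{ind.father or MISSING}\t"
                f"{ind.mother or MISSING}\t{ind.sex}\t{phen}\n"
            )
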