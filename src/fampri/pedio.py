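"""Pedigree data model, validation, and 6-column PED input/output.

The pedigree is the unit over which both the segregation filter and the
parametric linkage likelihood are computed.  Files follow the PLINK/Merlin
6-column dialect: FID IID PAT MAT SEX PHENO, whitespace-delimited, with
``0`` coding a missing parent, sex coded 1=male / 2=female / 0=unknown and
phenotype coded 2=affected / 1=unaffected / 0 or -9=unknown.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import networkx as nx

from .errors import PedigreeCycleError, PedigreeLoopError, PedigreeStructureError


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Phenotype(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_SEX_TO_CODE = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_PHENO_CODES = {"1": Phenotype.UNAFFECTED, "2": Phenotype.AFFECTED,
                "0": Phenotype.UNKNOWN, "-9": Phenotype.UNKNOWN}
_PHENO_TO_CODE = {Phenotype.UNAFFECTED: "1", Phenotype.AFFECTED: "2", Phenotype.UNKNOWN: "0"}


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father``/``mother`` are both ``None`` for founders and both set for
    non-founders; a half-specified parent pair is a structural error.
    """

    iid: str
    fid: str = "FAM"
    father: str | None = None
    mother: str | None = None
    sex: Sex = Sex.UNKNOWN
    phenotype: Phenotype = Phenotype.UNKNOWN

    def __post_init__(self) -> None:
        if (self.father is None) != (self.mother is None):
            raise PedigreeStructureError(
                f"individual {self.iid!r}: father and mother must both be set or both missing"
            )

    @property
    def is_founder(self) -> bool:
        return self.father is None


@dataclass
class Pedigree:
    """A validated, loop-checked family graph.

    Validation runs on construction: parent references must resolve, iids
    must be unique, the graph must be acyclic, and parental sexes must be
    compatible with their role (unknown sex is allowed — the role is carried
    by the PAT/MAT column, which matters when sexes are masked for privacy).
    ``has_loops`` records whether the family graph contains a marriage or
    inbreeding loop; loop-free structure is required by the linkage peeler.
    """

    individuals: list[Individual]
    name: str = "FAM"
    has_loops: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        self._by_iid: dict[str, Individual] = {}
        for ind in self.individuals:
            if ind.iid in self._by_iid:
                raise PedigreeStructureError(f"duplicate individual id {ind.iid!r}")
            self._by_iid[ind.iid] = ind
        for ind in self.individuals:
            for role, pid in (("father", ind.father), ("mother", ind.mother)):
                if pid is None:
                    continue
                if pid not in self._by_iid:
                    raise PedigreeStructureError(
                        f"individual {ind.iid!r} names missing {role} {pid!r}"
                    )
            if ind.father is not None:
                f = self._by_iid[ind.father]
                m = self._by_iid[ind.mother]
                if f.sex is Sex.FEMALE:
                    raise PedigreeStructureError(
                        f"father {f.iid!r} of {ind.iid!r} has female sex")
                if m.sex is Sex.MALE:
                    raise PedigreeStructureError(
                        f"mother {m.iid!r} of {ind.iid!r} has male sex")
        self._check_acyclic()
        self.has_loops = self._detect_loops()

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self._by_iid)
        for ind in self.individuals:
            if ind.father is not None:
                g.add_edge(ind.father, ind.iid)
                g.add_edge(ind.mother, ind.iid)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
        raise PedigreeCycleError(f"pedigree contains an ancestry cycle: {path}")

    def _detect_loops(self) -> bool:
        # The bipartite individual/nuclear-family graph of a loop-free
        # pedigree is a forest; any extra edge indicates a marriage or
        # inbreeding loop.
        g = nx.Graph()
        for (fid_, mid), children in self.nuclear_families().items():
            fam = ("fam", fid_, mid)
            for member in (fid_, mid, *children):
                g.add_edge(fam, ("ind", member))
        if g.number_of_nodes() == 0:
            return False
        return g.number_of_edges() > g.number_of_nodes() - nx.number_connected_components(g)

    # -- access -----------------------------------------------------------
    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals)

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_iid

    def __getitem__(self, iid: str) -> Individual:
        return self._by_iid[iid]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return self.name == other.name and self.individuals == other.individuals

    @property
    def founders(self) -> list[Individual]:
        return [i for i in self.individuals if i.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [i for i in self.individuals if not i.is_founder]

    def affected_ids(self) -> list[str]:
        return [i.iid for i in self.individuals if i.phenotype is Phenotype.AFFECTED]

    def unaffected_ids(self) -> list[str]:
        return [i.iid for i in self.individuals if i.phenotype is Phenotype.UNAFFECTED]

    def nuclear_families(self) -> dict[tuple[str, str], list[str]]:
        """Children grouped by (father, mother) couple, in input order."""
        fams: dict[tuple[str, str], list[str]] = {}
        for ind in self.individuals:
            if ind.father is not None:
                fams.setdefault((ind.father, ind.mother), []).append(ind.iid)
        return fams


@dataclass(frozen=True)
class NuclearFamily:
    """One father/mother/children unit in a peeling sequence.

    ``pivot`` is the member through which the family's likelihood
    contribution is passed to the rest of the pedigree; it is ``None`` for
    the last family of a connected component.
    """

    father: str
    mother: str
    children: tuple[str, ...]
    pivot: str | None

    @property
    def members(self) -> tuple[str, ...]:
        return (self.father, self.mother) + self.children


def read_ped(path: str | Path) -> Pedigree:
    """Read a 6-column PED file into a validated :class:`Pedigree`."""
    path = Path(path)
    individuals: list[Individual] = []
    name = "FAM"
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeStructureError(
                    f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            fid, iid, pat, mat, sex, pheno = fields[:6]
            name = fid
            individuals.append(Individual(
                iid=iid,
                fid=fid,
                father=None if pat == "0" else pat,
                mother=None if mat == "0" else mat,
                sex=_SEX_CODES.get(sex, Sex.UNKNOWN),
                phenotype=_PHENO_CODES.get(pheno, Phenotype.UNKNOWN),
            ))
    return Pedigree(individuals, name=name)


def write_ped(pedigree: Pedigree, path: str | Path) -> None:
    """Write a pedigree in the 6-column PED dialect read by :func:`read_ped`."""
    with open(path, "w") as fh:
        for ind in pedigree:
            fh.write(" ".join([
                ind.fid,
                ind.iid,
                ind.father or "0",
                ind.mother or "0",
                _SEX_TO_CODE[ind.sex],
                _PHENO_TO_CODE[ind.phenotype],
            ]) + "\n")


def peeling_order(pedigree: Pedigree) -> list[NuclearFamily]:
    """Order nuclear families for leaf-first (Elston–Stewart) elimination.

    Families are peeled one at a time; a family is peelable when at most one
    of its members still connects it to un-peeled families, and that member
    becomes the pivot.  Leaf families (pivot is a parent) are preferred over
    peel-down families, and ties break lexicographically on the (father,
    mother) couple, so the order is deterministic.

    Raises
    ------
    PedigreeLoopError
        If the pedigree contains a marriage or inbreeding loop.
    """
    if pedigree.has_loops:
        raise PedigreeLoopError(
            f"pedigree {pedigree.name!r} contains a marriage/inbreeding loop; "
            "peeling without loop-breaking is not supported")
    remaining = {couple: tuple(children)
                 for couple, children in pedigree.nuclear_families().items()}
    # membership: individual -> set of couples whose family includes them
    member_of: dict[str, set[tuple[str, str]]] = {}
    for couple, children in remaining.items():
        for iid in (couple[0], couple[1], *children):
            member_of.setdefault(iid, set()).add(couple)

    order: list[NuclearFamily] = []
    while remaining:
        candidates: list[tuple[int, tuple[str, str], str | None]] = []
        for couple, children in remaining.items():
            links = [iid for iid in (couple[0], couple[1], *children)
                     if len(member_of[iid]) > 1]
            if len(links) > 1:
                continue
            pivot = links[0] if links else None
            pivot_is_child = pivot in children if pivot is not None else False
            candidates.append((int(pivot_is_child), couple, pivot))
        if not candidates:
            raise PedigreeLoopError(
                f"pedigree {pedigree.name!r}: no peelable family remains "
                "(unexpected loop)")
        _, couple, pivot = min(candidates, key=lambda c: (c[0], c[1]))
        children = remaining.pop(couple)
        for iid in (couple[0], couple[1], *children):
            member_of[iid].discard(couple)
        order.append(NuclearFamily(couple[0], couple[1], children, pivot))
    return order
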