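"""Pedigree parsing, validation, and phenotype bookkeeping.

A pedigree is the frame of reference for Mendelian segregation filtering:
which family members are affected, which are unaffected, and how alleles
can flow from parents to children. Files are read and written in the
standard 6-column PED dialect (FID IID PAT MAT SEX PHENO).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator


class Sex(Enum):
    MALE = "male"
    FEMALE = "female"


class Phenotype(Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class PedigreeError(ValueError):
    """Raised for malformed or internally inconsistent pedigrees."""


@dataclass(frozen=True)
class Individual:
    """One family member.

    ``father_id``/``mother_id`` are ``None`` for founders; a member has
    either both parents or neither.
    """

    member_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex
    phenotype: Phenotype

    def __post_init__(self) -> None:
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"{self.member_id}: both parent ids must be present or both absent"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


@dataclass
class Pedigree:
    """A validated family graph plus the subset of members with genotypes.

    ``genotyped_subset`` defaults to all members; it is usually narrowed to
    the intersection of pedigree ids and VCF sample ids (the study family
    had 31 members of whom 12 were sequenced).
    """

    individuals: list[Individual]
    genotyped_subset: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.genotyped_subset:
            self.genotyped_subset = frozenset(i.member_id for i in self.individuals)
        self._validate()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        ids = [i.member_id for i in self.individuals]
        if len(ids) != len(set(ids)):
            dupes = sorted({m for m in ids if ids.count(m) > 1})
            raise PedigreeError(f"duplicate member ids: {dupes}")
        by_id = {i.member_id: i for i in self.individuals}
        for ind in self.individuals:
            for pid, want_sex, label in (
                (ind.father_id, Sex.MALE, "father"),
                (ind.mother_id, Sex.FEMALE, "mother"),
            ):
                if pid is None:
                    continue
                parent = by_id.get(pid)
                if parent is None:
                    raise PedigreeError(
                        f"{ind.member_id}: {label} {pid!r} not in pedigree"
                    )
                if parent.sex is not want_sex:
                    raise PedigreeError(
                        f"{ind.member_id}: {label} {pid!r} is not {want_sex.value}"
                    )
        extra = self.genotyped_subset - set(by_id)
        if extra:
            raise PedigreeError(f"genotyped_subset ids not in pedigree: {sorted(extra)}")
        self._check_acyclic(by_id)
        self._by_id = by_id

    def _check_acyclic(self, by_id: dict[str, Individual]) -> None:
        state: dict[str, int] = {}  # 0=visiting, 1=done

        def visit(mid: str, stack: list[str]) -> None:
            if state.get(mid) == 1:
                return
            if state.get(mid) == 0:
                raise PedigreeError(f"cyclic parentage involving {mid!r}")
            state[mid] = 0
            ind = by_id[mid]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    visit(pid, stack + [mid])
            state[mid] = 1

        for mid in by_id:
            visit(mid, [])

    # -- accessors --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals)

    def __getitem__(self, member_id: str) -> Individual:
        return self._by_id[member_id]

    def __contains__(self, member_id: str) -> bool:
        return member_id in self._by_id

    @property
    def member_ids(self) -> list[str]:
        return [i.member_id for i in self.individuals]

    def founders(self) -> list[Individual]:
        return [i for i in self.individuals if i.is_founder]

    def children_of(self, father_id: str, mother_id: str) -> list[Individual]:
        return [
            i
            for i in self.individuals
            if i.father_id == father_id and i.mother_id == mother_id
        ]

    def with_genotyped(self, sample_ids: Iterable[str]) -> "Pedigree":
        """Return a copy whose genotyped subset is ``pedigree ∩ sample_ids``."""
        subset = frozenset(sample_ids) & set(self.member_ids)
        if not subset:
            raise PedigreeError("no overlap between pedigree members and sample ids")
        return Pedigree(list(self.individuals), subset)

    # -- phenotype sets ---------------------------------------------------

    def genotyped_affected(self) -> set[str]:
        return {
            m for m in self.genotyped_subset
            if self[m].phenotype is Phenotype.AFFECTED
        }

    def genotyped_unaffected(self) -> set[str]:
        return {
            m for m in self.genotyped_subset
            if self[m].phenotype is Phenotype.UNAFFECTED
        }


def affected_members(ped: Pedigree) -> set[str]:
    """Ids of all members labelled affected.

    Unknown-phenotype members belong to neither comparison set; within the
    genotyped subset the unaffected complement is
    ``ped.genotyped_unaffected()``.
    """
    return {i.member_id for i in ped if i.phenotype is Phenotype.AFFECTED}


def unaffected_members(ped: Pedigree) -> set[str]:
    return {i.member_id for i in ped if i.phenotype is Phenotype.UNAFFECTED}


# -- PED file I/O ----------------------------------------------------------

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_PHENO_CODES = {
    "2": Phenotype.AFFECTED,
    "1": Phenotype.UNAFFECTED,
    "0": Phenotype.UNKNOWN,
    "-9": Phenotype.UNKNOWN,
}
_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2"}
_PHENO_OUT = {
    Phenotype.AFFECTED: "2",
    Phenotype.UNAFFECTED: "1",
    Phenotype.UNKNOWN: "0",
}


def read_ped(path: str | Path) -> Pedigree:
    """Read a 6-column PED file (tab- or space-delimited; extra columns ignored).

    Parent id "0" encodes an unknown parent; rows with both parents "0" are
    founders. SEX is 1=male/2=female; PHENO is 2=affected/1=unaffected/
    0 or -9=unknown.
    """
    individuals: list[Individual] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 6:
            raise PedigreeError(f"{path}:{lineno}: expected ≥6 columns, got {len(cols)}")
        fid, iid, pat, mat, sex, pheno = cols[:6]
        if sex not in _SEX_CODES:
            raise PedigreeError(f"{path}:{lineno}: bad sex code {sex!r}")
        if pheno not in _PHENO_CODES:
            raise PedigreeError(f"{path}:{lineno}: bad phenotype code {pheno!r}")
        individuals.append(
            Individual(
                member_id=iid,
                family_id=fid,
                father_id=None if pat == "0" else pat,
                mother_id=None if mat == "0" else mat,
                sex=_SEX_CODES[sex],
                phenotype=_PHENO_CODES[pheno],
            )
        )
    return Pedigree(individuals)


def write_ped(ped: Pedigree, path: str | Path) -> None:
    """Write the canonical 6 columns, tab-delimited, in pedigree order."""
    lines = []
    for ind in ped:
        lines.append(
            "\t".join(
                [
                    ind.family_id,
                    ind.member_id,
                    ind.father_id or "0",
                    ind.mother_id or "0",
                    _SEX_OUT[ind.sex],
                    _PHENO_OUT[ind.phenotype],
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
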