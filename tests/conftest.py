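"""Shared fixtures: the worked-example family, toy protein structures."""

from __future__ import annotations

import pytest
from hypothesis import settings

from mendelsieve.pedigree import Individual, Pedigree, Phenotype, Sex
from mendelsieve.simulate import build_canonical_pedigree, fixture_pedigree
from mendelsieve.variants import make_fixture_tables

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def canonical_ped() -> Pedigree:
    return build_canonical_pedigree()


@pytest.fixture()
def family12() -> Pedigree:
    """The 12 sequenced members as a standalone pedigree."""
    return fixture_pedigree()


@pytest.fixture()
def fixture_records():
    """The four published candidate variants with the 12-member genotypes."""
    return make_fixture_tables()


def make_individual(
    mid: str,
    sex: str = "M",
    pheno: str = "U",
    father: str | None = None,
    mother: str | None = None,
    family: str = "F",
) -> Individual:
    return Individual(
        member_id=mid,
        family_id=family,
        father_id=father,
        mother_id=mother,
        sex=Sex.MALE if sex == "M" else Sex.FEMALE,
        phenotype={
            "A": Phenotype.AFFECTED,
            "U": Phenotype.UNAFFECTED,
            "?": Phenotype.UNKNOWN,
        }[pheno],
    )


def pdb_text(atoms) -> str:
    """Render (serial, name, resname, chain, resseq, x, y, z, element)
    tuples as PDB ATOM records."""
    lines = []
    for serial, name, resname, chain, resseq, x, y, z, element in atoms:
        padded = name if len(name) >= 4 else (" " + name).ljust(4)
        lines.append(
            f"ATOM  {serial:5d} {padded}{'':1s}{resname:>3s} {chain:1s}"
            f"{resseq:4d}{'':1s}   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture()
def tripeptide_pdb(tmp_path):
    """Three residues along x, far enough apart that the ends are exposed."""
    atoms = [
        (1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0, "N"),
        (2, "CA", "GLY", "A", 1, 1.5, 0.0, 0.0, "C"),
        (3, "C", "GLY", "A", 1, 3.0, 0.0, 0.0, "C"),
        (4, "N", "ALA", "A", 2, 6.0, 0.0, 0.0, "N"),
        (5, "CA", "ALA", "A", 2, 7.5, 0.0, 0.0, "C"),
        (6, "CB", "ALA", "A", 2, 7.5, 1.5, 0.0, "C"),
        (7, "N", "VAL", "A", 3, 11.0, 0.0, 0.0, "N"),
        (8, "CA", "VAL", "A", 3, 12.5, 0.0, 0.0, "C"),
    ]
    path = tmp_path / "tri.pdb"
    path.write_text(pdb_text(atoms))
    return path
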