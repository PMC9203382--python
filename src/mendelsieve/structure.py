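"""Structure-based assessment of a missense site.

Computes solvent-accessible surface area (SASA) with the Shrake–Rupley
rolling-probe quadrature, converts it to relative solvent accessibility
(RSA, % of a per-residue reference maximum), builds a heavy-atom residue
contact network, and classifies burial. The purpose is to ask, for a
candidate missense position: is the residue buried in the protein core,
and does it contact known functional residues?

Quadrature points lie on a deterministic golden-spiral (Fibonacci) sphere,
so results are exactly reproducible; neighbour lookups use a k-d tree so
the cost is near-linear in the number of atoms.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)


class StructureError(ValueError):
    pass


class BurialClass(Enum):
    DEEPLY_BURIED = "deeply_buried"  # RSA < 10%
    BURIED = "buried"                # RSA < 25%
    EXPOSED = "exposed"


#: Van der Waals radii (Å) for heavy atoms; unknown elements fall back to
#: the carbon radius with a warning.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_RADIUS = 1.70

#: Theoretical maximum per-residue SASA (Å², extended Gly-X-Gly context;
#: Tien-style theoretical set) — the default RSA normaliser.
MAX_SASA_THEORETICAL: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: Naccess-style Ala-X-Ala extended-state reference (Å²), selectable for
#: compatibility with rolling-probe tools that normalise against it.
MAX_SASA_NACCESS: dict[str, float] = {
    "ALA": 107.95, "ARG": 238.76, "ASN": 143.94, "ASP": 140.39, "CYS": 134.28,
    "GLN": 178.50, "GLU": 172.25, "GLY": 80.10, "HIS": 182.88, "ILE": 175.12,
    "LEU": 178.63, "LYS": 200.81, "MET": 194.15, "PHE": 199.48, "PRO": 136.13,
    "SER": 116.50, "THR": 139.27, "TRP": 249.36, "TYR": 212.76, "VAL": 151.44,
}

REFERENCE_TABLES = {"theoretical": MAX_SASA_THEORETICAL, "naccess": MAX_SASA_NACCESS}


@dataclass(frozen=True)
class AtomRecord:
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    coords: tuple[float, float, float]
    vdw_radius: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise StructureError(f"non-finite coordinates for {self.atom_name}")
        if self.vdw_radius <= 0:
            raise StructureError(f"non-positive radius for {self.atom_name}")


@dataclass
class StructureModel:
    """Heavy atoms of one chain, grouped by residue."""

    atoms: list[AtomRecord]
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError("structure has no atoms")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def residue_of_atom(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    def residue_indices(self) -> list[int]:
        return sorted({a.residue_index for a in self.atoms})

    def residue_name(self, residue_index: int) -> str:
        for a in self.atoms:
            if a.residue_index == residue_index:
                return a.residue_name
        raise StructureError(f"no residue with index {residue_index}")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "StructureModel":
        """Rigid-body transformed copy (used for invariance checks)."""
        atoms = []
        for a in self.atoms:
            xyz = rotation @ np.asarray(a.coords) + translation
            atoms.append(AtomRecord(a.residue_index, a.residue_name, a.atom_name,
                                    a.element, tuple(float(x) for x in xyz),
                                    a.vdw_radius))
        return StructureModel(atoms, self.chain_id)


@dataclass
class ResidueMetrics:
    residue_index: int
    residue_name: str
    sasa_abs: float          # Å²
    rsa: float | None        # percent; None for non-standard residues
    contacts: set[int]
    burial_class: BurialClass | None
    functional_contacts: set[int]

    def __post_init__(self) -> None:
        if self.sasa_abs < 0 or (self.rsa is not None and self.rsa < 0):
            raise StructureError("negative accessibility")
        if self.residue_index in self.contacts:
            raise StructureError("residue cannot contact itself")


# -- PDB reading -----------------------------------------------------------

def read_pdb(
    path: str | Path,
    chain_id: str | None = None,
    *,
    radii: Mapping[str, float] | None = None,
) -> StructureModel:
    """Read ATOM records of one chain (first model) into a StructureModel.

    Hydrogens and HETATM records are excluded; each atom is assigned a van
    der Waals radius from its element (C 1.70, N 1.55, O 1.52, S 1.80 Å by
    default; unknown elements get the carbon radius with a warning).
    """
    radii = dict(radii or VDW_RADII)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise StructureError(f"{path}: no models")
    chains = {c.id: c for c in model}
    if chain_id is None:
        if len(chains) != 1:
            raise StructureError(
                f"{path}: multiple chains {sorted(chains)}; pass chain_id"
            )
        chain_id = next(iter(chains))
    if chain_id not in chains:
        raise StructureError(f"{path}: no chain {chain_id!r}")

    atoms: list[AtomRecord] = []
    for residue in chains[chain_id]:
        if residue.id[0] != " ":  # skip HETATM / waters
            continue
        for atom in residue:
            element = (atom.element or atom.get_name()[:1]).strip().upper()
            if element in ("H", "D"):
                continue
            if element not in radii:
                log.warning("unknown element %r: using default radius %.2f Å",
                            element, DEFAULT_RADIUS)
            atoms.append(AtomRecord(
                residue_index=residue.id[1],
                residue_name=residue.get_resname().strip(),
                atom_name=atom.get_name(),
                element=element,
                coords=tuple(float(x) for x in atom.coord),
                vdw_radius=radii.get(element, DEFAULT_RADIUS),
            ))
    if not atoms:
        raise StructureError(f"{path}: no ATOM records in chain {chain_id!r}")
    return StructureModel(atoms, chain_id)


# -- Shrake–Rupley SASA ----------------------------------------------------

def golden_spiral_points(n: int) -> np.ndarray:
    """n deterministic, near-uniform unit-sphere points (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley_sasa(
    s: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom SASA (Å²) by Shrake–Rupley quadrature.

    For each atom, ``n_points`` test points are placed on the expanded
    sphere of radius r+p; a point is accessible iff it lies outside every
    other atom's expanded sphere, and

        SASA = 4π (r+p)² · (accessible points) / n_points.

    Neighbour candidates come from a k-d tree query at the maximal
    occlusion distance, so the cost grows near-linearly with atom count.
    Coincident atom centres are tolerated (the duplicate occludes its twin
    completely) with a warning.
    """
    if n_points < 12:
        raise ValueError("n_points must be ≥ 12")
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    coords = s.coords
    radii = s.radii + probe_radius
    n_atoms = len(s.atoms)
    unit = golden_spiral_points(n_points)

    tree = cKDTree(coords)
    max_reach = 2.0 * radii.max()
    pairs = tree.query_pairs(max_reach, output_type="ndarray")
    neighbours: list[list[int]] = [[] for _ in range(n_atoms)]
    for i, j in pairs:
        d = np.linalg.norm(coords[i] - coords[j])
        if d < radii[i] + radii[j]:
            neighbours[i].append(j)
            neighbours[j].append(i)
        if d == 0.0:
            log.warning("coincident atom centres: %s and %s",
                        s.atoms[i].atom_name, s.atoms[j].atom_name)

    sasa = np.empty(n_atoms)
    for i in range(n_atoms):
        pts = coords[i] + radii[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours[i]:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        sasa[i] = 4.0 * math.pi * radii[i] ** 2 * accessible.sum() / n_points
    return sasa


def residue_sasa(s: StructureModel, atom_sasa: np.ndarray) -> dict[int, float]:
    """Sum per-atom SASA within each residue."""
    out: dict[int, float] = {}
    for a, v in zip(s.atoms, atom_sasa):
        out[a.residue_index] = out.get(a.residue_index, 0.0) + float(v)
    return out


def residue_rsa(
    s: StructureModel,
    atom_sasa: np.ndarray,
    reference: Mapping[str, float] | str = "theoretical",
) -> dict[int, float | None]:
    """Relative solvent accessibility per residue, in percent.

    rsa = 100 · (residue SASA) / reference[residue_name]; residues whose
    name is absent from the reference table (non-standard residues) map to
    None and are logged.
    """
    if isinstance(reference, str):
        reference = REFERENCE_TABLES[reference]
    per_res = residue_sasa(s, atom_sasa)
    out: dict[int, float | None] = {}
    for idx, total in per_res.items():
        name = s.residue_name(idx)
        ref = reference.get(name)
        if ref is None:
            log.warning("residue %s%d not in RSA reference; RSA undefined", name, idx)
            out[idx] = None
        else:
            out[idx] = 100.0 * total / ref
    return out


# -- contacts and site assessment -----------------------------------------

def contact_map(
    s: StructureModel,
    cutoff: float = 5.0,
    exclude_sequence_neighbors: int = 1,
) -> dict[int, set[int]]:
    """Residue contact network: residues i, j (|i−j| > window) are in
    contact iff any heavy-atom pair lies within ``cutoff`` Å. Symmetric and
    irreflexive by construction.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = s.coords
    res = s.residue_of_atom
    contacts: dict[int, set[int]] = {idx: set() for idx in s.residue_indices()}
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(cutoff, output_type="ndarray"):
        ri, rj = int(res[i]), int(res[j])
        if abs(ri - rj) > exclude_sequence_neighbors:
            contacts[ri].add(rj)
            contacts[rj].add(ri)
    return contacts


def classify_burial(rsa: float | None) -> BurialClass | None:
    if rsa is None:
        return None
    if rsa < 10.0:
        return BurialClass.DEEPLY_BURIED
    if rsa < 25.0:
        return BurialClass.BURIED
    return BurialClass.EXPOSED


def assess_site(
    s: StructureModel,
    residue_index: int,
    *,
    functional_residues: Iterable[int] = (),
    probe_radius: float = 1.4,
    n_points: int = 960,
    cutoff: float = 5.0,
    reference: Mapping[str, float] | str = "theoretical",
) -> tuple[ResidueMetrics, str]:
    """Full assessment of one residue: SASA, RSA, burial class, contact
    set, and whether any designated functional residue is a direct contact.

    Returns the metrics plus a human-readable report.
    """
    indices = s.residue_indices()
    if residue_index not in indices:
        raise StructureError(f"residue index {residue_index} not in structure "
                             f"(range {indices[0]}..{indices[-1]})")
    atom_sasa = shrake_rupley_sasa(s, probe_radius, n_points)
    sasa = residue_sasa(s, atom_sasa)[residue_index]
    rsa = residue_rsa(s, atom_sasa, reference)[residue_index]
    contacts = contact_map(s, cutoff)[residue_index]
    functional = set(functional_residues)
    metrics = ResidueMetrics(
        residue_index=residue_index,
        residue_name=s.residue_name(residue_index),
        sasa_abs=sasa,
        rsa=rsa,
        contacts=contacts,
        burial_class=classify_burial(rsa),
        functional_contacts=contacts & functional,
    )
    name = f"{metrics.residue_name}{residue_index}"
    lines = [
        f"Residue {name} (chain {s.chain_id})",
        f"  SASA: {sasa:.2f} Å²",
        ("  RSA: undefined (non-standard residue)" if rsa is None
         else f"  RSA: {rsa:.2f}% ({metrics.burial_class.value})"),
        f"  Contacts (≤ {cutoff:.1f} Å, heavy atoms): {len(contacts)} residues "
        f"{sorted(contacts)}",
    ]
    for f in sorted(functional):
        hit = "IS" if f in contacts else "is NOT"
        lines.append(f"  Functional residue {f} {hit} a direct contact of {name}")
    return metrics, "\n".join(lines)


def metrics_to_json(m: ResidueMetrics) -> str:
    return json.dumps({
        "residue_index": m.residue_index,
        "residue_name": m.residue_name,
        "sasa_abs": round(m.sasa_abs, 4),
        "rsa": None if m.rsa is None else round(m.rsa, 4),
        "burial_class": m.burial_class.value if m.burial_class else None,
        "contacts": sorted(m.contacts),
        "functional_contacts": sorted(m.functional_contacts),
    }, indent=2)


def plot_rsa_profile(
    s: StructureModel,
    rsa: Mapping[int, float | None],
    path: str | Path,
    highlight: Sequence[int] = (),
) -> None:
    """Bar plot of per-residue RSA with optional highlighted positions."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    idx = [i for i in sorted(rsa) if rsa[i] is not None]
    vals = [rsa[i] for i in idx]
    fig, ax = plt.subplots(figsize=(max(4.0, len(idx) / 10), 3))
    ax.bar(idx, vals, color="0.6", width=1.0)
    for h in highlight:
        if h in rsa and rsa[h] is not None:
            ax.bar([h], [rsa[h]], color="crimson", width=1.0)
    ax.axhline(10, ls="--", lw=0.8, color="k")
    ax.axhline(25, ls=":", lw=0.8, color="k")
    ax.set_xlabel("residue index")
    ax.set_ylabel("RSA (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
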