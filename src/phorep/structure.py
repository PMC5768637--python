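"""Active-site detection, solvent accessibility and rigid superposition.

Active-site residues are those with a heavy atom in noncovalent contact
(default 4.0 A) with the phosphate ligand or a metal co-factor. Per-residue
solvent-accessible surface area (SASA) is computed with the Shrake-Rupley
test-point method (960 points, 1.4 A probe, Bondi radii, hydrogens ignored);
the sum of per-residue SASA over the active-site residues — computed after
removing ligand, co-factors and any signal peptide — is the active-site
accessibility. Rigid superposition uses the Kabsch least-squares algorithm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .constants import VDW_RADII

#: Residue names recognised as the phosphate ligand or metal co-factors.
DEFAULT_LIGAND_RESIDUES = frozenset({"PO4", "PI", "2HP", "CA", "FE", "FE2", "ZN", "MG", "MN"})

_WATER_RESIDUES = frozenset({"HOH", "WAT", "H2O"})


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    x: float
    y: float
    z: float
    is_hetero: bool

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_number, self.residue_name)


@dataclass
class Structure:
    """A flat list of atom records with element radii."""

    atoms: list[Atom]
    name: str = "structure"

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not np.isfinite([a.x, a.y, a.z]).all():
                raise ValueError(f"atom {a.serial}: non-finite coordinates")

    def coordinates(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        out = np.empty(len(self.atoms))
        for i, a in enumerate(self.atoms):
            el = a.element.upper()
            if el not in VDW_RADII:
                raise ValueError(f"no van der Waals radius for element {el!r}")
            out[i] = VDW_RADII[el]
        return out

    def select(self, keep) -> "Structure":
        return Structure([a for a in self.atoms if keep(a)], name=self.name)

    def without_residues(self, residue_names: frozenset[str] | set[str]) -> "Structure":
        names = {r.upper() for r in residue_names}
        return self.select(lambda a: a.residue_name.upper() not in names)

    def without_hydrogens(self) -> "Structure":
        return self.select(lambda a: a.element.upper() != "H")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        coords = self.coordinates() @ np.asarray(rotation).T + np.asarray(translation)
        atoms = [
            Atom(a.serial, a.name, a.element, a.residue_name, a.residue_number,
                 a.chain, *xyz, a.is_hetero)
            for a, xyz in zip(self.atoms, coords)
        ]
        return Structure(atoms, name=self.name)

    def ca_coordinates(self, chain: str | None = None) -> np.ndarray:
        return np.array([
            [a.x, a.y, a.z] for a in self.atoms
            if a.name.strip() == "CA" and a.element.upper() == "C"
            and (chain is None or a.chain == chain)
        ])


def parse_pdb(text: str, name: str = "structure", chain: str | None = None) -> Structure:
    """Read ATOM/HETATM records from PDB text (optionally one chain)."""
    st = gemmi.read_pdb_string(text)
    st.setup_entities()
    atoms: list[Atom] = []
    for model in st:
        for ch in model:
            if chain is not None and ch.name != chain:
                continue
            for res in ch:
                het = res.het_flag == "H"
                for at in res:
                    atoms.append(Atom(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name.upper(),
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        chain=ch.name,
                        x=at.pos.x, y=at.pos.y, z=at.pos.z,
                        is_hetero=het,
                    ))
        break  # first model only
    if not atoms:
        raise ValueError("no atoms parsed from PDB input")
    return Structure(atoms, name=name)


def write_pdb(structure: Structure) -> str:
    """Serialize atoms as fixed-column ATOM/HETATM records."""
    lines = []
    for a in structure.atoms:
        record = "HETATM" if a.is_hetero else "ATOM  "
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"{record}{a.serial:>5d} {name:<4s}{a.residue_name:>4s} "
            f"{a.chain:1s}{a.residue_number:>4d}    "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element.upper():>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Active site detection
# ---------------------------------------------------------------------------

@dataclass
class ActiveSite:
    residues: list[tuple[str, int, str]]  # (chain, number, name)
    defining_ligands: list[tuple[str, int, str]]
    cutoff: float


def detect_active_site(
    structure: Structure,
    ligand_residues: frozenset[str] | set[str] = DEFAULT_LIGAND_RESIDUES,
    cutoff: float = 4.0,
) -> ActiveSite:
    """Residues with a heavy atom within ``cutoff`` of a ligand/ion atom.

    Ligand residues themselves and waters are excluded from the site; when no
    ligand is present an empty site is returned with a warning.
    """
    names = {r.upper() for r in ligand_residues}
    heavy = structure.without_hydrogens()
    ligand_atoms = [a for a in heavy.atoms if a.residue_name.upper() in names]
    if not ligand_atoms:
        warnings.warn("no ligand or metal co-factor found; empty active site")
        return ActiveSite([], [], cutoff)
    protein_atoms = [
        a for a in heavy.atoms
        if a.residue_name.upper() not in names
        and a.residue_name.upper() not in _WATER_RESIDUES
    ]
    lig_xyz = np.array([[a.x, a.y, a.z] for a in ligand_atoms])
    tree = cKDTree(lig_xyz)
    site: dict[tuple[str, int, str], None] = {}
    for a in protein_atoms:
        if tree.query_ball_point([a.x, a.y, a.z], cutoff):
            site.setdefault(a.residue_key)
    ligands = sorted({a.residue_key for a in ligand_atoms}, key=lambda k: (k[0], k[1]))
    residues = sorted(site, key=lambda k: (k[0], k[1]))
    return ActiveSite(residues, ligands, cutoff)


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA
# ---------------------------------------------------------------------------

def _local_frames(coords: np.ndarray) -> np.ndarray:
    """Per-atom orthonormal frames built from the two nearest neighbors.

    The frame co-rotates with the structure under any rigid motion, so test
    points expressed in it make the SASA estimate exactly invariant to
    rotation and translation (up to floating-point noise).
    """
    n = len(coords)
    frames = np.tile(np.eye(3), (n, 1, 1))
    if n < 2:
        return frames
    tree = cKDTree(coords)
    k = min(3, n)
    _, idx = tree.query(coords, k=k)
    for i in range(n):
        nb = [j for j in np.atleast_1d(idx[i]) if j != i]
        if not nb:
            continue
        u = coords[nb[0]] - coords[i]
        norm_u = np.linalg.norm(u)
        if norm_u < 1e-9:
            continue
        u /= norm_u
        v = None
        if len(nb) > 1:
            w = coords[nb[1]] - coords[i]
            v = w - (w @ u) * u
        if v is None or np.linalg.norm(v) < 1e-6:
            helper = np.array([1.0, 0.0, 0.0])
            if abs(u @ helper) > 0.9:
                helper = np.array([0.0, 1.0, 0.0])
            v = helper - (helper @ u) * u
        v /= np.linalg.norm(v)
        frames[i] = np.column_stack([u, v, np.cross(u, v)])
    return frames


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([
        np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)
    ])


@dataclass
class ResidueSASA:
    """Per-residue solvent-accessible surface areas in A^2."""

    areas: dict[tuple[str, int, str], float]
    probe_radius: float
    n_sphere_points: int
    per_atom: np.ndarray = field(repr=False, default=None)

    def total(self) -> float:
        return float(sum(self.areas.values()))


def shrake_rupley_sasa(
    structure: Structure,
    probe: float = 1.4,
    n_points: int = 960,
) -> ResidueSASA:
    """Shrake-Rupley SASA on the heavy atoms of the structure.

    Each atom's expanded sphere (r + probe) carries ``n_points`` test
    points; a point is buried if it falls within the expanded sphere of any
    other atom. Accessible area = accessible fraction x sphere area, summed
    per residue.
    """
    heavy = structure.without_hydrogens()
    if not heavy.atoms:
        raise ValueError("no heavy atoms")
    coords = heavy.coordinates()
    radii = heavy.radii() + probe
    sphere = _sphere_points(n_points)
    frames = _local_frames(coords)
    tree = cKDTree(coords)
    max_r = radii.max()
    per_atom = np.zeros(len(heavy.atoms))
    for i, (center, r) in enumerate(zip(coords, radii)):
        pts = center + r * (sphere @ frames[i].T)
        neighbors = [j for j in tree.query_ball_point(center, r + max_r) if j != i]
        if neighbors:
            d2 = ((pts[:, None, :] - coords[neighbors][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (radii[neighbors] ** 2)[None, :]).any(axis=1)
            accessible = int((~buried).sum())
        else:
            accessible = n_points
        per_atom[i] = 4.0 * np.pi * r * r * accessible / n_points
    areas: dict[tuple[str, int, str], float] = {}
    for a, area in zip(heavy.atoms, per_atom):
        areas[a.residue_key] = areas.get(a.residue_key, 0.0) + float(area)
    return ResidueSASA(areas, probe, n_points, per_atom=per_atom)


def active_site_accessibility(sasa: ResidueSASA, site: ActiveSite) -> float:
    """Sum of per-residue SASA over the active-site residues (A^2).

    The SASA should be computed on the structure with ligand, co-factors and
    signal peptide removed; a site residue absent from the SASA table is an
    error.
    """
    missing = [r for r in site.residues if r not in sasa.areas]
    if missing:
        raise ValueError(f"residues missing from SASA table: {missing}")
    return float(sum(sasa.areas[r] for r in site.residues))


def site_report(structure: Structure, site: ActiveSite, sasa: ResidueSASA) -> str:
    """JSON report of an active site and its accessibility."""
    return json.dumps({
        "structure": structure.name,
        "cutoff_A": site.cutoff,
        "ligands": [list(k) for k in site.defining_ligands],
        "residues": [
            {"chain": c, "number": n, "name": r, "sasa_A2": round(sasa.areas[(c, n, r)], 2)}
            for c, n, r in site.residues
        ],
        "accessibility_A2": round(active_site_accessibility(sasa, site), 2),
    }, indent=2)


# ---------------------------------------------------------------------------
# Homologous-position mapping
# ---------------------------------------------------------------------------

def map_site_to_homolog(
    aligned_ref: str,
    aligned_model: str,
    site_positions: list[int],
    ref_offset: int = 0,
    model_offset: int = 0,
) -> dict[int, int | None]:
    """Map reference residue numbers through a pairwise alignment.

    ``aligned_ref``/``aligned_model`` are equal-length gapped sequences;
    residue numbering starts at offset+1. Site positions aligned to a gap in
    the model map to None ("no equivalent"); a site position outside the
    alignment is an error.
    """
    if len(aligned_ref) != len(aligned_model):
        raise ValueError("aligned sequences differ in length")
    ref_num = ref_offset
    model_num = model_offset
    mapping_all: dict[int, int | None] = {}
    for ra, ma in zip(aligned_ref, aligned_model):
        if ra != "-":
            ref_num += 1
        if ma != "-":
            model_num += 1
        if ra != "-":
            mapping_all[ref_num] = model_num if ma != "-" else None
    out: dict[int, int | None] = {}
    for pos in site_positions:
        if pos not in mapping_all:
            raise ValueError(f"site position {pos} outside the alignment")
        out[pos] = mapping_all[pos]
    return out


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    rotation: np.ndarray     # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of B onto A (paired coordinates).

    Returns the proper rotation (det = +1) and translation minimizing the
    RMSD of R @ b + t against a. Requires >= 3 non-collinear pairs.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    n = a.shape[0]
    if n < 3:
        raise ValueError("at least 3 paired atoms required")
    ac, bc = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ac, b - bc
    if np.linalg.matrix_rank(b0, tol=1e-8) < 2 or np.linalg.matrix_rank(a0, tol=1e-8) < 2:
        raise ValueError("collinear (or coincident) points: superposition ill-defined")
    H = b0.T @ a0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ac - R @ bc
    moved = b @ R.T + t
    rmsd = float(np.sqrt(((moved - a) ** 2).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)
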