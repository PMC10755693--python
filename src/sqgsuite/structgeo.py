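"""Geometry analyses of macromolecular coordinates.

Operations used to characterise the SQase complexes: atomic distances (e.g.
the hydride-transfer distance from C3 of SQ to C4 of the nicotinamide ring),
χ1 side-chain rotation about the Cα–Cβ bond (the Tyr rotation on substrate
binding), least-squares backbone superposition RMSD (binary vs ternary
complex), Shrake–Rupley solvent-accessible surface area, and the buried
dimer-interface area (sum of monomer SASAs minus dimer SASA).

File I/O (PDB and mmCIF) goes through biotite; alternate locations are
resolved to the highest-occupancy conformer.  The SASA sampler uses a
deterministic golden-section sphere lattice — no RNG — so results are
bit-reproducible; it is therefore invariant to rotation only up to the
lattice discretisation (well below 1% at the default 960 points).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb
import biotite.structure.io.pdbx as bpdbx

#: van der Waals radii (Å) used for SASA; fixed so deviations from other
#: tools' (unstated) radii are explainable
VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20,
}

WATER_NAMES = ("HOH", "WAT", "DOD")

#: residue names treated as ligands/ions rather than polymer
LIGAND_NAMES = ("NAD", "SQH", "SQG", "CIT", "GOL", "EDO", "SO4", "CL", "NA",
                "MG", "MN", "ZN", "CA", "K")


@dataclass
class Structure:
    """A coordinate set: a thin wrapper over a biotite AtomArray."""

    atoms: bst.AtomArray
    name: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.atoms.coord)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return self.atoms.array_length()

    @property
    def chains(self) -> list[str]:
        return sorted(set(self.atoms.chain_id))

    def select(self, chain: str | None = None, res_id: int | None = None,
               res_name: str | None = None, atom_name: str | None = None,
               element: str | None = None) -> "Structure":
        mask = np.ones(len(self), dtype=bool)
        a = self.atoms
        if chain is not None:
            mask &= a.chain_id == chain
        if res_id is not None:
            mask &= a.res_id == res_id
        if res_name is not None:
            mask &= a.res_name == res_name
        if atom_name is not None:
            mask &= a.atom_name == atom_name
        if element is not None:
            mask &= a.element == element.upper()
        return Structure(a[mask], name=self.name)

    def without_solvent(self, keep_ligands: bool = False) -> "Structure":
        a = self.atoms
        mask = ~np.isin(a.res_name, WATER_NAMES)
        if not keep_ligands:
            mask &= ~(a.hetero & np.isin(a.res_name, LIGAND_NAMES))
            mask &= ~a.hetero
        return Structure(a[mask], name=self.name)


def read_structure(path: str | Path, keep_waters: bool = False,
                   model: int = 1) -> Structure:
    """Read PDB or mmCIF; altlocs resolved to the highest occupancy."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        f = bpdb.PDBFile.read(str(path))
        atoms = bpdb.get_structure(
            f, model=model, altloc="occupancy", extra_fields=["occupancy"]
        )
    elif suffix in (".cif", ".mmcif", ".pdbx"):
        f = bpdbx.CIFFile.read(str(path))
        atoms = bpdbx.get_structure(
            f, model=model, altloc="occupancy", extra_fields=["occupancy"]
        )
    else:
        raise ValueError(f"unrecognised coordinate format: {path.name}")
    if atoms.array_length() == 0:
        raise ValueError(f"{path.name}: empty model")
    if not keep_waters:
        atoms = atoms[~np.isin(atoms.res_name, WATER_NAMES)]
    return Structure(atoms, name=path.stem)


def write_structure(s: Structure, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".pdb", ".ent"):
        f = bpdb.PDBFile()
        bpdb.set_structure(f, s.atoms)
        f.write(str(path))
    elif path.suffix.lower() in (".cif", ".mmcif"):
        f = bpdbx.CIFFile()
        bpdbx.set_structure(f, s.atoms, data_block=s.name or "toy")
        f.write(str(path))
    else:
        raise ValueError(f"unrecognised coordinate format: {path.name}")


def _one_atom(s: Structure, sel: Mapping) -> np.ndarray:
    sub = s.select(**sel)
    if len(sub) == 0:
        raise ValueError(f"selection {sel} matches no atom")
    if len(sub) > 1:
        raise ValueError(f"selection {sel} is ambiguous ({len(sub)} atoms)")
    return sub.atoms.coord[0]


def distance(s: Structure, atom_sel_1: Mapping, atom_sel_2: Mapping) -> float:
    """Euclidean distance (Å) between two uniquely selected atoms."""
    p = _one_atom(s, atom_sel_1)
    q = _one_atom(s, atom_sel_2)
    return float(np.linalg.norm(p - q))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, IUPAC convention, range (−180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.degrees(np.arctan2(y, x)))


_CHI1_GAMMA_PRIORITY = ("CG", "CG1", "OG", "OG1", "SG", "CG2")


def chi1(s: Structure, chain: str, res_id: int) -> float:
    """χ1 dihedral N–CA–CB–Xγ of one residue (degrees)."""
    res = s.select(chain=chain, res_id=res_id)
    coords = {}
    for name in ("N", "CA", "CB"):
        sub = res.select(atom_name=name)
        if len(sub) != 1:
            raise ValueError(
                f"residue {chain}/{res_id}: atom {name} missing or ambiguous"
            )
        coords[name] = sub.atoms.coord[0]
    for name in _CHI1_GAMMA_PRIORITY:
        sub = res.select(atom_name=name)
        if len(sub) == 1:
            coords["G"] = sub.atoms.coord[0]
            break
    else:
        raise ValueError(f"residue {chain}/{res_id}: no γ atom found")
    return dihedral(coords["N"], coords["CA"], coords["CB"], coords["G"])


def sidechain_rotation(s1: Structure, s2: Structure, chain: str,
                       res_id: int, chain2: str | None = None,
                       res_id2: int | None = None) -> float:
    """Minimal absolute χ1 difference between the same residue in two
    structures, on the circle, in [0, 180]."""
    a = chi1(s1, chain, res_id)
    b = chi1(s2, chain2 or chain, res_id2 or res_id)
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


# --- superposition ---------------------------------------------------------

def kabsch(mobile: np.ndarray, target: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Returns (rotation, translation, rmsd); the rotation determinant is
    constrained to +1 (proper rotation, no reflection).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate sets must be matching (n, 3) arrays")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = (R @ P0.T).T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q0) ** 2, axis=1))))
    t = qc - R @ pc
    return R, t, rmsd


BACKBONE_ATOMS = ("N", "CA", "C", "O")


def superpose_rmsd(
    s1: Structure, s2: Structure,
    chain_map: Mapping[str, str] | None = None,
    backbone: Sequence[str] = BACKBONE_ATOMS,
) -> tuple[float, int]:
    """Backbone RMSD after optimal superposition over common residues.

    Residues are paired by (chain, residue number), with ``chain_map``
    translating s1 chains to s2 chains when the deposits label protomers
    differently.  Returns (RMSD in Å, number of residues used).
    """
    chain_map = dict(chain_map or {c: c for c in s1.chains})

    def backbone_index(s: Structure):
        idx = {}
        a = s.atoms
        amino = bst.filter_amino_acids(a)
        for i in np.flatnonzero(amino):
            if a.atom_name[i] in backbone:
                idx[(a.chain_id[i], int(a.res_id[i]), a.atom_name[i])] = i
        return idx

    i1, i2 = backbone_index(s1), backbone_index(s2)
    p, q, residues = [], [], set()
    for (c, r, name), i in sorted(i1.items()):
        c2 = chain_map.get(c)
        if c2 is None:
            continue
        j = i2.get((c2, r, name))
        if j is not None:
            p.append(s1.atoms.coord[i])
            q.append(s2.atoms.coord[j])
            residues.add((c, r))
    if len(residues) < 3:
        raise ValueError(f"only {len(residues)} common residues (need >= 3)")
    P, Q = np.array(p), np.array(q)
    if np.linalg.matrix_rank(P - P.mean(axis=0)) < 2:
        raise ValueError("degenerate (collinear) selection")
    _, _, rmsd = kabsch(P, Q)
    return rmsd, len(residues)


# --- solvent-accessible surface area ---------------------------------------

def sphere_lattice(n: int) -> np.ndarray:
    """Deterministic golden-section lattice of n points on the unit sphere."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = 2.0 * np.pi * i * (1.0 - 1.0 / np.sqrt(5.0))  # golden angle/2π frac
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    s: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    radii: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, float]:
    """Shrake–Rupley SASA with a fixed golden-section point set.

    Returns (per-atom areas, total) in Å².  Elements without a configured
    radius raise; hydrogens are included if present in the coordinates.
    """
    radii = dict(radii or VDW_RADII)
    elements = s.atoms.element
    missing = sorted(set(elements) - set(radii))
    if missing:
        raise ValueError(f"no van der Waals radius configured for {missing}")
    coords = s.atoms.coord.astype(float)
    n = len(s)
    r = np.array([radii[e] for e in elements]) + probe
    pts = sphere_lattice(n_points)
    areas = np.zeros(n)
    # neighbour search: two atoms can occlude each other's shells only if
    # centre distance < r_i + r_j
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    rmax = r.max()
    for i in range(n):
        shell = coords[i] + r[i] * pts
        nbr = [j for j in tree.query_ball_point(coords[i], r[i] + rmax)
               if j != i and np.linalg.norm(coords[j] - coords[i]) < r[i] + r[j]]
        if nbr:
            d2 = ((shell[:, None, :] - coords[nbr][None, :, :]) ** 2).sum(-1)
            accessible = np.all(d2 >= (r[nbr] ** 2)[None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * r[i] ** 2
    return areas, float(areas.sum())


@dataclass(frozen=True)
class InterfaceReport:
    """Buried-surface bookkeeping for a dimer.

    ``buried_total`` = SASA(A) + SASA(B) − SASA(AB), summed over both
    protomers; ``buried_per_side`` halves it; ``buried_fraction_of_monomer``
    is buried_total / (SASA(A)+SASA(B)) × 100.
    """

    sasa_monomer_a: float
    sasa_monomer_b: float
    sasa_dimer: float
    buried_total: float
    buried_per_side: float
    buried_fraction_of_monomer: float


def interface_report(
    dimer: Structure, chain_a: str, chain_b: str,
    include_ligands: bool = False,
    probe: float = 1.4, n_points: int = 960,
) -> InterfaceReport:
    """SASA of each isolated protomer and of the dimer; buried = A + B − AB.

    Waters, ions and ligands are excluded by default (``include_ligands``
    retains hetero ligand groups).
    """
    core = dimer.without_solvent(keep_ligands=include_ligands)
    a = core.select(chain=chain_a)
    b = core.select(chain=chain_b)
    if len(a) == 0:
        raise ValueError(f"chain {chain_a!r} not present")
    if len(b) == 0:
        raise ValueError(f"chain {chain_b!r} not present")
    ab = Structure(a.atoms + b.atoms, name=core.name)
    _, sa = sasa(a, probe=probe, n_points=n_points)
    _, sb = sasa(b, probe=probe, n_points=n_points)
    _, sab = sasa(ab, probe=probe, n_points=n_points)
    buried = max(sa + sb - sab, 0.0)
    return InterfaceReport(
        sasa_monomer_a=sa, sasa_monomer_b=sb, sasa_dimer=sab,
        buried_total=buried, buried_per_side=buried / 2.0,
        buried_fraction_of_monomer=100.0 * buried / (sa + sb),
    )
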