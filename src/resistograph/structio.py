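"""Macromolecular structure I/O and solvent-accessible surface area.

Structures are read from fixed-column PDB text into a flat list of atom
records (author residue numbering kept verbatim). SASA is computed with the
Shrake–Rupley rolling-probe method on a deterministic golden-section point
sphere and aggregated per residue, with residues classed as buried,
intermediate or exposed by configurable area thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "Structure",
    "ResidueSASA",
    "PDBParseError",
    "parse_pdb",
    "load_radii",
    "golden_spiral_points",
    "shrake_rupley_sasa",
    "residue_sasa",
    "write_residue_sasa_tsv",
]

_WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}

#: Residue-level exposure thresholds in Å² (buried below, exposed above).
DEFAULT_BURIED_MAX = 5.0
DEFAULT_EXPOSED_MIN = 70.0


class PDBParseError(ValueError):
    """Raised when a PDB record cannot be interpreted."""


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    position: tuple[float, float, float]
    occupancy: float = 1.0
    alt_loc: str = ""

    def residue_key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.residue_number, self.insertion_code, self.residue_name)


@dataclass
class Structure:
    atoms: list[AtomRecord]
    identifier: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class ResidueSASA:
    chain_id: str
    residue_number: int
    residue_name: str
    sasa: float
    exposure_class: str
    insertion_code: str = ""


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    # Two-letter elements in columns 13-14 start at column 13; heuristically
    # a leading H/C/N/O/S/P with trailing remoteness codes is one-letter.
    if len(stripped) >= 2 and stripped[:2].upper() in {"SE", "FE", "ZN", "MG", "CL", "BR", "NA", "MN", "CU"}:
        return stripped[:2].upper()
    return stripped[0].upper()


def parse_pdb(
    text: str,
    identifier: str = "",
    include_hetatm: bool = False,
    include_waters: bool = False,
    keep_all_alt_locs: bool = False,
) -> Structure:
    """Parse ATOM/HETATM records from fixed-column PDB text.

    By default HETATM records and waters are dropped and, when a position is
    present in several alternate locations, only the highest-occupancy one is
    kept (ties resolved to the first occurrence). Author chain IDs and residue
    numbers are preserved verbatim.
    """
    atoms: list[AtomRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[0:6].strip()
        if record not in ("ATOM", "HETATM"):
            continue
        if record == "HETATM" and not include_hetatm:
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated {record} record ({len(line)} columns)")
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            alt_loc = line[16].strip()
            residue_name = line[17:20].strip()
            chain_id = line[21].strip()
            residue_number = int(line[22:26])
            insertion_code = line[26].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ_field = line[54:60].strip() if len(line) >= 60 else ""
            occupancy = float(occ_field) if occ_field else 1.0
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed fixed-column field ({exc})") from exc
        if residue_name in _WATER_RESNAMES and not include_waters:
            continue
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
        if not element:
            element = _guess_element(line[12:16])
        if not all(math.isfinite(v) for v in (x, y, z)):
            raise PDBParseError(f"line {lineno}: non-finite coordinate")
        atoms.append(
            AtomRecord(
                serial=serial,
                name=name,
                element=element,
                residue_name=residue_name,
                chain_id=chain_id,
                residue_number=residue_number,
                insertion_code=insertion_code,
                position=(x, y, z),
                occupancy=occupancy,
                alt_loc=alt_loc,
            )
        )

    if not keep_all_alt_locs:
        best: dict[tuple, int] = {}
        for idx, atom in enumerate(atoms):
            key = (atom.chain_id, atom.residue_number, atom.insertion_code, atom.name)
            if key not in best or atom.occupancy > atoms[best[key]].occupancy:
                if key in best and atom.occupancy <= atoms[best[key]].occupancy:
                    continue
                best[key] = idx
        keep = sorted(best.values())
        atoms = [atoms[i] for i in keep]

    if not atoms:
        raise PDBParseError("empty structure after filtering")
    return Structure(atoms=atoms, identifier=identifier)


def load_radii() -> dict[str, float]:
    """Van der Waals radii (Å) by element, from the bundled table."""
    radii: dict[str, float] = {}
    data = resources.files("resistograph.data").joinpath("vdw_radii.tsv").read_text()
    for line in data.splitlines()[1:]:
        if not line.strip():
            continue
        element, value = line.split("\t")
        radii[element.upper()] = float(value)
    return radii


def golden_spiral_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points on a golden-section spiral.

    Deterministic: no random state involved.
    """
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    theta = math.pi * (3.0 - math.sqrt(5.0)) * k
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley_sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    radii: dict[str, float] | None = None,
    include_hydrogens: bool = False,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake–Rupley method.

    Each atom is expanded by the probe radius and covered with
    ``n_sphere_points`` deterministic test points; the accessible fraction is
    the share of points not inside any neighbour's expanded sphere. Hydrogens
    contribute no area and do not occlude by default.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if n_sphere_points < 32:
        raise ValueError("n_sphere_points must be at least 32")
    if radii is None:
        radii = load_radii()

    areas = np.zeros(len(structure.atoms))
    active = [
        (i, a)
        for i, a in enumerate(structure.atoms)
        if include_hydrogens or a.element not in ("H", "D")
    ]
    if not active:
        return areas
    unknown = sorted({a.element for _, a in active if a.element.upper() not in radii})
    if unknown:
        raise ValueError(f"no van der Waals radius for element(s): {', '.join(unknown)}")

    coords = np.array([a.position for _, a in active])
    rad = np.array([radii[a.element.upper()] for _, a in active])
    expanded = rad + probe_radius
    sphere = golden_spiral_points(n_sphere_points)

    tree = cKDTree(coords)
    for j in range(len(active)):
        # candidate neighbours within the loosest bound, pruned to the true
        # occlusion range r_i + r_j + 2*probe
        candidates = tree.query_ball_point(coords[j], rad[j] + rad.max() + 2.0 * probe_radius)
        neighbours = [
            m
            for m in candidates
            if m != j
            and np.linalg.norm(coords[m] - coords[j]) < rad[j] + rad[m] + 2.0 * probe_radius
        ]
        pts = coords[j] + expanded[j] * sphere
        if neighbours:
            nb = np.asarray(neighbours)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[active[j][0]] = 4.0 * math.pi * expanded[j] ** 2 * frac
    return areas


def residue_sasa(
    structure: Structure,
    per_atom_areas: Sequence[float] | np.ndarray,
    buried_max: float = DEFAULT_BURIED_MAX,
    exposed_min: float = DEFAULT_EXPOSED_MIN,
    side_chain_only: bool = False,
) -> list[ResidueSASA]:
    """Sum per-atom areas within each residue and class its exposure."""
    per_atom_areas = np.asarray(per_atom_areas, dtype=float)
    if len(per_atom_areas) != len(structure.atoms):
        raise ValueError("per-atom areas must align with the structure's atoms")
    backbone = {"N", "CA", "C", "O", "OXT"}
    order: list[tuple] = []
    totals: dict[tuple, float] = {}
    for atom, area in zip(structure.atoms, per_atom_areas):
        if side_chain_only and atom.name in backbone:
            continue
        key = atom.residue_key()
        if key not in totals:
            totals[key] = 0.0
            order.append(key)
        totals[key] += float(area)
    out = []
    for chain_id, resnum, icode, resname in order:
        area = totals[(chain_id, resnum, icode, resname)]
        if area < buried_max:
            cls = "buried"
        elif area > exposed_min:
            cls = "exposed"
        else:
            cls = "intermediate"
        out.append(
            ResidueSASA(
                chain_id=chain_id,
                residue_number=resnum,
                residue_name=resname,
                sasa=area,
                exposure_class=cls,
                insertion_code=icode,
            )
        )
    return out


def write_residue_sasa_tsv(records: Iterable[ResidueSASA], path) -> None:
    with open(path, "w") as fh:
        fh.write("chain\tresnum\tresname\tsasa_A2\texposure\n")
        for r in records:
            fh.write(f"{r.chain_id}\t{r.residue_number}\t{r.residue_name}\t{r.sasa:.4f}\t{r.exposure_class}\n")
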