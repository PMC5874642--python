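"""Backbone dihedral extraction and Ramachandran classification.

Reads N/CA/C coordinates from a PDB file, computes phi/psi (and omega)
torsions with the IUPAC sign convention, and classifies each residue as
favoured / allowed / outlier against polygonal region definitions shipped
as a plain-text data table. The shipped polygons are a documented
rectilinear approximation of the general-case regions (no Gly/Pro special
casing) and are fully swappable; percentages computed with them are
implementation-defined, not a reproduction of any density-based contour.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Point, Polygon

from . import tables

CHAIN_BREAK_DISTANCE = 2.5  # Angstrom, maximum peptide-bond C-N distance

_THREE_TO_DISPLAY = {
    "ALA": "Ala", "ARG": "Arg", "ASN": "Asn", "ASP": "Asp", "CYS": "Cys",
    "GLN": "Gln", "GLU": "Glu", "GLY": "Gly", "HIS": "His", "ILE": "Ile",
    "LEU": "Leu", "LYS": "Lys", "MET": "Met", "PHE": "Phe", "PRO": "Pro",
    "SER": "Ser", "THR": "Thr", "TRP": "Trp", "TYR": "Tyr", "VAL": "Val",
}


class GeometryError(ValueError):
    """Raised for degenerate atom geometry (collinear torsion points)."""


@dataclass(frozen=True)
class BackboneResidue:
    name: str  # 3-letter residue name
    number: int  # author-assigned residue number
    icode: str  # insertion code ("" if none)
    n: np.ndarray | None
    ca: np.ndarray | None
    c: np.ndarray | None

    @property
    def complete(self) -> bool:
        return self.n is not None and self.ca is not None and self.c is not None

    @property
    def display(self) -> str:
        return f"{_THREE_TO_DISPLAY.get(self.name, self.name.title())}{self.number}{self.icode}"


@dataclass(frozen=True)
class BackboneChain:
    """Ordered backbone residues plus recorded chain breaks.

    ``breaks`` holds 0-based indices i such that the peptide bond between
    residue i and i+1 is broken (C-N distance above 2.5 A or atoms missing).
    """

    chain_id: str
    residues: tuple[BackboneResidue, ...]
    breaks: frozenset[int] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.residues)


def read_pdb_backbone(path: str | Path, chain_id: str | None = None) -> BackboneChain:
    """Extract N/CA/C coordinates for one chain of a PDB file.

    Residues appear in file order; for alternate locations the
    highest-occupancy conformer is kept (Biopython's default); insertion
    codes are preserved. Consecutive residues whose C-N distance exceeds
    2.5 A are recorded as a chain break.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate sparse fixture files
        structure = PDBParser(QUIET=True).get_structure("model", str(path))
    model = next(iter(structure), None)
    if model is None:
        raise ValueError(f"{path}: no ATOM records")
    chains = {c.id: c for c in model}
    if not chains:
        raise ValueError(f"{path}: no chains with ATOM records")
    if chain_id is None:
        chain_id = next(iter(chains))
    if chain_id not in chains:
        raise ValueError(
            f"{path}: chain {chain_id!r} not present (have {sorted(chains)})"
        )
    residues = []
    for res in chains[chain_id]:
        hetflag, number, icode = res.id
        if hetflag.strip():
            continue
        coords = {}
        for name in ("N", "CA", "C"):
            if name in res:
                atom = res[name]
                if atom.is_disordered():
                    atom = max(atom, key=lambda a: a.get_occupancy() or 0.0)
                coords[name] = np.asarray(atom.get_coord(), dtype=float)
        residues.append(
            BackboneResidue(
                name=res.get_resname().strip(),
                number=number,
                icode=icode.strip(),
                n=coords.get("N"),
                ca=coords.get("CA"),
                c=coords.get("C"),
            )
        )
    if not residues:
        raise ValueError(f"{path}: chain {chain_id!r} has no residues")
    breaks = set()
    for i, (a, b) in enumerate(zip(residues, residues[1:])):
        if a.c is None or b.n is None:
            breaks.add(i)
        elif float(np.linalg.norm(a.c - b.n)) > CHAIN_BREAK_DISTANCE:
            breaks.add(i)
    return BackboneChain(chain_id, tuple(residues), frozenset(breaks))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed torsion angle a-b-c-d in degrees, IUPAC convention, (-180, 180].

    Computed from the normals of planes (a,b,c) and (b,c,d) about the b-c
    axis; positive for a clockwise rotation of d relative to a when viewed
    from b towards c.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm2 = np.linalg.norm(b2)
    if norm2 == 0 or np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("collinear points: torsion undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm2)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


@dataclass(frozen=True)
class DihedralRecord:
    """phi/psi/omega of one residue; None where undefined (termini/breaks)."""

    index: int  # 0-based position within the chain
    label: str  # e.g. "Leu77"
    phi: float | None
    psi: float | None
    omega: float | None = None


def phi_psi(chain: BackboneChain) -> list[DihedralRecord]:
    """Backbone torsions for every residue of a chain.

    phi(i) = torsion(C(i-1), N(i), CA(i), C(i));
    psi(i) = torsion(N(i), CA(i), C(i), N(i+1));
    omega(i) = torsion(CA(i), C(i), N(i+1), CA(i+1)).
    Angles are undefined at termini, across recorded chain breaks, and for
    residues with missing backbone atoms.
    """
    out = []
    res = chain.residues
    for i, r in enumerate(res):
        phi = psi = omega = None
        if r.complete:
            prev_ok = i > 0 and res[i - 1].complete and (i - 1) not in chain.breaks
            next_ok = (
                i + 1 < len(res) and res[i + 1].complete and i not in chain.breaks
            )
            if prev_ok:
                phi = dihedral(res[i - 1].c, r.n, r.ca, r.c)
            if next_ok:
                psi = dihedral(r.n, r.ca, r.c, res[i + 1].n)
                omega = dihedral(r.ca, r.c, res[i + 1].n, res[i + 1].ca)
        out.append(DihedralRecord(i, r.display, phi, psi, omega))
    return out


class RamaRegions:
    """Favoured/allowed polygons with boundary-inclusive membership.

    A point on a polygon edge belongs to the more permissive class: on a
    favoured edge it is favoured, on an allowed edge (outside all favoured
    polygons) it is allowed.
    """

    def __init__(
        self, polygons: list[tuple[str, str, list[tuple[float, float]]]] | None = None
    ):
        polygons = polygons if polygons is not None else tables.rama_regions()
        self.favoured = [
            (name, Polygon(verts)) for name, cls, verts in polygons if cls == "favoured"
        ]
        self.allowed = [
            (name, Polygon(verts)) for name, cls, verts in polygons if cls == "allowed"
        ]
        if not self.favoured:
            raise ValueError("region table defines no favoured polygons")

    def classify(self, phi: float, psi: float) -> str:
        pt = Point(phi, psi)
        if any(poly.covers(pt) for _, poly in self.favoured):
            return "favoured"
        if any(poly.covers(pt) for _, poly in self.allowed):
            return "allowed"
        return "outlier"


def classify_rama(record: DihedralRecord, regions: RamaRegions | None = None) -> str:
    """Class of one residue; requires both phi and psi to be defined."""
    if record.phi is None or record.psi is None:
        raise ValueError(f"{record.label}: phi/psi undefined, not classifiable")
    regions = regions or RamaRegions()
    return regions.classify(record.phi, record.psi)


@dataclass(frozen=True)
class RamachandranSummary:
    n_classified: int
    n_unclassified: int
    counts: dict[str, int]
    percentages: dict[str, float]  # over classified residues, full precision
    outliers: tuple[str, ...]

    def display(self) -> dict:
        return {
            "n_classified": self.n_classified,
            "n_unclassified": self.n_unclassified,
            "favoured_percent": round(self.percentages["favoured"], 1),
            "allowed_percent": round(self.percentages["allowed"], 1),
            "outlier_percent": round(self.percentages["outlier"], 1),
            "outliers": list(self.outliers),
        }


def rama_summary(
    records: list[DihedralRecord], regions: RamaRegions | None = None
) -> RamachandranSummary:
    """Favoured/allowed/outlier tallies over all classifiable residues.

    Residues with undefined phi or psi (termini, breaks, incomplete
    backbones) are excluded from the percentages and counted separately.
    """
    regions = regions or RamaRegions()
    counts = {"favoured": 0, "allowed": 0, "outlier": 0}
    outliers = []
    unclassified = 0
    for rec in records:
        if rec.phi is None or rec.psi is None:
            unclassified += 1
            continue
        cls = regions.classify(rec.phi, rec.psi)
        counts[cls] += 1
        if cls == "outlier":
            outliers.append(rec.label)
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no classifiable residues (all phi/psi undefined)")
    return RamachandranSummary(
        n_classified=n,
        n_unclassified=unclassified,
        counts=counts,
        percentages={k: 100.0 * v / n for k, v in counts.items()},
        outliers=tuple(outliers),
    )
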