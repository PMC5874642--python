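"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its parameters and an integer seed, so
fixtures are regenerable from a (parameters, seed) manifest and byte-identical
across runs. Planted antigenic segments are built from the extremes of the
Kolaskar-Tongaonkar scale, which makes their recoverability provable from the
scale table itself rather than dependent on sampling luck.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from . import tables
from .seqio import NucleotideRecord, ProteinRecord, STANDARD_AA
from .topology import TopologyAnnotation, TopologySegment, write_tmhmm


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_protein(
    length: int,
    weights: dict[str, float] | None = None,
    seed: int = 0,
    id: str = "synthetic",
) -> ProteinRecord:
    """I.i.d. residue draws from normalized composition weights."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if weights is None:
        w = np.ones(20)
    else:
        w = np.array([float(weights.get(aa, 0.0)) for aa in STANDARD_AA])
        if (w < 0).any() or w.sum() == 0:
            raise ValueError("weights must be nonnegative and not all zero")
    w = w / w.sum()
    rng = _rng(seed)
    letters = rng.choice(list(STANDARD_AA), size=length, p=w)
    return ProteinRecord(id, "random protein", "".join(letters))


@dataclass(frozen=True)
class PlantedEpitopeTruth:
    """A synthetic protein with known high-propensity (antigenic) spans."""

    record: ProteinRecord
    planted: tuple[tuple[int, int], ...]  # 1-based inclusive spans
    background_propensity_mean: float
    planted_propensity_mean: float
    contrast: float
    seed: int


def plant_epitopes(
    length: int,
    spans: list[tuple[int, int]],
    contrast: float = 0.15,
    seed: int = 0,
    id: str = "planted",
) -> PlantedEpitopeTruth:
    """Background from the lowest-propensity residues, planted spans from the
    highest, guaranteeing a scale-mean difference of at least ``contrast``.

    Background residues all score below 1.0 on the Kolaskar-Tongaonkar scale
    and planted residues all score above it, so any heptapeptide fully inside
    a planted span averages above the 1.0 cut and any window fully in
    background averages below it.
    """
    if contrast <= 0:
        raise ValueError("contrast must be positive")
    spans = sorted(spans)
    for s, e in spans:
        if s < 1 or e > length or e - s + 1 < 6:
            raise ValueError(f"span {s}-{e} out of range or shorter than 6")
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError(f"spans {s1}-{e1} and {s2}-{e2} overlap")

    scale = tables.kolaskar_scale()
    ranked = sorted(scale, key=scale.get)
    background_pool = [aa for aa in ranked if scale[aa] < 1.0]
    planted_pool = ranked[-5:]  # the five highest-propensity residues
    bg_mean = float(np.mean([scale[aa] for aa in background_pool]))
    pl_mean = float(np.mean([scale[aa] for aa in planted_pool]))
    if pl_mean - bg_mean < contrast:
        raise ValueError(
            f"requested contrast {contrast} exceeds the attainable "
            f"{pl_mean - bg_mean:.3f} for this scale"
        )
    rng = _rng(seed)
    seq = list(rng.choice(background_pool, size=length))
    for s, e in spans:
        seq[s - 1 : e] = rng.choice(planted_pool, size=e - s + 1)
    return PlantedEpitopeTruth(
        record=ProteinRecord(id, "planted-epitope protein", "".join(seq)),
        planted=tuple(spans),
        background_propensity_mean=bg_mean,
        planted_propensity_mean=pl_mean,
        contrast=contrast,
        seed=seed,
    )


def _codon_choices() -> tuple[dict[str, list[str]], list[str]]:
    table = CodonTable.unambiguous_dna_by_id[1]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        by_aa.setdefault(aa, []).append(codon)
    return by_aa, sorted(table.stop_codons)


def back_translate(p: ProteinRecord, seed: int = 0) -> NucleotideRecord:
    """Replace each residue by a uniformly chosen synonymous codon and append
    one stop codon; exactly inverted by CDS translation."""
    by_aa, stops = _codon_choices()
    rng = _rng(seed)
    codons = [by_aa[aa][rng.integers(len(by_aa[aa]))] for aa in p.sequence]
    codons.append(stops[rng.integers(len(stops))])
    return NucleotideRecord(p.id, f"back-translation of {p.id}", "".join(codons))


def make_topology(
    segments: list[tuple[str, int, int]],
    protein_id: str = "synthetic",
    length: int | None = None,
    path: str | Path | None = None,
    posterior: dict[int, float] | None = None,
) -> TopologyAnnotation:
    """Build (and optionally write) a TMHMM-style topology annotation.

    ``segments`` are (label, start, end) triples that must tile 1..length
    with legal label alternation; validation is delegated to the annotation
    type, so an illegal tiling raises before anything is written.
    """
    segs = tuple(TopologySegment(label, s, e) for label, s, e in segments)
    if length is None:
        length = segs[-1].end if segs else 0
    ann = TopologyAnnotation(
        protein_id=protein_id, length=length, segments=segs, posterior=posterior
    )
    if path is not None:
        write_tmhmm(ann, path)
    return ann


# --- ideal backbone geometry for the NeRF builder (Angstrom / degrees) ---
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 117.2
ANGLE_C_N_CA = 121.7


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Place atom d so that |c-d| = bond, angle(b,c,d) = angle and
    torsion(a,b,c,d) = torsion (natural-extension reference frame)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def build_backbone(
    n_residues: int,
    phi: float,
    psi: float,
    omega: float = 180.0,
) -> list[dict[str, np.ndarray]]:
    """N/CA/C coordinates for an ideal-geometry chain with uniform torsions.

    The first residue's phi and the last residue's psi are not represented
    (they do not exist); every internal torsion equals the requested value.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    n0 = np.zeros(3)
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    residues = [{"N": n0, "CA": ca0, "C": c0}]
    for _ in range(1, n_residues):
        prev = residues[-1]
        n_next = place_atom(prev["N"], prev["CA"], prev["C"],
                            BOND_C_N, ANGLE_CA_C_N, psi)
        ca_next = place_atom(prev["CA"], prev["C"], n_next,
                             BOND_N_CA, ANGLE_C_N_CA, omega)
        c_next = place_atom(prev["C"], n_next, ca_next,
                            BOND_CA_C, ANGLE_N_CA_C, phi)
        residues.append({"N": n_next, "CA": ca_next, "C": c_next})
    return residues


_PDB_ATOM = (
    "ATOM  {serial:5d} {name:<4s}{res:>3s} {chain}{num:4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}"
)


def write_backbone_pdb(
    residues: list[dict[str, np.ndarray]],
    path: str | Path,
    chain: str = "A",
    resname: str = "ALA",
) -> None:
    """Write backbone coordinates as minimal PDB ATOM records."""
    lines = []
    serial = 1
    for i, res in enumerate(residues, start=1):
        for name, el in (("N", "N"), ("CA", "C"), ("C", "C")):
            x, y, z = res[name]
            lines.append(_PDB_ATOM.format(
                serial=serial, name=f" {name}", res=resname, chain=chain,
                num=i, x=x, y=y, z=z, occ=1.0, b=0.0, el=el,
            ))
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def build_helix_coords(
    n_residues: int,
    phi: float = -57.0,
    psi: float = -47.0,
    omega: float = 180.0,
    path: str | Path | None = None,
) -> list[dict[str, np.ndarray]]:
    """Ideal-geometry backbone with prescribed torsions, optionally as PDB.

    With the alpha-helical defaults (phi -57, psi -47) the rise per residue
    comes out near 1.5 A. Measuring phi/psi on the built coordinates returns
    the inputs to well below 1e-6 degrees, which makes this the oracle input
    for the dihedral-extraction stage.
    """
    residues = build_backbone(n_residues, phi, psi, omega)
    if path is not None:
        write_backbone_pdb(residues, path)
    return residues
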