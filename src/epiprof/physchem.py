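"""ProtParam-style physicochemical descriptors of a protein.

All descriptors are computed from first principles against the shipped
constant tables: average residue masses (ExPASy table), the Bjellqvist pKa
set for the isoelectric point, the Guruprasad DIWV dipeptide weights for the
instability index, Ikai's aliphatic-index coefficients, and the
Kyte-Doolittle scale for GRAVY. Full precision is kept internally; display
rounding (MW/pI/II to 2 decimals, GRAVY to 3) happens only in reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from . import tables
from .seqio import ProteinRecord, STANDARD_AA

NEGATIVE_RESIDUES = "DE"
# ProtParam convention: His is excluded from the positively-charged count.
POSITIVE_RESIDUES = "RK"

EXTINCTION_TRP = 5500  # M^-1 cm^-1 at 280 nm
EXTINCTION_TYR = 1490
EXTINCTION_CYSTINE = 125

INSTABILITY_CUTOFF = 40.0


@dataclass(frozen=True)
class PhyschemProfile:
    """All scalar physicochemical descriptors of one protein."""

    n_residues: int
    molecular_weight: float
    theoretical_pI: float
    composition: dict[str, tuple[int, float]]
    atomic_composition: dict[str, int]
    n_negative: int
    n_positive: int
    extinction_reduced: float
    extinction_oxidized: float
    instability_index: float
    stability_call: str
    aliphatic_index: float
    gravy: float
    half_life: dict[str, str]


def composition(p: ProteinRecord) -> dict[str, tuple[int, float]]:
    """Residue → (count, mole-percent). Percents are exact, not pre-rounded."""
    n = p.length
    return {
        aa: (c, 100.0 * c / n)
        for aa in STANDARD_AA
        for c in (p.sequence.count(aa),)
    }


def molecular_weight(p: ProteinRecord) -> float:
    """Average molecular mass in Da: residue masses plus one water."""
    m = tables.residue_masses()
    return sum(m[aa] for aa in p.sequence) + tables.WATER_MASS


def charge_counts(p: ProteinRecord) -> tuple[int, int]:
    """(n_negative, n_positive) = (#Asp+#Glu, #Arg+#Lys); His excluded."""
    neg = sum(p.sequence.count(aa) for aa in NEGATIVE_RESIDUES)
    pos = sum(p.sequence.count(aa) for aa in POSITIVE_RESIDUES)
    return neg, pos


def net_charge(p: ProteinRecord, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH.

    Sums the protonated fraction of the N-terminus and basic side chains
    (K, R, H) minus the deprotonated fraction of the C-terminus and acidic
    side chains (D, E, C, Y), with terminal pKa values overridden by the
    identity of the terminal residue where the Bjellqvist set specifies one.
    """
    pk = tables.pka_set()
    pos_pk = dict(pk["positive"])
    neg_pk = dict(pk["negative"])
    nt, ct = p.sequence[0], p.sequence[-1]
    if nt in pk.get("nterm_residue", {}):
        pos_pk["Nterm"] = pk["nterm_residue"][nt]
    if ct in pk.get("cterm_residue", {}):
        neg_pk["Cterm"] = pk["cterm_residue"][ct]

    charge = 0.0
    for key, pka in pos_pk.items():
        n = 1 if key == "Nterm" else p.sequence.count(key)
        if n:
            charge += n * (10.0 ** pka) / (10.0 ** pka + 10.0 ** ph)
    for key, pka in neg_pk.items():
        n = 1 if key == "Cterm" else p.sequence.count(key)
        if n:
            charge -= n * (10.0 ** ph) / (10.0 ** pka + 10.0 ** ph)
    return charge


def isoelectric_point(p: ProteinRecord, tol: float = 1e-4) -> float:
    """pH at which :func:`net_charge` crosses zero, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so the root is unique.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(p, mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def extinction_coefficients(p: ProteinRecord) -> tuple[float, float]:
    """(reduced, oxidized) molar extinction at 280 nm.

    Reduced assumes free cysteines; oxidized adds a cystine term for each
    Cys pair (floor(#Cys / 2)).
    """
    w = p.sequence.count("W")
    y = p.sequence.count("Y")
    c = p.sequence.count("C")
    reduced = EXTINCTION_TRP * w + EXTINCTION_TYR * y
    return float(reduced), float(reduced + EXTINCTION_CYSTINE * (c // 2))


def instability_index(p: ProteinRecord) -> float:
    """Guruprasad instability index: (10/L) * sum of DIWV over dipeptides."""
    if p.length < 2:
        raise ValueError("instability index needs >= 2 residues")
    d = tables.diwv()
    s = p.sequence
    total = sum(d[s[i]][s[i + 1]] for i in range(len(s) - 1))
    return 10.0 * total / len(s)


def stability_call(ii: float) -> str:
    return "unstable" if ii > INSTABILITY_CUTOFF else "stable"


def aliphatic_index(p: ProteinRecord) -> float:
    """Ikai's aliphatic index: X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu)."""
    comp = composition(p)
    return (
        comp["A"][1]
        + 2.9 * comp["V"][1]
        + 3.9 * (comp["I"][1] + comp["L"][1])
    )


def gravy(p: ProteinRecord) -> float:
    """Grand average of hydropathicity: mean Kyte-Doolittle value."""
    kd = tables.kd_scale()
    return sum(kd[aa] for aa in p.sequence) / p.length


def half_life(p: ProteinRecord) -> dict[str, str]:
    """N-end-rule half-life estimates keyed by organism/system."""
    return dict(tables.half_life_table()[p.sequence[0]])


def atomic_composition(p: ProteinRecord) -> dict[str, int]:
    """Element → atom count: residue formulas summed plus one water."""
    formulas = tables.residue_formulas()
    out = {"C": 0, "H": 2, "N": 0, "O": 1, "S": 0}  # start from one water
    for aa in p.sequence:
        for el, n in formulas[aa].items():
            out[el] += n
    return out


def profile(p: ProteinRecord) -> PhyschemProfile:
    """Compute every descriptor for one protein."""
    neg, pos = charge_counts(p)
    red, oxi = extinction_coefficients(p)
    ii = instability_index(p)
    return PhyschemProfile(
        n_residues=p.length,
        molecular_weight=molecular_weight(p),
        theoretical_pI=isoelectric_point(p),
        composition=composition(p),
        atomic_composition=atomic_composition(p),
        n_negative=neg,
        n_positive=pos,
        extinction_reduced=red,
        extinction_oxidized=oxi,
        instability_index=ii,
        stability_call=stability_call(ii),
        aliphatic_index=aliphatic_index(p),
        gravy=gravy(p),
        half_life=half_life(p),
    )


def profile_as_display(prof: PhyschemProfile) -> dict:
    """Rounded, report-ready view of a profile (MW/pI/II 2 dp, GRAVY 3 dp)."""
    return {
        "n_residues": prof.n_residues,
        "molecular_weight": round(prof.molecular_weight, 2),
        "theoretical_pI": round(prof.theoretical_pI, 2),
        "n_negative": prof.n_negative,
        "n_positive": prof.n_positive,
        "extinction_reduced": prof.extinction_reduced,
        "extinction_oxidized": prof.extinction_oxidized,
        "instability_index": round(prof.instability_index, 2),
        "stability_call": prof.stability_call,
        "aliphatic_index": round(prof.aliphatic_index, 2),
        "gravy": round(prof.gravy, 3),
        "composition_percent": {
            aa: round(pct, 2) for aa, (_, pct) in prof.composition.items()
        },
        "atomic_composition": prof.atomic_composition,
        "half_life": prof.half_life,
    }
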