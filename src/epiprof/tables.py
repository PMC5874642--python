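"""Loaders for the plain-text constant tables shipped with the package.

Every scale or weight table used by the scoring stages lives under
``epiprof/data`` as a versioned TSV so values can be inspected, checksummed,
and swapped without touching code. Lines starting with ``#`` are comments.
"""

from __future__ import annotations

import hashlib
from functools import lru_cache
from importlib.resources import files
from pathlib import Path

DATA = files("epiprof") / "data"


def data_path(name: str) -> Path:
    return Path(str(DATA / name))


def data_sha256(name: str) -> str:
    return hashlib.sha256(data_path(name).read_bytes()).hexdigest()


def _rows(name: str) -> list[list[str]]:
    rows = []
    for line in data_path(name).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        rows.append(line.split("\t"))
    return rows


@lru_cache(maxsize=None)
def residue_scale(name: str) -> dict[str, float]:
    """A residue→float table (two columns)."""
    table = {r[0]: float(r[1]) for r in _rows(name)}
    if len(table) != 20:
        raise ValueError(f"{name}: expected 20 residues, got {len(table)}")
    return table


@lru_cache(maxsize=None)
def kd_scale() -> dict[str, float]:
    return residue_scale("kd_hydropathy.tsv")


@lru_cache(maxsize=None)
def kolaskar_scale() -> dict[str, float]:
    return residue_scale("kolaskar_propensity.tsv")


@lru_cache(maxsize=None)
def residue_masses() -> dict[str, float]:
    return residue_scale("residue_masses_average.tsv")


WATER_MASS = 18.01524  # Da, average


@lru_cache(maxsize=None)
def residue_formulas() -> dict[str, dict[str, int]]:
    out = {}
    for r in _rows("residue_formulas.tsv"):
        out[r[0]] = dict(zip("CHNOS", map(int, r[1:6])))
    return out


@lru_cache(maxsize=None)
def pka_set() -> dict[str, dict[str, float]]:
    """The Bjellqvist pKa set grouped by kind.

    Kinds: ``positive`` (Nterm, K, R, H), ``negative`` (Cterm, D, E, C, Y),
    ``nterm_residue`` / ``cterm_residue`` (terminal pKa overrides that depend
    on the identity of the terminal residue).
    """
    out: dict[str, dict[str, float]] = {}
    for kind, key, pka in _rows("pka_bjellqvist.tsv"):
        out.setdefault(kind, {})[key] = float(pka)
    return out


@lru_cache(maxsize=None)
def diwv() -> dict[str, dict[str, float]]:
    """Guruprasad dipeptide instability weight values, DIWV[first][second]."""
    out: dict[str, dict[str, float]] = {}
    for a, b, v in _rows("diwv_instability.tsv"):
        out.setdefault(a, {})[b] = float(v)
    return out


@lru_cache(maxsize=None)
def half_life_table() -> dict[str, dict[str, str]]:
    out = {}
    for r in _rows("half_life_nend.tsv"):
        out[r[0]] = {
            "mammalian_reticulocyte_invitro": r[1],
            "yeast_invivo": r[2],
            "ecoli_invivo": r[3],
        }
    return out


@lru_cache(maxsize=None)
def rama_regions() -> list[tuple[str, str, list[tuple[float, float]]]]:
    """Ramachandran region polygons as (name, class, vertices)."""
    polys: dict[str, tuple[str, list[tuple[float, float]]]] = {}
    order: list[str] = []
    for name, cls, phi, psi in _rows("rama_regions.tsv"):
        if name not in polys:
            polys[name] = (cls, [])
            order.append(name)
        polys[name][1].append((float(phi), float(psi)))
    return [(n, polys[n][0], polys[n][1]) for n in order]


def reference_mica_path() -> Path:
    """Path of the shipped reconstructed MIC-A precursor FASTA."""
    return data_path("mica_ky500939_reconstructed.fasta")
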