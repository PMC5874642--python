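"""Kolaskar-Tongaonkar antigenic-determinant prediction.

The four-step procedure: (1) the average antigenic propensity <Ap> of every
overlapping heptapeptide is computed from the Kolaskar-Tongaonkar scale;
(2) each window's average is allocated to a single anchor residue of the
window; (3) residues whose <Ap> meets the 1.0 cut are flagged as possibly
antigenic; (4) maximal runs of at least ``min_len`` consecutive flagged
residues are reported as antigenic determinants (epitopes).

Two anchor conventions are supported. The method description allocates the
window average to the FOURTH residue of the heptapeptide (``anchor=4``,
the package default). The hosted prediction server commonly used for this
method empirically allocates it to the THIRD residue and requires runs of
at least seven scored residues; ``convention="server"`` selects that pairing
and is the configuration that reproduces published epitope tables computed
with the server.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import tables
from .seqio import ProteinRecord

WINDOW = 7

#: convention name -> (anchor residue within the heptapeptide, min run length)
CONVENTIONS: dict[str, tuple[int, int]] = {
    "described": (4, 6),
    "server": (3, 7),
}


@dataclass(frozen=True)
class PropensityScale:
    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.values) != 20:
            raise ValueError(f"scale {self.name!r}: expected 20 residues")
        off = [aa for aa, v in self.values.items() if not 0.5 < v < 1.5]
        if off:
            raise ValueError(
                f"scale {self.name!r}: values outside the (0.5, 1.5) sanity "
                f"band for {off}"
            )


def kolaskar() -> PropensityScale:
    return PropensityScale("Kolaskar-Tongaonkar", tables.kolaskar_scale())


@dataclass(frozen=True)
class AntigenicityProfile:
    """Per-residue <Ap> values with window bookkeeping.

    ``ap`` maps each scored 1-based position to the mean propensity of the
    heptapeptide anchored there; with ``anchor=4`` positions run 4 ... L-3.
    ``mean_ap`` is the mean over all window values. ``overall_propensity``
    is the mean of the raw per-residue scale values — this is the quantity
    conventionally quoted as a protein's overall antigenic propensity, and
    the one compared against the 1.0 antigenicity benchmark.
    """

    window: int
    anchor: int
    ap: dict[int, float]
    mean_ap: float
    overall_propensity: float
    threshold: float = 1.0
    scale_name: str = "Kolaskar-Tongaonkar"

    def as_frame(self, p: ProteinRecord | None = None) -> pd.DataFrame:
        pos = sorted(self.ap)
        df = pd.DataFrame({"position": pos, "ap": [self.ap[i] for i in pos]})
        if p is not None:
            df.insert(1, "residue", [p.sequence[i - 1] for i in pos])
        return df


@dataclass(frozen=True)
class Epitope:
    """A called antigenic determinant, 1-based inclusive coordinates."""

    start: int
    end: int
    sequence: str
    mean_ap: float
    max_ap: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def propensity_profile(
    p: ProteinRecord,
    scale: PropensityScale | None = None,
    anchor: int = 4,
) -> AntigenicityProfile:
    """<Ap> of each heptapeptide, allocated to its ``anchor``-th residue."""
    scale = scale or kolaskar()
    if not 1 <= anchor <= WINDOW:
        raise ValueError(f"anchor must be in 1..{WINDOW}, got {anchor}")
    L = p.length
    if L < WINDOW:
        raise ValueError(
            f"sequence shorter than heptapeptide window ({L} < {WINDOW})"
        )
    vals = [scale.values[aa] for aa in p.sequence]
    ap = {
        i + anchor - 1: sum(vals[i - 1 : i - 1 + WINDOW]) / WINDOW
        for i in range(1, L - WINDOW + 2)
    }
    return AntigenicityProfile(
        window=WINDOW,
        anchor=anchor,
        ap=ap,
        mean_ap=sum(ap.values()) / len(ap),
        overall_propensity=sum(vals) / L,
        scale_name=scale.name,
    )


def call_epitopes(
    profile: AntigenicityProfile,
    p: ProteinRecord,
    min_len: int = 6,
    rule: str = "flat",
) -> list[Epitope]:
    """Maximal runs of consecutive scored positions with <Ap> >= cut.

    Under ``rule="flat"`` the cut is the profile threshold (1.0). Under
    ``rule="conditional"`` (the original publication's variant) the cut
    drops to the protein's mean window propensity when that mean is below
    1.0, so that low-propensity proteins still yield candidate determinants.
    Runs shorter than ``min_len`` are discarded; epitopes are returned in
    order of start position.
    """
    if rule == "flat":
        cut = profile.threshold
    elif rule == "conditional":
        cut = profile.threshold if profile.mean_ap >= 1.0 else profile.mean_ap
    else:
        raise ValueError(f"unknown rule {rule!r}")

    positions = sorted(profile.ap)
    epitopes: list[Epitope] = []
    run: list[int] = []

    def flush() -> None:
        if len(run) >= min_len:
            s, e = run[0], run[-1]
            vals = [profile.ap[i] for i in run]
            epitopes.append(
                Epitope(
                    start=s,
                    end=e,
                    sequence=p.sequence[s - 1 : e],
                    mean_ap=sum(vals) / len(vals),
                    max_ap=max(vals),
                )
            )

    for pos in positions:
        if profile.ap[pos] >= cut:
            if run and pos != run[-1] + 1:
                flush()
                run = []
            run.append(pos)
        else:
            flush()
            run = []
    flush()
    return epitopes


def predict_epitopes(
    p: ProteinRecord,
    scale: PropensityScale | None = None,
    convention: str = "described",
    min_len: int | None = None,
    rule: str = "flat",
) -> tuple[AntigenicityProfile, list[Epitope]]:
    """Profile + epitope calls under a named anchor/run-length convention."""
    if convention not in CONVENTIONS:
        raise ValueError(
            f"unknown convention {convention!r}; choose from {sorted(CONVENTIONS)}"
        )
    anchor, default_min_len = CONVENTIONS[convention]
    profile = propensity_profile(p, scale=scale, anchor=anchor)
    eps = call_epitopes(
        profile, p, min_len=default_min_len if min_len is None else min_len,
        rule=rule,
    )
    return profile, eps


def epitope_table(
    epitopes: list[Epitope],
    calls: list | None = None,
) -> pd.DataFrame:
    """One row per epitope, ordered by start; optionally merged with
    topology calls (location + score columns)."""
    rows = []
    for i, e in enumerate(sorted(epitopes, key=lambda e: e.start)):
        row = {
            "index": i + 1,
            "sequence": e.sequence,
            "start": e.start,
            "end": e.end,
            "length": e.length,
            "mean_ap": round(e.mean_ap, 4),
            "max_ap": round(e.max_ap, 4),
        }
        rows.append(row)
    df = pd.DataFrame(
        rows,
        columns=["index", "sequence", "start", "end", "length", "mean_ap", "max_ap"],
    )
    if calls is not None:
        by_span = {(c.epitope.start, c.epitope.end): c for c in calls}
        df["location"] = [
            by_span[(s, e)].location.capitalize()
            if (s, e) in by_span else ""
            for s, e in zip(df["start"], df["end"])
        ]
        df["topology_score"] = [
            round(by_span[(s, e)].score, 5) if (s, e) in by_span else float("nan")
            for s, e in zip(df["start"], df["end"])
        ]
        df["antigenic_flag"] = [
            bool(by_span[(s, e)].antigenic_flag) if (s, e) in by_span else False
            for s, e in zip(df["start"], df["end"])
        ]
    return df
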