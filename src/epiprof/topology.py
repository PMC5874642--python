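"""Membrane-topology annotation: TMHMM-output parsing and epitope placement.

The transmembrane HMM itself is not re-implemented; this module consumes
its standard long-format output (one segment per line: id, method, label,
start, end; ``#`` comment lines carry run metadata) and assigns each epitope
an inside / outside / transmembrane location by majority vote over its
residues, with a deterministic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .antigenicity import Epitope

LABELS = ("inside", "outside", "TMhelix")
#: display names used in report tables
DISPLAY = {"inside": "Inside", "outside": "Outside", "TMhelix": "Transmembrane"}
#: deterministic tie-break priority (highest first)
TIE_BREAK = ("TMhelix", "inside", "outside")


class TopologyFormatError(ValueError):
    """Raised for unparseable or geometrically illegal topology files."""


@dataclass(frozen=True)
class TopologySegment:
    label: str
    start: int  # 1-based
    end: int  # inclusive

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise TopologyFormatError(f"unknown topology label {self.label!r}")
        if self.start > self.end or self.start < 1:
            raise TopologyFormatError(
                f"bad segment span {self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TopologyAnnotation:
    """Ordered segments tiling positions 1..length with legal alternation."""

    protein_id: str
    length: int
    segments: tuple[TopologySegment, ...]
    metadata: dict[str, str] = field(default_factory=dict)
    posterior: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        segs = self.segments
        if not segs:
            raise TopologyFormatError("annotation has no segments")
        if segs[0].start != 1:
            raise TopologyFormatError("first segment must start at 1")
        if segs[-1].end != self.length:
            raise TopologyFormatError(
                f"last segment ends at {segs[-1].end}, expected {self.length}"
            )
        for a, b in zip(segs, segs[1:]):
            if b.start != a.end + 1:
                raise TopologyFormatError(
                    f"gap/overlap between segments ending {a.end} and "
                    f"starting {b.start}"
                )
            if a.label == b.label:
                raise TopologyFormatError(
                    f"adjacent segments share label {a.label!r}"
                )
            if {a.label, b.label} == {"inside", "outside"}:
                raise TopologyFormatError(
                    "inside and outside segments must be separated by a TMhelix"
                )
        if self.posterior is not None:
            bad = [p for p, v in self.posterior.items() if not 0.0 <= v <= 1.0]
            if bad:
                raise TopologyFormatError(
                    f"posterior probabilities outside [0,1] at positions {bad[:5]}"
                )

    def label_at(self, position: int) -> str:
        if not 1 <= position <= self.length:
            raise IndexError(
                f"position {position} outside annotation 1..{self.length}"
            )
        for seg in self.segments:
            if seg.start <= position <= seg.end:
                return seg.label
        raise AssertionError("tiling invariant violated")

    def n_helices(self) -> int:
        return sum(1 for s in self.segments if s.label == "TMhelix")


def normalize_segments(
    segments: list[TopologySegment],
) -> tuple[TopologySegment, ...]:
    """Merge adjacent same-label segments (useful before validation)."""
    merged: list[TopologySegment] = []
    for seg in segments:
        if merged and merged[-1].label == seg.label and seg.start == merged[-1].end + 1:
            merged[-1] = TopologySegment(seg.label, merged[-1].start, seg.end)
        else:
            merged.append(seg)
    return tuple(merged)


def parse_tmhmm(path: str | Path, merge_same_label: bool = False) -> TopologyAnnotation:
    """Parse one protein's TMHMM long-format output.

    ``#`` comment lines of the form ``# <id> Key: value`` (e.g. ``Length``,
    ``Number of predicted TMHs``, ``Exp number of AAs in TMHs``) are kept as
    metadata. Segment lines must tile the sequence without gaps or overlaps.
    """
    path = Path(path)
    metadata: dict[str, str] = {}
    segments: list[TopologySegment] = []
    protein_id = None
    for line in path.read_text().splitlines():
        line = line.rstrip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ").strip()
            if ":" in body:
                head, value = body.split(":", 1)
                parts = head.split(None, 1)
                if len(parts) == 2:
                    metadata[parts[1].strip()] = value.strip()
            continue
        fields = line.split()
        if len(fields) != 5:
            raise TopologyFormatError(
                f"{path}: expected 5 whitespace-separated fields, got {line!r}"
            )
        rid, _method, label, start, end = fields
        if protein_id is None:
            protein_id = rid
        elif rid != protein_id:
            raise TopologyFormatError(
                f"{path}: multiple protein ids ({protein_id!r}, {rid!r})"
            )
        segments.append(TopologySegment(label, int(start), int(end)))
    if not segments:
        raise TopologyFormatError(f"{path}: no topology segments")
    if merge_same_label:
        segments = list(normalize_segments(segments))
    length = int(metadata.get("Length", segments[-1].end))
    return TopologyAnnotation(
        protein_id=protein_id, length=length,
        segments=tuple(segments), metadata=metadata,
    )


def write_tmhmm(annotation: TopologyAnnotation, path: str | Path) -> None:
    """Write an annotation in TMHMM long format (round-trips through
    :func:`parse_tmhmm`)."""
    rid = annotation.protein_id
    lines = [
        f"# {rid} Length: {annotation.length}",
        f"# {rid} Number of predicted TMHs: {annotation.n_helices()}",
    ]
    exp_aa = annotation.metadata.get("Exp number of AAs in TMHs")
    if exp_aa is not None:
        lines.append(f"# {rid} Exp number of AAs in TMHs: {exp_aa}")
    for seg in annotation.segments:
        lines.append(f"{rid}\tTMHMM2.0\t{seg.label}\t{seg.start}\t{seg.end}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class EpitopeTopologyCall:
    """An epitope's assigned membrane location.

    ``location`` is the majority label over the epitope's residues
    (tie-break TMhelix > inside > outside), reported in lowercase
    (``transmembrane`` for TMhelix). ``score`` is the mean posterior of the
    assigned label over the epitope when per-residue posteriors are present,
    else the fraction of epitope residues carrying that label.
    ``antigenic_flag`` follows the source study's convention that epitopes
    on the cytoplasmic (inside) face are the antigenic ones; it is a
    bookkeeping flag, not a biological assertion.
    """

    epitope: Epitope
    location: str
    score: float
    antigenic_flag: bool


def label_fractions(e: Epitope, t: TopologyAnnotation) -> dict[str, float]:
    """Fraction of the epitope's residues under each label (sums to 1)."""
    counts = {label: 0 for label in LABELS}
    for pos in range(e.start, e.end + 1):
        counts[t.label_at(pos)] += 1
    n = e.length
    return {label: counts[label] / n for label in LABELS}


def classify_epitope(e: Epitope, t: TopologyAnnotation) -> EpitopeTopologyCall:
    """Majority-label location call with a deterministic tie-break."""
    if e.start < 1 or e.end > t.length:
        raise IndexError(
            f"epitope {e.start}-{e.end} outside annotation 1..{t.length}"
        )
    fractions = label_fractions(e, t)
    best = max(TIE_BREAK, key=lambda lab: (fractions[lab], -TIE_BREAK.index(lab)))
    if t.posterior is not None:
        member = [
            t.posterior.get(pos, 0.0)
            for pos in range(e.start, e.end + 1)
            if t.label_at(pos) == best
        ]
        score = sum(member) / len(member) if member else 0.0
    else:
        score = fractions[best]
    location = "transmembrane" if best == "TMhelix" else best
    return EpitopeTopologyCall(
        epitope=e,
        location=location,
        score=score,
        antigenic_flag=(best == "inside"),
    )


def flag_signal_peptide(
    t: TopologyAnnotation, n_term_cutoff: int = 30
) -> tuple[bool, str]:
    """True iff a transmembrane helix starts at or before ``n_term_cutoff``.

    An N-terminal helix this early is more plausibly a signal peptide than
    a genuine membrane anchor; the reason string records the helix span.
    """
    for seg in t.segments:
        if seg.label == "TMhelix" and seg.start <= n_term_cutoff:
            return True, (
                f"TMhelix at {seg.start}-{seg.end} starts within the first "
                f"{n_term_cutoff} residues; possible signal peptide"
            )
    return False, f"no TMhelix starting within the first {n_term_cutoff} residues"
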