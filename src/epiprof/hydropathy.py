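"""Kyte-Doolittle moving-window hydropathy profiling.

The profile assigns to each window its mean scale value, attached to the
window's center residue; termini that cannot host a full window carry no
score. Windows are uniformly weighted. Contiguous stretches of centers above
a hydrophobicity threshold (default 1.8, the classic transmembrane cut)
are reported as hydrophobic segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import tables
from .seqio import ProteinRecord


@dataclass(frozen=True)
class HydropathyScale:
    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.values) != 20:
            raise ValueError(f"scale {self.name!r}: expected 20 residues")


def kyte_doolittle() -> HydropathyScale:
    return HydropathyScale("Kyte-Doolittle", tables.kd_scale())


@dataclass(frozen=True)
class HydropathyProfile:
    """Moving-average hydropathy scores attached to window centers.

    ``positions`` are 1-based center residues, running ceil(w/2) ...
    L - floor(w/2); ``protein_mean`` is the unwindowed mean over all
    residues (equals GRAVY for the Kyte-Doolittle scale).
    """

    window: int
    positions: tuple[int, ...]
    scores: tuple[float, ...]
    protein_mean: float
    scale_name: str = "Kyte-Doolittle"

    def as_frame(self, p: ProteinRecord | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"position": self.positions, "score": self.scores})
        if p is not None:
            df.insert(1, "residue", [p.sequence[i - 1] for i in self.positions])
        return df


def hydropathy_profile(
    p: ProteinRecord,
    scale: HydropathyScale | None = None,
    window: int = 9,
) -> HydropathyProfile:
    """Mean scale value per sliding window, at the window's center residue."""
    scale = scale or kyte_doolittle()
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if p.length < window:
        raise ValueError(
            f"sequence length {p.length} shorter than window {window}"
        )
    vals = np.array([scale.values[aa] for aa in p.sequence])
    kernel = np.full(window, 1.0 / window)
    scores = np.convolve(vals, kernel, mode="valid")
    half = window // 2
    positions = tuple(range(half + 1, p.length - half + 1))
    return HydropathyProfile(
        window=window,
        positions=positions,
        scores=tuple(float(s) for s in scores),
        protein_mean=float(vals.mean()),
        scale_name=scale.name,
    )


def hydrophobic_segments(
    profile: HydropathyProfile,
    threshold: float = 1.8,
    min_len: int = 1,
) -> list[tuple[int, int, float]]:
    """Maximal runs of consecutive centers with score > threshold.

    Returns ``(start, end, peak)`` with 1-based inclusive center-residue
    coordinates; runs shorter than ``min_len`` are dropped.
    """
    segments: list[tuple[int, int, float]] = []
    start = None
    peak = -np.inf
    prev = None
    for pos, score in zip(profile.positions, profile.scores):
        if score > threshold:
            if start is None:
                start, peak = pos, score
            else:
                peak = max(peak, score)
            prev = pos
        elif start is not None:
            if prev - start + 1 >= min_len:
                segments.append((start, prev, peak))
            start = None
    if start is not None and prev - start + 1 >= min_len:
        segments.append((start, prev, peak))
    return segments


def plot_profile(
    profile: HydropathyProfile,
    path: str,
    threshold: float = 1.8,
    title: str = "Hydropathy profile",
) -> None:
    """Line plot of the profile with a midpoint line at 0 and the
    hydrophobicity threshold marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3.2))
    ax.plot(profile.positions, profile.scores, lw=1)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.axhline(threshold, color="red", lw=0.8, ls="--")
    ax.set_xlabel("window center position")
    ax.set_ylabel(f"{profile.scale_name} score (w={profile.window})")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
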