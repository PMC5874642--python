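"""End-to-end analysis: sequence -> physicochemistry -> hydropathy ->
epitopes -> topology integration -> optional backbone QC.

The pipeline is a pure composition of the stage modules: its report equals
what the modules produce when invoked individually on the same inputs, and
its JSON serialization is byte-identical across runs at fixed parameters.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Optional

import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from . import antigenicity, hydropathy, physchem, structqc, topology
from .seqio import NucleotideRecord, ProteinRecord, read_fasta, translate_cds, validate_protein

logger = logging.getLogger("epiprof")

#: configurable options with defaults; load_config rejects anything else
DEFAULT_OPTIONS: dict[str, Any] = {
    "window": 9,               # hydropathy window (odd)
    "hydrophobic_threshold": 1.8,
    "ap_threshold": 1.0,
    "min_len": None,           # None -> the convention's default run length
    "rule": "flat",            # flat | conditional
    "convention": "described",  # described | server
    "translate": False,
    "chain": None,             # PDB chain for backbone QC
    "signal_cutoff": 30,
}


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML key-value config, validate keys and types, apply defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of option: value")
    options = dict(DEFAULT_OPTIONS)
    for key, value in raw.items():
        if key not in DEFAULT_OPTIONS:
            raise ConfigError(f"unknown config key {key!r}")
        default = DEFAULT_OPTIONS[key]
        if default is not None and value is not None and not isinstance(
            value, (type(default), int) if isinstance(default, float) else type(default)
        ):
            raise ConfigError(
                f"config key {key!r}: expected {type(default).__name__}, "
                f"got {type(value).__name__}"
            )
        options[key] = value
    if options["window"] % 2 == 0 or options["window"] < 1:
        raise ConfigError("window must be odd and >= 1")
    if options["rule"] not in ("flat", "conditional"):
        raise ConfigError(f"unknown rule {options['rule']!r}")
    if options["convention"] not in antigenicity.CONVENTIONS:
        raise ConfigError(f"unknown convention {options['convention']!r}")
    return options


class AnalysisReport(BaseModel):
    """Schema of the machine-readable report (validated on construction)."""

    model_config = ConfigDict(extra="forbid")

    input: dict[str, Any]
    parameters: dict[str, Any]
    physchem: dict[str, Any]
    hydropathy: dict[str, Any]
    antigenicity: dict[str, Any]
    topology: dict[str, Any]
    ramachandran: dict[str, Any]
    provenance: dict[str, Any]


def run_pipeline(
    fasta_path: str | Path,
    tmhmm_path: str | Path | None = None,
    pdb_path: str | Path | None = None,
    options: dict[str, Any] | None = None,
    seed: int | None = None,
) -> AnalysisReport:
    """Run every applicable stage on the first record of a FASTA file.

    Optional inputs switch stages on: a topology file adds per-epitope
    location calls, a PDB file adds Ramachandran QC. Stages without input
    are recorded as skipped. Any stage error propagates with the stage named.
    """
    opts = dict(DEFAULT_OPTIONS)
    opts.update(options or {})

    records = read_fasta(fasta_path)
    rid, desc, raw_seq = records[0]
    if len(records) > 1:
        logger.info("using first of %d records (%s)", len(records), rid)

    translated = bool(opts["translate"])
    if translated:
        nt = NucleotideRecord(rid, desc, raw_seq)
        protein = translate_cds(nt)
    else:
        protein = validate_protein(raw_seq, id=rid, description=desc)

    # physicochemistry
    phys = physchem.profile(protein)

    # hydropathy
    hyd = hydropathy.hydropathy_profile(protein, window=int(opts["window"]))
    segments = hydropathy.hydrophobic_segments(
        hyd, threshold=float(opts["hydrophobic_threshold"])
    )

    # antigenicity
    ap_profile, epitopes = antigenicity.predict_epitopes(
        protein,
        convention=opts["convention"],
        min_len=opts["min_len"],
        rule=opts["rule"],
    )

    # topology integration
    calls = None
    if tmhmm_path is not None:
        annotation = topology.parse_tmhmm(tmhmm_path)
        calls = [topology.classify_epitope(e, annotation) for e in epitopes]
        sp_flag, sp_reason = topology.flag_signal_peptide(
            annotation, n_term_cutoff=int(opts["signal_cutoff"])
        )
        topo_block = {
            "skipped": False,
            "protein_id": annotation.protein_id,
            "length": annotation.length,
            "n_helices": annotation.n_helices(),
            "segments": [
                {"label": s.label, "start": s.start, "end": s.end}
                for s in annotation.segments
            ],
            "signal_peptide": {"flag": sp_flag, "reason": sp_reason},
        }
    else:
        topo_block = {"skipped": True}

    # backbone QC
    if pdb_path is not None:
        chain = structqc.read_pdb_backbone(pdb_path, chain_id=opts["chain"])
        dihedrals = structqc.phi_psi(chain)
        summary = structqc.rama_summary(dihedrals)
        rama_block = {"skipped": False, **summary.display()}
    else:
        rama_block = {"skipped": True}

    table = antigenicity.epitope_table(epitopes, calls)
    parameters = {k: opts[k] for k in sorted(DEFAULT_OPTIONS)}
    report = AnalysisReport(
        input={
            "path": str(fasta_path),
            "id": protein.id,
            "description": protein.description,
            "length": protein.length,
            "translated_from_cds": translated,
        },
        parameters=parameters,
        physchem=physchem.profile_as_display(phys),
        hydropathy={
            "window": hyd.window,
            "n_scores": len(hyd.scores),
            "protein_mean": round(hyd.protein_mean, 3),
            "min_score": round(min(hyd.scores), 3),
            "max_score": round(max(hyd.scores), 3),
            "hydrophobic_segments": [
                {"start": s, "end": e, "peak": round(p, 3)}
                for s, e, p in segments
            ],
        },
        antigenicity={
            "overall_propensity": round(ap_profile.overall_propensity, 4),
            "mean_window_ap": round(ap_profile.mean_ap, 4),
            "anchor": ap_profile.anchor,
            "n_epitopes": len(epitopes),
            "epitopes": table.to_dict(orient="records"),
        },
        topology=topo_block,
        ramachandran=rama_block,
        provenance={
            "tool": "epiprof",
            "version": __version__,
            "seed": seed,
        },
    )
    return report


def report_json(report: AnalysisReport) -> str:
    """Canonical JSON serialization (sorted keys, stable float repr)."""
    return json.dumps(report.model_dump(), sort_keys=True, indent=2)


def save_report(
    report: AnalysisReport,
    outdir: str | Path,
    protein: ProteinRecord | None = None,
    formats: tuple[str, ...] = ("json", "tsv"),
) -> list[Path]:
    """Write report.json and per-stage TSVs into a directory."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if "json" in formats:
        p = outdir / "report.json"
        p.write_text(report_json(report) + "\n")
        written.append(p)
    if "tsv" in formats:
        p = outdir / "epitopes.tsv"
        pd.DataFrame(report.antigenicity["epitopes"]).to_csv(
            p, sep="\t", index=False
        )
        written.append(p)
    return written
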