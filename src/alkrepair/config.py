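"""Run configuration: JSON parsing, validation, and FASTA input.

A :class:`RunConfig` is validated against every module's preconditions
before any sampling happens; unknown keys are rejected with their field
path so typos fail loudly rather than silently using defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import SeqIO

from .lesions import (
    AdductSpectrum,
    DoseCalibration,
    DEFAULT_CALIBRATION,
    BUILTIN_PLASMIDS,
    PlasmidSpec,
    spectrum_for_agent,
)
from .repair import RepairParams


class ConfigError(ValueError):
    """Invalid run configuration; message carries the offending field path."""


def load_plasmid_fasta(path, circular: bool = True, name: Optional[str] = None) -> PlasmidSpec:
    """Read a single-record FASTA into a :class:`PlasmidSpec`.

    Rejects multi-record files, empty sequences and non-IUPAC characters.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ConfigError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise ConfigError(f"{path}: expected a single record, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq:
        raise ConfigError(f"{path}: empty sequence")
    try:
        return PlasmidSpec(
            name=name or rec.id,
            length_bp=len(seq),
            circular=circular,
            sequence=seq,
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _reject_unknown(d: dict, allowed: set, path: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")


def _parse_plasmid(d, path: str) -> PlasmidSpec:
    if isinstance(d, str):
        if d in BUILTIN_PLASMIDS:
            return BUILTIN_PLASMIDS[d]
        raise ConfigError(
            f"{path}: unknown plasmid {d!r}; registered: {sorted(BUILTIN_PLASMIDS)}"
        )
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: expected name or object")
    _reject_unknown(d, {"name", "length_bp", "circular", "fasta", "sequence"}, path)
    if "fasta" in d:
        return load_plasmid_fasta(
            d["fasta"], circular=d.get("circular", True), name=d.get("name")
        )
    try:
        return PlasmidSpec(
            name=d.get("name", "custom"),
            length_bp=int(d["length_bp"]),
            circular=bool(d.get("circular", True)),
            sequence=d.get("sequence"),
        )
    except KeyError as exc:
        raise ConfigError(f"{path}.length_bp: required") from exc
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


_SPECTRUM_KEYS = {"agent", "frac_7mg", "frac_3ma", "frac_o6mg", "frac_other"}


def _parse_spectrum(d, path: str) -> AdductSpectrum:
    if isinstance(d, str):
        try:
            return spectrum_for_agent(d)
        except KeyError as exc:
            raise ConfigError(f"{path}: {exc.args[0]}") from exc
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: expected agent name or object")
    _reject_unknown(d, _SPECTRUM_KEYS, path)
    try:
        return AdductSpectrum(
            agent=d.get("agent", "custom"),
            frac_7mg=float(d["frac_7mg"]),
            frac_3ma=float(d["frac_3ma"]),
            frac_o6mg=float(d["frac_o6mg"]),
            frac_other=float(d["frac_other"]),
        )
    except KeyError as exc:
        raise ConfigError(f"{path}.{exc.args[0]}: required") from exc
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


_PARAM_KEYS = {f.name for f in dataclasses.fields(RepairParams)}


def _parse_params(d, path: str) -> RepairParams:
    if d is None:
        return RepairParams()
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: expected object of RepairParams overrides")
    _reject_unknown(d, _PARAM_KEYS, path)
    try:
        return RepairParams(**d)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


_TOP_KEYS = {
    "plasmid",
    "agent",
    "spectrum",
    "doses_mM",
    "densities",
    "calibration",
    "repair_params",
    "n_molecules",
    "seed",
    "out_dir",
    "target_linear_fraction",
    "genome",
}

_GENOME_KEYS = {
    "n_oalkyl",
    "n_nalkyl",
    "genome_nt_for_density",
    "genome_bp_for_scaling",
    "window_nt",
    "linear_fraction",
    "plasmid_bp",
    "dose_ref_mM",
    "dose_clinical_mM",
}


@dataclass(frozen=True)
class RunConfig:
    plasmid: PlasmidSpec = BUILTIN_PLASMIDS["pBR322"]
    spectrum: AdductSpectrum = field(default_factory=lambda: spectrum_for_agent("MNU"))
    doses_mM: tuple = ()
    densities: tuple = ()
    calibration: DoseCalibration = DEFAULT_CALIBRATION
    repair_params: RepairParams = field(default_factory=RepairParams)
    n_molecules: int = 10000
    seed: int = 0
    out_dir: str = "."
    target_linear_fraction: Optional[float] = None
    genome: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ConfigError("n_molecules: must be >= 1")
        for i, d in enumerate(self.doses_mM):
            if d < 0:
                raise ConfigError(f"doses_mM[{i}]: must be non-negative")
        for i, d in enumerate(self.densities):
            if not 0.0 <= d <= 0.5:
                raise ConfigError(f"densities[{i}]: must be in [0, 0.5]")
        if self.target_linear_fraction is not None and not (
            0.0 <= self.target_linear_fraction < 1.0
        ):
            raise ConfigError("target_linear_fraction: must be in [0, 1)")


def parse_config(obj: dict) -> RunConfig:
    """Build a validated :class:`RunConfig` from a JSON-decoded dict."""
    if not isinstance(obj, dict):
        raise ConfigError("config root: expected a JSON object")
    _reject_unknown(obj, _TOP_KEYS, "config")
    if "agent" in obj and "spectrum" in obj:
        raise ConfigError("config: give either 'agent' or 'spectrum', not both")
    spectrum = spectrum_for_agent("MNU")
    if "agent" in obj:
        spectrum = _parse_spectrum(obj["agent"], "config.agent")
    elif "spectrum" in obj:
        spectrum = _parse_spectrum(obj["spectrum"], "config.spectrum")
    plasmid = BUILTIN_PLASMIDS["pBR322"]
    if "plasmid" in obj:
        plasmid = _parse_plasmid(obj["plasmid"], "config.plasmid")
    cal = DEFAULT_CALIBRATION
    if "calibration" in obj:
        c = obj["calibration"]
        if not isinstance(c, dict):
            raise ConfigError("config.calibration: expected object")
        _reject_unknown(c, {"density_per_mM"}, "config.calibration")
        try:
            cal = DoseCalibration(float(c["density_per_mM"]))
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"config.calibration: {exc}") from exc
    genome = obj.get("genome", {})
    if genome:
        _reject_unknown(genome, _GENOME_KEYS, "config.genome")
    return RunConfig(
        plasmid=plasmid,
        spectrum=spectrum,
        doses_mM=tuple(obj.get("doses_mM", ())),
        densities=tuple(obj.get("densities", ())),
        calibration=cal,
        repair_params=_parse_params(obj.get("repair_params"), "config.repair_params"),
        n_molecules=int(obj.get("n_molecules", 10000)),
        seed=int(obj.get("seed", 0)),
        out_dir=str(obj.get("out_dir", ".")),
        target_linear_fraction=obj.get("target_linear_fraction"),
        genome=dict(genome),
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: invalid JSON ({exc})") from exc
    return parse_config(obj)


def config_manifest(config: RunConfig, seed: int, extra: Optional[dict] = None) -> dict:
    """JSON-serializable echo of a run, sufficient to reproduce it."""
    from . import __version__

    manifest = {
        "package": "alkrepair",
        "version": __version__,
        "seed": seed,
        "plasmid": {
            "name": config.plasmid.name,
            "length_bp": config.plasmid.length_bp,
            "circular": config.plasmid.circular,
            "has_sequence": config.plasmid.sequence is not None,
        },
        "spectrum": dataclasses.asdict(config.spectrum),
        "calibration": {"density_per_mM": config.calibration.density_per_mM},
        "repair_params": dataclasses.asdict(config.repair_params),
        "doses_mM": list(config.doses_mM),
        "densities": list(config.densities),
        "n_molecules": config.n_molecules,
    }
    if extra:
        manifest.update(extra)
    return manifest
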