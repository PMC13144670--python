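"""Run configuration and provenance plumbing for the command-line pipeline.

A :class:`RunConfig` is a fully serializable description of one run;
every CLI stage writes a ``manifest.json`` next to its outputs recording
input/output hashes, the effective configuration, the package version
and the seed, so that runs chain by hash and reproduce byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .cohort_builder import FilterConfig
from .synthetic_registry import PhenotypeSpec, SimulationParams

__all__ = ["RunConfig", "load_config", "sha256_file", "write_manifest",
           "simulation_params_from_dict"]


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    persons: str = ""
    diagnoses: str = ""
    icd8_map: str = ""
    icd10_map: str = ""
    cohort: str = "1955"
    design: str = "twin"
    registry_start: str = "1977-01-01"
    study_end: str = "2021-12-31"
    n_boot: int = 500
    seed: int = 0
    outdir: str = "heritmap_out"
    filters: FilterConfig = field(default_factory=FilterConfig)
    simulation: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


def simulation_params_from_dict(d: dict[str, Any]) -> SimulationParams:
    """Build SimulationParams from a plain config mapping."""
    d = dict(d)
    phen = [PhenotypeSpec(**p) for p in d.pop("phenotypes")]
    if "birth_year_range" in d:
        d["birth_year_range"] = tuple(d["birth_year_range"])
    return SimulationParams(phenotypes=phen, **d)


def load_config(path: str | Path, overrides: dict[str, Any] | None = None) -> RunConfig:
    """Load a YAML config; file values win over ``overrides`` with a logged diff."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    filters = FilterConfig(**data.pop("filters", {}))
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    merged = dict(overrides or {})
    for key, value in data.items():
        if key in merged and merged[key] != value:
            print(f"config file overrides --{key.replace('_', '-')}: "
                  f"{merged[key]!r} -> {value!r}", file=sys.stderr)
        merged[key] = value
    merged.pop("filters", None)
    return RunConfig(filters=filters, **merged)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str | Path, stage: str, *,
                   inputs: dict[str, str | Path],
                   outputs: dict[str, str | Path],
                   config: dict[str, Any], seed: int | None = None) -> Path:
    """Write ``manifest.json`` with input/output hashes for provenance chaining."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {name: {"path": str(p), "sha256": sha256_file(p)}
                   for name, p in inputs.items()},
        "outputs": {name: {"path": str(p), "sha256": sha256_file(p)}
                    for name, p in outputs.items()},
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
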