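"""Run configuration: YAML file + CLI flag merging and run manifests.

Precedence is flags > config file > built-in defaults. Unknown keys in a
config file are rejected so typos fail loudly. Every CLI run writes a
manifest (inputs, parameters, package version, seed) beside its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .design import DesignParams
from .simulate import SimulationConfig

logger = logging.getLogger("pemave")


@dataclass
class RunConfig:
    """Merged parameter set driving any pipeline stage."""

    design: DesignParams = field(default_factory=DesignParams)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    k: int = 25
    af_threshold: float = 0.001
    af_filter_mode: str = "any_replicate"
    min_reads: int = 200_000
    strategy: str = "vus"
    replicates: int = 3
    seed: int = 0
    log_level: str = "INFO"

    TOP_KEYS = (
        "k",
        "af_threshold",
        "af_filter_mode",
        "min_reads",
        "strategy",
        "replicates",
        "seed",
        "log_level",
    )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = cls()
        design_keys = {f.name for f in dataclasses.fields(DesignParams)}
        sim_keys = {f.name for f in dataclasses.fields(SimulationConfig)}
        design_over, sim_over = {}, {}
        for key, value in raw.items():
            if key == "design":
                unknown = set(value) - design_keys
                if unknown:
                    raise ValueError(f"unknown design key(s): {sorted(unknown)}")
                design_over = dict(value)
            elif key == "sim":
                unknown = set(value) - sim_keys
                if unknown:
                    raise ValueError(f"unknown sim key(s): {sorted(unknown)}")
                sim_over = dict(value)
            elif key in cls.TOP_KEYS:
                setattr(cfg, key, value)
            else:
                raise ValueError(f"unknown config key: {key!r}")
        if design_over:
            if "ngrna_offset_range" in design_over:
                design_over["ngrna_offset_range"] = tuple(
                    design_over["ngrna_offset_range"]
                )
            cfg.design = dataclasses.replace(cfg.design, **design_over)
        if sim_over:
            cfg.sim = dataclasses.replace(cfg.sim, **sim_over)
        return cfg

    def apply_flags(self, **flags) -> "RunConfig":
        """Override top-level fields from non-None CLI flags."""
        for key, value in flags.items():
            if value is None:
                continue
            if key not in self.TOP_KEYS:
                raise ValueError(f"unknown flag {key!r}")
            setattr(self, key, value)
        # seed and replicates propagate into the simulation config
        self.sim = dataclasses.replace(
            self.sim, seed=self.seed, replicates=self.replicates
        )
        return self


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )


def write_manifest(outdir, command: str, inputs: dict, params: dict) -> Path:
    """Write a machine-readable record of a run beside its outputs."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "pemave",
        "version": __version__,
        "command": command,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "parameters": params,
    }
    path = outdir / f"manifest_{command}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
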