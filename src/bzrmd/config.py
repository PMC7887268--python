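"""Pipeline configuration: a sectioned key=value plain-text dialect.

Parsed with :mod:`configparser`. Each analysis stage is a section; unknown
sections or keys are rejected with explicit messages so silent typos cannot
change an analysis. Referenced input paths must exist at parse time.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["AnalysisConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Raised for unknown keys/sections, bad values or missing paths."""


_SCHEMA: dict[str, set[str]] = {
    "general": {"output_dir", "seed", "log_level"},
    "rmsd": {"trajectory", "reference", "fit_selection", "measure_selections"},
    "tilt": {"structure", "trajectory", "helix_a", "helix_b"},
    "occupancy": {"trajectory", "pairs", "max_distance", "run_label"},
    "contacts": {"structure", "cargo_chains", "chaperone_chains",
                 "hbond_distance", "salt_bridge_distance", "vdw_tolerance"},
    "ddg": {"complex_samples", "dna_samples", "estimator", "n_states"},
}

_PATH_KEYS = {"trajectory", "reference", "structure", "complex_samples", "dna_samples"}


@dataclass
class AnalysisConfig:
    """Validated stage settings; only sections present in the file are run."""

    stages: dict[str, dict[str, str]]
    output_dir: Path = Path("bzrmd_out")
    seed: int = 0
    log_level: str = "INFO"
    source_path: Path | None = None

    @property
    def stage_names(self) -> list[str]:
        return [s for s in self.stages if s != "general"]


def load_config(path: str | Path) -> AnalysisConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    parser = configparser.ConfigParser()
    try:
        parser.read(path)
    except configparser.Error as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    stages: dict[str, dict[str, str]] = {}
    for section in parser.sections():
        if section not in _SCHEMA:
            raise ConfigError(
                f"{path}: unknown section [{section}]; known: {sorted(_SCHEMA)}"
            )
        allowed = _SCHEMA[section]
        values = dict(parser.items(section))
        unknown = set(values) - allowed
        if unknown:
            raise ConfigError(
                f"{path}: unknown key(s) {sorted(unknown)} in [{section}]; "
                f"allowed: {sorted(allowed)}"
            )
        for key in set(values) & _PATH_KEYS:
            p = Path(values[key])
            if not p.is_absolute():
                p = path.parent / p
            if not p.exists():
                raise ConfigError(f"{path}: [{section}] {key} = {values[key]}: path does not exist")
            values[key] = str(p)
        stages[section] = values
    general = stages.get("general", {})
    try:
        seed = int(general.get("seed", "0"))
    except ValueError as exc:
        raise ConfigError(f"{path}: seed must be an integer") from exc
    out_dir = Path(general.get("output_dir", "bzrmd_out"))
    if not out_dir.is_absolute():
        out_dir = path.parent / out_dir
    return AnalysisConfig(
        stages=stages,
        output_dir=out_dir,
        seed=seed,
        log_level=general.get("log_level", "INFO"),
        source_path=path,
    )
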