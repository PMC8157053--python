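"""Run configuration: a single YAML file drives simulate/fit/summarize.

Unknown keys anywhere in the file are rejected, so typos fail fast instead
of silently running with defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .gibbs import ChainConfig
from .phenotypes import TraitDefinition

__all__ = ["RunConfig", "load_config"]


class ConfigError(ValueError):
    pass


_TOP_KEYS = {
    "pedigree_file", "phenotype_file", "output_dir", "traits", "chain",
    "prior", "missing_tokens", "unknown_parent_tokens", "animal_column",
    "report_decimals", "seed",
}
_TRAIT_KEYS = {"name", "factors", "covariates", "units"}
_CHAIN_KEYS = {"total_iterations", "burn_in", "thin", "seed",
               "store_location_effects"}
_PRIOR_KEYS = {"nu0_G", "nu0_R", "S0_G", "S0_R"}


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}"
        )


@dataclass
class RunConfig:
    """Validated configuration for a fit run."""

    pedigree_file: Path
    phenotype_file: Path
    output_dir: Path
    traits: tuple[TraitDefinition, ...]
    chain: ChainConfig
    missing_tokens: tuple[str, ...] = ("", "NA")
    unknown_parent_tokens: tuple[str, ...] = ("", "0", "NA")
    animal_column: str = "animal"
    report_decimals: int = 2


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(raw, _TOP_KEYS, str(path))
    for req in ("pedigree_file", "phenotype_file", "output_dir", "traits"):
        if req not in raw:
            raise ConfigError(f"{path}: missing required key {req!r}")

    traits = []
    for i, t in enumerate(raw["traits"]):
        if not isinstance(t, dict):
            raise ConfigError(f"traits[{i}] must be a mapping")
        _check_keys(t, _TRAIT_KEYS, f"traits[{i}]")
        if "name" not in t:
            raise ConfigError(f"traits[{i}]: missing 'name'")
        traits.append(
            TraitDefinition(
                name=str(t["name"]),
                factors=tuple(t.get("factors", ())),
                covariates=tuple(t.get("covariates", ())),
                units=str(t.get("units", "")),
            )
        )

    chain_raw = dict(raw.get("chain", {}))
    _check_keys(chain_raw, _CHAIN_KEYS, "chain")
    prior_raw = dict(raw.get("prior", {}))
    _check_keys(prior_raw, _PRIOR_KEYS, "prior")
    for key in ("S0_G", "S0_R"):
        if prior_raw.get(key) is not None:
            prior_raw[key] = np.asarray(prior_raw[key], dtype=float)
    if "seed" in raw and "seed" not in chain_raw:
        chain_raw["seed"] = int(raw["seed"])
    chain = ChainConfig(**chain_raw, **prior_raw)

    base = path.parent
    return RunConfig(
        pedigree_file=(base / raw["pedigree_file"]).resolve(),
        phenotype_file=(base / raw["phenotype_file"]).resolve(),
        output_dir=(base / raw["output_dir"]).resolve(),
        traits=tuple(traits),
        chain=chain,
        missing_tokens=tuple(raw.get("missing_tokens", ("", "NA"))),
        unknown_parent_tokens=tuple(raw.get("unknown_parent_tokens", ("", "0", "NA"))),
        animal_column=str(raw.get("animal_column", "animal")),
        report_decimals=int(raw.get("report_decimals", 2)),
    )
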