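"""Analysis configuration: YAML schema, validation and normalization.

Validation collects *every* problem instead of failing on the first one;
unknown keys produce warnings (forward compatibility), not errors.  The
minimum-interaction-strength cutoff ``i_min`` has no default on purpose —
it shapes the network qualitatively and must be an explicit choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .topology import SelectionSpec

PARAMETER_DEFAULTS: dict[str, float | int] = {
    "cluster_cutoff": 1.8,          # Å, gromos RMSD threshold
    "correlation_threshold": 0.6,   # |C_ij| classification bound
    "sasa_probe": 1.4,              # Å, water probe
    "sasa_points": 960,
    "sasa_stride": 1,
    "contact_cutoff": 4.0,          # Å, residue contact definition
    "psn_cutoff": 4.5,              # Å, side-chain contact for the network
    "hub_min_degree": 3,
}

_PARAMETER_RANGES: dict[str, tuple[float, float]] = {
    "cluster_cutoff": (0.0, 100.0),
    "correlation_threshold": (0.0, 1.0),
    "sasa_probe": (0.0, 10.0),
    "sasa_points": (100, 100000),
    "sasa_stride": (1, 10**9),
    "contact_cutoff": (0.0, 100.0),
    "psn_cutoff": (0.0, 100.0),
    "i_min": (0.0, 10000.0),
    "hub_min_degree": (0, 10**6),
}

_KNOWN_TOP_KEYS = {"systems", "topology", "trajectories", "selections", "regions",
                   "parameters", "output_dir", "seed"}
_KNOWN_SELECTION_KEYS = {"fit", "rmsd", "cluster", "patch_group"}


@dataclass
class SystemInput:
    name: str
    topology: Path
    trajectories: list[Path]


@dataclass
class AnalysisConfig:
    systems: list[SystemInput]
    selections: dict[str, list[SelectionSpec]]
    regions: dict[str, tuple[int, int]]
    parameters: dict[str, float]
    output_dir: Path
    seed: int = 0
    warnings: list[str] = field(default_factory=list)


class ConfigError(ValueError):
    """Carries the full list of validation problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


def _parse_selection(raw, label: str, errors: list[str]) -> list[SelectionSpec]:
    items = raw if isinstance(raw, list) else [raw]
    specs: list[SelectionSpec] = []
    for item in items:
        if not isinstance(item, dict):
            errors.append(f"selection {label!r}: expected a mapping, got {type(item).__name__}")
            continue
        try:
            specs.append(SelectionSpec(
                ranges=[tuple(r) for r in item.get("ranges", [])],
                atom_class=item.get("atom_class", "all"),
                names=item.get("names"),
            ))
        except (ValueError, TypeError) as exc:
            errors.append(f"selection {label!r}: {exc}")
    return specs


def validate_config(path, check_paths: bool = True) -> AnalysisConfig:
    """Parse and validate a YAML config; raise :class:`ConfigError` with the
    complete error list if anything is wrong."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError([f"YAML parse error in {path}: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError([f"{path}: top level must be a mapping"])

    errors: list[str] = []
    warnings = [f"unknown key {k!r} ignored" for k in raw if k not in _KNOWN_TOP_KEYS]

    # systems (multi) or topology/trajectories (single)
    systems: list[SystemInput] = []
    if "systems" in raw:
        for k, sysraw in enumerate(raw["systems"] or []):
            name = str(sysraw.get("name", f"system{k}"))
            topo = sysraw.get("topology")
            trajs = sysraw.get("trajectories", [])
            if not topo:
                errors.append(f"system {name!r}: missing topology")
            if not trajs:
                errors.append(f"system {name!r}: missing trajectories")
            if topo and trajs:
                systems.append(SystemInput(name, Path(topo), [Path(t) for t in trajs]))
    elif "topology" in raw:
        if not raw.get("trajectories"):
            errors.append("missing trajectories")
        else:
            systems.append(SystemInput("system", Path(raw["topology"]),
                                       [Path(t) for t in raw["trajectories"]]))
    else:
        errors.append("config needs either 'systems' or 'topology'+'trajectories'")

    if check_paths:
        for s in systems:
            for p in [s.topology, *s.trajectories]:
                if not p.exists():
                    errors.append(f"system {s.name!r}: input file not found: {p}")

    selections: dict[str, list[SelectionSpec]] = {}
    rawsel = raw.get("selections", {}) or {}
    for k in rawsel:
        if k not in _KNOWN_SELECTION_KEYS:
            warnings.append(f"unknown selection {k!r} ignored")
    for key in _KNOWN_SELECTION_KEYS:
        if key in rawsel:
            selections[key] = _parse_selection(rawsel[key], key, errors)
    selections.setdefault("fit", [SelectionSpec(atom_class="CA")])
    selections.setdefault("rmsd", [SelectionSpec(atom_class="CA")])
    selections.setdefault("cluster", [SelectionSpec(atom_class="CA")])

    regions: dict[str, tuple[int, int]] = {}
    for name, span in (raw.get("regions", {}) or {}).items():
        try:
            a, b = int(span[0]), int(span[1])
            if b < a:
                errors.append(f"region {name!r}: stop < start")
            regions[str(name)] = (a, b)
        except (TypeError, ValueError, IndexError):
            errors.append(f"region {name!r}: expected [start, stop]")

    params: dict[str, float] = dict(PARAMETER_DEFAULTS)
    rawpar = raw.get("parameters", {}) or {}
    for k, v in rawpar.items():
        if k not in _PARAMETER_RANGES:
            warnings.append(f"unknown parameter {k!r} ignored")
            continue
        try:
            params[k] = float(v)
        except (TypeError, ValueError):
            errors.append(f"parameter {k}: not a number ({v!r})")
            continue
        lo, hi = _PARAMETER_RANGES[k]
        if not (lo <= params[k] <= hi):
            errors.append(f"parameter {k}={v} outside range [{lo}, {hi}]")
    if "i_min" not in rawpar:
        errors.append("parameter i_min is required (the network cutoff has no "
                      "defensible default; choose it explicitly)")

    if errors:
        raise ConfigError(errors)
    return AnalysisConfig(
        systems=systems,
        selections=selections,
        regions=regions,
        parameters=params,
        output_dir=Path(raw.get("output_dir", "allodyn_out")),
        seed=int(raw.get("seed", 0)),
        warnings=warnings,
    )
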