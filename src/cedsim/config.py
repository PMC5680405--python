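"""Run configuration: YAML with explicit unit-bearing keys.

A run file names the molecule(s), tissue, infusion protocol and solver
controls. Keys carry their units (``rate_ul_per_min``, not ``rate``) so a
file cannot be silently misread; unknown keys are rejected rather than
ignored.

Example::

    molecule: r-metHuGDNF        # preset, or an inline mapping (below)
    tracer: Gd-DTPA
    tissue:
      porosity: 0.3
      elimination_rate_per_h: 0.0372
      vd_vi_ratio: 3.87
    protocol:
      rate_ul_per_min: 5.0
      infusion_volume_ml: 0.105
      source_radius_cm: 0.2
    solver:
      n_cells: 1200
      r_max_cm: 3.0
      inner_bc: flux
    rates_ul_per_min: [0.1, 1.0, 3.0, 5.0]
    projected_vd_ml: 0.5
    observation_times_h: [0.0, 2.0]
    vd_threshold: 0.1
    seed: 0

An inline molecule mapping uses the keys ``name``,
``molecular_weight_da``, ``d_free_cm2_per_s`` and ``tortuosity``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .solver import InfusionProtocol, SolverSettings, TissueModel
from .transport import Molecule, get_molecule

__all__ = ["RunConfig", "load_config", "config_echo"]

_TISSUE_KEYS = {"porosity", "elimination_rate_per_h", "vd_vi_ratio"}
_PROTOCOL_KEYS = {
    "rate_ul_per_min",
    "infusion_volume_ml",
    "source_radius_cm",
    "infusate_concentration",
    "catheter_tip_radius_cm",
}
_SOLVER_KEYS = {
    "n_cells",
    "r_max_cm",
    "cfl",
    "scheme",
    "inner_bc",
    "source_strength",
    "refine",
}
_MOLECULE_KEYS = {"name", "molecular_weight_da", "d_free_cm2_per_s", "tortuosity"}
_TOP_KEYS = {
    "molecule",
    "tracer",
    "tissue",
    "protocol",
    "solver",
    "rates_ul_per_min",
    "projected_vd_ml",
    "observation_times_h",
    "vd_threshold",
    "seed",
    "output_dir",
}


@dataclass
class RunConfig:
    """Fully resolved configuration for one run."""

    molecule: Molecule
    tissue: TissueModel = field(default_factory=TissueModel)
    protocol: InfusionProtocol = field(
        default_factory=lambda: InfusionProtocol(rate=5.0, infusion_volume=0.105)
    )
    solver: SolverSettings = field(default_factory=SolverSettings)
    tracer: Molecule | None = None
    rates_ul_per_min: tuple[float, ...] = (0.1, 1.0, 3.0, 5.0)
    projected_vd_ml: float = 0.5
    observation_times_h: tuple[float, ...] = (0.0, 2.0)
    vd_threshold: float = 0.1
    seed: int = 0
    output_dir: str = "runs/run"


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}"
        )


def _parse_molecule(spec) -> Molecule:
    if isinstance(spec, str):
        return get_molecule(spec)
    if isinstance(spec, dict):
        _check_keys(spec, _MOLECULE_KEYS, "molecule")
        try:
            return Molecule(
                name=spec["name"],
                molecular_weight=spec["molecular_weight_da"],
                d_free=spec["d_free_cm2_per_s"],
                tortuosity=spec["tortuosity"],
            )
        except KeyError as exc:
            raise ConfigError(f"molecule mapping missing key {exc}") from None
    raise ConfigError(f"molecule must be a preset name or mapping, got {type(spec)}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run file into a :class:`RunConfig`."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw)}")
    _check_keys(raw, _TOP_KEYS, "config")
    if "molecule" not in raw:
        raise ConfigError("config must name a molecule")
    molecule = _parse_molecule(raw["molecule"])
    tracer = _parse_molecule(raw["tracer"]) if "tracer" in raw else None

    tissue_raw = raw.get("tissue", {})
    _check_keys(tissue_raw, _TISSUE_KEYS, "tissue")
    tissue = TissueModel(
        porosity=tissue_raw.get("porosity", 0.3),
        elimination_rate=tissue_raw.get("elimination_rate_per_h", 3.72e-2),
        vd_vi_ratio=tissue_raw.get("vd_vi_ratio", 3.87),
    )

    proto_raw = raw.get("protocol", {})
    _check_keys(proto_raw, _PROTOCOL_KEYS, "protocol")
    protocol = InfusionProtocol(
        rate=proto_raw.get("rate_ul_per_min", 5.0),
        infusion_volume=proto_raw.get("infusion_volume_ml", 0.105),
        source_radius=proto_raw.get("source_radius_cm", 0.2),
        infusate_concentration=proto_raw.get("infusate_concentration", 1.0),
        catheter_tip_radius=proto_raw.get("catheter_tip_radius_cm", 0.03),
    )

    solver_raw = raw.get("solver", {})
    _check_keys(solver_raw, _SOLVER_KEYS, "solver")
    solver = SolverSettings(
        n_cells=solver_raw.get("n_cells", 1200),
        r_max=solver_raw.get("r_max_cm", 3.0),
        cfl=solver_raw.get("cfl", 0.4),
        scheme=solver_raw.get("scheme", "vanleer"),
        inner_bc=solver_raw.get("inner_bc", "flux"),
        source_strength=solver_raw.get("source_strength", 1.0),
        refine=solver_raw.get("refine", 1.0),
    )

    return RunConfig(
        molecule=molecule,
        tracer=tracer,
        tissue=tissue,
        protocol=protocol,
        solver=solver,
        rates_ul_per_min=tuple(raw.get("rates_ul_per_min", (0.1, 1.0, 3.0, 5.0))),
        projected_vd_ml=raw.get("projected_vd_ml", 0.5),
        observation_times_h=tuple(raw.get("observation_times_h", (0.0, 2.0))),
        vd_threshold=raw.get("vd_threshold", 0.1),
        seed=int(raw.get("seed", 0)),
        output_dir=raw.get("output_dir", "runs/run"),
    )


def config_echo(config: RunConfig) -> dict:
    """JSON-serialisable echo of every parameter needed to reproduce a run."""

    def as_dict(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: as_dict(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [as_dict(v) for v in obj]
        return obj

    return as_dict(config)


def write_config_echo(config: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(config_echo(config), indent=2, sort_keys=True) + "\n")
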