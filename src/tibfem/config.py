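"""Run configuration: one YAML file with model / solver / validate sections."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import EquilibriumSettings

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class RunConfig:
    """Paths and settings tying one simulation/validation run together.

    All paths are resolved relative to the YAML file's directory; referenced
    files must exist at load time.  The seed is recorded in every output
    header so runs are reproducible byte-for-byte in quasi-static mode.
    """

    femur_bone: Path
    femur_cartilage: Path
    tibia_bone: Path
    tibia_cartilage: Path
    landmarks: Path
    ligaments: Path
    parameters: Path | None = None
    cycles: Path | None = None
    solver: EquilibriumSettings = field(default_factory=EquilibriumSettings)
    flexion_ranges: tuple = ((7.0, 90.0), (7.0, 112.0))
    output_dir: Path = Path("out")
    seed: int = 0
    log_level: str = "INFO"
    raw: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for name in ("femur_bone", "femur_cartilage", "tibia_bone",
                     "tibia_cartilage", "landmarks", "ligaments"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"config field {name!r}: {p} does not exist")
            setattr(self, name, p)
        for name in ("parameters", "cycles"):
            p = getattr(self, name)
            if p is not None:
                p = Path(p)
                if not p.exists():
                    raise FileNotFoundError(f"config field {name!r}: {p} does not exist")
                setattr(self, name, p)


_SOLVER_FIELDS = ("tol_force", "tol_torque", "max_iter", "step_deg",
                  "min_step_deg", "warm_start", "mode")


def load_config(path) -> RunConfig:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    base = path.parent
    model = raw.get("model", {})
    solver_raw = raw.get("solver", {})
    unknown = set(solver_raw) - set(_SOLVER_FIELDS)
    if unknown:
        raise ValueError(f"unknown solver settings: {sorted(unknown)}")
    validate_raw = raw.get("validate", {})

    def p(key, required=True):
        if key not in model:
            if required:
                raise KeyError(f"config model section missing {key!r}")
            return None
        return base / model[key]

    ranges = validate_raw.get("flexion_ranges", [[7.0, 90.0], [7.0, 112.0]])
    return RunConfig(
        femur_bone=p("femur_bone"), femur_cartilage=p("femur_cartilage"),
        tibia_bone=p("tibia_bone"), tibia_cartilage=p("tibia_cartilage"),
        landmarks=p("landmarks"), ligaments=p("ligaments"),
        parameters=p("parameters", required=False),
        cycles=p("cycles", required=False),
        solver=EquilibriumSettings(**solver_raw),
        flexion_ranges=tuple(tuple(r) for r in ranges),
        output_dir=base / raw.get("output_dir", "out"),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
        raw=raw)


def config_hash(cfg: RunConfig | dict) -> str:
    """Short stable hash of the configuration content."""
    raw = cfg.raw if isinstance(cfg, RunConfig) else cfg
    blob = yaml.safe_dump(raw, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
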