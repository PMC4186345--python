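"""Run configuration, deterministic seeding, and run-directory serialization.

A :class:`RunConfig` collects every model parameter in one round-trippable
object.  Config files are YAML with nested sections mirroring the parameter
dataclasses; omitted keys take the packaged defaults and unknown keys are
rejected by name.  :func:`save_run` writes a self-describing run directory
(JSON report, tables, array dumps, config snapshot, checksums) sufficient to
re-execute the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .field import GateParams, MFParams
from .integrate import IntegratorConfig
from .learning import LearningParams
from .store import WMParams

__all__ = ["RunConfig", "load_config", "save_run", "seed_substream"]


@dataclass(frozen=True)
class RunConfig:
    """Complete, reproducible description of one simulation run."""

    m: int = 5
    lmax: int = 4
    redundancy: int = 1
    alpha: float = 0.75
    beta: float = 0.75
    p: float = 3e-3                     # base fluctuation coefficient
    init_mode: str = "balanced_permuted"
    schedule_mode: str = "cyclic"
    cycles: int = 10
    seed: int = 0
    wm: WMParams = field(default_factory=WMParams)
    mf: MFParams = field(default_factory=MFParams)
    gates: GateParams = field(default_factory=GateParams)
    learning: LearningParams = field(default_factory=LearningParams)
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)

    def __post_init__(self) -> None:
        if not 1 <= self.lmax <= self.m:
            raise ValueError("need 1 <= lmax <= m")
        self.integrator.check_divides(self.alpha, "alpha")
        self.integrator.check_divides(self.beta, "beta")

    def to_dict(self) -> dict:
        def conv(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: conv(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            return obj

        return conv(self)


_SECTION_TYPES = {
    "wm": WMParams,
    "mf": MFParams,
    "gates": GateParams,
    "learning": LearningParams,
    "integrator": IntegratorConfig,
}


def load_config(path) -> RunConfig:
    """Load a YAML config file; defaults fill omitted keys, unknown keys fail."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    top_fields = {f.name for f in fields(RunConfig)}
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key not in top_fields:
            raise ValueError(f"unknown config key: {key!r}")
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            valid = {f.name for f in fields(cls)}
            if not isinstance(value, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            for sub in value:
                if sub not in valid:
                    raise ValueError(f"unknown config key: {key}.{sub}")
            kwargs[key] = cls(**value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def seed_substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent RNG substream derived from the run seed.

    Adding a new consumer name never perturbs the draws of existing ones.
    """
    digest = hashlib.sha256(name.encode()).digest()
    tag = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence((int(seed), tag)))


def save_run(artifacts: dict[str, Any], path, config: RunConfig | None = None) -> dict:
    """Write a run directory and return its manifest.

    ``artifacts`` maps names to numpy arrays (saved as .npy), pandas frames
    (saved as .tsv), or JSON-serializable objects (saved as .json).  The
    manifest lists every emitted file with a SHA-256 checksum and is itself
    written as ``manifest.json``.
    """
    import pandas as pd

    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        if config is not None:
            cfg_path = out / "config.yaml"
            cfg_path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
            written.append(cfg_path)
        for name, obj in artifacts.items():
            if isinstance(obj, np.ndarray):
                p = out / f"{name}.npy"
                np.save(p, obj)
            elif isinstance(obj, pd.DataFrame):
                p = out / f"{name}.tsv"
                obj.to_csv(p, sep="\t", index=False)
            else:
                p = out / f"{name}.json"
                p.write_text(json.dumps(obj, indent=2, default=_json_default))
            written.append(p)
    except OSError:
        (out / "INCOMPLETE").write_text("run interrupted before manifest\n")
        raise
    from . import __version__

    manifest = {
        "package_version": __version__,
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in written
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj).__name__}")
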