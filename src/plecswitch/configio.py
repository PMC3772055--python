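"""Plain-text (YAML) model configuration, config hashing and CSV output."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict

import pandas as pd
import yaml

from .dynamics import ModelConfig
from .network import BuildOptions
from .thermo import EnergyParams

__all__ = ["load_config", "dump_config", "config_hash", "write_csv"]


def load_config(path) -> ModelConfig:
    """Build a :class:`ModelConfig` from a YAML file.

    Recognized top-level keys: ``variant``, ``options`` (builder flags),
    ``energy`` (free-energy fields), ``scales``, ``named``, ``tolerances``
    (rtol/atol/ss_tol/t_max) and a flat ``parameters`` map routed by name.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = ModelConfig(
        variant=data.get("variant", "reduced"),
        options=BuildOptions(**data.get("options", {})),
        energy=EnergyParams(**data.get("energy", {})),
        scales=tuple(sorted((data.get("scales") or {}).items())),
        named=tuple(sorted((data.get("named") or {}).items())),
        **{k: v for k, v in (data.get("tolerances") or {}).items()},
    )
    for name, value in (data.get("parameters") or {}).items():
        cfg = cfg.updated(name, float(value))
    return cfg


def dump_config(config: ModelConfig, path=None) -> str:
    data = {
        "variant": config.variant,
        "options": asdict(config.options),
        "energy": asdict(config.energy),
        "scales": dict(config.scales),
        "named": dict(config.named),
        "tolerances": {
            "rtol": config.rtol,
            "atol": config.atol,
            "ss_tol": config.ss_tol,
            "t_max": config.t_max,
        },
    }
    text = yaml.safe_dump(data, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def config_hash(config: ModelConfig) -> str:
    """Short stable hash identifying a configuration."""
    blob = json.dumps(
        {
            "variant": config.variant,
            "options": asdict(config.options),
            "energy": asdict(config.energy),
            "scales": dict(config.scales),
            "named": dict(config.named),
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, config: ModelConfig | None = None,
              extra_header: dict | None = None):
    """Write a DataFrame as CSV with a comment header recording provenance."""
    lines = []
    if config is not None:
        lines.append(f"# config_hash={config_hash(config)}")
    for k, v in (extra_header or {}).items():
        lines.append(f"# {k}={v}")
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
        df.to_csv(fh, index=False)
    return path
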