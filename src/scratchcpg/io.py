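"""Structured-text serialization: configs (YAML), traces (CSV), reports (JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .network import (
    DriveSet,
    NetworkConfig,
    SynapseSpec,
    build_network,
)
from .params import PopulationParams
from .simulate import Trace

__all__ = [
    "save_config",
    "load_config",
    "save_drives",
    "load_drives",
    "save_trace",
    "load_trace",
    "save_report",
]

_FIXTURES = Path(__file__).parent / "fixtures"


def save_config(config: NetworkConfig, path: str | Path) -> None:
    doc = {
        "weight_class": config.weight_class,
        "params": config.params.to_dict(),
        "drives": config.drives.as_dict(),
        "synapses": [
            {"source": s.source, "target": s.target, "g": s.g, "reversal": s.reversal}
            for s in config.synapses
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> NetworkConfig:
    doc = yaml.safe_load(Path(path).read_text())
    drives = _drives_from_dict(doc["drives"])
    synapses = tuple(
        SynapseSpec(s["source"], s["target"], float(s["g"]), s["reversal"])
        for s in doc["synapses"]
    )
    params = PopulationParams.from_dict(doc.get("params", {}))
    return NetworkConfig(
        weight_class=doc.get("weight_class", "custom"),
        synapses=synapses,
        drives=drives,
        params=params,
    )


def _drives_from_dict(d: dict) -> DriveSet:
    key = {p: f"i_{p.lower()}" for p in
           ("IP", "EP", "ER", "IR", "HE", "KE", "HF")}
    kwargs = {}
    for p, attr in key.items():
        if p in d:
            kwargs[attr] = float(d[p])
        elif attr in d:
            kwargs[attr] = float(d[attr])
    return DriveSet(**kwargs)


def save_drives(drives: DriveSet, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(drives.as_dict(), sort_keys=False))


def load_drives(path: str | Path) -> DriveSet:
    return _drives_from_dict(yaml.safe_load(Path(path).read_text()))


def save_trace(trace: Trace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False)


def load_trace(path: str | Path, config: NetworkConfig | None = None) -> Trace:
    import pandas as pd

    return Trace.from_frame(pd.read_csv(path), config=config)


def save_report(obj, path: str | Path) -> None:
    def default(o):
        import numpy as np

        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        if hasattr(o, "__dict__"):
            return {k: v for k, v in o.__dict__.items()
                    if not k.startswith("_") and not isinstance(v, Trace)}
        return str(o)

    Path(path).write_text(json.dumps({"schema": "scratchcpg-report-1", **(
        obj if isinstance(obj, dict) else {"result": obj}
    )}, indent=2, default=default))


def fixture_path(name: str) -> Path:
    p = _FIXTURES / f"{name}.yaml"
    if not p.exists():
        raise FileNotFoundError(f"no fixture named {name!r}")
    return p


def load_fixture_drives(name: str) -> DriveSet:
    return load_drives(fixture_path(name))


def write_default_fixtures(directory: str | Path | None = None) -> list[Path]:
    """Write the shipped network and drive-set fixtures as YAML files."""
    from .network import (
        POCKET_DRIVES,
        ROSTRAL_DRIVES,
        ROSTRAL_DRIVES_1,
        ROSTRAL_DRIVES_2,
        baseline_drives,
    )

    directory = Path(directory) if directory else _FIXTURES
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for cls in ("S", "SCE"):
        p = directory / f"network_{cls}.yaml"
        save_config(build_network(cls), p)
        written.append(p)
        p = directory / f"drives_baseline_{cls}.yaml"
        save_drives(baseline_drives(cls), p)
        written.append(p)
    for name, ds in [
        ("drives_pocket", POCKET_DRIVES),
        ("drives_rostral", ROSTRAL_DRIVES),
        ("drives_rostral_1", ROSTRAL_DRIVES_1),
        ("drives_rostral_2", ROSTRAL_DRIVES_2),
    ]:
        p = directory / f"{name}.yaml"
        save_drives(ds, p)
        written.append(p)
    return written
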