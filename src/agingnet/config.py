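"""Parameter presets, configuration files and run manifests.

Config files are flat ``key = value`` text (``#`` comments); a JSON run
manifest produced by :func:`write_run_manifest` is accepted in the same
place, so a manifest reproduces the run that wrote it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

from .parameters import RateParameters


@dataclass(frozen=True)
class ParameterPreset:
    name: str
    params: RateParameters
    n: int
    notes: str = ""


#: Reference calibration of the health-network model: n = 10^4 nodes,
#: r+ = 10.27, r- = 6.5, R = 1.5, gamma0 = 0.00113 per year.
PRESETS: dict[str, ParameterPreset] = {
    "mitnitski2017": ParameterPreset(
        name="mitnitski2017",
        params=RateParameters(r_plus=10.27, r_minus=6.5, gamma0=0.00113, R=1.5),
        n=10_000,
        notes="reference calibration of the scale-free health-network model",
    ),
}

_BUILTINS: dict[str, object] = {
    "r_plus": 10.27,
    "r_minus": 6.5,
    "gamma0": 0.00113,
    "R": 1.5,
    "n": 10_000,
    "attachment": 2,
    "rewiring_steps": None,
    "seed": 0,
    "s_max": 0.15,
    "grid_points": 3001,
    "samples": 1000,
    "bin_width": 1.0,
}

_FLOAT_KEYS = {"r_plus", "r_minus", "gamma0", "R", "s_max", "bin_width"}
_INT_KEYS = {"n", "attachment", "rewiring_steps", "seed", "grid_points", "samples"}
_POSITIVE_KEYS = {"r_plus", "r_minus", "gamma0", "R"}


def _coerce(key: str, raw: object) -> object:
    if raw is None or (isinstance(raw, str) and raw.lower() in ("none", "")):
        return None
    if key in _FLOAT_KEYS:
        value: object = float(raw)
    elif key in _INT_KEYS:
        value = int(raw)
    else:
        value = raw
    if key in _POSITIVE_KEYS and not value > 0:  # type: ignore[operator]
        raise ValueError(f"{key}={value}: must lie in (0,∞)")
    return value


def load_config(path: str | Path | None = None, preset: str | None = None) -> dict:
    """Resolved run specification: file values over preset over built-ins.

    Unknown keys are an error, not a warning.
    """
    resolved = dict(_BUILTINS)
    if preset is not None:
        if preset not in PRESETS:
            raise KeyError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
        ps = PRESETS[preset]
        resolved.update(asdict(ps.params))
        resolved["n"] = ps.n
    if path is not None:
        text = Path(path).read_text()
        file_values = _parse(text)
        for key, raw in file_values.items():
            if key not in _BUILTINS:
                raise KeyError(f"unknown configuration key {key!r}")
            resolved[key] = _coerce(key, raw)
    return resolved


def _parse(text: str) -> dict:
    stripped = text.lstrip()
    if stripped.startswith("{"):  # JSON manifest
        data = json.loads(stripped)
        return data.get("spec", data)
    values: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, _, raw = line.partition("=")
        values[key.strip()] = raw.strip()
    return values


def write_run_manifest(
    spec: dict, seed: int, path: str | Path, versions: dict | None = None
) -> Path:
    """JSON manifest with parameters, master seed and package versions —
    enough to reproduce deterministic outputs bit-for-bit."""
    from . import __version__

    if versions is None:
        import numpy
        import scipy

        versions = {
            "agingnet": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
        }
    payload = {"spec": dict(spec), "master_seed": int(seed), "versions": versions}
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path


def preset_rate_parameters(name: str = "mitnitski2017") -> RateParameters:
    return PRESETS[name].params
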