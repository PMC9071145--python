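"""Configuration loading, manifests and deterministic seed management.

Every stochastic operation in the package receives a seed derived from a
single global seed plus a stable string label, so a whole experiment is
bitwise-reproducible from one integer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Any, Mapping

import numpy as np

__all__ = ["derive_seed", "rng_for", "RunConfig", "write_manifest", "setup_logging"]

log = logging.getLogger("perceptqa")


def setup_logging(verbosity: int = 0) -> None:
    level = logging.WARNING - 10 * min(int(verbosity), 2)
    logging.basicConfig(level=level, format="%(name)s: %(message)s")


def derive_seed(master: int, *labels: Any) -> int:
    """Derive a 31-bit seed from a master seed and a stable operation label.

    The label is hashed with SHA-256 (stable across platforms and sessions)
    and mixed with the master seed through a ``SeedSequence``.
    """
    text = "/".join(str(x) for x in labels)
    digest = hashlib.sha256(text.encode("utf-8")).digest()
    salt = int.from_bytes(digest[:4], "big")
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, salt])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def rng_for(master: int, *labels: Any) -> np.random.Generator:
    """Generator seeded by :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master, *labels))


@dataclasses.dataclass
class RunConfig:
    """Nested key-value configuration with a global seed and output directory."""

    params: dict = dataclasses.field(default_factory=dict)
    seed: int = 0
    outdir: Path | None = None
    verbosity: int = 0

    @classmethod
    def from_yaml(cls, path, overrides: Mapping[str, Any] | None = None) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        params = dict(data)
        seed = int(params.pop("seed", 0))
        outdir = params.pop("outdir", None)
        cfg = cls(params=params, seed=seed,
                  outdir=Path(outdir) if outdir else None)
        if overrides:
            cfg.update(overrides)
        return cfg

    def update(self, overrides: Mapping[str, Any]) -> None:
        """Flag overrides win over file values; ``None`` values are ignored."""
        for key, value in overrides.items():
            if value is None:
                continue
            if key == "seed":
                self.seed = int(value)
            elif key == "outdir":
                self.outdir = Path(value)
            else:
                self.params[key] = value


def write_manifest(outdir, command: str, config: Mapping[str, Any], seed: int) -> Path:
    """Write a JSON manifest beside outputs, sufficient to re-run the command."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": _jsonable(config),
        "seed": int(seed),
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "perceptqa": _package_version(),
        },
    }
    path = outdir / f"{command}.manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def _package_version() -> str:
    from perceptqa import __version__

    return __version__


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
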