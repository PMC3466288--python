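"""Run manifests, results bundles and trial-log serialization.

A results *bundle* is the dictionary an experiment driver returns: nested
scalars, numpy arrays, lists of arrays, pandas frames, stiffness ellipses
and protocol records.  ``save_bundle`` writes it as a JSON tree (structure,
scalars) plus one ``.npz`` container (all arrays, bit-exact) and CSV files
(frames), with SHA-256 checksums recorded in a manifest; ``load_bundle``
verifies the checksums and reproduces the arrays exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import Config
from .experiments import Protocol
from .metrics import StiffnessEllipse

__all__ = ["RunManifest", "save_bundle", "load_bundle", "trial_log_frame"]

_FORMAT_VERSION = 1


@dataclasses.dataclass
class RunManifest:
    """Everything needed to reproduce a run and verify its outputs."""

    experiment: str
    seed: int
    config: dict
    version: int = _FORMAT_VERSION
    timestamp: str = ""
    checksums: dict = dataclasses.field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _encode(obj, arrays: dict, frames: dict, prefix: str):
    if isinstance(obj, np.ndarray):
        key = f"a{len(arrays)}"
        arrays[key] = obj
        return {"__array__": key}
    if isinstance(obj, pd.DataFrame):
        key = f"f{len(frames)}.csv"
        frames[key] = obj
        return {"__frame__": key}
    if isinstance(obj, StiffnessEllipse):
        return {
            "__ellipse__": _encode(
                dataclasses.asdict(obj), arrays, frames, prefix
            )
        }
    if isinstance(obj, Protocol):
        return {"__protocol__": _encode(dataclasses.asdict(obj), arrays, frames, prefix)}
    if isinstance(obj, dict):
        return {str(k): _encode(v, arrays, frames, prefix) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v, arrays, frames, prefix) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    raise TypeError(f"cannot serialize object of type {type(obj)!r}")


def _decode(node, arrays, outdir: Path):
    if isinstance(node, dict):
        if "__array__" in node:
            return arrays[node["__array__"]]
        if "__frame__" in node:
            return pd.read_csv(outdir / node["__frame__"])
        if "__ellipse__" in node:
            d = _decode(node["__ellipse__"], arrays, outdir)
            return StiffnessEllipse(
                np.asarray(d["K"]), np.asarray(d["eigvals"]),
                d["orientation_deg"], d["area"],
            )
        if "__protocol__" in node:
            d = _decode(node["__protocol__"], arrays, outdir)
            return Protocol(**d)
        return {k: _decode(v, arrays, outdir) for k, v in node.items()}
    if isinstance(node, list):
        return [_decode(v, arrays, outdir) for v in node]
    return node


def save_bundle(
    results: dict,
    outdir: str | Path,
    experiment: str = "",
    seed: int = 0,
    cfg: Config | None = None,
) -> RunManifest:
    """Write a results bundle with manifest and checksums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arrays: dict = {}
    frames: dict = {}
    tree = _encode(results, arrays, frames, "")
    with open(outdir / "bundle.json", "w") as fh:
        json.dump(tree, fh)
    np.savez(outdir / "arrays.npz", **arrays)
    for name, frame in frames.items():
        frame.to_csv(outdir / name, index=False)
    manifest = RunManifest(
        experiment=experiment,
        seed=seed,
        config=cfg.to_dict() if cfg is not None else {},
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        checksums={
            name: _sha256(outdir / name)
            for name in ["bundle.json", "arrays.npz", *frames]
        },
    )
    with open(outdir / "manifest.json", "w") as fh:
        fh.write(manifest.to_json())
    return manifest


def load_bundle(outdir: str | Path) -> tuple[dict, RunManifest]:
    """Load a saved bundle, verifying checksums and completeness."""
    outdir = Path(outdir)
    mpath = outdir / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest in {outdir}")
    with open(mpath) as fh:
        manifest = RunManifest(**json.load(fh))
    missing = [n for n in manifest.checksums if not (outdir / n).exists()]
    if missing:
        raise FileNotFoundError(f"bundle incomplete, missing: {missing}")
    for name, digest in manifest.checksums.items():
        actual = _sha256(outdir / name)
        if actual != digest:
            raise ValueError(f"checksum mismatch for {name}: bundle corrupted")
    with open(outdir / "bundle.json") as fh:
        tree = json.load(fh)
    with np.load(outdir / "arrays.npz") as npz:
        arrays = {k: npz[k] for k in npz.files}
    return _decode(tree, arrays, outdir), manifest


def trial_log_frame(result) -> pd.DataFrame:
    """Tidy per-time-step table of one trial (one row per step)."""
    n = result.n_steps
    data = {"t": result.t[:n]}
    for j, name in enumerate(("q1", "q2")):
        data[name] = result.q[:n, j]
        data["d" + name] = result.qd[:n, j]
    data["hand_x"] = result.hand[:n, 0]
    data["hand_y"] = result.hand[:n, 1]
    for j in range(6):
        data[f"u{j}"] = result.u[:, j]
        data[f"u_ff{j}"] = result.u_ff[:, j]
        data[f"u_fb{j}"] = result.u_fb[:, j]
        data[f"T{j}"] = result.tensions[:, j]
        data[f"e{j}"] = result.e[:, j]
    data["F_x"] = result.F_ext[:, 0]
    data["F_y"] = result.F_ext[:, 1]
    frame = pd.DataFrame(data)
    frame.attrs["field"] = result.field.describe()
    return frame
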