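"""Serialization of projection sets, capacity results, tables and rate maps.

Conventions: JSON for structured results (floats survive a round trip exactly
thanks to shortest-repr float formatting), CSV with 17 significant digits for
tables, plain-text grids plus a JSON sidecar for sampled rate maps.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .capacity import AmbiguityBox, CapacityResult
from .encoding import ProjectionSet
from .tuning import RateMap

__all__ = [
    "projection_to_dict",
    "projection_from_dict",
    "save_projection",
    "load_projection",
    "capacity_to_dict",
    "save_capacity",
    "load_capacity",
    "save_table",
    "save_ratemap",
    "load_ratemap",
    "ratemap_to_csv",
    "load_config",
]


def projection_to_dict(P: ProjectionSet) -> dict:
    return {
        "M": P.M,
        "N_max": P.N_max,
        "seed": P.seed,
        "matrices": [m.tolist() for m in P.matrices],
    }


def projection_from_dict(d: dict) -> ProjectionSet:
    P = ProjectionSet(np.array(d["matrices"], dtype=float), seed=d.get("seed"))
    if P.M != d["M"] or P.N_max != d["N_max"]:
        raise ValueError("inconsistent projection-set metadata")
    return P


def save_projection(P: ProjectionSet, path) -> None:
    Path(path).write_text(json.dumps(projection_to_dict(P), indent=1) + "\n")


def load_projection(path) -> ProjectionSet:
    return projection_from_dict(json.loads(Path(path).read_text()))


def capacity_to_dict(res: CapacityResult) -> dict:
    return {
        "M": res.M,
        "N": res.N,
        "delta": res.delta,
        "L": res.L,
        "w": res.box.half_widths.tolist(),
        "collision_point": (
            None if res.collision_point is None else res.collision_point.tolist()
        ),
        "boxes_examined": res.boxes_examined,
        "certified": res.certified,
        "seed": res.seed,
    }


def save_capacity(res: CapacityResult, path) -> None:
    Path(path).write_text(json.dumps(capacity_to_dict(res), indent=1) + "\n")


def load_capacity(path) -> CapacityResult:
    d = json.loads(Path(path).read_text())
    return CapacityResult(
        L=d["L"],
        box=AmbiguityBox(np.array(d["w"], float)),
        collision_point=(
            None if d["collision_point"] is None else np.array(d["collision_point"])
        ),
        boxes_examined=d["boxes_examined"],
        certified=d["certified"],
        M=d["M"],
        N=d["N"],
        delta=d["delta"],
        seed=d.get("seed"),
    )


def save_table(df: pd.DataFrame, path) -> None:
    """CSV: comma separated, header row, LF endings, 17 significant digits."""
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def save_ratemap(rmap: RateMap, prefix) -> None:
    """Write ``<prefix>.txt`` (values, one 2D slab per block) and
    ``<prefix>.json`` (shape, origin, spacing)."""
    prefix = Path(prefix)
    v = rmap.values
    flat = v.reshape(-1, v.shape[-1]) if v.ndim > 1 else v.reshape(1, -1)
    np.savetxt(prefix.with_suffix(".txt"), flat, fmt="%.17g")
    meta = {
        "shape": list(v.shape),
        "origin": rmap.origin.tolist(),
        "spacing": rmap.spacing.tolist(),
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1) + "\n")


def load_ratemap(prefix) -> RateMap:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    vals = np.loadtxt(prefix.with_suffix(".txt")).reshape(meta["shape"])
    return RateMap(vals, meta["origin"], meta["spacing"])


def ratemap_to_csv(rmap: RateMap, path) -> None:
    """Long-format export: one (coords..., value) row per sample."""
    pts = rmap.points().reshape(-1, rmap.D)
    cols = {f"x{i}": pts[:, i] for i in range(rmap.D)}
    cols["value"] = rmap.values.reshape(-1)
    save_table(pd.DataFrame(cols), path)


def load_config(path) -> dict:
    """YAML or JSON run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return data


def dataclass_to_json(obj, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(obj), indent=1, default=_default) + "\n")


def _default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"cannot serialize {type(o)}")
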