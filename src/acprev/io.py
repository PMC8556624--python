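"""Lightweight geospatial and tabular I/O.

Polygon layers are carried as a :class:`PolygonLayer` — a pandas attribute
table plus a parallel list of shapely geometries — and exchanged on disk as
GeoJSON FeatureCollections.  CSV tables written by the pipeline carry
provenance (seed, config hash) as ``#``-prefixed header comments so a rerun
with the same seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry


class ParseError(ValueError):
    """Malformed input file, with feature/line context in the message."""


@dataclass
class PolygonLayer:
    """Attribute table + parallel geometry list (a minimal GeoDataFrame)."""

    df: pd.DataFrame
    geoms: list[BaseGeometry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.df) != len(self.geoms):
            raise ValueError(
                f"attribute table has {len(self.df)} rows but {len(self.geoms)} geometries"
            )
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def to_geojson(self, path: str | Path, *, metadata: dict | None = None) -> None:
        features = []
        for i in range(len(self.df)):
            props = {
                k: (None if pd.isna(v) else v) for k, v in self.df.iloc[i].to_dict().items()
            }
            features.append(
                {"type": "Feature", "properties": props, "geometry": mapping(self.geoms[i])}
            )
        doc = {"type": "FeatureCollection", "features": features}
        if metadata:
            doc["metadata"] = metadata
        Path(path).write_text(json.dumps(doc, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_geojson(cls, path: str | Path) -> "PolygonLayer":
        try:
            doc = json.loads(Path(path).read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
        if doc.get("type") != "FeatureCollection":
            raise ParseError(f"{path}: expected a GeoJSON FeatureCollection")
        rows, geoms = [], []
        for i, feat in enumerate(doc.get("features", [])):
            try:
                geoms.append(shape(feat["geometry"]))
            except (KeyError, TypeError, ValueError, AttributeError) as exc:
                raise ParseError(f"{path}: feature {i}: bad geometry ({exc})") from exc
            rows.append(feat.get("properties") or {})
        return cls(pd.DataFrame(rows), geoms)

    def repaired(self) -> "PolygonLayer":
        """Standard zero-width-buffer repair of invalid polygons."""
        fixed = [g if g.is_valid else g.buffer(0) for g in self.geoms]
        return PolygonLayer(self.df.copy(), fixed)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_csv(
    df: pd.DataFrame, path: str | Path, *, metadata: dict | None = None
) -> None:
    """CSV with ``# key=value`` provenance header comments; deterministic floats."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def read_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def read_csv_metadata(path: str | Path) -> dict:
    meta = {}
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value
    return meta


def write_gal(neighbors: dict, path: str | Path) -> None:
    """GAL contiguity file: header line with n, then per-unit id/degree + neighbour ids."""
    ids = sorted(neighbors)
    lines = [str(len(ids))]
    for uid in ids:
        nbrs = sorted(neighbors[uid])
        lines.append(f"{uid} {len(nbrs)}")
        lines.append(" ".join(str(n) for n in nbrs))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_gal(path: str | Path) -> dict:
    lines = [ln for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln.strip()]
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}: line 1: expected unit count") from exc
    neighbors: dict = {}
    i = 1
    for _ in range(n):
        uid, deg = lines[i].split()[:2]
        if int(deg) > 0:
            neighbors[uid] = set(lines[i + 1].split())
            i += 2
        else:
            neighbors[uid] = set()
            i += 1
    return neighbors
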