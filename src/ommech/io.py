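"""Readers and writers for the package's plain-text and TIFF interchange formats.

Curves travel as TSV (columns ``curve_id``, ``segment``, ``separation_nm``,
``force_nN``); height maps as 32-bit float TIFF in nm with a JSON sidecar
(pixel size, sample, seed) or as a plain-text matrix for portability;
correlograms as two-column TSV; size distributions and event tables as CSV;
truth records and summaries as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .datatypes import Correlogram, CurveResult, ForceCurve, HeightMap, SizeDistribution

# --------------------------------------------------------------------------
# Force curves
# --------------------------------------------------------------------------


def write_curves_tsv(curves: Sequence[ForceCurve], path) -> None:
    frames = []
    for i, c in enumerate(curves):
        cid = c.metadata.get("counter", i)
        frames.append(pd.DataFrame({
            "curve_id": cid,
            "segment": c.direction,
            "separation_nm": c.separation,
            "force_nN": c.force,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False,
                                                float_format="%.9g")


def read_curves_tsv(path, metadata: dict | None = None) -> list:
    """Read the package TSV dialect (or any file with those columns)."""
    df = pd.read_csv(path, sep="\t")
    required = {"separation_nm", "force_nN"}
    if not required <= set(df.columns):
        raise ValueError(f"curve file {path} lacks columns {sorted(required)}")
    if "curve_id" not in df.columns:
        df["curve_id"] = 0
    if "segment" not in df.columns:
        df["segment"] = "approach"
    curves = []
    for (cid, seg), grp in df.groupby(["curve_id", "segment"], sort=True):
        meta = {"counter": cid, "source": str(path)}
        meta.update(metadata or {})
        curves.append(ForceCurve(separation=grp["separation_nm"].to_numpy(),
                                 force=grp["force_nN"].to_numpy(),
                                 direction=str(seg), metadata=meta))
    return curves


def read_generic_curve(path, *, separation_col: int = 0, force_col: int = 1,
                       direction: str = "approach", comment: str = "#") -> ForceCurve:
    """Read a generic two-column text force-distance file (nm, nN)."""
    data = np.loadtxt(path, comments=comment)
    sep = data[:, separation_col]
    force = data[:, force_col]
    if sep[0] < sep[-1] and direction == "approach":
        sep, force = sep[::-1], force[::-1]
    return ForceCurve(separation=sep, force=force, direction=direction,
                      metadata={"source": str(path)})


# --------------------------------------------------------------------------
# Height maps
# --------------------------------------------------------------------------


def write_heightmap_tiff(hm: HeightMap, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, hm.heights.astype(np.float32))
    sidecar = {
        "pixel_size_nm": hm.pixel_size,
        "units": "nm",
        **{k: v for k, v in hm.metadata.items()
           if isinstance(v, (str, int, float, bool))},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_heightmap_tiff(path) -> HeightMap:
    path = Path(path)
    heights = tifffile.imread(path).astype(float)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    px = float(meta.pop("pixel_size_nm", 1.0))
    return HeightMap(heights=heights, pixel_size=px, metadata=meta)


def write_heightmap_txt(hm: HeightMap, path) -> None:
    header = json.dumps({"pixel_size_nm": hm.pixel_size, "units": "nm"})
    np.savetxt(path, hm.heights, fmt="%.6g", header=header)


def read_heightmap_txt(path) -> HeightMap:
    with open(path) as fh:
        first = fh.readline()
    meta = {}
    if first.startswith("#"):
        try:
            meta = json.loads(first.lstrip("# ").strip())
        except json.JSONDecodeError:
            meta = {}
    heights = np.loadtxt(path)
    return HeightMap(heights=heights, pixel_size=float(meta.get("pixel_size_nm", 1.0)),
                     metadata={k: v for k, v in meta.items() if k != "pixel_size_nm"})


def read_heightmap(path) -> HeightMap:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return read_heightmap_tiff(path)
    return read_heightmap_txt(path)


def write_labelmap_tiff(labels: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(labels).astype(np.uint8))


# --------------------------------------------------------------------------
# DLS
# --------------------------------------------------------------------------


def write_correlogram_tsv(corr: Correlogram, path) -> None:
    pd.DataFrame({"lag_s": corr.lags, "g2": corr.g2}).to_csv(
        path, sep="\t", index=False, float_format="%.9g")


def read_correlogram_tsv(path) -> Correlogram:
    df = pd.read_csv(path, sep="\t")
    if not {"lag_s", "g2"} <= set(df.columns):
        data = np.loadtxt(path)
        return Correlogram(lags=data[:, 0], g2=data[:, 1])
    return Correlogram(lags=df["lag_s"].to_numpy(), g2=df["g2"].to_numpy())


def write_distribution_csv(dist: SizeDistribution, path) -> None:
    pd.DataFrame({"diameter_nm": dist.diameters, "weight": dist.weights}).to_csv(
        path, index=False, float_format="%.9g")


def read_distribution_csv(path) -> SizeDistribution:
    df = pd.read_csv(path)
    return SizeDistribution(diameters=df["diameter_nm"].to_numpy(),
                            weights=df["weight"].to_numpy())


# --------------------------------------------------------------------------
# Events, truth, summaries
# --------------------------------------------------------------------------


def events_frame(results: Sequence[CurveResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for e in r.events:
            rows.append({
                "curve_id": r.curve_id,
                "index_in_curve": e.index_in_curve,
                "yield_separation_nm": e.yield_separation,
                "rupture_force_nN": e.rupture_force,
                "thickness_nm": e.thickness,
                "force_drop_nN": e.force_drop,
                "label": e.label or "",
            })
    return pd.DataFrame(rows, columns=["curve_id", "index_in_curve",
                                       "yield_separation_nm", "rupture_force_nN",
                                       "thickness_nm", "force_drop_nN", "label"])


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, cls=_NumpyEncoder)
                          + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
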