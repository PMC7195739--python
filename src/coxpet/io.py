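"""File formats: delimited tables for curves and cells, TIFF + JSON for scenes.

All tabular files are tab-delimited with a header row.  Numeric
round-trips are lossless to 1e-12 relative (values written with repr
precision).
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .curves import FrameSchedule, TimeActivityCurve
from .fish_quant import CellScore, QuantResult
from .fish_synth import SceneParams, SyntheticScene, TruthNucleus, TruthSpot
from .plasma_input import BloodSample, InputFunction

__all__ = [
    "write_tacs", "read_tacs",
    "write_input", "read_input",
    "write_blood", "read_blood",
    "write_scene", "read_scene",
    "write_cell_table", "write_quant_json",
]

_FLOAT_FMT = "%.17g"


def write_tacs(path: Union[str, Path], tacs: Sequence[TimeActivityCurve]) -> None:
    """TAC table: frame_start_min, frame_end_min, one column per region."""
    if not tacs:
        raise ValueError("no TACs to write")
    sched = tacs[0].schedule
    data = {"frame_start_min": sched.start, "frame_end_min": sched.end}
    for tac in tacs:
        if tac.schedule.n_frames != sched.n_frames or not np.allclose(
            tac.schedule.start, sched.start
        ):
            raise ValueError("all TACs in one file must share a schedule")
        data[tac.region] = tac.values
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_tacs(path: Union[str, Path]) -> List[TimeActivityCurve]:
    df = pd.read_csv(path, sep="\t")
    sched = FrameSchedule(df["frame_start_min"].to_numpy(),
                          df["frame_end_min"].to_numpy())
    regions = [c for c in df.columns if c not in ("frame_start_min", "frame_end_min")]
    return [TimeActivityCurve(r, sched, df[r].to_numpy()) for r in regions]


def write_input(path: Union[str, Path], input_function: InputFunction) -> None:
    """Input table: time_min, parent_plasma_kBq_per_mL (+ optional columns)."""
    data = {"time_min": input_function.times,
            "parent_plasma_kBq_per_mL": input_function.parent_plasma}
    if input_function.total_plasma is not None:
        data["total_plasma_kBq_per_mL"] = input_function.total_plasma
    if input_function.whole_blood is not None:
        data["whole_blood_kBq_per_mL"] = input_function.whole_blood
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_input(path: Union[str, Path],
               free_fraction: Optional[float] = None) -> InputFunction:
    df = pd.read_csv(path, sep="\t")
    return InputFunction(
        times=df["time_min"].to_numpy(),
        parent_plasma=df["parent_plasma_kBq_per_mL"].to_numpy(),
        total_plasma=(df["total_plasma_kBq_per_mL"].to_numpy()
                      if "total_plasma_kBq_per_mL" in df else None),
        whole_blood=(df["whole_blood_kBq_per_mL"].to_numpy()
                     if "whole_blood_kBq_per_mL" in df else None),
        free_fraction=free_fraction,
    )


def write_blood(path: Union[str, Path], samples: Sequence[BloodSample]) -> None:
    """Blood table: time_min, whole_blood, plasma, parent_fraction (blank ok)."""
    pd.DataFrame({
        "time_min": [s.time for s in samples],
        "whole_blood_kBq_per_mL": [s.whole_blood for s in samples],
        "plasma_kBq_per_mL": [s.plasma for s in samples],
        "parent_fraction": [s.parent_fraction for s in samples],
    }).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_blood(path: Union[str, Path]) -> List[BloodSample]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        pf = row.get("parent_fraction")
        out.append(BloodSample(
            time=float(row["time_min"]),
            whole_blood=float(row["whole_blood_kBq_per_mL"]),
            plasma=float(row["plasma_kBq_per_mL"]),
            parent_fraction=None if pd.isna(pf) else float(pf),
        ))
    return out


def write_scene(directory: Union[str, Path], scene: SyntheticScene,
                stem: str = "scene") -> Path:
    """Write a scene as multichannel TIFF (DAPI, Cy3, Cy5; 16-bit) plus a
    JSON ground-truth sidecar; returns the TIFF path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tiff_path = directory / f"{stem}.tif"
    stack = np.stack([scene.dapi, scene.cy3, scene.cy5])
    tifffile.imwrite(tiff_path, stack, photometric="minisblack",
                     planarconfig="separate", metadata={"axes": "CYX"})
    truth = {
        "params": dataclasses.asdict(scene.params),
        "nuclei": [dataclasses.asdict(n) for n in scene.nuclei],
        "spots": [dataclasses.asdict(s) for s in scene.spots],
        "autofluor": [list(c) for c in scene.autofluor],
    }
    (directory / f"{stem}.truth.json").write_text(json.dumps(truth, indent=1))
    return tiff_path


def read_scene(tiff_path: Union[str, Path]) -> SyntheticScene:
    tiff_path = Path(tiff_path)
    stack = tifffile.imread(tiff_path)
    truth = json.loads(tiff_path.with_suffix("").with_suffix(".truth.json").read_text())
    p = truth["params"]
    p["shape"] = tuple(p["shape"])
    params = SceneParams(**p)
    nuclei = [TruthNucleus(n["id"], tuple(n["center"]), tuple(n["radii"]),
                           n["angle"], n["cluster_id"], n["is_neuron"])
              for n in truth["nuclei"]]
    spots = [TruthSpot(s["channel"], tuple(s["center"]), s["nucleus_id"])
             for s in truth["spots"]]
    return SyntheticScene(params=params, dapi=stack[0], cy3=stack[1],
                          cy5=stack[2], nuclei=nuclei,
                          spots=spots,
                          autofluor=[tuple(c) for c in truth["autofluor"]])


def write_cell_table(path: Union[str, Path], masks, scores: Sequence[CellScore]) -> None:
    """Per-cell table: nucleus_id, area_um2, n_cy3, n_cy5, expressing flags."""
    areas = {m.id: m.area_um2 for m in masks}
    pd.DataFrame({
        "nucleus_id": [s.nucleus_id for s in scores],
        "area_um2": [areas.get(s.nucleus_id, float("nan")) for s in scores],
        "n_cy3": [s.n_cy3 for s in scores],
        "n_cy5": [s.n_cy5 for s in scores],
        "expressing_cy3": [int(s.expressing_cy3) for s in scores],
        "expressing_cy5": [int(s.expressing_cy5) for s in scores],
    }).to_csv(path, sep="\t", index=False)


def write_quant_json(path: Union[str, Path], result: QuantResult) -> None:
    payload = {"schema_version": 1, **dataclasses.asdict(result)}
    Path(path).write_text(json.dumps(payload, indent=1))
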