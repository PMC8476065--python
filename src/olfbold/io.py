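"""File formats: NIfTI volumes, TSV schedules/traces/tables, YAML configs.

Conventions: voxel arrays are indexed (x, y, z, t); the NIfTI affine is the
single source of spatial truth (RAS+, built from the voxel size); schedule
times are seconds from the first volume (volume 0 at t = 0).  The TR is
stored in the NIfTI header (4th zoom) and must be supplied explicitly if a
foreign file lacks it.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .paradigm import ParadigmSchedule, build_paradigm
from .phantom import Bold4D, DropoutSpec, RoiSpec, SimulationConfig
from .preprocess import PreprocConfig

__all__ = [
    "read_bold_nifti",
    "write_bold_nifti",
    "read_labels_nifti",
    "write_labels_nifti",
    "read_schedule",
    "write_schedule",
    "read_traces",
    "write_traces",
    "read_sim_config",
    "write_sim_config",
    "write_summary",
    "validate_summary",
]

_SCHEDULE_PARAMS = (
    "tr_seconds",
    "initial_off_seconds",
    "n_blocks",
    "on_seconds",
    "off_seconds",
    "pulse_on_seconds",
    "pulse_off_seconds",
)


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


# ------------------------------------------------------------------- NIfTI
def write_bold_nifti(path, vol: Bold4D, mask_path=None) -> None:
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_zooms(tuple(vol.voxel_mm) + (vol.tr_seconds,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    if mask_path is not None:
        write_labels_nifti(mask_path, vol.brain_mask.astype(np.int16), vol.affine)


def read_bold_nifti(path, tr_seconds: float | None = None,
                    brain_mask: np.ndarray | None = None) -> Bold4D:
    """Load a 4-D NIfTI; TR from the header unless overridden.

    Raises :class:`FormatError` for non-4-D images or a missing TR.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4-D BOLD image, got {data.ndim}-D")
    zooms = img.header.get_zooms()
    tr = tr_seconds if tr_seconds is not None else (
        float(zooms[3]) if len(zooms) > 3 else 0.0
    )
    if not tr or tr <= 0:
        raise FormatError(
            f"{path}: repetition time missing from header; pass tr_seconds"
        )
    if brain_mask is None:
        brain_mask = np.ones(data.shape[:3], dtype=bool)
    elif brain_mask.shape != data.shape[:3]:
        raise FormatError("brain mask dimensions do not match the image")
    return Bold4D(
        data=data.astype(float),
        tr_seconds=tr,
        voxel_mm=tuple(float(z) for z in zooms[:3]),
        affine=np.asarray(img.affine),
        brain_mask=brain_mask,
    )


def write_labels_nifti(path, labels: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine), str(path))


def read_labels_nifti(path) -> np.ndarray:
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D label image")
    return data.astype(np.int16)


# ---------------------------------------------------------------- schedules
def write_schedule(path, schedule: ParadigmSchedule) -> None:
    """Per-volume TSV with the paradigm parameters as '#' header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for name in _SCHEDULE_PARAMS:
            fh.write(f"# {name} = {getattr(schedule, name)}\n")
        schedule.to_frame().to_csv(fh, sep="\t", index=False)


def read_schedule(path) -> ParadigmSchedule:
    """Rebuild a schedule from its TSV; verifies the per-volume columns."""
    path = Path(path)
    params: dict[str, float] = {}
    with path.open() as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            try:
                key, val = line[1:].split("=")
                params[key.strip()] = float(val)
            except ValueError as exc:
                raise FormatError(f"{path}: malformed header line {line!r}") from exc
            body_start = i + 1
        else:
            break
    missing = set(_SCHEDULE_PARAMS) - set(params)
    if missing:
        raise FormatError(f"{path}: missing schedule parameters {sorted(missing)}")
    try:
        df = pd.read_csv(path, sep="\t", skiprows=body_start)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse schedule table: {exc}") from exc
    for col in ("volume_index", "label", "block_index"):
        if col not in df.columns:
            raise FormatError(f"{path}: schedule table lacks column {col!r}")
    params["n_blocks"] = int(params["n_blocks"])
    sched = build_paradigm(**params)
    if len(df) != sched.n_volumes:
        raise FormatError(
            f"{path}: table has {len(df)} rows, parameters imply {sched.n_volumes}"
        )
    if not (df["label"].to_numpy() == sched.labels).all():
        raise FormatError(f"{path}: labels are inconsistent with the parameters")
    return sched


# ------------------------------------------------------------------- traces
def write_traces(path, traces: np.ndarray, names=None) -> None:
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[0] < traces.shape[1]:
        traces = traces.T
    names = names or [f"trace_{i}" for i in range(traces.shape[1])]
    pd.DataFrame(traces, columns=list(names)).to_csv(path, sep="\t", index=False)


def read_traces(path) -> tuple[np.ndarray, list]:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse traces: {exc}") from exc
    return df.to_numpy(dtype=float), list(df.columns)


# ------------------------------------------------------------------ configs
def _sim_config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["roi_layout"] = [dataclasses.asdict(r) for r in cfg.roi_layout]
    d["dropout"] = {
        k: (None if v is None else dataclasses.asdict(v))
        for k, v in cfg.dropout.items()
    }
    return d


def _sim_config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "roi_layout" in d:
        d["roi_layout"] = tuple(
            RoiSpec(**{**r, "center": tuple(r["center"]),
                       "size": tuple(r["size"]) if isinstance(r["size"], (list, tuple)) else r["size"]})
            for r in d["roi_layout"]
        )
    if "dropout" in d:
        d["dropout"] = {
            k: (None if v is None else DropoutSpec(**{**v, "center": tuple(v["center"])}))
            for k, v in d["dropout"].items()
        }
    for key in ("grid_shape", "h", "h_neg"):
        if key in d:
            d[key] = tuple(d[key])
    cfg = SimulationConfig(**d)
    cfg.validate()
    return cfg


def write_sim_config(path, cfg: SimulationConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_sim_config_to_dict(cfg), fh, sort_keys=False)


def read_sim_config(path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    try:
        return _sim_config_from_dict(d)
    except TypeError as exc:
        raise FormatError(f"{path}: invalid simulation config: {exc}") from exc


def preproc_config_to_dict(cfg: PreprocConfig) -> dict:
    return {
        "fwhm_mm": cfg.fwhm_mm,
        "hp_cutoff_hz": cfg.hp_cutoff_hz,
        "lp_cutoff_hz": cfg.lp_cutoff_hz,
    }


# ------------------------------------------------------------------ summary
def _schema_path() -> Path:
    return Path(__file__).parent / "_schemas" / "summary_schema.json"


def validate_summary(obj: dict, schema: dict | None = None) -> None:
    """Minimal JSON-schema check (type / required / properties / items)."""
    if schema is None:
        schema = json.loads(_schema_path().read_text())

    def check(node, sch, where):
        typ = sch.get("type")
        types = {
            "object": dict, "array": list, "string": str,
            "number": (int, float), "integer": int, "boolean": bool,
        }
        if typ and not isinstance(node, types[typ]):
            raise FormatError(f"summary{where}: expected {typ}")
        if typ == "object":
            for req in sch.get("required", []):
                if req not in node:
                    raise FormatError(f"summary{where}: missing key {req!r}")
            for key, sub in sch.get("properties", {}).items():
                if key in node:
                    check(node[key], sub, f"{where}.{key}")
        if typ == "array" and "items" in sch:
            for i, item in enumerate(node):
                check(item, sch["items"], f"{where}[{i}]")

    check(obj, schema, "")


def write_summary(path, obj: dict) -> None:
    validate_summary(obj)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
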