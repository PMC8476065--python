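"""End-to-end orchestration: phantom -> preprocess -> activation -> metrics.

``run_pipeline`` simulates one subject under both acquisition conditions plus
a re-scan of the first condition, runs the full analysis, and writes all
intermediate volumes (NIfTI), per-ROI tables (TSV), a machine-readable
summary (JSON, validated against the packaged schema) and a run log.  The
run is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import __version__, io as oio, metrics
from .activation import block_response, cnr_compare, glm_activation_map, ks_activation_map
from .paradigm import build_paradigm
from .phantom import SimulationConfig, default_config, roi_label_map, simulate_dataset
from .preprocess import PreprocConfig, preprocess_bold

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("olfbold")


@dataclass
class RunConfig:
    """Everything one demo run needs; round-trips losslessly through YAML."""

    seed: int = 0
    alpha: float = 0.01
    hemodynamic_delay_s: float = 0.0
    conditions: tuple = ("t2prep_like", "epi_like")
    retest_condition: str = "t2prep_like"
    retest_seed_offset: int = 1000
    paradigm: dict = field(default_factory=lambda: {
        "tr_seconds": 2.0, "initial_off_seconds": 60.0, "n_blocks": 3,
        "on_seconds": 60.0, "off_seconds": 120.0,
        "pulse_on_seconds": 1.0, "pulse_off_seconds": 2.0,
    })
    sim: SimulationConfig = field(default_factory=default_config)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "alpha": self.alpha,
            "hemodynamic_delay_s": self.hemodynamic_delay_s,
            "conditions": list(self.conditions),
            "retest_condition": self.retest_condition,
            "retest_seed_offset": self.retest_seed_offset,
            "paradigm": dict(self.paradigm),
            "sim": oio._sim_config_to_dict(self.sim),
            "preproc": oio.preproc_config_to_dict(self.preproc),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = oio._sim_config_from_dict(d["sim"])
        if "preproc" in d:
            d["preproc"] = PreprocConfig(**d["preproc"])
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _stage(log, name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        log.error("stage %s failed: %s", name, exc)
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full demo pipeline; returns the summary dict (also written)."""
    outdir = Path(outdir)
    for sub in ("phantom", "preproc", "maps", "tables"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run_log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path) -> dict:
    logger.info("olfbold %s starting; config: %s", __version__,
                json.dumps(config.to_dict(), default=str))
    schedule = _stage(logger, "paradigm", build_paradigm, **config.paradigm)
    oio.write_schedule(outdir / "phantom" / "schedule.tsv", schedule)
    sim = config.sim
    labels, names = roi_label_map(sim)
    roi_set = metrics.RoiSet(labels, names)
    oio.write_labels_nifti(outdir / "phantom" / "roi_labels.nii",
                           labels, np.diag([sim.voxel_mm] * 3 + [1.0]))
    config.to_yaml(outdir / "config.yaml")

    runs = [(c, int(config.seed) + i) for i, c in enumerate(config.conditions)]
    runs.append((config.retest_condition, int(config.seed) + config.retest_seed_offset))
    run_names = list(config.conditions) + [f"{config.retest_condition}_rescan"]

    results = {}
    for run_name, (condition, seed) in zip(run_names, runs):
        bold, truth = _stage(logger, f"phantom:{run_name}", simulate_dataset,
                             schedule, sim, condition, seed)
        oio.write_bold_nifti(outdir / "phantom" / f"{run_name}_bold.nii", bold)
        oio.write_traces(outdir / "phantom" / f"{run_name}_traces.tsv",
                         truth.nuisance_traces, truth.trace_names)
        pp = dataclasses.replace(config.preproc,
                                 nuisance_traces=truth.nuisance_traces)
        clean = _stage(logger, f"preprocess:{run_name}", preprocess_bold,
                       bold, pp, False)
        oio.write_bold_nifti(outdir / "preproc" / f"{run_name}_preproc.nii", clean)
        amap = _stage(logger, f"activate:{run_name}", ks_activation_map,
                      clean, schedule, config.alpha, config.hemodynamic_delay_s)
        gmap = _stage(logger, f"activate_glm:{run_name}", glm_activation_map,
                      clean, schedule, config.alpha, config.hemodynamic_delay_s,
                      filter_hp_cutoff_hz=config.preproc.hp_cutoff_hz)
        resp = _stage(logger, f"quantify:{run_name}", block_response,
                      clean, schedule, config.hemodynamic_delay_s)
        for tag, arr in (("D", amap.statistic), ("p", amap.p_raw), ("q", amap.q),
                         ("sign", amap.sign.astype(np.int16)),
                         ("tsnr", resp.tsnr), ("cnr", resp.cnr)):
            nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), bold.affine),
                     str(outdir / "maps" / f"{run_name}_{tag}.nii"))
        results[run_name] = {"amap": amap, "gmap": gmap, "resp": resp}

    # per-ROI tables, both signs, all runs
    roi_tables = {}
    for run_name, res in results.items():
        roi_tables[run_name] = {}
        for sign in ("positive", "negative"):
            table = metrics.roi_summarize(
                res["amap"].sign, res["resp"].delta_pct, res["resp"].tsnr,
                res["resp"].cnr, roi_set, sign,
            )
            table.to_csv(outdir / "tables" / f"{run_name}_{sign}_roi_summary.tsv",
                         sep="\t", index=False)
            roi_tables[run_name][sign] = table.to_dict(orient="records")

    # condition comparison on the shared voxel set (single subject, voxelwise)
    cnr_rows = []
    if len(config.conditions) >= 2:
        a, b = config.conditions[0], config.conditions[1]
        table = cnr_compare(
            results[a]["resp"].cnr, results[b]["resp"].cnr,
            results[a]["amap"].sign, results[b]["amap"].sign,
            labels, names,
        )
        table.to_csv(outdir / "tables" / "cnr_compare.tsv", sep="\t", index=False)
        cnr_rows = table.to_dict(orient="records")

    # scan/re-scan reproducibility of the first condition
    first = config.conditions[0]
    rescan = f"{config.retest_condition}_rescan"
    dice_tab = metrics.retest_dice(
        results[first]["amap"].sign, results[rescan]["amap"].sign, roi_set
    )
    icc_tab = metrics.retest_icc(
        results[first]["amap"].sign, results[first]["resp"].delta_pct,
        results[rescan]["resp"].delta_pct, roi_set,
    )
    dice_tab.to_csv(outdir / "tables" / "retest_dice.tsv", sep="\t", index=False)
    icc_tab.to_csv(outdir / "tables" / "retest_icc.tsv", sep="\t", index=False)

    summary = {
        "version": __version__,
        "seed": int(config.seed),
        "alpha": config.alpha,
        "paradigm": {
            "n_volumes": schedule.n_volumes,
            "n_blocks": schedule.n_blocks,
            "total_seconds": schedule.total_seconds,
            "pulses_per_block": schedule.pulses_per_block,
        },
        "conditions": {
            run_name: {
                "ks_counts": res["amap"].counts(),
                "glm_counts": res["gmap"].counts(),
            }
            for run_name, res in results.items()
        },
        "roi_tables": roi_tables,
        "cnr_comparison": cnr_rows,
        "retest": {
            "dice": dice_tab.to_dict(orient="records"),
            "icc": icc_tab.replace({np.nan: None}).to_dict(orient="records"),
        },
    }
    summary = json.loads(json.dumps(summary, default=_jsonify))
    oio.write_summary(outdir / "summary.json", summary)
    logger.info("pipeline complete; summary written to %s", outdir / "summary.json")
    return summary


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
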