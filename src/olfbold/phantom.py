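"""Synthetic 4-D BOLD phantom with known activation structure.

The phantom emulates the signal phenomenology of a pulsed odor block design:

* a bi-phasic response within each stimulus-on block — two smooth bumps with
  peaks near 15 s and 45 s into the block; in a small olfactory-bulb-like
  region the second peak is strongly suppressed (second-peak ratio rho << 1),
  while cortical regions have rho ≈ 1;
* block-wise habituation — block b's response is scaled by a multiplier
  h_b (default (1, 0.35, 0.15) for positive voxels; negative voxels habituate
  weakly, default (1, 1, 0.8));
* negatively responding voxels with smaller magnitude;
* a post-stimulus transition: exponential decay (time constant tau) truncated
  to zero 45 s after block end, inside the 50-100%-of-on-duration transition
  range — so the second half of every off period is response-free and the
  ΔS/S baseline rule is exactly self-consistent;
* slow scanner drift, a respiratory component (emitted as a nuisance trace so
  regression can be exercised), white thermal noise, and static multiplicative
  signal-dropout fields distinguishing an EPI-like from a T2prep-like
  acquisition.

Amplitudes are in fractional ΔS/S: the within-block bump shape is normalized
to unit mean over each block's ON volumes, so a voxel with amplitude ``a`` and
habituation multiplier ``h_b`` has a true block-b ΔS/S of exactly
``100 * a * h_b`` percent under the analysis baseline rule.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .paradigm import ParadigmSchedule, build_paradigm

__all__ = [
    "RoiSpec",
    "DropoutSpec",
    "SimulationConfig",
    "GroundTruth",
    "Bold4D",
    "default_paradigm",
    "default_config",
    "null_config",
    "response_template",
    "simulate_dataset",
    "simulate_retest_pair",
    "simulate_subject_deltas",
    "roi_label_map",
    "dropout_field",
]


@dataclass
class Bold4D:
    """A 4-D BOLD series with voxel geometry.

    ``data`` is indexed (x, y, z, t); the affine maps voxel indices to mm
    (RAS+).  ``brain_mask`` marks voxels that belong to the imaged object.
    """

    data: np.ndarray
    tr_seconds: float
    voxel_mm: tuple[float, float, float]
    affine: np.ndarray
    brain_mask: np.ndarray

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def copy(self) -> "Bold4D":
        return Bold4D(
            data=self.data.copy(),
            tr_seconds=self.tr_seconds,
            voxel_mm=self.voxel_mm,
            affine=self.affine.copy(),
            brain_mask=self.brain_mask.copy(),
        )


@dataclass(frozen=True)
class RoiSpec:
    """A cuboid or spherical region with an optional activation assignment.

    ``amplitude`` (fractional ΔS/S), ``rho`` (second-peak ratio) and
    ``habituation`` default to the global values in :class:`SimulationConfig`.
    """

    name: str
    center: tuple[int, int, int]
    size: tuple[int, int, int] | int
    shape: str = "cuboid"             # 'cuboid' (size = extents) or 'sphere' (size = radius)
    activation: str = "none"          # 'positive' | 'negative' | 'none'
    amplitude: float | None = None
    rho: float | None = None
    habituation: tuple | None = None

    def voxels(self, grid_shape) -> np.ndarray:
        """Boolean mask of the ROI on the grid; raises if it does not fit."""
        mask = np.zeros(grid_shape, dtype=bool)
        c = np.asarray(self.center)
        if self.shape == "cuboid":
            ext = np.asarray(self.size)
            lo = c - ext // 2
            hi = lo + ext
            if (lo < 0).any() or (hi > np.asarray(grid_shape)).any():
                raise ValueError(
                    f"ROI {self.name!r} does not fit on grid {grid_shape}"
                )
            mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        elif self.shape == "sphere":
            r = float(self.size)
            if ((c - r) < 0).any() or ((c + r) >= np.asarray(grid_shape)).any():
                raise ValueError(
                    f"ROI {self.name!r} does not fit on grid {grid_shape}"
                )
            gx, gy, gz = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
            mask[(gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2 <= r**2] = True
        else:
            raise ValueError(f"unknown ROI shape {self.shape!r}")
        return mask


@dataclass(frozen=True)
class DropoutSpec:
    """Static multiplicative attenuation with a flat core.

    Attenuation = 1 - (1-floor) * exp(-(r^2 / 2 sigma^2)^2): a super-Gaussian
    well that sits at ``floor`` across the core (the bulb-like region) and
    recovers to 1 quickly, leaving distant control regions untouched.
    """

    center: tuple[int, int, int]
    sigma_mm: float
    floor: float = 0.05


def dropout_field(grid_shape, voxel_mm: float, spec: DropoutSpec | None) -> np.ndarray:
    """Attenuation map in [0, 1]; ``spec=None`` means no dropout (all ones)."""
    if spec is None:
        return np.ones(grid_shape)
    if not 0.0 <= spec.floor <= 1.0:
        raise ValueError("dropout floor must be in [0, 1]")
    c = np.asarray(spec.center, dtype=float)
    gx, gy, gz = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
    r2 = ((gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2) * voxel_mm**2
    return 1.0 - (1.0 - spec.floor) * np.exp(-((r2 / (2.0 * spec.sigma_mm**2)) ** 2))


def _default_roi_layout() -> tuple[RoiSpec, ...]:
    """Eight regions on the 40x40x24 grid.

    A desk-scale stand-in for the anatomical ROI set: a 15-voxel bulb-like
    region sitting inside the EPI dropout zone (strong response, suppressed
    second peak), four cortical/subcortical positive regions, two negative
    regions, and one quiet control region.
    """
    return (
        RoiSpec("olfactory_bulb", (20, 7, 6), (5, 3, 1), "cuboid",
                "positive", amplitude=0.022, rho=0.2),
        RoiSpec("piriform", (14, 14, 8), (4, 4, 3), "cuboid",
                "positive", amplitude=0.013),
        RoiSpec("orbitofrontal", (26, 10, 8), (4, 4, 3), "cuboid",
                "positive", amplitude=0.008),
        RoiSpec("thalamus", (20, 22, 12), (4, 4, 4), "cuboid",
                "positive", amplitude=0.012),
        RoiSpec("control_posterior", (20, 31, 12), (4, 4, 3), "cuboid",
                "positive", amplitude=0.010),
        RoiSpec("neg_insula", (27, 20, 10), (4, 4, 3), "cuboid",
                "negative", amplitude=0.005),
        RoiSpec("neg_cingulate", (20, 26, 16), (3, 3, 3), "cuboid",
                "negative", amplitude=0.004),
        RoiSpec("quiet", (12, 26, 12), (4, 4, 3), "cuboid", "none"),
    )


@dataclass
class SimulationConfig:
    """All knobs of the phantom.  Identical (config, seed) => identical data."""

    grid_shape: tuple[int, int, int] = (40, 40, 24)
    voxel_mm: float = 1.5
    roi_layout: tuple[RoiSpec, ...] = field(default_factory=_default_roi_layout)
    # positive response model
    a1: float = 0.022                     # block-1 fractional ΔS/S
    h: tuple = (1.0, 0.35, 0.15)          # habituation multipliers, h[0] == 1
    rho: float = 1.0                      # second-peak ratio (cortical default)
    t1_s: float = 15.0                    # first peak center within the block
    t2_s: float = 45.0                    # second peak center
    w_s: float = 8.0                      # Gaussian bump SD
    tau_trans_s: float = 15.0             # post-stimulus decay time constant
    transition_cutoff_s: float = 45.0     # decay truncated to 0 after this
    # negative response model
    a_neg: float = 0.005
    h_neg: tuple = (1.0, 1.0, 0.8)
    # signal and noise
    baseline_intensity: float = 1000.0
    sigma_thermal: float = 1000.0 / 60.0  # white noise SD (baseline tSNR 60)
    drift_amp: float = 5.0                # slow drift amplitude (signal units)
    drift_period_s: float = 300.0
    resp_amp: float = 2.0                 # respiratory amplitude (signal units)
    resp_freq_hz: float = 0.3
    # acquisition conditions: name -> DropoutSpec (None = no dropout)
    dropout: dict = field(default_factory=lambda: {
        "t2prep_like": None,
        "epi_like": DropoutSpec(center=(20, 7, 6), sigma_mm=9.0, floor=0.05),
    })
    seed: int = 0

    def validate(self) -> None:
        if abs(self.h[0] - 1.0) > 1e-12 or abs(self.h_neg[0] - 1.0) > 1e-12:
            raise ValueError("the first habituation multiplier must be 1")
        if self.tau_trans_s <= 0:
            raise ValueError("tau_trans_s must be positive")
        for name in ("a1", "a_neg", "baseline_intensity", "sigma_thermal",
                     "drift_amp", "resp_amp"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.a_neg < 0:
            raise ValueError("a_neg is a magnitude and must be >= 0")


@dataclass
class GroundTruth:
    """Validation targets emitted alongside a simulated dataset."""

    pos_mask: np.ndarray                   # boolean (x, y, z)
    neg_mask: np.ndarray
    true_delta: np.ndarray                 # (x, y, z, n_blocks) percent ΔS/S
    nuisance_traces: np.ndarray            # (n_volumes, n_traces)
    trace_names: tuple = ("respiratory",)


def default_paradigm() -> ParadigmSchedule:
    """The 10-min olfactory paradigm: 60 s off + 3 x (60 s pulsed-on + 120 s off)."""
    return build_paradigm(2.0, 60.0, 3, 60.0, 120.0, 1.0, 2.0)


def default_config(**overrides) -> SimulationConfig:
    cfg = SimulationConfig(**overrides)
    cfg.validate()
    return cfg


def null_config(**overrides) -> SimulationConfig:
    """Default config with all activation amplitudes set to zero."""
    cfg = default_config(**overrides)
    cfg.a1 = 0.0
    cfg.a_neg = 0.0
    cfg.roi_layout = tuple(
        dataclasses.replace(r, amplitude=0.0) for r in cfg.roi_layout
    )
    return cfg


# --------------------------------------------------------------------- model
def _bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def response_template(
    schedule: ParadigmSchedule,
    cfg: SimulationConfig,
    sign: str = "+",
    amplitude: float | None = None,
    rho: float | None = None,
    habituation: tuple | None = None,
) -> np.ndarray:
    """Per-volume fractional response of one voxel class.

    Within block b the response is ``a * h_b * [g(t; t1, w) + rho * g(t; t2, w)]``
    with g a unit-peak Gaussian bump, normalized so that the mean over the
    block's ON volumes equals ``a * h_b``.  After block cessation the response
    decays exponentially (time constant ``tau_trans_s``) and is truncated to
    zero beyond ``transition_cutoff_s``.  It is exactly zero before the first
    block.  ``sign='-'`` uses ``-a_neg`` and the negative habituation
    multipliers.
    """
    if cfg.tau_trans_s <= 0:
        raise ValueError("tau_trans_s must be positive")
    if sign == "+":
        a = cfg.a1 if amplitude is None else amplitude
        h = cfg.h if habituation is None else habituation
        sgn = 1.0
    elif sign == "-":
        a = cfg.a_neg if amplitude is None else amplitude
        h = cfg.h_neg if habituation is None else habituation
        sgn = -1.0
    else:
        raise ValueError("sign must be '+' or '-'")
    if len(h) < schedule.n_blocks:
        raise ValueError(
            f"habituation multipliers ({len(h)}) must cover all "
            f"{schedule.n_blocks} blocks"
        )
    r = cfg.rho if rho is None else rho
    if not 0.0 <= r <= 1.0:
        raise ValueError("rho must be in [0, 1]")

    t = schedule.times
    out = np.zeros(schedule.n_volumes)
    for b in range(1, schedule.n_blocks + 1):
        start = schedule.block_start(b)
        end = start + schedule.on_seconds
        on = (t >= start) & (t < end)
        if not on.any():
            raise ValueError(f"block {b} contains no ON volumes")
        tb = t[on] - start
        shape = _bump(tb, cfg.t1_s, cfg.w_s) + r * _bump(tb, cfg.t2_s, cfg.w_s)
        norm = shape.mean()
        if norm <= 0:
            raise ValueError("degenerate bump shape (zero mean over ON volumes)")
        shape = shape / norm
        out[on] = sgn * a * h[b - 1] * shape
        # post-stimulus transition, truncated so baselines stay response-free
        shape_end = (
            _bump(schedule.on_seconds, cfg.t1_s, cfg.w_s)
            + r * _bump(schedule.on_seconds, cfg.t2_s, cfg.w_s)
        ) / norm
        trans = (t >= end) & (t < end + cfg.transition_cutoff_s)
        out[trans] = (
            sgn * a * h[b - 1] * shape_end
            * np.exp(-(t[trans] - end) / cfg.tau_trans_s)
        )
    return out


def _drift_curve(schedule, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth aperiodic scanner drift, shared by all voxels.

    A random combination of the slow discrete-cosine modes with periods
    down to ``drift_period_s``, scaled so its RMS matches a sinusoid of
    amplitude ``drift_amp`` — i.e. drift is sub-cutoff trend content, the
    class of signal a high-pass at 1/(paradigm cycle) is meant to remove.
    The coefficients are drawn even when drift_amp is 0 so the rng stream
    (and hence the noise realization) does not depend on the amplitude.
    """
    n = schedule.n_volumes
    k_max = max(1, int(np.floor(2.0 * n * schedule.tr_seconds / cfg.drift_period_s)))
    coefs = rng.normal(size=k_max)
    i = np.arange(n)
    basis = np.column_stack(
        [np.cos(np.pi * k * (2 * i + 1) / (2.0 * n)) for k in range(1, k_max + 1)]
    )
    basis /= np.linalg.norm(basis, axis=0)
    curve = basis @ coefs
    sd = curve.std()
    if sd == 0:
        return np.zeros(n)
    return cfg.drift_amp / np.sqrt(2.0) * curve / sd


def _brain_mask(cfg: SimulationConfig, roi_masks) -> np.ndarray:
    nx, ny, nz = cfg.grid_shape
    gx, gy, gz = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ax, ay, az = 0.95 * nx / 2, 0.95 * ny / 2, 0.95 * nz / 2
    mask = (
        ((gx - cx) / ax) ** 2 + ((gy - cy) / ay) ** 2 + ((gz - cz) / az) ** 2
    ) <= 1.0
    for m in roi_masks:
        mask |= m
    return mask


def roi_label_map(cfg: SimulationConfig) -> tuple[np.ndarray, dict]:
    """Integer label image (0 = background) and {label: name} table."""
    labels = np.zeros(cfg.grid_shape, dtype=np.int16)
    names = {}
    for i, roi in enumerate(cfg.roi_layout, start=1):
        m = roi.voxels(cfg.grid_shape)
        if (labels[m] != 0).any():
            raise ValueError(f"ROI {roi.name!r} overlaps another ROI")
        labels[m] = i
        names[i] = roi.name
    return labels, names


def _true_block_deltas(schedule, cfg, roi: RoiSpec) -> np.ndarray:
    """Noiseless per-block ΔS/S (%) of an ROI, via the analysis baseline rule."""
    from .activation import delta_s_over_s

    sign = "+" if roi.activation == "positive" else "-"
    series = 1.0 + response_template(
        schedule, cfg, sign,
        amplitude=roi.amplitude, rho=roi.rho, habituation=roi.habituation,
    )
    return np.array(
        [delta_s_over_s(series, schedule, block=b) for b in range(1, schedule.n_blocks + 1)]
    )


def simulate_dataset(
    schedule: ParadigmSchedule,
    cfg: SimulationConfig,
    condition: str = "t2prep_like",
    seed: int | None = None,
) -> tuple[Bold4D, GroundTruth]:
    """Generate one 4-D dataset and its ground truth.

    Voxel value = baseline * dropout(x) * (1 + response(t)) + drift(t)
    + respiratory(x, t) + thermal noise.  Thermal noise is unattenuated by
    dropout (it is receiver noise), so dropout degrades tSNR as in real data.
    """
    cfg.validate()
    if condition not in cfg.dropout:
        raise ValueError(
            f"unknown condition {condition!r}; have {sorted(cfg.dropout)}"
        )
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)

    roi_masks = [roi.voxels(cfg.grid_shape) for roi in cfg.roi_layout]
    labels, _ = roi_label_map(cfg)  # also validates non-overlap
    brain = _brain_mask(cfg, roi_masks)
    nx, ny, nz = cfg.grid_shape
    t = schedule.times
    nt = schedule.n_volumes

    response = np.zeros((nx, ny, nz, nt))
    pos_mask = np.zeros(cfg.grid_shape, dtype=bool)
    neg_mask = np.zeros(cfg.grid_shape, dtype=bool)
    true_delta = np.zeros(cfg.grid_shape + (schedule.n_blocks,))
    for roi, m in zip(cfg.roi_layout, roi_masks):
        if roi.activation == "none":
            continue
        sign = "+" if roi.activation == "positive" else "-"
        tmpl = response_template(
            schedule, cfg, sign,
            amplitude=roi.amplitude, rho=roi.rho, habituation=roi.habituation,
        )
        response[m] = tmpl
        (pos_mask if sign == "+" else neg_mask)[m] = True
        true_delta[m] = _true_block_deltas(schedule, cfg, roi)

    drop = dropout_field(cfg.grid_shape, cfg.voxel_mm, cfg.dropout[condition])
    data = cfg.baseline_intensity * drop[..., None] * (1.0 + response)

    # deterministic draw order: drift coefficients, respiratory phase,
    # respiratory weights, thermal noise
    drift = _drift_curve(schedule, cfg, rng)
    resp_phase = rng.uniform(0, 2 * np.pi)
    resp_weight = rng.uniform(0.5, 1.5, size=cfg.grid_shape)
    if cfg.drift_amp != 0:
        data += drift
    resp_trace = np.sin(2 * np.pi * cfg.resp_freq_hz * t + resp_phase)
    if cfg.resp_amp != 0:
        data += cfg.resp_amp * resp_weight[..., None] * resp_trace
    if cfg.sigma_thermal > 0:
        data += rng.normal(0.0, cfg.sigma_thermal, size=data.shape)

    vx = cfg.voxel_mm
    affine = np.diag([vx, vx, vx, 1.0])
    bold = Bold4D(
        data=data,
        tr_seconds=schedule.tr_seconds,
        voxel_mm=(vx, vx, vx),
        affine=affine,
        brain_mask=brain,
    )
    truth = GroundTruth(
        pos_mask=pos_mask,
        neg_mask=neg_mask,
        true_delta=true_delta,
        nuisance_traces=resp_trace[:, None],
    )
    return bold, truth


def simulate_retest_pair(
    schedule: ParadigmSchedule,
    cfg: SimulationConfig,
    seed_a: int,
    seed_b: int,
    condition: str = "t2prep_like",
):
    """Scan/re-scan pair: identical response and truth fields, independent noise."""
    if seed_a == seed_b:
        raise ValueError("scan and re-scan seeds must differ")
    return (
        simulate_dataset(schedule, cfg, condition, seed=seed_a),
        simulate_dataset(schedule, cfg, condition, seed=seed_b),
    )


def simulate_subject_deltas(
    n_subjects: int,
    block_means,
    sd_between: float,
    sd_within: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Subject-by-block ΔS/S table: block mean + subject intercept + noise.

    Emulates a group-level habituation dataset: each subject has a random
    intercept (between-subject SD ``sd_between``) and independent
    within-subject error (SD ``sd_within``) around the population block means.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    means = np.asarray(block_means, dtype=float)
    subj = rng.normal(0.0, sd_between, size=(n_subjects, 1))
    err = rng.normal(0.0, sd_within, size=(n_subjects, means.size))
    return means[None, :] + subj + err
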