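"""Voxelwise detection and quantification of stimulus-locked signal change.

Detection uses the two-sample KS test between the ON-labelled and
OFF-labelled volumes of each voxel (the OFF sample deliberately includes the
post-stimulus transition; the transition-exclusion rule applies only to the
ΔS/S baseline).  Multiplicity is controlled with Benjamini–Hochberg FDR over
in-mask voxels, and activated voxels are split by the sign of their pooled
ΔS/S.  A conventional GLM detector (non-habituating regressor, t statistic)
is provided as a comparator: with strong habituation the ON-period signal is
high-variance rather than shifted, which the KS statistic is sensitive to and
a fixed-shape regressor is not.

ΔS/S for block b is the percent change of the mean ON-block signal relative
to the mean over the *second half* of the stimulus-off period preceding the
block; tSNR is temporal mean over temporal SD, and CNR = tSNR x block-1 ΔS/S
(as a fraction).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import ks as _ks
from .paradigm import ParadigmSchedule
from .phantom import Bold4D, SimulationConfig, response_template

__all__ = [
    "ActivationMap",
    "BlockResponse",
    "ks_activation_map",
    "glm_activation_map",
    "delta_s_over_s",
    "block_delta_maps",
    "block_response",
    "classify_sign",
    "tsnr_map",
    "cnr_map",
    "cnr_compare",
    "SIGN_NONE",
    "SIGN_POSITIVE",
    "SIGN_NEGATIVE",
]

logger = logging.getLogger("olfbold")

SIGN_NONE, SIGN_POSITIVE, SIGN_NEGATIVE = 0, 1, 2


@dataclass
class ActivationMap:
    """Per-voxel test results on the acquisition grid.

    ``sign`` uses integer labels {0: none, 1: positive, 2: negative}; a voxel
    has a nonzero sign only if it is active (q < alpha).  ``tested`` marks
    voxels that entered the test (in-mask, nonzero temporal SD).
    """

    statistic: np.ndarray
    p_raw: np.ndarray
    q: np.ndarray
    active: np.ndarray
    sign: np.ndarray
    alpha: float
    tested: np.ndarray
    method: str

    def counts(self):
        return {
            "tested": int(self.tested.sum()),
            "active": int(self.active.sum()),
            "positive": int((self.sign == SIGN_POSITIVE).sum()),
            "negative": int((self.sign == SIGN_NEGATIVE).sum()),
        }


@dataclass
class BlockResponse:
    """ΔS/S per block (percent), pooled ΔS/S, tSNR and CNR maps."""

    delta_pct: np.ndarray          # (x, y, z, n_blocks)
    delta_overall_pct: np.ndarray  # (x, y, z)
    tsnr: np.ndarray               # (x, y, z); inf where SD == 0
    cnr: np.ndarray                # tsnr * block-1 ΔS/S fraction


def _masked_series(vol: Bold4D) -> tuple[np.ndarray, np.ndarray]:
    mask = vol.brain_mask
    return vol.data[mask], mask


def _bh_fill(p_flat: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    if p_flat.size == 0:
        return p_flat.copy(), np.zeros(0, dtype=bool)
    _, q, _, _ = multipletests(p_flat, alpha=alpha, method="fdr_bh")
    return q, q < alpha


def ks_activation_map(
    vol: Bold4D,
    schedule: ParadigmSchedule,
    alpha: float = 0.01,
    hemodynamic_delay_s: float = 0.0,
    method: str = "auto",
    baseline_rule: str = "preceding",
) -> ActivationMap:
    """KS two-sample activation map with BH-FDR and sign classification."""
    if vol.n_volumes != schedule.n_volumes:
        raise ValueError("volume count does not match the schedule")
    on = schedule.on_volume_mask(delay_s=hemodynamic_delay_s)
    if on.all() or not on.any():
        raise ValueError("schedule is all-ON or all-OFF; KS test undefined")

    series, mask = _masked_series(vol)
    sd = series.std(axis=1, ddof=1)
    testable = sd > 0
    if not testable.all():
        logger.info("excluding %d zero-variance voxels from testing",
                    int((~testable).sum()))
    D_flat = np.zeros(series.shape[0])
    p_flat = np.ones(series.shape[0])
    if testable.any():
        D_flat[testable], p_flat[testable] = _ks.ks_map(
            series[testable], on, method=method
        )
    q_flat = np.ones(series.shape[0])
    act_flat = np.zeros(series.shape[0], dtype=bool)
    q_flat[testable], act_flat[testable] = _bh_fill(p_flat[testable], alpha)

    shape = vol.data.shape[:3]
    D = np.zeros(shape); D[mask] = D_flat
    p = np.ones(shape); p[mask] = p_flat
    q = np.ones(shape); q[mask] = q_flat
    active = np.zeros(shape, dtype=bool); active[mask] = act_flat
    tested = np.zeros(shape, dtype=bool); tested[mask] = testable

    delta_overall = block_delta_maps(
        vol, schedule, delay_s=hemodynamic_delay_s, baseline_rule=baseline_rule
    )[1]
    sign = classify_sign(delta_overall, active)
    amap = ActivationMap(D, p, q, active, sign, alpha, tested, method="ks")
    logger.info("ks_activation_map alpha=%g delay=%gs: %s",
                alpha, hemodynamic_delay_s, amap.counts())
    return amap


def glm_activation_map(
    vol: Bold4D,
    schedule: ParadigmSchedule,
    alpha: float = 0.01,
    hemodynamic_delay_s: float = 0.0,
    template: np.ndarray | None = None,
    baseline_rule: str = "preceding",
    filter_hp_cutoff_hz: float | None = None,
) -> ActivationMap:
    """GLM comparator: t test on a non-habituating block-response regressor.

    If the data were high-pass filtered, pass the same cutoff via
    ``filter_hp_cutoff_hz`` so the regressor is filtered identically.

    The regressor is the conventional non-habituating one: the stimulus
    boxcar convolved with a smooth response kernel (a Gaussian bump peaking
    ``t1_s`` after its input), i.e. every block is assumed to evoke the same
    sustained response.  Under strong habituation the true ON-period signal
    is block-1-heavy and high-variance, which this fixed-shape regressor
    cannot capture.
    """
    if vol.n_volumes != schedule.n_volumes:
        raise ValueError("volume count does not match the schedule")
    on = schedule.on_volume_mask(delay_s=hemodynamic_delay_s)
    if on.all() or not on.any():
        raise ValueError("schedule is all-ON or all-OFF; GLM undefined")
    if template is None:
        cfg = SimulationConfig()
        t = schedule.times
        kernel_t = np.arange(0.0, cfg.t1_s + 4 * cfg.w_s, schedule.tr_seconds)
        kernel = np.exp(-0.5 * ((kernel_t - cfg.t1_s) / cfg.w_s) ** 2)
        kernel /= kernel.sum()
        boxcar = schedule.on_volume_mask().astype(float)
        template = np.convolve(boxcar, kernel)[: schedule.n_volumes]
    template = np.asarray(template, dtype=float)
    if hemodynamic_delay_s > 0:
        shift = int(round(hemodynamic_delay_s / schedule.tr_seconds))
        template = np.concatenate([np.zeros(shift), template[: len(template) - shift]])
    if filter_hp_cutoff_hz:
        from .preprocess import dct_basis

        basis = dct_basis(len(template), schedule.tr_seconds, filter_hp_cutoff_hz)
        if basis.shape[1]:
            template = template - basis @ (basis.T @ template)

    series, mask = _masked_series(vol)
    sd = series.std(axis=1, ddof=1)
    testable = sd > 0
    nt = series.shape[1]
    x = template - template.mean()
    sxx = float(x @ x)
    if sxx <= 0:
        raise ValueError("degenerate (constant) GLM regressor")
    yc = series - series.mean(axis=1, keepdims=True)
    beta = yc @ x / sxx
    resid = yc - beta[:, None] * x[None, :]
    dof = nt - 2
    sigma2 = (resid**2).sum(axis=1) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta / np.sqrt(sigma2 / sxx)
    tval[~testable] = 0.0
    p_flat = np.ones(series.shape[0])
    p_flat[testable] = 2.0 * sps.t.sf(np.abs(tval[testable]), dof)
    q_flat = np.ones(series.shape[0])
    act_flat = np.zeros(series.shape[0], dtype=bool)
    q_flat[testable], act_flat[testable] = _bh_fill(p_flat[testable], alpha)

    shape = vol.data.shape[:3]
    # report |t| rescaled to [0, 1] is meaningless; store raw t magnitude map
    T = np.zeros(shape); T[mask] = np.abs(tval)
    p = np.ones(shape); p[mask] = p_flat
    q = np.ones(shape); q[mask] = q_flat
    active = np.zeros(shape, dtype=bool); active[mask] = act_flat
    tested = np.zeros(shape, dtype=bool); tested[mask] = testable

    delta_overall = block_delta_maps(
        vol, schedule, delay_s=hemodynamic_delay_s, baseline_rule=baseline_rule
    )[1]
    sign = classify_sign(delta_overall, active)
    amap = ActivationMap(T, p, q, active, sign, alpha, tested, method="glm")
    logger.info("glm_activation_map alpha=%g delay=%gs: %s",
                alpha, hemodynamic_delay_s, amap.counts())
    return amap


# ------------------------------------------------------------------- ΔS/S
def delta_s_over_s(
    series,
    schedule: ParadigmSchedule,
    block: int | str = "all",
    delay_s: float = 0.0,
    baseline_rule: str = "preceding",
) -> float:
    """Percent signal change of one voxel time course.

    ``block=b`` uses the mean over block b's ON volumes against the mean over
    the second half of the off period preceding the block; ``block='all'``
    pools all ON volumes against the union of all those baseline windows.
    """
    series = np.asarray(series, dtype=float).ravel()
    if series.size != schedule.n_volumes:
        raise ValueError("series length does not match the schedule")
    if block == "all":
        on = schedule.on_volume_mask(delay_s=delay_s)
        base = np.zeros(schedule.n_volumes, dtype=bool)
        for b in range(1, schedule.n_blocks + 1):
            base |= schedule.baseline_volume_mask(b, delay_s, baseline_rule)
    else:
        on = schedule.on_volume_mask(block=int(block), delay_s=delay_s)
        base = schedule.baseline_volume_mask(int(block), delay_s, baseline_rule)
    b_mean = series[base].mean()
    if b_mean == 0:
        raise ValueError("zero baseline mean; ΔS/S undefined for this voxel")
    return float(100.0 * (series[on].mean() - b_mean) / b_mean)


def block_delta_maps(
    vol: Bold4D,
    schedule: ParadigmSchedule,
    delay_s: float = 0.0,
    baseline_rule: str = "preceding",
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ΔS/S: per-block (x, y, z, B) and pooled (x, y, z) percent maps.

    Voxels with a zero baseline mean get NaN (logged), rather than an error
    as in the single-voxel routine, so whole-brain maps remain computable.
    """
    series, mask = _masked_series(vol)
    shape = vol.data.shape[:3]
    nb = schedule.n_blocks
    delta = np.full(shape + (nb,), np.nan)
    base_union = np.zeros(schedule.n_volumes, dtype=bool)
    dflat = np.empty((series.shape[0], nb))
    for b in range(1, nb + 1):
        on = schedule.on_volume_mask(block=b, delay_s=delay_s)
        base = schedule.baseline_volume_mask(b, delay_s, baseline_rule)
        base_union |= base
        bmean = series[:, base].mean(axis=1)
        bad = bmean == 0
        if bad.any():
            logger.warning("%d voxels with zero baseline in block %d set to NaN",
                           int(bad.sum()), b)
        with np.errstate(divide="ignore", invalid="ignore"):
            dflat[:, b - 1] = 100.0 * (series[:, on].mean(axis=1) - bmean) / bmean
        dflat[bad, b - 1] = np.nan
    delta[mask] = dflat

    on_all = schedule.on_volume_mask(delay_s=delay_s)
    bmean = series[:, base_union].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        oflat = 100.0 * (series[:, on_all].mean(axis=1) - bmean) / bmean
    oflat[bmean == 0] = np.nan
    overall = np.full(shape, np.nan)
    overall[mask] = oflat
    return delta, overall


def classify_sign(delta_overall_pct: np.ndarray, active: np.ndarray) -> np.ndarray:
    """{none, positive, negative} labels; active voxels with ΔS/S exactly 0
    (or NaN) stay 'none' and are logged."""
    sign = np.full(active.shape, SIGN_NONE, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        sign[active & (delta_overall_pct > 0)] = SIGN_POSITIVE
        sign[active & (delta_overall_pct < 0)] = SIGN_NEGATIVE
    odd = active & (sign == SIGN_NONE)
    if odd.any():
        logger.info("%d active voxels with zero/undefined ΔS/S left unclassified",
                    int(odd.sum()))
    return sign


# ---------------------------------------------------------------- tSNR / CNR
def tsnr_map(vol: Bold4D) -> np.ndarray:
    """Temporal mean over temporal SD (n-1 denominator); inf where SD == 0.

    Computed over the whole grid; in-mask restriction and the exclusion of
    infinite values are applied by ROI summaries.
    """
    if vol.n_volumes < 3:
        raise ValueError("tSNR needs at least 3 time points")
    mean = vol.data.mean(axis=3)
    sd = vol.data.std(axis=3, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = mean / sd
    out[sd == 0] = np.inf
    return out


def cnr_map(tsnr: np.ndarray, block1_delta_pct: np.ndarray) -> np.ndarray:
    """CNR = tSNR x block-1 ΔS/S expressed as a fraction."""
    if tsnr.shape != block1_delta_pct.shape:
        raise ValueError("tSNR and ΔS/S maps are on different grids")
    return tsnr * (block1_delta_pct / 100.0)


def block_response(
    vol: Bold4D,
    schedule: ParadigmSchedule,
    delay_s: float = 0.0,
    baseline_rule: str = "preceding",
) -> BlockResponse:
    delta, overall = block_delta_maps(vol, schedule, delay_s, baseline_rule)
    tsnr = tsnr_map(vol)
    return BlockResponse(delta, overall, tsnr, cnr_map(tsnr, delta[..., 0]))


def cnr_compare(
    cnr_a: np.ndarray,
    cnr_b: np.ndarray,
    sign_a: np.ndarray,
    sign_b: np.ndarray,
    roi_labels: np.ndarray,
    roi_names: dict,
):
    """Per-ROI mean CNR of two conditions over a shared voxel set.

    The comparison set in each ROI is the union of voxels positively
    activated in either condition, and the identical set is used for both
    conditions.  Returns a DataFrame (roi, n_voxels, cnr_a, cnr_b); ROIs with
    an empty union are flagged with n_voxels = 0 and NaN means.
    """
    import pandas as pd

    for arr in (cnr_b, sign_a, sign_b, roi_labels):
        if arr.shape != cnr_a.shape:
            raise ValueError("all maps must share one grid")
    union = (sign_a == SIGN_POSITIVE) | (sign_b == SIGN_POSITIVE)
    rows = []
    for lab, name in sorted(roi_names.items()):
        sel = union & (roi_labels == lab) & np.isfinite(cnr_a) & np.isfinite(cnr_b)
        n = int(sel.sum())
        rows.append({
            "roi": name,
            "n_voxels": n,
            "cnr_a": float(cnr_a[sel].mean()) if n else math.nan,
            "cnr_b": float(cnr_b[sel].mean()) if n else math.nan,
        })
    return pd.DataFrame(rows)
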