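"""ROI-level and group-level statistics.

Habituation across stimulation blocks is tested with a one-way
repeated-measures ANOVA (subjects as random blocks); acquisition conditions
are compared per ROI with paired t tests, BH-FDR across ROIs, Cohen's d with
the pooled SD, and the relative difference 100*(mean_a - mean_b)/mean_b %.
Scan–rescan reproducibility uses the Dice coefficient on binarized
activation masks and the two-way random-effects absolute-agreement
single-measure ICC(2, 1) on voxelwise ΔS/S pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

from .activation import SIGN_NEGATIVE, SIGN_POSITIVE

__all__ = [
    "RoiSet",
    "habituation_anova",
    "relative_difference",
    "paired_compare",
    "dice",
    "icc",
    "roi_visibility_count",
    "roi_summarize",
    "retest_dice",
    "retest_icc",
]

logger = logging.getLogger("olfbold")


@dataclass
class RoiSet:
    """Integer label image plus a {label: name} table."""

    labels: np.ndarray
    names: dict

    def __post_init__(self):
        if (self.labels < 0).any():
            raise ValueError("ROI labels must be non-negative")
        present = set(np.unique(self.labels)) - {0}
        missing = set(self.names) - present
        if missing:
            raise ValueError(f"named labels missing from the map: {sorted(missing)}")

    def mask(self, name: str) -> np.ndarray:
        for lab, n in self.names.items():
            if n == name:
                return self.labels == lab
        raise KeyError(name)


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D subjects x blocks table")
    if np.isnan(arr).any():
        raise ValueError("table has missing cells")
    return arr


def habituation_anova(delta_by_block) -> tuple[float, float]:
    """One-way repeated-measures ANOVA across blocks.

    ``delta_by_block`` is subjects x blocks (array or DataFrame).  Returns
    (F, p).  Identical values in every block give F = 0, p = 1.
    """
    arr = _as_table(delta_by_block)
    n_subj, n_blocks = arr.shape
    if n_subj < 2 or n_blocks < 2:
        raise ValueError("need at least 2 subjects and 2 blocks")
    if np.allclose(arr, arr[:, :1]):
        return 0.0, 1.0
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n_subj), n_blocks),
        "block": np.tile(np.arange(n_blocks), n_subj),
        "delta": arr.ravel(),
    })
    res = AnovaRM(long, depvar="delta", subject="subject", within=["block"]).fit()
    row = res.anova_table.iloc[0]
    return float(row["F Value"]), float(row["Pr > F"])


def relative_difference(delta_block_k, delta_block_1) -> tuple[float, float, np.ndarray]:
    """Relative difference of block k vs block 1, percent.

    Per subject: 100 * (Δ_k - Δ_1) / group mean of Δ_1.  Returns
    (mean, standard error, per-subject values).  The group-mean denominator
    keeps single subjects with a near-zero block-1 response from blowing up.
    """
    dk = np.asarray(delta_block_k, dtype=float).ravel()
    d1 = np.asarray(delta_block_1, dtype=float).ravel()
    if dk.shape != d1.shape:
        raise ValueError("block vectors must be paired")
    denom = d1.mean()
    if denom == 0:
        raise ValueError("group mean of block 1 is zero; relative difference undefined")
    per = 100.0 * (dk - d1) / denom
    se = per.std(ddof=1) / math.sqrt(per.size) if per.size > 1 else 0.0
    return float(per.mean()), float(se), per


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    return math.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)


def paired_compare(values_a, values_b, roi_names=None, alpha: float = 0.05) -> pd.DataFrame:
    """Per-ROI paired comparison of two conditions across subjects.

    ``values_a``/``values_b`` are subjects x ROIs.  Returns a DataFrame with
    mean_a, mean_b, paired-t p, BH-FDR q across ROIs, Cohen's d
    ((mean_a - mean_b)/pooled SD, pooled SD = sqrt((s_a^2 + s_b^2)/2)), and
    the relative difference 100*(mean_a - mean_b)/mean_b %.
    """
    a = _as_table(values_a)
    b = _as_table(values_b)
    if a.shape != b.shape:
        raise ValueError("condition tables must be paired and equal-shaped")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 subjects for a paired comparison")
    n_roi = a.shape[1]
    if roi_names is None:
        roi_names = [f"roi_{i}" for i in range(n_roi)]
    rows = []
    pvals = np.empty(n_roi)
    for j in range(n_roi):
        xa, xb = a[:, j], b[:, j]
        if np.allclose(xa, xb):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(xa, xb)
        pvals[j] = p
        s = _pooled_sd(xa, xb)
        d = 0.0 if s == 0 else (xa.mean() - xb.mean()) / s
        rel = (
            math.nan if xb.mean() == 0
            else 100.0 * (xa.mean() - xb.mean()) / xb.mean()
        )
        rows.append({
            "roi": roi_names[j],
            "mean_a": xa.mean(),
            "mean_b": xb.mean(),
            "p_paired": p,
            "cohens_d": d,
            "pooled_sd": s,
            "rel_diff_pct": rel,
        })
    out = pd.DataFrame(rows)
    _, q, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    out["q"] = q
    out["significant"] = q < alpha
    return out


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); two empty masks count as 1 (logged)."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks are on different grids")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        logger.info("dice of two empty masks defined as 1 (agreement of absence)")
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def icc(scan_values, rescan_values, kind: str = "icc2") -> float:
    """Intraclass correlation of paired measurements.

    ``kind='icc2'`` (default) is the two-way random-effects,
    absolute-agreement, single-measure ICC(2,1) with scan/rescan as random
    raters; ``kind='icc3'`` is the consistency variant ICC(3,1).  Returns NaN
    if the ratings have no variance.
    """
    x = np.asarray(scan_values, dtype=float).ravel()
    y = np.asarray(rescan_values, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("scan and rescan vectors must be paired")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 paired values")
    m = np.column_stack([x, y])
    if np.ptp(m) == 0:
        return math.nan
    k = 2
    gm = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    msr = k * ((row_means - gm) ** 2).sum() / (n - 1)
    msc = n * ((col_means - gm) ** 2).sum() / (k - 1)
    sse = ((m - row_means[:, None] - col_means[None, :] + gm) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    if kind == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif kind == "icc3":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError("kind must be 'icc2' or 'icc3'")
    if denom == 0:
        return math.nan
    return float((msr - mse) / denom)


def roi_visibility_count(image_slice: np.ndarray, roi_mask: np.ndarray) -> int:
    """Count in-mask voxels at or above (slice mean - 2 x slice SD).

    The threshold uses the whole slice, not just the ROI.  The comparison is
    inclusive so a uniform slice (zero SD) counts every mask voxel.
    """
    img = np.asarray(image_slice, dtype=float)
    m = np.asarray(roi_mask, dtype=bool)
    if img.shape != m.shape:
        raise ValueError("slice and mask are on different grids")
    if not m.any():
        raise ValueError("empty ROI mask")
    thr = img.mean() - 2.0 * img.std(ddof=1)
    return int((img[m] >= thr).sum())


def roi_summarize(
    sign_map: np.ndarray,
    delta_pct: np.ndarray,
    tsnr: np.ndarray,
    cnr: np.ndarray,
    roi_set: RoiSet,
    sign: str = "positive",
) -> pd.DataFrame:
    """Per-ROI means over sign-classified activated voxels.

    Returns one row per named ROI: activated-voxel count, mean ΔS/S per
    block, mean tSNR and mean CNR.  ROIs with no activated voxels are
    flagged ``missing`` (NaN means), not reported as zero.  Voxels with
    infinite tSNR are excluded from the tSNR/CNR means.
    """
    want = SIGN_POSITIVE if sign == "positive" else SIGN_NEGATIVE
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    nb = delta_pct.shape[3]
    rows = []
    for lab, name in sorted(roi_set.names.items()):
        roi = roi_set.labels == lab
        sel = roi & (sign_map == want)
        n = int(sel.sum())
        row = {"roi": name, "n_active": n, "missing": n == 0}
        finite = sel & np.isfinite(tsnr)
        for b in range(nb):
            row[f"delta_pct_block{b + 1}"] = (
                float(np.nanmean(delta_pct[sel, b])) if n else math.nan
            )
        row["tsnr"] = float(tsnr[finite].mean()) if finite.any() else math.nan
        row["cnr"] = float(cnr[finite].mean()) if finite.any() else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------- reproducibility
def retest_dice(sign_a: np.ndarray, sign_b: np.ndarray, roi_set: RoiSet,
                sign: str = "positive") -> pd.DataFrame:
    """Per-ROI Dice between scan and re-scan activation masks of one sign."""
    want = SIGN_POSITIVE if sign == "positive" else SIGN_NEGATIVE
    rows = []
    for lab, name in sorted(roi_set.names.items()):
        roi = roi_set.labels == lab
        rows.append({
            "roi": name,
            "dice": dice((sign_a == want) & roi, (sign_b == want) & roi),
        })
    return pd.DataFrame(rows)


def retest_icc(
    sign_a: np.ndarray,
    delta_a: np.ndarray,
    delta_b: np.ndarray,
    roi_set: RoiSet,
    sign: str = "positive",
    kind: str = "icc2",
) -> pd.DataFrame:
    """Per-ROI, per-block ICC of voxelwise ΔS/S between scan and re-scan.

    Voxels activated (with the requested sign) in the *first* scan are
    overlaid on the second scan; their paired ΔS/S values form the rating
    table.  ROIs with fewer than 2 such voxels get NaN.
    """
    want = SIGN_POSITIVE if sign == "positive" else SIGN_NEGATIVE
    nb = delta_a.shape[3]
    rows = []
    for lab, name in sorted(roi_set.names.items()):
        sel = (roi_set.labels == lab) & (sign_a == want)
        row = {"roi": name, "n_voxels": int(sel.sum())}
        for b in range(nb):
            if sel.sum() < 2:
                row[f"icc_block{b + 1}"] = math.nan
            else:
                row[f"icc_block{b + 1}"] = icc(
                    delta_a[sel, b], delta_b[sel, b], kind=kind
                )
        rows.append(row)
    return pd.DataFrame(rows)
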