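"""Two-sample Kolmogorov–Smirnov machinery for voxelwise activation testing.

The statistic is D = sup_x |F1(x) - F2(x)| over the two empirical CDFs,
evaluated right-continuously at the pooled sample points (so ties are handled
by stepping past each group of tied values).  Three p-value routes are
provided:

``exact``
    The exact null distribution of D for tie-free samples, from the classical
    lattice-path recursion: a random interleaving of the two samples is a
    monotone path from (0, 0) to (n1, n2), and D < d iff the path stays
    strictly inside the band |i/n1 - j/n2| < d.  The survival function is
    computed on the full grid of attainable D values and cached per
    (n1, n2), so a whole activation map costs one table.

``perm``
    Full enumeration over all C(n1+n2, n1) assignments of the pooled values
    (valid with ties); intended for small samples (n1 + n2 <= 20).

``asymp``
    The asymptotic Kolmogorov distribution with effective size
    ne = n1*n2/(n1+n2): p = Q(sqrt(ne) * D).

``auto`` picks ``exact`` for tie-free data with a tractable grid, ``perm``
for small tied samples, and ``asymp`` otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import special

__all__ = ["KsResult", "ks_two_sample", "ks_statistic", "ks_map"]

#: largest lcm(n1, n2) for which the exact lattice table is built by default
_MAX_EXACT_GRID = 20_000
#: largest pooled size for full permutation enumeration
_MAX_PERM = 20


@dataclass(frozen=True)
class KsResult:
    statistic: float
    pvalue: float
    method: str
    n1: int
    n2: int


def _as_sample(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError(f"{name} sample is empty")
    if x.size < 2:
        raise ValueError(f"{name} sample needs at least 2 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} sample contains non-finite values")
    return x


def ks_statistic(x, y) -> tuple[float, int]:
    """D and its integer numerator (D = numerator / (n1*n2)).

    The sup is taken over the pooled sample points with right-continuous
    ECDFs, which is exact also in the presence of ties.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ind1 = np.concatenate([np.ones(n1, bool), np.zeros(n2, bool)])
    order = np.argsort(pooled, kind="stable")
    v = pooled[order]
    ind1 = ind1[order]
    cum1 = np.cumsum(ind1)
    cum2 = np.arange(1, n1 + n2 + 1) - cum1
    # evaluate only after the last element of each tied group
    last = np.ones(n1 + n2, dtype=bool)
    last[:-1] = v[1:] != v[:-1]
    num = np.abs(cum1 * n2 - cum2 * n1)
    num[~last] = 0
    d_num = int(num.max())
    return d_num / (n1 * n2), d_num


@lru_cache(maxsize=64)
def _exact_sf_table(n1: int, n2: int) -> np.ndarray:
    """Exact null survival function of D for tie-free samples.

    Returns ``sf`` with ``sf[k] = P(D >= k*g / (n1*n2))`` where
    ``g = gcd(n1, n2)`` and ``k = 0 .. n1*n2/g``.  Probabilities are
    propagated along the lattice with hypergeometric transition weights, so
    no large integers arise.
    """
    g = math.gcd(n1, n2)
    n_thresh = n1 * n2 // g + 1           # thresholds t_k = k*g
    tvals = np.arange(n_thresh, dtype=np.int64) * g
    total = n1 + n2

    # A[k, j] = P(reach state (i, j) having stayed strictly inside band t_k)
    A = np.zeros((n_thresh, n2 + 1))
    A[tvals > 0, 0] = 1.0                 # state (0, 0), |0| < t
    for j in range(1, n2 + 1):
        p_y = (n2 - (j - 1)) / (total - (j - 1))
        inside = tvals > j * n1
        A[:, j] = A[:, j - 1] * p_y
        A[~inside, j] = 0.0
    for i in range(1, n1 + 1):
        B = np.zeros_like(A)
        p_x = (n1 - (i - 1)) / (total - (i - 1))
        inside = tvals > i * n2
        B[:, 0] = A[:, 0] * p_x
        B[~inside, 0] = 0.0
        for j in range(1, n2 + 1):
            p_x = (n1 - (i - 1)) / (total - (i - 1) - j)
            p_y = (n2 - (j - 1)) / (total - i - (j - 1))
            col = A[:, j] * p_x + B[:, j - 1] * p_y
            col[tvals <= abs(i * n2 - j * n1)] = 0.0
            B[:, j] = col
        A = B
    sf = 1.0 - A[:, n2]
    sf[0] = 1.0
    return np.clip(sf, 0.0, 1.0)


def _exact_pvalue(d_num: int, n1: int, n2: int) -> float:
    g = math.gcd(n1, n2)
    if d_num % g:
        raise ValueError("D numerator is not on the attainable grid")
    return float(_exact_sf_table(n1, n2)[d_num // g])


def _perm_pvalue(x: np.ndarray, y: np.ndarray, d_num: int) -> float:
    """Full enumeration over all splits of the pooled (possibly tied) values."""
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    n = n1 + n2
    hits = 0
    count = 0
    idx = np.arange(n)
    for comb in itertools.combinations(idx, n1):
        comb = np.asarray(comb)
        mask = np.zeros(n, dtype=bool)
        mask[comb] = True
        _, num = ks_statistic(pooled[mask], pooled[~mask])
        hits += num >= d_num
        count += 1
    return hits / count


def _asymp_pvalue(d: float, n1: int, n2: int) -> float:
    ne = n1 * n2 / (n1 + n2)
    return float(special.kolmogorov(math.sqrt(ne) * d))


def ks_two_sample(sample_on, sample_off, method: str = "auto") -> KsResult:
    """Two-sample KS test of ``sample_on`` vs ``sample_off``.

    Parameters
    ----------
    method : {'auto', 'exact', 'perm', 'asymp'}
        See module docstring.  ``exact`` requires tie-free data (falls back
        to ``perm`` for small tied samples, else raises).
    """
    x = _as_sample(sample_on, "on")
    y = _as_sample(sample_off, "off")
    n1, n2 = x.size, y.size
    d, d_num = ks_statistic(x, y)
    ties = np.unique(np.concatenate([x, y])).size < n1 + n2
    lcm = n1 * n2 // math.gcd(n1, n2)

    if method == "auto":
        if not ties and lcm <= _MAX_EXACT_GRID:
            method = "exact"
        elif n1 + n2 <= _MAX_PERM:
            method = "perm"
        else:
            method = "asymp"

    if method == "exact":
        if ties:
            if n1 + n2 <= _MAX_PERM:
                return KsResult(d, _perm_pvalue(x, y, d_num), "perm", n1, n2)
            raise ValueError(
                "exact p-value requires tie-free data (or n1+n2 <= "
                f"{_MAX_PERM} for permutation enumeration)"
            )
        p = _exact_pvalue(d_num, n1, n2)
    elif method == "perm":
        if n1 + n2 > _MAX_PERM:
            raise ValueError(
                f"permutation enumeration limited to n1+n2 <= {_MAX_PERM}"
            )
        p = _perm_pvalue(x, y, d_num)
    elif method == "asymp":
        p = _asymp_pvalue(d, n1, n2)
    else:
        raise ValueError(f"unknown method {method!r}")
    return KsResult(d, p, method, n1, n2)


def ks_map(data: np.ndarray, on_mask: np.ndarray, method: str = "auto"):
    """Vectorized KS test over many series sharing one ON/OFF split.

    Parameters
    ----------
    data : (n_series, n_volumes) array
    on_mask : boolean (n_volumes,) array, the ON sample membership

    Returns
    -------
    (D, p) arrays of shape (n_series,).  With ``method='auto'`` the exact
    table is used for tie-free series and the asymptotic formula for series
    containing ties (ties are vanishingly rare in floating-point fMRI data).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (series x volumes)")
    on_mask = np.asarray(on_mask, dtype=bool).ravel()
    if on_mask.size != data.shape[1]:
        raise ValueError("on_mask length must match the number of volumes")
    n1 = int(on_mask.sum())
    n2 = on_mask.size - n1
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 ON and 2 OFF volumes")

    order = np.argsort(data, axis=1, kind="stable")
    v = np.take_along_axis(data, order, axis=1)
    ind1 = on_mask[order]
    cum1 = np.cumsum(ind1, axis=1)
    cum2 = np.arange(1, n1 + n2 + 1)[None, :] - cum1
    last = np.ones_like(v, dtype=bool)
    last[:, :-1] = v[:, 1:] != v[:, :-1]
    num = np.abs(cum1 * n2 - cum2 * n1)
    num[~last] = 0
    d_num = num.max(axis=1).astype(np.int64)
    d = d_num / (n1 * n2)

    lcm = n1 * n2 // math.gcd(n1, n2)
    tied = ~last[:, :-1].all(axis=1)
    if method == "auto":
        method = "exact" if lcm <= _MAX_EXACT_GRID else "asymp"
    if method == "exact":
        if lcm > _MAX_EXACT_GRID:
            raise ValueError("exact table too large for this (n1, n2)")
        sf = _exact_sf_table(n1, n2)
        p = sf[d_num // math.gcd(n1, n2)]
        if tied.any():
            ne = n1 * n2 / (n1 + n2)
            p = p.copy()
            p[tied] = special.kolmogorov(np.sqrt(ne) * d[tied])
    elif method == "asymp":
        ne = n1 * n2 / (n1 + n2)
        p = special.kolmogorov(np.sqrt(ne) * d)
    else:
        raise ValueError(f"unknown method {method!r} for ks_map")
    return d, np.asarray(p, dtype=float)
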