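"""Rowwise Kendall matrix correlation (tau-Kr) with permutation inference.

Dyadic matrices violate the independence assumptions of ordinary rank
tests: each actor contributes a whole row.  The tau-Kr statistic therefore
correlates two actor x actor matrices row by row — for every actor the
Kendall S statistic between her out-going values in the two matrices is
computed over all off-diagonal column pairs — and sums the rows:

    S_i   = sum over column pairs (j, k) of sign(x_ij - x_ik) * sign(y_ij - y_ik)
    Kr    = sum_i S_i
    tauKr = Kr / sum_i D_i

with D_i the tie-corrected (tau-b style) maximal concordance of row i.
Significance comes from a permutation null that conserves each actor's
out-going value multiset: the off-diagonal entries of each row of ``y`` are
independently permuted.  When the permutation space is small the null
distribution is enumerated exactly (rows are independent, so the exact null
of Kr is the convolution of the per-row S distributions); otherwise it is
sampled.  Two-tailed p-values measure symmetric deviation from the null
mean of Kr, which is exactly zero under within-row permutation.

Cells that are undefined (NaN) in either matrix are excluded pairwise
within rows, which supports statistics defined only for interacting dyads
(e.g. the grooming reciprocity index).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError

EXHAUSTIVE_LIMIT = 1_000_000
_EPS = 1e-9


@dataclass
class TauKrResult:
    kr: float
    tau_kr: float
    p_two_tailed: float | None
    n_perm: int
    exhaustive: bool
    seed: int | None
    row_s: pd.Series | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "kr": self.kr,
            "tau_kr": self.tau_kr,
            "p_two_tailed": self.p_two_tailed,
            "n_perm": self.n_perm,
            "exhaustive": self.exhaustive,
            "seed": self.seed,
            "row_s": None if self.row_s is None else self.row_s.to_dict(),
        }


def _as_frame(obj) -> pd.DataFrame:
    data = getattr(obj, "data", obj)
    if isinstance(data, pd.DataFrame):
        return data.astype(float)
    arr = np.asarray(data, dtype=float)
    labels = [str(i) for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=labels, columns=labels)


def _offdiag_rows(df: pd.DataFrame) -> np.ndarray:
    """(n, n-1) array of each row's off-diagonal entries, column order preserved."""
    a = df.to_numpy(dtype=float)
    n = a.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return a[mask].reshape(n, n - 1)


def _sign_pairs(rows: np.ndarray) -> np.ndarray:
    """(n, m, m) tensor of sign(row[j] - row[k]); NaN comparisons give 0."""
    d = rows[..., :, None] - rows[..., None, :]
    return np.nan_to_num(np.sign(d), nan=0.0)


def _row_denominators(xr: np.ndarray, yr: np.ndarray) -> np.ndarray:
    """Tau-b style maximal concordance per row, tie-corrected, NaN-aware."""
    n, m = xr.shape
    denom = np.zeros(n)
    for i in range(n):
        valid = ~np.isnan(xr[i]) & ~np.isnan(yr[i])
        v = int(valid.sum())
        pairs = v * (v - 1) // 2
        if pairs == 0:
            continue
        tx = _tied_pairs(xr[i][valid])
        ty = _tied_pairs(yr[i][valid])
        if pairs - tx <= 0 or pairs - ty <= 0:
            continue  # constant row: contributes nothing
        denom[i] = math.sqrt((pairs - tx) * (pairs - ty))
    return denom


def _tied_pairs(values: np.ndarray) -> int:
    _, counts = np.unique(values, return_counts=True)
    return int(np.sum(counts * (counts - 1) // 2))


def _check_inputs(x: pd.DataFrame, y: pd.DataFrame) -> None:
    if list(x.index) != list(x.columns) or list(y.index) != list(y.columns):
        raise AnalysisError("matrices must be square with matching row/column labels")
    if list(x.index) != list(y.index):
        raise AnalysisError(f"matrix labels differ: {list(x.index)} vs {list(y.index)}")
    if len(x.index) < 3:
        raise AnalysisError("tau-Kr requires at least 3 actors")


def tau_kr_statistic(x, y) -> tuple[float, float]:
    """Return ``(Kr, tauKr)`` for two aligned square matrices (diagonals ignored)."""
    xf, yf = _as_frame(x), _as_frame(y)
    _check_inputs(xf, yf)
    xr, yr = _offdiag_rows(xf), _offdiag_rows(yf)
    sx, sy = _sign_pairs(xr), _sign_pairs(yr)
    row_s = 0.5 * np.einsum("ijk,ijk->i", sx, sy)
    denom = _row_denominators(xr, yr)
    total = denom.sum()
    if total == 0:
        raise AnalysisError("every row is constant; tau-Kr is undefined")
    return float(row_s.sum()), float(row_s.sum() / total)


def _exhaustive_row_distributions(sx: np.ndarray, yr: np.ndarray) -> list[np.ndarray]:
    """Per row, the S values over all permutations of that row of y."""
    n, m = yr.shape
    out = []
    for i in range(n):
        vals = []
        for perm in itertools.permutations(range(m)):
            sy = _sign_pairs(yr[i, list(perm)][None, :])[0]
            vals.append(0.5 * float(np.sum(sx[i] * sy)))
        out.append(np.asarray(vals))
    return out


def _exhaustive_p(kr_obs: float, row_dists: list[np.ndarray]) -> tuple[float, int]:
    """Exact two-tailed p by convolving independent per-row S distributions."""
    # All S values are integers (sums of sign products); use offset pmf arrays.
    pmf = np.array([1.0])
    offset = 0  # pmf[k] is P(sum = k + offset)
    for vals in row_dists:
        ivals = np.rint(vals).astype(int)
        lo, hi = ivals.min(), ivals.max()
        row_pmf = np.bincount(ivals - lo, minlength=hi - lo + 1).astype(float)
        row_pmf /= row_pmf.sum()
        pmf = np.convolve(pmf, row_pmf)
        offset += lo
    support = np.arange(len(pmf)) + offset
    # The within-row permutation null of each S_i is symmetric with mean 0,
    # so the null mean of Kr is exactly 0.
    extreme = np.abs(support) >= abs(kr_obs) - _EPS
    p = float(np.sum(pmf[extreme]))
    n_total = int(np.prod([len(v) for v in row_dists]))
    return p, n_total


def _sampled_kr(
    sx: np.ndarray, yr: np.ndarray, n_perm: int, rng: np.random.Generator,
    batch: int = 2000,
) -> np.ndarray:
    """Kr under ``n_perm`` independent within-row permutations of y."""
    n, m = yr.shape
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        idx = np.argsort(rng.random((b, n, m)), axis=-1)
        yp = np.take_along_axis(np.broadcast_to(yr, (b, n, m)), idx, axis=-1)
        sy = _sign_pairs(yp)
        out[done : done + b] = 0.5 * np.einsum("ijk,bijk->b", sx, sy)
        done += b
    return out


def tau_kr_test(
    x,
    y,
    n_perm: int = 10_000,
    seed: int | None = None,
    method: str = "auto",
    permute: str = "within_row",
) -> TauKrResult:
    """Two-tailed tau-Kr permutation test between two aligned square matrices.

    ``method``: "auto" enumerates the null exactly whenever the permutation
    space has at most a million arrangements, otherwise samples ``n_perm``
    within-row permutations; "sampled" / "exhaustive" force the choice.
    ``permute="actors"`` relabels whole actors of ``y`` instead of permuting
    within rows (a non-default option for sensitivity checks).
    """
    xf, yf = _as_frame(x), _as_frame(y)
    _check_inputs(xf, yf)
    if method not in {"auto", "sampled", "exhaustive"}:
        raise ValueError(f"unknown method {method!r}")
    if permute == "actors":
        return _actor_relabel_test(xf, yf, n_perm=n_perm, seed=seed)
    if permute != "within_row":
        raise ValueError(f"unknown permute mode {permute!r}")

    xr, yr = _offdiag_rows(xf), _offdiag_rows(yf)
    sx = _sign_pairs(xr)
    sy = _sign_pairs(yr)
    row_s = 0.5 * np.einsum("ijk,ijk->i", sx, sy)
    kr_obs = float(row_s.sum())
    denom = _row_denominators(xr, yr)
    if denom.sum() == 0:
        raise AnalysisError("every row is constant; tau-Kr is undefined")
    tau = kr_obs / denom.sum()

    n, m = yr.shape
    space = math.factorial(m) ** n
    exhaustive = method == "exhaustive" or (method == "auto" and space <= EXHAUSTIVE_LIMIT)
    if exhaustive:
        dists = _exhaustive_row_distributions(sx, yr)
        p, total = _exhaustive_p(kr_obs, dists)
        return TauKrResult(
            kr=kr_obs, tau_kr=tau, p_two_tailed=p, n_perm=total,
            exhaustive=True, seed=seed, row_s=pd.Series(row_s, index=xf.index),
        )
    if n_perm < 1000:
        raise ValueError("n_perm must be at least 1000 for a sampled test")
    rng = np.random.default_rng(seed)
    kr_perm = _sampled_kr(sx, yr, n_perm, rng)
    # null mean of Kr is exactly 0 under within-row permutation
    n_extreme = int(np.sum(np.abs(kr_perm) >= abs(kr_obs) - _EPS))
    p = (1 + n_extreme) / (n_perm + 1)
    return TauKrResult(
        kr=kr_obs, tau_kr=tau, p_two_tailed=p, n_perm=n_perm,
        exhaustive=False, seed=seed, row_s=pd.Series(row_s, index=xf.index),
    )


def _actor_relabel_test(
    xf: pd.DataFrame, yf: pd.DataFrame, n_perm: int, seed: int | None
) -> TauKrResult:
    kr_obs, tau = tau_kr_statistic(xf, yf)
    n = len(yf.index)
    rng = np.random.default_rng(seed)
    yv = yf.to_numpy()
    krs = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        yp = pd.DataFrame(yv[np.ix_(perm, perm)], index=yf.index, columns=yf.columns)
        krs[b], _ = tau_kr_statistic(xf, yp)
    mean_null = float(krs.mean())
    n_extreme = int(np.sum(np.abs(krs - mean_null) >= abs(kr_obs - mean_null) - _EPS))
    return TauKrResult(
        kr=kr_obs, tau_kr=tau, p_two_tailed=(1 + n_extreme) / (n_perm + 1),
        n_perm=n_perm, exhaustive=False, seed=seed,
    )


def _offdiag_scatter(base: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Place (B, n, m) off-diagonal rows back into (B, n, n) matrices."""
    b, n, m = rows.shape
    out = np.zeros((b, n, n))
    mask = ~np.eye(n, dtype=bool)
    out[:, mask] = rows.reshape(b, n * m)
    return out


def reciprocity_test(m, n_perm: int = 10_000, seed: int | None = None) -> TauKrResult:
    """Given-vs-received reciprocity of one directed matrix.

    The statistic is the tau-Kr correlation between the matrix and its
    transpose.  Because the two matrices share every dyad's values, the
    generic within-row null (permuting the transpose independently of the
    original) understates the null variance; instead, the null model here
    randomises each actor's *outgoing allocation* — the off-diagonal entries
    of each row of the directed matrix are permuted and given-vs-received is
    recomputed on the permuted matrix, so the dyadic coupling is preserved
    under the null.  The observed matrix is itself one such allocation,
    making the permutation p exact under the null of random partner
    allocation.  Two-tailed p measures symmetric deviation from the null
    mean (estimated over the observed value and all permutations).
    """
    mf = _as_frame(m)
    _check_inputs(mf, mf.T)
    xr = _offdiag_rows(mf)
    n, width = xr.shape
    kr_obs, tau = tau_kr_statistic(mf, mf.T)
    if n_perm < 1000:
        raise ValueError("n_perm must be at least 1000 for a sampled test")
    rng = np.random.default_rng(seed)
    kr_perm = np.empty(n_perm)
    done = 0
    base = mf.to_numpy()
    while done < n_perm:
        b = min(1000, n_perm - done)
        idx = np.argsort(rng.random((b, n, width)), axis=-1)
        rows = np.take_along_axis(np.broadcast_to(xr, (b, n, width)), idx, axis=-1)
        mats = _offdiag_scatter(base, rows)
        rp = _offdiag_rows_batch(mats)
        cp = _offdiag_rows_batch(np.swapaxes(mats, 1, 2))
        s = _sign_pairs(rp) * _sign_pairs(cp)
        kr_perm[done : done + b] = 0.5 * s.sum(axis=(1, 2, 3))
        done += b
    center = float((kr_perm.sum() + kr_obs) / (n_perm + 1))
    n_extreme = int(np.sum(np.abs(kr_perm - center) >= abs(kr_obs - center) - _EPS))
    p = (1 + n_extreme) / (n_perm + 1)
    return TauKrResult(
        kr=kr_obs, tau_kr=tau, p_two_tailed=p, n_perm=n_perm,
        exhaustive=False, seed=seed,
    )


def _offdiag_rows_batch(mats: np.ndarray) -> np.ndarray:
    b, n, _ = mats.shape
    mask = ~np.eye(n, dtype=bool)
    return mats[:, mask].reshape(b, n, n - 1)
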