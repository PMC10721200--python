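"""Contact-matrix container, Knight-Ruiz balancing, distance decay and O/E.

A :class:`ContactMatrix` stores one dense symmetric matrix per captured
region; captured regions are always treated independently (balancing,
insulation, pileups never mix bins across regions).  Missing values are NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .intervals import BinTable

__all__ = [
    "ContactMatrix",
    "DecayProfile",
    "kr_balance",
    "cis_decay_profile",
    "observed_over_expected",
]

logger = logging.getLogger(__name__)


@dataclass
class ContactMatrix:
    """Symmetric per-region contact matrices over a shared bin table.

    Attributes
    ----------
    bin_table : the coordinate backbone
    matrices : one dense symmetric float array per region
    valid : per-region boolean mask; False bins are excluded everywhere
    weights : per-region balancing multipliers (NaN over invalid bins), or
        None before balancing
    kind : ``'raw'`` (counts), ``'balanced'`` or ``'oe'``
    """

    bin_table: BinTable
    matrices: list[np.ndarray]
    valid: list[np.ndarray] = field(default=None)
    weights: list[np.ndarray] | None = None
    kind: str = "raw"

    def __post_init__(self) -> None:
        if len(self.matrices) != self.bin_table.n_regions:
            raise ValueError("one matrix per region required")
        for r, m in enumerate(self.matrices):
            n = self.bin_table.region_n_bins(r)
            if m.shape != (n, n):
                raise ValueError(
                    f"region {r}: matrix shape {m.shape} != ({n}, {n})"
                )
            if not np.allclose(m, m.T, equal_nan=True):
                raise ValueError(f"region {r}: matrix is not symmetric")
        if self.valid is None:
            self.valid = [np.ones(m.shape[0], dtype=bool) for m in self.matrices]

    @property
    def n_regions(self) -> int:
        return self.bin_table.n_regions

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.bin_table,
            [m.copy() for m in self.matrices],
            [v.copy() for v in self.valid],
            None if self.weights is None else [w.copy() for w in self.weights],
            self.kind,
        )


@dataclass
class DecayProfile:
    """Median +/- IQR of contact score as a function of genomic separation.

    Separations are multiples of the bin size; ``median_at`` indexes by
    separation in bins.  IQR bounds are NaN where fewer than two
    observations were available.
    """

    resolution: int
    separations_bins: np.ndarray
    median: np.ndarray
    iqr_lo: np.ndarray
    iqr_hi: np.ndarray

    @property
    def separations_bp(self) -> np.ndarray:
        return self.separations_bins * self.resolution

    def median_at(self, d_bins: int) -> float:
        idx = np.flatnonzero(self.separations_bins == d_bins)
        if idx.size == 0:
            raise KeyError(f"no decay value at separation {d_bins} bins")
        return float(self.median[idx[0]])


# ---------------------------------------------------------------------------
# Knight-Ruiz balancing


def _kr_core(A: np.ndarray, tol: float, max_outer: int) -> np.ndarray | None:
    """Inner-outer Newton scheme for symmetric doubly stochastic scaling.

    Returns the positive scaling vector x with x*(A@x) ~= 1, or None if the
    scheme stagnates or leaves the positivity box.
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5

    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rold = rho_km1

    for _ in range(max_outer):
        if np.abs(rk).max() <= tol:
            return x
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, tol**2)
        rho_km2 = rho_km1
        Z = rk / v
        p = Z.copy()
        rho_km1 = rk @ Z
        while rho_km1 > innertol and k <= n:
            k += 1
            if k > 1:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            denom = p @ w
            if denom <= 0:
                return None
            alpha = rho_km1 / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = ((Delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
        x = x * y
        if not np.all(np.isfinite(x)) or x.min() <= 0:
            return None
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold if rold > 0 else 0.0
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o**2 > 0.1:
            eta = max(eta, g * eta_o**2)
        eta = max(min(eta, etamax), stop_tol / res_norm) if res_norm > 0 else etamax
    return x if np.abs(rk).max() <= tol else None


def _sinkhorn_core(A: np.ndarray, tol: float, max_iter: int) -> np.ndarray | None:
    """Damped symmetric Sinkhorn-Knopp iteration (fallback and oracle twin)."""
    n = A.shape[0]
    x = np.ones(n)
    for _ in range(max_iter):
        s = A @ x
        if np.any(s <= 0):
            return None
        x = np.sqrt(x * (x / s))
        if np.abs(x * (A @ x) - 1.0).max() <= tol:
            return x
    return None


def kr_balance(
    matrix: ContactMatrix,
    tol: float = 1e-8,
    max_iter: int = 100,
    min_coverage_fraction: float = 0.02,
) -> ContactMatrix:
    """Balance each region's matrix to equal row sums (Knight-Ruiz).

    Bins with zero marginal, or with marginal in the lowest
    ``min_coverage_fraction`` quantile of the nonzero marginals, are masked
    invalid before balancing.  Each region is treated separately.  The
    balanced matrix B = w_i * counts[i,j] * w_j has all row sums over valid
    bins equal within ``tol`` (relative); weights are rescaled so their mean
    over valid bins is 1 (only ratios matter downstream).  When the
    Knight-Ruiz scheme fails to converge within ``max_iter`` outer
    iterations a damped Sinkhorn-Knopp iteration is used instead (logged).
    """
    if matrix.kind != "raw":
        raise ValueError("kr_balance expects a raw count matrix")
    out_mats, out_valid, out_weights = [], [], []
    for r, counts in enumerate(matrix.matrices):
        n = counts.shape[0]
        valid = matrix.valid[r].copy()
        marg = np.where(valid, counts.sum(axis=1), 0.0)
        nonzero = marg > 0
        valid &= nonzero
        if valid.sum() and min_coverage_fraction > 0:
            thr = np.quantile(marg[nonzero], min_coverage_fraction)
            valid &= ~(marg < thr)
        if valid.sum() == 0:
            raise ValueError(f"region {r}: no valid bins to balance")
        A = counts[np.ix_(valid, valid)].astype(float)
        # pre-scale to mean row sum 1 so the unit start vector is near the
        # fixed point; undone below (x solves the scaled problem)
        pre = A.sum(axis=1).mean()
        A = A / pre
        # per-row residual <= tol/2 guarantees pairwise row-sum agreement
        # within tol (relative)
        x = _kr_core(A, tol / 2, max_iter)
        if x is None:
            logger.warning(
                "region %d: Knight-Ruiz did not converge; falling back to Sinkhorn-Knopp",
                r,
            )
            x = _sinkhorn_core(A, tol / 2, max_iter * 500)
        if x is None:
            resid = np.abs(np.ones(A.shape[0]) - (A @ np.ones(A.shape[0]))).max()
            raise RuntimeError(
                f"region {r}: neither Knight-Ruiz nor Sinkhorn-Knopp converged "
                f"(initial residual {resid:.3g})"
            )
        x = x / np.sqrt(pre)  # weights for the unscaled counts
        x = x / x.mean()  # mean weight over valid bins = 1
        weights = np.full(n, np.nan)
        weights[valid] = x
        balanced = np.full((n, n), np.nan)
        balanced[np.ix_(valid, valid)] = (A * pre) * np.outer(x, x)
        out_mats.append(balanced)
        out_valid.append(valid)
        out_weights.append(weights)
    return ContactMatrix(matrix.bin_table, out_mats, out_valid, out_weights, "balanced")


# ---------------------------------------------------------------------------
# Distance decay and observed/expected


def cis_decay_profile(
    matrix: ContactMatrix, include_diagonal: bool = False
) -> DecayProfile:
    """Median +/- IQR of balanced score per genomic separation.

    Scores are pooled over all supplied regions at each separation (in
    bins); invalid bins and missing entries are excluded.  The diagonal
    (separation 0) is excluded by default: at restriction-fragment scale it
    is dominated by self-ligation artifacts.
    """
    if matrix.kind == "raw":
        raise ValueError("cis_decay_profile expects a balanced matrix")
    max_d = max(m.shape[0] for m in matrix.matrices) - 1
    d_min = 0 if include_diagonal else 1
    seps, med, lo, hi = [], [], [], []
    for d in range(d_min, max_d + 1):
        pool = []
        for m in matrix.matrices:
            n = m.shape[0]
            if d >= n:
                continue
            diag = np.diagonal(m, offset=d)
            pool.append(diag[np.isfinite(diag)])
        values = np.concatenate(pool) if pool else np.empty(0)
        if values.size == 0:
            continue
        seps.append(d)
        med.append(np.median(values))
        if values.size >= 2:
            lo.append(np.percentile(values, 25))
            hi.append(np.percentile(values, 75))
        else:
            lo.append(np.nan)
            hi.append(np.nan)
    return DecayProfile(
        matrix.bin_table.resolution,
        np.asarray(seps, dtype=int),
        np.asarray(med, dtype=float),
        np.asarray(lo, dtype=float),
        np.asarray(hi, dtype=float),
    )


def observed_over_expected(
    matrix: ContactMatrix, decay: DecayProfile, include_diagonal: bool = False
) -> ContactMatrix:
    """Divide each balanced entry by the decay median at its separation.

    O/E[i,j] = balanced[i,j] / median(d = |i-j|).  Entries with zero or
    missing expected value, and invalid bins, are NaN.  A separation that
    occurs in the matrix but is absent from ``decay`` raises.
    """
    if matrix.kind != "balanced":
        raise ValueError("observed_over_expected expects a balanced matrix")
    available = set(int(d) for d in decay.separations_bins)
    out = []
    for m in matrix.matrices:
        n = m.shape[0]
        d_min = 0 if include_diagonal else 1
        needed = {
            d
            for d in range(d_min, n)
            if np.isfinite(np.diagonal(m, offset=d)).any()
        }
        missing = sorted(needed - available)
        if missing:
            raise ValueError(
                f"decay profile missing separations (bins): {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        expected = np.full((n, n), np.nan)
        for d in range(d_min, n):
            if d not in available:
                continue
            e = decay.median_at(d)
            idx = np.arange(n - d)
            expected[idx, idx + d] = e
            expected[idx + d, idx] = e
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where(expected > 0, m / expected, np.nan)
        out.append(oe)
    return ContactMatrix(
        matrix.bin_table, out, [v.copy() for v in matrix.valid], None, "oe"
    )
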