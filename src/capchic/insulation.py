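"""Insulation scores, TAD boundary calling, and cross-sample comparisons.

The insulation score of a bin counts (balanced) contacts in a square window
sliding along the matrix diagonal; local minima are candidate domain
boundaries.  A boundary score ("delta") measures the depth of each minimum
against its 3-bin flanks, and robust boundaries are those reaching the score
threshold in at least two window sizes, with adjacent calls merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .intervals import BinTable, GenomicInterval
from .matrix import ContactMatrix

__all__ = [
    "InsulationProfile",
    "Boundary",
    "BoundarySet",
    "insulation_profile",
    "boundary_candidates",
    "call_robust_boundaries",
    "compare_boundary_sets",
    "insulation_ks",
    "insulation_spearman",
    "insulation_pca",
]

# window sets used in the original analyses, for reference/CLI defaults:
#   5 kb capture matrices  -> 3, 5, 7, 10, 15 bins (15-75 kb)
#   2 kb pooled capture    -> 15, 20, 25, 40, 50 bins (30-100 kb)
#   10 kb genome-wide Hi-C -> 7, 10, 15 bins (70-150 kb)
WINDOWS_5KB = (3, 5, 7, 10, 15)
WINDOWS_2KB = (15, 20, 25, 40, 50)
WINDOWS_10KB = (7, 10, 15)


@dataclass
class InsulationProfile:
    """Per-bin insulation scores for one window size.

    ``scores`` holds one array per region, NaN near region edges, over
    invalid bins, and where too much of the window was missing.  Scores are
    log2 ratios to the per-region mean of the raw window means, so 0 is the
    regional average, minima are insulating boundaries.  ``raw`` keeps the
    unlogged window means.
    """

    bin_table: BinTable
    window_bins: int
    scores: list[np.ndarray]
    raw: list[np.ndarray]

    @property
    def window_bp(self) -> int:
        return self.window_bins * self.bin_table.resolution

    def flat_scores(self) -> np.ndarray:
        return np.concatenate(self.scores)


@dataclass(frozen=True)
class Boundary:
    interval: GenomicInterval
    score: float
    supporting_windows: frozenset[int] = frozenset()


@dataclass
class BoundarySet:
    cell_type: str
    boundaries: list[Boundary] = field(default_factory=list)
    resolution: int | None = None

    def __len__(self) -> int:
        return len(self.boundaries)

    def __iter__(self):
        return iter(self.boundaries)


def insulation_profile(
    matrix: ContactMatrix,
    window_bins: int,
    max_missing_fraction: float = 0.5,
    log2_normalize: bool = True,
) -> InsulationProfile:
    """Mean balanced score in the off-diagonal window at each bin.

    raw_i is the mean over the square [i-w, i-1] x [i+1, i+w]; it is
    missing when bin i is invalid, lies within w bins of a region edge, or
    more than ``max_missing_fraction`` of the window cells are missing.
    The reported score is log2(raw_i / regional mean of raw) unless
    ``log2_normalize`` is False.
    """
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    if matrix.kind == "raw":
        raise ValueError("insulation_profile expects a balanced matrix")
    w = window_bins
    raws, scores = [], []
    for r, m in enumerate(matrix.matrices):
        n = m.shape[0]
        if w >= n:
            raise ValueError(
                f"window of {w} bins >= region size of {n} bins (region {r})"
            )
        valid = matrix.valid[r]
        raw = np.full(n, np.nan)
        for i in range(w, n - w):
            if not valid[i]:
                continue
            window = m[i - w : i, i + 1 : i + w + 1]
            n_missing = np.isnan(window).sum()
            if n_missing > max_missing_fraction * window.size:
                continue
            raw[i] = np.nanmean(window) if n_missing < window.size else np.nan
        raws.append(raw)
        if log2_normalize:
            mean_raw = np.nanmean(raw) if np.any(np.isfinite(raw)) else np.nan
            with np.errstate(divide="ignore", invalid="ignore"):
                score = np.log2(raw / mean_raw)
            score[~np.isfinite(score)] = np.nan
        else:
            score = raw.copy()
        scores.append(score)
    return InsulationProfile(matrix.bin_table, w, scores, raws)


def _plateau_minima(score: np.ndarray) -> list[int]:
    """Indices of local minima; a tied plateau yields its leftmost bin."""
    n = score.size
    minima = []
    i = 0
    while i < n:
        if not np.isfinite(score[i]):
            i += 1
            continue
        j = i
        while j + 1 < n and np.isfinite(score[j + 1]) and score[j + 1] == score[i]:
            j += 1
        left_ok = i > 0 and np.isfinite(score[i - 1]) and score[i - 1] > score[i]
        right_ok = j < n - 1 and np.isfinite(score[j + 1]) and score[j + 1] > score[i]
        if left_ok and right_ok:
            minima.append(i)
        i = j + 1
    return minima


def boundary_candidates(
    profile: InsulationProfile, delta_window: int = 3
) -> list[tuple[int, float]]:
    """Score each insulation minimum against its flanking bins.

    The component ("boundary") score of a minimum at bin i is
    ``min(mean(score[i-3..i-1]), mean(score[i+1..i+3])) - score[i]`` for a
    3-bin delta window: the conservative (smaller) of the two flank rises.
    All six flanking scores must be present; returns (global bin index,
    component score) pairs.
    """
    dw = delta_window
    out: list[tuple[int, float]] = []
    for r, score in enumerate(profile.scores):
        offset = profile.bin_table.region_slice(r).start
        for i in _plateau_minima(score):
            if i - dw < 0 or i + dw >= score.size:
                continue
            left = score[i - dw : i]
            right = score[i + 1 : i + 1 + dw]
            if np.isnan(left).any() or np.isnan(right).any():
                continue
            component = min(left.mean(), right.mean()) - score[i]
            out.append((offset + i, float(component)))
    return out


def call_robust_boundaries(
    candidates_per_window: dict[int, list[tuple[int, float]]],
    bin_table: BinTable,
    min_score: float = 0.1,
    min_windows: int = 2,
    merge_gap_bins: int = 1,
    cell_type: str = "",
) -> BoundarySet:
    """Keep minima scoring >= ``min_score`` in >= ``min_windows`` windows.

    Candidates from all windows whose bins lie within ``merge_gap_bins`` of
    each other (transitively, within a region) are merged into a single
    boundary spanning the member bins, scored by the mean of the member
    component scores.
    """
    if candidates_per_window and len(candidates_per_window) < min_windows:
        pass  # fewer windows than required support can still yield nothing
    items = [
        (bin_idx, window, score)
        for window, cands in candidates_per_window.items()
        for bin_idx, score in cands
        if score >= min_score
    ]
    boundaries: list[Boundary] = []
    if items:
        items.sort()
        # transitive clustering on sorted bins, split at region edges
        clusters: list[list[tuple[int, int, float]]] = [[items[0]]]
        for item in items[1:]:
            prev = clusters[-1][-1]
            same_region = bin_table.region_of_bin(item[0]) == bin_table.region_of_bin(
                prev[0]
            )
            if same_region and item[0] - max(b for b, _, _ in clusters[-1]) <= merge_gap_bins:
                clusters[-1].append(item)
            else:
                clusters.append([item])
        for cluster in clusters:
            windows = frozenset(w for _, w, _ in cluster)
            if len(windows) < min_windows:
                continue
            bins = [b for b, _, _ in cluster]
            lo, hi = min(bins), max(bins)
            interval = GenomicInterval(
                bin_table.bins[lo].chrom,
                bin_table.bins[lo].start,
                bin_table.bins[hi].end,
            )
            score = float(np.mean([s for _, _, s in cluster]))
            boundaries.append(Boundary(interval, score, windows))
    boundaries.sort(key=lambda b: (b.interval.chrom, b.interval.start))
    return BoundarySet(cell_type, boundaries, bin_table.resolution)


def compare_boundary_sets(
    a: BoundarySet, b: BoundarySet, slack_bins: int = 0
) -> dict:
    """Jaccard overlap between two boundary sets.

    Boundaries match when their intervals overlap after symmetric extension
    by ``slack_bins`` bins on each side; the number matched is a maximum
    bipartite matching so no boundary is counted twice.
    jaccard = matched / (|a| + |b| - matched).
    """
    resolution = a.resolution or b.resolution or 0
    pad = slack_bins * resolution
    ivs_a = [x.interval.expand(pad) for x in a.boundaries]
    ivs_b = [x.interval.expand(pad) for x in b.boundaries]
    rows, cols = [], []
    for i, iva in enumerate(ivs_a):
        for j, ivb in enumerate(ivs_b):
            if iva.overlaps(ivb):
                rows.append(i)
                cols.append(j)
    if rows:
        graph = csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(len(ivs_a), len(ivs_b))
        )
        matching = maximum_bipartite_matching(graph, perm_type="column")
        matched = int((matching >= 0).sum())
    else:
        matched = 0
    union = len(ivs_a) + len(ivs_b) - matched
    return {
        "jaccard": matched / union if union else 1.0,
        "n_matched": matched,
        "n_a_only": len(ivs_a) - matched,
        "n_b_only": len(ivs_b) - matched,
    }


def insulation_ks(scores_a, scores_b) -> dict:
    """Two-sample two-tailed Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 finite values per sample")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return {"D": float(res.statistic), "p": float(res.pvalue)}


def insulation_spearman(x, y) -> dict:
    """Spearman rank correlation over pairwise-complete finite pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 pairwise-complete pairs")
    constant = np.all(x == x[0]) or np.all(y == y[0])
    if constant:
        return {"rho": np.nan, "p": np.nan, "n": int(x.size), "constant": True}
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "n": int(x.size), "constant": False}


def insulation_pca(profiles: np.ndarray, n_components: int = 2) -> dict:
    """PCA of replicate insulation profiles (replicates x bins).

    Bins with any missing score are dropped listwise; columns are centered
    but not scaled.  Returns per-replicate coordinates on the leading
    components and the variance fraction each explains.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2D table with at least 3 replicates")
    keep = np.all(np.isfinite(X), axis=0)
    X = X[:, keep]
    if X.shape[1] < 2:
        raise ValueError("fewer than 2 bins retained after dropping missing")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    total = (s**2).sum()
    k = min(n_components, s.size)
    return {
        "coordinates": U[:, :k] * s[:k],
        "variance_fractions": (s[:k] ** 2 / total) if total > 0 else np.zeros(k),
        "n_bins": X.shape[1],
    }
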