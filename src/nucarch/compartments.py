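"""Matrix-level Hi-C and Repli-Seq analysis.

Operations on binned intra-chromosomal contact matrices: Knight–Ruiz (KR)
balancing, observed/expected transformation, Pearson correlation maps, the
A/B-compartment first eigenvector, k-means clustering of histone-mark
z-scores, between-cluster contact log2 ratios, aggregate peak analysis
(APA) over loop lists, and replication-timing (early/late ratio) tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

_SYM_TOL = 1e-9


@dataclass
class ContactMatrix:
    """Symmetric non-negative contact counts over contiguous bins."""

    matrix: np.ndarray
    resolution: int
    chrom: str = "chr1"
    balanced: bool = False
    scaling: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(m, m.T, atol=_SYM_TOL * max(1.0, np.abs(m).max())):
            raise ValueError("contact matrix must be symmetric")
        if np.any(m < 0):
            raise ValueError("contact matrix must be non-negative")
        self.matrix = m

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    @property
    def masked_bins(self) -> np.ndarray:
        """Bins whose row is entirely zero (unmappable)."""
        return ~self.matrix.any(axis=0)


@dataclass
class TrackSet:
    """Named per-bin signal tracks sharing one binning (0-based, half-open)."""

    tracks: pd.DataFrame
    resolution: int
    chrom: str = "chr1"

    @property
    def n_bins(self) -> int:
        return len(self.tracks)

    def values(self, names=None) -> np.ndarray:
        cols = list(self.tracks.columns if names is None else names)
        return self.tracks[cols].to_numpy(dtype=float)


@dataclass
class ClusterAssignment:
    """Per-bin cluster ids 1..k (0 = masked); numbering is arbitrary but
    deterministic (relabelled by descending cluster size)."""

    labels: np.ndarray
    k: int

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]


@dataclass
class ReplicationTimingTrack:
    """Per-bin early/late Repli-Seq summary."""

    early: np.ndarray
    late: np.ndarray
    log2_ratio: np.ndarray
    percentile: np.ndarray  # of the E/L ratio, in [0, 100]; NaN for masked bins
    mask: np.ndarray = field(default=None)  # True where usable


# ---------------------------------------------------------------------------
# balancing


def kr_balance(
    m: ContactMatrix, tol: float = 1e-6, max_iter: int = 100
) -> ContactMatrix:
    """Knight–Ruiz balancing to uniform (unit) row sums.

    Returns ``D M D`` where the diagonal scaling ``D`` gives every
    non-masked row sum 1.  Fully zero rows are masked out and left zero.
    Falls back to symmetric iterative proportional scaling with a warning
    if the Newton-style KR iteration fails to converge.
    """
    A = m.matrix
    keep = ~m.masked_bins
    sub = A[np.ix_(keep, keep)]
    if sub.size == 0:
        raise ValueError("matrix has no non-zero rows")
    x = _kr_vector(sub, tol=tol, max_iter=max_iter)
    if x is None:
        warnings.warn("KR iteration did not converge; falling back to iterative proportional scaling")
        x = _sinkhorn_vector(sub, tol=tol, max_iter=10000)
    scaling = np.zeros(m.n_bins)
    scaling[keep] = x
    out = A * scaling[:, None] * scaling[None, :]
    return ContactMatrix(
        out, resolution=m.resolution, chrom=m.chrom, balanced=True, scaling=scaling
    )


def _kr_vector(A: np.ndarray, tol: float, max_iter: int) -> np.ndarray | None:
    """Knight–Ruiz inner-outer Newton iteration (conjugate-gradient inner
    solves) for the vector x with diag(x) A diag(x) doubly stochastic."""
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    g = 0.9
    etamax = 0.1
    eta = etamax
    rt = tol**2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    i = 0
    while rout > rt and i < max_iter:
        i += 1
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, rt)
        rho_km2 = rho_km1
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= 0.01:  # delta lower bound
                gamma = np.min((0.01 - y[ap < 0]) / ap[ap < 0]) if np.any(ap < 0) else 1.0
                y = y + gamma * ap
                break
            if ynew.max() >= 10.0:  # Delta upper bound
                mask = ynew > 10.0
                gamma = np.min((10.0 - y[mask]) / ap[mask])
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k > 200:
                break
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta = min(max(g * rat, 0.5 * tol / max(res_norm, tol)), etamax)
        if not np.all(np.isfinite(x)) or x.min() <= 0:
            return None
    if rout > rt:
        return None
    return x


def _sinkhorn_vector(A: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    x = np.ones(A.shape[0])
    for _ in range(max_iter):
        s = x * (A @ x)
        if np.max(np.abs(s - 1.0)) < tol:
            break
        x = x / np.sqrt(s)
    return x


# ---------------------------------------------------------------------------
# O/E, Pearson, eigenvector


def oe_transform(m: ContactMatrix) -> np.ndarray:
    """Observed/expected: divide each entry by its diagonal (distance) mean.

    The expected model is the per-diagonal mean over non-masked bins.
    Entries on diagonals with zero mean become NaN (masked).  Idempotent up
    to masking: O/E of an O/E matrix is itself.
    """
    A = m.matrix
    keep = ~m.masked_bins
    n = m.n_bins
    out = np.full_like(A, np.nan)
    for d in range(n):
        i = np.arange(n - d)
        j = i + d
        valid = keep[i] & keep[j]
        if not valid.any():
            continue
        mean = A[i[valid], j[valid]].mean()
        if mean == 0:
            continue
        vals = A[i, j] / mean
        out[i, j] = np.where(valid, vals, np.nan)
        out[j, i] = out[i, j]
    return out


def pearson_map(oe: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of O/E rows; diagonal set to 1.

    Rows with any masked (NaN) entry or zero variance are masked (NaN) in
    the output rather than raising.
    """
    oe = np.asarray(oe, dtype=float)
    usable = ~np.isnan(oe).all(axis=1)
    # a row is usable if it has finite values and non-zero variance
    finite_rows = usable & np.array([np.nanstd(r) > 0 for r in oe])
    idx = np.flatnonzero(finite_rows)
    if idx.size < 3:
        raise ValueError("need at least 3 usable rows for a correlation map")
    sub = oe[np.ix_(idx, idx)]
    # column-wise masking: restrict to columns finite for the kept rows
    col_ok = np.all(np.isfinite(sub), axis=0)
    sub = sub[:, col_ok]
    corr = np.corrcoef(sub)
    out = np.full(oe.shape, np.nan)
    out[np.ix_(idx, idx)] = corr
    np.fill_diagonal(out[np.ix_(idx, idx)], 1.0)
    # restore exact diagonal ones on usable bins
    for i in idx:
        out[i, i] = 1.0
    return out


def compartment_eigenvector(
    pearson: np.ndarray, reference: np.ndarray | None = None
) -> np.ndarray:
    """First eigenvector of the (double-centred) Pearson map: A/B signs.

    The leading eigenvector of the centred correlation matrix captures the
    plaid compartment structure; its global sign is arbitrary, so it is
    flipped to correlate positively with ``reference`` (typically the
    early/late replication-timing ratio, since the A compartment replicates
    early).  Masked bins yield NaN entries.

    Raises if the two leading eigenvalues are (near-)degenerate, since the
    compartment vector is then not identifiable.
    """
    P = np.asarray(pearson, dtype=float)
    usable = np.flatnonzero(~np.isnan(P).all(axis=1))
    sub = P[np.ix_(usable, usable)]
    if not np.all(np.isfinite(sub)):
        sub = np.nan_to_num(sub)
    n = sub.shape[0]
    row_mean = sub.mean(axis=1, keepdims=True)
    grand = sub.mean()
    centred = sub - row_mean - row_mean.T + grand
    vals, vecs = np.linalg.eigh(centred)
    lead, second = vals[-1], vals[-2]
    if abs(lead) < 1e-12 or abs(lead - second) < 1e-9 * max(abs(lead), 1.0):
        raise ValueError("degenerate leading eigenvalue: compartment vector not identifiable")
    ev = vecs[:, -1]
    out = np.full(P.shape[0], np.nan)
    out[usable] = ev
    if reference is not None:
        ref = np.asarray(reference, dtype=float)[usable]
        ok = np.isfinite(ref)
        c = np.corrcoef(ev[ok], ref[ok])[0, 1]
        if c < 0:
            out = -out
    return out


# ---------------------------------------------------------------------------
# histone clusters and contact ratios


def kmeans_histone_clusters(
    tracks: TrackSet, k: int = 6, seed: int = 0, n_init: int = 25
) -> ClusterAssignment:
    """k-means clustering of per-bin histone-mark z-scores.

    Each mark is z-scored across bins first, to equalise dynamic ranges
    between marks.  Clusters are relabelled by descending size so that the
    (arbitrary) numbering is deterministic.
    """
    X = tracks.values()
    ok = np.all(np.isfinite(X), axis=1)
    if ok.sum() < k:
        raise ValueError(f"k={k} exceeds the {int(ok.sum())} usable bins")
    Z = X[ok]
    sd = Z.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("a mark has zero variance across bins; cannot z-score")
    Z = (Z - Z.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(Z)
    raw = km.labels_
    order = np.argsort(-np.bincount(raw, minlength=k), kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    labels = np.zeros(tracks.n_bins, dtype=int)
    labels[ok] = remap[raw]
    return ClusterAssignment(labels=labels, k=k)


def cluster_contact_log2ratio(
    post: ContactMatrix, pre: ContactMatrix, clusters: ClusterAssignment
) -> np.ndarray:
    """k x k log2 ratio of mean between-cluster contacts, post vs pre.

    For each cluster pair (a, b) the mean contact over all bin pairs
    (i in a, j in b, i != j) is computed in both matrices; the output entry
    is ``log2(mean_post / mean_pre)``.  Symmetric; rows/columns of empty
    clusters are NaN.
    """
    if post.n_bins != pre.n_bins or len(clusters.labels) != post.n_bins:
        raise ValueError("matrices and clusters must share the binning")
    k = clusters.k
    out = np.full((k, k), np.nan)
    members = [np.flatnonzero(clusters.labels == c) for c in range(1, k + 1)]
    for a in range(k):
        for b in range(a, k):
            ia, ib = members[a], members[b]
            if ia.size == 0 or ib.size == 0:
                continue
            sub_post = post.matrix[np.ix_(ia, ib)]
            sub_pre = pre.matrix[np.ix_(ia, ib)]
            if a == b:
                off = ~np.eye(ia.size, dtype=bool)
                if not off.any():
                    continue
                mp, mq = sub_post[off].mean(), sub_pre[off].mean()
            else:
                mp, mq = sub_post.mean(), sub_pre.mean()
            if mq > 0 and mp > 0:
                out[a, b] = out[b, a] = np.log2(mp / mq)
    return out


# ---------------------------------------------------------------------------
# aggregate peak analysis


def apa(
    m: ContactMatrix, loops, window: int = 10
) -> tuple[np.ndarray, float, float, int]:
    """Aggregate peak analysis over a loop list.

    Sums the ``(2*window+1)²`` submatrices centred on each loop pixel
    (bin_i, bin_j).  Loops closer than ``window`` bins to the diagonal or
    the matrix edge are skipped.  The centre score is the central value of
    the aggregate; the enrichment ratio divides it by the mean of the
    lower-left corner block (``window/2 × window/2``), which samples the
    distance-decay background.

    Returns ``(aggregate, center_score, enrichment_ratio, n_used)``.
    """
    A = m.matrix
    n = m.n_bins
    w = int(window)
    agg = np.zeros((2 * w + 1, 2 * w + 1))
    used = 0
    for bi, bj in loops:
        i, j = (int(bi), int(bj)) if bi <= bj else (int(bj), int(bi))
        if j - i < w or i - w < 0 or j + w >= n or i + w >= n or j - w < 0:
            continue
        agg += A[i - w : i + w + 1, j - w : j + w + 1]
        used += 1
    if used == 0:
        raise ValueError("no usable loops for APA at this window")
    center = float(agg[w, w])
    c = max(w // 2, 1)
    corner = agg[-c:, :c]  # lower-left: larger i (rows), smaller j (cols)
    ratio = center / corner.mean() if corner.mean() > 0 else np.inf
    return agg, center, float(ratio), used


# ---------------------------------------------------------------------------
# replication timing


def replication_timing(
    early: np.ndarray, late: np.ndarray, pseudocount: float = 1.0
) -> ReplicationTimingTrack:
    """Per-bin log2 early/late ratio and its percentile transform."""
    e = np.asarray(early, dtype=float)
    l = np.asarray(late, dtype=float)
    if e.shape != l.shape:
        raise ValueError("early and late tracks must share the binning")
    if not (e.any() or l.any()):
        raise ValueError("both tracks are all zero")
    ratio = np.log2((e + pseudocount) / (l + pseudocount))
    mask = np.isfinite(ratio)
    pct = np.full_like(ratio, np.nan)
    pct[mask] = 100.0 * (sps.rankdata(ratio[mask]) - 1) / max(mask.sum() - 1, 1)
    return ReplicationTimingTrack(early=e, late=l, log2_ratio=ratio, percentile=pct, mask=mask)


def timing_preservation(
    t1: ReplicationTimingTrack, t2: ReplicationTimingTrack
) -> tuple[float, pd.DataFrame]:
    """Spearman correlation of two timing tracks' percentiles.

    Returns the correlation and the paired scatter table (one row per
    shared usable bin).
    """
    if t1.percentile.shape != t2.percentile.shape:
        raise ValueError("tracks must share the binning")
    shared = t1.mask & t2.mask
    if shared.sum() < 3:
        raise ValueError("fewer than 3 shared usable bins")
    x = t1.percentile[shared]
    y = t2.percentile[shared]
    rho = float(sps.spearmanr(x, y).statistic)
    table = pd.DataFrame({"bin": np.flatnonzero(shared), "percentile_1": x, "percentile_2": y})
    return rho, table
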