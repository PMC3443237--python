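"""Smallest confidence-ellipsoid clustering of pooled participant peaks.

Given N participants' top-M peaks (N·M points), a k-means procedure with
k = M derives candidate clusters; after every assignment step each cluster
is *trimmed* so that no participant contributes more than one point (the
point nearest the cluster centroid is kept), centroids are recomputed from
the trimmed members, and the loop repeats.  Across iterations and random
restarts the engine records, for every achieved participant count
N' ∈ [n_min, N], the trimmed cluster with the smallest major 95% radius.

The cluster-size statistic is the major radius of the confidence
ellipsoid: eigen-decompose the 3×3 sample covariance of the member
locations; each axis half-length is 1.959964 × sqrt(eigenvalue), i.e. the
two-sided Gaussian 95% half-width of the point spread along that axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .peaks import PeakList

#: two-sided Gaussian 95% half-width in standard deviations
Z95 = 1.959964


@dataclass
class Ellipsoid:
    """95% confidence ellipsoid of a set of member peaks (≤1 per participant)."""

    center_mm: np.ndarray          # (3,) centroid of member locations
    axes: np.ndarray               # (3, 3) rows = orthonormal principal axes
    radii_mm: np.ndarray           # (3,) descending 95% half-lengths
    members: dict                  # participant -> Peak
    n_participants: int

    @property
    def major_radius_mm(self) -> float:
        return float(self.radii_mm[0])

    @property
    def volume_mm3(self) -> float:
        return float(4.0 / 3.0 * np.pi * np.prod(self.radii_mm))

    @property
    def mean_value(self) -> float:
        return float(np.mean([p.value for p in self.members.values()]))


def fit_ellipsoid(points) -> Ellipsoid:
    """Fit the 95% confidence ellipsoid to ``(participant, location_mm)`` pairs.

    Center is the centroid; axes are the eigenvectors of the sample
    covariance of the locations; radii are ``Z95 * sqrt(eigenvalues)``
    sorted descending.  With fewer than 3 distinct points the missing
    eigen-directions get radius 0.  Raises if any participant appears twice
    or fewer than 2 points are given.
    """
    from .peaks import Peak

    pairs = list(points)
    if len(pairs) < 2:
        raise ValueError("need at least 2 points to fit an ellipsoid")
    pids = []
    locs = []
    members = {}
    for item in pairs:
        if isinstance(item, Peak):
            pid, loc, peak = item.participant, item.location_mm, item
        else:
            pid, loc = item[0], np.asarray(item[1], dtype=float)
            peak = Peak(pid, loc, np.nan, 1)
        if pid in members:
            raise ValueError(f"participant {pid!r} contributes more than one point")
        members[pid] = peak
        pids.append(pid)
        locs.append(loc)
    X = np.asarray(locs, dtype=float)
    center = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    evals = np.clip(evals, 0.0, None)
    order = np.argsort(-evals)
    radii = Z95 * np.sqrt(evals[order])
    axes = evecs[:, order].T
    return Ellipsoid(center, axes, radii, members, len(members))


@dataclass
class ClusterSet:
    """Per subgroup size N', the smallest ellipsoid found with exactly N' members."""

    m: int
    n_total: int
    n_min: int
    clusters: dict[int, Ellipsoid] = field(default_factory=dict)

    def __getitem__(self, n: int) -> Ellipsoid:
        return self.clusters[n]

    def __contains__(self, n: int) -> bool:
        return n in self.clusters

    def subgroup_sizes(self):
        return sorted(self.clusters)


def _kmeanspp(pts: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding (D² sampling)."""
    n = pts.shape[0]
    centroids = np.empty((k, 3))
    centroids[0] = pts[rng.integers(n)]
    d2 = ((pts - centroids[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        tot = d2.sum()
        if tot <= 0:
            centroids[j:] = pts[rng.integers(n, size=k - j)]
            break
        probs = d2 / tot
        centroids[j] = pts[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((pts - centroids[j]) ** 2).sum(axis=1))
    return centroids


def _best_trimmed_clusters(pts, pids, ranks, k, n_min, iterations, restarts, rng,
                           keep_members):
    """Core search: best (smallest major radius) trimmed cluster per N'.

    ``pts`` (P,3), ``pids`` (P,) int codes, ``ranks`` (P,) int.  Returns
    ``best_r`` (dict n' -> radius) and ``best_idx`` (dict n' -> member row
    indices, only if ``keep_members``).  Trimming tie-break: of two
    equidistant points from one participant the better (lower) rank wins.
    """
    P = pts.shape[0]
    best_r: dict[int, float] = {}
    best_idx: dict[int, np.ndarray] = {}
    row = np.arange(P)
    for _ in range(restarts):
        centroids = _kmeanspp(pts, k, rng)
        for _ in range(iterations):
            d2 = ((pts[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
            assign = np.argmin(d2, axis=1)
            dmin = d2[row, assign]
            # keep, per (cluster, participant), the nearest point (then best rank)
            order = np.lexsort((ranks, dmin, pids, assign))
            a_s = assign[order]
            p_s = pids[order]
            first = np.empty(P, dtype=bool)
            first[0] = True
            first[1:] = (a_s[1:] != a_s[:-1]) | (p_s[1:] != p_s[:-1])
            keep = order[first]
            ka = assign[keep]
            X = pts[keep]
            cnt = np.bincount(ka, minlength=k)
            sums = np.stack([np.bincount(ka, weights=X[:, c], minlength=k)
                             for c in range(3)], axis=1)
            nz = cnt > 0
            means = np.zeros((k, 3))
            means[nz] = sums[nz] / cnt[nz, None]
            centroids = np.where(nz[:, None], means, centroids)

            rec = cnt >= max(2, n_min)
            if rec.any():
                # per-cluster sample covariance via second moments
                S2 = np.empty((k, 3, 3))
                for a in range(3):
                    for b in range(a, 3):
                        s = np.bincount(ka, weights=X[:, a] * X[:, b], minlength=k)
                        S2[:, a, b] = s
                        S2[:, b, a] = s
                ridx = np.flatnonzero(rec)
                c_r = cnt[ridx]
                m_r = means[ridx]
                cov = (S2[ridx] - c_r[:, None, None] * m_r[:, :, None] * m_r[:, None, :])
                cov /= (c_r - 1)[:, None, None]
                evmax = np.linalg.eigvalsh(cov)[:, -1]
                radii = Z95 * np.sqrt(np.clip(evmax, 0.0, None))
                for ci, n_c, r in zip(ridx, c_r, radii):
                    n_c = int(n_c)
                    if r < best_r.get(n_c, np.inf):
                        best_r[n_c] = float(r)
                        if keep_members:
                            best_idx[n_c] = keep[ka == ci].copy()
    return best_r, best_idx


def smallest_clusters(peaklists, m: int, n_min: int, iterations: int = 30,
                      restarts: int = 10,
                      seed: int | np.random.Generator | None = 0,
                      already_truncated: bool = False) -> ClusterSet:
    """Smallest one-peak-per-participant ellipsoid per subgroup size.

    Pools the top-``m`` peaks of each participant (``already_truncated``
    skips the truncation when the caller has applied :func:`top_m`), runs
    the trimmed k-means search with ``k = m`` for ``iterations`` rounds and
    ``restarts`` independent k-means++ initialisations, and returns the
    best ellipsoid found for every achieved participant count in
    ``[n_min, N]``.  Deterministic for a fixed ``seed``.
    """
    from .peaks import top_m

    peaklists = list(peaklists)
    N = len(peaklists)
    if n_min < 2:
        raise ValueError("n_min must be >= 2")
    if N < n_min:
        raise ValueError("need at least n_min participants")
    truncated = peaklists if already_truncated else [top_m(pl, m) for pl in peaklists]
    pts, pids, ranks, owners = _pool(truncated)
    if pts.shape[0] < n_min:
        raise ValueError("fewer pooled peaks than n_min")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best_r, best_idx = _best_trimmed_clusters(
        pts, pids, ranks, m, n_min, iterations, restarts, rng, keep_members=True)
    cs = ClusterSet(m=m, n_total=N, n_min=n_min)
    for n_c, idx in best_idx.items():
        cs.clusters[n_c] = fit_ellipsoid([owners[i] for i in idx])
    return cs


def min_radii_by_subgroup(peaklists, m: int, n_min: int, iterations: int = 30,
                          restarts: int = 10,
                          seed: int | np.random.Generator | None = 0,
                          already_truncated: bool = False) -> dict[int, float]:
    """Like :func:`smallest_clusters` but returns only {N': major radius}.

    Fast path used by the permutation null, where the ellipsoid geometry
    is never needed — only its major radius.
    """
    from .peaks import top_m

    peaklists = list(peaklists)
    truncated = peaklists if already_truncated else [top_m(pl, m) for pl in peaklists]
    pts, pids, ranks, _ = _pool(truncated)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best_r, _ = _best_trimmed_clusters(
        pts, pids, ranks, m, n_min, iterations, restarts, rng, keep_members=False)
    return best_r


def _pool(truncated):
    """Flatten truncated peak lists into arrays (+ Peak objects for recovery)."""
    pts, pid_codes, ranks, owners = [], [], [], []
    for code, pl in enumerate(truncated):
        srt = pl.sorted_by_rank()
        for i in range(len(srt)):
            pts.append(srt.locations_mm[i])
            pid_codes.append(code)
            ranks.append(srt.ranks[i])
            owners.append(srt.peak(i))
    return (np.asarray(pts, dtype=float), np.asarray(pid_codes),
            np.asarray(ranks), owners)
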