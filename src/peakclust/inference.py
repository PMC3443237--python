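"""Rank-shuffling permutation inference for peak clusters.

Under the null hypothesis that peak rank carries no spatial information,
the top-M peaks of a participant are exchangeable with any random M-subset
of that participant's peaks.  Shuffling ranks within each participant
(locations never move) and re-running the clustering therefore yields the
chance distribution of the smallest major radius, per subgroup size N'.
An observed cluster is significant when its major radius falls in the
lower tail of this distribution.

Testing a range of peak counts M re-tests one hypothesis on overlapping
data; an effectively independent dataset enters only each time M doubles,
so the Bonferroni family size is ``1 + log2(M_end / M_start)`` and the
test-wise threshold is ``alpha`` divided by that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import ClusterSet, Ellipsoid, min_radii_by_subgroup, smallest_clusters
from .peaks import PeakList


def permute_ranks(peaklists, rng: np.random.Generator) -> list[PeakList]:
    """Assign a uniform random rank permutation within each participant.

    Locations and values keep their pairing and never move; only the
    ``ranks`` array is permuted, so a subsequent ``top_m`` draws a uniform
    random m-subset of the participant's peaks.
    """
    out = []
    for pl in peaklists:
        new_ranks = rng.permutation(len(pl)) + 1
        out.append(PeakList(pl.participant, pl.locations_mm.copy(),
                            pl.values.copy(), pl.sign, new_ranks))
    return out


@dataclass
class NullDistribution:
    """Chance distribution of smallest major radii, per subgroup size N'.

    ``radii[n]`` holds one entry per permutation in which a trimmed
    cluster with exactly ``n`` participants was achieved (so it may have
    fewer than ``k_permutations`` entries; the missing permutations count
    as "larger than any observed radius" in the p-value).
    """

    m: int
    k_permutations: int
    radii: dict[int, np.ndarray] = field(default_factory=dict)

    def quantile(self, n: int, q: float) -> float:
        return float(np.quantile(self.radii[n], q))


def build_null(peaklists, m: int, n_min: int, k_permutations: int = 500,
               seed: int | np.random.Generator | None = 0,
               iterations: int = 30, restarts: int = 10) -> NullDistribution:
    """K rank permutations, each followed by the smallest-cluster search.

    The clustering engine runs with exactly the same settings
    (``iterations``, ``restarts``) the observed analysis uses, so observed
    and null radii are like-for-like.  For speed, each permutation draws a
    uniform random m-subset per participant directly — equivalent to
    ``top_m(permute_ranks(...), m)`` since locations are fixed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    peaklists = [pl.sorted_by_rank() for pl in peaklists]
    series: dict[int, list[float]] = {}
    for _ in range(k_permutations):
        drawn = []
        for pl in peaklists:
            take = min(m, len(pl))
            idx = rng.permutation(len(pl))[:take]
            drawn.append(PeakList(pl.participant, pl.locations_mm[idx],
                                  pl.values[idx], pl.sign))
        best = min_radii_by_subgroup(drawn, m, n_min, iterations=iterations,
                                     restarts=restarts, seed=rng,
                                     already_truncated=True)
        for n, r in best.items():
            series.setdefault(n, []).append(r)
    return NullDistribution(
        m=m, k_permutations=k_permutations,
        radii={n: np.asarray(v) for n, v in sorted(series.items())})


def p_value(observed: Ellipsoid | float, null: NullDistribution,
            n_participants: int | None = None) -> float:
    """Permutation p-value with the add-one rule: (1 + #{null ≤ obs}) / (K + 1).

    Permutations in which the subgroup size was never achieved count as
    larger than any observed radius.  ``observed`` may be an
    :class:`~peakclust.cluster.Ellipsoid` or a bare major radius (then
    ``n_participants`` is required).
    """
    if isinstance(observed, Ellipsoid):
        r = observed.major_radius_mm
        n = observed.n_participants
    else:
        r = float(observed)
        if n_participants is None:
            raise ValueError("n_participants required for a bare radius")
        n = n_participants
    if n not in null.radii:
        raise KeyError(f"null distribution has no entries for subgroup size {n}")
    count = int(np.sum(null.radii[n] <= r))
    return (1 + count) / (null.k_permutations + 1)


def corrected_alpha(alpha: float, m_start: int, m_end: int) -> float:
    """Test-wise threshold preserving family-wise ``alpha`` over M in [m_start, m_end].

    ``alpha / (1 + log2(m_end / m_start))`` — one Bonferroni unit per
    doubling of the peak count, since only a doubling introduces an
    effectively independent set of peaks.
    """
    if m_start < 1 or m_end < m_start:
        raise ValueError("need 1 <= m_start <= m_end")
    return alpha / (1.0 + math.log2(m_end / m_start))


@dataclass
class ScanRow:
    m: int
    n_participants: int
    ellipsoid: Ellipsoid
    mean_value: float
    p_raw: float
    p_corrected: float
    significant: bool


@dataclass
class ScanResult:
    """All (M, N') cluster findings of a multi-M scan with corrected p-values."""

    rows: list[ScanRow]
    m_range: tuple[int, int]
    alpha_family: float = 0.05

    @property
    def threshold(self) -> float:
        return corrected_alpha(self.alpha_family, *self.m_range)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            e = r.ellipsoid
            recs.append({
                "N": r.n_participants, "M": r.m,
                "x": e.center_mm[0], "y": e.center_mm[1], "z": e.center_mm[2],
                "volume_mm3": e.volume_mm3, "major_radius_mm": e.major_radius_mm,
                "mean_value": r.mean_value, "p_raw": r.p_raw,
                "p_corrected": r.p_corrected, "significant": r.significant,
            })
        return pd.DataFrame(recs)

    def significant_rows(self) -> list[ScanRow]:
        return [r for r in self.rows if r.significant]


def scan_m(peaklists, m_start: int, m_end: int, n_min: int,
           k_permutations: int = 500, seed: int = 0, alpha: float = 0.05,
           iterations: int = 30, restarts: int = 10) -> ScanResult:
    """Run the clustering test for every M in [m_start, m_end].

    For each M a fresh permutation null is built and every achieved
    subgroup size N' gets a raw p-value; significance is judged against
    the doubling-corrected threshold for the scanned M range.
    ``p_corrected`` is the raw p-value times the family size, clipped at 1.
    """
    rng = np.random.default_rng(seed)
    family = 1.0 + math.log2(m_end / m_start)
    thr = corrected_alpha(alpha, m_start, m_end)
    rows: list[ScanRow] = []
    for m in range(m_start, m_end + 1):
        observed = smallest_clusters(peaklists, m, n_min, iterations=iterations,
                                     restarts=restarts, seed=rng)
        null = build_null(peaklists, m, n_min, k_permutations, seed=rng,
                          iterations=iterations, restarts=restarts)
        for n in observed.subgroup_sizes():
            if n not in null.radii:
                continue
            ell = observed[n]
            p = p_value(ell, null)
            rows.append(ScanRow(m, n, ell, ell.mean_value, p,
                                min(1.0, p * family), p < thr))
    return ScanResult(rows, (m_start, m_end), alpha)


def select_reported(scan: ScanResult, link_mm: float = 15.0) -> list[ScanRow]:
    """One representative row per recurring region among significant findings.

    Significant ellipsoid centres are grouped by single-linkage proximity
    (``link_mm``); within each group the row with the largest N' is
    preferred, ties broken by the smallest major radius.
    """
    sig = scan.significant_rows()
    if not sig:
        return []
    centers = np.array([r.ellipsoid.center_mm for r in sig])
    n = len(sig)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(centers[i] - centers[j]) <= link_mm:
                parent[find(i)] = find(j)
    groups: dict[int, list[ScanRow]] = {}
    for i, row in enumerate(sig):
        groups.setdefault(find(i), []).append(row)
    return [min(g, key=lambda r: (-r.n_participants, r.ellipsoid.major_radius_mm))
            for g in groups.values()]


@dataclass
class HeuristicCurve:
    """Null-radius threshold curve R(M, N') and the trade-off J(M, N')."""

    m_values: np.ndarray                  # (nM,)
    r_by_subgroup: dict[int, np.ndarray]  # n' -> (nM,) radii, NaN when unachieved
    percentile: float = 95.0

    def j_series(self, n: int, m_scale: float = 1.0, r_scale: float = 1.0
                 ) -> np.ndarray:
        r = self.r_by_subgroup[n]
        return np.sqrt((m_scale * self.m_values) ** 2 + (r_scale * r) ** 2)


def heuristic_curve(peaklists, m_start: int, m_end: int, n_min: int,
                    k_permutations: int = 500, seed: int = 0,
                    percentile: float = 95.0, iterations: int = 30,
                    restarts: int = 10) -> HeuristicCurve:
    """R(M, N') = the given percentile of the null major-radius distribution."""
    rng = np.random.default_rng(seed)
    ms = np.arange(m_start, m_end + 1)
    peaklists = list(peaklists)
    N = len(peaklists)
    series = {n: np.full(ms.size, np.nan) for n in range(n_min, N + 1)}
    for k, m in enumerate(ms):
        null = build_null(peaklists, int(m), n_min, k_permutations, seed=rng,
                          iterations=iterations, restarts=restarts)
        for n, radii in null.radii.items():
            series[n][k] = np.percentile(radii, percentile)
    return HeuristicCurve(ms, series, percentile)


def heuristic_J(curve: HeuristicCurve, m_scale: float = 1.0, r_scale: float = 1.0
                ) -> dict[int, dict]:
    """J(M, N') = sqrt(M² + R²) per subgroup, with its minimising M.

    J is a heuristic distance-from-the-knee score in (peak count, mm)
    space: it grows at small M because the chance radius R is large, and
    at large M because M itself does.  Axis scalings let the caller weigh
    the two units differently.  Returns ``{n': {"m": M array, "J": J
    array, "m_opt": argmin M}}``.
    """
    out = {}
    for n in sorted(curve.r_by_subgroup):
        j = curve.j_series(n, m_scale, r_scale)
        if np.all(np.isnan(j)):
            continue
        m_opt = int(curve.m_values[int(np.nanargmin(j))])
        out[n] = {"m": curve.m_values.copy(), "J": j, "m_opt": m_opt}
    return out
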