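"""Local-maxima extraction from volumetric statistic images.

A beamformer contrast image is compressed to a rank-ordered list of its
local maxima ("peaks"); all group-level statistics downstream operate on
these point lists only.  A peak is a voxel that strictly exceeds every one
of its 18-connected in-volume neighbours (6 faces + 12 edges; the 8 corner
voxels are not neighbours), so two maxima can be as close as a single
non-maximal voxel apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

try:  # nibabel only needed when reading/writing NIfTI
    import nibabel as nib
except ImportError:  # pragma: no cover
    nib = None

Sign = Literal["positive", "negative"]

#: offsets of the 18-connected neighbourhood (faces + edges, no corners)
NEIGHBOUR_OFFSETS_18: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0) and abs(dx) + abs(dy) + abs(dz) <= 2
)


@dataclass(frozen=True)
class Peak:
    """A single local maximum of one participant's image."""

    participant: str
    location_mm: np.ndarray  # (3,) world-space mm
    value: float
    rank: int  # 1 = strongest for the chosen sign

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "location_mm", np.asarray(self.location_mm, dtype=float).reshape(3)
        )


@dataclass
class PeakList:
    """Rank-ordered peaks of one participant, for one sign of interest.

    ``locations_mm``, ``values`` and ``ranks`` are parallel arrays; rows are
    stored in rank order (rank 1 first).  Ranks are a permutation of
    ``1..P`` — after :func:`peakclust.inference.permute_ranks` they are no
    longer sorted, and :func:`top_m` always selects by rank.
    """

    participant: str
    locations_mm: np.ndarray  # (P, 3)
    values: np.ndarray  # (P,)
    sign: Sign = "positive"
    ranks: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.locations_mm = np.atleast_2d(np.asarray(self.locations_mm, dtype=float))
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.locations_mm.shape != (self.values.size, 3):
            raise ValueError("locations_mm must be (P, 3) matching values")
        if self.ranks is None:
            self.ranks = np.arange(1, self.values.size + 1)
        else:
            self.ranks = np.asarray(self.ranks, dtype=int).ravel()
            if sorted(self.ranks) != list(range(1, self.values.size + 1)):
                raise ValueError("ranks must be a permutation of 1..P")

    def __len__(self) -> int:
        return self.values.size

    def __iter__(self):
        for i in range(len(self)):
            yield self.peak(i)

    def peak(self, i: int) -> Peak:
        return Peak(self.participant, self.locations_mm[i], float(self.values[i]),
                    int(self.ranks[i]))

    def sorted_by_rank(self) -> "PeakList":
        order = np.argsort(self.ranks)
        return PeakList(self.participant, self.locations_mm[order],
                        self.values[order], self.sign, self.ranks[order])


@dataclass
class VolumetricImage:
    """A 3-D statistic image with a voxel→mm affine and optional mask."""

    values: np.ndarray  # (nx, ny, nz)
    affine: np.ndarray  # (4, 4) voxel index -> world mm
    brain_mask: np.ndarray | None = None  # bool, same shape

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.brain_mask is not None:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.values.shape:
                raise ValueError("mask shape must match values")

    def voxel_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Map (n, 3) 0-based voxel indices to world mm."""
        idx = np.atleast_2d(idx)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    @classmethod
    def from_nifti(cls, path: str | Path, mask: np.ndarray | None = None
                   ) -> "VolumetricImage":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj, dtype=float), img.affine, mask)

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), self.affine),
                 str(path))


def find_local_maxima(img: VolumetricImage, sign: Sign = "positive",
                      participant: str = "0",
                      require_sign_consistent: bool = False) -> PeakList:
    """All strict 18-neighbour local maxima of ``img``, rank-ordered.

    For ``sign="negative"`` the negated image is scanned, so ranks order
    peaks by increasing (most negative first) value.  Neighbours outside
    the array or outside the mask are ignored, so maxima on the volume
    boundary are reportable.  A constant image has no strict maximum and
    yields an empty list.

    ``require_sign_consistent`` drops peaks whose value has the "wrong"
    sign (e.g. negative values under ``sign="positive"``); by default they
    are kept, since only rank order enters the statistics.
    """
    vals = img.values if sign == "positive" else -img.values
    if not np.all(np.isfinite(vals)):
        raise ValueError("image contains non-finite values")
    mask = img.brain_mask
    if mask is None:
        mask = np.ones(vals.shape, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")

    work = np.where(mask, vals, -np.inf)
    padded = np.pad(work, 1, constant_values=-np.inf)
    is_max = mask.copy()
    sl = slice(1, -1)
    for dx, dy, dz in NEIGHBOUR_OFFSETS_18:
        nb = padded[1 + dx: padded.shape[0] - 1 + dx,
                    1 + dy: padded.shape[1] - 1 + dy,
                    1 + dz: padded.shape[2] - 1 + dz]
        is_max &= work > nb
        if not is_max.any():
            break
    del sl

    idx = np.argwhere(is_max)
    peak_vals = vals[is_max]
    if require_sign_consistent:
        keep = peak_vals > 0
        idx, peak_vals = idx[keep], peak_vals[keep]
    order = np.argsort(-peak_vals, kind="stable")
    idx, peak_vals = idx[order], peak_vals[order]
    locs = img.voxel_to_mm(idx) if idx.size else np.empty((0, 3))
    signed = peak_vals if sign == "positive" else -peak_vals
    return PeakList(participant, locs, signed, sign)


def top_m(pl: PeakList, m: int) -> PeakList:
    """The ``min(m, P)`` best-ranked peaks, in rank order.

    When the participant has fewer than ``m`` peaks the full list is
    returned and ``shortfall`` (attached attribute) records the deficit.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    srt = pl.sorted_by_rank()
    take = min(m, len(srt))
    out = PeakList(srt.participant, srt.locations_mm[:take], srt.values[:take],
                   srt.sign, srt.ranks[:take])
    out.shortfall = max(0, m - len(srt))  # type: ignore[attr-defined]
    return out


_COLUMNS = ["participant", "x_mm", "y_mm", "z_mm", "value"]


def write_peak_table(peaklists: Iterable[PeakList], path: str | Path) -> None:
    """Write peak lists as a TSV with columns participant/x_mm/y_mm/z_mm/value."""
    rows = []
    for pl in peaklists:
        srt = pl.sorted_by_rank()
        for i in range(len(srt)):
            rows.append((srt.participant, *srt.locations_mm[i], srt.values[i]))
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_peak_table(path: str | Path, sign: Sign = "positive") -> list[PeakList]:
    """Read a TSV peak table; ranks are recomputed from the values."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak table missing columns: {missing}")
    coords = df[["x_mm", "y_mm", "z_mm", "value"]]
    if not np.all(np.isfinite(coords.to_numpy(dtype=float, na_value=np.nan))):
        raise ValueError("non-numeric coordinates or values in peak table")
    out = []
    for pid, grp in df.groupby("participant", sort=False):
        vals = grp["value"].to_numpy(dtype=float)
        locs = grp[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        order = np.argsort(-vals if sign == "positive" else vals, kind="stable")
        out.append(PeakList(str(pid), locs[order], vals[order], sign))
    return out
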