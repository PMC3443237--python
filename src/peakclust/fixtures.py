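"""Deterministic synthetic peak-list generator for the clustering layer.

Emulates the statistical structure the clustering test assumes, without
running the MEG simulator: each participant contributes a ranked peak
list in which (optionally) one "true" peak is jittered around a common
mm-space location, among uniformly scattered decoy peaks inside a
brain-like bounding box.  The value model places the true peak's rank by
drawing its statistic value from the upper part of the decoy value range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .peaks import PeakList


@dataclass
class FixtureSpec:
    """Configuration for :func:`make_fixture`.

    ``true_rank_beta`` controls the value model: the true peak's value is
    drawn as the ``Beta(true_rank_beta, 1)`` quantile of the decoy value
    range, so large values of the parameter push the true peak towards
    rank 1 (``inf`` pins it at rank 1 exactly).
    """

    n_participants: int = 10
    peaks_per_participant: int = 50
    true_center_mm: tuple | None = (52.0, -29.0, 13.0)
    jitter_sd_mm: float = 5.0
    participation: float = 1.0
    box_min_mm: tuple = (-80.0, -110.0, -70.0)
    box_max_mm: tuple = (80.0, 80.0, 90.0)
    true_rank_beta: float = float("inf")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.participation <= 1.0:
            raise ValueError("participation must be in [0, 1]")
        if self.jitter_sd_mm < 0:
            raise ValueError("jitter SD must be >= 0")


def make_fixture(spec: FixtureSpec,
                 rng: np.random.Generator | None = None) -> list[PeakList]:
    """Generate one synthetic multi-participant peak-list dataset.

    A participant carries the planted peak with probability
    ``participation`` (location = true centre + isotropic Gaussian jitter);
    remaining peaks are uniform decoys in the bounding box with values
    uniform in (0, 1).  Deterministic for a fixed spec seed.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    lo = np.asarray(spec.box_min_mm, dtype=float)
    hi = np.asarray(spec.box_max_mm, dtype=float)
    out = []
    for pid in range(spec.n_participants):
        p = spec.peaks_per_participant
        has_true = (spec.true_center_mm is not None
                    and rng.random() < spec.participation)
        n_decoys = p - 1 if has_true else p
        locs = rng.uniform(lo, hi, size=(n_decoys, 3))
        vals = rng.uniform(0.0, 1.0, size=n_decoys)
        if has_true:
            true_loc = np.asarray(spec.true_center_mm) + rng.normal(
                0.0, spec.jitter_sd_mm, size=3)
            if np.isinf(spec.true_rank_beta):
                true_val = vals.max() + 1.0 if n_decoys else 1.0
            else:
                true_val = rng.beta(spec.true_rank_beta, 1.0)
            locs = np.vstack([locs, true_loc])
            vals = np.append(vals, true_val)
        order = np.argsort(-vals, kind="stable")
        out.append(PeakList(str(pid), locs[order], vals[order], "positive"))
    return out
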