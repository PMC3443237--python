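"""Cluster planted peaks across participants and test them against chance.

Builds a synthetic 10-participant dataset in which every participant's
strongest peak sits within ~5 mm jitter of a common location among 20
uniformly scattered decoys, finds the smallest one-peak-per-participant
ellipsoid for the top M = 3 peaks, and compares its major radius with a
rank-shuffled null.
"""

import numpy as np

from peakclust import (FixtureSpec, build_null, make_fixture, p_value,
                       smallest_clusters)

peaklists = make_fixture(FixtureSpec(
    n_participants=10, peaks_per_participant=20,
    true_center_mm=(52.0, -29.0, 13.0), jitter_sd_mm=5.0, seed=0))

clusters = smallest_clusters(peaklists, m=3, n_min=8, seed=0)
null = build_null(peaklists, m=3, n_min=8, k_permutations=500, seed=0)

for n in clusters.subgroup_sizes():
    e = clusters[n]
    p = p_value(e, null)
    print(f"N'={n}: centre {np.round(e.center_mm, 1)}, "
          f"major radius {e.major_radius_mm:.1f} mm, p = {p:.4f}")

# The N'=10 ellipsoid sits at the planted centre with a ~14 mm major
# radius (1.96 sigma of the 5 mm jitter, inflated by sampling), far below
# the chance radii of random peak subsets, so p is at the add-one floor
# 1/(K+1) ~ 0.002.  Subgroup sizes are exact counts: once the planted
# peaks are absorbed into the full-group cluster, the smallest cluster
# with exactly 8 contributors is a loose decoy cluster with p = 1.
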