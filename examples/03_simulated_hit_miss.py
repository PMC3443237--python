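"""Simulated dipole study: peak clustering vs the volumetric comparator.

Simulates a pool of participants with a jittered 40 Hz dipole, beamforms
pseudo-t images, draws repeated groups of 8, and counts hits (significant
finding within 20 mm of the seed centre) and misses for both group
methods.  Scaled down (5 groups, K = 100, two magnitudes) to run in about
a minute; the full protocol uses 20 groups and K = 500.
"""

from peakclust import SimulationConfig, run_hit_miss_experiment

cfg = SimulationConfig()  # seed N((52,-29,13), 5 mm), 40 Hz, 30/60 epochs
result = run_hit_miss_experiment(
    cfg, magnitudes_nam=[12.0, 50.0], n_groups=5, group_size=8,
    pool_size=10, m=5, k_permutations=100, alpha=0.05, seed=0)

print("method           magnitude  hits  misses")
for method in result.hits:
    for mag, h, s in zip(result.magnitudes_nam, result.hits[method],
                         result.misses[method]):
        print(f"{method:<16} {mag:>8.0f}  {h:>4d}  {s:>6d}")

# At 50 nAm both methods find the source in every group (hits = groups,
# no misses).  At a moderate 12 nAm the volumetric comparator also flags
# consistent smooth side-lobe structure far from the source (misses),
# while the peak-clustering statistic stays clean: those regions carry no
# tightly clustered local maxima.
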