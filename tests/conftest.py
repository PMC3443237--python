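import numpy as np
import pytest

from peakclust import FixtureSpec, make_fixture


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def planted_peaklists():
    """10 participants, tight planted cluster among uniform decoys."""
    return make_fixture(FixtureSpec(n_participants=10, peaks_per_participant=20,
                                    jitter_sd_mm=5.0, participation=1.0, seed=42))


def brute_force_maxima(values, mask):
    """Exhaustive 18-neighbour strict-maximum scan (independent oracle)."""
    offsets = [(dx, dy, dz)
               for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
               if (dx, dy, dz) != (0, 0, 0) and abs(dx) + abs(dy) + abs(dz) <= 2]
    nx, ny, nz = values.shape
    out = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    continue
                v = values[i, j, k]
                is_max = True
                for dx, dy, dz in offsets:
                    a, b, c = i + dx, j + dy, k + dz
                    if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz and mask[a, b, c]:
                        if values[a, b, c] >= v:
                            is_max = False
                            break
                if is_max:
                    out.append((i, j, k))
    return sorted(out)
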