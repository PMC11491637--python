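import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import commaddr as ca

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def dp_levenshtein(a: str, b: str) -> int:
    """Independent dynamic-programming edit-distance oracle."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[n]


def haversine_feet_oracle(lon1, lat1, lon2, lat2) -> float:
    """Pure-python haversine oracle, independent of the spatial module's
    k-d tree path."""
    import math

    r = 6_371_008.8
    p1, p2 = math.radians(lat1), math.radians(lat2)
    a = (
        math.sin((p2 - p1) / 2) ** 2
        + math.cos(p1) * math.cos(p2) * math.sin(math.radians(lon2 - lon1) / 2) ** 2
    )
    return 2 * r * math.asin(math.sqrt(a)) / 0.3048


@pytest.fixture(scope="session")
def small_reference():
    """Small deterministic reference fixture: 10 streets (3 community),
    8 points each, 2 confusables."""
    return ca.generate_reference(
        n_streets=10, points_per_street=8, community_fraction=0.3, seed=42, n_confusable=2
    )


@pytest.fixture(scope="session")
def quiet_extract(small_reference):
    """No-noise extract over the small reference."""
    return ca.generate_extract(
        400, 0.25, ca.NoiseProfile.quiet(seed=7), small_reference
    )


@pytest.fixture(scope="session")
def noisy_extract(small_reference):
    """Default-noise extract over the small reference."""
    return ca.generate_extract(800, 0.25, ca.NoiseProfile(seed=11), small_reference)
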