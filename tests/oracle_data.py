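"""Seeded datasets shared between the statistics tests and the frozen
reference values in ``tests/data/stats_reference_r.json``.

The reference p-values were computed once with R 4.3.3 (``t.test``,
``wilcox.test`` with exactness forced to match the package's rule,
``kruskal.test``, ``shapiro.test``) on exactly these datasets; the
generator must therefore stay byte-stable.
"""

from __future__ import annotations

import numpy as np

N_DATASETS = 50
_BASE_SEED = 7000


def oracle_dataset(i: int) -> dict:
    """Dataset ``i`` of the frozen-oracle collection.

    Every third dataset uses large groups (normal-approximation branch of
    the rank-sum test); the rest stay at combined n <= 50 (exact branch).
    Values are continuous so ties have probability zero.
    """
    rng = np.random.default_rng(_BASE_SEED + i)
    if i % 3 == 0:
        n1, n2, n3 = (int(rng.integers(60, 121)) for _ in range(3))
    else:
        n1, n2 = int(rng.integers(8, 26)), int(rng.integers(8, 26))
        n3 = int(rng.integers(8, 26))
    shift = float(rng.normal(0.0, 1.0))
    sd2 = float(rng.uniform(0.5, 2.0))
    x = rng.normal(shift, 1.0, n1)
    y = rng.normal(0.0, sd2, n2)
    z = rng.normal(float(rng.normal(0.0, 1.0)), 1.0, n3)
    return {"i": i, "x": x, "y": y, "z": z}


def all_datasets() -> list[dict]:
    return [oracle_dataset(i) for i in range(N_DATASETS)]
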