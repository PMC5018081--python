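"""Independent brute-force oracles used to validate the optimised paths."""

import itertools
from collections import Counter

import numpy as np


def brute_force_matching_objective(prev, next_):
    """Exhaustive search over all degree-feasible frame matchings.

    Enumerates every child→parent assignment (each child picks one parent
    or none, each parent takes at most two children) and returns the
    lexicographically best objective
    ``(unmatched_endpoints, bifurcations, total_distance)`` together with
    one optimal pair set.
    """
    prev = np.asarray(prev, float).reshape(-1, 3)
    next_ = np.asarray(next_, float).reshape(-1, 3)
    n, m = len(prev), len(next_)
    if n == 0 or m == 0:
        return (n + m, 0, 0.0), ()
    dist = np.linalg.norm(prev[:, None, :] - next_[None, :, :], axis=2)
    best_key, best_pairs = None, None
    for assign in itertools.product(range(n + 1), repeat=m):
        counts = Counter(p for p in assign if p < n)
        if counts and max(counts.values()) > 2:
            continue
        pairs = tuple((p, c) for c, p in enumerate(assign) if p < n)
        unmatched = (n - len(counts)) + (m - len(pairs))
        bifs = sum(1 for v in counts.values() if v == 2)
        d = float(sum(dist[p, c] for p, c in pairs))
        key = (unmatched, bifs, d)
        if best_key is None or key < best_key:
            best_key, best_pairs = key, pairs
    return best_key, best_pairs


def random_matching_instance(rng, max_per_frame=8, enum_cap=20000):
    """Random frame pair sized so the brute-force enumeration stays tractable."""
    while True:
        n = int(rng.integers(0, max_per_frame + 1))
        m = int(rng.integers(0, max_per_frame + 1))
        if (n + 1) ** m <= enum_cap:
            break
    prev = rng.uniform(0, 20, size=(n, 3))
    next_ = rng.uniform(0, 20, size=(m, 3))
    if rng.random() < 0.3:  # integer coordinates provoke distance ties
        prev, next_ = np.round(prev), np.round(next_)
    return prev, next_
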