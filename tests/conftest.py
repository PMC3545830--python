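"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pandas as pd
import pytest

from vitiseq import STAGES, generate_alignments, generate_catalog


@pytest.fixture(scope="session")
def small_catalog():
    """600 transcripts, all ten archetypes at 6% each, seeded."""
    fractions = {name: 0.06 for name in sorted_archetypes()}
    return generate_catalog(600, n_go_terms=60, archetype_fractions=fractions, seed=11)


def sorted_archetypes():
    from vitiseq.simulate import ARCHETYPE_TEMPLATES

    return sorted(ARCHETYPE_TEMPLATES)


@pytest.fixture(scope="session")
def small_alignments(small_catalog):
    catalog, truth = small_catalog
    return generate_alignments(
        truth, catalog, reads_per_stage=8000, multimap_rate=0.15,
        qc_fail_rate=0.05, seed=12,
    )


@pytest.fixture()
def rpkm_frame():
    """Hand-built 4-stage RPKM matrix with known classifications."""
    data = {
        # young-specific, >50 fold (published transcription-factor profile)
        "tf_young": (125.18, 0.51, 0.76, 0.35),
        # veraison-pair profile (published ABI3-like profile)
        "tf_veraison": (0.10, 50.36, 25.69, 7.32),
        "flat": (5.0, 5.0, 5.0, 5.0),
        "young_10_50": (30.0, 1.0, 1.0, 1.0),
        "all_low": (0.1, 0.2, 0.3, 0.1),
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=list(STAGES))


def brute_force_allocate(pairs):
    """Independent two-pass allocation on a list of (read, transcript) hits."""
    from collections import Counter, defaultdict

    by_read = defaultdict(list)
    for read, transcript in pairs:
        by_read[read].append(transcript)
    unique = Counter(
        ts[0] for ts in by_read.values() if len(ts) == 1
    )
    alloc = defaultdict(float, {t: float(c) for t, c in unique.items()})
    for ts in by_read.values():
        if len(ts) > 1:
            weights = [unique.get(t, 0) for t in ts]
            s = sum(weights)
            for t, w in zip(ts, weights):
                alloc[t] += w / s if s else 1.0 / len(ts)
    return dict(alloc), dict(unique)


def brute_force_hypergeom_p(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    from itertools import combinations

    marked = set(range(K))
    hits = total = 0
    for draw in combinations(range(N), n):
        total += 1
        if sum(1 for i in draw if i in marked) >= k:
            hits += 1
    return hits / total


def spearman_rank_formula(x, y):
    """Closed-form Spearman for tie-free vectors: 1 - 6*sum d^2 / (n(n^2-1))."""
    x = np.asarray(x)
    y = np.asarray(y)
    rx = x.argsort().argsort()
    ry = y.argsort().argsort()
    n = len(x)
    return 1.0 - 6.0 * ((rx - ry) ** 2).sum() / (n * (n**2 - 1))
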