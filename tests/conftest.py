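import math

import numpy as np
import pytest

from cisclust.catalog import IUPAC_CODES, expand_iupac, load_paper_catalog, reverse_complement
from cisclust.simulate import generate_study


@pytest.fixture(scope="session")
def catalog():
    return load_paper_catalog()


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study (nine regions, three planted clusters each)."""
    return generate_study(seed=42)


def naive_scan(sequence: str, catalog):
    """Independent scanning oracle: slide every pattern over every substring
    on both strands, scoring mismatches position by position (an N in the
    sequence matches nothing).  Returns {(start, end, tf, pattern, strand)}
    with the same both-strands-at-one-span dedup rule as the scanner."""
    sequence = sequence.upper()
    found = set()
    for motif in catalog:
        m = len(motif)
        rc = reverse_complement(motif.pattern)
        for s in range(len(sequence) - m + 1):
            window = sequence[s : s + m]
            fwd = sum(1 for p, w in zip(motif.pattern, window) if w == "N" or w not in IUPAC_CODES[p])
            rev = sum(1 for p, w in zip(rc, window) if w == "N" or w not in IUPAC_CODES[p])
            allowed = catalog.max_dissimilarity_percent * m / 100.0
            if fwd <= allowed + 1e-9:
                found.add((s + 1, s + m, motif.tf_class, motif.pattern, "+"))
            elif rev <= allowed + 1e-9:
                found.add((s + 1, s + m, motif.tf_class, motif.pattern, "-"))
    return found


def brute_force_best_count(hits, window_length, min_distinct_tfs=2):
    """Exhaustive rank-1 oracle: max member count over every window offset."""
    if not hits:
        return None
    hi = max(h.end for h in hits)
    best = None
    for s in range(1, hi + 1):
        e = s + window_length - 1
        members = [h for h in hits if h.start >= s and h.end <= e]
        if len({h.tf_class for h in members}) >= min_distinct_tfs:
            if best is None or len(members) > best:
                best = len(members)
    return best


def interval_jaccard(a, b):
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    union = max(a[1], b[1]) - min(a[0], b[0]) + 1
    return inter / union


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
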