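"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is deliberately naive (exhaustive enumeration) and kept
separate from the package so it cannot share a code path with the
implementations it checks.
"""

from itertools import product

import numpy as np


def enumerate_path_scores(scores, transitions, start, end):
    """Yield (path, score) for every label path of the chain."""
    scores = np.asarray(scores, dtype=float)
    L, K = scores.shape
    for path in product(range(K), repeat=L):
        total = start[path[0]] + end[path[-1]]
        for t, y in enumerate(path):
            total += scores[t, y]
        for a, b in zip(path, path[1:]):
            total += transitions[a, b]
        yield path, float(total)


def best_path_score(scores, transitions, start, end):
    return max(s for _, s in enumerate_path_scores(scores, transitions, start, end))


def log_partition_enum(scores, transitions, start, end):
    all_scores = [s for _, s in enumerate_path_scores(scores, transitions, start, end)]
    m = max(all_scores)
    return m + np.log(sum(np.exp(s - m) for s in all_scores))


def span_marginal_enum(scores, transitions, start, end, positions, span_labels):
    """P(labels at positions) by summing path weights, naively."""
    num = 0.0
    den = 0.0
    clamp = dict(zip(positions, span_labels))
    all_scores = list(enumerate_path_scores(scores, transitions, start, end))
    m = max(s for _, s in all_scores)
    for path, s in all_scores:
        w = np.exp(s - m)
        den += w
        if all(path[p] == lab for p, lab in clamp.items()):
            num += w
    return num / den


def spans_from_labels_reference(labels):
    """Truth-table reference for BIO run extraction with orphan-I repair.

    ``labels`` are strings 'B'/'I'/'O'; returns (start, end) index runs
    over positions, written directly from the documented rule.
    """
    runs = []
    current = None
    for i, lab in enumerate(labels):
        if lab == "B":
            if current is not None:
                runs.append(current)
            current = [i, i]
        elif lab == "I":
            if current is not None:
                current[1] = i
            else:  # orphan I opens a run
                current = [i, i]
        else:
            if current is not None:
                runs.append(current)
                current = None
    if current is not None:
        runs.append(current)
    return [(a, b) for a, b in runs]


def find_all_occurrences_reference(haystack, needles):
    """Every (start, end, needle_index) occurrence, by scanning positions."""
    hits = []
    for ni, needle in enumerate(needles):
        if not needle:
            continue
        for pos in range(len(haystack) - len(needle) + 1):
            if haystack[pos : pos + len(needle)] == needle:
                hits.append((pos, pos + len(needle), ni))
    return hits


def longest_leftmost_reference(hits):
    """Greedy longest-leftmost overlap resolution over (start, end, tag)."""
    chosen = []
    remaining = sorted(hits, key=lambda h: (h[0], -(h[1] - h[0])))
    last_end = 0
    for start, end, tag in remaining:
        if start >= last_end:
            chosen.append((start, end, tag))
            last_end = end
    return chosen
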