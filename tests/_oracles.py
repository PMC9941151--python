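"""Independent brute-force oracles used by the test suite.

These deliberately use naive enumeration (explicit loops, no shared code
with the package) so they can stand as independent references.
"""

from __future__ import annotations

import math


def brute_force_union(per_section_lists: list[dict], k: int) -> tuple[list[str], list[str]]:
    """Reference merge of planar top-K lists into the 3D set.

    ``per_section_lists`` holds, per section, ``{gene: signed rho}`` for
    the listed (top-K) genes only.  For every gene occurring anywhere, the
    occurrence with the greatest absolute value wins; a tie between
    conflicting signs keeps the positive one.  The surviving positive and
    negative genes are then sorted by (|rho| descending, gene id) and cut
    to K per direction.
    """
    occurrences: dict[str, list[float]] = {}
    for section in per_section_lists:
        for gene, rho in section.items():
            occurrences.setdefault(gene, []).append(rho)
    resolved: dict[str, float] = {}
    for gene, values in occurrences.items():
        best = values[0]
        for v in values[1:]:
            if abs(v) > abs(best) or (abs(v) == abs(best) and v > best):
                best = v
        resolved[gene] = best
    ups = sorted(
        [g for g, v in resolved.items() if v > 0],
        key=lambda g: (-abs(resolved[g]), g),
    )[:k]
    downs = sorted(
        [g for g, v in resolved.items() if v < 0],
        key=lambda g: (-abs(resolved[g]), g),
    )[:k]
    return ups, downs


def kruskal_wallis_reference(groups: list[list[float]]) -> float:
    """Textbook Kruskal-Wallis H with tie correction, by direct enumeration."""
    pooled = [x for g in groups for x in g]
    n = len(pooled)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg_rank = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg_rank
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        ni = len(g)
        r_sum = sum(ranks[start : start + ni])
        h += r_sum**2 / ni
        start += ni
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    tie_sum = 0.0
    sorted_vals = sorted(pooled)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        t = j - i + 1
        tie_sum += t**3 - t
        i = j + 1
    correction = 1 - tie_sum / (n**3 - n)
    if correction == 0:
        return math.nan
    return h / correction


def sign_aware_jaccard_reference(a: dict[str, int], b: dict[str, int]) -> float:
    """Set-enumeration reference for the subtype similarity."""
    union = set(a) | set(b)
    agree = [g for g in union if g in a and g in b and a[g] == b[g]]
    return len(agree) / len(union)
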