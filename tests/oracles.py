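"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately naive (exhaustive enumeration, O(n^2) scans,
per-character loops) and shares no code with the package paths it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

#: Three-adult sex x haplotype patterns with their published classification.
#: Haplotype sharing is encoded by index pattern; duplicated sex rows are
#: disambiguated by which carrier holds the singleton haplotype.
TABLE2_PATTERNS = [
    ((0, 0, 0), ("M", "M", "M"), "SH"),
    ((0, 0, 1), ("M", "M", "M"), "OMH"),
    ((0, 1, 2), ("M", "M", "M"), "MF"),
    ((0, 0, 0), ("F", "F", "F"), "SH"),
    ((0, 0, 1), ("F", "F", "F"), "MF"),
    ((0, 1, 2), ("F", "F", "F"), "MF"),
    ((0, 1, 1), ("M", "F", "F"), "OMH"),
    ((0, 0, 1), ("M", "F", "F"), "MF"),
    ((0, 0, 0), ("M", "F", "F"), "SH"),
    ((0, 1, 2), ("M", "F", "F"), "MF"),
    ((0, 1, 1), ("M", "M", "F"), "OMH"),
    ((0, 0, 1), ("M", "M", "F"), "MF"),
    ((0, 0, 0), ("M", "M", "F"), "SH"),
    ((0, 1, 2), ("M", "M", "F"), "MF"),
]


def single_family_consistent(members: list[tuple[int, str]]) -> bool:
    """Exhaustive role-assignment search for single-family consistency.

    Members are (haplotype, sex) pairs.  A single family founded by one
    male-female pair explains the assemblage iff some assignment of roles
    (at most one father, who must not be female; mother, sons and daughters
    all carrying the one maternal haplotype) covers every member.  That is:
    removing at most one non-female member leaves a monomorphic assemblage.
    """
    candidates: list[int | None] = [None]
    candidates += [i for i, (_, sex) in enumerate(members) if sex != "F"]
    for father in candidates:
        rest = {hap for i, (hap, _) in enumerate(members) if i != father}
        if len(rest) <= 1:
            return True
    return False


def oracle_classify(members: list[tuple[int, str]]) -> str:
    haps = {hap for hap, _ in members}
    if len(haps) == 1:
        return "SH"
    return "OMH" if single_family_consistent(members) else "MF"


def count_diffs(a: str, b: str) -> int:
    """Per-column unambiguous difference count."""
    assert len(a) == len(b)
    return sum(
        1
        for x, y in zip(a.upper(), b.upper())
        if x in "ACGT" and y in "ACGT" and x != y
    )


def segregating_sites(seqs: list[str]) -> int:
    """Columns with at least two distinct unambiguous bases (naive scan)."""
    s = 0
    for col in zip(*[q.upper() for q in seqs]):
        bases = {c for c in col if c in "ACGT"}
        if len(bases) >= 2:
            s += 1
    return s


def haversine_km(p: tuple[float, float], q: tuple[float, float]) -> float:
    r = 6371.0088
    phi1, phi2 = math.radians(p[0]), math.radians(q[0])
    dphi = phi2 - phi1
    dlam = math.radians(q[1] - p[1])
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * r * math.asin(math.sqrt(a))


def knn_bruteforce(points, k: int) -> list[list[int]]:
    """k nearest others by haversine, ties broken by ascending index."""
    out = []
    for i, p in enumerate(points):
        ranked = sorted(
            (j for j in range(len(points)) if j != i),
            key=lambda j: (haversine_km(p, points[j]), j),
        )
        out.append(ranked[:k])
    return out


def tk(labels, neighbors) -> int:
    return sum(
        sum(labels[j] for j in neighbors[i]) for i in range(len(labels)) if labels[i]
    )


def exact_permutation_p(points, labels, k: int) -> float:
    """Exact upper-tail permutation p for the case-neighbour count statistic."""
    n = len(points)
    n_cases = sum(labels)
    nbrs = knn_bruteforce(points, k)
    t_obs = tk(labels, nbrs)
    values = []
    for case_set in combinations(range(n), n_cases):
        y = [i in case_set for i in range(n)]
        values.append(tk(y, nbrs))
    return sum(v >= t_obs for v in values) / len(values)
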