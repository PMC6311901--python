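"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written for clarity over speed and stays independent of
the library's implementation paths: direct scans, exhaustive enumeration,
and plain-python arithmetic.
"""

from __future__ import annotations

import itertools
from typing import Optional

import numpy as np

STOPS = {"TAG", "TGA", "TAA"}


# ---------------------------------------------------------------------------
# ORF selection oracle: scan every position, every frame


def orf_scan(seq: str, starts: set[str]) -> list[tuple[int, int, str]]:
    out = []
    for p in range(len(seq) - 2):
        codon = seq[p : p + 3]
        if codon not in starts:
            continue
        q = p + 3
        while q + 3 <= len(seq):
            c = seq[q : q + 3]
            if c in STOPS:
                out.append((p, q + 3, codon))
                break
            q += 3
    return out


def oracle_primary(seq: str) -> Optional[tuple[int, int]]:
    orfs = orf_scan(seq, {"ATG"})
    if not orfs:
        return None
    best = sorted(orfs, key=lambda o: (-(o[1] - o[0]), o[0]))[0]
    return best[0], best[1]


def oracle_first(seq: str) -> Optional[tuple[int, int]]:
    orfs = orf_scan(seq, {"ATG"})
    if not orfs:
        return None
    best = sorted(orfs, key=lambda o: o[0])[0]
    return best[0], best[1]


def oracle_upstream(seq: str, porf: tuple[int, int]) -> Optional[tuple[int, int]]:
    cands = [o for o in orf_scan(seq, {"CTG", "GTG", "TTG"}) if o[1] <= porf[0]]
    if not cands:
        return None
    best = sorted(cands, key=lambda o: (-(o[1] - o[0]), o[0]))[0]
    return best[0], best[1]


# ---------------------------------------------------------------------------
# Nested-structure enumeration oracle for stem probabilities


def _enumerate_structures(seq, i, j, span, weight, min_loop):
    """Yield every nested pair set on seq[i..j] (inclusive) exactly once."""
    if i >= j:
        yield []
        return
    # base i unpaired
    for s in _enumerate_structures(seq, i + 1, j, span, weight, min_loop):
        yield s
    # base i paired with k
    for k in range(i + min_loop + 1, j + 1):
        if k - i > span:
            break
        w = weight(seq[i], seq[k])
        if w <= 0:
            continue
        for left in _enumerate_structures(seq, i + 1, k - 1, span, weight, min_loop):
            for right in _enumerate_structures(seq, k + 1, j, span, weight, min_loop):
                yield [(i, k)] + left + right


def oracle_stem_probs(seq: str, span: int, pair_weights: dict, min_loop: int = 3) -> np.ndarray:
    def weight(a, b):
        key = "".join(sorted(a + b))
        key = {"CG": "GC", "AT": "AT", "GT": "GT"}.get(key, key)
        return pair_weights.get(key, 0.0)

    n = len(seq)
    Z = 0.0
    paired = np.zeros(n)
    for st in _enumerate_structures(seq, 0, n - 1, span, weight, min_loop):
        w = 1.0
        for (a, b) in st:
            w *= weight(seq[a], seq[b])
        Z += w
        for (a, b) in st:
            paired[a] += w
            paired[b] += w
    return paired / Z


# ---------------------------------------------------------------------------
# G4 quadruplet enumeration oracle


def oracle_g4(seq, min_gscore, min_run=2, loop_min=0, loop_max=36, max_length=30,
              tetrad_weight=12.0, loop_weight=1.0, evenness_weight=2.0):
    """All-quadruplet enumeration with the same constants, then the same
    best-score-first non-overlap resolution."""
    n = len(seq)
    cands = []
    for t in range(min_run, max_length // 4 + 1):
        run_ok = [seq[p : p + t] == "G" * t for p in range(n - t + 1)]
        positions = [p for p, ok in enumerate(run_ok) if ok]
        for p1, p2, p3, p4 in itertools.combinations(positions, 4):
            loops = (p2 - p1 - t, p3 - p2 - t, p4 - p3 - t)
            if any(l < loop_min or l > loop_max for l in loops):
                continue
            if p4 + t - p1 > max_length:
                continue
            mean = sum(loops) / 3.0
            mad = sum(abs(l - mean) for l in loops) / 3.0
            score = tetrad_weight * t - loop_weight * mean - evenness_weight * mad
            if score >= min_gscore:
                cands.append((p1, p4 + t, score))
    cands.sort(key=lambda c: (-c[2], c[0], c[1] - c[0]))
    chosen = []
    for s, e, sc in cands:
        if all(e <= cs or s >= ce for cs, ce, _ in chosen):
            chosen.append((s, e, sc))
    chosen.sort()
    return chosen


# ---------------------------------------------------------------------------
# Two-sample KS oracle (statistic + full permutation enumeration)


def oracle_ks_D(a, b) -> float:
    vals = sorted(set(list(a) + list(b)))
    d = 0.0
    for v in vals:
        fa = sum(1 for x in a if x <= v) / len(a)
        fb = sum(1 for x in b if x <= v) / len(b)
        d = max(d, abs(fa - fb))
    return d


def oracle_ks_perm_p(a, b) -> tuple[float, float]:
    d_obs = oracle_ks_D(a, b)
    pooled = list(a) + list(b)
    total = 0
    hits = 0
    for comb in itertools.combinations(range(len(pooled)), len(a)):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in range(len(pooled)) if i not in set(comb)]
        total += 1
        if oracle_ks_D(ga, gb) >= d_obs - 1e-12:
            hits += 1
    return d_obs, hits / total
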