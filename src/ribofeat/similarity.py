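"""Sequence-similarity deduplication of lncRNA cohorts.

Before any feature statistics are computed, transcripts that share a large
fraction of their sequence are collapsed: if local similarity covers more
than a threshold fraction (default 60%) of the shorter sequence, the shorter
transcript is discarded.

Similarity is computed by an internal seeded local-alignment routine: exact
k-mer seeds (default k=11) are chained along each alignment diagonal into
ungapped blocks whose identity stays at or above a floor (default 80%);
coverage is the union of shorter-sequence positions inside qualifying
blocks. A precomputed pairwise-hits table can be supplied instead to
reproduce runs made with an external aligner.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .transcript import Transcript


@dataclass(frozen=True)
class SimilarityHit:
    id_a: str
    id_b: str
    coverage_of_shorter: float  # percentage in [0, 100]


def _seed_matches(short: str, long: str, k: int) -> dict[int, list[int]]:
    """Positions of exact k-mer matches grouped by diagonal (pos_long - pos_short)."""
    index: dict[str, list[int]] = defaultdict(list)
    for j in range(len(long) - k + 1):
        index[long[j : j + k]].append(j)
    diags: dict[int, list[int]] = defaultdict(list)
    for i in range(len(short) - k + 1):
        for j in index.get(short[i : i + k], ()):
            diags[j - i].append(i)
    return diags


def _chain_blocks(short: str, long: str, diag: int, seed_starts: list[int], k: int,
                  min_identity: float) -> list[tuple[int, int]]:
    """Merge seed intervals on one diagonal; bridge gaps while block identity holds."""
    seed_starts.sort()
    intervals: list[tuple[int, int]] = []
    for s in seed_starts:
        iv = (s, s + k)
        if intervals and s <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], s + k))
        else:
            intervals.append(iv)

    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ps, pe = merged[-1]
        # candidate bridged block [ps, e); identity over the whole block
        matches = sum(
            1 for i in range(ps, e)
            if short[i] == long[i + diag] and short[i] != "N"
        )
        if matches / (e - ps) >= min_identity:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


def pairwise_similarity(a: Transcript, b: Transcript, k: int = 11,
                        min_identity: float = 0.8) -> SimilarityHit:
    """Coverage of the shorter sequence by high-identity local blocks, in percent."""
    if not a.seq or not b.seq:
        raise ValueError("empty sequence")
    if len(a.seq) <= len(b.seq):
        short_t, long_t = a, b
    else:
        short_t, long_t = b, a
    short, long = short_t.seq, long_t.seq
    if len(short) < k:
        # too short to seed: fall back to direct substring check
        cov = 100.0 if short in long else 0.0
        return SimilarityHit(a.id, b.id, cov)

    covered = bytearray(len(short))
    for diag, seeds in _seed_matches(short, long, k).items():
        for s, e in _chain_blocks(short, long, diag, seeds, k, min_identity):
            covered[s:e] = b"\x01" * (e - s)
    cov = 100.0 * sum(covered) / len(short)
    return SimilarityHit(a.id, b.id, cov)


def deduplicate(
    ts: Sequence[Transcript],
    threshold: float = 60.0,
    k: int = 11,
    min_identity: float = 0.8,
    precomputed_hits: Optional[Iterable[SimilarityHit]] = None,
) -> list[Transcript]:
    """Greedy longest-first retention: discard a transcript whose coverage
    against any already-retained (longer or equal) transcript exceeds
    ``threshold`` percent of its own length.

    Output preserves the input order of retained transcripts. Equal-length
    ties are broken by discarding the later record in input order.
    """
    if not (0 < threshold <= 100):
        raise ValueError(f"threshold must be in (0, 100], got {threshold}")
    ids = [t.id for t in ts]
    if len(set(ids)) != len(ids):
        raise ValueError("transcript ids must be unique")

    hit_lookup: Optional[dict[frozenset, float]] = None
    if precomputed_hits is not None:
        hit_lookup = {
            frozenset((h.id_a, h.id_b)): h.coverage_of_shorter for h in precomputed_hits
        }

    order = sorted(range(len(ts)), key=lambda i: (-len(ts[i].seq), i))
    retained_idx: list[int] = []
    for i in order:
        cand = ts[i]
        keep = True
        for j in retained_idx:
            if hit_lookup is not None:
                cov = hit_lookup.get(frozenset((cand.id, ts[j].id)), 0.0)
            else:
                cov = pairwise_similarity(cand, ts[j], k=k, min_identity=min_identity).coverage_of_shorter
            if cov > threshold:
                keep = False
                break
        if keep:
            retained_idx.append(i)
    retained_idx.sort()
    return [ts[i] for i in retained_idx]
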