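"""Per-base stem probabilities from a nested secondary-structure ensemble.

Each base's probability of being paired is computed from a partition
function over nested (pseudoknot-free) structures built from canonical
pairs (A-T, G-C, G-T on the DNA alphabet, i.e. AU/GC/GU on RNA), with a
simple configurable Boltzmann weight per pair type and a minimum hairpin
loop length. A maximum pairing span constraint |j - i| <= max_span mirrors
the windowed convention of large-scale folding tools: the default span is
N-1 (all pairs allowed), falling back to 200 for very long (>9500 nt)
transcripts, and a complexity guard caps the span at 200 for transcripts
longer than 2000 nt (configurable).

The implementation is a banded McCaskill-style inside-outside algorithm
with adaptive per-base scaling, O(N * span^2) time and O(N * span) memory.
Precomputed per-base probability tables (e.g. from an external folding
tool) can be imported instead via :func:`read_profiles`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

DEFAULT_PAIR_WEIGHTS = {"GC": 3.0, "AT": 2.0, "GT": 1.0}
DEFAULT_MIN_LOOP = 3


@dataclass
class PairingModel:
    """Boltzmann weights per canonical pair type and hairpin constraint."""

    pair_weights: dict = field(default_factory=lambda: dict(DEFAULT_PAIR_WEIGHTS))
    min_loop: int = DEFAULT_MIN_LOOP

    def weight(self, a: str, b: str) -> float:
        key = a + b if a <= b else b + a
        key = {"CG": "GC", "TA": "AT", "GT": "GT", "TG": "GT"}.get(key, key)
        return self.pair_weights.get(key, 0.0)


@dataclass
class StemProfile:
    probs: np.ndarray  # per-base paired probability, in [0, 1]
    max_span: int


def _weight_matrix(seq: str, L: int, model: PairingModel) -> np.ndarray:
    """wmat[i, d] = pair weight of (i, i+d-1), 1-based i, 0 if unpairable."""
    n = len(seq)
    wmat = np.zeros((n + 2, L + 2))
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    pairw = np.zeros((256, 256))
    for (a, b), w in (
        ((x, y), model.weight(x, y))
        for x in "ACGT"
        for y in "ACGT"
    ):
        pairw[ord(a), ord(b)] = w
    for d in range(model.min_loop + 2, L + 1):
        m = n - d + 1
        if m < 1:
            break
        wmat[1 : m + 1, d] = pairw[arr[:m], arr[d - 1 :]]
    return wmat


def _inside_outside(seq: str, max_span: int, model: PairingModel, log_s: float):
    """One scaled inside-outside pass; returns (paired, Ztot_scaled) or None
    on numerical over/underflow at this scale."""
    n = len(seq)
    L = min(n, max_span + 1)  # max width of a paired interval
    s = math.exp(log_s)
    inv_s = 1.0 / s
    wmat = _weight_matrix(seq, L, model) * (inv_s * inv_s)
    ml = model.min_loop

    Z = np.zeros((n + 3, L + 2))
    Zb = np.zeros((n + 3, L + 2))
    Z[:, 0] = 1.0

    for d in range(1, L + 1):
        m = n - d + 1
        sl = slice(1, m + 1)
        if d >= ml + 2:
            Zb[sl, d] = wmat[sl, d] * Z[2 : m + 2, d - 2]
        acc = Z[sl, d - 1] * inv_s
        for mm in range(0, d - ml - 1):
            # last base pairs with k = i+mm; Z(i, k-1) * Zb(k, j)
            acc = acc + Z[sl, mm] * Zb[1 + mm : m + 1 + mm, d - mm]
        Z[sl, d] = acc

    if not np.all(np.isfinite(Z)):
        return None

    W = np.zeros(n + 2)
    W[0] = 1.0
    Wr = np.zeros(n + 3)
    Wr[n + 1] = 1.0
    for j in range(1, n + 1):
        tot = W[j - 1] * inv_s
        dmax = min(L, j)
        if dmax >= ml + 2:
            ds = np.arange(ml + 2, dmax + 1)
            tot += float(np.dot(W[j - ds], Zb[j - ds + 1, ds]))
        W[j] = tot
    for i in range(n, 0, -1):
        tot = Wr[i + 1] * inv_s
        dmax = min(L, n - i + 1)
        if dmax >= ml + 2:
            ds = np.arange(ml + 2, dmax + 1)
            tot += float(np.dot(Zb[i, ds], Wr[i + ds]))
        Wr[i] = tot

    Ztot = W[n]
    if not (np.isfinite(Ztot) and Ztot > 0.0 and np.all(np.isfinite(W)) and np.all(np.isfinite(Wr))):
        return None

    # Outside pass, widths descending; A[p, u] accumulates enclosing-pair
    # context for inner intervals ending at j' = p + u.
    A = np.zeros((n + 3, L + 2))
    Qh = np.zeros((n + 3, L + 2))
    paired = np.zeros(n + 2)
    for d in range(L, ml + 1, -1):
        m = n - d + 1
        if m < 1:
            continue
        i_idx = np.arange(1, m + 1)
        q = Wr[i_idx + d] * W[i_idx - 1]
        tmax = L - d - 1
        for t in range(1, tmax + 1):
            valid = i_idx - t >= 1
            if not valid.any():
                break
            iv = i_idx[valid]
            q_add = Z[iv - t + 1, t - 1] * A[iv - t, d - 1 + t]
            qv = q[valid]
            qv += q_add
            q[valid] = qv
        Qh[1 : m + 1, d] = q
        if d >= ml + 2:
            P = Zb[1 : m + 1, d] * q / Ztot
            paired[1 : m + 1] += P
            paired[d : m + d] += P
            coef = wmat[1 : m + 1, d] * q
            if coef.any():
                for u in range(1, d - 1):
                    A[1 : m + 1, u] += coef * Z[1 + u + 1 : m + 1 + u + 1, d - u - 2]
    if not np.all(np.isfinite(paired)):
        return None
    return np.clip(paired[1 : n + 1], 0.0, 1.0), Ztot


def stem_profile(
    seq: str,
    max_span: Optional[int] = None,
    model: Optional[PairingModel] = None,
    span_cap: int = 200,
    span_cap_length: int = 2000,
    long_rna_length: int = 9500,
) -> StemProfile:
    """Per-base paired probabilities under the nested-pair ensemble.

    ``max_span`` defaults to N-1 (all pairs), or ``span_cap`` when the
    transcript exceeds ``long_rna_length``; transcripts longer than
    ``span_cap_length`` are additionally capped at ``span_cap``.
    """
    if not seq:
        raise ValueError("empty sequence")
    model = model or PairingModel()
    n = len(seq)
    if max_span is None:
        max_span = n - 1 if n <= long_rna_length else span_cap
    if n > span_cap_length:
        max_span = min(max_span, span_cap)
    max_span = max(1, min(max_span, n - 1)) if n > 1 else 1

    seq = seq.upper().replace("U", "T")
    if n == 1:
        return StemProfile(np.zeros(1), max_span)

    # adaptive per-base scaling: retry with adjusted log-scale on over/underflow
    log_s = 0.0
    if n > 600:
        # estimate per-base growth from a prefix
        est = _inside_outside(seq[:300], min(max_span, 299), model, 0.0)
        if est is not None:
            log_s = max(0.0, math.log(max(est[1], 1e-300)) / 300.0)
    step = max(0.05, 400.0 / n)
    for _ in range(40):
        res = _inside_outside(seq, max_span, model, log_s)
        if res is None:
            log_s += step  # overflow: shrink everything harder
            continue
        probs, Ztot = res
        if Ztot < 1e-250:
            log_s = max(log_s - step, log_s * 0.5) if log_s > 0 else log_s - step
            continue
        return StemProfile(probs, max_span)
    raise ArithmeticError("stem_profile failed to find a stable numeric scale")


def region_mean_stem(profile: StemProfile, interval: Optional[tuple[int, int]]) -> float:
    """Mean paired probability over a half-open interval; NaN if empty/absent."""
    if interval is None:
        return math.nan
    s, e = interval
    if not (0 <= s <= e <= len(profile.probs)):
        raise ValueError(f"interval [{s},{e}) outside profile of length {len(profile.probs)}")
    if e == s:
        return math.nan
    return float(profile.probs[s:e].mean())


def stem_ratio(utr_mean: float, orf_mean: float, eps: float = 1e-6) -> float:
    """UTR/ORF mean stem-probability ratio; NaN when either side is missing
    or the ORF mean is numerically zero."""
    if math.isnan(utr_mean) or math.isnan(orf_mean) or orf_mean < eps:
        return math.nan
    return utr_mean / orf_mean


# ---------------------------------------------------------------------------
# TSV import/export (external-backend escape hatch)


def write_profiles(profiles: dict[str, StemProfile], path) -> None:
    rows = []
    for tid, prof in profiles.items():
        for pos, p in enumerate(prof.probs):
            rows.append((tid, pos, float(p)))
    pd.DataFrame(rows, columns=["transcript_id", "position", "stem_prob"]).to_csv(
        path, sep="\t", index=False
    )


def read_profiles(path, max_span: int = -1) -> dict[str, StemProfile]:
    """Import precomputed per-base stem probabilities (transcript_id,
    position, stem_prob); positions must be 0-based and contiguous."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for tid, grp in df.groupby("transcript_id", sort=False):
        grp = grp.sort_values("position")
        probs = grp["stem_prob"].to_numpy(dtype=float)
        if not np.array_equal(grp["position"].to_numpy(), np.arange(len(probs))):
            raise ValueError(f"{tid}: positions are not contiguous from 0")
        if probs.min() < 0 or probs.max() > 1:
            raise ValueError(f"{tid}: probabilities outside [0, 1]")
        out[str(tid)] = StemProfile(probs, max_span)
    return out
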