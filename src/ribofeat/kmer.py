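"""CPAT-style log-likelihood-ratio scores for putative ORFs.

Three scores share one form: the mean over units of log(F(x)/F'(x)), where
F is the unit frequency in an "active" reference (a set of real CDS
sequences) and F' the frequency in an "inactive" reference (the same
sequences with nucleotides shuffled).

* context score — position-specific nucleotide frequencies in a window
  around the start codon (default offsets -6..+3, the Kozak context; the
  first base of the start codon is offset 0);
* trimer score — in-frame codons of the ORF;
* hexamer score — in-frame overlapping codon pairs (step 3).

Logs are natural; a pseudocount (default 0.5) is added to every cell
before normalisation so that unseen units score finitely. Units containing
N are skipped. A positive score marks CDS-like (active) usage, a negative
score shuffle-like (inactive) usage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
DEFAULT_CONTEXT_OFFSETS = (-6, 3)  # inclusive offsets relative to start-codon base


@dataclass(frozen=True)
class KmerScore:
    value: float  # nats
    n_units: int


@dataclass
class FrequencyTable:
    """Active (F) and inactive (F') unit frequencies.

    For ``unit_kind == "context_position"`` the keys are ``(offset, base)``
    and frequencies sum to 1 per offset; for trimer/hexamer the keys are the
    k-mers and frequencies sum to 1 overall.
    """

    unit_kind: str  # "context_position" | "trimer" | "hexamer"
    F: dict
    F_prime: dict
    pseudocount: float = 0.5

    def log_ratio(self, unit) -> float:
        return math.log(self.F[unit] / self.F_prime[unit])


def _normalize(counts: Mapping, keys, pseudocount: float) -> dict:
    tot = sum(counts.get(k, 0) for k in keys) + pseudocount * len(keys)
    return {k: (counts.get(k, 0) + pseudocount) / tot for k in keys}


def _count_units(seqs: Sequence[str], k: int, counts: dict) -> None:
    for s in seqs:
        for p in range(0, len(s) - k + 1, 3):
            unit = s[p : p + k]
            if "N" not in unit:
                counts[unit] = counts.get(unit, 0) + 1


def _kmer_keys(k: int) -> list[str]:
    keys = [""]
    for _ in range(k):
        keys = [p + b for p in keys for b in BASES]
    return keys


def build_reference_tables(
    cds: Sequence[str],
    seed: int,
    pseudocount: float = 0.5,
    context_offsets: tuple[int, int] = DEFAULT_CONTEXT_OFFSETS,
    context_starts: Optional[Sequence[int]] = None,
) -> dict[str, FrequencyTable]:
    """Build context/trimer/hexamer tables from a CDS reference set.

    F' comes from a uniform per-sequence nucleotide shuffle driven by
    ``seed``. ``context_starts`` gives the CDS start coordinate within each
    reference sequence (default 0, i.e. the records are bare CDS; window
    positions falling outside a record are skipped, and offsets never
    observed fall back to the uniform pseudocount distribution, which
    contributes zero to the score).
    """
    if not cds:
        raise ValueError("empty CDS reference set")
    for s in cds:
        if len(s) < 9 or len(s) % 3:
            raise ValueError("each reference CDS must be >=9 nt and divisible by 3")
    rng = np.random.default_rng(seed)
    shuffled = ["".join(rng.permutation(list(s))) for s in cds]
    starts = list(context_starts) if context_starts is not None else [0] * len(cds)

    lo, hi = context_offsets
    offsets = range(lo, hi + 1)
    tables: dict[str, FrequencyTable] = {}

    ctx_counts = {"F": {}, "F_prime": {}}
    for name, ref in (("F", cds), ("F_prime", shuffled)):
        for s, st in zip(ref, starts):
            for off in offsets:
                p = st + off
                if 0 <= p < len(s) and s[p] in BASES:
                    key = (off, s[p])
                    ctx_counts[name][key] = ctx_counts[name].get(key, 0) + 1
    ctx_F, ctx_Fp = {}, {}
    for off in offsets:
        keys = [(off, b) for b in BASES]
        ctx_F.update(_normalize(ctx_counts["F"], keys, pseudocount))
        ctx_Fp.update(_normalize(ctx_counts["F_prime"], keys, pseudocount))
    tables["context_position"] = FrequencyTable("context_position", ctx_F, ctx_Fp, pseudocount)

    for kind, k in (("trimer", 3), ("hexamer", 6)):
        cF: dict = {}
        cFp: dict = {}
        _count_units(cds, k, cF)
        _count_units(shuffled, k, cFp)
        keys = _kmer_keys(k)
        tables[kind] = FrequencyTable(
            kind, _normalize(cF, keys, pseudocount), _normalize(cFp, keys, pseudocount), pseudocount
        )
    return tables


def context_score(
    seq: str,
    orf_start: int,
    table: FrequencyTable,
    offsets: tuple[int, int] = DEFAULT_CONTEXT_OFFSETS,
) -> Optional[KmerScore]:
    """Mean log(F/F') over the start-codon context window; None if the
    window does not fit inside the sequence."""
    lo, hi = offsets
    if orf_start + lo < 0 or orf_start + hi >= len(seq):
        return None
    total, n = 0.0, 0
    for off in range(lo, hi + 1):
        b = seq[orf_start + off]
        if b not in BASES:
            continue
        total += table.log_ratio((off, b))
        n += 1
    if n == 0:
        return None
    return KmerScore(total / n, n)


def _unit_score(orf_seq: str, table: FrequencyTable, k: int) -> Optional[KmerScore]:
    if len(orf_seq) % 3 or len(orf_seq) < k:
        return None
    total, n = 0.0, 0
    for p in range(0, len(orf_seq) - k + 1, 3):
        unit = orf_seq[p : p + k]
        if "N" in unit:
            continue
        total += table.log_ratio(unit)
        n += 1
    if n == 0:
        return None
    return KmerScore(total / n, n)


def trimer_score(orf_seq: str, table: FrequencyTable) -> Optional[KmerScore]:
    """Mean log(F/F') over in-frame codons."""
    return _unit_score(orf_seq, table, 3)


def hexamer_score(orf_seq: str, table: FrequencyTable) -> Optional[KmerScore]:
    """Mean log(F/F') over in-frame bi-codons (step 3)."""
    return _unit_score(orf_seq, table, 6)


# ---------------------------------------------------------------------------
# Serialization


def write_tables(tables: Mapping[str, FrequencyTable], path) -> None:
    rows = []
    for kind, tab in tables.items():
        for unit in tab.F:
            key = f"{unit[0]}:{unit[1]}" if kind == "context_position" else unit
            rows.append((kind, key, tab.F[unit], tab.F_prime[unit], tab.pseudocount))
    pd.DataFrame(rows, columns=["unit_kind", "unit", "F", "F_prime", "pseudocount"]).to_csv(
        path, sep="\t", index=False
    )


def read_tables(path) -> dict[str, FrequencyTable]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, FrequencyTable] = {}
    for kind, grp in df.groupby("unit_kind"):
        F, Fp = {}, {}
        for row in grp.itertuples(index=False):
            if kind == "context_position":
                off, base = str(row.unit).rsplit(":", 1)
                key = (int(off), base)
            else:
                key = row.unit
            F[key] = row.F
            Fp[key] = row.F_prime
        out[kind] = FrequencyTable(kind, F, Fp, float(grp["pseudocount"].iloc[0]))
    return out
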