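"""Primary / first / upstream putative ORFs on a mature transcript.

Three putative ORFs are selected per transcript:

* pORF — the longest ATG-initiated ORF (ties: 5'-most);
* fORF — the ATG-initiated ORF closest to the 5' end;
* uORF — the longest ORF started by a near-cognate codon (CTG/GTG/TTG)
  lying entirely 5' of the pORF (its end may abut the pORF start); ORFs
  overlapping the pORF are excluded, and a uORF is only defined when a
  pORF exists.

Every ORF runs from its start codon to the first in-frame stop
(TAG/TGA/TAA) and includes the stop; ORFs without an in-frame stop inside
the transcript are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

STOP_CODONS = {"TAG", "TGA", "TAA"}
ATG = frozenset({"ATG"})
NEAR_COGNATE = frozenset({"CTG", "GTG", "TTG"})


@dataclass(frozen=True)
class Orf:
    start: int
    end: int  # half-open; end - start divisible by 3, includes the stop codon
    start_codon: str
    kind: str  # "primary" | "first" | "upstream"

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class OrfSet:
    porf: Optional[Orf] = None
    forf: Optional[Orf] = None
    uorf: Optional[Orf] = None

    def get(self, kind: str) -> Optional[Orf]:
        return {"p": self.porf, "f": self.forf, "u": self.uorf}[kind]


def enumerate_orfs(seq: str, starts: frozenset[str]) -> list[Orf]:
    """All maximal ORFs: one per start-codon occurrence, each running to the
    first in-frame stop fully inside the sequence."""
    n = len(seq)
    # first in-frame stop at or after each position, per frame
    next_stop = [None] * 3  # type: list
    for frame in range(3):
        stops = []
        for p in range(frame, n - 2, 3):
            if seq[p : p + 3] in STOP_CODONS:
                stops.append(p)
        next_stop[frame] = stops
    out = []
    for p in range(n - 2):
        codon = seq[p : p + 3]
        if codon not in starts:
            continue
        frame = p % 3
        stop = next((s for s in next_stop[frame] if s >= p), None)
        if stop is None:
            continue
        out.append(Orf(p, stop + 3, codon, kind=""))
    return out


def _best(orfs: list[Orf], kind: str) -> Optional[Orf]:
    """Longest, tie -> 5'-most."""
    if not orfs:
        return None
    o = min(orfs, key=lambda o: (-(o.end - o.start), o.start))
    return Orf(o.start, o.end, o.start_codon, kind)


def primary_orf(seq: str) -> Optional[Orf]:
    """Longest ATG-initiated ORF (length tie -> 5'-most)."""
    return _best(enumerate_orfs(seq, ATG), "primary")


def first_orf(seq: str) -> Optional[Orf]:
    """ATG-initiated ORF with minimal start coordinate."""
    orfs = enumerate_orfs(seq, ATG)
    if not orfs:
        return None
    o = min(orfs, key=lambda o: o.start)
    return Orf(o.start, o.end, o.start_codon, "first")


def upstream_orf(seq: str, porf: Orf) -> Optional[Orf]:
    """Longest near-cognate ORF wholly upstream of the pORF (tie -> 5'-most).

    "Upstream" means uorf.end <= porf.start; candidates overlapping the
    pORF are excluded.
    """
    if porf is None:
        raise ValueError("upstream ORF requires a primary ORF")
    cands = [o for o in enumerate_orfs(seq, NEAR_COGNATE) if o.end <= porf.start]
    return _best(cands, "upstream")


def find_orfs(seq: str) -> OrfSet:
    """Select the pORF/fORF/uORF triplet for one transcript sequence."""
    p = primary_orf(seq)
    f = first_orf(seq)
    u = upstream_orf(seq, p) if p is not None else None
    return OrfSet(porf=p, forf=f, uorf=u)
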