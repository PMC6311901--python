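"""m6A and G-quadruplex site detection and ORF-anchored distance features.

m6A sites default to a DRACH-consensus scan (D in {A,G,T}, R in {A,G},
then A, C, H in {A,C,T}); an imported site table (e.g. from an external
m6A predictor) takes precedence when provided.

G4 segments follow a QGRS-style search: four G-runs of equal length
t >= 2 separated by loops of 0-36 nt, total length <= 30 nt. The G-score
rewards more tetrads and short, even loops::

    score = tetrad_weight * t - loop_weight * mean(loops)
            - evenness_weight * mean(|loop - mean(loops)|)

with defaults (12, 1, 2); candidates below ``min_gscore`` (default 30,
the conventional stability cut-off) are dropped, and surviving candidates
are resolved to a non-overlapping set by descending score.

Distance features relate the representative site of each kind (highest
score, ties to the 5'-most) to the transcript ends (TIS/TTS) and to the
start/end of each putative ORF: direct distance = log10(1 + bases),
relative distance = percent of transcript length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .orfs import OrfSet
from .transcript import Transcript

D_SET, R_SET, H_SET = set("AGT"), set("AG"), set("ACT")


@dataclass(frozen=True)
class SiteAnnotation:
    kind: str  # "m6A" | "G4"
    start: int
    end: int  # half-open; single base for m6A
    score: float

    @property
    def position(self) -> int:
        """Representative coordinate: 5' end of the site."""
        return self.start


@dataclass
class G4Config:
    min_run: int = 2
    loop_min: int = 0
    loop_max: int = 36
    max_length: int = 30
    tetrad_weight: float = 12.0
    loop_weight: float = 1.0
    evenness_weight: float = 2.0


def g4_score(t: int, loops: tuple[int, int, int], cfg: G4Config) -> float:
    mean = sum(loops) / 3.0
    mad = sum(abs(l - mean) for l in loops) / 3.0
    return cfg.tetrad_weight * t - cfg.loop_weight * mean - cfg.evenness_weight * mad


def predict_m6a(seq: str) -> list[SiteAnnotation]:
    """Central A of every DRACH match, score 1."""
    out = []
    for i in range(2, len(seq) - 2):
        if (
            seq[i] == "A"
            and seq[i + 1] == "C"
            and seq[i - 1] in R_SET
            and seq[i - 2] in D_SET
            and seq[i + 2] in H_SET
        ):
            out.append(SiteAnnotation("m6A", i, i + 1, 1.0))
    return out


def _g_runs(seq: str, t: int) -> list[int]:
    """Start positions of all length-t all-G windows."""
    return [i for i in range(len(seq) - t + 1) if seq[i : i + t] == "G" * t]


def detect_g4(
    seq: str, min_gscore: float = 30.0, cfg: Optional[G4Config] = None
) -> list[SiteAnnotation]:
    """QGRS-style G4 detection; returns a non-overlapping set of stable G4s."""
    cfg = cfg or G4Config()
    t_max = (cfg.max_length) // 4
    candidates: list[SiteAnnotation] = []
    for t in range(cfg.min_run, t_max + 1):
        runs = _g_runs(seq, t)
        runset = set(runs)
        for p1 in runs:
            limit = p1 + cfg.max_length
            for p2 in runs:
                if p2 < p1 + t + cfg.loop_min or p2 + t > limit or p2 - (p1 + t) > cfg.loop_max:
                    continue
                for p3 in runs:
                    if p3 < p2 + t + cfg.loop_min or p3 + t > limit or p3 - (p2 + t) > cfg.loop_max:
                        continue
                    for p4 in runs:
                        if (
                            p4 < p3 + t + cfg.loop_min
                            or p4 + t > limit
                            or p4 - (p3 + t) > cfg.loop_max
                        ):
                            continue
                        loops = (p2 - p1 - t, p3 - p2 - t, p4 - p3 - t)
                        score = g4_score(t, loops, cfg)
                        if score >= min_gscore:
                            candidates.append(SiteAnnotation("G4", p1, p4 + t, score))
    # resolve overlaps: best score first, ties 5'-most then shorter
    candidates.sort(key=lambda c: (-c.score, c.start, c.end - c.start))
    chosen: list[SiteAnnotation] = []
    for c in candidates:
        if all(c.end <= k.start or c.start >= k.end for k in chosen):
            chosen.append(c)
    chosen.sort(key=lambda c: c.start)
    return chosen


@dataclass(frozen=True)
class DistanceFeature:
    kind: str  # site kind
    anchor: str  # "TIS" | "TTS" | "{p,f,u}OrfStart" | "{p,f,u}OrfEnd"
    direct: float  # log10(1 + bases)
    relative: float  # percent of transcript length


def representative_site(sites: Iterable[SiteAnnotation]) -> Optional[SiteAnnotation]:
    """Highest score; tie -> 5'-most."""
    sites = list(sites)
    if not sites:
        return None
    return min(sites, key=lambda s: (-s.score, s.start))


def site_distance_features(
    t: Transcript, orfs: OrfSet, sites: Iterable[SiteAnnotation]
) -> list[DistanceFeature]:
    """Direct/relative distances from each kind's representative site to
    TIS, TTS, and ORF starts/ends; absent sites or ORFs yield NaN entries."""
    n = len(t.seq)
    by_kind: dict[str, list[SiteAnnotation]] = {}
    for s in sites:
        by_kind.setdefault(s.kind, []).append(s)

    anchors: list[tuple[str, Optional[int]]] = [("Tis", 0), ("Tts", n)]
    for short in "pfu":
        orf = orfs.get(short)
        anchors.append((f"{short}OrfStart", orf.start if orf else None))
        anchors.append((f"{short}OrfEnd", orf.end if orf else None))

    out = []
    for kind in ("m6A", "G4"):
        rep = representative_site(by_kind.get(kind, []))
        for name, anchor_pos in anchors:
            if rep is None or anchor_pos is None:
                out.append(DistanceFeature(kind, name, math.nan, math.nan))
            else:
                d = abs(rep.position - anchor_pos)
                out.append(DistanceFeature(kind, name, math.log10(1 + d), 100.0 * d / n))
    return out


# ---------------------------------------------------------------------------
# Site-table import/export


def write_site_table(sites_by_id: dict[str, list[SiteAnnotation]], path) -> None:
    rows = [
        (s.kind, tid, s.start, s.end, s.score)
        for tid, ss in sites_by_id.items()
        for s in ss
    ]
    pd.DataFrame(rows, columns=["kind", "transcript_id", "start", "end", "score"]).to_csv(
        path, sep="\t", index=False
    )


def read_site_table(path) -> dict[str, list[SiteAnnotation]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[SiteAnnotation]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.transcript_id), []).append(
            SiteAnnotation(row.kind, int(row.start), int(row.end), float(row.score))
        )
    return out
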