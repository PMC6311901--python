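"""Exon/intron (splicing) features and repeat-element overlap flags.

Splicing features summarise the exon/intron decomposition of the mature
transcript (counts, lengths, first-exon GC, ...). Intron GC requires a
genome FASTA and is left missing without one.

Repeat flags are binary per repeat class: a class is flagged when any
exon's genomic interval overlaps a repeat of that class by at least one
base. Repeats annotated as simple repeats, low-complexity, or non-coding
RNA are excluded, following RepeatMasker class conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .transcript import Transcript, gc_content

DEFAULT_REPEAT_CLASSES = ("LTR", "LINE", "SINE", "Alu", "SINEB2")
EXCLUDED_REPEAT_CLASSES = {
    "Simple_repeat",
    "Low_complexity",
    "RNA",
    "rRNA",
    "tRNA",
    "snRNA",
    "scRNA",
    "srpRNA",
    "ncRNA",
}


@dataclass
class SpliceFeatures:
    transcript_length: int
    exon_count: int
    longest_exon_length: int
    first_exon_length: int
    first_exon_gc: float
    first_intron_length: float  # NaN for single-exon transcripts
    first_intron_gc: float  # NaN without genomic sequence
    total_exon_length: int
    mean_exon_length: float
    total_intron_length: float
    mean_intron_length: float


def splice_features(t: Transcript, genome: Optional[dict[str, str]] = None) -> SpliceFeatures:
    """Exon/intron summary features for one transcript.

    ``genome`` maps chromosome name to sequence and is only needed for
    first-intron GC; everything else comes from the transcript itself.
    """
    exons = t.exons
    n_ex = len(t.exon_lengths)
    introns = t.intron_lengths
    f_intron_len = float(introns[0]) if introns else math.nan

    f_intron_gc = math.nan
    if introns and genome is not None and t.genome_intervals:
        ivs = sorted(t.genome_intervals, key=lambda iv: iv[1])
        chrom, strand = ivs[0][0], ivs[0][3]
        gaps = [(e1, s2) for (_, _, e1, _), (_, s2, _, _) in zip(ivs, ivs[1:])]
        # first intron in transcript order: last genomic gap on minus strand
        gap = gaps[-1] if strand == "-" else gaps[0]
        if chrom in genome:
            f_intron_gc = gc_content(genome[chrom][gap[0] : gap[1]])

    return SpliceFeatures(
        transcript_length=len(t.seq),
        exon_count=n_ex,
        longest_exon_length=max(t.exon_lengths),
        first_exon_length=t.exon_lengths[0],
        first_exon_gc=gc_content(exons[0]),
        first_intron_length=f_intron_len,
        first_intron_gc=f_intron_gc,
        total_exon_length=sum(t.exon_lengths),
        mean_exon_length=sum(t.exon_lengths) / n_ex,
        total_intron_length=float(sum(introns)) if introns else math.nan,
        mean_intron_length=float(sum(introns)) / len(introns) if introns else math.nan,
    )


@dataclass(frozen=True)
class RepeatInterval:
    chrom: str
    start: int
    end: int
    rep_class: str  # RepeatMasker class (or class/family string)


def _class_matches(flag: str, rep_class: str) -> bool:
    """Match a flag name against a repeat class/family annotation.

    ``rep_class`` may be a bare class ("LTR") or "class/family"
    ("SINE/Alu"); the family SINE/B2 answers to the conventional flag
    name SINEB2.
    """
    parts = rep_class.split("/")
    if flag in parts:
        return True
    if flag == "SINEB2" and parts[0] == "SINE" and any(p.startswith("B2") for p in parts[1:]):
        return True
    return False


def _excluded(rep_class: str) -> bool:
    parts = rep_class.split("/")
    return any(p in EXCLUDED_REPEAT_CLASSES for p in parts)


def repeat_flags(
    t: Transcript,
    repeats: Iterable[RepeatInterval],
    classes: tuple[str, ...] = DEFAULT_REPEAT_CLASSES,
) -> dict[str, float]:
    """Binary flags (one per repeat class): 1 iff any exon overlaps >= 1 bp
    of a repeat of that class. All flags NaN when the transcript has no
    genomic intervals."""
    if not t.genome_intervals:
        return {c: math.nan for c in classes}
    flags = {c: 0.0 for c in classes}
    for rep in repeats:
        if _excluded(rep.rep_class):
            continue
        hits = [c for c in classes if _class_matches(c, rep.rep_class)]
        if not hits:
            continue
        for chrom, s, e, _ in t.genome_intervals:
            if chrom == rep.chrom and s < rep.end and rep.start < e:
                for c in hits:
                    flags[c] = 1.0
                break
    return flags


# ---------------------------------------------------------------------------
# Annotation readers


def read_repeatmasker_out(path) -> list[RepeatInterval]:
    """Parse RepeatMasker .out: whitespace table with a 3-line header; the
    genomic interval is 1-based inclusive (columns 6-7), class/family in
    column 11."""
    out = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if len(fields) < 11 or not fields[0].isdigit():
                continue
            chrom, begin, end = fields[4], int(fields[5]) - 1, int(fields[6])
            out.append(RepeatInterval(chrom, begin, end, fields[10]))
    return out


def read_repeat_bed(path) -> list[RepeatInterval]:
    """BED with the repeat class in column 4 (name)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(RepeatInterval(f[0], int(f[1]), int(f[2]), f[3]))
    return out


def read_repeats(path) -> list[RepeatInterval]:
    path = Path(path)
    if path.suffix == ".out":
        return read_repeatmasker_out(path)
    return read_repeat_bed(path)
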