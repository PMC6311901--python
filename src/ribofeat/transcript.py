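"""Transcript representation and basic sequence utilities.

A mature lncRNA is modelled as its spliced, sense-strand sequence plus the
ordered exon/intron length decomposition (5'->3' in transcript order) and,
optionally, the genomic exon intervals used for repeat-element overlap.
All coordinates are 0-based half-open on the mature transcript.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

GenomeInterval = tuple[str, int, int, str]


def normalize_sequence(raw: str) -> str:
    """Uppercase, map U->T, and map any other non-ACGTN symbol to N."""
    s = raw.upper().replace("U", "T")
    if set(s) <= _VALID:
        return s
    return "".join(c if c in _VALID else "N" for c in s)


def reverse_complement(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class Transcript:
    """A mature transcript with its exon/intron structure.

    Invariants: ``sum(exon_lengths) == len(seq)``, exactly one fewer intron
    than exons (none for single-exon transcripts), all exon lengths positive.
    """

    id: str
    seq: str
    exon_lengths: list[int] = field(default_factory=list)
    intron_lengths: list[int] = field(default_factory=list)
    genome_intervals: Optional[list[GenomeInterval]] = None

    def __post_init__(self) -> None:
        if not self.exon_lengths:
            self.exon_lengths = [len(self.seq)]
        if not self.intron_lengths:
            self.intron_lengths = [0] * max(0, len(self.exon_lengths) - 1)
        if any(e <= 0 for e in self.exon_lengths):
            raise ValueError(f"{self.id}: exon lengths must be positive")
        if sum(self.exon_lengths) != len(self.seq):
            raise ValueError(
                f"{self.id}: exon lengths sum to {sum(self.exon_lengths)} "
                f"but sequence length is {len(self.seq)}"
            )
        if len(self.intron_lengths) != max(0, len(self.exon_lengths) - 1):
            raise ValueError(f"{self.id}: need one intron length per exon junction")
        if any(i < 0 for i in self.intron_lengths):
            raise ValueError(f"{self.id}: intron lengths must be non-negative")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def exons(self) -> list[str]:
        """Exon subsequences in transcript order."""
        out, pos = [], 0
        for L in self.exon_lengths:
            out.append(self.seq[pos : pos + L])
            pos += L
        return out


Interval = tuple[int, int]


@dataclass
class RegionMap:
    """5'UTR / ORF / 3'UTR partition of a transcript for one ORF kind.

    Each interval is 0-based half-open in transcript coordinates; ``None``
    marks a region that does not exist (no ORF, or an empty UTR).
    """

    five_utr: Optional[Interval]
    orf: Optional[Interval]
    three_utr: Optional[Interval]


def gc_content(s: str) -> float:
    """GC fraction of a sequence; N excluded from both counts.

    Returns NaN for empty or all-N input (propagated as a missing value).
    """
    gc = s.count("G") + s.count("C")
    atgc = gc + s.count("A") + s.count("T")
    if atgc == 0:
        return math.nan
    return gc / atgc


def extract_regions(t: Transcript, orf_interval: Optional[Interval]) -> RegionMap:
    """Split a transcript into 5'UTR / ORF / 3'UTR around one ORF interval."""
    if orf_interval is None:
        return RegionMap(None, None, None)
    s, e = orf_interval
    if not (0 <= s <= e <= len(t.seq)):
        raise ValueError(f"{t.id}: ORF interval [{s},{e}) out of bounds for length {len(t.seq)}")
    five = (0, s) if s > 0 else None
    three = (e, len(t.seq)) if e < len(t.seq) else None
    return RegionMap(five, (s, e), three)


# ---------------------------------------------------------------------------
# Readers / writers


def _read_bed12(path: Path) -> dict[str, dict]:
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "thickStart", "thickEnd", "rgb", "blockCount", "blockSizes", "blockStarts",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#", dtype=str)
    out: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        chrom, cstart, strand = row.chrom, int(row.start), row.strand
        exons = [(chrom, cstart + st, cstart + st + sz, strand) for st, sz in zip(starts, sizes)]
        out[row.name] = {"exons": exons, "strand": strand}
    return out


def _read_gtf(path: Path) -> dict[str, dict]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    out: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            continue
        rec = out.setdefault(tid, {"exons": [], "strand": feat.strand})
        # gffutils is 1-based inclusive; convert to 0-based half-open
        rec["exons"].append((feat.seqid, feat.start - 1, feat.end, feat.strand))
    for rec in out.values():
        rec["exons"].sort(key=lambda iv: iv[1])
    return out


def _structure_from_exons(tid: str, exons: list[GenomeInterval], strand: str, seq_len: int):
    exons = sorted(exons, key=lambda iv: iv[1])
    if strand == "-":
        ordered = exons[::-1]  # transcript order is genomic-descending on minus strand
    else:
        ordered = exons
    exon_lengths = [e - s for _, s, e, _ in ordered]
    gaps = []
    for (_, s1, e1, _), (_, s2, e2, _) in zip(exons, exons[1:]):
        gaps.append(s2 - e1)
    if strand == "-":
        gaps = gaps[::-1]
    if sum(exon_lengths) != seq_len:
        raise ValueError(
            f"{tid}: annotation exon lengths sum to {sum(exon_lengths)} "
            f"but sequence length is {seq_len}"
        )
    return exon_lengths, gaps, ordered


def read_transcripts(fasta_path, annotation_path=None) -> list[Transcript]:
    """Read transcripts from FASTA plus optional GTF/BED12 exon structure.

    Records without annotation become single-exon transcripts. The FASTA is
    assumed to hold mature sense-strand sequences; the annotation contributes
    exon/intron lengths (reordered 5'->3' for minus-strand models) and the
    genomic exon intervals.
    """
    fasta_path = Path(fasta_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"empty FASTA: {fasta_path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate FASTA record ids")

    ann: dict[str, dict] = {}
    if annotation_path is not None:
        annotation_path = Path(annotation_path)
        if annotation_path.suffix.lower() in {".bed", ".bed12"}:
            ann = _read_bed12(annotation_path)
        else:
            ann = _read_gtf(annotation_path)

    out = []
    for rec in records:
        seq = normalize_sequence(str(rec.seq))
        if rec.id in ann:
            entry = ann[rec.id]
            exon_lengths, introns, ordered = _structure_from_exons(
                rec.id, entry["exons"], entry["strand"], len(seq)
            )
            out.append(
                Transcript(rec.id, seq, exon_lengths, introns, genome_intervals=ordered)
            )
        else:
            out.append(Transcript(rec.id, seq))
    return out


def write_transcripts(ts: Iterable[Transcript], fasta_path, bed12_path=None) -> None:
    """Write transcripts to FASTA and (optionally) BED12 with exon blocks."""
    ts = list(ts)
    SeqIO.write(
        [SeqRecord(Seq(t.seq), id=t.id, description="") for t in ts],
        str(fasta_path),
        "fasta",
    )
    if bed12_path is None:
        return
    lines = []
    for t in ts:
        if t.genome_intervals:
            ivs = sorted(t.genome_intervals, key=lambda iv: iv[1])
            chrom, strand = ivs[0][0], ivs[0][3]
            start, end = ivs[0][1], ivs[-1][2]
            sizes = ",".join(str(e - s) for _, s, e, _ in ivs)
            starts = ",".join(str(s - start) for _, s, e, _ in ivs)
            n = len(ivs)
        else:
            chrom, strand, start = t.id, "+", 0
            end = len(t.seq)
            sizes, starts, n = str(len(t.seq)), "0", 1
        lines.append(
            f"{chrom}\t{start}\t{end}\t{t.id}\t0\t{strand}\t{start}\t{start}\t0\t{n}\t{sizes}\t{starts}"
        )
    Path(bed12_path).write_text("\n".join(lines) + "\n")
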