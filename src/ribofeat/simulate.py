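"""Synthetic labeled lncRNA cohorts with known, planted class structure.

The generator emulates the statistical shape the analysis assumes: two
labeled transcript cohorts with realistic exon/intron structure, a chosen
GC composition, embedded ATG ORFs whose codon usage follows either a
coding-like codon model or its nucleotide shuffle, planted m6A/G4 site
motifs, and repeat intervals inserted with class-dependent probabilities.

Planted class effects come in two flavours, both recorded in the cohort
truth:

* mechanistic — realised in the sequences themselves (first-exon GC shift,
  codon-model vs shuffled embedded ORFs, site-position biases, repeat
  insertion probabilities), so correlated features co-vary as in real data;
* injected — extra feature columns drawn around 0.5 with an exact
  class-mean shift, for effects that are hard to realise mechanistically.

A single global seed is fanned out to per-component generators through
``numpy.random.SeedSequence.spawn``, so any part of the cohort is
reproducible in isolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import sites as sites_mod
from .pipeline import FeatureMatrix
from .splicing import RepeatInterval
from .transcript import Transcript, write_transcripts

SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in {"TAG", "TGA", "TAA"}
]
STOPS = ["TAG", "TGA", "TAA"]
# codons boosted in the default usage; a non-product-form bias so that
# codon-model ORFs are distinguishable from their nucleotide shuffles
_PREFERRED = {"CTG", "GAG", "AAG", "GCC", "CAG", "GAC", "TTC", "ATC"}


def default_codon_usage() -> dict[str, float]:
    w = {c: (4.0 if c in _PREFERRED else 1.0) for c in SENSE_CODONS}
    tot = sum(w.values())
    return {c: v / tot for c, v in w.items()}


def generate_cds_reference(
    n: int,
    codon_usage: Optional[dict[str, float]] = None,
    length_range: tuple[int, int] = (300, 900),
    seed: int = 0,
) -> list[str]:
    """n CDS strings: ATG + i.i.d. sense codons + one stop, lengths
    divisible by 3 within ``length_range``."""
    usage = codon_usage or default_codon_usage()
    if abs(sum(usage.values()) - 1.0) > 1e-9 or set(usage) != set(SENSE_CODONS):
        raise ValueError("codon_usage must cover the 61 sense codons and sum to 1")
    rng = np.random.default_rng(seed)
    codons = np.array(SENSE_CODONS)
    probs = np.array([usage[c] for c in SENSE_CODONS])
    lo, hi = length_range
    out = []
    for _ in range(n):
        total = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
        n_mid = total // 3 - 2
        mid = "".join(rng.choice(codons, size=max(n_mid, 1), p=probs))
        out.append("ATG" + mid + STOPS[rng.integers(3)])
    return out


@dataclass
class CohortConfig:
    n_ribo: int = 200
    n_noribo: int = 200
    length_lognorm: tuple[float, float] = (math.log(600.0), 0.6)  # (mu, sigma)
    length_bounds: tuple[int, int] = (250, 3000)
    exon_count_probs: tuple[float, ...] = (0.25, 0.30, 0.25, 0.15, 0.05)  # 1..5 exons
    intron_lognorm: tuple[float, float] = (math.log(800.0), 0.8)
    base_gc: float = 0.45
    orf_length_range: tuple[int, int] = (150, 300)
    planted_effects: dict = field(default_factory=dict)  # feature -> signed delta
    site_rates: dict = field(default_factory=lambda: {"m6A": 2.0, "G4": 0.4})
    repeat_insertion_probs: dict = field(default_factory=lambda: {"LTR": (0.15, 0.15)})
    injected_noise_sd: float = 0.05
    seed: int = 0

    # features the generator can realise in the sequences themselves
    MECHANISTIC = ("fEgc", "pOrfSeqHexamer", "m6aTtsRel", "g4TisRel")

    def __post_init__(self) -> None:
        for name, delta in self.planted_effects.items():
            if abs(float(delta)) > 1.0:
                raise ValueError(f"planted effect {name}: |delta|={delta} beyond [0,1] scale")
        if not 0 < self.base_gc < 1:
            raise ValueError("base_gc must be in (0,1)")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class CohortTruth:
    labels: dict[str, int]
    planted: list[dict]  # {feature, sign, magnitude, mechanism}

    def planted_features(self) -> dict[str, int]:
        return {p["feature"]: (1 if p["sign"] == "+" else -1) for p in self.planted}


def planted_truth(cfg: CohortConfig) -> CohortTruth:
    """Deterministic truth listing (invariant to seed)."""
    ids = [f"ribo_{i:04d}" for i in range(cfg.n_ribo)] + [
        f"noribo_{i:04d}" for i in range(cfg.n_noribo)
    ]
    labels = {i: (1 if i.startswith("ribo") else 0) for i in ids}
    planted = [
        {
            "feature": name,
            "sign": "+" if delta > 0 else "-",
            "magnitude": abs(float(delta)),
            "mechanism": "mechanistic" if name in CohortConfig.MECHANISTIC else "injected",
        }
        for name, delta in cfg.planted_effects.items()
    ]
    return CohortTruth(labels, planted)


@dataclass
class SyntheticCohort:
    config: CohortConfig
    transcripts: list[Transcript]
    labels: dict[str, int]
    repeats: list[RepeatInterval]
    m6a_sites: dict[str, list]
    g4_sites: dict[str, list]
    injected: Optional[pd.DataFrame]
    truth: CohortTruth

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_transcripts(self.transcripts, out / "transcripts.fa", out / "transcripts.bed")
        pd.DataFrame(
            [(r.chrom, r.start, r.end, r.rep_class) for r in self.repeats],
            columns=["chrom", "start", "end", "class"],
        ).to_csv(out / "repeats.bed", sep="\t", index=False, header=False)
        sites_mod.write_site_table(self.m6a_sites, out / "sites_m6a.tsv")
        sites_mod.write_site_table(self.g4_sites, out / "sites_g4.tsv")
        pd.Series(self.labels, name="label").to_csv(
            out / "labels.tsv", sep="\t", index_label="id"
        )
        if self.injected is not None:
            self.injected.to_csv(out / "injected_features.tsv", sep="\t", index_label="id")
        (out / "truth.json").write_text(
            json.dumps({"labels": self.truth.labels, "planted": self.truth.planted}, indent=2)
        )


def _random_seq(rng, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _strip_stops(seq: str, rng) -> str:
    """Replace in-frame stops by random sense codons (frame 0)."""
    codons = [seq[i : i + 3] for i in range(0, len(seq) - 2, 3)]
    codons = [
        c if c not in STOPS else SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
        for c in codons
    ]
    return "".join(codons) + seq[len(codons) * 3 :]


def _make_orf(rng, cfg: CohortConfig, coding_like: bool, usage_probs, codon_arr) -> str:
    lo, hi = cfg.orf_length_range
    total = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
    n_mid = total // 3 - 2
    mid = "".join(rng.choice(codon_arr, size=max(n_mid, 1), p=usage_probs))
    if not coding_like:
        mid = "".join(rng.permutation(list(mid)))
        mid = _strip_stops(mid, rng)
    return "ATG" + mid + STOPS[rng.integers(3)]


def generate_cohort(cfg: CohortConfig) -> SyntheticCohort:
    """Generate the labeled cohort with the configured planted effects."""
    truth = planted_truth(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    rng_struct, rng_seq, rng_orf, rng_site, rng_rep, rng_inj = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    usage = default_codon_usage()
    codon_arr = np.array(SENSE_CODONS)
    usage_probs = np.array([usage[c] for c in SENSE_CODONS])

    eff = {k: float(v) for k, v in cfg.planted_effects.items()}
    gc_delta = eff.get("fEgc", 0.0)
    hexamer_delta = eff.get("pOrfSeqHexamer", 0.0)
    m6a_bias = eff.get("m6aTtsRel", 0.0)
    g4_bias = eff.get("g4TisRel", 0.0)
    injected_names = [k for k in eff if k not in CohortConfig.MECHANISTIC]

    mu, sigma = cfg.length_lognorm
    imu, isigma = cfg.intron_lognorm
    lb, ub = cfg.length_bounds
    chrom, cursor = "chrS1", 1000

    transcripts: list[Transcript] = []
    repeats: list[RepeatInterval] = []
    m6a_sites: dict[str, list] = {}
    g4_sites: dict[str, list] = {}

    for tid, label in truth.labels.items():
        n = int(np.clip(round(rng_struct.lognormal(mu, sigma)), lb, ub))
        n_ex = 1 + rng_struct.choice(len(cfg.exon_count_probs), p=np.asarray(cfg.exon_count_probs))
        n_ex = int(n_ex)
        # exon split: Dirichlet proportions with a floor of 40 nt per exon
        while True:
            props = rng_struct.dirichlet(np.full(n_ex, 2.0))
            lens = np.maximum((props * n).astype(int), 40)
            lens[-1] = n - lens[:-1].sum()
            if lens[-1] >= 40 or n_ex == 1:
                break
            n_ex = max(1, n_ex - 1)
        exon_lengths = [int(x) for x in lens] if n_ex > 1 else [n]

        # embed one ATG ORF; codon-model for coding-like, shuffled otherwise
        coding_like = (label == 1) if hexamer_delta > 0 else (
            (label == 0) if hexamer_delta < 0 else bool(rng_orf.integers(2))
        )
        orf = _make_orf(rng_orf, cfg, coding_like, usage_probs, codon_arr)
        orf_pos = None
        if len(orf) + 60 < n:
            # prefer placing the ORF past the first exon so its composition
            # does not disturb the planted first-exon GC
            pos_min = 30
            if exon_lengths[0] + len(orf) + 30 < n:
                pos_min = max(30, exon_lengths[0])
            orf_pos = int(rng_orf.integers(pos_min, n - len(orf) - 30))

        target_gc = float(np.clip(cfg.base_gc + (gc_delta if label == 1 else 0.0), 0.02, 0.98))
        L0 = exon_lengths[0]
        ov_s = ov_e = 0
        if orf_pos is not None:
            ov_s, ov_e = max(0, orf_pos), min(L0, orf_pos + len(orf))
        ov = max(0, ov_e - ov_s)
        free = L0 - ov
        if free > 0 and ov > 0:
            # compensate the non-ORF part of the first exon for the ORF's GC
            orf_slice = orf[ov_s - orf_pos : ov_e - orf_pos]
            gc_orf = (orf_slice.count("G") + orf_slice.count("C")) / ov
            p1 = float(np.clip((target_gc * L0 - gc_orf * ov) / free, 0.02, 0.98))
        else:
            p1 = target_gc
        seq = _random_seq(rng_seq, L0, p1) + _random_seq(rng_seq, n - L0, cfg.base_gc)
        if orf_pos is not None:
            seq = seq[:orf_pos] + orf + seq[orf_pos + len(orf) :]

        # m6A motifs (DRACH core GGACT), count ~ Poisson(rate)
        k_m6a = rng_site.poisson(cfg.site_rates.get("m6A", 0.0))
        for _ in range(k_m6a):
            if m6a_bias and label == 1:
                frac = rng_site.uniform(0.75, 0.95) if m6a_bias < 0 else rng_site.uniform(0.05, 0.25)
            else:
                frac = rng_site.uniform(0.05, 0.95)
            p = int(frac * (n - 6))
            seq = seq[:p] + "GGACT" + seq[p + 5 :]
        # G4 motif with per-transcript probability
        if rng_site.random() < cfg.site_rates.get("G4", 0.0):
            g4 = "GGGAGGGAGGGAGGG"
            if g4_bias and label == 1:
                frac = rng_site.uniform(0.02, 0.15) if g4_bias < 0 else rng_site.uniform(0.80, 0.95)
            else:
                frac = rng_site.uniform(0.02, 0.95)
            p = int(frac * (n - len(g4) - 1))
            seq = seq[:p] + g4 + seq[p + len(g4) :]

        # genomic placement (plus strand, sequential)
        intervals = []
        pos_g = cursor
        introns = []
        for i, L in enumerate(exon_lengths):
            intervals.append((chrom, pos_g, pos_g + L, "+"))
            pos_g += L
            if i < len(exon_lengths) - 1:
                gap = int(max(50, round(rng_struct.lognormal(imu, isigma))))
                introns.append(gap)
                pos_g += gap
        cursor = pos_g + 500

        for rclass, probs in cfg.repeat_insertion_probs.items():
            p0, p1 = (probs, probs) if np.isscalar(probs) else probs
            if rng_rep.random() < (p1 if label == 1 else p0):
                c, s, e, _ = intervals[rng_rep.integers(len(intervals))]
                width = min(120, e - s)
                start = int(rng_rep.integers(s, max(e - width, s) + 1))
                repeats.append(RepeatInterval(c, start, start + width, rclass))
        # decoy excluded-class repeats
        if rng_rep.random() < 0.1:
            c, s, e, _ = intervals[0]
            repeats.append(RepeatInterval(c, s, min(e, s + 40), "Simple_repeat"))

        t = Transcript(tid, seq, exon_lengths, introns, genome_intervals=intervals)
        transcripts.append(t)
        m6a_sites[tid] = sites_mod.predict_m6a(seq)
        g4_sites[tid] = sites_mod.detect_g4(seq)

    injected = None
    if injected_names:
        ids = [t.id for t in transcripts]
        y = np.array([truth.labels[i] for i in ids])
        cols = {}
        for name in injected_names:
            base = rng_inj.normal(0.5, cfg.injected_noise_sd, size=len(ids))
            cols[name] = base + eff[name] * (y == 1)
        injected = pd.DataFrame(cols, index=ids)

    return SyntheticCohort(
        cfg, transcripts, truth.labels, repeats, m6a_sites, g4_sites, injected, truth
    )


# ---------------------------------------------------------------------------
# Direct feature-matrix generation (injection-only path)


def synthetic_feature_matrix(
    n_per_class: int,
    n_features: int,
    planted: dict[str, float],
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[FeatureMatrix, dict[str, int]]:
    """A transcripts x features matrix of N(0.5, noise_sd) values with
    exact class-mean shifts planted on the named features (columns are
    named f00, f01, ...). Returns the matrix and the planted signs."""
    names = [f"f{i:02d}" for i in range(n_features)]
    for name, delta in planted.items():
        if name not in names:
            raise ValueError(f"planted feature {name} outside f00..f{n_features-1:02d}")
        if abs(delta) > 1.0:
            raise ValueError(f"planted effect {name}: |delta| beyond [0,1] scale")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    y = np.array([0] * n_per_class + [1] * n_per_class)
    X = rng.normal(0.5, noise_sd, size=(n, n_features))
    for name, delta in planted.items():
        X[:, names.index(name)] += delta * (y == 1)
    ids = [f"t{i:05d}" for i in range(n)]
    fm = FeatureMatrix(pd.DataFrame(X, index=ids, columns=names), y)
    return fm, {k: (1 if v > 0 else -1) for k, v in planted.items()}
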