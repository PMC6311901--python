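"""Feature-matrix assembly and screening.

The pipeline collects per-module feature tables into one named matrix
(transcripts x features, NaN marking missing values), then:

1. imputes missing entries with the column mean,
2. min-max scales every column to [0, 1],
3. prunes redundant features until no pair has |Pearson r| above a
   threshold (default 0.8), greedily removing the feature entangled with
   the most partners,
4. ranks the survivors by KS importance, the -log10 p of the two-sample
   Kolmogorov-Smirnov test between the class-conditional distributions
   (exact permutation p at tiny group sizes).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import kmer, orfs as orfs_mod, sites as sites_mod, splicing, structure
from .transcript import Transcript, extract_regions, gc_content

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Container


@dataclass
class FeatureMatrix:
    """Named feature columns x transcripts with a binary label vector
    (0 = ribosome-free, 1 = ribosome-associated)."""

    X: pd.DataFrame  # float values, NaN = missing
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.y) != len(self.X):
            raise ValueError("label vector length does not match matrix rows")

    @property
    def ids(self) -> list[str]:
        return list(self.X.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.X.copy(), self.y.copy())

    def to_tsv(self, path) -> None:
        df = self.X.copy()
        df.insert(0, "label", self.y)
        df.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="id")
        y = df.pop("label").to_numpy()
        return cls(df.astype(float), y)


def assemble(tables: Sequence[pd.DataFrame], y: Sequence[int]) -> FeatureMatrix:
    """Column-join per-module feature tables sharing one id index."""
    if not tables:
        raise ValueError("no feature tables")
    base = tables[0].index
    for tab in tables[1:]:
        if set(tab.index) != set(base):
            offenders = sorted(set(tab.index) ^ set(base))
            raise ValueError(f"inconsistent transcript ids across tables: {offenders[:10]}")
    aligned = [tab.reindex(base) for tab in tables]
    names = list(itertools.chain.from_iterable(t.columns for t in aligned))
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate feature names: {sorted(dupes)}")
    X = pd.concat(aligned, axis=1).astype(float)
    for col in X.columns[X.isna().all()]:
        logger.warning("feature %s is missing in every transcript", col)
    return FeatureMatrix(X, np.asarray(list(y)))


# ---------------------------------------------------------------------------
# Impute / scale / prune / rank


def impute_mean(m: FeatureMatrix) -> FeatureMatrix:
    """Replace missing entries by the column mean of observed entries."""
    if m.X.isna().all().any():
        bad = list(m.X.columns[m.X.isna().all()])
        raise ValueError(f"cannot impute all-missing columns: {bad}")
    return FeatureMatrix(m.X.fillna(m.X.mean()), m.y)


def minmax_scale(m: FeatureMatrix) -> FeatureMatrix:
    """Column-wise (x - min)/(max - min); constant columns map to all 0."""
    X = m.X.copy()
    mn, mx = X.min(), X.max()
    span = (mx - mn).replace(0, np.nan)
    X = ((X - mn) / span).fillna(0.0)
    return FeatureMatrix(X, m.y)


@dataclass(frozen=True)
class Removal:
    feature: str
    n_partners: int
    partners: tuple[str, ...]


def prune_redundant(
    m: FeatureMatrix, threshold: float = 0.8
) -> tuple[FeatureMatrix, list[Removal]]:
    """Greedy removal until no pair has |Pearson r| > threshold.

    At each step the feature with the most over-threshold partners goes;
    ties break on larger mean |r| over those partners, then on later
    position in the feature registry (column order).
    """
    X = m.X.copy()
    removals: list[Removal] = []
    while X.shape[1] > 1:
        vals = X.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(vals, rowvar=False)
        r = np.nan_to_num(np.abs(r), nan=0.0)
        np.fill_diagonal(r, 0.0)
        over = r > threshold
        deg = over.sum(axis=1)
        if deg.max() == 0:
            break
        mean_r = np.where(deg > 0, (r * over).sum(axis=1) / np.maximum(deg, 1), 0.0)
        # max degree, then larger mean |r| among partners, then later column
        order = sorted(
            range(X.shape[1]), key=lambda i: (-deg[i], -mean_r[i], -i)
        )
        victim = order[0]
        partners = tuple(X.columns[j] for j in np.nonzero(over[victim])[0])
        removals.append(Removal(X.columns[victim], int(deg[victim]), partners))
        X = X.drop(columns=X.columns[victim])
    return FeatureMatrix(X, m.y), removals


@dataclass(frozen=True)
class KSResult:
    feature: str
    D: float
    p: float
    importance: float  # -log10 p


def _ks_D(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    pooled.sort()
    ca = np.searchsorted(np.sort(a), pooled, side="right") / len(a)
    cb = np.searchsorted(np.sort(b), pooled, side="right") / len(b)
    return float(np.abs(ca - cb).max())


def _exact_permutation_p(a: np.ndarray, b: np.ndarray, d_obs: float) -> float:
    """Full enumeration of label assignments preserving group sizes."""
    pooled = np.concatenate([a, b])
    n = len(pooled)
    idx = range(n)
    total = 0
    at_least = 0
    for comb in itertools.combinations(idx, len(a)):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        d = _ks_D(pooled[mask], pooled[~mask])
        total += 1
        if d >= d_obs - 1e-12:
            at_least += 1
    return at_least / total


def ks_rank(m: FeatureMatrix, exact_max_n: int = 10) -> list[KSResult]:
    """KS statistic and p per feature between the two classes, ranked by
    importance (-log10 p) descending. Exact permutation p when both groups
    have at most ``exact_max_n`` samples, asymptotic otherwise."""
    g0 = m.X.loc[m.y == 0]
    g1 = m.X.loc[m.y == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("both classes need at least 2 samples")
    out = []
    for feat in m.X.columns:
        a = g0[feat].dropna().to_numpy()
        b = g1[feat].dropna().to_numpy()
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"feature {feat}: a class has no observed values")
        D = _ks_D(a, b)
        if len(a) <= exact_max_n and len(b) <= exact_max_n:
            p = _exact_permutation_p(a, b, D)
        else:
            p = float(stats.ks_2samp(a, b, method="asymp").pvalue)
        p = min(max(p, 1e-300), 1.0)
        out.append(KSResult(feat, D, p, -math.log10(p)))
    out.sort(key=lambda r: (-r.importance, -r.D, r.feature))
    return out


def ks_table(results: Iterable[KSResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.feature, r.D, r.p, r.importance) for r in results],
        columns=["feature", "D", "p", "importance"],
    )


# ---------------------------------------------------------------------------
# Feature extraction orchestration


REPEAT_CLASSES = splicing.DEFAULT_REPEAT_CLASSES


def registry(repeat_classes: tuple[str, ...] = REPEAT_CLASSES) -> list[str]:
    """Canonical feature-name registry, in column order."""
    names = [
        "txLen", "exCount", "longestELen", "fELen", "fEgc", "fILen", "fIgc",
        "totalELen", "meanELen", "totalILen", "meanILen",
    ]
    for x in "pfu":
        names += [
            f"{x}OrfLen", f"{x}OrfCov",
            f"{x}Orf5utrLen", f"{x}Orf5utrCov",
            f"{x}Orf3utrLen", f"{x}Orf3utrCov",
            f"{x}OrfSeqTrimer", f"{x}OrfSeqHexamer", f"{x}OrfContext",
        ]
    names += ["txStem"]
    for x in "pfu":
        names += [
            f"{x}OrfStem", f"{x}Orf5utrStem", f"{x}Orf3utrStem",
            f"{x}Orf5utrStemRatio", f"{x}Orf3utrStemRatio",
        ]
    names += ["m6aCount", "g4Count"]
    for kind in ("m6a", "g4"):
        for anchor in ("Tis", "Tts", "pOrfStart", "pOrfEnd", "fOrfStart",
                       "fOrfEnd", "uOrfStart", "uOrfEnd"):
            cap = anchor[0].upper() + anchor[1:]
            names += [f"{kind}{cap}Dist", f"{kind}{cap}Rel"]
    names += list(repeat_classes)
    return names


def _orf_features(t: Transcript, oset: orfs_mod.OrfSet,
                  tables: Optional[dict]) -> dict[str, float]:
    n = len(t.seq)
    feats: dict[str, float] = {}
    for x in "pfu":
        orf = oset.get(x)
        if orf is None:
            for suffix in ("OrfLen", "OrfCov", "Orf5utrLen", "Orf5utrCov",
                           "Orf3utrLen", "Orf3utrCov", "OrfSeqTrimer",
                           "OrfSeqHexamer", "OrfContext"):
                feats[f"{x}{suffix}"] = math.nan
            continue
        regions = extract_regions(t, (orf.start, orf.end))
        olen = orf.end - orf.start
        feats[f"{x}OrfLen"] = olen
        feats[f"{x}OrfCov"] = olen / n
        for tag, iv in (("5utr", regions.five_utr), ("3utr", regions.three_utr)):
            L = (iv[1] - iv[0]) if iv else math.nan
            feats[f"{x}Orf{tag}Len"] = L
            feats[f"{x}Orf{tag}Cov"] = L / n if iv else math.nan
        if tables is not None:
            oseq = t.seq[orf.start : orf.end]
            tri = kmer.trimer_score(oseq, tables["trimer"])
            hexs = kmer.hexamer_score(oseq, tables["hexamer"])
            ctx = kmer.context_score(t.seq, orf.start, tables["context_position"])
            feats[f"{x}OrfSeqTrimer"] = tri.value if tri else math.nan
            feats[f"{x}OrfSeqHexamer"] = hexs.value if hexs else math.nan
            feats[f"{x}OrfContext"] = ctx.value if ctx else math.nan
        else:
            feats[f"{x}OrfSeqTrimer"] = math.nan
            feats[f"{x}OrfSeqHexamer"] = math.nan
            feats[f"{x}OrfContext"] = math.nan
    return feats


def _structure_features(t: Transcript, oset: orfs_mod.OrfSet,
                        profile: structure.StemProfile) -> dict[str, float]:
    feats = {"txStem": structure.region_mean_stem(profile, (0, len(t.seq)))}
    for x in "pfu":
        orf = oset.get(x)
        if orf is None:
            for s in ("OrfStem", "Orf5utrStem", "Orf3utrStem",
                      "Orf5utrStemRatio", "Orf3utrStemRatio"):
                feats[f"{x}{s}"] = math.nan
            continue
        regions = extract_regions(t, (orf.start, orf.end))
        om = structure.region_mean_stem(profile, regions.orf)
        u5 = structure.region_mean_stem(profile, regions.five_utr)
        u3 = structure.region_mean_stem(profile, regions.three_utr)
        feats[f"{x}OrfStem"] = om
        feats[f"{x}Orf5utrStem"] = u5
        feats[f"{x}Orf3utrStem"] = u3
        feats[f"{x}Orf5utrStemRatio"] = structure.stem_ratio(u5, om)
        feats[f"{x}Orf3utrStemRatio"] = structure.stem_ratio(u3, om)
    return feats


def extract_features(
    transcripts: Sequence[Transcript],
    labels: dict[str, int],
    tables: Optional[dict] = None,
    repeats: Optional[list[splicing.RepeatInterval]] = None,
    m6a_sites: Optional[dict[str, list]] = None,
    g4_sites: Optional[dict[str, list]] = None,
    genome: Optional[dict[str, str]] = None,
    max_span: Optional[int] = None,
    structure_model: Optional[structure.PairingModel] = None,
    compute_structure: bool = True,
    extra_features: Optional[pd.DataFrame] = None,
    repeat_classes: tuple[str, ...] = REPEAT_CLASSES,
    min_gscore: float = 30.0,
    drop_empty: bool = True,
) -> FeatureMatrix:
    """Run every feature extractor over a cohort and assemble the matrix.

    ``m6a_sites``/``g4_sites`` are imported site tables taking precedence
    over the internal motif scans; ``extra_features`` is an optional
    id-indexed table joined to the computed columns. Columns observed in no
    transcript (e.g. intron GC without a genome) are dropped by default.
    """
    rows = {}
    for t in transcripts:
        if t.id not in labels:
            raise ValueError(f"no label for transcript {t.id}")
        oset = orfs_mod.find_orfs(t.seq)
        feats: dict[str, float] = {}

        sf = splicing.splice_features(t, genome=genome)
        feats.update(
            txLen=sf.transcript_length, exCount=sf.exon_count,
            longestELen=sf.longest_exon_length, fELen=sf.first_exon_length,
            fEgc=sf.first_exon_gc, fILen=sf.first_intron_length,
            fIgc=sf.first_intron_gc, totalELen=sf.total_exon_length,
            meanELen=sf.mean_exon_length, totalILen=sf.total_intron_length,
            meanILen=sf.mean_intron_length,
        )
        feats.update(_orf_features(t, oset, tables))

        if compute_structure:
            profile = structure.stem_profile(t.seq, max_span=max_span, model=structure_model)
            feats.update(_structure_features(t, oset, profile))
        else:
            for name in registry():
                if "Stem" in name:
                    feats[name] = math.nan

        m6a = m6a_sites.get(t.id, []) if m6a_sites is not None else sites_mod.predict_m6a(t.seq)
        g4 = g4_sites.get(t.id, []) if g4_sites is not None else sites_mod.detect_g4(
            t.seq, min_gscore=min_gscore
        )
        feats["m6aCount"] = float(len(m6a))
        feats["g4Count"] = float(len(g4))
        for df_ in sites_mod.site_distance_features(t, oset, list(m6a) + list(g4)):
            prefix = "m6a" if df_.kind == "m6A" else "g4"
            cap = df_.anchor[0].upper() + df_.anchor[1:]
            feats[f"{prefix}{cap}Dist"] = df_.direct
            feats[f"{prefix}{cap}Rel"] = df_.relative

        if repeats is not None:
            feats.update(splicing.repeat_flags(t, repeats, classes=repeat_classes))
        else:
            feats.update({c: math.nan for c in repeat_classes})

        rows[t.id] = feats

    X = pd.DataFrame.from_dict(rows, orient="index")
    X = X.reindex(columns=registry(repeat_classes))
    tables_ = [X]
    if extra_features is not None:
        tables_.append(extra_features)
    y = [labels[i] for i in X.index]
    fm = assemble(tables_, y)
    if drop_empty:
        fm = FeatureMatrix(fm.X.dropna(axis=1, how="all"), fm.y)
    return fm
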