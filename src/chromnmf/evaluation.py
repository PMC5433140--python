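"""Evaluation of chromatin profiles against genomic annotations and expression.

The central statistic is the 2x2 contingency fold-enrichment of a profile
against a feature set: with a = profile bins overlapping the feature,
b = profile bins not overlapping, c / d the same counts for all other
profiles, the enrichment ratio is (a*d)/(b*c) with a one-tail Fisher exact
p-value. Distance distributions, ROC recovery, expression-stratified
frequency maps and cross-run profile correlations complete the picture.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .profiles import UNASSIGNED, ProfileTrack

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSet",
    "EnrichmentResult",
    "ExpressionTable",
    "contingency_enrichment",
    "anchor_distance_distribution",
    "roc_recovery",
    "expression_pattern",
    "ExpressionPatternResult",
    "mean_overlap_and_coverage",
    "enumerate_subset_overlap",
    "profile_correlation",
]


@dataclass
class FeatureSet:
    """A named set of genomic intervals (BED semantics, 0-based half-open)."""

    name: str
    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    strands: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (np.asarray(self.starts) >= np.asarray(self.ends)).any():
            raise ValueError(f"feature {self.name!r}: empty or inverted intervals")
        order = np.lexsort((self.starts, self.chroms.astype(str)))
        self.chroms = np.asarray(self.chroms, dtype=object)[order]
        self.starts = np.asarray(self.starts, dtype=np.int64)[order]
        self.ends = np.asarray(self.ends, dtype=np.int64)[order]
        if self.strands is not None:
            self.strands = np.asarray(self.strands, dtype=object)[order]

    def __len__(self) -> int:
        return len(self.starts)

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None) -> "FeatureSet":
        chroms, starts, ends, strands = [], [], [], []
        any_strand = False
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) == 1:
                    f = line.split()
                chroms.append(f[0])
                starts.append(int(f[1]))
                ends.append(int(f[2]))
                if len(f) >= 6 and f[5] in ("+", "-"):
                    strands.append(f[5])
                    any_strand = True
                else:
                    strands.append("+")
        return cls(
            name=name or Path(path).stem,
            chroms=np.array(chroms, dtype=object),
            starts=np.array(starts, dtype=np.int64),
            ends=np.array(ends, dtype=np.int64),
            strands=np.array(strands, dtype=object) if any_strand else None,
        )

    def expand(self, pad: int) -> "FeatureSet":
        """Pad every interval by ``pad`` bp on both sides (point features)."""
        return FeatureSet(
            name=self.name,
            chroms=self.chroms.copy(),
            starts=np.maximum(self.starts - pad, 0),
            ends=self.ends + pad,
            strands=None if self.strands is None else self.strands.copy(),
        )

    def _by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for c in np.unique(self.chroms.astype(str)):
            m = self.chroms == c
            s = self.starts[m]
            e = self.ends[m]
            # merge to a disjoint set so searchsorted overlap tests are exact
            merged_s, merged_e = [], []
            for si, ei in zip(s, e):
                if merged_e and si <= merged_e[-1]:
                    merged_e[-1] = max(merged_e[-1], ei)
                else:
                    merged_s.append(si)
                    merged_e.append(ei)
            out[c] = (np.asarray(merged_s), np.asarray(merged_e))
        return out


@dataclass
class EnrichmentResult:
    """2x2 contingency enrichment of one profile against one feature set."""

    profile: int
    feature: str
    a: int
    b: int
    c: int
    d: int
    ratio: float
    p: float
    significant: bool
    profile_name: str = ""


@dataclass
class ExpressionTable:
    """Gene-level expression with TSS anchors."""

    gene_ids: np.ndarray
    chroms: np.ndarray
    tss: np.ndarray
    strands: np.ndarray
    rpkm: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if (np.asarray(self.rpkm) < 0).any():
            raise ValueError("RPKM values must be non-negative")

    def __len__(self) -> int:
        return len(self.gene_ids)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            gene_ids=df["gene_id"].to_numpy(dtype=object),
            chroms=df["chrom"].to_numpy(dtype=object),
            tss=df["tss"].to_numpy(dtype=np.int64),
            strands=df["strand"].to_numpy(dtype=object),
            rpkm=df["rpkm"].to_numpy(dtype=float),
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "chrom": self.chroms,
                "tss": self.tss,
                "strand": self.strands,
                "rpkm": self.rpkm,
            }
        ).to_csv(path, sep="\t", index=False)


def _overlap_mask(track: ProfileTrack, feature: FeatureSet) -> np.ndarray:
    """True for every track bin overlapping >= 1 bp of the feature set."""
    mask = np.zeros(track.n_bins, dtype=bool)
    by_chrom = feature._by_chrom()
    chrom_arr = track.bin_chroms.astype(str)
    for c, (fs, fe) in by_chrom.items():
        m = chrom_arr == c
        if not m.any():
            continue
        bs = track.bin_starts[m]
        be = track.bin_ends[m]
        # a bin [bs, be) overlaps some merged interval iff the first interval
        # with end > bs starts before be
        idx = np.searchsorted(fe, bs, side="right")
        ok = (idx < len(fs)) & (np.where(idx < len(fs), fs[np.minimum(idx, len(fs) - 1)], 0) < be)
        mask[np.where(m)[0]] = ok
    return mask


def contingency_enrichment(
    track: ProfileTrack,
    feature: FeatureSet,
    alpha: float = 1e-5,
) -> list[EnrichmentResult]:
    """Fold-enrichment ad/bc and one-tail Fisher p per profile vs a feature.

    Overlap means >= 1 bp between a bin and any feature interval. When b*c is
    zero the ratio is +inf (flagged by the sentinel); an empty feature yields
    NaN ratios.
    """
    hit = _overlap_mask(track, feature)
    assigned = track.labels != UNASSIGNED
    results: list[EnrichmentResult] = []
    for u in range(track.n_profiles):
        in_u = track.labels == u
        other = assigned & ~in_u
        a = int((in_u & hit).sum())
        b = int((in_u & ~hit).sum())
        c = int((other & hit).sum())
        d = int((other & ~hit).sum())
        if len(feature) == 0 or (a + c) == 0:
            ratio = float("nan")
        elif b * c == 0:
            ratio = float("inf")
        else:
            ratio = (a * d) / (b * c)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        results.append(
            EnrichmentResult(
                profile=u,
                feature=feature.name,
                a=a,
                b=b,
                c=c,
                d=d,
                ratio=ratio,
                p=float(p),
                significant=bool(p <= alpha),
                profile_name=track.name_of(u),
            )
        )
    return results


def anchor_distance_distribution(
    track: ProfileTrack,
    anchors: FeatureSet,
    window_bp: int = 10000,
    hist_bin_bp: int = 200,
    normalized_gene_mode: bool = False,
    n_norm_bins: int = 100,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Histogram of signed bin-to-closest-anchor distances per profile.

    Distance runs from the bin midpoint to the nearest anchor point (interval
    start for "+" / interval end for "-" strands, midpoint when strand-less);
    the sign is flipped for "-" anchors so negative always means upstream. In
    ``normalized_gene_mode`` each bin inside an anchor interval is instead
    mapped to [-50, 50] around the interval midpoint, scaled by its length.
    Returns {profile: (bin_edges, counts)}.
    """
    if len(anchors) == 0:
        raise ValueError("anchor set is empty")
    strands = anchors.strands if anchors.strands is not None else np.full(len(anchors), ".", dtype=object)

    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    mid = (track.bin_starts + track.bin_ends) / 2.0
    chrom_arr = track.bin_chroms.astype(str)

    if normalized_gene_mode:
        edges = np.linspace(-50, 50, n_norm_bins + 1)
        pos = np.full(track.n_bins, np.nan)
        for c in np.unique(anchors.chroms.astype(str)):
            am = anchors.chroms == c
            a_s, a_e = anchors.starts[am], anchors.ends[am]
            a_st = strands[am]
            bm = chrom_arr == c
            bmid = mid[bm]
            idxs = np.where(bm)[0]
            for s, e, st in zip(a_s, a_e, a_st):
                inside = (bmid >= s) & (bmid < e)
                rel = (bmid[inside] - (s + e) / 2.0) / (e - s) * 100.0
                if st == "-":
                    rel = -rel
                pos[idxs[inside]] = rel
        for u in range(track.n_profiles):
            sel = (track.labels == u) & ~np.isnan(pos)
            counts, _ = np.histogram(pos[sel], bins=edges)
            out[u] = (edges, counts)
        return out

    edges = np.arange(-window_bp, window_bp + hist_bin_bp, hist_bin_bp)
    dist = np.full(track.n_bins, np.nan)
    for c in np.unique(anchors.chroms.astype(str)):
        am = anchors.chroms == c
        a_pos = np.where(
            strands[am] == "-",
            anchors.ends[am].astype(float),
            np.where(
                strands[am] == "+",
                anchors.starts[am].astype(float),
                (anchors.starts[am] + anchors.ends[am]) / 2.0,
            ),
        )
        a_strand = strands[am]
        order = np.argsort(a_pos)
        a_pos = a_pos[order]
        a_strand = a_strand[order]
        bm = chrom_arr == c
        if not bm.any():
            continue
        bmid = mid[bm]
        idx = np.searchsorted(a_pos, bmid)
        left = np.clip(idx - 1, 0, len(a_pos) - 1)
        right = np.clip(idx, 0, len(a_pos) - 1)
        d_left = np.abs(bmid - a_pos[left])
        d_right = np.abs(bmid - a_pos[right])
        nearest = np.where(d_left <= d_right, left, right)
        d = bmid - a_pos[nearest]
        flip = a_strand[nearest] == "-"
        d = np.where(flip, -d, d)
        dist[np.where(bm)[0]] = d
    for u in range(track.n_profiles):
        sel = (track.labels == u) & ~np.isnan(dist)
        counts, _ = np.histogram(dist[sel], bins=edges)
        out[u] = (edges, counts)
    return out


def roc_recovery(
    scores: np.ndarray,
    positives: np.ndarray | None = None,
    track: ProfileTrack | None = None,
    feature: FeatureSet | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC curve and trapezoidal AUC for a per-bin score against a feature.

    Positives may be given directly as a boolean mask, or derived as the
    track bins overlapping the feature. Equal scores are grouped at one
    threshold. Returns (fpr, tpr, thresholds, auc).
    """
    scores = np.asarray(scores, dtype=float)
    if positives is None:
        if track is None or feature is None:
            raise ValueError("need either a positive mask or a track + feature")
        positives = _overlap_mask(track, feature)
    positives = np.asarray(positives, dtype=bool)
    P = int(positives.sum())
    N = int((~positives).sum())
    if P == 0 or N == 0:
        raise ValueError("ROC undefined: need both positive and negative bins")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = positives[order]
    # indices where a new (lower) score starts: group ties
    distinct = np.where(np.diff(s))[0]
    cut = np.r_[distinct, len(s) - 1]
    tp = np.cumsum(y)[cut]
    fp = np.cumsum(~y)[cut]
    tpr = np.r_[0.0, tp / P]
    fpr = np.r_[0.0, fp / N]
    thresholds = np.r_[np.inf, s[cut]]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thresholds, auc


@dataclass
class ExpressionPatternResult:
    """Expression-stratified profile-frequency maps around the TSS."""

    profiles: list[int]
    strata_edges: np.ndarray  # RPKM percentile edges, low to high
    positions: np.ndarray  # bp offsets of position-bin starts, TSS at 0
    observed: dict[int, np.ndarray]  # profile -> strata x positions frequency
    expected: dict[int, np.ndarray]  # permutation-null frequency
    logfc: dict[int, np.ndarray]
    subclusters: dict[int, np.ndarray]  # profile -> stratum cluster labels
    n_genes_used: int
    n_genes_skipped: int


def expression_pattern(
    track: ProfileTrack,
    expression: ExpressionTable,
    window: tuple[int, int] = (-2000, 2000),
    pos_bin_bp: int = 200,
    percentile_step: float = 2.5,
    n_permutations: int = 20,
    seed: int = 0,
    n_subclusters: int = 5,
) -> ExpressionPatternResult:
    """Profile frequency by expression stratum and TSS-relative position.

    Genes are binned into RPKM percentile intervals; for each profile the
    frequency of that profile among assigned bins in every
    (stratum, position) cell is compared with a bin-label-permutation null,
    giving log(observed/expected). Strata rows are then grouped by
    average-linkage hierarchical clustering into ``n_subclusters``.
    Positions are strand-aware (negative = upstream of the TSS).
    """
    lo, hi = window
    offsets = np.arange(lo, hi, pos_bin_bp)
    n_pos = len(offsets)

    # map (chrom, bin_start) -> track row
    row_of: dict[tuple[str, int], int] = {
        (str(c), int(s)): i
        for i, (c, s) in enumerate(zip(track.bin_chroms, track.bin_starts))
    }
    width = int(track.bin_ends[0] - track.bin_starts[0]) if track.n_bins else pos_bin_bp

    used, skipped = 0, 0
    gene_rows = []  # (rpkm, [track rows per position; -1 missing])
    for c, tss, strand, rp in zip(
        expression.chroms, expression.tss, expression.strands, expression.rpkm
    ):
        rows = np.full(n_pos, -1, dtype=np.int64)
        for p, off in enumerate(offsets):
            gpos = tss + off if strand != "-" else tss - off - pos_bin_bp
            bstart = (gpos // width) * width
            rows[p] = row_of.get((str(c), int(bstart)), -1)
        if (rows >= 0).any():
            used += 1
            gene_rows.append((rp, rows))
        else:
            skipped += 1
    if not gene_rows:
        raise ValueError("no gene TSS maps onto the track bins")

    rpkms = np.array([g[0] for g in gene_rows])
    pcts = np.arange(0, 100 + percentile_step, percentile_step)
    edges = np.percentile(rpkms, pcts)
    if np.allclose(edges[0], edges[-1]):
        logger.warning("all genes have identical RPKM: single expression stratum")
        strata = np.zeros(len(rpkms), dtype=np.int64)
        n_strata = 1
    else:
        strata = np.clip(np.searchsorted(edges[1:-1], rpkms, side="right"), 0, len(pcts) - 2)
        n_strata = len(pcts) - 1

    rows_mat = np.stack([g[1] for g in gene_rows])  # genes x positions

    def freq_maps(labels: np.ndarray) -> dict[int, np.ndarray]:
        maps = {u: np.zeros((n_strata, n_pos)) for u in range(track.n_profiles)}
        denom = np.zeros((n_strata, n_pos))
        lab_at = np.where(rows_mat >= 0, labels[np.maximum(rows_mat, 0)], UNASSIGNED)
        valid = rows_mat >= 0
        for srow in range(n_strata):
            gsel = strata == srow
            if not gsel.any():
                continue
            sub = lab_at[gsel]
            vsub = valid[gsel]
            denom[srow] = vsub.sum(axis=0)
            for u in range(track.n_profiles):
                maps[u][srow] = (sub == u).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            for u in maps:
                maps[u] = np.where(denom > 0, maps[u] / np.maximum(denom, 1), np.nan)
        return maps

    observed = freq_maps(track.labels)
    rng = np.random.default_rng(seed)
    acc = {u: np.zeros((n_strata, n_pos)) for u in range(track.n_profiles)}
    for _ in range(n_permutations):
        perm = track.labels[rng.permutation(track.n_bins)]
        fm = freq_maps(perm)
        for u in acc:
            acc[u] += np.nan_to_num(fm[u])
    expected = {u: acc[u] / n_permutations for u in acc}

    logfc: dict[int, np.ndarray] = {}
    subclusters: dict[int, np.ndarray] = {}
    for u in range(track.n_profiles):
        with np.errstate(invalid="ignore", divide="ignore"):
            lf = np.log(observed[u] / expected[u])
            lf[~np.isfinite(lf)] = np.nan
        logfc[u] = lf
        rowsX = np.nan_to_num(observed[u])
        if n_strata > n_subclusters:
            Z = hierarchy.linkage(pdist(rowsX), method="average")
            subclusters[u] = hierarchy.fcluster(Z, t=n_subclusters, criterion="maxclust")
        else:
            subclusters[u] = np.arange(1, n_strata + 1)

    return ExpressionPatternResult(
        profiles=list(range(track.n_profiles)),
        strata_edges=edges,
        positions=offsets,
        observed=observed,
        expected=expected,
        logfc=logfc,
        subclusters=subclusters,
        n_genes_used=used,
        n_genes_skipped=skipped,
    )


def _per_profile_overlap(track: ProfileTrack, feature: FeatureSet, profiles) -> dict[int, float]:
    hit = _overlap_mask(track, feature)
    return {
        u: float((hit & (track.labels == u)).sum() / max((track.labels == u).sum(), 1))
        for u in profiles
    }


def _feature_coverage(track: ProfileTrack, feature: FeatureSet, profiles) -> float:
    """Fraction of feature elements matched by >= 1 bin of any listed profile."""
    sel = np.isin(track.labels, list(profiles))
    bs = track.bin_starts[sel]
    be = track.bin_ends[sel]
    bc = track.bin_chroms[sel].astype(str)
    covered = 0
    for c, s, e in zip(feature.chroms.astype(str), feature.starts, feature.ends):
        m = bc == c
        if m.any() and ((be[m] > s) & (bs[m] < e)).any():
            covered += 1
    return covered / len(feature) if len(feature) else float("nan")


def mean_overlap_and_coverage(
    track: ProfileTrack,
    feature: FeatureSet,
    enriched_profiles: list[int],
) -> tuple[float, float]:
    """Mean profile overlap % and mean feature coverage % for a profile set.

    Overlap of a profile is the fraction of its bins touching the feature;
    coverage of a profile is the fraction of feature elements touched by its
    bins. Both are averaged over the enriched profiles and given in percent.
    """
    if not enriched_profiles:
        raise ValueError("enriched profile set is empty")
    overlaps = _per_profile_overlap(track, feature, enriched_profiles)
    coverages = [
        _feature_coverage(track, feature, [u]) for u in enriched_profiles
    ]
    return (
        100.0 * float(np.mean(list(overlaps.values()))),
        100.0 * float(np.mean(coverages)),
    )


def enumerate_subset_overlap(
    track: ProfileTrack,
    feature: FeatureSet,
    enriched_profiles: list[int],
    max_size: int | None = None,
) -> pd.DataFrame:
    """Overlap/coverage for every subset of the enriched profiles (size <= L)."""
    if not enriched_profiles:
        raise ValueError("enriched profile set is empty")
    max_size = max_size or len(enriched_profiles)
    rows = []
    for L in range(1, max_size + 1):
        for combo in itertools.combinations(enriched_profiles, L):
            ov, cov = mean_overlap_and_coverage(track, feature, list(combo))
            rows.append({"profiles": combo, "size": L, "mean_overlap_pct": ov, "mean_coverage_pct": cov})
    return pd.DataFrame(rows)


def profile_correlation(
    A: np.ndarray,
    B: np.ndarray,
) -> tuple[np.ndarray, list[tuple[int, int, float]]]:
    """Pearson correlation between all profile pairs of two runs.

    Rows of A and B are profiles over a shared axis (marks of H, or feature
    enrichments). Returns the full correlation matrix plus a greedy 1-1
    matching by descending correlation. Zero-variance profiles give NaN.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValueError("profile vectors must share their feature axis")
    ra, rb = A.shape[0], B.shape[0]
    corr = np.full((ra, rb), np.nan)
    for i in range(ra):
        for j in range(rb):
            if A[i].std() == 0 or B[j].std() == 0:
                continue
            corr[i, j] = float(np.corrcoef(A[i], B[j])[0, 1])
    pairs: list[tuple[int, int, float]] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    flat = [
        (corr[i, j], i, j)
        for i in range(ra)
        for j in range(rb)
        if np.isfinite(corr[i, j])
    ]
    for r, i, j in sorted(flat, reverse=True):
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j, r))
        used_a.add(i)
        used_b.add(j)
    return corr, pairs
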