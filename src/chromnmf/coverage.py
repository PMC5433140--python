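"""Binned, normalized coverage from read alignments.

The signal unit throughout the pipeline is a fold-enrichment per 200-bp bin:
observed reads assigned to the bin divided by the reads expected there if the
library were spread uniformly over the uniquely mappable genome. Replicates of
one mark are pooled at this stage (sum of observed over sum of expected), which
down-weights shallow replicates without rescaling raw counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeBins",
    "ReadSet",
    "CountTensor",
    "CoverageMatrix",
    "read_chrom_sizes",
    "make_bins",
    "load_reads",
    "count_reads",
    "expected_counts",
    "normalized_coverage",
]


class ConfigurationError(ValueError):
    """Raised when inputs or options are structurally invalid."""


@dataclass
class GenomeBins:
    """Non-overlapping fixed-width tiling of a genome.

    The last bin of each chromosome may be shorter than ``bin_width``.
    ``mappable_bp`` holds M(j), the number of uniquely mappable positions in
    bin j; ``genome_mappable`` is G, their genome-wide total.
    """

    chrom_sizes: dict[str, int]
    bin_width: int
    chroms: np.ndarray  # per-bin chromosome name
    starts: np.ndarray
    ends: np.ndarray
    mappable_bp: np.ndarray  # float, M(j)
    genome_mappable: float  # G

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def bin_ids(self) -> list[str]:
        return [f"{c}:{s}-{e}" for c, s, e in zip(self.chroms, self.starts, self.ends)]

    def chrom_offsets(self) -> dict[str, int]:
        """Index of the first bin of each chromosome, in storage order."""
        offsets: dict[str, int] = {}
        for i, c in enumerate(self.chroms):
            if c not in offsets:
                offsets[c] = i
        return offsets


@dataclass
class ReadSet:
    """Processed read intervals for one replicate of one mark."""

    mark: str
    sample: str
    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    strands: np.ndarray
    n_malformed: int = 0
    n_skipped_chrom: int = 0
    n_duplicates_removed: int = 0

    @property
    def total_mapped(self) -> int:
        """C(i): number of reads surviving filtering."""
        return len(self.starts)


@dataclass
class CountTensor:
    """Observed and expected read counts per bin, mark and replicate."""

    bins: GenomeBins
    marks: list[str]
    samples: dict[str, list[str]]  # mark -> replicate ids
    counts: dict[str, np.ndarray]  # mark -> (n_bins, n_samples) int, R(j,k,i)
    expected: dict[str, np.ndarray]  # mark -> (n_bins, n_samples) float, E(j,k,i)
    scale: dict[str, np.ndarray]  # mark -> Q(i,P) per replicate
    dataset_mean: dict[str, float]  # mark -> A(P)
    mode: str = "uniform"


@dataclass
class CoverageMatrix:
    """Bins-by-marks signal matrix with bin coordinates attached.

    ``stage`` tracks the pipeline stage of the values: ``raw`` fold-enrichment,
    ``filtered`` (significant bins only), ``transformed`` (sigmoid-scaled) or
    ``random`` (column-permuted null).
    """

    values: np.ndarray
    marks: list[str]
    bin_chroms: np.ndarray
    bin_starts: np.ndarray
    bin_ends: np.ndarray
    stage: str = "raw"
    unmappable: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (bins x marks)")
        if self.values.shape[1] != len(self.marks):
            raise ValueError("column count does not match mark labels")
        if len(set(self.marks)) != len(self.marks):
            raise ValueError("mark labels must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("coverage values must be finite")
        if (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def bin_ids(self) -> list[str]:
        return [
            f"{c}:{s}-{e}"
            for c, s, e in zip(self.bin_chroms, self.bin_starts, self.bin_ends)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.bin_ids(), columns=self.marks)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "bin"
        df.to_csv(path, sep="\t", float_format="%.9g")

    @classmethod
    def from_tsv(cls, path: str | Path, stage: str = "raw") -> "CoverageMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        chroms, starts, ends = [], [], []
        for bid in df.index.astype(str):
            chrom, span = bid.rsplit(":", 1)
            s, e = span.split("-")
            chroms.append(chrom)
            starts.append(int(s))
            ends.append(int(e))
        return cls(
            values=df.to_numpy(dtype=float),
            marks=list(df.columns),
            bin_chroms=np.array(chroms, dtype=object),
            bin_starts=np.array(starts, dtype=np.int64),
            bin_ends=np.array(ends, dtype=np.int64),
            stage=stage,
        )

    def select_rows(self, mask_or_idx: np.ndarray, stage: str | None = None) -> "CoverageMatrix":
        return CoverageMatrix(
            values=self.values[mask_or_idx],
            marks=list(self.marks),
            bin_chroms=self.bin_chroms[mask_or_idx],
            bin_starts=self.bin_starts[mask_or_idx],
            bin_ends=self.bin_ends[mask_or_idx],
            stage=stage or self.stage,
            unmappable=None if self.unmappable is None else self.unmappable[mask_or_idx],
        )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            sizes[fields[0]] = int(fields[1])
    if not sizes:
        raise ConfigurationError(f"no chromosomes found in {path}")
    return sizes


def _read_bedgraph(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            c, s, e, v = line.split()[:4]
            by_chrom.setdefault(c, []).append((int(s), int(e), float(v)))
    out = {}
    for c, rows in by_chrom.items():
        rows.sort()
        arr = np.array(rows, dtype=float)
        out[c] = (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
    return out


def make_bins(
    chrom_sizes: Mapping[str, int] | str | Path,
    bin_width: int = 200,
    mappability: str | Path | dict | None = None,
) -> GenomeBins:
    """Tile every chromosome into ``bin_width`` bins and attach mappability.

    Without a mappability track every position counts as mappable:
    M(j) = bin length and G = total genome length. A bedGraph track gives the
    per-base probability of unique mappability (0/1 tracks are the common
    case); M(j) is then the mappable-base total intersecting bin j and G the
    genome-wide total.
    """
    if isinstance(chrom_sizes, (str, Path)):
        chrom_sizes = read_chrom_sizes(chrom_sizes)
    if not chrom_sizes:
        raise ConfigurationError("chrom_sizes is empty")
    if bin_width <= 0:
        raise ConfigurationError("bin_width must be positive")
    for c, L in chrom_sizes.items():
        if L <= 0:
            raise ConfigurationError(f"chromosome {c} has non-positive length {L}")

    track = None
    if mappability is not None:
        track = mappability if isinstance(mappability, dict) else _read_bedgraph(mappability)
        for c in track:
            if c not in chrom_sizes:
                raise ConfigurationError(
                    f"mappability chromosome {c!r} absent from chrom_sizes"
                )

    chroms, starts, ends = [], [], []
    for c, L in chrom_sizes.items():
        bs = np.arange(0, L, bin_width, dtype=np.int64)
        be = np.minimum(bs + bin_width, L)
        chroms.append(np.full(len(bs), c, dtype=object))
        starts.append(bs)
        ends.append(be)
    chroms = np.concatenate(chroms)
    starts = np.concatenate(starts)
    ends = np.concatenate(ends)

    if track is None:
        mappable = (ends - starts).astype(float)
    else:
        mappable = np.zeros(len(starts), dtype=float)
        offset = 0
        for c, L in chrom_sizes.items():
            n = int(np.ceil(L / bin_width))
            if c in track:
                ts, te, tv = track[c]
                for s, e, v in zip(ts, te, tv):
                    e = min(e, L)
                    if s >= e:
                        continue
                    b0 = s // bin_width
                    b1 = (e - 1) // bin_width
                    for b in range(b0, b1 + 1):
                        lo = max(s, b * bin_width)
                        hi = min(e, (b + 1) * bin_width, L)
                        mappable[offset + b] += v * (hi - lo)
            offset += n

    G = float(mappable.sum())
    return GenomeBins(
        chrom_sizes=dict(chrom_sizes),
        bin_width=bin_width,
        chroms=chroms,
        starts=starts,
        ends=ends,
        mappable_bp=mappable,
        genome_mappable=G,
    )


def load_reads(
    path: str | Path,
    mark: str,
    sample: str,
    chrom_sizes: Mapping[str, int] | None = None,
    dedup: bool = True,
    extension_bp: int = 200,
    extension_dialect: str = "to",
) -> ReadSet:
    """Load a BED file of read alignments and apply the standard filters.

    Each read is extended toward its 3' end to a total footprint of
    ``extension_bp`` (half the typical ChIP fragment length), mirroring
    fragment-centre coverage; reads already at least that long are left alone.
    ``extension_dialect="by"`` instead lengthens every read by ``extension_bp``.
    Extension is clipped at chromosome ends when sizes are given. Exact
    duplicates (same chrom, start, end, strand) are collapsed when ``dedup``.
    """
    if extension_dialect not in ("to", "by"):
        raise ConfigurationError(f"unknown extension dialect {extension_dialect!r}")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    n_malformed = 0
    n_skipped = 0
    n_missing_strand = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) == 1:
                f = line.split()
            try:
                c, s, e = f[0], int(f[1]), int(f[2])
            except (IndexError, ValueError):
                n_malformed += 1
                continue
            if s >= e:
                n_malformed += 1
                continue
            if chrom_sizes is not None and c not in chrom_sizes:
                n_skipped += 1
                continue
            strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else None
            if strand is None:
                n_missing_strand += 1
                strand = "+"
            chroms.append(c)
            starts.append(s)
            ends.append(e)
            strands.append(strand)
    if n_missing_strand:
        logger.warning(
            "%s: %d records without strand treated as '+'", path, n_missing_strand
        )
    if n_malformed:
        logger.warning("%s: skipped %d malformed records", path, n_malformed)
    if n_skipped:
        logger.warning("%s: skipped %d reads on unknown chromosomes", path, n_skipped)

    ca = np.array(chroms, dtype=object)
    sa = np.array(starts, dtype=np.int64)
    ea = np.array(ends, dtype=np.int64)
    ta = np.array(strands, dtype=object)

    n_dup = 0
    if dedup and len(sa):
        seen = set()
        keep = np.zeros(len(sa), dtype=bool)
        for i in range(len(sa)):
            key = (ca[i], int(sa[i]), int(ea[i]), ta[i])
            if key not in seen:
                seen.add(key)
                keep[i] = True
        n_dup = int((~keep).sum())
        ca, sa, ea, ta = ca[keep], sa[keep], ea[keep], ta[keep]

    if extension_bp > 0 and len(sa):
        plus = ta == "+"
        lengths = ea - sa
        if extension_dialect == "to":
            grow = np.maximum(extension_bp - lengths, 0)
        else:
            grow = np.full(len(sa), extension_bp, dtype=np.int64)
        ea = np.where(plus, ea + grow, ea)
        sa = np.where(plus, sa, sa - grow)
        sa = np.maximum(sa, 0)
        if chrom_sizes is not None:
            limits = np.array([chrom_sizes[c] for c in ca], dtype=np.int64)
            ea = np.minimum(ea, limits)

    return ReadSet(
        mark=mark,
        sample=sample,
        chroms=ca,
        starts=sa,
        ends=ea,
        strands=ta,
        n_malformed=n_malformed,
        n_skipped_chrom=n_skipped,
        n_duplicates_removed=n_dup,
    )


def count_reads(reads: ReadSet, bins: GenomeBins) -> np.ndarray:
    """Assign each read to every bin it overlaps by at least one base."""
    counts = np.zeros(bins.n_bins, dtype=np.int64)
    if reads.total_mapped == 0:
        return counts
    offsets = bins.chrom_offsets()
    w = bins.bin_width
    for c in np.unique(reads.chroms):
        if c not in offsets:
            continue
        m = reads.chroms == c
        s = reads.starts[m]
        e = reads.ends[m]
        L = bins.chrom_sizes[c]
        nb = int(np.ceil(L / w))
        off = offsets[c]
        b0 = np.clip(s // w, 0, nb - 1)
        b1 = np.clip((e - 1) // w, 0, nb - 1)
        span = b1 - b0
        for d in range(int(span.max()) + 1 if len(span) else 0):
            sel = span >= d
            np.add.at(counts, off + b0[sel] + d, 1)
    return counts


def expected_counts(
    bins: GenomeBins,
    samples: Mapping[str, Sequence[ReadSet]],
    mode: str = "uniform",
) -> CountTensor:
    """Observed and expected per-bin counts for every mark and replicate.

    In the default ``uniform`` mode the expectation is the uniform-placement
    read count, E(j,k,i) = C(i) * M(j) / G, so S becomes a genuine
    fold-enrichment. The ``literal`` mode instead computes
    E(j,k,i) = M(j) / (G * Q(i,P)) with Q(i,P) = A(P)/C(i), reproducing the
    printed normalization verbatim (a fold-enrichment scaled by the dataset
    mean library size A(P)).
    """
    if mode not in ("uniform", "literal"):
        raise ConfigurationError(f"unknown normalization mode {mode!r}")
    if bins.genome_mappable <= 0 or not (bins.mappable_bp > 0).any():
        raise ConfigurationError("no mappable genome: all M(j) are zero")

    marks = list(samples)
    counts: dict[str, np.ndarray] = {}
    expected: dict[str, np.ndarray] = {}
    scale: dict[str, np.ndarray] = {}
    dataset_mean: dict[str, float] = {}
    sample_ids: dict[str, list[str]] = {}
    G = bins.genome_mappable
    M = bins.mappable_bp

    for mark in marks:
        reps = list(samples[mark])
        if not reps:
            raise ConfigurationError(f"mark {mark!r} has no replicates")
        C = np.array([r.total_mapped for r in reps], dtype=float)
        if (C <= 0).any():
            bad = [r.sample for r, c in zip(reps, C) if c <= 0]
            raise ConfigurationError(f"mark {mark!r}: replicates with zero reads: {bad}")
        A = float(C.mean())
        Q = A / C
        R = np.stack([count_reads(r, bins) for r in reps], axis=1)
        if mode == "uniform":
            E = np.outer(M / G, C)
        else:
            E = np.outer(M / G, 1.0 / Q)  # == M/(G*Q); equals uniform/A(P)
        counts[mark] = R
        expected[mark] = E
        scale[mark] = Q
        dataset_mean[mark] = A
        sample_ids[mark] = [r.sample for r in reps]

    return CountTensor(
        bins=bins,
        marks=marks,
        samples=sample_ids,
        counts=counts,
        expected=expected,
        scale=scale,
        dataset_mean=dataset_mean,
        mode=mode,
    )


def normalized_coverage(tensor: CountTensor) -> CoverageMatrix:
    """Pool replicates into the normalized coverage S(j,k) = sum R / sum E.

    Bins with no mappable bases have expected coverage zero; they get S = 0
    and are flagged in ``unmappable``.
    """
    bins = tensor.bins
    J = bins.n_bins
    K = len(tensor.marks)
    S = np.zeros((J, K), dtype=float)
    unmappable = bins.mappable_bp <= 0
    for k, mark in enumerate(tensor.marks):
        R = tensor.counts[mark]
        if (R < 0).any():
            raise ValueError(f"negative counts for mark {mark!r}")
        E = tensor.expected[mark]
        num = R.sum(axis=1).astype(float)
        den = E.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        S[:, k] = s
    return CoverageMatrix(
        values=S,
        marks=list(tensor.marks),
        bin_chroms=bins.chroms,
        bin_starts=bins.starts,
        bin_ends=bins.ends,
        stage="raw",
        unmappable=unmappable,
    )
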