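"""Synthetic chromatin-signal generator with planted combinatorial profiles.

The generator emulates the statistical structure the pipeline assumes: a
small library of chromatin profiles (recurrent mark combinations such as an
active-promoter Pol2/H3K27ac/DNase signature or an H3K27me3 polycomb
signature) plants signal regions on a toy genome; per-bin mark coverage is
the profile-implied mean corrupted by negative-binomial noise on top of an
NB background. Reads, annotations and an expression table can be derived
from the same ground truth, so every pipeline stage has an oracle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coverage import CoverageMatrix, GenomeBins, ReadSet, make_bins
from .evaluation import ExpressionTable, FeatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "ProfileLibrary",
    "SyntheticTruth",
    "MARK_NAMES",
    "PROFILE_NAMES",
    "default_profile_library",
    "simulate_matrix",
    "simulate_reads",
    "simulate_annotations",
]

MARK_NAMES = [
    "H3K27ac",
    "Pol2",
    "DNaseHS",
    "H3K4me3",
    "H3K4me2",
    "H3K9ac",
    "H2A.Z",
    "H3K4me1",
    "CTCF",
    "H3K36me3",
    "H3K79me1",
    "H3K9me3",
    "H3K27me3",
]

PROFILE_NAMES = ["ActProm", "TxInit", "Ehn", "RegEl", "GenBd", "RepChr", "RepReg"]


@dataclass
class ProfileLibrary:
    """Profiles-by-marks coefficient template on a 0-1 scale."""

    names: list[str]
    mark_names: list[str]
    H0: np.ndarray

    def __post_init__(self) -> None:
        H = np.asarray(self.H0, dtype=float)
        if H.shape != (len(self.names), len(self.mark_names)):
            raise ValueError("H0 shape inconsistent with labels")
        if (H < 0).any():
            raise ValueError("H0 must be non-negative")
        if (H.sum(axis=1) == 0).any():
            raise ValueError("every profile needs at least one positive mark load")
        # profiles must be pairwise non-proportional (> 5 degrees apart)
        norms = np.linalg.norm(H, axis=1)
        cos = (H @ H.T) / np.outer(norms, norms)
        np.fill_diagonal(cos, 0)
        if (cos > np.cos(np.deg2rad(5.0))).any():
            raise ValueError("two profiles are nearly proportional")
        self.H0 = H

    @property
    def n_profiles(self) -> int:
        return len(self.names)


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a simulated matrix."""

    labels: np.ndarray  # planted profile per bin; -1 = background
    W0: np.ndarray
    library: ProfileLibrary
    mean_coverage: np.ndarray  # bins x marks expectation used for noise
    params: dict = field(default_factory=dict)
    features: dict[str, FeatureSet] = field(default_factory=dict)
    expression: ExpressionTable | None = None
    expression_truth: dict = field(default_factory=dict)


def default_profile_library(common: float = 0.05) -> ProfileLibrary:
    """The bundled seven-profile library over the 13 canonical marks.

    Rows encode the qualitative mark combinations of the canonical chromatin
    profiles: active promoters (Pol2 + H3K27ac + open chromatin),
    transcription initiation (H3K4me2/3 + H3K9ac + H2A.Z), enhancers
    (H3K4me1), CTCF-bound regulatory elements, transcribed gene bodies
    (H3K36me3 + H3K79me1), constitutive heterochromatin (H3K9me3) and
    polycomb-repressed chromatin (H3K27me3).

    Each profile carries one "anchor" mark loading on it alone, which keeps
    the rank-7 factorization identifiable; the remaining marks carry
    moderate secondary loads on related profiles, mirroring real mark
    sharing (enhancer H3K27ac, promoter-proximal H3K4me3/H3K9ac, H2A.Z at
    CTCF sites and poised loci, 5' H3K79me1, H3K9me3/H3K27me3 cross-talk,
    H3K4me1 at poised polycomb enhancers). A small ``common`` load on every
    mark models the unspecific signal floor of active chromatin. Magnitudes
    are synthetic constants on a 0-1 scale chosen to look like post-sigmoid
    signal; they are the package's own design, not measured values.
    """
    idx = {m: i for i, m in enumerate(MARK_NAMES)}
    H0 = np.full((7, 13), float(common))

    def put(mark: str, **loads: float) -> None:
        for p, v in loads.items():
            H0[int(p[1]), idx[mark.replace("_", ".")]] += v

    put("Pol2", p0=1.0)
    put("H3K4me2", p1=1.0)
    put("H3K4me1", p2=1.0)
    put("CTCF", p3=1.0)
    put("H3K36me3", p4=1.0)
    put("H3K9me3", p5=1.35, p6=0.1)
    put("H3K27me3", p6=1.35, p5=0.1)
    put("H3K27ac", p0=1.0, p2=0.6, p1=0.55)
    put("DNaseHS", p0=1.0, p3=0.6, p2=0.55)
    put("H3K4me3", p1=1.0, p0=0.6, p6=0.3)
    put("H3K9ac", p1=1.0, p0=0.6, p2=0.55)
    put("H2A_Z", p1=1.0, p3=0.6, p0=0.5)
    put("H3K79me1", p4=1.0, p1=0.6, p0=0.55)
    return ProfileLibrary(names=list(PROFILE_NAMES), mark_names=list(MARK_NAMES), H0=H0)


def _planted_labels(
    n_bins: int,
    n_profiles: int,
    background_fraction: float,
    region_len: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Alternate background and single-profile regions of geometric length."""
    labels = np.full(n_bins, -1, dtype=np.int64)
    if background_fraction >= 1.0:
        return labels
    bg_len = region_len * background_fraction / max(1.0 - background_fraction, 1e-9)
    i = 0
    while i < n_bins:
        # gap supports zero so distinct profile regions can touch, as real
        # chromatin states do; mean gap length stays at bg_len
        gap = rng.geometric(1.0 / (1.0 + bg_len)) - 1 if background_fraction > 0 else 0
        i += gap
        if i >= n_bins:
            break
        run = rng.geometric(1.0 / region_len)
        c = rng.integers(0, n_profiles)
        labels[i : min(i + run, n_bins)] = c
        i += run
    return labels


def simulate_matrix(
    library: ProfileLibrary | None = None,
    n_bins: int = 20000,
    background_fraction: float = 0.2,
    signal_scale: float = 25.0,
    background_mean: float = 5.0,
    nb_shape: float = 2.0,
    signal_shape: float = 8.0,
    cross_loading: float = 0.1,
    cross_loading_range: tuple[float, float] = (0.2, 0.45),
    region_len: float = 5.0,
    signal_jitter: float = 0.15,
    genebody_sub_delta: float = 0.4,
    bin_width: int = 200,
    noise: bool = True,
    seed: int = 0,
) -> tuple[CoverageMatrix, SyntheticTruth]:
    """Simulate a significant-bin coverage matrix with planted profiles.

    The matrix emulates the post-filter analysis matrix: most bins carry
    signal (``background_fraction`` defaults to 0.2, standing in for weak or
    false-positive bins that slip past the tail filter). Signal regions
    (geometric length, mean ``region_len`` bins) carry one profile each with
    a random magnitude; a ``cross_loading`` fraction of signal bins also
    load a neighbouring profile at a fraction of the primary magnitude
    (genomic adjacency of states: promoters abut gene bodies, enhancers abut
    open chromatin), exercising the ambiguous-assignment machinery. Gene
    body regions come in a 5'-like and a 3'-like sub-state that tilt the
    H3K79me1:H3K36me3 ratio by ``genebody_sub_delta``, giving the data
    substructure below the profile level as real chromatin has.

    Per-cell coverage is the sum of two independent negative-binomial
    draws: unspecific background with mean ``background_mean`` and shape
    ``nb_shape`` (strongly overdispersed, as genome-wide ChIP-seq noise is),
    plus enrichment with mean ``signal_scale * (W0 @ H0)`` and the milder
    shape ``signal_shape`` (pooled replicates tame the dispersion inside
    enriched regions). The signal mean is jittered by a lognormal factor
    (sigma ``signal_jitter``) for region-to-region biological variability.
    ``noise=False`` returns the mean matrix itself. Deterministic under
    ``seed``.
    """
    library = library or default_profile_library()
    if n_bins < 10 * library.n_profiles:
        raise ValueError("need at least 10 bins per profile")
    if nb_shape <= 0 or signal_shape <= 0 or background_mean < 0 or signal_scale < 0:
        raise ValueError("invalid noise parameters")
    rng = np.random.default_rng(seed)
    r = library.n_profiles
    K = len(library.mark_names)
    midx = {m: i for i, m in enumerate(library.mark_names)}

    labels = _planted_labels(n_bins, r, background_fraction, region_len, rng)
    W0 = np.zeros((n_bins, r))
    sig = np.where(labels >= 0)[0]
    W0[sig, labels[sig]] = rng.uniform(0.7, 1.5, size=len(sig))
    crossed = sig[rng.random(len(sig)) < cross_loading]
    if len(crossed) and r > 1:
        neighbour = (labels[crossed] + rng.choice([-1, 1], size=len(crossed))) % r
        lo, hi = cross_loading_range
        W0[crossed, neighbour] = rng.uniform(lo, hi, size=len(crossed)) * W0[
            crossed, labels[crossed]
        ]

    signal_mean = signal_scale * (W0 @ library.H0)

    # gene-body sub-states: alternate 5'-like / 3'-like regions
    gb_profile = PROFILE_NAMES.index("GenBd") if "GenBd" in library.names else None
    if (
        noise
        and genebody_sub_delta > 0
        and gb_profile is not None
        and "H3K79me1" in midx
        and "H3K36me3" in midx
    ):
        gb = labels == gb_profile
        if gb.any():
            variant = rng.integers(0, 2, size=int(gb.sum()))
            shift = np.where(variant == 0, 1.0 + genebody_sub_delta, 1.0 - genebody_sub_delta)
            k79, k36 = midx["H3K79me1"], midx["H3K36me3"]
            signal_mean[gb, k79] *= shift
            signal_mean[gb, k36] /= shift

    if noise:
        if signal_jitter > 0:
            jit = rng.lognormal(-signal_jitter ** 2 / 2, signal_jitter, size=signal_mean.shape)
            signal_mean = signal_mean * jit
        bg = rng.negative_binomial(
            nb_shape, nb_shape / (nb_shape + background_mean), size=signal_mean.shape
        )
        p_sig = signal_shape / (signal_shape + np.maximum(signal_mean, 1e-12))
        sig_counts = np.where(
            signal_mean > 0, rng.negative_binomial(signal_shape, p_sig), 0
        )
        values = (bg + sig_counts).astype(float)
        mean = background_mean + signal_mean
    else:
        mean = background_mean + signal_mean
        values = mean.copy()

    starts = np.arange(n_bins, dtype=np.int64) * bin_width
    V = CoverageMatrix(
        values=values,
        marks=list(library.mark_names),
        bin_chroms=np.full(n_bins, "chrS1", dtype=object),
        bin_starts=starts,
        bin_ends=starts + bin_width,
        stage="raw",
    )
    truth = SyntheticTruth(
        labels=labels,
        W0=W0,
        library=library,
        mean_coverage=mean,
        params={
            "n_bins": n_bins,
            "background_fraction": background_fraction,
            "signal_scale": signal_scale,
            "background_mean": background_mean,
            "nb_shape": nb_shape,
            "signal_shape": signal_shape,
            "cross_loading": cross_loading,
            "cross_loading_range": cross_loading_range,
            "region_len": region_len,
            "signal_jitter": signal_jitter,
            "genebody_sub_delta": genebody_sub_delta,
            "bin_width": bin_width,
            "noise": noise,
            "seed": seed,
        },
    )
    return V, truth


def simulate_reads(
    truth: SyntheticTruth,
    depth: float = 30.0,
    read_len: int = 36,
    out_dir: str | Path | None = None,
    seed: int = 0,
) -> tuple[dict[str, ReadSet], GenomeBins]:
    """Sample per-mark reads whose per-bin intensity tracks planted coverage.

    For each mark the per-bin Poisson rate is ``depth`` scaled by the bin's
    planted mean over the mark's average, so the expected total is
    depth * n_bins. Reads start uniformly inside their bin on the + strand at
    ``read_len`` bp (downstream extension happens in the coverage loader).
    When ``out_dir`` is given, one BED per mark plus a chrom.sizes file are
    written there.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    p = truth.params
    n_bins, w = p["n_bins"], p["bin_width"]
    chrom_len = n_bins * w
    sizes = {"chrS1": chrom_len}
    bins = make_bins(sizes, bin_width=w)

    readsets: dict[str, ReadSet] = {}
    for k, mark in enumerate(truth.library.mark_names):
        lam = depth * truth.mean_coverage[:, k] / truth.mean_coverage[:, k].mean()
        counts = rng.poisson(lam)
        n_total = int(counts.sum())
        starts = np.repeat(np.arange(n_bins) * w, counts) + rng.integers(
            0, w, size=n_total
        )
        ends = np.minimum(starts + read_len, chrom_len)
        order = np.argsort(starts)
        readsets[mark] = ReadSet(
            mark=mark,
            sample=f"{mark}_rep1",
            chroms=np.full(n_total, "chrS1", dtype=object),
            starts=starts[order],
            ends=ends[order],
            strands=np.full(n_total, "+", dtype=object),
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "chrom.sizes", "w") as fh:
            fh.write(f"chrS1\t{chrom_len}\n")
        for mark, rs in readsets.items():
            with open(out / f"{mark}.bed", "w") as fh:
                for s, e in zip(rs.starts, rs.ends):
                    fh.write(f"chrS1\t{s}\t{e}\t.\t0\t+\n")
    return readsets, bins


def simulate_annotations(
    truth: SyntheticTruth,
    target_profile: int = 0,
    n_genes: int = 1000,
    precision: float = 0.9,
    expression_floor: float = 0.1,
    expression_gain: float = 0.8,
    seed: int = 0,
) -> SyntheticTruth:
    """Attach TSS-like features and an expression table tied to one profile.

    A fraction ``precision`` of the planted TSS points land on bins of the
    target profile (the rest on random other assigned bins). Each gene draws
    a latent expression quantile rho; the probability that its TSS sits on a
    target-profile bin is ``expression_floor + expression_gain * rho``, and
    RPKM is a log-normal monotone map of rho, so profile frequency rises
    monotonically with expression by construction. Also places an
    enhancer-like feature on the planted enhancer profile for enrichment
    tests. Generator parameters are recorded for oracle checks.
    """
    if not (0 <= precision <= 1):
        raise ValueError("precision must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = truth.params
    w = p["bin_width"]
    labels = truth.labels
    target_bins = np.where(labels == target_profile)[0]
    other_bins = np.where((labels >= 0) & (labels != target_profile))[0]
    if len(target_bins) == 0 or len(other_bins) == 0:
        raise ValueError("truth lacks target or non-target bins")

    def tss_feature(bin_idx: np.ndarray, strands: np.ndarray, name: str) -> FeatureSet:
        pos = bin_idx * w + w // 2
        return FeatureSet(
            name=name,
            chroms=np.full(len(bin_idx), "chrS1", dtype=object),
            starts=pos,
            ends=pos + 1,
            strands=strands,
        )

    # plain TSS-like annotation at the stated precision
    n_tss = min(500, len(target_bins))
    on_target = rng.random(n_tss) < precision
    tss_bins = np.where(
        on_target,
        rng.choice(target_bins, size=n_tss),
        rng.choice(other_bins, size=n_tss),
    )
    tss_strands = rng.choice(np.array(["+", "-"], dtype=object), size=n_tss)
    truth.features["TSS"] = tss_feature(tss_bins, tss_strands, "TSS")

    # enhancer-like intervals on the planted enhancer profile when present
    enh_profile = 2 if truth.library.n_profiles > 2 else target_profile
    enh_bins = np.where(labels == enh_profile)[0]
    if len(enh_bins):
        chosen = rng.choice(enh_bins, size=min(300, len(enh_bins)), replace=False)
        truth.features["Enhancer"] = FeatureSet(
            name="Enhancer",
            chroms=np.full(len(chosen), "chrS1", dtype=object),
            starts=chosen * w,
            ends=chosen * w + w,
        )

    # expression table: monotone link between expression and target profile
    rho = rng.uniform(0, 1, size=n_genes)
    prob_target = expression_floor + expression_gain * rho
    gene_on_target = rng.random(n_genes) < prob_target
    gene_bins = np.where(
        gene_on_target,
        rng.choice(target_bins, size=n_genes),
        rng.choice(other_bins, size=n_genes),
    )
    strands = rng.choice(np.array(["+", "-"], dtype=object), size=n_genes)
    from scipy.stats import norm

    rpkm = np.exp(1.0 + 1.5 * norm.ppf(np.clip(rho, 1e-9, 1 - 1e-9)))
    truth.expression = ExpressionTable(
        gene_ids=np.array([f"gene{i}" for i in range(n_genes)], dtype=object),
        chroms=np.full(n_genes, "chrS1", dtype=object),
        tss=gene_bins * w + w // 2,
        strands=strands,
        rpkm=rpkm,
    )
    truth.expression_truth = {
        "target_profile": target_profile,
        "precision": precision,
        "expression_floor": expression_floor,
        "expression_gain": expression_gain,
        "gene_on_target": gene_on_target,
        "rho": rho,
        "seed": seed,
    }
    return truth
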