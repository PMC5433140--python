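"""Per-bin chromatin-profile assignment and downstream track statistics.

Each significant bin is labelled with the profile of maximum weight in its W
row. The relative weight contribution (RWC) rescales each W row by its
maximum, so the assigned profile scores 1 and secondary profiles score their
fraction of the top weight; co-occurrence at an RWC threshold measures how
often a secondary profile comes close to the assigned one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ProfileTrack",
    "UNASSIGNED",
    "assign_profiles",
    "rwc",
    "cooccurrence",
    "transition_enrichment",
]

UNASSIGNED = -1


@dataclass
class ProfileTrack:
    """Per-bin profile labels with their weights and RWC values.

    ``labels`` holds the argmax profile index per bin (``UNASSIGNED`` for
    all-zero weight rows). Bin coordinates are carried so the track can be
    serialized and intersected with annotations.
    """

    labels: np.ndarray
    weights: np.ndarray  # W rows, bins x profiles
    rwc: np.ndarray  # bins x profiles, row max = 1 for assigned bins
    bin_chroms: np.ndarray
    bin_starts: np.ndarray
    bin_ends: np.ndarray
    profile_names: list[str] | None = None
    n_ties: int = 0

    @property
    def n_profiles(self) -> int:
        return self.weights.shape[1]

    @property
    def n_bins(self) -> int:
        return len(self.labels)

    def name_of(self, c: int) -> str:
        if c == UNASSIGNED:
            return "unassigned"
        if self.profile_names:
            return self.profile_names[c]
        return f"P{c + 1}"


def rwc(W: np.ndarray) -> np.ndarray:
    """Relative weight contribution: each row of W divided by its maximum.

    All-zero rows (unassigned bins) are returned as zeros.
    """
    W = np.asarray(W, dtype=float)
    if (W < 0).any():
        raise ValueError("W must be non-negative")
    mx = W.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(mx > 0, W / np.where(mx > 0, mx, 1.0), 0.0)
    return out


def assign_profiles(
    W: np.ndarray,
    bin_chroms: np.ndarray | None = None,
    bin_starts: np.ndarray | None = None,
    bin_ends: np.ndarray | None = None,
    profile_names: list[str] | None = None,
) -> ProfileTrack:
    """Label each bin with its maximum-weight profile.

    Ties go to the lowest profile index (counted and logged); bins whose
    weight row is entirely zero get the unassigned sentinel label.
    """
    W = np.asarray(W, dtype=float)
    if (W < 0).any():
        raise ValueError("W must be non-negative")
    J = W.shape[0]
    labels = W.argmax(axis=1).astype(np.int64)
    zero_rows = W.sum(axis=1) == 0
    labels[zero_rows] = UNASSIGNED
    mx = W.max(axis=1)
    n_ties = int((((W == mx[:, None]).sum(axis=1) > 1) & ~zero_rows).sum())
    if n_ties:
        logger.info("assign_profiles: %d tied bins resolved to the lowest index", n_ties)
    if bin_chroms is None:
        bin_chroms = np.full(J, "synthetic", dtype=object)
        bin_starts = np.arange(J, dtype=np.int64) * 200
        bin_ends = bin_starts + 200
    return ProfileTrack(
        labels=labels,
        weights=W,
        rwc=rwc(W),
        bin_chroms=np.asarray(bin_chroms),
        bin_starts=np.asarray(bin_starts),
        bin_ends=np.asarray(bin_ends),
        profile_names=profile_names,
        n_ties=n_ties,
    )


def cooccurrence(
    track: ProfileTrack,
    thresholds: tuple[float, ...] = (0.95, 0.85, 0.75, 0.5),
) -> dict[float, np.ndarray]:
    """Per-threshold co-occurrence matrices over profiles.

    Cell (u, v) is the fraction of bins assigned to u whose RWC on v reaches
    the threshold; the diagonal is 1 by construction (the assigned profile's
    RWC is 1). Rows for empty profiles are NaN. Entries can only grow as the
    threshold is lowered.
    """
    r = track.n_profiles
    out: dict[float, np.ndarray] = {}
    for t in thresholds:
        mat = np.full((r, r), np.nan)
        for u in range(r):
            mask = track.labels == u
            n = int(mask.sum())
            if n == 0:
                continue
            mat[u] = (track.rwc[mask] >= t).sum(axis=0) / n
            mat[u, u] = 1.0
        out[t] = mat
    return out


def _regions(track: ProfileTrack) -> tuple[np.ndarray, np.ndarray]:
    """Merge runs of identically-labelled, genomically adjacent bins.

    Returns (region_labels, block_ids) where a new block starts at every
    chromosome change, coordinate gap or unassigned bin; transitions are only
    counted between consecutive regions inside a block.
    """
    lab = track.labels
    n = len(lab)
    region_labels: list[int] = []
    block_ids: list[int] = []
    block = 0
    prev_lab = None
    prev_chrom = None
    prev_end = None
    for i in range(n):
        li = lab[i]
        adjacent = (
            prev_chrom == track.bin_chroms[i] and prev_end == track.bin_starts[i]
        )
        if li == UNASSIGNED:
            if prev_lab is not None:
                block += 1
            prev_lab = None
            prev_chrom = track.bin_chroms[i]
            prev_end = track.bin_ends[i]
            continue
        if not adjacent and prev_lab is not None:
            block += 1
            prev_lab = None
        if prev_lab is None or li != prev_lab:
            region_labels.append(int(li))
            block_ids.append(block)
            prev_lab = li
        prev_chrom = track.bin_chroms[i]
        prev_end = track.bin_ends[i]
    return np.asarray(region_labels, dtype=np.int64), np.asarray(block_ids, dtype=np.int64)


def _transition_freq(labels: np.ndarray, blocks: np.ndarray, r: int) -> np.ndarray:
    """f_AB: fraction of A-regions immediately followed by a B-region."""
    counts = np.zeros((r, r))
    totals = np.bincount(labels, minlength=r).astype(float)
    same_block = blocks[1:] == blocks[:-1]
    a = labels[:-1][same_block]
    b = labels[1:][same_block]
    np.add.at(counts, (a, b), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(totals[:, None] > 0, counts / np.maximum(totals[:, None], 1), np.nan)


def _remerge(labels: np.ndarray, blocks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse consecutive same-label regions within a block."""
    if len(labels) == 0:
        return labels, blocks
    keep = np.ones(len(labels), dtype=bool)
    keep[1:] = (labels[1:] != labels[:-1]) | (blocks[1:] != blocks[:-1])
    return labels[keep], blocks[keep]


def transition_enrichment(
    track: ProfileTrack,
    n_permutations: int = 100,
    seed: int = 0,
    mode: str = "region",
    log_base: str = "e",
) -> np.ndarray:
    """Log fold-change of observed over permuted profile-transition rates.

    Adjacent same-label bins are merged into regions; a transition A -> B is
    an A-region immediately followed (no gap, no unassigned bin, same
    chromosome) by a B-region. The null rate is the same statistic averaged
    over tracks whose region labels are permuted (label multiset preserved;
    ``mode="bin"`` permutes bin labels instead). Permuted sequences are
    re-merged so that, like the observed track, they contain no self
    transitions -- without this the null underestimates every cross rate and
    all log fold-changes inherit a positive bias. Cells where the null rate
    is zero come back NaN.
    """
    if mode not in ("region", "bin"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    r = track.n_profiles
    labels, blocks = _regions(track)
    if len(labels) < 2:
        return np.full((r, r), np.nan)
    f_obs = _transition_freq(labels, blocks, r)

    rng = np.random.default_rng(seed)
    acc = np.zeros((r, r))
    for _ in range(n_permutations):
        if mode == "region":
            perm = labels[rng.permutation(len(labels))]
            fp = _transition_freq(*_remerge(perm, blocks), r)
        else:
            shuffled = ProfileTrack(
                labels=track.labels[rng.permutation(track.n_bins)],
                weights=track.weights,
                rwc=track.rwc,
                bin_chroms=track.bin_chroms,
                bin_starts=track.bin_starts,
                bin_ends=track.bin_ends,
            )
            pl, pb = _regions(shuffled)
            fp = _transition_freq(pl, pb, r)
        acc += np.nan_to_num(fp)
    f_rand = acc / n_permutations

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = f_obs / f_rand
        out = np.where((f_rand > 0) & np.isfinite(f_obs), np.log(ratio), np.nan)
    if log_base == "2":
        out = out / np.log(2)
    elif log_base != "e":
        raise ValueError(f"unknown log base {log_base!r}")
    return out
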