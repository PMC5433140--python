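"""End-to-end pipeline: coverage -> filter -> transform -> NMF -> assignment.

Configuration is a plain dataclass validated up front and serialized (with a
hash) into every artifact's metadata, so a rerun with the same inputs, config
and seed reproduces the same numbers. Stages are resumable: an artifact whose
metadata carries the current config hash is reused instead of recomputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .coverage import (
    ConfigurationError,
    CoverageMatrix,
    expected_counts,
    load_reads,
    make_bins,
    normalized_coverage,
)
from .nmf import multirun, select_rank
from .profiles import UNASSIGNED, ProfileTrack, assign_profiles
from .signal import filter_significant_bins, sigmoid_transform

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "write_profile_track", "read_profile_track", "DEFAULT_PALETTE"]

# itemRgb palette keyed by canonical profile label
DEFAULT_PALETTE = {
    "ActProm": "144,238,144",  # light green
    "TxInit": "0,100,0",  # dark green
    "Ehn": "255,215,0",  # yellow
    "RegEl": "128,128,128",  # grey
    "GenBd": "220,20,60",  # red
    "RepChr": "128,0,128",  # purple
    "RepReg": "0,0,205",  # blue
}
_FALLBACK_RGB = "169,169,169"


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths."""

    out_dir: str
    reads: dict[str, list[str]] = field(default_factory=dict)  # mark -> BED paths
    chrom_sizes: str | None = None
    mappability: str | None = None
    matrix: str | None = None  # alternative entry point: precomputed matrix TSV
    bin_width: int = 200
    extension_bp: int = 200
    dedup: bool = True
    normalization_mode: str = "uniform"
    tail: float = 0.01
    percentile: float = 95.0
    rank: int | None = None  # fixed rank; None -> scan
    rank_range: tuple[int, int] = (3, 13)
    n_runs: int = 30
    random_repeats: int = 20
    sd_factor: float = 4.0
    max_iter: int = 2000
    tol: float = 1e-5
    seed: int = 0

    def validate(self) -> None:
        if not self.reads and self.matrix is None:
            raise ConfigurationError("need either read BED files or a matrix TSV")
        if self.reads and self.chrom_sizes is None:
            raise ConfigurationError("chrom_sizes is required with read input")
        if not (0 < self.tail < 1):
            raise ConfigurationError("tail must be in (0, 1)")
        if self.rank_range[0] < 2 or self.rank_range[1] < self.rank_range[0]:
            raise ConfigurationError(f"bad rank range {self.rank_range}")
        for mark, paths in self.reads.items():
            for p in paths:
                if not Path(p).exists():
                    raise ConfigurationError(f"missing input file for {mark!r}: {p}")
        for p in (self.chrom_sizes, self.mappability, self.matrix):
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"missing input file: {p}")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "rank_range" in data:
            data["rank_range"] = tuple(data["rank_range"])
        return cls(**data)


def _metadata(config: PipelineConfig) -> dict:
    return {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }


def _stage_done(path: Path, meta: dict) -> bool:
    if not path.exists():
        return False
    try:
        stored = json.loads(path.read_text())
        return stored.get("config_hash") == meta["config_hash"]
    except (json.JSONDecodeError, OSError):
        return False


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return a summary of artifacts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = _metadata(config)
    report: dict = {"artifacts": {}, **meta}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                res = fn()
            except Exception as exc:
                err = {"stage": name, "error": type(exc).__name__, "message": str(exc)}
                (out / "error.json").write_text(json.dumps(err, indent=2))
                raise
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return res

        return deco

    # --- coverage ---
    matrix_path = out / "matrix.tsv"

    @stage("coverage")
    def _coverage() -> CoverageMatrix:
        if config.matrix is not None:
            return CoverageMatrix.from_tsv(config.matrix, stage="raw")
        bins = make_bins(config.chrom_sizes, config.bin_width, config.mappability)
        samples = {
            mark: [
                load_reads(
                    p,
                    mark,
                    f"{mark}_rep{i + 1}",
                    chrom_sizes=bins.chrom_sizes,
                    dedup=config.dedup,
                    extension_bp=config.extension_bp,
                )
                for i, p in enumerate(paths)
            ]
            for mark, paths in config.reads.items()
        }
        tensor = expected_counts(bins, samples, mode=config.normalization_mode)
        V = normalized_coverage(tensor)
        V.to_tsv(matrix_path)
        return V

    V = _coverage

    # --- filter + transform ---
    @stage("filter")
    def _filter():
        Vf, pvals = filter_significant_bins(V, tail=config.tail)
        Vf.to_tsv(out / "matrix_filtered.tsv")
        return Vf

    Vf = _filter

    @stage("transform")
    def _transform():
        Vt = sigmoid_transform(Vf, percentile=config.percentile)
        Vt.to_tsv(out / "matrix_transformed.tsv")
        return Vt

    Vt = _transform

    # --- rank + factorization ---
    @stage("rank")
    def _rank() -> int:
        if config.rank is not None:
            return config.rank
        lo, hi = config.rank_range
        sel = select_rank(
            Vt,
            r_range=range(lo, hi + 1),
            n_runs=config.n_runs,
            random_repeats=config.random_repeats,
            sd_factor=config.sd_factor,
            seed=config.seed,
            max_iter=config.max_iter,
            tol=config.tol,
        )
        (out / "rank_selection.json").write_text(
            json.dumps(
                {
                    **meta,
                    "r_star": sel.r_star,
                    "r_star_rss": sel.r_star_rss,
                    "real_cophenetic": sel.real_cophenetic,
                    "random_mean": sel.random_mean,
                    "random_sd": sel.random_sd,
                },
                indent=2,
                default=float,
            )
        )
        if sel.r_star is None:
            raise RuntimeError("rank selection found no rank beating the null")
        return sel.r_star

    r = _rank

    @stage("factorize")
    def _factorize():
        best, stats = multirun(
            Vt,
            r,
            n_runs=config.n_runs,
            seed=config.seed,
            max_iter=config.max_iter,
            tol=config.tol,
        )
        np.savetxt(out / "W.tsv", best.W, delimiter="\t", fmt="%.9g")
        np.savetxt(out / "H.tsv", best.H, delimiter="\t", fmt="%.9g")
        (out / "consensus.json").write_text(
            json.dumps(
                {**meta, "r": r, "cophenetic": stats.cophenetic, "rss": stats.rss},
                indent=2,
            )
        )
        return best

    best = _factorize

    @stage("assign")
    def _assign() -> ProfileTrack:
        from .simulate import PROFILE_NAMES

        profile_names = PROFILE_NAMES[: r] if r <= len(PROFILE_NAMES) else None
        track = assign_profiles(
            best.W,
            bin_chroms=Vt.bin_chroms,
            bin_starts=Vt.bin_starts,
            bin_ends=Vt.bin_ends,
            profile_names=profile_names,
        )
        write_profile_track(track, out / "profiles.bed")
        return track

    track = _assign

    report["artifacts"] = {
        "matrix": str(matrix_path),
        "matrix_filtered": str(out / "matrix_filtered.tsv"),
        "matrix_transformed": str(out / "matrix_transformed.tsv"),
        "W": str(out / "W.tsv"),
        "H": str(out / "H.tsv"),
        "track": str(out / "profiles.bed"),
    }
    report["rank"] = int(r)
    report["n_bins_significant"] = int(Vf.n_bins)
    report["loss"] = float(best.loss)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def write_profile_track(
    track: ProfileTrack,
    path: str | Path,
    palette: dict[str, str] | None = None,
) -> None:
    """Serialize a profile track as BED9 with one record per merged region.

    Adjacent same-label bins merge into a single record; itemRgb comes from
    the palette keyed by profile name (unknown profiles get gray with a
    warning). Unassigned bins are not written.
    """
    palette = palette or DEFAULT_PALETTE
    warned: set[str] = set()
    with open(path, "w") as fh:
        fh.write(f'track name="chromnmf_profiles" itemRgb="On"\n')
        i = 0
        n = track.n_bins
        while i < n:
            lab = track.labels[i]
            if lab == UNASSIGNED:
                i += 1
                continue
            c = track.bin_chroms[i]
            start = track.bin_starts[i]
            end = track.bin_ends[i]
            j = i + 1
            while (
                j < n
                and track.labels[j] == lab
                and track.bin_chroms[j] == c
                and track.bin_starts[j] == end
            ):
                end = track.bin_ends[j]
                j += 1
            name = track.name_of(int(lab))
            rgb = palette.get(name)
            if rgb is None:
                if name not in warned:
                    logger.warning("no palette entry for profile %r; using gray", name)
                    warned.add(name)
                rgb = _FALLBACK_RGB
            fh.write(f"{c}\t{start}\t{end}\t{name}\t0\t.\t{start}\t{end}\t{rgb}\n")
            i = j


def read_profile_track(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read back a BED9 profile track as (chrom, start, end, label) records."""
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#", "browser")) or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            records.append((f[0], int(f[1]), int(f[2]), f[3]))
    return records
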