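"""Recurrent copy-number aberration regions and per-sample status.

The region caller is a deliberately simple recurrence scorer: the genome is
binned, each sample's log2 ratio is averaged (bp-overlap-weighted) per bin,
and a bin's amplification score is the cohort sum of excess over the +0.1
threshold (symmetrically for deletion below -0.1). Significance comes from
a cyclic-shift permutation null per sample, with Benjamini-Hochberg control
over bins. Externally computed region tables (e.g., GISTIC output) are
first-class input via :func:`read_region_table`.

A sample's aberration status over a region follows the log2-ratio rule:
overlap-weighted mean > 0.1 => amplified, < -0.1 => deleted; exactly at the
threshold counts as non-aberrated (strict inequalities).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._stats import bh_adjust
from .errors import ParseError, ValidationError
from .io_formats import Feature, Segment, provenance_line, segments_by_sample

logger = logging.getLogger(__name__)

__all__ = [
    "AberrationRegion",
    "RegionCallerConfig",
    "call_regions",
    "assign_status",
    "feature_centric_cn",
    "feature_centric_cn_matrix",
    "read_region_table",
    "write_region_table",
    "write_status_matrix",
    "AMP_THRESHOLD",
    "DEL_THRESHOLD",
]

AMP_THRESHOLD = 0.1
DEL_THRESHOLD = -0.1

ABERRATED = "aberrated"
NON_ABERRATED = "non_aberrated"


@dataclass
class AberrationRegion:
    """A recurrently aberrated interval with per-sample status."""

    region_id: str
    chrom: str
    start: int
    end: int
    direction: str  # "amp" | "del"
    score: float = float("nan")
    q_value: float = float("nan")
    status: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in ("amp", "del"):
            raise ValidationError(
                f"region {self.region_id}: direction must be 'amp' or 'del', "
                f"got {self.direction!r}"
            )
        if not self.start < self.end:
            raise ValidationError(f"region {self.region_id}: start must be < end")

    def aberrated_samples(self) -> list[str]:
        return [s for s, st in self.status.items() if st == ABERRATED]

    def non_aberrated_samples(self) -> list[str]:
        return [s for s, st in self.status.items() if st == NON_ABERRATED]


@dataclass(frozen=True)
class RegionCallerConfig:
    bin_size: int = 100_000
    amp_threshold: float = AMP_THRESHOLD
    del_threshold: float = DEL_THRESHOLD
    n_permutations: int = 500
    q_cutoff: float = 0.25
    min_region_bins: int = 1
    min_coverage_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.amp_threshold > 0 > self.del_threshold):
            raise ValidationError("need amp_threshold > 0 > del_threshold")
        if self.n_permutations < 100:
            raise ValidationError("n_permutations must be >= 100")
        if self.bin_size <= 0 or self.min_region_bins < 1:
            raise ValidationError("bin_size and min_region_bins must be positive")


def _bin_matrix(
    segs_by_sample: dict[str, list[Segment]], bin_size: int
) -> tuple[np.ndarray, list[str], list[tuple[str, int, int]]]:
    """Per-sample per-bin overlap-weighted mean log2 ratio (NaN = uncovered).

    Bins are laid per chromosome from the minimum covered start to the
    maximum covered end over the whole cohort.
    """
    samples = sorted(segs_by_sample)
    spans: dict[str, tuple[int, int]] = {}
    for segs in segs_by_sample.values():
        for s in segs:
            lo, hi = spans.get(s.chrom, (s.start, s.end))
            spans[s.chrom] = (min(lo, s.start), max(hi, s.end))
    bins: list[tuple[str, int, int]] = []
    for chrom in sorted(spans):
        lo, hi = spans[chrom]
        lo = (lo // bin_size) * bin_size
        for b in range(lo, hi, bin_size):
            bins.append((chrom, b, min(b + bin_size, hi)))
    bin_index: dict[str, list[int]] = {}
    for i, (chrom, _, _) in enumerate(bins):
        bin_index.setdefault(chrom, []).append(i)
    bin_starts = {c: bins[idx[0]][1] for c, idx in bin_index.items()}

    weighted = np.zeros((len(samples), len(bins)))
    weight = np.zeros_like(weighted)
    for si, sample in enumerate(samples):
        for seg in segs_by_sample[sample]:
            idx = bin_index.get(seg.chrom)
            if idx is None:
                continue
            first = idx[0] + (seg.start - bin_starts[seg.chrom]) // bin_size
            for bi in range(max(first, idx[0]), idx[-1] + 1):
                _, bstart, bend = bins[bi]
                if bstart >= seg.end:
                    break
                ov = min(seg.end, bend) - max(seg.start, bstart)
                if ov > 0:
                    weighted[si, bi] += ov * seg.log2_ratio
                    weight[si, bi] += ov
    with np.errstate(invalid="ignore"):
        x = weighted / weight
    x[weight == 0] = np.nan
    return x, samples, bins


def _direction_scores(x: np.ndarray, threshold: float, direction: str) -> np.ndarray:
    if direction == "amp":
        excess = np.clip(x - threshold, 0, None)
    else:
        excess = np.clip(threshold - x, 0, None)
    return np.nansum(excess, axis=0)


def call_regions(
    segments: list[Segment] | dict[str, list[Segment]],
    cfg: RegionCallerConfig = RegionCallerConfig(),
) -> list[AberrationRegion]:
    """Call recurrent amp/del regions by binned excess score + permutation null.

    Per direction, bin score ``G(b) = sum_s max(0, x_sb - t)`` (``t - x_sb``
    for deletions) where ``x_sb`` is sample ``s``'s overlap-weighted mean
    log2 ratio in bin ``b``. The null distribution is obtained by cyclically
    shifting each sample's genome-wide bin vector by an independent random
    offset, preserving each sample's marginal profile while destroying
    cross-sample alignment. Bins with BH q <= q_cutoff are merged when
    contiguous on one chromosome; runs shorter than ``min_region_bins`` are
    dropped. Amp and del are scored independently. Status is left empty
    (use :func:`assign_status`).
    """
    segs_by_sample = (
        segments if isinstance(segments, dict) else segments_by_sample(segments)
    )
    if len(segs_by_sample) < 2:
        raise ValidationError("region calling needs >= 2 samples")
    x, samples, bins = _bin_matrix(segs_by_sample, cfg.bin_size)
    n_samples, n_bins = x.shape
    covered = np.sum(~np.isnan(x), axis=0) >= cfg.min_coverage_fraction * n_samples
    if not covered.any():
        return []
    rng = np.random.default_rng(cfg.seed)

    regions: list[AberrationRegion] = []
    for direction, threshold in (("amp", cfg.amp_threshold), ("del", cfg.del_threshold)):
        if direction == "amp":
            contrib = np.clip(x - threshold, 0, None)
        else:
            contrib = np.clip(threshold - x, 0, None)
        contrib = np.nan_to_num(contrib, nan=0.0)
        obs = contrib.sum(axis=0)
        exceed = np.ones(n_bins, dtype=np.int64)  # +1 pseudo-count (obs itself)
        shifts = rng.integers(0, n_bins, size=(cfg.n_permutations, n_samples))
        base = np.arange(n_bins)
        for p in range(cfg.n_permutations):
            g = np.zeros(n_bins)
            for si in range(n_samples):
                g += contrib[si].take((base + shifts[p, si]) % n_bins)
            exceed += g >= obs
        pvals = exceed / (cfg.n_permutations + 1)
        qvals = np.full(n_bins, np.nan)
        qvals[covered] = bh_adjust(pvals[covered])
        sig = covered & (qvals <= cfg.q_cutoff) & (obs > 0)
        regions.extend(_merge_bins(sig, obs, qvals, bins, direction, cfg.min_region_bins))
    for i, r in enumerate(regions):
        r.region_id = f"{r.direction}_{r.chrom}_{i + 1}"
    return regions


def _merge_bins(sig, obs, qvals, bins, direction, min_region_bins):
    out = []
    i, n = 0, len(bins)
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and sig[j + 1] and bins[j + 1][0] == bins[i][0]:
            j += 1
        if j - i + 1 >= min_region_bins:
            chrom = bins[i][0]
            out.append(
                AberrationRegion(
                    region_id="pending",
                    chrom=chrom,
                    start=bins[i][1],
                    end=bins[j][2],
                    direction=direction,
                    score=float(np.max(obs[i : j + 1])),
                    q_value=float(np.min(qvals[i : j + 1])),
                )
            )
        i = j + 1
    return out


def _weighted_mean_over(
    chrom: str, start: int, end: int, segs: list[Segment]
) -> tuple[float, int]:
    total, weight = 0.0, 0
    for s in segs:
        if s.chrom != chrom:
            continue
        ov = min(s.end, end) - max(s.start, start)
        if ov > 0:
            total += ov * s.log2_ratio
            weight += ov
    return (total / weight if weight else float("nan")), weight


def assign_status(
    region: AberrationRegion,
    segments: list[Segment] | dict[str, list[Segment]],
    amp_threshold: float = AMP_THRESHOLD,
    del_threshold: float = DEL_THRESHOLD,
) -> AberrationRegion:
    """Fill per-sample aberration status for one region.

    A sample is ``aberrated`` iff its overlap-weighted mean log2 ratio over
    the region is strictly above ``amp_threshold`` (amp region) or strictly
    below ``del_threshold`` (del region). Samples with no overlapping
    segment are non-aberrated (logged).
    """
    segs_by_sample = (
        segments if isinstance(segments, dict) else segments_by_sample(segments)
    )
    status: dict[str, str] = {}
    n_uncovered = 0
    for sample, segs in segs_by_sample.items():
        mean, weight = _weighted_mean_over(region.chrom, region.start, region.end, segs)
        if weight == 0:
            n_uncovered += 1
            status[sample] = NON_ABERRATED
            continue
        if region.direction == "amp":
            status[sample] = ABERRATED if mean > amp_threshold else NON_ABERRATED
        else:
            status[sample] = ABERRATED if mean < del_threshold else NON_ABERRATED
    if n_uncovered == len(segs_by_sample):
        logger.warning(
            "region %s overlaps no segments in any sample; all non-aberrated",
            region.region_id,
        )
    elif n_uncovered:
        logger.info(
            "region %s: %d sample(s) without covering segments set non-aberrated",
            region.region_id, n_uncovered,
        )
    return replace(region, status=status)


def feature_centric_cn(
    feature: Feature,
    segments: list[Segment] | dict[str, list[Segment]],
    fill_value: float = 0.0,
) -> dict[str, float]:
    """Per-sample overlap-weighted mean log2 ratio over a feature's span.

    Samples whose segments do not reach the feature get ``fill_value``
    (default 0 = copy-neutral), logged.
    """
    segs_by_sample = (
        segments if isinstance(segments, dict) else segments_by_sample(segments)
    )
    out: dict[str, float] = {}
    n_fill = 0
    for sample, segs in segs_by_sample.items():
        mean, weight = _weighted_mean_over(feature.chrom, feature.start, feature.end, segs)
        if weight == 0:
            out[sample] = fill_value
            n_fill += 1
        else:
            out[sample] = mean
    if n_fill:
        logger.info(
            "feature %s: no segment overlap for %d sample(s); filled with %g",
            feature.feature_id, n_fill, fill_value,
        )
    return out


def feature_centric_cn_matrix(
    features: list[Feature],
    segments: list[Segment] | dict[str, list[Segment]],
    fill_value: float = 0.0,
) -> pd.DataFrame:
    """Vectorized :func:`feature_centric_cn` for many features at once.

    Returns a features x samples DataFrame of overlap-weighted mean log2
    ratios; zero-overlap cells get ``fill_value``.
    """
    segs_by_sample = (
        segments if isinstance(segments, dict) else segments_by_sample(segments)
    )
    samples = sorted(segs_by_sample)
    by_chrom: dict[str, list[Feature]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append(f)
    out = np.full((len(features), len(samples)), fill_value, dtype=float)
    row_of = {f.feature_id: i for i, f in enumerate(features)}
    for si, sample in enumerate(samples):
        chrom_segs: dict[str, list[Segment]] = {}
        for s in segs_by_sample[sample]:
            chrom_segs.setdefault(s.chrom, []).append(s)
        for chrom, feats in by_chrom.items():
            segs = chrom_segs.get(chrom)
            if not segs:
                continue
            s_start = np.array([s.start for s in segs])
            s_end = np.array([s.end for s in segs])
            s_val = np.array([s.log2_ratio for s in segs])
            f_start = np.array([f.start for f in feats])[:, None]
            f_end = np.array([f.end for f in feats])[:, None]
            ov = np.clip(np.minimum(f_end, s_end) - np.maximum(f_start, s_start), 0, None)
            w = ov.sum(axis=1)
            vals = np.where(w > 0, (ov * s_val).sum(axis=1) / np.where(w > 0, w, 1), fill_value)
            for f, v in zip(feats, vals):
                out[row_of[f.feature_id], si] = v
    return pd.DataFrame(out, index=[f.feature_id for f in features], columns=samples)


def read_region_table(path) -> list[AberrationRegion]:
    """Read an external region table (region_id, chrom, start, end, direction).

    Coordinates are taken as internal 0-based half-open. Optional score and
    q columns are honored; status is left empty.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = {str(c).strip().lower(): c for c in df.columns}
    needed = {"region_id", "chrom", "start", "end", "direction"}
    if not needed <= set(cols):
        raise ParseError(f"{path}: region table needs columns {sorted(needed)}")
    regions = []
    seen = set()
    for i, row in df.iterrows():
        direction = str(row[cols["direction"]]).strip().lower()
        if direction not in ("amp", "del"):
            raise ValidationError(
                f"{path}: row {i + 2}: unknown direction {direction!r} "
                "(accepted tokens: amp, del)"
            )
        region_id = str(row[cols["region_id"]])
        if region_id in seen:
            raise ValidationError(f"{path}: duplicate region_id {region_id!r}")
        seen.add(region_id)
        regions.append(
            AberrationRegion(
                region_id=region_id,
                chrom=str(row[cols["chrom"]]),
                start=int(row[cols["start"]]),
                end=int(row[cols["end"]]),
                direction=direction,
                score=float(row[cols["score"]]) if "score" in cols else float("nan"),
                q_value=float(row[cols["q"]]) if "q" in cols else float("nan"),
            )
        )
    return regions


def write_region_table(path, regions: list[AberrationRegion], context: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(provenance_line(context) + "\n")
        fh.write("region_id\tchrom\tstart\tend\tdirection\tscore\tq\n")
        for r in regions:
            fh.write(
                f"{r.region_id}\t{r.chrom}\t{r.start}\t{r.end}\t{r.direction}\t"
                f"{r.score:.6g}\t{r.q_value:.6g}\n"
            )


def write_status_matrix(path, regions: list[AberrationRegion], context: str = "") -> None:
    """Regions x samples 0/1 status matrix (1 = aberrated)."""
    samples = sorted({s for r in regions for s in r.status})
    with open(path, "w") as fh:
        fh.write(provenance_line(context) + "\n")
        fh.write("region_id\t" + "\t".join(samples) + "\n")
        for r in regions:
            row = "\t".join("1" if r.status.get(s) == ABERRATED else "0" for s in samples)
            fh.write(f"{r.region_id}\t{row}\n")
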