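"""Variant-blind scanning of pileups for biased regions.

Without foreknowledge of the donor's variants, reference bias still
leaves footprints in the pileup: excess read depth (collapsed repeats
accumulating reads), excess SNV density, and positions whose allele
profile is inconsistent with a diploid donor. Scan mode slides a window
over the pileup, computes the window means of these three measures
-- read depth (RD), variant density (VD) and non-diploidy (ND) -- turns
each into a Z score against a sampled baseline,

    Z(score) = (window_mean - sampled_mean) / sampled_std,

and combines them as

    bias_score = trunc(Z_RD, 1) + trunc(Z_VD, 0) + trunc(Z_ND, 0),

where trunc(x, t) = x if x >= t else 0 (only depth *excess* well above
baseline, and any above-baseline variant density or non-diploidy, count
as evidence). Windows with combined score >= 5 are biased, >= 3 and < 5
suspicious; qualifying windows are merged and nearby same-label regions
(within 1 kbp) chained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import PileupColumn, Region

__all__ = [
    "ScanConfig",
    "ColumnProfile",
    "WindowStats",
    "Baseline",
    "column_allele_profile",
    "columns_to_tracks",
    "estimate_baseline",
    "window_scores",
    "call_regions",
    "compare_workflows",
]

_STD_FLOOR = 1e-9


@dataclass
class ScanConfig:
    window_len: int = 400
    stride: int = 100
    allele_freq_threshold: float = 0.15
    dominance_ratio: float = 2.0
    biased_threshold: float = 5.0
    suspicious_threshold: float = 3.0
    chain_distance: int = 1000
    sample_fraction: float = 1 / 1000
    min_baseline_windows: int = 30
    improved_frac: float = 0.25
    well_covered_frac: float = 1 / 5
    low_depth_frac: float = 1 / 20

    def __post_init__(self) -> None:
        if not 0 < self.suspicious_threshold < self.biased_threshold:
            raise ValueError("need 0 < suspicious < biased thresholds")
        if self.stride > self.window_len:
            raise ValueError("stride must not exceed window_len")


@dataclass
class ColumnProfile:
    pos: int
    depth: int
    alleles: tuple[str, ...]
    is_snv: bool
    is_nondiploid: bool


@dataclass
class WindowStats:
    chrom: str
    start: int
    end: int  # 1-based inclusive
    rd: float
    vd: float
    nd: float
    z_rd: float = 0.0
    z_vd: float = 0.0
    z_nd: float = 0.0
    bias_score: float = 0.0
    truncated: bool = False


@dataclass
class Baseline:
    """Sampled means and stds of RD/VD/ND used for Z-scoring.

    Can be estimated from one pileup, jointly from two alignment
    workflows (half the sample from each, so both are scored on the same
    scale), or supplied by the user. Stds are floored at a tiny epsilon;
    a window exactly at a degenerate baseline mean scores Z = 0.
    """

    mean_rd: float
    std_rd: float
    mean_vd: float
    std_vd: float
    mean_nd: float
    std_nd: float
    provenance: str = "user"

    def z(self, which: str, value: float) -> float:
        mean = getattr(self, f"mean_{which}")
        std = max(getattr(self, f"std_{which}"), _STD_FLOOR)
        if value == mean:
            return 0.0
        return (value - mean) / std


def column_allele_profile(column: PileupColumn, config: Optional[ScanConfig] = None) -> ColumnProfile:
    """Allele profile of one pileup column.

    Bases above the 15% frequency threshold (of counted A/C/G/T bases)
    are alleles; >=2 alleles makes the position an SNV. The position is
    non-diploid when more than two alleles are present, or when two or
    more are present and the top allele is more than twice as frequent as
    the runner-up (a diploid HET should be near 50/50). A single-allele
    column carries no non-diploid evidence.
    """
    config = config or ScanConfig()
    counted = sum(column.base_counts.values())
    if counted == 0:
        return ColumnProfile(column.pos, column.depth, (), False, False)
    passing = sorted(
        (b for b, c in column.base_counts.items() if c / counted > config.allele_freq_threshold),
        key=lambda b: (-column.base_counts[b], b),
    )
    is_snv = len(passing) >= 2
    nondip = len(passing) > 2
    if not nondip and len(passing) == 2:
        top, second = (column.base_counts[b] for b in passing[:2])
        nondip = top > config.dominance_ratio * second
    return ColumnProfile(column.pos, column.depth, tuple(passing), is_snv, nondip)


def columns_to_tracks(
    columns: Iterable[PileupColumn], config: Optional[ScanConfig] = None
) -> tuple[str, int, np.ndarray, np.ndarray, np.ndarray]:
    """Densify pileup columns into per-position arrays.

    Returns (chrom, start_pos, depth, is_snv, is_nondiploid) with one
    entry per reference position from the first to the last column;
    positions absent from the pileup have zero depth and no flags.
    """
    config = config or ScanConfig()
    cols = list(columns)
    if not cols:
        raise ValueError("empty pileup")
    chrom = cols[0].chrom
    start, end = cols[0].pos, cols[-1].pos
    n = end - start + 1
    depth = np.zeros(n)
    snv = np.zeros(n, dtype=bool)
    nondip = np.zeros(n, dtype=bool)
    for col in cols:
        if col.chrom != chrom:
            raise ValueError("columns_to_tracks expects a single chromosome")
        prof = column_allele_profile(col, config)
        i = col.pos - start
        depth[i] = col.depth
        snv[i] = prof.is_snv
        nondip[i] = prof.is_nondiploid
    return chrom, start, depth, snv, nondip


def _window_means(
    depth: np.ndarray, snv: np.ndarray, nondip: np.ndarray, s: int, e: int
) -> tuple[float, float, float]:
    sl = slice(s, e)
    return float(depth[sl].mean()), float(snv[sl].mean()), float(nondip[sl].mean())


def estimate_baseline(
    sources: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
    config: Optional[ScanConfig] = None,
    seed: int = 0,
) -> Baseline:
    """Estimate RD/VD/ND means and stds from randomly sampled windows.

    The sampled-window count is sample_fraction of the possible window
    starts, floored at min_baseline_windows (and capped at the number of
    possible windows). With two sources -- two alignment workflows over
    the same reference -- half the sample is drawn from each, yielding
    one joint baseline so both scans share a scoring scale.
    """
    config = config or ScanConfig()
    if not sources:
        raise ValueError("estimate_baseline needs at least one pileup source")
    rng = np.random.default_rng(seed)
    rds: list[float] = []
    vds: list[float] = []
    nds: list[float] = []
    for depth, snv, nondip in sources:
        n_possible = len(depth) - config.window_len + 1
        if n_possible < 1:
            raise ValueError("source shorter than one window")
        want = max(config.min_baseline_windows, int(n_possible * config.sample_fraction))
        want = min(want, n_possible)
        want = max(1, want // len(sources) if len(sources) > 1 else want)
        starts = rng.choice(n_possible, size=want, replace=n_possible < want)
        for s in np.sort(starts):
            rd, vd, nd = _window_means(depth, snv, nondip, int(s), int(s) + config.window_len)
            rds.append(rd)
            vds.append(vd)
            nds.append(nd)
    if not rds:
        raise ValueError("no windows sampled")
    prov = "joint" if len(sources) > 1 else "sampled"
    return Baseline(
        mean_rd=float(np.mean(rds)),
        std_rd=float(np.std(rds)),
        mean_vd=float(np.mean(vds)),
        std_vd=float(np.std(vds)),
        mean_nd=float(np.mean(nds)),
        std_nd=float(np.std(nds)),
        provenance=f"{prov} (n={len(rds)}, seed={seed})",
    )


def _trunc(x: float, t: float) -> float:
    return x if x >= t else 0.0


def window_scores(
    chrom: str,
    start: int,
    depth: np.ndarray,
    snv: np.ndarray,
    nondip: np.ndarray,
    baseline: Baseline,
    config: Optional[ScanConfig] = None,
) -> list[WindowStats]:
    """Slide the window over the tracks and score each placement.

    RD is the window mean depth; VD and ND are the window fractions of
    SNV / non-diploid positions (depth- and length-invariant). A final
    shorter-than-window placement at the data's edge is scored over the
    remaining positions and flagged truncated.
    """
    config = config or ScanConfig()
    n = len(depth)
    out: list[WindowStats] = []
    s = 0
    while s < n:
        e = min(s + config.window_len, n)
        truncated = e - s < config.window_len
        rd, vd, nd = _window_means(depth, snv, nondip, s, e)
        w = WindowStats(
            chrom=chrom,
            start=start + s,
            end=start + e - 1,
            rd=rd,
            vd=vd,
            nd=nd,
            z_rd=baseline.z("rd", rd),
            z_vd=baseline.z("vd", vd),
            z_nd=baseline.z("nd", nd),
            truncated=truncated,
        )
        w.bias_score = _trunc(w.z_rd, 1.0) + _trunc(w.z_vd, 0.0) + _trunc(w.z_nd, 0.0)
        out.append(w)
        if truncated or e == n:
            break
        s += config.stride
    return out


def call_regions(
    window_stats: Sequence[WindowStats], config: Optional[ScanConfig] = None
) -> list[Region]:
    """Call biased/suspicious regions from scored windows.

    Windows with bias_score >= biased_threshold are biased; scores in
    [suspicious, biased) are suspicious. Overlapping or book-ended
    qualifying windows of the same label merge (region extent is the
    union of qualifying windows); same-label regions within
    chain_distance then chain into one. The region score is the maximum
    window score. Idempotent at the region level.
    """
    config = config or ScanConfig()
    regions: list[Region] = []
    for label, lo, hi in (
        ("biased", config.biased_threshold, float("inf")),
        ("suspicious", config.suspicious_threshold, config.biased_threshold),
    ):
        qualifying = [w for w in window_stats if lo <= w.bias_score < hi]
        merged: list[Region] = []
        for w in sorted(qualifying, key=lambda w: (w.chrom, w.start)):
            if (
                merged
                and merged[-1].chrom == w.chrom
                and w.start <= merged[-1].end + 1
            ):
                merged[-1].end = max(merged[-1].end, w.end)
                merged[-1].score = max(merged[-1].score, w.bias_score)
            else:
                merged.append(Region(w.chrom, w.start, w.end, label, w.bias_score))
        chained: list[Region] = []
        for r in merged:
            if (
                chained
                and chained[-1].chrom == r.chrom
                and r.start - chained[-1].end - 1 <= config.chain_distance
            ):
                chained[-1].end = max(chained[-1].end, r.end)
                chained[-1].score = max(chained[-1].score, r.score)
            else:
                chained.append(r)
        regions.extend(chained)
    return sorted(regions, key=lambda r: (r.chrom, r.start))


def compare_workflows(
    regions_a: Sequence[Region],
    regions_b: Sequence[Region],
    depth_b: np.ndarray,
    start_b: int,
    overall_mean_depth_b: float,
    config: Optional[ScanConfig] = None,
) -> list[tuple[Region, str]]:
    """Judge whether workflow B improves each region called biased in A.

    Both scans must have used the same joint baseline. A region is
    "improved" when at least 25% of its bases in B are simultaneously
    well covered (depth above 1/5 of B's overall mean) and outside B's
    biased regions; regions with near-zero depth in B (mean below 1/20 of
    B's overall mean) are excluded as uninterpretable.
    """
    config = config or ScanConfig()
    biased_b = [r for r in regions_b if r.label == "biased"]
    verdicts: list[tuple[Region, str]] = []
    for region in (r for r in regions_a if r.label == "biased"):
        lo = region.start - start_b
        hi = region.end - start_b + 1
        lo_c, hi_c = max(lo, 0), min(hi, len(depth_b))
        if lo_c >= hi_c:
            verdicts.append((region, "low_depth"))
            continue
        d = depth_b[lo_c:hi_c]
        if d.mean() < config.low_depth_frac * overall_mean_depth_b:
            verdicts.append((region, "low_depth"))
            continue
        covered = d > config.well_covered_frac * overall_mean_depth_b
        unbiased = np.ones(hi_c - lo_c, dtype=bool)
        for rb in biased_b:
            if rb.chrom != region.chrom:
                continue
            s = max(rb.start - start_b, lo_c) - lo_c
            e = min(rb.end - start_b + 1, hi_c) - lo_c
            if s < e:
                unbiased[s:e] = False
        frac = float((covered & unbiased).mean())
        verdicts.append((region, "improved" if frac >= config.improved_frac else "not_improved"))
    return verdicts
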