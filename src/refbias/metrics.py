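"""Allelic-balance measures and bias-event classification.

Three balances are measured per HET site, each as REF/(REF+ALT):

* SB (simulation balance)  -- from simulated reads' true origins;
* MB (mapping balance)     -- truth-restricted, post-alignment: only reads
  that both truly originated overlapping the site and aligned overlapping
  it; mismapped arrivals are excluded;
* AB (assignment balance)  -- from an assignment algorithm's REF/ALT calls
  (BOTH and OTHER reads excluded); the only one computable on real reads.

The derived coordinates NMB = MB - SB and NAB = AB - SB place each site
on a plane where bias events separate geometrically: balanced sites sit
in a radius-0.1 circle at the origin, loss events along the diagonal
wedge (slopes 1/2..2), flux/local events displaced vertically
(distinguished by the mismapped-read count), and outliers elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .assign import SiteEvidence
from .io import AlignedRead
from .sim import SimRead
from .variants import HetSite

__all__ = [
    "ClassifierConfig",
    "BalanceRecord",
    "simulation_balance",
    "mapping_balance",
    "assignment_balance",
    "categorize_site",
    "collapse_to_binary",
    "bias_by_length",
    "records_to_frame",
]

CATEGORIES = ("balanced", "loss", "flux", "local", "outlier", "unclassifiable")


@dataclass
class ClassifierConfig:
    balanced_radius: float = 0.1
    wedge_slope: float = 2.0  # with its reciprocal bounding the loss wedge
    mismap_threshold: int = 5  # flux requires more than this many mismapped reads
    #: which axis bounds the flux/local (blue) region; "nab" is the reading
    #: consistent with the vertical flux/local clusters, "nmb" the literal
    #: figure-caption alternative.
    blue_region_axis: str = "nab"

    def __post_init__(self) -> None:
        if not 0 < self.balanced_radius < 1:
            raise ValueError("balanced_radius must be in (0, 1)")
        if self.wedge_slope <= 1:
            raise ValueError("wedge_slope must exceed 1")
        if self.blue_region_axis not in ("nab", "nmb"):
            raise ValueError("blue_region_axis must be 'nab' or 'nmb'")


@dataclass
class BalanceRecord:
    site: HetSite
    SB: Optional[float]
    MB: Optional[float]
    AB: Optional[float]
    n_mismapped: int = 0
    mean_mapq: float = 0.0
    category: str = "unclassifiable"

    @property
    def NMB(self) -> Optional[float]:
        if self.MB is None or self.SB is None:
            return None
        return self.MB - self.SB

    @property
    def NAB(self) -> Optional[float]:
        if self.AB is None or self.SB is None:
            return None
        return self.AB - self.SB


def _ratio(n_ref: int, n_alt: int) -> Optional[float]:
    total = n_ref + n_alt
    return n_ref / total if total else None


def simulation_balance(site: HetSite, sim_reads: Iterable[SimRead]) -> Optional[float]:
    """REF/(REF+ALT) over simulated reads whose true interval overlaps the
    site footprint; undefined (None) with no overlapping reads."""
    fs, fe = site.variant.footprint
    ref_hap = site.variant.ref_hap() + 1
    n_ref = n_alt = 0
    for r in sim_reads:
        if r.ref_interval is None:
            continue
        if r.ref_interval[0] <= fe and r.ref_interval[1] >= fs:
            if r.hap_index == ref_hap:
                n_ref += 1
            else:
                n_alt += 1
    return _ratio(n_ref, n_alt)


def mapping_balance(site: HetSite, aligned_reads: Iterable[AlignedRead]) -> Optional[float]:
    """Balance over reads that truly originated overlapping the site AND
    aligned overlapping it; mismapped arrivals are not counted."""
    fs, fe = site.variant.footprint
    ref_hap = site.variant.ref_hap() + 1
    n_ref = n_alt = 0
    for r in aligned_reads:
        if r.truth is None:
            continue
        if not r.truth.overlaps(site.chrom, fs, fe):
            continue
        if not (r.chrom == site.chrom and r.overlaps(fs, fe)):
            continue
        if r.truth.hap_index == ref_hap:
            n_ref += 1
        else:
            n_alt += 1
    return _ratio(n_ref, n_alt)


def assignment_balance(evidence: SiteEvidence) -> Optional[float]:
    """AB = n_ref/(n_ref + n_alt); BOTH and OTHER reads are excluded."""
    return _ratio(evidence.n_ref, evidence.n_alt)


def categorize_site(
    record: BalanceRecord, config: Optional[ClassifierConfig] = None
) -> str:
    """Classify one site by its position in the NMB-NAB plane.

    Rule order (ties resolve toward the earlier rule):
      1. inside the radius-r circle at the origin        -> balanced
      2. in the diagonal wedge (same signs, |NMB|/2 <= |NAB| <= 2|NMB|)
                                                         -> loss
      3. |NAB| > r: flux if n_mismapped > threshold else -> local
      4. otherwise                                       -> outlier
    Undefined measures give "unclassifiable".
    """
    config = config or ClassifierConfig()
    nmb, nab = record.NMB, record.NAB
    if nmb is None or nab is None:
        return "unclassifiable"
    r = config.balanced_radius
    if math.hypot(nmb, nab) <= r:
        return "balanced"
    s = config.wedge_slope
    same_sign = (nmb > 0 and nab > 0) or (nmb < 0 and nab < 0)
    if same_sign and abs(nmb) / s <= abs(nab) <= abs(nmb) * s:
        return "loss"
    blue = abs(nab) if config.blue_region_axis == "nab" else abs(nmb)
    if blue > r:
        return "flux" if record.n_mismapped > config.mismap_threshold else "local"
    return "outlier"


def collapse_to_binary(category: str) -> Optional[str]:
    """Collapse the event categories to balanced/biased for evaluation.

    Returns None for unclassifiable sites (excluded from evaluation)."""
    if category == "balanced":
        return "balanced"
    if category in ("loss", "flux", "local", "outlier"):
        return "biased"
    return None


def build_records(
    sites: Sequence[HetSite],
    evidence: dict[int, SiteEvidence],
    sim_reads: Optional[Sequence[SimRead]] = None,
    aligned_reads: Optional[Sequence[AlignedRead]] = None,
    config: Optional[ClassifierConfig] = None,
) -> list[BalanceRecord]:
    """Assemble and classify BalanceRecords for all non-disregarded sites.

    Indexes reads by coordinate once so per-site lookups stay cheap.
    """
    from .assign import ReadIndex

    sim_index = _SimIndex(sim_reads) if sim_reads is not None else None
    aln_index = ReadIndex(aligned_reads) if aligned_reads is not None else None
    records = []
    for site in sites:
        if site.disregarded:
            continue
        ev = evidence.get(site.pos)
        if ev is None:
            continue
        sb = mb = None
        if sim_index is not None:
            sb = simulation_balance(site, sim_index.overlapping(*site.variant.footprint))
        if aln_index is not None:
            mb = mapping_balance(site, aln_index.overlapping(*site.variant.footprint))
        rec = BalanceRecord(
            site=site,
            SB=sb,
            MB=mb,
            AB=assignment_balance(ev),
            n_mismapped=ev.n_mismapped,
            mean_mapq=ev.mean_mapq,
        )
        rec.category = categorize_site(rec, config)
        records.append(rec)
    return records


class _SimIndex:
    """Coordinate index over simulated reads (by true reference interval)."""

    def __init__(self, reads: Sequence[SimRead]):
        placed = [r for r in reads if r.ref_interval is not None]
        self._reads = sorted(placed, key=lambda r: r.ref_interval[0])
        self._starts = [r.ref_interval[0] for r in self._reads]
        self._max_span = max(
            (r.ref_interval[1] - r.ref_interval[0] + 1 for r in self._reads), default=0
        )

    def overlapping(self, start: int, end: int) -> list[SimRead]:
        from bisect import bisect_left, bisect_right

        lo = bisect_left(self._starts, start - self._max_span)
        hi = bisect_right(self._starts, end)
        return [r for r in self._reads[lo:hi] if r.ref_interval[1] >= start]


def records_to_frame(records: Sequence[BalanceRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "chrom": r.site.chrom,
                "pos": r.site.pos,
                "ref": r.site.variant.ref_allele,
                "alt": r.site.variant.alt_allele,
                "length_delta": r.site.variant.length_delta,
                "SB": r.SB,
                "MB": r.MB,
                "AB": r.AB,
                "NMB": r.NMB,
                "NAB": r.NAB,
                "n_mismapped": r.n_mismapped,
                "mean_mapq": r.mean_mapq,
                "category": r.category,
            }
        )
    return pd.DataFrame(rows)


def bias_by_length(
    records: Sequence[BalanceRecord],
    measures: Sequence[str] = ("SB", "MB", "AB"),
    normalize: bool = False,
    clamp: int = 25,
) -> pd.DataFrame:
    """Bias-by-allele-length summary (median and quartiles of ALT fraction).

    The ALT fraction is 1 - balance (putting ALT in the numerator, the
    convention of bias-by-length plots). Variant lengths beyond +/-clamp
    collapse into the extreme strata; 0 is SNVs. With ``normalize`` the
    per-stratum median SB ALT fraction is subtracted from every measure.
    Empty strata are omitted.
    """
    df = records_to_frame(records)
    if df.empty:
        return pd.DataFrame(
            columns=["stratum", "measure", "median", "q1", "q3", "n_sites"]
        )
    df["stratum"] = df["length_delta"].clip(-clamp, clamp)
    rows = []
    for stratum, grp in df.groupby("stratum"):
        sb_alt_median = (1.0 - grp["SB"].dropna()).median() if "SB" in grp else np.nan
        for measure in measures:
            vals = (1.0 - grp[measure].dropna()).to_numpy()
            if vals.size == 0:
                continue
            if normalize and np.isfinite(sb_alt_median):
                vals = vals - sb_alt_median
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append(
                {
                    "stratum": int(stratum),
                    "measure": measure,
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "n_sites": int(vals.size),
                }
            )
    return pd.DataFrame(rows)
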