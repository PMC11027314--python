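"""Read-to-haplotype assignment at HET sites.

Two algorithms:

* naive -- trusts the aligner: extracts the read bases aligned to the
  variant's exact reference coordinates via a CIGAR walk and requires an
  exact allele match. Sensitive to the aligner's gap placement.
* context-aware -- ignores the aligner's base-level decisions and scans
  the read sequence for the REF/ALT allelic context sequences (exact
  match only). Reads that truncate a context are matched by an
  end-anchored prefix/suffix, equivalent to anchoring the comparison
  window at the left or right variant boundary; a read that cannot cover
  the whole effective variant is called BOTH, and cohort-level matching
  takes precedence over single-variant matching.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

from .io import AlignedRead
from .variants import AssignmentConfig, Cohort, HetSite

__all__ = [
    "AlleleCall",
    "SiteEvidence",
    "assign_read_naive",
    "assign_read_context",
    "assign_read_cohort",
    "tally_site",
    "tally_sites",
    "ReadIndex",
]


class AlleleCall(Enum):
    REF = "REF"
    ALT = "ALT"
    BOTH = "BOTH"
    OTHER = "OTHER"


@dataclass
class SiteEvidence:
    """Per-site assignment tallies.

    ``n_mismapped`` counts overlapping reads whose simulation truth places
    them elsewhere (available only with truth tags); ``mean_mapq`` averages
    over *all* overlapping reads regardless of call, since mapping quality
    characterizes the locus rather than the called subset.
    """

    site: HetSite
    n_ref: int = 0
    n_alt: int = 0
    n_both: int = 0
    n_other: int = 0
    n_mismapped: int = 0
    mean_mapq: float = 0.0

    @property
    def n_overlapping(self) -> int:
        return self.n_ref + self.n_alt + self.n_both + self.n_other


# ---------------------------------------------------------------------------
# naive assignment


def assign_read_naive(site: HetSite, read: AlignedRead) -> AlleleCall:
    """Assign by the bases the aligner placed at the variant's coordinates.

    Extracts the read bases aligned to the REF-allele footprint (plus any
    insertion anchored inside it) and demands an exact match to REF or
    ALT; anything else -- sequencing errors, or a gap placed differently
    from the VCF -- is OTHER. Never emits BOTH.
    """
    v = site.variant
    fs, fe = v.footprint
    if read.pos > fs or read.end < fe:
        return AlleleCall.OTHER  # does not align across the full footprint
    out: list[str] = []
    ref = read.pos
    q = 0
    for op, ln in read.cigar:
        if op == "M":
            lo = max(ref, fs)
            hi = min(ref + ln - 1, fe)
            if lo <= hi:
                out.append(read.sequence[q + (lo - ref) : q + (hi - ref) + 1])
            ref += ln
            q += ln
        elif op == "I":
            # insertion anchored after reference base ref-1
            if fs <= ref - 1 <= fe:
                out.append(read.sequence[q : q + ln])
            q += ln
        elif op == "D":
            ref += ln
        elif op == "S":
            q += ln
        if ref > fe and op in "MD":
            pass  # keep walking; later I ops cannot anchor inside the footprint
    extracted = "".join(out)
    if extracted == v.ref_allele:
        return AlleleCall.REF
    if extracted == v.alt_allele:
        return AlleleCall.ALT
    return AlleleCall.OTHER


# ---------------------------------------------------------------------------
# context-aware assignment


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


_FULL = 3
_DECISIVE = 2
_PARTIAL = 1
_ABSENT = 0


def _match_context(seq: str, ctx: str, other: str, lf: int, rf: int) -> int:
    """How strongly a context occurs in a read.

    Returns 3 (full) when the entire context occurs in the read. Returns
    2 (decisive) when a truncated context occurs at a read end -- a
    prefix of the context at the read's right end (read truncated on the
    right, window anchored at the left variant boundary) or a suffix at
    the read's left end (anchored at the right boundary) -- that covers
    the whole anchored-side flank plus at least one allele base AND
    extends past the point where this context diverges from the other
    one. The divergence requirement is what enforces effective-variant
    coverage in repeat regions: there the two contexts share a long
    prefix, so only a read reaching through the whole repeat tract can
    decide. A read tail matching only the shared portion of the two
    contexts supports neither allele over the other: that is a partial
    (1). Returns 0 when no end-anchored overlap reaching through the
    anchored flank exists. Full matches outrank end-anchored ones so a
    coincidental few-base collision at a read end cannot override an
    exact context occurrence elsewhere in the read.
    """
    if ctx in seq:
        return _FULL
    top = min(len(ctx) - 1, len(seq))
    best = _ABSENT
    # read right-truncated: prefix of ctx at end of read
    cp = _common_prefix_len(ctx, other)
    min_pref = max(lf + 1, cp + 1)
    for k in range(top, max(lf, 1) - 1, -1):
        if seq.endswith(ctx[:k]):
            if k >= min_pref:
                return _DECISIVE
            best = _PARTIAL
            break
    # read left-truncated: suffix of ctx at start of read
    cs = _common_prefix_len(ctx[::-1], other[::-1])
    min_suf = max(rf + 1, cs + 1)
    for k in range(top, max(rf, 1) - 1, -1):
        if seq.startswith(ctx[-k:]):
            if k >= min_suf:
                return _DECISIVE
            best = max(best, _PARTIAL)
            break
    return best


def _spans_effective(site: HetSite, read: AlignedRead) -> bool:
    return read.pos <= site.eff_start and read.end >= site.eff_end


def assign_read_context(
    site: HetSite, read: AlignedRead, config: Optional[AssignmentConfig] = None
) -> AlleleCall:
    """Assign a read by scanning its sequence for the allelic contexts.

    Both contexts found decisively (or the read unable to span the
    effective variant, or only an ambiguous end-anchored partial
    present) -> BOTH; exactly one decisive -> that allele; neither
    found at all, despite the read spanning the effective variant ->
    OTHER (sequencing errors broke every match). Gap placement cannot
    affect the result because only the read sequence is examined.
    """
    if site.disregarded:
        raise ValueError("disregarded sites produce no evidence")
    ref_m = _match_context(read.sequence, site.ref_context, site.alt_context, *site.flanks_ref)
    alt_m = _match_context(read.sequence, site.alt_context, site.ref_context, *site.flanks_alt)
    if ref_m >= _DECISIVE and ref_m > alt_m:
        return AlleleCall.REF
    if alt_m >= _DECISIVE and alt_m > ref_m:
        return AlleleCall.ALT
    if max(ref_m, alt_m) >= _PARTIAL:
        return AlleleCall.BOTH
    return AlleleCall.OTHER if _spans_effective(site, read) else AlleleCall.BOTH


def assign_read_cohort(cohort: Cohort, read: AlignedRead) -> Optional[int]:
    """Match a read against the cohort's combined haplotype strings.

    Returns the matching haplotype index (0/1) when exactly one combined
    string occurs in the read, else None (ambiguous or no match -- the
    caller falls back to variant-by-variant assignment).
    """
    h0 = cohort.hap_strings[0] in read.sequence
    h1 = cohort.hap_strings[1] in read.sequence
    if h0 == h1:
        return None
    return 0 if h0 else 1


# ---------------------------------------------------------------------------
# tallying


class ReadIndex:
    """Coordinate index over reads for fast interval overlap queries."""

    def __init__(self, reads: Sequence[AlignedRead]):
        self._reads = sorted(reads, key=lambda r: r.pos)
        self._starts = [r.pos for r in self._reads]
        self._max_span = max((r.end - r.pos + 1 for r in self._reads), default=0)

    def overlapping(self, start: int, end: int) -> list[AlignedRead]:
        lo = bisect_left(self._starts, start - self._max_span)
        hi = bisect_right(self._starts, end)
        return [r for r in self._reads[lo:hi] if r.end >= start]


def _mismapped(site: HetSite, read: AlignedRead) -> bool:
    t = read.truth
    if t is None:
        return False
    return not t.overlaps(site.chrom, site.eff_start, site.eff_end)


def tally_site(
    site: HetSite,
    reads: Iterable[AlignedRead],
    method: str = "context",
    config: Optional[AssignmentConfig] = None,
    cohort_calls: Optional[dict[str, AlleleCall]] = None,
) -> SiteEvidence:
    """Tally assignment calls over all reads overlapping the effective
    interval. ``cohort_calls`` (read_id -> call) take precedence over
    per-variant calls when supplied."""
    ev = SiteEvidence(site=site)
    mapqs: list[int] = []
    for read in reads:
        if not read.overlaps(site.eff_start, site.eff_end):
            continue
        mapqs.append(read.mapq)
        if _mismapped(site, read):
            ev.n_mismapped += 1
        if cohort_calls is not None and read.read_id in cohort_calls:
            call = cohort_calls[read.read_id]
        elif method == "naive":
            call = assign_read_naive(site, read)
        else:
            call = assign_read_context(site, read, config)
        if call is AlleleCall.REF:
            ev.n_ref += 1
        elif call is AlleleCall.ALT:
            ev.n_alt += 1
        elif call is AlleleCall.BOTH:
            ev.n_both += 1
        else:
            ev.n_other += 1
    ev.mean_mapq = sum(mapqs) / len(mapqs) if mapqs else 0.0
    return ev


def tally_sites(
    sites: Sequence[HetSite],
    cohorts: Sequence[Cohort],
    reads: Sequence[AlignedRead],
    method: str = "context",
    config: Optional[AssignmentConfig] = None,
) -> dict[int, SiteEvidence]:
    """Tally every non-disregarded site, cohort-first for the context method.

    Returns a dict keyed by variant position. For multi-variant cohorts a
    read matching an entire combined haplotype string is tallied for all
    member sites; other reads fall back to single-variant assignment.
    """
    index = ReadIndex(reads)
    out: dict[int, SiteEvidence] = {}
    for cohort in cohorts:
        cohort_calls: Optional[dict[str, AlleleCall]] = None
        if method == "context" and len(cohort.members) > 1:
            cohort_calls = {}
            for read in index.overlapping(cohort.start, cohort.end):
                hap = assign_read_cohort(cohort, read)
                if hap is not None:
                    cohort_calls[read.read_id] = hap
        for site in cohort.members:
            if site.disregarded:
                continue
            per_site_calls = None
            if cohort_calls is not None:
                per_site_calls = {
                    rid: AlleleCall[cohort.member_call(hap, site)]
                    for rid, hap in cohort_calls.items()
                }
            out[site.pos] = tally_site(
                site,
                index.overlapping(site.eff_start, site.eff_end),
                method=method,
                config=config,
                cohort_calls=per_site_calls,
            )
    return out
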