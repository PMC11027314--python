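"""HET-site preparation for read-to-haplotype assignment.

Selects heterozygous sites, removes interdependent (overlapping) variants,
builds phased allelic context sequences (allele + flanking bases drawn from
the same haplotype), extends variants across tandem repeats into
"effective variants", and clusters nearby variants into cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io import PhasedVariant

__all__ = [
    "AssignmentConfig",
    "HetSite",
    "Cohort",
    "select_het_sites",
    "remove_overlapping",
    "build_context",
    "extend_effective",
    "build_cohorts",
    "prepare_sites",
]


@dataclass
class AssignmentConfig:
    flank_len: int = 5
    cohort_distance: int = 25
    effective_len_limit: int = 70
    mapq_max: int = 42

    def __post_init__(self) -> None:
        for name in ("flank_len", "cohort_distance", "effective_len_limit", "mapq_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class HetSite:
    """A HET variant prepared for assignment.

    ``ref_context``/``alt_context`` are the allelic context sequences:
    flank_len bases of the allele-carrying haplotype on each side of the
    (possibly repeat-extended) allele. ``eff_start``/``eff_end`` bound the
    effective variant on the reference; the contexts additionally carry the
    flanks outside that interval. ``flanks`` records the realized
    (left, right) flank lengths per context (they can be truncated at
    contig ends).
    """

    variant: PhasedVariant
    ref_context: str = ""
    alt_context: str = ""
    flanks_ref: tuple[int, int] = (0, 0)
    flanks_alt: tuple[int, int] = (0, 0)
    eff_start: int = 0
    eff_end: int = 0
    extended_side: str = "none"  # none | left | right
    disregarded: bool = False
    truncated_flanks: bool = False
    cohort_id: Optional[int] = None

    @property
    def chrom(self) -> str:
        return self.variant.chrom

    @property
    def pos(self) -> int:
        return self.variant.pos

    def eff_allele_len(self, which: str) -> int:
        ctx, (lf, rf) = (
            (self.ref_context, self.flanks_ref)
            if which == "ref"
            else (self.alt_context, self.flanks_alt)
        )
        return len(ctx) - lf - rf


@dataclass
class Cohort:
    """A cluster of nearby phased variants assigned jointly.

    ``hap_strings`` are the two combined haplotype strings over the cohort's
    reference interval plus flank_len anchor bases on each end; a read
    matching haplotype h supports, for each member, whichever of REF/ALT
    that member carries on haplotype h.
    """

    members: list[HetSite]
    start: int  # reference interval spanned by member footprints
    end: int
    hap_strings: tuple[str, str] = ("", "")

    def member_call(self, hap_index: int, member: HetSite) -> str:
        """'REF' or 'ALT' supported at ``member`` by a read matching hap ``hap_index`` (0/1)."""
        return "REF" if member.variant.genotype[hap_index] == 0 else "ALT"


def select_het_sites(variants: Sequence[PhasedVariant]) -> list[HetSite]:
    """Wrap usable HET variants as HetSites (contexts not yet built)."""
    return [HetSite(variant=v) for v in variants if v.usable and v.is_het]


def remove_overlapping(
    variants: Sequence[PhasedVariant],
) -> tuple[list[PhasedVariant], list[PhasedVariant]]:
    """Drop every group of variants whose reference footprints intersect.

    Interdependent variants (e.g. a deletion extending through an SNV)
    cannot vary independently, so the whole group is removed. Unusable
    variants (missing or unphased genotypes) are removed too, and knock
    out anything they overlap. Idempotent; the kept set has pairwise
    disjoint footprints.
    """
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos))
    kept: list[PhasedVariant] = []
    removed: list[PhasedVariant] = []
    group: list[PhasedVariant] = []
    group_end = -1
    group_chrom = None

    def flush() -> None:
        if not group:
            return
        if len(group) == 1 and group[0].usable:
            kept.append(group[0])
        else:
            removed.extend(group)

    for v in ordered:
        fs, fe = v.footprint
        if group and v.chrom == group_chrom and fs <= group_end:
            group.append(v)
            group_end = max(group_end, fe)
        else:
            flush()
            group = [v]
            group_chrom = v.chrom
            group_end = fe
    flush()
    return kept, removed


def _apply_haplotype(
    ref_seq: str,
    window_start: int,
    window_end: int,
    neighbors: Sequence[PhasedVariant],
    hap_index: int,
) -> str:
    """Reference substring [window_start, window_end] with one haplotype's
    neighbor alleles substituted. Neighbors whose footprints are not fully
    inside the window are ignored (the window is padded by callers so this
    only drops variants too far away to matter)."""
    window_start = max(1, window_start)
    window_end = min(len(ref_seq), window_end)
    if window_start > window_end:
        return ""
    pieces: list[str] = []
    cursor = window_start
    for v in sorted(neighbors, key=lambda x: x.pos):
        if v.genotype[hap_index] != 1:
            continue
        fs, fe = v.footprint
        if fs < cursor or fe > window_end:
            continue
        pieces.append(ref_seq[cursor - 1 : fs - 1])
        pieces.append(v.alt_allele)
        cursor = fe + 1
    pieces.append(ref_seq[cursor - 1 : window_end])
    return "".join(pieces)


def build_context(
    site: HetSite,
    ref_seq: str,
    phased_neighbors: Sequence[PhasedVariant],
    config: AssignmentConfig,
) -> HetSite:
    """Build the REF and ALT allelic context sequences for a site.

    Each context is flank_len bases of the allele-carrying haplotype, the
    allele itself, then flank_len bases on the right; phased neighbor
    alleles falling within a flank are substituted so each appears --
    phased appropriately -- in the other's flanking sequence. Flanks are
    truncated (and flagged) near contig ends.
    """
    v = site.variant
    pad = config.flank_len + 20  # slack so neighbor indels cannot starve a flank
    fs, fe = v.footprint
    neighbors = [n for n in phased_neighbors if n is not v]

    def flanks_for(hap: int) -> tuple[str, str]:
        left_full = _apply_haplotype(ref_seq, fs - pad, fs - 1, neighbors, hap)
        right_full = _apply_haplotype(ref_seq, fe + 1, fe + pad, neighbors, hap)
        return left_full[-config.flank_len :], right_full[: config.flank_len]

    ref_hap, alt_hap = v.ref_hap(), v.alt_hap()
    lr, rr = flanks_for(ref_hap)
    la, ra = flanks_for(alt_hap)
    site.ref_context = lr + v.ref_allele + rr
    site.alt_context = la + v.alt_allele + ra
    site.flanks_ref = (len(lr), len(rr))
    site.flanks_alt = (len(la), len(ra))
    site.eff_start, site.eff_end = fs, fe
    site.truncated_flanks = min(len(lr), len(rr), len(la), len(ra)) < config.flank_len
    return site


def _relation(a: str, b: str) -> Optional[str]:
    """prefix/suffix/substring relation between the two context strings.

    Returns 'prefix' if the shorter is a prefix of the longer (repeat on
    the right), 'suffix' for a suffix, 'substring' for an interior
    occurrence, 'equal' when identical, or None when the contexts are
    distinguishable."""
    if a == b:
        return "equal"
    short, long_ = (a, b) if len(a) < len(b) else (b, a)
    if long_.startswith(short):
        return "prefix"
    if long_.endswith(short):
        return "suffix"
    if short in long_:
        return "substring"
    return None


def extend_effective(site: HetSite, ref_seq: str, config: AssignmentConfig) -> HetSite:
    """Extend the variant across a tandem repeat into its effective form.

    While one context sequence is a prefix of the other, the variant is
    extended to the right, one reference base at a time, until the first
    difference; a suffix relation extends to the left. When the shorter
    context occurs strictly inside the other, the side needing the shorter
    extension is chosen. Sites whose effective reference span exceeds the
    configured limit (or whose extension runs past a contig end) are
    disregarded.
    """
    if not site.ref_context or not site.alt_context:
        raise ValueError("contexts must be built before extension")
    lock: Optional[str] = None
    cap = config.effective_len_limit + config.flank_len + 1
    for _ in range(2 * cap):
        if site.eff_end - site.eff_start + 1 > config.effective_len_limit:
            site.disregarded = True
            return site
        rel = _relation(site.ref_context, site.alt_context)
        if rel is None:
            return site
        if rel == "substring" and lock is None:
            lock = _shorter_extension_side(site, ref_seq, cap)
        side = lock or ("left" if rel == "suffix" else "right")
        if not _extend_one(site, ref_seq, side):
            site.disregarded = True  # ran past the contig end
            return site
        site.extended_side = side if site.extended_side in ("none", side) else site.extended_side
    site.disregarded = True
    return site


def _extend_one(site: HetSite, ref_seq: str, side: str) -> bool:
    """Grow the effective variant by one reference base on ``side``.

    Outside the variant both haplotypes equal the reference, so the same
    base is appended to (or prepended before) both contexts, and the
    absorbed flank base is compensated by one new outer flank base -- the
    net string operation is a single-character append/prepend.
    """
    if side == "right":
        nxt = site.eff_end + site.flanks_ref[1] + 1
        if nxt > len(ref_seq):
            return False
        base = ref_seq[nxt - 1]
        site.ref_context += base
        site.alt_context += base
        site.eff_end += 1
    else:
        nxt = site.eff_start - site.flanks_ref[0] - 1
        if nxt < 1:
            return False
        base = ref_seq[nxt - 1]
        site.ref_context = base + site.ref_context
        site.alt_context = base + site.alt_context
        site.eff_start -= 1
    return True


def _shorter_extension_side(site: HetSite, ref_seq: str, cap: int) -> str:
    """Simulate extension in each direction; pick the side resolving sooner."""
    costs = {}
    for side in ("left", "right"):
        a, b = site.ref_context, site.alt_context
        lo = site.eff_start - site.flanks_ref[0]
        hi = site.eff_end + site.flanks_ref[1]
        steps = 0
        while _relation(a, b) is not None and steps < cap:
            if side == "right":
                hi += 1
                if hi > len(ref_seq):
                    steps = cap
                    break
                a += ref_seq[hi - 1]
                b += ref_seq[hi - 1]
            else:
                lo -= 1
                if lo < 1:
                    steps = cap
                    break
                a = ref_seq[lo - 1] + a
                b = ref_seq[lo - 1] + b
            steps += 1
        costs[side] = steps
    return "left" if costs["left"] <= costs["right"] else "right"


def build_cohorts(sites: Sequence[HetSite], ref_seq: str, config: AssignmentConfig) -> list[Cohort]:
    """Cluster nearby HET sites into cohorts by transitive chaining.

    Two consecutive sites join the same cohort when the gap between the
    end of one footprint and the start of the next is at most
    ``cohort_distance``; the cohort extends in either direction until no
    other variant can be reached. Combined per-haplotype strings span the
    cohort's reference interval plus flank_len anchor bases on each end.
    Singleton cohorts are returned too (callers may ignore them).
    """
    ordered = sorted(sites, key=lambda s: s.pos)
    cohorts: list[Cohort] = []
    group: list[HetSite] = []
    group_end = None
    for s in ordered:
        fs, fe = s.variant.footprint
        if group and fs - group_end <= config.cohort_distance:
            group.append(s)
            group_end = max(group_end, fe)
        else:
            if group:
                cohorts.append(_finish_cohort(group, ref_seq, config, len(cohorts)))
            group = [s]
            group_end = fe
    if group:
        cohorts.append(_finish_cohort(group, ref_seq, config, len(cohorts)))
    return cohorts


def _finish_cohort(
    members: list[HetSite], ref_seq: str, config: AssignmentConfig, cohort_id: int
) -> Cohort:
    start = min(m.variant.footprint[0] for m in members)
    end = max(m.variant.footprint[1] for m in members)
    neighbors = [m.variant for m in members]
    lo = start - config.flank_len
    hi = end + config.flank_len
    strings = tuple(
        _apply_haplotype(ref_seq, lo, hi, neighbors, hap) for hap in (0, 1)
    )
    for m in members:
        m.cohort_id = cohort_id
    return Cohort(members=members, start=start, end=end, hap_strings=strings)  # type: ignore[arg-type]


def prepare_sites(
    variants: Sequence[PhasedVariant],
    ref_seq: str,
    config: Optional[AssignmentConfig] = None,
) -> tuple[list[HetSite], list[Cohort]]:
    """Full site-preparation pipeline: overlap removal, HET selection,
    context construction, repeat extension, cohort clustering."""
    config = config or AssignmentConfig()
    kept, _removed = remove_overlapping(variants)
    sites = select_het_sites(kept)
    for site in sites:
        near = [
            v
            for v in kept
            if v is not site.variant and abs(v.pos - site.pos) <= config.flank_len + 30
        ]
        build_context(site, ref_seq, near, config)
        extend_effective(site, ref_seq, config)
    cohorts = build_cohorts([s for s in sites if not s.disregarded], ref_seq, config)
    return sites, cohorts
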