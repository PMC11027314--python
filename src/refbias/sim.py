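"""Diploid read simulation with ground truth, and controlled bias injection.

This module is the package's synthetic-data generator. It builds the two
personalized haplotypes of a diploid donor from a reference plus phased
variants, simulates Illumina-like single-end reads carrying truth tags
(haplotype of origin and true reference interval), places them with a
truth-preserving oracle aligner, and can inject three controlled bias
modes:

* ``loss``      -- ALT-haplotype reads overlapping target sites are dropped
                   with probability f (reads failing to align);
* ``flux``      -- foreign low-MAPQ reads (true origin elsewhere) are added
                   at target sites (reads mismapped from other loci);
* ``gap_shift`` -- alignment gaps of reads over tandem repeats are re-placed
                   to a score-equivalent leftmost/rightmost position,
                   leaving read sequences unchanged (gap-placement
                   ambiguity).

The simulator is deliberately simple: substitution errors only, no
quality model, uniform read starts with Poisson read counts per haplotype
and independent per-haplotype seeds (so the two coverage profiles are
uncorrelated). That is all the downstream bias analyses require.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .io import AlignedRead, PhasedVariant, ReadTruth

__all__ = [
    "CoordMap",
    "SimRead",
    "SimParams",
    "BiasInjectionSpec",
    "build_consensus",
    "simulate_reads",
    "oracle_align",
    "inject_bias",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class _Seg:
    kind: str  # 'M', 'I' (haplotype-only bases) or 'D' (reference-only bases)
    hap_start: int  # first haplotype base of the segment; for D, the next hap base
    ref_start: int  # first reference base; for I, the next ref base after the anchor
    length: int


class CoordMap:
    """Piecewise-monotone mapping between haplotype and reference coordinates.

    Built from the variants applied to one haplotype; identity when no
    variants are applied. All coordinates are 1-based inclusive.
    """

    def __init__(self, segs: list[_Seg], hap_len: int, ref_len: int):
        self._segs = segs
        self.hap_len = hap_len
        self.ref_len = ref_len
        self._hap_starts = [s.hap_start for s in segs]

    @classmethod
    def from_variants(
        cls, ref_len: int, variants: Sequence[PhasedVariant], hap_index: int
    ) -> "CoordMap":
        """Build the map for haplotype ``hap_index`` (0 or 1).

        ``variants`` must be non-overlapping and sorted by position; only
        those whose genotype entry for this haplotype is the ALT allele
        alter the map.
        """
        segs: list[_Seg] = []
        ref = 1
        hap = 1
        for v in variants:
            if v.genotype[hap_index] != 1:
                continue
            if v.pos < ref:
                raise ValueError(f"overlapping variant at {v.chrom}:{v.pos}")
            if v.pos > ref:
                segs.append(_Seg("M", hap, ref, v.pos - ref))
                hap += v.pos - ref
                ref = v.pos
            r, a = v.ref_allele, v.alt_allele
            c = min(len(r), len(a))  # VCF shared-prefix convention
            if c:
                segs.append(_Seg("M", hap, ref, c))
                hap += c
                ref += c
            if len(a) > c:
                segs.append(_Seg("I", hap, ref, len(a) - c))
                hap += len(a) - c
            if len(r) > c:
                segs.append(_Seg("D", hap, ref, len(r) - c))
                ref += len(r) - c
        if ref <= ref_len:
            segs.append(_Seg("M", hap, ref, ref_len - ref + 1))
            hap += ref_len - ref + 1
        merged: list[_Seg] = []
        for s in segs:
            if merged and merged[-1].kind == s.kind == "M":
                merged[-1] = dataclasses.replace(merged[-1], length=merged[-1].length + s.length)
            else:
                merged.append(s)
        return cls(merged, hap - 1, ref_len)

    def project_interval(self, start: int, end: int) -> Optional[tuple[int, int]]:
        """Project a haplotype interval onto the reference (both inclusive).

        Returns None if the interval lies entirely within inserted sequence.
        """
        if start > end:
            raise ValueError("empty interval")
        ref_s = ref_e = None
        for seg in self._iter_overlapping(start, end):
            if seg.kind != "M":
                continue
            seg_end = seg.hap_start + seg.length - 1
            ov_s = max(start, seg.hap_start)
            ov_e = min(end, seg_end)
            if ov_s > ov_e:
                continue
            if ref_s is None:
                ref_s = seg.ref_start + (ov_s - seg.hap_start)
            ref_e = seg.ref_start + (ov_e - seg.hap_start)
        if ref_s is None:
            return None
        return ref_s, ref_e

    def cigar_for(self, start: int, end: int) -> Optional[tuple[int, list[tuple[str, int]]]]:
        """CIGAR for a read spanning haplotype interval [start, end].

        Returns (leftmost reference position, cigar). Haplotype-only bases
        at the read ends (an unanchored inserted prefix/suffix) are
        soft-clipped; internal ones become I; deleted reference bases
        strictly inside the read become D. Returns None for a read lying
        entirely within inserted sequence.
        """
        ops: list[tuple[str, int]] = []
        pos = None
        for seg in self._iter_overlapping(start, end):
            if seg.kind == "D":
                if start < seg.hap_start <= end:
                    ops.append(("D", seg.length))
                continue
            seg_end = seg.hap_start + seg.length - 1
            ov_s = max(start, seg.hap_start)
            ov_e = min(end, seg_end)
            if ov_s > ov_e:
                continue
            if seg.kind == "M" and pos is None:
                pos = seg.ref_start + (ov_s - seg.hap_start)
            ops.append((seg.kind, ov_e - ov_s + 1))
        if pos is None:
            return None
        # strip dangling deletions, soft-clip unanchored insertions
        while ops and ops[0][0] == "D":
            ops.pop(0)
        while ops and ops[-1][0] == "D":
            ops.pop()
        if ops and ops[0][0] == "I":
            ops[0] = ("S", ops[0][1])
        if ops and ops[-1][0] == "I":
            ops[-1] = ("S", ops[-1][1])
        merged: list[tuple[str, int]] = []
        for op, ln in ops:
            if merged and merged[-1][0] == op:
                merged[-1] = (op, merged[-1][1] + ln)
            else:
                merged.append((op, ln))
        return pos, merged

    def _iter_overlapping(self, start: int, end: int):
        i = bisect_right(self._hap_starts, start) - 1
        i = max(i, 0)
        for seg in self._segs[i:]:
            if seg.hap_start > end + 1:
                break
            yield seg


def build_consensus(
    ref_seq: str, variants: Sequence[PhasedVariant], hap_index: int
) -> tuple[str, CoordMap]:
    """Apply one haplotype's alleles to the reference.

    ``variants`` must be sorted and non-overlapping (enforce upstream with
    :func:`refbias.variants.remove_overlapping`). Raises if a variant's REF
    allele does not match the reference sequence, which signals a wrong
    reference build.
    """
    pieces: list[str] = []
    cursor = 1
    for v in variants:
        if v.genotype[hap_index] != 1:
            continue
        if v.pos < cursor:
            raise ValueError(f"overlapping variant at {v.chrom}:{v.pos}")
        observed = ref_seq[v.pos - 1 : v.pos - 1 + len(v.ref_allele)]
        if observed != v.ref_allele:
            raise ValueError(
                f"REF mismatch at {v.chrom}:{v.pos}: VCF says {v.ref_allele!r}, "
                f"reference has {observed!r}"
            )
        pieces.append(ref_seq[cursor - 1 : v.pos - 1])
        pieces.append(v.alt_allele)
        cursor = v.pos + len(v.ref_allele)
    pieces.append(ref_seq[cursor - 1 :])
    hap_seq = "".join(pieces)
    cmap = CoordMap.from_variants(len(ref_seq), variants, hap_index)
    assert cmap.hap_len == len(hap_seq)
    return hap_seq, cmap


@dataclass
class SimParams:
    """Read-simulation parameters.

    ``coverage`` is per haplotype (default 15x each, so ~30x total).
    The two haplotype seeds must differ so the coverage profiles of the
    two haplotypes are uncorrelated.
    """

    read_length: int = 150
    coverage: float = 15.0
    error_rate: float = 0.002
    seeds: tuple[int, int] = (1, 2)

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error rate must be in [0, 1)")
        if self.seeds[0] == self.seeds[1]:
            raise ValueError("the two haplotype seeds must differ")


@dataclass
class SimRead:
    read_id: str
    hap_index: int  # 1 or 2
    hap_start: int
    hap_end: int
    ref_interval: Optional[tuple[int, int]]
    sequence: str
    errors: list[tuple[int, str, str]] = field(default_factory=list)


def simulate_reads(
    hap_seqs: Sequence[str],
    coord_maps: Sequence[CoordMap],
    params: SimParams,
    chrom: str = "chr1",
) -> list[SimRead]:
    """Simulate single-end reads from both haplotypes.

    Read counts are Poisson(coverage * L / read_length) per haplotype with
    uniform start positions and i.i.d. substitution errors. Fully
    reproducible given the per-haplotype seeds.
    """
    rl = params.read_length
    reads: list[SimRead] = []
    for hap_idx, (seq, cmap) in enumerate(zip(hap_seqs, coord_maps), start=1):
        if rl > len(seq):
            raise ValueError("read_length exceeds haplotype length")
        rng = np.random.default_rng(params.seeds[hap_idx - 1])
        n = int(rng.poisson(params.coverage * len(seq) / rl))
        starts = np.sort(rng.integers(1, len(seq) - rl + 2, size=n))
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        n_err = rng.binomial(rl, params.error_rate, size=n)
        for i in range(n):
            s = int(starts[i])
            sub = arr[s - 1 : s - 1 + rl]
            errors: list[tuple[int, str, str]] = []
            if n_err[i]:
                sub = sub.copy()
                offs = rng.choice(rl, size=n_err[i], replace=False)
                for off in np.sort(offs):
                    old = chr(sub[off])
                    choices = [b for b in b"ACGT" if b != sub[off]]
                    new = choices[rng.integers(0, 3)]
                    sub[off] = new
                    errors.append((int(off), old, chr(new)))
            reads.append(
                SimRead(
                    read_id=f"sim_h{hap_idx}_{i}",
                    hap_index=hap_idx,
                    hap_start=s,
                    hap_end=s + rl - 1,
                    ref_interval=cmap.project_interval(s, s + rl - 1),
                    sequence=sub.tobytes().decode(),
                    errors=errors,
                )
            )
    return reads


def oracle_align(
    sim_reads: Iterable[SimRead],
    coord_maps: Sequence[CoordMap],
    chrom: str = "chr1",
    mapq_max: int = 42,
) -> list[AlignedRead]:
    """Place each simulated read at its true reference interval.

    A perfect, truth-preserving aligner: the CIGAR is forced by the
    coordinate map (I for inserted haplotype bases, D for deleted reference
    bases, M elsewhere; unanchored inserted read ends soft-clipped) and
    MAPQ is the configured maximum. Reads falling entirely within inserted
    sequence have no reference placement and are skipped.
    """
    out: list[AlignedRead] = []
    for r in sim_reads:
        cmap = coord_maps[r.hap_index - 1]
        placed = cmap.cigar_for(r.hap_start, r.hap_end)
        if placed is None or r.ref_interval is None:
            continue
        pos, cigar = placed
        out.append(
            AlignedRead(
                read_id=r.read_id,
                chrom=chrom,
                pos=pos,
                cigar=cigar,
                mapq=mapq_max,
                sequence=r.sequence,
                truth=ReadTruth(r.hap_index, chrom, r.ref_interval[0], r.ref_interval[1]),
            )
        )
    return out


@dataclass
class BiasInjectionSpec:
    """One controlled bias injection (exactly one mode per spec).

    loss      : drop ALT-haplotype reads over ``sites`` with prob ``loss_fraction``
    flux      : add ``flux_count`` foreign reads with MAPQ ``flux_mapq`` at each site
    gap_shift : re-place gaps of reads over ``sites`` per ``gap_policy``
    """

    mode: Literal["loss", "flux", "gap_shift"]
    sites: list[PhasedVariant]
    loss_fraction: float = 0.0
    flux_count: int = 0
    flux_mapq: int = 0
    gap_policy: Literal["leftmost", "rightmost"] = "rightmost"
    flux_true_chrom: str = "decoy"

    def __post_init__(self) -> None:
        if self.mode == "loss" and not 0 <= self.loss_fraction <= 1:
            raise ValueError("loss fraction must be in [0, 1]")


def inject_bias(
    alignments: Sequence[AlignedRead],
    spec: BiasInjectionSpec,
    seed: int,
    ref_seqs: Optional[dict[str, str]] = None,
    read_length: int = 150,
    mapq_max: int = 42,
) -> list[AlignedRead]:
    """Apply one bias injection and return the new alignment list."""
    rng = np.random.default_rng(seed)
    if spec.mode == "loss":
        out = []
        for read in alignments:
            drop = False
            if read.truth is not None:
                for site in spec.sites:
                    fs, fe = site.footprint
                    if (
                        read.truth.hap_index - 1 == site.alt_hap()
                        and read.truth.overlaps(site.chrom, fs, fe)
                    ):
                        drop = rng.random() < spec.loss_fraction
                        break
            if not drop:
                out.append(read)
        return out

    if spec.mode == "flux":
        out = list(alignments)
        for site in spec.sites:
            if ref_seqs is None or site.chrom not in ref_seqs:
                raise ValueError(f"flux injection needs reference sequence for {site.chrom}")
            ref = ref_seqs[site.chrom]
            start = max(1, min(site.pos - read_length // 2, len(ref) - read_length + 1))
            seq = ref[start - 1 : start - 1 + read_length]
            for k in range(spec.flux_count):
                out.append(
                    AlignedRead(
                        read_id=f"flux_{site.chrom}_{site.pos}_{k}",
                        chrom=site.chrom,
                        pos=start,
                        cigar=[("M", len(seq))],
                        mapq=spec.flux_mapq,
                        sequence=seq,
                        truth=ReadTruth(1, spec.flux_true_chrom, 1, len(seq)),
                    )
                )
        return out

    if spec.mode == "gap_shift":
        if ref_seqs is None:
            raise ValueError("gap_shift needs the reference sequence")
        out = []
        targets = [(s.chrom,) + s.footprint for s in spec.sites]
        for read in alignments:
            over = any(
                read.chrom == c and read.pos <= e and read.end >= s for c, s, e in targets
            )
            if over and any(op in "ID" for op, _ in read.cigar):
                out.append(shift_gap(read, ref_seqs[read.chrom], spec.gap_policy))
            else:
                out.append(read)
        return out

    raise ValueError(f"unknown injection mode {spec.mode!r}")


def alignment_mismatches(seq: str, pos: int, cigar: Sequence[tuple[str, int]], ref: str) -> int:
    """Number of mismatched M bases of an alignment against the reference."""
    mm = 0
    q = 0
    r = pos
    for op, ln in cigar:
        if op == "M":
            mm += sum(1 for i in range(ln) if seq[q + i] != ref[r - 1 + i])
            q += ln
            r += ln
        elif op in "IS":
            q += ln
        elif op == "D":
            r += ln
    return mm


def shift_gap(read: AlignedRead, ref: str, policy: str) -> AlignedRead:
    """Re-place a single internal gap to a score-equivalent extreme position.

    Handles the [S] M gap M [S] pattern (one I or D between two aligned
    blocks). Candidate placements keep the read sequence and total M length
    fixed; only placements with an unchanged mismatch count (hence an equal
    alignment score) are eligible. Returns the read unchanged when the
    pattern does not apply.
    """
    cig = read.cigar
    lead: list[tuple[str, int]] = []
    tail: list[tuple[str, int]] = []
    core = list(cig)
    if core and core[0][0] == "S":
        lead = [core.pop(0)]
    if core and core[-1][0] == "S":
        tail = [core.pop()]
    if len(core) != 3 or core[0][0] != "M" or core[2][0] != "M" or core[1][0] not in "ID":
        return read
    a, gap, b = core[0][1], core[1], core[2][1]
    total = a + b

    def candidate(k: int) -> list[tuple[str, int]]:
        return lead + [("M", k), gap, ("M", total - k)] + tail

    baseline = alignment_mismatches(read.sequence, read.pos, cig, ref)
    eligible = [
        k
        for k in range(1, total)
        if alignment_mismatches(read.sequence, read.pos, candidate(k), ref) == baseline
    ]
    if not eligible:
        return read
    k = min(eligible) if policy == "leftmost" else max(eligible)
    if k == a:
        return read
    return dataclasses.replace(read, cigar=candidate(k))
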