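"""Readers and writers for the standard formats the toolkit touches.

Handles FASTA references, phased diploid VCFs, SAM/BAM alignments, the
samtools/bcftools mpileup text dialect, and BED region output, plus an
in-process pileup generator so the variant-blind scan mode is testable
without external tools.

Coordinate conventions
----------------------
All genomic positions inside the package are 1-based inclusive, matching
VCF/SAM/mpileup. BED output is converted to 0-based half-open at the
output boundary only.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pysam
from Bio import SeqIO

__all__ = [
    "FormatError",
    "PhasedVariant",
    "ReadTruth",
    "AlignedRead",
    "PileupColumn",
    "Region",
    "read_fasta",
    "read_phased_vcf",
    "read_alignments",
    "write_alignments",
    "read_mpileup",
    "pileup_from_alignments",
    "write_regions_bed",
]

#: SAM optional tags carrying simulation truth (self-describing, survive sorting).
TAG_HAP = "Zh"
TAG_TRUE_CHROM = "Zc"
TAG_TRUE_START = "Zs"
TAG_TRUE_END = "Ze"

_QUERY_OPS = frozenset("MIS")
_REF_OPS = frozenset("MD")


class FormatError(ValueError):
    """Raised when an input file does not conform to its expected dialect."""


@dataclass(frozen=True)
class PhasedVariant:
    """A phased diploid variant (assumed biallelic).

    ``genotype`` is the ordered pair of allele indices, haplotype 1 first.
    A ``None`` entry means the genotype was missing ("./."); ``phased`` is
    False for "/"-separated genotypes. Either condition makes the variant
    unusable for assignment, though it still participates in overlap
    removal.
    """

    chrom: str
    pos: int  # 1-based position of the first REF base
    ref_allele: str
    alt_allele: str
    genotype: tuple[Optional[int], Optional[int]]
    phased: bool = True

    def __post_init__(self) -> None:
        if not self.ref_allele:
            raise ValueError("ref_allele must be non-empty")
        if len(self.genotype) != 2:
            raise ValueError("genotype must have exactly two entries")

    @property
    def usable(self) -> bool:
        return self.phased and None not in self.genotype

    @property
    def is_het(self) -> bool:
        a, b = self.genotype
        return a is not None and b is not None and a != b

    @property
    def length_delta(self) -> int:
        """len(ALT) - len(REF); 0 for SNVs, >0 insertions, <0 deletions."""
        return len(self.alt_allele) - len(self.ref_allele)

    @property
    def footprint(self) -> tuple[int, int]:
        """Reference interval occupied by the REF allele (1-based inclusive).

        Insertions occupy only their single anchor base.
        """
        return self.pos, self.pos + len(self.ref_allele) - 1

    def ref_hap(self) -> int:
        """0-based index of the haplotype carrying the REF allele (HETs only)."""
        if not self.is_het:
            raise ValueError("ref_hap is defined for HET variants only")
        return 0 if self.genotype[0] == 0 else 1

    def alt_hap(self) -> int:
        return 1 - self.ref_hap()


@dataclass(frozen=True)
class ReadTruth:
    """Simulation ground truth attached to a read."""

    hap_index: int  # 1 or 2
    chrom: str
    start: int
    end: int  # 1-based inclusive reference interval of origin

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= end and self.end >= start


@dataclass
class AlignedRead:
    read_id: str
    chrom: str
    pos: int  # 1-based leftmost aligned reference coordinate
    cigar: list[tuple[str, int]]  # ops in {M, I, D, S}
    mapq: int
    sequence: str
    truth: Optional[ReadTruth] = None

    def __post_init__(self) -> None:
        qlen = sum(ln for op, ln in self.cigar if op in _QUERY_OPS)
        if qlen != len(self.sequence):
            raise FormatError(
                f"read {self.read_id}: CIGAR consumes {qlen} query bases, "
                f"sequence has {len(self.sequence)}"
            )

    @property
    def end(self) -> int:
        """Rightmost aligned reference coordinate (1-based inclusive)."""
        return self.pos + sum(ln for op, ln in self.cigar if op in _REF_OPS) - 1

    def overlaps(self, start: int, end: int) -> bool:
        return self.pos <= end and self.end >= start

    def cigar_string(self) -> str:
        return "".join(f"{ln}{op}" for op, ln in self.cigar)


@dataclass
class PileupColumn:
    chrom: str
    pos: int
    depth: int
    base_counts: dict[str, int] = field(default_factory=dict)
    ref_base: Optional[str] = None


@dataclass
class Region:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    label: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"region end {self.end} < start {self.start}")

    def __len__(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a dict of name -> uppercased sequence.

    Sequences are keyed by the first whitespace-delimited token of each
    header line.
    """
    out: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            out[rec.id] = str(rec.seq).upper()
    except ValueError as err:
        raise FormatError(f"{path}: malformed FASTA ({err})") from err
    return out


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# VCF


def read_phased_vcf(path, region: Optional[tuple[str, int, int]] = None) -> list[PhasedVariant]:
    """Read phased diploid variants from a VCF (first sample's GT field).

    Only records with FILTER in {PASS, "."} are returned. Records with
    unphased or missing genotypes are returned flagged unusable so that
    downstream overlap-removal can act on them. Multi-allelic records are
    assumed to have been split upstream and are skipped.
    """
    variants: list[PhasedVariant] = []
    with pysam.VariantFile(str(path)) as vf:
        if not vf.header.samples:
            raise FormatError(f"{path}: VCF has no sample columns (GT required)")
        sample = vf.header.samples[0]
        for rec in vf:
            if region is not None:
                chrom, start, end = region
                if rec.chrom != chrom or rec.pos > end or rec.pos < start:
                    continue
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                continue
            if rec.alts is None or len(rec.alts) != 1:
                continue
            call = rec.samples[sample]
            if "GT" not in call:
                raise FormatError(f"{path}: record at {rec.chrom}:{rec.pos} lacks GT")
            gt = call["GT"]
            if gt is None or len(gt) != 2:
                gt = (None, None)
            variants.append(
                PhasedVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref.upper(),
                    alt_allele=rec.alts[0].upper(),
                    genotype=(gt[0], gt[1]),
                    phased=bool(call.phased),
                )
            )
    return variants


# ---------------------------------------------------------------------------
# SAM/BAM

_CIGAR_OPS = "MIDNSHP=X"


def read_alignments(path, region: Optional[str] = None) -> Iterator[AlignedRead]:
    """Stream mapped primary alignments from a SAM/BAM file.

    Unmapped, secondary and supplementary records are skipped. Simulation
    truth tags are parsed when present.
    """
    with pysam.AlignmentFile(str(path), require_index=False) as af:
        it = af.fetch(region=region) if region else af
        for seg in it:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            cigar: list[tuple[str, int]] = []
            for opcode, ln in seg.cigartuples:
                op = _CIGAR_OPS[opcode]
                if op in "=X":
                    op = "M"
                if op not in "MIDS":
                    raise FormatError(
                        f"read {seg.query_name}: unsupported CIGAR op {op}"
                    )
                cigar.append((op, ln))
            truth = None
            if seg.has_tag(TAG_HAP):
                truth = ReadTruth(
                    hap_index=int(seg.get_tag(TAG_HAP)),
                    chrom=str(seg.get_tag(TAG_TRUE_CHROM)),
                    start=int(seg.get_tag(TAG_TRUE_START)),
                    end=int(seg.get_tag(TAG_TRUE_END)),
                )
            yield AlignedRead(
                read_id=seg.query_name,
                chrom=seg.reference_name,
                pos=seg.reference_start + 1,
                cigar=_merge_ops(cigar),
                mapq=seg.mapping_quality,
                sequence=seg.query_sequence.upper(),
                truth=truth,
            )


def write_alignments(reads: Iterable[AlignedRead], path, ref_lengths: dict[str, int]) -> None:
    """Write reads as a coordinate-sorted SAM file with truth tags."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": ln} for name, ln in ref_lengths.items()],
    }
    reads = sorted(reads, key=lambda r: (r.chrom, r.pos))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.read_id
            seg.reference_name = r.chrom
            seg.reference_start = r.pos - 1
            seg.mapping_quality = r.mapq
            seg.cigartuples = [(_CIGAR_OPS.index(op), ln) for op, ln in r.cigar]
            seg.query_sequence = r.sequence
            seg.flag = 0
            if r.truth is not None:
                seg.set_tag(TAG_HAP, r.truth.hap_index, "i")
                seg.set_tag(TAG_TRUE_CHROM, r.truth.chrom, "Z")
                seg.set_tag(TAG_TRUE_START, r.truth.start, "i")
                seg.set_tag(TAG_TRUE_END, r.truth.end, "i")
            out.write(seg)


def _merge_ops(cigar: list[tuple[str, int]]) -> list[tuple[str, int]]:
    merged: list[tuple[str, int]] = []
    for op, ln in cigar:
        if ln == 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return merged


# ---------------------------------------------------------------------------
# mpileup


def read_mpileup(source) -> Iterator[PileupColumn]:
    """Parse samtools/bcftools mpileup text into pileup columns.

    ``source`` is a path or an iterable of lines. The base string is decoded
    per samtools semantics: "." / "," count the reference base; ACGT
    (either case) count that base; "^X" read-start markers (the following
    mapping-quality char is skipped) and "$" end markers are consumed;
    "+n.../-n..." indel text is attached to the anchor column and never to
    base_counts; "*"/"#" deletion placeholders and "><" reference skips
    count toward depth but not base_counts. N bases are excluded from
    base_counts.
    """
    if hasattr(source, "__iter__") and not isinstance(source, (str, bytes)):
        lines = iter(source)
        yield from _parse_mpileup_lines(lines, "<stream>")
    else:
        with open(source) as fh:
            yield from _parse_mpileup_lines(fh, str(source))


def _parse_mpileup_lines(lines, name) -> Iterator[PileupColumn]:
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise FormatError(f"{name}:{lineno}: expected >=5 tab-separated fields")
        chrom, pos_s, ref_base, depth_s, bases = fields[:5]
        try:
            pos, depth = int(pos_s), int(depth_s)
        except ValueError as err:
            raise FormatError(f"{name}:{lineno}: bad pos/depth") from err
        if depth == 0:
            # zero-coverage columns (mpileup -a) use "*" placeholders
            yield PileupColumn(
                chrom=chrom, pos=pos, depth=0, base_counts={}, ref_base=ref_base.upper()
            )
            continue
        counts, decoded = _decode_bases(bases, ref_base.upper(), name, lineno)
        if decoded != depth:
            raise FormatError(
                f"{name}:{lineno} (pos {pos}): decoded {decoded} reads, depth says {depth}"
            )
        yield PileupColumn(
            chrom=chrom, pos=pos, depth=depth, base_counts=counts, ref_base=ref_base.upper()
        )


def _decode_bases(s: str, ref_base: str, name: str, lineno: int) -> tuple[dict[str, int], int]:
    counts: Counter[str] = Counter()
    decoded = 0
    i = 0
    n = len(s)
    while i < n:
        c = s[i]
        if c == "^":
            i += 2  # skip the encoded mapping quality
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            i += 1
            j = i
            while j < n and s[j].isdigit():
                j += 1
            if j == i:
                raise FormatError(f"{name}:{lineno}: indel marker without length")
            i = j + int(s[i:j])
            continue
        if c in ".,":
            base = ref_base
        elif c.upper() in "ACGTN":
            base = c.upper()
        elif c in "*#><":
            base = None  # deletion placeholder / reference skip: depth only
        else:
            raise FormatError(f"{name}:{lineno}: unexpected pileup token {c!r}")
        decoded += 1
        if base is not None and base in "ACGT":
            counts[base] += 1
        i += 1
    return dict(counts), decoded


def pileup_from_alignments(
    reads: Iterable[AlignedRead], ref_seqs: Optional[dict[str, str]] = None
) -> list[PileupColumn]:
    """Build pileup columns directly from alignments.

    Matches the mpileup reader's decoding of samtools output on the same
    input: M adds a base to depth and base_counts, D adds depth only, S and
    I contribute nothing at reference positions. Columns are returned
    sorted by (chrom, pos); zero-depth positions are omitted, as samtools
    does by default.
    """
    depth: dict[tuple[str, int], int] = {}
    bases: dict[tuple[str, int], Counter] = {}
    for read in reads:
        ref = read.pos
        q = 0
        for op, ln in read.cigar:
            if op == "M":
                for k in range(ln):
                    key = (read.chrom, ref + k)
                    depth[key] = depth.get(key, 0) + 1
                    b = read.sequence[q + k]
                    if b in "ACGT":
                        bases.setdefault(key, Counter())[b] += 1
                ref += ln
                q += ln
            elif op == "D":
                for k in range(ln):
                    key = (read.chrom, ref + k)
                    depth[key] = depth.get(key, 0) + 1
                ref += ln
            elif op in "IS":
                q += ln
    cols = []
    for (chrom, pos) in sorted(depth):
        rb = None
        if ref_seqs is not None and chrom in ref_seqs:
            rb = ref_seqs[chrom][pos - 1]
        cols.append(
            PileupColumn(
                chrom=chrom,
                pos=pos,
                depth=depth[(chrom, pos)],
                base_counts=dict(bases.get((chrom, pos), {})),
                ref_base=rb,
            )
        )
    return cols


# ---------------------------------------------------------------------------
# BED


def write_regions_bed(regions: Iterable[Region], path) -> None:
    """Write regions as BED4+score (0-based, half-open), sorted by start."""
    regions = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.label}\t{r.score:g}\n")
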