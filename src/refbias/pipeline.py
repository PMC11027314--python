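"""End-to-end experiment orchestration over synthetic diploid data.

Chains the package's stages -- consensus construction, truth-tagged read
simulation, oracle alignment, optional bias injection, site preparation,
assignment, balance measurement and classification -- into the
experiments the toolkit is built around: an unbiased (null) run, and
runs with controlled loss/flux/gap-shift injections. Also provides the
random reference and variant generators that define the synthetic study
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assign import SiteEvidence, tally_sites
from .io import AlignedRead, PhasedVariant
from .metrics import (
    BalanceRecord,
    ClassifierConfig,
    build_records,
    records_to_frame,
)
from .sim import (
    BiasInjectionSpec,
    CoordMap,
    SimParams,
    SimRead,
    build_consensus,
    inject_bias,
    oracle_align,
    simulate_reads,
)
from .variants import AssignmentConfig, Cohort, HetSite, prepare_sites

__all__ = [
    "random_reference",
    "random_het_snvs",
    "random_het_indels",
    "SimulationResult",
    "run_simulation",
    "null_experiment",
]

DEFAULT_CHROM = "chrS"


def random_reference(length: int, seed: int, chrom: str = DEFAULT_CHROM) -> dict[str, str]:
    """A uniformly random nucleotide sequence (no repeat structure)."""
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, size=length)]
    return {chrom: arr.tobytes().decode()}


def random_het_snvs(
    ref_seq: str,
    n: int,
    seed: int,
    chrom: str = DEFAULT_CHROM,
    margin: int = 200,
    min_spacing: int = 0,
) -> list[PhasedVariant]:
    """n phased HET SNVs with random phase.

    By default positions are distinct and uniform; with ``min_spacing``
    the sites are placed on an evenly spaced grid with jitter, so no two
    sites fall within min_spacing of each other (needed when per-site
    effects must not interact through shared reads).
    """
    rng = np.random.default_rng(seed)
    if min_spacing:
        span = len(ref_seq) - 2 * margin
        step = span // n
        if step <= min_spacing:
            raise ValueError("reference too short for requested spacing")
        jitter = rng.integers(0, step - min_spacing, size=n)
        positions = margin + np.arange(n) * step + jitter + 1
    else:
        positions = rng.choice(
            np.arange(margin + 1, len(ref_seq) - margin), size=n, replace=False
        )
    out = []
    for pos in np.sort(positions):
        ref_base = ref_seq[pos - 1]
        alt_base = "ACGT".replace(ref_base, "")[rng.integers(0, 3)]
        gt = (0, 1) if rng.random() < 0.5 else (1, 0)
        out.append(PhasedVariant(chrom, int(pos), ref_base, alt_base, gt))
    return out


def random_het_indels(
    ref_seq: str,
    n: int,
    seed: int,
    max_len: int = 10,
    chrom: str = DEFAULT_CHROM,
    margin: int = 200,
    min_spacing: int = 100,
) -> list[PhasedVariant]:
    """n phased HET indels (half insertions, half deletions) of length
    1..max_len, spaced at least min_spacing apart."""
    rng = np.random.default_rng(seed)
    step = max(min_spacing, (len(ref_seq) - 2 * margin) // max(n, 1))
    out = []
    pos = margin
    for i in range(n):
        pos += step
        if pos + max_len + margin >= len(ref_seq):
            break
        ln = int(rng.integers(1, max_len + 1))
        gt = (0, 1) if rng.random() < 0.5 else (1, 0)
        anchor = ref_seq[pos - 1]
        if i % 2 == 0:  # insertion
            ins = "".join("ACGT"[b] for b in rng.integers(0, 4, size=ln))
            out.append(PhasedVariant(chrom, pos, anchor, anchor + ins, gt))
        else:  # deletion
            out.append(
                PhasedVariant(chrom, pos, ref_seq[pos - 1 : pos + ln], anchor, gt)
            )
    return out


@dataclass
class SimulationResult:
    chrom: str
    ref_seqs: dict[str, str]
    variants: list[PhasedVariant]
    sites: list[HetSite]
    cohorts: list[Cohort]
    sim_reads: list[SimRead]
    aligned: list[AlignedRead]
    evidence: dict[int, SiteEvidence]
    records: list[BalanceRecord]
    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    def median_alt_fractions(self, snv_only: bool = True) -> dict[str, float]:
        """Median ALT fraction (1 - balance) per measure across sites."""
        df = self.frame
        if snv_only:
            df = df[df["length_delta"] == 0]
        return {
            m: float((1.0 - df[m].dropna()).median()) for m in ("SB", "MB", "AB")
        }


def run_simulation(
    ref_seqs: dict[str, str],
    variants: Sequence[PhasedVariant],
    params: Optional[SimParams] = None,
    injections: Sequence[BiasInjectionSpec] = (),
    injection_seed: int = 99,
    method: str = "context",
    assign_config: Optional[AssignmentConfig] = None,
    classifier_config: Optional[ClassifierConfig] = None,
    chrom: Optional[str] = None,
) -> SimulationResult:
    """Run the full simulate-mode workflow on one chromosome.

    SB is measured on the simulated reads before any injection; MB and
    the mismap counts on the post-injection alignments; AB via the chosen
    assignment method.
    """
    params = params or SimParams()
    assign_config = assign_config or AssignmentConfig()
    chrom = chrom or next(iter(ref_seqs))
    ref_seq = ref_seqs[chrom]

    from .variants import remove_overlapping

    kept, _ = remove_overlapping(variants)
    haps: list[str] = []
    maps: list[CoordMap] = []
    for hap_index in (0, 1):
        hap_seq, cmap = build_consensus(ref_seq, kept, hap_index)
        haps.append(hap_seq)
        maps.append(cmap)

    sim_reads = simulate_reads(haps, maps, params, chrom=chrom)
    aligned = oracle_align(sim_reads, maps, chrom=chrom, mapq_max=assign_config.mapq_max)
    for k, spec in enumerate(injections):
        aligned = inject_bias(
            aligned,
            spec,
            seed=injection_seed + k,
            ref_seqs=ref_seqs,
            read_length=params.read_length,
            mapq_max=assign_config.mapq_max,
        )

    sites, cohorts = prepare_sites(variants, ref_seq, assign_config)
    evidence = tally_sites(sites, cohorts, aligned, method=method, config=assign_config)
    records = build_records(
        sites, evidence, sim_reads=sim_reads, aligned_reads=aligned,
        config=classifier_config,
    )
    result = SimulationResult(
        chrom=chrom,
        ref_seqs=ref_seqs,
        variants=list(variants),
        sites=sites,
        cohorts=cohorts,
        sim_reads=sim_reads,
        aligned=aligned,
        evidence=evidence,
        records=records,
    )
    result.frame = records_to_frame(records)
    return result


def null_experiment(
    seed: int,
    ref_len: int = 1_000_000,
    n_snv: int = 1000,
    coverage: float = 15.0,
    read_length: int = 150,
    error_rate: float = 0.002,
) -> SimulationResult:
    """The unbiased end-to-end run: random diploid donor, oracle
    alignment, no injections. Every measure should center on 0.5."""
    ref = random_reference(ref_len, seed)
    chrom = next(iter(ref))
    snvs = random_het_snvs(ref[chrom], n_snv, seed + 1, chrom=chrom)
    params = SimParams(
        read_length=read_length,
        coverage=coverage,
        error_rate=error_rate,
        seeds=(seed + 2, seed + 3),
    )
    return run_simulation(ref, snvs, params)
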