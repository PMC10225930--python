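"""Transcriptome-, region- and gene-level editing quantification.

Three quantities summarise a sample's A-to-I editing activity:

* the Alu editing index (AEI): total G-mismatch observations at
  transcribed-strand adenosines inside Alu intervals divided by the total
  read coverage of those adenosines — an activity-weighted, coverage-robust
  transcriptome-level index;
* a region editing index (the MAVS-3'UTR style quantity): the same ratio
  restricted to one genomic interval;
* the gene-level editing frequency: the fraction of quality-filtered reads
  covering at least one of a gene's cataloged A-to-G sites that carry at
  least one edited base. Reads qualify with base quality above 20, mapping
  quality above 30, and the site at least 7 bp from the raw read ends.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    CODE_A,
    CODE_C,
    CODE_G,
    CODE_T,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    PileupTable,
    ReferenceGenome,
)

#: Named preset regions for the region editing index. The MAVS 3'UTR preset
#: is the hg19 interval conventionally used for the MAVS editing index.
PRESET_REGIONS: dict[str, GenomicInterval] = {
    "MAVS_3UTR_hg19": GenomicInterval("chr20", 3848102, 3855844, "+"),
}


@dataclass
class IndexConfig:
    """Quality thresholds for the editing indices.

    AEI and region indices use inclusive cutoffs matching detection
    (``qual >= q_base``, ``mapq >= q_map``); the gene-level read rule uses
    the strict form (quality above 20, mapping quality above 30) plus the
    7 bp raw-read end-distance requirement.
    """

    q_base: int = 20
    q_map: int = 30
    gene_q_base: int = 20       # strict >
    gene_q_map: int = 30        # strict >
    gene_end_distance: int = 7  # >= bp from raw read ends


@dataclass
class RatioIndex:
    """An editing index with its raw numerator/denominator counts."""

    value: float | None
    numerator: int
    denominator: int


@dataclass
class GeneEditingResult:
    value: float | None
    edited_reads: int
    covering_reads: int
    reason: str | None = None  # set when value is None


@dataclass
class SampleEditingProfile:
    """One sample's sites plus its transcriptome-level editing indices."""

    sample_id: str
    sites: list
    n_sites: int
    n_a2i_sites: int
    aei: float | None
    aei_counts: tuple[int, int]
    region_indices: dict[str, float | None] = field(default_factory=dict)
    gene_editing: dict[str, GeneEditingResult] = field(default_factory=dict)


def _alu_a_observation_counts(
    pileup: PileupTable,
    intervals: IntervalSet,
    reference: ReferenceGenome,
    cfg: IndexConfig,
) -> tuple[int, int]:
    """(G-at-A observations, total observations at adenosines) over intervals.

    Transcribed-strand adenosines are reference A under '+' intervals and
    reference T under '-'; unstranded intervals contribute both, counted
    separately and summed.
    """
    num = den = 0
    fwd = IntervalSet([iv for iv in intervals if iv.strand in ("+", ".")])
    rev = IntervalSet([iv for iv in intervals if iv.strand in ("-", ".")])
    for chrom, cp in pileup.chroms.items():
        qual_ok = (cp.qual >= cfg.q_base) & (cp.mapq >= cfg.q_map)
        obs_ref = reference.codes(chrom)[cp.pos - 1]
        for ivset, want_ref, want_alt in ((fwd, CODE_A, CODE_G), (rev, CODE_T, CODE_C)):
            if len(ivset) == 0:
                continue
            m = qual_ok & ivset.mask(chrom, cp.pos) & (obs_ref == want_ref)
            den += int(m.sum())
            num += int((m & (cp.base == want_alt)).sum())
    return num, den


def compute_aei(
    pileup: PileupTable,
    alu_intervals: IntervalSet,
    reference: ReferenceGenome,
    config: IndexConfig | None = None,
) -> RatioIndex:
    """Alu editing index with raw counts; None if no adenosine coverage."""
    cfg = config or IndexConfig()
    num, den = _alu_a_observation_counts(pileup, alu_intervals, reference, cfg)
    if den == 0:
        print("[edscape] AEI: zero adenosine coverage in Alu territory", file=sys.stderr)
        return RatioIndex(None, 0, 0)
    return RatioIndex(num / den, num, den)


def region_editing_index(
    pileup: PileupTable,
    region: GenomicInterval,
    reference: ReferenceGenome,
    config: IndexConfig | None = None,
) -> RatioIndex:
    """Editing index over one interval: A-to-G observations over total
    coverage of the region's transcribed-strand adenosines."""
    cfg = config or IndexConfig()
    num, den = _alu_a_observation_counts(pileup, IntervalSet([region]), reference, cfg)
    if den == 0:
        return RatioIndex(None, 0, 0)
    return RatioIndex(num / den, num, den)


def gene_editing_level(
    gene: GeneModel,
    site_positions: list[int],
    pileup: PileupTable,
    config: IndexConfig | None = None,
) -> GeneEditingResult:
    """Read-aggregated editing level of one gene.

    ``site_positions`` must already be the cohort-filtered A-to-G sites of
    the gene (reported in at least two samples, non-intergenic). A read
    enters the denominator if it covers at least one listed site with base
    quality above ``gene_q_base``, mapping quality above ``gene_q_map`` and
    the site at least ``gene_end_distance`` bp from the raw read ends; it
    enters the numerator if at least one such observation shows the edited
    base. Duplicate site entries and site order have no effect.
    """
    cfg = config or IndexConfig()
    positions = np.unique(np.asarray(site_positions, dtype=np.int64))
    if len(positions) == 0:
        return GeneEditingResult(None, 0, 0, reason="no_sites")
    cp = pileup.chroms.get(gene.chrom)
    if cp is None:
        return GeneEditingResult(None, 0, 0, reason="no_qualifying_reads")
    at_site = np.isin(cp.pos, positions)
    ok = (
        at_site
        & (cp.qual > cfg.gene_q_base)
        & (cp.mapq > cfg.gene_q_map)
        & (cp.end_dist >= cfg.gene_end_distance)
    )
    if not ok.any():
        return GeneEditingResult(None, 0, 0, reason="no_qualifying_reads")
    alt_code = CODE_G if gene.strand == "+" else CODE_C
    covering = np.unique(cp.read_index[ok])
    edited = np.unique(cp.read_index[ok & (cp.base == alt_code)])
    return GeneEditingResult(len(edited) / len(covering), len(edited), len(covering))


def build_profile(
    sample_id: str,
    sites: list,
    pileup: PileupTable,
    alu_intervals: IntervalSet,
    reference: ReferenceGenome,
    regions: dict[str, GenomicInterval] | None = None,
    config: IndexConfig | None = None,
) -> SampleEditingProfile:
    """Assemble a sample profile: site set, AEI and named region indices."""
    aei = compute_aei(pileup, alu_intervals, reference, config)
    region_vals: dict[str, float | None] = {}
    for name, iv in (regions or {}).items():
        region_vals[name] = region_editing_index(pileup, iv, reference, config).value
    n_a2i = sum(1 for s in sites if s.is_a_to_i and not s.ambiguous_strand)
    return SampleEditingProfile(
        sample_id=sample_id,
        sites=list(sites),
        n_sites=len(sites),
        n_a2i_sites=n_a2i,
        aei=aei.value,
        aei_counts=(aei.numerator, aei.denominator),
        region_indices=region_vals,
    )
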