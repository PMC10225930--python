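"""Shared fixtures: hand-built SAM/FASTA writers and a small simulated cohort."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pytest

from edscape import SimConfig, simulate_cohort
from edscape.io_formats import GeneModel, GenomicInterval


@dataclass
class Read:
    """A hand-specified ungapped alignment for fixture SAM files."""

    chrom: str
    start: int          # 1-based leftmost
    seq: str
    qual: int | str = 37
    mapq: int = 60
    flag: int = 0
    cigar: str | None = None

    def qual_string(self) -> str:
        if isinstance(self.qual, str):
            return self.qual
        return chr(self.qual + 33) * len(self.seq)


def write_sam(path: Path, reads: list[Read], chrom_lengths: dict[str, int]) -> Path:
    reads = sorted(reads, key=lambda r: (r.chrom, r.start))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, ln in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{ln}\n")
        for i, r in enumerate(reads):
            cig = r.cigar or f"{len(r.seq)}M"
            fh.write(
                f"r{i:04d}\t{r.flag}\t{r.chrom}\t{r.start}\t{r.mapq}\t{cig}"
                f"\t*\t0\t0\t{r.seq}\t{r.qual_string()}\n"
            )
    return path


def write_fasta(path: Path, seqs: dict[str, str]) -> Path:
    with open(path, "w") as fh:
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    return path


def write_vcf(path: Path, records: list[tuple[str, int, str, str]],
              chrom_lengths: dict[str, int]) -> Path:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, ln in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in sorted(records):
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")
    return path


def naive_pileup_counts(reads: list[Read], chrom: str, pos: int) -> dict[str, int]:
    """Brute-force per-base counts at a position from raw read strings."""
    counts: dict[str, int] = {}
    for r in reads:
        if r.chrom != chrom or r.cigar is not None:
            continue
        off = pos - r.start
        if 0 <= off < len(r.seq):
            b = r.seq[off]
            counts[b] = counts.get(b, 0) + 1
    return counts


def single_gene_models(
    chrom: str, start: int, end: int, strand: str = "+", gene_id: str = "geneA",
    utr3: tuple[int, int] | None = None,
) -> dict[str, GeneModel]:
    """One single-exon gene covering [start, end]."""
    utr = [GenomicInterval(chrom, *utr3, strand)] if utr3 else []
    return {gene_id: GeneModel(gene_id, strand, [GenomicInterval(chrom, start, end, strand)], utr)}


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A compact simulated cohort shared across tests (3 tumors, 2 controls)."""
    cfg = SimConfig(
        seed=11, n_tumor=3, n_control=2, n_chroms=1, chrom_length=70_000,
        n_genes=24, n_edit_sites=400, n_germline_snv=120, n_somatic_snv=10,
        coverage=35.0,
    )
    outdir = tmp_path_factory.mktemp("cohort")
    paths, truth = simulate_cohort(cfg, outdir)
    return cfg, paths, truth


@pytest.fixture(scope="session")
def small_cohort_resources(small_cohort):
    """Parsed reference/annotation/pileups for the shared cohort."""
    from edscape import GeneIndex, build_pileup_table, read_bed, read_gtf, read_reference, read_vcf

    cfg, paths, truth = small_cohort
    ref = read_reference(str(paths.reference))
    gene_models = read_gtf(str(paths.gtf))
    resources = {
        "reference": ref,
        "gene_models": gene_models,
        "gene_index": GeneIndex(gene_models),
        "alu": read_bed(str(paths.alu_bed)),
        "repeats": read_bed(str(paths.repeats_bed)),
        "pileups": {
            sid: build_pileup_table(str(paths.sam(sid)), ref)
            for sid in paths.sample_ids
        },
        "vcfs": {sid: read_vcf(str(paths.vcf(sid))) for sid in paths.sample_ids},
    }
    return resources


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def make_diffedit_pools(tmp_path: Path, name: str, freqs_a, freqs_b,
                        coverage: int = 100, seed: int = 0):
    """Two pooled single-gene samples with per-site editing frequencies.

    Returns (reference, gene_models, pileup_a, pileup_b, {pos: freq_a}).
    """
    from edscape.io_formats import build_pileup_table, read_reference
    from edscape.synthetic_data import simulate_pooled_pair

    fasta, genes, sam_a, sam_b, sites_a = simulate_pooled_pair(
        tmp_path, freqs_a, freqs_b, coverage=coverage, seed=seed, name=name
    )
    ref = read_reference(str(fasta))
    pa = build_pileup_table(str(sam_a), ref)
    pb = build_pileup_table(str(sam_b), ref)
    return ref, genes, pa, pb, sites_a
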