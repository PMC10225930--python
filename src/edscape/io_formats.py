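"""Readers/writers for genomic file formats and the pileup engine.

All internal coordinates are 1-based inclusive (VCF-style). BED's 0-based
half-open convention is converted at the file boundary, in both directions.

The pileup engine turns coordinate-sorted SAM/BAM alignments into columnar
per-observation tables (position, base, base quality, mapping quality,
distance to the nearer raw-read end, read strand, source read index). The
columnar form is what detection and the editing indices consume; a
:class:`PileupColumn` stream view is provided on top of it.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pysam
from intervaltree import IntervalTree
from pyfaidx import Fasta

# ---------------------------------------------------------------------------
# Base encoding shared across the package
# ---------------------------------------------------------------------------

BASES = "ACGTN"
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
CODE_A, CODE_C, CODE_G, CODE_T, CODE_N = range(5)

_ASCII_TO_CODE = np.full(256, CODE_N, dtype=np.uint8)
for _b, _c in BASE_TO_CODE.items():
    _ASCII_TO_CODE[ord(_b)] = _c
    _ASCII_TO_CODE[ord(_b.lower())] = _c

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode_bases(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0 C=1 G=2 T=3 N=4)."""
    return _ASCII_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class GeneModel:
    """Exon/intron/3'UTR structure of one gene.

    Exons must be non-overlapping and sorted; introns are the gaps between
    consecutive exons. All intervals share the gene's chrom and strand.
    """

    gene_id: str
    strand: str
    exons: list[GenomicInterval]
    utr3: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping exons in {self.gene_id}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end + 1:
                out.append(GenomicInterval(self.chrom, a.end + 1, b.start - 1, self.strand))
        return out

    def region_class(self, pos: int) -> str:
        """Classify a position within the gene span.

        Returns one of ``utr3``, ``utr5``, ``exon_cds``, ``intron``;
        ``intergenic`` if the position lies outside the gene span.
        """
        if not (self.span.start <= pos <= self.span.end):
            return "intergenic"
        for u in self.utr3:
            if u.start <= pos <= u.end:
                return "utr3"
        for u in self.utr5:
            if u.start <= pos <= u.end:
                return "utr5"
        for e in self.exons:
            if e.start <= pos <= e.end:
                return "exon_cds"
        return "intron"


class IntervalSet:
    """Point- and interval-queryable set of GenomicIntervals (per chrom)."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self.intervals: list[GenomicInterval] = []
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self.intervals.append(iv)
        # intervaltree is half-open; store [start, end+1)
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end + 1, iv)

    def at(self, chrom: str, pos: int) -> list[GenomicInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((h.data for h in tree.at(pos)), key=lambda iv: (iv.start, iv.end))

    def contains(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return tree is not None and bool(tree.at(pos))

    def mask(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorised membership test for an array of 1-based positions."""
        tree = self._trees.get(chrom)
        if tree is None or len(tree) == 0:
            return np.zeros(len(positions), dtype=bool)
        starts = np.array(sorted(i.begin for i in tree))
        # merge intervals to disjoint runs for a searchsorted test
        runs: list[tuple[int, int]] = []
        for i in sorted(tree, key=lambda x: x.begin):
            if runs and i.begin <= runs[-1][1]:
                runs[-1] = (runs[-1][0], max(runs[-1][1], i.end))
            else:
                runs.append((i.begin, i.end))
        starts = np.array([r[0] for r in runs])
        ends = np.array([r[1] for r in runs])  # half-open ends
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(positions), dtype=bool)
        out[ok] = positions[ok] < ends[idx[ok]]
        return out

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)


@dataclass
class DnaVariantTable:
    """Per-sample set of DNA SNVs, keyed by (chrom, pos).

    Indels in the source VCF are ignored; the count of skipped records is
    kept so callers can log attrition.
    """

    records: dict[tuple[str, int], tuple[str, str]] = field(default_factory=dict)
    source: str = "germline"
    n_skipped_indels: int = 0

    def add(self, chrom: str, pos: int, ref: str, alt: str) -> None:
        self.records[(chrom, pos)] = (ref.upper(), alt.upper())

    def has(self, chrom: str, pos: int) -> bool:
        return (chrom, pos) in self.records

    def positions(self, chrom: str) -> np.ndarray:
        return np.array(sorted(p for c, p in self.records if c == chrom), dtype=np.int64)

    def mask(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        known = self.positions(chrom)
        if len(known) == 0:
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(known, positions)
        idx = np.clip(idx, 0, len(known) - 1)
        return known[idx] == positions

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------


class ReferenceGenome:
    """Indexed FASTA accessor; ``fetch`` uses 1-based inclusive coordinates."""

    def __init__(self, fasta_path: str) -> None:
        self._fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)

    @property
    def chroms(self) -> list[str]:
        return list(self._fa.keys())

    def chrom_length(self, chrom: str) -> int:
        if chrom not in self._fa:
            raise KeyError(f"unknown chrom {chrom!r}")
        return len(self._fa[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fa:
            raise KeyError(f"unknown chrom {chrom!r}")
        if start < 1 or end < start:
            raise ValueError(f"bad coordinates {start}-{end}")
        return str(self._fa[chrom][start - 1 : end])

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)

    def codes(self, chrom: str) -> np.ndarray:
        """Whole-chromosome base codes (cached)."""
        if not hasattr(self, "_code_cache"):
            self._code_cache: dict[str, np.ndarray] = {}
        if chrom not in self._code_cache:
            self._code_cache[chrom] = encode_bases(str(self._fa[chrom][:]))
        return self._code_cache[chrom]


def read_reference(fasta_path: str) -> ReferenceGenome:
    """Open an indexed FASTA reference (index built on first use)."""
    return ReferenceGenome(fasta_path)


# ---------------------------------------------------------------------------
# BED / GTF / VCF / GMT readers
# ---------------------------------------------------------------------------


def read_bed(bed_path: str) -> IntervalSet:
    """Read a BED(6) file into an IntervalSet (1-based inclusive internally).

    Records with start >= end on disk are rejected with a warning on stderr.
    """
    out = IntervalSet()
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            if start0 >= end0:
                print(
                    f"[edscape] {bed_path}:{lineno}: rejected BED record with "
                    f"start >= end ({start0} >= {end0})",
                    file=sys.stderr,
                )
                continue
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            out.add(GenomicInterval(chrom, start0 + 1, end0, strand))
    return out


# Alias matching the field's naming for the Alu track.
read_alu_bed = read_bed


def write_bed(intervals: Iterable[GenomicInterval], bed_path: str) -> None:
    with open(bed_path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\tiv{i}\t0\t{iv.strand}\n")


def _gtf_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part.split(" ", 1)[1].strip('"')
    return None


def read_gtf(gtf_path: str) -> dict[str, GeneModel]:
    """Parse gene models from a GTF; uses exon / three_prime_utr /
    five_prime_utr features and the gene_id attribute."""
    exons: dict[str, list[GenomicInterval]] = {}
    utr3: dict[str, list[GenomicInterval]] = {}
    utr5: dict[str, list[GenomicInterval]] = {}
    strands: dict[str, str] = {}
    with open(gtf_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, feature, start, end, strand, attrs = (
                f[0], f[2], int(f[3]), int(f[4]), f[6], f[8],
            )
            gid = _gtf_attr(attrs, "gene_id")
            if gid is None:
                continue
            iv = GenomicInterval(chrom, start, end, strand)
            strands[gid] = strand
            if feature == "exon":
                exons.setdefault(gid, []).append(iv)
            elif feature == "three_prime_utr":
                utr3.setdefault(gid, []).append(iv)
            elif feature == "five_prime_utr":
                utr5.setdefault(gid, []).append(iv)
    return {
        gid: GeneModel(gid, strands[gid], exons[gid], utr3.get(gid, []), utr5.get(gid, []))
        for gid in exons
    }


class GeneIndex:
    """Point lookup of overlapping genes with region classification."""

    def __init__(self, genes: dict[str, GeneModel]) -> None:
        self.genes = genes
        self._spans = IntervalSet()
        self._by_span: dict[tuple[str, int, int], str] = {}
        for gid, g in genes.items():
            sp = GenomicInterval(g.chrom, g.span.start, g.span.end, g.strand)
            self._spans.add(sp)
            self._by_span[(sp.chrom, sp.start, sp.end)] = gid

    def genes_at(self, chrom: str, pos: int) -> list[GeneModel]:
        hits = self._spans.at(chrom, pos)
        return [self.genes[self._by_span[(h.chrom, h.start, h.end)]] for h in hits]

    def canonical_gene_at(self, chrom: str, pos: int) -> GeneModel | None:
        """Longest-span gene overlapping the position, ties by gene_id."""
        hits = self.genes_at(chrom, pos)
        if not hits:
            return None
        return max(hits, key=lambda g: (len(g.span), g.gene_id))

    def classify(self, chrom: str, pos: int) -> tuple[str | None, str, str | None]:
        """Return (canonical gene_id, region class, gene strand) at a position.

        Intergenic positions return (None, 'intergenic', None). Positions in
        genes on both strands return strand None (ambiguous polarity).
        """
        hits = self.genes_at(chrom, pos)
        if not hits:
            return None, "intergenic", None
        canon = max(hits, key=lambda g: (len(g.span), g.gene_id))
        strands = {g.strand for g in hits}
        strand = canon.strand if len(strands) == 1 else None
        return canon.gene_id, canon.region_class(pos), strand


def read_vcf(vcf_path: str, source: str = "germline") -> DnaVariantTable:
    """Read SNVs from a VCF v4.x file; indels are counted and skipped."""
    table = DnaVariantTable(source=source)
    with pysam.VariantFile(str(vcf_path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                if len(rec.ref) == 1 and len(alt) == 1 and alt != "*":
                    table.add(rec.chrom, rec.pos, rec.ref, alt)
                else:
                    table.n_skipped_indels += 1
    return table


def read_gmt(gmt_path: str) -> dict[str, list[str]]:
    """Read gene sets from a GMT file: name, description, genes (tab-split)."""
    sets: dict[str, list[str]] = {}
    with open(gmt_path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            genes = [g for g in parts[2:] if g]
            seen: list[str] = []
            for g in genes:  # preserve order, drop duplicates
                if g not in seen:
                    seen.append(g)
            sets[parts[0]] = seen
    return sets


def write_gmt(sets: dict[str, list[str]], gmt_path: str) -> None:
    with open(gmt_path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


# ---------------------------------------------------------------------------
# Pileup engine
# ---------------------------------------------------------------------------

STRAND_FWD, STRAND_REV = 0, 1

# flags excluded from pileup: unmapped, secondary, QC fail, duplicate, supplementary
_EXCLUDE_FLAGS = 0x4 | 0x100 | 0x200 | 0x400 | 0x800


@dataclass
class PileupColumn:
    """All read observations at one reference position."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    base: np.ndarray       # uint8 codes per observation
    qual: np.ndarray       # phred base quality
    mapq: np.ndarray       # phred mapping quality
    end_dist: np.ndarray   # bp to the nearer raw-read end
    strand: np.ndarray     # 0 fwd / 1 rev
    read_index: np.ndarray  # index of the source read in file order

    @property
    def depth(self) -> int:
        return len(self.base)

    def base_counts(self) -> dict[str, int]:
        counts = np.bincount(self.base, minlength=5)
        return {BASES[i]: int(counts[i]) for i in range(5) if counts[i]}


class ChromPileup:
    """Columnar observation table for one chromosome, sorted by position."""

    def __init__(self, chrom: str, pos, base, qual, mapq, end_dist, strand, read_index):
        order = np.argsort(pos, kind="stable")
        self.chrom = chrom
        self.pos = pos[order]
        self.base = base[order]
        self.qual = qual[order]
        self.mapq = mapq[order]
        self.end_dist = end_dist[order]
        self.strand = strand[order]
        self.read_index = read_index[order]

    def __len__(self) -> int:
        return len(self.pos)

    def covered_positions(self) -> np.ndarray:
        return np.unique(self.pos)

    def slice_at(self, pos: int) -> slice:
        lo = np.searchsorted(self.pos, pos, side="left")
        hi = np.searchsorted(self.pos, pos, side="right")
        return slice(lo, hi)

    def column(self, pos: int, ref: ReferenceGenome) -> PileupColumn:
        s = self.slice_at(pos)
        return PileupColumn(
            self.chrom, int(pos), ref.base(self.chrom, int(pos)),
            self.base[s], self.qual[s], self.mapq[s],
            self.end_dist[s], self.strand[s], self.read_index[s],
        )


class PileupTable:
    """Per-chromosome columnar pileup for one sample's alignments."""

    def __init__(self, chroms: dict[str, ChromPileup], n_reads: int) -> None:
        self.chroms = chroms
        self.n_reads = n_reads

    def column(self, chrom: str, pos: int, ref: ReferenceGenome) -> PileupColumn:
        return self.chroms[chrom].column(pos, ref)

    def iter_columns(self, ref: ReferenceGenome) -> Iterator[PileupColumn]:
        for chrom in self.chroms:
            cp = self.chroms[chrom]
            for pos in cp.covered_positions():
                yield cp.column(int(pos), ref)


def build_pileup_table(
    alignment_path: str,
    reference: ReferenceGenome,
    regions: Iterable[GenomicInterval] | None = None,
    trim_to_length: int | None = None,
) -> PileupTable:
    """Stream coordinate-sorted SAM/BAM into a columnar pileup table.

    Secondary, supplementary, duplicate-flagged and unmapped reads are
    excluded. Reads with insertions/deletions contribute only aligned match
    positions; soft-clipped bases are skipped but count toward the raw-read
    end distance. ``trim_to_length`` drops observations beyond the first N
    query bases (read-length cutting for index computations); end distances
    still refer to the raw read. Raises ValueError on coordinate-unsorted
    input.
    """
    per_chrom: dict[str, dict[str, list[np.ndarray]]] = {}
    n_reads = 0
    region_list = list(regions) if regions is not None else None

    with pysam.AlignmentFile(str(alignment_path), check_sq=False) as af:
        ref_chroms = set(reference.chroms)
        for sq in af.references:
            if sq not in ref_chroms:
                raise ValueError(
                    f"alignment chrom {sq!r} absent from reference "
                    f"(reference has {sorted(ref_chroms)})"
                )
        last: tuple[int, int] | None = None
        for read in af:
            if read.flag & _EXCLUDE_FLAGS:
                continue
            key = (read.reference_id, read.reference_start)
            if last is not None and key < last:
                raise ValueError(
                    "alignments are not coordinate-sorted; sort with "
                    "'samtools sort' first"
                )
            last = key
            chrom = read.reference_name
            seq = read.query_sequence
            if seq is None:
                continue
            read_idx = n_reads
            n_reads += 1
            raw_len = len(seq)
            quals = read.query_qualities
            qual_arr = (
                np.asarray(quals, dtype=np.uint8)
                if quals is not None
                else np.full(raw_len, 30, dtype=np.uint8)
            )
            base_arr = encode_bases(seq)

            cig = read.cigartuples
            if cig is not None and len(cig) == 1 and cig[0][0] == 0:
                qpos = np.arange(raw_len, dtype=np.int64)
                rpos = (read.reference_start + 1 + qpos).astype(np.int32)
            else:
                pairs = read.get_aligned_pairs(matches_only=True)
                if not pairs:
                    continue
                qpos = np.array([p[0] for p in pairs], dtype=np.int64)
                rpos = (np.array([p[1] for p in pairs], dtype=np.int64) + 1).astype(np.int32)

            end_dist = np.minimum(qpos, raw_len - 1 - qpos).astype(np.int16)
            if trim_to_length is not None and raw_len > trim_to_length:
                keep = qpos < trim_to_length
                qpos, rpos, end_dist = qpos[keep], rpos[keep], end_dist[keep]
            n = len(qpos)
            store = per_chrom.setdefault(
                chrom,
                {k: [] for k in ("pos", "base", "qual", "mapq", "end_dist", "strand", "read_index")},
            )
            store["pos"].append(rpos)
            store["base"].append(base_arr[qpos])
            store["qual"].append(qual_arr[qpos])
            store["mapq"].append(np.full(n, read.mapping_quality, dtype=np.uint8))
            store["end_dist"].append(end_dist)
            store["strand"].append(
                np.full(n, STRAND_REV if read.is_reverse else STRAND_FWD, dtype=np.uint8)
            )
            store["read_index"].append(np.full(n, read_idx, dtype=np.int32))

    chrom_tables: dict[str, ChromPileup] = {}
    for chrom, store in per_chrom.items():
        arrs = {k: np.concatenate(v) for k, v in store.items()}
        if region_list is not None:
            keep = np.zeros(len(arrs["pos"]), dtype=bool)
            for iv in region_list:
                if iv.chrom == chrom:
                    keep |= (arrs["pos"] >= iv.start) & (arrs["pos"] <= iv.end)
            arrs = {k: v[keep] for k, v in arrs.items()}
        if len(arrs["pos"]):
            chrom_tables[chrom] = ChromPileup(chrom, **arrs)
    return PileupTable(chrom_tables, n_reads)


def pileup(
    alignment_path: str,
    reference: ReferenceGenome,
    regions: Iterable[GenomicInterval] | None = None,
) -> Iterator[PileupColumn]:
    """Yield one PileupColumn per covered reference position."""
    table = build_pileup_table(alignment_path, reference, regions)
    yield from table.iter_columns(reference)


def write_pileup_tsv(table: PileupTable, reference: ReferenceGenome, out_path: str) -> None:
    """Debug dump: chrom, pos, ref, A/C/G/T counts per covered position."""
    with open(out_path, "w") as fh:
        fh.write("chrom\tpos\tref\tA\tC\tG\tT\n")
        for col in table.iter_columns(reference):
            c = np.bincount(col.base, minlength=5)
            fh.write(
                f"{col.chrom}\t{col.pos}\t{col.ref_base}\t{c[0]}\t{c[1]}\t{c[2]}\t{c[3]}\n"
            )
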