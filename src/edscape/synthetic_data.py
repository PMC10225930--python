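"""Synthetic tumor/control cohort generator with planted A-to-I editing.

Emulates the statistical structure of ADAR1-driven editing in a B-cell
lymphoma cohort: edited adenosines concentrated in Alu repeats inside genes
(default 90%), a 5'-U / 3'-G neighbor preference, per-sample editing
activity (tumor activity ~3x control), germline and somatic DNA SNVs,
per-gene expression levels, and fixed-length ungapped sequencing reads with
base-call errors. Every planted quantity is written to a machine-readable
truth table so downstream detection, indices and cohort statistics can be
tested for parameter recovery without any external download.

Reads are emitted directly as aligned SAM records: all downstream
computations start post-alignment, so no aligner is needed. Splice
junctions, isoforms and fragment-size structure are deliberately absent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    BASES,
    COMPLEMENT,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    encode_bases,
)

_CODE = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def _default_motif_bias() -> dict:
    # ADAR1 neighbor preference: depleted 5' G, enriched 5' U; enriched 3' G.
    return {
        "five_prime": {"A": 0.15, "C": 0.15, "G": 0.10, "T": 0.60},
        "three_prime": {"A": 0.15, "C": 0.15, "G": 0.55, "T": 0.15},
    }


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults model a small tumor/control cohort: 10 tumors vs 4 controls,
    1,000 planted editing sites of which 90% fall in Alu intervals and 95%
    are A-to-I, mean tumor editing activity 3x the control mean, 30x mean
    coverage with 100 bp reads and a 1e-3 per-base error rate, and 200
    germline plus 20 somatic SNVs per sample.
    """

    seed: int = 0
    n_tumor: int = 10
    n_control: int = 4
    n_chroms: int = 2
    chrom_length: int = 100_000
    n_genes: int = 40
    alu_density: float = 0.35
    n_edit_sites: int = 1000
    alu_site_fraction: float = 0.9
    a2g_fraction: float = 0.95
    motif_bias: dict = field(default_factory=_default_motif_bias)
    tumor_activity_mean: float = 1.0
    control_activity_mean: float = 1.0 / 3.0
    activity_sigma: float = 0.25
    base_freq_low: float = 0.05
    base_freq_high: float = 0.60
    tumor_exclusive_fraction: float = 0.3
    coverage: float = 30.0
    read_length: int = 100
    seq_error_rate: float = 0.001
    qual_high: int = 37
    qual_low: int = 12
    qual_low_fraction: float = 0.08
    mapq_high: int = 60
    mapq_low: int = 20
    mapq_low_fraction: float = 0.03
    n_germline_snv: int = 200
    n_somatic_snv: int = 20
    somatic_read_fraction: float = 0.4
    n_simple_repeats: int = 10
    expr_sigma: float = 0.8
    # If set, every transcribed-strand adenosine inside Alu intervals is
    # edited at this frequency in every sample (discrete site planting is
    # bypassed); used for editing-index parameter-recovery experiments.
    uniform_alu_editing: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "alu_density", "alu_site_fraction", "a2g_fraction",
            "tumor_exclusive_fraction", "seq_error_rate",
            "qual_low_fraction", "mapq_low_fraction", "somatic_read_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_tumor < 1 or self.n_control < 1:
            raise ValueError("n_tumor and n_control must be >= 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not self.base_freq_low <= self.base_freq_high:
            raise ValueError("base_freq_low must be <= base_freq_high")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SimTruth:
    """Planted ground truth of one simulated cohort.

    ``sites`` has one row per planted site (chrom, pos, strand, ref, alt,
    edit_type, is_a2i, alu, gene_id, region, base_freq) plus one
    ``freq:<sample>`` column per sample with the true per-sample editing
    frequency. ``samples`` holds group labels and activity multipliers;
    ``expression`` the true TPM matrix (genes x samples).
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    expression: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample"])

    def freq_columns(self) -> list[str]:
        return [c for c in self.sites.columns if c.startswith("freq:")]


@dataclass
class CohortPaths:
    """Locations of all files written by :func:`simulate_cohort`."""

    outdir: Path
    reference: Path
    gtf: Path
    alu_bed: Path
    repeats_bed: Path
    expression: Path
    truth_sites: Path
    truth_samples: Path
    config_yaml: Path
    sample_ids: list[str]
    tumor_ids: list[str]
    control_ids: list[str]

    def sam(self, sample: str) -> Path:
        return self.outdir / f"{sample}.sam"

    def vcf(self, sample: str) -> Path:
        return self.outdir / f"{sample}.vcf"


# ---------------------------------------------------------------------------
# Genome and annotation layout
# ---------------------------------------------------------------------------

_GENE_PARTS = (600, 300, 600, 300, 400)  # exon, intron, exon, intron, exon
_GENE_LEN = sum(_GENE_PARTS)
_UTR3_LEN = 300
_INTERGENIC_GAP = 400


def _layout_genes(cfg: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    needed = 1000 + per_chrom * (_GENE_LEN + _INTERGENIC_GAP)
    if needed > cfg.chrom_length:
        raise ValueError(
            f"chrom_length {cfg.chrom_length} too small for "
            f"{per_chrom} genes per chrom (need >= {needed})"
        )
    genes: list[GeneModel] = []
    g = 0
    for chrom in chroms:
        cursor = 1000
        for _ in range(per_chrom):
            if g >= cfg.n_genes:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            exons: list[GenomicInterval] = []
            p = cursor
            for k, ln in enumerate(_GENE_PARTS):
                iv = GenomicInterval(chrom, p, p + ln - 1, strand)
                if k % 2 == 0:
                    exons.append(iv)
                p += ln
            # 3'UTR: terminal exon end in transcription direction
            if strand == "+":
                last = exons[-1]
                utr3 = [GenomicInterval(chrom, last.end - _UTR3_LEN + 1, last.end, strand)]
            else:
                first = exons[0]
                utr3 = [GenomicInterval(chrom, first.start, first.start + _UTR3_LEN - 1, strand)]
            genes.append(GeneModel(f"gene{g:03d}", strand, exons, utr3))
            cursor += _GENE_LEN + _INTERGENIC_GAP
            g += 1
    return genes


def _layout_alu(cfg: SimConfig, genes: list[GeneModel], rng: np.random.Generator) -> list[GenomicInterval]:
    """Non-overlapping ~300 bp Alu intervals covering ~alu_density of each gene."""
    alus: list[GenomicInterval] = []
    alu_len = 300
    for gm in genes:
        span = gm.span
        n_alu = int(round(cfg.alu_density * len(span) / alu_len))
        slots = (len(span) - 1) // alu_len
        if n_alu == 0 or slots == 0:
            continue
        chosen = rng.choice(slots, size=min(n_alu, slots), replace=False)
        for s in sorted(chosen):
            start = span.start + int(s) * alu_len
            alus.append(GenomicInterval(span.chrom, start, min(start + alu_len - 1, span.end), gm.strand))
    return alus


def _layout_repeats(cfg: SimConfig, genes: list[GeneModel], rng: np.random.Generator) -> list[GenomicInterval]:
    """Short simple-repeat intervals placed in intergenic gaps."""
    out: list[GenomicInterval] = []
    gaps: list[GenomicInterval] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for gm in genes:
        by_chrom.setdefault(gm.chrom, []).append(gm)
    for chrom, gms in by_chrom.items():
        gms = sorted(gms, key=lambda g: g.span.start)
        for a, b in zip(gms, gms[1:]):
            if b.span.start - a.span.end > 120:
                gaps.append(GenomicInterval(chrom, a.span.end + 30, b.span.start - 30, "."))
    for i in range(min(cfg.n_simple_repeats, len(gaps))):
        gap = gaps[int(rng.integers(len(gaps)))]
        start = int(rng.integers(gap.start, max(gap.start + 1, gap.end - 50)))
        out.append(GenomicInterval(gap.chrom, start, min(start + 49, gap.end), "."))
    return out


# ---------------------------------------------------------------------------
# Site planting
# ---------------------------------------------------------------------------


def _transcribed_a_positions(seq_codes: np.ndarray, gm: GeneModel) -> np.ndarray:
    """1-based positions within the gene span whose transcribed-strand base is A."""
    span = gm.span
    codes = seq_codes[span.start - 1 : span.end]
    want = _CODE["A"] if gm.strand == "+" else _CODE["T"]
    rel = np.flatnonzero(codes == want)
    return rel + span.start


def _motif_weights(cfg: SimConfig, seqs: dict[str, np.ndarray],
                   chrom: str, pos: np.ndarray, strand: str) -> np.ndarray:
    """Planting weight per candidate adenosine from its transcribed-strand
    5' and 3' neighbor bases."""
    codes = seqs[chrom]
    w5 = np.array([cfg.motif_bias["five_prime"][b] for b in "ACGT"] + [0.0])
    w3 = np.array([cfg.motif_bias["three_prime"][b] for b in "ACGT"] + [0.0])
    left = codes[pos - 2]   # reference base 5' on forward strand
    right = codes[pos]      # reference base 3' on forward strand
    if strand == "+":
        return w5[left] * w3[right]
    comp = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G
    return w5[comp[right]] * w3[comp[left]]


def _plant_sites(cfg: SimConfig, seqs: dict[str, np.ndarray],
                 genes: list[GeneModel], alu: IntervalSet,
                 rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    cand_chrom, cand_pos, cand_gene, cand_alu, cand_w = [], [], [], [], []
    for gm in genes:
        pos = _transcribed_a_positions(seqs[gm.chrom], gm)
        # exclude span edges so both neighbors exist within the chrom
        pos = pos[(pos > 1) & (pos < len(seqs[gm.chrom]))]
        if len(pos) == 0:
            continue
        in_alu = alu.mask(gm.chrom, pos)
        w = _motif_weights(cfg, seqs, gm.chrom, pos, gm.strand)
        cand_chrom.extend([gm.chrom] * len(pos))
        cand_pos.append(pos)
        cand_gene.extend([gm.gene_id] * len(pos))
        cand_alu.append(in_alu)
        cand_w.append(w)
    pos_all = np.concatenate(cand_pos)
    alu_all = np.concatenate(cand_alu)
    w_all = np.concatenate(cand_w)
    chrom_all = np.array(cand_chrom)
    gene_all = np.array(cand_gene)

    n_alu_target = int(rng.binomial(cfg.n_edit_sites, cfg.alu_site_fraction))
    picked: list[int] = []
    for want_alu, n_want in ((True, n_alu_target), (False, cfg.n_edit_sites - n_alu_target)):
        idx = np.flatnonzero(alu_all == want_alu)
        if n_want > len(idx):
            raise ValueError(
                f"n_edit_sites={cfg.n_edit_sites}: only {len(idx)} candidate "
                f"adenosines with alu={want_alu} available ({n_want} requested)"
            )
        if n_want == 0:
            continue
        w = w_all[idx]
        p = w / w.sum()
        picked.extend(rng.choice(idx, size=n_want, replace=False, p=p).tolist())

    gene_by_id = {g.gene_id: g for g in genes}
    for i in sorted(picked, key=lambda k: (chrom_all[k], pos_all[k])):
        chrom, pos, gid = chrom_all[i], int(pos_all[i]), gene_all[i]
        gm = gene_by_id[gid]
        ref_fwd = BASES[seqs[chrom][pos - 1]]
        is_a2i = rng.random() < cfg.a2g_fraction
        if is_a2i:
            alt_t = "G"  # transcribed-strand alt
        else:
            alt_t = "C" if rng.random() < 0.5 else "T"
        alt_fwd = alt_t if gm.strand == "+" else COMPLEMENT[alt_t]
        rows.append({
            "chrom": chrom, "pos": pos, "strand": gm.strand,
            "ref_fwd": ref_fwd, "alt_fwd": alt_fwd,
            "edit_type": f"A>{alt_t}", "is_a2i": bool(is_a2i),
            "alu": bool(alu_all[i]), "gene_id": gid,
            "region": gm.region_class(pos),
            "base_freq": float(rng.uniform(cfg.base_freq_low, cfg.base_freq_high)),
            "tumor_exclusive": bool(rng.random() < cfg.tumor_exclusive_fraction),
        })
    return pd.DataFrame(rows)


def _uniform_alu_sites(cfg: SimConfig, seqs: dict[str, np.ndarray],
                       genes: list[GeneModel], alu: IntervalSet) -> pd.DataFrame:
    rows = []
    for gm in genes:
        pos = _transcribed_a_positions(seqs[gm.chrom], gm)
        pos = pos[(pos > 1) & (pos < len(seqs[gm.chrom]))]
        pos = pos[alu.mask(gm.chrom, pos)]
        for p in pos:
            rows.append({
                "chrom": gm.chrom, "pos": int(p), "strand": gm.strand,
                "ref_fwd": BASES[seqs[gm.chrom][p - 1]],
                "alt_fwd": "G" if gm.strand == "+" else "C",
                "edit_type": "A>G", "is_a2i": True, "alu": True,
                "gene_id": gm.gene_id, "region": gm.region_class(int(p)),
                "base_freq": float(cfg.uniform_alu_editing),
                "tumor_exclusive": False,
            })
    return pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _simulate_sample_reads(
    cfg: SimConfig,
    seqs: dict[str, np.ndarray],
    genes: list[GeneModel],
    sites: pd.DataFrame,
    site_freq: np.ndarray,
    rel_expr: np.ndarray,
    variants: list[tuple[str, int, str, str, str]],
    rng: np.random.Generator,
) -> list[tuple[str, int, int, int, str, str]]:
    """Simulate one sample's reads; returns (chrom, start, flag, mapq, seq, qual)."""
    L = cfg.read_length
    out: list[tuple[str, int, int, int, str, str]] = []
    site_by_gene: dict[str, list[int]] = {}
    for i, gid in enumerate(sites["gene_id"]):
        site_by_gene.setdefault(gid, []).append(i)
    var_by_gene: dict[str, list[tuple[str, int, str, str, str]]] = {}
    gene_span = {g.gene_id: g.span for g in genes}
    for v in variants:
        for gm in genes:
            sp = gene_span[gm.gene_id]
            if v[0] == sp.chrom and sp.start <= v[1] <= sp.end:
                var_by_gene.setdefault(gm.gene_id, []).append(v)

    base_lut = np.frombuffer("ACGTN".encode(), dtype=np.uint8)

    for gi, gm in enumerate(genes):
        span = gm.span
        depth = cfg.coverage * rel_expr[gi]
        n_reads = int(rng.poisson(depth * len(span) / L))
        if n_reads == 0 or len(span) < L:
            continue
        starts = rng.integers(span.start, span.end - L + 2, size=n_reads)
        ref_codes = seqs[span.chrom]
        mat = ref_codes[starts[:, None] - 1 + np.arange(L)].astype(np.uint8)

        for chrom, vpos, vref, valt, vsource in var_by_gene.get(gm.gene_id, []):
            off = vpos - starts
            cover = (off >= 0) & (off < L)
            if vsource == "somatic":
                cover &= rng.random(n_reads) < cfg.somatic_read_fraction
            mat[cover, off[cover]] = _CODE[valt]

        for si in site_by_gene.get(gm.gene_id, []):
            f = site_freq[si]
            if f <= 0:
                continue
            spos = int(sites.at[si, "pos"])
            off = spos - starts
            cover = (off >= 0) & (off < L)
            edited = cover & (rng.random(n_reads) < f)
            mat[edited, off[edited]] = _CODE[sites.at[si, "alt_fwd"]]

        if cfg.seq_error_rate > 0:
            err = rng.random(mat.shape) < cfg.seq_error_rate
            shift = rng.integers(1, 4, size=int(err.sum()))
            mat[err] = (mat[err] + shift) % 4

        quals = np.where(
            rng.random(mat.shape) < cfg.qual_low_fraction, cfg.qual_low, cfg.qual_high
        ).astype(np.uint8)
        mapqs = np.where(
            rng.random(n_reads) < cfg.mapq_low_fraction, cfg.mapq_low, cfg.mapq_high
        ).astype(int)
        flags = np.where(rng.random(n_reads) < 0.5, 16, 0)

        seq_bytes = np.ascontiguousarray(base_lut[mat]).view(f"S{L}").ravel()
        qual_bytes = np.ascontiguousarray(quals + 33).view(f"S{L}").ravel()
        for r in range(n_reads):
            out.append((
                span.chrom, int(starts[r]), int(flags[r]), int(mapqs[r]),
                seq_bytes[r].decode("ascii"), qual_bytes[r].decode("ascii"),
            ))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def _write_sam(path: Path, reads, chrom_lengths: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, ln in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{ln}\n")
        L = None
        for i, (chrom, start, flag, mapq, seq, qual) in enumerate(reads):
            L = len(seq)
            fh.write(
                f"r{i:07d}\t{flag}\t{chrom}\t{start}\t{mapq}\t{L}M\t*\t0\t0\t{seq}\t{qual}\n"
            )


def _write_vcf(path: Path, variants, chrom_lengths: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Somatic variant">\n')
        for chrom, ln in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt, source in sorted(variants, key=lambda v: (v[0], v[1])):
            info = "SOMATIC" if source == "somatic" else "."
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")


def _write_fasta(path: Path, seqs: dict[str, np.ndarray]) -> None:
    base_lut = "ACGTN"
    with open(path, "w") as fh:
        for chrom, codes in seqs.items():
            fh.write(f">{chrom}\n")
            s = "".join(base_lut[c] for c in codes)
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")


def _write_gtf(path: Path, genes: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        for gm in genes:
            attrs = f'gene_id "{gm.gene_id}";'
            sp = gm.span
            fh.write(
                f"{sp.chrom}\tsim\tgene\t{sp.start}\t{sp.end}\t.\t{gm.strand}\t.\t{attrs}\n"
            )
            for e in gm.exons:
                fh.write(
                    f"{e.chrom}\tsim\texon\t{e.start}\t{e.end}\t.\t{gm.strand}\t.\t{attrs}\n"
                )
            for u in gm.utr3:
                fh.write(
                    f"{u.chrom}\tsim\tthree_prime_utr\t{u.start}\t{u.end}\t.\t{gm.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


def _lognormal_mean(rng: np.random.Generator, mean: float, sigma: float, size: int) -> np.ndarray:
    mu = np.log(mean) - sigma**2 / 2.0
    return rng.lognormal(mu, sigma, size=size)


def simulate_cohort(cfg: SimConfig, outdir: str | Path) -> tuple[CohortPaths, SimTruth]:
    """Generate a full cohort on disk and return its paths and truth.

    Emits reference FASTA, GTF gene models, Alu and simple-repeat BED, one
    VCF and one coordinate-sorted SAM per sample, the TPM expression matrix,
    and the truth tables. Byte-identical outputs for identical configs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    seqs = {c: rng.integers(0, 4, size=cfg.chrom_length).astype(np.uint8) for c in chroms}
    genes = _layout_genes(cfg, rng)
    alu_ivs = _layout_alu(cfg, genes, rng)
    alu = IntervalSet(alu_ivs)
    repeats = _layout_repeats(cfg, genes, rng)

    if cfg.uniform_alu_editing is not None:
        sites = _uniform_alu_sites(cfg, seqs, genes, alu)
    else:
        sites = _plant_sites(cfg, seqs, genes, alu, rng)

    sample_ids = [f"tumor{i:02d}" for i in range(cfg.n_tumor)] + [
        f"control{i:02d}" for i in range(cfg.n_control)
    ]
    groups = ["tumor"] * cfg.n_tumor + ["control"] * cfg.n_control
    if cfg.uniform_alu_editing is not None:
        activities = np.ones(len(sample_ids))
    else:
        activities = np.concatenate([
            _lognormal_mean(rng, cfg.tumor_activity_mean, cfg.activity_sigma, cfg.n_tumor),
            _lognormal_mean(rng, cfg.control_activity_mean, cfg.activity_sigma, cfg.n_control),
        ])

    # Per-gene expression: shared lognormal base level, mild per-sample noise.
    base_expr = _lognormal_mean(rng, 1.0, cfg.expr_sigma, len(genes))
    expr = base_expr[:, None] * _lognormal_mean(rng, 1.0, 0.1, len(genes) * len(sample_ids)).reshape(
        len(genes), len(sample_ids)
    )
    rel_expr = expr / expr.mean(axis=0, keepdims=True)  # mean depth ~ coverage
    tpm = expr / expr.sum(axis=0, keepdims=True) * 1e6
    expression = pd.DataFrame(tpm, index=[g.gene_id for g in genes], columns=sample_ids)
    expression.index.name = "gene_id"

    # DNA variants per sample: germline applied to all reads, somatic to a
    # configured read fraction; never placed on a planted editing site.
    site_pos = {(c, int(p)) for c, p in zip(sites["chrom"], sites["pos"])} if len(sites) else set()
    gene_territory = [(g.span.chrom, g.span.start, g.span.end) for g in genes]
    sample_variants: dict[str, list[tuple[str, int, str, str, str]]] = {}
    for sid in sample_ids:
        vs: list[tuple[str, int, str, str, str]] = []
        taken: set[tuple[str, int]] = set()
        n_som = cfg.n_somatic_snv if sid.startswith("tumor") else 0
        for n_want, source in ((cfg.n_germline_snv, "germline"), (n_som, "somatic")):
            made = 0
            while made < n_want:
                chrom, lo, hi = gene_territory[int(rng.integers(len(gene_territory)))]
                pos = int(rng.integers(lo, hi + 1))
                if (chrom, pos) in site_pos or (chrom, pos) in taken:
                    continue
                ref = BASES[seqs[chrom][pos - 1]]
                alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
                vs.append((chrom, pos, ref, alt, source))
                taken.add((chrom, pos))
                made += 1
        sample_variants[sid] = vs

    # True per-sample frequencies per site.
    freqs = np.zeros((len(sites), len(sample_ids)))
    for j, (sid, grp) in enumerate(zip(sample_ids, groups)):
        f = sites["base_freq"].to_numpy() * activities[j]
        if grp == "control":
            f = np.where(sites["tumor_exclusive"].to_numpy(), 0.0, f)
        freqs[:, j] = np.clip(f, 0.0, 0.95)

    # Write shared files.
    paths = CohortPaths(
        outdir=outdir,
        reference=outdir / "reference.fa",
        gtf=outdir / "genes.gtf",
        alu_bed=outdir / "alu.bed",
        repeats_bed=outdir / "repeats.bed",
        expression=outdir / "expression.tsv",
        truth_sites=outdir / "truth_sites.tsv",
        truth_samples=outdir / "truth_samples.tsv",
        config_yaml=outdir / "sim_config.yaml",
        sample_ids=sample_ids,
        tumor_ids=sample_ids[: cfg.n_tumor],
        control_ids=sample_ids[cfg.n_tumor :],
    )
    _write_fasta(paths.reference, seqs)
    _write_gtf(paths.gtf, genes)
    from .io_formats import write_bed

    write_bed(alu_ivs, paths.alu_bed)
    write_bed(repeats, paths.repeats_bed)
    expression.to_csv(paths.expression, sep="\t")
    cfg.to_yaml(paths.config_yaml)

    chrom_lengths = {c: cfg.chrom_length for c in chroms}
    for j, sid in enumerate(sample_ids):
        reads = _simulate_sample_reads(
            cfg, seqs, genes, sites, freqs[:, j], rel_expr[:, j],
            sample_variants[sid], rng,
        )
        _write_sam(paths.sam(sid), reads, chrom_lengths)
        _write_vcf(paths.vcf(sid), sample_variants[sid], chrom_lengths)

    truth_sites = sites.copy()
    for j, sid in enumerate(sample_ids):
        truth_sites[f"freq:{sid}"] = freqs[:, j]
    truth_samples = pd.DataFrame({
        "sample": sample_ids,
        "group": groups,
        "activity": activities,
        "n_germline_snv": [sum(v[4] == "germline" for v in sample_variants[s]) for s in sample_ids],
        "n_somatic_snv": [sum(v[4] == "somatic" for v in sample_variants[s]) for s in sample_ids],
    })
    truth_sites.to_csv(paths.truth_sites, sep="\t", index=False)
    truth_samples.to_csv(paths.truth_samples, sep="\t", index=False)

    return paths, SimTruth(truth_sites, truth_samples, expression)


def simulate_pooled_pair(
    outdir: str | Path,
    freqs_a: list[float],
    freqs_b: list[float],
    coverage: int = 100,
    seed: int = 0,
    read_length: int = 40,
    gene_length: int = 600,
    name: str = "pool",
):
    """Two pooled single-gene alignments with matched planted site frequencies.

    Plants ``len(freqs_a)`` adenosine sites in one gene and edits them at
    ``freqs_a`` in condition A and ``freqs_b`` in condition B — the minimal
    substrate for differential-editing experiments (identical lists give a
    null pair). Returns (reference_fasta, gene_models, sam_a, sam_b,
    {pos: freq_a}).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if len(freqs_a) != len(freqs_b):
        raise ValueError("freqs_a and freqs_b must have equal length")
    rng = np.random.default_rng(seed)
    L = read_length
    seq_codes = rng.integers(0, 4, size=gene_length + 200).astype(np.uint8)
    refseq = "".join("ACGTN"[c] for c in seq_codes)
    gene = GeneModel("geneA", "+", [GenomicInterval("chr1", 1, gene_length, "+")])
    a_positions = [i + 1 for i in range(gene_length - L) if refseq[i] == "A"]
    if len(freqs_a) > len(a_positions):
        raise ValueError(f"only {len(a_positions)} adenosines available")
    chosen = sorted(rng.choice(len(a_positions), size=len(freqs_a), replace=False))
    sites_a = {a_positions[i]: f for i, f in zip(chosen, freqs_a)}
    sites_b = {a_positions[i]: f for i, f in zip(chosen, freqs_b)}
    sams = []
    for tag, site_freqs in (("A", sites_a), ("B", sites_b)):
        n_reads = int(coverage * gene_length / L)
        starts = rng.integers(1, gene_length - L + 2, size=n_reads)
        reads = []
        for st in starts:
            s = list(refseq[st - 1 : st - 1 + L])
            for pos, f in site_freqs.items():
                off = pos - st
                if 0 <= off < L and rng.random() < f:
                    s[off] = "G"
            reads.append(("chr1", int(st), 0, 60, "".join(s), "F" * L))
        reads.sort(key=lambda t: t[1])
        path = outdir / f"{name}_{tag}.sam"
        _write_sam(path, reads, {"chr1": len(refseq)})
        sams.append(path)
    fasta = outdir / f"{name}.fa"
    _write_fasta(fasta, {"chr1": seq_codes})
    return fasta, {"geneA": gene}, sams[0], sams[1], sites_a


def expression_from_truth(truth: SimTruth) -> pd.DataFrame:
    """TPM matrix (genes x samples) from the truth table, columns scaled to 1e6."""
    m = truth.expression.copy().astype(float)
    return m / m.sum(axis=0) * 1e6


def load_truth(paths: CohortPaths) -> SimTruth:
    sites = pd.read_csv(paths.truth_sites, sep="\t")
    samples = pd.read_csv(paths.truth_samples, sep="\t")
    expression = pd.read_csv(paths.expression, sep="\t", index_col=0)
    return SimTruth(sites, samples, expression)
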