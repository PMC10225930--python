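"""Cohort-level editing analysis: recurrence catalogs, editing-vs-mutation
landscapes, exclusivity statistics, hyper-editing clusters and differential
editing between conditions.

The tumor-enriched catalog keeps A-to-I genic sites detected in strictly
more than a configured fraction of tumor samples (default 10%), in zero
control samples, and in at least two samples overall. Gene-level
edited/mutated status matrices support the editing-vs-mutation landscape
and a per-gene Fisher exclusivity test. Differential editing compares
edited/unedited read counts between two conditions position by position
with Fisher's exact test and Benjamini-Hochberg control, after
mode-specific coverage gates (pooled: at least 10 reads per pool and one
A-to-G read; replicate: at least 50 reads per replicate and 0.2 editing
frequency in the first condition).
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import (
    CODE_A,
    CODE_C,
    CODE_G,
    CODE_T,
    DnaVariantTable,
    GeneModel,
    PileupTable,
    ReferenceGenome,
)
from .indices import IndexConfig, SampleEditingProfile

SiteKey = tuple[str, int]


# ---------------------------------------------------------------------------
# Recurrence catalog
# ---------------------------------------------------------------------------


@dataclass
class RecurrenceCatalog:
    """Tumor-enriched site catalog with per-site recurrence counts."""

    sites: pd.DataFrame      # all considered sites with counts + retained flag
    retained: set[SiteKey]
    min_fraction: float
    n_tumor: int
    n_control: int

    def retained_sites(self) -> pd.DataFrame:
        return self.sites[self.sites["retained"]]


def _profile_site_keys(profile: SampleEditingProfile) -> dict[SiteKey, object]:
    return {
        (s.chrom, s.pos): s
        for s in profile.sites
        if s.is_a_to_i and not s.ambiguous_strand and s.frequency > 0
    }


def build_recurrence_catalog(
    tumor_profiles: list[SampleEditingProfile],
    control_profiles: list[SampleEditingProfile],
    min_fraction: float = 0.10,
    covered_positions: dict[str, set[SiteKey]] | None = None,
) -> RecurrenceCatalog:
    """Catalog A-to-I genic sites enriched in tumors and absent in controls.

    A site is retained iff it is genic, detected in strictly more than
    ``min_fraction`` of tumor samples, detected in zero control samples,
    and reported in at least two samples overall. By default all tumors
    count in the recurrence denominator whether or not they cover the
    position; passing ``covered_positions`` (sample id -> covered site
    keys) switches to a covered-samples denominator.
    """
    if not tumor_profiles:
        raise ValueError("empty tumor cohort")
    tumor_hits = [_profile_site_keys(p) for p in tumor_profiles]
    control_hits = [_profile_site_keys(p) for p in control_profiles]

    all_keys: dict[SiteKey, object] = {}
    for hits in tumor_hits + control_hits:
        for k, s in hits.items():
            all_keys.setdefault(k, s)

    rows = []
    retained: set[SiteKey] = set()
    for key in sorted(all_keys):
        site = all_keys[key]
        n_t = sum(key in h for h in tumor_hits)
        n_c = sum(key in h for h in control_hits)
        genic = site.gene_id is not None and site.region != "intergenic"
        if covered_positions is None:
            denom = len(tumor_profiles)
        else:
            denom = sum(
                key in covered_positions.get(p.sample_id, set())
                for p in tumor_profiles
            )
        frac = n_t / denom if denom else 0.0
        keep = genic and frac > min_fraction and n_c == 0 and (n_t + n_c) >= 2
        if keep:
            retained.add(key)
        rows.append({
            "chrom": key[0], "pos": key[1], "strand": site.strand,
            "gene_id": site.gene_id, "region": site.region, "alu": site.alu,
            "n_tumor_detected": n_t, "n_control_detected": n_c,
            "tumor_denominator": denom, "tumor_fraction": frac,
            "retained": keep,
        })
    df = pd.DataFrame(rows, columns=[
        "chrom", "pos", "strand", "gene_id", "region", "alu",
        "n_tumor_detected", "n_control_detected", "tumor_denominator",
        "tumor_fraction", "retained",
    ])
    return RecurrenceCatalog(
        sites=df, retained=retained, min_fraction=min_fraction,
        n_tumor=len(tumor_profiles), n_control=len(control_profiles),
    )


# ---------------------------------------------------------------------------
# Cohort catalog: editing-vs-mutation matrices
# ---------------------------------------------------------------------------


@dataclass
class CohortCatalog:
    """Sites x samples and genes x samples matrices for landscape analysis."""

    site_freq: pd.DataFrame     # retained sites x samples, NaN = not detected
    site_info: pd.DataFrame
    gene_edited: pd.DataFrame   # genes x samples, bool
    gene_mutated: pd.DataFrame  # genes x samples, bool
    sample_groups: pd.Series    # sample -> tumor/control
    recurrence: RecurrenceCatalog


def build_cohort_catalog(
    tumor_profiles: list[SampleEditingProfile],
    control_profiles: list[SampleEditingProfile],
    dna_variants: dict[str, DnaVariantTable],
    gene_models: dict[str, GeneModel],
    min_fraction: float = 0.10,
    covered_positions: dict[str, set[SiteKey]] | None = None,
) -> CohortCatalog:
    """Assemble the cohort catalog from per-sample profiles and DNA VCFs.

    Mutation status uses genic SNVs only: a gene is mutated in a sample iff
    the sample's variant table contains an SNV within the gene span.
    """
    rec = build_recurrence_catalog(
        tumor_profiles, control_profiles, min_fraction, covered_positions
    )
    profiles = list(tumor_profiles) + list(control_profiles)
    samples = [p.sample_id for p in profiles]
    groups = pd.Series(
        ["tumor"] * len(tumor_profiles) + ["control"] * len(control_profiles),
        index=samples, name="group",
    )

    retained_keys = sorted(rec.retained)
    freq = pd.DataFrame(
        np.nan, index=pd.MultiIndex.from_tuples(retained_keys, names=["chrom", "pos"])
        if retained_keys else pd.MultiIndex.from_arrays([[], []], names=["chrom", "pos"]),
        columns=samples,
    )
    site_gene: dict[SiteKey, str] = {}
    info = rec.retained_sites().set_index(["chrom", "pos"]) if retained_keys else rec.sites.iloc[0:0]
    for p in profiles:
        for s in p.sites:
            key = (s.chrom, s.pos)
            if key in rec.retained:
                freq.loc[key, p.sample_id] = s.frequency
                site_gene[key] = s.gene_id

    genes = sorted(gene_models)
    edited = pd.DataFrame(False, index=genes, columns=samples)
    for p in profiles:
        for s in p.sites:
            key = (s.chrom, s.pos)
            if key in rec.retained and s.frequency > 0 and s.gene_id in gene_models:
                edited.loc[s.gene_id, p.sample_id] = True

    mutated = pd.DataFrame(False, index=genes, columns=samples)
    for sid, table in dna_variants.items():
        if sid not in mutated.columns:
            continue
        for (chrom, pos) in table.records:
            for gid in genes:
                gm = gene_models[gid]
                if gm.chrom == chrom and gm.span.start <= pos <= gm.span.end:
                    mutated.loc[gid, sid] = True
    return CohortCatalog(
        site_freq=freq, site_info=info, gene_edited=edited,
        gene_mutated=mutated, sample_groups=groups, recurrence=rec,
    )


# ---------------------------------------------------------------------------
# Landscape matrices and exclusivity
# ---------------------------------------------------------------------------


@dataclass
class PathwayLandscape:
    pathway: str
    edited: pd.DataFrame    # member genes x samples
    mutated: pd.DataFrame
    marginals: pd.DataFrame  # per gene: fraction_edited, fraction_mutated


def landscape_matrices(
    catalog: CohortCatalog, gene_sets: dict[str, list[str]]
) -> dict[str, PathwayLandscape]:
    """Per-pathway gene x sample edited/mutated status tables + marginals."""
    out: dict[str, PathwayLandscape] = {}
    for name, members in gene_sets.items():
        present = [g for g in members if g in catalog.gene_edited.index]
        if not present:
            print(f"[edscape] pathway {name!r}: no member genes in catalog", file=sys.stderr)
        edited = catalog.gene_edited.loc[present]
        mutated = catalog.gene_mutated.loc[present]
        marg = pd.DataFrame({
            "fraction_edited": edited.mean(axis=1) if len(present) else pd.Series(dtype=float),
            "fraction_mutated": mutated.mean(axis=1) if len(present) else pd.Series(dtype=float),
        })
        out[name] = PathwayLandscape(name, edited, mutated, marg)
    return out


@dataclass
class ExclusivityResult:
    odds_ratio: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]
    degenerate: bool


def exclusivity_test(edited_row, mutated_row) -> ExclusivityResult:
    """Two-sided Fisher's exact test of per-gene editing vs mutation status.

    The 2x2 table crosses edited +/- with mutated +/- over samples; an odds
    ratio below 1 indicates mutual exclusivity. Rows with a degenerate
    margin (all-true or all-false) are flagged and given p = 1, OR = NaN.
    """
    e = np.asarray(edited_row, dtype=bool)
    m = np.asarray(mutated_row, dtype=bool)
    if e.shape != m.shape:
        raise ValueError("status rows must cover identical samples")
    a = int((e & m).sum())
    b = int((e & ~m).sum())
    c = int((~e & m).sum())
    d = int((~e & ~m).sum())
    table = ((a, b), (c, d))
    if e.all() or (~e).all() or m.all() or (~m).all():
        return ExclusivityResult(float("nan"), 1.0, table, True)
    orat, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return ExclusivityResult(float(orat), float(p), table, False)


# ---------------------------------------------------------------------------
# Differential editing
# ---------------------------------------------------------------------------


@dataclass
class DifferentialEditingResult:
    table: pd.DataFrame           # per tested site: counts, freqs, p, q, passed
    attrition: dict[str, int] = field(default_factory=dict)
    mode: str = "pooled"
    fdr: float = 0.05


def _strand_array(gene_models: dict[str, GeneModel], chrom: str, length: int) -> np.ndarray:
    """Per-position gene strand codes: 0 none, 1 '+', 2 '-', 3 conflicting."""
    arr = np.zeros(length + 2, dtype=np.uint8)
    for gm in gene_models.values():
        if gm.chrom != chrom:
            continue
        sp = gm.span
        code = 1 if gm.strand == "+" else 2
        seg = arr[sp.start : sp.end + 1]
        seg[seg == 0] = code
        seg[(seg != 0) & (seg != code)] = 3
        arr[sp.start : sp.end + 1] = seg
    return arr


def _condition_counts(
    pileups: list[PileupTable],
    reference: ReferenceGenome,
    chrom: str,
    cfg: IndexConfig,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Pooled (edited, coverage) per position plus per-replicate coverages.

    Adenosine coverage/editing is counted on reference A (G as edited) and
    reference T (C as edited); which of the two applies at a position is
    resolved by the caller via the gene strand.
    """
    length = reference.chrom_length(chrom)
    ref = reference.codes(chrom)
    cov = np.zeros((2, length + 2), dtype=np.int64)    # [A-context, T-context]
    edi = np.zeros((2, length + 2), dtype=np.int64)
    per_rep_cov = []
    for pt in pileups:
        rep = np.zeros((2, length + 2), dtype=np.int64)
        cp = pt.chroms.get(chrom)
        if cp is not None:
            ok = (cp.qual >= cfg.q_base) & (cp.mapq >= cfg.q_map)
            obs_ref = ref[cp.pos - 1]
            for row, (want_ref, want_alt) in enumerate(((CODE_A, CODE_G), (CODE_T, CODE_C))):
                m = ok & (obs_ref == want_ref)
                rep[row] += np.bincount(cp.pos[m], minlength=length + 2)
                edi[row] += np.bincount(cp.pos[m & (cp.base == want_alt)], minlength=length + 2)
        cov += rep
        per_rep_cov.append(rep)
    return edi, cov, per_rep_cov


def differential_editing(
    condition_a: list[PileupTable] | PileupTable,
    condition_b: list[PileupTable] | PileupTable,
    reference: ReferenceGenome,
    gene_models: dict[str, GeneModel],
    mode: str = "pooled",
    fdr: float = 0.05,
    config: IndexConfig | None = None,
) -> DifferentialEditingResult:
    """Per-position differential A-to-I editing between two conditions.

    Replicates within a condition are pooled for the test; the mode selects
    the gate. ``pooled``: at least 10 reads per pool in both conditions and
    at least one A-to-G read in either. ``replicate``: at least 50 reads in
    every replicate of both conditions and editing frequency at least 0.2
    in condition A. Gated positions get a two-sided Fisher's exact test on
    (edited, unedited) counts, Benjamini-Hochberg adjusted.
    """
    if mode not in ("pooled", "replicate"):
        raise ValueError(f"unknown mode {mode!r}")
    cfg = config or IndexConfig()
    reps_a = [condition_a] if isinstance(condition_a, PileupTable) else list(condition_a)
    reps_b = [condition_b] if isinstance(condition_b, PileupTable) else list(condition_b)

    attrition = {"positions_considered": 0, "failed_coverage": 0,
                 "failed_candidate": 0, "tested": 0}
    rows = []
    for chrom in reference.chroms:
        strand = _strand_array(gene_models, chrom, reference.chrom_length(chrom))
        edi_a, cov_a, rep_a = _condition_counts(reps_a, reference, chrom, cfg)
        edi_b, cov_b, rep_b = _condition_counts(reps_b, reference, chrom, cfg)
        for row, scode, strand_sym in ((0, 1, "+"), (1, 2, "-")):
            pos_mask = (strand == scode) & ((cov_a[row] > 0) | (cov_b[row] > 0))
            positions = np.flatnonzero(pos_mask)
            attrition["positions_considered"] += len(positions)
            for pos in positions:
                ca, cb = int(cov_a[row, pos]), int(cov_b[row, pos])
                ea, eb = int(edi_a[row, pos]), int(edi_b[row, pos])
                if mode == "pooled":
                    if ca < 10 or cb < 10:
                        attrition["failed_coverage"] += 1
                        continue
                    if ea + eb < 1:
                        attrition["failed_candidate"] += 1
                        continue
                else:
                    if any(int(r[row, pos]) < 50 for r in rep_a + rep_b):
                        attrition["failed_coverage"] += 1
                        continue
                    if ea / ca < 0.2:
                        attrition["failed_candidate"] += 1
                        continue
                _, p = stats.fisher_exact([[ea, ca - ea], [eb, cb - eb]])
                rows.append({
                    "chrom": chrom, "pos": int(pos), "strand": strand_sym,
                    "edited_a": ea, "coverage_a": ca, "freq_a": ea / ca,
                    "edited_b": eb, "coverage_b": cb, "freq_b": eb / cb,
                    "p_value": float(p),
                })
                attrition["tested"] += 1

    if rows:
        df = pd.DataFrame(rows)
        passed, q, _, _ = multipletests(df["p_value"], alpha=fdr, method="fdr_bh")
        df["q_value"] = np.maximum(q, df["p_value"])
        df["passed"] = passed
    else:
        df = pd.DataFrame(columns=[
            "chrom", "pos", "strand", "edited_a", "coverage_a", "freq_a",
            "edited_b", "coverage_b", "freq_b", "p_value", "q_value", "passed",
        ])
    return DifferentialEditingResult(table=df, attrition=attrition, mode=mode, fdr=fdr)


# ---------------------------------------------------------------------------
# Hyper-editing clusters
# ---------------------------------------------------------------------------


@dataclass
class SiteCluster:
    start: int
    end: int
    n_sites: int


def cluster_sites(positions: list[int], max_gap: int = 50) -> list[SiteCluster]:
    """Single-linkage clustering of sites on one chromosome.

    Consecutive sites at most ``max_gap`` bp apart are merged; the default
    50 bp resolves short hyper-edited runs separated by unedited stretches.
    """
    if len(positions) == 0:
        return []
    pos = sorted(positions)
    clusters: list[SiteCluster] = []
    start = prev = pos[0]
    n = 1
    for p in pos[1:]:
        if p - prev <= max_gap:
            prev = p
            n += 1
        else:
            clusters.append(SiteCluster(start, prev, n))
            start = prev = p
            n = 1
    clusters.append(SiteCluster(start, prev, n))
    return clusters
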