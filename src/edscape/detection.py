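"""Candidate RNA editing site extraction, artifact filtering and scoring.

Candidates are mismatch positions in the RNA pileup that survive a filter
cascade: minimum alternate-read support at base/mapping-quality thresholds,
exclusion of known DNA variant positions (germline and somatic), a raw-read
end-distance rule against alignment-end artifacts, a strand-bias test, and
optional exclusion of simple-repeat regions. Each surviving site carries a
feature vector covering three classes of evidence: basic read support
(counts, putative frequency), artifact indicators (qualities, end
distances, strand bias, simple repeats) and editing-specific context
(A-to-I polarity, Alu membership, neighbor bases). A retrainable logistic
classifier over these features assigns a confidence score in [0, 1].
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .io_formats import (
    BASES,
    CODE_N,
    COMPLEMENT,
    STRAND_FWD,
    DnaVariantTable,
    GeneIndex,
    IntervalSet,
    PileupTable,
    ReferenceGenome,
)

FEATURE_NAMES = (
    "alt_reads",
    "coverage",
    "frequency",
    "mean_alt_qual",
    "mean_alt_mapq",
    "min_alt_end_dist",
    "strand_bias_p",
    "in_simple_repeat",
    "in_alu",
    "is_a_to_i",
    "five_prime_is_u",
    "three_prime_is_g",
)


@dataclass
class DetectConfig:
    """Thresholds of the candidate filter cascade.

    Base/mapping quality cutoffs reuse the gene-level read filters (base
    quality 20, mapping quality 30); ``end_distance`` is the 5 bp
    read-end artifact rule. ``bias_alpha`` gates a two-sided exact binomial
    test of the alt-read strand composition against the reference reads'.
    """

    min_alt_reads: int = 2
    min_coverage: int = 10
    q_base: int = 20
    q_map: int = 30
    end_distance: int = 5
    bias_alpha: float = 0.01
    exclude_simple_repeats: bool = False

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "DetectConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SiteFeatureVector:
    alt_reads: int
    coverage: int
    frequency: float
    mean_alt_qual: float
    mean_alt_mapq: float
    min_alt_end_dist: int
    strand_bias_p: float
    in_simple_repeat: bool
    in_alu: bool
    is_a_to_i: bool
    five_prime_base: str
    three_prime_base: str

    def to_array(self) -> np.ndarray:
        return np.array([
            self.alt_reads,
            self.coverage,
            self.frequency,
            self.mean_alt_qual,
            self.mean_alt_mapq,
            self.min_alt_end_dist,
            self.strand_bias_p,
            float(self.in_simple_repeat),
            float(self.in_alu),
            float(self.is_a_to_i),
            float(self.five_prime_base == "T"),  # transcribed-strand U
            float(self.three_prime_base == "G"),
        ])


@dataclass
class EditingSite:
    """One candidate/validated editing event in reference-forward coordinates.

    ``ref``/``alt`` are transcribed-strand bases; ``strand`` is the gene
    strand ('.' for intergenic sites with polarity inferred from the
    mismatch, None-like '.' also used for strand-ambiguous sites, which are
    flagged and excluded from A-to-I summaries).
    """

    chrom: str
    pos: int
    strand: str
    ref: str
    alt: str
    edited_reads: int
    coverage: int
    frequency: float
    features: SiteFeatureVector
    region: str
    alu: bool
    gene_id: str | None
    all_gene_ids: tuple[str, ...] = ()
    confidence: float | None = None
    ambiguous_strand: bool = False

    @property
    def is_a_to_i(self) -> bool:
        return self.features.is_a_to_i


@dataclass
class DetectionResult:
    sample_id: str
    sites: list[EditingSite]
    dna_filter_applied: bool
    attrition: dict[str, int] = field(default_factory=dict)

    def a2i_sites(self) -> list[EditingSite]:
        return [s for s in self.sites if s.is_a_to_i and not s.ambiguous_strand]


def _strand_bias_p(alt_fwd: int, n_alt: int, ref_fwd: int, n_ref: int) -> float:
    """Two-sided exact test of alt-read strand split vs the reference reads'.

    Fisher's exact test on the 2x2 table (alt fwd/rev vs ref fwd/rev): a
    proper two-sample comparison that stays calibrated when the reference
    depth is itself small. With no reference reads the alt split is tested
    against a fair binomial.
    """
    if n_alt == 0:
        return 1.0
    if n_ref == 0:
        return float(stats.binomtest(alt_fwd, n_alt, 0.5).pvalue)
    _, p = stats.fisher_exact(
        [[alt_fwd, n_alt - alt_fwd], [ref_fwd, n_ref - ref_fwd]]
    )
    return float(p)


def call_candidate_sites(
    pileup: PileupTable,
    reference: ReferenceGenome,
    dna_variants: DnaVariantTable | None,
    gene_index: GeneIndex,
    alu_intervals: IntervalSet,
    repeat_intervals: IntervalSet | None = None,
    config: DetectConfig | None = None,
    sample_id: str = "sample",
) -> DetectionResult:
    """Extract editing-site candidates passing the filter cascade.

    Cascade order: (i) alt support at quality thresholds and minimum
    coverage; (ii) DNA-variant exclusion (skipped with a warning if no
    table is supplied); (iii) at least one alt observation >= end_distance
    bp from the raw read ends; (iv) strand-bias p >= bias_alpha;
    (v) optional simple-repeat exclusion. Every retained site carries its
    full feature vector.
    """
    cfg = config or DetectConfig()
    if dna_variants is None:
        print(
            f"[edscape] {sample_id}: no DNA variant table supplied; "
            "DNA-mutation filter skipped",
            file=sys.stderr,
        )
    attrition = {
        "candidates": 0, "dna_variant": 0, "end_distance": 0,
        "strand_bias": 0, "simple_repeat": 0, "retained": 0,
    }
    sites: list[EditingSite] = []

    for chrom, cp in pileup.chroms.items():
        ref_codes = reference.codes(chrom)
        qual_ok = (cp.qual >= cfg.q_base) & (cp.mapq >= cfg.q_map)
        obs_ref = ref_codes[cp.pos - 1]
        mism = qual_ok & (cp.base != obs_ref) & (cp.base != CODE_N) & (obs_ref != CODE_N)
        if not mism.any():
            continue
        # count qualifying alt observations per (pos, alt base)
        key = cp.pos[mism].astype(np.int64) * 4 + cp.base[mism]
        uniq, counts = np.unique(key, return_counts=True)
        cand = uniq[counts >= cfg.min_alt_reads]

        for k in cand:
            pos, alt_code = int(k // 4), int(k % 4)
            s = cp.slice_at(pos)
            q = qual_ok[s]
            bases = cp.base[s]
            cov = int(q.sum())
            if cov < cfg.min_coverage:
                continue
            alt_mask = q & (bases == alt_code)
            ref_mask = q & (bases == ref_codes[pos - 1])
            n_alt = int(alt_mask.sum())
            attrition["candidates"] += 1

            if dna_variants is not None and dna_variants.has(chrom, pos):
                attrition["dna_variant"] += 1
                continue

            end_d = cp.end_dist[s]
            if not (alt_mask & (end_d >= cfg.end_distance)).any():
                attrition["end_distance"] += 1
                continue

            strands = cp.strand[s]
            bias_p = _strand_bias_p(
                int((alt_mask & (strands == STRAND_FWD)).sum()), n_alt,
                int((ref_mask & (strands == STRAND_FWD)).sum()), int(ref_mask.sum()),
            )
            if bias_p < cfg.bias_alpha:
                attrition["strand_bias"] += 1
                continue

            in_repeat = bool(repeat_intervals.contains(chrom, pos)) if repeat_intervals else False
            if cfg.exclude_simple_repeats and in_repeat:
                attrition["simple_repeat"] += 1
                continue

            gene_hits = gene_index.genes_at(chrom, pos)
            gene_id, region, strand = gene_index.classify(chrom, pos)
            ambiguous = strand is None and gene_id is not None
            ref_fwd = BASES[ref_codes[pos - 1]]
            alt_fwd = BASES[alt_code]
            if gene_id is None:
                # intergenic: infer polarity from the mismatch itself
                if ref_fwd == "A" and alt_fwd == "G":
                    strand = "+"
                elif ref_fwd == "T" and alt_fwd == "C":
                    strand = "-"
                else:
                    strand = "."
            if ambiguous or strand is None or strand == ".":
                ref_t, alt_t = ref_fwd, alt_fwd
                is_a2i = False if ambiguous else (ref_fwd == "A" and alt_fwd == "G")
                out_strand = "."
            elif strand == "+":
                ref_t, alt_t = ref_fwd, alt_fwd
                is_a2i = ref_fwd == "A" and alt_fwd == "G"
                out_strand = "+"
            else:
                ref_t, alt_t = COMPLEMENT[ref_fwd], COMPLEMENT[alt_fwd]
                is_a2i = ref_fwd == "T" and alt_fwd == "C"
                out_strand = "-"

            left = BASES[ref_codes[pos - 2]] if pos >= 2 else "N"
            right = BASES[ref_codes[pos]] if pos < len(ref_codes) else "N"
            if out_strand == "-":
                five_p, three_p = COMPLEMENT[right], COMPLEMENT[left]
            else:
                five_p, three_p = left, right

            in_alu = bool(alu_intervals.contains(chrom, pos))
            fv = SiteFeatureVector(
                alt_reads=n_alt,
                coverage=cov,
                frequency=n_alt / cov,
                mean_alt_qual=float(cp.qual[s][alt_mask].mean()),
                mean_alt_mapq=float(cp.mapq[s][alt_mask].mean()),
                min_alt_end_dist=int(end_d[alt_mask].min()),
                strand_bias_p=bias_p,
                in_simple_repeat=in_repeat,
                in_alu=in_alu,
                is_a_to_i=is_a2i,
                five_prime_base=five_p,
                three_prime_base=three_p,
            )
            sites.append(EditingSite(
                chrom=chrom, pos=pos, strand=out_strand,
                ref=ref_t, alt=alt_t,
                edited_reads=n_alt, coverage=cov, frequency=n_alt / cov,
                features=fv, region=region, alu=in_alu,
                gene_id=gene_id,
                all_gene_ids=tuple(g.gene_id for g in gene_hits),
                ambiguous_strand=ambiguous,
            ))
            attrition["retained"] += 1

    sites.sort(key=lambda x: (x.chrom, x.pos))
    return DetectionResult(
        sample_id=sample_id,
        sites=sites,
        dna_filter_applied=dna_variants is not None,
        attrition=attrition,
    )


# ---------------------------------------------------------------------------
# Logistic site classifier
# ---------------------------------------------------------------------------


@dataclass
class SiteClassifier:
    """Logistic regression over the 12 site features, with held-out AUC."""

    pipeline: Pipeline
    holdout_auc: float
    feature_names: tuple[str, ...] = FEATURE_NAMES

    @property
    def weights(self) -> np.ndarray:
        return self.pipeline.named_steps["logit"].coef_.ravel()

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature dimension {X.shape[1]} != {len(self.feature_names)}"
            )
        return self.pipeline.predict_proba(X)[:, 1]


def features_matrix(sites: Sequence[EditingSite]) -> np.ndarray:
    if not sites:
        return np.empty((0, len(FEATURE_NAMES)))
    return np.vstack([s.features.to_array() for s in sites])


def label_sites_by_truth(
    sites: Sequence[EditingSite], truth_positions: set[tuple[str, int]]
) -> np.ndarray:
    """1 for candidates at planted positions, 0 for artifact/error candidates."""
    return np.array([(s.chrom, s.pos) in truth_positions for s in sites], dtype=int)


def train_site_classifier(
    X: np.ndarray, y: np.ndarray, seed: int = 0, holdout_fraction: float = 0.3
) -> SiteClassifier:
    """Fit the logistic site classifier on labeled feature vectors.

    Labels come from simulation truth (planted site = 1, artifact/error
    candidate = 0). Returns the fitted model with its AUC on a stratified
    held-out split. Raises on single-class labels; warns below 50 examples
    per class.
    """
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < 50:
        print(
            f"[edscape] classifier training with only {counts.min()} examples "
            "in the rarer class; scores may be unstable",
            file=sys.stderr,
        )
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("logit", LogisticRegression(max_iter=2000, random_state=seed)),
    ])
    pipe.fit(Xtr, ytr)
    if len(np.unique(yte)) == 2:
        auc = float(roc_auc_score(yte, pipe.predict_proba(Xte)[:, 1]))
    else:  # degenerate holdout (tiny inputs)
        auc = float("nan")
    return SiteClassifier(pipeline=pipe, holdout_auc=auc)


def score_sites(
    sites: Sequence[EditingSite], classifier: SiteClassifier, threshold: float = 0.5
) -> list[EditingSite]:
    """Annotate sites with classifier confidence; keep those >= threshold."""
    if not sites:
        return []
    probs = classifier.predict_proba(features_matrix(sites))
    kept = []
    for s, p in zip(sites, probs):
        s.confidence = float(p)
        if p >= threshold:
            kept.append(s)
    return kept


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------

_SITE_COLUMNS = (
    "chrom", "pos", "strand", "ref", "alt", "edited_reads", "coverage",
    "frequency", "region", "alu", "gene_id", "confidence",
)


def read_sites_tsv(path: str) -> DetectionResult:
    """Read a per-sample sites TSV back into a DetectionResult.

    Feature vectors are reconstructed from the summary columns (quality
    aggregates default to the filter thresholds); sufficient for cohort
    cataloging and landscape analysis, not for re-scoring.
    """
    sample_id = "sample"
    dna_applied = False
    sites: list[EditingSite] = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                if line.startswith("# sample="):
                    sample_id = line.split("=", 1)[1]
                elif line.startswith("# dna_filter_applied="):
                    dna_applied = line.split("=", 1)[1] == "True"
                continue
            if header is None:
                header = line.split("\t")
                continue
            rec = dict(zip(header, line.split("\t")))
            ref_t, alt_t, strand = rec["ref"], rec["alt"], rec["strand"]
            is_a2i = ref_t == "A" and alt_t == "G"
            fv = SiteFeatureVector(
                alt_reads=int(rec["edited_reads"]),
                coverage=int(rec["coverage"]),
                frequency=float(rec["frequency"]),
                mean_alt_qual=float("nan"),
                mean_alt_mapq=float("nan"),
                min_alt_end_dist=0,
                strand_bias_p=1.0,
                in_simple_repeat=False,
                in_alu=rec["alu"] == "1",
                is_a_to_i=is_a2i,
                five_prime_base="N",
                three_prime_base="N",
            )
            sites.append(EditingSite(
                chrom=rec["chrom"], pos=int(rec["pos"]), strand=strand,
                ref=ref_t, alt=alt_t,
                edited_reads=int(rec["edited_reads"]),
                coverage=int(rec["coverage"]),
                frequency=float(rec["frequency"]),
                features=fv, region=rec["region"], alu=rec["alu"] == "1",
                gene_id=rec["gene_id"] or None,
                confidence=float(rec["confidence"]) if rec.get("confidence") else None,
            ))
    return DetectionResult(sample_id, sites, dna_applied)


def write_sites_tsv(result: DetectionResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample={result.sample_id}\n")
        fh.write(f"# dna_filter_applied={result.dna_filter_applied}\n")
        for k, v in result.attrition.items():
            fh.write(f"# attrition.{k}={v}\n")
        fh.write("\t".join(_SITE_COLUMNS) + "\n")
        for s in result.sites:
            conf = "" if s.confidence is None else f"{s.confidence:.6g}"
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.strand}\t{s.ref}\t{s.alt}\t"
                f"{s.edited_reads}\t{s.coverage}\t{s.frequency:.6g}\t"
                f"{s.region}\t{int(s.alu)}\t{s.gene_id or ''}\t{conf}\n"
            )
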