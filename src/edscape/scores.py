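"""Expression normalisation, signature scoring and cohort statistics.

Signature scores (interferon-stimulated genes, NF-kB targets, T-cell
exhaustion) are the mean across member genes of each gene's across-sample
z-score of log2(TPM+1) expression — a simple, reproducible single-sample
construction. High/low splits, Pearson correlation, Mann-Whitney group
comparison, Fisher-based gene-set over-representation, motif profiles of
edited adenosines, and length/GC/expression bias diagnostics complete the
module.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import COMPLEMENT, ReferenceGenome


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values, TPM or log2(TPM+1) scale."""

    values: pd.DataFrame
    log_scale: bool = False


def normalize_expression(raw: pd.DataFrame | ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(TPM+1); refuses negative input or double transform."""
    if isinstance(raw, ExpressionMatrix):
        if raw.log_scale:
            raise ValueError("expression matrix is already log-transformed")
        raw = raw.values
    if (raw.to_numpy() < 0).any():
        raise ValueError("negative expression values")
    return ExpressionMatrix(np.log2(raw + 1.0), log_scale=True)


@dataclass
class SignatureScoreResult:
    scores: pd.Series          # per sample
    n_genes_used: int
    n_genes_dropped: int       # zero-variance or absent


def signature_score(expr: ExpressionMatrix, genes: list[str], name: str = "signature") -> SignatureScoreResult:
    """Mean across-sample z-score of member genes, per sample.

    Genes absent from the matrix or with zero variance across samples are
    dropped (counted); duplicate gene ids contribute once. NA scores if no
    member gene remains.
    """
    if not expr.log_scale:
        raise ValueError("signature_score expects log-scale expression")
    mat = expr.values
    if mat.shape[1] < 2:
        raise ValueError("z-scores need at least 2 samples")
    members = list(dict.fromkeys(genes))
    present = [g for g in members if g in mat.index]
    sub = mat.loc[present]
    sd = sub.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = (len(members) - len(present)) + int((~keep).sum())
    sub = sub[keep]
    if sub.empty:
        print(f"[edscape] signature {name!r}: no usable genes", file=sys.stderr)
        return SignatureScoreResult(
            pd.Series(np.nan, index=mat.columns), 0, dropped
        )
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd[keep], axis=0)
    return SignatureScoreResult(z.mean(axis=0), len(sub), dropped)


def score_table(expr: ExpressionMatrix, gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Samples x signatures score table for a set of signatures."""
    cols = {}
    for name, genes in gene_sets.items():
        cols[name] = signature_score(expr, genes, name).scores
    return pd.DataFrame(cols)


def split_high_low(values: pd.Series) -> pd.Series:
    """Label the top 50% of samples 'high' and the bottom 50% 'low'.

    With odd n the median sample goes to 'low'. All-equal values admit no
    split and raise.
    """
    v = pd.Series(values)
    if v.nunique() <= 1:
        raise ValueError("all values equal; no high/low split exists")
    order = v.sort_values(kind="stable", ascending=False)
    n_high = len(v) // 2
    labels = pd.Series("low", index=v.index)
    labels[order.index[:n_high]] = "high"
    return labels


def correlate(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p; (nan, nan) on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("paired input of length >= 3 required")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def compare_groups(values, labels) -> tuple[float, float]:
    """Two-sided Mann-Whitney U between the two label groups.

    Exact p-values when both groups have <= 8 observations and no ties;
    otherwise the normal approximation with tie correction.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {list(uniq)}")
    a = values[labels == uniq[0]]
    b = values[labels == uniq[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(values)) < len(values)
    method = "exact" if (max(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def overrepresentation(
    foreground: list[str], background: list[str], gene_sets: dict[str, list[str]]
) -> pd.DataFrame:
    """One-sided Fisher (hypergeometric tail) over-representation per set.

    Tests whether the foreground overlaps each gene set more than expected
    under draws from the background; BH-adjusted across sets. Sets disjoint
    from the background are skipped with a warning.
    """
    fg = set(foreground)
    bg = set(background)
    missing = fg - bg
    if missing:
        raise ValueError(f"foreground genes not in background: {sorted(missing)[:10]}")
    N, n = len(bg), len(fg)
    rows = []
    for name, members in gene_sets.items():
        in_bg = bg.intersection(members)
        if not in_bg:
            print(f"[edscape] gene set {name!r} disjoint from background; skipped",
                  file=sys.stderr)
            continue
        K = len(in_bg)
        k = len(fg.intersection(in_bg))
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "overlap": k, "set_size": K,
                     "foreground_size": n, "background_size": N, "p_value": p})
    df = pd.DataFrame(rows, columns=["set", "overlap", "set_size",
                                     "foreground_size", "background_size", "p_value"])
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df


def bias_diagnostics(
    edited_genes: list[str], all_genes: list[str], metadata: pd.DataFrame
) -> pd.DataFrame:
    """Check whether edited genes are biased in length, GC or expression.

    For every metadata column, compares edited vs non-edited genes with a
    two-sided Mann-Whitney test and reports the rank-biserial effect size.
    Identical sets give p = 1 by convention.
    """
    edited = [g for g in set(edited_genes) if g in metadata.index]
    others = [g for g in metadata.index if g not in set(edited_genes)]
    rows = []
    for cov in metadata.columns:
        col = metadata[cov].dropna()
        coverage = len(col) / len(metadata)
        if coverage < 0.9:
            print(f"[edscape] covariate {cov!r} missing for "
                  f"{1 - coverage:.0%} of genes", file=sys.stderr)
        a = col.reindex(edited).dropna().to_numpy()
        b = col.reindex(others).dropna().to_numpy()
        if len(b) == 0 or len(a) == 0:
            rows.append({"covariate": cov, "p_value": 1.0, "rank_biserial": 0.0,
                         "n_edited": len(a), "n_other": len(b)})
            continue
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rb = 1.0 - 2.0 * u / (len(a) * len(b))
        rows.append({"covariate": cov, "p_value": float(p),
                     "rank_biserial": float(rb), "n_edited": len(a),
                     "n_other": len(b)})
    return pd.DataFrame(rows)


def motif_profile(sites, reference: ReferenceGenome) -> pd.DataFrame:
    """5' / 3' neighbor base frequencies of edited adenosines.

    Neighbors are read on the transcribed strand (reverse-complemented for
    minus-strand sites); contig-edge neighbors are recorded as N and
    excluded from the frequencies. Returns a 2 x 4 table (rows ``5p``,
    ``3p``; columns A, C, G, U) with rows summing to 1.
    """
    counts = {side: {b: 0 for b in "ACGU"} for side in ("5p", "3p")}
    for s in sites:
        chrom_len = reference.chrom_length(s.chrom)
        left = reference.base(s.chrom, s.pos - 1) if s.pos > 1 else "N"
        right = reference.base(s.chrom, s.pos + 1) if s.pos < chrom_len else "N"
        if s.strand == "-":
            five, three = COMPLEMENT[right], COMPLEMENT[left]
        else:
            five, three = left, right
        for side, b in (("5p", five), ("3p", three)):
            b = "U" if b == "T" else b
            if b in counts[side]:
                counts[side][b] += 1
    df = pd.DataFrame(counts).T[list("ACGU")].astype(float)
    totals = df.sum(axis=1)
    return df.div(totals.where(totals > 0, 1.0), axis=0)
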