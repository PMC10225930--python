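"""Cohort catalog: recurrence, landscapes, exclusivity, differential editing,
hyper-editing clusters — checked against brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from edscape.catalog import (
    SiteCluster,
    build_cohort_catalog,
    build_recurrence_catalog,
    cluster_sites,
    differential_editing,
    exclusivity_test,
    landscape_matrices,
)
from edscape.detection import EditingSite, SiteFeatureVector
from edscape.indices import SampleEditingProfile
from edscape.io_formats import DnaVariantTable, build_pileup_table, read_reference

from conftest import Read, make_diffedit_pools, single_gene_models, write_fasta, write_sam


def _mk_site(chrom="chr1", pos=100, strand="+", freq=0.3, gene_id="geneA",
             region="utr3", alu=True, is_a2i=True):
    fv = SiteFeatureVector(3, 10, freq, 37.0, 60.0, 20, 1.0, False, alu, is_a2i, "T", "G")
    return EditingSite(chrom, pos, strand, "A", "G", 3, 10, freq, fv, region,
                       alu, gene_id)


def _mk_profile(sample_id, site_specs):
    sites = [_mk_site(**spec) for spec in site_specs]
    return SampleEditingProfile(sample_id, sites, len(sites),
                                sum(s.is_a_to_i for s in sites), 0.01, (1, 100))


class TestRecurrence:
    def test_forced_examples(self):
        # site A: 12/106 tumors (>10%), 0/41 controls, 3'UTR -> retained
        # site B: 15 tumors + 1 control -> dropped
        # site C: intergenic in 50 tumors -> dropped
        tumors = []
        for i in range(106):
            specs = []
            if i < 12:
                specs.append(dict(pos=100))
            if i < 15:
                specs.append(dict(pos=200))
            if i < 50:
                specs.append(dict(pos=300, gene_id=None, region="intergenic"))
            tumors.append(_mk_profile(f"t{i}", specs))
        controls = [_mk_profile(f"c{i}", [dict(pos=200)] if i == 0 else [])
                    for i in range(41)]
        cat = build_recurrence_catalog(tumors, controls, min_fraction=0.10)
        assert cat.retained == {("chr1", 100)}
        row = cat.sites.set_index("pos").loc[100]
        assert row["n_tumor_detected"] == 12 and row["n_control_detected"] == 0

    def test_exactly_at_threshold_excluded(self):
        # 10% exactly is not "more than 10%"
        tumors = [_mk_profile(f"t{i}", [dict(pos=100)] if i < 1 else [])
                  for i in range(10)]
        controls = [_mk_profile("c0", [])]
        cat = build_recurrence_catalog(tumors, controls, min_fraction=0.10)
        assert cat.retained == set()

    def test_two_sample_rule(self):
        # >10% of 5 tumors is satisfied by 1/5 = 20%, but 1 sample total < 2
        tumors = [_mk_profile(f"t{i}", [dict(pos=100)] if i == 0 else [])
                  for i in range(5)]
        cat = build_recurrence_catalog(tumors, [_mk_profile("c0", [])], 0.10)
        assert cat.retained == set()

    def test_non_a2i_sites_ignored(self):
        tumors = [_mk_profile(f"t{i}", [dict(pos=100, is_a2i=False)])
                  for i in range(10)]
        cat = build_recurrence_catalog(tumors, [_mk_profile("c0", [])], 0.10)
        assert len(cat.sites) == 0

    def test_empty_tumor_cohort_raises(self):
        with pytest.raises(ValueError, match="empty tumor cohort"):
            build_recurrence_catalog([], [_mk_profile("c0", [])])

    def test_matches_bruteforce_set_algebra(self):
        """Catalog on a random 30-sample toy cohort equals direct set algebra."""
        rng = np.random.default_rng(42)
        n_t, n_c, n_sites = 22, 8, 60
        positions = [(f"chr{1 + i % 2}", 100 + 10 * i) for i in range(n_sites)]
        meta = {}
        for i, key in enumerate(positions):
            meta[key] = dict(
                gene_id=None if i % 7 == 0 else f"g{i % 9}",
                region="intergenic" if i % 7 == 0 else "utr3",
                is_a2i=i % 11 != 0,
            )
        t_members = {key: set(np.flatnonzero(rng.random(n_t) < 0.3)) for key in positions}
        c_members = {key: set(np.flatnonzero(rng.random(n_c) < 0.15)) for key in positions}
        tumors = [
            _mk_profile(f"t{j}", [
                dict(chrom=k[0], pos=k[1], **meta[k])
                for k in positions if j in t_members[k]
            ]) for j in range(n_t)
        ]
        controls = [
            _mk_profile(f"c{j}", [
                dict(chrom=k[0], pos=k[1], **meta[k])
                for k in positions if j in c_members[k]
            ]) for j in range(n_c)
        ]
        cat = build_recurrence_catalog(tumors, controls, min_fraction=0.10)

        expected = set()
        for key in positions:
            m = meta[key]
            nt, nc = len(t_members[key]), len(c_members[key])
            if (m["is_a2i"] and m["gene_id"] is not None
                    and m["region"] != "intergenic"
                    and nt / n_t > 0.10 and nc == 0 and nt + nc >= 2):
                expected.add(key)
        assert cat.retained == expected

    def test_covered_denominator_mode(self):
        tumors = [_mk_profile(f"t{i}", [dict(pos=100)] if i < 2 else [])
                  for i in range(10)]
        controls = [_mk_profile("c0", [])]
        # only 4 tumors cover the position: 2/4 = 50% > 10%
        covered = {f"t{i}": {("chr1", 100)} for i in range(4)}
        covered["c0"] = set()
        cat = build_recurrence_catalog(tumors, controls, 0.10, covered_positions=covered)
        assert cat.retained == {("chr1", 100)}
        row = cat.sites.set_index("pos").loc[100]
        assert row["tumor_denominator"] == 4


class TestLandscape:
    def _catalog(self):
        genes = {}
        for gid, start in (("geneA", 100), ("geneB", 1100), ("geneC", 2100)):
            genes.update(single_gene_models("chr1", start, start + 500, gene_id=gid))
        tumors = [
            _mk_profile(f"t{i}", [dict(pos=150, gene_id="geneA")] if i < 8 else [])
            for i in range(10)
        ]
        controls = [_mk_profile(f"c{i}", []) for i in range(3)]
        dna = {}
        for i in range(10):
            t = DnaVariantTable()
            if i < 3:
                t.add("chr1", 1200, "C", "T")  # geneB mutated in 3/13 samples
            dna[f"t{i}"] = t
        for i in range(3):
            dna[f"c{i}"] = DnaVariantTable()
        return build_cohort_catalog(tumors, controls, dna, genes, min_fraction=0.10)

    def test_marginals(self):
        cat = self._catalog()
        sets = {"pathway1": ["geneA", "geneB", "geneC"]}
        ls = landscape_matrices(cat, sets)["pathway1"]
        assert ls.marginals.loc["geneA", "fraction_edited"] == pytest.approx(8 / 13)
        assert ls.marginals.loc["geneB", "fraction_mutated"] == pytest.approx(3 / 13)
        assert ls.marginals.loc["geneC", "fraction_edited"] == 0.0
        assert ls.marginals.loc["geneC", "fraction_mutated"] == 0.0

    def test_missing_pathway_warns(self, capsys):
        cat = self._catalog()
        ls = landscape_matrices(cat, {"empty": ["nope1", "nope2"]})["empty"]
        assert ls.edited.empty
        assert "no member genes" in capsys.readouterr().err

    def test_sample_permutation_equivariance(self):
        cat = self._catalog()
        ls = landscape_matrices(cat, {"p": ["geneA", "geneB"]})["p"]
        perm = list(reversed(ls.edited.columns))
        assert (ls.edited[perm].columns == ls.mutated[perm].columns).all()
        pd.testing.assert_frame_equal(ls.edited[perm], ls.edited.loc[:, perm])


def fisher_two_sided_oracle(a, b, c, d):
    """Exact two-sided Fisher p by enumerating tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def table_p(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    obs = table_p(a)
    return sum(table_p(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if table_p(x) <= obs * (1 + 1e-9))


class TestExclusivity:
    def test_perfect_cooccurrence_matches_hypergeometric_oracle(self):
        e = np.array([True] * 10 + [False] * 10)
        m = e.copy()
        res = exclusivity_test(e, m)
        assert res.odds_ratio == float("inf")
        oracle = fisher_two_sided_oracle(10, 0, 0, 10)
        assert res.p_value == pytest.approx(oracle, rel=1e-9)
        assert res.p_value == pytest.approx(1.082509e-5, rel=1e-4)

    def test_exclusive_pattern_has_or_below_one(self):
        e = np.array([True] * 8 + [False] * 8)
        m = ~e
        res = exclusivity_test(e, m)
        assert res.odds_ratio < 1
        assert res.p_value == pytest.approx(fisher_two_sided_oracle(0, 8, 8, 0), rel=1e-9)

    def test_null_pvalues_uniform(self):
        """Independent status rows give approximately uniform p-values."""
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(300):
            e = rng.random(40) < 0.4
            m = rng.random(40) < 0.4
            r = exclusivity_test(e, m)
            if not r.degenerate:
                ps.append(r.p_value)
        from scipy import stats
        # Fisher p-values are discrete and conservative; check super-uniformity
        assert np.mean(np.array(ps) < 0.05) <= 0.07
        assert stats.kstest(ps, "uniform").statistic < 0.35

    def test_degenerate_margin_flagged(self):
        res = exclusivity_test([True, True, True], [True, False, True])
        assert res.degenerate and res.p_value == 1.0 and math.isnan(res.odds_ratio)

    def test_mismatched_rows_raise(self):
        with pytest.raises(ValueError):
            exclusivity_test([True, False], [True, False, True])


class TestDifferentialEditing:
    def test_pooled_coverage_gate(self, tmp_path):
        # 9 reads in one pool -> position gated out
        refseq = "A" * 60 + "C" * 40
        genes = single_gene_models("chr1", 1, 100)
        fa = write_fasta(tmp_path / "r.fa", {"chr1": refseq})
        ref = read_reference(str(fa))
        reads_a = [Read("chr1", 1, "G" + "A" * 19) for _ in range(9)]
        reads_b = [Read("chr1", 1, "A" * 20) for _ in range(12)]
        pa = build_pileup_table(str(write_sam(tmp_path / "a.sam", reads_a,
                                              {"chr1": 100})), ref)
        pb = build_pileup_table(str(write_sam(tmp_path / "b.sam", reads_b,
                                              {"chr1": 100})), ref)
        res = differential_editing(pa, pb, ref, genes, mode="pooled")
        assert len(res.table) == 0
        assert res.attrition["failed_coverage"] > 0

    def test_pooled_candidate_gate_needs_one_edited_read(self, tmp_path):
        refseq = "A" * 60 + "C" * 40
        genes = single_gene_models("chr1", 1, 100)
        fa = write_fasta(tmp_path / "r.fa", {"chr1": refseq})
        ref = read_reference(str(fa))
        reads = [Read("chr1", 1, "A" * 20) for _ in range(15)]
        pa = build_pileup_table(str(write_sam(tmp_path / "a.sam", reads, {"chr1": 100})), ref)
        pb = build_pileup_table(str(write_sam(tmp_path / "b.sam", reads, {"chr1": 100})), ref)
        res = differential_editing(pa, pb, ref, genes, mode="pooled")
        assert len(res.table) == 0
        assert res.attrition["failed_candidate"] == 20

    def test_replicate_mode_gates(self, tmp_path):
        refseq = "A" * 60 + "C" * 40
        genes = single_gene_models("chr1", 1, 100)
        fa = write_fasta(tmp_path / "r.fa", {"chr1": refseq})
        ref = read_reference(str(fa))

        def pool(n, n_edit, name):
            reads = [Read("chr1", 1, ("G" if i < n_edit else "A") + "A" * 19)
                     for i in range(n)]
            return build_pileup_table(
                str(write_sam(tmp_path / name, reads, {"chr1": 100})), ref)

        # coverage 60 per replicate, WT frequency 0.15 < 0.2 -> gated out
        pa = pool(60, 9, "w1.sam")
        pb = pool(60, 0, "k1.sam")
        res = differential_editing([pa], [pb], ref, genes, mode="replicate")
        assert 1 not in set(res.table["pos"])
        # WT frequency 0.5 passes the gate
        pa2 = pool(60, 30, "w2.sam")
        res2 = differential_editing([pa2], [pb], ref, genes, mode="replicate")
        assert 1 in set(res2.table["pos"])
        # a 40-read replicate fails the 50-read rule
        pa3 = pool(40, 20, "w3.sam")
        res3 = differential_editing([pa3], [pb], ref, genes, mode="replicate")
        assert 1 not in set(res3.table["pos"])

    def test_planted_site_significant_with_bh_oracle(self, tmp_path):
        """A 0.20-vs-0.02 site on a ~100-position null panel is called; p and
        q values match an exact-test + hand Benjamini-Hochberg oracle."""
        ref, genes, pa, pb, sites_a = make_diffedit_pools(
            tmp_path, "planted",
            freqs_a=[0.1] * 20 + [0.20], freqs_b=[0.1] * 20 + [0.02], seed=3,
        )
        res = differential_editing(pa, pb, ref, genes, mode="pooled", fdr=0.05)
        planted_pos = max(sites_a, key=lambda p: sites_a[p])
        row = res.table.set_index("pos").loc[planted_pos]
        oracle_p = fisher_two_sided_oracle(
            int(row["edited_a"]), int(row["coverage_a"] - row["edited_a"]),
            int(row["edited_b"]), int(row["coverage_b"] - row["edited_b"]),
        )
        assert row["p_value"] == pytest.approx(oracle_p, rel=1e-6)
        assert bool(row["passed"])
        # hand BH: step-up on sorted raw p
        ps = np.sort(res.table["p_value"].to_numpy())
        m = len(ps)
        bh = np.minimum.accumulate((m / np.arange(m, 0, -1)) * ps[::-1])[::-1]
        got = np.sort(res.table["q_value"].to_numpy())
        assert np.allclose(np.minimum(bh, 1.0), got, atol=1e-12)

    def test_bh_adjusted_monotone_and_geq_raw(self, tmp_path):
        ref, genes, pa, pb, _ = make_diffedit_pools(
            tmp_path, "mono", freqs_a=[0.15] * 10, freqs_b=[0.05] * 10, seed=5)
        res = differential_editing(pa, pb, ref, genes, mode="pooled")
        df = res.table.sort_values("p_value")
        assert (df["q_value"].to_numpy() >= df["p_value"].to_numpy() - 1e-15).all()
        assert (np.diff(df["q_value"].to_numpy()) >= -1e-15).all()

    def test_unknown_mode_raises(self, tmp_path):
        refseq = "A" * 100
        fa = write_fasta(tmp_path / "r.fa", {"chr1": refseq})
        ref = read_reference(str(fa))
        with pytest.raises(ValueError, match="unknown mode"):
            differential_editing([], [], ref, {}, mode="bogus")


class TestClusters:
    def test_hand_example(self):
        got = cluster_sites([100, 110, 120, 500, 505], max_gap=50)
        assert got == [SiteCluster(100, 120, 3), SiteCluster(500, 505, 2)]

    def test_single_site(self):
        assert cluster_sites([42]) == [SiteCluster(42, 42, 1)]

    def test_zero_gap_all_singletons(self):
        pos = [10, 11, 13, 20]
        got = cluster_sites(pos, max_gap=0)
        assert [c.n_sites for c in got] == [1, 1, 1, 1]

    def test_empty_input(self):
        assert cluster_sites([]) == []

    def test_matches_bruteforce_single_linkage(self):
        rng = np.random.default_rng(8)
        pos = sorted(rng.choice(5000, size=80, replace=False).tolist())
        for gap in (0, 10, 50, 200):
            got = cluster_sites(pos, max_gap=gap)
            # brute force: transitive closure of |pi - pj| <= gap adjacency
            groups = [[pos[0]]]
            for p in pos[1:]:
                if p - groups[-1][-1] <= gap:
                    groups[-1].append(p)
                else:
                    groups.append([p])
            assert [(c.start, c.end, c.n_sites) for c in got] == [
                (g[0], g[-1], len(g)) for g in groups
            ]
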