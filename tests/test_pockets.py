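"""Pocket construction, conformation classification, contingency statistics."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import hypergeom

from csramod.energy import BindingSite
from csramod.ensemble import Conformation, Ensemble
from csramod.pockets import (
    build_pockets,
    classify_conformation_terms,
    classify_conformations,
    flag_flexible_pockets,
    hypergeometric_enrichment,
    hypergeometric_point_probability,
    sd_overlap_report,
    sd_region,
)
from csramod.records import MRNARecord
from oracles import hypergeom_tail_exact


def _site(start: int, seq: str = "AAGAA") -> BindingSite:
    from csramod.energy import is_high_affinity, score_window

    return BindingSite(
        start=start, sequence=seq, dG_site=min(score_window(seq), -0.1),
        is_high_affinity=is_high_affinity(seq),
    )


def _conf(s1: BindingSite, s2: BindingSite, coop=-4.6, ddg=0.0) -> Conformation:
    return Conformation(
        site1=s1, site2=s2, d=s2.start - s1.start, dG_coop=coop, ddG_unfold=ddg,
        dG_total=s1.dG_site + s2.dG_site + coop + ddg, scaled_p=0.1,
    )


def _confs_from_starts(pairs):
    return [_conf(_site(a), _site(b)) for a, b in pairs]


class TestBuildPockets:
    def test_overlapping_sites_chain_into_one_pocket(self):
        confs = _confs_from_starts([(10, 30), (12, 30), (14, 30)])
        pockets = build_pockets(confs)
        spans = [p.span for p in pockets]
        assert (10, 19) in spans
        cluster = next(p for p in pockets if p.span == (10, 19))
        assert cluster.n_sites == 3

    def test_two_nucleotide_gap_splits_pockets(self):
        # windows [10,15) and [17,22): two intervening nucleotides
        confs = _confs_from_starts([(10, 40), (17, 40)])
        spans = [p.span for p in build_pockets(confs)]
        assert (10, 15) in spans and (17, 22) in spans

    def test_one_nucleotide_gap_chains(self):
        # windows [10,15) and [16,21): exactly one nucleotide between them
        confs = _confs_from_starts([(10, 40), (16, 40)])
        spans = [p.span for p in build_pockets(confs)]
        assert (10, 21) in spans

    def test_single_site_single_pocket(self):
        pockets = build_pockets(_confs_from_starts([(10, 40)]))
        assert all(p.n_sites == 1 for p in pockets)

    def test_occurrence_counts_across_conformations(self):
        confs = _confs_from_starts([(10, 30), (10, 40), (10, 50)])
        pockets = build_pockets(confs)
        first = next(p for p in pockets if p.span[0] == 10)
        assert first.occurrences[(10, "AAGAA")] == 3

    def test_order_independent(self):
        pairs = [(10, 30), (12, 44), (14, 30), (25, 44)]
        a = build_pockets(_confs_from_starts(pairs))
        b = build_pockets(_confs_from_starts(list(reversed(pairs))))
        assert [(p.span, p.n_sites) for p in a] == [(p.span, p.n_sites) for p in b]

    def test_numbered_5prime_to_3prime(self):
        pockets = build_pockets(_confs_from_starts([(40, 80), (10, 80)]))
        assert [p.index for p in pockets] == list(range(1, len(pockets) + 1))
        assert all(
            a.span[0] < b.span[0] for a, b in zip(pockets, pockets[1:])
        )


class TestFlexibleFlag:
    def _pocket_with(self, n_nonconsensus: int, n_consensus: int = 0):
        sites = [_site(i * 2, "AAGAA") for i in range(n_nonconsensus)]
        sites += [_site(100 + i * 2, "AAGGA") for i in range(n_consensus)]
        confs = [_conf(s, _site(s.start + 200)) for s in sites]
        pockets = build_pockets(confs)
        return flag_flexible_pockets(pockets)

    def test_eight_nonconsensus_flagged(self):
        pockets = self._pocket_with(8)
        assert any(p.flexible_flag and p.n_nonconsensus == 8 for p in pockets)

    def test_three_sites_not_flagged(self):
        confs = _confs_from_starts([(10, 100), (12, 100), (14, 100)])
        pockets = flag_flexible_pockets(build_pockets(confs))
        assert not any(p.flexible_flag for p in pockets if p.span[0] == 10)

    def test_consensus_members_do_not_count(self):
        # 9-site pocket with 2 ANGGN members: 7 non-consensus -> flagged
        sites = [_site(10 + 2 * i, "AAGAA") for i in range(7)]
        sites += [_site(10 + 2 * 7, "AAGGA"), _site(10 + 2 * 8, "AAGGA")]
        confs = [_conf(s, _site(s.start + 200)) for s in sites]
        pockets = flag_flexible_pockets(build_pockets(confs))
        big = max(pockets, key=lambda p: p.n_sites)
        assert big.n_sites == 9 and big.n_consensus == 2 and big.flexible_flag

    def test_above_upper_bound_not_flagged(self):
        pockets = self._pocket_with(11)
        assert not any(p.flexible_flag for p in pockets)


class TestClassification:
    def test_consensus_pair_short_distance(self):
        c = _conf(_site(0, "AAGGA"), _site(12, "AAGGA"), coop=-4.601, ddg=0.0)
        cls = classify_conformation_terms(c)
        assert cls.n_high_affinity == 2
        assert cls.strong_cooperativity
        assert not cls.large_structural_change

    def test_d30_never_strong_cooperativity(self):
        c = _conf(_site(0, "AAGGA"), _site(30, "AAGGA"), coop=-3.125)
        assert not classify_conformation_terms(c).strong_cooperativity

    def test_d24_with_weak_coop_not_strong(self):
        c = _conf(_site(0, "AAGGA"), _site(24, "AAGGA"), coop=-3.9)
        assert not classify_conformation_terms(c).strong_cooperativity

    def test_structure_threshold_inclusive(self):
        c = _conf(_site(0), _site(40), ddg=3.0)
        assert classify_conformation_terms(c).large_structural_change

    def test_strata_partition(self):
        confs = [
            _conf(_site(0, "AAGGA"), _site(12, "AAGGA")),
            _conf(_site(0, "AAGGA"), _site(12, "AAGAA")),
            _conf(_site(0, "AAGAA"), _site(12, "AAGAA")),
            _conf(_site(0, "AAGAA"), _site(40, "AAGAA"), coop=0.0, ddg=5.0),
        ]
        ens = Ensemble("x", confs, confs, beta=1.0, k_requested=4)
        counts = classify_conformations([ens])
        assert counts.total == 4
        assert sum(row["total"] for row in counts.strata.values()) == counts.total
        assert counts.strata[2]["total"] == 1
        assert counts.strata[1]["total"] == 1
        assert counts.strata[0]["total"] == 2
        assert counts.total_structure == 1


class TestHypergeometric:
    def test_matches_scipy_tails(self):
        assert hypergeometric_enrichment(990, 258, 75, 49, "upper") == pytest.approx(
            float(hypergeom.sf(48, 990, 258, 75)), rel=1e-9
        )
        assert hypergeometric_enrichment(990, 518, 75, 25, "lower") == pytest.approx(
            float(hypergeom.cdf(25, 990, 518, 75)), rel=1e-9
        )

    def test_point_probability_matches_scipy(self):
        assert hypergeometric_point_probability(990, 258, 75, 49) == pytest.approx(
            float(hypergeom.pmf(49, 990, 258, 75)), rel=1e-9
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exact_enumeration_small_populations(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(5, 61))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(1, N + 1))
        k = int(rng.integers(max(0, n - (N - K)), min(n, K) + 1))
        for tail in ("upper", "lower"):
            exact = hypergeom_tail_exact(N, K, n, k, tail)
            assert hypergeometric_enrichment(N, K, n, k, tail) == pytest.approx(
                exact, rel=1e-10, abs=1e-300
            )

    def test_symmetric_toy_case(self):
        # N=10, K=5, n=4, k=2: both one-sided tails exceed one half
        assert hypergeometric_enrichment(10, 5, 4, 2, "upper") > 0.5
        assert hypergeometric_enrichment(10, 5, 4, 2, "lower") > 0.5

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(10, 12, 4, 2, "upper")
        with pytest.raises(ValueError):
            hypergeometric_enrichment(10, 5, 4, 5, "lower")
        with pytest.raises(ValueError):
            hypergeometric_enrichment(10, 5, 4, 2, "two-sided")


class TestSDOverlap:
    def _setup(self, site_starts: tuple[int, int], cds_start: int = 40):
        seq = "C" * cds_start + "AUG" + "C" * 40
        rec = MRNARecord(id="r", sequence=seq, cds_start=cds_start)
        conf = _conf(_site(site_starts[0]), _site(site_starts[1]))
        ens = Ensemble("r", [conf], [conf], beta=1.0)
        return [rec], [ens]

    def test_sd_region_definition(self):
        rec = MRNARecord(id="r", sequence="C" * 40 + "AUG" + "C" * 10, cds_start=40)
        assert sd_region(rec) == (25, 35)

    def test_site_in_sd_region(self):
        records, ensembles = self._setup((32, 10))  # window [32,37) meets [25,35)
        rep = sd_overlap_report(records, ensembles)
        assert rep["rows"][0]["sd_overlap"] is True

    def test_site_ending_at_cds_start_not_start_overlap(self):
        records, ensembles = self._setup((35, 10))  # window [35,40) ends at cds_start
        rep = sd_overlap_report(records, ensembles)
        assert rep["rows"][0]["start_overlap"] is False
        assert rep["rows"][0]["sd_overlap"] is False  # [35,40) vs [25,35)

    def test_site_deep_in_cds_neither(self):
        records, ensembles = self._setup((60, 10))
        rep = sd_overlap_report(records, ensembles)
        assert rep["rows"][0]["neither"] is True

    def test_cohort_percentages(self):
        records, ensembles = self._setup((32, 10))
        rep = sd_overlap_report(records, ensembles)
        assert rep["pct_sd_overlap"] == 100.0
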