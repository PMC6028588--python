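"""Ribosome-binding energetics and regulation classification."""

from __future__ import annotations

import math

import pytest

from csramod.ensemble import build_ensemble
from csramod.energy import scan_sites
from csramod.fixtures import generate_fixture
from csramod.folding import FoldCache
from csramod.records import MRNARecord
from csramod.translation import (
    BETA_RATE_PER_RT,
    TranslationEnergyBreakdown,
    TranslationParams,
    call_ensemble_regulation,
    classify_conformation,
    footprint_interval,
    regulate_record,
    ribosome_energy_bound,
    ribosome_energy_free,
)


def _breakdown(total_shift: float = 0.0, **overrides) -> TranslationEnergyBreakdown:
    base = dict(
        dG_mRNA_rRNA=-8.0, dG_start=-1.94, dG_spacing=0.0, dG_standby=0.0,
        dG_initial=-total_shift,
    )
    base.update(overrides)
    return TranslationEnergyBreakdown(**base)


class TestFreeEnergyModel:
    def test_perfect_sd_scaffold_has_zero_spacing_penalty(self, engine, analyze):
        fx, _, _, _ = analyze("planted_pair", 0)
        free = ribosome_energy_free(fx.record, FoldCache(engine))
        assert free.dG_spacing == 0.0
        assert free.sd_spacing == 5
        assert free.dG_mRNA_rRNA < -5.0  # strong SD:anti-SD duplex

    def test_sequestered_sd_weakens_initiation(self, engine):
        fx = generate_fixture("hairpin_sequestered_sd", seed=0)
        rec = fx.record
        # control: same scaffold with the antisense arm replaced by inert C/U
        arm_lo, arm_hi = fx.truth["arm"]
        seq = rec.sequence
        control = seq[:arm_lo] + "CU" * ((arm_hi - arm_lo + 1) // 2) + seq[arm_hi:]
        control_rec = MRNARecord(id="ctrl", sequence=control[: len(seq)], cds_start=rec.cds_start)
        cache = FoldCache(engine)
        sequestered = ribosome_energy_free(rec, cache)
        open_sd = ribosome_energy_free(control_rec, cache)
        assert sequestered.dG_total > open_sd.dG_total

    def test_polya_utr_no_sd_hybridization(self, engine):
        rec = MRNARecord(id="noSD", sequence="A" * 40 + "AUG" + "A" * 30, cds_start=40)
        free = ribosome_energy_free(rec, FoldCache(engine))
        assert free.dG_mRNA_rRNA == pytest.approx(0.0, abs=0.5)
        assert free.dG_start == pytest.approx(-1.94)

    def test_total_identity(self, engine, analyze):
        fx, _, _, _ = analyze("planted_pair", 0)
        b = ribosome_energy_free(fx.record, FoldCache(engine))
        assert b.dG_total == pytest.approx(
            b.dG_mRNA_rRNA + b.dG_start + b.dG_spacing + b.dG_standby - b.dG_initial
        )
        assert b.dG_spacing >= 0.0

    def test_footprint_interval_clipping(self):
        rec = MRNARecord(id="x", sequence="ACGU" * 10, cds_start=4)
        lo, hi = footprint_interval(rec, TranslationParams())
        assert (lo, hi) == (0, 20)


class TestBoundEnergyModel:
    def test_far_upstream_pair_not_impacted(self, engine, analyze):
        fx, _, ens, _ = analyze("planted_pair", 0)
        cache = FoldCache(engine)
        free = ribosome_energy_free(fx.record, cache)
        top = ens.top_k[0]
        assert (top.site1.start, top.site2.start) == tuple(fx.truth["planted_sites"])
        bound = ribosome_energy_bound(fx.record, top, cache)
        r, label = classify_conformation(free, bound)
        assert 0.8 <= r <= 1.2 and label == "not_impacted"

    def test_sd_occluding_pair_repressed(self, engine, analyze):
        fx, _, ens, _ = analyze("sd_occluder", 0)
        cache = FoldCache(engine)
        free = ribosome_energy_free(fx.record, cache)
        bound = ribosome_energy_bound(fx.record, ens.top_k[0], cache)
        r, label = classify_conformation(free, bound)
        assert r > 1.2 and label == "repressed"

    def test_hairpin_melting_pair_activated(self, engine, analyze):
        fx, _, ens, _ = analyze("activation_candidate", 0)
        cache = FoldCache(engine)
        free = ribosome_energy_free(fx.record, cache)
        top = ens.top_k[0]
        assert (top.site1.start, top.site2.start) == tuple(fx.truth["planted_sites"])
        bound = ribosome_energy_bound(fx.record, top, cache)
        r, label = classify_conformation(free, bound)
        assert r < 0.8 and label == "activated"

    def test_eviction_cost_charged_to_hybridization_term(self, engine, analyze):
        fx, _, ens, _ = analyze("sd_occluder", 0)
        cache = FoldCache(engine)
        free = ribosome_energy_free(fx.record, cache)
        top = ens.top_k[0]  # downstream site inside the footprint
        bound = ribosome_energy_bound(fx.record, top, cache)
        expected_eviction = -top.site2.dG_site - top.dG_coop
        assert bound.dG_mRNA_rRNA == pytest.approx(free.dG_mRNA_rRNA + expected_eviction)


class TestClassifier:
    def test_equal_totals_not_impacted(self):
        r, label = classify_conformation(_breakdown(), _breakdown())
        assert r == 1.0 and label == "not_impacted"

    @pytest.mark.parametrize("target,expected", [(1.5, "repressed"), (0.5, "activated")])
    def test_threshold_labels(self, target, expected):
        gap = math.log(target) / BETA_RATE_PER_RT
        r, label = classify_conformation(_breakdown(), _breakdown(total_shift=gap))
        assert r == pytest.approx(target, rel=1e-9)
        assert label == expected

    def test_depends_only_on_energy_difference(self):
        gap = 2.5
        r1, _ = classify_conformation(_breakdown(), _breakdown(total_shift=gap))
        shifted_free = _breakdown(dG_standby=100.0)
        shifted_bound = _breakdown(total_shift=gap, dG_standby=100.0)
        r2, _ = classify_conformation(shifted_free, shifted_bound)
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_monotone_in_eviction_cost(self):
        free = _breakdown()
        previous = 0.0
        for cost in (0.0, 2.0, 5.0, 12.0):
            bound = _breakdown(dG_mRNA_rRNA=-8.0 + cost)
            r, _ = classify_conformation(free, bound)
            assert r >= previous
            previous = r

    def test_non_finite_energy_rejected(self):
        with pytest.raises(ValueError):
            classify_conformation(_breakdown(), _breakdown(dG_standby=float("nan")))


class TestEnsembleVerdict:
    def test_dominant_mass_wins(self):
        verdict, mass = call_ensemble_regulation(
            [("repressed", 0.9), ("activated", 0.05), ("not_impacted", 0.05)]
        )
        assert verdict == "repressed"
        assert sum(mass.values()) == pytest.approx(1.0, abs=1e-9)

    def test_close_masses_heterogeneous(self):
        verdict, _ = call_ensemble_regulation(
            [("repressed", 0.5), ("activated", 0.4), ("not_impacted", 0.1)]
        )
        assert verdict == "heterogeneous"

    def test_exact_boundary_is_inclusive(self):
        verdict, _ = call_ensemble_regulation(
            [("repressed", 9 / 14), ("activated", 5 / 14), ("not_impacted", 0.0)]
        )
        assert verdict == "repressed"  # exactly 1.8-fold

    def test_just_below_boundary_flips(self):
        x = 5 / 14
        verdict, _ = call_ensemble_regulation(
            [("repressed", 1.799 * x), ("activated", x), ("not_impacted", 1 - 2.799 * x)]
        )
        assert verdict == "heterogeneous"

    def test_empty_not_assessable(self):
        verdict, mass = call_ensemble_regulation([])
        assert verdict == "not_assessable"
        assert sum(mass.values()) == 0.0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            call_ensemble_regulation([("enhanced", 1.0)])


class TestRegulateRecord:
    @pytest.mark.parametrize(
        "kind,expected",
        [
            ("sd_occluder", "repressed"),
            ("start_occluder", "repressed"),
            ("planted_pair", "no_impact"),
            ("activation_candidate", "activated"),
        ],
    )
    def test_fixture_battery_verdicts(self, analyze, kind, expected):
        _, _, _, call = analyze(kind, 0)
        assert call.verdict == expected
        assert sum(call.label_mass.values()) == pytest.approx(1.0, abs=1e-9)

    def test_no_conformations_not_assessable(self, engine):
        fx = generate_fixture("no_site_null", seed=0)
        with pytest.warns(UserWarning):
            ens = build_ensemble(fx.record.sequence, scan_sites(fx.record.sequence), FoldCache(engine))
        call = regulate_record(fx.record, ens, FoldCache(engine))
        assert call.verdict == "not_assessable" and call.calls == []
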