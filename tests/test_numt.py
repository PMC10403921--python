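"""NUMT catalog building, bisulfite-space read attribution, co-occurrence."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mtbsqc.calling import call_methylation
from mtbsqc.numt import (
    SBD,
    NumtRecord,
    build_numt_catalog,
    classify_read_origin,
    filter_and_recompute,
    read_bisulfite_space,
    sbd_cooccurrence,
)
from mtbsqc.reference import MtGenome, revcomp
from mtbsqc.simulate import NumtSpike, SimConfig, simulate_library

from conftest import fisher_exact_oracle, make_read, plant_numt, random_mt_genome


class TestBisulfiteSpace:
    def test_l_space_collapses_c(self):
        assert read_bisulfite_space("ACGT", "L") == "ATGT"

    def test_h_space_collapses_g(self):
        assert read_bisulfite_space("ACGT", "H") == "ACAT"

    def test_idempotent(self):
        for cls in ("L", "H"):
            once = read_bisulfite_space("ACGTNACGT", cls)
            assert read_bisulfite_space(once, cls) == once

    def test_exhaustive_sbd_informativeness(self):
        # C/T differences are invisible to L-informative reads, G/A to H;
        # checked over all 12 ordered base pairs and both classes
        for mt, nu in itertools.permutations("ACGT", 2):
            sbd = SBD(0, mt, nu)
            for cls in ("L", "H"):
                collapses = read_bisulfite_space(mt, cls) == read_bisulfite_space(nu, cls)
                assert (cls in sbd.informative_for) == (not collapses)
        assert "L" not in SBD(0, "C", "T").informative_for
        assert "H" not in SBD(0, "G", "A").informative_for


class TestCatalog:
    def test_planted_sbds_recovered_exactly(self, mt16k, numt_fixture):
        catalog = build_numt_catalog(mt16k, {numt_fixture["locus_id"]: numt_fixture["sequence"]})
        (rec,) = catalog
        assert rec.mt_start == numt_fixture["mt_start"]
        assert rec.mt_end == numt_fixture["mt_end"]
        assert [s.mt_position for s in rec.sbds] == numt_fixture["sbd_positions"]
        assert not rec.identical

    def test_exact_copy_identical(self, mt16k):
        nuc = mt16k.fetch(2000, 2300)
        (rec,) = build_numt_catalog(mt16k, {"copy": nuc})
        assert rec.identical and rec.sbds == []

    def test_reverse_oriented_numt_located(self, mt16k, numt_fixture):
        catalog = build_numt_catalog(
            mt16k, {"rev": revcomp(numt_fixture["sequence"])}
        )
        (rec,) = catalog
        assert rec.mt_start == numt_fixture["mt_start"]
        assert len(rec.sbds) == len(numt_fixture["sbd_positions"])

    def test_ct_sbd_annotated_uninformative(self, mt16k):
        # find a plus-C inside an interval and plant a C->T difference
        start = 6000
        seq = list(mt16k.fetch(start, start + 200))
        c_off = next(i for i, b in enumerate(seq) if b == "C")
        seq[c_off] = "T"
        (rec,) = build_numt_catalog(mt16k, {"ct": "".join(seq)})
        (sbd,) = rec.sbds
        assert (sbd.mt_base, sbd.numt_base) == ("C", "T")
        assert "L" not in sbd.informative_for and "H" in sbd.informative_for

    def test_unrelated_sequence_skipped(self, mt16k):
        rng = np.random.default_rng(99)
        junk = "".join(rng.choice(list("ACGT"), size=200))
        with pytest.warns(UserWarning, match="skipped"):
            catalog = build_numt_catalog(mt16k, {"junk": junk}, min_len=100)
        assert catalog == []

    def test_simulator_numt_round_trip(self, mt16k, numt_fixture):
        # rebuild the catalog from the record's own allele sequence
        (rec,) = build_numt_catalog(mt16k, {numt_fixture["locus_id"]: numt_fixture["sequence"]})
        rebuilt = build_numt_catalog(mt16k, {"again": rec.numt_sequence(mt16k)})
        assert [(s.mt_position, s.mt_base, s.numt_base) for s in rebuilt[0].sbds] == [
            (s.mt_position, s.mt_base, s.numt_base) for s in rec.sbds
        ]


class TestClassifyReadOrigin:
    @pytest.fixture()
    def setup(self, mt16k, numt_fixture):
        catalog = build_numt_catalog(
            mt16k, {numt_fixture["locus_id"]: numt_fixture["sequence"]}
        )
        return mt16k, numt_fixture, catalog

    def test_mt_read_matches_mt_alleles(self, setup):
        g, fx, catalog = setup
        bases = read_bisulfite_space(g.fetch(fx["mt_start"], fx["mt_start"] + 100), "L")
        call = classify_read_origin(make_read("r", fx["mt_start"], bases, "L"), g, catalog)
        assert call.verdict == "MT" and call.mt_allele_matches >= 2

    def test_numt_read_assigned_to_locus(self, setup):
        g, fx, catalog = setup
        numt_seq = catalog[0].numt_sequence(g)
        bases = read_bisulfite_space(numt_seq[:100], "L")
        call = classify_read_origin(make_read("r", fx["mt_start"], bases, "L"), g, catalog)
        assert call.verdict == f"NUMT:{fx['locus_id']}"
        assert call.numt_allele_matches == 2  # SBDs at offsets 25 and 75

    def test_read_outside_catalog_is_mt(self, setup):
        g, fx, catalog = setup
        call = classify_read_origin(make_read("r", 0, "AAAA", "L"), g, catalog)
        assert call.verdict == "MT" and call.informative_sbds_covered == 0

    def test_identical_region_read_ambiguous(self, mt16k):
        nuc = mt16k.fetch(2000, 2300)
        catalog = build_numt_catalog(mt16k, {"copy": nuc})
        bases = read_bisulfite_space(mt16k.fetch(2050, 2150), "L")
        call = classify_read_origin(make_read("r", 2050, bases, "L"), mt16k, catalog)
        assert call.verdict == "AMBIGUOUS"

    def test_uninformative_sbd_carries_no_evidence(self, mt16k):
        # single C->T SBD: an L read over it must remain uninformative
        start = 6000
        seq = list(mt16k.fetch(start, start + 200))
        c_off = next(i for i, b in enumerate(seq) if b == "C")
        seq[c_off] = "T"
        catalog = build_numt_catalog(mt16k, {"ct": "".join(seq)})
        bases = read_bisulfite_space("".join(seq[:100]), "L")
        call = classify_read_origin(make_read("r", start, bases, "L"), mt16k, catalog)
        assert call.verdict == "AMBIGUOUS" and call.informative_sbds_covered == 0

    def test_unconverted_c_count_recorded(self, setup):
        g, fx, _catalog = setup
        bases = g.fetch(fx["mt_start"], fx["mt_start"] + 100)  # nothing converted
        call = classify_read_origin(make_read("r", fx["mt_start"], bases, "L"), g, _catalog)
        assert call.unconverted_c_count == bases.count("C")

    def test_simulated_classification_perfect_at_full_conversion(self, mt16k, numt_fixture):
        catalog = build_numt_catalog(
            mt16k, {numt_fixture["locus_id"]: numt_fixture["sequence"]}
        )
        cfg = SimConfig(seed=71, target_depth_L=20, target_depth_H=20, read_len=100,
                        fragment_len_mean=150, fragment_len_sd=15, conversion_rate=1.0,
                        numt_spike=NumtSpike(numt_fixture["locus_id"], 0.05, 1.0))
        reads, truth = simulate_library(mt16k, cfg, catalog)
        truth_by_id = {t.read_id: t.origin for t in truth}
        n_eval = n_correct = 0
        for read in reads:
            call = classify_read_origin(read, mt16k, catalog)
            if call.informative_sbds_covered == 0:
                continue
            n_eval += 1
            n_correct += call.verdict == truth_by_id[read.read_id]
        assert n_eval > 50
        assert n_correct == n_eval  # exactly 100% without sequencing errors


class TestCooccurrence:
    def _reads_at_site(self, g, catalog, fx, n_numt, n_mt):
        numt_seq = catalog[0].numt_sequence(g)
        site_pos = fx["mt_start"] + numt_seq[:100].index("C")
        reads = []
        for i in range(n_numt):  # methylated NUMT reads: retained C + SBD alleles
            bases = numt_seq[:100]
            reads.append(make_read(f"n{i}", fx["mt_start"], bases, "L"))
        for i in range(n_mt):  # converted genuine reads
            bases = read_bisulfite_space(g.fetch(fx["mt_start"], fx["mt_start"] + 100), "L")
            reads.append(make_read(f"m{i}", fx["mt_start"], bases, "L"))
        return reads, site_pos

    def test_perfect_cooccurrence_tiny_p(self, mt16k, numt_fixture):
        catalog = build_numt_catalog(
            mt16k, {numt_fixture["locus_id"]: numt_fixture["sequence"]}
        )
        reads, site_pos = self._reads_at_site(mt16k, catalog, numt_fixture, 10, 90)
        res = sbd_cooccurrence(reads, site_pos, "L", mt16k, catalog)
        assert res.table == ((10, 0), (0, 90))
        assert res.p_value < 1e-6
        assert res.p_value == pytest.approx(fisher_exact_oracle(10, 0, 0, 90), rel=1e-6)

    def test_independent_case_p_near_one(self):
        # association absent by construction: 5/50 unconverted in both groups
        g = MtGenome("m", "A" * 30 + "C" + "A" * 69, circular=False)
        catalog = [NumtRecord("x", 0, 100, [SBD(10, "A", "G")])]
        reads = []
        i = 0
        for carries in (True, False):
            for unconv in range(50):
                bases = list("A" * 100)
                bases[10] = "G" if carries else "A"
                bases[30] = "C" if unconv < 5 else "T"
                reads.append(make_read(f"r{i}", 0, "".join(bases), "L"))
                i += 1
        res = sbd_cooccurrence(reads, 30, "L", g, catalog)
        assert res.table == ((5, 45), (5, 45))
        assert res.p_value == pytest.approx(1.0, abs=1e-9)
        assert res.p_value == pytest.approx(fisher_exact_oracle(5, 45, 5, 45), rel=1e-6)

    def test_fisher_matches_oracle_on_random_tables(self):
        g = MtGenome("m", "A" * 30 + "C" + "A" * 69, circular=False)
        catalog = [NumtRecord("x", 0, 100, [SBD(10, "A", "G")])]
        rng = np.random.default_rng(81)
        for _ in range(10):
            a, b, c, d = (int(x) for x in rng.integers(0, 50, size=4))
            if a + b == 0 or c + d == 0 or a + b + c + d > 200:
                continue
            reads = []
            i = 0
            for (carries, unconv), count in (((1, 1), a), ((1, 0), b), ((0, 1), c), ((0, 0), d)):
                for _ in range(count):
                    bases = list("A" * 100)
                    bases[10] = "G" if carries else "A"
                    bases[30] = "C" if unconv else "T"
                    reads.append(make_read(f"r{i}", 0, "".join(bases), "L"))
                    i += 1
            if not reads:
                continue
            res = sbd_cooccurrence(reads, 30, "L", g, catalog)
            assert res.p_value == pytest.approx(fisher_exact_oracle(a, b, c, d), rel=1e-6)

    def test_haldane_correction_on_zero_cell(self, mt16k, numt_fixture):
        catalog = build_numt_catalog(
            mt16k, {numt_fixture["locus_id"]: numt_fixture["sequence"]}
        )
        reads, site_pos = self._reads_at_site(mt16k, catalog, numt_fixture, 4, 16)
        res = sbd_cooccurrence(reads, site_pos, "L", mt16k, catalog)
        assert res.odds_ratio == pytest.approx((4.5 * 16.5) / (0.5 * 0.5))

    def test_no_covering_read_errors(self, mt16k, numt_fixture):
        catalog = build_numt_catalog(
            mt16k, {numt_fixture["locus_id"]: numt_fixture["sequence"]}
        )
        with pytest.raises(ValueError):
            sbd_cooccurrence([], 4000, "L", mt16k, catalog)

    def test_degenerate_no_sbd_coverage_undefined(self):
        g = MtGenome("m", "A" * 30 + "C" + "A" * 69, circular=False)
        catalog = [NumtRecord("x", 200, 300, [SBD(250, "A", "G")])]
        reads = [make_read("r", 0, "A" * 29 + "AC", "L")]
        res = sbd_cooccurrence(reads, 30, "L", g, catalog)
        assert res.p_value is None and res.odds_ratio is None


class TestFilterAndRecompute:
    def test_no_numt_verdicts_identity(self, mt16k):
        cfg = SimConfig(seed=91, target_depth_L=5, target_depth_H=5, read_len=50,
                        fragment_len_mean=80, fragment_len_sd=8, conversion_rate=1.0)
        reads, _ = simulate_library(mt16k, cfg)
        me = call_methylation(reads, mt16k)
        corrected, deltas = filter_and_recompute(me, reads, {}, policy="drop_numt")
        assert deltas == []
        assert np.array_equal(corrected.n_meth, me.n_meth)
        assert np.array_equal(corrected.n_unmeth, me.n_unmeth)

    def test_spike_contained_and_removed(self, mt16k, numt_fixture):
        catalog = build_numt_catalog(
            mt16k, {numt_fixture["locus_id"]: numt_fixture["sequence"]}
        )
        cfg = SimConfig(seed=92, target_depth_L=20, target_depth_H=20, read_len=100,
                        fragment_len_mean=150, fragment_len_sd=15, conversion_rate=1.0,
                        numt_spike=NumtSpike(numt_fixture["locus_id"], 0.05, 1.0))
        reads, _ = simulate_library(mt16k, cfg, catalog)
        me = call_methylation(reads, mt16k)
        levels = me.levels
        meth_sites = [s.position for i, s in enumerate(me.sites)
                      if me.n_meth[i] > 0]
        # contamination confined to the spiked interval
        assert meth_sites
        assert all(numt_fixture["mt_start"] <= p < numt_fixture["mt_end"] for p in meth_sites)
        calls = {r.read_id: classify_read_origin(r, mt16k, catalog) for r in reads}
        corrected, deltas = filter_and_recompute(me, reads, calls, policy="drop_numt")
        assert corrected.n_meth.sum() == 0  # full conversion: every signal was NUMT
        assert len(deltas) > 0
        # conservation: corrected + dropped = original
        dropped = [r for r in reads if calls[r.read_id].is_numt]
        dropped_me = call_methylation(dropped, mt16k)
        assert np.array_equal(corrected.n_meth + dropped_me.n_meth, me.n_meth)
        assert np.array_equal(corrected.n_unmeth + dropped_me.n_unmeth, me.n_unmeth)

    def test_drop_ambiguous_policy_empties_identical_region(self, mt16k):
        nuc = mt16k.fetch(8000, 8300)
        catalog = build_numt_catalog(mt16k, {"ident": nuc})
        cfg = SimConfig(seed=93, target_depth_L=10, target_depth_H=10, read_len=100,
                        fragment_len_mean=150, fragment_len_sd=15, conversion_rate=1.0,
                        numt_spike=NumtSpike("ident", 0.05, 1.0))
        reads, truth = simulate_library(mt16k, cfg, catalog)
        me = call_methylation(reads, mt16k)
        calls = {r.read_id: classify_read_origin(r, mt16k, catalog) for r in reads}
        corrected, _ = filter_and_recompute(
            me, reads, calls, policy="drop_numt_and_ambiguous"
        )
        # spiked reads sit entirely inside the identical interval: all dropped
        spiked = [t.read_id for t in truth if t.origin != "MT"]
        assert spiked
        assert all(calls[rid].verdict == "AMBIGUOUS" for rid in spiked)
        assert corrected.n_meth.sum() == 0

    def test_unknown_policy_rejected(self, mt16k):
        me = call_methylation([], mt16k)
        with pytest.raises(ValueError):
            filter_and_recompute(me, [], {}, policy="nope")
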