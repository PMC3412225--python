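"""Generator behaviour: determinism, planted structure, and the Poisson
well model."""

import math

import numpy as np
import pytest

from l1screen import (
    SimConfig,
    classify,
    count_en_sites,
    gen_bio_oligos,
    gen_chimeric_amplicon,
    gen_dilution_series,
    gen_donor_locus,
    gen_insertion_amplicon,
    gen_l1_reference,
    gen_target_locus,
    junction_composition,
    scan_oligos,
    simulate_bundle,
)
from l1screen.simulate import find_a_rich_tract, gen_empty_amplicon


class TestL1Reference:
    def test_deterministic_under_seed(self):
        a = gen_l1_reference(SimConfig(seed=1))
        b = gen_l1_reference(SimConfig(seed=1))
        assert a == b
        assert len(a) == 6000

    def test_different_seeds_diverge(self):
        # i.i.d. backgrounds from distinct seeds should disagree at ~75%
        # of positions; well above a 10% floor for every pair
        for s in range(10):
            a = gen_l1_reference(SimConfig(seed=s))
            b = gen_l1_reference(SimConfig(seed=s + 1000))
            frac = sum(x != y for x, y in zip(a, b)) / len(a)
            assert frac > 0.10

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError):
            gen_l1_reference(SimConfig(seed=1, l1_length=1000))


class TestBioOligos:
    def test_four_oligos_hit_terminal_region_exactly(self, l1_ref, oligos):
        assert len(oligos) == 4
        hits = scan_oligos(l1_ref, oligos, max_mismatch=0)
        assert len(hits) == 4
        assert all(h.position >= len(l1_ref) - 1500 for h in hits)

    def test_no_close_match_in_five_prime_half(self, l1_ref, oligos):
        assert scan_oligos(l1_ref[: len(l1_ref) // 2], oligos, 3) == []

    def test_single_full_window(self, l1_ref):
        out = gen_bio_oligos(l1_ref, n=1, length=1500)
        (oligo,) = out.values()
        assert len(oligo) == 1500
        assert scan_oligos(l1_ref, out, 0)[0].position == len(l1_ref) - 1500

    def test_oversized_window_rejected(self, l1_ref):
        with pytest.raises(ValueError):
            gen_bio_oligos(l1_ref, n=1, length=1501)


class TestTargetLocus:
    def test_planted_motifs_are_found(self, target):
        seq, info = target
        sites = count_en_sites(seq)
        assert len(sites) >= 5
        plus = {p for p, s in sites if s == "+"}
        assert set(info["en_positions"]) <= plus

    def test_motif_free_background(self):
        seq, _ = gen_target_locus(length=5000, planted_en_sites=0, seed=9)
        assert count_en_sites(seq) == []

    def test_passes_oligo_screen(self, target, oligos):
        seq, _ = target
        assert scan_oligos(seq, oligos, 3) == []

    def test_length_precondition(self):
        with pytest.raises(ValueError):
            gen_target_locus(length=500, seed=1)


class TestInsertionAmplicon:
    def test_full_length_insert_bookkeeping(self, target, l1_ref):
        seq, info = target
        cfg = SimConfig(seed=5, truncation_offset=0, tsd_length=15,
                        polyA_length=20)
        amp, truth = gen_insertion_amplicon(seq, l1_ref, cfg)
        assert len(amp) == len(seq) + len(l1_ref) + 20 + 15
        assert truth.kind == "genuine"
        assert truth.tsd_sequence == seq[truth.insertion_point:
                                         truth.insertion_point + 15]
        # spans consistent with construction
        s, e = truth.l1_span
        assert amp[s:e] == l1_ref
        s, e = truth.polyA_span
        assert amp[s:e] == "A" * 20

    def test_minus_orientation_spans(self, target, l1_ref):
        seq, _ = target
        cfg = SimConfig(seed=5, truncation_offset=4000, orientation="minus")
        amp, truth = gen_insertion_amplicon(seq, l1_ref, cfg)
        s, e = truth.l1_span
        from l1screen.seq import revcomp
        assert amp[s:e] == revcomp(l1_ref[4000:])
        s, e = truth.polyA_span
        assert set(amp[s:e]) == {"T"}  # tail reads as T-tract on plus strand

    def test_truncation_beyond_element_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, truncation_offset=6000)


class TestChimericAmplicon:
    def test_junction_is_a_rich(self, target, l1_ref):
        seq, _ = target
        donor = gen_donor_locus(l1_ref, seed=21)
        amp, truth = gen_chimeric_amplicon(seq, donor, seed=22)
        assert truth.kind == "chimera"
        assert truth.junction_position is not None
        assert junction_composition(amp, truth.junction_position, 20) >= 0.7

    def test_prefix_is_target_suffix_is_donor(self, target, l1_ref):
        seq, _ = target
        donor = gen_donor_locus(l1_ref, seed=21)
        amp, truth = gen_chimeric_amplicon(seq, donor, seed=22)
        j = truth.junction_position
        assert amp[:j] == seq[:j]
        assert amp[j:] == donor.sequence[donor.a_tract[0]:]

    def test_donor_without_element_gives_no_insertion(self, target, l1_ref):
        seq, _ = target
        donor = gen_donor_locus(l1_ref, seed=21, include_l1=False)
        amp, truth = gen_chimeric_amplicon(seq, donor, seed=22)
        ann = classify(amp, seq, l1_ref)
        assert ann.verdict == "no_insertion"

    def test_requires_a_rich_tract(self, l1_ref):
        plain = gen_l1_reference(SimConfig(seed=33))[:3000]  # no A tract
        assert find_a_rich_tract(plain) is None
        with pytest.raises(Exception):
            gen_chimeric_amplicon(plain, plain, seed=1)


class TestDilutionSeries:
    def test_zero_rate_all_negative(self):
        ser = gen_dilution_series(0.0, [1.0, 10.0], 8, seed=1)
        assert ser.wells_positive.sum() == 0

    def test_saturation_all_positive(self):
        ser = gen_dilution_series(50.0, [1.0], 8, seed=1)
        assert (ser.wells_positive == ser.wells_total).all()

    def test_reproducible(self):
        a = gen_dilution_series(0.1, [1, 5, 25], 8, seed=4)
        b = gen_dilution_series(0.1, [1, 5, 25], 8, seed=4)
        assert (a.wells_positive == b.wells_positive).all()

    def test_positive_fraction_matches_zero_class_model(self):
        lam = 0.5
        inputs = [1.0, 2.0, 4.0, 8.0]
        ser = gen_dilution_series(lam, inputs, 1000, seed=5)
        for m, k, n in zip(ser.input_pg, ser.wells_positive, ser.wells_total):
            p = 1 - math.exp(-lam * m)
            se = math.sqrt(p * (1 - p) / n)
            assert abs(k / n - p) <= 3 * se

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            gen_dilution_series(0.1, [-1.0], 8, seed=1)


class TestBundle:
    def test_bundle_is_deterministic(self):
        a = simulate_bundle(seed=13, n_targets=1, n_genuine=1, n_chimera=1,
                            n_empty=1)
        b = simulate_bundle(seed=13, n_targets=1, n_genuine=1, n_chimera=1,
                            n_empty=1)
        assert a["l1_ref"] == b["l1_ref"]
        assert [x["sequence"] for x in a["amplicons"]] == \
            [x["sequence"] for x in b["amplicons"]]
        assert (a["dilution"].wells_positive ==
                b["dilution"].wells_positive).all()

    def test_truth_records_label_every_kind(self):
        b = simulate_bundle(seed=13, n_targets=2, n_genuine=2, n_chimera=2,
                            n_empty=2)
        kinds = [a["truth"].kind for a in b["amplicons"]]
        assert kinds.count("genuine") == 2
        assert kinds.count("chimera") == 2
        assert kinds.count("empty") == 2
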