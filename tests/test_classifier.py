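"""Amplicon annotation: flanks, element, poly-A, TSD, and verdicts against
simulated ground truth."""

import numpy as np
import pytest

from l1screen import (
    CandidateAmplicon,
    SimConfig,
    classify,
    find_polyA,
    find_tsd,
    gen_chimeric_amplicon,
    gen_donor_locus,
    gen_insertion_amplicon,
    junction_composition,
    locate_l1,
    simulate_bundle,
)
from l1screen.classify import align_flanks
from l1screen.seq import random_seq

EXPECTED_VERDICT = {"genuine": "genuine", "chimera": "chimera",
                    "empty": "no_insertion"}


@pytest.fixture(scope="module")
def bundle():
    return simulate_bundle(seed=42, n_targets=3, n_genuine=12, n_chimera=12,
                           n_empty=3)


@pytest.fixture(scope="module")
def annotated(bundle):
    targets = {t["id"]: t["sequence"] for t in bundle["targets"]}
    out = []
    for a in bundle["amplicons"]:
        ann = classify(a["sequence"], targets[a["target_id"]],
                       bundle["l1_ref"])
        out.append((a, ann))
    return out


class TestAlignFlanks:
    def test_exact_target_copy_is_one_full_flank(self, target):
        seq, _ = target
        f5, f3 = align_flanks(seq, seq)
        assert f5 is not None and f5.r_span == (0, len(seq))
        assert f3 is not None and f3.r_span == (0, len(seq))

    def test_genuine_flanks_abut_insertion_point(self, target, l1_ref):
        seq, _ = target
        cfg = SimConfig(seed=8, tsd_length=15, polyA_length=20,
                        truncation_offset=4000)
        amp, truth = gen_insertion_amplicon(seq, l1_ref, cfg)
        f5, f3 = align_flanks(amp, seq)
        p = truth.insertion_point
        # 5' flank ends at the nick + TSD; 3' flank resumes at the nick
        assert abs(f5.r_end - (p + 15)) <= 15 + 5
        assert abs(f3.r_start - p) <= 15 + 5

    def test_chimera_has_no_three_prime_flank(self, target, l1_ref):
        seq, _ = target
        donor = gen_donor_locus(l1_ref, seed=30)
        amp, truth = gen_chimeric_amplicon(seq, donor, seed=31)
        ann = classify(amp, seq, l1_ref)
        assert ann.flank5 is not None
        assert ann.flank3 is None
        assert abs(ann.flank5.q_end - truth.junction_position) <= 10


class TestLocateL1:
    def test_full_length_element(self, target, l1_ref):
        seq, _ = target
        cfg = SimConfig(seed=8, truncation_offset=0)
        amp, truth = gen_insertion_amplicon(seq, l1_ref, cfg)
        hit = locate_l1(amp, l1_ref)
        assert hit.orientation == "plus"
        assert hit.truncation_offset == 0
        assert hit.q_span[0] == truth.l1_span[0]

    @pytest.mark.parametrize("orientation", ["plus", "minus"])
    def test_truncation_offset_recovered(self, target, l1_ref, orientation):
        seq, _ = target
        cfg = SimConfig(seed=8, truncation_offset=4000,
                        orientation=orientation)
        amp, _ = gen_insertion_amplicon(seq, l1_ref, cfg)
        hit = locate_l1(amp, l1_ref)
        assert hit.orientation == orientation
        assert abs(hit.truncation_offset - 4000) <= 5

    def test_absent_element(self, target, l1_ref):
        seq, _ = target
        assert locate_l1(seq, l1_ref) is None


class TestPolyA:
    def test_planted_tail_found(self):
        rng = np.random.default_rng(7)
        seq = random_seq(rng, 300, gc=0.6) + "A" * 20 + \
            random_seq(rng, 300, gc=0.6)
        result = find_polyA(seq, anchor=300)
        assert result is not None
        (s, e), purity = result
        assert e - s >= 18
        assert purity >= 0.9

    def test_no_tail(self):
        seq = "CG" * 200
        assert find_polyA(seq, anchor=200) is None

    def test_minus_strand_t_tract(self):
        rng = np.random.default_rng(7)
        seq = random_seq(rng, 300, gc=0.6) + "T" * 20 + \
            random_seq(rng, 300, gc=0.6)
        result = find_polyA(seq, anchor=320, direction="left", base="T")
        assert result is not None
        (s, e), purity = result
        assert e - s >= 18 and purity >= 0.9


class TestTsd:
    def _target(self):
        # handmade junction-unambiguous case: the duplicated motif cannot be
        # extended by chance on either side
        rng = np.random.default_rng(10)
        left = random_seq(rng, 200, gc=0.6)
        tsd = "ACGTGATCCATTGCA"  # 15 nt
        right = random_seq(rng, 200, gc=0.6)
        t = left + "G" + tsd + "C" + right
        p = len(left) + 1
        return t, p, tsd

    def test_planted_fifteen_mer(self):
        t, p, tsd = self._target()
        # breaks as the classifier would report them after TPRT duplication
        assert find_tsd(t, p + 15, p) == tsd

    def test_blunt_insertion(self):
        rng = np.random.default_rng(11)
        t = random_seq(rng, 500)
        assert find_tsd(t, 250, 250) is None

    def test_discordant_breaks(self):
        rng = np.random.default_rng(12)
        t = random_seq(rng, 4000)
        assert find_tsd(t, 120, 3300) is None


class TestJunctionComposition:
    def test_pure_a_window(self):
        assert junction_composition("A" * 50, 25, 20) == 1.0

    def test_random_balanced_sequence(self):
        rng = np.random.default_rng(13)
        seq = random_seq(rng, 4000, gc=0.5)
        fracs = [junction_composition(seq, p, 20)
                 for p in range(100, 3900, 100)]
        # mean of many windows ~ 0.5 within 3 binomial sigma
        se = (0.25 / (20 * len(fracs))) ** 0.5
        assert abs(np.mean(fracs) - 0.5) < 3 * se

    def test_planted_linker(self):
        rng = np.random.default_rng(14)
        seq = random_seq(rng, 200) + "A" * 25 + random_seq(rng, 200)
        assert junction_composition(seq, 212, 20) >= 0.95


class TestClassifyRoundTrip:
    def test_verdicts_match_truth(self, annotated):
        for a, ann in annotated:
            assert ann.verdict == EXPECTED_VERDICT[a["truth"].kind], \
                (a["id"], ann.evidence)

    def test_genuine_annotations_are_coordinate_consistent(self, annotated):
        for a, ann in annotated:
            if a["truth"].kind != "genuine":
                continue
            truth = a["truth"]
            seg = ann.l1_segment
            assert seg.orientation == truth.orientation
            assert abs(seg.truncation_offset - truth.truncation_offset) <= 5
            assert abs(seg.q_start - truth.l1_span[0]) <= 5
            assert abs(seg.q_end - truth.l1_span[1]) <= 5
            (s, e), purity = ann.polyA
            assert purity >= 0.8
            ts, te = truth.polyA_span
            assert s >= ts - 5 and e <= te + 5
            # intervals are disjoint and ordered along the amplicon
            spans = [ann.flank5.q_span, seg.q_span, ann.polyA[0],
                     ann.flank3.q_span]
            spans.sort()
            for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                assert b1 <= a2

    def test_genuine_tsd_recovered_within_ambiguity(self, annotated):
        for a, ann in annotated:
            if a["truth"].kind != "genuine":
                continue
            planted = len(a["truth"].tsd_sequence)
            if ann.tsd is None:
                continue  # not required for the verdict
            # chance microhomology can extend the exact repeat slightly
            assert planted <= len(ann.tsd) <= planted + 4

    def test_chimera_junctions_are_at_rich(self, annotated):
        for a, ann in annotated:
            if a["truth"].kind != "chimera":
                continue
            assert ann.junction_at_fraction
            assert min(ann.junction_at_fraction.values()) >= 0.7

    def test_invalid_characters_raise_rather_than_classify(self, target,
                                                           l1_ref):
        seq, _ = target
        with pytest.raises(ValueError):
            classify(CandidateAmplicon(id="bad", sequence="ACGT!" * 100),
                     seq, l1_ref)

    def test_short_amplicon_rejected(self):
        with pytest.raises(ValueError):
            CandidateAmplicon(id="tiny", sequence="ACGT")
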