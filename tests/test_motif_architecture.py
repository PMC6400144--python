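from itertools import product

import numpy as np
import pytest

from ctldscreen.io_formats import DomainAnnotation, ProteinRecord
from ctldscreen.motif_architecture import (
    BUILTIN_MOTIFS,
    LocationClass,
    MotifSpec,
    PatternError,
    find_motifs,
    locate_in_domains,
    predict_tm,
    scan_proteins,
    summarize_architecture,
)
from ctldscreen.synthetic_data import SimConfig, generate_proteome

# ---------------------------------------------------------------------------
# independent brute-force matcher (oracle)
# ---------------------------------------------------------------------------


def _expansions(pattern_tokens):
    """All concrete token-length assignments of a pattern."""
    choices = [range(t.min_len, t.max_len + 1) for t in pattern_tokens]
    return list(product(*choices))


def brute_force_hits(seq, spec):
    """Test every (start, token-length assignment) explicitly."""
    seq = seq.upper()
    tokens = spec.tokens
    found = set()
    for lengths in _expansions(tokens):
        total = sum(lengths)
        for start in range(len(seq) - total + 1):
            pos = start
            ok = True
            for tok, run in zip(tokens, lengths):
                if tok.residues is None:
                    pos += run
                    continue
                if seq[pos] not in tok.residues:
                    ok = False
                    break
                pos += 1
            if ok:
                found.add((start + 1, start + total))
    return found


class TestMatcher:
    @pytest.mark.parametrize(
        "seq,pattern,expected",
        [
            ("AWLHAAAAY", "WxH", {(2, 4)}),
            ("AWLHAAAAY", "WxHx{1,4}Y", {(2, 9)}),
            ("YAALYAAV", "Yxx[LI]", {(1, 4)}),
            ("WAHWAH", "WxH", {(1, 3), (4, 6)}),
            ("WWAHA", "WxH", {(2, 4)}),
            ("WAHAYAY", "WxHx{1,4}Y", {(1, 5), (1, 7)}),  # overlapping ends
            ("WXHXXXXXY", "WxHx{5}Y", {(1, 9)}),  # sequence X matches wildcards
            ("XAH", "WxH", set()),  # sequence X never matches a literal
        ],
    )
    def test_hand_enumerated_examples(self, seq, pattern, expected):
        hits = find_motifs(ProteinRecord("p", seq), MotifSpec("m", pattern))
        assert {(h.start, h.end) for h in hits} == expected

    def test_matched_text_equals_sequence_slice(self):
        prot = ProteinRecord("p", "AWLHAAAAY")
        for h in find_motifs(prot, MotifSpec("m", "WxHx{1,4}Y")):
            assert h.matched_text == prot.sequence[h.start - 1 : h.end]

    def test_case_insensitive(self):
        assert find_motifs(ProteinRecord("p", "awlh".upper()), MotifSpec("m", "wxh"))

    @pytest.mark.parametrize("pattern", ["", "x{1,4}", "W?H", "Wx{0,3}H", "[Z]x", "Wx{4,2}H", "[AB"])
    def test_malformed_patterns_rejected(self, pattern):
        with pytest.raises(PatternError):
            MotifSpec("bad", pattern)

    def test_agrees_with_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(11)
        specs = [MotifSpec(n, p) for n, p in BUILTIN_MOTIFS.items()]
        alphabet = list("ACDEFGHIKLMNPQRSTVWYX")
        for _ in range(150):
            seq = "".join(rng.choice(alphabet, size=int(rng.integers(5, 60))))
            prot = ProteinRecord("p", seq)
            for spec in specs:
                got = {(h.start, h.end) for h in find_motifs(prot, spec)}
                assert got == brute_force_hits(seq, spec), (seq, spec.pattern)

    def test_wxhxny_starts_are_a_subset_of_wxh_starts(self):
        rng = np.random.default_rng(3)
        wxh = MotifSpec("WxH", "WxH")
        long = MotifSpec("WxHx{1,4}Y", "WxHx{1,4}Y")
        for _ in range(100):
            seq = "".join(rng.choice(list("WHYAL"), size=30))
            prot = ProteinRecord("p", seq)
            starts_long = {h.start for h in find_motifs(prot, long)}
            starts_wxh = {h.start for h in find_motifs(prot, wxh)}
            assert starts_long <= starts_wxh


class TestLocation:
    DOM = [DomainAnnotation("p", "CTLD", 1, 10)]

    def _hit(self, start, end):
        from ctldscreen.motif_architecture import MotifHit

        return MotifHit("p", "WxH", start, end, "WAH")

    @pytest.mark.parametrize(
        "interval,expected",
        [
            ((2, 4), LocationClass.IN_DOMAIN),
            ((12, 14), LocationClass.NEAR_BOUNDARY),  # gap 1 <= margin
            ((30, 32), LocationClass.OUTSIDE),
            ((8, 12), LocationClass.NEAR_BOUNDARY),  # partial overlap
            ((21, 23), LocationClass.NEAR_BOUNDARY),  # gap 10 == margin, inclusive
            ((22, 24), LocationClass.OUTSIDE),  # gap 11 > margin
        ],
    )
    def test_classification(self, interval, expected):
        (hit,) = locate_in_domains([self._hit(*interval)], self.DOM, margin=10)
        assert hit.location_class == expected

    def test_in_domain_sets_domain_ref(self):
        (hit,) = locate_in_domains([self._hit(2, 4)], self.DOM, margin=10)
        assert hit.domain_ref == self.DOM[0]

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            locate_in_domains([], self.DOM, margin=-1)

    def test_increasing_margin_never_demotes_to_outside(self):
        rng = np.random.default_rng(9)
        order = {
            LocationClass.IN_DOMAIN: 0,
            LocationClass.NEAR_BOUNDARY: 1,
            LocationClass.OUTSIDE: 2,
        }
        for _ in range(200):
            start = int(rng.integers(1, 60))
            hit = self._hit(start, start + 2)
            m1, m2 = sorted(rng.integers(0, 30, size=2))
            (a,) = locate_in_domains([hit], self.DOM, margin=int(m1))
            (b,) = locate_in_domains([hit], self.DOM, margin=int(m2))
            assert order[b.location_class] <= order[a.location_class]

    def test_nearest_domain_wins_on_tie(self):
        doms = [
            DomainAnnotation("p", "CTLD", 1, 10),
            DomainAnnotation("p", "CTLD", 30, 40),
        ]
        (hit,) = locate_in_domains([self._hit(13, 15)], doms, margin=20)
        assert hit.domain_ref == doms[0]  # gap 2 vs gap 14


class TestTM:
    def test_thirty_ile_in_hydrophilic_context_is_one_segment(self):
        prot = ProteinRecord("p", "R" * 25 + "I" * 30 + "R" * 25)
        segs = predict_tm(prot)
        assert len(segs) == 1
        s = segs[0]
        assert s.start <= 26 and s.end >= 55  # covers the planted core

    def test_all_arginine_has_no_segment(self):
        assert predict_tm(ProteinRecord("p", "R" * 60)) == []

    def test_two_separated_stretches_give_two_segments(self):
        prot = ProteinRecord("p", "R" * 10 + "I" * 25 + "R" * 25 + "I" * 25 + "R" * 10)
        assert len(predict_tm(prot)) == 2

    def test_short_sequence_yields_zero_segments(self):
        assert predict_tm(ProteinRecord("p", "I" * 10)) == []

    @pytest.mark.parametrize("window", [4, 6, 18])
    def test_even_or_tiny_window_rejected(self, window):
        with pytest.raises(ValueError):
            predict_tm(ProteinRecord("p", "I" * 40), window=window)


class TestArchitecture:
    def _summary(self, seq, domains, tm=()):
        prot = ProteinRecord("p", seq)
        hits = scan_proteins([prot])
        located = {n: locate_in_domains(h, domains, margin=10) for n, h in hits.items()}
        return summarize_architecture(prot, domains, located, list(tm))

    def test_complete_dectin1_like_architecture(self):
        # CTLD with WxH inside, one ITAM outside, one TM segment
        seq = "A" * 5 + "WAH" + "A" * 42 + "YAAL" + "A" * 6 + "I" * 25 + "A" * 5
        domains = [DomainAnnotation("p", "CTLD", 1, 20)]
        from ctldscreen.motif_architecture import TMSegment

        summary = self._summary(seq, domains, tm=[TMSegment("p", 61, 85)])
        assert summary.n_ctld == 1 and summary.n_itam == 1 and summary.n_tm == 1
        assert summary.wxh_in_ctld and summary.dectin1_like

    def test_wxh_outside_ctld_does_not_count(self):
        seq = "A" * 30 + "WAH" + "A" * 30
        domains = [DomainAnnotation("p", "CTLD", 1, 10)]
        summary = self._summary(seq, domains)
        assert not summary.wxh_in_ctld and not summary.dectin1_like

    def test_no_ctld_still_summarizable(self):
        summary = self._summary("WAHYAAL" + "A" * 20, [])
        assert summary.n_ctld == 0 and not summary.dectin1_like

    def test_many_itams_break_dectin1_likeness(self):
        # three ITAMs exceed the one-or-two rule even with CTLD+WxH+TM
        seq = "WAH" + "A" * 17 + "YAAL" * 3 + "A" * 10
        domains = [DomainAnnotation("p", "CTLD", 1, 10)]
        from ctldscreen.motif_architecture import TMSegment

        summary = self._summary(seq, domains, tm=[TMSegment("p", 40, 44)])
        assert summary.n_itam == 3 and not summary.dectin1_like


class TestPlantedRecovery:
    def test_all_planted_motifs_recovered_at_recorded_coordinates(self):
        config = SimConfig(seed=13, n_proteins=40)
        proteins, domains, truth = generate_proteome(config)
        hits = scan_proteins(proteins)
        located = {
            n: locate_in_domains(h, domains, margin=config.boundary_margin)
            for n, h in hits.items()
        }
        found = {
            (h.protein_id, h.motif_name, h.start, h.end, h.location_class.value)
            for hs in located.values()
            for h in hs
        }
        planted = set(map(tuple, truth.planted_motifs))
        assert planted, "generator planted nothing — fixture too small"
        assert planted <= found

    def test_planted_tm_segments_are_called(self):
        config = SimConfig(seed=13, n_proteins=40)
        proteins, _, truth = generate_proteome(config)
        by_id = {p.id: p for p in proteins}
        for pid, start, end in truth.planted_tm:
            segs = predict_tm(by_id[pid])
            assert any(s.start <= start and s.end >= end - 2 for s in segs), (pid, start, end)
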