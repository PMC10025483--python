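import numpy as np
import pytest

from mirstress.degradome import TranscriptProfile
from mirstress.simulate import MIR172B_5P, reverse_complement
from mirstress.targets import (
    CLEAVAGE_MIRNA_POSITION,
    DuplexAlignment,
    align_duplex,
    compliance_score,
    render_alignment,
    score_hit,
    select_best_targets,
    validate_cleavage,
)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
WOBBLE_PARTNER = {"T": "G", "G": "T"}  # mRNA base forming G:U with the miRNA base


def oracle_penalty(mirna, window):
    """Exhaustive per-position duplex scorer (independent of the aligner)."""
    L = len(mirna)
    total = 0.0
    for i in range(1, L + 1):  # miRNA position 5'->3'
        m = mirna[i - 1]
        t = window[L - i]  # antiparallel pairing partner
        if t == COMPLEMENT[m]:
            cost = 0.0
        elif (t == "G" and m == "T") or (t == "T" and m == "G"):
            cost = 0.5
        else:
            cost = 1.0
        total += cost * (2.0 if 2 <= i <= 13 else 1.0)
    return total


def perfect_site(mirna):
    return reverse_complement(mirna)


def mutate_opposite(mirna, site, position, kind="mismatch"):
    """Mutate the transcript base opposite a given miRNA position."""
    L = len(mirna)
    k = L - position  # window index pairing miRNA position
    m = mirna[position - 1]
    if kind == "mismatch":
        banned = {site[k], COMPLEMENT[m], WOBBLE_PARTNER.get(m, "")}
        new = next(b for b in "ACGT" if b not in banned)
    else:  # wobble
        new = WOBBLE_PARTNER[m]
    return site[:k] + new + site[k + 1 :]


class TestAlignDuplex:
    def test_perfect_duplex_penalty_zero(self, random_seq_factory):
        mirna = random_seq_factory(21)
        site = perfect_site(mirna)
        hits = align_duplex(mirna, "AAAA" + site + "TTTT")
        assert hits[0].penalty == 0.0
        assert hits[0].site_start == 5
        assert all(s == "match" for s in hits[0].per_position_state)

    @pytest.mark.parametrize("position, expected", [(1, 1.0), (5, 2.0), (14, 1.0), (2, 2.0), (13, 2.0)])
    def test_single_mismatch_position_weights(self, position, expected):
        mirna = MIR172B_5P
        site = mutate_opposite(mirna, perfect_site(mirna), position)
        hits = align_duplex(mirna, site)
        assert hits[0].penalty == pytest.approx(expected)
        assert hits[0].per_position_state[position - 1] == "mismatch"

    @pytest.mark.parametrize("position, expected", [(1, 0.5), (7, 1.0)])
    def test_single_wobble_half_weight(self, position, expected):
        # pick a miRNA whose relevant positions are G/T so a wobble exists
        mirna = "GTGTGTGTGTGTGTGTGTGTG"
        site = mutate_opposite(mirna, perfect_site(mirna), position, kind="wobble")
        hits = align_duplex(mirna, site)
        assert hits[0].penalty == pytest.approx(expected)
        assert hits[0].per_position_state[position - 1] == "gu_wobble"

    def test_mir172b_5p_planted_site(self, random_seq_factory):
        site = perfect_site(MIR172B_5P)
        offset = 17
        transcript = random_seq_factory(offset) + site + random_seq_factory(60 - offset - len(site))
        hits = [h for h in align_duplex(MIR172B_5P, transcript) if h.penalty == 0.0]
        assert len(hits) == 1
        assert hits[0].site_start == offset + 1
        # cleavage opposite miRNA position 10
        assert hits[0].predicted_cleavage == offset + 1 + len(MIR172B_5P) - CLEAVAGE_MIRNA_POSITION

    def test_transcript_shorter_than_mirna(self):
        assert align_duplex(MIR172B_5P, "ACGT") == []

    def test_mirna_length_contract(self):
        with pytest.raises(ValueError, match="18-26"):
            align_duplex("ACGT", "ACGTACGTACGTACGTACGTACGT")

    def test_agrees_with_exhaustive_scorer(self, rng, random_seq_factory):
        """Every window of random transcripts scores identically to the
        brute-force per-position oracle (penalties above the reporting
        cap checked by raising the cap)."""
        for _ in range(10):
            mirna = random_seq_factory(21)
            transcript = random_seq_factory(int(rng.integers(100, 500)))
            # plant a corrupted site so low penalties occur too
            site = perfect_site(mirna)
            for _ in range(int(rng.integers(0, 4))):
                pos = int(rng.integers(1, 22))
                site = mutate_opposite(mirna, site, pos)
            start = int(rng.integers(0, len(transcript) - 21))
            transcript = transcript[:start] + site + transcript[start + 21 :]
            hits = align_duplex(mirna, transcript, penalty_max=1e9)
            assert len(hits) == len(transcript) - 21 + 1
            by_start = {h.site_start: h.penalty for h in hits}
            for s0 in range(len(transcript) - 21 + 1):
                window = transcript[s0 : s0 + 21]
                assert by_start[s0 + 1] == pytest.approx(oracle_penalty(mirna, window))


class TestComplianceScore:
    def test_best_case_zero(self):
        assert compliance_score(0.0, 1, True) == 0.0

    def test_worst_case_eighteen(self):
        assert compliance_score(7.5, None, False) == 18.0
        assert compliance_score(12.0, None, False) == 18.0  # capped

    def test_stated_formula(self):
        assert compliance_score(2.0, 2, True) == 5.0

    @pytest.mark.parametrize("rank, expected", [(1, 0.0), (2, 1.0), (3, 1.0), (4, 2.0), (10, 2.0), (11, 3.0)])
    def test_rank_categories(self, rank, expected):
        assert compliance_score(0.0, rank, True) == expected

    def test_monotone_in_penalty_and_rank(self):
        penalties = np.linspace(0, 10, 41)
        for rank in (1, 2, 4, 11, None):
            scores = [compliance_score(p, rank, rank is not None) for p in penalties]
            assert all(a <= b for a, b in zip(scores, scores[1:]))
        for p in penalties:
            by_rank = [compliance_score(p, r, True) for r in (1, 2, 4, 11)]
            assert all(a <= b for a, b in zip(by_rank, by_rank[1:]))

    def test_negative_penalty_is_error(self):
        with pytest.raises(ValueError, match="non-negative"):
            compliance_score(-0.5, 1, True)


class TestSelectBestTargets:
    def _hits(self, scores):
        from mirstress.targets import TargetHit

        return [
            TargetHit(
                DuplexAlignment("m", f"t{i}", 1, 21, ("match",) * 21, 0.0, 12),
                None, 0.0, 0.0, s,
            )
            for i, s in enumerate(scores)
        ]

    def test_delta_window(self):
        hits = self._hits([0.0, 0.5, 6.0])
        best = select_best_targets(hits, delta=1.0)
        assert [h.alignment.transcript_id for h in best] == ["t0", "t1"]

    def test_single_hit(self):
        hits = self._hits([4.0])
        assert len(select_best_targets(hits)) == 1

    def test_all_tied(self):
        hits = self._hits([2.0, 2.0, 2.0])
        assert len(select_best_targets(hits)) == 3

    def test_empty(self):
        assert select_best_targets([]) == []


class TestValidateCleavage:
    def _alignment(self, site_start=11, length=21):
        return DuplexAlignment(
            "m", "t", site_start, site_start + length - 1, ("match",) * length, 0.0,
            site_start + length - CLEAVAGE_MIRNA_POSITION,
        )

    def test_planted_peak_validates(self):
        aln = self._alignment()
        raw = np.zeros(60, dtype=int)
        raw[aln.predicted_cleavage - 1] = 40
        ok, offset = validate_cleavage(aln, TranscriptProfile("t", 60, "ak", raw))
        assert ok and offset == 0

    def test_distant_peak_rejected(self):
        aln = self._alignment()
        raw = np.zeros(60, dtype=int)
        raw[aln.predicted_cleavage - 1 - 5] = 40  # 5 nt off, inside site
        ok, offset = validate_cleavage(aln, TranscriptProfile("t", 60, "ak", raw), window=1)
        assert not ok and offset == -5

    def test_matches_distance_oracle(self, rng):
        for _ in range(200):
            aln = self._alignment(site_start=int(rng.integers(1, 40)))
            raw = np.zeros(80, dtype=int)
            peak = int(rng.integers(aln.site_start, aln.site_end + 1))
            raw[peak - 1] = 50
            raw[rng.integers(0, 80, 5)] += rng.integers(1, 10, 5)
            profile = TranscriptProfile("t", 80, "ak", raw)
            ok, _ = validate_cleavage(aln, profile, window=1)
            segment = raw[aln.site_start - 1 : aln.site_end]
            peaks = np.flatnonzero(segment == segment.max()) + aln.site_start
            assert ok == bool(np.min(np.abs(peaks - aln.predicted_cleavage)) <= 1)


def test_render_alignment_shows_pairing(random_seq_factory):
    mirna = MIR172B_5P
    transcript = "AAAA" + perfect_site(mirna) + "TTTT"
    hit = align_duplex(mirna, transcript)[0]
    text = render_alignment(hit, mirna, transcript)
    lines = text.splitlines()
    assert lines[0].startswith("5' ") and lines[2].startswith("3' ")
    assert set(lines[1].strip()) == {"|"}
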