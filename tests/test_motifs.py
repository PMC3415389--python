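import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from chipem.formats import BindingEvent, GenomeAccessor
from chipem.motifs import (
    LOGISTIC_SCALE,
    PosRecord,
    Pwm,
    build_weighted_pwm,
    canonical_kmer,
    discover_motifs,
    extract_sets,
    find_enriched_kmers,
    grow_kmer_class,
    logistic_weight,
    revcomp,
    scan_pwm,
    trim_pwm,
    zero_order_background,
)
from chipem.simulate import default_pwm_probs, simulate_dataset


def _rand_seq(rng, n):
    return "".join("ACGT"[c] for c in rng.integers(0, 4, n))


def _pwm_from_consensus(consensus, strength=0.85, bg=None):
    return Pwm(
        probs=default_pwm_probs(consensus, strength),
        background=np.full(4, 0.25) if bg is None else bg,
    )


class TestExtractSets:
    def test_window_arithmetic(self):
        rng = np.random.default_rng(0)
        g = GenomeAccessor({"chr1": _rand_seq(rng, 5000)})
        events = [BindingEvent("chr1", 1000, 10.0)]
        pos, neg = extract_sets(events, g)
        assert len(pos) == 1 and pos[0].seq == g.fetch("chr1", 970, 1031)
        assert pos[0].center == 30
        assert neg == [g.fetch("chr1", 670, 731), g.fetch("chr1", 1270, 1331)]

    def test_negative_overlapping_positive_dropped(self):
        rng = np.random.default_rng(0)
        g = GenomeAccessor({"chr1": _rand_seq(rng, 5000)})
        events = [BindingEvent("chr1", 1000, 10.0), BindingEvent("chr1", 1300, 10.0)]
        pos, neg = extract_sets(events, g)
        # the negatives at 1000+300 and 1300-300 coincide with positives
        assert len(pos) == 2 and len(neg) == 2
        assert g.fetch("chr1", 1270, 1331) not in neg

    def test_no_negative_overlaps_any_positive(self):
        rng = np.random.default_rng(1)
        g = GenomeAccessor({"chr1": _rand_seq(rng, 200_000)})
        events = sorted(
            (BindingEvent("chr1", int(p), 1.0) for p in rng.integers(500, 199_500, 100)),
            key=lambda e: e.pos,
        )
        pos, neg = extract_sets(events, g)
        pos_set = {r.seq for r in pos}
        starts = {g.fetch("chr1", e.pos - 30, e.pos + 31) for e in events}
        for n in neg:
            assert n not in starts | pos_set


class TestKmerEnrichment:
    def test_canonicalization(self):
        assert canonical_kmer("ACGTT") == canonical_kmer("AACGT")
        assert canonical_kmer("ACGT") == "ACGT"  # palindrome fixed point

    def test_ubiquitous_kmer_not_enriched(self):
        motif = "ACGTTGCAC"
        rng = np.random.default_rng(0)
        pos = [PosRecord(_rand_seq(rng, 20) + motif + _rand_seq(rng, 20), 1.0, 24) for _ in range(40)]
        neg = [_rand_seq(rng, 20) + motif + _rand_seq(rng, 20) for _ in range(40)]
        ks = find_enriched_kmers(pos, neg, 9)
        assert canonical_kmer(motif) not in {s.kmer for s in ks}

    def test_p_value_matches_exhaustive_hypergeometric(self):
        # 40/100 positive hits, 5/100 negative hits
        def tail(k, M, n, N):
            return sum(
                math.comb(n, i) * math.comb(M - n, N - i) / math.comb(M, N)
                for i in range(k, min(n, N) + 1)
            )

        p = tail(40, 200, 100, 45)
        assert sps.hypergeom.sf(39, 200, 100, 45) == pytest.approx(p, rel=1e-9)
        # through the public surface: fold 8 >= 3 and p < 1e-3 -> enriched
        motif = "ACGTTGCAC"
        rng = np.random.default_rng(3)
        pos = [
            PosRecord(
                _rand_seq(rng, 20) + (motif if i < 40 else _rand_seq(rng, 9)) + _rand_seq(rng, 20),
                1.0,
                24,
            )
            for i in range(100)
        ]
        neg = [
            _rand_seq(rng, 20) + (motif if i < 5 else _rand_seq(rng, 9)) + _rand_seq(rng, 20)
            for i in range(100)
        ]
        ks = {s.kmer: s for s in find_enriched_kmers(pos, neg, 9)}
        key = canonical_kmer(motif)
        assert key in ks
        got = ks[key]
        expect = tail(got.pos_hits, 200, 100, got.pos_hits + got.neg_hits)
        assert got.p_hyper == pytest.approx(expect, rel=1e-9)
        assert got.fold >= 3

    def test_k_larger_than_sequences_rejected(self):
        with pytest.raises(ValueError):
            find_enriched_kmers([PosRecord("ACGT", 1.0, 2)], ["ACGT"], 5)

    def test_reverse_complement_input_invariance(self):
        motif = "GGGTAACCGCA"
        rng = np.random.default_rng(4)
        pos = [PosRecord(_rand_seq(rng, 25) + motif + _rand_seq(rng, 25), 1.0, 30) for _ in range(30)]
        neg = [_rand_seq(rng, 61) for _ in range(60)]
        rc_pos = [PosRecord(revcomp(r.seq), r.strength, 60 - r.center) for r in pos]
        rc_neg = [revcomp(s) for s in neg]
        a = {(s.kmer, s.pos_hits, round(s.p_hyper, 12)) for s in find_enriched_kmers(pos, neg, 6)}
        b = {(s.kmer, s.pos_hits, round(s.p_hyper, 12)) for s in find_enriched_kmers(rc_pos, rc_neg, 6)}
        assert a == b


class TestLogisticWeight:
    def test_w0_is_one(self):
        assert logistic_weight(0) == 1.0

    def test_closed_form_at_5bp(self):
        s = math.sqrt(39) / math.pi
        e = math.exp(-5 / s)
        assert logistic_weight(5) == pytest.approx(4 * e / (1 + e) ** 2, rel=1e-12)
        assert logistic_weight(5) == pytest.approx(0.277, abs=5e-3)
        assert LOGISTIC_SCALE == pytest.approx(math.sqrt(39) / math.pi, rel=1e-12)


class TestWeightedPwm:
    def test_equal_weight_columns(self):
        bg = np.full(4, 0.25)
        pwm = build_weighted_pwm(["AA", "AC"], [1.0, 1.0], [0.0, 0.0], bg)
        lo = pwm.log_odds
        assert lo[0].argmax() == 0
        assert lo[1, 0] == pytest.approx(lo[1, 1])

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            build_weighted_pwm(["AA"], [1.0], [0.0], np.full(4, 0.25))


class TestScanPwm:
    def test_threshold_is_60_percent_of_max(self):
        pwm = _pwm_from_consensus("GGGTAACCG")
        assert pwm.threshold == pytest.approx(0.6 * pwm.max_score)
        scaled = Pwm(probs=pwm.probs, background=pwm.background)
        assert scaled.threshold / scaled.max_score == pytest.approx(0.6)

    def test_consensus_scores_max(self):
        pwm = _pwm_from_consensus("GGGTAACCG")
        hits = scan_pwm(pwm, "AAAA" + "GGGTAACCG" + "TTTT")
        best = max(hits, key=lambda h: h[2])
        assert best[0] == 4 and best[1] == "+"
        assert best[2] == pytest.approx(pwm.max_score)

    def test_matches_equal_naive_rescoring(self):
        rng = np.random.default_rng(9)
        seq = _rand_seq(rng, 10_000)
        pwm = _pwm_from_consensus("GGTAAC", strength=0.7)
        got = set(scan_pwm(pwm, seq))
        lo = pwm.log_odds
        naive = set()
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for i in range(len(seq) - pwm.width + 1):
                sc = sum(lo[j, "ACGT".index(s[i + j])] for j in range(pwm.width))
                if sc >= pwm.threshold:
                    pos = i if strand == "+" else len(seq) - pwm.width - i
                    naive.add((pos, strand, round(sc, 9)))
        assert {(p, s, round(sc, 9)) for p, s, sc in got} == naive


class TestTrim:
    def test_background_flanks_trimmed_off(self):
        rng = np.random.default_rng(2)
        core = "GGTAACC"
        probs = np.vstack([
            np.full((3, 4), 0.25),
            default_pwm_probs(core, 0.9),
            np.full((3, 4), 0.25),
        ])
        pwm = Pwm(probs=probs, background=np.full(4, 0.25))
        pos = [PosRecord(_rand_seq(rng, 27) + core + _rand_seq(rng, 27), 1.0, 30) for _ in range(40)]
        neg = [_rand_seq(rng, 61) for _ in range(80)]
        trimmed = trim_pwm(pwm, pos, neg)
        assert trimmed.width <= pwm.width
        # brute-force best sub-range by exhaustive hit recount
        assert trimmed.width < pwm.width  # flanking background columns gone

    def test_idempotent_and_never_wider(self):
        rng = np.random.default_rng(3)
        pwm = _pwm_from_consensus("GGTAACCA")
        pos = [PosRecord(_rand_seq(rng, 26) + "GGTAACCA" + _rand_seq(rng, 27), 1.0, 30) for _ in range(30)]
        neg = [_rand_seq(rng, 61) for _ in range(60)]
        t1 = trim_pwm(pwm, pos, neg)
        t2 = trim_pwm(t1, pos, neg)
        assert t1.width <= pwm.width
        assert t2.width == t1.width
        np.testing.assert_allclose(t2.probs, t1.probs)


class TestClassGrowth:
    def test_hamming_one_neighbors_seed_the_class(self):
        from chipem.motifs import KmerStat

        seed = KmerStat("GGGTGGGG", 30, 1, 1e-10, 10.0, 0.0)
        pool = [
            seed,
            KmerStat("GGGAGGGG", 20, 1, 1e-8, 8.0, 0.0),
            KmerStat("TTTTTTTT", 15, 1, 1e-6, 6.0, 0.0),
        ]
        rng = np.random.default_rng(0)
        pos = [PosRecord(_rand_seq(rng, 26) + "GGGTGGGG" + _rand_seq(rng, 27), 1.0, 30) for _ in range(20)]
        neg = [_rand_seq(rng, 61) for _ in range(40)]
        cls = grow_kmer_class(seed, pool, pos, neg)
        members = {m.kmer for m in cls.members}
        assert "GGGTGGGG" in members and "GGGAGGGG" in members
        assert "TTTTTTTT" not in members and "AAAAAAAA" not in members

    def test_planted_pwm_recovered_with_high_column_correlation(self):
        truth = simulate_dataset(seed=21, n_events=60, genome_length=600_000)
        genome = GenomeAccessor(truth.genome)
        motifs = discover_motifs(truth.truth_events(), genome, k_range=range(5, 10))
        assert motifs, "no motif recovered"
        planted = default_pwm_probs(truth.params["motif"])
        r = _best_alignment_corr(motifs[0].pwm, planted)
        assert r > 0.9

    def test_shuffled_sequences_give_no_motif(self):
        rng = np.random.default_rng(17)
        g = GenomeAccessor({"chr1": _rand_seq(rng, 300_000)})
        events = sorted(
            (BindingEvent("chr1", int(p), 10.0) for p in rng.integers(1000, 299_000, 60)),
            key=lambda e: e.pos,
        )
        hits = 0
        for _ in range(5):
            events = sorted(
                (BindingEvent("chr1", int(p), 10.0) for p in rng.integers(1000, 299_000, 60)),
                key=lambda e: e.pos,
            )
            hits += bool(discover_motifs(events, g, k_range=range(5, 10)))
        assert hits == 0


def _best_alignment_corr(pwm, planted_probs):
    """Best per-column Pearson r between a discovered PWM and the planted
    letter-probability matrix over all offsets and both orientations."""
    best = -1.0
    for probs in (pwm.probs, pwm.probs[::-1, ::-1]):
        w, wt = probs.shape[0], planted_probs.shape[0]
        for off in range(-w + 3, wt - 2):
            cols = []
            for j in range(w):
                if 0 <= j + off < wt:
                    cols.append((probs[j], planted_probs[j + off]))
            if len(cols) < min(w, wt) // 2 + 1:
                continue
            a = np.concatenate([c[0] for c in cols])
            b = np.concatenate([c[1] for c in cols])
            r = np.corrcoef(a, b)[0, 1]
            best = max(best, r)
    return best


class TestDiscovery:
    def test_two_planted_motifs_found_in_significance_order(self):
        # the two consensi share no 4-mer (in either orientation), so the
        # equivalence classes cannot legitimately bridge them
        rng = np.random.default_rng(30)
        g = list(_rand_seq(rng, 400_000))
        m1, m2 = "GGGTAACCGCA", "CATTGCCTGAA"
        events = []
        positions = np.sort(rng.choice(np.arange(2000, 398_000, 1500), 80, replace=False))
        for i, p in enumerate(positions):
            motif = m1 if i % 2 == 0 else m2
            g[p - 5 : p + 6] = motif
            events.append(BindingEvent("chr1", int(p), 10.0))
        genome = GenomeAccessor({"chr1": "".join(g)})
        found = discover_motifs(events, genome, k_range=range(5, 10), max_motifs=4)
        assert len(found) >= 2
        ps = [c.pwm.p_hyper for c in found]
        assert ps == sorted(ps)
        consensi = [c.pwm.consensus for c in found[:2]]
        for planted in (m1, m2):
            assert any(c in planted or revcomp(c) in planted for c in consensi)
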