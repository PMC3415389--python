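import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from chipem.events import (
    Region,
    bh_correct,
    em_fit,
    m_step_update,
    segment_regions,
    test_significance,
)
from chipem.formats import BindingEvent, ReadAlignment
from chipem.read_model import ReadSpatialDistribution

from conftest import reads_for_event


def _reads(positions, strand="+", chrom="chr1"):
    return [ReadAlignment(chrom, p, strand) for p in positions]


class TestSegmentation:
    def test_contiguous_reads_form_one_region(self):
        regions = segment_regions(_reads([10, 11, 12, 13, 14, 15]))
        assert len(regions) == 1
        assert regions[0].n_reads == 6

    def test_large_gap_splits_and_small_region_dropped(self):
        regions = segment_regions(_reads([10, 11, 12, 13, 14, 15, 520]))
        assert len(regions) == 1  # the singleton at 520 is dropped (<6 reads)
        assert regions[0].n_reads == 6

    def test_bounds_are_reads_padded_and_clipped(self):
        regions = segment_regions(
            _reads([100, 101, 102, 103, 104, 105]), pad=500,
            chrom_lengths={"chr1": 400},
        )
        assert regions[0].start == 0
        assert regions[0].end == 400

    @given(st.lists(st.integers(0, 5000), min_size=0, max_size=120))
    def test_partition_properties_match_brute_force(self, positions):
        """Regions contain exactly the retained reads and no internal gap > 500."""
        reads = _reads(sorted(positions))
        regions = segment_regions(reads, min_reads=3, gap=500)
        collected = sorted(
            int(p) for r in regions for p, w in zip(r.pos5, r.weight) for _ in range(int(w))
        )
        # brute-force: scan sorted positions, split at gaps, drop small blocks
        blocks, block = [], []
        for p in sorted(positions):
            if block and p - block[-1] > 500:
                blocks.append(block)
                block = []
            block.append(p)
        if block:
            blocks.append(block)
        expected = sorted(p for b in blocks if len(b) >= 3 for p in b)
        assert collected == expected
        for r in regions:
            expanded = np.repeat(r.pos5, r.weight.astype(int))
            assert (np.diff(expanded) <= 500).all()


class TestMStep:
    def test_single_survivor(self):
        pi, keep = m_step_update(np.array([10.0]), 3.0, np.array([0.0]))
        np.testing.assert_allclose(pi, [1.0])

    def test_truncation_eliminates_component(self):
        pi, keep = m_step_update(np.array([10.0, 2.0]), 5.0, np.array([0.0, 0.0]))
        assert keep.tolist() == [True, False]
        np.testing.assert_allclose(pi, [1.0])

    def test_closed_form_with_positional_prior(self):
        pi, keep = m_step_update(np.array([10.0, 6.0, 4.0]), 3.0, np.array([0.0, 2.0, 0.0]))
        np.testing.assert_allclose(pi, [7 / 13, 5 / 13, 1 / 13])

    def test_all_eliminated_signals_no_events(self):
        pi, keep = m_step_update(np.array([1.0, 2.0]), 5.0, np.array([0.0, 0.0]))
        assert pi.size == 0 and not keep.any()

    def test_alpha_must_be_below_alpha_s(self):
        with pytest.raises(ValueError):
            m_step_update(np.array([10.0]), 3.0, np.array([3.0]))


def _point_mass_dist(W=500):
    p = np.zeros(2 * W + 1)
    p[W] = 1.0
    return ReadSpatialDistribution(p)


def _flat_laplace_dist(W=500, b=20.0):
    d = np.arange(-W, W + 1, dtype=float)
    return ReadSpatialDistribution(np.exp(-np.abs(d) / b))


class TestEmFit:
    def test_point_mass_degenerate_event(self):
        reads = _reads([50] * 10)
        region = Region.from_reads("chr1", reads, 0, 200)
        events, state = em_fit(region, _point_mass_dist(), alpha_s=1.0)
        assert [(e.pos, e.strength) for e in events] == [(50, 10.0)]

    def test_resolves_two_events_32bp_apart(self, chipseq_dist):
        rng = np.random.default_rng(0)
        reads = reads_for_event(rng, 2000, 500, chipseq_dist)
        reads += reads_for_event(rng, 2032, 500, chipseq_dist)
        region = Region.from_reads("chr1", sorted(reads, key=lambda r: r.pos5), 1000, 3100)
        events, _ = em_fit(region, chipseq_dist)
        assert len(events) == 2
        got = sorted(e.pos for e in events)
        assert abs(got[0] - 2000) <= 2 and abs(got[1] - 2032) <= 2

    @pytest.mark.parametrize("boosted", [0, 2])
    def test_positional_prior_breaks_likelihood_tie(self, boosted):
        """A symmetric read pile between p and p+2 lands on the alpha-boosted
        base; the double-exponential likelihood ties every interior base."""
        dist = _flat_laplace_dist()
        p = 1000
        reads = _reads([p - 10, p - 4], "+") + _reads([p + 12, p + 6], "+")
        reads = reads * 10
        region = Region.from_reads("chr1", reads, 900, 1100)
        alpha = np.zeros(region.length)
        alpha_s = 2.0
        alpha[(p + boosted) - region.start] = 0.5 * alpha_s
        events, _ = em_fit(region, dist, alpha=alpha, alpha_s=alpha_s)
        assert len(events) == 1
        assert events[0].pos == p + boosted

    def test_objective_monotone_between_restructures(self, chipseq_dist):
        rng = np.random.default_rng(3)
        reads = reads_for_event(rng, 3000, 150, chipseq_dist)
        region = Region.from_reads("chr1", sorted(reads, key=lambda r: r.pos5), 2000, 4000)
        _, state = em_fit(region, chipseq_dist)
        diffs = np.diff(state.objective_trace)
        stable = ~state.restructured[1:]
        assert (diffs[stable] >= -1e-9).all()

    def test_effective_counts_conserve_live_reads(self, chipseq_dist):
        rng = np.random.default_rng(4)
        reads = reads_for_event(rng, 3000, 120, chipseq_dist)
        region = Region.from_reads("chr1", sorted(reads, key=lambda r: r.pos5), 2000, 4000)
        events, state = em_fit(region, chipseq_dist)
        assert sum(e.strength for e in events) == pytest.approx(state.live_weight)
        assert state.pi.sum() == pytest.approx(1.0)

    def test_sparse_prior_limit_recovers_single_event(self, chipseq_dist):
        """alpha_s -> 0 reduces to ML; a lone event lands at the planted
        position where the distribution's mode offsets cancel."""
        rng = np.random.default_rng(8)
        reads = reads_for_event(rng, 2500, 400, chipseq_dist)
        region = Region.from_reads("chr1", sorted(reads, key=lambda r: r.pos5), 1500, 3500)
        events, _ = em_fit(region, chipseq_dist, alpha_s=1e-6, anneal_iters=0)
        top = max(events, key=lambda e: e.strength)
        assert abs(top.pos - 2500) <= 1


def _binom_tail(k, n):
    return sum(math.comb(n, i) for i in range(k, n + 1)) / 2**n


class TestSignificance:
    def test_binomial_with_matched_control(self):
        ev = [BindingEvent("chr1", 1000, 8.0)]
        chip = _reads(range(8))
        ctrl = _reads([1000] * 8)
        test_significance(ev, chip, ctrl, genome_size=100_000)
        assert ev[0].p_value == pytest.approx(_binom_tail(8, 16), rel=1e-9)
        assert ev[0].fold == pytest.approx(8.0 / 9.0)

    def test_strong_enrichment_is_tiny(self):
        ev = [BindingEvent("chr1", 1000, 50.0)]
        chip = _reads(range(52))
        ctrl = _reads([1000, 1001] + list(range(5000, 5050)))
        test_significance(ev, chip, ctrl, genome_size=100_000)
        assert ev[0].p_value < 1e-9

    def test_poisson_without_control(self):
        # 1000 reads over 201 kb -> genome-wide rate 1 per 201 bp window
        ev = [BindingEvent("chr1", 190_000, 1.0)]
        chip = _reads(np.linspace(0, 180_000, 1000).astype(int))
        test_significance(ev, chip, None, genome_size=201_000)
        assert ev[0].p_value == pytest.approx(1 - math.exp(-1), rel=1e-6)
        assert ev[0].fold == math.inf

    def test_zero_genome_rejected(self):
        with pytest.raises(ValueError):
            test_significance([], [], None, genome_size=0)


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_correct([0.01]), [0.01])

    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_correct([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_empty(self):
        assert bh_correct([]).size == 0

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=30))
    def test_permutation_invariance_and_q_ge_p(self, ps):
        q = bh_correct(ps)
        assert (q >= np.asarray(ps) - 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(ps))
        q2 = bh_correct([ps[i] for i in perm])
        np.testing.assert_allclose(q2, q[perm], rtol=1e-12)
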