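"""Six-phase pipeline: events -> motifs -> positional prior -> events -> motifs.

Phase 1 calls binding events with the sparse-prior EM and a generic read
distribution; Phases 2-3 discover the primary k-mer equivalence class from
those events; Phase 4 converts it into a per-base positional prior; Phase 5
re-calls events with the prior and a re-estimated read distribution; Phase 6
repeats motif discovery from the improved events.  The whole run is
deterministic for a given configuration and inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import events as ev
from . import formats, motifs as mo, prior as pr, read_model as rm

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "GemResult", "run_gem"]


@dataclass
class RunConfig:
    expt: str | Path | None = None
    ctrl: str | Path | None = None
    genome: str | Path | None = None
    out_prefix: str | Path | None = None
    k_min: int = 5
    k_max: int = 13
    q_threshold: float = 0.01
    alpha_override: float | None = None  # fixed alpha_s instead of sqrt(region reads)
    mu: float = 0.8
    read_dist: str | Path = "chipseq"  # chipseq | chipexo | distribution file
    rounds: int = 1  # prior-assisted re-estimation rounds (ChIP-exo: 2)
    min_reads_per_region: int = 6
    gap: int = 500
    top_k_dist: int = 1000
    max_motifs: int = 5
    smooth_bw: float = 5.0

    def __post_init__(self) -> None:
        if self.k_min > self.k_max:
            raise ValueError("k_min must be <= k_max")
        if not 0 <= self.mu < 1:
            raise ValueError("mu must be in [0, 1)")


@dataclass
class GemResult:
    events: list[formats.BindingEvent]  # final (last round) events
    phase1_events: list[formats.BindingEvent]
    motifs: list[mo.KmerClass]  # final motif classes
    phase3_motifs: list[mo.KmerClass]
    read_dist: rm.ReadSpatialDistribution
    log_lines: list[str] = field(default_factory=list)


def _initial_distribution(config: RunConfig) -> rm.ReadSpatialDistribution:
    rd = config.read_dist
    if isinstance(rd, rm.ReadSpatialDistribution):
        return rd
    if rd in ("chipseq", "chipexo"):
        return rm.default_distribution(rd)
    return formats.read_read_distribution(rd)


def _call_events(
    regions: Sequence[ev.Region],
    dist: rm.ReadSpatialDistribution,
    priors: pr.PositionalPrior | None,
    config: RunConfig,
    chip_reads,
    ctrl_reads,
    genome_size: int,
) -> list[formats.BindingEvent]:
    called: list[formats.BindingEvent] = []
    for i, region in enumerate(regions):
        alpha_s = config.alpha_override or math.sqrt(region.n_reads)
        alpha = priors.alpha(i, alpha_s) if priors is not None else None
        evs, _state = ev.em_fit(region, dist, alpha=alpha, alpha_s=alpha_s)
        called.extend(evs)
    called.sort(key=lambda e: (e.chrom, e.pos))
    ev.test_significance(called, chip_reads, ctrl_reads, genome_size)
    q = ev.bh_correct([e.p_value for e in called])
    for e, qv in zip(called, q):
        e.q_value = float(max(qv, e.p_value))
    return called


def _significant(events_list, q_threshold):
    return [e for e in events_list if e.q_value <= q_threshold]


def _update_distribution(events_list, reads, config, fallback, pwm=None, genome=None):
    """Re-estimate the read distribution from called events.

    When a primary motif is available the events are first snapped to the
    nearest motif match: the motif center is the most accurate available
    estimate of the interaction point, which lets the distribution escape
    a mis-specified initialization (the ChIP-exo adaptation mechanism)."""
    if pwm is not None and genome is not None:
        from .spacing import snap_to_motif

        events_list = snap_to_motif(events_list, pwm, genome, max_dist=50)
    try:
        return rm.estimate_distribution(
            events_list, reads, top_k=config.top_k_dist, smooth_bw=config.smooth_bw
        )
    except ValueError:
        log.warning("could not re-estimate read distribution; keeping previous")
        return fallback


def _annotate_motif(events_list, pwm, genome):
    if pwm is None:
        return
    w = pwm.width
    for e in events_list:
        lo = max(0, e.pos - 100 - w)
        seq = genome.fetch_clipped(e.chrom, lo, e.pos + 100 + w + 1)
        best = None
        for j, strand, _sc in mo.scan_pwm(pwm, seq):
            mid = lo + j + w // 2
            d = mid - e.pos
            if abs(d) <= 100 and (best is None or abs(d) < abs(best[0])):
                best = (d, strand)
        if best:
            e.motif_offset, e.motif_strand = int(best[0]), best[1]


def run_gem(
    config: RunConfig,
    reads: list[formats.ReadAlignment] | None = None,
    ctrl_reads: list[formats.ReadAlignment] | None = None,
    genome: formats.GenomeAccessor | None = None,
) -> GemResult:
    """Execute the six phases.  Inputs may be given as parsed objects or via
    the paths in ``config``."""
    lines: list[str] = []

    def note(msg: str) -> None:
        lines.append(msg)
        log.info(msg)

    if reads is None:
        reads = formats.parse_reads(config.expt)
    if ctrl_reads is None and config.ctrl is not None:
        ctrl_reads = formats.parse_reads(config.ctrl)
    if genome is None:
        genome = formats.GenomeAccessor.from_fasta(config.genome)
    genome_size = genome.total_length
    note(f"input: {len(reads)} reads, genome {genome_size} bp")

    dist = _initial_distribution(config)
    regions = ev.segment_regions(
        reads,
        min_reads=config.min_reads_per_region,
        gap=config.gap,
        pad=dist.W,
        chrom_lengths=genome.lengths,
    )
    note(f"phase 1: {len(regions)} regions after segmentation")
    if not regions:
        raise RuntimeError("no signal: no regions survive segmentation")

    # Phase 1: prior-free EM
    phase1 = _call_events(regions, dist, None, config, reads, ctrl_reads, genome_size)
    sig1 = _significant(phase1, config.q_threshold)
    note(f"phase 1: {len(phase1)} events ({len(sig1)} with q <= {config.q_threshold})")

    # Phases 2-3: motif discovery
    k_range = range(config.k_min, config.k_max + 1)
    seed_events = sig1 if sig1 else phase1
    phase3_motifs = mo.discover_motifs(
        seed_events, genome, k_range=k_range, max_motifs=config.max_motifs
    )
    note(f"phase 2-3: {len(phase3_motifs)} motif classes")

    final_events, final_motifs = phase1, phase3_motifs
    region_seqs = [genome.fetch_clipped(r.chrom, r.start, r.end) for r in regions]
    for rnd in range(1, config.rounds + 1):
        # Phase 4: positional prior from the primary class
        if final_motifs and config.mu > 0:
            priors = pr.build_priors(final_motifs[0], region_seqs, mu=config.mu)
            note(f"round {rnd}: prior C_max = {priors.c_max:g}")
        else:
            priors = None
            note(f"round {rnd}: no positional prior (mu=0 or no motif)")
        # Phase 5: prior-assisted EM
        final_events = _call_events(
            regions, dist, priors, config, reads, ctrl_reads, genome_size
        )
        sig = _significant(final_events, config.q_threshold)
        note(f"round {rnd}: {len(final_events)} events ({len(sig)} significant)")
        # read distribution is updated after each round of event prediction
        pwm = final_motifs[0].pwm if final_motifs else None
        dist = _update_distribution(sig or final_events, reads, config, dist, pwm, genome)
        # Phase 6: motif discovery from improved events
        final_motifs = mo.discover_motifs(
            sig if sig else final_events, genome, k_range=k_range, max_motifs=config.max_motifs
        )
        note(f"round {rnd}: {len(final_motifs)} motif classes")

    if final_motifs:
        _annotate_motif(final_events, final_motifs[0].pwm, genome)

    result = GemResult(
        events=final_events,
        phase1_events=phase1,
        motifs=final_motifs,
        phase3_motifs=phase3_motifs,
        read_dist=dist,
        log_lines=lines,
    )
    if config.out_prefix is not None:
        _write_outputs(result, config)
    return result


def _write_outputs(result: GemResult, config: RunConfig) -> None:
    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    formats.write_events(result.events, f"{prefix}.events.tsv")
    formats.write_events(result.phase1_events, f"{prefix}.phase1_events.tsv")
    formats.write_read_distribution(result.read_dist, f"{prefix}.read_dist.txt")
    if result.motifs:
        formats.write_meme(
            [c.pwm for c in result.motifs],
            f"{prefix}.motifs.meme",
            background=result.motifs[0].pwm.background,
        )
        with open(f"{prefix}.ksm.txt", "w") as fh:
            for i, cls in enumerate(result.motifs, 1):
                fh.write(f"#class {i} seed={cls.seed.kmer} k={cls.k} p={cls.pwm.p_hyper:.3g}\n")
                for m in sorted(cls.members, key=lambda m: m.seed_offset):
                    fh.write(f"{m.kmer}\t{m.seed_offset}\t{m.stat.pos_hits}\t{m.stat.offset:.2f}\n")
    with open(f"{prefix}.log", "w") as fh:
        fh.write("\n".join(result.log_lines) + "\n")
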