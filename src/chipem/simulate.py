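"""Synthetic ChIP-seq / ChIP-exo data with full ground truth.

The generator plants binding events on a zero-order background genome, writes
a motif instance (sampled from a PWM) centered on each event, and emits reads
whose 5' ends follow a specified strand-asymmetric offset distribution, plus
uniform noise reads and a matched uniform control.  Everything is
reproducible bit-exactly from (parameters, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .formats import BindingEvent, ReadAlignment, write_fasta
from .read_model import ReadSpatialDistribution, default_distribution

__all__ = ["SimulationTruth", "simulate_dataset", "simulate_spacing_pair", "default_pwm_probs"]

#: zero-order base composition of the background genome (A, C, G, T);
#: mildly AT-rich, like mammalian sequence
BACKGROUND = np.array([0.3, 0.2, 0.2, 0.3])
BASES = "ACGT"
READ_LEN = 36


@dataclass
class PlantedEvent:
    chrom: str
    pos: int  # motif middle == event coordinate
    n_reads: int
    motif: str
    strand: str


@dataclass
class SimulationTruth:
    """Ground truth of one simulated experiment."""

    genome: dict[str, str]
    events: list[PlantedEvent]
    reads: list[ReadAlignment]
    control: list[ReadAlignment]
    params: dict
    dist: ReadSpatialDistribution

    def truth_events(self) -> list[BindingEvent]:
        """Planted events as BindingEvents (for feeding analysis code)."""
        evs = [
            BindingEvent(chrom=e.chrom, pos=e.pos, strength=float(e.n_reads))
            for e in self.events
        ]
        evs.sort(key=lambda e: (e.chrom, e.pos))
        return evs

    # -- writers ---------------------------------------------------------

    def write(self, prefix: str | Path) -> dict[str, Path]:
        prefix = Path(prefix)
        paths = {
            "genome": prefix.with_suffix(".genome.fa"),
            "reads": prefix.with_suffix(".reads.bed"),
            "control": prefix.with_suffix(".control.bed"),
            "truth": prefix.with_suffix(".truth.tsv"),
            "config": prefix.with_suffix(".config.json"),
        }
        write_fasta(self.genome, paths["genome"])
        _write_reads_bed(self.reads, paths["reads"])
        _write_reads_bed(self.control, paths["control"])
        with open(paths["truth"], "w") as fh:
            fh.write("chrom\tpos\tn_reads\tmotif\tstrand\n")
            for e in self.events:
                fh.write(f"{e.chrom}\t{e.pos}\t{e.n_reads}\t{e.motif}\t{e.strand}\n")
        with open(paths["config"], "w") as fh:
            json.dump(self.params, fh, indent=1, sort_keys=True)
        return paths


def _write_reads_bed(reads: Sequence[ReadAlignment], path: Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            if r.strand == "+":
                s, e = r.pos5, r.pos5 + READ_LEN
            else:
                s, e = r.pos5 - READ_LEN + 1, r.pos5 + 1
            fh.write(f"{r.chrom}\t{s}\t{e}\tread{i}\t0\t{r.strand}\n")


def default_pwm_probs(consensus: str, strength: float = 0.85) -> np.ndarray:
    """Letter-probability matrix concentrated on a consensus sequence."""
    w = len(consensus)
    probs = np.full((w, 4), (1.0 - strength) / 3.0)
    for i, c in enumerate(consensus):
        probs[i, BASES.index(c)] = strength
    return probs


def _sample_background(rng: np.random.Generator, length: int) -> str:
    codes = rng.choice(4, size=length, p=BACKGROUND)
    return "".join(BASES[c] for c in codes)


def _sample_motif(rng: np.random.Generator, probs: np.ndarray) -> str:
    return "".join(BASES[rng.choice(4, p=row / row.sum())] for row in probs)


_COMP = str.maketrans("ACGTN", "TGCAN")


def _place_events(
    rng: np.random.Generator,
    genome_length: int,
    n_events: int,
    margin: int,
    min_spacing: int = 10,
    max_tries: int = 1000,
) -> np.ndarray:
    positions: list[int] = []
    tries = 0
    while len(positions) < n_events:
        p = int(rng.integers(margin, genome_length - margin))
        if all(abs(p - q) >= min_spacing for q in positions):
            positions.append(p)
            tries = 0
        else:
            tries += 1
            if tries > max_tries:
                raise RuntimeError("could not place events without overlap")
    return np.asarray(sorted(positions))


def _event_reads(
    rng: np.random.Generator,
    chrom: str,
    pos: int,
    n: int,
    dist: ReadSpatialDistribution,
    genome_length: int,
) -> list[ReadAlignment]:
    support = dist.support
    offs = rng.choice(support, size=n, p=dist.prob_plus)
    plus = rng.random(n) < 0.5
    pos5 = np.where(plus, pos + offs, pos - offs)
    pos5 = np.clip(pos5, 0, genome_length - 1)
    return [
        ReadAlignment(chrom, int(p), "+" if pl else "-") for p, pl in zip(pos5, plus)
    ]


def simulate_dataset(
    genome_length: int = 500_000,
    n_events: int = 50,
    motif: str | np.ndarray = "GGGTAACCGCA",
    reads_per_event: int = 100,
    strength_sigma: float = 0.5,
    noise_frac: float = 0.3,
    read_dist: ReadSpatialDistribution | str | None = None,
    seed: int = 0,
    chrom: str = "chr1",
    min_spacing: int = 10,
) -> SimulationTruth:
    """Simulate one ChIP experiment with planted, motif-centered events.

    Per-event read counts follow a log-normal law with median
    ``reads_per_event`` and log-sd ``strength_sigma``; ``noise_frac`` is the
    fraction of all ChIP reads that are uniform noise; the control is a
    uniform read set at matched depth."""
    rng = np.random.default_rng(seed)
    if isinstance(read_dist, str) or read_dist is None:
        dist = default_distribution(read_dist or "chipseq")
    else:
        dist = read_dist
    probs = default_pwm_probs(motif) if isinstance(motif, str) else np.asarray(motif)
    w = probs.shape[0]
    margin = dist.W + w + 10

    seq = list(_sample_background(rng, genome_length))
    positions = _place_events(rng, genome_length, n_events, margin, max(min_spacing, w))
    events: list[PlantedEvent] = []
    reads: list[ReadAlignment] = []
    for pos in positions:
        inst = _sample_motif(rng, probs)
        strand = "+" if rng.random() < 0.5 else "-"
        planted = inst if strand == "+" else inst.translate(_COMP)[::-1]
        start = pos - w // 2
        seq[start : start + w] = planted
        n = max(1, int(round(rng.lognormal(math.log(reads_per_event), strength_sigma))))
        events.append(PlantedEvent(chrom, int(pos), n, planted, strand))
        reads.extend(_event_reads(rng, chrom, int(pos), n, dist, genome_length))

    n_signal = len(reads)
    if not 0 <= noise_frac < 1:
        raise ValueError("noise_frac must be in [0, 1)")
    n_noise = int(round(n_signal * noise_frac / (1.0 - noise_frac))) if noise_frac else 0
    for p in rng.integers(0, genome_length, size=n_noise):
        reads.append(ReadAlignment(chrom, int(p), "+" if rng.random() < 0.5 else "-"))

    control = [
        ReadAlignment(chrom, int(p), "+" if rng.random() < 0.5 else "-")
        for p in rng.integers(0, genome_length, size=len(reads))
    ]
    params = {
        "genome_length": genome_length,
        "n_events": n_events,
        "motif": motif if isinstance(motif, str) else "pwm",
        "reads_per_event": reads_per_event,
        "strength_sigma": strength_sigma,
        "noise_frac": noise_frac,
        "read_dist": getattr(read_dist, "name", read_dist) if isinstance(read_dist, str) else "custom",
        "seed": seed,
        "min_spacing": min_spacing,
    }
    return SimulationTruth(
        genome={chrom: "".join(seq)},
        events=events,
        reads=reads,
        control=control,
        params=params,
        dist=dist,
    )


def simulate_spacing_pair(
    offset: int = 25,
    n_pairs: int = 150,
    motif_A: str = "TTTGTTATGCAAAT",
    motif_B: str = "GGGTGGGC",
    n_background_A: int = 50,
    n_background_B: int = 50,
    genome_length: int = 2_000_000,
    reads_per_event: int = 100,
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[SimulationTruth, SimulationTruth]:
    """Heterotypic event pairs at a fixed offset, sharing one genome.

    n_pairs B anchors are planted with their motif on a random strand; the
    paired A event sits at exactly ``offset`` bp in the B motif orientation
    (anchor - offset for minus-oriented anchors).  Independent background
    events are added for both factors.  Returns (truth_A, truth_B)."""
    if abs(offset) > 100:
        raise ValueError("|offset| must be <= 100")
    rng = np.random.default_rng(seed)
    dist = default_distribution("chipseq")
    probs_A = default_pwm_probs(motif_A)
    probs_B = default_pwm_probs(motif_B)
    wA, wB = probs_A.shape[0], probs_B.shape[0]
    margin = dist.W + 200

    seq = list(_sample_background(rng, genome_length))
    n_total = n_pairs + n_background_A + n_background_B
    positions = _place_events(rng, genome_length, n_total, margin, min_spacing=1200)

    order = rng.permutation(n_total)
    anchor_pos = positions[order[:n_pairs]]
    bgA_pos = positions[order[n_pairs : n_pairs + n_background_A]]
    bgB_pos = positions[order[n_pairs + n_background_A :]]

    events_A: list[PlantedEvent] = []
    events_B: list[PlantedEvent] = []

    def plant(pos: int, probs: np.ndarray, strand: str) -> str:
        winst = _sample_motif(rng, probs)
        planted = winst if strand == "+" else winst.translate(_COMP)[::-1]
        start = pos - probs.shape[0] // 2
        seq[start : start + probs.shape[0]] = planted
        return planted

    for bpos in anchor_pos:
        strand = "+" if rng.random() < 0.5 else "-"
        planted_b = plant(int(bpos), probs_B, strand)
        events_B.append(PlantedEvent(chrom, int(bpos), reads_per_event, planted_b, strand))
        apos = int(bpos) + (offset if strand == "+" else -offset)
        planted_a = plant(apos, probs_A, strand)
        events_A.append(PlantedEvent(chrom, apos, reads_per_event, planted_a, strand))
    for p in bgA_pos:
        strand = "+" if rng.random() < 0.5 else "-"
        events_A.append(PlantedEvent(chrom, int(p), reads_per_event, plant(int(p), probs_A, strand), strand))
    for p in bgB_pos:
        strand = "+" if rng.random() < 0.5 else "-"
        events_B.append(PlantedEvent(chrom, int(p), reads_per_event, plant(int(p), probs_B, strand), strand))

    genome = {chrom: "".join(seq)}

    def reads_for(events: list[PlantedEvent]) -> list[ReadAlignment]:
        out: list[ReadAlignment] = []
        for e in events:
            out.extend(_event_reads(rng, chrom, e.pos, e.n_reads, dist, genome_length))
        return out

    reads_A = reads_for(events_A)
    reads_B = reads_for(events_B)
    base_params = {
        "offset": offset,
        "n_pairs": n_pairs,
        "genome_length": genome_length,
        "seed": seed,
    }
    truth_A = SimulationTruth(genome, sorted(events_A, key=lambda e: e.pos), reads_A, [], dict(base_params, factor="A"), dist)
    truth_B = SimulationTruth(genome, sorted(events_B, key=lambda e: e.pos), reads_B, [], dict(base_params, factor="B"), dist)
    return truth_A, truth_B
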