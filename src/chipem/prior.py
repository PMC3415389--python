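"""Positional prior: per-base alpha_m from the primary k-mer class.

Every genomic occurrence of a class member k-mer votes for the base where
the k-mer's expected binding event sits, with weight equal to the number of
positive-set sequences containing that k-mer (its pos_hits).  The resulting
count track C is scaled into the event-specific Dirichlet parameter

    alpha_m = mu * alpha_s * C_m / C_max

with mu in [0, 1) (default 0.8) and C_max taken globally over all evaluated
regions, so alpha_m < alpha_s always holds: the sequence prior can bias an
event toward an explanatory k-mer but can never force one into existence.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np

from ._aho import build_automaton
from .motifs import KmerClass, revcomp

__all__ = ["PositionalPrior", "build_prior_counts", "alpha_from_counts", "build_priors"]


@dataclass
class PositionalPrior:
    """Prior count tracks for a set of regions and the global maximum."""

    counts: list[np.ndarray]
    c_max: float
    mu: float = 0.8

    def alpha(self, region_index: int, alpha_s: float) -> np.ndarray:
        return alpha_from_counts(
            self.counts[region_index], alpha_s, mu=self.mu, c_max=self.c_max
        )


def _class_patterns(kclass: KmerClass):
    """(pattern, (is_forward, offset votes)) for all member k-mers and their
    reverse complements, deduplicating palindromes.

    The votes are the k-mer's empirical offset histogram over the positive
    set, so C at a base counts the positive-set sequences whose binding
    offset matches that base.  A k-mer without a recorded histogram (e.g.
    constructed directly in tests) votes its full pos_hits at the rounded
    expected offset."""
    patterns = []
    seen: set[str] = set()
    for m in kclass.members:
        canon = m.stat.kmer
        if canon in seen:
            continue
        seen.add(canon)
        votes = [(int(o), float(c)) for o, c in sorted(m.stat.offset_hist.items())]
        if not votes:
            votes = [(int(round(m.stat.offset)), float(m.stat.pos_hits))]
        rc = revcomp(canon)
        patterns.append((canon, (True, votes)))
        if rc != canon:
            patterns.append((rc, (False, votes)))
    return patterns


def build_prior_counts(kclass: KmerClass, region_seq: str) -> np.ndarray:
    """Per-base prior counts C over a region sequence.

    A forward occurrence of a member k-mer at p contributes pos_hits at
    p + offset; a reverse-complement occurrence at p contributes at
    p + k - 1 - offset (the strand-mirrored base).  Contributions from
    multiple k-mers voting for the same base are summed; votes landing
    outside the region are clipped."""
    C = np.zeros(len(region_seq))
    if not kclass.members:
        return C
    ac = build_automaton(_class_patterns(kclass))
    k = kclass.k
    n = len(region_seq)
    for start, (fwd, votes) in ac.iter_matches(region_seq):
        for off, h in votes:
            target = start + off if fwd else start + k - 1 - off
            if 0 <= target < n:
                C[target] += h
    return C


def alpha_from_counts(
    C: np.ndarray, alpha_s: float, mu: float = 0.8, c_max: float | None = None
) -> np.ndarray:
    """Scale prior counts into alpha_m = mu * alpha_s * C / C_max."""
    if not 0 <= mu < 1:
        raise ValueError("mu must satisfy 0 <= mu < 1")
    if alpha_s <= 0:
        raise ValueError("alpha_s must be positive")
    C = np.asarray(C, dtype=float)
    if c_max is None:
        c_max = float(C.max()) if C.size else 0.0
    if c_max <= 0:
        return np.zeros_like(C)
    return mu * alpha_s * C / c_max


def build_priors(kclass: KmerClass, region_seqs: list[str], mu: float = 0.8) -> PositionalPrior:
    """Prior count tracks for all regions with the shared global C_max."""
    counts = [build_prior_counts(kclass, s) for s in region_seqs]
    c_max = max((float(c.max()) for c in counts if c.size), default=0.0)
    return PositionalPrior(counts=counts, c_max=c_max, mu=mu)
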