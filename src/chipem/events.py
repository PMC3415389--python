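"""Binding event calling: region segmentation, sparse-prior EM, significance.

The genome is split into independent regions at read gaps > 500 bp.  Within a
region every base is a candidate event m with mixing weight pi_m; a read's
likelihood under event m comes from the strand-aware read spatial
distribution.  A negative Dirichlet prior with exponent (-alpha_s + alpha_m)
penalizes each component by a pseudo-count alpha_s and rewards bases
supported by enriched k-mers by alpha_m < alpha_s, giving the M-step

    pi_m  propto  max(0, N_m - alpha_s + alpha_m)

where N_m is the effective (responsibility-weighted) read count.  Components
whose weight is driven to zero are eliminated, so the surviving components
are the called events at single-base resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .formats import BindingEvent, ReadAlignment
from .read_model import ReadSpatialDistribution

__all__ = [
    "Region",
    "MixtureState",
    "segment_regions",
    "m_step_update",
    "em_fit",
    "test_significance",
    "bh_correct",
]


@dataclass
class Region:
    """A separable stretch of genome with the (collapsed) reads inside it."""

    chrom: str
    start: int
    end: int
    pos5: np.ndarray  # unique (pos5, strand) pairs
    is_plus: np.ndarray
    weight: np.ndarray  # read multiplicity of each unique pair

    @classmethod
    def from_reads(
        cls, chrom: str, reads: Sequence[ReadAlignment], start: int, end: int
    ) -> "Region":
        pairs: dict[tuple[int, bool], float] = {}
        for r in reads:
            key = (r.pos5, r.strand == "+")
            pairs[key] = pairs.get(key, 0.0) + 1.0
        keys = sorted(pairs)
        return cls(
            chrom=chrom,
            start=start,
            end=end,
            pos5=np.asarray([k[0] for k in keys], dtype=np.int64),
            is_plus=np.asarray([k[1] for k in keys], dtype=bool),
            weight=np.asarray([pairs[k] for k in keys], dtype=float),
        )

    @property
    def n_reads(self) -> float:
        return float(self.weight.sum())

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MixtureState:
    """Converged mixture over a region: surviving components and diagnostics."""

    positions: np.ndarray  # genomic coords of surviving components
    pi: np.ndarray
    gamma: np.ndarray  # (n unique reads, n surviving components)
    alpha_s: float
    alpha: np.ndarray  # alpha_m of surviving components
    objective_trace: np.ndarray  # penalized objective, post-annealing iterations
    restructured: np.ndarray  # marks trace entries where a component was eliminated
    n_iter: int
    live_weight: float  # total weight of reads with nonzero likelihood


def segment_regions(
    reads: Sequence[ReadAlignment],
    min_reads: int = 6,
    gap: int = 500,
    pad: int = 500,
    chrom_lengths: dict[str, int] | None = None,
) -> list[Region]:
    """Split reads into separable regions at 5'-position gaps > ``gap`` bp.

    Regions with fewer than ``min_reads`` reads are dropped.  Region bounds
    are [first read - pad, last read + pad], clipped to the chromosome.
    """
    by_chrom: dict[str, list[ReadAlignment]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)

    regions: list[Region] = []
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: r.pos5)
        block: list[ReadAlignment] = []
        for r in rs:
            if block and r.pos5 - block[-1].pos5 > gap:
                regions.extend(_finish_block(chrom, block, min_reads, pad, chrom_lengths))
                block = []
            block.append(r)
        regions.extend(_finish_block(chrom, block, min_reads, pad, chrom_lengths))
    return regions


def _finish_block(chrom, block, min_reads, pad, chrom_lengths):
    if len(block) < min_reads:
        return []
    start = max(0, block[0].pos5 - pad)
    end = block[-1].pos5 + pad + 1
    if chrom_lengths is not None and chrom in chrom_lengths:
        end = min(end, chrom_lengths[chrom])
    return [Region.from_reads(chrom, block, start, end)]


def m_step_update(
    n_eff: np.ndarray, alpha_s: float, alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form M-step with component elimination.

    Returns ``(pi, keep)`` where ``keep`` marks surviving components and
    ``pi`` are their renormalized weights.  All-zero ``pi`` (empty ``keep``)
    signals that the region yields no events.
    """
    n_eff = np.asarray(n_eff, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(n_eff < 0):
        raise ValueError("negative effective counts")
    if np.any(alpha >= alpha_s) and alpha_s > 0:
        raise ValueError("alpha_m must be < alpha_s")
    u = np.maximum(0.0, n_eff - alpha_s + alpha)
    keep = u > 0
    total = u.sum()
    if total == 0:
        return np.empty(0), keep
    return u[keep] / total, keep


def em_fit(
    region: Region,
    dist: ReadSpatialDistribution,
    alpha: np.ndarray | None = None,
    alpha_s: float | None = None,
    tol: float = 1e-5,
    max_iter: int = 500,
    anneal_iters: int = 10,
) -> tuple[list[BindingEvent], MixtureState]:
    """Fit the sparse-prior mixture over every base of a region.

    ``alpha`` is the per-base positional prior over ``range(region.start,
    region.end)`` (zeros when None).  ``alpha_s`` defaults to
    sqrt(region read count) and is annealed linearly from 0 over the first
    ``anneal_iters`` iterations to avoid premature component death; the
    positional prior is scaled with it so alpha_m < alpha_s holds throughout.
    Convergence: absolute change of the penalized objective below ``tol``
    after annealing has finished.  The objective trace marks iterations at
    which a component was eliminated: the improper negative-Dirichlet prior
    makes the objective discontinuous in the number of components, so
    monotonicity is guaranteed only between eliminations.
    """
    positions = np.arange(region.start, region.end, dtype=np.int64)
    M = positions.size
    if alpha is None:
        alpha_full = np.zeros(M)
    else:
        alpha_full = np.asarray(alpha, dtype=float)
        if alpha_full.shape != (M,):
            raise ValueError(f"alpha must have length {M}")
    if alpha_s is None:
        alpha_s = math.sqrt(region.n_reads)
    if alpha_s > 0 and np.any(alpha_full >= alpha_s):
        raise ValueError("alpha_m must be < alpha_s everywhere")

    W = dist.W
    off = region.pos5[:, None] - positions[None, :]
    signed = np.where(region.is_plus[:, None], off, -off)
    valid = (signed >= -W) & (signed <= W)
    L = np.where(valid, dist.prob_plus[np.clip(signed + W, 0, 2 * W)], 0.0)

    active = np.flatnonzero(L.max(axis=0) > 0)
    if active.size == 0:
        state = MixtureState(
            positions=np.empty(0, dtype=np.int64),
            pi=np.empty(0),
            gamma=np.empty((region.pos5.size, 0)),
            alpha_s=alpha_s,
            alpha=np.empty(0),
            objective_trace=np.empty(0),
            restructured=np.empty(0, dtype=bool),
            n_iter=0,
            live_weight=0.0,
        )
        return [], state

    w = region.weight
    pi = np.full(active.size, 1.0 / active.size)
    trace: list[float] = []
    restructured: list[bool] = []
    prev_obj = None
    gamma = np.empty((0, 0))
    live_weight = 0.0
    it = 0

    for it in range(1, max_iter + 1):
        ramp = min(1.0, it / anneal_iters) if anneal_iters > 0 else 1.0
        a_s = alpha_s * ramp
        a_m = alpha_full[active] * ramp

        La = L[:, active]
        num = La * pi[None, :]
        denom = num.sum(axis=1)
        live = denom > 0
        gamma = np.zeros_like(num)
        gamma[live] = num[live] / denom[live, None]
        n_eff = (w[:, None] * gamma).sum(axis=0)

        pi_new, keep = m_step_update(n_eff, a_s, a_m)
        if keep.sum() == 0:
            active = active[:0]
            pi = pi_new
            gamma = gamma[:, :0]
            live_weight = 0.0
            break
        eliminated = bool(keep.sum() < keep.size)
        active = active[keep]
        pi = pi_new
        gamma = gamma[:, keep]

        denom_new = (L[:, active] * pi[None, :]).sum(axis=1)
        live = denom_new > 0
        live_weight = float(w[live].sum())
        obj = float(np.sum(w[live] * np.log(denom_new[live])))
        obj += float(np.sum((alpha_full[active] * ramp - a_s) * np.log(pi)))
        if not np.isfinite(obj):
            raise FloatingPointError(f"non-finite penalized objective at iteration {it}")

        post_anneal = it >= anneal_iters
        if post_anneal:
            trace.append(obj)
            restructured.append(eliminated)
        if post_anneal and prev_obj is not None:
            if abs(obj - prev_obj) <= tol:
                break
        prev_obj = obj if post_anneal else None

    # renormalize responsibilities rows to the final component set
    if gamma.size:
        rows = gamma.sum(axis=1)
        nz = rows > 0
        gamma[nz] = gamma[nz] / rows[nz, None]

    n_final = (w[:, None] * gamma).sum(axis=0) if gamma.size else np.empty(0)
    events = [
        BindingEvent(chrom=region.chrom, pos=int(p), strength=float(s))
        for p, s in zip(positions[active] if active.size else [], n_final)
    ]
    events.sort(key=lambda e: e.pos)
    state = MixtureState(
        positions=positions[active] if active.size else np.empty(0, dtype=np.int64),
        pi=pi if active.size else np.empty(0),
        gamma=gamma,
        alpha_s=alpha_s,
        alpha=alpha_full[active] if active.size else np.empty(0),
        objective_trace=np.asarray(trace),
        restructured=np.asarray(restructured, dtype=bool),
        n_iter=it,
        live_weight=live_weight,
    )
    return events, state


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------


def _sorted_positions(reads: Sequence[ReadAlignment]) -> dict[str, np.ndarray]:
    by: dict[str, list[int]] = {}
    for r in reads:
        by.setdefault(r.chrom, []).append(r.pos5)
    return {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in by.items()}


def _count_window(pos: dict[str, np.ndarray], chrom: str, center: int, half: int) -> int:
    arr = pos.get(chrom)
    if arr is None:
        return 0
    lo = np.searchsorted(arr, center - half, side="left")
    hi = np.searchsorted(arr, center + half, side="right")
    return int(hi - lo)


def test_significance(
    events: Sequence[BindingEvent],
    chip_reads: Sequence[ReadAlignment],
    control_reads: Sequence[ReadAlignment] | None,
    genome_size: int,
    window: int = 201,
) -> list[BindingEvent]:
    """Assign p-values and fold enrichment to events (in place; returned).

    With a control: an upper-tail binomial test with n = round(chip strength)
    + round(depth-scaled control count in a ``window`` bp window) and success
    probability 0.5.  Without a control: an upper-tail Poisson test with a
    dynamic rate, the max of the genome-wide, 5 kb and 10 kb local rates
    scaled to the event window.  Only the event read counts are tested.
    """
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    half = window // 2
    if control_reads is not None and len(control_reads) > 0:
        ctrl_pos = _sorted_positions(control_reads)
        scale = len(chip_reads) / len(control_reads)
        for e in events:
            ctrl = _count_window(ctrl_pos, e.chrom, e.pos, half) * scale
            nc = int(round(e.strength))
            nt = nc + int(round(ctrl))
            e.p_value = float(stats.binom.sf(nc - 1, nt, 0.5)) if nt > 0 else 1.0
            e.fold = e.strength / (ctrl + 1.0)
    else:
        chip_pos = _sorted_positions(chip_reads)
        lam_genome = len(chip_reads) / genome_size * window
        for e in events:
            lam5 = _count_window(chip_pos, e.chrom, e.pos, 2500) / 5000 * window
            lam10 = _count_window(chip_pos, e.chrom, e.pos, 5000) / 10000 * window
            lam = max(lam_genome, lam5, lam10)
            k = int(round(e.strength))
            e.p_value = float(stats.poisson.sf(k - 1, lam)) if lam > 0 else 1.0
            e.fold = math.inf
    return list(events)


def bh_correct(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


# not a pytest test, despite the name
test_significance.__test__ = False  # type: ignore[attr-defined]
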