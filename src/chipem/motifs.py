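"""Motif discovery by k-mer enrichment and equivalence-class clustering.

Enriched k-mers are found by comparing per-sequence hit counts between 61 bp
windows centered on called events (positive set) and windows 300 bp away
(negative set), with a hypergeometric test and a fold-enrichment gate, k-mers
and their reverse complements identified.  The most enriched k-mer seeds an
equivalence class: a set of k-mers at fixed alignment offsets that jointly
describe one binding specificity.  Positive sequences matched by the class
are aligned and summarized as a PWM, weighted by event strength and by a
logistic function of the distance between the sequence's class match and the
event position; the PWM is trimmed to the most discriminative sub-range and
used to re-admit k-mers until its significance stops improving.  Secondary
motifs are found after masking primary occurrences, and k is chosen to
maximize primary-PWM significance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .formats import BindingEvent, GenomeAccessor

log = logging.getLogger(__name__)

__all__ = [
    "KmerStat",
    "ClassMember",
    "KmerClass",
    "Pwm",
    "PosRecord",
    "revcomp",
    "canonical_kmer",
    "logistic_weight",
    "extract_sets",
    "find_enriched_kmers",
    "grow_kmer_class",
    "build_weighted_pwm",
    "trim_pwm",
    "scan_pwm",
    "discover_motifs",
    "zero_order_background",
]

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_CODE = {c: i for i, c in enumerate("ACGTN")}
#: scale of the logistic distance-weight density (variance 13)
LOGISTIC_SCALE = math.sqrt(39.0) / math.pi


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def logistic_weight(d: float) -> float:
    """Distance weight w(d) = f(d)/f(0) for the logistic density with
    mean 0 and variance 13; w(0) = 1."""
    e = math.exp(-abs(d) / LOGISTIC_SCALE)
    return 4.0 * e / (1.0 + e) ** 2


_ENC = np.full(256, 4, dtype=np.int8)
for _c, _i in _CODE.items():
    _ENC[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else -> 4 (scores as background)."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def zero_order_background(seqs: Iterable[str]) -> np.ndarray:
    counts = np.ones(4)  # +1 pseudocount keeps log-odds finite
    for s in seqs:
        codes = encode(s)
        for b in range(4):
            counts[b] += int((codes == b).sum())
    return counts / counts.sum()


def _modal_offset(offs: list[float]) -> float:
    """Expected event offset of a k-mer over the positive set.

    Sequences whose central site lacks the k-mer contribute an off-site
    occurrence at an arbitrary offset; a plain mean is dragged toward zero
    by them.  The estimate therefore anchors on the modal (most common
    rounded) offset and averages the raw offsets within 1 bp of it."""
    arr = np.asarray(offs, dtype=float)
    rounded = np.round(arr).astype(int)
    vals, cnt = np.unique(rounded, return_counts=True)
    order = sorted(range(vals.size), key=lambda i: (-cnt[i], abs(vals[i]), vals[i]))
    mode = vals[order[0]]
    sel = arr[np.abs(arr - mode) <= 1.0]
    return float(sel.mean())


def _offset_hist(offs: list[float]) -> dict[int, int]:
    vals, cnt = np.unique(np.round(np.asarray(offs)).astype(int), return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, cnt)}


def _hyper_sf(k, M, n, N):
    """Upper-tail hypergeometric P(X >= k) with population M, n successes,
    N draws."""
    return stats.hypergeom.sf(np.asarray(k) - 1, M, n, N)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class KmerStat:
    """Enrichment record for one canonical k-mer.

    ``offset`` is the expected event position relative to the k-mer start in
    the canonical orientation (event = occurrence_start + offset for a
    forward occurrence; mirrored for a reverse-complement occurrence).
    """

    kmer: str
    pos_hits: int
    neg_hits: int
    p_hyper: float
    fold: float
    offset: float
    #: empirical distribution of rounded event offsets over the positive set
    offset_hist: dict[int, int] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.kmer)


@dataclass
class ClassMember:
    kmer: str  # oriented string as it sits in the seed frame
    seed_offset: int  # start relative to seed start, in the seed frame
    stat: KmerStat


@dataclass
class Pwm:
    """Letter-probability matrix with log-odds scoring vs a zero-order
    background.  A sequence position matches when its score reaches 60% of
    the maximum achievable score."""

    probs: np.ndarray  # (width, 4)
    background: np.ndarray  # (4,)
    p_hyper: float = 1.0
    frame_offset: int = 0  # seed-frame coordinate of column 0
    name: str | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self._log_odds = np.log2(self.probs / self.background[None, :])

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return self._log_odds

    @property
    def max_score(self) -> float:
        return float(self._log_odds.max(axis=1).sum())

    @property
    def threshold(self) -> float:
        return 0.6 * self.max_score

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self._log_odds.argmax(axis=1))

    def probabilities(self) -> np.ndarray:
        return self.probs

    def sub(self, a: int, b: int) -> "Pwm":
        return Pwm(
            probs=self.probs[a:b],
            background=self.background,
            p_hyper=self.p_hyper,
            frame_offset=self.frame_offset + a,
            name=self.name,
        )

    def rc(self) -> "Pwm":
        return Pwm(
            probs=self.probs[::-1, ::-1],
            background=self.background[::-1],
            p_hyper=self.p_hyper,
            frame_offset=self.frame_offset,
            name=self.name,
        )


@dataclass
class KmerClass:
    """An equivalence class of offset-aligned k-mers and its derived PWM."""

    seed: KmerStat
    members: list[ClassMember]
    pwm: Pwm | None
    k: int


@dataclass
class PosRecord:
    """One positive-set sequence: the window, the strength of its event and
    the event position inside the window."""

    seq: str
    strength: float
    center: int


# ---------------------------------------------------------------------------
# positive / negative sequence sets
# ---------------------------------------------------------------------------


def extract_sets(
    events: Sequence[BindingEvent],
    genome: GenomeAccessor,
    flank: int = 30,
    neg_shift: int = 300,
) -> tuple[list[PosRecord], list[str]]:
    """Windows of width 2*flank+1 centered on events (positive set) and at
    +/- ``neg_shift`` bp (negative set, dropped when overlapping any positive
    window)."""
    width = 2 * flank + 1
    lengths = genome.lengths
    pos_records: list[PosRecord] = []
    pos_centers: dict[str, list[int]] = {}
    for e in events:
        L = lengths.get(e.chrom)
        if L is None or e.pos - flank < 0 or e.pos + flank + 1 > L:
            log.info("event %s:%d too close to contig edge; skipped", e.chrom, e.pos)
            continue
        pos_records.append(
            PosRecord(genome.fetch(e.chrom, e.pos - flank, e.pos + flank + 1), e.strength, flank)
        )
        pos_centers.setdefault(e.chrom, []).append(e.pos)
    centers_sorted = {c: np.sort(np.asarray(v)) for c, v in pos_centers.items()}

    neg_seqs: list[str] = []
    for e in events:
        L = lengths.get(e.chrom)
        if L is None:
            continue
        for c in (e.pos - neg_shift, e.pos + neg_shift):
            if c - flank < 0 or c + flank + 1 > L:
                continue
            arr = centers_sorted.get(e.chrom)
            if arr is not None and arr.size:
                i = np.searchsorted(arr, c)
                near = min(
                    abs(int(arr[j]) - c) for j in (max(0, i - 1), min(arr.size - 1, i))
                )
                if near <= 2 * flank:  # overlaps a positive window
                    continue
            neg_seqs.append(genome.fetch(e.chrom, c - flank, c + flank + 1))
    return pos_records, neg_seqs


# ---------------------------------------------------------------------------
# k-mer enrichment
# ---------------------------------------------------------------------------


def find_enriched_kmers(
    pos: Sequence[PosRecord],
    neg: Sequence[str],
    k: int,
    p_max: float = 1e-3,
    min_fold: float = 3.0,
) -> list[KmerStat]:
    """Canonical k-mers over-represented in the positive set.

    Hit counting is per-sequence presence.  Returned k-mers have
    hypergeometric p < ``p_max`` and fold >= ``min_fold``, sorted most
    enriched first (ascending p, descending fold, lexicographic)."""
    if not pos or not neg:
        return []
    min_len = min(min(len(r.seq) for r in pos), min(len(s) for s in neg))
    if k > min_len:
        raise ValueError(f"k={k} exceeds shortest sequence length {min_len}")

    pos_hits: dict[str, int] = {}
    offsets: dict[str, list[float]] = {}
    for rec in pos:
        # per k-mer keep the occurrence closest to the event: background
        # occurrences elsewhere in the window would otherwise bias the
        # expected binding offset toward zero
        seen: dict[str, float] = {}
        L = len(rec.seq)
        for j in range(L - k + 1):
            w = rec.seq[j : j + k]
            if "N" in w:
                continue
            c = canonical_kmer(w)
            # event offset relative to canonical k-mer start
            off = rec.center - j if w == c else j + k - 1 - rec.center
            prev = seen.get(c)
            center_dist = abs(rec.center - (j + (k - 1) / 2.0))
            if prev is None or center_dist < prev[1]:
                seen[c] = (off, center_dist)
        for c, (off, _d) in seen.items():
            pos_hits[c] = pos_hits.get(c, 0) + 1
            offsets.setdefault(c, []).append(off)

    neg_hits: dict[str, int] = {}
    for s in neg:
        seen_set = set()
        for j in range(len(s) - k + 1):
            w = s[j : j + k]
            if "N" in w:
                continue
            seen_set.add(canonical_kmer(w))
        for c in seen_set:
            neg_hits[c] = neg_hits.get(c, 0) + 1

    n_pos, n_neg = len(pos), len(neg)
    kmers = sorted(pos_hits)
    ph = np.asarray([pos_hits[c] for c in kmers])
    nh = np.asarray([neg_hits.get(c, 0) for c in kmers])
    fold = (ph / n_pos) / (np.maximum(nh, 1) / n_neg)
    pvals = _hyper_sf(ph, n_pos + n_neg, n_pos, ph + nh)

    stats_out = [
        KmerStat(
            kmer=c,
            pos_hits=int(ph[i]),
            neg_hits=int(nh[i]),
            p_hyper=float(pvals[i]),
            fold=float(fold[i]),
            offset=_modal_offset(offsets[c]),
            offset_hist=_offset_hist(offsets[c]),
        )
        for i, c in enumerate(kmers)
        if pvals[i] < p_max and fold[i] >= min_fold
    ]
    stats_out.sort(key=lambda s: (s.p_hyper, -s.fold, s.kmer))
    return stats_out


# ---------------------------------------------------------------------------
# vectorized PWM scanning
# ---------------------------------------------------------------------------


def _lo5(log_odds: np.ndarray) -> np.ndarray:
    return np.hstack([log_odds, np.zeros((log_odds.shape[0], 1))])


def _scores_plus(log_odds: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Scores of all plus-strand start positions; codes is (n, L)."""
    lo5 = _lo5(log_odds)
    w = log_odds.shape[0]
    n, L = codes.shape
    if L < w:
        return np.empty((n, 0))
    S = np.zeros((n, L - w + 1))
    for j in range(w):
        S += lo5[j][codes[:, j : j + L - w + 1]]
    return S


def _rc_log_odds(log_odds: np.ndarray) -> np.ndarray:
    return log_odds[::-1, ::-1]


def scan_pwm(pwm: Pwm, sequence: str) -> list[tuple[int, str, float]]:
    """All matches (start, strand, score) with score >= 60% of max score on
    either strand; overlapping matches all reported."""
    codes = encode(sequence)[None, :]
    thr = pwm.threshold
    out: list[tuple[int, str, float]] = []
    sp = _scores_plus(pwm.log_odds, codes)[0]
    sm = _scores_plus(_rc_log_odds(pwm.log_odds), codes)[0]
    for i in np.flatnonzero(sp >= thr):
        out.append((int(i), "+", float(sp[i])))
    for i in np.flatnonzero(sm >= thr):
        out.append((int(i), "-", float(sm[i])))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def _hits_any(pwm_lo: np.ndarray, codes: np.ndarray, thr: float) -> np.ndarray:
    sp = _scores_plus(pwm_lo, codes)
    sm = _scores_plus(_rc_log_odds(pwm_lo), codes)
    hit = np.zeros(codes.shape[0], dtype=bool)
    if sp.size:
        hit |= (sp >= thr).any(axis=1)
    if sm.size:
        hit |= (sm >= thr).any(axis=1)
    return hit


def _best_hits(pwm_lo: np.ndarray, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sequence best score, start position and strand (+1/-1).

    Ties prefer the plus strand, then the lower coordinate."""
    sp = _scores_plus(pwm_lo, codes)
    sm = _scores_plus(_rc_log_odds(pwm_lo), codes)
    n = codes.shape[0]
    if sp.shape[1] == 0:
        return np.full(n, -np.inf), np.zeros(n, int), np.ones(n, int)
    bp, ip = sp.max(axis=1), sp.argmax(axis=1)
    bm, im = sm.max(axis=1), sm.argmax(axis=1)
    use_minus = bm > bp
    best = np.where(use_minus, bm, bp)
    pos = np.where(use_minus, im, ip)
    strand = np.where(use_minus, -1, 1)
    return best, pos, strand


# ---------------------------------------------------------------------------
# weighted PWM construction and trimming
# ---------------------------------------------------------------------------


def build_weighted_pwm(
    windows: Sequence[str],
    strengths: Sequence[float],
    distances: Sequence[float],
    background: np.ndarray,
    pseudocount: float = 0.375,
    frame_offset: int = 0,
) -> Pwm:
    """PWM from aligned equal-length windows.

    Each window is weighted by its event strength times the logistic distance
    weight w(d); non-ACGT characters contribute nothing to their column.
    """
    if len(windows) < 2:
        raise ValueError("need at least 2 matched sequences")
    width = len(windows[0])
    counts = np.zeros((width, 4))
    total_w = 0.0
    for seq, s, d in zip(windows, strengths, distances):
        wgt = float(s) * logistic_weight(d)
        total_w += wgt
        codes = encode(seq)
        for c in range(width):
            b = codes[c]
            if b < 4:
                counts[c, b] += wgt
    if total_w <= 0:
        raise ValueError("all sequence weights are zero")
    counts += pseudocount
    probs = counts / counts.sum(axis=1, keepdims=True)
    return Pwm(probs=probs, background=background, frame_offset=frame_offset)


def _sub_hit_counts(pwm: Pwm, codes: np.ndarray, subranges: list[tuple[int, int]]) -> np.ndarray:
    """Number of sequences with >= 1 match of each sub-PWM [a, b)."""
    w = pwm.width
    n, L = codes.shape
    lo5 = _lo5(pwm.log_odds)
    lo5_rc = _lo5(_rc_log_odds(pwm.log_odds))
    padded = np.full((n, L + 2 * w), 4, dtype=codes.dtype)
    padded[:, w : w + L] = codes

    # G[n, S, j] = column-j score when the full frame starts at s = S - w
    nS = L + w
    P = np.zeros((n, nS, w))
    Prc = np.zeros((n, nS, w))
    for j in range(w):
        P[:, :, j] = lo5[j][padded[:, j : j + nS]]
        Prc[:, :, j] = lo5_rc[j][padded[:, j : j + nS]]
    np.cumsum(P, axis=2, out=P)
    np.cumsum(Prc, axis=2, out=Prc)

    colmax = pwm.log_odds.max(axis=1)
    cmax = np.concatenate([[0.0], np.cumsum(colmax)])

    hits = np.zeros(len(subranges), dtype=np.int64)
    for idx, (a, b) in enumerate(subranges):
        thr = 0.6 * (cmax[b] - cmax[a])
        s_lo, s_hi = w - a, w + L - b  # valid frame index range, inclusive
        if s_hi < s_lo:
            continue
        sc = P[:, s_lo : s_hi + 1, b - 1]
        if a > 0:
            sc = sc - P[:, s_lo : s_hi + 1, a - 1]
        hit = (sc >= thr).any(axis=1)
        # minus strand: sub-range (a, b) of the forward PWM is sub-range
        # (w-b, w-a) of the reverse-complement PWM
        ra, rb = w - b, w - a
        s_lo2, s_hi2 = w - ra, w + L - rb
        sc2 = Prc[:, s_lo2 : s_hi2 + 1, rb - 1]
        if ra > 0:
            sc2 = sc2 - Prc[:, s_lo2 : s_hi2 + 1, ra - 1]
        hit |= (sc2 >= thr).any(axis=1)
        hits[idx] = int(hit.sum())
    return hits


def trim_pwm(
    pwm: Pwm,
    pos: Sequence[PosRecord] | Sequence[str],
    neg: Sequence[str],
    min_width: int = 5,
) -> Pwm:
    """Best-discriminating contiguous sub-PWM of width >= ``min_width``.

    All sub-ranges are scored by the hypergeometric p-value of their
    positive/negative 60%-threshold hit counts; ties prefer the widest, then
    the leftmost range."""
    pos_seqs = [r.seq if isinstance(r, PosRecord) else r for r in pos]
    pos_codes = np.stack([encode(s) for s in pos_seqs])
    neg_codes = np.stack([encode(s) for s in neg])
    w = pwm.width
    if w < min_width:
        raise ValueError(f"PWM width {w} < {min_width}")
    subranges = [(a, b) for a in range(w) for b in range(a + min_width, w + 1)]
    ph = _sub_hit_counts(pwm, pos_codes, subranges)
    nh = _sub_hit_counts(pwm, neg_codes, subranges)
    n_pos, n_neg = len(pos_seqs), len(neg_codes)
    pvals = _hyper_sf(ph, n_pos + n_neg, n_pos, ph + nh)
    order = sorted(
        range(len(subranges)),
        key=lambda i: (pvals[i], -(subranges[i][1] - subranges[i][0]), subranges[i][0]),
    )
    a, b = subranges[order[0]]
    out = pwm.sub(a, b)
    out.p_hyper = float(pvals[order[0]])
    return out


# ---------------------------------------------------------------------------
# equivalence-class growth
# ---------------------------------------------------------------------------


@dataclass
class _Match:
    oseq: str  # positive sequence, oriented into the class frame
    anchor: int  # seed start position within oseq
    strength: float
    center: int  # event position within oseq


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _member_matches(members: list[ClassMember], pos: Sequence[PosRecord]) -> list[_Match]:
    ordered = sorted(members, key=lambda m: (m.stat.p_hyper, -m.stat.fold, m.kmer))
    out: list[_Match] = []
    for rec in pos:
        L = len(rec.seq)
        found = None
        for m in ordered:
            for oriented, oseq, center in (
                (rec.seq, rec.seq, rec.center),
                (revcomp(rec.seq), revcomp(rec.seq), L - 1 - rec.center),
            ):
                j = oriented.find(m.kmer)
                if j >= 0:
                    found = _Match(oseq, j - m.seed_offset, rec.strength, center)
                    break
            if found:
                break
        if found:
            out.append(found)
    return out


def _pwm_matches(pwm: Pwm, pos: Sequence[PosRecord]) -> list[_Match]:
    codes = np.stack([encode(r.seq) for r in pos])
    best, ppos, strand = _best_hits(pwm.log_odds, codes)
    thr = pwm.threshold
    w = pwm.width
    out: list[_Match] = []
    for i, rec in enumerate(pos):
        if best[i] < thr:
            continue
        L = len(rec.seq)
        if strand[i] > 0:
            oseq, center, j = rec.seq, rec.center, int(ppos[i])
        else:
            oseq, center, j = revcomp(rec.seq), L - 1 - rec.center, L - w - int(ppos[i])
        out.append(_Match(oseq, j - pwm.frame_offset, rec.strength, center))
    return out


def _admit_members(
    members: list[ClassMember],
    pool: Sequence[KmerStat],
    matches: Sequence[_Match],
    k: int,
    min_frac: float = 1.0 / 3.0,
    min_count: int = 3,
) -> None:
    """Admit pool k-mers that occur with a consistent seed-frame offset in at
    least ``min_frac`` of their occurrences inside the 2k+1 bp windows around
    class matches (mutates ``members``).

    ``min_count`` consistent occurrences are additionally required: with only
    one or two occurrences the one-third consistency rule is satisfied
    trivially and admits spuriously aligned k-mers."""
    pad = (k + 1) // 2
    width = 2 * k + 1
    windows = []
    for m in matches:
        s = m.anchor - pad
        win = m.oseq[max(0, s) : s + width]
        if s < 0:
            win = "N" * (-s) + win
        win = win + "N" * (width - len(win))
        windows.append(win)
    have = {m.stat.kmer for m in members}
    for stat in pool:
        if stat.kmer in have:
            continue
        variants = [stat.kmer]
        rc = revcomp(stat.kmer)
        if rc != stat.kmer:
            variants.append(rc)
        best: tuple[int, int, str] | None = None  # (count, -offset rank, oriented)
        for oriented in variants:
            offs: dict[int, int] = {}
            total = 0
            for win in windows:
                start = 0
                while True:
                    j = win.find(oriented, start)
                    if j < 0:
                        break
                    offs[j - pad] = offs.get(j - pad, 0) + 1
                    total += 1
                    start = j + 1
            if not total:
                continue
            off_mode, cnt = min(offs.items(), key=lambda t: (-t[1], t[0]))
            if cnt >= min_count and cnt / total >= min_frac:
                if best is None or cnt > best[0]:
                    best = (cnt, off_mode, oriented)
        if best is not None:
            members.append(ClassMember(kmer=best[2], seed_offset=best[1], stat=stat))
            have.add(stat.kmer)


def _pwm_from_matches(
    matches: Sequence[_Match], members: list[ClassMember], k: int, background: np.ndarray
) -> Pwm | None:
    lo = min(m.seed_offset for m in members)
    hi = max(m.seed_offset + len(m.kmer) for m in members)
    windows, strengths, dists = [], [], []
    for m in matches:
        s, e = m.anchor + lo, m.anchor + hi
        win = m.oseq[max(0, s) : max(0, e)]
        if s < 0:
            win = "N" * (-s) + win
        win = win + "N" * ((hi - lo) - len(win))
        windows.append(win)
        strengths.append(m.strength)
        dists.append(abs(m.anchor + (k - 1) / 2.0 - m.center))
    if len(windows) < 2:
        return None
    return build_weighted_pwm(windows, strengths, dists, background, frame_offset=lo)


def grow_kmer_class(
    seed: KmerStat,
    pool: Sequence[KmerStat],
    pos: Sequence[PosRecord],
    neg: Sequence[str],
    max_rounds: int = 6,
) -> KmerClass:
    """Grow an equivalence class from the most enriched k-mer.

    The class starts with the seed and its Hamming-distance-1 neighbors,
    then alternates k-mer admission around class/PWM matches with weighted
    PWM re-construction and trimming, stopping when the PWM hypergeometric
    p-value stops improving."""
    k = seed.k
    members = [ClassMember(kmer=seed.kmer, seed_offset=0, stat=seed)]
    for stat in pool:
        if stat.kmer == seed.kmer or stat.k != k:
            continue
        if _hamming(stat.kmer, seed.kmer) == 1:
            members.append(ClassMember(kmer=stat.kmer, seed_offset=0, stat=stat))
        elif _hamming(revcomp(stat.kmer), seed.kmer) == 1:
            members.append(ClassMember(kmer=revcomp(stat.kmer), seed_offset=0, stat=stat))

    background = zero_order_background(neg)
    matches = _member_matches(members, pos)
    if not matches:
        return KmerClass(seed=seed, members=members, pwm=None, k=k)
    _admit_members(members, pool, matches, k)

    best_pwm: Pwm | None = None
    for _ in range(max_rounds):
        pwm = _pwm_from_matches(matches, members, k, background)
        if pwm is None:
            break
        pwm = trim_pwm(pwm, pos, neg)
        if best_pwm is not None and pwm.p_hyper >= best_pwm.p_hyper:
            break
        best_pwm = pwm
        matches = _pwm_matches(pwm, pos)
        if not matches:
            break
        _admit_members(members, pool, matches, k)
    return KmerClass(seed=seed, members=members, pwm=best_pwm, k=k)


# ---------------------------------------------------------------------------
# full discovery with k selection and secondary motifs
# ---------------------------------------------------------------------------


def _mask_pwm(seqs: list[str], pwm: Pwm) -> list[str]:
    out = []
    w = pwm.width
    for s in seqs:
        hits = scan_pwm(pwm, s)
        if not hits:
            out.append(s)
            continue
        chars = list(s)
        for j, _strand, _sc in hits:
            chars[j : j + w] = "N" * w
        out.append("".join(chars))
    return out


def discover_motifs(
    events: Sequence[BindingEvent],
    genome: GenomeAccessor,
    k_range: Iterable[int] = range(5, 14),
    max_motifs: int = 5,
    p_class: float = 1e-6,
    flank: int = 30,
    max_restarts: int = 3,
) -> list[KmerClass]:
    """Full motif discovery: k selection, primary class, secondary classes.

    For every k the enrichment + clustering pipeline runs and the k whose
    trimmed primary PWM is most significant wins.  Secondary motifs are found
    by removing the previous seed from the pool and masking PWM occurrences;
    when a secondary PWM out-significs the primary, discovery restarts seeded
    from it.  Returns classes ordered by significance (may be empty)."""
    if len(events) < 50:
        log.warning("only %d events; motif discovery may be unreliable", len(events))
    pos, neg = extract_sets(events, genome, flank=flank)
    if not pos or not neg:
        return []

    best: KmerClass | None = None
    best_k = None
    for k in k_range:
        try:
            pool = find_enriched_kmers(pos, neg, k)
        except ValueError:
            continue
        if not pool:
            continue
        cls = grow_kmer_class(pool[0], pool, pos, neg)
        if cls.pwm is None or cls.pwm.p_hyper >= p_class:
            continue
        if best is None or cls.pwm.p_hyper < best.pwm.p_hyper:
            best, best_k = cls, k
    if best is None:
        return []

    for _restart in range(max_restarts):
        motifs = [best]
        used_seeds = {best.seed.kmer}
        cur_pos = list(pos)
        cur_neg = list(neg)
        restart_seed: KmerStat | None = None
        while len(motifs) < max_motifs:
            prev = motifs[-1]
            masked = _mask_pwm([r.seq for r in cur_pos], prev.pwm)
            cur_pos = [replace(r, seq=s) for r, s in zip(cur_pos, masked)]
            cur_neg = _mask_pwm(cur_neg, prev.pwm)
            pool = [
                s
                for s in find_enriched_kmers(cur_pos, cur_neg, best_k)
                if s.kmer not in used_seeds
            ]
            if not pool:
                break
            cls = grow_kmer_class(pool[0], pool, cur_pos, cur_neg)
            if cls.pwm is None or cls.pwm.p_hyper >= p_class:
                break
            if cls.pwm.p_hyper < motifs[0].pwm.p_hyper:
                restart_seed = cls.seed
                break
            used_seeds.add(cls.seed.kmer)
            motifs.append(cls)
        if restart_seed is None:
            break
        # rebuild the primary from the stronger secondary seed on unmasked data
        pool = find_enriched_kmers(pos, neg, best_k)
        seed = next((s for s in pool if s.kmer == restart_seed.kmer), None)
        if seed is None:
            break
        rebuilt = grow_kmer_class(seed, pool, pos, neg)
        if rebuilt.pwm is None or rebuilt.pwm.p_hyper >= motifs[0].pwm.p_hyper:
            break
        best = rebuilt

    motifs.sort(key=lambda c: c.pwm.p_hyper)
    for i, c in enumerate(motifs, 1):
        c.pwm.name = f"motif_{i}_{c.pwm.consensus}"
    return motifs
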