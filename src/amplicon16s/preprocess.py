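"""Read QC and selection for long-read 16S amplicons.

Stages mirror a standard nanopore 16S workflow: mean-quality pass filter
(> Q7), primer-anchored adapter trimming, amplicon-size selection
(1300-1950 bp for V1-V9, 350-600 bp for V3-V4), DUST low-complexity
masking, host-read screening and seeded subsampling.

Mean read quality follows the error-probability convention used by
long-read QC tools: ``Q = -10*log10(mean_i 10^(-q_i/10))``, which equals
the arithmetic mean of the per-base scores only when they are all equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from .seqio import SequenceRecord, revcomp

__all__ = [
    "IUPAC_SETS",
    "PrimerSet",
    "PRIMERS_V1V9",
    "PRIMERS_V3V4",
    "PreprocessStats",
    "mean_qscore",
    "pass_filter",
    "trim_to_amplicon",
    "length_filter",
    "subsample",
    "mask_low_complexity",
    "screen_host",
]

#: IUPAC nucleotide ambiguity codes -> concrete base sets.
IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: edlib equality pairs letting degenerate primer symbols match their bases.
_IUPAC_EQUALITIES = [
    (code, base)
    for code, bases in IUPAC_SETS.items()
    if len(bases) > 1
    for base in bases
]


@dataclass(frozen=True)
class PrimerSet:
    """A degenerate primer pair with its expected amplicon length window."""

    name: str
    fwd: str
    rev: str
    length_window: tuple[int, int]

    def __post_init__(self):
        if not self.fwd or not self.rev:
            raise ValueError("primers must be non-empty")
        lo, hi = self.length_window
        if not lo < hi:
            raise ValueError("length window must satisfy min < max")


#: 27F-equivalent (with degeneracies) / 1492R pair spanning V1-V9.
PRIMERS_V1V9 = PrimerSet("V1-V9", "AGRGTTYGATYMTGGCTCAG", "CGGYTACCTTGTTACGACTT", (1300, 1950))
#: 341F / 806R pair spanning V3-V4.
PRIMERS_V3V4 = PrimerSet("V3-V4", "CCTACGGGNGGCWGCAG", "GGACTACHVGGGTWTCTAAT", (350, 600))


@dataclass
class PreprocessStats:
    """Per-stage read accounting mirroring a sequencing-stats table."""

    n_input: int = 0
    n_trimmed: int = 0
    n_filtered: int = 0
    avg_len_before: float = 0.0
    avg_len_after: float = 0.0
    mean_q: float = float("nan")
    retained_fraction: float = 0.0  # percent of input retained

    def __post_init__(self):
        if not (self.n_filtered <= self.n_trimmed <= self.n_input):
            raise ValueError("expected n_filtered <= n_trimmed <= n_input")


def mean_qscore(record: SequenceRecord) -> float:
    """Mean Phred quality via averaged error probabilities."""
    q = record.quals
    if record.qual is None or len(q) == 0:
        raise ValueError(f"record {record.id!r} has no quality data")
    p = np.power(10.0, -q / 10.0)
    return float(-10.0 * np.log10(p.mean()))


def pass_filter(
    records: Iterable[SequenceRecord], min_mean_q: float = 7.0
) -> list[SequenceRecord]:
    """Retain reads with mean quality strictly greater than ``min_mean_q``."""
    return [r for r in records if mean_qscore(r) > min_mean_q]


def _best_site(query: str, target: str, max_dist: int, last: bool = False):
    """Best semi-global (infix) match of an IUPAC query in target.

    Among equally good placements, takes the leftmost (or, with ``last``,
    the rightmost -- used for the reverse site so that end-to-end dimer
    reads keep their full length and die at size selection).
    Returns ``(start, end_exclusive, edit_distance)`` or ``None``.
    """
    res = edlib.align(
        query, target, mode="HW", task="locations", k=max_dist,
        additionalEqualities=_IUPAC_EQUALITIES,
    )
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][-1 if last else 0]
    return start, end + 1, res["editDistance"]


def _trim_oriented(seq: str, primers: PrimerSet, max_mismatches: int):
    """Locate fwd primer ... revcomp(rev primer) on the given orientation."""
    fwd = _best_site(primers.fwd, seq, max_mismatches)
    rev = _best_site(revcomp(primers.rev), seq, max_mismatches, last=True)
    if fwd is None or rev is None:
        return None
    f_start, f_end, f_dist = fwd
    r_start, r_end, r_dist = rev
    if r_end <= f_start or r_start < f_end:
        return None  # sites absent, overlapping, or in the wrong order
    return f_start, r_end, f_dist + r_dist


def trim_to_amplicon(
    record: SequenceRecord, primers: PrimerSet, max_mismatches: int = 3
) -> Optional[SequenceRecord]:
    """Trim a read to the span between its primer-binding sites.

    Both strands are searched; the orientation with the smaller combined
    primer edit distance wins, and reverse-strand reads are flipped to
    forward orientation. Primer sequences stay inside the retained span
    (they are part of the amplicon and of reference 16S genes). Returns
    ``None`` (untrimmable) when either site is missing -- e.g. truncated
    reads carrying only one primer-binding site.
    """
    plus = _trim_oriented(record.seq, primers, max_mismatches)
    rc_seq = revcomp(record.seq)
    minus = _trim_oriented(rc_seq, primers, max_mismatches)
    if plus is None and minus is None:
        return None
    use_minus = plus is None or (minus is not None and minus[2] < plus[2])
    if use_minus:
        start, end, _ = minus
        qual = record.qual[::-1][start:end] if record.qual is not None else None
        return SequenceRecord(record.id, rc_seq[start:end], qual)
    start, end, _ = plus
    qual = record.qual[start:end] if record.qual is not None else None
    return SequenceRecord(record.id, record.seq[start:end], qual)


def length_filter(
    records: Sequence[SequenceRecord],
    window: tuple[int, int],
) -> tuple[list[SequenceRecord], PreprocessStats]:
    """Retain reads whose length lies in ``[min_bp, max_bp]`` (inclusive).

    The window necessarily removes end-to-end amplicon dimers (~2x the
    amplicon size) and most truncated single-primer fragments.
    """
    lo, hi = window
    records = list(records)
    kept = [r for r in records if lo <= len(r) <= hi]
    with_q = [r for r in kept if r.qual is not None]
    stats = PreprocessStats(
        n_input=len(records),
        n_trimmed=len(records),
        n_filtered=len(kept),
        avg_len_before=float(np.mean([len(r) for r in records])) if records else 0.0,
        avg_len_after=float(np.mean([len(r) for r in kept])) if kept else 0.0,
        mean_q=float(np.mean([mean_qscore(r) for r in with_q])) if with_q else float("nan"),
        retained_fraction=100.0 * len(kept) / len(records) if records else 0.0,
    )
    return kept, stats


def subsample(
    records: Sequence[SequenceRecord], n: int, seed: int
) -> list[SequenceRecord]:
    """Uniform sampling of ``n`` records without replacement, seed-stable."""
    records = list(records)
    if n > len(records):
        raise ValueError(f"cannot subsample {n} from {len(records)} records")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(records))[:n]
    return [records[i] for i in idx]


def _dust_score(window: str) -> float:
    """Classic DUST triplet score of an (uppercase) window."""
    n_trip = len(window) - 2
    if n_trip < 2:
        return 0.0
    counts: dict[str, int] = {}
    for i in range(n_trip):
        t = window[i : i + 3]
        if "N" in t:
            continue
        counts[t] = counts.get(t, 0) + 1
    s = sum(c * (c - 1) // 2 for c in counts.values())
    return s / (n_trip - 1)


def mask_low_complexity(
    record: SequenceRecord, window: int = 64, threshold: float = 2.0
) -> SequenceRecord:
    """Lowercase simple-repeat regions using a DUST-style triplet score.

    Windows of ``window`` bp (half-window step) whose triplet score exceeds
    ``threshold`` are masked in place; length is unchanged and masked
    positions are later excluded from alignment seeding. Idempotent.
    """
    seq = record.seq.upper()
    n = len(seq)
    if n < 4:
        return SequenceRecord(record.id, record.seq, record.qual)
    mask = np.zeros(n, dtype=bool)
    step = max(window // 2, 1)
    starts = list(range(0, max(n - window, 0) + 1, step))
    if not starts or starts[-1] + window < n:
        starts.append(max(n - window, 0))
    for s in starts:
        e = min(s + window, n)
        if _dust_score(seq[s:e]) > threshold:
            mask[s:e] = True
    chars = np.array(list(seq))
    chars[mask] = np.char.lower(chars[mask])
    return SequenceRecord(record.id, "".join(chars), record.qual)


def screen_host(
    records: Sequence[SequenceRecord],
    host_reference: Sequence[SequenceRecord],
    min_score: int = 200,
    k: int = 13,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Partition reads into (host, non-host) by alignment against a host genome.

    A read is host-derived when its best local alignment score against the
    host reference reaches ``min_score`` (default: the score of a perfect
    100 bp match under the default scoring). The partition is exhaustive
    and disjoint; unmatched reads are regarded as bacterial.
    """
    from .classify import ReferenceDB, Scoring, align_read

    host_reference = list(host_reference)
    if not host_reference:
        raise ValueError("empty host reference")
    db = ReferenceDB.build(host_reference, mapping=None, taxonomy=None, k=k)
    scoring = Scoring(min_score=min_score)
    host: list[SequenceRecord] = []
    non_host: list[SequenceRecord] = []
    for rec in records:
        hits = align_read(rec, db, scoring)
        (host if hits else non_host).append(rec)
    return host, non_host
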