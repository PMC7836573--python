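"""Per-read taxonomic assignment by best alignment score with LCA tie-breaking.

Each read is aligned against a reference collection of 16S sequences by a
seed--chain--extend strategy: shared k-mers (default k=13) are collected per
reference and strand, clustered by diagonal, and promising candidates are
extended with a banded local alignment under an affine-gap scheme
(match +2, mismatch -4, gap open -4, gap extend -2; a gap of length L costs
open + L*extend).

The species achieving the exact maximum integer score is assigned to the
read. When several species tie, the read is assigned to the lowest common
ancestor of the tied set -- possibly far above genus when the tie spans
distant taxa. Strain-level references are rolled up to species before the
tie set is built, so two strains of one species never force an LCA above
species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from . import _kernels
from .preprocess import mask_low_complexity
from .seqio import SequenceRecord, read_fasta, revcomp
from .taxonomy import Taxonomy

__all__ = [
    "Scoring",
    "AlignmentHit",
    "ReadClassification",
    "ReferenceDB",
    "DatabaseError",
    "PafParseError",
    "build_reference_db",
    "align_read",
    "classify_read",
    "classify_batch",
    "write_paf",
    "ingest_paf",
    "SPECIES_LEVEL",
    "AMBIGUOUS_LCA",
    "UNCLASSIFIED",
]

SPECIES_LEVEL = "species_level"
AMBIGUOUS_LCA = "ambiguous_lca"
UNCLASSIFIED = "unclassified"
HOST = "host"
FILTERED = "filtered"

_POS_BITS = 39
_POS_MASK = (1 << _POS_BITS) - 1
_COMBO_SHIFT = np.int64(1) << 40
_DIAG_OFF = np.int64(1) << 39


class DatabaseError(ValueError):
    """Structural problem in the reference collection or its taxon mapping."""


class PafParseError(ValueError):
    """Malformed PAF input."""


@dataclass(frozen=True)
class Scoring:
    """Alignment and candidate-generation parameters.

    ``band_frac`` is the banded-extension band width as a fraction of read
    length (matched to nanopore indel rates); ``chain_prune`` discards
    candidate references whose seed-chain count falls below that fraction
    of the best candidate's, which cannot drop members of a genuine
    score tie (tied references share near-identical seed counts).
    """

    match: int = 2
    mismatch: int = -4
    gap_open: int = -4
    gap_extend: int = -2
    min_score: int = 100
    min_seed_count: int = 3
    band_frac: float = 0.15
    chain_prune: float = 0.5
    max_candidates: int = 10
    seed_stride: int = 1


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment of a read against a reference.

    Spans are 0-based half-open; ``ref_span`` is always on the forward
    reference coordinate system, with ``strand`` recording orientation.
    """

    read_id: str
    ref_id: str
    score: int
    identity: float
    read_span: tuple[int, int]
    ref_span: tuple[int, int]
    strand: str


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    taxon_id: Optional[str]
    assigned_rank: Optional[str]
    status: str
    best_score: Optional[int] = None


def _encode_with_mask(seq: str) -> np.ndarray:
    """Codes 0-3 for uppercase ACGT; 4 for masked (lowercase) or ambiguous."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _kernels.encode(seq)
    codes = codes.copy()
    codes[(raw >= 97)] = 4  # lowercase = masked
    return codes


def _kmer_positions(codes: np.ndarray, k: int, stride: int = 1):
    """Yield (kmer_int, start) for every window free of masked/ambiguous bases."""
    out = []
    kmer = 0
    run = 0
    mod = 4**k
    for i, c in enumerate(codes):
        if c > 3:
            run = 0
            kmer = 0
            continue
        kmer = (kmer * 4 + int(c)) % mod
        run += 1
        if run >= k:
            start = i - k + 1
            if start % stride == 0:
                out.append((kmer, start))
    return out


class ReferenceDB:
    """Reference sequences + taxon mapping + k-mer seed index (both strands)."""

    def __init__(self, entries, taxonomy: Optional[Taxonomy], k: int = 13):
        self.k = k
        self.taxonomy = taxonomy
        self.entries: list[tuple[str, SequenceRecord, Optional[str]]] = list(entries)
        seen = set()
        for ref_id, _rec, taxon_id in self.entries:
            if ref_id in seen:
                raise DatabaseError(f"duplicate ref_id {ref_id!r}")
            seen.add(ref_id)
            if taxonomy is not None:
                if taxon_id is None:
                    raise DatabaseError(f"reference {ref_id!r} has no taxon mapping")
                if taxon_id not in taxonomy:
                    raise DatabaseError(
                        f"reference {ref_id!r} maps to unknown taxon {taxon_id!r}"
                    )
        self._ref_index = {ref_id: i for i, (ref_id, _, _) in enumerate(self.entries)}
        self._codes: dict[tuple[int, int], np.ndarray] = {}
        self.index: dict[int, np.ndarray] = {}
        self._build_index()

    @classmethod
    def build(
        cls,
        records: Sequence[SequenceRecord],
        mapping: Optional[dict[str, str]],
        taxonomy: Optional[Taxonomy],
        k: int = 13,
    ) -> "ReferenceDB":
        """Build from in-memory records; references are DUST-masked first."""
        entries = []
        for rec in records:
            masked = mask_low_complexity(rec)
            if mapping is None:
                taxon: Optional[str] = None
            else:
                if rec.id not in mapping:
                    raise DatabaseError(f"reference {rec.id!r} missing from mapping")
                taxon = mapping[rec.id]
            entries.append((rec.id, masked, taxon))
        return cls(entries, taxonomy, k=k)

    def _build_index(self) -> None:
        acc: dict[int, list[int]] = {}
        for idx, (_ref_id, rec, _t) in enumerate(self.entries):
            if len(rec.seq) >= (1 << _POS_BITS):
                raise DatabaseError("reference sequence too long to index")
            for strand in (0, 1):
                seq = rec.seq if strand == 0 else revcomp(rec.seq)
                codes = _encode_with_mask(seq)
                self._codes[(idx, strand)] = _kernels.encode(seq)
                base = (idx << (_POS_BITS + 1)) | (strand << _POS_BITS)
                for kmer, pos in _kmer_positions(codes, self.k):
                    acc.setdefault(kmer, []).append(base | pos)
        self.index = {k: np.array(v, dtype=np.int64) for k, v in acc.items()}

    # -- accessors -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.entries)

    def ref_record(self, ref_id: str) -> SequenceRecord:
        return self.entries[self._ref_index[ref_id]][1]

    def taxon_of(self, ref_id: str) -> Optional[str]:
        return self.entries[self._ref_index[ref_id]][2]

    def has_ref(self, ref_id: str) -> bool:
        return ref_id in self._ref_index

    def oriented_codes(self, entry_idx: int, strand: int) -> np.ndarray:
        return self._codes[(entry_idx, strand)]


def build_reference_db(
    fasta, mapping_tsv, taxonomy: Taxonomy, k: int = 13
) -> ReferenceDB:
    """Load references from FASTA + 2-column (ref_id, taxon_id) mapping TSV."""
    records = list(read_fasta(fasta))
    mapping: dict[str, str] = {}
    with open(mapping_tsv) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if fields[:2] == ["ref_id", "taxon_id"]:
                continue  # optional header
            if len(fields) < 2:
                raise DatabaseError(f"mapping line {lineno}: expected 2 columns")
            mapping[fields[0]] = fields[1]
    return ReferenceDB.build(records, mapping, taxonomy, k=k)


# -- alignment -----------------------------------------------------------


def _chain_candidates(read_codes: np.ndarray, db: ReferenceDB, scoring: Scoring):
    """Diagonal-clustered seed counts per (reference, strand).

    Returns a list of ``(count, entry_idx, strand, diag_lo, diag_hi)``
    sorted by decreasing count, already thresholded and pruned.
    """
    kmers = _kmer_positions(read_codes, db.k, scoring.seed_stride)
    if not kmers:
        return []
    arrs = []
    rpos = []
    for kmer, pos in kmers:
        arr = db.index.get(kmer)
        if arr is not None:
            arrs.append(arr)
            rpos.append(np.full(len(arr), pos, dtype=np.int64))
    if not arrs:
        return []
    hits = np.concatenate(arrs)
    rpos = np.concatenate(rpos)
    tpos = hits & _POS_MASK
    key = hits >> _POS_BITS  # entry*2 + strand
    diag = tpos - rpos
    combo = key * _COMBO_SHIFT + (diag + _DIAG_OFF)
    combo.sort()
    n = len(combo)
    w_tol = max(20, len(read_codes) // 20)
    hi = np.searchsorted(combo, combo + w_tol, side="right")
    counts = hi - np.arange(n)
    keys = (combo // _COMBO_SHIFT).astype(np.int64)
    diags = (combo % _COMBO_SHIFT) - _DIAG_OFF
    boundaries = np.flatnonzero(np.diff(keys)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    cands = []
    for s, e in zip(starts, ends):
        seg = counts[s:e]
        i = int(np.argmax(seg)) + s
        count = int(counts[i])
        if count < scoring.min_seed_count:
            continue
        d_lo = int(diags[i])
        d_hi = int(diags[min(i + count - 1, n - 1)])
        k = int(keys[s])
        cands.append((count, k >> 1, k & 1, d_lo, d_hi))
    cands.sort(key=lambda c: (-c[0], c[1], c[2]))
    if not cands:
        return []
    best = cands[0][0]
    floor = max(scoring.min_seed_count, int(np.ceil(best * scoring.chain_prune)))
    cands = [c for c in cands if c[0] >= floor]
    return cands[: scoring.max_candidates]


def _span_identity(read_seq: str, target_seq: str) -> float:
    if not read_seq or not target_seq:
        return 0.0
    res = edlib.align(read_seq.upper(), target_seq.upper(), mode="NW", task="distance")
    d = res["editDistance"]
    longest = max(len(read_seq), len(target_seq))
    return max(0.0, 1.0 - d / longest)


def align_read(
    read: SequenceRecord, db: ReferenceDB, scoring: Scoring = Scoring()
) -> list[AlignmentHit]:
    """Seed, chain and band-extend a read against every candidate reference.

    Returns hits with score >= ``scoring.min_score`` sorted by decreasing
    score (ties by ref_id); deterministic for fixed inputs. Masked
    (lowercase) read positions are excluded from seeding but participate
    in extension.
    """
    if len(read.seq) == 0:
        raise ValueError("cannot align an empty read")
    read_codes = _encode_with_mask(read.seq)
    ext_codes = _kernels.encode(read.seq)
    pad = max(8, int(np.ceil(scoring.band_frac * len(read.seq) / 2)))
    hits: list[AlignmentHit] = []
    for _count, entry_idx, strand, d_lo, d_hi in _chain_candidates(
        read_codes, db, scoring
    ):
        target = db.oriented_codes(entry_idx, strand)
        score, qs, qe, ts, te = _kernels.banded_local_affine(
            ext_codes,
            target,
            d_lo - pad,
            d_hi + pad,
            scoring.match,
            scoring.mismatch,
            scoring.gap_open,
            scoring.gap_extend,
        )
        if score < scoring.min_score:
            continue
        ref_id, rec, _taxon = db.entries[entry_idx]
        if strand == 0:
            ref_span = (ts, te)
            t_seq = rec.seq[ts:te]
        else:
            L = len(rec.seq)
            ref_span = (L - te, L - ts)
            t_seq = revcomp(rec.seq)[ts:te]
        identity = _span_identity(read.seq[qs:qe], t_seq)
        hits.append(
            AlignmentHit(
                read_id=read.id,
                ref_id=ref_id,
                score=score,
                identity=identity,
                read_span=(qs, qe),
                ref_span=ref_span,
                strand="+" if strand == 0 else "-",
            )
        )
    hits.sort(key=lambda h: (-h.score, h.ref_id))
    return hits


# -- classification ------------------------------------------------------


def _species_taxon(taxon_id: str, taxonomy: Taxonomy) -> str:
    """Roll a reference taxon up to species; taxa at/above species stand."""
    sp = taxonomy.rollup(taxon_id, "species")
    return sp if sp is not None else taxon_id


def classify_read(
    hits: Sequence[AlignmentHit], db: ReferenceDB, taxonomy: Taxonomy
) -> ReadClassification:
    """Assign the best-scoring species, or the LCA of an exact score tie."""
    if not hits:
        return ReadClassification("", None, None, UNCLASSIFIED)
    read_ids = {h.read_id for h in hits}
    if len(read_ids) > 1:
        raise ValueError(f"hits span multiple reads: {sorted(read_ids)}")
    read_id = hits[0].read_id
    best = max(h.score for h in hits)
    tied = {
        _species_taxon(db.taxon_of(h.ref_id), taxonomy)
        for h in hits
        if h.score == best
    }
    if len(tied) == 1:
        taxon = next(iter(tied))
        rank = taxonomy.rank(taxon)
        status = SPECIES_LEVEL if rank == "species" else AMBIGUOUS_LCA
        return ReadClassification(read_id, taxon, rank, status, best)
    lca = taxonomy.lca(tied)
    return ReadClassification(read_id, lca, taxonomy.rank(lca), AMBIGUOUS_LCA, best)


def classify_batch(
    records: Iterable[SequenceRecord],
    db: ReferenceDB,
    taxonomy: Taxonomy,
    scoring: Scoring = Scoring(),
) -> tuple[list[ReadClassification], dict[str, int]]:
    """Classify every read; returns per-read outcomes + per-status counts."""
    out: list[ReadClassification] = []
    summary: dict[str, int] = {}
    for rec in records:
        hits = align_read(rec, db, scoring)
        cls = classify_read(hits, db, taxonomy)
        if not hits:
            cls = ReadClassification(rec.id, None, None, UNCLASSIFIED)
        out.append(cls)
        summary[cls.status] = summary.get(cls.status, 0) + 1
    return out, summary


def write_classifications(
    classifications: Iterable[ReadClassification], path, header_comment: str = ""
) -> int:
    """Write per-read outcomes as TSV: read_id, taxon_id, rank, status, score."""
    n = 0
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("read_id\ttaxon_id\trank\tstatus\tbest_score\n")
        for c in classifications:
            fh.write(
                f"{c.read_id}\t{c.taxon_id or ''}\t{c.assigned_rank or ''}"
                f"\t{c.status}\t{'' if c.best_score is None else c.best_score}\n"
            )
            n += 1
    return n


def read_classifications(path) -> list[ReadClassification]:
    out: list[ReadClassification] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("read_id\t"):
                continue
            f = line.split("\t")
            out.append(
                ReadClassification(
                    f[0],
                    f[1] or None,
                    f[2] or None,
                    f[3],
                    int(f[4]) if len(f) > 4 and f[4] else None,
                )
            )
    return out


# -- PAF interchange -----------------------------------------------------


def write_paf(
    hits: Iterable[AlignmentHit],
    read_lengths: dict[str, int],
    db: ReferenceDB,
    path,
) -> int:
    """Export hits as PAF (12 mandatory columns + AS:i score tag)."""
    n = 0
    with open(path, "w") as fh:
        for h in hits:
            qs, qe = h.read_span
            ts, te = h.ref_span
            block = max(qe - qs, te - ts)
            matches = int(round(h.identity * block))
            tlen = len(db.ref_record(h.ref_id).seq)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.read_id,
                        read_lengths[h.read_id],
                        qs,
                        qe,
                        h.strand,
                        h.ref_id,
                        tlen,
                        ts,
                        te,
                        matches,
                        block,
                        255,
                        f"AS:i:{h.score}",
                    )
                )
                + "\n"
            )
            n += 1
    return n


def ingest_paf(path, db: ReferenceDB) -> list[AlignmentHit]:
    """Read alignments produced by an external long-read mapper.

    The ``AS:i`` alignment-score tag is used as the hit score when present,
    else the matching-bases count (column 10). Hits naming references
    absent from the database are skipped with a warning.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise PafParseError(f"PAF line {lineno}: fewer than 12 columns")
            try:
                qs, qe = int(f[2]), int(f[3])
                ts, te = int(f[7]), int(f[8])
                matches, block = int(f[9]), int(f[10])
            except ValueError as exc:
                raise PafParseError(f"PAF line {lineno}: {exc}") from exc
            if f[4] not in "+-":
                raise PafParseError(f"PAF line {lineno}: bad strand {f[4]!r}")
            if not db.has_ref(f[5]):
                warnings.warn(
                    f"PAF line {lineno}: unknown reference {f[5]!r}, skipped"
                )
                continue
            score = matches
            for tag in f[12:]:
                if tag.startswith("AS:i:"):
                    score = int(tag[5:])
                    break
            identity = matches / block if block else 0.0
            hits.append(
                AlignmentHit(f[0], f[5], score, identity, (qs, qe), (ts, te), f[4])
            )
    return hits
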