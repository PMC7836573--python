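"""Synthetic 16S amplicon communities with known per-read truth.

This module makes every pipeline stage testable without sequencing data.
It builds 16S-like reference sets (a random ancestor evolved along a
genus/species tree with conserved primer-binding blocks implanted at both
ends), models degenerate-primer PCR bias, and emits error-bearing long
reads with nanopore-like substitution/indel rates, plus the artifact
classes seen in real runs: truncated fragments carrying a single
primer-binding site and end-to-end amplicon dimers.

PCR bias model
--------------
A community member amplifies with per-cycle efficiency
``E = E0 * m**w`` where ``w`` counts primer-site mismatches, weighting
mismatches in the 3'-terminal 5 primer bases by ``t`` (polymerase
extension is most sensitive there). After ``n`` cycles the member's
template weight is ``fraction * (1 + E)**n``, renormalized over the
community. With perfectly matched primers this reduces to the true
composition; more mismatches can only shrink a member's share (the
mechanism behind primer-dependent underrepresentation of taxa such as
*Bifidobacterium*).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .preprocess import IUPAC_SETS, PrimerSet, PRIMERS_V1V9
from .seqio import SequenceRecord, revcomp
from .taxonomy import Taxonomy, TaxonomyNode

__all__ = [
    "Community",
    "PcrModel",
    "ErrorModel",
    "NANOPORE_R9",
    "NOISELESS",
    "ArtifactRates",
    "SimTruth",
    "ReferenceSet",
    "make_reference_set",
    "make_even_community",
    "make_fecal_like_community",
    "count_primer_mismatches",
    "primer_mismatch_positions",
    "amplify",
    "simulate_reads",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Community:
    """True composition: ``(taxon_id, ref_id, fraction)`` per member."""

    members: tuple[tuple[str, str, float], ...]

    def __post_init__(self):
        total = sum(f for _, _, f in self.members)
        if self.members and abs(total - 1.0) > 1e-9:
            raise ValueError(f"member fractions sum to {total}, expected 1")

    @property
    def fractions(self) -> dict[str, float]:
        return {taxon: f for taxon, _ref, f in self.members}


@dataclass(frozen=True)
class PcrModel:
    """Per-cycle efficiency model for primer-mismatch amplification bias."""

    base_efficiency: float = 0.9
    per_mismatch_penalty: float = 0.5
    three_prime_multiplier: float = 3.0
    n_cycles: int = 35
    three_prime_window: int = 5

    def __post_init__(self):
        if not 0 < self.base_efficiency <= 1:
            raise ValueError("base_efficiency must be in (0, 1]")
        if not 0 < self.per_mismatch_penalty < 1:
            raise ValueError("per_mismatch_penalty must be in (0, 1)")
        if self.three_prime_multiplier < 1:
            raise ValueError("three_prime_multiplier must be >= 1")


@dataclass(frozen=True)
class ErrorModel:
    """Per-base substitution/indel rates and the target mean read quality."""

    sub_rate: float
    ins_rate: float
    del_rate: float
    target_mean_q: float = 9.0

    def __post_init__(self):
        rates = (self.sub_rate, self.ins_rate, self.del_rate)
        if any(r < 0 for r in rates) or sum(rates) >= 1:
            raise ValueError("rates must be >= 0 and sum to < 1")


#: Nanopore R9.4-like profile: ~12% total error, reads around Q9.
NANOPORE_R9 = ErrorModel(sub_rate=0.06, ins_rate=0.03, del_rate=0.03, target_mean_q=9.0)
#: Error-free reads (noiseless limit).
NOISELESS = ErrorModel(sub_rate=0.0, ins_rate=0.0, del_rate=0.0, target_mean_q=30.0)


@dataclass(frozen=True)
class ArtifactRates:
    """Read-artifact probabilities: single-primer truncations and dimers."""

    truncated: float = 0.0
    dimer: float = 0.0

    def __post_init__(self):
        if self.truncated < 0 or self.dimer < 0 or self.truncated + self.dimer > 0.5:
            raise ValueError("artifact rates must be >= 0 and sum to <= 0.5")


@dataclass
class SimTruth:
    """Ground truth: per read (true species, artifact class) + community."""

    per_read: dict[str, tuple[str, str]]
    community: Community


@dataclass
class ReferenceSet:
    """Simulated reference collection with matching taxonomy.

    ``species`` maps each species taxon_id to its ref_id; ``genus_of``
    maps species taxon_id to genus taxon_id.
    """

    records: list[SequenceRecord]
    mapping: dict[str, str]  # ref_id -> taxon_id
    taxonomy: Taxonomy
    primers: PrimerSet
    species: dict[str, str] = field(default_factory=dict)  # taxon_id -> ref_id

    def write(self, fasta_path, mapping_path, taxonomy_path) -> None:
        from .seqio import write_fasta

        write_fasta(self.records, fasta_path)
        with open(mapping_path, "w") as fh:
            fh.write("ref_id\ttaxon_id\n")
            for ref_id, taxon in self.mapping.items():
                fh.write(f"{ref_id}\t{taxon}\n")
        with open(taxonomy_path, "w") as fh:
            fh.write("taxon_id\tparent_id\trank\tname\n")
            for node in self.taxonomy.nodes.values():
                fh.write(f"{node.taxon_id}\t{node.parent_id}\t{node.rank}\t{node.name}\n")

    def to_reference_db(self, k: int = 13):
        from .classify import ReferenceDB

        return ReferenceDB.build(self.records, self.mapping, self.taxonomy, k=k)


# -- primer arithmetic ---------------------------------------------------


def _expand_concrete(primer: str, rng: np.random.Generator) -> str:
    """One concrete expansion of a degenerate primer (random choice per code)."""
    return "".join(
        IUPAC_SETS[c][rng.integers(len(IUPAC_SETS[c]))] for c in primer.upper()
    )


def primer_mismatch_positions(primer_iupac: str, site_sequence: str) -> list[int]:
    """Primer positions where the site base falls outside the IUPAC set."""
    if len(primer_iupac) != len(site_sequence):
        raise ValueError(
            f"primer length {len(primer_iupac)} != site length {len(site_sequence)}"
        )
    out = []
    for i, (p, s) in enumerate(zip(primer_iupac.upper(), site_sequence.upper())):
        if s not in IUPAC_SETS.get(p, ""):
            out.append(i)
    return out


def count_primer_mismatches(primer_iupac: str, site_sequence: str) -> int:
    """Number of site positions incompatible with the degenerate primer."""
    return len(primer_mismatch_positions(primer_iupac, site_sequence))


def _locate_site(seq: str, primer: str) -> tuple[int, int]:
    """Best gapless primer placement in ``seq``: (start, mismatches)."""
    L = len(primer)
    best_start, best_mm = -1, L + 1
    for s in range(0, len(seq) - L + 1):
        mm = count_primer_mismatches(primer, seq[s : s + L])
        if mm < best_mm:
            best_start, best_mm = s, mm
    return best_start, best_mm


# -- reference-set construction ------------------------------------------


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position with probability ``rate`` (never to itself)."""
    if rate <= 0:
        return seq.copy()
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    shift = rng.integers(1, 4, size=int(hit.sum()))
    out[hit] = (out[hit] + shift) % 4
    return out


_CODE2BYTE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _CODE2BYTE[codes.astype(np.int64)].tobytes().decode("ascii")


def _mismatch_site(site: str, primer: str, n_mm: int, rng: np.random.Generator) -> str:
    """Introduce ``n_mm`` genuine mismatches into a primer-binding site."""
    site = list(site)
    pos = rng.permutation(len(site))[:n_mm]
    for p in pos:
        allowed = IUPAC_SETS[primer[p].upper()]
        bad = [b for b in "ACGT" if b not in allowed]
        site[p] = bad[rng.integers(len(bad))] if bad else site[p]
    return "".join(site)


def make_reference_set(
    n_species: int,
    seed: int,
    divergence: float = 0.04,
    genus_sizes: Optional[Sequence[int]] = None,
    genus_divergence: float = 0.12,
    pair_divergence: Optional[dict[int, float]] = None,
    primers: PrimerSet = PRIMERS_V1V9,
    interior_len: int = 1400,
    primer_site_mismatches: Optional[dict[int, tuple[int, int]]] = None,
    n_phyla: int = 2,
) -> ReferenceSet:
    """Generate ~1.5 kb 16S-like references and a matching taxonomy.

    Species interiors descend from genus ancestors, which descend from a
    single random root; primer-binding blocks are implanted verbatim at
    both ends (unless ``primer_site_mismatches`` assigns a species index a
    ``(fwd, rev)`` mismatch count, emulating primer-incompatible taxa).
    ``genus_sizes`` defaults to two genera of two species plus singletons.
    ``pair_divergence`` overrides within-genus divergence per genus index
    (for building confusable sister species). Genera are spread round-robin
    over ``n_phyla`` phylum/class/order/family chains.

    Expected pairwise divergence is ~``divergence`` within a genus and
    ~``genus_divergence`` (plus the within-genus part) between genera.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if not 0 < divergence < 0.3:
        raise ValueError("divergence must be in (0, 0.3)")
    rng = np.random.default_rng(seed)
    if genus_sizes is None:
        if n_species >= 6:
            genus_sizes = [2, 2] + [1] * (n_species - 4)
        else:
            genus_sizes = [1] * n_species
    if sum(genus_sizes) != n_species:
        raise ValueError("genus_sizes must sum to n_species")

    fwd_site = _expand_concrete(primers.fwd, rng)
    rev_site_rc = revcomp(_expand_concrete(primers.rev, rng))
    root_interior = rng.integers(0, 4, size=interior_len).astype(np.int8)

    # taxonomy scaffold: root > domain > n_phyla x (phylum>class>order>family)
    nodes: dict[str, TaxonomyNode] = {
        "1": TaxonomyNode("1", "1", "root", "root"),
        "2": TaxonomyNode("2", "1", "domain", "Bacteria"),
    }
    family_ids = []
    nid = 10
    for p in range(n_phyla):
        chain = [("phylum", f"Phylum{p+1}"), ("class", f"Class{p+1}"),
                 ("order", f"Order{p+1}"), ("family", f"Family{p+1}")]
        parent = "2"
        for rank, name in chain:
            tid = str(nid)
            nid += 1
            nodes[tid] = TaxonomyNode(tid, parent, rank, name)
            parent = tid
        family_ids.append(parent)

    records: list[SequenceRecord] = []
    mapping: dict[str, str] = {}
    species_map: dict[str, str] = {}
    sp_idx = 0
    for gi, size in enumerate(genus_sizes):
        genus_tid = str(1000 + gi)
        genus_name = f"Genus{gi+1:02d}"
        nodes[genus_tid] = TaxonomyNode(
            genus_tid, family_ids[gi % n_phyla], "genus", genus_name
        )
        within = divergence
        if pair_divergence and gi in pair_divergence:
            within = pair_divergence[gi]
        genus_anc = _mutate(root_interior, genus_divergence / 2, rng)
        for si in range(size):
            sp_tid = str(10000 + sp_idx)
            sp_name = f"{genus_name} species{si+1}"
            nodes[sp_tid] = TaxonomyNode(sp_tid, genus_tid, "species", sp_name)
            interior = _mutate(genus_anc, within / 2, rng)
            f_site, r_site = fwd_site, rev_site_rc
            if primer_site_mismatches and sp_idx in primer_site_mismatches:
                n_f, n_r = primer_site_mismatches[sp_idx]
                if n_f:
                    f_site = _mismatch_site(fwd_site, primers.fwd, n_f, rng)
                if n_r:
                    # site is the revcomp of the primer: mutate on primer axis
                    site = revcomp(r_site)
                    site = _mismatch_site(site, primers.rev, n_r, rng)
                    r_site = revcomp(site)
            seq = f_site + _codes_to_str(interior) + r_site
            ref_id = f"ref_{sp_idx:03d}"
            records.append(SequenceRecord(ref_id, seq))
            mapping[ref_id] = sp_tid
            species_map[sp_tid] = ref_id
            sp_idx += 1

    taxonomy = Taxonomy(nodes)
    return ReferenceSet(records, mapping, taxonomy, primers, species_map)


# -- communities ---------------------------------------------------------


def make_even_community(
    refset: ReferenceSet, species_ids: Optional[Sequence[str]] = None
) -> Community:
    """Even mixture over the given species (default: all in the set)."""
    ids = list(species_ids) if species_ids is not None else sorted(refset.species)
    f = 1.0 / len(ids)
    members = tuple((t, refset.species[t], f) for t in ids)
    # renormalize exactly against float rounding
    total = sum(m[2] for m in members)
    members = tuple((t, r, x / total) for t, r, x in members)
    return Community(members)


def make_fecal_like_community(
    refset: ReferenceSet,
    seed: int,
    sigma: float = 1.5,
    dominant_genera: Optional[int] = None,
    dominance_boost: float = 5.0,
) -> Community:
    """Skewed community mimicking gut microbiota rank-abundance structure.

    Species abundances are drawn i.i.d. LogNormal(0, sigma) and normalized;
    optionally, members of ``dominant_genera`` randomly chosen genera are
    boosted so a few genera dominate the profile (the structure seen in
    top-15 genus heat maps of fecal samples).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    ids = sorted(refset.species)
    if len(ids) < 10:
        raise ValueError("fecal-like community needs >= 10 species")
    rng = np.random.default_rng(seed)
    x = rng.lognormal(mean=0.0, sigma=sigma, size=len(ids))
    if dominant_genera:
        genera = sorted({refset.taxonomy.rollup(t, "genus") for t in ids})
        chosen = set(
            np.array(genera)[rng.permutation(len(genera))[:dominant_genera]]
        )
        for i, t in enumerate(ids):
            if refset.taxonomy.rollup(t, "genus") in chosen:
                x[i] *= dominance_boost
    x /= x.sum()
    members = tuple(
        (t, refset.species[t], float(f)) for t, f in zip(ids, x)
    )
    return Community(members)


# -- benchmark study designs ---------------------------------------------


def benchmark_mock_design(
    seed: int,
) -> tuple[ReferenceSet, Community, list[str]]:
    """Even ten-member mock with confuser pairs in the reference set.

    Mirrors the structure of a ten-strain even mock community: ten
    community species in ten distinct genera, classified against a
    reference set that additionally contains one near-identical sister
    species (~1.5% divergence) for two of the genera -- the situation in
    which even full-length 16S reads cannot reliably separate species
    (e.g. *Bacillus cereus* vs *B. anthracis*, *Escherichia* vs
    *Shigella*). All other genera are well separated (~4% within,
    ~12% between genera).

    Returns ``(refset, community, designated_genera)`` where
    ``designated_genera`` are the seven well-separated genera (sorted by
    name) over which per-genus species accuracy is scored.
    """
    refset = make_reference_set(
        12,
        seed=seed,
        divergence=0.04,
        genus_sizes=[2, 2] + [1] * 8,
        pair_divergence={0: 0.015, 1: 0.015},
    )
    tax = refset.taxonomy
    by_genus: dict[str, list[str]] = {}
    for sp in sorted(refset.species):
        by_genus.setdefault(tax.rollup(sp, "genus"), []).append(sp)
    members = [
        sorted(v)[0]
        for _g, v in sorted(by_genus.items(), key=lambda kv: tax.name(kv[0]))
    ]
    community = make_even_community(refset, members)
    clean = sorted(
        (g for g, v in by_genus.items() if len(v) == 1), key=tax.name
    )
    return refset, community, clean[:7]


def benchmark_fecal_design(seed: int) -> tuple[ReferenceSet, Community]:
    """150-species fecal-like community (lognormal sigma=1.5).

    Genus sizes are drawn uniformly in 1..6, giving the mixture of
    species-rich and singleton genera seen in gut profiles.
    """
    rng = np.random.default_rng(seed)
    sizes: list[int] = []
    n = 0
    while n < 150:
        s = min(int(rng.integers(1, 7)), 150 - n)
        sizes.append(s)
        n += s
    refset = make_reference_set(
        150, seed=seed + 1, divergence=0.04, genus_sizes=sizes
    )
    community = make_fecal_like_community(refset, seed=seed + 2, sigma=1.5)
    return refset, community


# -- PCR bias ------------------------------------------------------------


def _site_weight(
    primer: str, site: str, pcr: PcrModel
) -> float:
    """Weighted mismatch count w for one primer site (3'-terminal weighting)."""
    w = 0.0
    L = len(primer)
    for pos in primer_mismatch_positions(primer, site):
        if pos >= L - pcr.three_prime_window:
            w += pcr.three_prime_multiplier
        else:
            w += 1.0
    return w


def amplify(
    community: Community,
    primers: PrimerSet,
    pcr: PcrModel,
    refset: ReferenceSet,
    max_site_mismatches: int = 8,
) -> dict[str, float]:
    """Template-pool fractions after PCR with primer-mismatch bias.

    Returns ``ref_id -> fraction``. Raises if a member's primer-binding
    site cannot be located (more than ``max_site_mismatches`` mismatches
    at the best gapless placement).
    """
    weights: dict[str, float] = {}
    refs = {r.id: r for r in refset.records}
    for taxon, ref_id, fraction in community.members:
        seq = refs[ref_id].seq.upper()
        f_start, f_mm = _locate_site(seq, primers.fwd)
        r_start, r_mm = _locate_site(revcomp(seq), primers.rev)
        if f_start < 0 or f_mm > max_site_mismatches:
            raise ValueError(f"forward primer site not found in {ref_id}")
        if r_start < 0 or r_mm > max_site_mismatches:
            raise ValueError(f"reverse primer site not found in {ref_id}")
        w = _site_weight(primers.fwd, seq[f_start : f_start + len(primers.fwd)], pcr)
        rc = revcomp(seq)
        w += _site_weight(primers.rev, rc[r_start : r_start + len(primers.rev)], pcr)
        eff = pcr.base_efficiency * pcr.per_mismatch_penalty**w
        weights[ref_id] = fraction * (1.0 + eff) ** pcr.n_cycles
    total = sum(weights.values())
    return {r: w / total for r, w in weights.items()}


# -- read generation -----------------------------------------------------


def _apply_errors(
    codes: np.ndarray, model: ErrorModel, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized per-base substitution / insertion / deletion."""
    n = len(codes)
    keep = rng.random(n) >= model.del_rate
    sub = (rng.random(n) < model.sub_rate) & keep
    ins = rng.random(n) < model.ins_rate
    bases = codes.copy()
    if sub.any():
        bases[sub] = (bases[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4
    reps = keep.astype(np.int64) + ins.astype(np.int64)
    total = int(reps.sum())
    out = np.zeros(total, dtype=np.int8)
    ends = np.cumsum(reps)
    base_pos = ends - reps
    out[base_pos[keep]] = bases[keep]
    if ins.any():
        out[ends[ins] - 1] = rng.integers(0, 4, size=int(ins.sum()))
    return out


def simulate_reads(
    pool: dict[str, float],
    refset: ReferenceSet,
    error_model: ErrorModel,
    n_reads: int,
    seed: int,
    artifact_rates: ArtifactRates = ArtifactRates(),
) -> tuple[list[SequenceRecord], SimTruth]:
    """Draw error-bearing reads from a template pool with known truth.

    Templates are drawn multinomially by pool weight; each read gets
    substitutions/indels at the model's per-base rates, a random strand,
    and a Phred string drawn uniformly in ``target_mean_q +- 3``. With the
    stated probabilities a read is instead a truncated fragment (random
    cut keeping one primer-binding site) or a head-to-tail dimer of two
    independently drawn amplicons. Dimer truth records the first template.
    Fully reproducible from the seed.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    ref_ids = sorted(pool)
    probs = np.array([pool[r] for r in ref_ids])
    probs = probs / probs.sum()
    refs = {r.id: r for r in refset.records}
    ref_codes = {
        r: np.frombuffer(refs[r].seq.upper().encode(), dtype=np.uint8)
        for r in ref_ids
    }
    code_map = np.full(256, 0, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        code_map[ord(b)] = i
    ref_codes = {r: code_map[a] for r, a in ref_codes.items()}
    taxon_of = {r: refset.mapping[r] for r in ref_ids}

    choices = rng.choice(len(ref_ids), size=n_reads, p=probs)
    art_u = rng.random(n_reads)
    records: list[SequenceRecord] = []
    per_read: dict[str, tuple[str, str]] = {}
    qlo = max(0, int(round(error_model.target_mean_q)) - 3)
    qhi = int(round(error_model.target_mean_q)) + 3
    for i in range(n_reads):
        ref_id = ref_ids[choices[i]]
        template = ref_codes[ref_id]
        artifact = "none"
        if art_u[i] < artifact_rates.truncated:
            artifact = "truncated"
            cut = int(rng.integers(60, max(len(template) - 60, 61)))
            template = template[:cut] if rng.random() < 0.5 else template[-cut:]
        elif art_u[i] < artifact_rates.truncated + artifact_rates.dimer:
            artifact = "dimer"
            other = ref_codes[ref_ids[int(rng.integers(len(ref_ids)))]]
            template = np.concatenate([template, other])
        codes = _apply_errors(template, error_model, rng)
        seq = _codes_to_str(codes)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        quals = rng.integers(qlo, qhi + 1, size=len(seq))
        qual = (quals.astype(np.uint8) + 33).tobytes().decode("ascii")
        read_id = f"read_{i:06d}"
        records.append(SequenceRecord(read_id, seq, qual))
        per_read[read_id] = (taxon_of[ref_id], artifact)
    truth_members = tuple(
        (taxon_of[r], r, float(p)) for r, p in zip(ref_ids, probs)
    )
    return records, SimTruth(per_read, Community(truth_members))
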