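"""Abundance profiles and evaluation statistics.

Turns per-read classifications into rank-level relative-abundance tables
(with the standard <0.01% low-abundance filter), scores classifications
against a known mock community (correct / misclassified / unclassified at
a rank, plus per-genus species accuracy), measures the fraction of
ambiguous reads stuck above species level, and computes the sampling-depth
diagnostics used for community profiling: species-accumulation curves and
the Pearson correlation of abundance vectors between subsampling depths,
as well as cross-method profile comparison over the union of top-N taxa.

Relative abundances are always percentages of *classified* reads
(host/filtered/unclassified reads are excluded before profiling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import AMBIGUOUS_LCA, SPECIES_LEVEL, ReadClassification
from .simulate import SimTruth
from .taxonomy import CANONICAL_RANKS, Taxonomy

__all__ = [
    "AbundanceProfile",
    "EvalReport",
    "build_profile",
    "filter_low_abundance",
    "conditional_species_profile",
    "score_mock",
    "ambiguous_fraction",
    "accumulation_curve",
    "depth_correlation",
    "compare_methods",
]

_CLASSIFIED = (SPECIES_LEVEL, AMBIGUOUS_LCA)


@dataclass
class AbundanceProfile:
    """Taxon read counts and relative abundances (%) at one rank.

    ``unassigned_count`` holds classified reads whose assignment sits above
    the profile rank (e.g. genus-level LCA reads in a species profile).
    Percentages are relative to ``total_classified``; before filtering,
    entry percentages plus the unassigned fraction sum to 100.
    """

    rank: str
    counts: dict[str, int]
    total_classified: int
    unassigned_count: int = 0
    filtered: bool = False

    def percent(self, taxon_id: str) -> float:
        if self.total_classified == 0:
            return 0.0
        return 100.0 * self.counts.get(taxon_id, 0) / self.total_classified

    @property
    def percentages(self) -> dict[str, float]:
        return {t: self.percent(t) for t in self.counts}

    def to_frame(self, taxonomy: Optional[Taxonomy] = None) -> pd.DataFrame:
        rows = [
            {
                "taxon_id": t,
                "name": taxonomy.name(t) if taxonomy else t,
                "read_count": c,
                "relative_abundance_pct": self.percent(t),
            }
            for t, c in sorted(
                self.counts.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ]
        return pd.DataFrame(
            rows,
            columns=["taxon_id", "name", "read_count", "relative_abundance_pct"],
        )


@dataclass
class EvalReport:
    """Mock-community scoring at one rank (percentages sum to 100)."""

    rank: str
    correct_pct: float
    misclassified_pct: float
    unclassified_pct: float
    n_reads: int
    per_genus_species_accuracy: dict[str, float] = field(default_factory=dict)


def build_profile(
    classifications: Sequence[ReadClassification],
    taxonomy: Taxonomy,
    rank: str,
) -> AbundanceProfile:
    """Tally classified reads at ``rank`` via taxonomic rollup.

    Reads assigned above the requested rank (or whose lineage skips it)
    land in the unassigned-at-rank bucket.
    """
    if rank not in CANONICAL_RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    counts: dict[str, int] = {}
    unassigned = 0
    total = 0
    for c in classifications:
        if c.status not in _CLASSIFIED or c.taxon_id is None:
            continue
        total += 1
        t = taxonomy.rollup(c.taxon_id, rank)
        if t is None:
            unassigned += 1
        else:
            counts[t] = counts.get(t, 0) + 1
    return AbundanceProfile(rank, counts, total, unassigned)


def filter_low_abundance(
    profile: AbundanceProfile, threshold_pct: float = 0.01
) -> AbundanceProfile:
    """Discard taxa with relative abundance strictly below ``threshold_pct``."""
    if threshold_pct < 0:
        raise ValueError("threshold must be >= 0")
    kept = {
        t: c for t, c in profile.counts.items()
        if profile.percent(t) >= threshold_pct
    }
    return AbundanceProfile(
        profile.rank, kept, profile.total_classified,
        profile.unassigned_count, filtered=True,
    )


def conditional_species_profile(
    classifications: Sequence[ReadClassification],
    taxonomy: Taxonomy,
    genus_id: str,
) -> AbundanceProfile:
    """Species composition within one genus.

    Restricted to classified reads whose genus rollup equals ``genus_id``;
    percentages are within that subset. Reads resolved only to the genus
    itself (within-genus LCA ties) form the unassigned remainder bucket.
    """
    if taxonomy.rank(genus_id) != "genus":
        raise ValueError(f"{genus_id!r} is not a genus")
    counts: dict[str, int] = {}
    remainder = 0
    total = 0
    for c in classifications:
        if c.status not in _CLASSIFIED or c.taxon_id is None:
            continue
        if taxonomy.rollup(c.taxon_id, "genus") != genus_id:
            continue
        total += 1
        sp = taxonomy.rollup(c.taxon_id, "species")
        if sp is None:
            remainder += 1
        else:
            counts[sp] = counts.get(sp, 0) + 1
    return AbundanceProfile("species", counts, total, remainder)


def score_mock(
    classifications: Sequence[ReadClassification],
    truth: SimTruth,
    taxonomy: Taxonomy,
    rank: str,
) -> EvalReport:
    """Score classifications against mock-community truth at one rank.

    Per read: *correct* when the rollup at ``rank`` matches the read's true
    taxon at that rank; *unclassified* when the read carries no taxon at
    that rank (assigned only higher up); *misclassified* otherwise.
    Per-genus species accuracy: among reads whose genus call is correct,
    the fraction whose species call is also correct.
    """
    if rank not in CANONICAL_RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    n = 0
    correct = miscls = uncls = 0
    genus_tot: dict[str, int] = {}
    genus_ok: dict[str, int] = {}
    for c in classifications:
        if c.read_id not in truth.per_read:
            raise ValueError(f"read {c.read_id!r} missing from per-read truth")
        true_sp, _artifact = truth.per_read[c.read_id]
        true_at_rank = taxonomy.rollup(true_sp, rank)
        n += 1
        assigned = (
            taxonomy.rollup(c.taxon_id, rank) if c.taxon_id is not None else None
        )
        if assigned is None:
            uncls += 1
        elif assigned == true_at_rank:
            correct += 1
        else:
            miscls += 1
        # per-genus species accuracy bookkeeping
        true_genus = taxonomy.rollup(true_sp, "genus")
        if true_genus is not None and c.taxon_id is not None:
            if taxonomy.rollup(c.taxon_id, "genus") == true_genus:
                genus_tot[true_genus] = genus_tot.get(true_genus, 0) + 1
                if taxonomy.rollup(c.taxon_id, "species") == true_sp:
                    genus_ok[true_genus] = genus_ok.get(true_genus, 0) + 1
    per_genus = {
        g: 100.0 * genus_ok.get(g, 0) / tot for g, tot in genus_tot.items()
    }
    if n == 0:
        return EvalReport(rank, 0.0, 0.0, 0.0, 0, per_genus)
    return EvalReport(
        rank,
        100.0 * correct / n,
        100.0 * miscls / n,
        100.0 * uncls / n,
        n,
        per_genus,
    )


def ambiguous_fraction(
    classifications: Sequence[ReadClassification],
) -> float:
    """Percent of classified reads not resolved to species level (NaN if none)."""
    amb = sum(1 for c in classifications if c.status == AMBIGUOUS_LCA)
    sp = sum(1 for c in classifications if c.status == SPECIES_LEVEL)
    if amb + sp == 0:
        return math.nan
    return 100.0 * amb / (amb + sp)


def _species_vector(
    classifications: Sequence[ReadClassification],
    taxonomy: Taxonomy,
) -> dict[str, int]:
    counts: dict[str, int] = {}
    for c in classifications:
        if c.status != SPECIES_LEVEL or c.taxon_id is None:
            continue
        sp = taxonomy.rollup(c.taxon_id, "species")
        if sp is not None:
            counts[sp] = counts.get(sp, 0) + 1
    return counts


def accumulation_curve(
    classifications: Sequence[ReadClassification],
    taxonomy: Taxonomy,
    depths: Sequence[int],
    n_reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Species-accumulation (rarefaction) table: depth, mean species, sd.

    At each depth, reads are subsampled without replacement ``n_reps``
    times and distinct species-level taxa (>= 1 read, no abundance filter)
    are counted. Deterministic under a fixed seed.
    """
    classifications = list(classifications)
    total = len(classifications)
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        if depth > total:
            raise ValueError(f"depth {depth} exceeds total reads {total}")
        vals = []
        for _ in range(n_reps):
            idx = rng.permutation(total)[:depth]
            sub = [classifications[i] for i in idx]
            vals.append(len(_species_vector(sub, taxonomy)))
        rows.append(
            {
                "depth": depth,
                "mean_species": float(np.mean(vals)),
                "sd_species": float(np.std(vals, ddof=0)),
            }
        )
    return pd.DataFrame(rows, columns=["depth", "mean_species", "sd_species"])


def depth_correlation(
    classifications: Sequence[ReadClassification],
    taxonomy: Taxonomy,
    d1: int,
    d2: int,
    seed: int = 0,
) -> float:
    """Pearson r of species relative-abundance vectors at two depths.

    Subsamples the classifications at ``d1`` and ``d2`` reads, builds
    species-level relative abundances over the union of detected species
    (absent = 0) and correlates them. Returns NaN when fewer than two
    species are detected in the union.
    """
    classifications = list(classifications)
    if not d1 < d2:
        raise ValueError("expected d1 < d2")
    if d2 > len(classifications):
        raise ValueError(f"depth {d2} exceeds total reads {len(classifications)}")
    rng = np.random.default_rng(seed)
    vecs = []
    for depth in (d1, d2):
        idx = rng.permutation(len(classifications))[:depth]
        counts = _species_vector([classifications[i] for i in idx], taxonomy)
        total = sum(counts.values())
        vecs.append({t: 100.0 * c / total for t, c in counts.items()} if total else {})
    union = sorted(set(vecs[0]) | set(vecs[1]))
    if len(union) < 2:
        return math.nan
    x = np.array([vecs[0].get(t, 0.0) for t in union])
    y = np.array([vecs[1].get(t, 0.0) for t in union])
    return float(stats.pearsonr(x, y).statistic)


def compare_methods(
    profiles: dict[str, AbundanceProfile],
    top_n: int = 15,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-method comparison over the union of each profile's top-N taxa.

    Returns a plot-ready long-format table ``(sample, taxon_id, percent)``
    and the pairwise Pearson correlation matrix over relative abundances
    (taxa absent from a profile count as 0).
    """
    names = list(profiles)
    ranks = {p.rank for p in profiles.values()}
    if len(ranks) > 1:
        raise ValueError(f"profiles at mixed ranks: {sorted(ranks)}")
    union: list[str] = []
    for p in profiles.values():
        top = sorted(p.counts, key=lambda t: (-p.counts[t], t))[:top_n]
        for t in top:
            if t not in union:
                union.append(t)
    union.sort()
    rows = [
        {"sample": name, "taxon_id": t, "percent": profiles[name].percent(t)}
        for name in names
        for t in union
    ]
    long = pd.DataFrame(rows, columns=["sample", "taxon_id", "percent"])
    mat = np.array([[profiles[n].percent(t) for t in union] for n in names])
    r = np.full((len(names), len(names)), np.nan)
    for i in range(len(names)):
        for j in range(len(names)):
            if len(union) >= 2:
                r[i, j] = stats.pearsonr(mat[i], mat[j]).statistic
    rmat = pd.DataFrame(r, index=names, columns=names)
    return long, rmat
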