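"""Transcription-factor calling by two evidence routes, merged with provenance.

Route 1 (domain): a protein is called a TF when it carries a qualifying hit
(E-value <= 1e-3 by default) to one of the TF-associated PFAM families; its
family is the best such hit. Overlapping within-clan hits are all retained
upstream; family assignment always takes the single best qualifying hit.

Route 2 (orthology): a protein is called a TF when it forms a reciprocal
best hit (RBH) with a member of the curated catalog, requiring E-value <=
1e-5 and alignment coverage >= 70% on both sides by default.

The merge partitions calls into domain_only / both / orthology_only, the
provenance classes used to audit how much each route contributes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from .formats_io import DomainHit, GeneRecord, SimilarityHit

__all__ = [
    "TFPrediction",
    "GenomeCensus",
    "assign_tf_by_domain",
    "find_orthologs_rbh",
    "merge_predictions",
    "partition_counts",
    "census",
    "family_genome_prevalence",
]

PROVENANCES = ("domain_only", "both", "orthology_only")


@dataclass(frozen=True)
class TFPrediction:
    """One protein called as a TF, with family and method provenance."""

    genome_id: str
    protein_id: str
    family_pfam: str
    provenance: str
    best_e: float | None = None

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"{self.protein_id}: unknown provenance {self.provenance!r}")
        if self.provenance in ("domain_only", "both") and not self.family_pfam:
            raise ValueError(f"{self.protein_id}: domain-supported call needs a family")
        if self.best_e is not None and self.best_e <= 0:
            raise ValueError(f"{self.protein_id}: best_e must be positive")


@dataclass(frozen=True)
class GenomeCensus:
    """Per-genome TF tally: ORF count, TF count and TF density."""

    genome_id: str
    n_orfs: int
    n_tfs: int
    division: str = ""

    def __post_init__(self) -> None:
        if self.n_orfs < 1:
            raise ValueError(f"{self.genome_id}: n_orfs must be positive")
        if not (0 <= self.n_tfs <= self.n_orfs):
            raise ValueError(f"{self.genome_id}: n_tfs outside [0, n_orfs]")

    @property
    def tf_density(self) -> float:
        return self.n_tfs / self.n_orfs


def assign_tf_by_domain(
    hits: Iterable[DomainHit],
    tf_pfams: set[str] | frozenset[str],
    e_max: float = 1e-3,
) -> dict[str, str]:
    """Map each protein with a qualifying TF-family hit to its family.

    A hit qualifies iff its accession is in ``tf_pfams`` and its E-value is
    <= ``e_max``. The family is the minimum-E-value qualifying hit; ties go
    to the higher bit score, then the lexically smallest accession.
    """
    if not tf_pfams:
        raise ValueError("tf_pfams must be nonempty")
    best: dict[str, DomainHit] = {}
    for hit in hits:
        if hit.pfam_acc not in tf_pfams or hit.e_value > e_max:
            continue
        cur = best.get(hit.protein_id)
        if cur is None or (hit.e_value, -hit.bit_score, hit.pfam_acc) < (
            cur.e_value,
            -cur.bit_score,
            cur.pfam_acc,
        ):
            best[hit.protein_id] = hit
    return {pid: h.pfam_acc for pid, h in best.items()}


def best_domain_evalues(
    hits: Iterable[DomainHit],
    tf_pfams: set[str] | frozenset[str],
    e_max: float = 1e-3,
) -> dict[str, float]:
    """Best qualifying E-value per protein (companion to assign_tf_by_domain)."""
    best: dict[str, float] = {}
    for hit in hits:
        if hit.pfam_acc in tf_pfams and hit.e_value <= e_max:
            if hit.protein_id not in best or hit.e_value < best[hit.protein_id]:
                best[hit.protein_id] = hit.e_value
    return best


def _qualifies(hit: SimilarityHit, e_max: float, cov_min: float, both_sides: bool) -> bool:
    if hit.e_value > e_max:
        return False
    cov = min(hit.query_cov, hit.subject_cov) if both_sides else hit.query_cov
    return cov >= cov_min


def _best_by_query(
    hits: Iterable[SimilarityHit], e_max: float, cov_min: float, both_sides: bool
) -> dict[str, SimilarityHit]:
    best: dict[str, SimilarityHit] = {}
    for hit in hits:
        if not _qualifies(hit, e_max, cov_min, both_sides):
            continue
        cur = best.get(hit.query_id)
        if cur is None or (-hit.bit_score, hit.e_value, hit.subject_id) < (
            -cur.bit_score,
            cur.e_value,
            cur.subject_id,
        ):
            best[hit.query_id] = hit
    return best


def find_orthologs_rbh(
    hits_ab: Iterable[SimilarityHit],
    hits_ba: Iterable[SimilarityHit],
    e_max: float = 1e-5,
    cov_min: float = 0.70,
    both_sides_coverage: bool = True,
) -> set[tuple[str, str]]:
    """Reciprocal-best-hit ortholog pairs between proteomes A and B.

    A hit qualifies iff ``e_value <= e_max`` and coverage >= ``cov_min``
    (on both alignment sides by default; set ``both_sides_coverage=False``
    for a one-sided query-coverage rule). ``(a, b)`` is returned iff b is
    a's best qualifying subject and a is b's best qualifying subject, with
    best meaning maximal bit score (ties: minimal E-value, then lexically
    smallest subject id). Each id appears in at most one pair.
    """
    best_ab = _best_by_query(hits_ab, e_max, cov_min, both_sides_coverage)
    best_ba = _best_by_query(hits_ba, e_max, cov_min, both_sides_coverage)
    pairs = set()
    for a, hit in best_ab.items():
        b = hit.subject_id
        back = best_ba.get(b)
        if back is not None and back.subject_id == a:
            pairs.add((a, b))
    return pairs


def merge_predictions(
    genome_id: str,
    domain_calls: Mapping[str, str],
    ortho_ids: Iterable[str],
    domain_e: Mapping[str, float] | None = None,
    ortho_e: Mapping[str, float] | None = None,
) -> list[TFPrediction]:
    """Merge the two call sets into provenance-partitioned predictions.

    The partition is disjoint and its union is exactly
    ``set(domain_calls) | set(ortho_ids)``. Orthology-only proteins are
    emitted with an empty family (the catalog family is not inherited).
    """
    domain_e = domain_e or {}
    ortho_e = ortho_e or {}
    ortho_set = set(ortho_ids)
    predictions = []
    for pid in sorted(set(domain_calls) | ortho_set):
        if pid in domain_calls and pid in ortho_set:
            prov = "both"
        elif pid in domain_calls:
            prov = "domain_only"
        else:
            prov = "orthology_only"
        predictions.append(
            TFPrediction(
                genome_id=genome_id,
                protein_id=pid,
                family_pfam=domain_calls.get(pid, ""),
                provenance=prov,
                best_e=domain_e.get(pid, ortho_e.get(pid)),
            )
        )
    return predictions


def partition_counts(predictions: Iterable[TFPrediction]) -> dict[str, int]:
    """Counts per provenance class, all three classes always present."""
    counts = Counter(p.provenance for p in predictions)
    return {prov: counts.get(prov, 0) for prov in PROVENANCES}


def census(
    predictions: Iterable[TFPrediction],
    genes: Iterable[GeneRecord],
    division_map: Mapping[str, str] | None = None,
) -> list[GenomeCensus]:
    """Per-genome census: ORFs, TF calls and TF density.

    Every prediction must map to an annotated gene of its genome; an
    unknown protein is a hard error naming it.
    """
    division_map = division_map or {}
    genes_by_genome: dict[str, set[str]] = {}
    for g in genes:
        genes_by_genome.setdefault(g.genome_id, set()).add(g.protein_id)
    tfs_by_genome: dict[str, set[str]] = {gid: set() for gid in genes_by_genome}
    for p in predictions:
        known = genes_by_genome.get(p.genome_id, set())
        if p.protein_id not in known:
            raise ValueError(
                f"prediction for unknown protein {p.protein_id} in genome {p.genome_id}"
            )
        tfs_by_genome[p.genome_id].add(p.protein_id)
    return [
        GenomeCensus(
            genome_id=gid,
            n_orfs=len(genes_by_genome[gid]),
            n_tfs=len(tfs_by_genome[gid]),
            division=division_map.get(gid, ""),
        )
        for gid in sorted(genes_by_genome)
    ]


def family_genome_prevalence(
    predictions: Iterable[TFPrediction], n_genomes: int
) -> dict[str, float]:
    """Fraction of genomes carrying >= 1 member of each family.

    ``n_genomes`` is the size of the surveyed collection (genomes with no
    prediction at all still count in the denominator).
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be positive")
    genomes_by_family: dict[str, set[str]] = {}
    for p in predictions:
        if p.family_pfam:
            genomes_by_family.setdefault(p.family_pfam, set()).add(p.genome_id)
    return {fam: len(gids) / n_genomes for fam, gids in sorted(genomes_by_family.items())}
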