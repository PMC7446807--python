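"""Functional layers on top of the TF calls: enzymes, virulence, Table rows.

Enzyme association comes from a two-column protein -> EC-number table
(consumed, not computed here); a protein is enzyme-associated iff it has at
least one valid EC entry, and its class is the first EC field (1
oxidoreductases ... 6 ligases). Virulence association is reciprocal-best-hit
orthology against a curated virulence-factor reference set under the same
thresholds as TF orthology (E <= 1e-5, coverage >= 70%). The per-family
context/function table pools TFs of each family across genomes and reports
divergent, in-TU, enzyme and virulence counts with the mixed printed scale
(divergent as a fraction, the rest as percentages).
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

from .context import ContextCall
from .formats_io import ParseResult, SimilarityHit
from .predict import TFPrediction, find_orthologs_rbh

__all__ = [
    "ECAnnotation",
    "ECJoin",
    "FamilyContextRow",
    "parse_ec_table",
    "join_ec",
    "ec_class_distribution",
    "flag_virulence",
    "top_families",
    "family_context_table",
]

_EC_RE = re.compile(r"^([1-6])\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


@dataclass(frozen=True)
class ECAnnotation:
    """One protein -> EC-number assignment; trailing '-' fields allowed."""

    protein_id: str
    ec: str

    def __post_init__(self) -> None:
        if not _EC_RE.match(self.ec):
            raise ValueError(f"{self.protein_id}: malformed EC number {self.ec!r}")

    @property
    def ec_class(self) -> int:
        return int(self.ec.split(".", 1)[0])


@dataclass
class ECJoin:
    """EC annotations joined onto a protein set, with the enzyme flag set."""

    annotations: dict[str, list[ECAnnotation]]
    enzyme_proteins: set[str]
    n_rejected: int = 0
    diagnostics: list[str] = field(default_factory=list)


def parse_ec_table(stream: IO[str] | Iterable[str]) -> ParseResult:
    """Parse a two-column (protein_id, EC) TSV; malformed ECs are rejected."""
    result = ParseResult(records=[])
    for raw in stream:
        line = raw.rstrip("\n")
        if not line or line.startswith("#") or line.lower().startswith("protein_id"):
            continue
        result.n_rows += 1
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 2:
            result.reject(f"EC row with {len(fields)} columns: {line[:60]!r}")
            continue
        try:
            result.records.append(ECAnnotation(protein_id=fields[0], ec=fields[1]))
        except ValueError as exc:
            result.reject(str(exc))
    return result


def join_ec(proteins: Iterable[str], ec_rows: Iterable[ECAnnotation]) -> ECJoin:
    """Attach EC entries to a protein set and flag enzyme-associated members.

    Rows for proteins outside the set are kept out of the join but noted in
    the diagnostics (they are not errors: the EC table may cover the whole
    proteome while the caller asks about TFs only).
    """
    proteins = set(proteins)
    join = ECJoin(annotations={}, enzyme_proteins=set())
    for row in ec_rows:
        if row.protein_id not in proteins:
            join.diagnostics.append(f"EC row for out-of-scope protein {row.protein_id}")
            continue
        join.annotations.setdefault(row.protein_id, []).append(row)
        join.enzyme_proteins.add(row.protein_id)
    return join


def ec_class_distribution(annotations: Iterable[ECAnnotation]) -> dict[int, float]:
    """Fractions over EC classes 1-6 (all six keys present, summing to 1)."""
    annotations = list(annotations)
    if not annotations:
        raise ValueError("no EC annotations to summarise")
    counts = Counter(a.ec_class for a in annotations)
    total = len(annotations)
    return {cls: counts.get(cls, 0) / total for cls in range(1, 7)}


def flag_virulence(
    proteome_hits_vs_vf: Iterable[SimilarityHit],
    vf_hits_vs_proteome: Iterable[SimilarityHit],
    e_max: float = 1e-5,
    cov_min: float = 0.70,
) -> set[str]:
    """Proteins forming an RBH pair with any virulence-factor reference protein.

    Identical machinery and thresholds as TF orthology detection; only the
    reference set differs.
    """
    pairs = find_orthologs_rbh(proteome_hits_vs_vf, vf_hits_vs_proteome, e_max, cov_min)
    return {a for a, _ in pairs}


@dataclass(frozen=True)
class FamilyContextRow:
    """One family's pooled context/function tally.

    ``frac_divergent`` is a plain fraction while the other shares are
    percentages — the mixed scale the per-family table is conventionally
    printed on is preserved rather than harmonised.
    """

    family_pfam: str
    total_tfs: int
    n_divergent: int
    n_in_tu: int
    n_enzyme: int
    n_virulence: int

    def __post_init__(self) -> None:
        for name in ("n_divergent", "n_in_tu", "n_enzyme", "n_virulence"):
            if not (0 <= getattr(self, name) <= max(self.total_tfs, 0)):
                raise ValueError(f"{self.family_pfam}: {name} exceeds total_tfs")

    @property
    def frac_divergent(self) -> float:
        return self.n_divergent / self.total_tfs if self.total_tfs else 0.0

    @property
    def pct_in_tu(self) -> float:
        return 100.0 * self.n_in_tu / self.total_tfs if self.total_tfs else 0.0

    @property
    def pct_enzyme(self) -> float:
        return 100.0 * self.n_enzyme / self.total_tfs if self.total_tfs else 0.0

    @property
    def pct_virulence(self) -> float:
        return 100.0 * self.n_virulence / self.total_tfs if self.total_tfs else 0.0


def top_families(predictions: Iterable[TFPrediction], k: int = 10) -> list[str]:
    """The k most abundant families across all predictions (ties by accession)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = Counter(p.family_pfam for p in predictions if p.family_pfam)
    ranked = sorted(counts.items(), key=lambda item: (-item[1], item[0]))
    return [fam for fam, _ in ranked[:k]]


def family_context_table(
    families: Sequence[str],
    predictions: Iterable[TFPrediction],
    context_calls: Mapping[tuple[str, str], ContextCall],
    ec_flags: set[str] | frozenset[str],
    vf_flags: set[str] | frozenset[str],
) -> list[FamilyContextRow]:
    """Pool each family's TFs across genomes into one context/function row.

    ``context_calls`` is keyed by ``(genome_id, protein_id)``; ``ec_flags``
    and ``vf_flags`` hold enzyme- and virulence-associated protein ids.
    A requested family with zero TFs yields an all-zero row with a warning.
    """
    by_family: dict[str, list[TFPrediction]] = {fam: [] for fam in families}
    for p in predictions:
        if p.family_pfam in by_family:
            by_family[p.family_pfam].append(p)
    rows = []
    for fam in families:
        members = by_family[fam]
        if not members:
            warnings.warn(f"family {fam} has no predicted TFs; emitting a zero row")
            rows.append(FamilyContextRow(fam, 0, 0, 0, 0, 0))
            continue
        n_div = n_tu = n_ec = n_vf = 0
        for p in members:
            call = context_calls.get((p.genome_id, p.protein_id))
            if call is not None:
                if call.relation == "divergent":
                    n_div += 1
                elif call.relation == "in_tu":
                    n_tu += 1
            if p.protein_id in ec_flags:
                n_ec += 1
            if p.protein_id in vf_flags:
                n_vf += 1
        rows.append(
            FamilyContextRow(
                family_pfam=fam,
                total_tfs=len(members),
                n_divergent=n_div,
                n_in_tu=n_tu,
                n_enzyme=n_ec,
                n_virulence=n_vf,
            )
        )
    return rows
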