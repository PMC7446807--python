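"""The curated transcription-factor catalog and its descriptive statistics.

The catalog is the experimentally supported gold-standard set used to seed
orthology-based prediction: each entry is one protein validated as a
DNA-binding transcription factor, with its PFAM domain architecture, its
regulatory role and the experimental evidence behind it. Evidence codes are
dichotomised into *strong* (direct binding or structural demonstration) and
*weak* (expression-level or inferential support).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "EVIDENCE_STRENGTH",
    "ROLES",
    "EvidenceCode",
    "CatalogEntry",
    "classify_evidence",
    "summarize_domain_architecture",
    "summarize_roles",
    "family_frequency",
    "read_catalog_tsv",
    "write_catalog_tsv",
]

# Evidence-code -> strength dichotomy. Strong codes demonstrate the
# factor-operator interaction directly (structures, footprints, site
# mutations, direct binding assays); weak codes are expression-level or
# inferential.
EVIDENCE_STRENGTH: dict[str, str] = {
    "PDB": "strong",
    "BPP": "strong",
    "SM": "strong",
    "IDA": "strong",
    "APPH": "strong",
    "QRT-PCR": "strong",
    "OHR": "strong",
    "CHIP-SEQ": "strong",
    "PRM": "strong",
    "BCE": "weak",
    "GEA": "weak",
    "AS": "weak",
    "IEP": "weak",
    "IMP": "weak",
    "IGI": "weak",
    "RBM": "weak",
    "MIC": "weak",
}

ROLES = ("activator", "repressor", "dual", "undefined")


@dataclass(frozen=True)
class EvidenceCode:
    code: str
    strength: str

    def __post_init__(self) -> None:
        if classify_evidence(self.code) != self.strength:
            raise ValueError(f"evidence {self.code!r} carries strength {self.strength!r}")


@dataclass(frozen=True)
class CatalogEntry:
    """One curated TF: identifiers, domain architecture, role, evidence."""

    tf_id: str
    species: str
    family_pfam: str
    all_pfams: tuple[str, ...]
    role: str
    evidence: tuple[EvidenceCode, ...]

    def __post_init__(self) -> None:
        if not self.all_pfams:
            raise ValueError(f"{self.tf_id}: catalog entry needs at least one PFAM")
        if self.family_pfam not in self.all_pfams:
            raise ValueError(f"{self.tf_id}: family {self.family_pfam} not among its PFAMs")
        if self.role not in ROLES:
            raise ValueError(f"{self.tf_id}: unknown role {self.role!r} (valid: {ROLES})")

    @property
    def n_domains(self) -> int:
        return len(self.all_pfams)


def classify_evidence(code: str) -> str:
    """Map an evidence code (case-insensitive) to ``strong`` or ``weak``."""
    strength = EVIDENCE_STRENGTH.get(code.strip().upper())
    if strength is None:
        valid = ", ".join(sorted(EVIDENCE_STRENGTH))
        raise ValueError(f"unknown evidence code {code!r}; valid codes: {valid}")
    return strength


def _require_nonempty(entries: list) -> None:
    if not entries:
        raise ValueError("catalog is empty")


def summarize_domain_architecture(entries: Iterable[CatalogEntry]) -> dict[int, float]:
    """Percent of entries per domain count (monodomain, two-domain, ...)."""
    entries = list(entries)
    _require_nonempty(entries)
    counts = Counter(e.n_domains for e in entries)
    total = len(entries)
    return {n: 100.0 * c / total for n, c in sorted(counts.items())}


def summarize_roles(entries: Iterable[CatalogEntry]) -> dict[str, float]:
    """Percent of entries per regulatory role (activator/repressor/dual/undefined)."""
    entries = list(entries)
    _require_nonempty(entries)
    counts = Counter(e.role for e in entries)
    total = len(entries)
    return {role: 100.0 * counts.get(role, 0) / total for role in ROLES if counts.get(role)}


def family_frequency(entries: Iterable[CatalogEntry]) -> list[tuple[str, float]]:
    """Family -> percent table, descending by percent (ties by accession)."""
    entries = list(entries)
    _require_nonempty(entries)
    counts = Counter(e.family_pfam for e in entries)
    total = len(entries)
    return sorted(
        ((fam, 100.0 * c / total) for fam, c in counts.items()),
        key=lambda item: (-item[1], item[0]),
    )


# ---------------------------------------------------------------------------
# Catalog file: TSV with columns tf_id, species, pfams (;-joined, first is
# the family unless a family column is present), role, evidence (;-joined).


def read_catalog_tsv(path) -> list[CatalogEntry]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    entries = []
    for row in df.itertuples():
        pfams = tuple(p for p in row.pfams.split(";") if p)
        family = getattr(row, "family", "") or (pfams[0] if pfams else "")
        role = row.role if row.role in ROLES else "undefined"
        evidence = tuple(
            EvidenceCode(code=c.upper(), strength=classify_evidence(c))
            for c in row.evidence.split(";")
            if c
        )
        entries.append(
            CatalogEntry(
                tf_id=row.tf_id,
                species=row.species,
                family_pfam=family,
                all_pfams=pfams,
                role=role,
                evidence=evidence,
            )
        )
    return entries


def write_catalog_tsv(entries: Iterable[CatalogEntry], path) -> None:
    rows = [
        {
            "tf_id": e.tf_id,
            "species": e.species,
            "family": e.family_pfam,
            "pfams": ";".join(e.all_pfams),
            "role": e.role,
            "evidence": ";".join(ev.code for ev in e.evidence),
        }
        for e in entries
    ]
    pd.DataFrame(rows, columns=["tf_id", "species", "family", "pfams", "role", "evidence"]).to_csv(
        path, sep="\t", index=False
    )
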