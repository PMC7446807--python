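"""Readers and writers for every external format the pipeline touches.

All genomic coordinates are 1-based inclusive (GFF3 convention); every
distance computed downstream is documented against that convention.
Parsers validate rows strictly and never drop anything silently: each
parse function returns a :class:`ParseResult` whose ``n_rows`` /
``n_rejected`` bookkeeping satisfies ``accepted = n_rows - n_rejected``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import pandas as pd
from gffutils.feature import feature_from_line

__all__ = [
    "GeneRecord",
    "DomainHit",
    "SimilarityHit",
    "Pfam2GoEntry",
    "ParseResult",
    "parse_gene_annotations",
    "parse_domain_hits",
    "parse_similarity_hits",
    "parse_pfam2go",
    "strip_accession_version",
    "read_gene_records_tsv",
    "write_gene_records_tsv",
    "read_domain_hits_tsv",
    "write_domain_hits_tsv",
    "read_similarity_hits_tsv",
    "write_similarity_hits_tsv",
]

_PFAM_VERSION_RE = re.compile(r"^(PF\d+)\.\d+$")
_GO_ID_RE = re.compile(r"GO:\d{7}")


def strip_accession_version(acc: str) -> str:
    """Normalise ``PF00126.27`` to ``PF00126`` (release-independent matching)."""
    m = _PFAM_VERSION_RE.match(acc)
    return m.group(1) if m else acc


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: coordinates, orientation and identifiers.

    ``start``/``end`` are 1-based inclusive with ``end >= start``
    regardless of strand.
    """

    gene_id: str
    protein_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    genome_id: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start must be >= 1")
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end < start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class DomainHit:
    """One protein-vs-PFAM profile hit (pfam_scan-style row)."""

    protein_id: str
    pfam_acc: str
    clan_acc: str
    e_value: float
    bit_score: float
    ali_start: int
    ali_end: int

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError(f"hit {self.protein_id}/{self.pfam_acc}: e_value must be > 0")
        if not (1 <= self.ali_start <= self.ali_end):
            raise ValueError(
                f"hit {self.protein_id}/{self.pfam_acc}: need ali_end >= ali_start >= 1"
            )


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise similarity hit with per-side alignment coverage."""

    query_id: str
    subject_id: str
    e_value: float
    bit_score: float
    query_cov: float
    subject_cov: float

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: e_value must be > 0")
        for name, cov in (("query_cov", self.query_cov), ("subject_cov", self.subject_cov)):
            if not (0.0 <= cov <= 1.0):
                raise ValueError(
                    f"hit {self.query_id}->{self.subject_id}: {name}={cov} outside [0,1]"
                )


@dataclass(frozen=True)
class Pfam2GoEntry:
    """One PFAM accession -> GO term mapping line."""

    pfam_acc: str
    go_id: str
    go_term: str

    def __post_init__(self) -> None:
        if not _GO_ID_RE.fullmatch(self.go_id):
            raise ValueError(f"{self.pfam_acc}: malformed GO id {self.go_id!r}")


@dataclass
class ParseResult:
    """Accepted records plus an audit trail of rejected input rows."""

    records: list
    n_rows: int = 0
    n_rejected: int = 0
    diagnostics: list[str] = field(default_factory=list)

    def reject(self, message: str) -> None:
        self.n_rejected += 1
        self.diagnostics.append(message)


def _lines(stream: IO[str] | Iterable[str]) -> Iterable[str]:
    for raw in stream:
        yield raw.rstrip("\n")


def parse_gene_annotations(
    gff3_stream: IO[str] | Iterable[str],
    genome_id: str,
    protein_attr: str = "protein_id",
    feature_types: tuple[str, ...] = ("CDS",),
) -> ParseResult:
    """Parse gene/CDS features from a GFF3 stream into :class:`GeneRecord` rows.

    ``protein_id`` is taken from the ``protein_attr`` attribute when present,
    otherwise from the feature ``ID``. Records with a malformed strand,
    ``end < start`` or a duplicate ``(genome_id, gene_id)`` are rejected with
    a diagnostic; accepted records come back sorted by (replicon, start).
    """
    result = ParseResult(records=[])
    seen: set[str] = set()
    for line in _lines(gff3_stream):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            result.n_rows += 1
            result.reject(f"malformed GFF3 line ({len(fields)} columns): {line[:60]!r}")
            continue
        if fields[2] not in feature_types:
            continue
        result.n_rows += 1
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # gffutils raises assorted parse errors
            result.reject(f"unparseable GFF3 line: {exc}")
            continue
        gene_id = feat.attributes.get("ID", [None])[0]
        if gene_id is None:
            result.reject(f"feature at {feat.seqid}:{feat.start} lacks an ID attribute")
            continue
        protein_id = feat.attributes.get(protein_attr, [gene_id])[0]
        try:
            record = GeneRecord(
                gene_id=gene_id,
                protein_id=protein_id,
                replicon_id=feat.seqid,
                start=int(feat.start),
                end=int(feat.end),
                strand=feat.strand,
                genome_id=genome_id,
            )
        except (ValueError, TypeError) as exc:
            result.reject(str(exc))
            continue
        if gene_id in seen:
            result.reject(f"duplicate gene id {gene_id} in genome {genome_id}")
            continue
        seen.add(gene_id)
        result.records.append(record)
    result.records.sort(key=lambda g: (g.replicon_id, g.start, g.gene_id))
    return result


def parse_domain_hits(tsv_stream: IO[str] | Iterable[str]) -> ParseResult:
    """Parse a whitespace/tab-delimited domain-hit table.

    Expected columns: protein_id, pfam_acc, clan_acc, e_value, bit_score,
    ali_start, ali_end. Accession version suffixes (``PF00126.27``) are
    stripped; a ``-`` clan becomes the empty string.
    """
    result = ParseResult(records=[])
    for line in _lines(tsv_stream):
        if not line or line.startswith("#"):
            continue
        result.n_rows += 1
        fields = line.split()
        if len(fields) < 7:
            result.reject(f"domain-hit row has {len(fields)} columns, need 7: {line[:60]!r}")
            continue
        protein_id, pfam_acc, clan_acc = fields[0], fields[1], fields[2]
        try:
            hit = DomainHit(
                protein_id=protein_id,
                pfam_acc=strip_accession_version(pfam_acc),
                clan_acc="" if clan_acc in ("-", ".") else strip_accession_version(clan_acc),
                e_value=float(fields[3]),
                bit_score=float(fields[4]),
                ali_start=int(fields[5]),
                ali_end=int(fields[6]),
            )
        except ValueError as exc:
            result.reject(f"row for {protein_id}/{pfam_acc}: {exc}")
            continue
        result.records.append(hit)
    return result


def parse_similarity_hits(
    tsv_stream: IO[str] | Iterable[str],
    query_lengths: Mapping[str, int],
    subject_lengths: Mapping[str, int],
) -> ParseResult:
    """Parse BLAST tabular (outfmt 6) rows, computing per-side coverage.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore. Coverage is aligned span over sequence
    length on each side; subject spans on the minus orientation
    (``sstart > send``) are handled by absolute span. An id missing from
    its length map is a hard error naming the id.
    """
    result = ParseResult(records=[])
    for line in _lines(tsv_stream):
        if not line or line.startswith("#"):
            continue
        result.n_rows += 1
        fields = line.split()
        if len(fields) < 12:
            result.reject(f"similarity row has {len(fields)} columns, need 12: {line[:60]!r}")
            continue
        qid, sid = fields[0], fields[1]
        if qid not in query_lengths:
            raise KeyError(f"unknown sequence {qid}")
        if sid not in subject_lengths:
            raise KeyError(f"unknown sequence {sid}")
        try:
            qstart, qend = int(fields[6]), int(fields[7])
            sstart, send = int(fields[8]), int(fields[9])
            hit = SimilarityHit(
                query_id=qid,
                subject_id=sid,
                e_value=float(fields[10]),
                bit_score=float(fields[11]),
                query_cov=(abs(qend - qstart) + 1) / query_lengths[qid],
                subject_cov=(abs(send - sstart) + 1) / subject_lengths[sid],
            )
        except ValueError as exc:
            result.reject(f"row {qid}->{sid}: {exc}")
            continue
        result.records.append(hit)
    return result


_PFAM2GO_RE = re.compile(
    r"^Pfam:(?P<acc>PF\d+(?:\.\d+)?)\s+\S+\s*>\s*GO:(?P<term>.+?)\s*;\s*(?P<goid>GO:\d{7})\s*$"
)


def parse_pfam2go(text_stream: IO[str] | Iterable[str]) -> ParseResult:
    """Parse the flat pfam2go mapping (``Pfam:PFxxxxx name > GO:term ; GO:id``).

    Comment lines (leading ``!``) are skipped without counting; a data line
    with no GO id is rejected with a diagnostic. One entry per (PFAM, GO)
    pair: a PFAM mapped to several GO terms yields several entries.
    """
    result = ParseResult(records=[])
    for line in _lines(text_stream):
        if not line.strip() or line.startswith("!"):
            continue
        result.n_rows += 1
        m = _PFAM2GO_RE.match(line)
        if m is None:
            result.reject(f"pfam2go line without a GO id: {line[:60]!r}")
            continue
        result.records.append(
            Pfam2GoEntry(
                pfam_acc=strip_accession_version(m.group("acc")),
                go_id=m.group("goid"),
                go_term=m.group("term"),
            )
        )
    return result


# ---------------------------------------------------------------------------
# TSV persistence. All internal tables round-trip through headered TSV.

_GENE_COLS = ["gene_id", "protein_id", "replicon_id", "start", "end", "strand", "genome_id"]
_DOMAIN_COLS = ["protein_id", "pfam_acc", "clan_acc", "e_value", "bit_score", "ali_start", "ali_end"]
_SIM_COLS = ["query_id", "subject_id", "e_value", "bit_score", "query_cov", "subject_cov"]


def write_gene_records_tsv(records: Iterable[GeneRecord], path) -> None:
    pd.DataFrame([vars(r) for r in records], columns=_GENE_COLS).to_csv(
        path, sep="\t", index=False
    )


def read_gene_records_tsv(path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in _GENE_COLS if c not in ("start", "end")})
    return [
        GeneRecord(
            gene_id=row.gene_id,
            protein_id=row.protein_id,
            replicon_id=row.replicon_id,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            genome_id=row.genome_id,
        )
        for row in df.itertuples()
    ]


def write_domain_hits_tsv(hits: Iterable[DomainHit], path) -> None:
    df = pd.DataFrame([vars(h) for h in hits], columns=_DOMAIN_COLS)
    df["clan_acc"] = df["clan_acc"].fillna("")
    df.to_csv(path, sep="\t", index=False)


def read_domain_hits_tsv(path) -> list[DomainHit]:
    df = pd.read_csv(
        path,
        sep="\t",
        keep_default_na=False,
        dtype={"protein_id": str, "pfam_acc": str, "clan_acc": str},
        float_precision="round_trip",
    )
    return [
        DomainHit(
            protein_id=row.protein_id,
            pfam_acc=row.pfam_acc,
            clan_acc=row.clan_acc,
            e_value=float(row.e_value),
            bit_score=float(row.bit_score),
            ali_start=int(row.ali_start),
            ali_end=int(row.ali_end),
        )
        for row in df.itertuples()
    ]


def write_similarity_hits_tsv(hits: Iterable[SimilarityHit], path) -> None:
    pd.DataFrame([vars(h) for h in hits], columns=_SIM_COLS).to_csv(path, sep="\t", index=False)


def read_similarity_hits_tsv(path) -> list[SimilarityHit]:
    df = pd.read_csv(
        path,
        sep="\t",
        keep_default_na=False,
        dtype={"query_id": str, "subject_id": str},
        float_precision="round_trip",
    )
    return [
        SimilarityHit(
            query_id=row.query_id,
            subject_id=row.subject_id,
            e_value=float(row.e_value),
            bit_score=float(row.bit_score),
            query_cov=float(row.query_cov),
            subject_cov=float(row.subject_cov),
        )
        for row in df.itertuples()
    ]
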