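"""Genomic context of TF genes: transcription units and divergent pairs.

Transcription units (TUs, operons) are predicted from strand and intergenic
distance: maximal runs of consecutive same-strand genes whose pairwise gaps
do not exceed a threshold (default 50 bp, the conventional heuristic for
prokaryotic operon calling). A TF gene is *divergent* when its upstream
(promoter-proximal) neighbor lies on the opposite strand with both promoters
facing the shared intergenic region — the classic regulator/target
architecture in which the TF can control the adjacent gene and repress
itself from overlapping or adjacent promoters. A TF co-transcribed with at
least one neighbor is *in_tu*; everything else is *isolated*.

Coordinates are 1-based inclusive throughout; the intergenic distance
between ordered non-overlapping genes is the count of bases strictly
between them, ``downstream.start - upstream.end - 1``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .formats_io import GeneRecord

__all__ = [
    "TranscriptionUnit",
    "ContextCall",
    "IntergenicGap",
    "DistanceHistogram",
    "intergenic_distance",
    "predict_tus",
    "classify_tf_context",
    "divergent_distance_histogram",
]

RELATIONS = ("divergent", "in_tu", "isolated")


@dataclass(frozen=True)
class IntergenicGap:
    """Distance between two ordered genes; overlap clamps to 0 with a flag."""

    bp: int
    overlap: bool = False


@dataclass(frozen=True)
class TranscriptionUnit:
    tu_id: str
    replicon_id: str
    strand: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"{self.tu_id}: a TU needs at least one gene")


@dataclass(frozen=True)
class ContextCall:
    """A TF gene's relationship to its neighborhood."""

    tf_gene_id: str
    relation: str
    partner_gene_id: str = ""
    intergenic_bp: int | None = None
    overlap: bool = False

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"{self.tf_gene_id}: unknown relation {self.relation!r}")
        if self.relation == "divergent" and (not self.partner_gene_id or self.intergenic_bp is None):
            raise ValueError(f"{self.tf_gene_id}: divergent call needs partner and distance")
        if self.relation == "in_tu" and not self.partner_gene_id:
            raise ValueError(f"{self.tf_gene_id}: in_tu call needs a co-TU partner")


def intergenic_distance(upstream: GeneRecord, downstream: GeneRecord) -> IntergenicGap:
    """Bases strictly between two genes ordered along the replicon.

    Overlapping genes get distance 0 with the overlap flag set rather than
    a negative distance.
    """
    if upstream.replicon_id != downstream.replicon_id:
        raise ValueError(
            f"{upstream.gene_id} and {downstream.gene_id} lie on different replicons"
        )
    if downstream.start <= upstream.end:
        return IntergenicGap(bp=0, overlap=True)
    return IntergenicGap(bp=downstream.start - upstream.end - 1)


def predict_tus(
    genes: Sequence[GeneRecord], gap_max: int = 50, replicon_id: str | None = None
) -> list[TranscriptionUnit]:
    """Partition one replicon's genes into transcription units.

    Maximal runs of consecutive same-strand genes with adjacent gaps <=
    ``gap_max`` (overlapping same-strand genes count as gap 0). Every gene
    lands in exactly one TU; strand switches and large gaps both break runs.
    """
    genes = sorted(genes, key=lambda g: g.start)
    if not genes:
        return []
    rep = replicon_id or genes[0].replicon_id
    if any(g.replicon_id != rep for g in genes):
        raise ValueError("predict_tus expects genes of a single replicon")
    tus: list[TranscriptionUnit] = []
    run: list[GeneRecord] = [genes[0]]
    for prev, cur in zip(genes, genes[1:]):
        gap = intergenic_distance(prev, cur)
        if cur.strand == prev.strand and gap.bp <= gap_max:
            run.append(cur)
        else:
            tus.append(_make_tu(rep, len(tus), run))
            run = [cur]
    tus.append(_make_tu(rep, len(tus), run))
    return tus


def _make_tu(replicon_id: str, index: int, run: list[GeneRecord]) -> TranscriptionUnit:
    return TranscriptionUnit(
        tu_id=f"{replicon_id}:TU{index:05d}",
        replicon_id=replicon_id,
        strand=run[0].strand,
        gene_ids=tuple(g.gene_id for g in run),
    )


def _neighbor(
    genes: Sequence[GeneRecord], idx: int, offset: int, circular: bool
) -> GeneRecord | None:
    j = idx + offset
    if circular and len(genes) > 1:
        return genes[j % len(genes)]
    if 0 <= j < len(genes):
        return genes[j]
    return None


def classify_tf_context(
    tf_gene: GeneRecord,
    genes: Sequence[GeneRecord],
    tus: Sequence[TranscriptionUnit],
    circular: bool = False,
) -> ContextCall:
    """Classify a TF gene as divergent, in_tu or isolated.

    Divergence keys on the upstream (promoter-side) neighbor: a plus-strand
    TF with its left neighbor on the minus strand, or a minus-strand TF
    with its right neighbor on the plus strand — the two promoters then
    face the shared intergenic region. A TF at a linear replicon edge with
    no upstream neighbor cannot be divergent and is classified by TU
    membership; with ``circular=True`` the neighborhood wraps around.
    """
    genes = sorted(
        (g for g in genes if g.replicon_id == tf_gene.replicon_id), key=lambda g: g.start
    )
    try:
        idx = next(i for i, g in enumerate(genes) if g.gene_id == tf_gene.gene_id)
    except StopIteration:
        raise ValueError(f"TF gene {tf_gene.gene_id} not among the replicon's genes") from None

    upstream_offset = -1 if tf_gene.strand == "+" else 1
    neighbor = _neighbor(genes, idx, upstream_offset, circular)
    if neighbor is not None and neighbor.gene_id != tf_gene.gene_id and neighbor.strand != tf_gene.strand:
        # promoters face each other only for the (-) <- gap -> (+) geometry
        left, right = (neighbor, tf_gene) if tf_gene.strand == "+" else (tf_gene, neighbor)
        if left.strand == "-" and right.strand == "+":
            if circular and not (left.start <= right.start):
                # wrapped neighbor: gap runs through the origin; measure it
                # as the wraparound span (right follows left around the end)
                gap = IntergenicGap(bp=max(right.start - 1, 0), overlap=False)
            else:
                gap = intergenic_distance(left, right)
            return ContextCall(
                tf_gene_id=tf_gene.gene_id,
                relation="divergent",
                partner_gene_id=neighbor.gene_id,
                intergenic_bp=gap.bp,
                overlap=gap.overlap,
            )

    tu = next((t for t in tus if tf_gene.gene_id in t.gene_ids), None)
    if tu is not None and len(tu.gene_ids) > 1:
        pos = tu.gene_ids.index(tf_gene.gene_id)
        partner = tu.gene_ids[pos - 1] if pos > 0 else tu.gene_ids[pos + 1]
        by_id = {g.gene_id: g for g in genes}
        a, b = sorted((by_id[partner], tf_gene), key=lambda g: g.start)
        gap = intergenic_distance(a, b)
        return ContextCall(
            tf_gene_id=tf_gene.gene_id,
            relation="in_tu",
            partner_gene_id=partner,
            intergenic_bp=gap.bp,
            overlap=gap.overlap,
        )
    return ContextCall(tf_gene_id=tf_gene.gene_id, relation="isolated")


@dataclass
class DistanceHistogram:
    """Binned divergent-pair intergenic distances plus the <=100 bp share."""

    bin_width: int
    bins: dict[int, int] = field(default_factory=dict)
    n: int = 0
    frac_le_100: float | None = None

    def bin_start(self, index: int) -> int:
        return index * self.bin_width


def divergent_distance_histogram(
    calls: Iterable[ContextCall], bin_width: int = 50
) -> DistanceHistogram:
    """Histogram of intergenic distances over divergent context calls.

    Bin k covers ``[k*bin_width, (k+1)*bin_width)``; the fraction of
    divergent pairs separated by <= 100 bp is reported alongside (None
    when there are no divergent calls).
    """
    if bin_width < 1:
        raise ValueError("bin_width must be positive")
    distances = [c.intergenic_bp for c in calls if c.relation == "divergent"]
    hist = DistanceHistogram(bin_width=bin_width)
    if not distances:
        return hist
    counts = Counter(d // bin_width for d in distances)
    hist.bins = dict(sorted(counts.items()))
    hist.n = len(distances)
    hist.frac_le_100 = sum(1 for d in distances if d <= 100) / len(distances)
    return hist
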