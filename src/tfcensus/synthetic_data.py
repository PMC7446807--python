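"""Ground-truthed synthetic genome collections for exercising the pipeline.

The generator emits everything the analysis consumes — GFF3 gene layouts,
domain-hit tables, similarity tables against a catalog and against a
virulence reference, EC tables, a TF-PFAM list, a pfam2go mapping and a
curated-catalog file — together with a ground-truth object stating, for
every planted TF, its family, its per-route detectability, its genomic
context and its functional flags.

Statistical structure emulated:

* TF abundance follows a power law in genome size,
  ``n_tfs = round(a * n_orfs**b * exp(eps))`` with log-normal noise
  ``eps ~ N(0, sigma^2)``, defaults a = 0.0007, b = 1.5283, sigma = 0.2.
* Genome sizes are log-uniform over ``orf_range``.
* TF family frequencies follow the curated-collection distribution
  (TetR/AcrR most abundant at 9.8%, OmpR/PhoB 7.9%, a long minor-family
  tail making up the rest of the 111 TF-associated families).
* Each TF is planted divergent, inside an operon, or isolated; divergent
  gaps are short (geometric, mean 60 bp) so most pairs sit within 100 bp.
* Every genome carries near-threshold decoy evidence rows (E-values and
  coverages straddling 1e-3, 1e-5 and 0.70) so boundary behaviour is
  always exercised.

Genes sit on one circular replicon per genome with a fixed 900 bp length
(a typical prokaryotic ORF); only the gaps matter downstream. All
randomness flows from one seeded generator per collection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .catalog import EVIDENCE_STRENGTH, CatalogEntry, EvidenceCode, classify_evidence
from .formats_io import DomainHit, GeneRecord, SimilarityHit

__all__ = [
    "GeneratorConfig",
    "TruthRecord",
    "GenomeTruth",
    "GroundTruth",
    "GenomeBundle",
    "DEFAULT_FAMILY_FREQS",
    "TF_PFAM_LIST",
    "sample_scaling_points",
    "generate_collection",
    "generate_catalog",
    "generate_division_panel",
    "pfam2go_text",
    "write_collection",
]

GENE_LENGTH = 900

# Top-10 family frequencies anchored to the curated-collection distribution
# (TetR/AcrR 9.8%, OmpR/PhoB 7.9%, the rest descending); together ~57% of
# TFs, consistent with the top 10 families covering ~60% of the collection.
DEFAULT_FAMILY_FREQS: dict[str, float] = {
    "PF00440": 0.098,  # TetR/AcrR
    "PF00486": 0.079,  # OmpR/PhoB
    "PF00126": 0.075,  # LysR
    "PF12833": 0.060,  # HTH_18
    "PF00392": 0.055,  # GntR
    "PF00196": 0.050,  # LuxR/UhpA
    "PF01381": 0.045,  # HTH_3
    "PF02954": 0.040,  # Fis
    "PF00356": 0.035,  # GalR/LacI
    "PF01047": 0.030,  # MarR
}

# Minor-family tail filling the TF-associated list out to 111 accessions.
_TAIL_PFAMS = tuple(f"PF9{i:04d}" for i in range(101))
TF_PFAM_LIST: tuple[str, ...] = tuple(DEFAULT_FAMILY_FREQS) + _TAIL_PFAMS

# Domain pool for neighbor (non-TF) genes: transport, kinase and metabolic
# domains of the kind that border regulators. Disjoint from TF_PFAM_LIST so
# planted neighbors can never be called TFs.
NEIGHBOR_PFAM_POOL: tuple[str, ...] = (
    "PF00005",  # ABC transporter ATPase
    "PF00512",  # histidine kinase dimerisation domain
    "PF07690",  # MFS transporter
    "PF00155",  # aminotransferase
    "PF00083",  # sugar transporter
    "PF01547",  # solute-binding protein
    "PF00118",  # chaperonin
    "PF00478",  # IMP dehydrogenase
)

_ROLE_FREQS = {"repressor": 0.294, "dual": 0.239, "activator": 0.181, "undefined": 0.286}
_DOMAIN_COUNT_FREQS = {1: 0.4177, 2: 0.5022, 3: 0.0603, 4: 0.009, 5: 0.002, 6: 0.0035, 7: 0.0035}
_EC_CLASS_FREQS = (0.15, 0.40, 0.20, 0.10, 0.10, 0.05)  # transferase-dominant


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic collection. ``seed`` is mandatory."""

    seed: int
    n_genomes: int = 30
    orf_range: tuple[int, int] = (500, 12000)
    scaling_a: float = 0.0007
    scaling_b: float = 1.5283
    noise_sigma: float = 0.2
    family_freqs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FAMILY_FREQS))
    divergent_frac: float = 0.25
    in_tu_frac: float = 0.30
    operon_geom_p: float = 0.5
    intra_tu_gap_mean: float = 20.0
    divergent_gap_mean: float = 60.0
    filler_gap_mean: float = 250.0
    tu_gap_max: int = 50
    domain_detectable_frac: float = 0.90
    ortho_detectable_frac: float = 0.70
    ec_class_freqs: tuple[float, ...] = _EC_CLASS_FREQS
    enzyme_frac: float = 0.05
    virulence_frac: float = 0.10
    divisions: tuple[str, ...] = ("all",)
    replicon_length: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in (
            "divergent_frac",
            "in_tu_frac",
            "domain_detectable_frac",
            "ortho_detectable_frac",
            "enzyme_frac",
            "virulence_frac",
            "operon_geom_p",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.divergent_frac + self.in_tu_frac > 1.0:
            raise ValueError("divergent_frac + in_tu_frac exceed 1")
        total = sum(self.family_freqs.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"family_freqs sum to {total} > 1")
        if abs(sum(self.ec_class_freqs) - 1.0) > 1e-6:
            raise ValueError("ec_class_freqs must sum to 1")
        if self.orf_range[0] < 10 or self.orf_range[1] < self.orf_range[0]:
            raise ValueError("invalid orf_range")


@dataclass
class TruthRecord:
    """Ground truth for one planted TF."""

    protein_id: str
    family: str
    domain_detectable: bool
    orthology_detectable: bool
    relation: str
    divergent_gap: int | None = None
    ec_class: int | None = None
    virulence: bool = False


@dataclass
class GenomeTruth:
    genome_id: str
    division: str
    n_orfs: int
    n_tfs: int
    tfs: dict[str, TruthRecord] = field(default_factory=dict)


@dataclass
class GroundTruth:
    scaling_a: float
    scaling_b: float
    noise_sigma: float
    genomes: dict[str, GenomeTruth] = field(default_factory=dict)


@dataclass
class GenomeBundle:
    """All emitted evidence for one synthetic genome."""

    genome_id: str
    division: str
    genes: list[GeneRecord]
    domain_hits: list[DomainHit]
    sim_vs_catalog_ab: list[SimilarityHit]
    sim_vs_catalog_ba: list[SimilarityHit]
    sim_vs_vf_ab: list[SimilarityHit]
    sim_vs_vf_ba: list[SimilarityHit]
    ec_rows: list[tuple[str, str]]

    def gff3_text(self) -> str:
        lines = ["##gff-version 3"]
        for g in self.genes:
            lines.append(
                f"{g.replicon_id}\ttfcensus\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id};protein_id={g.protein_id}"
            )
        return "\n".join(lines) + "\n"


def sample_scaling_points(
    n_genomes: int,
    orf_range: tuple[int, int],
    scaling_a: float,
    scaling_b: float,
    noise_sigma: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (n_orfs, n_tfs) pairs under the power-law abundance model.

    ORF counts are log-uniform over ``orf_range``; TF counts are
    ``round(a * n**b * exp(eps))`` with ``eps ~ N(0, sigma^2)``, clipped to
    ``[0, n_orfs]``. This is the count-level core of the generator, shared
    by the full-layout path and by scaling-only studies.
    """
    lo, hi = orf_range
    n_orfs = np.rint(np.exp(rng.uniform(np.log(lo), np.log(hi), n_genomes))).astype(int)
    eps = rng.normal(0.0, noise_sigma, n_genomes) if noise_sigma > 0 else np.zeros(n_genomes)
    expected = scaling_a * n_orfs.astype(float) ** scaling_b * np.exp(eps)
    n_tfs = np.clip(np.rint(expected).astype(int), 0, n_orfs)
    return n_orfs, n_tfs


def _family_probability_vector(family_freqs: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    names = list(family_freqs)
    probs = [family_freqs[f] for f in names]
    tail = [f for f in _TAIL_PFAMS if f not in family_freqs]
    remainder = 1.0 - sum(probs)
    if tail and remainder > 0:
        names.extend(tail)
        probs.extend([remainder / len(tail)] * len(tail))
    p = np.asarray(probs, dtype=float)
    return names, p / p.sum()


def _geometric_gap(rng: np.random.Generator, mean: float, high: int | None = None) -> int:
    gap = int(rng.geometric(1.0 / max(mean, 1.0))) - 1
    if high is not None:
        gap = min(gap, high)
    return gap


class _Counters:
    def __init__(self) -> None:
        self.catalog = 0
        self.vf = 0

    def next_catalog(self) -> str:
        self.catalog += 1
        return f"CAT{self.catalog:06d}"

    def next_vf(self) -> str:
        self.vf += 1
        return f"VF{self.vf:06d}"


def generate_collection(config: GeneratorConfig) -> tuple[list[GenomeBundle], GroundTruth]:
    """Generate a full genome collection with consistent evidence and truth.

    Identical config (including seed) always yields identical bundles.
    Raises before emitting anything if a fixed ``replicon_length`` cannot
    hold the layout.
    """
    rng = np.random.default_rng(config.seed)
    n_orfs_arr, n_tfs_arr = sample_scaling_points(
        config.n_genomes,
        config.orf_range,
        config.scaling_a,
        config.scaling_b,
        config.noise_sigma,
        rng,
    )
    fam_names, fam_probs = _family_probability_vector(config.family_freqs)
    truth = GroundTruth(
        scaling_a=config.scaling_a,
        scaling_b=config.scaling_b,
        noise_sigma=config.noise_sigma,
    )
    counters = _Counters()
    bundles = []
    for i in range(config.n_genomes):
        gid = f"G{i:04d}"
        division = config.divisions[i % len(config.divisions)]
        bundle, gtruth = _generate_genome(
            gid,
            division,
            int(n_orfs_arr[i]),
            int(n_tfs_arr[i]),
            fam_names,
            fam_probs,
            config,
            rng,
            counters,
        )
        bundles.append(bundle)
        truth.genomes[gid] = gtruth
    return bundles, truth


def _generate_genome(
    gid: str,
    division: str,
    n_orfs: int,
    n_tfs: int,
    fam_names: list[str],
    fam_probs: np.ndarray,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    counters: _Counters,
) -> tuple[GenomeBundle, GenomeTruth]:
    gtruth = GenomeTruth(genome_id=gid, division=division, n_orfs=n_orfs, n_tfs=n_tfs)
    replicon = f"{gid}_chr"

    families = [fam_names[j] for j in rng.choice(len(fam_names), size=n_tfs, p=fam_probs)]
    p_iso = 1.0 - cfg.divergent_frac - cfg.in_tu_frac
    relations = [
        ("divergent", "in_tu", "isolated")[j]
        for j in rng.choice(3, size=n_tfs, p=[cfg.divergent_frac, cfg.in_tu_frac, p_iso])
    ]

    # Plan elements: each element is a list of (role, strand, gap_before)
    # gene slots; gaps between elements always exceed tu_gap_max so TUs
    # never bridge elements. role is "tf", "partner" (divergent neighbor)
    # or "filler".
    def filler_gap() -> int:
        return cfg.tu_gap_max + 1 + _geometric_gap(rng, cfg.filler_gap_mean)

    def intra_gap() -> int:
        return _geometric_gap(rng, cfg.intra_tu_gap_mean, high=cfg.tu_gap_max - 5)

    elements: list[list[tuple[str, str, int]]] = []
    tf_slots: list[tuple[int, int]] = []  # (element index, slot index) per TF
    partner_of: dict[int, tuple[int, int]] = {}  # tf index -> partner slot
    divergent_gap: dict[int, int] = {}
    genes_used = 0
    for t in range(n_tfs):
        rel = relations[t]
        if rel == "divergent":
            gap = _geometric_gap(rng, cfg.divergent_gap_mean)
            element = [("partner", "-", filler_gap()), ("tf", "+", gap)]
            partner_of[t] = (len(elements), 0)
            tf_slots.append((len(elements), 1))
            divergent_gap[t] = gap
            genes_used += 2
        elif rel == "in_tu":
            k = 2 + int(rng.geometric(cfg.operon_geom_p))
            strand = "+" if rng.random() < 0.5 else "-"
            element = [("filler", strand, filler_gap())]
            element += [("filler", strand, intra_gap()) for _ in range(k - 1)]
            slot = 1 + int(rng.integers(0, k - 2)) if k > 2 else 1
            element[slot] = ("tf", strand, element[slot][2])
            tf_slots.append((len(elements), slot))
            genes_used += k
        else:  # isolated: same-strand upstream filler, large gaps both sides
            element = [("filler", "+", filler_gap()), ("tf", "+", filler_gap())]
            tf_slots.append((len(elements), 1))
            genes_used += 2
        elements.append(element)

    n_fillers = max(n_orfs - genes_used, 2)
    filler_elements = [[("filler", "+" if rng.random() < 0.5 else "-", filler_gap())]
                       for _ in range(n_fillers)]
    # Interleave TF elements among plain fillers, keeping fillers at both
    # ends so no TF sits at a replicon edge. Element order is permuted but
    # slot bookkeeping tracks elements by identity.
    order = list(rng.permutation(len(elements)))
    laid = [filler_elements[0]]
    fi = 1
    per_tf = max((n_fillers - 2) // max(len(elements), 1), 0)
    for ei in order:
        laid.append(elements[ei])
        for _ in range(per_tf):
            if fi < n_fillers - 1:
                laid.append(filler_elements[fi])
                fi += 1
    while fi < n_fillers:
        laid.append(filler_elements[fi])
        fi += 1

    # Lay genes on the replicon.
    genes: list[GeneRecord] = []
    slot_gene: dict[tuple[int, int], str] = {}
    element_index = {id(el): i for i, el in enumerate(elements)}
    cursor = 0
    gi = 0
    for el in laid:
        for si, (role, strand, gap) in enumerate(el):
            start = cursor + gap + 1
            end = start + GENE_LENGTH - 1
            gene_id = f"{gid}_g{gi:05d}"
            gi += 1
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    protein_id=gene_id,
                    replicon_id=replicon,
                    start=start,
                    end=end,
                    strand=strand,
                    genome_id=gid,
                )
            )
            if id(el) in element_index:
                slot_gene[(element_index[id(el)], si)] = gene_id
            cursor = end
    if cfg.replicon_length is not None and cursor + cfg.tu_gap_max + 1 > cfg.replicon_length:
        raise ValueError(
            f"{gid}: layout needs {cursor} bp but replicon_length={cfg.replicon_length}"
        )

    tf_ids = [slot_gene[s] for s in tf_slots]
    partner_ids = {t: slot_gene[s] for t, s in partner_of.items()}
    filler_ids = [g.gene_id for g in genes if g.gene_id not in set(tf_ids) | set(partner_ids.values())]

    # Truth flags.
    dom_flags = rng.random(n_tfs) < cfg.domain_detectable_frac
    orth_flags = rng.random(n_tfs) < cfg.ortho_detectable_frac
    vir_flags = rng.random(n_tfs) < cfg.virulence_frac
    enz_flags = rng.random(n_tfs) < cfg.enzyme_frac
    for t, pid in enumerate(tf_ids):
        ec_class = (
            1 + int(rng.choice(6, p=np.asarray(cfg.ec_class_freqs))) if enz_flags[t] else None
        )
        gtruth.tfs[pid] = TruthRecord(
            protein_id=pid,
            family=families[t],
            domain_detectable=bool(dom_flags[t]),
            orthology_detectable=bool(orth_flags[t]),
            relation=relations[t],
            divergent_gap=divergent_gap.get(t),
            ec_class=ec_class,
            virulence=bool(vir_flags[t]),
        )

    bundle = GenomeBundle(
        genome_id=gid,
        division=division,
        genes=genes,
        domain_hits=[],
        sim_vs_catalog_ab=[],
        sim_vs_catalog_ba=[],
        sim_vs_vf_ab=[],
        sim_vs_vf_ba=[],
        ec_rows=[],
    )
    _emit_domain_hits(bundle, gtruth, tf_ids, families, partner_ids, filler_ids, cfg, rng)
    _emit_similarity(bundle, gtruth, tf_ids, partner_ids, filler_ids, cfg, rng, counters)
    _emit_ec(bundle, gtruth, tf_ids, partner_ids, cfg, rng)
    return bundle, gtruth


def _loguniform_e(rng: np.random.Generator, lo_exp: float, hi_exp: float) -> float:
    return float(10.0 ** rng.uniform(lo_exp, hi_exp))


def _emit_domain_hits(
    bundle: GenomeBundle,
    gtruth: GenomeTruth,
    tf_ids: list[str],
    families: list[str],
    partner_ids: dict[int, str],
    filler_ids: list[str],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> None:
    hits = bundle.domain_hits
    boundary_used = False
    for t, pid in enumerate(tf_ids):
        rec = gtruth.tfs[pid]
        if rec.domain_detectable:
            e = 1e-3 if not boundary_used else _loguniform_e(rng, -20, -4)
            boundary_used = True  # exactly-at-threshold decoy, once per genome
            hits.append(
                DomainHit(pid, families[t], "", e, float(rng.uniform(50, 300)), 1, 90)
            )
            if rng.random() < 0.2:  # secondary qualifying-but-worse hit (tie-breaks)
                other = families[(t + 1) % len(families)] if len(families) > 1 else families[t]
                hits.append(
                    DomainHit(pid, other, "", min(e * 100, 1e-3), 40.0, 1, 80)
                )
        elif rng.random() < 0.5:
            # above-threshold decoy: right family, unconvincing E-value
            hits.append(
                DomainHit(pid, families[t], "", float(rng.uniform(2e-3, 1e-1)), 20.0, 1, 60)
            )
    # neighbor-gene annotations (functional signal for enrichment)
    pool = NEIGHBOR_PFAM_POOL
    for t, nid in partner_ids.items():
        fam = families[t]
        if rng.random() < 0.4:
            # stable family -> preferred-neighbor-domain mapping (process-
            # independent, unlike builtin str hashing)
            acc = pool[sum(ord(ch) for ch in fam) % len(pool)]
        else:
            acc = pool[int(rng.integers(0, len(pool)))]
        hits.append(DomainHit(nid, acc, "", _loguniform_e(rng, -12, -4), 80.0, 1, 100))
    # background annotations on fillers, plus one mandatory near-threshold decoy
    for fid in filler_ids[:: max(len(filler_ids) // 20, 1)]:
        acc = pool[int(rng.integers(0, len(pool)))]
        hits.append(DomainHit(fid, acc, "", _loguniform_e(rng, -10, -4), 60.0, 1, 100))
    if filler_ids:
        hits.append(DomainHit(filler_ids[0], "PF00440", "", 2e-3, 15.0, 1, 50))


def _mutual_pair(
    ab: list[SimilarityHit],
    ba: list[SimilarityHit],
    query: str,
    subject: str,
    e: float,
    cov: float,
    bit: float,
) -> None:
    ab.append(SimilarityHit(query, subject, e, bit, cov, cov))
    ba.append(SimilarityHit(subject, query, e, bit, cov, cov))


def _emit_similarity(
    bundle: GenomeBundle,
    gtruth: GenomeTruth,
    tf_ids: list[str],
    partner_ids: dict[int, str],
    filler_ids: list[str],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    counters: _Counters,
) -> None:
    boundary_used = False
    for pid in tf_ids:
        rec = gtruth.tfs[pid]
        if rec.orthology_detectable:
            subject = counters.next_catalog()
            if not boundary_used:
                e, cov = 1e-5, 0.70  # exactly-at-threshold pass, once per genome
                boundary_used = True
            else:
                e = _loguniform_e(rng, -30, -6)
                cov = float(rng.uniform(0.75, 1.0))
            _mutual_pair(
                bundle.sim_vs_catalog_ab,
                bundle.sim_vs_catalog_ba,
                pid,
                subject,
                e,
                cov,
                float(rng.uniform(100, 500)),
            )
    # mandatory decoys straddling the thresholds
    if len(filler_ids) >= 3:
        # mutual best but coverage fails
        _mutual_pair(
            bundle.sim_vs_catalog_ab,
            bundle.sim_vs_catalog_ba,
            filler_ids[1],
            counters.next_catalog(),
            1e-20,
            0.65,
            400.0,
        )
        # good one-directional hit only: no reciprocal row emitted
        bundle.sim_vs_catalog_ab.append(
            SimilarityHit(filler_ids[2], counters.next_catalog(), 1e-18, 350.0, 0.9, 0.9)
        )
        # E-value just above threshold
        _mutual_pair(
            bundle.sim_vs_catalog_ab,
            bundle.sim_vs_catalog_ba,
            filler_ids[0],
            counters.next_catalog(),
            2e-5,
            0.9,
            60.0,
        )

    vir_partner = {
        t: bool(rng.random() < cfg.virulence_frac) for t in partner_ids
    }
    for pid in tf_ids:
        rec = gtruth.tfs[pid]
        if rec.virulence:
            _mutual_pair(
                bundle.sim_vs_vf_ab,
                bundle.sim_vs_vf_ba,
                pid,
                counters.next_vf(),
                _loguniform_e(rng, -30, -6),
                float(rng.uniform(0.75, 1.0)),
                float(rng.uniform(100, 500)),
            )
    for t, nid in partner_ids.items():
        if vir_partner[t]:
            _mutual_pair(
                bundle.sim_vs_vf_ab,
                bundle.sim_vs_vf_ba,
                nid,
                counters.next_vf(),
                _loguniform_e(rng, -30, -6),
                float(rng.uniform(0.75, 1.0)),
                float(rng.uniform(100, 500)),
            )
    if filler_ids:
        # coverage-fail decoy against the virulence reference
        _mutual_pair(
            bundle.sim_vs_vf_ab, bundle.sim_vs_vf_ba, filler_ids[0],
            counters.next_vf(), 1e-15, 0.60, 300.0,
        )


def _random_ec(rng: np.random.Generator, ec_class: int) -> str:
    sub = [str(int(rng.integers(1, 30))) for _ in range(2)]
    serial = str(int(rng.integers(1, 200))) if rng.random() < 0.8 else "-"
    return f"{ec_class}.{sub[0]}.{sub[1]}.{serial}"


def _emit_ec(
    bundle: GenomeBundle,
    gtruth: GenomeTruth,
    tf_ids: list[str],
    partner_ids: dict[int, str],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> None:
    for pid in tf_ids:
        rec = gtruth.tfs[pid]
        if rec.ec_class is not None:
            bundle.ec_rows.append((pid, _random_ec(rng, rec.ec_class)))
    for t, nid in partner_ids.items():
        if rng.random() < cfg.enzyme_frac * 2:
            cls = 1 + int(rng.choice(6, p=np.asarray(cfg.ec_class_freqs)))
            bundle.ec_rows.append((nid, _random_ec(rng, cls)))
    # mandatory malformed decoy row (invalid class) exercising rejection
    if bundle.genes:
        bundle.ec_rows.append((bundle.genes[0].gene_id, "9.1.1.1"))


# ---------------------------------------------------------------------------
# Catalog generator


def generate_catalog(
    n: int = 668,
    seed: int = 0,
    family_freqs: Mapping[str, float] | None = None,
    role_freqs: Mapping[str, float] | None = None,
    domain_count_freqs: Mapping[int, float] | None = None,
) -> list[CatalogEntry]:
    """Draw a synthetic curated catalog with the collection's distributions.

    Defaults: family frequencies as in the collection generator, roles
    29.4% repressor / 23.9% dual / 18.1% activator / 28.6% undefined,
    domain counts 41.77% monodomain / 50.22% two-domain / 6.03% three and a
    small >= 4 tail. Each entry carries 1-3 evidence codes drawn uniformly
    from the 17 recognised codes (per-TF evidence multiplicity is not
    pinned down by the curation statistics).
    """
    rng = np.random.default_rng(seed)
    fam_names, fam_probs = _family_probability_vector(family_freqs or DEFAULT_FAMILY_FREQS)
    roles = list((role_freqs or _ROLE_FREQS).items())
    role_p = np.asarray([v for _, v in roles], dtype=float)
    if abs(role_p.sum() - 1.0) > 1e-6:
        raise ValueError("role frequencies must sum to 1")
    role_p = role_p / role_p.sum()
    dcf = domain_count_freqs or _DOMAIN_COUNT_FREQS
    counts = list(dcf)
    count_p = np.asarray([dcf[c] for c in counts], dtype=float)
    if abs(count_p.sum() - 1.0) > 1e-2:
        raise ValueError("domain-count frequencies must sum to ~1")
    count_p = count_p / count_p.sum()
    codes = sorted(EVIDENCE_STRENGTH)
    entries = []
    for i in range(n):
        family = fam_names[int(rng.choice(len(fam_names), p=fam_probs))]
        n_dom = counts[int(rng.choice(len(counts), p=count_p))]
        extra = [
            NEIGHBOR_PFAM_POOL[int(rng.integers(0, len(NEIGHBOR_PFAM_POOL)))]
            for _ in range(n_dom - 1)
        ]
        role = roles[int(rng.choice(len(roles), p=role_p))][0]
        n_ev = int(rng.integers(1, 4))
        evidence = tuple(
            EvidenceCode(code=c, strength=classify_evidence(c))
            for c in rng.choice(codes, size=n_ev, replace=False)
        )
        entries.append(
            CatalogEntry(
                tf_id=f"TF{i:04d}",
                species=f"species_{int(rng.integers(0, 81)):02d}",
                family_pfam=family,
                all_pfams=tuple([family] + extra),
                role=role,
                evidence=evidence,
            )
        )
    return entries


# ---------------------------------------------------------------------------
# Division panels for scaling-model selection studies


def generate_division_panel(
    division_models: Mapping[str, str],
    n_genomes: int = 50,
    seed: int = 0,
    orf_range: tuple[int, int] = (500, 12000),
    power_params: tuple[float, float, float] = (0.0007, 1.5283, 0.2),
    linear_params: tuple[float, float, float] = (5.0, 0.03, 20.0),
) -> dict[str, list[tuple[int, int]]]:
    """Generate labelled per-division census panels under declared models.

    ``division_models`` maps division name -> ``power`` or ``linear``.
    Power divisions follow ``a * x**b`` with multiplicative log-normal
    noise ``(a, b, sigma) = power_params``; linear divisions follow
    ``c + m*x`` with additive Gaussian noise ``(c, m, sd) = linear_params``.
    """
    rng = np.random.default_rng(seed)
    panels: dict[str, list[tuple[int, int]]] = {}
    for division in division_models:
        model = division_models[division]
        if model == "power":
            a, b, sigma = power_params
            x, y = sample_scaling_points(n_genomes, orf_range, a, b, sigma, rng)
        elif model == "linear":
            c, m, sd = linear_params
            lo, hi = orf_range
            x = np.rint(np.exp(rng.uniform(np.log(lo), np.log(hi), n_genomes))).astype(int)
            y = np.clip(np.rint(c + m * x + rng.normal(0, sd, n_genomes)).astype(int), 0, x)
        else:
            raise ValueError(f"division {division}: unknown model {model!r}")
        panels[division] = list(zip(x.tolist(), y.tolist()))
    return panels


# ---------------------------------------------------------------------------
# pfam2go emission and on-disk fixture bundles

_GO_TERMS = {
    "PF00005": ("GO:0016887", "ATP hydrolysis activity"),
    "PF00512": ("GO:0000155", "phosphorelay sensor kinase activity"),
    "PF07690": ("GO:0022857", "transmembrane transporter activity"),
    "PF00155": ("GO:0008483", "transaminase activity"),
    "PF00083": ("GO:0015144", "carbohydrate transmembrane transporter activity"),
    "PF01547": ("GO:0043190", "ATP-binding cassette transporter complex"),
    "PF00118": ("GO:0140662", "ATP-dependent protein folding chaperone"),
    "PF00478": ("GO:0003938", "IMP dehydrogenase activity"),
}


def pfam2go_text() -> str:
    """Synthetic pfam2go flat file covering the neighbor-domain pool and
    a DNA-binding line per top TF family."""
    lines = ["!synthetic pfam2go mapping (generated fixture)"]
    for acc, (go_id, term) in sorted(_GO_TERMS.items()):
        lines.append(f"Pfam:{acc} {acc}_dom > GO:{term} ; {go_id}")
    for acc in DEFAULT_FAMILY_FREQS:
        lines.append(f"Pfam:{acc} {acc}_dom > GO:DNA binding ; GO:0003677")
    return "\n".join(lines) + "\n"


def write_collection(
    bundles: Sequence[GenomeBundle],
    truth: GroundTruth,
    outdir,
    catalog_entries: Sequence[CatalogEntry] | None = None,
) -> None:
    """Write a collection to disk in exactly the formats the pipeline reads.

    Layout: ``genomes/<gid>.{gff3,domains.tsv,...}`` per genome plus
    collection-level ``tf_pfams.txt``, ``pfam2go.txt``, ``divisions.tsv``,
    ``catalog.tsv`` and ``truth.json``.
    """
    from .catalog import write_catalog_tsv
    from .formats_io import write_similarity_hits_tsv, write_domain_hits_tsv

    outdir = Path(outdir)
    gdir = outdir / "genomes"
    gdir.mkdir(parents=True, exist_ok=True)
    for b in bundles:
        (gdir / f"{b.genome_id}.gff3").write_text(b.gff3_text())
        write_domain_hits_tsv(b.domain_hits, gdir / f"{b.genome_id}.domains.tsv")
        write_similarity_hits_tsv(b.sim_vs_catalog_ab, gdir / f"{b.genome_id}.cat_ab.tsv")
        write_similarity_hits_tsv(b.sim_vs_catalog_ba, gdir / f"{b.genome_id}.cat_ba.tsv")
        write_similarity_hits_tsv(b.sim_vs_vf_ab, gdir / f"{b.genome_id}.vf_ab.tsv")
        write_similarity_hits_tsv(b.sim_vs_vf_ba, gdir / f"{b.genome_id}.vf_ba.tsv")
        ec_lines = ["protein_id\tec"] + [f"{pid}\t{ec}" for pid, ec in b.ec_rows]
        (gdir / f"{b.genome_id}.ec.tsv").write_text("\n".join(ec_lines) + "\n")
    (outdir / "tf_pfams.txt").write_text("\n".join(TF_PFAM_LIST) + "\n")
    (outdir / "pfam2go.txt").write_text(pfam2go_text())
    div_lines = ["genome_id\tdivision"] + [f"{b.genome_id}\t{b.division}" for b in bundles]
    (outdir / "divisions.tsv").write_text("\n".join(div_lines) + "\n")
    if catalog_entries is not None:
        write_catalog_tsv(catalog_entries, outdir / "catalog.tsv")
    (outdir / "truth.json").write_text(json.dumps(asdict(truth), indent=1, sort_keys=True))
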