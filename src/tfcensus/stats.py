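"""Enrichment statistics and TF-abundance scaling-law analysis.

Neighbor-PFAM enrichment: for each domain family observed among a TF
family's divergent neighbors, a one-tailed (upper-tail, enrichment-only)
Fisher exact test compares its foreground rate against a background gene
set, p-values are adjusted with the Benjamini-Hochberg step-up procedure,
and significant families are annotated with their pfam2go GO terms.

Scaling: the number of TFs a genome encodes grows with its gene count; the
relationship is modelled both as a power law ``y = a * x**b`` (fit by
ordinary least squares on the log-log scale — closed-form and the
convention for scaling exponents, though it can differ from a nonlinear fit
in the third decimal) and as a straight line ``y = a + b*x`` (OLS on the
natural scale). Per-division model selection picks whichever fit explains
more variance on its own scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "ScalingFit",
    "fisher_one_tailed",
    "bh_adjust",
    "enrich_neighbor_pfams",
    "fit_scaling",
    "select_model_per_division",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One PFAM's enrichment test among a family's neighbor genes.

    ``a`` counts foreground (neighbor) genes carrying the PFAM, ``b`` those
    without it; ``c``/``d`` are the same split over the rest of the
    background, so ``a+b+c+d`` is the number of genes tested.
    """

    family_pfam: str
    neighbor_pfam: str
    a: int
    b: int
    c: int
    d: int
    p_value: float
    fdr: float
    go_terms: tuple[tuple[str, str], ...] = ()
    significant: bool = False


@dataclass(frozen=True)
class ScalingFit:
    """A fitted abundance model; for ``power`` y = a*x**b, for ``linear``
    y = a + b*x. ``r2`` and ``pearson_r`` are computed on the model's own
    scale (log-log for power, natural for linear)."""

    model: str
    a: float
    b: float
    r2: float
    pearson_r: float
    n: int


def fisher_one_tailed(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail Fisher exact p-value P[X >= a] for a 2x2 table.

    The enrichment direction only; an all-zero table has no evidence and
    returns p = 1.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0:
            raise ValueError(f"count {name} is negative")
    if a + b + c + d == 0:
        return 1.0
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def enrich_neighbor_pfams(
    family: str,
    neighbor_domains: Mapping[str, set[str] | frozenset[str]],
    background_domains: Mapping[str, set[str] | frozenset[str]],
    pfam2go: Mapping[str, Sequence[tuple[str, str]]] | None = None,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every PFAM seen in the foreground for enrichment over background.

    ``neighbor_domains`` maps each foreground (neighbor) gene to its PFAM
    set; ``background_domains`` must be a superset of genes. One Fisher
    test per foreground PFAM, BH-adjusted jointly; results are sorted by
    p-value and flagged significant iff ``fdr <= alpha``. GO annotations
    come from a pfam2go mapping (accession -> [(go_id, go_term), ...]).
    """
    fg = set(neighbor_domains)
    bg = set(background_domains)
    if not fg <= bg:
        missing = sorted(fg - bg)[:5]
        raise ValueError(f"foreground genes missing from background, e.g. {missing}")
    pfam2go = pfam2go or {}
    tested = sorted({pf for doms in neighbor_domains.values() for pf in doms})
    n_fg, n_bg_only = len(fg), len(bg) - len(fg)
    results = []
    for pf in tested:
        a = sum(1 for g in fg if pf in neighbor_domains[g])
        c = sum(1 for g in bg - fg if pf in background_domains[g])
        results.append(
            (pf, a, n_fg - a, c, n_bg_only - c, fisher_one_tailed(a, n_fg - a, c, n_bg_only - c))
        )
    fdrs = bh_adjust([r[5] for r in results]) if results else []
    out = [
        EnrichmentResult(
            family_pfam=family,
            neighbor_pfam=pf,
            a=a,
            b=b,
            c=c,
            d=d,
            p_value=p,
            fdr=fdr,
            go_terms=tuple(pfam2go.get(pf, ())),
            significant=fdr <= alpha,
        )
        for (pf, a, b, c, d, p), fdr in zip(results, fdrs)
    ]
    out.sort(key=lambda r: (r.p_value, r.neighbor_pfam))
    return out


def _fit(x: np.ndarray, y: np.ndarray, model: str) -> ScalingFit:
    res = sps.linregress(x, y)
    if model == "power":
        a, b = float(np.exp(res.intercept)), float(res.slope)
    else:
        a, b = float(res.intercept), float(res.slope)
    return ScalingFit(
        model=model,
        a=a,
        b=b,
        r2=float(res.rvalue**2),
        pearson_r=float(res.rvalue),
        n=int(x.size),
    )


def fit_scaling(points: Iterable[tuple[float, float]]) -> tuple[ScalingFit, ScalingFit]:
    """Fit both the power-law and the linear abundance model.

    Points are (genome size in ORFs, TF count). Genomes with zero TFs
    cannot enter the log-log fit and are excluded from it with a warning
    (the linear fit keeps them). Needs at least 3 usable points per model.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (n_orfs, n_tfs) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(x <= 0):
        raise ValueError("genome sizes must be positive")
    positive = y > 0
    if not np.all(positive):
        warnings.warn(
            f"excluding {int((~positive).sum())} zero-TF genomes from the power fit"
        )
    if positive.sum() < 3:
        raise ValueError("fewer than 3 positive points for the power fit")
    power = _fit(np.log(x[positive]), np.log(y[positive]), "power")
    linear = _fit(x, y, "linear")
    return power, linear


def select_model_per_division(
    census_by_division: Mapping[str, Iterable[tuple[float, float]]],
    min_genomes: int = 10,
    margin: float = 0.01,
) -> dict[str, str]:
    """Pick power vs linear per division by r2 on each model's own scale.

    Divisions with fewer than ``min_genomes`` genomes are skipped with a
    warning; an r2 gap below ``margin`` is reported as ``ambiguous``.
    Accepts (n_orfs, n_tfs) pairs or objects with those attributes.
    """
    choices: dict[str, str] = {}
    for division, rows in census_by_division.items():
        pts = [
            (row.n_orfs, row.n_tfs) if hasattr(row, "n_orfs") else tuple(row) for row in rows
        ]
        if len(pts) < min_genomes:
            warnings.warn(
                f"division {division}: only {len(pts)} genomes (< {min_genomes}); skipped"
            )
            continue
        power, linear = fit_scaling(pts)
        if abs(power.r2 - linear.r2) < margin:
            choices[division] = "ambiguous"
        else:
            choices[division] = "power" if power.r2 > linear.r2 else "linear"
    return choices
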