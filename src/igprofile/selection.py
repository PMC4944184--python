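"""Selection-pressure quantification from mutation placement (CDR vs FWR).

Affinity maturation leaves a statistical footprint in where somatic
hypermutation accumulates: purifying (negative) selection depletes
mutations — replacement mutations especially — from regions where change is
costly, while antigen-driven (positive) selection enriches them in the
antigen-contacting CDRs. Following the expected-versus-observed framework of
BASELINe, each sequence's mutation placement is compared to a null in which
every analysable V-region nucleotide is equally likely to mutate (optionally
re-weighted by AID hotspot mutability), and departure is scored with an
exact binomial test:

    observed ~ Binomial(total, f_region)  under no selection,

where ``f_region`` is the expected fraction of mutations falling in the
region class (CDR = CDR1+CDR2, FWR = FR1+FR2+FR3; CDR3 is excluded because
junctional nucleotides have no germline counterpart). Two-sided p-values
double the smaller exact tail and cap at 1. A sequence with
observed/total below ``f_region`` is under *negative* selection for that
region class, above it *positive*, exactly at it *none*.

The full BASELINe posterior machinery (selection strength Sigma, focused
test, targeting priors) is intentionally not reproduced; the two-region
exact binomial keeps the math fully specified and testable. Sequences with
zero V-region mutations carry no placement information and are withheld
from cohort fractions.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .germline import GermlineGene, region_of
from .simulate import hotspot_mask

__all__ = [
    "SelectionResult",
    "CDR_CLASS",
    "FWR_CLASS",
    "expected_region_fraction",
    "selection_test",
    "sequence_selection",
    "cohort_selection_summary",
    "compare_mutation_rates",
]

CDR_CLASS = ("CDR1", "CDR2")
FWR_CLASS = ("FR1", "FR2", "FR3")
_ANALYSIS_NT = 3 * 104   # IMGT codons 1..104 of the V gene


@dataclass(frozen=True)
class SelectionResult:
    """Direction and significance of selection for one sequence and region class."""

    seq_id: str
    region_class: str            # "CDR" or "FWR"
    observed: int
    total: int
    expected_fraction: float
    direction: str               # "negative" | "positive" | "none"
    p_value: float

    def __post_init__(self):
        if not 0 <= self.observed <= self.total:
            raise ValueError("observed must be in [0, total]")
        if not 0.0 < self.expected_fraction < 1.0:
            raise ValueError("expected_fraction must be in (0,1)")


def expected_region_fraction(v_gene: GermlineGene, region_class: str,
                             mode: str = "uniform",
                             hotspot_multiplier: float = 5.0) -> float:
    """Null probability that a V-region mutation falls in CDR (or FWR).

    ``uniform`` mode: the fraction of analysable V-region nucleotides (IMGT
    codons 1-104, CDR3 excluded) lying in the region class. ``hotspot_weighted``
    mode: the same fraction with each nucleotide inside a WRC/GYW motif of the
    germline sequence weighted by ``hotspot_multiplier``, matching the
    simulator's targeting model.
    """
    if region_class not in ("CDR", "FWR"):
        raise ValueError("region_class must be 'CDR' or 'FWR'")
    if mode not in ("uniform", "hotspot_weighted"):
        raise ValueError("mode must be 'uniform' or 'hotspot_weighted'")
    limit = min(_ANALYSIS_NT, 3 * v_gene.n_codons)
    regions = CDR_CLASS if region_class == "CDR" else FWR_CLASS
    if mode == "uniform":
        weights = np.ones(limit)
    else:
        weights = np.ones(limit)
        hot = hotspot_mask(v_gene.nt_sequence, limit)
        weights[hot] = hotspot_multiplier
    in_class = np.array([region_of(t // 3 + 1) in regions
                         for t in range(limit)])
    if not in_class.any() or in_class.all():
        raise ValueError(
            f"{v_gene.name}: gene too short to contain both region classes")
    return float(weights[in_class].sum() / weights.sum())


def selection_test(observed: int, total: int, expected_fraction: float,
                   seq_id: str = "", region_class: str = "CDR") -> SelectionResult:
    """Exact two-sided binomial test of mutation placement for one sequence.

    The p-value doubles the smaller of the two exact tails
    ``P(X <= observed)`` and ``P(X >= observed)`` and caps at 1.
    Requires ``total >= 1``; zero-mutation sequences carry no information and
    must be withheld upstream (see :func:`sequence_selection`).
    """
    if total < 1:
        raise ValueError("selection_test requires total >= 1 mutation")
    lower = float(stats.binom.cdf(observed, total, expected_fraction))
    upper = float(stats.binom.sf(observed - 1, total, expected_fraction))
    p = min(1.0, 2.0 * min(lower, upper))
    rate = observed / total
    if rate < expected_fraction:
        direction = "negative"
    elif rate > expected_fraction:
        direction = "positive"
    else:
        direction = "none"
    return SelectionResult(seq_id=seq_id, region_class=region_class,
                           observed=observed, total=total,
                           expected_fraction=expected_fraction,
                           direction=direction, p_value=p)


def sequence_selection(annotated, v_gene: GermlineGene,
                       mode: str = "uniform",
                       hotspot_multiplier: float = 5.0) -> dict:
    """Run the CDR and FWR selection tests for one annotated sequence.

    Returns ``{"CDR": SelectionResult | None, "FWR": ...}``; ``None`` marks a
    withheld result (zero total mutations).
    """
    total = annotated.mutations_in(CDR_CLASS) + annotated.mutations_in(FWR_CLASS)
    out: dict[str, Optional[SelectionResult]] = {}
    for region_class, regions in (("CDR", CDR_CLASS), ("FWR", FWR_CLASS)):
        if total == 0:
            out[region_class] = None
            continue
        frac = expected_region_fraction(v_gene, region_class, mode,
                                        hotspot_multiplier)
        out[region_class] = selection_test(
            annotated.mutations_in(regions), total, frac,
            seq_id=annotated.seq_id, region_class=region_class)
    return out


def cohort_selection_summary(results: Sequence[Optional[SelectionResult]],
                             alpha: float = 0.05) -> dict:
    """Cohort fractions of sequences under negative/positive selection.

    ``results`` are SelectionResults of one region class (``None`` entries =
    withheld, excluded from the denominator). Reports direction fractions
    regardless of significance plus the fractions significant at ``alpha``.
    """
    informative = [r for r in results if r is not None]
    n = len(informative)
    classes = {r.region_class for r in informative}
    if len(classes) > 1:
        raise ValueError(f"results mix region classes: {sorted(classes)}")
    summary = {"n": n, "n_withheld": len(results) - n, "alpha": alpha}
    if n == 0:
        summary.update(negative_fraction=None, positive_fraction=None,
                       negative_significant_fraction=None,
                       positive_significant_fraction=None, undefined=True)
        return summary
    neg = [r for r in informative if r.direction == "negative"]
    pos = [r for r in informative if r.direction == "positive"]
    summary.update(
        undefined=False,
        negative_fraction=len(neg) / n,
        positive_fraction=len(pos) / n,
        negative_significant_fraction=sum(r.p_value < alpha for r in neg) / n,
        positive_significant_fraction=sum(r.p_value < alpha for r in pos) / n,
    )
    return summary


def compare_mutation_rates(cohort_a: Sequence[float],
                           cohort_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of per-sequence mutation counts.

    Exact enumeration for small samples (either cohort < 8), normal
    approximation with tie correction otherwise. Returns ``(U, p)``.
    """
    a = np.asarray(cohort_a, dtype=float)
    b = np.asarray(cohort_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both cohorts must be nonempty")
    method = "exact" if min(a.size, b.size) < 8 and not _has_ties(a, b) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return np.unique(pooled).size < pooled.size
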