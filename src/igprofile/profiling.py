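"""Cohort-level repertoire profiling.

Summaries of an annotated IgG repertoire that mirror the descriptive
statistics used for cutaneous B-cell repertoires: IgG1-4 subclass
distribution, VH family usage, CDR3 length spectratype with a
D'Agostino-Pearson omnibus normality test (a bimodal CDR3 length
distribution rejects normality), per-position non-silent mutation
frequencies with an SHM "hotspot" call at >35% of sequences, and the
concordance (Jaccard overlap) between SHM hotspots and positions predicted
to contact antigen in >25% of sequences.

The normality test is implemented from the omnibus formulas (skewness
transform of D'Agostino; kurtosis transform of Anscombe & Glynn;
K^2 = Z1^2 + Z2^2 ~ chi-square with 2 df) rather than delegated, so it can
be cross-checked against an independent reference implementation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotatedSequence

__all__ = [
    "CohortProfile",
    "BindingConcordance",
    "subclass_distribution",
    "vh_family_usage",
    "dagostino_pearson",
    "positional_mutation_frequency",
    "binding_concordance",
    "build_cohort_profile",
    "HOTSPOT_THRESHOLD",
    "BINDING_THRESHOLD",
]

SUBCLASSES = ("IgG1", "IgG2", "IgG3", "IgG4")
HOTSPOT_THRESHOLD = 0.35
BINDING_THRESHOLD = 0.25


def subclass_distribution(records: Sequence[AnnotatedSequence]) -> dict:
    """Proportion of each IgG subclass among assigned calls.

    Unassigned records are excluded from the proportions and reported
    separately under ``n_unassigned``.
    """
    calls = [r.subclass for r in records]
    assigned = [c for c in calls if c in SUBCLASSES]
    n = len(assigned)
    proportions = {} if n == 0 else {
        sub: assigned.count(sub) / n for sub in SUBCLASSES
        if assigned.count(sub) > 0}
    return {"proportions": proportions, "n_assigned": n,
            "n_unassigned": len(calls) - n}


def vh_family_usage(records: Sequence[AnnotatedSequence]) -> dict:
    """Proportion of each VH family (VH1..VH7) parsed from the V call."""
    families = []
    skipped = 0
    for r in records:
        fam = getattr(r, "vh_family", None)
        if fam is None:
            skipped += 1
        else:
            families.append(int(fam))
    n = len(families)
    proportions = {} if n == 0 else {
        f"VH{f}": families.count(f) / n for f in sorted(set(families))}
    return {"proportions": proportions, "n": n, "n_skipped": skipped}


def dagostino_pearson(sample: Sequence[float]) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus normality test.

    Combines the standard-normal transforms of sample skewness (D'Agostino
    1970) and sample kurtosis (Anscombe & Glynn 1983) into
    K^2 = Z1^2 + Z2^2, referred to a chi-square distribution with 2 df.
    Requires n >= 20 (the kurtosis transform is unreliable below) and
    positive sample variance. Returns ``(K2, p)``.
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 20:
        raise ValueError(f"D'Agostino-Pearson test requires n >= 20, got {n}")
    mu = x.mean()
    m2 = ((x - mu) ** 2).mean()
    if m2 <= 0:
        raise ValueError("sample variance is zero")
    m3 = ((x - mu) ** 3).mean()
    m4 = ((x - mu) ** 4).mean()
    g1 = m3 / m2 ** 1.5
    b2 = m4 / m2 ** 2

    # --- skewness transform (D'Agostino) ---
    y = g1 * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = (3.0 * (n ** 2 + 27 * n - 70) * (n + 1) * (n + 3)
             / ((n - 2) * (n + 5) * (n + 7) * (n + 9)))
    w2 = -1.0 + math.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / math.sqrt(0.5 * math.log(w2))
    alpha = math.sqrt(2.0 / (w2 - 1.0))
    if y == 0:
        z1 = 0.0
    else:
        z1 = delta * math.log(y / alpha + math.sqrt((y / alpha) ** 2 + 1.0))

    # --- kurtosis transform (Anscombe & Glynn) ---
    e_b2 = 3.0 * (n - 1) / (n + 1)
    var_b2 = (24.0 * n * (n - 2) * (n - 3)) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    xk = (b2 - e_b2) / math.sqrt(var_b2)
    sqrt_beta1 = (6.0 * (n ** 2 - 5 * n + 2) / ((n + 7) * (n + 9))
                  * math.sqrt(6.0 * (n + 3) * (n + 5) / (n * (n - 2) * (n - 3))))
    a = 6.0 + (8.0 / sqrt_beta1) * (2.0 / sqrt_beta1
                                    + math.sqrt(1.0 + 4.0 / sqrt_beta1 ** 2))
    term = (1.0 - 2.0 / a) / (1.0 + xk * math.sqrt(2.0 / (a - 4.0)))
    z2 = ((1.0 - 2.0 / (9.0 * a)) - np.sign(term) * abs(term) ** (1.0 / 3.0)) \
        / math.sqrt(2.0 / (9.0 * a))

    k2 = z1 * z1 + z2 * z2
    from scipy.stats import chi2
    p = float(chi2.sf(k2, df=2))
    return float(k2), p


def positional_mutation_frequency(records: Sequence[AnnotatedSequence],
                                  threshold: float = HOTSPOT_THRESHOLD):
    """Per-IMGT-position non-silent mutation frequency and hotspot set.

    For each IMGT codon position, the fraction of sequences carrying at
    least one non-silent substitution there; hotspots are positions with
    frequency strictly above ``threshold`` (default 0.35).
    """
    n = len(records)
    freq: dict[int, float] = {}
    if n:
        counts: dict[int, int] = {}
        for rec in records:
            for pos in rec.nonsilent_positions:
                counts[pos] = counts.get(pos, 0) + 1
        freq = {pos: c / n for pos, c in sorted(counts.items())}
    hotspots = {pos for pos, f in freq.items() if f > threshold}
    return freq, hotspots


def _count_runs(positions: set) -> int:
    """Number of maximal runs of consecutive integer positions."""
    if not positions:
        return 0
    ordered = sorted(positions)
    return 1 + sum(1 for a, b in zip(ordered, ordered[1:]) if b - a > 1)


@dataclass
class BindingConcordance:
    """Overlap between SHM hotspots and predicted antigen-binding positions."""

    binding_frequency: dict
    flagged_positions: set
    hotspot_positions: set
    jaccard: float
    n_binding_clusters: int


def binding_concordance(hotspot_positions: set,
                        binding_table: pd.DataFrame,
                        cohort_seq_ids: Optional[Sequence[str]] = None,
                        binding_threshold: float = BINDING_THRESHOLD
                        ) -> BindingConcordance:
    """Score concordance between SHM hotspots and predicted binding residues.

    ``binding_table`` has columns ``sequence_id, imgt_position,
    predicted_binding`` (IMGT codon positions). A position is flagged when
    predicted binding in a fraction of sequences strictly above
    ``binding_threshold`` (default 0.25). The overlap score is the Jaccard
    index between the flagged set and the hotspot set; the clustering
    summary counts maximal runs of consecutive flagged positions.
    """
    required = {"sequence_id", "imgt_position", "predicted_binding"}
    if not required.issubset(binding_table.columns):
        raise ValueError(f"binding table must have columns {sorted(required)}")
    table_ids = set(binding_table["sequence_id"])
    if cohort_seq_ids is not None:
        cohort = set(cohort_seq_ids)
        strays = sorted(table_ids - cohort)
        if strays:
            raise ValueError(
                "binding table sequence ids not in cohort: "
                + ", ".join(strays[:10]))
        n_seq = len(cohort & table_ids)
    else:
        n_seq = len(table_ids)
    if n_seq == 0:
        raise ValueError("binding table contains no usable sequences")
    hits = (binding_table[binding_table["predicted_binding"].astype(bool)]
            .groupby("imgt_position")["sequence_id"].nunique())
    binding_freq = {int(pos): cnt / n_seq for pos, cnt in hits.items()}
    flagged = {pos for pos, f in binding_freq.items() if f > binding_threshold}
    union = flagged | hotspot_positions
    jaccard = (len(flagged & hotspot_positions) / len(union)) if union else 0.0
    return BindingConcordance(binding_frequency=binding_freq,
                              flagged_positions=flagged,
                              hotspot_positions=set(hotspot_positions),
                              jaccard=jaccard,
                              n_binding_clusters=_count_runs(flagged))


@dataclass
class CohortProfile:
    """Bundle of cohort-level summaries for one sample cohort."""

    cohort_id: str
    subclass: dict
    vh_families: dict
    cdr3_lengths: list
    cdr3_normality: Optional[tuple]       # (K2, p) or None when n < 20
    positional_nonsilent_frequency: dict
    hotspot_positions: set
    binding: Optional[BindingConcordance] = None
    n_sequences: int = 0

    def to_dict(self) -> dict:
        out = {
            "cohort_id": self.cohort_id,
            "n_sequences": self.n_sequences,
            "subclass": self.subclass,
            "vh_families": self.vh_families,
            "cdr3_lengths": list(map(int, self.cdr3_lengths)),
            "cdr3_normality": (None if self.cdr3_normality is None
                               else {"k2": self.cdr3_normality[0],
                                     "p": self.cdr3_normality[1]}),
            "positional_nonsilent_frequency":
                {str(k): v for k, v in self.positional_nonsilent_frequency.items()},
            "hotspot_positions": sorted(self.hotspot_positions),
        }
        if self.binding is not None:
            out["binding"] = {
                "flagged_positions": sorted(self.binding.flagged_positions),
                "jaccard": self.binding.jaccard,
                "n_binding_clusters": self.binding.n_binding_clusters,
            }
        return out


def build_cohort_profile(cohort_id: str,
                         records: Sequence[AnnotatedSequence],
                         binding_table: Optional[pd.DataFrame] = None,
                         hotspot_threshold: float = HOTSPOT_THRESHOLD,
                         binding_threshold: float = BINDING_THRESHOLD
                         ) -> CohortProfile:
    """Assemble the full cohort profile from annotated records.

    CDR3 lengths enter the spectratype only for productive sequences with an
    extracted CDR3; the normality test is run when at least 20 lengths with
    positive variance are available.
    """
    lengths = [r.cdr3_length for r in records
               if r.productive and r.cdr3_length is not None]
    normality = None
    if len(lengths) >= 20 and np.var(lengths) > 0:
        normality = dagostino_pearson(lengths)
    freq, hotspots = positional_mutation_frequency(records, hotspot_threshold)
    binding = None
    if binding_table is not None:
        binding = binding_concordance(hotspots, binding_table,
                                      [r.seq_id for r in records],
                                      binding_threshold)
    return CohortProfile(
        cohort_id=cohort_id,
        subclass=subclass_distribution(records),
        vh_families=vh_family_usage(records),
        cdr3_lengths=lengths,
        cdr3_normality=normality,
        positional_nonsilent_frequency=freq,
        hotspot_positions=hotspots,
        binding=binding,
        n_sequences=len(records))
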