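"""Candidate selection, energy ranking, top-N evaluation and enrichment.

The evaluation protocol mirrors how tissue-aware interaction prediction is
benchmarked against an experimentally validated target set: candidate
mRNAs (either the full expressed "initial" universe or the subset
specifically expressed in one tissue) are ranked by interaction energy
(MinEnergy or SumEnergy, most negative first), and the cumulative number
of validated targets among the top n predictions is traced for
n = 1..n_max, together with the expectation under random guessing
(hypergeometric mean, n*K/M).  Enrichment of validated targets inside a
tissue-specific candidate subset relative to the remaining candidates is
tested with a one-tailed Fisher's exact test, Bonferroni-corrected over
the tissues examined.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .errors import UsageError
from .interactions import PairScore
from .specificity import TissueGeneSets

__all__ = [
    "CandidateSet",
    "EvaluationCurve",
    "EnrichmentResult",
    "select_candidates",
    "rank_candidates",
    "tp_curve",
    "random_baseline",
    "hypergeom_tail_p",
    "fisher_enrichment",
    "bonferroni",
    "adjust_enrichment",
    "write_evaluation_tsv",
    "write_enrichment_tsv",
]

logger = logging.getLogger(__name__)

RANKING_METHODS = ("MinEnergy", "SumEnergy")


@dataclass(frozen=True)
class CandidateSet:
    """An ordered set of candidate mRNA IDs with a label.

    The label is ``"initial"`` for the full expressed universe or
    ``"tissue:<name>"`` for a tissue-specific subset.
    """

    label: str
    mrna_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.mrna_ids)) != len(self.mrna_ids):
            raise UsageError(f"candidate set {self.label}: duplicate mRNA IDs")

    def __len__(self) -> int:
        return len(self.mrna_ids)


@dataclass(frozen=True)
class EvaluationCurve:
    """Cumulative true positives at each prediction depth, with baseline.

    ``baseline[i]`` is the expected TP count when drawing ``depths[i]``
    candidates at random from the ``n_candidates``-sized universe that
    contains ``n_truth`` validated targets.
    """

    depths: np.ndarray
    tp_counts: np.ndarray
    baseline: np.ndarray
    n_candidates: int
    n_truth: int


@dataclass(frozen=True)
class EnrichmentResult:
    """One-tailed Fisher's exact test of truth enrichment in a subset.

    The 2x2 table rows are (subset, initial minus subset) -- disjoint by
    construction, giving a valid independence structure -- and columns are
    (validated target, not).  ``odds_ratio`` is the sample odds ratio
    a*d / (b*c), infinite when a denominator cell is zero.
    """

    tissue: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    p_adjusted: float | None = None


def select_candidates(
    initial: CandidateSet,
    tissue_sets: TissueGeneSets,
    tissue: str,
) -> CandidateSet:
    """Intersect the initial candidates with a tissue's specific genes.

    Order is inherited from the initial set.
    """
    if tissue not in tissue_sets:
        raise UsageError(
            f"unknown tissue {tissue!r}; available: {tissue_sets.tissues}"
        )
    members = tissue_sets[tissue]
    return CandidateSet(
        label=f"tissue:{tissue}",
        mrna_ids=tuple(m for m in initial.mrna_ids if m in members),
    )


def rank_candidates(
    scores: Iterable[PairScore],
    candidates: CandidateSet,
    method: str = "SumEnergy",
) -> list[str]:
    """Rank candidate mRNAs by interaction energy, most negative first.

    Candidates without a pair score are treated as no-site pairs
    (SumEnergy 0, MinEnergy +inf) and rank last.  Ties break by MinEnergy,
    then lexicographic mRNA ID, so rankings are fully deterministic.
    """
    if method not in RANKING_METHODS:
        raise UsageError(f"method must be one of {RANKING_METHODS}, got {method!r}")
    by_mrna: dict[str, PairScore] = {}
    for s in scores:
        if s.mrna_id in by_mrna:
            raise UsageError(
                f"multiple pair scores for mRNA {s.mrna_id}; rank one lncRNA "
                "at a time"
            )
        by_mrna[s.mrna_id] = s

    def key(mrna_id: str) -> tuple[float, float, str]:
        sc = by_mrna.get(mrna_id)
        if sc is None:
            return (0.0 if method == "SumEnergy" else math.inf, math.inf, mrna_id)
        primary = (
            sc.sum_energy_kcal if method == "SumEnergy" else sc.min_energy_kcal
        )
        return (primary, sc.min_energy_kcal, mrna_id)

    return sorted(candidates.mrna_ids, key=key)


def random_baseline(n: int, K: int, M: int) -> float:
    """Expected TPs among n random draws from M candidates with K positives.

    This is the mean of the hypergeometric distribution, n*K/M.
    """
    if not 0 <= K <= M:
        raise UsageError(f"need 0 <= K <= M, got K={K}, M={M}")
    if not 1 <= n <= M:
        raise UsageError(f"need 1 <= n <= M, got n={n}, M={M}")
    return n * K / M


def tp_curve(
    ranking: Sequence[str],
    truth: Iterable[str],
    n_max: int = 100,
) -> EvaluationCurve:
    """Cumulative validated targets among the top n, for n = 1..n_max.

    Validated targets absent from the ranking's candidate universe are
    dropped with a warning so that the curve and its random baseline share
    one universe; the reported ``n_truth`` is the post-drop count.
    """
    if n_max < 1:
        raise UsageError(f"n_max must be >= 1, got {n_max}")
    ranking = list(ranking)
    truth_set = set(truth)
    universe = set(ranking)
    outside = truth_set - universe
    if outside:
        logger.warning(
            "dropping %d validated target(s) absent from the candidate "
            "universe (e.g. %s)",
            len(outside),
            sorted(outside)[:3],
        )
        truth_set &= universe
    n_cand = len(ranking)
    n_truth = len(truth_set)
    depth = min(n_max, n_cand)
    hits = np.fromiter(
        (1 if r in truth_set else 0 for r in ranking[:depth]), dtype=int, count=depth
    )
    depths = np.arange(1, depth + 1)
    baseline = depths * (n_truth / n_cand) if n_cand else np.zeros(0)
    return EvaluationCurve(
        depths=depths,
        tp_counts=np.cumsum(hits),
        baseline=baseline,
        n_candidates=n_cand,
        n_truth=n_truth,
    )


def hypergeom_tail_p(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for X ~ Hypergeom(M=a+b+c+d, K=a+c, n=a+b).

    The one-tailed Fisher's exact p-value for observing at least ``a``
    validated targets in the subset row of the 2x2 table [[a, b], [c, d]].
    """
    if a <= 0:
        return 1.0  # the lower tail bound holds trivially (covers empty tables)
    total = a + b + c + d
    return float(min(1.0, max(0.0, hypergeom.sf(a - 1, total, a + c, a + b))))


def fisher_enrichment(
    initial: CandidateSet,
    subset: CandidateSet,
    truth: Iterable[str],
    tissue: str | None = None,
) -> EnrichmentResult:
    """One-tailed Fisher's exact test for truth enrichment in ``subset``.

    ``subset`` must be contained in ``initial``.  Validated targets outside
    the initial universe are ignored.
    """
    initial_set = set(initial.mrna_ids)
    subset_set = set(subset.mrna_ids)
    if not subset_set <= initial_set:
        raise UsageError(
            f"subset {subset.label!r} is not contained in {initial.label!r}"
        )
    truth_set = set(truth) & initial_set
    rest = initial_set - subset_set
    a = len(subset_set & truth_set)
    b = len(subset_set) - a
    c = len(rest & truth_set)
    d = len(rest) - c
    numer, denom = a * d, b * c
    if denom:
        odds = numer / denom
    else:
        odds = math.inf if numer else math.nan
    return EnrichmentResult(
        tissue=tissue if tissue is not None else subset.label,
        table=((a, b), (c, d)),
        odds_ratio=odds,
        p_value=hypergeom_tail_p(a, b, c, d),
    )


def bonferroni(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Multiply each p-value by the number of tests, clipping at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise UsageError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def adjust_enrichment(results: Sequence[EnrichmentResult]) -> list[EnrichmentResult]:
    """Return copies of the results with Bonferroni-adjusted p-values filled."""
    adjusted = bonferroni([r.p_value for r in results])
    return [replace(r, p_adjusted=float(p)) for r, p in zip(results, adjusted)]


def write_evaluation_tsv(
    curve_min: EvaluationCurve,
    curve_sum: EvaluationCurve,
    path: str | Path,
) -> None:
    """Write both rankings' curves: depth, tp_minenergy, tp_sumenergy, baseline."""
    if not np.array_equal(curve_min.depths, curve_sum.depths):
        raise UsageError("curves to be written together must share depths")
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("depth\ttp_minenergy\ttp_sumenergy\tbaseline\n")
        for i, n in enumerate(curve_min.depths):
            fh.write(
                f"{n}\t{curve_min.tp_counts[i]}\t{curve_sum.tp_counts[i]}\t"
                f"{float(curve_min.baseline[i])!r}\n"
            )


def write_enrichment_tsv(
    results: Iterable[EnrichmentResult], path: str | Path
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("tissue\ta\tb\tc\td\todds_ratio\tp\tp_bonferroni\n")
        for r in results:
            (a, b), (c, d) = r.table
            adj = "" if r.p_adjusted is None else repr(r.p_adjusted)
            fh.write(
                f"{r.tissue}\t{a}\t{b}\t{c}\t{d}\t{r.odds_ratio!r}\t"
                f"{r.p_value!r}\t{adj}\n"
            )
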