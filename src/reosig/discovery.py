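"""Reversal-pair signature discovery pipeline.

The workflow mirrors a two-platform design:

1. On the discovery platform, find gene pairs whose orientation is highly
   stable (frequency ≥ threshold) within every reference-class group and,
   with the *opposite* orientation, within the alternative-class group —
   the reversal pairs.
2. Optionally re-test the surviving pairs on an independent platform's
   cohorts (pooled non-reference vs reference), dropping pairs that fail
   the same threshold there or whose genes are unmeasured.
3. Rank pairs by reversal coverage rate — the geometric mean of the
   reference-orientation frequency in reference samples and the reversed
   frequency in alternative samples — on the pooled training data.
4. Scan every odd k from 1 upward, classifying the training samples with
   the top-k majority vote, and keep the smallest k that attains the
   highest geometric mean of sensitivity and specificity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classify as _classify
from .data import (
    ExpressionMatrix,
    Orientation,
    PhenotypeLabels,
    Signature,
    SignaturePair,
    ValidationError,
)
from .pairs import PairFrequencyTable, StablePairSet, pair_frequency_table, stable_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "ReversalPair",
    "RankedSignature",
    "CrossPlatformOutcome",
    "DiscoveryResult",
    "find_reversal_pairs",
    "orientation_frequency",
    "reversal_coverage_rate",
    "cross_platform_filter",
    "smallest_odd_argmax",
    "rank_and_select_k",
    "fold_change_summary",
    "discover",
]


@dataclass(frozen=True)
class ReversalPair:
    """A gene pair stable in both classes with opposite orientations.

    ``reference_orientation`` is the ordering seen in reference-class
    samples; the alternative class shows the flipped ordering.
    """

    gene_i: str
    gene_j: str
    reference_orientation: Orientation
    freq_reference: float
    freq_alternative: float

    def __post_init__(self) -> None:
        if self.reference_orientation not in (
            Orientation.I_GREATER,
            Orientation.J_GREATER,
        ):
            raise ValidationError("reversal pair orientation must be '>' or '<'")
        for f in (self.freq_reference, self.freq_alternative):
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"frequency {f} outside [0, 1]")

    @property
    def coverage_rate(self) -> float:
        """Geometric mean of the two class frequencies, in (0, 1]."""
        return math.sqrt(self.freq_reference * self.freq_alternative)

    def with_frequencies(self, freq_reference: float, freq_alternative: float) -> "ReversalPair":
        return ReversalPair(
            self.gene_i,
            self.gene_j,
            self.reference_orientation,
            freq_reference,
            freq_alternative,
        )

    def to_signature_pair(self) -> SignaturePair:
        return SignaturePair(
            gene_i=self.gene_i,
            gene_j=self.gene_j,
            reference_orientation=self.reference_orientation,
            coverage_rate=self.coverage_rate,
        )


def find_reversal_pairs(
    stable_reference: StablePairSet, stable_alternative: StablePairSet
) -> list[ReversalPair]:
    """Pairs present in both stable sets with opposite orientations.

    Pairs stable with the *same* orientation in both classes carry no
    class information and are excluded.  The stored reference (alternative)
    frequency is the minimum across the reference (alternative) set's
    groups, so multi-group discovery stays conservative.
    """
    alt = stable_alternative.as_dict()
    ref_min = stable_reference.min_frequency()
    alt_min_all = stable_alternative.min_frequency()
    alt_min = {
        (row.gene_i, row.gene_j): float(alt_min_all.iloc[pos])
        for pos, row in enumerate(stable_alternative.pairs.itertuples(index=False))
    }
    out: list[ReversalPair] = []
    for pos, row in enumerate(stable_reference.pairs.itertuples(index=False)):
        key = (row.gene_i, row.gene_j)
        if key not in alt:
            continue
        if alt[key] is row.orientation:
            continue  # same ordering in both classes: not a reversal
        out.append(
            ReversalPair(
                gene_i=row.gene_i,
                gene_j=row.gene_j,
                reference_orientation=row.orientation,
                freq_reference=float(ref_min.iloc[pos]),
                freq_alternative=alt_min[key],
            )
        )
    out.sort(key=lambda p: (p.gene_i, p.gene_j))
    return out


def orientation_frequency(
    matrix: ExpressionMatrix,
    gene_i: str,
    gene_j: str,
    sample_ids: Sequence[str],
    orientation: Orientation,
) -> float:
    """Fraction of the listed samples showing the given orientation.

    Ties and missing values support neither orientation; the denominator is
    the full sample count.
    """
    if len(sample_ids) == 0:
        raise ValidationError("empty sample list")
    for g in (gene_i, gene_j):
        if not matrix.has_gene(g):
            raise ValidationError(f"unknown gene id: {g!r}")
    vi = matrix.values.loc[gene_i, list(sample_ids)].to_numpy(dtype=float)
    vj = matrix.values.loc[gene_j, list(sample_ids)].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if orientation is Orientation.I_GREATER:
            hits = int(np.sum(vi > vj))
        elif orientation is Orientation.J_GREATER:
            hits = int(np.sum(vi < vj))
        else:
            raise ValidationError("frequency is defined for '>' and '<' only")
    return hits / len(sample_ids)


def reversal_coverage_rate(
    pair: ReversalPair,
    matrix: ExpressionMatrix,
    labels: PhenotypeLabels,
    reference_classes: Sequence[str],
    alternative_class: str,
) -> float:
    """sqrt(f_ref × f_alt) on pooled training samples.

    f_ref: frequency of the reference orientation among all pooled
    reference-class samples; f_alt: frequency of the reversed orientation
    among alternative-class samples.
    """
    ref_samples = [
        s for s in labels.samples_of(*reference_classes) if s in matrix.values.columns
    ]
    alt_samples = [
        s for s in labels.samples_of(alternative_class) if s in matrix.values.columns
    ]
    if not ref_samples or not alt_samples:
        raise ValidationError("both classes must have at least one sample")
    f_ref = orientation_frequency(
        matrix, pair.gene_i, pair.gene_j, ref_samples, pair.reference_orientation
    )
    f_alt = orientation_frequency(
        matrix,
        pair.gene_i,
        pair.gene_j,
        alt_samples,
        pair.reference_orientation.flipped(),
    )
    return math.sqrt(f_ref * f_alt)


@dataclass
class CrossPlatformOutcome:
    """Surviving pairs plus a log of dropped pairs with reasons."""

    kept: list[ReversalPair]
    dropped: list[tuple[ReversalPair, str]]

    def dropped_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_i": [p.gene_i for p, _ in self.dropped],
                "gene_j": [p.gene_j for p, _ in self.dropped],
                "reason": [r for _, r in self.dropped],
            }
        )


def cross_platform_filter(
    pairs: Sequence[ReversalPair],
    matrix: ExpressionMatrix,
    labels: PhenotypeLabels,
    reference_classes: Sequence[str],
    alternative_class: str,
    threshold: float,
) -> CrossPlatformOutcome:
    """Keep pairs whose reversal replicates on an independent platform.

    A pair survives iff its reference orientation holds in ≥ *threshold* of
    the pooled reference-class samples AND the reversed orientation holds in
    ≥ *threshold* of the alternative-class samples of *matrix*.  Pairs with
    a gene unmeasured on this platform are dropped and logged.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValidationError(f"threshold must lie in (0.5, 1.0], got {threshold}")
    ref_samples = [
        s for s in labels.samples_of(*reference_classes) if s in matrix.values.columns
    ]
    alt_samples = [
        s for s in labels.samples_of(alternative_class) if s in matrix.values.columns
    ]
    if not ref_samples or not alt_samples:
        raise ValidationError(
            "cross-platform matrix lacks labeled samples of one of the classes"
        )
    kept: list[ReversalPair] = []
    dropped: list[tuple[ReversalPair, str]] = []
    for pair in pairs:
        absent = [g for g in (pair.gene_i, pair.gene_j) if not matrix.has_gene(g)]
        if absent:
            reason = f"gene(s) not measured on this platform: {','.join(absent)}"
            dropped.append((pair, reason))
            logger.info("dropped pair (%s, %s): %s", pair.gene_i, pair.gene_j, reason)
            continue
        f_ref = orientation_frequency(
            matrix, pair.gene_i, pair.gene_j, ref_samples, pair.reference_orientation
        )
        f_alt = orientation_frequency(
            matrix,
            pair.gene_i,
            pair.gene_j,
            alt_samples,
            pair.reference_orientation.flipped(),
        )
        if f_ref >= threshold and f_alt >= threshold:
            kept.append(pair)
        else:
            reason = f"frequencies {f_ref:.3f}/{f_alt:.3f} below threshold {threshold}"
            dropped.append((pair, reason))
    return CrossPlatformOutcome(kept=kept, dropped=dropped)


def smallest_odd_argmax(scores: Mapping[int, float]) -> int:
    """Smallest odd k attaining the maximum score (exact comparison)."""
    odd = {k: v for k, v in scores.items() if k % 2 == 1 and not math.isnan(v)}
    if not odd:
        raise ValidationError("no odd k with a defined score")
    best = max(odd.values())
    return min(k for k, v in odd.items() if v == best)


@dataclass
class RankedSignature:
    """Reversal pairs sorted by descending coverage rate, with selected k.

    ``scores`` holds the per-odd-k training sensitivity/specificity scan
    that determined ``selected_k``.
    """

    pairs: list[ReversalPair]
    selected_k: int
    scores: pd.DataFrame
    reference_class: str
    alternative_class: str
    provenance: dict = field(default_factory=dict)

    def signature(self, k: int | None = None) -> Signature:
        return Signature(
            pairs=[p.to_signature_pair() for p in self.pairs],
            reference_class=self.reference_class,
            alternative_class=self.alternative_class,
            k=self.selected_k if k is None else k,
        )


def rank_and_select_k(
    pairs: Sequence[ReversalPair],
    matrix: ExpressionMatrix,
    labels: PhenotypeLabels,
    reference_classes: Sequence[str],
    alternative_class: str,
    k_max: int | None = None,
    reference_name: str | None = None,
) -> RankedSignature:
    """Sort pairs by coverage rate and pick the smallest best odd k.

    Frequencies and coverage rates are recomputed on the pooled training
    samples of *matrix*; equal coverage rates break lexicographically by
    (gene_i, gene_j).  For each odd k ≤ min(k_max, #pairs) every training
    sample is classified by the top-k majority vote (same abstention/tie
    semantics as deployment) and the geometric mean of sensitivity and
    specificity recorded; the smallest k attaining the maximum wins.
    """
    if not pairs:
        raise ValidationError("no reversal pairs to rank")
    ref_samples = [
        s for s in labels.samples_of(*reference_classes) if s in matrix.values.columns
    ]
    alt_samples = [
        s for s in labels.samples_of(alternative_class) if s in matrix.values.columns
    ]
    if not ref_samples or not alt_samples:
        raise ValidationError("training data must contain both classes")

    rescored = []
    for pair in pairs:
        f_ref = orientation_frequency(
            matrix, pair.gene_i, pair.gene_j, ref_samples, pair.reference_orientation
        )
        f_alt = orientation_frequency(
            matrix,
            pair.gene_i,
            pair.gene_j,
            alt_samples,
            pair.reference_orientation.flipped(),
        )
        rescored.append(pair.with_frequencies(f_ref, f_alt))
    rescored.sort(key=lambda p: (-p.coverage_rate, p.gene_i, p.gene_j))

    limit = len(rescored) if k_max is None else min(int(k_max), len(rescored))
    if limit < 1:
        raise ValidationError("k_max must be at least 1")

    # Per-pair votes per training sample: +1 reference, -1 alternative, 0 abstain.
    all_samples = ref_samples + alt_samples
    is_positive = np.array([False] * len(ref_samples) + [True] * len(alt_samples))
    votes = np.zeros((len(rescored), len(all_samples)), dtype=np.int64)
    for row, pair in enumerate(rescored):
        vi = matrix.values.loc[pair.gene_i, all_samples].to_numpy(dtype=float)
        vj = matrix.values.loc[pair.gene_j, all_samples].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            gt = vi > vj
            lt = vi < vj
        if pair.reference_orientation is Orientation.I_GREATER:
            ref_match, alt_match = gt, lt
        else:
            ref_match, alt_match = lt, gt
        votes[row] = ref_match.astype(np.int64) - alt_match.astype(np.int64)

    margins = np.cumsum(votes, axis=0)  # net reference-vote margin after k pairs
    records = []
    score_by_k: dict[int, float] = {}
    for k in range(1, limit + 1, 2):
        margin = margins[k - 1]
        pred_alt = margin < 0
        pred_ref = margin > 0
        tp = int(np.sum(pred_alt & is_positive))
        fp = int(np.sum(pred_alt & ~is_positive))
        tn = int(np.sum(pred_ref & ~is_positive))
        fn = int(np.sum(pred_ref & is_positive))
        ind_pos = int(np.sum((margin == 0) & is_positive))
        ind_neg = int(np.sum((margin == 0) & ~is_positive))
        m = _classify.metrics_from_counts(tp, tn, fp, fn, ind_pos, ind_neg)
        g = m.geometric_mean if m.geometric_mean is not None else float("nan")
        score_by_k[k] = g
        records.append(
            {
                "k": k,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "geometric_mean": g,
                "indeterminate": m.indeterminate,
            }
        )
    selected = smallest_odd_argmax(score_by_k)
    scores = pd.DataFrame.from_records(records)
    ref_name = reference_name or "+".join(reference_classes)
    return RankedSignature(
        pairs=rescored,
        selected_k=selected,
        scores=scores,
        reference_class=ref_name,
        alternative_class=alternative_class,
        provenance={
            "n_pairs": len(rescored),
            "k_max": limit,
            "n_reference_samples": len(ref_samples),
            "n_alternative_samples": len(alt_samples),
        },
    )


def fold_change_summary(
    matrix: ExpressionMatrix,
    labels: PhenotypeLabels,
    gene_i: str,
    gene_j: str,
    classes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-class {n, min, median, max} of the value_i / value_j ratio.

    Samples with either gene masked are excluded from the summaries; a
    zero or negative denominator among the used samples is an error naming
    the offending samples.
    """
    for g in (gene_i, gene_j):
        if not matrix.has_gene(g):
            raise ValidationError(f"unknown gene id: {g!r}")
    if classes is None:
        classes = sorted(labels.label_set)
    rows = []
    for cl in classes:
        members = [s for s in labels.samples_of(cl) if s in matrix.values.columns]
        vi = matrix.values.loc[gene_i, members].to_numpy(dtype=float)
        vj = matrix.values.loc[gene_j, members].to_numpy(dtype=float)
        unmasked = ~(np.isnan(vi) | np.isnan(vj))
        bad = [m for m, keep, denom in zip(members, unmasked, vj) if keep and denom <= 0]
        if bad:
            raise ValidationError(
                f"non-positive denominator ({gene_j}) in sample(s): {bad}"
            )
        ratios = vi[unmasked] / vj[unmasked]
        if ratios.size == 0:
            raise ValidationError(f"class {cl!r} has no unmasked samples for the pair")
        rows.append(
            {
                "class": cl,
                "n": int(ratios.size),
                "min": float(np.min(ratios)),
                "median": float(np.median(ratios)),
                "max": float(np.max(ratios)),
            }
        )
    return pd.DataFrame(rows).set_index("class")


@dataclass
class DiscoveryResult:
    """End-to-end discovery output with the stage-count funnel."""

    ranked: RankedSignature
    funnel: dict[str, int]
    cross_platform: CrossPlatformOutcome | None = None

    def signature(self, k: int | None = None) -> Signature:
        return self.ranked.signature(k)


def discover(
    matrix: ExpressionMatrix,
    labels: PhenotypeLabels,
    reference_groups: Sequence[str],
    alternative_group: str,
    stability_threshold: float = 0.90,
    cross_matrix: ExpressionMatrix | None = None,
    cross_labels: PhenotypeLabels | None = None,
    cross_threshold: float = 0.90,
    rank_matrix: ExpressionMatrix | None = None,
    rank_labels: PhenotypeLabels | None = None,
    k_max: int | None = None,
    undefined_policy: str = "count",
    reference_name: str | None = None,
    block_size: int = 256,
) -> DiscoveryResult:
    """Run the full discovery pipeline and log the pair-count funnel.

    Stability is required separately in every reference group (e.g. normal
    and IBD) and in the alternative group; the optional cross-platform stage
    pools the reference groups.  Ranking/k-selection run on *rank_matrix*
    (defaults to the discovery matrix).
    """
    groups = list(reference_groups) + [alternative_group]
    table = pair_frequency_table(matrix, labels, groups, block_size=block_size)
    funnel: dict[str, int] = {"pairs_total": table.n_pairs}

    stable_ref = stable_pairs(
        table, list(reference_groups), stability_threshold, undefined_policy
    )
    stable_alt = stable_pairs(
        table, [alternative_group], stability_threshold, undefined_policy
    )
    funnel["stable_reference"] = len(stable_ref)
    funnel["stable_alternative"] = len(stable_alt)

    reversal = find_reversal_pairs(stable_ref, stable_alt)
    funnel["reversal"] = len(reversal)
    if not reversal:
        raise ValidationError("no reversal pairs found at this threshold")

    outcome: CrossPlatformOutcome | None = None
    if cross_matrix is not None:
        if cross_labels is None:
            raise ValidationError("cross-platform matrix given without labels")
        outcome = cross_platform_filter(
            reversal,
            cross_matrix,
            cross_labels,
            reference_groups,
            alternative_group,
            cross_threshold,
        )
        reversal = outcome.kept
        funnel["cross_platform"] = len(reversal)
        if not reversal:
            raise ValidationError("no pairs survived the cross-platform filter")

    ranked = rank_and_select_k(
        reversal,
        rank_matrix if rank_matrix is not None else matrix,
        rank_labels if rank_labels is not None else labels,
        reference_groups,
        alternative_group,
        k_max=k_max,
        reference_name=reference_name,
    )
    funnel["selected_k"] = ranked.selected_k
    for stage, count in funnel.items():
        logger.info("funnel %s: %d", stage, count)
    return DiscoveryResult(ranked=ranked, funnel=funnel, cross_platform=outcome)
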