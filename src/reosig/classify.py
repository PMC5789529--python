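"""Single-sample majority-vote classification and evaluation metrics.

A deployed signature classifies one sample at a time using only the ordering
of that sample's own measurements: each of the top-k pairs votes for the
alternative class when its orientation is reversed relative to the reference
orientation, for the reference class when it matches, and abstains on exact
ties or missing measurements.  The majority of cast votes decides; an equal
split yields "indeterminate" rather than a forced call.  No inter-sample
normalization is involved at any point.

A nearest-centroid quantitative baseline is included purely to demonstrate,
on synthetic cohorts, how classifiers built on raw expression magnitudes
degrade under sample-wise monotone batch transforms that leave the
rank-based classifier untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import (
    ExpressionMatrix,
    Orientation,
    PhenotypeLabels,
    Signature,
    ValidationError,
    orient_values,
)

INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ClassificationResult:
    """Vote breakdown and call for one sample."""

    sample_id: str
    votes_reference: int
    votes_alternative: int
    abstentions: int
    call: str

    @property
    def k(self) -> int:
        return self.votes_reference + self.votes_alternative + self.abstentions


def classify_sample(
    signature: Signature, sample: pd.Series, sample_id: str | None = None
) -> ClassificationResult:
    """Classify one sample (a gene-id-indexed value vector).

    Pairs whose genes are absent from the vector, masked, or exactly tied
    abstain; the majority of the cast votes decides the call.
    """
    votes_ref = votes_alt = abstain = 0
    for pair in signature.top_pairs:
        try:
            vi = float(sample[pair.gene_i])
            vj = float(sample[pair.gene_j])
        except KeyError:
            abstain += 1
            continue
        observed = orient_values(vi, vj)
        if observed in (Orientation.TIE, Orientation.UNDEFINED):
            abstain += 1
        elif observed is pair.reference_orientation:
            votes_ref += 1
        else:
            votes_alt += 1
    if votes_alt > votes_ref:
        call = signature.alternative_class
    elif votes_ref > votes_alt:
        call = signature.reference_class
    else:
        call = INDETERMINATE
    return ClassificationResult(
        sample_id=sample_id if sample_id is not None else str(sample.name),
        votes_reference=votes_ref,
        votes_alternative=votes_alt,
        abstentions=abstain,
        call=call,
    )


def classify_matrix(
    signature: Signature, matrix: ExpressionMatrix
) -> list[ClassificationResult]:
    """Classify every sample of a matrix independently."""
    return [
        classify_sample(signature, matrix.values[s], sample_id=s)
        for s in matrix.sample_ids
    ]


def results_frame(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "votes_alternative": [r.votes_alternative for r in results],
            "votes_reference": [r.votes_reference for r in results],
            "abstentions": [r.abstentions for r in results],
            "call": [r.call for r in results],
        }
    )


def _gmean(a: float | None, b: float | None) -> float | None:
    if a is None or b is None:
        return None
    return math.sqrt(a * b)


@dataclass(frozen=True)
class EvaluationMetrics:
    """Confusion counts and derived rates for one evaluation run.

    ``sensitivity``/``specificity`` are computed over determinate calls
    only; the ``strict_*`` variants count indeterminate calls as errors.
    A rate whose denominator is empty (no positives, or no negatives) is
    ``None`` — flagged undefined rather than silently zero.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    indeterminate_positive: int
    indeterminate_negative: int
    sensitivity: float | None
    specificity: float | None
    geometric_mean: float | None
    strict_sensitivity: float | None
    strict_specificity: float | None
    strict_geometric_mean: float | None

    @property
    def indeterminate(self) -> int:
        return self.indeterminate_positive + self.indeterminate_negative

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("tp", self.tp),
            ("tn", self.tn),
            ("fp", self.fp),
            ("fn", self.fn),
            ("indeterminate", self.indeterminate),
            ("sensitivity", self.sensitivity),
            ("specificity", self.specificity),
            ("geometric_mean", self.geometric_mean),
            ("strict_sensitivity", self.strict_sensitivity),
            ("strict_specificity", self.strict_specificity),
            ("strict_geometric_mean", self.strict_geometric_mean),
        ]
        return pd.DataFrame(rows, columns=["metric", "value"])


def metrics_from_counts(
    tp: int,
    tn: int,
    fp: int,
    fn: int,
    indeterminate_positive: int = 0,
    indeterminate_negative: int = 0,
) -> EvaluationMetrics:
    """Derive rates from confusion counts.

    sensitivity = TP / (TP + FN);  specificity = TN / (TN + FP);
    their geometric mean summarizes both in one number.
    """
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    n_pos = tp + fn + indeterminate_positive
    n_neg = tn + fp + indeterminate_negative
    strict_sens = tp / n_pos if n_pos > 0 else None
    strict_spec = tn / n_neg if n_neg > 0 else None
    return EvaluationMetrics(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        indeterminate_positive=indeterminate_positive,
        indeterminate_negative=indeterminate_negative,
        sensitivity=sens,
        specificity=spec,
        geometric_mean=_gmean(sens, spec),
        strict_sensitivity=strict_sens,
        strict_specificity=strict_spec,
        strict_geometric_mean=_gmean(strict_sens, strict_spec),
    )


def evaluate(
    signature: Signature,
    matrix: ExpressionMatrix,
    labels: PhenotypeLabels,
    positive_class: str,
) -> EvaluationMetrics:
    """Confusion counts over a labeled matrix.

    Samples labeled *positive_class* are positives; every other label is a
    negative.  A prediction is positive when the call equals the signature's
    alternative class and negative when it equals the reference class.
    """
    if positive_class not in labels.label_set:
        raise ValidationError(f"positive class {positive_class!r} not in labels")
    tp = tn = fp = fn = ind_pos = ind_neg = 0
    for result in classify_matrix(signature, matrix):
        actual_positive = labels.class_of(result.sample_id) == positive_class
        if result.call == INDETERMINATE:
            if actual_positive:
                ind_pos += 1
            else:
                ind_neg += 1
        elif result.call == signature.alternative_class:
            if actual_positive:
                tp += 1
            else:
                fp += 1
        else:
            if actual_positive:
                fn += 1
            else:
                tn += 1
    return metrics_from_counts(tp, tn, fp, fn, ind_pos, ind_neg)


# ---------------------------------------------------------------------------
# Quantitative baseline (demonstration stand-in)
# ---------------------------------------------------------------------------


@dataclass
class CentroidBaseline:
    """Nearest class-mean classifier on raw expression values.

    Deliberately simple: Euclidean distance to per-class mean vectors over a
    fixed feature-gene list.  Exists only to contrast the fragility of
    magnitude-based classification under monotone batch transforms with the
    invariance of the rank-based classifier.  Distance ties break to the
    first class in sorted class-name order (deterministic).
    """

    feature_genes: list[str]
    class_order: list[str]
    centroids: pd.DataFrame  # classes × feature genes

    @classmethod
    def fit(
        cls,
        matrix: ExpressionMatrix,
        labels: PhenotypeLabels,
        feature_genes: Sequence[str] | None = None,
    ) -> "CentroidBaseline":
        if feature_genes is None:
            feature_genes = matrix.gene_ids
        feature_genes = list(feature_genes)
        missing = [g for g in feature_genes if not matrix.has_gene(g)]
        if missing:
            raise ValidationError(f"feature gene(s) absent from matrix: {missing}")
        classes = sorted(labels.label_set)
        if len(classes) < 2:
            raise ValidationError("training data must contain at least two classes")
        rows = {}
        for cl in classes:
            members = [s for s in labels.samples_of(cl) if s in matrix.values.columns]
            if not members:
                raise ValidationError(f"no training samples of class {cl!r}")
            rows[cl] = matrix.values.loc[feature_genes, members].mean(axis=1)
        centroids = pd.DataFrame(rows).T
        return cls(
            feature_genes=feature_genes, class_order=classes, centroids=centroids
        )

    def predict_sample(self, sample: pd.Series) -> str:
        missing = [g for g in self.feature_genes if g not in sample.index]
        if missing:
            raise ValidationError(f"feature gene(s) absent from sample: {missing}")
        x = sample[self.feature_genes].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValidationError("masked feature gene in test sample")
        best_class = self.class_order[0]
        best_dist = np.inf
        for cl in self.class_order:
            d = float(np.linalg.norm(x - self.centroids.loc[cl].to_numpy(dtype=float)))
            if d < best_dist:
                best_dist = d
                best_class = cl
        return best_class

    def predict(self, matrix: ExpressionMatrix) -> pd.Series:
        calls = {s: self.predict_sample(matrix.values[s]) for s in matrix.sample_ids}
        return pd.Series(calls, name="call")
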