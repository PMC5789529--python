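"""Synthetic multi-cohort expression data with planted reversal gene pairs.

The generator emulates the statistical structure the signature method
assumes: within each phenotype class, a planted gene pair holds one
ordering with a configurable probability p, and the ordering flips between
classes; all other gene pairs order class-independently.

Model
-----
Each gene g has a baseline log2-expression mu_g ~ Normal(log2_loc,
log2_scale) drawn once per cohort spec; each measurement adds i.i.d.
Normal(0, noise_scale) log2 noise and the matrix holds 2**(log2 value),
i.e. positive linear-scale measurements.  A planted pair shares one
baseline and receives class-dependent offsets ±delta/2 of opposite sign in
the two classes, with delta calibrated from the noise scale via the normal
difference distribution so that the intended ordering holds with probability
exactly p:  P(Normal(delta, 2*noise_scale**2) > 0) = p, i.e.
delta = sqrt(2) * noise_scale * Phi^{-1}(p).  In the noise-free reading
p = 1, the pair's two genes share their noise so the ordering is
deterministic.

Batch structure
---------------
* sample-wise monotone batch: each sample is independently passed through a
  strictly increasing map (positive-slope affine in log2 space), which
  provably leaves every within-sample ordering unchanged;
* gene-wise batch: independent per-gene multiplicative perturbations, which
  *can* flip orderings of closely ranked pairs — the harmful component of
  batch effects.

All randomness flows through one numpy Generator seeded from the spec; the
same seed reproduces bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import (
    ExpressionMatrix,
    Orientation,
    PhenotypeLabels,
    Signature,
    SignaturePair,
    ValidationError,
)
from .variation import ASSAY_GENERIC, ReplicateTable

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "generate_cohort",
    "apply_sample_monotone_batch",
    "apply_genewise_batch",
    "generate_replicates",
    "planted_offset",
]


def planted_offset(p: float, noise_scale: float) -> float:
    """log2 offset giving the planted ordering probability exactly p."""
    if not 0.5 < p <= 1.0:
        raise ValidationError(f"orientation probability must lie in (0.5, 1], got {p}")
    if p == 1.0:
        return 1.0  # noise is shared within the pair in this limit
    return float(np.sqrt(2.0) * noise_scale * norm.ppf(p))


@dataclass(frozen=True)
class CohortSpec:
    """Design of one synthetic multi-cohort study.

    ``p_orientation`` is the within-class probability that a planted pair
    shows its class's ordering.  ``batch_slope_range``/``batch_shift_scale``
    optionally pass each cohort through its own sample-wise monotone batch
    transform (harmless to orderings by construction).
    """

    n_genes: int = 500
    n_reference: int = 100
    n_alternative: int = 100
    n_planted: int = 20
    p_orientation: float = 0.97
    log2_loc: float = 6.0
    log2_scale: float = 1.5
    noise_scale: float = 0.5
    n_cohorts: int = 1
    batch_slope_range: tuple[float, float] | None = None
    batch_shift_scale: float = 1.0
    reference_class: str = "normal"
    alternative_class: str = "cancer"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.p_orientation <= 1.0:
            raise ValidationError(
                f"p_orientation must lie in (0.5, 1], got {self.p_orientation}"
            )
        if 2 * self.n_planted > self.n_genes:
            raise ValidationError(
                f"{self.n_planted} planted pairs need {2 * self.n_planted} genes, "
                f"but only {self.n_genes} are available"
            )
        if self.n_reference < 1 or self.n_alternative < 1 or self.n_cohorts < 1:
            raise ValidationError("sample and cohort counts must be positive")


@dataclass
class GroundTruth:
    """Planted pairs with their reference orientations and realized stats."""

    pairs: list[SignaturePair]
    realized: pd.DataFrame  # gene_i, gene_j, freq_reference, freq_alternative
    p_orientation: float

    def pair_keys(self) -> set[tuple[str, str]]:
        return {(p.gene_i, p.gene_j) for p in self.pairs}

    def signature(
        self,
        k: int | None = None,
        reference_class: str = "normal",
        alternative_class: str = "cancer",
    ) -> Signature:
        """Oracle signature built directly from the planted pairs."""
        ordered = sorted(
            self.pairs, key=lambda p: (-p.coverage_rate, p.gene_i, p.gene_j)
        )
        if k is None:
            k = len(ordered) if len(ordered) % 2 == 1 else len(ordered) - 1
        return Signature(
            pairs=ordered,
            reference_class=reference_class,
            alternative_class=alternative_class,
            k=k,
        )


def _monotone_log_affine(
    values: np.ndarray, slopes: np.ndarray, shifts: np.ndarray
) -> np.ndarray:
    """Per-sample strictly increasing map 2**(a*log2(x) + b), columns = samples."""
    if np.nanmin(values) <= 0:
        raise ValidationError("monotone log-affine transform requires positive values")
    log2 = np.log2(values)
    return 2.0 ** (log2 * slopes[None, :] + shifts[None, :])


def generate_cohort(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, PhenotypeLabels, GroundTruth]:
    """Generate one study (possibly several cohorts) from a spec.

    Returns the concatenated expression matrix, its labels (class and
    cohort), and the ground truth of planted pairs with their realized
    within-class orientation frequencies.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = np.array([f"G{i:05d}" for i in range(spec.n_genes)])
    mu = rng.normal(spec.log2_loc, spec.log2_scale, spec.n_genes)

    planted_idx = rng.choice(spec.n_genes, size=2 * spec.n_planted, replace=False)
    pair_a = planted_idx[0::2]
    pair_b = planted_idx[1::2]
    mu[pair_b] = mu[pair_a]  # planted pair genes share one baseline
    delta = planted_offset(spec.p_orientation, spec.noise_scale)

    blocks: list[np.ndarray] = []
    sample_ids: list[str] = []
    classes: list[str] = []
    cohorts: list[str] = []
    for c in range(spec.n_cohorts):
        n_ref, n_alt = spec.n_reference, spec.n_alternative
        n_tot = n_ref + n_alt
        log2x = mu[:, None] + rng.normal(0.0, spec.noise_scale, (spec.n_genes, n_tot))
        if spec.p_orientation == 1.0:
            log2x[pair_b, :] = log2x[pair_a, :] - (mu[pair_a, None] - mu[pair_b, None])
        ref_cols = np.arange(n_ref)
        alt_cols = np.arange(n_ref, n_tot)
        # gene a sits delta/2 above the shared baseline in the reference
        # class and delta/2 below it in the alternative class (b mirrored)
        log2x[np.ix_(pair_a, ref_cols)] += delta / 2.0
        log2x[np.ix_(pair_b, ref_cols)] -= delta / 2.0
        log2x[np.ix_(pair_a, alt_cols)] -= delta / 2.0
        log2x[np.ix_(pair_b, alt_cols)] += delta / 2.0
        values = 2.0 ** log2x
        if spec.batch_slope_range is not None:
            slopes = rng.uniform(*spec.batch_slope_range, n_tot)
            shifts = rng.normal(0.0, spec.batch_shift_scale, n_tot)
            values = _monotone_log_affine(values, slopes, shifts)
        blocks.append(values)
        cname = f"cohort{c}"
        for s in range(n_tot):
            label = spec.reference_class if s < n_ref else spec.alternative_class
            sample_ids.append(f"{cname}_{label}_{s:04d}")
            classes.append(label)
            cohorts.append(cname)

    matrix = ExpressionMatrix(
        pd.DataFrame(np.hstack(blocks), index=gene_ids, columns=sample_ids)
    )
    labels = PhenotypeLabels(
        classes=pd.Series(classes, index=sample_ids, name="class"),
        cohorts=pd.Series(cohorts, index=sample_ids, name="cohort"),
    )

    class_arr = np.array(classes)
    ref_mask = class_arr == spec.reference_class
    alt_mask = ~ref_mask
    all_values = matrix.values.to_numpy()
    pairs: list[SignaturePair] = []
    rows = []
    for a, b in zip(pair_a, pair_b):
        ga, gb = gene_ids[a], gene_ids[b]
        # canonical storage: gene_i < gene_j lexicographically
        if ga < gb:
            gi, gj = ga, gb
            hi, lo = a, b
            orient = Orientation.I_GREATER
        else:
            gi, gj = gb, ga
            hi, lo = a, b
            orient = Orientation.J_GREATER
        f_ref = float(np.mean(all_values[hi, ref_mask] > all_values[lo, ref_mask]))
        f_alt = float(np.mean(all_values[hi, alt_mask] < all_values[lo, alt_mask]))
        pairs.append(
            SignaturePair(
                gene_i=gi,
                gene_j=gj,
                reference_orientation=orient,
                coverage_rate=float(np.sqrt(f_ref * f_alt)),
            )
        )
        rows.append(
            {
                "gene_i": gi,
                "gene_j": gj,
                "freq_reference": f_ref,
                "freq_alternative": f_alt,
            }
        )
    order = np.argsort([f"{r['gene_i']}\t{r['gene_j']}" for r in rows])
    pairs = [pairs[i] for i in order]
    realized = pd.DataFrame([rows[i] for i in order])
    truth = GroundTruth(
        pairs=pairs, realized=realized, p_orientation=spec.p_orientation
    )
    return matrix, labels, truth


def apply_sample_monotone_batch(
    matrix: ExpressionMatrix,
    seed: int,
    slope_range: tuple[float, float] = (0.5, 2.0),
    shift_scale: float = 1.0,
    base_slope: float = 1.0,
    base_shift: float = 0.0,
) -> ExpressionMatrix:
    """Transform each sample by a random strictly increasing map.

    Each map is affine in log2 space with a positive slope, hence strictly
    increasing on positive values: every within-sample ordering — and thus
    every pair-orientation count and every majority-vote call — is provably
    unchanged.  ``base_slope``/``base_shift`` add a systematic lab-level
    component shared by the whole batch (e.g. a re-measurement on a platform
    with a compressed dynamic range and lower overall intensity), composed
    with the independent per-sample slopes and shifts that model residual
    sample-to-sample variation.
    """
    if slope_range[0] <= 0 or base_slope <= 0:
        raise ValidationError("slopes must be positive for a monotone transform")
    rng = np.random.default_rng(seed)
    values = matrix.values.to_numpy(dtype=float)
    slopes = rng.uniform(*slope_range, matrix.n_samples) * base_slope
    shifts = rng.normal(0.0, shift_scale, matrix.n_samples) + base_shift
    out = _monotone_log_affine(values, slopes, shifts)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    )


def apply_genewise_batch(
    matrix: ExpressionMatrix, scale: float, seed: int
) -> ExpressionMatrix:
    """Multiply each gene row by an independent factor 2**(scale * z_g).

    At scale 0 this is the identity; as the scale grows it increasingly
    flips the orderings of closely ranked pairs, emulating the component of
    batch effects that rank-based methods are *not* immune to.
    """
    if scale < 0:
        raise ValidationError("perturbation scale must be non-negative")
    rng = np.random.default_rng(seed)
    factors = 2.0 ** (scale * rng.standard_normal(matrix.n_genes))
    out = matrix.values.to_numpy(dtype=float) * factors[:, None]
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    )


def generate_replicates(
    n_genes: int,
    n_replicates: int,
    cv_profile: float | Sequence[float] | Callable[[np.random.Generator, int], np.ndarray],
    seed: int,
    assay: str = ASSAY_GENERIC,
    mean_log2_loc: float = 6.0,
    mean_log2_scale: float = 1.5,
) -> ReplicateTable:
    """Replicate table whose per-gene true CV follows *cv_profile*.

    Each gene's replicates are its true mean times lognormal multiplicative
    noise with sigma chosen so the population CV equals the assigned value
    (CV of a lognormal is sqrt(exp(sigma^2) - 1)); the noise is mean-one, so
    the expected measurement is the true mean.
    """
    rng = np.random.default_rng(seed)
    if callable(cv_profile):
        cvs = np.asarray(cv_profile(rng, n_genes), dtype=float)
    else:
        cvs = np.broadcast_to(np.asarray(cv_profile, dtype=float), (n_genes,)).copy()
    if cvs.shape != (n_genes,):
        raise ValidationError("cv_profile must assign one CV per gene")
    if np.any(cvs < 0):
        raise ValidationError("true CVs must be non-negative")
    means = 2.0 ** rng.normal(mean_log2_loc, mean_log2_scale, n_genes)
    sigma = np.sqrt(np.log1p(cvs**2))
    z = rng.standard_normal((n_genes, n_replicates))
    noise = np.exp(sigma[:, None] * z - 0.5 * sigma[:, None] ** 2)
    values = means[:, None] * noise
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    rep_ids = [f"rep{r + 1}" for r in range(n_replicates)]
    return ReplicateTable(
        values=pd.DataFrame(values, index=gene_ids, columns=rep_ids), assay=assay
    )
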