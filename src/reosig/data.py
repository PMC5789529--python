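"""Core data containers and plain-text I/O.

Everything downstream (pair counting, signature discovery, classification,
replicate-variation analysis) consumes the containers defined here:

* :class:`ExpressionMatrix` — a genes × samples table of non-negative
  expression measurements on any monotone-consistent scale.  Missing cells
  are held as NaN and never participate in a pairwise ordering comparison.
* :class:`PhenotypeLabels` — sample → class (and optionally cohort) labels.
* :class:`ProbeGeneMap` — probe → gene-set mapping used to collapse
  probe-level arrays to gene level.
* :class:`Signature` — an ordered list of oriented gene pairs plus the odd
  vote count ``k``; the deployable classifier artifact.

All file formats are tab-separated UTF-8 text; gene and sample identifiers
are opaque strings (no Entrez validation is attempted — the method is
identifier-agnostic).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Cell contents that mark a missing measurement in expression files.
DEFAULT_MISSING_TOKENS: tuple[str, ...] = ("", "NA", "nan", "NaN")


class ReosigError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(ReosigError):
    """A file could not be parsed; the message names the offending cell."""


class ValidationError(ReosigError):
    """An input violated a documented invariant."""


class Orientation(str, enum.Enum):
    """Within-sample ordering of a gene pair (i, j).

    Only two orientations are biologically meaningful; TIE and UNDEFINED
    cover exact equality in processed data and missing measurements, and by
    default count *against* the stability of a pair.
    """

    I_GREATER = ">"
    J_GREATER = "<"
    TIE = "="
    UNDEFINED = "?"

    def flipped(self) -> "Orientation":
        """Orientation after swapping the roles of gene i and gene j."""
        if self is Orientation.I_GREATER:
            return Orientation.J_GREATER
        if self is Orientation.J_GREATER:
            return Orientation.I_GREATER
        return self


def orient_values(value_i: float, value_j: float) -> Orientation:
    """Orientation of a single (value_i, value_j) observation."""
    if math.isnan(value_i) or math.isnan(value_j):
        return Orientation.UNDEFINED
    if value_i > value_j:
        return Orientation.I_GREATER
    if value_i < value_j:
        return Orientation.J_GREATER
    return Orientation.TIE


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes × samples expression table; NaN cells are masked/missing."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene id(s): {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample id(s): {dups}")
        self.values = self.values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def has_gene(self, gene_id: str) -> bool:
        return gene_id in self.values.index

    def sample(self, sample_id: str) -> pd.Series:
        """One sample's expression vector, indexed by gene id."""
        if sample_id not in self.values.columns:
            raise ValidationError(f"unknown sample id: {sample_id!r}")
        return self.values[sample_id]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"unknown sample id(s): {missing}")
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)].copy())


def read_expression_matrix(
    path: str | Path,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    Layout: row 1 = sample ids (first cell is an arbitrary corner label),
    column 1 = gene ids.  Cells equal to one of *missing_tokens* (after
    whitespace stripping) are masked; any other non-numeric cell is a parse
    error naming the offending row and column.  ``transpose=True`` reads a
    samples-in-rows file; orientation is never autodetected.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise ParseError(f"{path}: empty or malformed header row")
    header = header_line.rstrip("\n").rstrip("\r").split("\t")
    col_ids = header[1:]
    dup_cols = {c for c in col_ids if col_ids.count(c) > 1}
    if dup_cols:
        raise ParseError(f"{path}: duplicate column id(s): {sorted(dup_cols)}")

    raw = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        dtype=str,
        header=None,
        names=["__gene__"] + col_ids,
        skiprows=1,
        keep_default_na=False,
    )
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate row id(s): {dups}")

    tokens = set(missing_tokens)
    cells = raw.to_numpy(dtype=object)
    values = np.empty(cells.shape, dtype=float)
    for (r, c), cell in np.ndenumerate(cells):
        cell = str(cell).strip()
        if cell in tokens:
            values[r, c] = np.nan
            continue
        try:
            values[r, c] = float(cell)  # exact round trip, unlike pd.to_numeric
        except ValueError:
            raise ParseError(
                f"{path}: non-numeric cell {cell!r} at "
                f"row {raw.index[r]!r}, column {raw.columns[c]!r}"
            ) from None
    numeric = pd.DataFrame(values, index=raw.index.astype(str), columns=raw.columns)
    if transpose:
        numeric = numeric.T
    return ExpressionMatrix(numeric)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV; masked cells are written as ``NA``."""
    matrix.values.to_csv(path, sep="\t", na_rep="NA", index_label="gene_id")


# ---------------------------------------------------------------------------
# Phenotype labels
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeLabels:
    """Sample → class mapping, with an optional sample → cohort mapping."""

    classes: pd.Series
    cohorts: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.classes.index.has_duplicates:
            dups = self.classes.index[self.classes.index.duplicated()].unique()
            raise ValidationError(f"duplicate sample id(s) in labels: {list(dups)}")
        self.classes = self.classes.astype(str)
        self.classes.index = self.classes.index.astype(str)
        if self.cohorts is not None:
            self.cohorts = self.cohorts.astype(str)
            self.cohorts.index = self.cohorts.index.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.classes.index)

    @property
    def label_set(self) -> set[str]:
        return set(self.classes.unique())

    def class_of(self, sample_id: str) -> str:
        if sample_id not in self.classes.index:
            raise ValidationError(f"sample {sample_id!r} has no phenotype label")
        return str(self.classes[sample_id])

    def samples_of(self, *labels: str) -> list[str]:
        """Sample ids (in stored order) whose class is one of *labels*."""
        wanted = set(labels)
        unknown = wanted - self.label_set
        if unknown:
            raise ValidationError(f"unknown class label(s): {sorted(unknown)}")
        mask = self.classes.isin(wanted)
        return list(self.classes.index[mask])


def read_labels(path: str | Path) -> PhenotypeLabels:
    """Read a 2- or 3-column TSV: sample_id, class[, cohort].

    A first line starting with ``sample_id`` is treated as a header.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, keep_default_na=False)
    if df.shape[1] not in (2, 3):
        raise ParseError(f"{path}: expected 2 or 3 columns, found {df.shape[1]}")
    if str(df.iat[0, 0]).strip() == "sample_id":
        df = df.iloc[1:]
    if df.empty:
        raise ParseError(f"{path}: no labeled samples")
    classes = pd.Series(df[1].to_numpy(), index=df[0].to_numpy(), name="class")
    cohorts = None
    if df.shape[1] == 3:
        cohorts = pd.Series(df[2].to_numpy(), index=df[0].to_numpy(), name="cohort")
    return PhenotypeLabels(classes=classes, cohorts=cohorts)


def write_labels(labels: PhenotypeLabels, path: str | Path) -> None:
    cols = {"sample_id": labels.classes.index, "class": labels.classes.to_numpy()}
    if labels.cohorts is not None:
        cols["cohort"] = labels.cohorts.reindex(labels.classes.index).to_numpy()
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Probe → gene mapping
# ---------------------------------------------------------------------------


@dataclass
class ProbeGeneMap:
    """Mapping from probe id to the set of genes it interrogates."""

    mapping: dict[str, frozenset[str]]

    def genes_for(self, probe_id: str) -> frozenset[str]:
        return self.mapping.get(probe_id, frozenset())


def read_probe_map(path: str | Path) -> ProbeGeneMap:
    """Read a two-column TSV: probe_id, comma-separated gene ids."""
    mapping: dict[str, frozenset[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split("\t")
            probe = parts[0].strip()
            if lineno == 1 and probe == "probe_id":
                continue
            if probe in mapping:
                raise ParseError(f"{path}: duplicate probe id {probe!r} (line {lineno})")
            genes_field = parts[1].strip() if len(parts) > 1 else ""
            genes = frozenset(g.strip() for g in genes_field.split(",") if g.strip())
            mapping[probe] = genes
    return ProbeGeneMap(mapping)


def map_probes_to_genes(
    probe_matrix: ExpressionMatrix, probe_map: ProbeGeneMap
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    Probes mapping to zero or to multiple genes are dropped.  When several
    probes map to the same gene, the gene's value per sample is the
    arithmetic mean of the (unmasked) probe values.
    """
    gene_for_probe: dict[str, str] = {}
    for probe in probe_matrix.gene_ids:
        genes = probe_map.genes_for(probe)
        if len(genes) == 1:
            gene_for_probe[probe] = next(iter(genes))
    if not gene_for_probe:
        raise ValidationError("no probe maps uniquely to a gene; output would be empty")
    sub = probe_matrix.values.loc[list(gene_for_probe)]
    grouped = sub.groupby([gene_for_probe[p] for p in sub.index]).mean()
    grouped = grouped.sort_index()
    return ExpressionMatrix(grouped)


# ---------------------------------------------------------------------------
# Signatures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignaturePair:
    """One oriented gene pair of a signature.

    ``reference_orientation`` is the ordering expected in the reference
    (e.g. non-cancer) class; the reversed ordering votes for the
    alternative class.  ``coverage_rate`` is the geometric mean of the
    reference-orientation frequency in reference-class training samples and
    the reversed-orientation frequency in alternative-class samples.
    """

    gene_i: str
    gene_j: str
    reference_orientation: Orientation
    coverage_rate: float

    def __post_init__(self) -> None:
        if self.reference_orientation not in (
            Orientation.I_GREATER,
            Orientation.J_GREATER,
        ):
            raise ValidationError(
                "signature pair orientation must be '>' or '<', got "
                f"{self.reference_orientation!r}"
            )
        if self.gene_i == self.gene_j:
            raise ValidationError(f"degenerate pair ({self.gene_i!r}, {self.gene_j!r})")
        if not 0.0 <= self.coverage_rate <= 1.0:
            raise ValidationError(f"coverage rate {self.coverage_rate} outside [0, 1]")

    @property
    def unordered(self) -> frozenset[str]:
        return frozenset((self.gene_i, self.gene_j))


@dataclass
class Signature:
    """An ordered reversal-pair list plus the odd vote count ``k``.

    Only the top ``k`` pairs vote at classification time; the remainder are
    retained for provenance and for re-selection of ``k``.
    """

    pairs: list[SignaturePair]
    reference_class: str
    alternative_class: str
    k: int

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValidationError("signature pair list is empty")
        if not isinstance(self.k, (int, np.integer)) or isinstance(self.k, bool):
            raise ValidationError(f"k must be an integer, got {self.k!r}")
        self.k = int(self.k)
        if self.k < 1 or self.k % 2 == 0:
            raise ValidationError(f"k must be a positive odd integer, got {self.k}")
        if self.k > len(self.pairs):
            raise ValidationError(
                f"k={self.k} exceeds the number of pairs ({len(self.pairs)})"
            )
        seen: set[frozenset[str]] = set()
        for p in self.pairs:
            if p.unordered in seen:
                raise ValidationError(
                    f"gene pair ({p.gene_i}, {p.gene_j}) appears more than once"
                )
            seen.add(p.unordered)
        if self.reference_class == self.alternative_class:
            raise ValidationError("reference and alternative class names coincide")

    @property
    def top_pairs(self) -> list[SignaturePair]:
        return self.pairs[: self.k]


_SIG_HEADER = "gene_i\tgene_j\treference_orientation\tcoverage_rate"


def write_signature(signature: Signature, path: str | Path) -> None:
    """Write a signature as human-readable structured text (lossless)."""
    lines = [
        "# reosig-signature\t1",
        f"# reference_class\t{signature.reference_class}",
        f"# alternative_class\t{signature.alternative_class}",
        f"# k\t{signature.k}",
        _SIG_HEADER,
    ]
    for p in signature.pairs:
        lines.append(
            f"{p.gene_i}\t{p.gene_j}\t{p.reference_orientation.value}"
            f"\t{p.coverage_rate!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_signature(path: str | Path) -> Signature:
    path = Path(path)
    meta: dict[str, str] = {}
    pairs: list[SignaturePair] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) == 2:
                    meta[parts[0]] = parts[1]
                continue
            if line == _SIG_HEADER:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}: malformed signature row {line!r}")
            try:
                orientation = Orientation(fields[2])
                rate = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}: malformed signature row {line!r}") from exc
            pairs.append(SignaturePair(fields[0], fields[1], orientation, rate))
    for key in ("reference_class", "alternative_class", "k"):
        if key not in meta:
            raise ParseError(f"{path}: missing signature header field {key!r}")
    return Signature(
        pairs=pairs,
        reference_class=meta["reference_class"],
        alternative_class=meta["alternative_class"],
        k=int(meta["k"]),
    )
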