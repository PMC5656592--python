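"""Expression matrices, sample metadata, and gene-set I/O.

The central container is :class:`ExpressionMatrix`: a dense genes x samples
matrix of normalized expression intensities with per-sample phenotype
metadata (group, age, leukocyte subtype).  Everything downstream of this
module operates on within-sample orderings, so the absolute scale of the
values never matters -- any strictly increasing per-sample transform of the
values leaves every result of the package unchanged.

Identifiers are compared as exact strings after whitespace trimming.
Numeric (Entrez-style) identifiers are ordered as zero-padded strings so
that the canonical gene order is deterministic across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("control", "case", "none")

_PAD = 16  # zero-padding width for numeric identifiers


def gene_sort_key(gene_id: str) -> str:
    """Canonical sort key: numeric ids compare as zero-padded strings."""
    g = gene_id.strip()
    return g.zfill(_PAD) if g.isdigit() else g


def canonical_gene_order(gene_ids: Iterable[str]) -> list[str]:
    """Sort identifiers under the canonical total order."""
    return sorted((g.strip() for g in gene_ids), key=gene_sort_key)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample metadata.

    Parameters
    ----------
    gene_ids : array of str
        Unique gene identifiers, one per row.
    sample_ids : array of str
        Unique sample identifiers, one per column.
    values : 2-D float array
        Normalized expression intensities (platform-arbitrary units; this
        package treats them as log-scale intensities but only their
        within-sample order is ever used).
    group : array of str, optional
        Per-sample phenotype, each in ``{"control", "case", "none"}``.
    age : array of float, optional
        Per-sample age in years; NaN for missing.
    subtype : array of str, optional
        Purified-cell subtype label, ``"none"`` where not applicable.
    dataset : str
        Free-text tag naming the source dataset.
    """

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray
    group: np.ndarray = field(default=None)  # type: ignore[assignment]
    age: np.ndarray = field(default=None)  # type: ignore[assignment]
    subtype: np.ndarray = field(default=None)  # type: ignore[assignment]
    dataset: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray([str(g).strip() for g in self.gene_ids], dtype=object)
        self.sample_ids = np.asarray([str(s).strip() for s in self.sample_ids], dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n_genes, n_samples = len(self.gene_ids), len(self.sample_ids)
        if self.values.shape != (n_genes, n_samples):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n_genes} genes x {n_samples} samples"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene_ids (collapse probes first)")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("duplicate sample_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must all be finite")
        if self.group is None:
            self.group = np.full(n_samples, "none", dtype=object)
        self.group = np.asarray(self.group, dtype=object)
        if self.age is None:
            self.age = np.full(n_samples, np.nan)
        self.age = np.asarray(self.age, dtype=float)
        if self.subtype is None:
            self.subtype = np.full(n_samples, "none", dtype=object)
        self.subtype = np.asarray(self.subtype, dtype=object)
        for arr, name in ((self.group, "group"), (self.age, "age"), (self.subtype, "subtype")):
            if len(arr) != n_samples:
                raise ValueError(f"{name} length {len(arr)} != {n_samples} samples")
        bad = set(self.group) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; expected one of {GROUPS}")

    # -- basic introspection -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "group": self.group,
                "age": self.age,
                "subtype": self.subtype,
            }
        )

    # -- subsetting ----------------------------------------------------------

    def select_samples(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ExpressionMatrix(
            self.gene_ids,
            self.sample_ids[idx],
            self.values[:, idx],
            self.group[idx],
            self.age[idx],
            self.subtype[idx],
            self.dataset,
        )

    def select_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(gene_ids)
        return ExpressionMatrix(
            np.asarray(gene_ids, dtype=object),
            self.sample_ids,
            self.values[idx, :],
            self.group,
            self.age,
            self.subtype,
            self.dataset,
        )

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        """Row indices for ``gene_ids``; raises KeyError listing absentees."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}"
                           + (" ..." if len(missing) > 10 else ""))
        return np.fromiter((pos[g] for g in gene_ids), dtype=np.intp, count=len(gene_ids))

    def controls(self) -> "ExpressionMatrix":
        return self.select_samples(self.group == "control")

    def cases(self) -> "ExpressionMatrix":
        return self.select_samples(self.group == "case")

    def with_group(self, group: np.ndarray) -> "ExpressionMatrix":
        return replace(self, group=np.asarray(group, dtype=object))


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (GMT line)."""

    name: str
    genes: frozenset
    source: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet needs a non-empty name")
        object.__setattr__(self, "genes", frozenset(str(g).strip() for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------


class ExpressionParseError(ValueError):
    pass


def read_expression(
    path,
    layout: str = "plain-tsv",
    metadata_path=None,
    collapse_rule: str = "median",
) -> ExpressionMatrix:
    """Read an expression matrix from disk.

    ``plain-tsv``: UTF-8 TSV whose first header field is ``gene_id`` followed
    by sample ids; one gene per row.  ``series-matrix``: best-effort reader
    for the GEO series-matrix layout (the table between the
    ``!series_matrix_table_begin/end`` markers; phenotype metadata is not
    interpreted).

    Rows containing any missing or non-numeric value are dropped (within-
    sample order comparisons need complete pairs); the count is logged.
    Duplicate gene rows are collapsed with :func:`collapse_duplicates`.
    """
    path = Path(path)
    if layout == "plain-tsv":
        frame = _read_plain_tsv(path)
    elif layout == "series-matrix":
        frame = _read_series_matrix(path)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    numeric = frame.apply(pd.to_numeric, errors="coerce")
    keep = numeric.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d gene rows with missing/non-numeric values", n_dropped)
    numeric = numeric.loc[keep]
    if numeric.shape[0] == 0:
        raise ExpressionParseError(f"{path}: no complete gene rows after cleaning")

    gene_ids = np.asarray([str(g).strip() for g in numeric.index], dtype=object)
    m = _matrix_allowing_duplicates(
        gene_ids, np.asarray(numeric.columns, dtype=object), numeric.to_numpy(float)
    )
    m = collapse_duplicates(m, rule=collapse_rule)
    if metadata_path is not None:
        m = attach_metadata(m, metadata_path)
    m.dataset = path.stem
    return m


def _read_plain_tsv(path: Path) -> pd.DataFrame:
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
    fields = header.rstrip("\n").split("\t")
    if len(fields) < 2:
        raise ExpressionParseError(f"{path}:1: header has {len(fields)} field(s); "
                                   "expected gene_id + at least one sample id")
    return pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})


def _read_series_matrix(path: Path) -> pd.DataFrame:
    lines = []
    inside = False
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if line.startswith("!series_matrix_table_end"):
                inside = False
                continue
            if inside:
                lines.append(line)
    if not lines:
        raise ExpressionParseError(f"{path}: no series_matrix_table block found")
    from io import StringIO

    frame = pd.read_csv(StringIO("".join(lines)), sep="\t", index_col=0)
    frame.index = [str(g).strip().strip('"') for g in frame.index]
    frame.columns = [str(c).strip().strip('"') for c in frame.columns]
    return frame


class _MatrixWithDuplicates(ExpressionMatrix):
    """Internal: relaxes the unique-gene invariant until probes are collapsed."""

    def __post_init__(self) -> None:  # duplicate gene ids tolerated here only
        saved = self.gene_ids
        self.gene_ids = np.asarray(
            [f"{g}\x00{i}" for i, g in enumerate(saved)], dtype=object
        )
        super().__post_init__()
        self.gene_ids = np.asarray([str(g).strip() for g in saved], dtype=object)


def _matrix_allowing_duplicates(gene_ids, sample_ids, values) -> ExpressionMatrix:
    return _MatrixWithDuplicates(gene_ids, sample_ids, values)


def collapse_duplicates(matrix: ExpressionMatrix, rule: str = "median") -> ExpressionMatrix:
    """Resolve repeated gene rows (probe-level input) to one row per gene.

    ``median`` takes the per-sample median across a gene's probes (robust to
    a single aberrant probe and the least disruptive to within-sample
    orderings); ``max-mean-probe`` keeps the single probe with the highest
    overall mean, a common microarray convention.
    """
    if rule not in ("median", "max-mean-probe"):
        raise ValueError(f"unknown collapse rule {rule!r}")
    ids = matrix.gene_ids
    uniq, inverse, counts = np.unique(ids, return_inverse=True, return_counts=True)
    if counts.max(initial=0) <= 1:
        if isinstance(matrix, _MatrixWithDuplicates):
            return ExpressionMatrix(
                matrix.gene_ids, matrix.sample_ids, matrix.values,
                matrix.group, matrix.age, matrix.subtype, matrix.dataset,
            )
        return matrix
    n_dup = int((counts > 1).sum())
    logger.info("collapsing %d duplicated gene id(s) with rule %r", n_dup, rule)
    out = np.empty((len(uniq), matrix.n_samples))
    for u in range(len(uniq)):
        rows = matrix.values[inverse == u]
        if rule == "median":
            out[u] = np.median(rows, axis=0)
        else:
            out[u] = rows[np.argmax(rows.mean(axis=1))]
    return ExpressionMatrix(
        uniq.astype(object), matrix.sample_ids, out,
        matrix.group, matrix.age, matrix.subtype, matrix.dataset,
    )


def attach_metadata(matrix: ExpressionMatrix, metadata_path) -> ExpressionMatrix:
    """Attach a sidecar metadata TSV (sample_id, group, age, subtype)."""
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    meta = meta.set_index("sample_id")
    missing = [s for s in matrix.sample_ids if s not in meta.index]
    if missing:
        raise ExpressionParseError(f"metadata missing samples: {missing[:10]}")
    meta = meta.loc[list(matrix.sample_ids)]
    group = meta["group"].fillna("none").astype(str).to_numpy(object) if "group" in meta else None
    age = pd.to_numeric(meta["age"], errors="coerce").to_numpy(float) if "age" in meta else None
    subtype = (
        meta["subtype"].fillna("none").astype(str).to_numpy(object) if "subtype" in meta else None
    )
    return ExpressionMatrix(
        matrix.gene_ids, matrix.sample_ids, matrix.values, group, age, subtype, matrix.dataset
    )


def write_expression(matrix: ExpressionMatrix, path, metadata_path=None) -> None:
    """Write the plain-tsv layout; round-trips values bit-identically."""
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    # repr-based float formatting preserves the exact binary value
    frame.to_csv(path, sep="\t", float_format=None)
    if metadata_path is not None:
        matrix.metadata_frame().to_csv(metadata_path, sep="\t", index=False)


def intersect_universe(matrices: Sequence[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict every matrix to the genes common to all, in canonical order."""
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to intersect")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValueError("gene universes have empty intersection")
    ordered = canonical_gene_order(common)
    logger.info("common gene universe: %d genes", len(ordered))
    return [m.select_genes(ordered) for m in matrices]


def read_gmt(path) -> list[GeneSet]:
    """Read a standard GMT gene-set file (name, description, members...)."""
    sets: list[GeneSet] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ExpressionParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, desc = fields[0], fields[1]
            members = [f.strip() for f in fields[2:] if f.strip()]
            sets.append(GeneSet(name=name, genes=frozenset(members), source=desc))
    return sets


def write_gmt(sets: Sequence[GeneSet], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.source or "."] + sorted(s.genes)) + "\n")
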