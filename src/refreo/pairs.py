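"""Reference gene-pair detection from purified leukocyte profiles.

A *reference pair* is a gene pair whose within-sample ordering (relative
expression ordering, REO) is stable within every purified leukocyte subtype
and points the same way in all subtypes.  Because a bulk blood sample is a
convex combination of its constituent cell types, such an ordering is
preserved in any mixture as long as neither gene changes expression inside
the cells -- which is exactly what makes reference pairs immune to
cell-proportion confounding.

Pairs are stored canonically: ``gene_a`` precedes ``gene_b`` under the
canonical identifier order (lexicographic; numeric ids zero-padded), and
``orientation`` is +1 when the reference says gene_a is the higher of the
two ("a_gt_b"), -1 otherwise.  Internally a pair set holds integer indices
into its sorted gene universe, which keeps the O(G^2) pair stage vectorized
and lets the enumeration run in fixed-size row blocks so the full pair list
never has to exist in memory at once.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .matrix import ExpressionMatrix, canonical_gene_order

logger = logging.getLogger(__name__)

ORIENT_LABEL = {1: "a_gt_b", -1: "b_gt_a"}
ORIENT_VALUE = {v: k for k, v in ORIENT_LABEL.items()}


@dataclass
class ReferencePairSet:
    """A set of canonically stored, oriented gene pairs.

    ``genes`` is the pair universe in canonical order; ``ia``/``ib`` index
    into it with ``ia < ib`` for every pair; ``orientation`` is +1 for
    "first gene higher", -1 for "second gene higher".
    """

    genes: np.ndarray
    ia: np.ndarray
    ib: np.ndarray
    orientation: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.ia = np.asarray(self.ia, dtype=np.int64)
        self.ib = np.asarray(self.ib, dtype=np.int64)
        self.orientation = np.asarray(self.orientation, dtype=np.int8)
        if not (len(self.ia) == len(self.ib) == len(self.orientation)):
            raise ValueError("pair arrays must have equal length")
        if len(self.ia) and not np.all(self.ia < self.ib):
            raise ValueError("pairs must be stored canonically (ia < ib)")
        if len(self.ia) and not np.all(np.isin(self.orientation, (-1, 1))):
            raise ValueError("orientation must be +1 or -1")

    def __len__(self) -> int:
        return len(self.ia)

    @property
    def gene_a(self) -> np.ndarray:
        return self.genes[self.ia]

    @property
    def gene_b(self) -> np.ndarray:
        return self.genes[self.ib]

    def pair_dict(self) -> dict[tuple[str, str], int]:
        """Mapping (gene_a, gene_b) -> orientation; convenient for tests."""
        return {
            (a, b): int(o)
            for a, b, o in zip(self.gene_a, self.gene_b, self.orientation)
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene_a": self.gene_a,
                "gene_b": self.gene_b,
                "orientation": [ORIENT_LABEL[int(o)] for o in self.orientation],
            }
        )


def _subtype_blocks(matrix: ExpressionMatrix) -> list[np.ndarray]:
    labels = [s for s in np.unique(matrix.subtype) if s != "none"]
    return [matrix.values[:, matrix.subtype == s] for s in labels]


def stable_pairs(
    matrix: ExpressionMatrix,
    within_subtype_frac: float | None = None,
    block_size: int = 256,
) -> ReferencePairSet:
    """Enumerate gene pairs with a stable, subtype-consistent ordering.

    A pair qualifies when one orientation holds in at least
    ``within_subtype_frac`` of the samples of *every* subtype, and that
    orientation is the within-subtype majority everywhere.  A tied sample
    (equal values) supports neither orientation, so at the default
    ``within_subtype_frac = 1.0`` a single tie disqualifies a pair.

    Rows are processed in blocks of ``block_size`` genes, so memory use is
    O(block_size x n_genes) rather than O(n_genes^2).
    """
    if not np.all(np.isfinite(matrix.values)):
        raise ValueError("expression values must be finite")
    blocks = _subtype_blocks(matrix)
    if len(blocks) < 2 and within_subtype_frac is None:
        raise ValueError(
            "only one subtype present: pass within_subtype_frac explicitly to "
            "confirm single-subtype stability is intended"
        )
    frac = 1.0 if within_subtype_frac is None else float(within_subtype_frac)
    if not 0.0 < frac <= 1.0:
        raise ValueError("within_subtype_frac must be in (0, 1]")
    if not blocks:
        raise ValueError("matrix has no subtype labels")

    order = canonical_gene_order(matrix.gene_ids)
    m = matrix.select_genes(order)
    blocks = _subtype_blocks(m)
    G = m.n_genes

    ia_parts, ib_parts, orient_parts = [], [], []
    for lo in range(0, G, block_size):
        hi = min(lo + block_size, G)
        ok_pos = np.ones((hi - lo, G), dtype=bool)
        ok_neg = np.ones((hi - lo, G), dtype=bool)
        for X in blocks:
            n_s = X.shape[1]
            need = frac * n_s - 1e-9
            gt = X[lo:hi, None, :] > X[None, :, :]
            lt = X[lo:hi, None, :] < X[None, :, :]
            npos = gt.sum(axis=2)
            nneg = lt.sum(axis=2)
            ok_pos &= (npos >= need) & (npos > nneg)
            ok_neg &= (nneg >= need) & (nneg > npos)
        # keep only the canonical upper triangle j > i
        cols = np.arange(G)[None, :]
        rows = np.arange(lo, hi)[:, None]
        upper = cols > rows
        for ok, sign in ((ok_pos, 1), (ok_neg, -1)):
            r, c = np.nonzero(ok & upper)
            if len(r):
                ia_parts.append(r + lo)
                ib_parts.append(c)
                orient_parts.append(np.full(len(r), sign, dtype=np.int8))

    if ia_parts:
        ia = np.concatenate(ia_parts)
        ib = np.concatenate(ib_parts)
        orientation = np.concatenate(orient_parts)
        idx = np.lexsort((ib, ia))
        ia, ib, orientation = ia[idx], ib[idx], orientation[idx]
    else:
        ia = np.empty(0, dtype=np.int64)
        ib = np.empty(0, dtype=np.int64)
        orientation = np.empty(0, dtype=np.int8)

    logger.info("stable pairs: %d of %d possible", len(ia), G * (G - 1) // 2)
    return ReferencePairSet(
        genes=np.asarray(order, dtype=object),
        ia=ia,
        ib=ib,
        orientation=orientation,
        provenance={
            "source": matrix.dataset,
            "within_subtype_frac": frac,
            "n_genes": G,
            "n_subtypes": len(blocks),
        },
    )


def _pair_keys(pairs: ReferencePairSet) -> np.ndarray:
    return np.asarray(
        [f"{a}\x00{b}" for a, b in zip(pairs.gene_a, pairs.gene_b)], dtype=object
    )


def intersect_references(
    set_a: ReferencePairSet, set_b: ReferencePairSet
) -> tuple[ReferencePairSet, dict]:
    """Pairs present in both sets with matching orientation, plus a report.

    The report gives the shared-pair count, how many of those agree on
    orientation, the consistency fraction, and a one-sided binomial p-value
    for consistency exceeding the coin-flip rate 0.5 -- the check used to
    argue that two independently derived reference lists describe the same
    underlying ordering structure.
    """
    keys_a = _pair_keys(set_a)
    keys_b = _pair_keys(set_b)
    common, idx_a, idx_b = np.intersect1d(keys_a, keys_b, return_indices=True)
    n_shared = len(common)
    if n_shared == 0:
        logger.warning("reference pair sets share no pairs")
        empty = ReferencePairSet(
            genes=set_a.genes, ia=np.empty(0, int), ib=np.empty(0, int),
            orientation=np.empty(0, np.int8),
            provenance={"intersection_of": [set_a.provenance, set_b.provenance]},
        )
        return empty, {"n_shared": 0, "n_consistent": 0,
                       "consistency": float("nan"), "binom_p": float("nan")}
    same = set_a.orientation[idx_a] == set_b.orientation[idx_b]
    n_consistent = int(same.sum())
    consistency = n_consistent / n_shared
    binom_p = float(stats.binom.sf(n_consistent - 1, n_shared, 0.5))
    keep_a = idx_a[same]
    out = ReferencePairSet(
        genes=set_a.genes,
        ia=set_a.ia[keep_a],
        ib=set_a.ib[keep_a],
        orientation=set_a.orientation[keep_a],
        provenance={"intersection_of": [set_a.provenance, set_b.provenance]},
    )
    report = {
        "n_shared": n_shared,
        "n_consistent": n_consistent,
        "consistency": consistency,
        "binom_p": binom_p,
    }
    return out, report


# ---------------------------------------------------------------------------
# on-disk pair lists
# ---------------------------------------------------------------------------


def write_pairs(pairs: ReferencePairSet, path) -> None:
    """Write a pair list as TSV with a '#'-prefixed provenance header.

    A checksum over the data lines is embedded so silent truncation or
    corruption is caught on read.
    """
    body_lines = [
        f"{a}\t{b}\t{ORIENT_LABEL[int(o)]}"
        for a, b, o in zip(pairs.gene_a, pairs.gene_b, pairs.orientation)
    ]
    body = "\n".join(body_lines)
    digest = hashlib.sha256(body.encode()).hexdigest()
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# refreo pair list\n")
        fh.write(f"# n_pairs: {len(pairs)}\n")
        fh.write(f"# sha256: {digest}\n")
        for k, v in pairs.provenance.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("gene_a\tgene_b\torientation\n")
        if body:
            fh.write(body + "\n")


def read_pairs(path) -> ReferencePairSet:
    """Read a pair list written by :func:`write_pairs`; verifies checksum."""
    header: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                if ":" in line:
                    k, v = line[1:].split(":", 1)
                    header[k.strip()] = v.strip()
                continue
            if line.startswith("gene_a\t") or not line:
                continue
            body_lines.append(line)
    body = "\n".join(body_lines)
    digest = hashlib.sha256(body.encode()).hexdigest()
    if "sha256" in header and header["sha256"] != digest:
        raise IOError(f"{path}: checksum mismatch, pair list is corrupt")
    if "n_pairs" in header and int(header["n_pairs"]) != len(body_lines):
        raise IOError(f"{path}: expected {header['n_pairs']} pairs, "
                      f"found {len(body_lines)}")
    ga, gb, orient = [], [], []
    for line in body_lines:
        a, b, o = line.split("\t")
        ga.append(a)
        gb.append(b)
        orient.append(ORIENT_VALUE[o])
    genes = np.asarray(canonical_gene_order(set(ga) | set(gb)), dtype=object)
    pos = {g: i for i, g in enumerate(genes)}
    ia = np.asarray([pos[g] for g in ga], dtype=np.int64)
    ib = np.asarray([pos[g] for g in gb], dtype=np.int64)
    prov = {k: v for k, v in header.items() if k not in ("sha256", "n_pairs")}
    return ReferencePairSet(genes, ia, ib, np.asarray(orient, np.int8), prov)
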