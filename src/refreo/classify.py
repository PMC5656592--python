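"""Reversed-pair diagnostic signature: scoring and AUC evaluation.

The reversed pairs found in a discovery cohort double as a rank-based
diagnostic signature.  A sample's score is the fraction of signature pairs
whose within-sample ordering matches the *disease* orientation (the
reverse of the reference orientation); ties match neither orientation and
therefore only lower the score.  The score is a pure rank statistic, so it
transfers across platforms and normalizations unchanged.

Discrimination is summarized by the AUC in its Mann-Whitney form: the
probability that a randomly chosen case outscores a randomly chosen
control, with tied scores counting one half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._core import pair_sign
from .matrix import ExpressionMatrix
from .pairs import ORIENT_LABEL, ORIENT_VALUE
from .reversal import FilteredPairSet

logger = logging.getLogger(__name__)


@dataclass
class PairSignature:
    """Oriented pair list used as a diagnostic signature.

    ``orientation`` stores the *reference* (normal) orientation; the
    disease orientation is its opposite for every pair.
    """

    gene_a: np.ndarray
    gene_b: np.ndarray
    orientation: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_a = np.asarray(self.gene_a, dtype=object)
        self.gene_b = np.asarray(self.gene_b, dtype=object)
        self.orientation = np.asarray(self.orientation, dtype=np.int8)
        if not (len(self.gene_a) == len(self.gene_b) == len(self.orientation)):
            raise ValueError("signature arrays must have equal length")

    def __len__(self) -> int:
        return len(self.gene_a)

    @property
    def genes(self) -> set:
        return set(self.gene_a) | set(self.gene_b)


def signature_from_reversals(
    filtered: FilteredPairSet, reversals: pd.DataFrame, tag: str = ""
) -> PairSignature:
    """Build a signature from the pairs flagged ``reversed_in_cases``."""
    flagged = reversals["reversed_in_cases"].to_numpy(bool)
    if not flagged.any():
        raise ValueError("no reversed pairs: cannot build a signature")
    return PairSignature(
        gene_a=filtered.gene_a[flagged],
        gene_b=filtered.gene_b[flagged],
        orientation=filtered.orientation[flagged],
        provenance={"discovery": tag or filtered.provenance.get("source", ""),
                    "n_pairs": int(flagged.sum())},
    )


def score_samples(matrix: ExpressionMatrix, signature: PairSignature) -> pd.Series:
    """Disease-orientation match fraction per sample, in [0, 1].

    0 means every signature pair sits in its normal orientation; 1 means
    every pair is flipped the disease way.  Raises on missing genes.
    """
    if len(signature) == 0:
        raise ValueError("empty signature")
    genes = sorted(signature.genes)
    idx = matrix.gene_index(genes)  # raises KeyError listing missing ids
    pos = {g: i for g, i in zip(genes, idx)}
    ia = np.asarray([pos[g] for g in signature.gene_a], dtype=np.int64)
    ib = np.asarray([pos[g] for g in signature.gene_b], dtype=np.int64)
    s = pair_sign(matrix.values, ia, ib)
    disease = -signature.orientation[:, None]
    score = (s == disease).sum(axis=0) / len(signature)
    return pd.Series(score, index=matrix.sample_ids, name="score")


def score_sample(sample_values: np.ndarray, gene_ids, signature: PairSignature) -> float:
    """Score a single expression vector (convenience wrapper)."""
    m = ExpressionMatrix(gene_ids, ["s"], np.asarray(sample_values, float)[:, None])
    return float(score_samples(m, signature).iloc[0])


def evaluate_auc(scores, labels) -> float:
    """AUC = P(random case outscores random control); ties count 0.5.

    Computed from midranks (the Mann-Whitney identity), exact for any
    number of ties.  ``labels`` is boolean-like with True = case.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def roc_points(scores, labels) -> list[dict]:
    """(fpr, tpr, threshold) points of the empirical ROC curve."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    order = np.argsort(-scores, kind="stable")
    thresholds = np.unique(scores)[::-1]
    pts = [{"fpr": 0.0, "tpr": 0.0, "threshold": float("inf")}]
    for t in thresholds:
        pred = scores >= t
        tpr = float((pred & y).sum() / max(y.sum(), 1))
        fpr = float((pred & ~y).sum() / max((~y).sum(), 1))
        pts.append({"fpr": fpr, "tpr": tpr, "threshold": float(t)})
    return pts


def cross_dataset_transfer(
    signature: PairSignature, matrix: ExpressionMatrix
) -> dict:
    """Apply a discovery signature to an independent cohort.

    Pairs whose genes are missing from the target are dropped with a
    warning; the report carries the retained fraction.  Returns a dict with
    the AUC, the per-sample score table, and coverage details.
    """
    if len(signature) == 0:
        raise ValueError("empty signature")
    present = set(matrix.gene_ids)
    keep = np.asarray(
        [a in present and b in present
         for a, b in zip(signature.gene_a, signature.gene_b)]
    )
    coverage = float(keep.mean())
    if coverage == 0:
        raise ValueError("target matrix covers none of the signature genes")
    sig = signature
    if coverage < 1.0:
        logger.warning("signature restricted to %.1f%% of pairs covered by target",
                       100 * coverage)
        sig = PairSignature(
            signature.gene_a[keep], signature.gene_b[keep],
            signature.orientation[keep],
            {**signature.provenance, "restricted_to": coverage},
        )
    scores = score_samples(matrix, sig)
    labeled = np.isin(matrix.group, ("control", "case"))
    y = matrix.group[labeled] == "case"
    auc = evaluate_auc(scores.to_numpy()[labeled], y)
    table = pd.DataFrame(
        {"sample_id": matrix.sample_ids, "score": scores.to_numpy(),
         "group": matrix.group}
    )
    return {
        "auc": auc,
        "scores": table,
        "n_pairs_used": len(sig),
        "coverage": coverage,
    }


# ---------------------------------------------------------------------------
# signature files
# ---------------------------------------------------------------------------


def write_signature(signature: PairSignature, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# refreo pair signature\n")
        for k, v in signature.provenance.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("gene_a\tgene_b\tdisease_orientation\n")
        for a, b, o in zip(signature.gene_a, signature.gene_b, signature.orientation):
            fh.write(f"{a}\t{b}\t{ORIENT_LABEL[-int(o)]}\n")


def read_signature(path) -> PairSignature:
    prov: dict = {}
    ga, gb, orient = [], [], []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                if ":" in line:
                    k, v = line[1:].split(":", 1)
                    prov[k.strip()] = v.strip()
                continue
            if not line or line.startswith("gene_a\t"):
                continue
            a, b, o = line.split("\t")
            ga.append(a)
            gb.append(b)
            orient.append(-ORIENT_VALUE[o])  # file stores the disease orientation
    return PairSignature(np.asarray(ga, object), np.asarray(gb, object),
                         np.asarray(orient, np.int8), prov)
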