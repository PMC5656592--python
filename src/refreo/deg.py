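"""Gene-level DEG calling from reversed pairs (hypergeometric urn model).

A gene participating in many filtered pairs should, by chance alone, carry
its share of whatever reversals the dataset shows.  The urn model makes
this exact: with N filtered pairs of which K are reversed, a gene sitting
in n of them would contain a hypergeometric number of reversed pairs; the
gene's p-value is the upper tail P(X >= k) at its observed count k.
BH adjustment runs over all genes that appear in at least one filtered
pair, and a gene is a DEG when the adjusted p falls below alpha.

Direction comes from the geometry of each reversal: in a reversed pair the
previously lower gene now sits above its partner (it rose -> "up") and the
previously higher one fell ("down").  Each reversed pair containing the
gene casts one vote; the majority wins and an exact tie is "undetermined".
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .reversal import FilteredPairSet
from .stats import bh_adjust

logger = logging.getLogger(__name__)

DIRECTIONS = ("up", "down", "undetermined")


def _gene_pair_counts(filtered: FilteredPairSet, flagged: np.ndarray):
    G = len(filtered.genes)
    n_pairs = np.bincount(filtered.ia, minlength=G) + np.bincount(filtered.ib, minlength=G)
    k_rev = (np.bincount(filtered.ia[flagged], minlength=G)
             + np.bincount(filtered.ib[flagged], minlength=G))
    return n_pairs, k_rev


def _direction_votes(filtered: FilteredPairSet, flagged: np.ndarray):
    """Per-gene (up, down) vote counts across reversed pairs.

    orientation +1 means gene_a was reference-higher: in a reversal gene_a
    fell (down) and gene_b rose (up); -1 is the mirror image.
    """
    G = len(filtered.genes)
    ia, ib = filtered.ia[flagged], filtered.ib[flagged]
    o = filtered.orientation[flagged]
    up = (np.bincount(ia[o == -1], minlength=G)
          + np.bincount(ib[o == 1], minlength=G))
    down = (np.bincount(ia[o == 1], minlength=G)
            + np.bincount(ib[o == -1], minlength=G))
    return up, down


def call_degs(
    filtered: FilteredPairSet,
    reversals: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric DEG calling over all genes in >= 1 filtered pair.

    ``reversals`` is the table from :func:`refreo.reversal.detect_reversals`
    (its ``reversed_in_cases`` flags define the reversed-pair universe).
    Returns one row per tested gene: pair-participation counts, upper-tail
    hypergeometric ``p``, BH ``p_adj``, the DEG flag, and the majority-vote
    direction (empty string for genes in no reversed pair).
    """
    if len(reversals) != len(filtered):
        raise ValueError("reversal table must cover exactly the filtered pairs")
    flagged = reversals["reversed_in_cases"].to_numpy(bool)
    N = len(filtered)
    K = int(flagged.sum())
    n_pairs, k_rev = _gene_pair_counts(filtered, flagged)
    tested = n_pairs > 0
    if K == 0:
        logger.warning("no reversed pairs: all gene p-values are 1")
    p = np.ones(len(filtered.genes))
    p[tested] = sps.hypergeom.sf(k_rev[tested] - 1, N, K, n_pairs[tested])
    p_adj = np.ones_like(p)
    p_adj[tested] = bh_adjust(p[tested])

    up, down = _direction_votes(filtered, flagged)
    direction = np.where(up > down, "up", np.where(down > up, "down", "undetermined"))
    direction = np.where(k_rev == 0, "", direction)

    out = pd.DataFrame(
        {
            "gene_id": filtered.genes,
            "n_pairs": n_pairs,
            "k_reversed": k_rev,
            "p": p,
            "p_adj": p_adj,
            "direction": direction,
            "is_deg": (p_adj < alpha) & tested,
        }
    )
    out = out[tested].reset_index(drop=True)
    logger.info("DEG calling: %d of %d tested genes at FDR %g",
                int(out["is_deg"].sum()), len(out), alpha)
    return out


def assign_direction(gene_id: str, filtered: FilteredPairSet,
                     reversals: pd.DataFrame) -> str:
    """Majority-vote direction for one gene; errors if the gene sits in no
    reversed pair (its direction is undefined)."""
    flagged = reversals["reversed_in_cases"].to_numpy(bool)
    pos = np.flatnonzero(filtered.genes == gene_id)
    if len(pos) == 0:
        raise KeyError(f"gene {gene_id!r} not in pair universe")
    g = pos[0]
    up, down = _direction_votes(filtered, flagged)
    if up[g] + down[g] == 0:
        raise ValueError(f"gene {gene_id!r} participates in no reversed pair")
    if up[g] > down[g]:
        return "up"
    if down[g] > up[g]:
        return "down"
    return "undetermined"
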