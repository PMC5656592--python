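"""Permutation nulls for reversal counts and gene-set interaction overlap.

Two randomization experiments accompany the pipeline.  The first asks
whether the number of significantly reversed pairs in a study could arise
with exchangeable labels: group labels are shuffled B times (group sizes
preserved), the full reversal test is re-run each time, and the empirical
p-value is the fraction of shuffles whose reversed-pair count strictly
exceeds the observed one; zero exceedances are reported as "p < 1/B".
The second asks whether a candidate gene list interacts with a reference
biomarker set more often than random gene lists of the same size drawn
from the background universe.

Randomness is governed by one seed through a spawned-substream scheme
(``numpy.random.SeedSequence(seed).spawn(B)``): iteration i always sees
the same generator state regardless of execution order, so results are
bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ._core import pair_sign
from .matrix import ExpressionMatrix
from .reversal import FilteredPairSet, _aligned_values, reversal_pvalues
from .stats import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    B: int
    seed: int
    null_mean: float = field(init=False)
    null_sd: float = field(init=False)
    p: float = field(init=False)
    p_label: str = field(init=False)

    def __post_init__(self) -> None:
        self.null = np.asarray(self.null)
        if len(self.null) != self.B:
            raise ValueError("null draw count must equal B")
        self.null_mean = float(self.null.mean()) if self.B else float("nan")
        self.null_sd = float(self.null.std(ddof=1)) if self.B > 1 else float("nan")
        # ties between a null draw and the observed statistic count toward p
        # (a draw equalling the observation is not evidence of excess)
        exceed = int((self.null >= self.observed).sum())
        self.p = exceed / self.B
        self.p_label = f"p < {1 / self.B:g}" if exceed == 0 else f"p = {self.p:g}"

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "B": self.B,
            "seed": self.seed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "p": self.p,
            "p_label": self.p_label,
        }


def _flag_count(conc, rev, case_mask, alpha, sided) -> int:
    """Reversal-test flag count for one labelling, from precomputed
    per-(pair, sample) concordance/reversal indicators."""
    cc = conc[:, ~case_mask].sum(axis=1)
    cr = rev[:, ~case_mask].sum(axis=1)
    ac = conc[:, case_mask].sum(axis=1)
    ar = rev[:, case_mask].sum(axis=1)
    p = reversal_pvalues(cc, cr, ac, ar, sided=sided)
    p_adj = bh_adjust(p)
    flag = (p_adj < alpha) & (ar * (cc + cr) > cr * (ac + ar))
    return int(flag.sum())


def shuffle_labels_null(
    filtered: FilteredPairSet,
    controls: ExpressionMatrix,
    cases: ExpressionMatrix,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    sided: str = "one",
) -> PermutationResult:
    """Label-shuffle null for the reversed-pair count.

    Group sizes are preserved in every shuffle.  The observed statistic is
    the reversed-pair count under the true labels; each iteration re-runs
    the identical Fisher + BH reversal test under shuffled labels.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if controls.n_samples == 0 or cases.n_samples == 0:
        raise ValueError("both groups must be non-empty")
    Xc = _aligned_values(filtered, controls)
    Xa = _aligned_values(filtered, cases)
    X = np.concatenate([Xc, Xa], axis=1)
    s = pair_sign(X, filtered.ia, filtered.ib)
    o = filtered.orientation[:, None]
    conc = (s == o)
    rev = (s == -o)
    n_total = X.shape[1]
    n_cases = cases.n_samples

    true_mask = np.zeros(n_total, dtype=bool)
    true_mask[controls.n_samples:] = True
    observed = _flag_count(conc, rev, true_mask, alpha, sided)

    children = np.random.SeedSequence(seed).spawn(B)
    null = np.empty(B, dtype=np.int64)
    for i in range(B):
        rng = np.random.default_rng(children[i])
        mask = np.zeros(n_total, dtype=bool)
        mask[rng.choice(n_total, size=n_cases, replace=False)] = True
        null[i] = _flag_count(conc, rev, mask, alpha, sided)
    result = PermutationResult(observed=observed, null=null, B=B, seed=seed)
    logger.info("label-shuffle null: observed %d reversed pairs, %s",
                observed, result.p_label)
    return result


def random_geneset_overlap_null(
    candidates,
    background,
    partner_map: Mapping[str, object],
    n_draw: int | None = None,
    B: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Random gene-draw null for interaction overlap.

    The statistic is the number of genes in a list that have at least one
    interaction partner recorded in ``partner_map`` (gene -> collection of
    partners).  ``candidates`` provides the observed list; the null draws
    ``n_draw`` genes (default: the candidate count) uniformly without
    replacement from ``background``.
    """
    cand = set(getattr(candidates, "genes", candidates))
    bg = np.asarray(sorted(set(background)), dtype=object)
    has_partner = {g for g, partners in partner_map.items() if partners}
    if not has_partner:
        logger.warning("partner map is empty: all statistics are zero")
    n = len(cand) if n_draw is None else int(n_draw)
    if n > len(bg):
        raise ValueError("cannot draw more genes than the background holds")
    observed = len(cand & has_partner)
    in_set = np.asarray([g in has_partner for g in bg])
    children = np.random.SeedSequence(seed).spawn(B)
    null = np.empty(B, dtype=np.int64)
    for i in range(B):
        rng = np.random.default_rng(children[i])
        draw = rng.choice(len(bg), size=n, replace=False)
        null[i] = int(in_set[draw].sum())
    result = PermutationResult(observed=observed, null=null, B=B, seed=seed)
    logger.info("gene-draw null: observed %d, null %.2f +/- %.2f, %s",
                observed, result.null_mean, result.null_sd, result.p_label)
    return result
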