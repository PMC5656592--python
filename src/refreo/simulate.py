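"""Synthetic purified-subtype profiles and mixed-cell cohorts.

The generator realizes the confounding mechanism the rank-pair pipeline is
designed to defeat.  Each leukocyte subtype has a log-normal expression
profile; a bulk blood sample is a convex combination of the subtype
profiles (in linear intensity space) with per-sample mixing proportions
drawn around a group-level vector; disease can act through two separable
channels:

* **proportion shift** -- the case group mixes the same subtype profiles
  with different weights.  No gene changes expression inside any cell, yet
  most genes' bulk means move, so naive per-gene tests light up.  Because
  every subtype keeps its ordering, reference-pair orderings are preserved
  and the rank-pair pipeline stays silent.
* **planted subtype DEGs** -- selected genes get a log2 fold change inside
  chosen subtypes, in case samples only.  These do flip orderings in the
  mixture and are the ground truth for precision/recall evaluation.

Ages are uniform over a configurable range with linear log2-scale effects
planted on a gene subset disjoint from the DEGs, and multiplicative
measurement noise (normal on the log2 scale) is applied last.  All
randomness flows from explicit seeds; identical inputs give bit-identical
outputs.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

# group-level mixing vectors: a neutrophil-dominated control blood and a
# shifted case profile used when proportion_shift is requested
DEFAULT_CONTROL_PROPS = (0.35, 0.25, 0.20, 0.12, 0.08)
DEFAULT_SHIFTED_PROPS = (0.50, 0.20, 0.14, 0.10, 0.06)


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic study; the evaluation oracle."""

    gene_ids: np.ndarray
    subtypes: list
    subtype_log2_means: np.ndarray          # genes x subtypes
    seed: int
    noise_sigma: float                      # log2-scale noise sd
    deg_genes: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    deg_lfc: np.ndarray = field(default_factory=lambda: np.empty(0))
    deg_subtypes: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    aging_gene_idx: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    age_slopes: np.ndarray = field(default_factory=lambda: np.empty(0))  # log2/yr
    control_props: np.ndarray | None = None
    case_props: np.ndarray | None = None
    proportion_shift: bool = False
    concentration: float = 300.0
    age_range: tuple = (52.0, 90.0)
    realized_props: dict = field(default_factory=dict)  # cohort tag -> array

    @property
    def deg_gene_ids(self) -> set:
        return {self.gene_ids[i] for i in self.deg_genes}

    @property
    def deg_direction(self) -> dict:
        """Planted direction per DEG gene id ('up'/'down' in cases)."""
        return {
            self.gene_ids[g]: ("up" if l > 0 else "down")
            for g, l in zip(self.deg_genes, self.deg_lfc)
        }


def generate_purified(
    n_genes: int = 1000,
    n_subtypes: int = 5,
    samples_per_subtype: int = 5,
    seed: int = 0,
    base_log2_mean: float = 7.0,
    gene_sd: float = 1.5,
    subtype_sd: float = 0.3,
    noise_sigma: float = 0.15,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Purified-subtype expression profiles with a known mean structure.

    Per-gene base log2 means are normal(``base_log2_mean``, ``gene_sd``);
    each subtype deviates by normal(0, ``subtype_sd``).  Because gene
    spacing (sd 1.5) dominates subtype deviation (sd 0.3), the bulk of
    gene pairs order the same way in every subtype -- the raw material for
    reference pairs.  Samples add normal(0, ``noise_sigma``) log2 noise
    (log-normal intensities).
    """
    if n_genes < 10:
        raise ValueError("need at least 10 genes")
    if n_subtypes < 2:
        raise ValueError("need at least 2 subtypes")
    if samples_per_subtype < 1:
        raise ValueError("need at least 1 sample per subtype")
    rng = np.random.default_rng(seed)
    gene_ids = np.asarray([f"G{i:05d}" for i in range(n_genes)], dtype=object)
    subtypes = [f"subtype{j}" for j in range(n_subtypes)]
    base = base_log2_mean + gene_sd * rng.standard_normal(n_genes)
    dev = subtype_sd * rng.standard_normal((n_genes, n_subtypes))
    means = base[:, None] + dev

    cols, labels = [], []
    for j in range(n_subtypes):
        noise = noise_sigma * rng.standard_normal((n_genes, samples_per_subtype))
        cols.append(means[:, [j]] + noise)
        labels += [subtypes[j]] * samples_per_subtype
    values = np.concatenate(cols, axis=1)
    sample_ids = [f"P{j:03d}" for j in range(values.shape[1])]
    matrix = ExpressionMatrix(
        gene_ids, sample_ids, values,
        subtype=np.asarray(labels, dtype=object),
        dataset="synthetic-purified",
    )
    truth = SyntheticTruth(
        gene_ids=gene_ids,
        subtypes=subtypes,
        subtype_log2_means=means,
        seed=seed,
        noise_sigma=noise_sigma,
    )
    return matrix, truth


def plant_signal(
    truth: SyntheticTruth,
    n_degs: int = 40,
    lfc_range: tuple = (2.0, 3.0),
    affected_subtypes: tuple = (0,),
    n_aging: int = 50,
    slope_range: tuple = (0.01, 0.03),
    seed: int = 0,
) -> SyntheticTruth:
    """Plant subtype-specific DEGs and aging slopes into a truth object.

    DEG log2 fold changes have magnitudes uniform in ``lfc_range`` with
    random signs and act inside ``affected_subtypes`` (default: subtype 0,
    the largest mixture component under the default proportions) in case
    samples only.  Aging genes are drawn from the remaining genes so the
    two truths stay separable; slopes are log2-units per year with random
    signs.  Returns a new truth; the input is not modified.
    """
    rng = np.random.default_rng(seed)
    t = copy.deepcopy(truth)
    n_genes = len(t.gene_ids)
    if n_degs + n_aging > n_genes:
        raise ValueError("n_degs + n_aging exceeds the gene count")
    perm = rng.permutation(n_genes)
    deg_idx = np.sort(perm[:n_degs])
    aging_idx = np.sort(perm[n_degs:n_degs + n_aging])
    lfc = rng.uniform(*lfc_range, size=n_degs) * rng.choice((-1.0, 1.0), size=n_degs)
    if np.any(lfc == 0):
        raise AssertionError("planted fold changes must be non-zero")
    slopes = rng.uniform(*slope_range, size=n_aging) * rng.choice((-1.0, 1.0), size=n_aging)
    t.deg_genes = deg_idx
    t.deg_lfc = lfc
    t.deg_subtypes = np.asarray(affected_subtypes, dtype=int)
    t.aging_gene_idx = aging_idx
    t.age_slopes = slopes
    return t


def generate_mixed_cohort(
    truth: SyntheticTruth,
    n_controls: int = 50,
    n_cases: int = 50,
    seed: int = 0,
    control_props=None,
    case_props=None,
    proportion_shift: bool = False,
    concentration: float = 300.0,
    noise_sigma: float | None = None,
    age_range: tuple = (52.0, 90.0),
    tag: str = "synthetic-mixed",
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Mixed-cell case/control cohort realized from a truth object.

    Each sample draws subtype proportions from a Dirichlet centred on its
    group vector (``concentration`` controls the per-sample jitter), mixes
    the subtype profiles in linear intensity space, and is reported as
    log2 intensity with planted age effects and multiplicative noise.
    Planted DEG fold changes act only inside the affected subtypes of case
    samples.  The returned truth carries the realized proportions.
    """
    if n_controls < 2 or n_cases < 2:
        raise ValueError("need at least 2 samples per group")
    S = len(truth.subtypes)
    if control_props is not None:
        cp = np.asarray(control_props, dtype=float)
    else:  # default vector truncated to S subtypes, renormalized
        cp = np.asarray(DEFAULT_CONTROL_PROPS[:S], dtype=float)
        cp = cp / cp.sum()
    if case_props is not None:
        ap = np.asarray(case_props, dtype=float)
    elif proportion_shift:
        ap = np.asarray(DEFAULT_SHIFTED_PROPS[:S], dtype=float)
        ap = ap / ap.sum()
    else:
        ap = cp.copy()
    for v, name in ((cp, "control_props"), (ap, "case_props")):
        if len(v) != S:
            raise ValueError(f"{name} has length {len(v)}, expected {S} subtypes")
        if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} must be non-negative and sum to 1")
    sigma = truth.noise_sigma if noise_sigma is None else float(noise_sigma)

    rng = np.random.default_rng(seed)
    n_genes = len(truth.gene_ids)

    # linear-scale subtype profiles; case profiles add the planted changes
    normal_linear = 2.0 ** truth.subtype_log2_means
    case_linear = normal_linear.copy()
    for g, lfc in zip(truth.deg_genes, truth.deg_lfc):
        case_linear[g, truth.deg_subtypes] *= 2.0 ** lfc

    n_total = n_controls + n_cases
    groups = np.asarray(["control"] * n_controls + ["case"] * n_cases, dtype=object)
    props = np.empty((n_total, S))
    values = np.empty((n_genes, n_total))
    ages = rng.uniform(age_range[0], age_range[1], size=n_total)
    age_mid = 0.5 * (age_range[0] + age_range[1])

    slope_vec = np.zeros(n_genes)
    slope_vec[truth.aging_gene_idx] = truth.age_slopes

    for i in range(n_total):
        is_case = groups[i] == "case"
        base_props = ap if is_case else cp
        if concentration and np.isfinite(concentration):
            p = rng.dirichlet(np.maximum(concentration * base_props, 1e-12))
        else:
            p = base_props.copy()
        props[i] = p
        profile = case_linear if is_case else normal_linear
        mixed = profile @ p
        log2v = np.log2(mixed)
        log2v = log2v + slope_vec * (ages[i] - age_mid)
        log2v = log2v + sigma * rng.standard_normal(n_genes)
        values[:, i] = log2v

    sample_ids = [f"S{i:04d}" for i in range(n_total)]
    matrix = ExpressionMatrix(
        truth.gene_ids, sample_ids, values,
        group=groups, age=ages, dataset=tag,
    )
    out = copy.deepcopy(truth)
    out.control_props = cp
    out.case_props = ap
    out.proportion_shift = bool(proportion_shift or not np.allclose(cp, ap))
    out.concentration = concentration
    out.age_range = tuple(age_range)
    out.realized_props = {**truth.realized_props, tag: props}
    return matrix, out


def make_two_cohorts(
    truth: SyntheticTruth,
    sizes=((50, 50), (50, 50)),
    seeds=(1, 2),
    **kwargs,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Two independent cohorts from one truth (for transfer experiments)."""
    if seeds[0] == seeds[1]:
        warnings.warn("cohorts share a seed; they will not be independent")
    m1, _ = generate_mixed_cohort(
        truth, *sizes[0], seed=seeds[0], tag="synthetic-cohort-1", **kwargs
    )
    m2, _ = generate_mixed_cohort(
        truth, *sizes[1], seed=seeds[1], tag="synthetic-cohort-2", **kwargs
    )
    return m1, m2
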