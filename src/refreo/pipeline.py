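"""End-to-end pipeline orchestration with provenance.

``run_pipeline`` executes the full chain -- reference pairs from purified
profiles, control filtering, reversal detection, DEG calling, and the
optional permutation / aging / classifier stages -- writing every stage's
table plus a provenance manifest (config hash, seed, stage row counts)
into a run directory.  Re-running over an up-to-date run directory is a
no-op unless ``force`` is set.

Inputs come either from plain-TSV files (purified-subtype matrix + study
matrix, each with a metadata sidecar) or from the bundled synthetic
generator when ``synthetic`` settings are given.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .classify import signature_from_reversals, write_signature, score_samples, evaluate_auc
from .deg import call_degs
from .matrix import ExpressionMatrix, intersect_universe, read_expression
from .pairs import stable_pairs, write_pairs
from .permute import shuffle_labels_null
from .reversal import detect_reversals, filter_by_controls
from .stats import aging_genes
from . import simulate as sim

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline thresholds and inputs in one validated object."""

    control_frac: float = 0.95
    fdr_alpha: float = 0.05
    within_subtype_frac: float = 1.0
    permutation_b: int = 1000
    seed: int = 0
    sided: str = "one"
    # file inputs (ignored when synthetic settings are present)
    purified_path: str | None = None
    purified_metadata: str | None = None
    study_path: str | None = None
    study_metadata: str | None = None
    # synthetic generation settings (kwargs for the simulate module)
    synthetic: dict | None = None
    run_permutation: bool = False
    run_aging: bool = False
    run_classifier: bool = False

    def validate(self) -> None:
        if not 0.0 < self.control_frac <= 1.0:
            raise ValueError("control_frac must be in (0, 1]")
        if not 0.0 < self.within_subtype_frac <= 1.0:
            raise ValueError("within_subtype_frac must be in (0, 1]")
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if self.permutation_b < 1:
            raise ValueError("permutation_b must be >= 1")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")
        if self.synthetic is None:
            for p in (self.purified_path, self.study_path):
                if p is None:
                    raise ValueError("file inputs or synthetic settings required")
                if not Path(p).exists():
                    raise FileNotFoundError(p)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        s = dict(config.synthetic)
        gen_keys = ("n_genes", "n_subtypes", "samples_per_subtype",
                    "base_log2_mean", "gene_sd", "subtype_sd", "noise_sigma")
        plant_keys = ("n_degs", "lfc_range", "affected_subtypes",
                      "n_aging", "slope_range")
        cohort_keys = ("n_controls", "n_cases", "control_props", "case_props",
                       "proportion_shift", "concentration", "age_range")
        purified, truth = sim.generate_purified(
            seed=config.seed, **{k: s[k] for k in gen_keys if k in s}
        )
        truth = sim.plant_signal(
            truth, seed=config.seed + 1, **{k: s[k] for k in plant_keys if k in s}
        )
        study, truth = sim.generate_mixed_cohort(
            truth, seed=config.seed + 2, **{k: s[k] for k in cohort_keys if k in s}
        )
        return purified, study, truth
    purified = read_expression(config.purified_path, metadata_path=config.purified_metadata)
    study = read_expression(config.study_path, metadata_path=config.study_metadata)
    purified, study = intersect_universe([purified, study])
    return purified, study, None


def run_pipeline(config: PipelineConfig, outdir, force: bool = False) -> dict:
    """Run all configured stages; returns the provenance manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    chash = config.config_hash()
    if manifest_path.exists() and not force:
        previous = json.loads(manifest_path.read_text())
        if previous.get("config_hash") == chash:
            logger.info("run directory up to date (config %s); skipping", chash)
            return previous

    counts: dict[str, int] = {}

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("inputs")
        purified, study, truth = _load_inputs(config)
        controls, cases = study.controls(), study.cases()

        _stage("refpairs")
        refs = stable_pairs(purified, within_subtype_frac=config.within_subtype_frac)
        write_pairs(refs, outdir / "reference_pairs.tsv")
        counts["reference_pairs"] = len(refs)

        _stage("filter")
        filtered = filter_by_controls(refs, controls, control_frac=config.control_frac)
        write_pairs(filtered, outdir / "filtered_pairs.tsv")
        counts["filtered_pairs"] = len(filtered)

        _stage("reversals")
        reversals = detect_reversals(
            filtered, controls, cases, alpha=config.fdr_alpha, sided=config.sided
        )
        reversals.drop(columns=["ia", "ib"]).to_csv(
            outdir / "reversals.tsv", sep="\t", index=False
        )
        counts["reversed_pairs"] = int(reversals["reversed_in_cases"].sum())

        _stage("degs")
        degs = call_degs(filtered, reversals, alpha=config.fdr_alpha)
        degs.to_csv(outdir / "degs.tsv", sep="\t", index=False)
        counts["genes_tested"] = len(degs)
        counts["degs"] = int(degs["is_deg"].sum())

        extra: dict = {}
        if config.run_permutation:
            _stage("permutation")
            perm = shuffle_labels_null(
                filtered, controls, cases, B=config.permutation_b,
                seed=config.seed, alpha=config.fdr_alpha, sided=config.sided,
            )
            extra["permutation"] = perm.to_dict()
            (outdir / "permutation.json").write_text(json.dumps(perm.to_dict(), indent=2))

        if config.run_aging:
            _stage("aging")
            aging = aging_genes(controls, alpha=config.fdr_alpha)
            aging.to_csv(outdir / "aging_genes.tsv", sep="\t", index=False)
            counts["aging_genes"] = int(aging["is_significant"].sum())

        if config.run_classifier and counts["reversed_pairs"] > 0:
            _stage("classifier")
            signature = signature_from_reversals(filtered, reversals, tag=study.dataset)
            write_signature(signature, outdir / "signature.tsv")
            scores = score_samples(study, signature)
            auc = evaluate_auc(scores.to_numpy(), study.group == "case")
            scores.rename_axis("sample_id").to_frame().assign(group=study.group).to_csv(
                outdir / "scores.tsv", sep="\t"
            )
            extra["classifier"] = {"auc": auc, "n_pairs": len(signature)}

        if truth is not None:
            called = set(degs.loc[degs["is_deg"], "gene_id"])
            planted = truth.deg_gene_ids
            tp = len(called & planted)
            extra["truth_eval"] = {
                "n_planted": len(planted),
                "n_called": len(called),
                "true_positives": tp,
                "precision": tp / len(called) if called else float("nan"),
                "recall": tp / len(planted) if planted else float("nan"),
            }
    except Exception as exc:  # annotate failures with the stage; keep partials
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    manifest = {
        "config_hash": chash,
        "config": asdict(config),
        "seed": config.seed,
        "version": __version__,
        "counts": counts,
        **extra,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
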