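"""End-to-end orchestration with declarative configuration and a report.

``run_all`` executes the full chain on either user-supplied files or a
synthetic panel: normalization (TPM -> pTPM -> nTPM), disease-level
aggregation and gene classification, CLD-vs-cohort correlation, per-cohort
cell-line prioritization (correlation + preranked GSEA), and pathway-activity
scoring, returning a JSON-serializable report with category counts,
per-cohort rankings and significance tallies.  Identical config + seed gives
an identical report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import activity as act
from . import classify as cls
from . import compare as cmp
from . import normalize as norm
from . import prioritize as pri
from . import synthetic as syn
from .matrix import ExpressionMatrix, SampleAnnotation

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """The pipeline's fixed analysis constants, auditable in one place."""

    detection_cutoff: float = 1.0
    fold: float = 4.0
    purity: float = 0.7
    consensus_z: float = 1.0
    cytokine_p: float = 0.05
    top_k: int = 5

    def validate(self) -> list[str]:
        bad = [k for k, v in asdict(self).items() if not v > 0]
        return [f"threshold {k} must be positive" for k in bad]


@dataclass
class RunConfig:
    """Declarative run configuration.

    Exactly one of ``synthetic`` (a PanelConfig) or ``inputs`` (paths to a
    TPM matrix + annotation, cohort TPM + annotation, and a disease-to-cohort
    match map) must be given.
    """

    synthetic: Optional[syn.PanelConfig] = None
    inputs: Optional[dict[str, str]] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    gsea: pri.GseaParams = field(default_factory=pri.GseaParams)
    samples_per_cohort: int = 20
    purity_range: tuple[float, float] = (0.75, 1.0)
    n_stages: int = 3
    n_signatures: int = 8
    genes_per_signature: int = 50
    activity_noise_sd: float = 0.1
    seed: int = 0
    out_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict[str, Any] = {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            kwargs["synthetic"] = syn.PanelConfig(**raw["synthetic"])
        if "inputs" in raw and raw["inputs"] is not None:
            kwargs["inputs"] = dict(raw["inputs"])
        if "thresholds" in raw:
            kwargs["thresholds"] = Thresholds(**raw["thresholds"])
        if "gsea" in raw:
            kwargs["gsea"] = pri.GseaParams(**raw["gsea"])
        for key in ("samples_per_cohort", "n_stages", "seed", "out_dir",
                    "n_signatures", "genes_per_signature", "activity_noise_sd"):
            if key in raw:
                kwargs[key] = raw[key]
        if "purity_range" in raw:
            kwargs["purity_range"] = tuple(raw["purity_range"])
        return cls(**kwargs)


def validate_inputs(cfg: RunConfig) -> list[str]:
    """Return a list of violations (empty means the config is consistent)."""
    violations: list[str] = []
    if (cfg.synthetic is None) == (cfg.inputs is None):
        violations.append("exactly one of synthetic config or input paths required")
    violations.extend(cfg.thresholds.validate())
    if cfg.inputs is not None:
        required = ("tpm", "annotation", "cohort_tpm", "cohort_annotation")
        for key in required:
            if key not in cfg.inputs:
                violations.append(f"missing input path {key!r}")
            elif not Path(cfg.inputs[key]).exists():
                violations.append(f"input file not found: {cfg.inputs[key]}")
        if not violations:
            tpm = ExpressionMatrix.from_tsv(cfg.inputs["tpm"], "TPM")
            ann = SampleAnnotation.from_tsv(cfg.inputs["annotation"])
            missing = tpm.sample_ids.difference(ann.sample_ids)
            if len(missing):
                violations.append(
                    f"samples missing from annotation: {list(missing[:5])}")
            if (tpm.data.to_numpy() < 0).any():
                violations.append("negative expression value in TPM input")
    if cfg.synthetic is not None:
        try:
            cfg.synthetic.validate()
        except syn.ConfigurationError as exc:
            violations.append(str(exc))
    return violations


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage name."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage=%s status=start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage=%s status=done", name)
            return False
    return _Ctx()


def run_all(cfg: RunConfig) -> dict:
    """Execute the full pipeline and return the report dictionary."""
    violations = validate_inputs(cfg)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    th = cfg.thresholds
    report: dict[str, Any] = {"provenance": {"seed": cfg.seed,
                                             "thresholds": asdict(th)}}

    truth = None
    with _stage("load"):
        if cfg.synthetic is not None:
            panel_cfg = cfg.synthetic
            counts, tpm, ann, truth = syn.generate_panel(panel_cfg)
            cohort_tpm, cohort_ann, truth = syn.generate_cohorts(
                panel_cfg, truth, samples_per_cohort=cfg.samples_per_cohort,
                purity_range=cfg.purity_range, n_stages=cfg.n_stages)
        else:
            counts = None
            tpm = ExpressionMatrix.from_tsv(cfg.inputs["tpm"], "TPM")
            ann = SampleAnnotation.from_tsv(cfg.inputs["annotation"])
            cohort_tpm = ExpressionMatrix.from_tsv(cfg.inputs["cohort_tpm"], "TPM")
            cohort_ann = SampleAnnotation.from_tsv(cfg.inputs["cohort_annotation"])

    with _stage("normalize"):
        ntpm = norm.tpm_to_ntpm(tpm)
        cohort_ntpm = norm.tpm_to_ntpm(cohort_tpm)

    with _stage("purity-filter"):
        if "purity" in cohort_ann.table.columns:
            kept = cmp.filter_by_purity(cohort_ann, threshold=th.purity)
            report["purity_filter"] = {
                "n_input": int(cohort_ntpm.n_samples),
                "n_kept": len(kept),
                "n_removed": int(cohort_ntpm.n_samples) - len(kept),
            }
            cohort_ntpm = cohort_ntpm.subset_samples(kept)
            cohort_ann = SampleAnnotation(cohort_ann.table.loc[kept])

    with _stage("classify"):
        clds = cls.aggregate_cld(ntpm, ann)
        calls = cls.classify_matrix(clds, fold=th.fold, cutoff=th.detection_cutoff)
        dist = cls.distribution_matrix(ntpm, cutoff=th.detection_cutoff)
        cat_counts = {c: 0 for c in cls.SPECIFICITY_CATEGORIES}
        for call in calls.values():
            cat_counts[call.category] += 1
        dist_counts = {c: 0 for c in cls.DISTRIBUTION_CATEGORIES}
        for d in dist.values():
            dist_counts[d.category] += 1
        report["specificity_counts"] = cat_counts
        report["distribution_counts"] = dist_counts
        cohort_groups = cohort_ann.groups("cohort" if "cohort" in
                                          cohort_ann.table.columns else "disease")
        cohort_clds = cls.aggregate_cld(
            cohort_ntpm, cohort_ann,
            by="cohort" if "cohort" in cohort_ann.table.columns else "disease")
        cohort_calls = cls.classify_matrix(cohort_clds, fold=th.fold,
                                           cutoff=th.detection_cutoff)

    with _stage("compare"):
        if cfg.synthetic is not None and truth is not None:
            match_map = dict(truth.disease_cohort)
        else:
            match_map = {d: c for d, c in zip(sorted(ann.groups("disease")),
                                              sorted(cohort_groups))}
        rho, tests = cmp.cld_cohort_correlation(clds, cohort_clds, match_map)
        report["matched_correlation"] = {
            str(c): float(rho.loc[c, match_map[c]]) for c in rho.index
            if match_map.get(str(c)) in rho.columns
        }

    with _stage("prioritize"):
        rankings = {}
        n_best_rank1 = 0
        for disease, cohort_id in sorted(match_map.items()):
            line_ids = [s for s in ann.groups("disease").get(disease, [])
                        if s in ntpm.sample_ids]
            if not line_ids:
                continue
            lines = ntpm.subset_samples(line_ids)
            members = cohort_groups.get(cohort_id, [])
            members = [m for m in members if m in cohort_ntpm.sample_ids]
            if not members:
                continue
            cohort_m = cohort_ntpm.subset_samples(members)
            signature = cls.elevated_set(cohort_calls, cohort_id)
            if not signature:
                logger.warning("cohort %r has an empty elevated set; skipped",
                               cohort_id)
                continue
            params = pri.GseaParams(
                weight_exponent=cfg.gsea.weight_exponent,
                n_permutations=cfg.gsea.n_permutations,
                seed=cfg.seed, pseudocount=cfg.gsea.pseudocount)
            records = pri.prioritize_cohort(
                lines, cohort_m, clds, signature, cohort_id=cohort_id,
                params=params, top_k=th.top_k,
                min_common_genes=min(100, ntpm.n_genes))
            rankings[cohort_id] = pri.records_to_frame(records)
            if truth is not None:
                best = truth.cohort_best_line.get(cohort_id)
                if best is not None and records and records[0].cell_line_id == best:
                    n_best_rank1 += 1
        report["rankings"] = {
            c: df[["rho", "nes", "combined_rank", "final_rank", "selected"]]
            .to_dict(orient="index") for c, df in rankings.items()
        }
        if truth is not None:
            report["best_line_rank1"] = {"n_cohorts": len(rankings),
                                         "n_rank1": n_best_rank1}

    with _stage("activity"):
        weights, planted, expr = syn.generate_signature_matrix(
            n_genes=min(500, ntpm.n_genes), n_signatures=cfg.n_signatures,
            genes_per_signature=cfg.genes_per_signature, seed=cfg.seed,
            n_samples=ntpm.n_samples, noise_sd=cfg.activity_noise_sd)
        expr = ExpressionMatrix(
            expr.data.set_axis(list(ntpm.sample_ids), axis=1), "centered-log")
        planted.index = list(ntpm.sample_ids)
        sig = act.SignatureMatrix(weights)
        table = act.score_consensus(expr, sig, n_perm=500, seed=cfg.seed,
                                    z_threshold=th.consensus_z)
        n_total = int(table.z.size)
        n_sig = table.n_significant()
        recov = {
            str(s): float(np.corrcoef(planted[s], table.z[s])[0, 1])
            for s in table.signature_ids
        }
        report["activity"] = {
            "n_entries": n_total,
            "n_significant": n_sig,
            "frac_significant": n_sig / n_total,
            "planted_consensus_correlation": recov,
        }

    if truth is not None:
        agree = sum(
            1 for gid, call in calls.items()
            if call.category == truth.gene_category.get(gid))
        report["planted_agreement"] = {"n_genes": len(calls), "n_agree": agree,
                                       "fraction": agree / len(calls)}

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1,
                                                    sort_keys=True))
        ntpm.to_tsv(out / "ntpm.tsv")
        cls.calls_to_frame(calls, dist).to_csv(out / "classification.tsv",
                                               sep="\t")
        for cohort_id, df in rankings.items():
            df.to_csv(out / f"ranking_{cohort_id}.tsv", sep="\t")
    return report
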