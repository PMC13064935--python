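"""Configuration-driven pipeline chaining simulate -> preprocess ->
signatures -> alan -> stratify, writing a reproducible result bundle.

All randomness flows from the single run seed via per-stage derived
seeds (stable CRC32 hashing of stage names), so an identical config +
seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as ckio
from .containers import ExpressionMatrix, Unit
from . import preprocess, signatures, alan as alanmod, stratify as stratmod
from .cohort import CohortSpec, spec_from_dict, write_fixture_set

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config", "stage_seed"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "signatures", "alan", "stratify")


class PipelineError(RuntimeError):
    """Raised with the failing stage name prefixed, e.g. '[stratify] ...'."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the run seed by hashing the stage name."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; exactly one of ``simulate`` or
    ``expression_path`` must be set."""

    output_dir: str
    seed: int = 0
    simulate: CohortSpec | None = None
    expression_path: str | None = None
    expression_unit: str = "TPM"
    gene_lengths_path: str | None = None
    alterations_path: str | None = None
    annotations_path: str | None = None
    signatures_gmt: str | None = None
    focal_genes: list[str] = field(default_factory=list)
    panel_names: list[str] = field(default_factory=list)
    stratify_gene: str | None = None
    assume_all_profiled: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.expression_path is None):
            raise ValueError("exactly one of simulate / expression_path must be set")


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run config; a ``simulate:`` block is a CohortSpec."""
    d = yaml.safe_load(Path(path).read_text())
    sim = d.pop("simulate", None)
    return RunConfig(simulate=spec_from_dict(sim) if sim is not None else None, **d)


def _fail(stage: str, exc: Exception) -> PipelineError:
    return PipelineError(stage, str(exc))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in fixed order; returns the manifest.

    Each stage writes its tables under ``output_dir``; a machine-readable
    run log (config echo, package versions, seed, per-stage row counts)
    and the manifest are written at the end.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    counts: dict[str, dict] = {}

    # -- simulate / load ---------------------------------------------------
    alterations = None
    annotations = None
    gmt_path = config.signatures_gmt
    try:
        if config.simulate is not None:
            spec = config.simulate
            spec.seed = stage_seed(config.seed, "simulate")
            fixtures = write_fixture_set(outdir / "input", spec)
            manifest.update({f"input_{k}": str(v) for k, v in fixtures.items()})
            matrix = ckio.read_expression_tsv(fixtures["expression"], Unit.TPM)
            alterations = ckio.read_alterations_tsv(fixtures["alterations"])
            annotations = ckio.read_annotations_tsv(fixtures["annotations"])
            gmt_path = gmt_path or str(fixtures["gene_sets"])
            counts["simulate"] = {"n_genes": matrix.n_genes,
                                  "n_samples": matrix.n_samples,
                                  "n_alteration_rows": len(alterations)}
        else:
            matrix = ckio.read_expression_tsv(config.expression_path,
                                              Unit(config.expression_unit))
            if config.alterations_path:
                alterations = ckio.read_alterations_tsv(config.alterations_path)
            if config.annotations_path:
                annotations = ckio.read_annotations_tsv(config.annotations_path)
            counts["simulate"] = {"n_genes": matrix.n_genes,
                                  "n_samples": matrix.n_samples, "loaded": True}
    except (OSError, ValueError, KeyError) as exc:
        raise _fail("simulate", exc)

    # -- preprocess --------------------------------------------------------
    try:
        if matrix.unit is Unit.FPKM:
            matrix = preprocess.fpkm_to_tpm(matrix)
        elif matrix.unit is Unit.COUNTS:
            if not config.gene_lengths_path:
                raise ValueError("counts input requires gene_lengths_path")
            lengths = ckio.read_gene_lengths_tsv(config.gene_lengths_path)
            matrix = preprocess.counts_to_tpm(matrix, lengths)
        matrix = preprocess.drop_zero_genes(matrix)
        matrix = preprocess.dedupe_gene_names(matrix)
        logm = preprocess.log_transform(matrix)
        manifest["preprocessed_log_tpm"] = str(
            ckio.write_expression_tsv(logm, outdir / "log_tpm.tsv"))
        counts["preprocess"] = {"n_genes": logm.n_genes, "n_samples": logm.n_samples}
    except (OSError, ValueError, KeyError) as exc:
        raise _fail("preprocess", exc)

    # -- signatures --------------------------------------------------------
    gene_sets = []
    try:
        if gmt_path:
            gene_sets = ckio.read_gmt(gmt_path)
            activities = {}
            for gs in gene_sets:
                score = signatures.score_signature(logm, gs)
                activities[gs.name] = score.values
                ranking = signatures.correlate_genes_to_score(logm, score)
                snake = signatures.snake_ranking(ranking, config.focal_genes)
                p = outdir / f"snake_{gs.name}.tsv"
                snake.to_csv(p, sep="\t", index=False, float_format="%.10g")
                manifest[f"snake_{gs.name}"] = str(p)
            act = pd.DataFrame(activities)
            act.index.name = "sample_id"
            p = outdir / "activity_scores.tsv"
            act.to_csv(p, sep="\t", float_format="%.10g")
            manifest["activity_scores"] = str(p)
            counts["signatures"] = {"n_gene_sets": len(gene_sets)}
    except (OSError, ValueError, KeyError) as exc:
        raise _fail("signatures", exc)

    # -- alan --------------------------------------------------------------
    try:
        if config.focal_genes:
            for g in config.focal_genes:
                if g not in logm.genes:
                    raise KeyError(f"focal gene {g!r} not in expression matrix")
            behavior = alanmod.build_behavior_matrix(logm)
            rows = behavior.data.loc[config.focal_genes]
            p = outdir / "behavior_rows.tsv"
            rows.to_csv(p, sep="\t", float_format="%.10g")
            manifest["behavior_rows"] = str(p)
            panels = [gs for gs in gene_sets
                      if not config.panel_names or gs.name in config.panel_names]
            for panel in panels:
                hm = alanmod.geneset_alan_heatmap(behavior, config.focal_genes, panel)
                p = outdir / f"alan_scores_{panel.name}.tsv"
                hm.to_csv(p, sep="\t", float_format="%.10g")
                manifest[f"alan_scores_{panel.name}"] = str(p)
            if len(config.focal_genes) >= 2:
                a, b = config.focal_genes[:2]
                r2, slope, intercept = alanmod.compare_profiles_r2(
                    behavior.profile(a), behavior.profile(b))
                pair = behavior.data.loc[[a, b]].T
                pair.columns = [f"rho_with_{a}", f"rho_with_{b}"]
                p = outdir / "profile_pair.tsv"
                pair.to_csv(p, sep="\t", float_format="%.10g")
                manifest["profile_pair"] = str(p)
                reg = pd.DataFrame([{"profile_x": a, "profile_y": b, "r_squared": r2,
                                     "slope": slope, "intercept": intercept}])
                p = outdir / "profile_regression.tsv"
                reg.to_csv(p, sep="\t", index=False, float_format="%.10g")
                manifest["profile_regression"] = str(p)
            counts["alan"] = {"n_focal": len(config.focal_genes),
                              "n_potential_interactions":
                                  alanmod.count_potential_interactions(logm.n_genes)}
    except (OSError, ValueError, KeyError) as exc:
        raise _fail("alan", exc)

    # -- stratify ----------------------------------------------------------
    try:
        if config.stratify_gene:
            split = stratmod.quartile_split(logm, config.stratify_gene)
            membership = pd.DataFrame(
                {"sample_id": list(split.high) + list(split.low),
                 "group": ["high"] * len(split.high) + ["low"] * len(split.low)})
            p = outdir / "quartile_split.tsv"
            membership.to_csv(p, sep="\t", index=False)
            manifest["quartile_split"] = str(p)

            comp_rows = []
            for g in config.focal_genes:
                u, pval = stratmod.compare_groups_numeric(logm.data.loc[g], split)
                comp_rows.append({"feature": g, "kind": "expression", "U": u, "p": pval})
            if annotations is not None:
                for col in annotations.columns:
                    u, pval = stratmod.compare_groups_numeric(annotations[col], split)
                    comp_rows.append({"feature": col, "kind": "annotation",
                                      "U": u, "p": pval})
            if comp_rows:
                comp = pd.DataFrame(comp_rows)
                comp["q"] = stratmod.bh_adjust(comp["p"])
                comp["stars"] = comp["q"].map(stratmod.significance_stars)
                p = outdir / "group_comparisons.tsv"
                comp.to_csv(p, sep="\t", index=False, float_format="%.10g")
                manifest["group_comparisons"] = str(p)

            cont_rows = []
            if alterations is not None and len(alterations):
                profiled = list(logm.samples) if config.assume_all_profiled else None
                results = []
                for g in sorted(alterations["gene"].astype(str).unique()):
                    calls = stratmod.categorize_alterations(alterations, g, profiled)
                    results.append(stratmod.fisher_alteration_test(calls, split, g))
                qs = stratmod.bh_adjust([r.p for r in results])
                for r, q in zip(results, qs):
                    r.q = float(q)
                    r.stars = stratmod.significance_stars(r.q)
                    cont_rows.append({"gene": r.gene,
                                      "high_altered": int(r.table[0, 0]),
                                      "high_unaltered": int(r.table[0, 1]),
                                      "low_altered": int(r.table[1, 0]),
                                      "low_unaltered": int(r.table[1, 1]),
                                      "p": r.p, "q": r.q, "stars": r.stars,
                                      "degenerate": r.degenerate, "n_na": r.n_na})
                cont = pd.DataFrame(cont_rows)
                p = outdir / "alteration_tests.tsv"
                cont.to_csv(p, sep="\t", index=False, float_format="%.10g")
                manifest["alteration_tests"] = str(p)
            counts["stratify"] = {"n_high": len(split.high), "n_low": len(split.low),
                                  "n_cohort": split.n_cohort,
                                  "n_comparisons": len(comp_rows),
                                  "n_alteration_tests": len(cont_rows)}
    except (OSError, ValueError, KeyError) as exc:
        raise _fail("stratify", exc)

    # -- run log + manifest ------------------------------------------------
    run_log = {
        "coexkit_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "config": {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in vars(config).items() if k != "simulate"},
        "simulated": config.simulate is not None,
        "stage_counts": counts,
    }
    log_path = outdir / "run_log.yaml"
    log_path.write_text(yaml.safe_dump(run_log, sort_keys=True))
    manifest["run_log"] = str(log_path)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["manifest"] = str(manifest_path)
    return manifest
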