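"""Synthetic bulk RNA-seq cohort generator with planted ground truth.

The generator emulates the structure of clinical prostate-cancer
expression cohorts: a few thousand genes, heavy-tailed TPM magnitudes,
and latent co-expression programs (e.g. a "luminal" and an
anti-correlated "basal" module) shared by groups of genes. Each module m
has a standard-normal latent factor Z_m per sample; a member gene's
natural-log expression is

    log x_gs = baseline_g + loading_m * Z_m[s] + eps_gs,   eps ~ N(0, sd)

inter-module dependence comes from a latent correlation matrix, columns
are exponentiated and rescaled to TPM (sum 1e6 per sample). Alteration
tables with group-dependent event frequencies are planted against the
top/bottom quartile of the first module's latent factor. Ground truth
(module membership, latent factors, planted groups) is returned as a
separate artifact that analysis stages never read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix, GeneSet, Unit
from . import io as ckio

__all__ = [
    "ModuleSpec",
    "AlterationSpec",
    "CohortSpec",
    "GroundTruth",
    "generate_cohort",
    "plant_alterations",
    "write_fixture_set",
    "default_demo_spec",
]

TPM_TOTAL = 1e6
VALID_EVENT_CODES = {"MUT", "-2", "-1", "0", "1", "2"}


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression program.

    ``loading`` sets the sign and magnitude of member genes' coupling to
    the module's standard-normal latent factor, in natural-log
    expression units.
    """

    name: str
    genes: tuple[str, ...]
    loading: float = 1.0

    def __init__(self, name, genes, loading=1.0):
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "genes", tuple(genes))
        object.__setattr__(self, "loading", float(loading))
        if not self.genes:
            raise ValueError(f"module {name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"module {name!r} has duplicate genes")


@dataclass(frozen=True)
class AlterationSpec:
    """Group-dependent Bernoulli event frequency for one gene."""

    gene: str
    event_code: str
    prob_high: float
    prob_low: float

    def __post_init__(self) -> None:
        if str(self.event_code) not in VALID_EVENT_CODES:
            raise ValueError(f"event_code must be one of {sorted(VALID_EVENT_CODES)}")
        for p in (self.prob_high, self.prob_low):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probabilities must be in [0, 1], got {p}")


@dataclass
class CohortSpec:
    """Full parameterization of one synthetic cohort (deterministic given seed)."""

    n_samples: int
    n_genes: int
    modules: list[ModuleSpec] = field(default_factory=list)
    latent_correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    background_noise_sd: float = 0.5
    baseline_log_mean_range: tuple[float, float] = (0.0, 6.0)
    alteration_specs: list[AlterationSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise ValueError("n_samples and n_genes must be positive")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")
        lo, hi = self.baseline_log_mean_range
        if hi < lo:
            raise ValueError("baseline_log_mean_range must be (lo, hi) with lo <= hi")
        all_genes = [g for m in self.modules for g in m.genes]
        if len(set(all_genes)) != len(all_genes):
            raise ValueError("module gene lists must be disjoint")
        if len(all_genes) > self.n_genes:
            raise ValueError(f"modules claim {len(all_genes)} genes but n_genes = "
                             f"{self.n_genes}")
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise ValueError("module names must be unique")
        for (a, b), r in self.latent_correlations.items():
            if a not in names or b not in names:
                raise ValueError(f"latent correlation refers to unknown module pair "
                                 f"({a!r}, {b!r})")
            if abs(r) > 1:
                raise ValueError(f"|latent correlation| must be <= 1 for ({a}, {b})")
        self.latent_corr_matrix()  # validates PSD at construction

    def latent_corr_matrix(self) -> pd.DataFrame:
        """Assemble and validate the module latent correlation matrix."""
        names = [m.name for m in self.modules]
        corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for (a, b), r in self.latent_correlations.items():
            corr.loc[a, b] = corr.loc[b, a] = r
        eigmin = float(np.linalg.eigvalsh(corr.to_numpy())[0]) if names else 0.0
        if eigmin < -1e-10:
            pairs = sorted(self.latent_correlations,
                           key=lambda p: -abs(self.latent_correlations[p]))
            offender = pairs[0] if pairs else ("?", "?")
            raise ValueError(
                f"latent correlation structure is not positive semi-definite "
                f"(min eigenvalue {eigmin:.4g}); check module pair {offender}")
        return corr


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort; never an analysis input."""

    modules: dict[str, tuple[str, ...]]
    latent_factors: pd.DataFrame       # samples x modules
    baselines: pd.Series               # per-gene natural-log baseline
    high_samples: tuple[str, ...]      # anchor-factor top quartile
    low_samples: tuple[str, ...]       # anchor-factor bottom quartile
    anchor_module: str | None


def _sample_latents(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    names = [m.name for m in spec.modules]
    if not names:
        return pd.DataFrame(index=range(spec.n_samples))
    corr = spec.latent_corr_matrix().to_numpy()
    # eigen factorization tolerates semi-definite structures (|r| = 1)
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    factor = v @ np.diag(np.sqrt(w))
    z = rng.standard_normal((spec.n_samples, len(names))) @ factor.T
    return pd.DataFrame(z, columns=names)


def generate_cohort(spec: CohortSpec) -> tuple[ExpressionMatrix, pd.DataFrame,
                                               pd.DataFrame, GroundTruth]:
    """Generate (TPM expression, alteration table, annotations, ground truth).

    Deterministic given ``spec.seed``. Samples are named S0001..; genes
    claimed by no module are background genes named BG0001.. drawing
    only baseline + noise.
    """
    rng = np.random.default_rng([spec.seed, 0xC0E])
    samples = [f"S{i + 1:04d}" for i in range(spec.n_samples)]
    module_genes = [g for m in spec.modules for g in m.genes]
    taken = set(module_genes)
    background = []
    i = 1
    while len(module_genes) + len(background) < spec.n_genes:
        name = f"BG{i:04d}"
        if name not in taken:
            background.append(name)
        i += 1
    genes = module_genes + background

    latents = _sample_latents(spec, rng)
    latents.index = samples

    lo, hi = spec.baseline_log_mean_range
    baselines = pd.Series(rng.uniform(lo, hi, size=len(genes)), index=genes)
    log_expr = np.tile(baselines.to_numpy()[:, None], (1, spec.n_samples))
    for m in spec.modules:
        idx = [genes.index(g) for g in m.genes]
        log_expr[idx, :] += m.loading * latents[m.name].to_numpy()[None, :]
    if spec.background_noise_sd > 0:
        log_expr += rng.normal(0.0, spec.background_noise_sd,
                               size=(len(genes), spec.n_samples))

    expr = np.exp(log_expr)
    expr = expr / expr.sum(axis=0, keepdims=True) * TPM_TOTAL
    matrix = ExpressionMatrix(pd.DataFrame(expr, index=pd.Index(genes, name="gene"),
                                           columns=samples), Unit.TPM)

    # anchor-factor quartile groups for alteration planting
    anchor = spec.modules[0].name if spec.modules else None
    if anchor is not None:
        order = sorted(samples, key=lambda s: (latents.loc[s, anchor], s))
        k = spec.n_samples // 4
        low_samples, high_samples = tuple(order[:k]), tuple(order[-k:])
    else:
        low_samples, high_samples = (), ()

    if spec.alteration_specs and anchor is not None and high_samples:
        alterations = plant_alterations(spec, list(high_samples), list(low_samples))
    else:
        alterations = pd.DataFrame(columns=ckio.ALTERATION_COLUMNS)

    # scalar annotation emulating a splice-variant SRPM tracking the
    # anchor program (log-normal, noisy)
    if anchor is not None:
        srpm = np.exp(0.8 * latents[anchor].to_numpy()
                      + rng.normal(0.0, 0.5, spec.n_samples))
    else:
        srpm = np.exp(rng.normal(0.0, 1.0, spec.n_samples))
    annotations = pd.DataFrame({"variant_srpm": srpm},
                               index=pd.Index(samples, name="sample_id"))

    truth = GroundTruth(modules={m.name: m.genes for m in spec.modules},
                        latent_factors=latents, baselines=baselines,
                        high_samples=high_samples, low_samples=low_samples,
                        anchor_module=anchor)
    return matrix, alterations, annotations, truth


def plant_alterations(spec: CohortSpec, high_samples: list[str],
                      low_samples: list[str]) -> pd.DataFrame:
    """Draw alteration events independently per sample and spec entry.

    Each :class:`AlterationSpec` fires with ``prob_high`` in the high
    group and ``prob_low`` in the low group; output rows are
    (sample_id, gene, event_code) — events only, no neutral rows.
    """
    overlap = set(high_samples) & set(low_samples)
    if overlap:
        raise ValueError(f"high/low groups overlap: {sorted(overlap)}")
    rng = np.random.default_rng([spec.seed, 0xA17])
    rows = []
    for aspec in spec.alteration_specs:
        for group, prob in ((high_samples, aspec.prob_high),
                            (low_samples, aspec.prob_low)):
            draws = rng.random(len(group)) < prob
            for s, hit in zip(group, draws):
                if hit:
                    rows.append({"sample_id": s, "gene": aspec.gene,
                                 "event_code": str(aspec.event_code)})
    return pd.DataFrame(rows, columns=ckio.ALTERATION_COLUMNS)


def _spec_to_dict(spec: CohortSpec) -> dict:
    return {
        "n_samples": spec.n_samples,
        "n_genes": spec.n_genes,
        "modules": [{"name": m.name, "genes": list(m.genes), "loading": m.loading}
                    for m in spec.modules],
        "latent_correlations": [{"a": a, "b": b, "r": r}
                                for (a, b), r in spec.latent_correlations.items()],
        "background_noise_sd": spec.background_noise_sd,
        "baseline_log_mean_range": list(spec.baseline_log_mean_range),
        "alteration_specs": [asdict(a) for a in spec.alteration_specs],
        "seed": spec.seed,
    }


def spec_from_dict(d: dict) -> CohortSpec:
    """Inverse of the YAML serialization used by :func:`write_fixture_set`."""
    return CohortSpec(
        n_samples=int(d["n_samples"]),
        n_genes=int(d["n_genes"]),
        modules=[ModuleSpec(m["name"], m["genes"], m.get("loading", 1.0))
                 for m in d.get("modules", [])],
        latent_correlations={(e["a"], e["b"]): float(e["r"])
                             for e in d.get("latent_correlations", [])},
        background_noise_sd=float(d.get("background_noise_sd", 0.5)),
        baseline_log_mean_range=tuple(d.get("baseline_log_mean_range", (0.0, 6.0))),
        alteration_specs=[AlterationSpec(a["gene"], str(a["event_code"]),
                                         float(a["prob_high"]), float(a["prob_low"]))
                          for a in d.get("alteration_specs", [])],
        seed=int(d.get("seed", 0)),
    )


def write_fixture_set(outdir: str | Path, spec: CohortSpec) -> dict[str, Path]:
    """Generate a cohort and write the full fixture file set.

    Emits expression TSV, GMT of planted modules, alteration TSV,
    annotation TSV, the spec as YAML and the ground-truth table; returns
    a manifest mapping artifact names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, alterations, annotations, truth = generate_cohort(spec)
    manifest: dict[str, Path] = {}
    manifest["expression"] = ckio.write_expression_tsv(matrix, outdir / "expression.tsv")
    sets = [GeneSet(name, genes, "planted module")
            for name, genes in truth.modules.items()]
    if not sets:
        sets = [GeneSet("all_genes", tuple(matrix.genes), "no planted modules")]
    manifest["gene_sets"] = ckio.write_gmt(sets, outdir / "modules.gmt")
    manifest["alterations"] = ckio.write_alterations_tsv(alterations,
                                                         outdir / "alterations.tsv")
    manifest["annotations"] = ckio.write_annotations_tsv(annotations,
                                                         outdir / "annotations.tsv")
    spec_path = outdir / "cohort_spec.yaml"
    spec_path.write_text(yaml.safe_dump(_spec_to_dict(spec), sort_keys=False))
    manifest["spec"] = spec_path
    gt = truth.latent_factors.copy()
    gt["group"] = "mid"
    gt.loc[list(truth.high_samples), "group"] = "high"
    gt.loc[list(truth.low_samples), "group"] = "low"
    gt.index.name = "sample_id"
    gt_path = outdir / "ground_truth.tsv"
    gt.to_csv(gt_path, sep="\t", float_format="%.10g")
    manifest["ground_truth"] = gt_path
    return manifest


def default_demo_spec(seed: int = 0, n_samples: int = 208, n_genes: int = 1000,
                      loading: float = 1.0, noise_sd: float = 0.5,
                      module_size: int = 10) -> CohortSpec:
    """A small two-program cohort: anti-correlated basal vs luminal
    modules plus a planted deletion enriched in basal-high samples.

    Defaults mirror a mid-size clinical cohort (208 samples) with
    moderate module coupling (loading 1.0 on the natural-log scale)
    over per-gene noise sd 0.5.
    """
    basal = [f"BAS{i:03d}" for i in range(1, module_size + 1)]
    luminal = [f"LUM{i:03d}" for i in range(1, module_size + 1)]
    return CohortSpec(
        n_samples=n_samples,
        n_genes=n_genes,
        modules=[ModuleSpec("basal", basal, loading),
                 ModuleSpec("luminal", luminal, loading)],
        latent_correlations={("basal", "luminal"): -0.7},
        background_noise_sd=noise_sd,
        baseline_log_mean_range=(0.0, 6.0),
        alteration_specs=[AlterationSpec("BG0001", "-2", 0.4, 0.05),
                          AlterationSpec("BG0002", "MUT", 0.15, 0.15)],
        seed=seed,
    )
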