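"""Config-driven orchestration: data in, equivalence report out.

A run is described by a YAML config (see :func:`validate_config`), either
generating synthetic studies or loading TSV files, and executes the
stages in a fixed order:

    load/generate → (optional) quantile normalize → assemble meta data →
    exclude probes → batch removal → DE + CV (+ ORA) on the focal study →
    joint PCA → parallel analysis (or k override) → distance matrix
    (intact and weighted) → report.

Every stage is timed and logged as a JSON line; the report directory is
written atomically (a failed run leaves no partial outputs behind).
Given the same config and seed, the report tables are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, distance, enrichment, io, preprocess, simulate

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "PipelineError",
    "RunConfig",
    "EquivalenceReport",
    "validate_config",
    "config_from_mapping",
    "run_pipeline",
    "write_report",
]


class ConfigError(ValueError):
    """Raised with the full list of schema violations at once."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid run config:\n" + "\n".join(f"- {e}" for e in errors))


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_TOP_KEYS = {
    "mode", "seed", "output_dir", "quantile_normalize", "synthetic", "files",
    "exclude", "de", "ora", "pa", "k_override", "permutation",
}
_SYNTH_KEYS = {"focal_study", "baseline_studies", "gene_sets"}
_STUDY_KEYS = {
    "n_genes", "groups", "batch_assignments", "baseline_mean_log2",
    "baseline_sd_log2", "replicate_sd_log2", "high_cv_fraction",
    "high_cv_range", "de_spikes", "batch_sd_log2", "seed", "gene_prefix",
}
_DE_KEYS = {"alpha", "fold_threshold"}
_ORA_KEYS = {"gmt", "fdr"}
_PA_KEYS = {"n_iterations", "criterion"}
_PERM_KEYS = {"n_permutations", "exact_enumeration_threshold", "sidedness", "seed"}
_FILES_KEYS = {"studies"}


@dataclass
class RunConfig:
    """Fully resolved run description (all defaults filled in)."""

    mode: str = "synthetic"
    seed: int = 0
    output_dir: str = "results/run"
    quantile_normalize: bool = False
    synthetic: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)
    exclude: list[str] = field(default_factory=list)
    de: diffexpr.DEParams = field(default_factory=diffexpr.DEParams)
    ora_gmt: str | None = None
    ora_fdr: float = 0.05
    pa_iterations: int = 100
    pa_criterion: str = "p95"
    k_override: int | None = None
    permutation: distance.PermutationConfig = field(
        default_factory=distance.PermutationConfig
    )


def _check_unknown(mapping: Mapping, allowed: set[str], where: str, errors: list[str]):
    for key in mapping:
        if key not in allowed:
            errors.append(f"{where}: unknown key {key!r}")


def config_from_mapping(raw: Mapping[str, Any], base_dir: Path | None = None) -> RunConfig:
    """Validate a parsed YAML mapping; all violations are reported together."""
    errors: list[str] = []
    if not isinstance(raw, Mapping):
        raise ConfigError(["config must be a mapping"])
    _check_unknown(raw, _TOP_KEYS, "top level", errors)

    mode = raw.get("mode", "synthetic")
    if mode not in ("synthetic", "files"):
        errors.append(f"mode: must be 'synthetic' or 'files', got {mode!r}")
    if "synthetic" in raw and "files" in raw:
        errors.append("exactly one of 'synthetic'/'files' sections allowed")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed: must be an integer")

    de_raw = raw.get("de", {}) or {}
    _check_unknown(de_raw, _DE_KEYS, "de", errors)
    alpha = de_raw.get("alpha", 0.05)
    fold = de_raw.get("fold_threshold", 2.0)
    de_params = None
    try:
        de_params = diffexpr.DEParams(alpha=alpha, fold_threshold=fold)
    except (ValueError, TypeError) as exc:
        errors.append(f"de: {exc}")

    ora_raw = raw.get("ora", {}) or {}
    _check_unknown(ora_raw, _ORA_KEYS, "ora", errors)
    fdr = ora_raw.get("fdr", 0.05)
    if not (isinstance(fdr, (int, float)) and 0 < fdr < 1):
        errors.append(f"ora.fdr: must lie in (0, 1), got {fdr!r}")
    gmt = ora_raw.get("gmt")
    if gmt is not None:
        gmt = str(Path(base_dir or ".", gmt))
        if not Path(gmt).exists():
            errors.append(f"ora.gmt: file not found: {gmt}")

    pa_raw = raw.get("pa", {}) or {}
    _check_unknown(pa_raw, _PA_KEYS, "pa", errors)
    pa_iter = pa_raw.get("n_iterations", 100)
    pa_crit = pa_raw.get("criterion", "p95")
    if not (isinstance(pa_iter, int) and pa_iter >= 10):
        errors.append(f"pa.n_iterations: must be an integer >= 10, got {pa_iter!r}")
    if pa_crit not in ("p95", "mean"):
        errors.append(f"pa.criterion: must be 'p95' or 'mean', got {pa_crit!r}")

    k_override = raw.get("k_override")
    if k_override is not None and not (isinstance(k_override, int) and k_override >= 1):
        errors.append(f"k_override: must be a positive integer or null, got {k_override!r}")

    perm_raw = raw.get("permutation", {}) or {}
    _check_unknown(perm_raw, _PERM_KEYS, "permutation", errors)
    perm = None
    try:
        perm = distance.PermutationConfig(
            n_permutations=perm_raw.get("n_permutations", 999),
            exact_enumeration_threshold=perm_raw.get(
                "exact_enumeration_threshold", 10000
            ),
            sidedness=perm_raw.get("sidedness", "greater"),
            seed=perm_raw.get("seed"),
        )
    except (ValueError, TypeError) as exc:
        errors.append(f"permutation: {exc}")

    exclude_raw = raw.get("exclude", [])
    if isinstance(exclude_raw, str):
        path = Path(base_dir or ".", exclude_raw)
        if path.exists():
            exclude = io.read_gene_list(path)
        else:
            errors.append(f"exclude: file not found: {path}")
            exclude = []
    elif isinstance(exclude_raw, (list, tuple)):
        exclude = [str(g) for g in exclude_raw]
    else:
        errors.append("exclude: must be a file path or a list of IDs")
        exclude = []

    synthetic_raw = dict(raw.get("synthetic", {}) or {})
    files_raw = dict(raw.get("files", {}) or {})
    if mode == "synthetic":
        _check_unknown(synthetic_raw, _SYNTH_KEYS, "synthetic", errors)
        focal = synthetic_raw.get("focal_study", {}) or {}
        _check_unknown(focal, _STUDY_KEYS, "synthetic.focal_study", errors)
        for i, study in enumerate(synthetic_raw.get("baseline_studies", []) or []):
            _check_unknown(study, _STUDY_KEYS, f"synthetic.baseline_studies[{i}]", errors)
    else:
        _check_unknown(files_raw, _FILES_KEYS, "files", errors)
        studies = files_raw.get("studies", [])
        if not studies:
            errors.append("files.studies: at least one study required")
        for i, study in enumerate(studies):
            for key in ("expression", "metadata"):
                if key not in study:
                    errors.append(f"files.studies[{i}]: missing {key!r}")
                else:
                    path = Path(base_dir or ".", study[key])
                    if not path.exists():
                        errors.append(f"files.studies[{i}].{key}: file not found: {path}")
                    else:
                        study[key] = str(path)

    if errors:
        raise ConfigError(errors)
    return RunConfig(
        mode=mode,
        seed=seed,
        output_dir=str(raw.get("output_dir", "results/run")),
        quantile_normalize=bool(raw.get("quantile_normalize", False)),
        synthetic=synthetic_raw,
        files=files_raw,
        exclude=exclude,
        de=de_params,
        ora_gmt=gmt,
        ora_fdr=float(fdr),
        pa_iterations=pa_iter,
        pa_criterion=pa_crit,
        k_override=k_override,
        permutation=perm,
    )


def validate_config(path: str | Path) -> RunConfig:
    """Load + validate a YAML run config; raises :class:`ConfigError`
    listing every violation at once."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    return config_from_mapping(raw, base_dir=path.parent)


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------

@dataclass
class EquivalenceReport:
    """Everything the run computed, ready for serialization."""

    de_summary: pd.DataFrame
    venn_summary: pd.DataFrame
    cv_summary: pd.DataFrame
    ora_tables: dict[str, pd.DataFrame]
    pca_summary: pd.DataFrame
    k_retained: int
    distance_results: dict[tuple[str, str], distance.DistanceResult]
    distance_table: pd.DataFrame
    metadata: dict


def _df_hash(frame: pd.DataFrame) -> str:
    return hashlib.md5(frame.to_csv().encode()).hexdigest()


class _StageRunner:
    def __init__(self) -> None:
        self.log: list[dict] = []

    def run(self, stage: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            logger.error(json.dumps({"stage": stage, "status": "failed",
                                     "error": str(exc)}))
            raise PipelineError(stage, exc) from exc
        entry = {"stage": stage, "seconds": round(time.perf_counter() - t0, 4)}
        self.log.append(entry)
        logger.info(json.dumps(entry))
        return result


def _study_config(raw: Mapping, default_seed: int, prefix: str) -> simulate.StudyConfig:
    kwargs = dict(raw)
    if "groups" in kwargs:
        kwargs["groups"] = [tuple(g) for g in kwargs["groups"]]
    if "de_spikes" in kwargs:
        kwargs["de_spikes"] = [tuple(s) for s in kwargs["de_spikes"]]
    if "high_cv_range" in kwargs:
        kwargs["high_cv_range"] = tuple(kwargs["high_cv_range"])
    kwargs.setdefault("seed", default_seed)
    kwargs.setdefault("gene_prefix", prefix)
    return simulate.StudyConfig(**kwargs)


def _generate_synthetic(config: RunConfig):
    """Focal + baseline studies plus (optionally) constructed gene sets."""
    synth = config.synthetic
    focal_cfg = _study_config(synth.get("focal_study", {}) or {}, config.seed, "G")
    focal_matrix, focal_meta, focal_truth = simulate.generate_expression_study(focal_cfg)
    studies = [(focal_matrix, focal_meta)]
    labels = ["focal"]
    baseline_raw = synth.get("baseline_studies", None)
    if baseline_raw is None:
        # default baseline: two accession-style studies on the same genes,
        # with genuine accession-vs-accession differences and their own
        # highly variable genes
        baseline_raw = [
            {"groups": [["AccA", 3], ["AccB", 3]],
             "de_spikes": [["AccB", 25, 1.2], ["AccB", 25, -1.2]],
             "high_cv_fraction": 0.04},
            {"groups": [["AccC", 3], ["AccD", 3]],
             "de_spikes": [["AccD", 25, 1.2], ["AccD", 25, -1.2]],
             "high_cv_fraction": 0.04},
        ]
    for i, raw in enumerate(baseline_raw):
        raw = dict(raw)
        raw.setdefault("n_genes", focal_cfg.n_genes)
        cfg = _study_config(raw, config.seed + 1 + i, "G")
        m, meta, _ = simulate.generate_expression_study(cfg)
        studies.append((m, meta))
        labels.append(f"baseline{i + 1}")

    collection = None
    gs_cfg = synth.get("gene_sets", {}) or {}
    n_sets = gs_cfg.get("n_sets", 20)
    set_size = gs_cfg.get("set_size", 40)
    if n_sets:
        rng = np.random.default_rng(config.seed + 10_000)
        genes = list(focal_matrix.index)
        collection = enrichment.GeneSetCollection()
        for i in range(n_sets):
            members = sorted(rng.choice(genes, size=min(set_size, len(genes)),
                                        replace=False))
            collection.add(enrichment.GeneSet(f"SET{i + 1:03d}", "random", members))
        # one category per spiked group, seeded with the truly perturbed genes
        for group in focal_truth.de_effects.columns:
            spiked = focal_truth.de_effects.index[
                focal_truth.de_effects[group] != 0
            ].tolist()
            if spiked:
                collection.add(
                    enrichment.GeneSet(f"SPIKED_{group}", "construction", spiked)
                )
    return studies, labels, focal_meta, collection


def _load_files(config: RunConfig):
    studies, labels = [], []
    for i, study in enumerate(config.files.get("studies", [])):
        matrix = io.read_expression(study["expression"])
        meta = io.read_metadata(study["metadata"])
        studies.append((matrix, meta))
        labels.append(study.get("label", f"study{i + 1}"))
    return studies, labels, studies[0][1], None


def run_pipeline(config: RunConfig) -> EquivalenceReport:
    """Execute the full assessment and return the report object."""
    runner = _StageRunner()

    if config.mode == "synthetic":
        studies, labels, focal_meta, collection = runner.run(
            "generate", _generate_synthetic, config
        )
    else:
        studies, labels, focal_meta, collection = runner.run(
            "load", _load_files, config
        )
    if config.ora_gmt:
        collection = runner.run("read_gmt", enrichment.read_gmt, config.ora_gmt)

    if config.quantile_normalize:
        studies = runner.run(
            "quantile_normalize",
            lambda: [(preprocess.quantile_normalize(m), meta) for m, meta in studies],
        )

    meta_matrix, meta_meta = runner.run(
        "assemble", preprocess.assemble_meta_data, studies, labels
    )
    meta_matrix = runner.run(
        "exclude_probes", preprocess.exclude_probes, meta_matrix, config.exclude
    )
    if meta_matrix.shape[0] == 0:
        raise PipelineError("exclude_probes", ValueError("all genes excluded"))
    meta_matrix = runner.run(
        "remove_batch_effect", preprocess.remove_batch_effect, meta_matrix, meta_meta
    )

    # --- focal-study univariate stage ------------------------------------
    focal_samples = [s for s in meta_matrix.columns if s.startswith(f"{labels[0]}:")]
    focal_matrix = meta_matrix[focal_samples]
    focal_groups = list(dict.fromkeys(meta_meta.loc[focal_samples, "group"]))
    de_result = runner.run(
        "anova_tukey", diffexpr.anova_tukey, focal_matrix, meta_meta
    )
    calls = diffexpr.call_de(de_result, config.de)
    n_total = focal_matrix.shape[0]
    rows = []
    for pair, sets in calls.items():
        rows.append(
            {
                "pair": f"{pair[0]} vs {pair[1]}",
                "n_total": n_total,
                "n_significant": len(sets["significant"]),
                "pct_significant": diffexpr.summarize_counts(
                    len(sets["significant"]), n_total
                ),
                "n_up": len(sets["up"]),
                "pct_up": diffexpr.summarize_counts(len(sets["up"]), n_total),
                "n_down": len(sets["down"]),
                "pct_down": diffexpr.summarize_counts(len(sets["down"]), n_total),
            }
        )
    de_summary = pd.DataFrame(rows).set_index("pair")

    venn_rows = []
    pairs = list(calls)
    for i, pa in enumerate(pairs):
        for pb in pairs[i + 1 :]:
            venn = diffexpr.venn_overlap(
                calls[pa]["significant"], calls[pb]["significant"]
            )
            a, b, both = venn.counts
            venn_rows.append(
                {
                    "pair_a": f"{pa[0]} vs {pa[1]}",
                    "pair_b": f"{pb[0]} vs {pb[1]}",
                    "only_a": a,
                    "only_b": b,
                    "both": both,
                    "pct_both": diffexpr.summarize_counts(both, n_total),
                }
            )
    venn_summary = pd.DataFrame(venn_rows)

    cv_rows = []
    for group in focal_groups:
        cv = diffexpr.cv_profile(focal_matrix, meta_meta, group)
        high = cv["valid"] & (cv["cv"] >= 20.0)
        cv_rows.append(
            {
                "group": group,
                "n_cv_ge_20": int(high.sum()),
                "pct_cv_ge_20": diffexpr.summarize_counts(int(high.sum()), n_total),
                "max_cv": float(cv.loc[cv["valid"], "cv"].max()),
            }
        )
    cv_summary = pd.DataFrame(cv_rows).set_index("group")

    ora_tables: dict[str, pd.DataFrame] = {}
    if collection is not None and len(collection):
        reference = set(focal_matrix.index)
        for pair, sets in calls.items():
            for direction in ("up", "down"):
                if sets[direction]:
                    key = f"{pair[0]}_vs_{pair[1]}_{direction}"
                    ora_tables[key] = runner.run(
                        f"ora:{key}",
                        enrichment.ora,
                        sets[direction],
                        reference,
                        collection,
                        config.ora_fdr,
                    )

    # --- multivariate stage ----------------------------------------------
    model = runner.run("pca", distance.pca, meta_matrix)
    if config.k_override is not None:
        k = min(config.k_override, model.scores.shape[1])
    else:
        k = runner.run(
            "parallel_analysis",
            distance.horns_parallel_analysis,
            meta_matrix,
            config.pa_iterations,
            config.pa_criterion,
            config.seed,
        )
        k = max(k, 1)  # the distance needs at least one axis
    model.k_retained = k
    pca_summary = pd.DataFrame(
        {
            "eigenvalue": model.eigenvalues,
            "explained_fraction": model.explained_fraction,
            "retained": [i < k for i in range(len(model.eigenvalues))],
        },
        index=model.scores.columns,
    )

    perm = dataclasses.replace(config.permutation)
    if perm.seed is None:
        perm.seed = config.seed
    results = runner.run(
        "distance_matrix", distance.distance_matrix, model,
        meta_meta.loc[model.scores.index, "group"], perm,
    )
    table = distance.format_distance_table(results)

    metadata = {
        "seed": config.seed,
        "mode": config.mode,
        "k_retained": k,
        "k_source": "override" if config.k_override is not None else "parallel_analysis",
        "n_genes_analyzed": int(meta_matrix.shape[0]),
        "n_samples": int(meta_matrix.shape[1]),
        "excluded_probes": list(config.exclude),
        "permutation": {
            "n_permutations": perm.n_permutations,
            "exact_enumeration_threshold": perm.exact_enumeration_threshold,
            "sidedness": perm.sidedness,
            "seed": perm.seed,
        },
        "input_hash": _df_hash(meta_matrix),
        "stages": runner.log,
        "distances": [
            {
                "groups": [res.group_a, res.group_b],
                "d_intact": res.d_intact,
                "d_weighted": res.d_weighted,
                "p_intact": res.p_intact,
                "p_weighted": res.p_weighted,
                "scheme": res.scheme,
                "n_labelings": res.n_labelings,
                "group_sizes": list(res.group_sizes),
            }
            for res in results.values()
        ],
    }
    return EquivalenceReport(
        de_summary=de_summary,
        venn_summary=venn_summary,
        cv_summary=cv_summary,
        ora_tables=ora_tables,
        pca_summary=pca_summary,
        k_retained=k,
        distance_results=results,
        distance_table=table,
        metadata=metadata,
    )


def write_report(report: EquivalenceReport, output_dir: str | Path) -> Path:
    """Serialize the report as a directory of TSV + JSON, atomically."""
    output_dir = Path(output_dir)
    staging = output_dir.with_name(output_dir.name + ".partial")
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)
    try:
        report.de_summary.to_csv(staging / "de_summary.tsv", sep="\t")
        report.venn_summary.to_csv(staging / "venn_summary.tsv", sep="\t", index=False)
        report.cv_summary.to_csv(staging / "cv_summary.tsv", sep="\t")
        report.pca_summary.to_csv(staging / "pca_summary.tsv", sep="\t",
                                  index_label="component")
        report.distance_table.to_csv(staging / "distance_matrix.tsv", sep="\t",
                                     index_label="group")
        for name, table in report.ora_tables.items():
            enrichment.write_ora_tsv(table, staging / f"ora_{name}.tsv")
        (staging / "report.json").write_text(
            json.dumps(report.metadata, indent=2, sort_keys=True) + "\n"
        )
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    if output_dir.exists():
        shutil.rmtree(output_dir)
    staging.rename(output_dir)
    return output_dir
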