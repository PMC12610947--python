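"""End-to-end orchestration: simulate/load -> DEG -> rank -> panel -> screen.

A single structured config drives the whole run.  Every stage writes its
table(s) under the run directory and the manifest records the config, its
hash, the seed, and package versions, so a rerun with the same config is
byte-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deg import DEGConfig, call_degs, harmonize_symbols, moderated_t_test
from .errors import ConfigError, ValidationError
from .io import read_studies_dir, read_table, write_study, write_table
from .lifespan import adjust_and_call, bonferroni_within_batch, compare_to_control
from .orthologs import build_screen_panel
from .ranking import (
    BinomialNull,
    estimate_success_rate,
    score_genes,
    select_candidates,
    tissue_fraction_matrix,
)
from .synthetic import (
    DriverSpec,
    SimulationConfig,
    simulate_expression_studies,
    simulate_homolog_table,
    simulate_ortholog_table,
    simulate_screen_stage,
)

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    """Hit-calling criteria and simulated-screen design."""

    min_extension_pct: float = 5.0
    alpha: float = 0.05
    n_initial: int = 100
    n_validation: int = 120
    hit_hazard_multiplier: float = 0.3
    censor_prob: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"screen.alpha must be in (0,1), got {self.alpha}")
        if self.n_initial < 2 or self.n_validation < 2:
            raise ConfigError("screen group sizes must be >= 2")


@dataclass
class RunConfig:
    """Full pipeline configuration (simulation-driven or file-driven)."""

    seed: int = 0
    out_dir: str = "run"
    deg_threshold: float = 0.25
    rank_cutoff_pathway: int = 6
    rank_cutoff_screen: int = 7
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    expression: SimulationConfig | None = None
    fraction_conserved: float = 0.7
    fraction_mapped: float = 0.95
    studies_dir: str | None = None
    homologs_path: str | None = None
    orthologs_path: str | None = None
    write_studies: bool = False

    def __post_init__(self) -> None:
        if self.rank_cutoff_pathway < 0 or self.rank_cutoff_screen < 0:
            raise ConfigError("rank cutoffs must be >= 0")
        if not 0.0 < self.deg_threshold < 1.0:
            raise ConfigError(f"deg_threshold must be in (0,1), got {self.deg_threshold}")
        if self.expression is None and self.studies_dir is None:
            raise ConfigError("config needs either an 'expression' simulation section or 'studies_dir'")
        for name in ("studies_dir", "homologs_path", "orthologs_path"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{name}: path does not exist: {path}")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        screen = ScreenConfig(**raw.pop("screen", {}))
        expr_raw = raw.pop("expression", None)
        expression = None
        if expr_raw is not None:
            expr_raw = dict(expr_raw)
            drivers = tuple(
                DriverSpec(*d) if not isinstance(d, DriverSpec) else d
                for d in expr_raw.pop("drivers", ())
            )
            for key in ("species_pool", "tissue_pool"):
                if key in expr_raw:
                    expr_raw[key] = tuple(expr_raw[key])
            expression = SimulationConfig(drivers=drivers, **expr_raw)
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(screen=screen, expression=expression, **raw)

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the run directory.

    Stage order: simulate (or load) expression studies -> per-dataset DEG
    calling -> homolog harmonisation -> success-rate estimate + gene scores
    -> candidate selection at the pathway and screen cutoffs -> ortholog
    panel -> simulated two-stage lifespan screen -> survival analysis and
    hit calls -> manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "outputs": {},
        "log": {},
    }

    def _save(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = write_table(df, out / f"{name}.tsv", index=index)
        manifest["outputs"][name] = path.name

    # -- stage 1: expression studies -------------------------------------
    truth = pd.DataFrame(columns=["gene", "dataset_id", "planted_sign"])
    if config.expression is not None:
        sim = config.expression
        studies, registry, truth = simulate_expression_studies(sim)
        homologs = simulate_homolog_table(sim, fraction_mapped=config.fraction_mapped)
        if config.write_studies:
            for study in studies:
                write_study(study, out / "studies")
    else:
        studies = read_studies_dir(config.studies_dir)
        registry = pd.DataFrame(
            [
                {"dataset_id": s.dataset_id, "species": s.species, "tissue": s.tissue}
                for s in studies
            ]
        )
        homologs = (
            read_table(config.homologs_path)
            if config.homologs_path
            else pd.DataFrame(columns=["species", "symbol", "human_symbol"])
        )
    _save("dataset_registry", registry)
    _save("driver_truth", truth)

    # -- stage 2: per-dataset DEG calling + harmonisation ------------------
    deg_config = DEGConfig(deg_threshold=config.deg_threshold)
    all_records = []
    per_dataset = []
    n_dropped = 0
    for study in studies:
        stats = moderated_t_test(study, deg_config)
        records = call_degs(stats, deg_config, study)
        records = harmonize_symbols(records, homologs)
        n_dropped += records.attrs.get("n_dropped", 0)
        all_records.append(records)
        per_dataset.append(
            {
                "dataset_id": study.dataset_id,
                "species": study.species,
                "tissue": study.tissue,
                "n_genes_tested": int(stats.loc[~stats["zero_variance"], "gene"].nunique()),
                "n_degs": int(records["gene"].nunique()),
                "n_conflicted": records.attrs.get("n_conflicted", 0),
                "n_dropped_unmapped": records.attrs.get("n_dropped", 0),
            }
        )
    deg_records = pd.concat(all_records, ignore_index=True)
    per_dataset = pd.DataFrame(per_dataset)
    manifest["log"]["n_unmapped_dropped"] = int(n_dropped)
    _save("deg_records", deg_records)
    _save("per_dataset_counts", per_dataset)

    # -- stage 3: vote counting -------------------------------------------
    rate, rate_table = estimate_success_rate(
        per_dataset["n_degs"], per_dataset["n_genes_tested"]
    )
    null = BinomialNull(n_trials=len(registry), success_rate=rate)
    manifest["log"]["success_rate"] = rate
    scores = score_genes(deg_records, registry, null=null)
    _save("gene_scores", scores)

    candidates_pathway = select_candidates(scores, config.rank_cutoff_pathway)
    candidates_screen = select_candidates(scores, config.rank_cutoff_screen)
    _save("candidates_pathway", candidates_pathway)
    _save("candidates_screen", candidates_screen)
    if len(candidates_screen):
        tissue_matrix = tissue_fraction_matrix(
            list(candidates_screen["gene"]), deg_records, registry
        )
        tissue_matrix.index.name = "gene"
        _save("tissue_fractions", tissue_matrix, index=True)

    # -- stage 4: ortholog panel -------------------------------------------
    if config.orthologs_path:
        ortholog_table = read_table(config.orthologs_path)
    elif len(candidates_screen):
        ortholog_table = simulate_ortholog_table(
            list(candidates_screen["gene"]),
            fraction_conserved=config.fraction_conserved,
            seed=config.seed + 7,
        )
    else:
        ortholog_table = pd.DataFrame(
            columns=["human_gene", "worm_gene", "clone_id", "support_count", "list_position"]
        )
    panel, conservation = build_screen_panel(candidates_screen, ortholog_table)
    _save("screen_panel", panel)
    _save("conservation_summary", conservation)

    # -- stage 5: simulated two-stage screen + survival analysis -----------
    clones = panel.loc[panel["clone_id"].notna()]
    driver_genes = set(truth["gene"].unique())
    hits_df = pd.DataFrame(
        columns=["clone", "initial_pct_ext_mean", "initial_adjusted_p",
                 "validation_adjusted_p", "initial_pass", "hit", "status"]
    )
    if len(clones):
        multipliers = {
            str(r.clone_id): (
                config.screen.hit_hazard_multiplier
                if r.human_gene in driver_genes
                else 1.0
            )
            for r in clones.itertuples(index=False)
        }
        initial_table = simulate_screen_stage(
            multipliers, n_per_group=config.screen.n_initial,
            censor_prob=config.screen.censor_prob, seed=config.seed + 11,
        )
        initial = compare_to_control(initial_table, "GFP", exclude_groups=("daf-2",))
        # validation re-tests initial passers only (screen funnel)
        ini_adj = bonferroni_within_batch(initial.loc[initial["is_test_clone"]])
        passers = set(
            ini_adj.loc[
                (ini_adj["adjusted_p"] < config.screen.alpha)
                & (ini_adj["pct_ext_mean"] >= config.screen.min_extension_pct),
                "group",
            ]
        )
        validation = pd.DataFrame(columns=initial.columns)
        if passers:
            validation_table = simulate_screen_stage(
                {c: multipliers[c] for c in sorted(passers)},
                n_per_group=config.screen.n_validation,
                censor_prob=config.screen.censor_prob, seed=config.seed + 13,
            )
            validation = compare_to_control(validation_table, "GFP", exclude_groups=("daf-2",))
            _save("screen_validation_results", validation)
        _save("screen_initial_results", initial)
        hits_df = adjust_and_call(
            initial.loc[initial["is_test_clone"]],
            validation.loc[validation["is_test_clone"]] if len(validation) else validation,
            alpha=config.screen.alpha,
            min_extension_pct=config.screen.min_extension_pct,
        )
    _save("screen_hits", hits_df)
    manifest["log"]["n_hits"] = int(hits_df["hit"].sum()) if len(hits_df) else 0

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out


def write_report(run_dir: "str | Path") -> Path:
    """Render one human-readable summary of a completed run."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise ValidationError(f"{run_dir} has no manifest.json; run the pipeline first")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    required = ["dataset_registry", "per_dataset_counts", "gene_scores",
                "screen_panel", "screen_hits"]
    missing = [n for n in required if n not in manifest["outputs"]]
    if missing:
        raise ValidationError(f"incomplete run: missing stage outputs {missing}")

    def _load(name: str) -> pd.DataFrame:
        return read_table(run_dir / manifest["outputs"][name])

    registry = _load("dataset_registry")
    counts = _load("per_dataset_counts")
    scores = _load("gene_scores")
    panel = _load("screen_panel")
    hits = _load("screen_hits")

    lines = ["# agerank run report", ""]
    lines += [f"Config hash: `{manifest['config_hash']}`  |  seed: {manifest['seed']}", ""]
    lines += ["## Dataset census", ""]
    lines += [f"- datasets: {len(registry)}"]
    by_species = registry.groupby("species")["dataset_id"].count().to_dict()
    by_tissue = registry.groupby("tissue")["dataset_id"].count().to_dict()
    lines += [f"- by species: {by_species}", f"- by tissue: {by_tissue}"]
    if len(counts):
        lines += [
            f"- DEGs per dataset: min {int(counts['n_degs'].min())}, "
            f"median {counts['n_degs'].median():g}, max {int(counts['n_degs'].max())}",
            f"- estimated per-dataset DEG success rate: {manifest['log'].get('success_rate', float('nan')):.4f}",
        ]
    def _block(df: pd.DataFrame, empty: str, index: bool = False) -> list[str]:
        body = df.to_string(index=index) if len(df) else empty
        return ["```", body, "```"]

    lines += ["", "## Ranked genes", ""]
    lines += _block(scores, "(no genes scored)")
    tf_name = manifest["outputs"].get("tissue_fractions")
    if tf_name:
        tf = pd.read_csv(run_dir / tf_name, sep="\t", index_col=0)
        lines += ["", "## Tissue fractions (signed S_tissue / n_tissue)", ""]
        lines += _block(tf, "(none)", index=True)
    lines += ["", "## Screen panel", ""]
    lines += _block(panel, "(empty panel)")
    lines += ["", "## Lifespan screen hit calls", ""]
    lines += _block(hits, "(no clones screened)")
    n_hits = int(hits["hit"].sum()) if len(hits) else 0
    lines += ["", f"Total hits (two-stage rule): {n_hits}", ""]

    report_path = run_dir / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path
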