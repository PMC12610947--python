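"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators stand in for the study's real inputs so the whole workflow
is testable offline:

* **Expression-study collections** — a configurable number of datasets
  spread over several species and tissue classes on a shared gene
  namespace.  Values are log-scale, per-gene baseline ~ Normal(8, 2) with
  i.i.d. Normal noise, so a two-group t-type contrast is exactly calibrated.
  Two kinds of true signal are planted: *driver* genes with a directionally
  consistent standardized effect appearing in a Bernoulli(penetrance) subset
  of datasets, and per-dataset *transcriptional drift* — a random fraction
  of non-driver genes per dataset receives a large transient effect with a
  random sign, independently across datasets.  The drift-planting fraction
  is back-computed from the target per-dataset DEG call rate
  (``null_deg_rate``) so that the realized call rate under BH at the stated
  threshold hits the target: planting at rate rho yields roughly
  rho + (1 - rho) * q * rate extra false calls at BH level q, so the
  generator plants at rho (1 - q) / (1 - q rho).

* **Ortholog tables** — compendium-style rows (human gene, worm gene, RNAi
  clone coordinate, method-support count, list position), with deliberate
  support-count ties to exercise the first-listed tie-break.

* **Lifespan cohorts** — Gompertz-distributed death days with per-group
  proportional-hazard multipliers, batch/plate structure, and independent
  uniform censoring standing in for wall-crawler losses.  Defaults put the
  control median near 22 days (shape 0.35/day), the scale of a wild-type
  *C. elegans* assay at 20 C.

All generators are pure functions of their config (including the seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deg import OLD, YOUNG, ExpressionStudy
from .errors import ConfigError

DEFAULT_SPECIES = ("human", "mouse", "rat", "dog")
DEFAULT_TISSUES = ("muscle", "brain", "adipose", "immune", "heart", "liver")

#: Gompertz shape (1/day) and the control-median target (days) behind the
#: default rate; rate solves S(median)=1/2 for the Gompertz survivor function.
DEFAULT_GOMPERTZ_SHAPE = 0.35
_CONTROL_MEDIAN_TARGET = 22.14


def default_gompertz_rate(shape: float = DEFAULT_GOMPERTZ_SHAPE,
                          median: float = _CONTROL_MEDIAN_TARGET) -> float:
    """Baseline hazard rate giving the requested median under Gompertz."""
    return shape * math.log(2.0) / (math.exp(shape * median) - 1.0)


@dataclass(frozen=True)
class DriverSpec:
    """A planted driver gene: symbol, direction, penetrance, effect size (SMD)."""

    symbol: str
    direction: str  # "up" or "down" with age
    penetrance: float
    effect_size: float

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ConfigError(f"driver direction must be 'up' or 'down', got {self.direction!r}")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ConfigError(f"driver penetrance must be in [0,1], got {self.penetrance}")
        if self.effect_size < 0:
            raise ConfigError(f"driver effect_size must be >= 0, got {self.effect_size}")


@dataclass
class SimulationConfig:
    """Conditions for the simulated expression-study collection."""

    n_datasets: int = 25
    genes_per_dataset: int = 30_000
    species_pool: tuple[str, ...] = DEFAULT_SPECIES
    tissue_pool: tuple[str, ...] = DEFAULT_TISSUES
    samples_per_group: int = 5
    null_deg_rate: float = 0.06
    deg_threshold: float = 0.25  # analysis threshold the call-rate target assumes
    drift_effect_size: float = 4.0  # SMD of transient drift effects
    drivers: tuple[DriverSpec, ...] = ()
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    multi_probe_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_datasets < 1:
            raise ConfigError(f"n_datasets must be >= 1, got {self.n_datasets}")
        if self.genes_per_dataset < 1:
            raise ConfigError(f"genes_per_dataset must be >= 1, got {self.genes_per_dataset}")
        if self.samples_per_group < 2:
            raise ConfigError(f"samples_per_group must be >= 2, got {self.samples_per_group}")
        if not 0.0 <= self.null_deg_rate <= 1.0:
            raise ConfigError(f"null_deg_rate must be in [0,1], got {self.null_deg_rate}")
        if not 0.0 < self.deg_threshold < 1.0:
            raise ConfigError(f"deg_threshold must be in (0,1), got {self.deg_threshold}")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not 0.0 <= self.multi_probe_fraction <= 1.0:
            raise ConfigError(f"multi_probe_fraction must be in [0,1], got {self.multi_probe_fraction}")
        if not self.species_pool:
            raise ConfigError("species_pool must be non-empty")
        if not self.tissue_pool:
            raise ConfigError("tissue_pool must be non-empty")
        self.drivers = tuple(
            d if isinstance(d, DriverSpec) else DriverSpec(*d) for d in self.drivers
        )

    @property
    def drift_plant_rate(self) -> float:
        """Per-dataset drift planting rate hitting the target call rate.

        BH at level q rejects, alongside essentially all planted drift
        genes, a share of true nulls at the adaptive threshold q * rate, so
        the fixed point rate = plant + (1 - plant) q rate gives
        plant = rate (1 - q) / (1 - q rate).
        """
        rho, q = self.null_deg_rate, self.deg_threshold
        return rho * (1.0 - q) / (1.0 - q * rho)


def gene_namespace(config: SimulationConfig) -> list[str]:
    """Shared human-symbol namespace: driver symbols then filler symbols."""
    names = [d.symbol for d in config.drivers]
    if len(set(names)) != len(names):
        raise ConfigError("drivers: duplicate symbols")
    n_fill = config.genes_per_dataset - len(names)
    if n_fill < 0:
        raise ConfigError("drivers: more drivers than genes_per_dataset")
    names += [f"G{i:05d}" for i in range(n_fill)]
    return names


def species_symbol(species: str, human_symbol: str) -> str:
    """Species-native spelling of a human gene symbol (rodents capitalise)."""
    if species in ("mouse", "rat"):
        return human_symbol.capitalize()
    return human_symbol


def simulate_expression_studies(
    config: SimulationConfig,
) -> tuple[list[ExpressionStudy], pd.DataFrame, pd.DataFrame]:
    """Generate the dataset collection.

    Returns ``(studies, registry, truth)``: the studies (probe x sample
    matrices with native-species symbols), a dataset registry (dataset_id,
    species, tissue, sample counts), and the ground-truth table of planted
    driver effects with one row per (driver, dataset) stating the planted
    sign (0 = not planted in that dataset).
    """
    genes = gene_namespace(config)
    n_genes = len(genes)
    driver_idx = {d.symbol: i for i, d in enumerate(config.drivers)}
    is_driver = np.zeros(n_genes, dtype=bool)
    is_driver[: len(config.drivers)] = True

    root = np.random.SeedSequence(config.seed)
    ds_seeds = root.spawn(config.n_datasets + 1)
    meta_rng = np.random.default_rng(ds_seeds[-1])

    # second probes for a fixed subset of genes, shared across datasets
    n_multi = int(round(config.multi_probe_fraction * n_genes))
    multi_idx = np.sort(
        meta_rng.choice(n_genes, size=n_multi, replace=False)
    ) if n_multi else np.empty(0, dtype=int)

    studies: list[ExpressionStudy] = []
    registry_rows = []
    truth_rows = []
    n, sd = config.samples_per_group, config.noise_sd

    for d in range(config.n_datasets):
        rng = np.random.default_rng(ds_seeds[d])
        dataset_id = f"SYN{d + 1:03d}"
        species = config.species_pool[d % len(config.species_pool)]
        tissue = config.tissue_pool[d % len(config.tissue_pool)]

        delta = np.zeros(n_genes)
        # transcriptional drift: transient per-dataset effects, random sign
        drift_mask = (~is_driver) & (rng.random(n_genes) < config.drift_plant_rate)
        drift_sign = rng.choice([-1.0, 1.0], size=n_genes)
        delta[drift_mask] = drift_sign[drift_mask] * config.drift_effect_size * sd
        # drivers: directionally consistent effect in a penetrance subset
        for spec in config.drivers:
            gi = driver_idx[spec.symbol]
            planted = rng.random() < spec.penetrance
            sign = 1.0 if spec.direction == "up" else -1.0
            if planted:
                delta[gi] = sign * spec.effect_size * sd
            truth_rows.append(
                {
                    "gene": spec.symbol,
                    "dataset_id": dataset_id,
                    "planted_sign": int(sign) if planted else 0,
                }
            )

        probe_gene_idx = np.concatenate([np.arange(n_genes), multi_idx])
        n_probes = probe_gene_idx.size
        baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_probes)
        values = baseline[:, None] + rng.normal(0.0, sd, size=(n_probes, 2 * n))
        values[:, n:] += delta[probe_gene_idx, None]

        sample_ids = [f"{dataset_id}_Y{i + 1}" for i in range(n)] + [
            f"{dataset_id}_O{i + 1}" for i in range(n)
        ]
        age_group = pd.Series([YOUNG] * n + [OLD] * n, index=sample_ids)
        native = [species_symbol(species, genes[g]) for g in probe_gene_idx]
        probe_ids = [f"{genes[g]}_at" for g in np.arange(n_genes)] + [
            f"{genes[g]}_x_at" for g in multi_idx
        ]
        study = ExpressionStudy(
            dataset_id=dataset_id,
            species=species,
            tissue=tissue,
            values=pd.DataFrame(values, index=probe_ids, columns=sample_ids),
            age_group=age_group,
            probe_to_gene=pd.Series(native, index=probe_ids, name="gene"),
        )
        studies.append(study)
        registry_rows.append(
            {
                "dataset_id": dataset_id,
                "species": species,
                "tissue": tissue,
                "n_probes": n_probes,
                "n_genes": n_genes,
                "n_young": n,
                "n_old": n,
            }
        )

    registry = pd.DataFrame(registry_rows)
    truth = pd.DataFrame(truth_rows, columns=["gene", "dataset_id", "planted_sign"])
    return studies, registry, truth


def simulate_homolog_table(
    config: SimulationConfig,
    fraction_mapped: float = 0.95,
    seed: int | None = None,
) -> pd.DataFrame:
    """Homolog table (species, native symbol, human symbol) for the namespace.

    A ``fraction_mapped`` share of filler genes per non-human species gets a
    mapping (the remainder emulates genes absent from homolog databases);
    driver genes are always mapped, modelling the fact that screen panels
    are drawn from well-annotated genes.
    """
    if not 0.0 <= fraction_mapped <= 1.0:
        raise ConfigError(f"fraction_mapped must be in [0,1], got {fraction_mapped}")
    genes = gene_namespace(config)
    driver_names = {d.symbol for d in config.drivers}
    rng = np.random.default_rng(config.seed + 101 if seed is None else seed)
    rows = []
    for species in config.species_pool:
        if species == "human":
            continue
        mapped = rng.random(len(genes)) < fraction_mapped
        for g, m in zip(genes, mapped):
            if m or g in driver_names:
                rows.append(
                    {"species": species, "symbol": species_symbol(species, g),
                     "human_symbol": g}
                )
    return pd.DataFrame(rows, columns=["species", "symbol", "human_symbol"])


_ROMAN = ("I", "II", "III", "IV", "V", "X")
_LETTERS = "ABCDEFGHIJKLMNOP"


def _clone_id(rng: np.random.Generator) -> str:
    chrom = _ROMAN[rng.integers(len(_ROMAN))]
    plate = int(rng.integers(1, 13))
    row = _LETTERS[rng.integers(len(_LETTERS))]
    col = int(rng.integers(1, 25))
    return f"{chrom}-{plate}{row}{col:02d}"


def _worm_gene(rng: np.random.Generator) -> str:
    stem = "".join(chr(ord("a") + rng.integers(26)) for _ in range(3))
    return f"{stem}-{int(rng.integers(1, 10))}"


def simulate_ortholog_table(
    human_genes: "list[str]",
    fraction_conserved: float,
    seed: int = 0,
    tie_fraction: float = 0.3,
) -> pd.DataFrame:
    """Compendium-style ortholog rows for a list of candidate human genes.

    Each conserved gene receives 1-3 candidate worm genes with integer
    method-support counts (1-6) and Ahringer-style clone coordinates; with
    probability ``tie_fraction`` the top two candidates share the maximal
    support count, exercising the first-listed tie-break downstream.  Row
    order follows the results listing and is materialised in
    ``list_position``.
    """
    if len(human_genes) == 0:
        raise ConfigError("human_genes must be non-empty")
    if not 0.0 <= fraction_conserved <= 1.0:
        raise ConfigError(f"fraction_conserved must be in [0,1], got {fraction_conserved}")
    rng = np.random.default_rng(seed)
    rows = []
    position = 0
    for gene in human_genes:
        if rng.random() >= fraction_conserved:
            continue
        n_cand = int(rng.integers(1, 4))
        supports = sorted(
            (int(rng.integers(1, 7)) for _ in range(n_cand)), reverse=True
        )
        if n_cand >= 2 and rng.random() < tie_fraction:
            supports[1] = supports[0]
        for s in supports:
            rows.append(
                {
                    "human_gene": gene,
                    "worm_gene": _worm_gene(rng),
                    "clone_id": _clone_id(rng),
                    "support_count": s,
                    "list_position": position,
                }
            )
            position += 1
    return pd.DataFrame(
        rows, columns=["human_gene", "worm_gene", "clone_id", "support_count", "list_position"]
    )


@dataclass
class LifespanSimConfig:
    """Conditions for one simulated lifespan assay batch set."""

    groups: tuple[tuple[str, float], ...] = (("GFP", 1.0),)
    n_per_group: int = 100
    gompertz_shape: float = DEFAULT_GOMPERTZ_SHAPE
    gompertz_rate: float | None = None  # default tuned to control median ~22 d
    censor_prob: float = 0.05
    batches: int = 1
    worms_per_plate: int = 20
    adulthood_offset_days: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gompertz_rate is None:
            self.gompertz_rate = default_gompertz_rate(self.gompertz_shape)
        if not self.groups:
            raise ConfigError("groups must be non-empty")
        for label, mult in self.groups:
            if mult <= 0:
                raise ConfigError(f"hazard_multiplier for group {label!r} must be > 0, got {mult}")
        if self.n_per_group < 1:
            raise ConfigError(f"n_per_group must be >= 1, got {self.n_per_group}")
        if self.gompertz_shape <= 0:
            raise ConfigError(f"gompertz_shape must be > 0, got {self.gompertz_shape}")
        if self.gompertz_rate <= 0:
            raise ConfigError(f"gompertz_rate must be > 0, got {self.gompertz_rate}")
        if not 0.0 <= self.censor_prob < 1.0:
            raise ConfigError(f"censor_prob must be in [0,1), got {self.censor_prob}")
        if self.batches < 1:
            raise ConfigError(f"batches must be >= 1, got {self.batches}")
        if self.worms_per_plate < 1:
            raise ConfigError(f"worms_per_plate must be >= 1, got {self.worms_per_plate}")


def gompertz_survival(t: np.ndarray, shape: float, rate: float,
                      hazard_multiplier: float = 1.0) -> np.ndarray:
    """Closed-form Gompertz survivor function S(t) = exp(-m (a/b)(e^{bt}-1))."""
    t = np.asarray(t, dtype=float)
    return np.exp(-hazard_multiplier * (rate / shape) * (np.exp(shape * t) - 1.0))


def simulate_lifespan_cohort(config: LifespanSimConfig) -> pd.DataFrame:
    """Per-animal lifespan table with Gompertz deaths and uniform censoring.

    Death days (from the first day of adulthood) are drawn by inverse
    transform from the Gompertz distribution under each group's
    proportional-hazard multiplier; each animal is independently censored
    with probability ``censor_prob`` at a uniform day before its death.
    Animals are split evenly over batches and filled onto plates of
    ``worms_per_plate``.
    """
    rng = np.random.default_rng(config.seed)
    a, b = config.gompertz_rate, config.gompertz_shape
    rows = []
    for label, mult in config.groups:
        u = rng.uniform(size=config.n_per_group)
        death = np.log1p(-b * np.log(u) / (a * mult)) / b
        censored = rng.uniform(size=config.n_per_group) < config.censor_prob
        obs_day = np.where(censored, rng.uniform(size=config.n_per_group) * death, death)
        for i in range(config.n_per_group):
            batch = i % config.batches + 1
            plate = i // config.worms_per_plate + 1
            rows.append(
                {
                    "animal_id": f"{label}-b{batch}-{i + 1}",
                    "group": label,
                    "batch": f"batch{batch}",
                    "plate": f"{label}-p{plate}",
                    "day": float(obs_day[i]),
                    "event": int(not censored[i]),
                }
            )
    return pd.DataFrame(rows, columns=["animal_id", "group", "batch", "plate", "day", "event"])


def simulate_screen_stage(
    clone_multipliers: "dict[str, float]",
    n_per_group: int = 100,
    control_group: str = "GFP",
    positive_control: tuple[str, float] | None = ("daf-2", 0.5),
    censor_prob: float = 0.05,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """One screen stage: test clones plus negative and positive controls.

    ``clone_multipliers`` maps each test clone to its true hazard multiplier
    (1.0 = no effect).  The negative control has multiplier 1; the optional
    positive control emulates a well-characterised longevity RNAi.
    """
    groups = [(control_group, 1.0)]
    if positive_control is not None:
        groups.append(positive_control)
    groups += list(clone_multipliers.items())
    config = LifespanSimConfig(
        groups=tuple(groups),
        n_per_group=n_per_group,
        censor_prob=censor_prob,
        seed=seed,
        **kwargs,
    )
    return simulate_lifespan_cohort(config)
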