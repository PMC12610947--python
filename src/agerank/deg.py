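"""Per-dataset differential-expression calling between young and old samples.

Each expression dataset is analysed on its own: a two-group contrast
(old minus young) on normalised log-scale values, with empirical-Bayes
moderation of the per-gene variances, Benjamini-Hochberg adjustment of the
raw p-values within the dataset, and a permissive adjusted-p threshold
(default 0.25) chosen for sensitivity rather than stringency.  Probe-level
calls are collapsed to gene symbols and, for non-human datasets, harmonised
to the human namespace through a homolog table so that downstream
cross-dataset counting operates on one shared vocabulary.

The variance moderation is the standard empirical-Bayes shrinkage for gene
expression contrasts: the observed residual variances s_g^2 (df d_g) are
modelled as draws from a scaled-F prior with parameters (d0, s0^2) estimated
by moment matching on log s_g^2, and each gene's variance is replaced by the
posterior mean

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

giving a t-statistic with d0 + d_g degrees of freedom.  With d0 = 0 this
reduces exactly to the ordinary pooled two-sample t-test; with d0 -> inf all
genes share the common variance s0^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

YOUNG = "young"
OLD = "old"

#: Column schema of a DEG record table (one row per gene x dataset call).
DEG_COLUMNS = ["gene", "dataset_id", "direction", "adjusted_p", "tissue", "species"]


@dataclass
class ExpressionStudy:
    """One dataset: a probe x sample matrix of log-scale values plus metadata.

    ``values`` is indexed by probe identifier; ``probe_to_gene`` maps each
    probe to a gene symbol (identity when the platform is already gene-level).
    ``age_group`` assigns every sample column to ``"young"`` or ``"old"``.
    """

    dataset_id: str
    species: str
    tissue: str
    values: pd.DataFrame
    age_group: pd.Series
    probe_to_gene: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.probe_to_gene is None:
            self.probe_to_gene = pd.Series(
                self.values.index, index=self.values.index, name="gene"
            )
        self.validate()

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError(
                f"{self.dataset_id}: duplicate probe identifiers in values"
            )
        missing = set(self.values.columns) - set(self.age_group.index)
        if missing:
            raise ValidationError(
                f"{self.dataset_id}: samples without an age group: {sorted(missing)[:5]}"
            )
        groups = set(self.age_group.loc[list(self.values.columns)])
        if not groups <= {YOUNG, OLD}:
            raise ValidationError(
                f"{self.dataset_id}: age groups must be 'young'/'old', got {groups}"
            )
        for g in (YOUNG, OLD):
            if (self.age_group.loc[list(self.values.columns)] == g).sum() < 2:
                raise ValidationError(
                    f"{self.dataset_id}: need >=2 samples in age group '{g}'"
                )
        if not self.probe_to_gene.index.equals(self.values.index):
            raise ValidationError(
                f"{self.dataset_id}: probe_to_gene index must match values index"
            )

    @property
    def sample_groups(self) -> tuple[list[str], list[str]]:
        cols = list(self.values.columns)
        labels = self.age_group.loc[cols]
        young = [c for c, g in zip(cols, labels) if g == YOUNG]
        old = [c for c, g in zip(cols, labels) if g == OLD]
        return young, old


@dataclass
class DEGConfig:
    """Thresholds and moderation settings for DEG calling."""

    deg_threshold: float = 0.25
    moderation: str = "empirical_bayes"
    prior_df_limit: float = field(default=np.inf)

    def __post_init__(self) -> None:
        if not 0.0 < self.deg_threshold < 1.0:
            raise ConfigError(f"deg_threshold must be in (0,1), got {self.deg_threshold}")
        if self.moderation not in ("empirical_bayes", "ordinary"):
            raise ConfigError(f"moderation must be 'empirical_bayes' or 'ordinary', got {self.moderation!r}")
        if self.prior_df_limit < 0:
            raise ConfigError(f"prior_df_limit must be >= 0, got {self.prior_df_limit}")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Uses the asymptotic closed forms outside the numerically comfortable
    range; inside it, Newton steps on the monotone decreasing trigamma.
    """
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if -dif / y < 1e-8:
            break
    return float(y)


def fit_scaled_f_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior (d0, s0^2) to observed variances.

    ``log(s2)`` for a scaled chi-square variance has known mean/variance in
    terms of digamma/trigamma; the excess dispersion of ``log(s2)`` beyond
    the sampling component identifies the prior df d0, and the centring
    identifies s0^2.  Zero excess dispersion gives d0 = inf (all genes share
    one variance).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValidationError("need >=2 positive variances to fit the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.sum((e - emean) ** 2) / (e.size - 1))
    evar -= float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    return d0, s0_2


def moderated_t_test(
    study: ExpressionStudy,
    config: DEGConfig | None = None,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Old-minus-young moderated t-test for every probe of one study.

    Returns a frame indexed by probe with columns ``gene``, ``effect``,
    ``s2`` (pooled variance, df ``df_residual``), ``s2_post`` (moderated),
    ``t``, ``p``, ``df`` (total df used for the p-value) and
    ``zero_variance`` (probes with no within-group variability; these are
    excluded from testing and carry NaN statistics).

    ``prior_df`` forces the prior df d0 (0 = ordinary pooled t-test,
    ``np.inf`` = full shrinkage to the common variance); by default d0 is
    estimated from the data, capped at ``config.prior_df_limit``.
    """
    config = config or DEGConfig()
    young, old = study.sample_groups
    n1, n2 = len(young), len(old)
    y = study.values[young].to_numpy(dtype=float)
    o = study.values[old].to_numpy(dtype=float)

    effect = o.mean(axis=1) - y.mean(axis=1)
    df_resid = n1 + n2 - 2
    ss = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (o - o.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid
    c2 = 1.0 / n1 + 1.0 / n2

    zero_var = s2 <= 0
    n_zero = int(zero_var.sum())
    if n_zero:
        logger.warning(
            "%s: %d probe(s) with zero variance in both groups excluded from testing",
            study.dataset_id,
            n_zero,
        )

    if prior_df is not None:
        d0 = float(prior_df)
        if d0 > 0 and np.isfinite(d0):
            # prior scale still has to come from the data
            _, s0_2 = fit_scaled_f_prior(s2[~zero_var], df_resid)
        elif np.isinf(d0):
            _, s0_2 = fit_scaled_f_prior(s2[~zero_var], df_resid)
        else:
            s0_2 = np.nan
    elif config.moderation == "ordinary":
        d0, s0_2 = 0.0, np.nan
    else:
        d0, s0_2 = fit_scaled_f_prior(s2[~zero_var], df_resid)
        d0 = min(d0, config.prior_df_limit)

    if d0 == 0:
        s2_post = s2.copy()
        df_total = float(df_resid)
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(s2_post * c2)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    t = np.where(zero_var, np.nan, t)
    p = np.where(zero_var, np.nan, p)

    out = pd.DataFrame(
        {
            "gene": study.probe_to_gene.to_numpy(),
            "effect": effect,
            "s2": s2,
            "s2_post": s2_post,
            "t": t,
            "p": p,
            "df": df_total,
            "zero_variance": zero_var,
        },
        index=study.values.index,
    )
    out.attrs["prior_df"] = d0
    out.attrs["prior_s2"] = s0_2
    return out


def bh_adjust(raw_p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped to 1)."""
    p = np.asarray(raw_p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("raw_p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("raw p-values must all lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    stats_table: pd.DataFrame,
    config: DEGConfig,
    study: ExpressionStudy,
) -> pd.DataFrame:
    """Collapse probe-level statistics into gene-level DEG records.

    BH adjustment is applied to the probe-level raw p-values within this one
    dataset.  A gene is called if any of its probes has adjusted p below the
    threshold; its direction is taken from the passing probe with the
    smallest adjusted p.  If passing probes disagree in direction the gene is
    dropped (it contributes to neither the up nor the down count), which the
    consistency-first ranking downstream requires.  Returns a frame with
    columns ``DEG_COLUMNS``; the number of direction-conflicted genes is
    stored in ``.attrs["n_conflicted"]``.
    """
    tested = stats_table.loc[~stats_table["zero_variance"]].copy()
    records = []
    n_conflicted = 0
    if len(tested):
        tested["adjusted_p"] = bh_adjust(tested["p"].to_numpy())
        passing = tested.loc[tested["adjusted_p"] < config.deg_threshold]
        for gene, grp in passing.groupby("gene", sort=True):
            directions = set(np.sign(grp["effect"]))
            if len(directions) > 1:
                n_conflicted += 1
                continue
            best = grp.loc[grp["adjusted_p"].idxmin()]
            records.append(
                {
                    "gene": gene,
                    "dataset_id": study.dataset_id,
                    "direction": "up" if best["effect"] > 0 else "down",
                    "adjusted_p": float(best["adjusted_p"]),
                    "tissue": study.tissue,
                    "species": study.species,
                }
            )
    out = pd.DataFrame(records, columns=DEG_COLUMNS)
    out.attrs["n_conflicted"] = n_conflicted
    out.attrs["n_tested"] = int(len(tested))
    if n_conflicted:
        logger.info(
            "%s: %d gene(s) with direction-conflicting probes contribute to neither count",
            study.dataset_id,
            n_conflicted,
        )
    return out


def harmonize_symbols(
    records: pd.DataFrame,
    homolog_map: pd.DataFrame,
    human_species: str = "human",
) -> pd.DataFrame:
    """Convert non-human gene symbols in DEG records to human symbols.

    ``homolog_map`` has columns ``species``, ``symbol``, ``human_symbol``.
    Records from ``human_species`` pass through untouched; non-human records
    without a mapping are dropped and the drop count is logged and stored in
    ``.attrs["n_dropped"]``.  Conflicting duplicate entries for one
    (species, symbol) raise a validation error.
    """
    required = {"species", "symbol", "human_symbol"}
    if not required <= set(homolog_map.columns):
        raise ValidationError(f"homolog_map must have columns {sorted(required)}")
    dedup = homolog_map.drop_duplicates()
    key_counts = dedup.groupby(["species", "symbol"]).size()
    if (key_counts > 1).any():
        bad = key_counts[key_counts > 1].index.tolist()[:5]
        raise ValidationError(f"conflicting homolog entries for (species, symbol): {bad}")

    lookup = {
        (r.species, r.symbol): r.human_symbol for r in dedup.itertuples(index=False)
    }
    keep_rows = []
    n_dropped = 0
    for row in records.itertuples(index=False):
        if row.species == human_species:
            keep_rows.append(row._asdict())
            continue
        human = lookup.get((row.species, row.gene))
        if human is None:
            n_dropped += 1
            continue
        d = row._asdict()
        d["gene"] = human
        keep_rows.append(d)
    out = pd.DataFrame(keep_rows, columns=records.columns if len(records.columns) else DEG_COLUMNS)
    out.attrs["n_dropped"] = n_dropped
    if n_dropped:
        logger.info("harmonize_symbols: dropped %d unmapped record(s)", n_dropped)
    return out
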