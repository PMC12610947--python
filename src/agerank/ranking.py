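"""Vote-counting meta-analysis: rank genes by cross-dataset consistency.

For gene *i*, ``s_up`` and ``s_down`` count the datasets in which it was
called significantly up- or down-regulated with age.  The signed total score
and the rank are

    S_i = S_i^up - S_i^down,        R_i = |S_i|,

so genes with opposing calls in different datasets cancel and never rank
highly.  Effect sizes are deliberately discarded: consistency across
heterogeneous species/tissues/platforms is the signal of interest, and
magnitudes are not comparable across them.

Significance of a rank is assigned under a binomial null in which each
dataset is an independent trial that calls any given gene a DEG with
probability equal to the average per-dataset DEG rate (estimated as mean
DEGs per dataset over mean genes tested per dataset).  The upper-tail
probability P(X >= R) for X ~ Binomial(n_datasets, rate) is reported.  This
null pools both directions into one success class, so it is conservative for
the absolute-difference rank (a gene's calls split between directions only
lower R); that conservatism is documented rather than corrected, keeping the
printed p-values directly interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

#: Columns of the ranked score table.
SCORE_COLUMNS = ["gene", "s_up", "s_down", "s_total", "rank", "n_called", "cancelled"]


@dataclass(frozen=True)
class BinomialNull:
    """Null model: each dataset calls a gene a DEG with fixed probability."""

    n_trials: int
    success_rate: float

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValidationError(f"n_trials must be >= 1, got {self.n_trials}")
        if not 0.0 < self.success_rate < 1.0:
            raise ValidationError(
                f"success_rate must be in (0,1), got {self.success_rate}"
            )


def _check_registry(deg_records: pd.DataFrame, dataset_registry: pd.DataFrame) -> None:
    if "dataset_id" not in dataset_registry.columns:
        raise ValidationError("dataset_registry must have a 'dataset_id' column")
    known = set(dataset_registry["dataset_id"])
    if len(deg_records):
        unknown = set(deg_records["dataset_id"]) - known
        if unknown:
            raise ValidationError(f"DEG records reference unknown dataset_id(s): {sorted(unknown)[:5]}")


def score_genes(
    deg_records: pd.DataFrame,
    dataset_registry: pd.DataFrame,
    null: BinomialNull | None = None,
) -> pd.DataFrame:
    """Per-gene dataset counts, signed total score, rank, and optional rank p.

    One row per gene that was ever called in any dataset; genes never called
    are omitted (their implicit score is 0, and omission distinguishes them
    from genes whose up and down calls cancelled — the latter appear with
    ``cancelled=True``).  If one gene carries both an up and a down call in
    the same dataset (possible after homolog merging), that dataset
    contributes to neither count.
    """
    _check_registry(deg_records, dataset_registry)
    if len(deg_records) == 0:
        out = pd.DataFrame(columns=SCORE_COLUMNS)
        return out

    # direction sets per (gene, dataset); within-dataset conflicts net out
    per_pair = deg_records.groupby(["gene", "dataset_id"])["direction"].agg(set)
    rows = {}
    for (gene, _dataset), dirs in per_pair.items():
        rec = rows.setdefault(gene, {"s_up": 0, "s_down": 0, "n_called": 0})
        rec["n_called"] += 1
        if dirs == {"up"}:
            rec["s_up"] += 1
        elif dirs == {"down"}:
            rec["s_down"] += 1
        # both directions in one dataset: counts toward neither

    table = pd.DataFrame(
        [
            {
                "gene": g,
                "s_up": r["s_up"],
                "s_down": r["s_down"],
                "s_total": r["s_up"] - r["s_down"],
                "rank": abs(r["s_up"] - r["s_down"]),
                "n_called": r["n_called"],
                "cancelled": r["s_up"] - r["s_down"] == 0,
            }
            for g, r in rows.items()
        ],
        columns=SCORE_COLUMNS,
    ).sort_values(["rank", "gene"], ascending=[False, True], ignore_index=True)

    if null is not None:
        table["rank_p"] = [binomial_rank_pvalue(r, null) for r in table["rank"]]
    return table


def estimate_success_rate(
    per_dataset_deg_counts: "pd.Series | np.ndarray | list",
    per_dataset_genes_tested: "pd.Series | np.ndarray | list",
) -> tuple[float, pd.DataFrame]:
    """Average per-dataset DEG rate for the binomial null.

    Returns ``(rate, per_dataset_table)`` where the headline rate is the
    ratio of means (mean DEG count over mean genes tested), matching the
    convention of dividing the average DEG count by the average platform
    size; the per-dataset table also carries each dataset's own ratio and
    the mean-of-ratios alternative in ``.attrs``.
    """
    counts = np.asarray(per_dataset_deg_counts, dtype=float)
    tested = np.asarray(per_dataset_genes_tested, dtype=float)
    if counts.shape != tested.shape or counts.ndim != 1 or counts.size == 0:
        raise ValidationError("counts and genes_tested must be equal-length 1-d sequences")
    if np.any(tested <= 0):
        raise ValidationError("every dataset must have > 0 genes tested")
    if np.any(counts > tested):
        raise ValidationError("DEG count cannot exceed genes tested")
    rate = float(counts.mean() / tested.mean())
    per_dataset = pd.DataFrame(
        {"deg_count": counts, "genes_tested": tested, "ratio": counts / tested}
    )
    per_dataset.attrs["mean_of_ratios"] = float((counts / tested).mean())
    per_dataset.attrs["ratio_of_means"] = rate
    return rate, per_dataset


def binomial_rank_pvalue(rank: int, null: BinomialNull) -> float:
    """Upper-tail P(X >= rank) under the binomial null (survival function)."""
    if rank < 0 or rank > null.n_trials:
        raise ValidationError(
            f"rank must be in [0, {null.n_trials}], got {rank}"
        )
    if rank == 0:
        return 1.0
    return float(stats.binom.sf(rank - 1, null.n_trials, null.success_rate))


def tissue_breakdown(
    gene: str,
    deg_records: pd.DataFrame,
    dataset_registry: pd.DataFrame,
) -> pd.DataFrame:
    """Signed per-tissue consistency fractions for one gene.

    For each tissue with at least one dataset in the registry, reports the
    signed within-tissue score ``s_tissue`` (up minus down calls restricted
    to that tissue's datasets), the number of datasets of that tissue
    ``n_tissue``, and ``fraction = s_tissue / n_tissue`` (signed; its
    absolute value is the displayed percentage).
    """
    _check_registry(deg_records, dataset_registry)
    if "tissue" not in dataset_registry.columns or dataset_registry["tissue"].isna().any():
        raise ValidationError("every dataset in the registry needs a tissue label")
    n_tissue = dataset_registry.groupby("tissue")["dataset_id"].count()

    recs = deg_records.loc[deg_records["gene"] == gene]
    signed = recs["direction"].map({"up": 1, "down": -1})
    tissue_of = dataset_registry.set_index("dataset_id")["tissue"]
    s_tissue = (
        pd.DataFrame({"tissue": recs["dataset_id"].map(tissue_of), "sign": signed})
        .groupby("tissue")["sign"]
        .sum()
    )
    out = pd.DataFrame(
        {
            "tissue": n_tissue.index,
            "s_tissue": [int(s_tissue.get(t, 0)) for t in n_tissue.index],
            "n_tissue": n_tissue.to_numpy(),
        }
    )
    out["fraction"] = out["s_tissue"] / out["n_tissue"]
    out.insert(0, "gene", gene)
    return out.reset_index(drop=True)


def tissue_fraction_matrix(
    genes: "list[str]",
    deg_records: pd.DataFrame,
    dataset_registry: pd.DataFrame,
) -> pd.DataFrame:
    """Genes x tissues matrix of signed fractions, ready for heatmap export."""
    rows = []
    for g in genes:
        bd = tissue_breakdown(g, deg_records, dataset_registry)
        rows.append(bd.set_index("tissue")["fraction"].rename(g))
    return pd.DataFrame(rows)


def select_candidates(scores: pd.DataFrame, rank_cutoff: int) -> pd.DataFrame:
    """Genes at or above the rank cutoff, ordered for the screen panel.

    Sorted by rank descending then symbol ascending (rank ties carry no
    ordering information, so the tie-break is alphabetical).  A ``direction``
    column summarises the sign of the total score.
    """
    if rank_cutoff < 0:
        raise ValidationError(f"rank_cutoff must be >= 0, got {rank_cutoff}")
    if len(scores) == 0:
        out = scores.copy()
        out["direction"] = pd.Series(dtype=object)
        return out
    sel = scores.loc[scores["rank"] >= rank_cutoff].copy()
    sel["direction"] = np.select(
        [sel["s_total"] > 0, sel["s_total"] < 0], ["up", "down"], default="none"
    )
    return sel.sort_values(
        ["rank", "gene"], ascending=[False, True], ignore_index=True
    )
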