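"""Worm ortholog and RNAi-clone selection for the screen panel.

Candidate human genes are mapped to *C. elegans* genes through a
compendium-style ortholog table in which each candidate row carries the
number of orthology-prediction methods supporting it (``support_count``) and
its position in the original results listing (``list_position``).  The
selection rule: take the row with the highest support count, breaking ties
by earliest list position; if the chosen clone is not available (failed
culture or sequence verification), fall back to the next row in preference
order and mark the choice accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

import pandas as pd

from .errors import ValidationError

ORTHOLOG_COLUMNS = ["human_gene", "worm_gene", "clone_id", "support_count", "list_position"]

SELECTED = "selected"
FALLBACK = "fallback"
UNAVAILABLE = "unavailable"


@dataclass(frozen=True)
class OrthologChoice:
    human_gene: str
    worm_gene: str | None
    clone_id: str | None
    support_count: int | None
    status: str


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(ORTHOLOG_COLUMNS) - set(table.columns)
    if missing - {"list_position"}:
        raise ValidationError(f"ortholog table missing columns: {sorted(missing)}")
    table = table.copy()
    if "list_position" not in table.columns:
        # materialize the on-file row order so the tie-break is reproducible
        table["list_position"] = range(len(table))
    if table["support_count"].isna().any():
        raise ValidationError("ortholog table has rows with missing support_count")
    if (table["support_count"] < 1).any():
        raise ValidationError("support_count must be >= 1 for every row")
    return table


def _is_available(clone_id, clone_availability: Mapping[str, bool] | None) -> bool:
    if clone_id is None or (isinstance(clone_id, float) and pd.isna(clone_id)):
        return False
    if clone_availability is None:
        return True
    return bool(clone_availability.get(clone_id, False))


def select_ortholog(
    human_gene: str,
    ortholog_table: pd.DataFrame,
    clone_availability: Mapping[str, bool] | None = None,
) -> OrthologChoice:
    """Pick one worm gene / RNAi clone for a candidate human gene.

    ``clone_availability`` maps clone ids to culture/verification status;
    ``None`` treats every listed clone as available.  Preference order is
    (support_count descending, list_position ascending); the first available
    row wins.  The top-preference row gives status ``selected``, any later
    row ``fallback``, and a gene with no usable row is ``unavailable``.
    """
    table = _validate_table(ortholog_table)
    rows = table.loc[table["human_gene"] == human_gene]
    if len(rows) == 0:
        return OrthologChoice(human_gene, None, None, None, UNAVAILABLE)
    ordered = rows.sort_values(
        ["support_count", "list_position"], ascending=[False, True]
    )
    for i, row in enumerate(ordered.itertuples(index=False)):
        if _is_available(row.clone_id, clone_availability):
            return OrthologChoice(
                human_gene,
                row.worm_gene,
                row.clone_id,
                int(row.support_count),
                SELECTED if i == 0 else FALLBACK,
            )
    return OrthologChoice(human_gene, None, None, None, UNAVAILABLE)


def build_screen_panel(
    candidates: pd.DataFrame,
    ortholog_table: pd.DataFrame,
    clone_availability: Mapping[str, bool] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ortholog choices for every candidate plus a conservation summary.

    ``candidates`` comes from the rank-cutoff selection and must carry
    ``gene`` and ``direction`` columns.  Returns ``(panel, summary)``:
    the panel has one row per candidate (duplicates rejected) in candidate
    order; the summary reports, per direction, the number of candidates,
    how many are conserved (present in the ortholog table), the conserved
    fraction as a nearest-integer percent, and how many clones were
    obtained (available for screening).
    """
    if len(candidates) and candidates["gene"].duplicated().any():
        raise ValidationError("candidate list contains duplicate genes")
    table = _validate_table(ortholog_table)
    conserved_genes = set(table["human_gene"])

    rows = []
    for cand in candidates.itertuples(index=False):
        choice = select_ortholog(cand.gene, table, clone_availability)
        d = asdict(choice)
        d["direction"] = cand.direction
        d["rank"] = getattr(cand, "rank", None)
        d["conserved"] = cand.gene in conserved_genes
        rows.append(d)
    panel = pd.DataFrame(
        rows,
        columns=["human_gene", "direction", "rank", "worm_gene", "clone_id",
                 "support_count", "status", "conserved"],
    )

    summaries = []
    directions: Iterable[str] = (
        panel["direction"].unique() if len(panel) else []
    )
    for direction in directions:
        sub = panel.loc[panel["direction"] == direction]
        n = len(sub)
        n_conserved = int(sub["conserved"].sum())
        n_clones = int(sub["status"].isin([SELECTED, FALLBACK]).sum())
        summaries.append(
            {
                "direction": direction,
                "n_candidates": n,
                "n_conserved": n_conserved,
                "pct_conserved": round(100.0 * n_conserved / n) if n else 0,
                "n_clones_obtained": n_clones,
            }
        )
    summary = pd.DataFrame(
        summaries,
        columns=["direction", "n_candidates", "n_conserved", "pct_conserved",
                 "n_clones_obtained"],
    )
    return panel, summary
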