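"""Nominate novel related miRNAs from significantly enriched categories.

Because categories group miRNAs directly (not through predicted
targets), the members of a significantly enriched category that are
*absent* from the input list are natural candidates for involvement in
the same process — e.g. the unmeasured members of a muscle-development
set enriched among infarction-deregulated miRNAs.  Only
over-representation results nominate candidates: a depleted set argues
against, not for, its remaining members.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .enrich import EnrichmentResult
from .errors import UsageFault, ValidationError


@dataclass(frozen=True)
class PredictionRecord:
    """One candidate miRNA nominated by one significant category."""

    mirna: str
    source_category: str
    class_label: str
    category_p: float
    category_fdr: float


def predict_related(
    results: Sequence[EnrichmentResult],
    input_hits: Iterable[str],
    alpha: float = 0.05,
    use_fdr: bool = False,
) -> list[PredictionRecord]:
    """Emit one record per unmatched member of each significant category.

    A category is significant when its raw p-value (or its FDR q-value
    when ``use_fdr``) is <= ``alpha``.  A miRNA backed by several
    significant categories yields one record per category; use
    :func:`summarize_predictions` for a per-miRNA view.  Output is
    deterministic: category p ascending, then miRNA name.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must lie in (0, 1)")
    hits = frozenset(input_hits)
    for r in results:
        if r.direction != "over":
            raise UsageFault(
                "prediction requires over-representation results; depleted "
                "categories do not nominate candidates"
            )
    records: list[PredictionRecord] = []
    for r in sorted(results, key=lambda r: (r.p_raw, r.category_id)):
        gate = r.p_fdr if use_fdr else r.p_raw
        if gate > alpha:
            continue
        for mirna in sorted(r.unmatched_members - hits):
            records.append(
                PredictionRecord(
                    mirna=mirna,
                    source_category=r.category_id,
                    class_label=r.class_label,
                    category_p=r.p_raw,
                    category_fdr=r.p_fdr,
                )
            )
    return records


def summarize_predictions(
    records: Sequence[PredictionRecord],
) -> list[dict]:
    """Deduplicate to one row per miRNA, ranked by best supporting category.

    Ranking: smallest category p first, ties broken by the number of
    supporting categories (more first), then by name.
    """
    by_mirna: dict[str, list[PredictionRecord]] = {}
    for rec in records:
        by_mirna.setdefault(rec.mirna, []).append(rec)
    rows = []
    for mirna, recs in by_mirna.items():
        best = min(recs, key=lambda r: (r.category_p, r.source_category))
        rows.append(
            {
                "mirna": mirna,
                "best_p": best.category_p,
                "best_fdr": best.category_fdr,
                "n_categories": len(recs),
                "categories": ",".join(sorted({r.source_category for r in recs})),
            }
        )
    rows.sort(key=lambda r: (r["best_p"], -r["n_categories"], r["mirna"]))
    return rows


PREDICTION_COLUMNS = ["mirna", "source_category", "class", "category_p", "category_fdr"]


def predictions_to_frame(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna": r.mirna,
                "source_category": r.source_category,
                "class": r.class_label,
                "category_p": r.category_p,
                "category_fdr": r.category_fdr,
            }
            for r in records
        ],
        columns=PREDICTION_COLUMNS,
    )


def write_predictions(
    records: Sequence[PredictionRecord],
    path: str | Path,
    summary: bool = False,
) -> None:
    """Write predictions (or the per-miRNA summary) as TSV."""
    if summary:
        frame = pd.DataFrame(
            summarize_predictions(records),
            columns=["mirna", "best_p", "best_fdr", "n_categories", "categories"],
        )
    else:
        frame = predictions_to_frame(records)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
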