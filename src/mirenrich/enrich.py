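"""The four-step enrichment pipeline.

1. normalize the input miRNA list and match it to the population;
2. resolve the background population (the catalog universe by default,
   or a user-supplied background list intersected with it);
3. score every sufficiently large category with the hypergeometric
   upper tail (over-representation) or lower tail (depletion);
4. adjust all raw p-values (Bonferroni and BH-FDR), sort and report.

Every category is returned — significance filtering is the caller's
concern, and both the depletion view and novel-miRNA prediction need
the full table.  With a custom background, category sizes are recomputed
within the background so that all four counts refer to one urn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .catalog import Catalog, normalize_name
from .errors import AnalysisError, FormatError, ValidationError
from .stats import (
    ContingencyCounts,
    bh_fdr_adjust,
    bonferroni_adjust,
    hypergeom_pmf,
    p_over,
    p_under,
)

logger = logging.getLogger(__name__)

DIRECTIONS = ("over", "under")
CORRECTION_SCOPES = ("global", "per_class")

#: Column order of the results table.
RESULT_COLUMNS = [
    "category_id", "class", "HS", "S", "HP", "P", "percent_matched",
    "percent_of_category", "fold", "p_value", "bonferroni", "fdr",
    "matched_members", "unmatched_members",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Run options: test direction, significance level, correction scope."""

    direction: str = "over"
    alpha: float = 0.05
    correction_scope: str = "global"
    min_category_size: int = 2
    strict_arm_matching: bool = False

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"direction must be one of {DIRECTIONS}")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.correction_scope not in CORRECTION_SCOPES:
            raise ValidationError(
                f"correction_scope must be one of {CORRECTION_SCOPES}"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-category statistics, one row of the results table."""

    category_id: str
    class_label: str
    HS: int
    S: int
    HP: int
    P: int
    percent_matched: float   # 100 * HS / HP, share of the input list
    percent_of_category: float  # 100 * HS / S, share of the category
    fold: float              # (HS/HP) / (S/P)
    p_raw: float
    p_bonferroni: float
    p_fdr: float
    matched_members: frozenset[str]
    unmatched_members: frozenset[str]
    direction: str = "over"


def resolve_population(
    catalog: Catalog,
    background: Sequence[str] | None = None,
) -> tuple[frozenset[str], list[str]]:
    """Determine the urn population P.

    Without a background list the population is the catalog universe
    (every miRNA appearing in any category).  With one, it is the
    normalized background intersected with the universe; names outside
    the universe are returned as ``dropped`` and warned about, never
    silently discarded.
    """
    universe = catalog.universe
    if background is None:
        return universe, []
    keys = {normalize_name(b).key: b for b in background}
    population = frozenset(k for k in keys if k in universe)
    dropped = sorted(keys[k] for k in keys if k not in universe)
    if dropped:
        logger.warning(
            "%d background name(s) absent from the catalog universe: %s",
            len(dropped), ", ".join(dropped),
        )
    if not population:
        raise AnalysisError(
            "background list shares no miRNA with the catalog universe"
        )
    return population, dropped


def match_input(
    input_list: Sequence[str],
    population: Iterable[str],
) -> tuple[frozenset[str], list[str]]:
    """Normalize the input list and intersect it with the population.

    Duplicates count once.  Names outside the population are returned
    as ``dropped``; an entirely unmatched input raises
    :class:`AnalysisError` telling the user to check identifiers.
    """
    if not input_list:
        raise AnalysisError("input miRNA list is empty")
    population = frozenset(population)
    keys = {normalize_name(n).key: n for n in input_list}
    hits = frozenset(k for k in keys if k in population)
    dropped = sorted(keys[k] for k in keys if k not in population)
    if dropped:
        logger.warning(
            "%d input name(s) not in the background population: %s",
            len(dropped), ", ".join(dropped),
        )
    if not hits:
        raise AnalysisError(
            "no input miRNA matched the background population; check the "
            "identifiers (species prefixes are stripped automatically)"
        )
    return hits, dropped


def run_enrichment(
    input_list: Sequence[str],
    catalog: Catalog,
    background: Sequence[str] | None = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> list[EnrichmentResult]:
    """Score every catalog category against the input list.

    Returns one :class:`EnrichmentResult` per category whose size within
    the population is at least ``config.min_category_size``, sorted by
    raw p-value (ties broken by category id).  Corrections are applied
    over all tested categories (``global``) or within each class
    (``per_class``).
    """
    population, _ = resolve_population(catalog, background)
    hits, _ = match_input(input_list, population)
    P, HP = len(population), len(hits)

    rows: list[dict] = []
    for cat in catalog.categories:
        members_in_pop = cat.members & population
        S = len(members_in_pop)
        if S < config.min_category_size:
            logger.info(
                "category %r skipped: %d member(s) in population "
                "(min_category_size=%d)", cat.id, S, config.min_category_size,
            )
            continue
        matched = frozenset(members_in_pop & hits)
        HS = len(matched)
        counts = ContingencyCounts(P=P, HP=HP, S=S, HS=HS)
        p_raw = p_over(counts) if config.direction == "over" else p_under(counts)
        rows.append(
            dict(
                category=cat,
                S=S,
                HS=HS,
                matched=matched,
                unmatched=frozenset(members_in_pop - hits),
                p_raw=p_raw,
            )
        )

    if not rows:
        raise AnalysisError(
            "no category large enough to test within the population"
        )

    # multiplicity corrections over the configured family
    bonf = [0.0] * len(rows)
    fdr = [0.0] * len(rows)
    if config.correction_scope == "global":
        praws = [r["p_raw"] for r in rows]
        bonf = bonferroni_adjust(praws)
        fdr = bh_fdr_adjust(praws)
    else:
        by_class: dict[str, list[int]] = {}
        for i, r in enumerate(rows):
            by_class.setdefault(r["category"].class_label, []).append(i)
        for idxs in by_class.values():
            sub = [rows[i]["p_raw"] for i in idxs]
            for i, b, q in zip(idxs, bonferroni_adjust(sub), bh_fdr_adjust(sub)):
                bonf[i], fdr[i] = b, q

    results = [
        EnrichmentResult(
            category_id=r["category"].id,
            class_label=r["category"].class_label,
            HS=r["HS"],
            S=r["S"],
            HP=HP,
            P=P,
            percent_matched=100.0 * r["HS"] / HP,
            percent_of_category=100.0 * r["HS"] / r["S"],
            fold=(r["HS"] / HP) / (r["S"] / P),
            p_raw=r["p_raw"],
            p_bonferroni=b,
            p_fdr=q,
            matched_members=r["matched"],
            unmatched_members=r["unmatched"],
            direction=config.direction,
        )
        for r, b, q in zip(rows, bonf, fdr)
    ]
    results.sort(key=lambda res: (res.p_raw, res.category_id))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Results as a DataFrame in the canonical column order."""
    return pd.DataFrame(
        [
            {
                "category_id": r.category_id,
                "class": r.class_label,
                "HS": r.HS,
                "S": r.S,
                "HP": r.HP,
                "P": r.P,
                "percent_matched": r.percent_matched,
                "percent_of_category": r.percent_of_category,
                "fold": r.fold,
                "p_value": r.p_raw,
                "bonferroni": r.p_bonferroni,
                "fdr": r.p_fdr,
                "matched_members": ",".join(sorted(r.matched_members)),
                "unmatched_members": ",".join(sorted(r.unmatched_members)),
            }
            for r in results
        ],
        columns=RESULT_COLUMNS,
    )


def write_results(
    results: Sequence[EnrichmentResult],
    path: str | Path,
    direction: str | None = None,
) -> None:
    """Write the results TSV with a ``# direction:`` comment header."""
    direction = direction or (results[0].direction if results else "over")
    frame = results_to_frame(results)
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"# direction: {direction}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_results(path: str | Path) -> tuple[pd.DataFrame, str]:
    """Read a results TSV back; returns (table, direction)."""
    direction = "over"
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("# direction:"):
        direction = first.split(":", 1)[1].strip()
    try:
        frame = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse results table {path.name}: {exc}") from exc
    missing = [c for c in RESULT_COLUMNS[:-2] if c not in frame.columns]
    if missing:
        raise FormatError(
            f"{path.name} is not an enrichment results table (missing {missing})"
        )
    for col in ("matched_members", "unmatched_members"):
        if col not in frame.columns:
            frame[col] = ""
        frame[col] = frame[col].fillna("")
    return frame, direction
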