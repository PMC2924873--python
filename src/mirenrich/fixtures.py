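"""Deterministic toy-data generators and the packaged AMI worked example.

Synthetic catalogs and loci make every module testable offline; all
generators are pure functions of their :class:`FixtureSpec` (seed
included).  Synthetic miRNAs live in a reserved ``mir-s#`` namespace so
they can never collide with real identifiers in mixed tests.

The worked example is the acute myocardial infarction (AMI) microarray
signature: 8 miRNAs upregulated and 8 downregulated in infarcted rat
myocardium, together with the 11-member muscle-development function
category.  Two of the deregulated miRNAs (miR-1 and miR-499) sit in
that category; its other nine members are the candidate novel
AMI-related miRNAs the prediction step should nominate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .builder import GenomicLocus
from .catalog import CLASS_LABELS, Catalog, Category, normalize_names
from .errors import ValidationError

# -- the AMI worked example (published microarray signature) -----------------

#: miRNAs upregulated in infarcted vs. normal myocardium.
AMI_UPREGULATED = (
    "miR-31", "miR-18a", "miR-18b", "miR-214",
    "miR-223", "miR-923", "miR-711", "miR-199a",
)

#: miRNAs downregulated in infarcted vs. normal myocardium.
AMI_DOWNREGULATED = (
    "miR-499", "miR-29b", "miR-126", "miR-1",
    "miR-181d", "miR-181c", "miR-451", "miR-26b",
)

#: The curated muscle-development function category (11 members).
MUSCLE_DEVELOPMENT_MEMBERS = (
    "miR-1", "miR-499", "miR-24", "miR-124", "miR-133a", "miR-23a",
    "miR-133b", "miR-206", "miR-221", "miR-222", "miR-208b",
)

#: Enrichment significance reported for the muscle-development category
#: against the AMI signature in the original case study.  The full
#: category database behind that run is not redistributed here, so the
#: worked example gates the category at this published level rather
#: than recomputing it against an unavailable background.
MUSCLE_DEVELOPMENT_REPORTED_P = 0.04


@dataclass(frozen=True)
class AmiExample:
    up: tuple[str, ...]
    down: tuple[str, ...]
    muscle_category: Category
    muscle_members: tuple[str, ...]

    @property
    def deregulated(self) -> tuple[str, ...]:
        """All 16 deregulated miRNAs (up then down)."""
        return self.up + self.down


def ami_fixture() -> AmiExample:
    """The packaged AMI worked example.

    Returns the 8 upregulated and 8 downregulated miRNA names verbatim,
    plus the 11-member muscle-development category (members normalized).
    """
    return AmiExample(
        up=AMI_UPREGULATED,
        down=AMI_DOWNREGULATED,
        muscle_category=Category(
            id="muscle-development",
            class_label="function",
            display_name="Muscle development",
            members=frozenset(normalize_names(MUSCLE_DEVELOPMENT_MEMBERS)),
        ),
        muscle_members=MUSCLE_DEVELOPMENT_MEMBERS,
    )


def ami_catalog() -> Catalog:
    """A minimal two-category catalog around the AMI example.

    Holds the muscle-development category plus a disease category of
    the 16 deregulated miRNAs themselves, so that the catalog universe
    covers the whole input list (HP = 16 by default background).
    """
    ex = ami_fixture()
    return Catalog(
        [
            ex.muscle_category,
            Category(
                id="ami-deregulated",
                class_label="disease",
                display_name="Acute myocardial infarction deregulated",
                members=frozenset(normalize_names(ex.deregulated)),
            ),
        ]
    )


# -- synthetic generators -----------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic generators; same spec => same fixture."""

    seed: int = 0
    n_per_class: int = 3
    size_range: tuple[int, int] = (2, 8)
    universe_size: int = 60
    n_loci: int = 12
    n_chroms: int = 2

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if min(self.n_per_class, self.universe_size, self.n_loci,
               self.n_chroms, lo) < 1 or lo > hi:
            raise ValidationError("all fixture sizes must be >= 1 and lo <= hi")
        if hi > self.universe_size:
            raise ValidationError(
                f"category size {hi} exceeds universe of {self.universe_size}"
            )


def synthetic_universe(n: int) -> list[str]:
    """``n`` synthetic miRNA names in the reserved namespace."""
    return [f"mir-s{i}" for i in range(1, n + 1)]


def make_random_catalog(spec: FixtureSpec = FixtureSpec()) -> Catalog:
    """A seeded random catalog with ``n_per_class`` categories per class."""
    rng = np.random.default_rng(spec.seed)
    universe = synthetic_universe(spec.universe_size)
    lo, hi = spec.size_range
    categories: list[Category] = []
    for label in CLASS_LABELS:
        for i in range(1, spec.n_per_class + 1):
            size = int(rng.integers(max(lo, 2), hi + 1))
            members = rng.choice(len(universe), size=size, replace=False)
            categories.append(
                Category(
                    id=f"{label}-set-{i}",
                    class_label=label,
                    display_name=f"synthetic {label} set {i}",
                    members=frozenset(universe[j] for j in members),
                )
            )
    return Catalog(categories)


def make_random_loci(
    spec: FixtureSpec = FixtureSpec(),
    gap_choices: Sequence[int] = (1_000, 20_000, 49_999, 50_000, 50_001, 120_000),
) -> list[GenomicLocus]:
    """Seeded loci whose inter-gene gaps straddle the 50 kb boundary.

    Gaps are drawn from ``gap_choices`` (default mixes sub- and
    super-threshold values, including 50,000 exactly), so cluster tests
    exercise both sides of the chaining rule.
    """
    rng = np.random.default_rng(spec.seed)
    loci: list[GenomicLocus] = []
    per_chrom = max(1, spec.n_loci // spec.n_chroms)
    idx = 1
    for chrom_no in range(1, spec.n_chroms + 1):
        pos = int(rng.integers(1_000, 10_000))
        for _ in range(per_chrom):
            length = int(rng.integers(60, 120))
            strand = "+" if rng.random() < 0.5 else "-"
            loci.append(
                GenomicLocus(
                    mirna=f"mir-s{idx}",
                    chrom=f"chr{chrom_no}",
                    start=pos,
                    end=pos + length,
                    strand=strand,
                )
            )
            gap = int(rng.choice(gap_choices))
            pos = pos + length + gap + 1  # next start leaves exactly `gap` bp
            idx += 1
    return loci


def make_random_tsi(
    spec: FixtureSpec = FixtureSpec(),
    tissues: Sequence[str] = ("heart", "brain", "liver"),
) -> tuple[list, dict[str, str]]:
    """Seeded TSI records spanning the 0.7 threshold, with tissue labels."""
    from .builder import TSIRecord

    rng = np.random.default_rng(spec.seed)
    universe = synthetic_universe(spec.universe_size)
    records = []
    grouping: dict[str, str] = {}
    for name in universe:
        tsi = float(np.round(rng.uniform(0.0, 1.0), 3))
        records.append(TSIRecord(mirna=name, tsi=tsi))
        grouping[name] = str(rng.choice(tissues))
    return records, grouping


def write_mirna_list(names: Sequence[str], path) -> None:
    """Write a plain-text miRNA list, one identifier per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for n in names:
            fh.write(n + "\n")
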