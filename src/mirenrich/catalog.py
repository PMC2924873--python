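"""Data model for miRNA categories and catalogs, with GMT-dialect I/O.

A *category* is one named set of miRNAs sharing a curated property —
membership in a sequence family, co-location in a genomic cluster, a
common function, an associated disease, or tissue-restricted expression.
A *catalog* is an ordered collection of categories; the union of all
members is the default background population for enrichment testing.

Catalogs persist in a GMT dialect (the de facto gene-set exchange
format): one tab-separated line per category, with the class label
carried in the description column::

    <category_id>\tclass=<label>[;name=<display name>]\t<member1>\t<member2>...

Lines starting with ``#`` are comments.  Member names are normalized on
read (lowercased, species prefix stripped), so ``hsa-miR-1`` in a file
and ``rno-miR-1`` in an input list match.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import FormatError, InvalidIdentifierError, ValidationError

logger = logging.getLogger(__name__)

#: The five category classes.
CLASS_LABELS = ("family", "cluster", "function", "disease", "tissue")

# A 3-4 letter species prefix ("hsa-", "rno-", "mmu-" ...) is stripped only
# when what follows looks like a miRNA stem, so "let-7a" is never mangled.
_SPECIES_PREFIX = re.compile(r"^[a-z]{3,4}-(?=(?:mir|let))")
_WS = re.compile(r"\s+")


@dataclass(frozen=True)
class MiRNAKey:
    """A miRNA identifier as supplied plus its normalized matching key."""

    raw: str
    key: str


def normalize_name(raw: str) -> MiRNAKey:
    """Normalize a miRNA identifier to a species-agnostic matching key.

    Lowercases, removes internal whitespace, and strips a leading
    species prefix (``hsa-``, ``rno-``, ``mmu-`` ...) when the remainder
    begins with ``mir`` or ``let``.  Arm suffixes (``-5p``/``-3p``) and
    lettered/numbered variants are kept: distinct mature species stay
    distinct.  Idempotent.

    >>> normalize_name("hsa-miR-199a").key
    'mir-199a'
    >>> normalize_name("let-7a").key
    'let-7a'
    """
    if raw is None or not raw.strip():
        raise InvalidIdentifierError("empty or whitespace-only miRNA identifier")
    key = _WS.sub("", raw.strip()).lower()
    key = _SPECIES_PREFIX.sub("", key)
    return MiRNAKey(raw=raw, key=key)


def normalize_names(names: Iterable[str]) -> list[str]:
    """Normalize many identifiers, returning keys in input order."""
    return [normalize_name(n).key for n in names]


@dataclass(frozen=True)
class Category:
    """One named miRNA set with a class label and normalized members."""

    id: str
    class_label: str
    display_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("category id must be non-empty")
        if self.class_label not in CLASS_LABELS:
            raise ValidationError(
                f"category {self.id!r}: unknown class label {self.class_label!r}; "
                f"expected one of {CLASS_LABELS}"
            )
        if not self.members:
            raise ValidationError(f"category {self.id!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class Catalog:
    """An ordered collection of categories; the test population.

    ``universe`` is always the exact union of all member sets.
    """

    categories: list[Category] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.categories]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate category ids: {dupes}")
        if not self.categories:
            raise ValidationError("catalog must contain at least one category")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.categories:
            out |= c.members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.categories)

    def __iter__(self):
        return iter(self.categories)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Catalog):
            return NotImplemented
        if len(self.categories) != len(other.categories):
            return False
        return all(
            a.id == b.id and a.class_label == b.class_label and a.members == b.members
            for a, b in zip(self.categories, other.categories)
        )

    def class_counts(self) -> dict[str, int]:
        """Per-class category tally (the catalog summary)."""
        counts: dict[str, int] = {}
        for c in self.categories:
            counts[c.class_label] = counts.get(c.class_label, 0) + 1
        return counts


def _parse_description(desc: str, lineno: int) -> tuple[str, str]:
    """Split the GMT description column into (class_label, display_name)."""
    label = ""
    name = ""
    for part in desc.split(";"):
        part = part.strip()
        if part.startswith("class="):
            label = part[len("class="):].strip()
        elif part.startswith("name="):
            name = part[len("name="):].strip()
    if label not in CLASS_LABELS:
        raise FormatError(
            f"line {lineno}: missing or unknown class label in description "
            f"column {desc!r} (expected class=<{'|'.join(CLASS_LABELS)}>)"
        )
    return label, name


def read_catalog(path: str | Path) -> Catalog:
    """Read a GMT-dialect set file into a :class:`Catalog`.

    One category per non-comment line; member names are normalized;
    duplicate members within a line are deduplicated with a warning.
    Raises :class:`FormatError` (naming the line) on duplicate category
    ids, memberless lines, or unknown class labels.
    """
    path = Path(path)
    categories: list[Category] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(
                    f"{path.name} line {lineno}: expected "
                    "<id>\\t<description>\\t<member>... (at least one member)"
                )
            cat_id, desc = cols[0].strip(), cols[1]
            if not cat_id:
                raise FormatError(f"{path.name} line {lineno}: empty category id")
            if cat_id in seen:
                raise FormatError(
                    f"{path.name} line {lineno}: duplicate category id {cat_id!r}"
                )
            seen.add(cat_id)
            label, display = _parse_description(desc, lineno)
            raw_members = [m for m in cols[2:] if m.strip()]
            if not raw_members:
                raise FormatError(f"{path.name} line {lineno}: no members")
            keys = normalize_names(raw_members)
            if len(set(keys)) < len(keys):
                logger.warning(
                    "%s line %d: duplicate members in %r deduplicated",
                    path.name, lineno, cat_id,
                )
            categories.append(
                Category(
                    id=cat_id,
                    class_label=label,
                    display_name=display or cat_id,
                    members=frozenset(keys),
                )
            )
    return Catalog(categories)


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    """Write a catalog in the GMT dialect.

    Members are emitted sorted lexicographically so output is
    deterministic; ``read_catalog(write_catalog(c)) == c``.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for c in catalog.categories:
            desc = f"class={c.class_label}"
            if c.display_name and c.display_name != c.id:
                desc += f";name={c.display_name}"
            fh.write("\t".join([c.id, desc, *sorted(c.members)]) + "\n")


def read_mirna_list(path: str | Path) -> list[str]:
    """Read a plain-text miRNA list (one identifier per line, ``#`` comments)."""
    out: list[str] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def merge_member_sets(sets: Sequence[Iterable[str]]) -> frozenset[str]:
    """Union of already-normalized member iterables."""
    out: set[str] = set()
    for s in sets:
        out.update(s)
    return frozenset(out)
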