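"""Build miRNA categories from raw resources.

Four construction routes feed a catalog:

* **clusters** — single-linkage chaining of miRNA gene loci along each
  chromosome: two genes belong to the same cluster when the gap between
  their intervals is at most 50 kb (the empirical co-transcription
  distance), and chaining is transitive.
* **families** — sequence families from a miRBase-style table or miFam
  stanza file; singleton families are dropped.
* **tissue sets** — miRNAs whose tissue specificity index (TSI) is at
  or above a threshold (default 0.7), grouped by their tissue.
* **annotation sets** — hand-curated function or disease membership
  tables.

All builders are deterministic given identical inputs, and singleton
sets are excluded everywhere: a one-member category cannot be enriched
and only inflates the multiple-testing burden.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils

from .catalog import Catalog, Category, normalize_name
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Empirical genomic distance (bp) within which miRNA genes are
#: considered clustered / co-transcribed.
DEFAULT_CLUSTER_GAP = 50_000

#: Default tissue specificity index cut-off (inclusive).
DEFAULT_TSI_THRESHOLD = 0.7


@dataclass(frozen=True)
class GenomicLocus:
    """One miRNA gene's coordinates (1-based, inclusive, as in GFF3)."""

    mirna: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError(f"locus {self.mirna!r}: empty chromosome")
        if self.start < 1 or self.start > self.end:
            raise ValidationError(
                f"locus {self.mirna!r}: invalid interval "
                f"[{self.start}, {self.end}] (need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(
                f"locus {self.mirna!r}: strand must be '+', '-' or '.'"
            )


@dataclass(frozen=True)
class TSIRecord:
    """A miRNA's tissue specificity index: 1 = single-tissue, 0 = ubiquitous."""

    mirna: str
    tsi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.tsi <= 1.0:
            raise ValidationError(
                f"TSI for {self.mirna!r} is {self.tsi}; must lie in [0, 1]"
            )


_NAT_SPLIT = re.compile(r"(\d+)")


def _natural_key(name: str) -> tuple:
    """Sort key treating digit runs numerically, so mir-2 < mir-10."""
    return tuple(
        int(tok) if tok.isdigit() else tok for tok in _NAT_SPLIT.split(name)
    )


def _gap(left_end: int, right_start: int) -> int:
    """Inter-interval gap in bp; 0 when the intervals touch or overlap."""
    return max(0, right_start - left_end - 1)


def build_clusters(
    loci: Sequence[GenomicLocus],
    max_gap: int = DEFAULT_CLUSTER_GAP,
    same_strand: bool = False,
) -> list[Category]:
    """Chain loci into genomic clusters by single linkage.

    Per chromosome (and per strand when ``same_strand``), loci sorted by
    start are linked whenever the gap from the rightmost end seen so far
    to the next start is <= ``max_gap`` (inclusive; overlap counts as
    gap 0).  Connected components with >= 2 distinct miRNAs become
    ``cluster`` categories, each named after its natural-sort first
    member.  Output order is deterministic: by chromosome, then by the
    leftmost start of the component.
    """
    if max_gap < 0:
        raise ValidationError("max_gap must be >= 0")
    seen: set[tuple[str, str, int]] = set()
    for loc in loci:
        key = (loc.mirna, loc.chrom, loc.start)
        if key in seen:
            raise ValidationError(f"duplicate locus {key}")
        seen.add(key)

    def group_key(loc: GenomicLocus):
        return (loc.chrom, loc.strand) if same_strand else (loc.chrom,)

    groups: dict[tuple, list[GenomicLocus]] = {}
    for loc in loci:
        groups.setdefault(group_key(loc), []).append(loc)

    components: list[tuple[str, int, list[GenomicLocus]]] = []
    for key in sorted(groups):
        block = sorted(groups[key], key=lambda l: (l.start, l.end, l.mirna))
        current: list[GenomicLocus] = []
        reach = None  # rightmost end of the running component
        for loc in block:
            if current and _gap(reach, loc.start) <= max_gap:
                current.append(loc)
                reach = max(reach, loc.end)
            else:
                if current:
                    components.append((current[0].chrom, current[0].start, current))
                current = [loc]
                reach = loc.end
        if current:
            components.append((current[0].chrom, current[0].start, current))

    components.sort(key=lambda t: (t[0], t[1]))
    out: list[Category] = []
    for chrom, _, comp in components:
        members = frozenset(l.mirna for l in comp)
        if len(members) < 2:
            continue
        first = min(members, key=_natural_key)
        cid = f"{first}-cluster"
        if any(c.id == cid for c in out):  # same lead name on two chromosomes
            cid = f"{first}-cluster-{chrom}"
        out.append(
            Category(
                id=cid,
                class_label="cluster",
                display_name=f"{first} cluster",
                members=members,
            )
        )
    return out


def read_gff3_loci(path: str | Path) -> list[GenomicLocus]:
    """Read miRNA gene loci from GFF3; ``Name=`` (or ``ID=``) names the miRNA."""
    loci: list[GenomicLocus] = []
    for feat in gffutils.iterators.DataIterator(str(path)):
        attrs = feat.attributes
        name = (attrs.get("Name") or attrs.get("ID") or [None])[0]
        if name is None:
            raise FormatError(
                f"{Path(path).name}: feature at {feat.seqid}:{feat.start}-"
                f"{feat.end} has neither Name= nor ID= attribute"
            )
        loci.append(
            GenomicLocus(
                mirna=normalize_name(name).key,
                chrom=feat.seqid,
                start=int(feat.start),
                end=int(feat.end),
                strand=feat.strand if feat.strand in ("+", "-") else ".",
            )
        )
    return loci


FamilyRecord = tuple[str, str, Sequence[str]]  # (family_id, family_name, members)


def build_family_sets(records: Iterable[FamilyRecord]) -> list[Category]:
    """One ``family`` category per family with >= 2 distinct members.

    Members are normalized (species prefixes stripped), then
    deduplicated; families left with a single member are dropped with a
    log line.
    """
    out: list[Category] = []
    for fam_id, fam_name, members in records:
        keys = frozenset(normalize_name(m).key for m in members if m.strip())
        if not keys:
            raise FormatError(f"family {fam_id!r} has no members")
        if len(keys) < 2:
            logger.info("family %r dropped: single member after normalization", fam_id)
            continue
        out.append(
            Category(
                id=fam_id,
                class_label="family",
                display_name=fam_name or fam_id,
                members=keys,
            )
        )
    return out


def read_family_table(path: str | Path) -> list[FamilyRecord]:
    """Read a 3-column TSV (family_id, family_name, member), one member per row."""
    fams: dict[str, tuple[str, list[str]]] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3 or not cols[0].strip() or not cols[2].strip():
                raise FormatError(
                    f"{Path(path).name} line {lineno}: expected "
                    "family_id\\tfamily_name\\tmember"
                )
            fam_id = cols[0].strip()
            name, members = fams.setdefault(fam_id, (cols[1].strip(), []))
            members.append(cols[2].strip())
    return [(fid, name, members) for fid, (name, members) in fams.items()]


def read_mifam(path: str | Path) -> list[FamilyRecord]:
    """Read a miFam-style stanza file.

    Stanzas are separated by ``//``; ``AC`` gives the accession, ``ID``
    the family name, and each ``MI`` line lists one member (last token).
    """
    fams: list[FamilyRecord] = []
    acc = fam_name = None
    members: list[str] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("//"):
                if acc is None and fam_name is None and not members:
                    continue
                if not members:
                    raise FormatError(
                        f"{Path(path).name} line {lineno}: stanza without MI lines"
                    )
                fams.append((acc or fam_name, fam_name or acc, members))
                acc = fam_name = None
                members = []
                continue
            tag, _, rest = line.partition(" ")
            rest = rest.strip()
            if tag == "AC":
                acc = rest
            elif tag == "ID":
                fam_name = rest
            elif tag == "MI":
                toks = rest.split()
                if not toks:
                    raise FormatError(f"{Path(path).name} line {lineno}: bare MI line")
                members.append(toks[-1])
    if acc is not None or fam_name is not None or members:
        fams.append((acc or fam_name, fam_name or acc, members))
    return fams


def build_tissue_sets(
    records: Iterable[TSIRecord],
    grouping: Mapping[str, str] | Iterable[tuple[str, str]],
    threshold: float = DEFAULT_TSI_THRESHOLD,
) -> list[Category]:
    """Group tissue-specific miRNAs (TSI >= threshold, inclusive) by tissue.

    ``grouping`` maps each miRNA to its tissue label; miRNAs without a
    tissue label are ignored, as are tissues with no retained miRNA.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold {threshold} outside [0, 1]")
    tissue_of = dict(grouping.items() if isinstance(grouping, Mapping) else grouping)
    tissue_of = {normalize_name(k).key: v for k, v in tissue_of.items()}
    by_tissue: dict[str, set[str]] = {}
    for rec in records:
        if rec.tsi < threshold:
            continue
        key = normalize_name(rec.mirna).key
        tissue = tissue_of.get(key)
        if tissue is None:
            continue
        by_tissue.setdefault(tissue, set()).add(key)
    out: list[Category] = []
    for tissue in sorted(by_tissue):
        out.append(
            Category(
                id=f"tissue-{tissue.lower().replace(' ', '-')}",
                class_label="tissue",
                display_name=f"{tissue} specific",
                members=frozenset(by_tissue[tissue]),
            )
        )
    return out


def read_tsi_table(path: str | Path) -> tuple[list[TSIRecord], dict[str, str]]:
    """Read a TSV of (mirna, tsi[, tissue]) rows.

    Returns the TSI records plus the miRNA -> tissue grouping gathered
    from the optional third column.
    """
    records: list[TSIRecord] = []
    grouping: dict[str, str] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError(
                    f"{Path(path).name} line {lineno}: expected mirna\\ttsi[\\ttissue]"
                )
            try:
                tsi = float(cols[1])
            except ValueError as exc:
                raise FormatError(
                    f"{Path(path).name} line {lineno}: bad TSI value {cols[1]!r}"
                ) from exc
            records.append(TSIRecord(mirna=cols[0].strip(), tsi=tsi))
            if len(cols) >= 3 and cols[2].strip():
                grouping[normalize_name(cols[0]).key] = cols[2].strip()
    return records, grouping


AnnotationRow = tuple[str, str, str]  # (set_name, class_label, member)


def build_annotation_sets(
    records: Iterable[AnnotationRow],
    source_tag: str = "",
) -> list[Category]:
    """One category per curated function/disease set name.

    Rows with the same set name are unioned; provenance (``source_tag``)
    is recorded in the display name.
    """
    sets: dict[str, tuple[str, set[str]]] = {}
    for set_name, class_label, member in records:
        if class_label not in ("function", "disease"):
            raise ValidationError(
                f"annotation set {set_name!r}: class must be function or "
                f"disease, got {class_label!r}"
            )
        if not member or not member.strip():
            raise FormatError(f"annotation set {set_name!r}: empty member column")
        label, members = sets.setdefault(set_name, (class_label, set()))
        if label != class_label:
            raise ValidationError(
                f"annotation set {set_name!r} listed under two classes"
            )
        members.add(normalize_name(member).key)
    out: list[Category] = []
    for set_name in sorted(sets):
        class_label, members = sets[set_name]
        display = set_name if not source_tag else f"{set_name} [{source_tag}]"
        out.append(
            Category(
                id=set_name.lower().replace(" ", "-"),
                class_label=class_label,
                display_name=display,
                members=frozenset(members),
            )
        )
    return out


def read_annotation_table(path: str | Path, class_label: str) -> list[AnnotationRow]:
    """Read a 2-column TSV (set_name, member) for one annotation class."""
    rows: list[AnnotationRow] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2 or not cols[0].strip() or not cols[1].strip():
                raise FormatError(
                    f"{Path(path).name} line {lineno}: expected set_name\\tmember"
                )
            rows.append((cols[0].strip(), class_label, cols[1].strip()))
    return rows


def merge_catalogs(parts: Sequence[Catalog]) -> Catalog:
    """Concatenate catalogs; id collisions get a ``-<class>`` suffix."""
    if not parts:
        raise ValidationError("no catalogs to merge")
    seen: set[str] = set()
    merged: list[Category] = []
    for part in parts:
        for c in part.categories:
            cid = c.id
            if cid in seen:
                cid = f"{c.id}-{c.class_label}"
            n = 2
            while cid in seen:
                cid = f"{c.id}-{c.class_label}{n}"
                n += 1
            if cid != c.id:
                logger.warning("category id %r renamed to %r on merge", c.id, cid)
                c = Category(cid, c.class_label, c.display_name, c.members)
            seen.add(cid)
            merged.append(c)
    return Catalog(merged)


def loci_to_gff3(loci: Sequence[GenomicLocus], path: str | Path) -> None:
    """Write loci to a minimal GFF3 file (round-trips via read_gff3_loci)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for i, loc in enumerate(sorted(loci, key=lambda l: (l.chrom, l.start)), 1):
            fh.write(
                f"{loc.chrom}\tmirenrich\tmiRNA_primary_transcript\t{loc.start}\t"
                f"{loc.end}\t.\t{loc.strand}\t.\tID=LOC{i:04d};Name={loc.mirna}\n"
            )
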