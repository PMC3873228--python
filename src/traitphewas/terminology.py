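"""ICD-10 code handling and phenotype-group (PheWAS code) construction.

Billing codes are too fine-grained to test one by one, so they are
aggregated into phenotype groups under two schemes:

* ``icd10_block`` — the native ICD-10 hierarchy: one group per block
  (the superclass of the three-character codes, e.g. C15–C26), with the
  enclosing chapter as the sibling *exclusion range*.
* ``icd9cm_phewas`` — ICD-10 codes projected onto ICD-9-CM through a
  crosswalk table and from there onto the classic ICD-9-CM-based PheWAS
  code definitions, with manual overrides taking precedence.

A patient carrying a code inside a group's case range is a case for that
group; a patient whose only nearby codes fall elsewhere in the exclusion
range is dropped from that group's comparison instead of being counted
as a control.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "IcdCode",
    "CodeRange",
    "PhewasGroup",
    "TerminologyMap",
    "Terminology",
    "TerminologyError",
    "IcdParseError",
    "normalize_icd10",
    "compare_codes",
    "build_block_groups",
    "build_mapped_groups",
    "exclusion_range",
    "load_hierarchy",
    "load_chapters",
    "expand_block_table",
    "data_path",
]

_ROOT_RE = re.compile(r"^([A-Z])([0-9]{2})(.*)$")


class TerminologyError(ValueError):
    """Inconsistent terminology tables (duplicate assignment, orphan block...)."""


class IcdParseError(ValueError):
    """A string that cannot be normalized into an ICD-10 code."""


@dataclass(frozen=True, order=False)
class IcdCode:
    """A normalized ICD-10 identifier: letter + 2-digit number + optional extension.

    Ordering is total: by letter, then number, then extension
    lexicographically. Range membership uses the three-character root only.
    """

    letter: str
    number: int
    extension: str = ""

    def __post_init__(self) -> None:
        if not (len(self.letter) == 1 and "A" <= self.letter <= "Z"):
            raise IcdParseError(f"bad ICD-10 letter: {self.letter!r}")
        if not (0 <= self.number <= 99):
            raise IcdParseError(f"bad ICD-10 number: {self.number!r}")

    @property
    def root(self) -> str:
        return f"{self.letter}{self.number:02d}"

    @property
    def root_key(self) -> int:
        """Integer encoding of the root, monotone in the code order."""
        return (ord(self.letter) - ord("A")) * 100 + self.number

    def display(self) -> str:
        if self.extension:
            return f"{self.root}.{self.extension}"
        return self.root

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.display()

    def _key(self) -> tuple[str, int, str]:
        return (self.letter, self.number, self.extension)

    def __lt__(self, other: "IcdCode") -> bool:
        return self._key() < other._key()

    def __le__(self, other: "IcdCode") -> bool:
        return self._key() <= other._key()

    def __gt__(self, other: "IcdCode") -> bool:
        return self._key() > other._key()

    def __ge__(self, other: "IcdCode") -> bool:
        return self._key() >= other._key()


def normalize_icd10(raw: str) -> IcdCode:
    """Parse a raw ICD-10 string in dotted or undotted dialect.

    Accepts e.g. ``"K500"``, ``"k50.0"``, ``"C18"``; the root must be a
    letter followed by two digits. Anything after the root (dot-separated
    or not) becomes the extension.
    """
    if raw is None:
        raise IcdParseError("empty ICD-10 code")
    s = str(raw).strip().upper().replace(" ", "")
    if not s:
        raise IcdParseError("empty ICD-10 code")
    m = _ROOT_RE.match(s)
    if m is None:
        raise IcdParseError(f"malformed ICD-10 code: {raw!r}")
    letter, number, rest = m.group(1), int(m.group(2)), m.group(3)
    extension = rest.lstrip(".")
    if "." in extension:
        extension = extension.replace(".", "")
    return IcdCode(letter, number, extension)


def compare_codes(a: IcdCode, b: IcdCode) -> int:
    """Three-way comparison under the total code order."""
    ka, kb = a._key(), b._key()
    return -1 if ka < kb else (1 if ka > kb else 0)


@dataclass(frozen=True)
class CodeRange:
    """Inclusive range of three-character roots, e.g. C15–C26.

    Membership ignores extensions: a range contains a code iff the
    code's root lies between ``start`` and ``end``.
    """

    start: IcdCode
    end: IcdCode

    def __post_init__(self) -> None:
        if self.start.root_key > self.end.root_key:
            raise TerminologyError(
                f"range start {self.start.root} after end {self.end.root}"
            )

    def __contains__(self, code: IcdCode) -> bool:
        return self.start.root_key <= code.root_key <= self.end.root_key

    def contains_range(self, other: "CodeRange") -> bool:
        return (
            self.start.root_key <= other.start.root_key
            and other.end.root_key <= self.end.root_key
        )

    def display(self) -> str:
        return f"{self.start.root}-{self.end.root}"

    @classmethod
    def parse(cls, start: str, end: str) -> "CodeRange":
        return cls(normalize_icd10(start), normalize_icd10(end))


@dataclass(frozen=True)
class PhewasGroup:
    """An aggregated phenotype code under one scheme.

    ``case_ranges`` define case membership; ``exclusion_range`` is the
    wider sibling range (the enclosing chapter for block groups) whose
    carriers are removed from this group's comparison.
    """

    id: str
    label: str
    scheme: str  # icd10_block | icd9cm_phewas
    case_ranges: tuple[CodeRange, ...]
    exclusion_range: CodeRange

    def __post_init__(self) -> None:
        if self.scheme not in ("icd10_block", "icd9cm_phewas"):
            raise TerminologyError(f"unknown scheme {self.scheme!r}")
        for r in self.case_ranges:
            if not self.exclusion_range.contains_range(r):
                raise TerminologyError(
                    f"group {self.id}: case range {r.display()} outside "
                    f"exclusion range {self.exclusion_range.display()}"
                )


@dataclass
class TerminologyMap:
    """Mapping from ICD-10 roots (and extensions where needed) to group ids.

    ``entries`` keys are display forms (root or root.ext); ``provenance``
    records whether each entry came from the automatic composition or a
    manual override. ``excluded`` lists codes deemed not a proper
    diagnosis, removed from the analysis universe up front.
    """

    scheme: str
    entries: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    excluded: set[str] = field(default_factory=set)

    def assign(self, code: IcdCode) -> str | None:
        """Group id for a code, or None when excluded/unmapped.

        Extension-level entries win over the root entry.
        """
        disp = code.display()
        if disp in self.excluded or code.root in self.excluded:
            return None
        if disp in self.entries:
            return self.entries[disp]
        return self.entries.get(code.root)

    def add(self, key: str, group_id: str, provenance: str = "automatic") -> None:
        prior = self.entries.get(key)
        if prior is not None and prior != group_id:
            if provenance == "manual_override":
                pass  # override wins, recorded below
            elif self.provenance.get(key) == "manual_override":
                return  # keep the existing override
            else:
                raise TerminologyError(
                    f"code {key} assigned to both {prior} and {group_id}"
                )
        self.entries[key] = group_id
        self.provenance[key] = provenance


@dataclass
class Terminology:
    """One aggregation scheme ready for scanning: groups plus the code map."""

    scheme: str
    groups: dict[str, PhewasGroup]
    map: TerminologyMap

    def group_list(self) -> list[PhewasGroup]:
        return [self.groups[g] for g in sorted(self.groups)]


# ---------------------------------------------------------------------------
# fixtures and loaders


def data_path(name: str) -> Path:
    """Path to a packaged terminology/config fixture."""
    return Path(__file__).parent / "data" / name


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TerminologyError(f"{what}: missing columns {missing}")


def load_chapters(path: str | Path | None = None) -> pd.DataFrame:
    """Load the chapter-span table (chapter_id, label, start, end)."""
    path = Path(path) if path else data_path("icd10_chapters.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["chapter_id", "start", "end"], "chapter table")
    return df


def expand_block_table(blocks: pd.DataFrame) -> pd.DataFrame:
    """Expand a block-span table into the per-code hierarchy table.

    Input columns: block_id, block_label, start, end, chapter_id,
    chapter_start, chapter_end. Output: one row per three-character code
    with (code, block_id, block_label, chapter_id, chapter_start, chapter_end).
    """
    _require_columns(
        blocks,
        ["block_id", "block_label", "start", "end", "chapter_id",
         "chapter_start", "chapter_end"],
        "block table",
    )
    rows = []
    for rec in blocks.itertuples(index=False):
        lo = normalize_icd10(rec.start)
        hi = normalize_icd10(rec.end)
        for k in range(lo.root_key, hi.root_key + 1):
            letter = chr(ord("A") + k // 100)
            code = f"{letter}{k % 100:02d}"
            rows.append(
                (code, rec.block_id, rec.block_label, rec.chapter_id,
                 rec.chapter_start, rec.chapter_end)
            )
    return pd.DataFrame(
        rows,
        columns=["code", "block_id", "block_label", "chapter_id",
                 "chapter_start", "chapter_end"],
    )


def load_hierarchy(path: str | Path | None = None) -> pd.DataFrame:
    """Load the packaged block fixture and expand it to the per-code table."""
    path = Path(path) if path else data_path("icd10_blocks_toy.tsv")
    blocks = pd.read_csv(path, sep="\t", dtype=str)
    return expand_block_table(blocks)


def build_block_groups(hierarchy: pd.DataFrame) -> Terminology:
    """Build one phenotype group per ICD-10 block.

    ``hierarchy`` has one row per three-character code:
    (code, block_id, block_label, chapter_id, chapter_start, chapter_end).
    Each block becomes a group whose case range is the block span and whose
    exclusion range is the enclosing chapter span.
    """
    if len(hierarchy) == 0:
        return Terminology("icd10_block", {}, TerminologyMap("icd10_block"))
    _require_columns(
        hierarchy,
        ["code", "block_id", "chapter_id", "chapter_start", "chapter_end"],
        "hierarchy table",
    )
    dup = hierarchy["code"][hierarchy["code"].duplicated()]
    if len(dup):
        raise TerminologyError(
            f"codes assigned to two blocks: {sorted(set(dup))[:5]}"
        )
    groups: dict[str, PhewasGroup] = {}
    tmap = TerminologyMap("icd10_block")
    for block_id, sub in hierarchy.groupby("block_id", sort=True):
        chapters = sub[["chapter_id", "chapter_start", "chapter_end"]].drop_duplicates()
        if len(chapters) != 1:
            raise TerminologyError(f"block {block_id} straddles two chapters")
        ch = chapters.iloc[0]
        codes = sorted(normalize_icd10(c) for c in sub["code"])
        span = CodeRange(codes[0], codes[-1])
        excl = CodeRange.parse(ch["chapter_start"], ch["chapter_end"])
        label = (
            str(sub["block_label"].iloc[0]) if "block_label" in sub.columns else block_id
        )
        groups[str(block_id)] = PhewasGroup(
            id=str(block_id),
            label=label,
            scheme="icd10_block",
            case_ranges=(span,),
            exclusion_range=excl,
        )
        for c in codes:
            tmap.add(c.root, str(block_id))
    return Terminology("icd10_block", groups, tmap)


@dataclass
class CoverageReport:
    """Outcome of composing the two mapping tables."""

    n_source_codes: int
    n_automatic: int
    n_manual: int
    unmapped: list[str]
    excluded: list[str]

    @property
    def automatic_fraction(self) -> float:
        if self.n_source_codes == 0:
            return 0.0
        return self.n_automatic / self.n_source_codes


def build_mapped_groups(
    nz_map: pd.DataFrame,
    phewas9_defs: pd.DataFrame,
    overrides: pd.DataFrame | None = None,
    excluded_codes: Iterable[str] = (),
) -> tuple[Terminology, CoverageReport]:
    """Compose ICD-10 → ICD-9-CM → PheWAS-code into one terminology.

    ``nz_map``: columns (icd10, icd9cm) — the crosswalk table.
    ``phewas9_defs``: columns (icd9cm, phewas_code, label,
    exclusion_start, exclusion_end) — group definitions with their
    explicit exclusion range expressed in ICD-10 space.
    ``overrides``: columns (icd10, phewas_code), manual entries that take
    precedence over the automatic composition.

    Returns the terminology plus a coverage report listing unmapped
    codes and the automatic-coverage fraction.
    """
    _require_columns(nz_map, ["icd10", "icd9cm"], "crosswalk table")
    _require_columns(
        phewas9_defs,
        ["icd9cm", "phewas_code", "label", "exclusion_start", "exclusion_end"],
        "group definition table",
    )
    defs = phewas9_defs.drop_duplicates()
    icd9_to_group: dict[str, str] = {}
    group_meta: dict[str, dict] = {}
    for rec in defs.itertuples(index=False):
        code9 = str(rec.icd9cm)
        gid = str(rec.phewas_code)
        if icd9_to_group.get(code9, gid) != gid:
            raise TerminologyError(
                f"ICD-9-CM code {code9} defined under two PheWAS codes"
            )
        icd9_to_group[code9] = gid
        meta = group_meta.setdefault(
            gid,
            {"label": str(rec.label),
             "exclusion": CodeRange.parse(str(rec.exclusion_start),
                                          str(rec.exclusion_end)),
             "codes": set()},
        )
        meta["codes"].add(code9)

    tmap = TerminologyMap("icd9cm_phewas", excluded=set(excluded_codes))
    case_codes: dict[str, set[str]] = {g: set() for g in group_meta}
    unmapped: list[str] = []
    n_auto = 0
    source_codes = sorted(set(str(c) for c in nz_map["icd10"]))
    # automatic composition; a code reaching two groups is ambiguous
    for code10, sub in nz_map.groupby("icd10", sort=True):
        key = normalize_icd10(str(code10)).display()
        if key in tmap.excluded:
            continue
        targets = {
            icd9_to_group[str(c9)]
            for c9 in sub["icd9cm"]
            if str(c9) in icd9_to_group
        }
        if len(targets) > 1:
            if overrides is not None and key in set(
                normalize_icd10(str(c)).display() for c in overrides["icd10"]
            ):
                continue  # resolved below
            raise TerminologyError(
                f"ICD-10 code {key} composes to several PheWAS codes: "
                f"{sorted(targets)}"
            )
        if not targets:
            unmapped.append(key)
            continue
        gid = targets.pop()
        tmap.add(key, gid, "automatic")
        case_codes[gid].add(key)
        n_auto += 1

    n_manual = 0
    if overrides is not None and len(overrides):
        _require_columns(overrides, ["icd10", "phewas_code"], "override table")
        for rec in overrides.itertuples(index=False):
            key = normalize_icd10(str(rec.icd10)).display()
            gid = str(rec.phewas_code)
            if gid not in group_meta:
                raise TerminologyError(f"override targets unknown group {gid}")
            tmap.add(key, gid, "manual_override")
            case_codes[gid].add(key)
            if key in unmapped:
                unmapped.remove(key)
            n_manual += 1

    groups: dict[str, PhewasGroup] = {}
    for gid, meta in group_meta.items():
        roots = sorted(
            {normalize_icd10(c) for c in case_codes[gid]},
            key=lambda c: c.root_key,
        )
        if roots:
            ranges = tuple(
                CodeRange(IcdCode(r.letter, r.number), IcdCode(r.letter, r.number))
                for r in {IcdCode(c.letter, c.number) for c in roots}
            )
            ranges = tuple(sorted(ranges, key=lambda r: r.start.root_key))
        else:
            ranges = ()
        groups[gid] = PhewasGroup(
            id=gid,
            label=meta["label"],
            scheme="icd9cm_phewas",
            case_ranges=ranges,
            exclusion_range=meta["exclusion"],
        )
    report = CoverageReport(
        n_source_codes=len(source_codes),
        n_automatic=n_auto,
        n_manual=n_manual,
        unmapped=sorted(unmapped),
        excluded=sorted(tmap.excluded),
    )
    return Terminology("icd9cm_phewas", groups, tmap), report


def exclusion_range(group: PhewasGroup, chapters: pd.DataFrame) -> CodeRange:
    """Sibling exclusion range for a group.

    Block groups take the enclosing chapter span from the chapter table;
    mapped groups carry an explicit configured range. A case range
    straddling two chapters is a terminology error.
    """
    if group.scheme == "icd9cm_phewas":
        return group.exclusion_range
    _require_columns(chapters, ["chapter_id", "start", "end"], "chapter table")
    spans = [
        (CodeRange.parse(r.start, r.end), r.chapter_id)
        for r in chapters.itertuples(index=False)
    ]
    hits = {
        cid
        for rng, cid in spans
        for cr in group.case_ranges
        if cr.start in rng or cr.end in rng
    }
    if len(hits) != 1:
        raise TerminologyError(
            f"group {group.id} case ranges straddle chapters {sorted(hits)}"
        )
    cid = hits.pop()
    for rng, c in spans:
        if c == cid:
            for cr in group.case_ranges:
                if not rng.contains_range(cr):
                    raise TerminologyError(
                        f"group {group.id} range {cr.display()} straddles "
                        f"chapter {cid}"
                    )
            return rng
    raise TerminologyError(f"chapter {cid} vanished")  # pragma: no cover
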