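"""Alignment and metadata input/output.

Sequences are assumed to be pre-aligned to a common coordinate frame
(for human mtDNA, the 16,569-site rCRS frame); this module never
realigns.  Characters are normalised to the six-letter alphabet
``{A, C, G, T, N, -}``: ``U`` is mapped to ``T`` and every other IUPAC
ambiguity code to ``N``.  Gaps (``-``) are treated as missing data by
every downstream statistic, exactly like ``N``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_CHARS = frozenset("ACGTN-")
_AMBIGUITY = frozenset("RYSWKMBDHVU")


class AlignmentShapeError(ValueError):
    """Records of unequal length, or an otherwise malformed alignment."""


class FormatError(ValueError):
    """Empty or structurally invalid input file."""


def _normalise(seq: str) -> str:
    out = []
    for ch in seq.upper():
        if ch in VALID_CHARS:
            out.append(ch)
        elif ch == "U":
            out.append("T")
        elif ch in _AMBIGUITY:
            out.append("N")
        elif ch == "?" or ch == ".":
            out.append("N")
        else:
            raise FormatError(f"invalid sequence character {ch!r}")
    return "".join(out)


@dataclass(frozen=True)
class Alignment:
    """Equal-length sequences over ``{A,C,G,T,N,-}`` with unique ids."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise AlignmentShapeError("ids and sequences differ in cardinality")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentShapeError("duplicate sequence ids")
        if not self.sequences:
            raise AlignmentShapeError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"sequences have unequal lengths: {sorted(lengths)}"
            )
        if next(iter(lengths)) == 0:
            raise AlignmentShapeError("zero-length sequences")
        for s in self.sequences:
            bad = set(s) - VALID_CHARS
            if bad:
                raise AlignmentShapeError(f"invalid characters {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def subset(self, ids: Iterable[str]) -> "Alignment":
        wanted = list(ids)
        index = {sid: i for i, sid in enumerate(self.ids)}
        missing = [sid for sid in wanted if sid not in index]
        if missing:
            raise KeyError(f"ids not in alignment: {missing}")
        return Alignment(
            ids=tuple(wanted),
            sequences=tuple(self.sequences[index[sid]] for sid in wanted),
        )

    @classmethod
    def from_records(cls, records: Mapping[str, str]) -> "Alignment":
        return cls(
            ids=tuple(records),
            sequences=tuple(_normalise(s) for s in records.values()),
        )


@dataclass
class SampleTable:
    """Per-sample metadata: group, site, culture/period, age, haplogroup.

    Thin wrapper around a DataFrame with columns ``id``, ``group``,
    ``site``, ``culture_period``, ``age_bp`` (years before 1950,
    nullable) and ``haplogroup`` (nullable).
    """

    data: pd.DataFrame = field(repr=False)

    REQUIRED = ("id",)
    OPTIONAL = ("group", "site", "culture_period", "age_bp", "haplogroup")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise FormatError(f"metadata missing required column {col!r}")
        if self.data["id"].duplicated().any():
            dupes = self.data.loc[self.data["id"].duplicated(), "id"].tolist()
            raise FormatError(f"duplicate sample ids in metadata: {dupes}")
        for col in self.OPTIONAL:
            if col not in self.data.columns:
                self.data[col] = pd.NA
        if "age_bp" in self.data:
            ages = pd.to_numeric(self.data["age_bp"], errors="coerce")
            if (ages.dropna() < 0).any():
                raise FormatError("negative age_bp in metadata")
            self.data["age_bp"] = ages

    @property
    def ids(self) -> list[str]:
        return self.data["id"].tolist()

    def __len__(self) -> int:
        return len(self.data)

    def groups(self, field_name: str = "group") -> dict[str, list[str]]:
        sub = self.data.dropna(subset=[field_name])
        out: dict[str, list[str]] = {}
        for label, chunk in sub.groupby(field_name, sort=False):
            if not str(label):
                raise FormatError("empty group label")
            out[str(label)] = chunk["id"].tolist()
        return out


@dataclass(frozen=True)
class GroupedAlignment:
    """An alignment partitioned into named groups with optional ages."""

    alignment: Alignment
    partition: dict[str, tuple[str, ...]]
    ages: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.partition:
            raise ValueError("empty partition")
        seen: set[str] = set()
        known = set(self.alignment.ids)
        for label, members in self.partition.items():
            if not members:
                raise ValueError(f"group {label!r} is empty")
            for sid in members:
                if sid in seen:
                    raise ValueError(f"sample {sid!r} assigned to two groups")
                if sid not in known:
                    raise ValueError(f"sample {sid!r} not in alignment")
                seen.add(sid)

    @property
    def group_labels(self) -> list[str]:
        return list(self.partition)

    def group_alignment(self, label: str) -> Alignment:
        return self.alignment.subset(self.partition[label])

    def sizes(self) -> dict[str, int]:
        return {g: len(m) for g, m in self.partition.items()}


# ---------------------------------------------------------------------------
# readers / writers


def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    seqs = [_normalise(str(r.seq)) for r in records]
    if len({len(s) for s in seqs}) != 1:
        raise AlignmentShapeError(
            f"{path}: records of unequal length — input is not an alignment"
        )
    return Alignment(ids=tuple(ids), sequences=tuple(seqs))


def write_fasta_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta-2line")


# Calendar-date parsing.  BP is years before 1950; a "600–400 BCE"
# interval becomes its midpoint, 500 BCE = 2450 BP.  "cal." prefixes are
# ignored; "3rd cen. BCE" becomes the century midpoint (250 BCE).
_RANGE_RE = re.compile(r"^(\d+)\s*[–—-]\s*(\d+)\s*(BCE|CE|BP)$")
_SINGLE_RE = re.compile(r"^(\d+)\s*(BCE|CE|BP)$")
_CENTURY_RE = re.compile(r"^(\d+)(?:st|nd|rd|th)\s*cen\.?\s*(BCE|CE)$")

_PRESENT_YEAR = 1950


def parse_age_bp(date_str: object) -> float | None:
    """Convert a printed date string to years BP (midpoint rule).

    Returns None for empty/missing dates; raises FormatError for
    unparseable non-empty strings.
    """
    if date_str is None or (isinstance(date_str, float) and pd.isna(date_str)):
        return None
    text = str(date_str).strip()
    if not text or text.lower() in {"na", "nan", "none"}:
        return None
    text = text.replace(",", "")
    text = re.sub(r"\bcal\.?\s*", "", text)
    m = _RANGE_RE.match(text)
    if m:
        lo, hi, era = float(m.group(1)), float(m.group(2)), m.group(3)
        mid = (lo + hi) / 2.0
        if era == "BCE":
            return mid + _PRESENT_YEAR
        if era == "CE":
            return _PRESENT_YEAR - mid
        return mid
    m = _SINGLE_RE.match(text)
    if m:
        year, era = float(m.group(1)), m.group(2)
        if era == "BCE":
            return year + _PRESENT_YEAR
        if era == "CE":
            return _PRESENT_YEAR - year
        return year
    m = _CENTURY_RE.match(text)
    if m:
        century, era = int(m.group(1)), m.group(2)
        mid = century * 100 - 50
        if era == "BCE":
            return mid + _PRESENT_YEAR
        return _PRESENT_YEAR - mid
    raise FormatError(f"cannot parse date {date_str!r}")


DEFAULT_SCHEMA = {
    "id": "id",
    "group": "group",
    "site": "site",
    "culture_period": "culture_period",
    "date": "date",
    "age_bp": "age_bp",
    "haplogroup": "haplogroup",
}


def read_metadata(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str = ",",
) -> SampleTable:
    """Read a delimited metadata table into a :class:`SampleTable`.

    ``schema`` maps canonical field names (keys of ``DEFAULT_SCHEMA``)
    to the column names actually present in the file.  A ``date``
    column, when mapped, is converted to ``age_bp`` via the midpoint
    rule of :func:`parse_age_bp`; an explicit ``age_bp`` column wins.
    """
    mapping = dict(DEFAULT_SCHEMA)
    if schema:
        mapping.update(schema)
    raw = pd.read_csv(path, sep=sep, dtype=str).rename(
        columns={v: k for k, v in mapping.items() if v is not None}
    )
    if "id" not in raw.columns:
        raise FormatError(f"{path}: no id column (looked for {mapping['id']!r})")
    raw["id"] = raw["id"].str.strip()
    if "age_bp" not in raw.columns and "date" in raw.columns:
        raw["age_bp"] = raw["date"].map(parse_age_bp)
    keep = [c for c in ("id", *SampleTable.OPTIONAL) if c in raw.columns]
    return SampleTable(raw[keep].copy())


def build_grouped(
    alignment: Alignment,
    table: SampleTable,
    group_field: str = "group",
    ages_field: str = "age_bp",
) -> GroupedAlignment:
    """Partition an alignment by a metadata field.

    Samples present in the table but absent from the alignment are
    excluded with a logged warning; the resulting partition must be
    non-empty.
    """
    if group_field not in table.data.columns:
        raise FormatError(f"metadata has no column {group_field!r}")
    known = set(alignment.ids)
    partition: dict[str, tuple[str, ...]] = {}
    n_dropped = 0
    for label, members in table.groups(group_field).items():
        present = tuple(sid for sid in members if sid in known)
        n_dropped += len(members) - len(present)
        if present:
            partition[label] = present
    if n_dropped:
        logger.warning(
            "%d metadata sample(s) absent from the alignment were excluded",
            n_dropped,
        )
    if not partition:
        raise ValueError("no metadata sample matches the alignment")
    ages = {}
    if ages_field in table.data.columns:
        for sid, age in zip(table.data["id"], table.data[ages_field]):
            if sid in known and pd.notna(age):
                ages[sid] = float(age)
    return GroupedAlignment(alignment=alignment, partition=partition, ages=ages)
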