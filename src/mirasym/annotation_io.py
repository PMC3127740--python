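"""Readers and writers for hairpin annotations and small-RNA tag-count libraries.

Hairpins come in as FASTA plus mature-arm coordinates (miRBase-dialect GFF3 or
a 6-column TSV).  Small-RNA libraries are tag -> read-count mappings, read from
2-column TSV or FASTA with an ``_xN`` count suffix in the header.  All
sequences are normalized to the RNA alphabet (T -> U) on input; coordinates
are 1-based inclusive throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")

__all__ = [
    "PreMirnaRecord",
    "ReadLibrary",
    "read_annotations",
    "read_tag_counts",
    "write_tag_counts",
    "write_annotations",
    "pool_libraries",
]


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U."""
    return seq.strip().upper().replace("T", "U")


def _check_rna(seq: str, context: str) -> None:
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-ACGU symbol(s) {sorted(bad)} in {context}")


@dataclass
class PreMirnaRecord:
    """One pre-miRNA hairpin with optional 5p/3p mature-arm coordinates.

    Coordinates are 1-based inclusive positions on ``hairpin_seq``; either
    arm may be absent (``None``).
    """

    id: str
    hairpin_seq: str
    species: str = ""
    arm5p_start: Optional[int] = None
    arm5p_end: Optional[int] = None
    arm3p_start: Optional[int] = None
    arm3p_end: Optional[int] = None

    def __post_init__(self) -> None:
        self.hairpin_seq = normalize_rna(self.hairpin_seq)
        _check_rna(self.hairpin_seq, f"hairpin {self.id!r}")
        n = len(self.hairpin_seq)
        for arm in ("5p", "3p"):
            s, e = self.arm_bounds(arm)
            if (s is None) != (e is None):
                raise ValueError(f"hairpin {self.id!r}: partial {arm} arm coordinates")
            if s is not None and not (1 <= s <= e <= n):
                raise ValueError(
                    f"hairpin {self.id!r}: {arm} arm {s}-{e} out of bounds (len {n})"
                )
        if self.arm5p_end is not None and self.arm3p_start is not None:
            if not self.arm5p_end < self.arm3p_start:
                raise ValueError(
                    f"hairpin {self.id!r}: 5p arm must end before 3p arm starts"
                )

    def arm_bounds(self, arm: str) -> tuple[Optional[int], Optional[int]]:
        if arm == "5p":
            return self.arm5p_start, self.arm5p_end
        if arm == "3p":
            return self.arm3p_start, self.arm3p_end
        raise ValueError(f"arm must be '5p' or '3p', got {arm!r}")

    def arm_seq(self, arm: str) -> Optional[str]:
        s, e = self.arm_bounds(arm)
        if s is None:
            return None
        return self.hairpin_seq[s - 1 : e]

    @property
    def arms(self) -> tuple[str, ...]:
        return tuple(a for a in ("5p", "3p") if self.arm_bounds(a)[0] is not None)


@dataclass
class ReadLibrary:
    """A tag-sequence -> read-count mapping pooled from one or more sources."""

    source_ids: list[str] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tag, c in self.counts.items():
            if not tag:
                raise ValueError("empty tag sequence")
            _check_rna(tag, f"tag {tag!r}")
            if not isinstance(c, (int,)) or isinstance(c, bool) or c < 0:
                raise ValueError(f"tag {tag!r}: count must be a non-negative integer")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)


# ---------------------------------------------------------------------------
# annotation input


def _parse_coord_tsv(path: Path) -> list[tuple[str, str, int, int, str, str]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 tab-separated columns")
            hid, arm, start, end = parts[:4]
            name = parts[4] if len(parts) > 4 else ""
            species = parts[5] if len(parts) > 5 else ""
            if arm not in ("5p", "3p"):
                raise ValueError(f"{path}:{lineno}: arm must be 5p or 3p, got {arm!r}")
            rows.append((hid, arm, int(start), int(end), name, species))
    return rows


_GFF_ATTR = re.compile(r"(\w+)=([^;]+)")


def _parse_coord_gff3(path: Path) -> list[tuple[str, str, int, int, str, str]]:
    """miRBase-dialect GFF3: type ``miRNA`` rows carry ID and Derives_from.

    The hairpin id is taken from Derives_from; the arm from an ``ID``/``Name``
    suffix (``-5p``/``-3p``) or, failing that, resolved later by coordinate
    order.  Coordinates are interpreted on the hairpin sequence.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 line")
            _, _, ftype, start, end, _, _, _, attrs = parts
            if ftype != "miRNA":
                continue
            d = dict(_GFF_ATTR.findall(attrs))
            hid = d.get("Derives_from")
            if hid is None:
                raise ValueError(f"{path}:{lineno}: miRNA row lacks Derives_from")
            name = d.get("Name", d.get("ID", ""))
            arm = ""
            if name.endswith("-5p"):
                arm = "5p"
            elif name.endswith("-3p"):
                arm = "3p"
            rows.append((hid, arm, int(start), int(end), name, ""))
    # resolve missing arms by coordinate order within a hairpin
    by_hid: dict[str, list[int]] = {}
    for i, r in enumerate(rows):
        by_hid.setdefault(r[0], []).append(i)
    for hid, idxs in by_hid.items():
        unarmed = [i for i in idxs if not rows[i][1]]
        if not unarmed:
            continue
        ordered = sorted(idxs, key=lambda i: rows[i][2])
        for rank, i in enumerate(ordered):
            if not rows[i][1]:
                arm = "5p" if rank == 0 else "3p"
                r = rows[i]
                rows[i] = (r[0], arm, r[2], r[3], r[4], r[5])
    return rows


def read_annotations(hairpin_fasta, mature_coords) -> list[PreMirnaRecord]:
    """Read hairpin FASTA plus mature coordinates into :class:`PreMirnaRecord` s.

    ``mature_coords`` may be a 6-column TSV (hairpin_id, arm, start, end,
    name, species) or a miRBase-dialect GFF3 (detected by extension/content).
    Input order of the FASTA is preserved; hairpins without coordinate rows
    are returned with no arms.  A coordinate row naming a missing hairpin id,
    or out-of-bounds coordinates, raise ``ValueError``.
    """
    hairpin_fasta = Path(hairpin_fasta)
    mature_coords = Path(mature_coords)
    seqs: dict[str, str] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(hairpin_fasta), "fasta"):
        seqs[rec.id] = normalize_rna(str(rec.seq))
        order.append(rec.id)

    if mature_coords.suffix.lower() in (".gff", ".gff3"):
        coord_rows = _parse_coord_gff3(mature_coords)
    else:
        coord_rows = _parse_coord_tsv(mature_coords)

    arms: dict[str, dict[str, tuple[int, int]]] = {}
    species: dict[str, str] = {}
    for hid, arm, start, end, _name, sp in coord_rows:
        if hid not in seqs:
            raise ValueError(f"coordinate file references unknown hairpin id {hid!r}")
        arms.setdefault(hid, {})[arm] = (start, end)
        if sp:
            species[hid] = sp

    records = []
    for hid in order:
        a = arms.get(hid, {})
        records.append(
            PreMirnaRecord(
                id=hid,
                hairpin_seq=seqs[hid],
                species=species.get(hid, ""),
                arm5p_start=a.get("5p", (None, None))[0],
                arm5p_end=a.get("5p", (None, None))[1],
                arm3p_start=a.get("3p", (None, None))[0],
                arm3p_end=a.get("3p", (None, None))[1],
            )
        )
    return records


def write_annotations(records: Iterable[PreMirnaRecord], hairpin_fasta, coords_tsv) -> None:
    """Write hairpins as FASTA and arm coordinates as the 6-column TSV dialect."""
    records = list(records)
    SeqIO.write(
        [SeqRecord(Seq(r.hairpin_seq), id=r.id, description="") for r in records],
        str(hairpin_fasta),
        "fasta",
    )
    with open(coords_tsv, "w") as fh:
        for r in records:
            for arm in r.arms:
                s, e = r.arm_bounds(arm)
                fh.write(f"{r.id}\t{arm}\t{s}\t{e}\t{r.id}-{arm}\t{r.species}\n")


# ---------------------------------------------------------------------------
# tag-count input

_FASTA_COUNT = re.compile(r"_x(\d+)$")


def read_tag_counts(path, dialect: str = "tsv", source_id: Optional[str] = None) -> ReadLibrary:
    """Read one tag-count file into a :class:`ReadLibrary`.

    Dialects: ``tsv`` (sequence<TAB>count) or ``fasta_count_header``
    (FASTA where headers end in ``_xN``).  Duplicate tags within one file
    have their counts summed.
    """
    path = Path(path)
    counts: dict[str, int] = {}
    if dialect == "tsv":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected sequence<TAB>count")
                tag = normalize_rna(parts[0])
                try:
                    c = int(parts[1])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer count {parts[1]!r}") from exc
                if c < 0:
                    raise ValueError(f"{path}:{lineno}: negative count {c}")
                _check_rna(tag, f"{path}:{lineno}")
                counts[tag] = counts.get(tag, 0) + c
    elif dialect == "fasta_count_header":
        for rec in SeqIO.parse(str(path), "fasta"):
            m = _FASTA_COUNT.search(rec.id)
            if not m:
                raise ValueError(f"{path}: header {rec.id!r} lacks _xN count suffix")
            tag = normalize_rna(str(rec.seq))
            _check_rna(tag, f"{path} record {rec.id!r}")
            counts[tag] = counts.get(tag, 0) + int(m.group(1))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return ReadLibrary(source_ids=[source_id or path.stem], counts=counts)


def write_tag_counts(library: ReadLibrary, path, dialect: str = "tsv") -> None:
    path = Path(path)
    items = sorted(library.counts.items())
    if dialect == "tsv":
        with open(path, "w") as fh:
            for tag, c in items:
                fh.write(f"{tag}\t{c}\n")
    elif dialect == "fasta_count_header":
        with open(path, "w") as fh:
            for i, (tag, c) in enumerate(items, 1):
                fh.write(f">tag{i}_x{c}\n{tag}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def pool_libraries(libraries: list[ReadLibrary]) -> ReadLibrary:
    """Tag-wise sum of one or more libraries; source ids are concatenated."""
    if not libraries:
        raise ValueError("pool_libraries requires at least one library")
    counts: dict[str, int] = {}
    sources: list[str] = []
    for lib in libraries:
        sources.extend(lib.source_ids)
        for tag, c in lib.counts.items():
            counts[tag] = counts.get(tag, 0) + c
    return ReadLibrary(source_ids=sources, counts=counts)
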