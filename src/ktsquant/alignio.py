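"""Reading and writing junction-spanning alignments.

Two on-disk dialects are supported:

* ``SAM`` — standard SAM via :mod:`pysam`, with cell barcodes in the ``CB``
  tag and UMIs in the ``UB`` tag (the 10x convention). SAM positions are
  1-based on disk; records are 0-based in memory.
* ``TSV`` — a plain 8-column table, one alignment per line::

      read_id  cell  umi  chrom  strand  start  cigar  mapq

  ``start`` is 0-based; ``umi`` is ``.`` when absent; ``cigar`` uses only
  the ``M`` (aligned block) and ``N`` (splice gap) operations.

Both dialects round-trip losslessly through this module.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam

TSV_COLUMNS = ("read_id", "cell", "umi", "chrom", "strand", "start", "cigar", "mapq")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# CIGAR ops that consume reference bases and count as aligned (anchor) bases.
_REF_MATCH_OPS = frozenset("M=XD")


@dataclass(frozen=True)
class AlignedReadRecord:
    """A gapped alignment reduced to its reference-coordinate structure.

    ``blocks`` is an ordered sequence of ``(op, length)`` pairs with
    ``op in {"M", "N"}``: aligned stretches and splice gaps, in genomic
    order starting at ``start`` (0-based). Strand is carried for
    bookkeeping; genomic coordinates always increase left to right.
    """

    read_id: str
    cell: str
    umi: str | None
    chrom: str
    strand: str
    start: int
    blocks: tuple[tuple[str, int], ...]
    mapq: int = 60

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for op, length in self.blocks:
            if op not in ("M", "N"):
                raise ValueError(f"unsupported block op {op!r}")
            if length <= 0:
                raise ValueError(f"block lengths must be positive, got {op}{length}")

    @property
    def end(self) -> int:
        """0-based exclusive genomic end."""
        return self.start + sum(n for _, n in self.blocks)

    def gaps(self) -> list[tuple[int, int, int, int]]:
        """Splice gaps as ``(gstart, gend, left_anchor, right_anchor)``.

        Coordinates are 0-based half-open; anchors are the lengths of the
        aligned blocks immediately flanking the gap.
        """
        out = []
        pos = self.start
        for i, (op, length) in enumerate(self.blocks):
            if op == "N":
                left = self.blocks[i - 1][1] if i > 0 and self.blocks[i - 1][0] == "M" else 0
                right = (
                    self.blocks[i + 1][1]
                    if i + 1 < len(self.blocks) and self.blocks[i + 1][0] == "M"
                    else 0
                )
                out.append((pos, pos + length, left, right))
            pos += length
        return out

    @property
    def cigar(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.blocks)


def blocks_from_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
    """Collapse a CIGAR string to (M, N) reference-space blocks.

    ``M``/``=``/``X``/``D`` consume reference and are merged into aligned
    blocks (small deletions are treated as part of the anchor); ``N`` is a
    splice gap; ``I``/``S``/``H``/``P`` do not consume reference and are
    dropped.
    """
    pos = 0
    blocks: list[list] = []
    for m in _CIGAR_RE.finditer(cigar):
        n, op = int(m.group(1)), m.group(2)
        if op in _REF_MATCH_OPS:
            if blocks and blocks[-1][0] == "M":
                blocks[-1][1] += n
            else:
                blocks.append(["M", n])
        elif op == "N":
            if blocks and blocks[-1][0] == "N":
                blocks[-1][1] += n
            else:
                blocks.append(["N", n])
        pos += n
    consumed = sum(int(m.group(1)) for m in _CIGAR_RE.finditer(cigar))
    if consumed == 0 or pos == 0:
        raise ValueError(f"empty or unparseable CIGAR {cigar!r}")
    return tuple((op, n) for op, n in blocks)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------


def _write_tsv(records: Iterable[AlignedReadRecord], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(TSV_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    (
                        r.read_id,
                        r.cell,
                        r.umi if r.umi is not None else ".",
                        r.chrom,
                        r.strand,
                        str(r.start),
                        r.cigar,
                        str(r.mapq),
                    )
                )
                + "\n"
            )


def _load_tsv(path: Path) -> list[AlignedReadRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(TSV_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(TSV_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            try:
                records.append(
                    AlignedReadRecord(
                        read_id=fields[0],
                        cell=fields[1],
                        umi=None if fields[2] == "." else fields[2],
                        chrom=fields[3],
                        strand=fields[4],
                        start=int(fields[5]),
                        blocks=blocks_from_cigar(fields[6]),
                        mapq=int(fields[7]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# SAM dialect
# ---------------------------------------------------------------------------


def _sam_header(records: Sequence[AlignedReadRecord]) -> dict:
    # Reference lengths are not tracked by the simulator; pad past the
    # right-most alignment so the header stays valid.
    lengths: dict[str, int] = {}
    for r in records:
        lengths[r.chrom] = max(lengths.get(r.chrom, 0), r.end + 1000)
    if not lengths:
        lengths = {"chr1": 1000}
    return {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": ln} for name, ln in sorted(lengths.items())],
    }


def _write_sam(records: Sequence[AlignedReadRecord], path: Path) -> None:
    header = pysam.AlignmentHeader.from_dict(_sam_header(records))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(header)
            a.query_name = r.read_id
            a.reference_name = r.chrom
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            a.flag = 16 if r.strand == "-" else 0
            a.cigarstring = r.cigar
            qlen = sum(n for op, n in r.blocks if op == "M")
            a.query_sequence = "N" * qlen
            a.query_qualities = pysam.qualitystring_to_array("I" * qlen)
            tags = [("CB", r.cell)]
            if r.umi is not None:
                tags.append(("UB", r.umi))
            a.set_tags(tags)
            out.write(a)


def _load_sam(path: Path) -> list[AlignedReadRecord]:
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.cigarstring is None:
                continue
            records.append(
                AlignedReadRecord(
                    read_id=a.query_name,
                    cell=a.get_tag("CB") if a.has_tag("CB") else "",
                    umi=a.get_tag("UB") if a.has_tag("UB") else None,
                    chrom=a.reference_name,
                    strand="-" if a.is_reverse else "+",
                    start=a.reference_start,
                    blocks=blocks_from_cigar(a.cigarstring),
                    mapq=a.mapping_quality,
                )
            )
    return records


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def write_alignments(
    records: Sequence[AlignedReadRecord], path, dialect: str = "TSV"
) -> None:
    """Write alignment records to ``path`` in the given dialect."""
    path = Path(path)
    dialect = dialect.upper()
    if dialect == "TSV":
        _write_tsv(records, path)
    elif dialect == "SAM":
        _write_sam(list(records), path)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected SAM or TSV)")


def load_alignments(path, dialect: str | None = None) -> list[AlignedReadRecord]:
    """Load alignment records; the dialect is inferred from the suffix when
    not given (``.sam`` vs anything else)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "SAM" if path.suffix.lower() == ".sam" else "TSV"
    dialect = dialect.upper()
    if dialect == "TSV":
        return _load_tsv(path)
    if dialect == "SAM":
        return _load_sam(path)
    raise ValueError(f"unknown dialect {dialect!r} (expected SAM or TSV)")
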