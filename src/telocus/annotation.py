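"""Transposable-element annotation handling.

Parses RepeatMasker-derived annotation dialects (native ``.out`` files and
UCSC ``rmsk`` table dumps) into a normalized set of :class:`TELocus`
records, optionally merges user-supplied non-reference TE contigs, and
builds an interval index for overlap queries.  All coordinates are held
internally in BED convention (0-based, half-open); the RepeatMasker
``.out`` dialect (1-based, inclusive) is converted on ingest so that a
single convention flows through the rest of the pipeline.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree
from pyfaidx import Fasta

__all__ = [
    "TELocus",
    "AnnotationSet",
    "TE_CLASSES",
    "parse_rmsk",
    "merge_extra",
    "taxonomy_string",
    "write_te_bed",
    "read_te_bed",
]

#: Repeat classes quantified by default.  Simple repeats, low-complexity
#: regions and satellites are annotation noise for TE expression work and
#: are dropped unless the caller asks for everything.
TE_CLASSES = frozenset(
    {"LINE", "SINE", "LTR", "DNA", "Retroposon", "RC", "Unknown", "Other"}
)


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True, slots=True)
class TELocus:
    """One annotated TE interval with taxonomy and divergence.

    Coordinates are 0-based half-open.  ``milli_div`` is the RepeatMasker
    per-mil divergence of the locus from its subfamily consensus; low
    values mark evolutionarily young, hard-to-map elements.
    """

    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    family: str
    clazz: str
    milli_div: float = 0.0
    is_reference: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"unknown strand symbol {self.strand!r}")

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}|{self.start}|{self.end}|{self.subfamily}|{self.strand}"

    def __len__(self) -> int:
        return self.end - self.start


def taxonomy_string(locus: TELocus) -> str:
    """Return the three-level repeat taxonomy ``subfamily:family:class``."""
    return f"{locus.subfamily}:{locus.family}:{locus.clazz}"


def _split_class_family(token: str) -> tuple[str, str]:
    """Split a RepeatMasker ``class/family`` token into (clazz, family).

    RepeatMasker writes e.g. ``SINE/Alu`` or bare ``Retroposon``; when no
    family level exists the class name doubles as the family.
    """
    if "/" in token:
        clazz, family = token.split("/", 1)
    else:
        clazz = family = token
    return clazz, family


def _parse_rm_out(handle: io.TextIOBase) -> Iterator[TELocus]:
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        # RepeatMasker .out carries 2 header lines + 1 blank; headers start
        # with non-numeric score columns.
        if not fields[0].lstrip("-").isdigit():
            continue
        try:
            # .out prints divergence as percent; convert to per-mil to
            # match the UCSC table convention.
            milli_div = float(fields[1]) * 10.0
            chrom = fields[4]
            start = int(fields[5]) - 1  # 1-based inclusive -> 0-based
            end = int(fields[6])
            strand = fields[8]
            subfamily = fields[9]
            clazz, family = _split_class_family(fields[10])
        except (IndexError, ValueError) as exc:
            raise AnnotationError(
                f"malformed rm_out line {lineno}: {line!r}"
            ) from exc
        if strand == "C":
            strand = "-"
        elif strand != "+":
            raise AnnotationError(
                f"unknown strand symbol {strand!r} on rm_out line {lineno}"
            )
        yield TELocus(chrom, start, end, strand, subfamily, family, clazz, milli_div)


def _parse_ucsc_rmsk(handle: io.TextIOBase) -> Iterator[TELocus]:
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        # The table dump has 16 columns; with a leading `bin` column, 17.
        # Autodetect by column count.
        if len(fields) == 17:
            fields = fields[1:]
        if len(fields) != 16:
            raise AnnotationError(
                f"malformed ucsc_rmsk line {lineno}: expected 16 or 17 "
                f"columns, got {len(fields)}"
            )
        try:
            milli_div = float(fields[1])
            chrom = fields[4]
            start = int(fields[5])  # genoStart is already 0-based
            end = int(fields[6])
            strand = fields[8]
            subfamily = fields[9]
            clazz = fields[10]
            family = fields[11]
        except ValueError as exc:
            raise AnnotationError(
                f"malformed ucsc_rmsk line {lineno}: {line!r}"
            ) from exc
        if strand == "C":
            strand = "-"
        elif strand not in ("+", "-"):
            raise AnnotationError(
                f"unknown strand symbol {strand!r} on ucsc_rmsk line {lineno}"
            )
        yield TELocus(chrom, start, end, strand, subfamily, family, clazz, milli_div)


def parse_rmsk(
    path: str | Path,
    dialect: str = "rm_out",
    *,
    all_repeats: bool = False,
) -> list[TELocus]:
    """Parse a RepeatMasker annotation file into normalized loci.

    Parameters
    ----------
    path
        RepeatMasker ``.out`` file or UCSC ``rmsk`` table dump (TSV).
    dialect
        ``"rm_out"`` (whitespace-delimited, 1-based inclusive coordinates,
        strand ``C`` meaning minus) or ``"ucsc_rmsk"`` (tab-delimited,
        0-based half-open ``genoStart``/``genoEnd``).
    all_repeats
        Keep Simple_repeat/Low_complexity/Satellite entries too.  By
        default only interspersed TE classes are retained.
    """
    parsers = {"rm_out": _parse_rm_out, "ucsc_rmsk": _parse_ucsc_rmsk}
    if dialect not in parsers:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "rt") as handle:
        loci = list(parsers[dialect](handle))
    if not all_repeats:
        loci = [
            loc for loc in loci
            if loc.clazz.rstrip("?") in TE_CLASSES
        ]
    return loci


@dataclass
class AnnotationSet:
    """A locus collection with a per-chromosome interval index."""

    loci: list[TELocus]
    genome_build_label: str = ""
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _by_id: dict[str, TELocus] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for locus in self.loci:
            if locus.locus_id in self._by_id:
                raise AnnotationError(f"duplicate locus_id {locus.locus_id}")
            self._by_id[locus.locus_id] = locus
            self._trees.setdefault(locus.chrom, IntervalTree()).addi(
                locus.start, locus.end, locus
            )

    def __len__(self) -> int:
        return len(self.loci)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._by_id

    def get(self, locus_id: str) -> TELocus:
        return self._by_id[locus_id]

    def query(self, chrom: str, start: int, end: int) -> list[TELocus]:
        """Return loci overlapping ``[start, end)``, in coordinate order."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        hits.sort(key=lambda loc: (loc.start, loc.end, loc.locus_id))
        return hits

    @classmethod
    def from_loci(
        cls, loci: Iterable[TELocus], genome_build_label: str = ""
    ) -> "AnnotationSet":
        return cls(list(loci), genome_build_label)


def merge_extra(
    loci: Sequence[TELocus],
    extra_bed: str | Path | None,
    extra_fasta: str | Path | None,
    genome_build_label: str = "",
) -> AnnotationSet:
    """Merge reference loci with a non-reference TE table.

    The extra table describes exogenous or polymorphic TE sequences (e.g.
    an expression construct) living on their own contigs: ``extra_fasta``
    supplies the contig sequences and ``extra_bed`` the TE intervals on
    them.  Extra contig names must not collide with reference chromosome
    names; merged loci are flagged ``is_reference=False``.
    """
    merged = list(loci)
    if extra_bed is not None:
        ref_chroms = {loc.chrom for loc in loci}
        contig_lengths: dict[str, int] = {}
        if extra_fasta is not None:
            fasta = Fasta(str(extra_fasta))
            contig_lengths = {name: len(rec) for name, rec in fasta.items()}
        for extra in read_te_bed(extra_bed):
            if extra.chrom in ref_chroms:
                raise AnnotationError(
                    f"extra contig {extra.chrom!r} collides with a reference "
                    "chromosome name"
                )
            if contig_lengths and extra.end > contig_lengths.get(extra.chrom, 0):
                raise AnnotationError(
                    f"extra locus {extra.locus_id} exceeds contig length "
                    f"{contig_lengths.get(extra.chrom)}"
                )
            merged.append(replace(extra, is_reference=False))
    return AnnotationSet(merged, genome_build_label)


# --- BED round-trip -------------------------------------------------------
#
# 6-column BED plus extra columns: subfamily, family, clazz, milli_div,
# is_reference.  Column 4 holds the locus_id; no header or track line.

def write_te_bed(loci: Iterable[TELocus], path: str | Path) -> None:
    with open(path, "wt") as out:
        for loc in sorted(loci, key=lambda x: (x.chrom, x.start, x.end, x.locus_id)):
            out.write(
                "\t".join(
                    (
                        loc.chrom,
                        str(loc.start),
                        str(loc.end),
                        loc.locus_id,
                        "0",
                        loc.strand,
                        loc.subfamily,
                        loc.family,
                        loc.clazz,
                        f"{loc.milli_div:g}",
                        "1" if loc.is_reference else "0",
                    )
                )
                + "\n"
            )


def read_te_bed(path: str | Path) -> list[TELocus]:
    loci: list[TELocus] = []
    with open(path, "rt") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationError(f"malformed BED line {lineno}: {line!r}")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5]
            subfamily = fields[6] if len(fields) > 6 else fields[3]
            family = fields[7] if len(fields) > 7 else subfamily
            clazz = fields[8] if len(fields) > 8 else family
            milli_div = float(fields[9]) if len(fields) > 9 else 0.0
            is_reference = fields[10] != "0" if len(fields) > 10 else True
            loci.append(
                TELocus(
                    chrom, start, end, strand, subfamily, family, clazz,
                    milli_div, is_reference,
                )
            )
    return loci
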