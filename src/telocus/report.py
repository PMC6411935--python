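"""Output writers: locus/subfamily TSV tables, transcript-span BED, and
per-base coverage bedgraphs for genome-browser inspection.

All coordinates written are 0-based half-open (BED/bedGraph convention);
floats are printed with six decimals and a C-locale decimal point so runs
are byte-reproducible across machines.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .alignio import CandidateSet, FragmentAlignments
from .quant import FractionTable, Key, LocusEstimate, SubfamilySummary

__all__ = [
    "LOCUS_COLUMNS",
    "write_locus_table",
    "read_locus_table",
    "write_subfamily_table",
    "write_transcript_bed",
    "write_bedgraph",
]

LOCUS_COLUMNS = [
    "chrom", "tx_start", "tx_end", "locus_id", "score", "tx_strand",
    "subfamily", "family", "clazz", "milli_div", "C_U",
    "C_TE_float", "C_TE_int", "R_TE", "L_TE", "l_TE", "fpkm",
]

SUBFAMILY_COLUMNS = [
    "subfamily", "family", "clazz", "total_count", "total_fpkm",
    "n_loci_expressed",
]

#: Coverage below this is not written (keeps bedgraphs sparse).
BEDGRAPH_MIN_VALUE = 1e-6


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def write_locus_table(
    estimates: Mapping[Key, LocusEstimate], path: str | Path
) -> None:
    """Write the per-(locus, orientation) table, sorted by position."""
    rows = sorted(
        estimates.values(),
        key=lambda e: (e.chrom, e.tx_start, e.tx_end, e.locus_id, e.orientation),
    )
    with open(path, "wt") as out:
        out.write("\t".join(LOCUS_COLUMNS) + "\n")
        for e in rows:
            out.write(
                "\t".join(
                    (
                        e.chrom,
                        str(e.tx_start),
                        str(e.tx_end),
                        e.locus_id,
                        _fmt(e.score),
                        e.tx_strand,
                        e.subfamily,
                        e.family,
                        e.clazz,
                        f"{e.milli_div:g}",
                        str(e.c_u),
                        _fmt(e.c_te),
                        str(e.c_te_int),
                        str(e.r_te),
                        f"{e.length_transcribed:g}",
                        f"{e.length_effective:g}",
                        _fmt(e.fpkm),
                    )
                )
                + "\n"
            )


def read_locus_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_subfamily_table(
    summaries: Iterable[SubfamilySummary], path: str | Path
) -> None:
    with open(path, "wt") as out:
        out.write("\t".join(SUBFAMILY_COLUMNS) + "\n")
        for s in summaries:
            out.write(
                "\t".join(
                    (
                        s.subfamily, s.family, s.clazz,
                        _fmt(s.total_count), _fmt(s.total_fpkm),
                        str(s.n_loci_expressed),
                    )
                )
                + "\n"
            )


def write_transcript_bed(
    estimates: Mapping[Key, LocusEstimate], path: str | Path
) -> None:
    """BED6 of observed transcript spans; score column holds the
    confidence score rounded to an integer (BED caps scores at 1000)."""
    rows = sorted(
        estimates.values(),
        key=lambda e: (e.chrom, e.tx_start, e.tx_end, e.locus_id, e.orientation),
    )
    with open(path, "wt") as out:
        for e in rows:
            out.write(
                "\t".join(
                    (
                        e.chrom, str(e.tx_start), str(e.tx_end),
                        f"{e.locus_id}|{e.orientation}",
                        str(int(round(e.score))), e.tx_strand,
                    )
                )
                + "\n"
            )


def _coverage_records(
    events: dict[str, dict[int, float]]
) -> Iterable[tuple[str, int, int, float]]:
    """Turn per-chromosome ±depth events into sorted step records."""
    for chrom in sorted(events):
        depth = 0.0
        prev = None
        for pos in sorted(events[chrom]):
            if prev is not None and depth > BEDGRAPH_MIN_VALUE and pos > prev:
                yield chrom, prev, pos, depth
            depth += events[chrom][pos]
            prev = pos


def write_bedgraph(
    fragments: Iterable[tuple[FragmentAlignments, CandidateSet]],
    assignments: FractionTable,
    path: str | Path,
    *,
    label: str = "telocus",
    strand_split: bool = False,
) -> list[Path]:
    """Write unique and multi coverage tracks.

    Unique fragments add depth 1 over each mate's aligned span (read
    coverage).  Multi-mapping fragments add their assigned fraction over
    each candidate fragment span, so the height of a multi-read pile is
    inversely related to how many loci share it.  Separate
    ``.plus``/``.minus`` files are produced when ``strand_split`` is on
    (strand taken from each record; multi spans use the candidate locus
    chromosomal span with the strand of the records that nominated it).

    Returns the list of files written.
    """
    path = Path(path)
    tracks: dict[tuple[str, str], dict[str, dict[int, float]]] = defaultdict(
        lambda: defaultdict(lambda: defaultdict(float))
    )

    def add(kind: str, strand: str, chrom: str, s: int, e: int, value: float) -> None:
        key = (kind, strand if strand_split else ".")
        tracks[key][chrom][s] += value
        tracks[key][chrom][e] -= value

    for frag, cands in fragments:
        if frag.is_unique or frag.full_count:
            for group in frag.kept:
                for rec in group:
                    add("unique", rec.strand, rec.chrom, rec.start, rec.end, 1.0)
        else:
            assigned = assignments.get(frag.read_id, {})
            chrom_of = {}
            strand_of = {}
            for group in frag.kept:
                for rec in group:
                    for key, spans in cands.candidates.items():
                        for s, e in spans:
                            if rec.chrom and rec.start >= s and rec.end <= e:
                                chrom_of.setdefault((key, (s, e)), rec.chrom)
                                strand_of.setdefault((key, (s, e)), rec.strand)
            for key, spans in cands.candidates.items():
                f = assigned.get(key, 0.0)
                if f <= BEDGRAPH_MIN_VALUE:
                    continue
                for s, e in spans:
                    chrom = chrom_of.get((key, (s, e)))
                    if chrom is None:
                        continue
                    add("multi", strand_of[(key, (s, e))], chrom, s, e, f)

    written: list[Path] = []
    for (kind, strand), events in sorted(tracks.items()):
        suffix = {"+": ".plus", "-": ".minus", ".": ""}[strand]
        out_path = path.with_name(f"{path.stem}.{kind}{suffix}.bedgraph")
        with open(out_path, "wt") as out:
            out.write(
                f'track type=bedGraph name="{label} {kind}{suffix}"\n'
            )
            for chrom, s, e, depth in _coverage_records(events):
                out.write(f"{chrom}\t{s}\t{e}\t{_fmt(depth)}\n")
        written.append(out_path)
    return written
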