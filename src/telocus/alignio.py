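"""SAM/BAM ingestion and fragment classification.

A sequenced *fragment* (a read pair, or a single-end read) may be reported
at several genomic placements by a multi-mapping-aware aligner.  This
module groups all reported records of a fragment, classifies the fragment
as ``unique`` or ``multi`` using mate-rescue rules, and nominates the TE
loci the fragment could plausibly originate from:

* a mate nominates a locus when its aligned span overlaps the locus by at
  least half the aligned length — reads are allowed to dangle into
  flanking sequence, which recovers unique alignments at TE boundaries;
* if one mate aligns uniquely, the whole pair is unique and the other
  alignments of its multi-mapping mate are discarded;
* if both mates are multi-mapping but map concordantly to exactly one
  place, the discordant placements are dropped and the fragment
  contributes a full read count there — without counting as unique
  evidence (its positions never enter the uniquely alignable length);
* with stranded libraries the sense and antisense direction of a TE are
  treated as separate transcripts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pysam

from .annotation import AnnotationSet

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentRecord",
    "FragmentAlignments",
    "CandidateSet",
    "group_fragments",
    "classify_fragment",
    "candidate_loci",
    "SENSE",
    "ANTISENSE",
]

SENSE = "sense"
ANTISENSE = "antisense"

#: Default upper bound on the reference span of a concordant pair.
#: Splice-aware aligners accept very large "fragments" (introns), so the
#: default mirrors their wide gap bound; it is configurable throughout.
DEFAULT_MAX_PAIR_SPAN = 1_000_000


@dataclass(frozen=True, slots=True)
class AlignmentRecord:
    """One reported placement of one mate (0-based half-open span)."""

    read_id: str
    mate: int  # 1, 2, or 0 for single-end
    chrom: str
    start: int
    end: int
    strand: str
    pair_key: int | None = None


@dataclass(slots=True)
class FragmentAlignments:
    """All reported placements of one fragment, plus classification.

    ``kept`` holds placement groups surviving classification: each group is
    a tuple of one record (single mate) or two records (a mate pair).
    ``full_count`` marks the concordant-single-placement rescue of a
    doubly multi-mapping pair: a certain full count that is nevertheless
    not unique evidence.
    """

    read_id: str
    alignments: list[AlignmentRecord] = field(default_factory=list)
    uniqueness: str | None = None  # "unique" | "multi"
    kept: list[tuple[AlignmentRecord, ...]] = field(default_factory=list)
    full_count: bool = False

    @property
    def is_unique(self) -> bool:
        return self.uniqueness == "unique"


@dataclass(slots=True)
class CandidateSet:
    """TE loci a fragment may originate from, keyed by orientation.

    ``candidates`` maps ``(locus_id, orientation)`` to the fragment's
    aligned span(s) at that locus — one ``(start, end)`` per kept placement
    group that nominated it.  ``n`` is the number of distinct candidates,
    the *N* of the initial fractional assignment.
    """

    read_id: str
    candidates: dict[tuple[str, str], list[tuple[int, int]]] = field(
        default_factory=dict
    )

    @property
    def n(self) -> int:
        return len(self.candidates)


def group_fragments(path: str | Path) -> Iterator[FragmentAlignments]:
    """Yield one :class:`FragmentAlignments` per read name in a SAM/BAM.

    The input need not be name-sorted: records are grouped by read name in
    a single pass (insertion-ordered), so coordinate-sorted files work
    unchanged.  NH tags, when present, are checked against the observed
    record count; the observed records win on disagreement.
    """
    frags: dict[str, FragmentAlignments] = {}
    nh_seen: dict[str, int] = {}
    hi_counters: dict[tuple[str, int], int] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_supplementary:
                continue
            name = rec.query_name
            if rec.has_tag("NH"):
                nh_seen[name] = max(nh_seen.get(name, 0), int(rec.get_tag("NH")))
            mate = 1 if rec.is_read1 else 2 if rec.is_read2 else 0
            if rec.has_tag("HI"):
                pair_key = int(rec.get_tag("HI"))
            else:
                # Fall back to per-mate occurrence order: the i-th placement
                # of mate 1 pairs with the i-th placement of mate 2.
                idx = hi_counters.get((name, mate), 0)
                hi_counters[(name, mate)] = idx + 1
                pair_key = idx
            record = AlignmentRecord(
                read_id=name,
                mate=mate,
                chrom=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                pair_key=pair_key,
            )
            frags.setdefault(name, FragmentAlignments(read_id=name)).alignments.append(
                record
            )
    for name, frag in frags.items():
        nh = nh_seen.get(name)
        if nh is not None:
            per_mate = {}
            for rec in frag.alignments:
                per_mate[rec.mate] = per_mate.get(rec.mate, 0) + 1
            if per_mate and nh != max(per_mate.values()):
                logger.warning(
                    "read %s: NH=%d contradicts %d observed placements; "
                    "trusting observed records",
                    name, nh, max(per_mate.values()),
                )
        yield frag


def _is_concordant(
    r1: AlignmentRecord, r2: AlignmentRecord, max_pair_span: int
) -> bool:
    if r1.chrom != r2.chrom or r1.strand == r2.strand:
        return False
    span = max(r1.end, r2.end) - min(r1.start, r2.start)
    return span <= max_pair_span


def _pairs(
    m1: list[AlignmentRecord], m2: list[AlignmentRecord]
) -> list[tuple[AlignmentRecord, AlignmentRecord]]:
    by_key = {r.pair_key: r for r in m2}
    return [(r, by_key[r.pair_key]) for r in m1 if r.pair_key in by_key]


def classify_fragment(
    frag: FragmentAlignments,
    max_pair_span: int = DEFAULT_MAX_PAIR_SPAN,
) -> FragmentAlignments:
    """Classify a fragment as unique or multi, filling ``kept``.

    Classification is order-independent: it depends only on the set of
    reported placements and their pair keys.
    """
    m1 = sorted(
        (r for r in frag.alignments if r.mate == 1),
        key=lambda r: (r.chrom, r.start, r.pair_key or 0),
    )
    m2 = sorted(
        (r for r in frag.alignments if r.mate == 2),
        key=lambda r: (r.chrom, r.start, r.pair_key or 0),
    )
    single = sorted(
        (r for r in frag.alignments if r.mate == 0),
        key=lambda r: (r.chrom, r.start),
    )
    frag.full_count = False

    if single and not (m1 or m2):
        frag.uniqueness = "unique" if len(single) == 1 else "multi"
        frag.kept = [(r,) for r in single]
        return frag

    if (m1 and not m2) or (m2 and not m1):
        only = m1 or m2
        logger.warning(
            "read %s: unpaired mate in paired library; treating as single-end",
            frag.read_id,
        )
        frag.uniqueness = "unique" if len(only) == 1 else "multi"
        frag.kept = [(r,) for r in only]
        return frag

    if len(m1) == 1 and len(m2) == 1:
        frag.uniqueness = "unique"
        frag.kept = [(m1[0], m2[0])]
        return frag

    if len(m1) == 1 or len(m2) == 1:
        # Mate rescue: the unique mate anchors the pair; the multi mate's
        # other alignments are discarded.
        anchor, other = (m1[0], m2) if len(m1) == 1 else (m2[0], m1)
        partner = [r for r in other if r.pair_key == anchor.pair_key]
        frag.uniqueness = "unique"
        frag.kept = [(anchor, partner[0]) if partner else (anchor,)]
        return frag

    pairs = _pairs(m1, m2)
    concordant = [
        p for p in pairs if _is_concordant(p[0], p[1], max_pair_span)
    ]
    frag.uniqueness = "multi"
    if len(concordant) == 1:
        # Doubly multi-mapping pair with a single concordant placement:
        # the discordant alignments are discarded and the fragment counts
        # in full there, but not as unique evidence.
        frag.full_count = True
        frag.kept = [concordant[0]]
    elif concordant:
        frag.kept = [tuple(p) for p in concordant]
    else:
        frag.kept = [(r,) for r in m1 + m2]
    return frag


def _group_strand(group: tuple[AlignmentRecord, ...], strand_mode: str) -> str | None:
    """Infer the strand of the fragment's source transcript (dUTP rules)."""
    if strand_mode == "none":
        return None
    rec = min(group, key=lambda r: r.mate if r.mate else 1)
    # fr: mate 1 carries the transcript strand; rf: mate 1 is opposite.
    # A lone mate 2 record reports the opposite of the transcript under fr.
    flip = (strand_mode == "rf") != (rec.mate == 2)
    if flip:
        return "-" if rec.strand == "+" else "+"
    return rec.strand


def candidate_loci(
    frag: FragmentAlignments,
    ann: AnnotationSet,
    strand_mode: str = "none",
) -> CandidateSet:
    """Nominate (locus, orientation) candidates for a classified fragment.

    A placement group nominates a locus when at least one of its mates
    overlaps the locus by ``ceil(0.5 × aligned length)`` bases or more.
    In stranded modes a candidate is *sense* when the inferred fragment
    strand matches the locus strand, *antisense* otherwise; unstranded
    libraries see every candidate as sense.
    """
    if strand_mode not in ("none", "rf", "fr"):
        raise ValueError(f"unknown strand mode {strand_mode!r}")
    cands = CandidateSet(read_id=frag.read_id)
    for group in frag.kept:
        frag_strand = _group_strand(group, strand_mode)
        hit_loci = {}
        for rec in group:
            need = math.ceil(0.5 * (rec.end - rec.start))
            for locus in ann.query(rec.chrom, rec.start, rec.end):
                overlap = min(rec.end, locus.end) - max(rec.start, locus.start)
                if overlap >= need:
                    hit_loci[locus.locus_id] = locus
        for locus_id, locus in hit_loci.items():
            if frag_strand is None:
                orientation = SENSE
            else:
                orientation = SENSE if frag_strand == locus.strand else ANTISENSE
            on_chrom = [r for r in group if r.chrom == locus.chrom]
            span = (
                min(r.start for r in on_chrom),
                max(r.end for r in on_chrom),
            )
            cands.candidates.setdefault((locus_id, orientation), []).append(span)
    return cands


def classified_candidates(
    path: str | Path,
    ann: AnnotationSet,
    strand_mode: str = "none",
    max_pair_span: int = DEFAULT_MAX_PAIR_SPAN,
) -> Iterator[tuple[FragmentAlignments, CandidateSet]]:
    """Stream classified fragments with their TE candidates from a SAM/BAM.

    Fragments with no TE candidate are skipped; callers that need the
    library size (all aligned fragments, TE or not) should count fragments
    from :func:`group_fragments` themselves.
    """
    for frag in group_fragments(path):
        classify_fragment(frag, max_pair_span=max_pair_span)
        cands = candidate_loci(frag, ann, strand_mode=strand_mode)
        if cands.n:
            yield frag, cands
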