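"""Locus-level TE expression quantification.

The quantifier turns classified fragments into per-locus counts in four
stages:

1. **Unique statistics.**  Fragments with a single certain placement and a
   single TE candidate contribute whole counts.  Truly unique fragments
   additionally build each locus's *uniquely alignable length* ``L_U`` —
   the number of distinct unique-fragment start positions — a proxy for
   how much of the locus is distinguishable sequence.

2. **Initial assignment.**  Each multi-mapping fragment's count is split
   across its ``N`` candidate loci.  Candidates with no unique evidence
   receive ``1/N`` each; the remainder ``1 − n/N`` is apportioned to
   candidates with unique reads in proportion to their normalized unique
   count ``C_U / L_U``.

3. **EM refinement.**  Expectation and maximization alternate: fractions
   are reassigned in proportion to each candidate's length-normalized
   total count ``C / l`` (with ``l`` the *effective* transcribed length),
   then totals are re-summed, until every locus with ≥ 10 counts changes
   by < 1 % (``auto``) or an iteration budget is exhausted.  Loci whose
   total count falls below one read are judged unlikely to have produced
   any read and are zeroed out of the denominators.

4. **Reporting statistics.**  Per (locus, orientation): the transcribed
   span and length observed from aligned fragments, a confidence *score*
   ``100 × C_TE / R_TE`` (assigned count over all fragments touching the
   locus), and FPKM over the transcribed length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .alignio import ANTISENSE, SENSE, CandidateSet, FragmentAlignments
from .annotation import AnnotationSet, TELocus

logger = logging.getLogger(__name__)

__all__ = [
    "Key",
    "UniqueStats",
    "LocusEstimate",
    "SubfamilySummary",
    "unique_stats",
    "initial_assignment",
    "effective_length",
    "em_step",
    "run_em",
    "compute_score",
    "compute_fpkm",
    "quantify",
    "aggregate_subfamilies",
    "apply_score_threshold",
]

#: (locus_id, orientation) — the unit of quantification.  With stranded
#: libraries the sense and antisense directions of a TE are separate
#: transcripts; unstranded data only ever sees the "sense" key.
Key = tuple[str, str]

#: Per-fragment fractional assignments: read_id -> {key: fraction}.
FractionTable = dict[str, dict[Key, float]]

#: Default per-locus count below which the EM zeroes a candidate.
ZEROING_MIN_COUNT = 1.0
#: Loci with at least this many counts gate auto-convergence...
CONVERGENCE_MIN_COUNT = 10.0
#: ...when their relative change drops below this.
CONVERGENCE_REL_TOL = 0.01


@dataclass(slots=True)
class UniqueStats:
    """Unique-read evidence for one (locus, orientation).

    ``c_u`` counts truly unique fragments; ``l_u`` is the number of
    distinct leftmost start positions among them (the uniquely alignable
    length).  ``c_full`` counts doubly-multi-mapping pairs rescued by a
    single concordant placement: they add whole counts but no unique
    evidence, so they appear in neither ``c_u`` nor ``l_u``.
    """

    c_u: int = 0
    c_full: int = 0
    starts: set[int] = field(default_factory=set)
    span_start: int | None = None
    span_end: int | None = None

    @property
    def l_u(self) -> int:
        return len(self.starts)

    @property
    def base_count(self) -> float:
        """Fixed whole-count contribution to the locus total."""
        return float(self.c_u + self.c_full)


def unique_stats(
    certain: Iterable[tuple[FragmentAlignments, CandidateSet]],
) -> dict[Key, UniqueStats]:
    """Accumulate unique-read statistics from certainly placed fragments.

    Each input fragment must have exactly one candidate key (single kept
    placement over a single TE).  Full-count rescued pairs increase the
    base count only; their positions do not contribute to ``l_u``.
    """
    stats: dict[Key, UniqueStats] = {}
    for frag, cands in certain:
        if cands.n != 1:
            raise ValueError(
                f"fragment {frag.read_id} has {cands.n} candidates; "
                "certain fragments must have exactly one"
            )
        (key, spans), = cands.candidates.items()
        st = stats.setdefault(key, UniqueStats())
        start = min(s for s, _ in spans)
        end = max(e for _, e in spans)
        if frag.full_count:
            st.c_full += 1
        else:
            st.c_u += 1
            st.starts.add(start)
        if st.span_start is None or start < st.span_start:
            st.span_start = start
        if st.span_end is None or end > st.span_end:
            st.span_end = end
    return stats


def initial_assignment(
    multi: Mapping[str, Iterable[Key]],
    ustats: Mapping[Key, UniqueStats],
) -> FractionTable:
    """Split each multi-mapping fragment across its candidates.

    Candidates without unique reads each take ``1/N``; the remainder
    ``1 − n/N`` is split among candidates with unique reads proportionally
    to ``C_U / L_U``.  Per-fragment fractions sum to exactly one.
    """
    table: FractionTable = {}
    for read_id, keys in multi.items():
        keys = list(keys)
        n_total = len(keys)
        if n_total == 0:
            continue
        weights: dict[Key, float] = {}
        for key in keys:
            st = ustats.get(key)
            weights[key] = (st.c_u / st.l_u) if st is not None and st.c_u else 0.0
        zero = [k for k in keys if weights[k] == 0.0]
        n_zero = len(zero)
        fractions = {k: 1.0 / n_total for k in zero}
        remainder = 1.0 - n_zero / n_total
        if n_zero < n_total:
            wsum = sum(weights[k] for k in keys if weights[k] > 0.0)
            for key in keys:
                if weights[key] > 0.0:
                    fractions[key] = remainder * weights[key] / wsum
        table[read_id] = fractions
    return table


def effective_length(length_transcribed: float, frag_len_mean: float) -> float:
    """Effective transcript length: ``max(L − l_avg + 1, 1)``.

    The number of distinct start positions a transcript of length ``L``
    admits for fragments of mean length ``l_avg``; clamped at one so it
    can always serve as a normalizing denominator.
    """
    return max(length_transcribed - frag_len_mean + 1.0, 1.0)


def em_step(
    candidates: Mapping[str, Iterable[Key]],
    counts: Mapping[Key, float],
    eff_len: Mapping[Key, float],
    *,
    zeroing: bool = True,
    min_count: float = ZEROING_MIN_COUNT,
) -> FractionTable:
    """E-step: reassign fractions proportional to ``C / l``.

    With ``zeroing`` on, candidates whose total count is below
    ``min_count`` are excluded from the denominator and receive zero; if
    that removes every candidate of a fragment, the fragment falls back to
    an equal ``1/N`` split.
    """
    table: FractionTable = {}
    for read_id, keys in candidates.items():
        keys = list(keys)
        if zeroing:
            eligible = [k for k in keys if counts.get(k, 0.0) >= min_count]
        else:
            eligible = keys
        denom = sum(counts.get(k, 0.0) / eff_len[k] for k in eligible)
        if not eligible or denom <= 0.0:
            table[read_id] = {k: 1.0 / len(keys) for k in keys}
            continue
        fractions = {k: 0.0 for k in keys}
        for key in eligible:
            fractions[key] = (counts.get(key, 0.0) / eff_len[key]) / denom
        table[read_id] = fractions
    return table


def _totals(
    base: Mapping[Key, float], fractions: FractionTable
) -> dict[Key, float]:
    """M-step: total count = fixed whole counts + multi fractions."""
    counts = dict(base)
    for assigned in fractions.values():
        for key, f in assigned.items():
            counts[key] = counts.get(key, 0.0) + f
    return counts


def run_em(
    base: Mapping[Key, float],
    fractions0: FractionTable,
    eff_len: Mapping[Key, float],
    candidates: Mapping[str, Iterable[Key]] | None = None,
    iterations: int | str = "auto",
    max_iter: int = 100,
    zeroing: str = "per-step",
) -> tuple[dict[Key, float], FractionTable, dict]:
    """Run the EM loop from an initial fractional assignment.

    Parameters
    ----------
    base
        Fixed whole-count contribution per key (unique + full-count).
    fractions0
        Initial per-fragment fractions (stage-2 assignment).
    eff_len
        Effective length per key, frozen across iterations.
    candidates
        Candidate keys per multi fragment; defaults to the keys present in
        ``fractions0``.
    iterations
        ``"auto"`` (iterate to convergence), or a fixed iteration count;
        ``0`` returns the initial totals unchanged.
    zeroing
        ``"per-step"`` applies the below-one-count zeroing rule inside
        every E-step; ``"final"`` iterates without zeroing and applies the
        rule once after convergence.

    Returns ``(counts, fractions, info)`` where ``info`` records the
    number of iterations and a convergence flag.
    """
    if zeroing not in ("per-step", "final"):
        raise ValueError(f"unknown zeroing mode {zeroing!r}")
    if candidates is None:
        candidates = {rid: list(fr) for rid, fr in fractions0.items()}
    auto = iterations == "auto"
    if not auto:
        iterations = int(iterations)
        if iterations < 0:
            raise ValueError("iterations must be >= 0 or 'auto'")
    n_rounds = max_iter if auto else min(iterations, max_iter)

    fractions = {rid: dict(fr) for rid, fr in fractions0.items()}
    counts = _totals(base, fractions)
    converged = not auto
    it = 0
    for it in range(1, n_rounds + 1):
        fractions = em_step(
            candidates, counts, eff_len, zeroing=(zeroing == "per-step")
        )
        new_counts = _totals(base, fractions)
        if auto and _converged(counts, new_counts):
            counts = new_counts
            converged = True
            break
        counts = new_counts
    else:
        it = n_rounds
        if auto and n_rounds > 0:
            converged = False
            logger.warning("EM did not converge within %d iterations", max_iter)
    if zeroing == "final" and n_rounds > 0:
        fractions = em_step(candidates, counts, eff_len, zeroing=True)
        counts = _totals(base, fractions)
    return counts, fractions, {"iterations": it, "converged": converged}


def _converged(prev: Mapping[Key, float], new: Mapping[Key, float]) -> bool:
    for key in set(prev) | set(new):
        c_prev = prev.get(key, 0.0)
        c_new = new.get(key, 0.0)
        if max(c_prev, c_new) < CONVERGENCE_MIN_COUNT:
            continue
        if abs(c_new - c_prev) / max(c_prev, 1.0) >= CONVERGENCE_REL_TOL:
            return False
    return True


def compute_score(c_te: float, r_te: int) -> float:
    """Confidence score ``100 × C_TE / R_TE`` in [0, 100].

    ``R_TE`` is the number of fragments (unique and multi) aligned to the
    locus; a low score flags loci whose assigned reads may belong to other
    loci.
    """
    if r_te < 1:
        raise ValueError("score undefined for a locus with no aligned fragments")
    return 100.0 * c_te / r_te


def compute_fpkm(c_te: float, length_transcribed: float, library_fragments: int) -> float:
    """Fragments per kilobase of transcript per million library fragments."""
    if length_transcribed < 1 or library_fragments < 1:
        raise ValueError("fpkm needs length >= 1 and library size >= 1")
    return c_te / ((length_transcribed / 1000.0) * (library_fragments / 1e6))


@dataclass(slots=True)
class LocusEstimate:
    """Final per-(locus, orientation) expression estimate."""

    locus_id: str
    orientation: str
    chrom: str
    tx_start: int
    tx_end: int
    tx_strand: str
    subfamily: str
    family: str
    clazz: str
    milli_div: float
    c_u: int
    c_te: float
    r_te: int
    length_transcribed: float
    frag_len_mean: float
    length_effective: float
    score: float
    fpkm: float
    low_score: bool = False

    @property
    def key(self) -> Key:
        return (self.locus_id, self.orientation)

    @property
    def c_te_int(self) -> int:
        # Half-up rounding for count-based downstream tools.
        return int(math.floor(self.c_te + 0.5))


@dataclass(slots=True)
class SubfamilySummary:
    subfamily: str
    family: str
    clazz: str
    total_count: float
    total_fpkm: float
    n_loci_expressed: int


def quantify(
    stream: Iterable[tuple[FragmentAlignments, CandidateSet]],
    ann: AnnotationSet,
    *,
    iterations: int | str = "auto",
    max_iter: int = 100,
    zeroing: str = "per-step",
    library_fragments: int | None = None,
    details: dict | None = None,
) -> dict[Key, LocusEstimate]:
    """Quantify TE expression from classified fragments with candidates.

    ``library_fragments`` is the FPKM per-million denominator — fragments
    with at least one reported alignment anywhere in the genome.  When
    omitted, the number of TE-candidate fragments seen in ``stream`` is
    used (a lower bound appropriate for TE-only fixtures).

    When a ``details`` dict is supplied it is filled with the final
    per-fragment fractions (``"fractions"``), the unique statistics
    (``"ustats"``) and the EM info record (``"em"``).
    """
    certain: list[tuple[FragmentAlignments, CandidateSet]] = []
    multi_keys: dict[str, list[Key]] = {}
    multi_spans: dict[str, dict[Key, list[tuple[int, int]]]] = {}
    r_te: dict[Key, int] = {}
    n_fragments = 0
    for frag, cands in stream:
        if cands.n == 0:
            continue
        n_fragments += 1
        for key in cands.candidates:
            r_te[key] = r_te.get(key, 0) + 1
        if cands.n == 1 and (frag.is_unique or frag.full_count):
            certain.append((frag, cands))
        else:
            multi_keys[frag.read_id] = list(cands.candidates)
            multi_spans[frag.read_id] = {
                k: list(v) for k, v in cands.candidates.items()
            }

    ustats = unique_stats(certain)
    fractions0 = initial_assignment(multi_keys, ustats)

    # Transcribed spans and fragment lengths are frozen from the initial
    # contributing set (every candidate holds a positive initial fraction,
    # so this is all candidates plus the certain placements).
    span: dict[Key, tuple[int, int]] = {}
    frag_lens: dict[Key, list[int]] = {}
    for key, st in ustats.items():
        span[key] = (st.span_start, st.span_end)
    for frag, cands in certain:
        (key, spans), = cands.candidates.items()
        frag_lens.setdefault(key, []).extend(e - s for s, e in spans)
    for read_id, per_key in multi_spans.items():
        for key, spans in per_key.items():
            s = min(x for x, _ in spans)
            e = max(y for _, y in spans)
            if key in span:
                span[key] = (min(span[key][0], s), max(span[key][1], e))
            else:
                span[key] = (s, e)
            frag_lens.setdefault(key, []).extend(y - x for x, y in spans)

    length_tx = {k: float(e - s) for k, (s, e) in span.items()}
    l_avg = {
        k: (sum(v) / len(v)) if v else 0.0 for k, v in frag_lens.items()
    }
    eff_len = {
        k: effective_length(length_tx[k], l_avg[k]) for k in length_tx
    }

    base = {k: st.base_count for k, st in ustats.items()}
    counts, fractions, em_info = run_em(
        base, fractions0, eff_len, multi_keys,
        iterations=iterations, max_iter=max_iter, zeroing=zeroing,
    )
    if details is not None:
        details.update(fractions=fractions, ustats=ustats, em=em_info)

    if library_fragments is None:
        library_fragments = n_fragments

    estimates: dict[Key, LocusEstimate] = {}
    for key, n_reads in r_te.items():
        if key not in span:
            continue
        locus_id, orientation = key
        locus = ann.get(locus_id)
        tx_strand = _transcript_strand(locus, orientation)
        c_te = counts.get(key, 0.0)
        st = ustats.get(key, UniqueStats())
        estimates[key] = LocusEstimate(
            locus_id=locus_id,
            orientation=orientation,
            chrom=locus.chrom,
            tx_start=span[key][0],
            tx_end=span[key][1],
            tx_strand=tx_strand,
            subfamily=locus.subfamily,
            family=locus.family,
            clazz=locus.clazz,
            milli_div=locus.milli_div,
            c_u=st.c_u,
            c_te=c_te,
            r_te=n_reads,
            length_transcribed=length_tx[key],
            frag_len_mean=l_avg[key],
            length_effective=eff_len[key],
            score=compute_score(c_te, n_reads),
            fpkm=compute_fpkm(
                c_te, length_tx[key], max(library_fragments, 1)
            ),
        )
    return estimates


def _transcript_strand(locus: TELocus, orientation: str) -> str:
    if orientation == ANTISENSE:
        return "-" if locus.strand == "+" else "+"
    return locus.strand


def aggregate_subfamilies(
    estimates: Mapping[Key, LocusEstimate],
    ann: AnnotationSet,
    expressed_threshold: float = 10.0,
) -> list[SubfamilySummary]:
    """Aggregate locus counts and FPKM to the subfamily level.

    Orientations are collapsed per locus; a locus counts as expressed when
    its summed count reaches ``expressed_threshold``.
    """
    per_locus: dict[str, float] = {}
    groups: dict[tuple[str, str, str], dict[str, float]] = {}
    for est in estimates.values():
        if est.locus_id not in ann:
            raise KeyError(f"locus_id {est.locus_id} not in annotation set")
        tax = (est.subfamily, est.family, est.clazz)
        grp = groups.setdefault(
            tax, {"count": 0.0, "fpkm": 0.0}
        )
        grp["count"] += est.c_te
        grp["fpkm"] += est.fpkm
        per_locus[est.locus_id] = per_locus.get(est.locus_id, 0.0) + est.c_te
    summaries = []
    for (sub, fam, clz), grp in sorted(groups.items()):
        n_expr = sum(
            1
            for est_id, total in per_locus.items()
            if total >= expressed_threshold
            and ann.get(est_id).subfamily == sub
        )
        summaries.append(
            SubfamilySummary(
                subfamily=sub,
                family=fam,
                clazz=clz,
                total_count=grp["count"],
                total_fpkm=grp["fpkm"],
                n_loci_expressed=n_expr,
            )
        )
    return summaries


def apply_score_threshold(
    estimates: Mapping[Key, LocusEstimate],
    threshold: float = 50.0,
    drop: bool = False,
) -> dict[Key, LocusEstimate]:
    """Flag (or drop) loci whose confidence score is below ``threshold``."""
    if not 0.0 <= threshold <= 100.0:
        raise ValueError("threshold must be within [0, 100]")
    out: dict[Key, LocusEstimate] = {}
    for key, est in estimates.items():
        low = est.score < threshold
        if low and drop:
            continue
        est.low_score = low
        out[key] = est
    return out
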