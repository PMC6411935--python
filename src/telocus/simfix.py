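"""Synthetic benchmark generator and exhaustive oracle aligner.

This module makes the whole quantification pipeline testable with no
downloads and no external aligner.  It builds toy genomes containing
divergent TE subfamilies (each subfamily descends from one random
consensus; each locus is that consensus with per-base substitutions at a
recorded divergence), simulates stranded paired-end reads with realistic
bulk RNA-seq parameters (100 bp mates, ~250 bp fragments, 0.5 % uniform
error, ~20x per-locus coverage), and aligns reads *exhaustively*: every
ungapped placement of every mate within a mismatch budget is reported,
with NH/HI tags, so alignment is exact rather than heuristic.

Divergence is substitution-only — no indels — which keeps the oracle
aligner ungapped and provably complete (pigeonhole seeding guarantees
every placement within the mismatch budget is found).  That is enough to
create the unique/multi-mapping structure the quantifier adjudicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import AnnotationSet, TELocus

__all__ = [
    "SimConfig",
    "TruthTable",
    "ReadPair",
    "make_genome",
    "default_expression",
    "simulate_reads",
    "oracle_align",
    "evaluate",
    "write_fastq",
    "write_genome_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = bytes.maketrans(b"ACGT", b"TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(slots=True)
class SimConfig:
    """Parameters of the synthetic benchmark.

    Defaults emulate a stranded (fr) paired-end bulk RNA-seq library:
    100 bp mates, fragment lengths ~ Normal(250, 25) truncated at the read
    length, a uniform 0.5 % per-base sequencing error, and a mean
    per-locus coverage of 20x.  Subfamily divergences are evenly spaced
    across ``divergence_range``; all loci of one subfamily share its
    divergence, so accuracy can be stratified by element age.
    """

    seed: int = 0
    read_length: int = 100
    frag_mean: float = 250.0
    frag_sd: float = 25.0
    error_rate: float = 0.005
    coverage_mean: float = 20.0
    n_subfamilies: int = 5
    loci_per_subfamily: int = 20
    consensus_length: int = 1500
    divergence_range: tuple[float, float] = (0.02, 0.25)
    genome_background_length: int = 50_000
    flank_extension: int = 0
    # Expression model: most loci transcribed at coverage_mean, a fraction
    # silent (needed for detection metrics), a fraction deviating from the
    # mean by a 2-100x factor up or down.
    expressed_fraction: float = 0.8
    deviant_fraction: float = 0.1
    deviation_fold_range: tuple[float, float] = (2.0, 100.0)

    def __post_init__(self) -> None:
        for rate in (self.error_rate, self.expressed_fraction, self.deviant_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.frag_mean < self.read_length:
            raise ValueError("frag_mean must be >= read_length")


@dataclass(slots=True)
class TruthTable:
    """Simulated ground truth, one row per locus.

    ``expressed`` mirrors the evaluation convention that only loci with at
    least ``expressed_threshold`` simulated fragments count as expressed.
    """

    counts: dict[str, int]
    divergence: dict[str, float]
    expressed_threshold: int = 10

    def expressed(self, locus_id: str) -> bool:
        return self.counts.get(locus_id, 0) >= self.expressed_threshold

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "locus_id": lid,
                "sim_count": n,
                "divergence": self.divergence.get(lid, float("nan")),
                "expressed": n >= self.expressed_threshold,
            }
            for lid, n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(slots=True)
class ReadPair:
    name: str
    seq1: str
    seq2: str
    # Truth origin of the fragment (genomic, 0-based half-open).
    chrom: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    locus_id: str = ""
    n_errors: int = 0


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(
    rng: np.random.Generator, seq: np.ndarray, rate: float
) -> tuple[np.ndarray, int]:
    """Substitute each base independently with probability ``rate``."""
    out = seq.copy()
    hits = np.nonzero(rng.random(seq.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out, hits.size


def make_genome(
    cfg: SimConfig,
) -> tuple[dict[str, str], AnnotationSet, dict[str, str]]:
    """Build a toy genome with divergent TE subfamilies.

    Returns ``(genome, annotation, consensus)``: a single-chromosome
    genome, the annotation of every inserted locus (``milli_div`` set from
    its simulated divergence), and each subfamily's consensus sequence.
    Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_loci = cfg.n_subfamilies * cfg.loci_per_subfamily
    total_te = n_loci * cfg.consensus_length
    if cfg.genome_background_length < (n_loci + 1) * 2 * cfg.read_length:
        raise ValueError(
            "background too short to separate loci by at least two read lengths"
        )
    gap = cfg.genome_background_length // (n_loci + 1)

    if cfg.n_subfamilies == 1:
        div_levels = [sum(cfg.divergence_range) / 2.0]
    else:
        lo, hi = cfg.divergence_range
        div_levels = list(np.linspace(lo, hi, cfg.n_subfamilies))

    consensus: dict[str, str] = {}
    chunks: list[np.ndarray] = []
    loci: list[TELocus] = []
    pos = 0
    chrom = "chrSim"
    for si in range(cfg.n_subfamilies):
        sub = f"SIM{si + 1}"
        consensus_arr = _random_seq(rng, cfg.consensus_length)
        consensus[sub] = consensus_arr.tobytes().decode()
        for li in range(cfg.loci_per_subfamily):
            chunks.append(_random_seq(rng, gap))
            pos += gap
            locus_arr, _ = _mutate(rng, consensus_arr, div_levels[si])
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                seq = _revcomp(locus_arr.tobytes().decode())
                locus_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            chunks.append(locus_arr)
            loci.append(
                TELocus(
                    chrom=chrom,
                    start=pos,
                    end=pos + cfg.consensus_length,
                    strand=strand,
                    subfamily=sub,
                    family="SIMFAM",
                    clazz="SIMTE",
                    milli_div=round(div_levels[si] * 1000.0, 3),
                )
            )
            pos += cfg.consensus_length
    chunks.append(_random_seq(rng, gap))
    genome = {chrom: np.concatenate(chunks).tobytes().decode()}
    assert total_te <= len(genome[chrom])
    return genome, AnnotationSet(loci, genome_build_label=f"sim(seed={cfg.seed})"), consensus


def default_expression(
    cfg: SimConfig, ann: AnnotationSet, rng: np.random.Generator
) -> dict[str, float]:
    """Per-locus target coverage under the default expression model."""
    coverage: dict[str, float] = {}
    for locus in ann.loci:
        if rng.random() >= cfg.expressed_fraction:
            coverage[locus.locus_id] = 0.0
            continue
        cov = cfg.coverage_mean
        if rng.random() < cfg.deviant_fraction:
            lo, hi = cfg.deviation_fold_range
            fold = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            cov = cov * fold if rng.random() < 0.5 else cov / fold
        coverage[locus.locus_id] = cov
    return coverage


def simulate_reads(
    genome: Mapping[str, str],
    ann: AnnotationSet,
    cfg: SimConfig,
    coverage: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[ReadPair], TruthTable]:
    """Simulate stranded paired-end reads from expressed loci.

    Fragments start uniformly along each locus's transcript (the annotated
    span, optionally extended by ``cfg.flank_extension`` on both sides to
    emulate transcription running past the annotation).  Fragment lengths
    are Normal(frag_mean, frag_sd) truncated at the read length; each base
    is miscalled independently at ``cfg.error_rate``.  Mate 1 carries the
    transcript strand (fr protocol).  Expected fragments per locus:
    ``coverage × transcript_length / (2 × read_length)``, Poisson-sampled.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    if coverage is None:
        coverage = default_expression(cfg, ann, rng)
    pairs: list[ReadPair] = []
    counts: dict[str, int] = {}
    divergence: dict[str, float] = {}
    idx = 0
    for locus in ann.loci:
        lid = locus.locus_id
        divergence[lid] = locus.milli_div / 1000.0
        cov = coverage.get(lid, 0.0)
        chrom_seq = genome[locus.chrom]
        tx_start = max(locus.start - cfg.flank_extension, 0)
        tx_end = min(locus.end + cfg.flank_extension, len(chrom_seq))
        tx_len = tx_end - tx_start
        mean_frags = cov * tx_len / (2.0 * cfg.read_length)
        n_frags = int(rng.poisson(mean_frags)) if mean_frags > 0 else 0
        counts[lid] = n_frags
        if n_frags == 0:
            continue
        transcript = chrom_seq[tx_start:tx_end]
        if locus.strand == "-":
            transcript = _revcomp(transcript)
        for _ in range(n_frags):
            flen = int(round(rng.normal(cfg.frag_mean, cfg.frag_sd)))
            flen = max(cfg.read_length, min(flen, tx_len))
            u = int(rng.integers(0, tx_len - flen + 1))
            frag = transcript[u : u + flen]
            mate1 = frag[: cfg.read_length]
            mate2 = _revcomp(frag[flen - cfg.read_length :])
            m1, e1 = _mutate(
                rng, np.frombuffer(mate1.encode(), dtype=np.uint8), cfg.error_rate
            )
            m2, e2 = _mutate(
                rng, np.frombuffer(mate2.encode(), dtype=np.uint8), cfg.error_rate
            )
            if locus.strand == "+":
                g_start = tx_start + u
            else:
                g_start = tx_end - u - flen
            name = f"sim{idx:07d}"
            pairs.append(
                ReadPair(
                    name=name,
                    seq1=m1.tobytes().decode(),
                    seq2=m2.tobytes().decode(),
                    chrom=locus.chrom,
                    start=g_start,
                    end=g_start + flen,
                    strand=locus.strand,
                    locus_id=lid,
                    n_errors=e1 + e2,
                )
            )
            idx += 1
    truth = TruthTable(counts=counts, divergence=divergence)
    return pairs, truth


# --- Exhaustive oracle alignment -----------------------------------------


@dataclass(slots=True)
class _Placement:
    chrom: str
    start: int
    strand: str
    nm: int


class _SeedIndex:
    """Pigeonhole seed index over a small genome.

    With seed length ``k = floor(read_length / (max_mismatches + 1))``, any
    ungapped placement with at most ``max_mismatches`` substitutions leaves
    at least one of the non-overlapping seeds exact, so looking every seed
    up and verifying the implied start positions finds *every* qualifying
    placement.
    """

    def __init__(self, genome: Mapping[str, str], seed_len: int):
        self.seed_len = seed_len
        self.arrays = {
            chrom: np.frombuffer(seq.encode(), dtype=np.uint8)
            for chrom, seq in genome.items()
        }
        self.index: dict[bytes, list[tuple[str, int]]] = {}
        for chrom, seq in genome.items():
            data = seq.encode()
            for pos in range(len(data) - seed_len + 1):
                kmer = data[pos : pos + seed_len]
                self.index.setdefault(kmer, []).append((chrom, pos))

    def placements(self, seq: str, max_mismatches: int) -> list[_Placement]:
        out: list[_Placement] = []
        for strand, s in (("+", seq), ("-", _revcomp(seq))):
            arr = np.frombuffer(s.encode(), dtype=np.uint8)
            data = s.encode()
            L = len(data)
            k = self.seed_len
            offsets = list(range(0, L - k + 1, k))
            cand: dict[str, set[int]] = {}
            for off in offsets:
                for chrom, pos in self.index.get(data[off : off + k], ()):
                    start = pos - off
                    if 0 <= start <= self.arrays[chrom].size - L:
                        cand.setdefault(chrom, set()).add(start)
            for chrom, starts in cand.items():
                starts_arr = np.fromiter(sorted(starts), dtype=np.int64)
                window = starts_arr[:, None] + np.arange(L)
                nm = (self.arrays[chrom][window] != arr).sum(axis=1)
                for start, n in zip(starts_arr, nm):
                    if n <= max_mismatches:
                        out.append(_Placement(chrom, int(start), strand, int(n)))
        out.sort(key=lambda p: (p.chrom, p.start, p.strand))
        return out


def oracle_align(
    pairs: Sequence[ReadPair],
    genome: Mapping[str, str],
    out_sam: str | Path,
    *,
    read_length: int | None = None,
    max_mismatches: int = 5,
    max_pair_span: int = 2000,
) -> Path:
    """Exhaustively align read pairs and write a SAM with NH/HI tags.

    Every ungapped placement of each mate on either strand with at most
    ``max_mismatches`` substitutions is found.  Mates are joined into
    concordant pairs (same chromosome, opposite strands, reference span at
    most ``max_pair_span``); when at least one concordant pair exists only
    the pairs are reported, otherwise each mate's placements are reported
    as unpaired-in-pair records.  Deterministic output order.
    """
    out_sam = Path(out_sam)
    if read_length is None:
        read_length = len(pairs[0].seq1) if pairs else 100
    seed_len = max(8, read_length // (max_mismatches + 1))
    index = _SeedIndex(genome, seed_len)

    chroms = sorted(genome)
    header = {
        "HD": {"VN": "1.6", "SO": "queryname"},
        "SQ": [{"SN": c, "LN": len(genome[c])} for c in chroms],
        "PG": [{"ID": "telocus-oracle", "PN": "telocus-oracle"}],
    }
    tid = {c: i for i, c in enumerate(chroms)}

    with pysam.AlignmentFile(str(out_sam), "wh", header=header) as out:
        for pair in pairs:
            p1 = index.placements(pair.seq1, max_mismatches)
            p2 = index.placements(pair.seq2, max_mismatches)
            concordant = [
                (a, b)
                for a in p1
                for b in p2
                if a.chrom == b.chrom
                and a.strand != b.strand
                and max(a.start + read_length, b.start + read_length)
                - min(a.start, b.start)
                <= max_pair_span
            ]
            if concordant:
                nh = len(concordant)
                for hi, (a, b) in enumerate(concordant):
                    _write_mate(out, pair, a, b, 1, hi, nh, tid, read_length)
                    _write_mate(out, pair, b, a, 2, hi, nh, tid, read_length)
            else:
                # No concordant pairing: report each mate independently;
                # disjoint HI keys keep the mates from being re-paired.
                for hi, a in enumerate(p1):
                    _write_mate(out, pair, a, None, 1, 2 * hi, len(p1), tid, read_length)
                for hi, b in enumerate(p2):
                    _write_mate(out, pair, b, None, 2, 2 * hi + 1, len(p2), tid, read_length)
    return out_sam


def _write_mate(
    out: pysam.AlignmentFile,
    pair: ReadPair,
    self_p: _Placement,
    mate_p: _Placement | None,
    mate: int,
    hi: int,
    nh: int,
    tid: Mapping[str, int],
    read_length: int,
) -> None:
    rec = pysam.AlignedSegment(out.header)
    rec.query_name = pair.name
    seq = pair.seq1 if mate == 1 else pair.seq2
    rec.query_sequence = _revcomp(seq) if self_p.strand == "-" else seq
    rec.query_qualities = pysam.qualitystring_to_array("I" * read_length)
    rec.flag = 0x1 | (0x40 if mate == 1 else 0x80)
    if self_p.strand == "-":
        rec.flag |= 0x10
    rec.reference_id = tid[self_p.chrom]
    rec.reference_start = self_p.start
    rec.mapping_quality = 255
    rec.cigarstring = f"{read_length}M"
    if mate_p is not None:
        rec.flag |= 0x2
        if mate_p.strand == "-":
            rec.flag |= 0x20
        rec.next_reference_id = tid[mate_p.chrom]
        rec.next_reference_start = mate_p.start
        span_l = min(self_p.start, mate_p.start)
        span_r = max(self_p.start, mate_p.start) + read_length
        rec.template_length = (span_r - span_l) * (
            1 if self_p.start <= mate_p.start else -1
        )
    else:
        rec.flag |= 0x8  # mate placement not co-reported
        rec.next_reference_id = -1
        rec.next_reference_start = -1
    rec.set_tag("NH", nh)
    rec.set_tag("HI", hi)
    rec.set_tag("NM", self_p.nm)
    out.write(rec)


# --- Truth-based evaluation ----------------------------------------------


@dataclass(slots=True)
class EvalResult:
    """Accuracy of quantification against simulated truth."""

    per_locus: pd.DataFrame = field(repr=False)
    mean_obs_over_exp: float
    tpr: float
    ppv: float
    by_divergence: dict[str, float]


def evaluate(
    estimates: Mapping,
    truth: TruthTable,
    *,
    divergence_split: float = 0.10,
) -> EvalResult:
    """Score quantification output against the simulated truth.

    ``%O/E`` (observed over expected, x100) is averaged over truth-
    expressed loci only; TPR is the fraction of truth-expressed loci
    reported at or above the expressed threshold, PPV the fraction of
    loci reported at or above the threshold that are truth-expressed.
    ``by_divergence`` holds mean %O/E below and at/above
    ``divergence_split``.
    """
    observed: dict[str, float] = {}
    for est in estimates.values():
        observed[est.locus_id] = observed.get(est.locus_id, 0.0) + est.c_te

    thr = truth.expressed_threshold
    rows = []
    for lid, exp_count in truth.counts.items():
        obs = observed.get(lid, 0.0)
        rows.append(
            {
                "locus_id": lid,
                "sim_count": exp_count,
                "obs_count": obs,
                "divergence": truth.divergence.get(lid, float("nan")),
                "expressed": exp_count >= thr,
                "reported": obs >= thr,
                "pct_obs_exp": (100.0 * obs / exp_count) if exp_count >= thr else float("nan"),
            }
        )
    per_locus = pd.DataFrame(rows)

    expressed = per_locus[per_locus["expressed"]]
    reported = per_locus[per_locus["reported"]]
    mean_oe = float(expressed["pct_obs_exp"].mean()) if len(expressed) else float("nan")
    tpr = (
        100.0 * float(expressed["reported"].mean()) if len(expressed) else float("nan")
    )
    ppv = (
        100.0 * float(reported["expressed"].mean()) if len(reported) else float("nan")
    )
    low = expressed[expressed["divergence"] < divergence_split]
    high = expressed[expressed["divergence"] >= divergence_split]
    by_div = {
        f"<{divergence_split:g}": float(low["pct_obs_exp"].mean()) if len(low) else float("nan"),
        f">={divergence_split:g}": float(high["pct_obs_exp"].mean()) if len(high) else float("nan"),
    }
    return EvalResult(
        per_locus=per_locus,
        mean_obs_over_exp=mean_oe,
        tpr=tpr,
        ppv=ppv,
        by_divergence=by_div,
    )


# --- Plain-text serialization helpers ------------------------------------


def write_genome_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    with open(path, "wt") as out:
        for chrom in sorted(genome):
            out.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 80):
                out.write(seq[i : i + 80] + "\n")


def write_fastq(
    pairs: Iterable[ReadPair], prefix: str | Path
) -> tuple[Path, Path]:
    """Write mates to ``<prefix>_1.fastq`` / ``<prefix>_2.fastq``."""
    prefix = Path(prefix)
    r1 = prefix.with_name(prefix.name + "_1.fastq")
    r2 = prefix.with_name(prefix.name + "_2.fastq")
    with open(r1, "wt") as f1, open(r2, "wt") as f2:
        for p in pairs:
            qual1 = "I" * len(p.seq1)
            qual2 = "I" * len(p.seq2)
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{qual1}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{qual2}\n")
    return r1, r2
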