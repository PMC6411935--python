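"""Shared fixtures: the three-locus worked example (at both the abstract
count level and the SAM level) and random small quantification instances.

The worked example has TE A with 4 unique fragments at 2 distinct start
positions, TE B with 1 unique fragment, TE C with none, and 4
multi-mapping fragments each aligning concordantly to all three loci.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import pysam
import pytest

from telocus.annotation import AnnotationSet, TELocus
from telocus.quant import Key, UniqueStats

SENSE = "sense"


def key(name: str) -> Key:
    return (name, SENSE)


@dataclass
class Fig2:
    """Abstract (annotation-free) form of the worked example."""

    ustats: dict[Key, UniqueStats]
    multi: dict[str, list[Key]]  # read_id -> candidate keys
    base: dict[Key, float]
    eff_len: dict[Key, float]
    r_te: dict[Key, int]


@pytest.fixture()
def fig2() -> Fig2:
    a, b, c = key("A"), key("B"), key("C")
    ustats = {
        a: UniqueStats(c_u=4, starts={1200, 1500}, span_start=1200, span_end=1750),
        b: UniqueStats(c_u=1, starts={10500}, span_start=10500, span_end=10750),
    }
    multi = {f"m{i}": [a, b, c] for i in range(4)}
    base = {a: 4.0, b: 1.0, c: 0.0}
    # Equal effective lengths keep the worked example's arithmetic clean.
    eff_len = {a: 1000.0, b: 1000.0, c: 1000.0}
    r_te = {a: 8, b: 5, c: 4}
    return Fig2(ustats=ustats, multi=multi, base=base, eff_len=eff_len, r_te=r_te)


# --- SAM-level fixture ----------------------------------------------------

CHROM = "chr1"
CHROM_LEN = 30_000
#: Annotated spans of the three loci (equal annotated lengths).
LOCUS_SPANS = {"A": (1000, 7000), "B": (10_000, 16_000), "C": (19_000, 25_000)}


def fig2_annotation() -> AnnotationSet:
    loci = [
        TELocus(CHROM, s, e, "+", f"Sub{name}", "Fam", "SIMTE")
        for name, (s, e) in LOCUS_SPANS.items()
    ]
    return AnnotationSet(loci)


def fig2_locus_ids() -> dict[str, str]:
    return {
        name: f"{CHROM}|{s}|{e}|Sub{name}|+"
        for name, (s, e) in LOCUS_SPANS.items()
    }


def _pair_records(header, name, placements, read_len=100, frag_len=250):
    """Yield SAM records for a pair placed at each (chrom, start) given.

    Mate 1 maps forward at ``start``; mate 2 maps reverse ending at
    ``start + frag_len``.
    """
    nh = len(placements)
    for hi, start in enumerate(placements):
        for mate, (s, reverse) in enumerate(
            [(start, False), (start + frag_len - read_len, True)], start=1
        ):
            rec = pysam.AlignedSegment(header)
            rec.query_name = name
            rec.query_sequence = "A" * read_len
            rec.flag = 0x1 | 0x2 | (0x40 if mate == 1 else 0x80)
            if reverse:
                rec.flag |= 0x10
            else:
                rec.flag |= 0x20
            rec.reference_id = 0
            rec.reference_start = s
            rec.mapping_quality = 255
            rec.cigarstring = f"{read_len}M"
            rec.next_reference_id = 0
            rec.next_reference_start = (
                start if reverse else start + frag_len - read_len
            )
            rec.set_tag("NH", nh)
            rec.set_tag("HI", hi)
            yield rec


def write_fig2_sam(path) -> None:
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": CHROM, "LN": CHROM_LEN}]}
    )
    a0, b0, c0 = (LOCUS_SPANS[k][0] for k in "ABC")
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        # TE A: 4 unique fragments at 2 distinct start positions.
        for i, start in enumerate([a0 + 200, a0 + 200, a0 + 500, a0 + 500]):
            for rec in _pair_records(header, f"uA{i}", [start]):
                out.write(rec)
        # TE B: 1 unique fragment.
        for rec in _pair_records(header, "uB0", [b0 + 500]):
            out.write(rec)
        # 4 multi fragments, one concordant placement in each locus.
        for i in range(4):
            placements = [a0 + 2000 + 10 * i, b0 + 2000 + 10 * i, c0 + 2000 + 10 * i]
            for rec in _pair_records(header, f"m{i}", placements):
                out.write(rec)


@pytest.fixture()
def fig2_sam(tmp_path):
    sam = tmp_path / "fig2.sam"
    write_fig2_sam(sam)
    return sam


@pytest.fixture()
def fig2_ann():
    return fig2_annotation()


# --- Random small instances ----------------------------------------------


def random_instance(rng: random.Random, max_loci=10, max_frags=100):
    """A random quantification instance in the abstract form used by
    :func:`telocus.quant.run_em` (base counts, unique stats, effective
    lengths, candidate sets)."""
    n_loci = rng.randint(2, max_loci)
    keys = [key(f"L{i}") for i in range(n_loci)]
    ustats: dict[Key, UniqueStats] = {}
    base: dict[Key, float] = {}
    eff_len: dict[Key, float] = {}
    for k in keys:
        c_u = rng.choice([0, 0, 1, 2, 5, 20])
        st = UniqueStats(c_u=c_u)
        if c_u:
            l_u = rng.randint(1, c_u)
            st.starts = set(range(l_u))
        if rng.random() < 0.2:
            st.c_full = rng.randint(1, 3)
        ustats[k] = st
        base[k] = st.base_count
        eff_len[k] = float(rng.randint(1, 5000))
    n_frags = rng.randint(1, max_frags)
    multi: dict[str, list[Key]] = {}
    for i in range(n_frags):
        size = rng.randint(1, min(4, n_loci))
        multi[f"r{i}"] = rng.sample(keys, size)
    return keys, ustats, base, eff_len, multi
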