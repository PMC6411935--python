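"""Loop-explicit brute-force reference for the count assignment.

An independently written, dictionary-and-for-loop evaluation of the
initial proportional assignment and of the EM recursion, used to check
the package implementation on small instances.  Deliberately naive: no
shared helpers, no vectorization, every rule spelled out inline.
"""

from __future__ import annotations


def brute_initial(cu, lu, frag_cands):
    """Initial fractions: zero-unique candidates take 1/N each; the rest
    share 1 - n/N proportionally to C_U/L_U."""
    out = {}
    for rid, cands in frag_cands.items():
        cands = list(cands)
        N = len(cands)
        with_unique = []
        without_unique = []
        for k in cands:
            if cu.get(k, 0) > 0:
                with_unique.append(k)
            else:
                without_unique.append(k)
        n = len(without_unique)
        f = {}
        for k in without_unique:
            f[k] = 1.0 / N
        if with_unique:
            total_w = 0.0
            for k in with_unique:
                total_w += cu[k] / lu[k]
            for k in with_unique:
                f[k] = (1.0 - n / N) * (cu[k] / lu[k]) / total_w
        out[rid] = f
    return out


def brute_totals(base, fractions):
    counts = {}
    for k, v in base.items():
        counts[k] = v
    for f in fractions.values():
        for k, val in f.items():
            counts[k] = counts.get(k, 0.0) + val
    return counts


def brute_estep(frag_cands, counts, eff_len, zeroing):
    out = {}
    for rid, cands in frag_cands.items():
        cands = list(cands)
        keep = []
        for k in cands:
            if not zeroing or counts.get(k, 0.0) >= 1.0:
                keep.append(k)
        denom = 0.0
        for k in keep:
            denom += counts.get(k, 0.0) / eff_len[k]
        f = {}
        if len(keep) == 0 or denom <= 0.0:
            for k in cands:
                f[k] = 1.0 / len(cands)
        else:
            for k in cands:
                f[k] = 0.0
            for k in keep:
                f[k] = (counts.get(k, 0.0) / eff_len[k]) / denom
        out[rid] = f
    return out


def brute_converged(prev, new):
    for k in set(list(prev) + list(new)):
        a = prev.get(k, 0.0)
        b = new.get(k, 0.0)
        if max(a, b) < 10.0:
            continue
        if abs(b - a) / max(a, 1.0) >= 0.01:
            return False
    return True


def brute_em(base, cu, lu, eff_len, frag_cands, iterations, max_iter=100,
             zeroing="per-step"):
    """Full pipeline: initial assignment then EM to a fixed count or
    convergence ('auto').  Returns (counts, fractions)."""
    fractions = brute_initial(cu, lu, frag_cands)
    counts = brute_totals(base, fractions)
    auto = iterations == "auto"
    n_rounds = max_iter if auto else min(int(iterations), max_iter)
    for _ in range(n_rounds):
        fractions = brute_estep(
            frag_cands, counts, eff_len, zeroing == "per-step"
        )
        new_counts = brute_totals(base, fractions)
        if auto and brute_converged(counts, new_counts):
            counts = new_counts
            break
        counts = new_counts
    if zeroing == "final" and n_rounds > 0:
        fractions = brute_estep(frag_cands, counts, eff_len, True)
        counts = brute_totals(base, fractions)
    return counts, fractions
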