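"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (direct
summation, exhaustive enumeration) and shares no code path with the
package.
"""
from __future__ import annotations

import itertools
import math

_PAIRS = {"AT", "TA", "GC", "CG", "GT", "TG"}


def ac_pvalue_direct(x: int, y: int, n_a: float, n_b: float) -> float:
    """Audic-Claverie two-sided p by direct log-space tail summation.

    Sums the conditional pmf P(K=k | a) = f^k (a+k)! / (a! k! (1+f)^(a+k+1))
    in both conditioning directions and doubles the smaller inclusive
    upper tail.
    """

    def upper_tail(a: int, b: int, f: float) -> float:
        # P(K >= b | a) = 1 - sum_{k < b} P(K = k | a)
        acc = 0.0
        for k in range(b):
            acc += math.exp(
                k * math.log(f)
                + math.lgamma(a + k + 1)
                - math.lgamma(a + 1)
                - math.lgamma(k + 1)
                - (a + k + 1) * math.log1p(f)
            )
        return 1.0 - acc

    tail_y = upper_tail(x, y, n_b / n_a)  # P(Y >= y | x)
    tail_x = upper_tail(y, x, n_a / n_b)  # P(X >= x | y)
    return min(1.0, 2.0 * min(tail_y, tail_x))


def bh_stepup(p_values) -> list[float]:
    """Benjamini-Hochberg by the literal step-up definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p_values[i] / rank)
        q[i] = min(running, 1.0)
    return q


def match_read_windows(read: str, sequence: str, start: int, end: int,
                       max_offset: int = 4, max_mismatches: int = 1):
    """Exhaustive 9x9 window enumeration for isomiR matching.

    Tries every (offset5, offset3) pair independently, keeps windows whose
    length equals the read length, and applies the same tie-break order
    as the matcher: (mismatches, |o5|+|o3|, |o5|, o5, o3).
    """
    best = None
    for o5 in range(-max_offset, max_offset + 1):
        for o3 in range(-max_offset, max_offset + 1):
            ws, we = start - o5, end + o3
            if ws < 0 or we > len(sequence) or ws >= we:
                continue
            if we - ws != len(read):
                continue
            mm = sum(a != b for a, b in zip(read, sequence[ws:we]))
            if mm > max_mismatches:
                continue
            rank = (mm, abs(o5) + abs(o3), abs(o5), o5, o3)
            if best is None or rank < best:
                best = rank
    if best is None:
        return None
    mm, _, _, o5, o3 = best
    return (o5, o3, mm)


_WC = {"AT", "TA", "GC", "CG"}


def max_pairs_enumerate(
    sequence: str,
    min_loop: int = 3,
    wobble: bool = True,
    allow_lonely_pairs: bool = False,
) -> int:
    """Maximum nested pair count by explicit enumeration of every nested
    structure (exponential; short sequences only), under the same rules
    as the folder: pairing alphabet, min_loop, and - unless
    allow_lonely_pairs - helices of at least two stacked pairs.
    """
    seq = sequence.upper().replace("U", "T")
    pairs = _PAIRS if wobble else _WC

    def structures(i: int, j: int):
        """All non-crossing pair sets on [i, j] respecting min_loop."""
        if i >= j:
            yield frozenset()
            return
        yield from structures(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if seq[i] + seq[k] in pairs:
                for inner in structures(i + 1, k - 1):
                    for rest in structures(k + 1, j):
                        yield inner | rest | {(i, k)}

    def no_lonely(struct: frozenset) -> bool:
        return all(
            (a + 1, b - 1) in struct or (a - 1, b + 1) in struct
            for a, b in struct
        )

    best = 0
    for struct in structures(0, len(seq) - 1):
        if allow_lonely_pairs or no_lonely(struct):
            best = max(best, len(struct))
    return best


def hypergeom_sf_enumerate(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by pmf summation."""
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        if n - i > N - K:
            continue
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom
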