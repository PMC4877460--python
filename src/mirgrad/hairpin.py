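"""Stem-loop plausibility check for miRNA precursor candidates.

A candidate precursor is folded by Nussinov-style base-pair maximization
(Watson-Crick plus G·U wobble, nested structures only, a minimum hairpin
loop of 3 unpaired bases) and judged a plausible pre-miRNA hairpin when
the fold has exactly one terminal loop, the mature region stays out of
that loop, and most mature bases are paired. Base-pair maximization is a
deliberate simplification of free-energy folding: it asserts only the
qualitative hairpin shape, which is what the plausibility check needs,
and requires no thermodynamic parameter tables.

By default lonely (isolated) base pairs are disallowed — every helix
must carry at least two stacked pairs — because pure pair maximization
otherwise decorates loops with single-pair micro-hairpins that no
thermodynamic model would form; plain maximization is available via
``allow_lonely_pairs=True``.
"""
from __future__ import annotations

from dataclasses import dataclass

from .records import as_dna

#: Allowed pairs in the DNA-stored alphabet (U is stored as T): canonical
#: Watson-Crick plus the G·U (here G·T) wobble. Note the wobble pair is
#: not closed under reverse complement (G·T maps to A·C), so strand
#: symmetry of the pair count holds only for Watson-Crick-only folding.
WC_PAIRS = frozenset({"AT", "TA", "GC", "CG"})
WOBBLE_PAIRS = WC_PAIRS | {"GT", "TG"}
PAIRS = WOBBLE_PAIRS

DEFAULT_MIN_LOOP = 3


def can_pair(a: str, b: str, wobble: bool = True) -> bool:
    return a + b in (WOBBLE_PAIRS if wobble else WC_PAIRS)


@dataclass(frozen=True)
class HairpinFold:
    """A nested secondary structure: pairing table and derived metrics.

    ``pair_table[i]`` is the 0-based partner of position ``i`` or None;
    pairing is an involution with no pseudoknots.
    """

    sequence: str
    pair_table: tuple
    n_pairs: int
    terminal_loops: int
    dot_bracket: str


def _dot_bracket(pair_table) -> str:
    chars = []
    for i, j in enumerate(pair_table):
        if j is None:
            chars.append(".")
        else:
            chars.append("(" if i < j else ")")
    return "".join(chars)


def count_terminal_loops(pair_table) -> int:
    """Number of hairpin (terminal) loops: pairs whose interior is
    entirely unpaired."""
    n = 0
    for i, j in enumerate(pair_table):
        if j is not None and j > i:
            if all(pair_table[k] is None for k in range(i + 1, j)):
                n += 1
    return n


def terminal_loop_spans(pair_table) -> list[tuple[int, int]]:
    """0-based half-open spans of the unpaired interiors of terminal loops."""
    spans = []
    for i, j in enumerate(pair_table):
        if j is not None and j > i:
            if all(pair_table[k] is None for k in range(i + 1, j)):
                spans.append((i + 1, j))
    return spans


def _fold_plain(seq: str, min_loop: int, wobble: bool) -> list:
    """Classic Nussinov maximization (lonely pairs allowed)."""
    n = len(seq)
    S = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = S[i][j - 1]
            for k in range(i, j - min_loop):
                if can_pair(seq[k], seq[j], wobble):
                    paired = 1 + S[k + 1][j - 1]
                    if k > i:
                        paired += S[i][k - 1]
                    if paired > best:
                        best = paired
            S[i][j] = best

    pair_table: list = [None] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop or S[i][j] == 0:
            continue
        paired_here = False
        for k in range(i, j - min_loop):
            if can_pair(seq[k], seq[j], wobble):
                paired = 1 + S[k + 1][j - 1] + (S[i][k - 1] if k > i else 0)
                if paired == S[i][j]:
                    pair_table[k] = j
                    pair_table[j] = k
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    paired_here = True
                    break
        if not paired_here:
            stack.append((i, j - 1))
    return pair_table


def _fold_no_lonely(seq: str, min_loop: int, wobble: bool) -> list:
    """Pair maximization over structures whose helices stack >= 2 pairs.

    ``H[i][j]`` is the best count when (i, j) is the outermost pair of a
    helix of depth h >= 2 (stacked pairs (i+t, j-t)) enclosing a free
    substructure; ``F[i][j]`` is the best count of any structure on
    [i, j].
    """
    n = len(seq)
    NEG = float("-inf")
    F = [[0] * n for _ in range(n)]
    H = [[NEG] * n for _ in range(n)]

    def f(i: int, j: int) -> float:
        return F[i][j] if i <= j else 0

    for span in range(min_loop + 3, n):  # helix of 2 needs span > min_loop+2
        for i in range(0, n - span):
            j = i + span
            # H: grow the stack while consecutive pairs are admissible
            best_h = NEG
            h = 0
            while (
                can_pair(seq[i + h], seq[j - h], wobble)
                and (j - h) - (i + h) > min_loop
            ):
                h += 1
                if h >= 2:
                    value = h + f(i + h, j - h)
                    if value > best_h:
                        best_h = value
            H[i][j] = best_h
            # F: j unpaired, or j closes a helix starting at k
            best_f = F[i][j - 1] if j > i else 0
            for k in range(i, j - min_loop - 2):
                if H[k][j] != NEG:
                    value = (F[i][k - 1] if k > i else 0) + H[k][j]
                    if value > best_f:
                        best_f = value
            F[i][j] = int(best_f)

    pair_table: list = [None] * n

    def trace_h(i: int, j: int) -> None:
        target = H[i][j]
        h = 0
        best = None
        while (
            can_pair(seq[i + h], seq[j - h], wobble) and (j - h) - (i + h) > min_loop
        ):
            h += 1
            if h >= 2 and h + f(i + h, j - h) == target:
                best = h  # prefer the deepest stack among co-optimal
        for t in range(best):
            pair_table[i + t] = j - t
            pair_table[j - t] = i + t
        if i + best <= j - best:
            trace_f(i + best, j - best)

    def trace_f(i: int, j: int) -> None:
        while i < j and F[i][j] > 0:
            if F[i][j] == F[i][j - 1]:
                j -= 1
                continue
            for k in range(i, j - min_loop - 2):
                if H[k][j] != NEG and (
                    (F[i][k - 1] if k > i else 0) + H[k][j] == F[i][j]
                ):
                    trace_h(k, j)
                    if k > i:
                        j = k - 1
                        break
                    return
            else:  # pragma: no cover - DP and traceback always agree
                raise AssertionError("traceback failed")
            continue

    if n > 0:
        trace_f(0, n - 1)
    return pair_table


def fold_maxpairs(
    sequence: str,
    min_loop: int = DEFAULT_MIN_LOOP,
    wobble: bool = True,
    allow_lonely_pairs: bool = False,
) -> HairpinFold:
    """Fold a sequence by maximizing the number of nested base pairs.

    ``n_pairs`` is the maximum attainable under the pairing rule
    (Watson-Crick, plus G·U when ``wobble``), the ``min_loop`` hairpin
    constraint and — unless ``allow_lonely_pairs`` — the no-isolated-pair
    rule. The traceback prefers long stacks and outermost pairings, which
    recovers a single long stem from hairpin-shaped inputs among
    co-optimal structures.
    """
    seq = as_dna(sequence)
    if min_loop < 0:
        raise ValueError("min_loop must be >= 0")
    if allow_lonely_pairs:
        pair_table = _fold_plain(seq, min_loop, wobble)
    else:
        pair_table = _fold_no_lonely(seq, min_loop, wobble)

    n_pairs = sum(1 for j in pair_table if j is not None) // 2
    return HairpinFold(
        sequence=seq,
        pair_table=tuple(pair_table),
        n_pairs=n_pairs,
        terminal_loops=count_terminal_loops(pair_table),
        dot_bracket=_dot_bracket(pair_table),
    )


@dataclass(frozen=True)
class StemloopVerdict:
    passed: bool
    terminal_loops: int
    mature_in_loop: bool
    mature_paired_fraction: float


def stemloop_check(
    fold: HairpinFold,
    mature_start: int,
    mature_end: int,
    min_paired_fraction: float = 0.6,
) -> StemloopVerdict:
    """Judge whether a fold looks like a pre-miRNA hairpin.

    Pass requires (a) exactly one terminal loop, (b) the mature region
    [mature_start, mature_end) not overlapping that loop, and (c) at
    least ``min_paired_fraction`` of mature bases paired — i.e. the
    mature miRNA sits in the stem, away from loops and bulges.
    """
    n = len(fold.sequence)
    if not (0 <= mature_start < mature_end <= n):
        raise ValueError("mature coordinates out of range")
    loops = terminal_loop_spans(fold.pair_table)
    in_loop = any(
        mature_start < stop and start < mature_end for start, stop in loops
    )
    paired = sum(
        1 for k in range(mature_start, mature_end) if fold.pair_table[k] is not None
    )
    fraction = paired / (mature_end - mature_start)
    passed = (
        len(loops) == 1 and not in_loop and fraction >= min_paired_fraction
    )
    return StemloopVerdict(passed, len(loops), in_loop, fraction)
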