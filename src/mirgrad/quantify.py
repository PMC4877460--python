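"""Read-to-miRNA matching and isomiR-aware quantification.

A read is assigned to a mature miRNA when it equals the precursor window
obtained by shifting the annotated mature region by at most 4 nt at each
end, with at most one substitution (the standard isomiR definition used
here). Indels are not isomiR events. Reads are assumed sense-strand and
adapter-trimmed; no reverse-complement search is performed (directional
small-RNA libraries).

``match_read`` is the exhaustive single-arm matcher; ``quantify_sample``
uses a k-mer anchor index (:class:`PrecursorIndex`) to find candidate
arms quickly and then verifies each candidate with ``match_read``, so its
assignments are identical to brute force over every arm.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FastqRead
from .records import CountMatrix, MatureArm, PrecursorRecord, as_dna

MIN_READ_LEN = 15
MAX_READ_LEN = 35

ProfileKey = tuple[int, int, int]  # (offset5, offset3, n_mismatches)

CANONICAL: ProfileKey = (0, 0, 0)


@dataclass(frozen=True)
class IsomirCall:
    """One read's isomiR classification against a mature miRNA.

    ``offset5``/``offset3`` are signed end shifts relative to the
    canonical mature ends, positive meaning extension beyond the mature
    region (upstream at the 5' end, downstream at the 3' end).
    """

    mature_id: str
    offset5: int
    offset3: int
    n_mismatches: int

    @property
    def is_canonical(self) -> bool:
        return self.offset5 == 0 and self.offset3 == 0 and self.n_mismatches == 0

    @property
    def key(self) -> ProfileKey:
        return (self.offset5, self.offset3, self.n_mismatches)


def _mismatches(a: str, b: str, limit: int) -> int:
    """Hamming distance with early exit once ``limit`` is exceeded."""
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def match_read(
    read: str,
    precursor: PrecursorRecord,
    arm: str | MatureArm,
    max_offset: int = 4,
    max_mismatches: int = 1,
) -> IsomirCall | None:
    """Match one read against one mature arm's isomiR windows.

    Enumerates every window of the precursor whose length equals the read
    length and whose ends lie within ``max_offset`` of the mature ends;
    returns the best call or ``None``. Ties are broken by fewest
    mismatches, then smallest ``|offset5| + |offset3|``, then smallest
    ``|offset5|``, then by (offset5, offset3) for full determinism.
    """
    if not read:
        raise ValueError("empty read")
    read = as_dna(read)
    if not (MIN_READ_LEN <= len(read) <= MAX_READ_LEN):
        raise ValueError(
            f"read length {len(read)} outside {MIN_READ_LEN}-{MAX_READ_LEN}"
        )
    mature = precursor.arm(arm)
    seq = precursor.sequence
    best: tuple | None = None
    # The window length must equal the read length, so offset3 is
    # determined by offset5: only 2*max_offset+1 windows exist per arm.
    for offset5 in range(-max_offset, max_offset + 1):
        offset3 = len(read) - len(mature) - offset5
        if abs(offset3) > max_offset:
            continue
        wstart, wend = mature.start - offset5, mature.end + offset3
        if wstart < 0 or wend > len(seq) or wstart >= wend:
            continue
        mm = _mismatches(read, seq[wstart:wend], max_mismatches)
        if mm > max_mismatches:
            continue
        rank = (mm, abs(offset5) + abs(offset3), abs(offset5), offset5, offset3)
        if best is None or rank < best[0]:
            best = (rank, offset5, offset3, mm)
    if best is None:
        return None
    _, offset5, offset3, mm = best
    return IsomirCall(mature.mature_id, offset5, offset3, mm)


class PrecursorIndex:
    """k-mer anchor index over every arm's admissible isomiR windows.

    For each arm and each admissible 5' offset the window start is fixed,
    so the window's first k bases are a fixed precursor substring (and
    symmetrically for 3' offsets and window suffixes). A read carrying at
    most one mismatch must agree exactly with a window on at least one of
    its two k-base halves (k <= len/2), so looking up both read anchors
    yields a superset of every arm that can match; candidates are then
    verified with :func:`match_read`.
    """

    def __init__(
        self,
        precursors: Sequence[PrecursorRecord],
        max_offset: int = 4,
        max_mismatches: int = 1,
    ):
        self.precursors = list(precursors)
        self.max_offset = max_offset
        self.max_mismatches = max_mismatches
        self.arms: list[tuple[PrecursorRecord, MatureArm]] = [
            (pre, arm) for pre in self.precursors for arm in pre.mature_arms
        ]
        self._anchors: dict[int, tuple[dict, dict]] = {}

    def _build(self, k: int) -> tuple[dict, dict]:
        heads: dict[str, set[int]] = {}
        tails: dict[str, set[int]] = {}
        for idx, (pre, arm) in enumerate(self.arms):
            seq = pre.sequence
            for off in range(-self.max_offset, self.max_offset + 1):
                wstart = arm.start - off
                if 0 <= wstart and wstart + k <= len(seq):
                    heads.setdefault(seq[wstart : wstart + k], set()).add(idx)
                wend = arm.end + off
                if k <= wend <= len(seq):
                    tails.setdefault(seq[wend - k : wend], set()).add(idx)
        return heads, tails

    def candidates(self, read: str) -> list[tuple[PrecursorRecord, MatureArm]]:
        k = 10 if len(read) >= 20 else len(read) // 2
        if k not in self._anchors:
            self._anchors[k] = self._build(k)
        heads, tails = self._anchors[k]
        hits = heads.get(read[:k], set()) | tails.get(read[-k:], set())
        return [self.arms[i] for i in sorted(hits)]


@dataclass
class SampleQuant:
    """Quantification of one sample: counts, isomiR profiles, length histogram."""

    counts: pd.Series
    profiles: dict[str, dict[ProfileKey, int]]
    length_hist: pd.Series
    n_reads: int
    n_unassigned: int
    multi_assignments: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)

    @property
    def n_assigned(self) -> int:
        return self.n_reads - self.n_unassigned


def quantify_sample(
    reads: Iterable[FastqRead | tuple[str, str] | str],
    precursors: Sequence[PrecursorRecord],
    index: PrecursorIndex | None = None,
    max_offset: int = 4,
    max_mismatches: int = 1,
) -> SampleQuant:
    """Assign each read to at most one mature miRNA and aggregate.

    Assignment picks the call with fewest mismatches across all arms;
    remaining ties go to the lexicographically smallest ``mature_id`` and
    are logged in ``multi_assignments`` for audit. Reads matching nothing
    (or outside the 15-35 nt window) are counted as unassigned, never
    dropped silently. The length histogram covers every read in 15-35 nt.
    """
    if not precursors:
        raise ValueError("precursor set is empty")
    if index is None:
        index = PrecursorIndex(precursors, max_offset, max_mismatches)
    mature_ids = sorted(arm.mature_id for pre in precursors for arm in pre.mature_arms)
    counts: dict[str, int] = {m: 0 for m in mature_ids}
    profiles: dict[str, dict[ProfileKey, int]] = {}
    length_hist = {l: 0 for l in range(MIN_READ_LEN, MAX_READ_LEN + 1)}
    n_reads = 0
    n_unassigned = 0
    multi: list[tuple[str, tuple[str, ...]]] = []
    for item in reads:
        if isinstance(item, str):
            read_id, seq = f"read{n_reads + 1}", item
        else:
            read_id, seq = item[0], item[1]
        n_reads += 1
        seq = seq.upper().replace("U", "T")
        if len(seq) in length_hist:
            length_hist[len(seq)] += 1
        else:
            n_unassigned += 1
            continue
        calls = []
        for pre, arm in index.candidates(seq):
            call = match_read(seq, pre, arm, max_offset, max_mismatches)
            if call is not None:
                calls.append(call)
        if not calls:
            n_unassigned += 1
            continue
        best_mm = min(c.n_mismatches for c in calls)
        contenders = sorted(
            (c for c in calls if c.n_mismatches == best_mm),
            key=lambda c: c.mature_id,
        )
        if len(contenders) > 1:
            multi.append((read_id, tuple(c.mature_id for c in contenders)))
        chosen = contenders[0]
        counts[chosen.mature_id] += 1
        profile = profiles.setdefault(chosen.mature_id, {})
        profile[chosen.key] = profile.get(chosen.key, 0) + 1
    return SampleQuant(
        counts=pd.Series(counts, name="count").sort_index(),
        profiles=profiles,
        length_hist=pd.Series(length_hist, name="n_reads").sort_index(),
        n_reads=n_reads,
        n_unassigned=n_unassigned,
        multi_assignments=multi,
    )


def dominant_isomir(profile: Mapping[ProfileKey, int]) -> ProfileKey:
    """The most abundant isomiR key of one miRNA's profile.

    Ties break toward the canonical key, then the smallest total end
    shift, then deterministically by the key itself.
    """
    if not profile:
        raise ValueError("empty isomiR profile")

    def rank(item: tuple[ProfileKey, int]):
        (o5, o3, mm), count = item
        return (-count, (o5, o3, mm) != CANONICAL, abs(o5) + abs(o3), o5, o3, mm)

    return min(profile.items(), key=rank)[0]


def counts_from_samples(
    quants: Mapping[str, SampleQuant],
    library_size: Mapping[str, int] | None = None,
) -> CountMatrix:
    """Stack per-sample quantifications into a CountMatrix.

    Library sizes default to each sample's total read count (assigned
    plus unassigned), so they are never below the assigned column sum.
    """
    if not quants:
        raise ValueError("no samples")
    frame = pd.DataFrame({s: q.counts for s, q in quants.items()}).fillna(0)
    if library_size is None:
        library_size = {s: q.n_reads for s, q in quants.items()}
    return CountMatrix(frame, library_size)


def profile_table(quants: Mapping[str, SampleQuant]) -> pd.DataFrame:
    """Long-format isomiR profile across samples (for the TSV writer)."""
    rows = []
    for sample, quant in quants.items():
        for mature_id, profile in sorted(quant.profiles.items()):
            for (o5, o3, mm), count in sorted(profile.items()):
                rows.append((sample, mature_id, o5, o3, mm, count))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "mature_id", "offset5", "offset3", "mismatches", "count"],
    )
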