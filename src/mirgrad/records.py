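"""Core data containers shared across the pipeline.

A :class:`PrecursorRecord` holds one pre-miRNA hairpin sequence together
with the coordinates of its annotated mature arm(s); a
:class:`CountMatrix` holds raw read counts (miRNA x sample) plus the
per-sample library sizes used for counts-per-million normalization.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_ARMS = ("5p", "3p")


def as_dna(sequence: str) -> str:
    """Uppercase a nucleotide string and store it in the DNA alphabet.

    RNA input (U) is accepted and converted to T; any character outside
    ACGTUN raises ``ValueError``.
    """
    seq = sequence.upper().replace("U", "T")
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    return seq


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatureArm:
    """Location of a mature miRNA within its precursor (0-based, half-open)."""

    arm: str
    start: int
    end: int
    mature_id: str

    def __post_init__(self) -> None:
        if self.arm not in VALID_ARMS:
            raise ValueError(f"arm must be one of {VALID_ARMS}, got {self.arm!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid arm coordinates [{self.start}, {self.end})")
        if not (16 <= self.end - self.start <= 30):
            raise ValueError(
                f"mature length {self.end - self.start} outside 16-30 nt"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PrecursorRecord:
    """A pre-miRNA sequence with one or two annotated mature arms."""

    id: str
    sequence: str
    mature_arms: tuple[MatureArm, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", as_dna(self.sequence))
        object.__setattr__(self, "mature_arms", tuple(self.mature_arms))
        if not self.mature_arms or len(self.mature_arms) > 2:
            raise ValueError("a precursor carries one or two mature arms")
        for arm in self.mature_arms:
            if arm.end > len(self.sequence):
                raise ValueError(
                    f"{self.id}: arm {arm.mature_id} extends past the precursor"
                )
        if len(self.mature_arms) == 2:
            a, b = sorted(self.mature_arms, key=lambda m: m.start)
            if b.start < a.end:
                raise ValueError(f"{self.id}: mature arms overlap")

    def arm(self, which: str | MatureArm) -> MatureArm:
        """Resolve an arm given as '5p'/'3p', a mature_id, or a MatureArm."""
        if isinstance(which, MatureArm):
            return which
        for arm in self.mature_arms:
            if which in (arm.arm, arm.mature_id):
                return arm
        raise KeyError(f"{self.id} has no arm {which!r}")

    def mature_sequence(self, which: str | MatureArm) -> str:
        arm = self.arm(which)
        return self.sequence[arm.start : arm.end]


class CountMatrix:
    """Raw miRNA read counts per sample plus per-sample library sizes.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, miRNAs as rows, samples as
        columns.
    library_size
        Per-sample total read count used for normalization. Defaults to
        the column sums (every assigned read counted once), matching the
        convention that the total copy number of a sample defines its
        library.
    """

    def __init__(self, counts: pd.DataFrame, library_size: Mapping | pd.Series | None = None):
        counts = pd.DataFrame(counts)
        if counts.empty:
            raise ValueError("counts matrix is empty")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        self.counts = counts.astype(np.int64)
        if library_size is None:
            library_size = self.counts.sum(axis=0)
        library_size = pd.Series(library_size).reindex(self.counts.columns)
        if library_size.isna().any():
            raise ValueError("library_size must cover every sample column")
        if (library_size <= 0).any():
            raise ValueError("library sizes must be positive")
        colsums = self.counts.sum(axis=0)
        if (library_size < colsums).any():
            raise ValueError("library size below the column's assigned counts")
        self.library_size = library_size.astype(np.int64)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def column(self, sample: str) -> pd.Series:
        return self.counts[sample]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CountMatrix({len(self.counts)} miRNAs x "
            f"{len(self.counts.columns)} samples)"
        )
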