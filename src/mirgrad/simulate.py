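"""Synthetic small-RNA data with known ground truth.

Everything downstream (quantification, differential expression, gradient
calling, qPCR analysis) is testable without any external download: this
module fabricates hairpin precursors, sequencing reads with isomiR end
offsets, Poisson count matrices for a normal/adjacent/tumor design, and
triplicate qPCR Ct tables with a U6 reference.

Counts are drawn Poisson (not negative binomial) so the generator matches
the exact test's sampling model; the study design emulated is one pooled
library per tissue class. Per-read ground truth travels in the FASTQ
comment field so quantification can be scored without side files.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FastqRead
from .records import MatureArm, PrecursorRecord, reverse_complement

TISSUES = ("normal", "adjacent", "tumor")

GRADIENT_UP = "up_gradient"
GRADIENT_DOWN = "down_gradient"
NULL = "null"

#: Read-length distribution peaking at 22 nt, the canonical mature-miRNA
#: mode in small RNA-seq length histograms.
DEFAULT_READ_LENGTH_WEIGHTS: Mapping[int, float] = {
    18: 0.02,
    19: 0.03,
    20: 0.10,
    21: 0.22,
    22: 0.38,
    23: 0.15,
    24: 0.07,
    25: 0.03,
}

#: End-offset distribution: most reads are canonical, trimming/extension
#: probability decays with distance, slightly favouring 3' trimming.
DEFAULT_OFFSET_PROBS: Mapping[int, float] = {
    0: 0.55,
    -1: 0.15,
    1: 0.10,
    -2: 0.07,
    2: 0.05,
    -3: 0.03,
    3: 0.02,
    -4: 0.02,
    4: 0.01,
}

_BASES = np.array(list("ACGT"))


def _validate_probs(mapping: Mapping[int, float], keys: range, name: str) -> None:
    if not mapping:
        raise ValueError(f"{name} is empty")
    for k, v in mapping.items():
        if k not in keys:
            raise ValueError(f"{name}: key {k} outside {keys}")
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}: probability {v} outside [0, 1]")
    total = float(sum(mapping.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {total})")


@dataclass
class SimulationDesign:
    """Parameters of a synthetic three-tissue small RNA-seq study.

    ``baseline_mean`` is the expected raw count of a miRNA in normal
    tissue; gradient miRNAs are multiplied (up) or divided (down) by
    ``gradient_step`` at each tissue step normal -> adjacent -> tumor.
    ``library_size`` is the number of reads per simulated FASTQ sample.
    ``isomir_offset_probs`` may be a single mapping used for both read
    ends or a ``(five_prime, three_prime)`` pair of mappings.
    """

    n_mirnas: int = 200
    n_gradient_up: int = 10
    n_gradient_down: int = 10
    baseline_mean: float = 100.0
    gradient_step: float = 2.0
    library_size: int = 10_000
    read_length_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_READ_LENGTH_WEIGHTS)
    )
    isomir_offset_probs: (
        Mapping[int, float] | tuple[Mapping[int, float], Mapping[int, float]]
    ) = field(default_factory=lambda: dict(DEFAULT_OFFSET_PROBS))
    mismatch_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas must be positive")
        if self.n_gradient_up < 0 or self.n_gradient_down < 0:
            raise ValueError("gradient counts must be non-negative")
        if self.n_gradient_up + self.n_gradient_down > self.n_mirnas:
            raise ValueError("more gradient miRNAs than miRNAs")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.gradient_step < 2:
            raise ValueError("gradient_step must be >= 2")
        if self.library_size < 1:
            raise ValueError("library_size must be positive")
        if not (0.0 <= self.mismatch_rate <= 1.0):
            raise ValueError("mismatch_rate must be a probability")
        _validate_probs(self.read_length_weights, range(18, 26), "read_length_weights")
        for name, probs in (
            ("offset5 probabilities", self.offset5_probs),
            ("offset3 probabilities", self.offset3_probs),
        ):
            _validate_probs(probs, range(-4, 5), name)

    @property
    def offset5_probs(self) -> Mapping[int, float]:
        probs = self.isomir_offset_probs
        return probs[0] if isinstance(probs, tuple) else probs

    @property
    def offset3_probs(self) -> Mapping[int, float]:
        probs = self.isomir_offset_probs
        return probs[1] if isinstance(probs, tuple) else probs


# ---------------------------------------------------------------------------
# Precursors
# ---------------------------------------------------------------------------

def _mature_length_weights(
    read_length_weights: Mapping[int, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Restrict the read-length distribution to the 20-23 nt mature range."""
    lengths = np.array([l for l in sorted(read_length_weights) if 20 <= l <= 23])
    if lengths.size == 0:
        raise ValueError("read_length_weights has no mass on 20-23 nt")
    weights = np.array([read_length_weights[l] for l in lengths], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("read_length_weights has no mass on 20-23 nt")
    return lengths, weights / weights.sum()


def simulate_precursors(
    n: int,
    seed: int,
    read_length_weights: Mapping[int, float] | None = None,
) -> list[PrecursorRecord]:
    """Generate ``n`` hairpin-shaped precursors with one mature arm each.

    Each precursor is built as ``arm + loop + revcomp(arm)`` with at most
    two planted point changes on the far arm, so folding it recovers a
    stem-loop. Total length lands in 60-90 nt; the mature region (20-23
    nt, length drawn from the 20-23 nt slice of ``read_length_weights``)
    sits inside one arm with a >=4 nt margin from the molecule's outer
    end, leaving room for +/-4 nt isomiR windows.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lengths, weights = _mature_length_weights(
        read_length_weights or DEFAULT_READ_LENGTH_WEIGHTS
    )
    precursors = []
    for i in range(n):
        mature_len = int(rng.choice(lengths, p=weights))
        arm_len = int(rng.integers(28, 39))
        loop_len = int(rng.integers(8, 13))
        arm5 = "".join(rng.choice(_BASES, size=arm_len))
        loop = "".join(rng.choice(_BASES, size=loop_len))
        arm3 = list(reverse_complement(arm5))
        for pos in rng.choice(arm_len, size=int(rng.integers(0, 3)), replace=False):
            current = arm3[pos]
            arm3[pos] = str(rng.choice(_BASES[_BASES != current]))
        sequence = arm5 + loop + "".join(arm3)
        which = "5p" if rng.random() < 0.5 else "3p"
        if which == "5p":
            start = int(rng.integers(4, arm_len - mature_len + 1))
        else:
            lo = arm_len + loop_len
            start = int(rng.integers(lo, len(sequence) - mature_len - 4 + 1))
        name = f"mir-{i + 1:04d}"
        arm = MatureArm(which, start, start + mature_len, f"{name}-{which}")
        precursors.append(PrecursorRecord(f"pre-{name}", sequence, (arm,)))
    return precursors


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def _sample_from(rng: np.random.Generator, probs: Mapping[int, float]) -> int:
    keys = sorted(probs)
    return int(rng.choice(keys, p=np.array([probs[k] for k in keys])))


def simulate_reads(
    precursors: Sequence[PrecursorRecord],
    design: SimulationDesign,
    seed: int | None = None,
    n_reads: int | None = None,
) -> tuple[list[FastqRead], pd.DataFrame]:
    """Draw reads from mature regions with isomiR end offsets.

    Each read is the precursor substring covering the mature region
    shifted by ``offset5`` at the 5' end and ``offset3`` at the 3' end
    (positive = extension), both drawn from the design's offset
    distributions and constrained to stay within the precursor and to a
    15-35 nt read; at most one substitution is planted at
    ``mismatch_rate``. Ground truth is returned as a DataFrame and also
    embedded in each FASTQ comment.
    """
    if not precursors:
        raise ValueError("precursor set is empty")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n = design.library_size if n_reads is None else n_reads
    arms = [(pre, arm) for pre in precursors for arm in pre.mature_arms]
    reads: list[FastqRead] = []
    truth_rows = []
    for r in range(n):
        pre, arm = arms[int(rng.integers(len(arms)))]
        offset5 = offset3 = 0
        for _ in range(100):
            o5 = _sample_from(rng, design.offset5_probs)
            o3 = _sample_from(rng, design.offset3_probs)
            wstart, wend = arm.start - o5, arm.end + o3
            if 0 <= wstart < wend <= len(pre.sequence) and 15 <= wend - wstart <= 35:
                offset5, offset3 = o5, o3
                break
        wstart, wend = arm.start - offset5, arm.end + offset3
        seq = pre.sequence[wstart:wend]
        n_mismatches = 0
        if design.mismatch_rate > 0 and rng.random() < design.mismatch_rate:
            pos = int(rng.integers(len(seq)))
            new_base = str(rng.choice(_BASES[_BASES != seq[pos]]))
            seq = seq[:pos] + new_base + seq[pos + 1 :]
            n_mismatches = 1
        read_id = f"read{r + 1:06d}"
        comment = (
            f"precursor={pre.id} mature={arm.mature_id} "
            f"offset5={offset5} offset3={offset3} mismatches={n_mismatches}"
        )
        reads.append(FastqRead(read_id, seq, comment))
        truth_rows.append(
            (read_id, pre.id, arm.mature_id, offset5, offset3, n_mismatches)
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id",
            "precursor",
            "mature_id",
            "offset5",
            "offset3",
            "n_mismatches",
        ],
    )
    return reads, truth


def parse_read_truth(comment: str) -> dict:
    """Recover the ground-truth fields embedded in a FASTQ comment."""
    fields = dict(item.split("=", 1) for item in comment.split())
    return {
        "precursor": fields["precursor"],
        "mature_id": fields["mature"],
        "offset5": int(fields["offset5"]),
        "offset3": int(fields["offset3"]),
        "n_mismatches": int(fields["mismatches"]),
    }


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def truth_table(
    design: SimulationDesign, mirna_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Expected per-tissue means and class labels implied by a design.

    The first ``n_gradient_up`` miRNAs rise by ``gradient_step`` per
    tissue step, the next ``n_gradient_down`` fall by the same factor,
    and the remainder are null (constant ``baseline_mean``).
    """
    if mirna_ids is None:
        mirna_ids = [f"mir-{i + 1:04d}" for i in range(design.n_mirnas)]
    if len(mirna_ids) != design.n_mirnas:
        raise ValueError("mirna_ids length must equal n_mirnas")
    b, s = design.baseline_mean, design.gradient_step
    rows = []
    for i in range(design.n_mirnas):
        if i < design.n_gradient_up:
            rows.append((GRADIENT_UP, b, b * s, b * s * s))
        elif i < design.n_gradient_up + design.n_gradient_down:
            rows.append((GRADIENT_DOWN, b, b / s, b / (s * s)))
        else:
            rows.append((NULL, b, b, b))
    truth = pd.DataFrame(
        rows,
        index=pd.Index(mirna_ids, name="mirna_id"),
        columns=["class", "mean_normal", "mean_adjacent", "mean_tumor"],
    )
    return truth


def simulate_counts(
    design: SimulationDesign,
    mirna_ids: Sequence[str] | None = None,
    depth_factors: Mapping[str, float] | None = None,
):
    """Draw the miRNA x tissue count matrix from the design's Poisson means.

    Returns ``(CountMatrix, truth)``. Library sizes are the realized
    column totals, so normalizing a column to counts-per-million sums to
    exactly 10^6. ``depth_factors`` (tissue -> multiplier, default all 1)
    tilts sequencing depth per sample to exercise the normalization path.
    """
    from .records import CountMatrix  # local import to keep module load light

    truth = truth_table(design, mirna_ids)
    rng = np.random.default_rng(design.seed)
    means = truth[["mean_normal", "mean_adjacent", "mean_tumor"]].to_numpy()
    factors = np.array(
        [1.0 if depth_factors is None else float(depth_factors.get(t, 1.0)) for t in TISSUES]
    )
    if (factors <= 0).any():
        raise ValueError("depth factors must be positive")
    counts = rng.poisson(means * factors)
    frame = pd.DataFrame(counts, index=truth.index, columns=list(TISSUES))
    library_size = frame.sum(axis=0).clip(lower=1)
    return CountMatrix(frame, library_size), truth


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_qpcr(
    truth: pd.DataFrame,
    n_samples: int = 9,
    noise_sd: float = 0.1,
    seed: int = 0,
    targets: Sequence[str] | None = None,
    reference_id: str = "U6",
    reference_ct: float = 18.0,
    base_ct: float = 30.0,
) -> pd.DataFrame:
    """Emulate triplicate qRT-PCR of selected miRNAs with a U6 reference.

    Per sample and target the expected Ct is ``base_ct - log2(mean)`` for
    the tissue's expected expression, so Ct drops by exactly one cycle per
    doubling; the reference gene sits at a constant expected Ct. Gaussian
    noise of ``noise_sd`` cycles is added independently to every
    replicate well.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if targets is None:
        targets = list(truth.index)
    missing = [t for t in targets if t not in truth.index]
    if missing:
        raise ValueError(f"targets absent from truth table: {missing}")
    rng = np.random.default_rng(seed)
    rows = []
    for group in TISSUES:
        mean_col = f"mean_{group}"
        for j in range(n_samples):
            sample_id = f"{group}_{j + 1:02d}"
            for target in targets:
                expected = base_ct - math.log2(float(truth.loc[target, mean_col]))
                reps = expected + rng.normal(0.0, noise_sd, size=3)
                rows.append((sample_id, group, target, *np.round(reps, 6)))
            reps = reference_ct + rng.normal(0.0, noise_sd, size=3)
            rows.append((sample_id, group, reference_id, *np.round(reps, 6)))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "group", "target_id", "ct_rep1", "ct_rep2", "ct_rep3"],
    )
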