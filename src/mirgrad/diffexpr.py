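"""Two-library differential expression for pooled small RNA-seq counts.

The selection follows three steps: a reliability filter (drop a miRNA
only when BOTH libraries have <= ``min_count`` reads), an exact test of
the two counts under Poisson sampling, and a fold-change gate on
counts-per-million, with Benjamini-Hochberg control of the false
discovery rate across miRNAs in between.

The exact test is the Audic-Claverie conditional test: with library
sizes ``N_A`` and ``N_B`` and independent Poisson counts, the count in B
given ``x`` reads in A follows a negative binomial,

    Y | x  ~  NegBin(size = x + 1, prob = N_A / (N_A + N_B)),

whose pmf is ``P(Y=y|x) = (N_B/N_A)^y (x+y)! / (x! y! (1+N_B/N_A)^(x+y+1))``.
The two-sided p-value doubles the smaller of the two inclusive "as
extreme" tails, each taken under its own conditioning —
``P(Y >= y | x)`` and ``P(X >= x | y)`` — and caps at 1. By the
negative-binomial/binomial tail identity this equals the doubled-tail
exact binomial test of ``y`` successes in ``x + y`` trials at success
probability ``N_B/(N_A+N_B)`` (the law of one count given the total for
independent Poissons), which makes the statistic exactly symmetric under
exchanging the two libraries. Tails are evaluated in log space through
scipy, exact and overflow-free at counts far beyond 10^4.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DEConfig:
    """Thresholds of the three-step differential-expression selection.

    ``min_count`` — reliability cutoff; a miRNA is removed only when both
    compared libraries have <= min_count reads (strictly more than
    min_count on either side keeps it).
    ``q_threshold`` — BH false-discovery-rate cutoff (default 0.01).
    ``fc_threshold`` — minimum fold change in either direction (default 2).
    ``pseudocount_cpm`` — added to both CPM values in the ratio so a zero
    count on one side never divides by zero.
    """

    min_count: int = 10
    q_threshold: float = 0.01
    fc_threshold: float = 2.0
    pseudocount_cpm: float = 1.0

    def __post_init__(self) -> None:
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")
        if not (0 < self.q_threshold <= 1):
            raise ValueError("q_threshold must be in (0, 1]")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if self.pseudocount_cpm <= 0:
            raise ValueError("pseudocount_cpm must be positive")


def normalize_cpm(counts, library_size: float) -> np.ndarray:
    """Scale raw counts so the library total maps to 1,000,000.

    ``value_i = count_i * 1e6 / library_size``; when ``library_size`` is
    the column total, the normalized column sums to exactly 10^6.
    """
    counts = np.asarray(counts, dtype=float)
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    return counts * 1_000_000.0 / float(library_size)


def low_count_filter(x, y, min_count: int = 10):
    """Keep a miRNA unless BOTH libraries are at or below ``min_count``.

    Reliability rule for pooled designs: a pair like (3, 8) is removed at
    min_count=10 while (3, 12) is kept — only simultaneous low copy
    number marks a miRNA unreliable.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    keep = (x > min_count) | (y > min_count)
    return bool(keep) if keep.ndim == 0 else keep


def ac_pvalue(x, y, n_a: float, n_b: float):
    """Two-sided Audic-Claverie p-value for counts ``x`` (library A, size
    ``n_a``) and ``y`` (library B, size ``n_b``).

    ``p = min(1, 2 * min(P(Y >= y | x), P(X >= x | y)))`` with the
    conditional laws ``Y | x ~ NegBin(x + 1, n_a / (n_a + n_b))`` and
    ``X | y ~ NegBin(y + 1, n_b / (n_a + n_b))``; equivalently the
    doubled-tail exact binomial test of ``y`` out of ``x + y`` at
    probability ``n_b / (n_a + n_b)``. Symmetric in the two libraries.
    Accepts scalars or arrays (broadcast elementwise).
    """
    x_arr = np.asarray(x)
    y_arr = np.asarray(y)
    scalar = x_arr.ndim == 0 and y_arr.ndim == 0
    if (x_arr < 0).any() or (y_arr < 0).any():
        raise ValueError("counts must be non-negative")
    if not (
        np.allclose(x_arr, np.round(x_arr)) and np.allclose(y_arr, np.round(y_arr))
    ):
        raise ValueError("counts must be integers")
    if n_a <= 0 or n_b <= 0:
        raise ValueError("library sizes must be positive")
    x_arr = np.round(x_arr)
    y_arr = np.round(y_arr)
    total = x_arr + y_arr
    prob_b = n_b / (n_a + n_b)
    # inclusive tails of Y | total ~ Binomial(total, prob_b); identical to
    # the inclusive upper AC tails P(Y>=y|x) and P(X>=x|y)
    lower = stats.binom.cdf(y_arr, total, prob_b)
    upper = stats.binom.sf(y_arr - 1, total, prob_b)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return float(p) if scalar else p


def bh_fdr(p_values):
    """Benjamini-Hochberg step-up q-values, in the input order.

    ``q_(i) = min_{j >= i} (m / j) p_(j)``, clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = stats.false_discovery_control(p, method="bh")
    return float(q[0]) if scalar else q


def de_call(
    x,
    y,
    n_a: float,
    n_b: float,
    config: DEConfig = DEConfig(),
    mirna_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Full three-step DE selection between two libraries, vectorized.

    Returns one row per miRNA with raw counts, CPM values, fold change
    (B over A, pseudocounted), the exact-test p-value, the BH q-value
    (computed across the filtered miRNAs only, NaN for removed rows), the
    final call and its direction ('up' means higher in B).
    """
    x = pd.Series(x)
    y = pd.Series(y)
    if mirna_ids is not None:
        x.index = y.index = pd.Index(mirna_ids)
    elif not x.index.equals(y.index):
        raise ValueError("the two samples cover different miRNA id sets")
    if len(x) != len(y):
        raise ValueError("count vectors differ in length")

    cpm_a = normalize_cpm(x.to_numpy(), n_a)
    cpm_b = normalize_cpm(y.to_numpy(), n_b)
    pc = config.pseudocount_cpm
    fold_change = (cpm_b + pc) / (cpm_a + pc)
    log2_fc = np.log2(fold_change)

    kept = low_count_filter(x.to_numpy(), y.to_numpy(), config.min_count)
    p_value = ac_pvalue(x.to_numpy(), y.to_numpy(), n_a, n_b)
    q_value = np.full(len(x), np.nan)
    if kept.any():
        q_value[kept] = bh_fdr(p_value[kept])

    fc_extreme = np.maximum(fold_change, 1.0 / fold_change)
    called = kept & (q_value < config.q_threshold) & (fc_extreme >= config.fc_threshold)
    direction = np.where(called, np.where(log2_fc > 0, "up", "down"), "none")

    return pd.DataFrame(
        {
            "mirna_id": x.index,
            "x": x.to_numpy(),
            "y": y.to_numpy(),
            "cpm_a": cpm_a,
            "cpm_b": cpm_b,
            "fold_change": fold_change,
            "log2_fc": log2_fc,
            "p_value": p_value,
            "q_value": q_value,
            "kept": kept,
            "called": called,
            "direction": direction,
        }
    ).set_index("mirna_id", drop=False)


def compare_samples(matrix, sample_a: str, sample_b: str, config: DEConfig = DEConfig()):
    """DE table between two columns of a CountMatrix (B relative to A)."""
    return de_call(
        matrix.column(sample_a),
        matrix.column(sample_b),
        float(matrix.library_size[sample_a]),
        float(matrix.library_size[sample_b]),
        config,
    )
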