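"""Three-state gradient calling across normal -> adjacent -> tumor.

A miRNA is an up-gradient when it is a called DE (FDR and fold gates)
versus normal in BOTH the tumor and the adjacent comparison, with both
directions up, and its CPM rises strictly at each tissue step; the
down-gradient is symmetric. Ties in CPM break monotonicity ("gradually"
implies change at every step). The tumor-vs-adjacent comparison is not
required by default; ``strict`` mode additionally demands it be a called
DE in the same direction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

UP = "up_gradient"
DOWN = "down_gradient"
NONE = "none"


@dataclass(frozen=True)
class GradientCall:
    mirna_id: str
    cpm_normal: float
    cpm_adjacent: float
    cpm_tumor: float
    de_tumor_vs_normal: bool
    de_adjacent_vs_normal: bool
    gradient_class: str


def venn_partition(set_t: Iterable, set_a: Iterable):
    """Split the two normal-referenced DE sets into a disjoint partition.

    Returns ``(tumor_only, adjacent_only, shared)`` with
    ``tumor_only | shared == set_t`` and ``adjacent_only | shared == set_a``.
    """
    set_t = frozenset(set_t)
    set_a = frozenset(set_a)
    shared = set_t & set_a
    return set_t - shared, set_a - shared, shared


def _row(de, mirna_id: str) -> Mapping:
    """Accept a DE-table row as a Series/mapping and check its identity."""
    row_id = de["mirna_id"] if "mirna_id" in de else mirna_id
    if row_id != mirna_id:
        raise ValueError(f"DE row is for {row_id!r}, expected {mirna_id!r}")
    return de


def gradient_call(
    cpm_triple,
    de_tn,
    de_an,
    mirna_id: str | None = None,
    de_ta=None,
    strict: bool = False,
) -> GradientCall:
    """Classify one miRNA from its (normal, adjacent, tumor) CPM triple
    and its two normal-referenced DE rows.

    ``de_tn``/``de_an`` are rows of :func:`mirgrad.diffexpr.de_call`
    tables (or any mapping with ``called`` and ``direction``).
    """
    cpm_n, cpm_a, cpm_t = (float(v) for v in cpm_triple)
    if mirna_id is None:
        mirna_id = de_tn["mirna_id"] if "mirna_id" in de_tn else ""
    de_tn = _row(de_tn, mirna_id)
    de_an = _row(de_an, mirna_id)
    called_tn = bool(de_tn["called"])
    called_an = bool(de_an["called"])
    strict_ok_up = strict_ok_down = True
    if strict:
        if de_ta is None:
            raise ValueError("strict mode requires the tumor-vs-adjacent DE row")
        de_ta = _row(de_ta, mirna_id)
        strict_ok_up = bool(de_ta["called"]) and de_ta["direction"] == "up"
        strict_ok_down = bool(de_ta["called"]) and de_ta["direction"] == "down"

    label = NONE
    if called_tn and called_an:
        if (
            de_tn["direction"] == "up"
            and de_an["direction"] == "up"
            and cpm_n < cpm_a < cpm_t
            and strict_ok_up
        ):
            label = UP
        elif (
            de_tn["direction"] == "down"
            and de_an["direction"] == "down"
            and cpm_n > cpm_a > cpm_t
            and strict_ok_down
        ):
            label = DOWN
    return GradientCall(mirna_id, cpm_n, cpm_a, cpm_t, called_tn, called_an, label)


def gradient_table(
    cpm: pd.DataFrame,
    de_tn: pd.DataFrame,
    de_an: pd.DataFrame,
    de_ta: pd.DataFrame | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Gradient calls for every miRNA of a three-tissue CPM table.

    ``cpm`` must carry columns ``normal``, ``adjacent``, ``tumor``; the DE
    tables are :func:`mirgrad.diffexpr.de_call` outputs indexed by
    mirna_id (tumor-vs-normal and adjacent-vs-normal, plus
    tumor-vs-adjacent when ``strict``).
    """
    for col in ("normal", "adjacent", "tumor"):
        if col not in cpm.columns:
            raise ValueError(f"cpm table lacks column {col!r}")
    if not (cpm.index.equals(de_tn.index) and cpm.index.equals(de_an.index)):
        raise ValueError("CPM and DE tables cover different miRNA id sets")
    if strict and (de_ta is None or not cpm.index.equals(de_ta.index)):
        raise ValueError("strict mode requires a matching tumor-vs-adjacent table")
    rows = []
    for mirna_id in cpm.index:
        call = gradient_call(
            cpm.loc[mirna_id, ["normal", "adjacent", "tumor"]],
            de_tn.loc[mirna_id],
            de_an.loc[mirna_id],
            mirna_id=mirna_id,
            de_ta=None if de_ta is None else de_ta.loc[mirna_id],
            strict=strict,
        )
        rows.append(
            (
                call.mirna_id,
                call.cpm_normal,
                call.cpm_adjacent,
                call.cpm_tumor,
                call.de_tumor_vs_normal,
                call.de_adjacent_vs_normal,
                call.gradient_class,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "cpm_normal",
            "cpm_adjacent",
            "cpm_tumor",
            "de_tumor_vs_normal",
            "de_adjacent_vs_normal",
            "class",
        ],
    ).set_index("mirna_id", drop=False)


def log2_transform(values, pseudocount: float = 1.0) -> np.ndarray:
    """log2(value + pseudocount), the transform used before clustering
    or plotting normalized expression."""
    values = np.asarray(values, dtype=float)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (values < 0).any():
        raise ValueError("expression values must be non-negative")
    return np.log2(values + pseudocount)


def cpm_table(matrix) -> pd.DataFrame:
    """Counts-per-million for every column of a CountMatrix."""
    from .diffexpr import normalize_cpm

    return pd.DataFrame(
        {
            sample: normalize_cpm(
                matrix.column(sample).to_numpy(), float(matrix.library_size[sample])
            )
            for sample in matrix.sample_ids
        },
        index=matrix.counts.index,
    )
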