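"""Over-representation analysis of a target-gene list against gene sets.

A generic one-sided hypergeometric (Fisher) test against user-supplied
collections (GMT format), with BH correction across sets. The background
universe is always an explicit argument — no default is guessed, since
enrichment p-values are meaningless without a stated background.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr
from .io import _open_text


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets over an explicit background universe."""

    sets: Mapping[str, GeneSet]
    universe: frozenset

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("universe is empty")
        if not self.sets:
            raise ValueError("collection has no gene sets")
        for set_id, gs in self.sets.items():
            if not gs.members:
                raise ValueError(f"gene set {set_id!r} is empty")
            extra = gs.members - self.universe
            if extra:
                raise ValueError(
                    f"gene set {set_id!r} has members outside the universe: "
                    f"{sorted(extra)[:5]}"
                )


def read_gmt(path, universe: Iterable[str]) -> GeneSetCollection:
    """Load a GMT file (set_id, description, members...) over ``universe``.

    Members outside the universe are dropped with a warning; sets left
    empty are discarded.
    """
    universe = frozenset(universe)
    sets: dict[str, GeneSet] = {}
    dropped = 0
    with _open_text(path) as handle:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            members = frozenset(g for g in fields[2:] if g)
            inside = members & universe
            dropped += len(members - universe)
            if inside:
                sets[fields[0]] = GeneSet(fields[1] or fields[0], inside)
    if dropped:
        warnings.warn(f"{dropped} gene-set members outside the universe were dropped")
    return GeneSetCollection(sets, universe)


def hypergeom_ora(targets: Iterable[str], collection: GeneSetCollection) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``targets`` in
    every set of ``collection``.

    Per set: overlap ``k``, set size ``K``, target-list size ``n``,
    universe size ``N``, ``p = P(X >= k)`` for X ~ Hypergeom(N, K, n),
    and BH q-values across sets. Sorted ascending by p. Targets outside
    the universe are dropped with a warning.
    """
    targets = set(targets)
    if not targets:
        raise ValueError("empty target list")
    outside = targets - collection.universe
    if outside:
        warnings.warn(
            f"{len(outside)} target genes outside the universe were dropped: "
            f"{sorted(outside)[:5]}"
        )
        targets -= outside
    if not targets:
        raise ValueError("no target genes remain inside the universe")
    n = len(targets)
    N = len(collection.universe)
    rows = []
    for set_id in sorted(collection.sets):
        gene_set = collection.sets[set_id]
        K = len(gene_set.members)
        k = len(targets & gene_set.members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((set_id, gene_set.name, k, K, n, N, min(p, 1.0)))
    table = pd.DataFrame(
        rows, columns=["set_id", "name", "k", "K", "n", "N", "p_value"]
    )
    table["q_value"] = bh_fdr(table["p_value"].to_numpy())
    return table.sort_values(["p_value", "set_id"], kind="mergesort").reset_index(
        drop=True
    )


def intersect_gene_lists(*lists: Iterable[str]) -> list[str]:
    """Common genes of several prediction lists (sorted).

    Utility for the usual 'intersection of several target-prediction
    tools' step that precedes enrichment.
    """
    if not lists:
        raise ValueError("no gene lists supplied")
    common = set(lists[0])
    for other in lists[1:]:
        common &= set(other)
    return sorted(common)
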