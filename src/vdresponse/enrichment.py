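"""EASE-score gene-set over-representation testing.

The EASE score is a conservative variant of the one-sided Fisher exact
test: one gene is removed from the list/category overlap before taking
the hypergeometric upper tail, which penalizes categories supported by
a single gene (an overlap of 0 or 1 scores p = 1).  Following the EASE
convention, only over-representation is tested and pathway p-values
are reported unadjusted by default (BH adjustment available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust


@dataclass(frozen=True)
class EnrichmentRecord:
    """Contingency counts and p-values for one gene set."""

    set_id: str
    list_hits: int
    list_total: int
    pop_hits: int
    pop_total: int
    ease_p: float
    fisher_p: float


def _check_counts(list_hits: int, list_total: int, pop_hits: int, pop_total: int):
    if min(list_hits, list_total, pop_hits, pop_total) < 0:
        raise ValueError("counts must be non-negative")
    if list_total > pop_total or pop_hits > pop_total:
        raise ValueError("list/category cannot exceed the population")
    if list_hits > min(list_total, pop_hits):
        raise ValueError(
            f"list_hits={list_hits} exceeds min(list_total={list_total}, "
            f"pop_hits={pop_hits})"
        )


def fisher_upper_p(
    list_hits: int, list_total: int, pop_hits: int, pop_total: int
) -> float:
    """One-sided Fisher exact upper tail, P(X >= list_hits)."""
    _check_counts(list_hits, list_total, pop_hits, pop_total)
    return float(hypergeom.sf(list_hits - 1, pop_total, pop_hits, list_total))


def ease_score(
    list_hits: int, list_total: int, pop_hits: int, pop_total: int
) -> float:
    """EASE p-value: Fisher upper tail after removing one overlap gene.

    With 0 or 1 overlapping genes the penalized overlap is empty and
    the score is 1.
    """
    _check_counts(list_hits, list_total, pop_hits, pop_total)
    if list_hits <= 1:
        return 1.0
    return float(hypergeom.sf(list_hits - 2, pop_total, pop_hits, list_total))


def enrich_gene_sets(
    gene_list,
    gene_sets: dict[str, set[str]] | pd.DataFrame,
    population,
    p_thresh: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Over-representation of a gene list across gene sets.

    ``gene_sets`` maps set ids to gene-id collections, or is a
    two-column (set_id, gene_id) DataFrame.  ``population`` is the
    background (all assayed genes).  Returns one row per set with
    EASE p below ``p_thresh``, ascending by EASE p.
    """
    population = set(population)
    if not population:
        raise ValueError("empty background population")
    genes = set(gene_list) & population
    if isinstance(gene_sets, pd.DataFrame):
        gene_sets = {
            sid: set(grp["gene_id"])
            for sid, grp in gene_sets.groupby("set_id", sort=True)
        }
    rows = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & population
        if not members:
            continue
        k = len(genes & members)
        ease_p = ease_score(k, len(genes), len(members), len(population))
        fisher_p = fisher_upper_p(k, len(genes), len(members), len(population))
        rows.append(
            {
                "set_id": set_id,
                "list_hits": k,
                "list_total": len(genes),
                "pop_hits": len(members),
                "pop_total": len(population),
                "ease_p": ease_p,
                "fisher_p": fisher_p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "set_id", "list_hits", "list_total", "pop_hits", "pop_total",
            "ease_p", "fisher_p",
        ],
    )
    if adjust and len(out):
        out["ease_p_adj"] = bh_adjust(out["ease_p"].to_numpy())
        out = out[out["ease_p_adj"] < p_thresh]
    else:
        out = out[out["ease_p"] < p_thresh]
    return out.sort_values("ease_p", kind="stable").reset_index(drop=True)
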