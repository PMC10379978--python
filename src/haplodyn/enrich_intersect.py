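"""Term enrichment (hypergeometric over-representation) and set reporting.

Enrichment is the one-sided Fisher/hypergeometric upper-tail test of a gene
set of interest against a universe, BH-corrected across terms.  The
intersection helpers produce exclusive-region ("upset") cardinalities for
arbitrary named sets, ASE x network-connectivity fractions, and the
comparison of responsive ASE genes against an external gene list.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ValidationError, get_logger
from .ase_bias import round_half_up
from .diffexpr import bh_adjust

__all__ = [
    "fisher_enrich",
    "upset_counts",
    "ase_network_overlap",
    "external_list_overlap",
]

_log = get_logger("enrich")


def fisher_enrich(
    interest: Iterable[str],
    universe: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in ``interest``.

    For a term annotating K of the N universe genes, with n genes of
    interest of which k carry the term, p = P(X >= k), X ~
    Hypergeom(N, K, n).  Terms with no universe gene are skipped; q-values
    are BH across all tested terms; ``enriched`` flags q < alpha.
    """
    interest = set(interest)
    universe = set(universe)
    stray = interest - universe
    if stray:
        raise ValidationError(f"interest genes outside the universe: {sorted(stray)[:10]}")
    N, n = len(universe), len(interest)
    rows = []
    for term, genes in term_map.items():
        annotated = set(genes) & universe
        K = len(annotated)
        if K == 0:
            continue
        k = len(annotated & interest)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, n, K, N, min(p, 1.0)))
    result = pd.DataFrame(rows, columns=["term_id", "k", "n", "K", "N", "p_value"])
    if len(result):
        result["q_value"] = bh_adjust(result["p_value"].to_numpy())
        result["enriched"] = result["q_value"] < alpha
        result = result.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    else:
        result["q_value"] = []
        result["enriched"] = []
    return result


def upset_counts(sets: Mapping[str, Iterable[str]]) -> dict:
    """Exclusive-region cardinalities for every non-empty membership
    combination, plus per-set totals (upset-plot accounting)."""
    named = {name: set(s) for name, s in sets.items()}
    if len(named) < 2:
        raise ValidationError("upset_counts needs at least two sets")
    names = list(named)
    regions: dict[str, int] = {}
    all_items = set().union(*named.values())
    for item in all_items:
        membership = tuple(name for name in names if item in named[name])
        key = "&".join(membership)
        regions[key] = regions.get(key, 0) + 1
    return {
        "set_sizes": {name: len(named[name]) for name in names},
        "regions": regions,
        "union_size": len(all_items),
    }


def ase_network_overlap(
    ase_sets: Mapping[str, Iterable[str]],
    edge_counts: Mapping[str, int] | pd.Series,
    thresholds: Sequence[int] = (5, 50),
) -> pd.DataFrame:
    """Fraction of each ASE class meeting each connectivity tier.

    Genes absent from ``edge_counts`` (e.g. filtered before networking)
    count as zero edges.  Percentages half-up to two decimals.
    """
    if isinstance(edge_counts, pd.Series):
        edge_counts = edge_counts.to_dict()
    rows = []
    for name, genes in ase_sets.items():
        genes = set(genes)
        total = len(genes)
        row: dict[str, object] = {"ase_set": name, "n_genes": total}
        for t in thresholds:
            hit = sum(1 for g in genes if edge_counts.get(g, 0) >= t)
            row[f"n_ge_{t}"] = hit
            row[f"pct_ge_{t}"] = round_half_up(100.0 * hit / total) if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def external_list_overlap(
    ase_salt: Iterable[str],
    ase_drought: Iterable[str],
    external: Iterable[str],
) -> dict:
    """Three-way intersection of responsive ASE sets with an external gene
    list, with each stress overlap as a percentage of its ASE set."""
    salt, drought, ext = set(ase_salt), set(ase_drought), set(external)
    salt_hit = salt & ext
    drought_hit = drought & ext
    if ext and (salt or drought) and not salt_hit and not drought_hit:
        _log.warning(
            "external list shares no genes with either ASE set; id namespaces may differ"
        )
    report = upset_counts({"salt": salt, "drought": drought, "external": ext})
    report["salt_in_external"] = len(salt_hit)
    report["pct_salt_in_external"] = (
        round_half_up(100.0 * len(salt_hit) / len(salt)) if salt else 0.0
    )
    report["drought_in_external"] = len(drought_hit)
    report["pct_drought_in_external"] = (
        round_half_up(100.0 * len(drought_hit) / len(drought)) if drought else 0.0
    )
    return report
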