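"""Over-representation analysis with hypergeometric tests and Rich Factor.

Generic term enrichment of a selected gene/pair set against a universe: for
each term with K annotated members of which k are selected out of n draws
from a universe of N, the upper-tail hypergeometric p-value is
P(X >= k), BH-adjusted across all tested terms.  The Rich Factor is k / K —
the proportion of a term's annotated members that are selected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core_io import AnnotationMap
from .errors import DomainError
from .deg_calling import bh_adjust


def hypergeom_enrich(
    selected: set[str],
    universe: set[str],
    term_map: AnnotationMap,
) -> pd.DataFrame:
    """Test every term for over-representation of ``selected`` in ``universe``.

    Returns one row per term with overlap counts, upper-tail hypergeometric
    p-value, BH q-value across all tested terms, and rich_factor = overlap /
    annotated.  Only annotations inside the universe count.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        raise DomainError("selected set must be a subset of the universe")
    n_universe = len(universe)
    n_selected = len(selected)

    term_members: dict[str, set] = {}
    for gid, terms in term_map.entries.items():
        if gid in universe:
            for t in terms:
                term_members.setdefault(t, set()).add(gid)

    rows = []
    for term, members in sorted(term_members.items()):
        big_k = len(members)
        k = len(members & selected)
        p = float(hypergeom.sf(k - 1, n_universe, big_k, n_selected))
        rows.append(
            {
                "term_id": term,
                "term_label": term_map.term_names.get(term, term),
                "k_overlap": k,
                "K_annotated": big_k,
                "n_selected": n_selected,
                "N_universe": n_universe,
                "p_value": min(p, 1.0),
                "rich_factor": k / big_k if big_k else 0.0,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_label", "k_overlap", "K_annotated",
            "n_selected", "N_universe", "p_value", "rich_factor",
        ],
    )
    result["q_value"] = bh_adjust(result["p_value"].to_numpy()) if len(result) else []
    return result


def top_terms(results: pd.DataFrame, n: int = 20, q_cutoff: float = 0.05) -> pd.DataFrame:
    """Significant terms, best first.

    Filters q <= q_cutoff, sorts by ascending q, breaking ties by descending
    rich_factor then term_id, and truncates to ``n`` rows.
    """
    keep = results[results["q_value"] <= q_cutoff].copy()
    keep = keep.sort_values(
        ["q_value", "rich_factor", "term_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return keep.head(n).reset_index(drop=True)
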