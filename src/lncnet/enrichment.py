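"""Over-representation analysis of module genes against gene sets.

A generic hypergeometric test replaces web-service annotation lookups:
for a module of size ``n`` drawn from a universe of size ``N``, a gene
set with ``K`` members in the universe and ``x`` of them in the module
scores the upper tail P(X >= x) of Hypergeometric(N, K, n). Sets
overlapping the module in fewer than ``min_overlap`` genes (default 5)
are dropped before Benjamini-Hochberg adjustment, mirroring the common
display rule of reporting only categories containing at least five
differential genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection


class EnrichmentError(ValueError):
    pass


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise EnrichmentError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    module_genes,
    universe_genes,
    sets: GeneSetCollection,
    min_overlap: int = 5,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``module_genes`` in each set.

    Returns one row per retained set (overlap >= min_overlap) with
    columns ``overlap``, ``set_size`` (within the universe),
    ``module_size``, ``universe_size``, ``p`` and ``fdr``, sorted by p
    (ties by set name).
    """
    universe = set(universe_genes)
    module = set(module_genes)
    strays = module - universe
    if strays:
        raise EnrichmentError(
            f"module gene(s) outside the universe: {sorted(strays)[:10]}"
        )
    n_univ, n_mod = len(universe), len(module)
    rows = []
    for name, members in sets.sets.items():
        in_univ = set(members) & universe
        overlap = len(in_univ & module)
        if overlap < min_overlap:
            continue
        k = len(in_univ)
        p = float(stats.hypergeom.sf(overlap - 1, n_univ, k, n_mod))
        rows.append(
            {
                "set": name,
                "overlap": overlap,
                "set_size": k,
                "module_size": n_mod,
                "universe_size": n_univ,
                "p": min(1.0, max(p, np.nextafter(0, 1))),
            }
        )
    table = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "module_size",
                       "universe_size", "p"]
    )
    if table.empty:
        table["fdr"] = pd.Series(dtype=float)
        return table.set_index("set")
    table["fdr"] = bh_fdr(table["p"])
    return (
        table.sort_values(["p", "set"], kind="mergesort")
        .set_index("set")
    )
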