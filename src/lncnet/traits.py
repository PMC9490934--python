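"""Module-stage relationships and per-gene scores.

Traits are derived from the sample table either as a single numeric day
vector (the primary encoding: one signed correlation per module, as in
published module-stage heatmaps that report a single r such as -0.94) or
as one 0/1 indicator vector per stage. Module eigengenes are correlated
with each trait using Pearson's test (two-sided Student t on
t = r * sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom).

Per-gene scores:

* gene significance GS = |cor(gene expression, trait)|, with the p-value
  of that correlation (GS_p), later used to rank lncRNAs;
* module membership MM = |cor(gene expression, module eigengene)|, an
  intra-modular connectivity proxy.

Signed versions are kept alongside for reporting; thresholds such as
GS > 0.5 and MM > 0.9 act on the magnitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import EigengeneMatrix, ModuleAssignment


class TraitError(ValueError):
    """Trait encoding or alignment problem."""


@dataclass
class TraitDesign:
    """Per-sample trait vectors: ``vectors`` is traits x samples."""

    mode: str
    vectors: pd.DataFrame

    @property
    def primary(self) -> pd.Series:
        """The vector used for GS and key-module selection (first trait)."""
        return self.vectors.iloc[0]


def encode_traits(samples: pd.DataFrame, mode: str = "numeric_day") -> TraitDesign:
    """Encode sample days as trait vectors.

    ``numeric_day`` yields one vector of day values; ``stage_indicator``
    yields one 0/1 vector per distinct day (ascending day order).
    """
    days = samples["day"]
    if days.nunique() < 2:
        raise TraitError("need at least 2 distinct days")
    if mode == "numeric_day":
        vectors = pd.DataFrame([days.to_numpy(float)], index=["day"],
                               columns=samples.index)
    elif mode == "stage_indicator":
        rows = {
            f"day{d}": (days == d).astype(float).to_numpy()
            for d in sorted(days.unique())
        }
        vectors = pd.DataFrame(rows, index=samples.index).T
    else:
        raise TraitError(f"unknown trait mode {mode!r}")
    return TraitDesign(mode=mode, vectors=vectors)


def correlate_with_p(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided Student-t p-value (df = n - 2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise TraitError("vectors differ in length")
    if x.size < 3:
        raise TraitError("need at least 3 paired values")
    if x.std() == 0 or y.std() == 0:
        raise TraitError("constant vector in correlation")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    return r, float(res.pvalue)


def module_trait_table(
    eig: EigengeneMatrix, traits: TraitDesign
) -> pd.DataFrame:
    """(module, trait) -> (r, p) for every eigengene/trait pair."""
    if list(eig.eigengenes.columns) != list(traits.vectors.columns):
        raise TraitError("eigengene and trait sample orders differ")
    rows = []
    for m, e in eig.eigengenes.iterrows():
        for t, v in traits.vectors.iterrows():
            r, p = correlate_with_p(e.to_numpy(), v.to_numpy())
            rows.append({"module": m, "trait": t, "r": r, "p": p})
    return pd.DataFrame(rows).set_index(["module", "trait"])


def gene_scores(
    expr: pd.DataFrame,
    modules: ModuleAssignment,
    eig: EigengeneMatrix,
    trait: pd.Series,
) -> pd.DataFrame:
    """GS, GS_p and MM for every gene.

    Returns a frame indexed by gene with columns ``module``, ``GS``
    (absolute), ``GS_signed``, ``GS_p``, ``MM`` (absolute, vs the gene's
    own module; 0 for unassigned genes), ``MM_signed``, and one
    ``MM_<module>`` column per module.
    """
    x = expr.to_numpy()
    n = x.shape[1]
    if list(expr.columns) != list(trait.index):
        raise TraitError("expression and trait sample orders differ")

    def cor_rows(mat: np.ndarray, v: np.ndarray) -> np.ndarray:
        vz = v - v.mean()
        vden = np.sqrt((vz**2).sum())
        mz = mat - mat.mean(axis=1, keepdims=True)
        mden = np.sqrt((mz**2).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (mz @ vz) / (mden * vden)
        return np.nan_to_num(np.clip(r, -1.0, 1.0))

    sd = x.std(axis=1)
    if (sd == 0).any():
        warnings.warn("constant gene(s): GS set to 0")
    gs_signed = cor_rows(x, trait.to_numpy(float))
    with np.errstate(divide="ignore"):
        t = gs_signed * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - gs_signed**2))
    gs_p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    gs_p = np.where(np.abs(gs_signed) >= 1.0, 0.0, gs_p)

    out = pd.DataFrame(
        {
            "module": modules.labels.reindex(expr.index),
            "GS": np.abs(gs_signed),
            "GS_signed": gs_signed,
            "GS_p": gs_p,
        },
        index=expr.index,
    )
    mm_cols = {}
    for m in modules.modules:
        e = eig.eigengenes.loc[m].to_numpy()
        mm_cols[f"MM_{m}"] = cor_rows(x, e)
    mm = pd.DataFrame(mm_cols, index=expr.index)
    own = out["module"].to_numpy()
    mm_signed = np.zeros(len(out))
    for m in modules.modules:
        mask = own == m
        mm_signed[mask] = mm.loc[mask, f"MM_{m}"]
    out["MM"] = np.abs(mm_signed)
    out["MM_signed"] = mm_signed
    return pd.concat([out, mm.abs()], axis=1)


def gs_mm_relation(scores: pd.DataFrame, module: str) -> tuple[float, float]:
    """Correlation (r, p) between GS and MM over one module's genes."""
    sub = scores[scores["module"] == module]
    if len(sub) < 3:
        raise TraitError(f"module {module} has fewer than 3 scored genes")
    return correlate_with_p(sub["GS"].to_numpy(), sub["MM"].to_numpy())


def select_key_module(
    table: pd.DataFrame, sizes: dict[str, int], trait: str | None = None
) -> str:
    """Module with the largest |r| against the (primary) trait.

    Ties break by larger module size, then by label order.
    """
    if table.empty:
        raise TraitError("empty module-trait table")
    sub = table.reset_index()
    if trait is not None:
        sub = sub[sub["trait"] == trait]
        if sub.empty:
            raise TraitError(f"trait {trait!r} not in table")
    else:
        sub = sub[sub["trait"] == sub["trait"].iloc[0]]
    sub = sub.assign(
        abs_r=sub["r"].abs(),
        size=sub["module"].map(lambda m: sizes.get(m, 0)),
        rank=sub["module"].map(lambda m: int(str(m)[1:]) if str(m)[1:].isdigit() else 0),
    )
    sub = sub.sort_values(["abs_r", "size", "rank"],
                          ascending=[False, False, True], kind="mergesort")
    return str(sub["module"].iloc[0])
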