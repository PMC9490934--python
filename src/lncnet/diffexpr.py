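"""Differential probeset selection and probe-to-symbol collapse.

Probesets are tested per time-point comparison (baseline day vs test day)
with a two-sided two-sample t-test on log2 intensities, and filtered on
unadjusted p-value and absolute fold change (defaults p < 0.05, FC > 2,
FC computed as 2^|mean log2 difference|). Passing probesets from all
comparisons are united, collapsed to gene symbols (keeping, per symbol,
the probe with the largest maximal |log2 FC| across comparisons) and
split by biotype into the differential lncRNA and mRNA universes that the
network stage consumes.

The per-comparison test is Student's pooled-variance t: with 2-4
replicates per stage the Welch-Satterthwaite approximation is badly
conservative (its true size at 3 vs 3 normal samples is ~0.035 at a
nominal 0.05), whereas the pooled test is exact when the two groups
share a variance — which holds for log-scale intensities of the same
gene across nearby time points. A standalone :func:`welch_t` is provided
for unequal-variance comparisons. P-values are left unadjusted within a
comparison; the selection criterion is a plain per-gene p threshold.

Also provides the 2^(-ddCt) relative-expression formula used to express
qPCR validation measurements against a reference gene and control
condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class DesignError(ValueError):
    """Comparison impossible with the given samples/annotation."""


@dataclass
class DEThresholds:
    """Selection thresholds: p_cut on the unadjusted p-value, fc_cut on the
    absolute fold change (strict inequalities, so FC exactly 2 fails)."""

    p_cut: float = 0.05
    fc_cut: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_cut < 1.0:
            raise ValueError("p_cut must be in (0, 1)")
        if self.fc_cut < 1.0:
            raise ValueError("fc_cut must be >= 1")


@dataclass
class DEUniverse:
    """Union of differential probesets across comparisons, collapsed to
    symbols and split by biotype."""

    de_lncrna: set[str]
    de_mrna: set[str]
    probe_of_symbol: dict[str, str] = field(default_factory=dict)
    n_probes_lncrna: int = 0
    n_probes_mrna: int = 0

    @property
    def symbols(self) -> set[str]:
        return self.de_lncrna | self.de_mrna


def welch_t(group_a, group_b) -> tuple[float, float]:
    """Two-sided Welch t-test; returns (t, p).

    Degenerate conventions: both groups constant and equal -> (0, 1);
    constant with different means -> (+-inf, 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DesignError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def fold_change_log2(group_a_log2, group_b_log2) -> tuple[float, float]:
    """log2 fold change (mean B - mean A) and absolute fold change
    2^|log2 FC| — the geometric-mean ratio on the raw scale."""
    a = np.asarray(group_a_log2, dtype=float)
    b = np.asarray(group_b_log2, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DesignError("fold change needs non-empty groups")
    log2_fc = float(b.mean() - a.mean())
    return log2_fc, float(2.0 ** abs(log2_fc))


def differential_probesets(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    baseline_day: int,
    test_day: int,
    thresholds: DEThresholds | None = None,
) -> pd.DataFrame:
    """Per-gene DE table for one baseline-vs-test-day comparison.

    Returns a frame indexed by gene id with columns ``log2_fc``,
    ``fold_change`` (absolute), ``t``, ``p_value`` and ``passes``.
    """
    th = thresholds or DEThresholds()
    days = samples["day"]
    cols_a = samples.index[days == baseline_day].intersection(expr.columns)
    cols_b = samples.index[days == test_day].intersection(expr.columns)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise DesignError(
            f"comparison day {baseline_day} vs {test_day} needs >= 2 replicates "
            f"per day (got {len(cols_a)} and {len(cols_b)})"
        )
    a = expr[cols_a].to_numpy()
    b = expr[cols_b].to_numpy()
    log2_fc = b.mean(axis=1) - a.mean(axis=1)
    abs_fc = 2.0 ** np.abs(log2_fc)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    # degenerate rows: both groups constant
    both_const = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    if both_const.any():
        equal = both_const & (log2_fc == 0)
        t = np.where(equal, 0.0, t)
        p = np.where(equal, 1.0, p)
        differ = both_const & (log2_fc != 0)
        t = np.where(differ, np.sign(-log2_fc) * np.inf, t)
        p = np.where(differ, 0.0, p)
    passes = (p < th.p_cut) & (abs_fc > th.fc_cut)
    return pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "fold_change": abs_fc,
            "t": t,
            "p_value": p,
            "passes": passes,
        },
        index=expr.index,
    )


def unite_de(
    results: dict[tuple[int, int], pd.DataFrame],
    annotation: pd.DataFrame,
) -> DEUniverse:
    """Unite passing probesets across comparisons and collapse to symbols.

    Per symbol the representative probe is the one with the largest
    maximal |log2 FC| over all comparisons (ties by probe id).
    """
    if not results:
        raise DesignError("need at least one comparison")
    passing: set[str] = set()
    best_fc: dict[str, float] = {}
    for table in results.values():
        hits = table.index[table["passes"]]
        passing.update(hits)
        fc = table["log2_fc"].abs()
        for g in table.index:
            v = float(fc.loc[g])
            if v > best_fc.get(g, -1.0):
                best_fc[g] = v
    missing = sorted(passing - set(annotation.index))
    if missing:
        raise DesignError(f"annotation missing passing gene(s): {', '.join(missing)}")

    n_lnc = sum(annotation.loc[g, "biotype"] == "lncRNA" for g in passing)
    n_mrna = len(passing) - n_lnc

    chosen: dict[str, str] = {}  # symbol -> probe
    for g in sorted(passing):
        sym = annotation.loc[g, "symbol"]
        cur = chosen.get(sym)
        if cur is None or best_fc[g] > best_fc[cur]:
            chosen[sym] = g
    de_lnc = {s for s, g in chosen.items() if annotation.loc[g, "biotype"] == "lncRNA"}
    de_mrna = {s for s, g in chosen.items() if annotation.loc[g, "biotype"] == "mRNA"}
    return DEUniverse(
        de_lncrna=de_lnc,
        de_mrna=de_mrna,
        probe_of_symbol=chosen,
        n_probes_lncrna=n_lnc,
        n_probes_mrna=n_mrna,
    )


def ddct_relative_expression(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative qPCR expression by the 2^(-ddCt) method.

    ddCt = (Ct_target,test - Ct_ref,test) - (Ct_target,ctrl - Ct_ref,ctrl).
    """
    ddct = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
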