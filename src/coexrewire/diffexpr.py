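"""Per-probe direction of expression in MCI and AD relative to NC.

Each retained probe is tested with a two-sided Welch (unequal-variance)
t-test against the NC group, p-values are FDR-adjusted across the retained
probes within each contrast, and a display string is formed by the table
conventions used for blood-expression summaries here:

* adjusted p <= 0.1           -> direction alone (``Up`` / ``Down``)
* 0.1 < adjusted p <= 0.75    -> direction plus the p-value
* adjusted p > 0.75           -> ``-`` (no reliable direction, either way)
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import LabeledDataset

logger = logging.getLogger("coexrewire")

REFERENCE = "NC"
CONTRASTS = ("MCI", "AD")

DASH_ABOVE = 0.75  # adjusted p above this -> "-"
SHOW_P_ABOVE = 0.1  # adjusted p above this (and <= DASH_ABOVE) -> p printed


def welch_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Welch t-test with Welch-Satterthwaite degrees of freedom.

    Two constant, equal groups carry no evidence either way; that degenerate
    case returns (0, 1) with a warning instead of NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_test needs at least 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            logger.warning("both groups constant and equal: p set to 1")
            return 0.0, 1.0
        return np.inf if a.mean() > b.mean() else -np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bh_adjust(pvals, method: str = "fdr_bh") -> np.ndarray:
    """Step-up FDR adjustment (Benjamini-Hochberg by default).

    ``method`` may be ``fdr_bh`` or ``fdr_by``.  Input order is preserved.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("fdr_bh", "fdr_by"):
        raise ValueError(f"unsupported adjustment method {method!r}")
    return multipletests(p, method=method)[1]


def _display(direction: str, p_adj: float) -> str:
    if p_adj > DASH_ABOVE:
        return "-"
    if p_adj > SHOW_P_ABOVE:
        return f"{direction}, p = {p_adj:.3g}"
    return direction


def direction_table(
    dataset: LabeledDataset, fdr_method: str = "fdr_bh"
) -> pd.DataFrame:
    """Directions and FDR-adjusted Welch p-values for MCI and AD vs NC.

    Returns a probe-indexed DataFrame with, per contrast, the raw direction
    (sign of the mean difference on the dataset's scale), the adjusted p,
    and the display string.
    """
    present = dataset.states_present()
    for state in (REFERENCE, *CONTRASTS):
        if state not in present:
            raise ValueError(f"state {state} absent from the dataset")
    vals = dataset.matrix.values
    ref_cols = dataset.samples_for(REFERENCE)
    out = pd.DataFrame(index=vals.index)
    for cond in CONTRASTS:
        cond_cols = dataset.samples_for(cond)
        raw = np.array(
            [
                welch_test(vals.loc[probe, cond_cols], vals.loc[probe, ref_cols])[1]
                for probe in vals.index
            ]
        )
        p_adj = bh_adjust(raw, method=fdr_method)
        diff = vals[cond_cols].mean(axis=1) - vals[ref_cols].mean(axis=1)
        direction = np.where(diff >= 0, "Up", "Down")
        key = cond.lower()
        out[f"{key}_direction"] = direction
        out[f"{key}_p_adj"] = p_adj
        out[f"{key}_display"] = [
            _display(d, p) for d, p in zip(direction, p_adj)
        ]
    return out


def write_direction_table(table: pd.DataFrame, path, gene_labels=None) -> None:
    """Emit the per-probe direction table as TSV."""
    out = table.copy()
    out.insert(0, "gene_label", pd.Series(gene_labels) if gene_labels is not None else out.index)
    cols = [
        "gene_label",
        "mci_direction",
        "mci_display",
        "ad_direction",
        "ad_display",
        "mci_p_adj",
        "ad_p_adj",
    ]
    out[cols].to_csv(path, sep="\t", index_label="probe")
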