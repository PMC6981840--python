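"""Diagnosis merging, log-scale reversal, and the two-stage probe filter.

The cascade mirrors the standard genefilter-style pre-selection for blood
microarray data: intensities are first de-logged back to the linear scale,
probes are kept when their coefficient of variation lies in a window
(default [0.7, 10]) and when at least a minimum fraction of samples
(default 20%) exceeds an absolute intensity cut (default 100), and the
survivors are then screened by a one-way ANOVA across the diagnostic groups
(default keep p < 0.1).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import LINEAR, LOG2, STATES, ExpressionMatrix, LabeledDataset

logger = logging.getLogger("coexrewire")

DIAGNOSIS_COLUMNS = ["SubjectID", "ExamDate", "Diagnosis"]

_SAMPLE_ID_RE = re.compile(r"^(?P<subject>.+)_(?P<date>\d{8})$")


def load_diagnosis_table(path) -> pd.DataFrame:
    """Read a diagnosis CSV (SubjectID, ExamDate, Diagnosis) and validate it."""
    table = pd.read_csv(path, dtype=str)
    missing = [c for c in DIAGNOSIS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"diagnosis table {path} lacks columns {missing}")
    return validate_diagnosis_table(table)


def validate_diagnosis_table(table: pd.DataFrame) -> pd.DataFrame:
    if table.empty:
        raise ValueError("diagnosis table is empty")
    bad = sorted(set(table["Diagnosis"].unique()) - set(STATES))
    if bad:
        raise ValueError(f"unknown diagnosis labels: {bad} (expected {list(STATES)})")
    out = table.copy()
    parsed = pd.to_datetime(out["ExamDate"], errors="coerce", format="ISO8601")
    if parsed.isna().any():
        row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise ValueError(
            f"unparseable ExamDate {out['ExamDate'].iloc[row]!r} in diagnosis row {row}"
        )
    out["ExamDate"] = parsed
    return out


def sample_meta_from_ids(sample_ids) -> pd.DataFrame:
    """Parse ``<subject>_<YYYYMMDD>`` sample IDs into per-sample metadata.

    Returns a DataFrame with columns ``sample, subject, collection_date``.
    """
    rows = []
    for sid in sample_ids:
        m = _SAMPLE_ID_RE.match(str(sid))
        if not m:
            raise ValueError(
                f"sample ID {sid!r} does not follow the <subject>_<YYYYMMDD> convention"
            )
        rows.append((sid, m["subject"], pd.Timestamp(m["date"])))
    return pd.DataFrame(rows, columns=["sample", "subject", "collection_date"])


def assign_diagnosis(sample_meta: pd.DataFrame, diagnoses: pd.DataFrame) -> pd.Series:
    """Assign each sample the diagnosis given on or nearest to its draw date.

    Ties in date distance are broken toward the earlier exam record, so the
    merge is deterministic.  Samples whose subject has no diagnosis record
    are dropped (and logged), not errors.
    """
    diagnoses = validate_diagnosis_table(diagnoses)
    merged = sample_meta.merge(
        diagnoses, left_on="subject", right_on="SubjectID", how="left"
    )
    dropped = merged[merged["Diagnosis"].isna()]["sample"].unique().tolist()
    if dropped:
        logger.warning(
            "dropping %d sample(s) with no diagnosis record: %s",
            len(dropped),
            dropped[:10],
        )
    merged = merged.dropna(subset=["Diagnosis"])
    merged = merged.assign(
        _dist=(merged["ExamDate"] - merged["collection_date"]).abs()
    ).sort_values(["sample", "_dist", "ExamDate"], kind="mergesort")
    best = merged.groupby("sample", sort=False).first()
    labels = best["Diagnosis"]
    # preserve the input sample order
    order = [s for s in sample_meta["sample"] if s in labels.index]
    return labels.reindex(order).rename("diagnosis")


def delog(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Reverse the RMA log2 scaling: every value x becomes 2**x."""
    if matrix.scale != LOG2:
        raise ValueError(
            "delog expects a log2-scale matrix; refusing to exponentiate twice"
        )
    return ExpressionMatrix(np.exp2(matrix.values), scale=LINEAR)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the two-stage probe filter (linear-scale intensities)."""

    cv_min: float = 0.7
    cv_max: float = 10.0
    intensity_cut: float = 100.0
    min_frac: float = 0.2
    anova_alpha: float = 0.1
    #: run the ANOVA stage on log2 values instead of linear intensities
    anova_on_log2: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.cv_min < self.cv_max:
            raise ValueError("need 0 < cv_min < cv_max")
        if self.intensity_cut <= 0:
            raise ValueError("intensity_cut must be > 0")
        if not 0 < self.min_frac <= 1:
            raise ValueError("min_frac must be in (0, 1]")
        if not 0 < self.anova_alpha < 1:
            raise ValueError("anova_alpha must be in (0, 1)")


@dataclass
class FilterReport:
    n_in: int
    n_stage1: int
    n_stage2: int
    table: pd.DataFrame = field(repr=False)  # probe-indexed per-stage stats

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="probe")


def filter_variation(
    matrix: ExpressionMatrix, cfg: FilterConfig
) -> tuple[list[str], pd.DataFrame]:
    """Stage 1: CV window plus minimum fraction above an intensity cut.

    CV uses the sample (n-1) standard deviation pooled over all samples.
    Probes with mean 0 have undefined CV and are excluded with a flag.
    """
    if matrix.scale != LINEAR:
        raise ValueError("variation/intensity filter operates on the linear scale")
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples to compute a CV")
    vals = matrix.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, np.nan)
    frac = (vals > cfg.intensity_cut).mean(axis=1)
    cv_ok = (cv >= cfg.cv_min) & (cv <= cfg.cv_max) & np.isfinite(cv)
    frac_ok = frac >= cfg.min_frac
    keep = cv_ok & frac_ok
    zero_mean = mean == 0
    if zero_mean.any():
        logger.warning("%d probe(s) with mean 0 excluded (CV undefined)", zero_mean.sum())
    stats_df = pd.DataFrame(
        {
            "cv": cv,
            "frac_above_cut": frac,
            "pass_stage1": keep,
        },
        index=matrix.values.index,
    )
    kept = [p for p, k in zip(matrix.probes, keep) if k]
    return kept, stats_df


def _anova_pvalues(vals: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Vectorised per-row one-way fixed-effects ANOVA p-values."""
    n_total = sum(g.size for g in groups)
    k = len(groups)
    grand = vals.mean(axis=1)
    ssb = np.zeros(vals.shape[0])
    ssw = np.zeros(vals.shape[0])
    for g in groups:
        sub = vals[:, g]
        m = sub.mean(axis=1)
        ssb += g.size * (m - grand) ** 2
        ssw += ((sub - m[:, None]) ** 2).sum(axis=1)
    dfb, dfw = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    p = np.empty(vals.shape[0])
    ok = ssw > 0
    p[ok] = stats.f.sf(f[ok], dfb, dfw)
    # degenerate rows: no within-group variance
    degenerate = ~ok
    p[degenerate & (ssb > 0)] = 0.0  # groups differ with zero noise
    flat = degenerate & (ssb == 0)
    p[flat] = 1.0  # identical everywhere: no evidence of group differences
    if flat.any():
        logger.warning("%d probe(s) constant across all groups: ANOVA p set to 1", flat.sum())
    return p


def filter_anova(
    matrix: ExpressionMatrix, labels: pd.Series, alpha: float
) -> tuple[list[str], pd.Series]:
    """Stage 2: keep probes with one-way ANOVA p < alpha across the groups."""
    labels = labels.reindex(matrix.samples)
    present = [s for s in STATES if (labels == s).any()]
    groups = []
    for state in present:
        idx = np.flatnonzero((labels == state).to_numpy())
        if idx.size < 2:
            raise ValueError(f"state {state} has fewer than 2 samples")
        groups.append(idx)
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    p = _anova_pvalues(matrix.values.to_numpy(dtype=float), groups)
    pvals = pd.Series(p, index=matrix.values.index, name="anova_p")
    kept = [probe for probe, pv in pvals.items() if pv < alpha]
    return kept, pvals


def run_filter_cascade(
    matrix: ExpressionMatrix, labels: pd.Series, cfg: FilterConfig | None = None
) -> tuple[LabeledDataset, FilterReport]:
    """De-log, then variation/intensity filter, then ANOVA on the survivors.

    Returns the surviving probes as a linear-scale labelled dataset plus a
    per-probe report.  Probe order is preserved from the input.
    """
    cfg = cfg or FilterConfig()
    labeled_samples = [s for s in matrix.samples if s in labels.index and pd.notna(labels.get(s))]
    matrix = matrix.subset_samples(labeled_samples)
    linear = delog(matrix) if matrix.scale == LOG2 else matrix

    stage1, table = filter_variation(linear, cfg)
    table["anova_p"] = np.nan
    table["pass_stage2"] = False
    if stage1:
        anova_input = (matrix if cfg.anova_on_log2 else linear).subset_probes(stage1)
        stage2, pvals = filter_anova(anova_input, labels, cfg.anova_alpha)
        table.loc[stage1, "anova_p"] = pvals
        table.loc[stage2, "pass_stage2"] = True
    else:
        stage2 = []
    if not stage2:
        logger.warning("filter cascade left zero surviving probes")
    report = FilterReport(
        n_in=matrix.n_probes, n_stage1=len(stage1), n_stage2=len(stage2), table=table
    )
    survivors = ExpressionMatrix(linear.values.loc[stage2], scale=LINEAR)
    dataset = LabeledDataset(survivors, labels.reindex(survivors.samples))
    return dataset, report
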