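"""Core in-memory containers shared across the pipeline.

Expression values travel as a probes x samples :class:`pandas.DataFrame`
wrapped in :class:`ExpressionMatrix`, which carries an explicit scale flag so
that the log-reversal step cannot be applied twice (RMA output is log2; the
correlation and filtering calculations run on the linear intensity scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Diagnostic states, in canonical order. NC is the reference condition.
STATES = ("NC", "MCI", "AD")

LOG2 = "log2"
LINEAR = "linear"


@dataclass
class ExpressionMatrix:
    """Probes x samples intensity matrix with an explicit scale flag.

    Parameters
    ----------
    values
        DataFrame indexed by probe ID with sample IDs as columns.
    scale
        Either ``"log2"`` (RMA output) or ``"linear"`` (de-logged intensity).
    """

    values: pd.DataFrame
    scale: str = LOG2

    def __post_init__(self) -> None:
        if self.scale not in (LOG2, LINEAR):
            raise ValueError(f"scale must be 'log2' or 'linear', got {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe IDs: {dups[:5]}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def probes(self) -> list[str]:
        return [str(p) for p in self.values.index]

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(probes)], self.scale)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], self.scale)


@dataclass
class LabeledDataset:
    """An expression matrix plus one diagnostic label per sample."""

    matrix: ExpressionMatrix
    labels: pd.Series = field(repr=False)  # sample ID -> state

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(str)
        missing = [s for s in self.matrix.samples if s not in self.labels.index]
        if missing:
            raise ValueError(f"samples without a label: {missing[:5]}")
        bad = sorted(set(self.labels.unique()) - set(STATES))
        if bad:
            raise ValueError(f"unknown diagnosis labels: {bad}")
        # keep labels aligned to matrix column order
        self.labels = self.labels.reindex(self.matrix.samples)

    def samples_for(self, state: str) -> list[str]:
        return [s for s, lab in self.labels.items() if lab == state]

    def states_present(self) -> list[str]:
        present = set(self.labels.unique())
        return [s for s in STATES if s in present]
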