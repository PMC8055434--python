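"""Labelled trial datasets of windowed burst features.

A trial dataset ``S = ((S_1, L_1), ..., (S_N, L_N))`` pairs each trial's
feature matrix (windows x variables, here ERS″ values) with its class
label.  The per-trial summary used for classifier training is the
positive peak of each variable over the trial's windows — the burst
signature of the trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TrialDataset", "trial_peak_vector"]


def trial_peak_vector(matrix: pd.DataFrame) -> np.ndarray:
    """Per-variable positive burst peak (max over windows) of one trial."""
    return matrix.max(axis=0).to_numpy(dtype=float)


@dataclass
class TrialDataset:
    """Labelled trials with consistent feature columns.

    ``trials[i]`` is a (windows x variables) DataFrame indexed by window
    end time (ms); ``labels[i]`` is the trial's class label.
    """

    trials: list[pd.DataFrame]
    labels: np.ndarray
    participant: str | None = None
    classes: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.trials) != len(self.labels):
            raise ValueError("trials and labels lengths differ")
        if self.trials:
            cols = list(self.trials[0].columns)
            for k, t in enumerate(self.trials):
                if list(t.columns) != cols:
                    raise ValueError(f"trial {k} has inconsistent variable columns")
        if not self.classes:
            self.classes = tuple(sorted(np.unique(self.labels).tolist()))

    @property
    def variables(self) -> list[str]:
        return list(self.trials[0].columns) if self.trials else []

    def label_matrix(self) -> np.ndarray:
        """One-hot label rows L_i = (l_iC1, ..., l_iCk)."""
        idx = {c: j for j, c in enumerate(self.classes)}
        out = np.zeros((len(self.labels), len(self.classes)), dtype=int)
        for i, lab in enumerate(self.labels):
            out[i, idx[int(lab)]] = 1
        return out

    def to_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) for training: per-trial peak vectors and labels."""
        X = np.vstack([trial_peak_vector(t) for t in self.trials])
        return X, self.labels.copy()
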