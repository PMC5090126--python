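"""The samples x variables data matrix that every pipeline stage consumes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DataMatrix"]


def _check_unique(labels, axis: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {axis} id: {lab!r}")
        seen.add(lab)


@dataclass
class DataMatrix:
    """A numeric samples x variables table, possibly with missing entries.

    Rows are samples (observations, e.g. biological replicates), columns are
    variables (e.g. metabolites). Missing measurements are NaN. This is the
    entry point of the correlation-network pipeline: correlations are computed
    between columns across rows.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric frame; index = sample ids, columns = variable ids.
    condition_label : str, optional
        Free-text label of the experimental condition (e.g. "control",
        "hypoxia"); carried through for reporting only.
    """

    values: pd.DataFrame
    condition_label: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique(list(self.values.index), "sample")
        _check_unique(list(self.values.columns), "variable")
        if self.n_samples < 3:
            raise ValueError(
                f"need at least 3 samples for correlation, got {self.n_samples}"
            )
        if self.n_variables < 2:
            raise ValueError(
                f"need at least 2 variables, got {self.n_variables}"
            )
        # coerce everything numeric; unparseable cells become NaN
        self.values = self.values.apply(pd.to_numeric, errors="coerce")
        self.values = self.values.astype(float)

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def variable_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        cond = f", condition={self.condition_label!r}" if self.condition_label else ""
        return (
            f"DataMatrix({self.n_samples} samples x "
            f"{self.n_variables} variables{cond})"
        )
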