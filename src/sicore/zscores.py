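"""Regulator x target z-score matrices.

The primary input is a real-valued matrix of normalized z-scores: entry
``(r, t)`` quantifies how strongly target ``t`` (e.g. a protein read out on a
reverse phase protein array) deviates from its resting level when regulator
``r`` (e.g. a transfected miRNA mimic) is active.  Positive scores mean the
level went up, negative scores that it went down.  Missing measurements (failed
spots) are allowed and simply produce no edge downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

#: Accepted string markers for a missing measurement in TSV input.
MISSING_MARKERS = ("NA", "")

ORIENTATIONS = ("regulators-as-rows", "targets-as-rows")


@dataclass
class ZScoreMatrix:
    """A regulator x target matrix of normalized z-scores.

    Canonical orientation is regulators on the rows and targets on the
    columns.  ``values`` is a float array; missing entries are ``nan``.
    """

    regulator_ids: list[str]
    target_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.regulator_ids = [str(x) for x in self.regulator_ids]
        self.target_ids = [str(x) for x in self.target_ids]
        self.values = np.asarray(self.values, dtype=float)
        for name, labels in (("regulator", self.regulator_ids),
                             ("target", self.target_ids)):
            dup = _first_duplicate(labels)
            if dup is not None:
                raise ValueError(f"duplicate {name} label: {dup!r}")
        if self.values.shape != (len(self.regulator_ids), len(self.target_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.regulator_ids)} regulators x {len(self.target_ids)} targets"
            )
        finite = np.isfinite(self.values) | np.isnan(self.values)
        if not finite.all():
            i, j = map(int, np.argwhere(~finite)[0])
            raise ValueError(
                f"non-finite z-score at row {self.regulator_ids[i]!r}, "
                f"column {self.target_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.regulator_ids,
                            columns=self.target_ids)

    def transposed(self) -> "ZScoreMatrix":
        return ZScoreMatrix(list(self.target_ids), list(self.regulator_ids),
                            self.values.T.copy())

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "regulator"
        df.to_csv(path, sep="\t", na_rep="NA")


def _first_duplicate(labels) -> str | None:
    seen = set()
    for x in labels:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_zscore_matrix(path, orientation: str = "regulators-as-rows") -> ZScoreMatrix:
    """Read a TSV z-score matrix.

    The file must have one header row and one leading label column; cells are
    numeric or the missing marker ``NA``.  With
    ``orientation="targets-as-rows"`` the file is transposed into the
    canonical regulator x target orientation.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}, got {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "targets-as-rows":
        df = df.T
    raw = df.to_numpy()
    values = np.full(raw.shape, np.nan)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j].strip()
            if cell in MISSING_MARKERS:
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric value {cell!r} at row {df.index[i]!r}, "
                    f"column {df.columns[j]!r}"
                ) from None
            if not math.isfinite(values[i, j]):
                raise ValueError(
                    f"non-finite value {cell!r} at row {df.index[i]!r}, "
                    f"column {df.columns[j]!r}"
                )
    return ZScoreMatrix(list(df.index), list(df.columns), values)


def zscore_for_pvalue(p_two_sided: float) -> float:
    """Invert a two-sided standard-normal p-value into a z-score threshold.

    Returns the ``t >= 0`` with ``2 * (1 - Phi(t)) = p`` where ``Phi`` is the
    standard normal CDF, so that ``|z| >= t`` corresponds to an unadjusted
    two-sided p-value of at most ``p`` under the standard-normal assumption.
    """
    if not 0.0 < p_two_sided <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p_two_sided}")
    return float(norm.isf(p_two_sided / 2.0))
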