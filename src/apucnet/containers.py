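"""Core in-memory containers shared across the pipeline.

Expression matrices are gene × sample pandas DataFrames with an explicit
abundance unit; keeping the unit on the object prevents silently mixing
counts, FPKM, TPM and log-TPM in downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_UNITS = ("counts", "FPKM", "TPM", "logTPM")

#: one million — TPM columns sum to this by construction
TPM_SUM = 1_000_000.0


@dataclass
class ExpressionMatrix:
    """Gene × sample abundance matrix with a declared unit.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample-id columns. Values must be
        non-negative unless ``unit == "logTPM"`` (log space is still
        non-negative under the +1 pseudocount, but this is not re-checked).
    unit
        One of ``counts``, ``FPKM``, ``TPM``, ``logTPM``.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids after deduplication: {dups}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.unit != "logTPM" and (self.values.to_numpy() < 0).any():
            raise ValueError(f"negative values not allowed for unit {self.unit}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class AlanMatrix:
    """Gene × gene second-order association matrix.

    Symmetric, unit diagonal, entries in [−1, 1]. ``method_meta`` records the
    first- and second-order correlation methods used to build it.
    """

    values: pd.DataFrame
    method_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = self.values.to_numpy(dtype=float)
        if a.shape[0] != a.shape[1]:
            raise ValueError("association matrix must be square")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("association matrix must be symmetric within 1e-10")
        if not np.allclose(np.diag(a), 1.0):
            raise ValueError("association matrix diagonal must be 1")
        if np.nanmax(np.abs(a)) > 1 + 1e-12:
            raise ValueError("association values must lie in [-1, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ScoreVector:
    """Per-sample signature score with its provenance.

    ``kind`` is one of ``sumlog_raw`` (sum of ln(TPM+1) over the set),
    ``scaled_0_100`` (min-max rescaled across the cohort) or ``mean_z``
    (mean of per-gene cohort z-scores).
    """

    scores: pd.Series
    kind: str
    gene_set_name: str = ""
    scaling_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("sumlog_raw", "scaled_0_100", "mean_z"):
            raise ValueError(f"unknown score kind {self.kind!r}")
        self.scores = self.scores.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations for survival analysis.

    Columns: ``os_months`` (non-negative), ``event`` (0/1), ``biopsy_site``,
    ``histology`` (adenocarcinoma | NEPC), ``hormone_status`` (sensitive |
    castration-resistant) and optionally ``claim_dates`` (list of ordered
    ``datetime.date``).
    """

    table: pd.DataFrame

    REQUIRED = ("os_months", "event")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        if (self.table["os_months"] < 0).any():
            raise ValueError("os_months must be >= 0")
        if not self.table["event"].isin([0, 1]).all():
            raise ValueError("event must be 0 or 1")
        if "claim_dates" in self.table.columns:
            for sid, dates in self.table["claim_dates"].items():
                if dates is None or (isinstance(dates, float) and np.isnan(dates)):
                    continue
                dl = list(dates)
                if any(b <= a for a, b in zip(dl, dl[1:])):
                    raise ValueError(f"claim_dates for {sid} must be strictly increasing")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)
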