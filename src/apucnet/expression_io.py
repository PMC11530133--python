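"""Reading, writing and normalising expression matrices and clinical tables.

All downstream analyses run on TPM (transcripts per million), so this module
carries the unit conversions: raw counts + transcript lengths → TPM, and
FPKM → TPM. Both are within-sample renormalisations; after either, every
sample column sums to 10^6.
"""

from __future__ import annotations

import datetime
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import TPM_SUM, ClinicalTable, ExpressionMatrix

__all__ = [
    "load_expression",
    "write_expression",
    "filter_zero_genes",
    "counts_to_tpm",
    "fpkm_to_tpm",
    "log_transform",
    "median_by_group",
    "load_gene_sets",
    "load_clinical",
    "write_clinical",
]


def _dedup_gene_ids(ids: list[str]) -> list[str]:
    """Suffix repeated gene ids ``.1``, ``.2``, ... in file order."""
    seen: dict[str, int] = {}
    out = []
    for g in ids:
        if g in seen:
            seen[g] += 1
            out.append(f"{g}.{seen[g]}")
        else:
            seen[g] = 0
            out.append(g)
    return out


def load_expression(path: str | Path, unit: str, dialect: str = "tsv") -> ExpressionMatrix:
    """Load a gene × sample expression table.

    The first column holds gene ids, the header row sample ids. Duplicate
    gene ids are made unique deterministically (``A``, ``A.1``, ``A.2`` in
    file order). Any non-numeric cell is a hard parse error naming the
    offending gene and sample.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"empty expression matrix in {path}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell {raw.iat[gi, si]!r} at gene {raw.index[gi]!r}, "
            f"sample {raw.columns[si]!r} in {path}"
        )
    values.index = _dedup_gene_ids([str(g) for g in values.index])
    return ExpressionMatrix(values=values.astype(float), unit=unit)


def write_expression(m: ExpressionMatrix, path: str | Path, dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    m.values.to_csv(path, sep=sep, index_label="gene_id")


def filter_zero_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes with zero expression across all samples."""
    keep = (m.values != 0).any(axis=1)
    if not keep.any():
        raise ValueError("all genes have zero expression across all samples")
    return ExpressionMatrix(values=m.values.loc[keep], unit=m.unit)


def counts_to_tpm(m: ExpressionMatrix, lengths: pd.Series | dict) -> ExpressionMatrix:
    """Convert raw read counts to TPM using effective transcript lengths.

    Per sample: ``rate_g = count_g / length_g``; ``TPM_g = 1e6 · rate_g / Σ rate``.
    This normalises for both transcript length and sequencing depth.
    """
    if m.unit != "counts":
        raise ValueError(f"expected counts, got {m.unit}")
    lengths = pd.Series(lengths, dtype=float)
    missing = [g for g in m.gene_ids if g not in lengths.index]
    if missing:
        raise ValueError(f"missing transcript length for genes: {missing}")
    lens = lengths.reindex(m.values.index)
    if (lens <= 0).any():
        bad = list(lens.index[lens <= 0])
        raise ValueError(f"non-positive transcript length for genes: {bad}")
    rate = m.values.div(lens, axis=0)
    colsum = rate.sum(axis=0)
    if (colsum == 0).any():
        bad = list(colsum.index[colsum == 0])
        raise ValueError(f"samples with all-zero counts: {bad}")
    tpm = rate.div(colsum, axis=1) * TPM_SUM
    return ExpressionMatrix(values=tpm, unit="TPM")


def fpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convert FPKM to TPM: rescale each sample so its column sums to 10^6."""
    if m.unit != "FPKM":
        raise ValueError(f"expected FPKM, got {m.unit}")
    colsum = m.values.sum(axis=0)
    if (colsum == 0).any():
        bad = list(colsum.index[colsum == 0])
        raise ValueError(f"samples with all-zero FPKM: {bad}")
    tpm = m.values.div(colsum, axis=1) * TPM_SUM
    return ExpressionMatrix(values=tpm, unit="TPM")


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Element-wise natural log with +1 pseudocount: ln(TPM + 1)."""
    if m.unit != "TPM":
        raise ValueError(f"expected TPM, got {m.unit}")
    if (m.values.to_numpy() < 0).any():
        raise ValueError("negative TPM values")
    return ExpressionMatrix(values=np.log1p(m.values), unit="logTPM")


def median_by_group(m: ExpressionMatrix, groups: pd.Series | dict) -> pd.DataFrame:
    """Gene × group-label table of per-group median expression."""
    groups = pd.Series(groups)
    unlabeled = [s for s in m.sample_ids if s not in groups.index or pd.isna(groups.get(s))]
    if unlabeled:
        raise ValueError(f"unlabeled samples: {unlabeled}")
    groups = groups.reindex(m.sample_ids)
    out = m.values.T.groupby(groups).median().T
    for label in out.columns:
        if (groups == label).sum() == 0:  # pragma: no cover - groupby drops these
            raise ValueError(f"empty group {label!r}")
    return out


# ---------------------------------------------------------------------------
# gene sets and clinical tables


def load_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Load gene sets from GMT (name, description, members...) or a plain list.

    A file without tabs is read as one-gene-per-line and named after its stem.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"empty gene-set file {path}")
    lines = text.splitlines()
    if any("\t" in ln for ln in lines):
        sets = {}
        for ln in lines:
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {ln!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
        return sets
    return {path.stem: [ln.strip() for ln in lines if ln.strip()]}


def _parse_claims(cell: str) -> list[datetime.date] | None:
    if not cell or pd.isna(cell):
        return None
    return [datetime.date.fromisoformat(tok) for tok in str(cell).split(";") if tok]


def load_clinical(path: str | Path, dialect: str = "tsv") -> ClinicalTable:
    """Load a clinical TSV/CSV keyed by sample_id.

    ``claim_dates``, when present, is a semicolon-separated list of ISO dates.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("clinical table must have a sample_id column")
    df = df.set_index("sample_id")
    if "claim_dates" in df.columns:
        df["claim_dates"] = df["claim_dates"].apply(_parse_claims)
    return ClinicalTable(table=df)


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    df = clin.table.copy()
    if "claim_dates" in df.columns:
        df["claim_dates"] = df["claim_dates"].apply(
            lambda ds: ";".join(d.isoformat() for d in ds) if ds is not None else ""
        )
    df.to_csv(path, sep="\t", index_label="sample_id")
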