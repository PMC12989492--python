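"""Expression normalization and per-gene differential expression.

Counts are normalized to transcripts per million (TPM) from recorded gene
lengths; group contrasts are summarized as log2 fold changes of group-mean
TPM with a pseudocount, tested per gene with a two-sided Wilcoxon rank-sum
test (exact at small n, mid-ranks under ties), and adjusted by the
Benjamini-Hochberg step-up.  The significance filter keeps genes with
FDR < alpha and |log2FC| above a minimum, both strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "read_counts_tsv",
    "counts_to_tpm",
    "log2_fold_change",
    "paired_log2fc",
    "rank_de_test",
    "bh_fdr",
    "differential_expression",
    "de_filter",
]

LESION = "lesion"
CONTROL = "control"


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a two-group design.

    ``kind`` flags whether ``values`` holds raw counts or TPM.  ``groups``
    maps each sample to one of exactly two groups; ``patients`` (optional)
    records the paired design; ``lengths`` (nt) are required to convert
    counts to TPM.
    """

    values: pd.DataFrame
    kind: str
    groups: pd.Series
    patients: pd.Series | None = None
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "tpm"):
            raise ValueError(f"kind must be 'counts' or 'tpm', got {self.kind!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without a group label: {missing}")
        if self.groups.nunique() != 2:
            raise ValueError(
                f"exactly two groups required, got {sorted(self.groups.unique())}"
            )
        if self.patients is not None:
            self.patients = self.patients.reindex(self.values.columns)
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.values.index)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group_samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def read_counts_tsv(
    counts_path: str | Path,
    samples_path: str | Path,
    lengths_path: str | Path | None = None,
    kind: str = "counts",
) -> ExpressionMatrix:
    """Load an expression matrix from TSV files.

    ``counts_path``: genes x samples table (first column = gene id).
    ``samples_path``: sample sheet with columns ``sample``, ``group`` and
    optionally ``patient``.  ``lengths_path``: two columns, gene and length.
    """
    values = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    sheet = pd.read_csv(samples_path, sep="\t", comment="#")
    sheet = sheet.set_index("sample")
    groups = sheet["group"]
    patients = sheet["patient"] if "patient" in sheet.columns else None
    lengths = None
    if lengths_path is not None:
        ltab = pd.read_csv(lengths_path, sep="\t", index_col=0, comment="#")
        lengths = ltab.iloc[:, 0]
    return ExpressionMatrix(values, kind, groups, patients, lengths)


def counts_to_tpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Length-normalize counts so every sample sums to 1e6 (TPM)."""
    if counts.kind != "counts":
        raise ValueError("counts_to_tpm requires a counts-flagged matrix")
    if counts.lengths is None or counts.lengths.isna().any():
        raise ValueError("gene lengths are required to compute TPM")
    rates = counts.values.div(counts.lengths, axis=0)
    libs = rates.sum(axis=0)
    zero = libs.index[libs <= 0]
    if len(zero):
        raise ValueError(f"zero library size in sample(s) {list(zero)}")
    tpm = rates.div(libs, axis=1) * 1e6
    return ExpressionMatrix(
        tpm, "tpm", counts.groups, counts.patients, counts.lengths
    )


def log2_fold_change(
    tpm: ExpressionMatrix,
    pseudocount: float = 1.0,
    lesion: str = LESION,
    control: str = CONTROL,
) -> pd.Series:
    """log2((mean_lesion + pc) / (mean_control + pc)) per gene."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    mean_l = tpm.values[tpm.group_samples(lesion)].mean(axis=1)
    mean_c = tpm.values[tpm.group_samples(control)].mean(axis=1)
    lfc = np.log2((mean_l + pseudocount) / (mean_c + pseudocount))
    return pd.Series(lfc, index=tpm.genes, name="log2fc")


def paired_log2fc(
    tpm: ExpressionMatrix,
    pseudocount: float = 1.0,
    lesion: str = LESION,
    control: str = CONTROL,
) -> pd.DataFrame:
    """Per-patient log2 fold-change profiles (genes x patients)."""
    if tpm.patients is None:
        raise ValueError("paired log2FC profiles require patient labels")
    out = {}
    for patient in pd.unique(tpm.patients):
        cols = tpm.samples[(tpm.patients == patient)]
        les = [c for c in cols if tpm.groups[c] == lesion]
        con = [c for c in cols if tpm.groups[c] == control]
        if len(les) != 1 or len(con) != 1:
            raise ValueError(
                f"patient {patient!r} needs exactly one sample per group"
            )
        out[patient] = np.log2(
            (tpm.values[les[0]] + pseudocount) / (tpm.values[con[0]] + pseudocount)
        )
    return pd.DataFrame(out)


def rank_de_test(
    tpm: ExpressionMatrix,
    lesion: str = LESION,
    control: str = CONTROL,
    exact_max_n: int = 10,
) -> pd.Series:
    """Two-sided Wilcoxon rank-sum p per gene.

    Exact permutation null when both groups have <= ``exact_max_n`` samples
    and the pooled values are tie-free; otherwise the mid-rank normal
    approximation.  A gene constant across all samples gets p = 1.
    """
    les = tpm.values[tpm.group_samples(lesion)].to_numpy()
    con = tpm.values[tpm.group_samples(control)].to_numpy()
    if les.shape[1] < 2 or con.shape[1] < 2:
        raise ValueError("rank test requires >= 2 samples per group")
    pvals = np.ones(len(tpm.genes))
    for i in range(len(tpm.genes)):
        x, y = les[i], con[i]
        pooled = np.concatenate([x, y])
        if np.ptp(pooled) == 0:
            continue
        ties = len(np.unique(pooled)) < pooled.size
        method = (
            "exact"
            if not ties and max(x.size, y.size) <= exact_max_n
            else "asymptotic"
        )
        pvals[i] = stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method
        ).pvalue
    return pd.Series(pvals, index=tpm.genes, name="p")


def bh_fdr(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_fdr expects a 1-d vector")
    if np.isnan(p).any():
        raise ValueError("bh_fdr does not accept NaN p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def differential_expression(
    tpm: ExpressionMatrix,
    alpha: float = 0.05,
    lfc_min: float = 0.01,
    pseudocount: float = 1.0,
    lesion: str = LESION,
    control: str = CONTROL,
) -> pd.DataFrame:
    """Per-gene log2FC, rank-test p, BH-FDR and the significance flag."""
    lfc = log2_fold_change(tpm, pseudocount, lesion, control)
    p = rank_de_test(tpm, lesion, control)
    fdr = bh_fdr(p.to_numpy())
    table = pd.DataFrame(
        {"log2fc": lfc, "p": p, "fdr": fdr},
        index=tpm.genes,
    )
    table["passes_filter"] = (table["fdr"] < alpha) & (table["log2fc"].abs() > lfc_min)
    return table


def de_filter(
    table: pd.DataFrame, alpha: float = 0.05, lfc_min: float = 0.01
) -> pd.Index:
    """Genes with fdr < alpha AND |log2FC| > lfc_min (strict inequalities)."""
    keep = (table["fdr"] < alpha) & (table["log2fc"].abs() > lfc_min)
    return table.index[keep]
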