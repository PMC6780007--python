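"""Two-group differential expression on log2-scale intensities.

The disease-related gene list of the screen comes from a small two-group
microarray comparison: per gene, the log2 fold change is the difference
of group means on the log2 scale, and significance is a two-sided Welch
unequal-variance t-test with Welch-Satterthwaite degrees of freedom.  A
gene is called differentially expressed when ``p < p_max`` and
``|log2fc| > lfc_min`` — both inequalities strict, and no multiple-testing
correction at this stage, mirroring the raw-threshold convention of the
screening procedure (defaults p < 0.005, |log2fc| > 1).

Degenerate-variance conventions: if both groups have zero variance the
p-value is 1.0 for equal means and 0.0 for unequal means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "DegRecord",
    "log2_fold_change",
    "welch_pvalue",
    "call_degs",
    "volcano_table",
    "read_expression",
    "write_expression",
    "write_deg_table",
]

VOLCANO_CAP = 300.0  # -log10(p) ordinate clamp for p == 0


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples log2 intensities with a two-group sample labeling.

    ``values`` is a DataFrame indexed by gene symbol with sample-id
    columns; ``groups`` maps every sample id to "case" or "control".
    """

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][:5]
            raise ValueError(f"duplicate gene symbols, e.g. {list(dup)}")
        labels = set(self.groups.values())
        if not labels <= {"case", "control"}:
            raise ValueError(f"group labels must be case/control, got {labels}")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        if not self.case_samples or not self.control_samples:
            raise ValueError("both groups must be non-empty")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == "case"]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == "control"]

    def swapped(self) -> "ExpressionMatrix":
        """The same matrix with case and control labels exchanged."""
        flip = {"case": "control", "control": "case"}
        return ExpressionMatrix(
            values=self.values,
            groups={s: flip[g] for s, g in self.groups.items()},
        )


@dataclass(frozen=True)
class DegRecord:
    """Per-gene differential-expression call."""

    gene: str
    log2fc: float
    pvalue: float
    is_deg: bool


def _gene_row(matrix: ExpressionMatrix, gene: str) -> pd.Series:
    if gene not in matrix.values.index:
        raise KeyError(f"unknown gene {gene!r}")
    return matrix.values.loc[gene]


def log2_fold_change(matrix: ExpressionMatrix, gene: str) -> float:
    """Case-minus-control difference of mean log2 intensities."""
    row = _gene_row(matrix, gene)
    return float(
        row[matrix.case_samples].mean() - row[matrix.control_samples].mean()
    )


def _welch(case: np.ndarray, ctrl: np.ndarray) -> float:
    """Two-sided Welch p for one gene, with zero-variance conventions."""
    v1, v2 = case.var(ddof=1), ctrl.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        return 1.0 if case.mean() == ctrl.mean() else 0.0
    return float(stats.ttest_ind(case, ctrl, equal_var=False).pvalue)


def welch_pvalue(matrix: ExpressionMatrix, gene: str) -> float:
    """Two-sided Welch unequal-variance t-test on one gene's log2 values."""
    row = _gene_row(matrix, gene)
    case = row[matrix.case_samples].to_numpy(float)
    ctrl = row[matrix.control_samples].to_numpy(float)
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("welch_pvalue needs at least 2 samples per group")
    return _welch(case, ctrl)


def call_degs(
    matrix: ExpressionMatrix, p_max: float = 0.005, lfc_min: float = 1.0
) -> list[DegRecord]:
    """Call DEGs gene-wise; records sorted by p ascending, then gene.

    ``is_deg`` is exactly ``pvalue < p_max and |log2fc| > lfc_min``
    (strict on both arms).
    """
    case = matrix.values[matrix.case_samples].to_numpy(float)
    ctrl = matrix.values[matrix.control_samples].to_numpy(float)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("call_degs needs at least 2 samples per group")
    lfc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pvals = stats.ttest_ind(case, ctrl, axis=1, equal_var=False).pvalue
    # repair rows where both groups are constant (vectorized path gives nan)
    both_flat = (case.var(axis=1, ddof=1) == 0) & (ctrl.var(axis=1, ddof=1) == 0)
    pvals = np.where(both_flat, np.where(lfc == 0.0, 1.0, 0.0), pvals)
    records = [
        DegRecord(
            gene=g,
            log2fc=float(f),
            pvalue=float(p),
            is_deg=bool(p < p_max and abs(f) > lfc_min),
        )
        for g, f, p in zip(matrix.genes, lfc, pvals)
    ]
    return sorted(records, key=lambda r: (r.pvalue, r.gene))


def volcano_table(records: list[DegRecord], cap: float = VOLCANO_CAP) -> pd.DataFrame:
    """Volcano-plot data: log2fc abscissa, -log10(p) ordinate, DEG flag."""
    rows = []
    for r in records:
        if r.pvalue > 0:
            ordinate = min(-np.log10(r.pvalue), cap)
        else:
            ordinate = cap
        rows.append((r.gene, r.log2fc, float(ordinate), r.is_deg))
    return pd.DataFrame(
        rows, columns=["gene", "log2fc", "neg_log10_pvalue", "is_deg"]
    )


# ---------------------------------------------------------------------------
# file formats


def read_expression(
    path, groups: dict[str, str], log2_transform: bool = False
) -> ExpressionMatrix:
    """Read a series-matrix-style TSV (first column gene, header samples).

    Intensities are assumed to be log2 scale already; ``log2_transform``
    applies log2(x + 1) to linear-scale input.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if log2_transform:
        df = np.log2(df + 1.0)
    return ExpressionMatrix(values=df, groups=dict(groups))


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


def write_deg_table(records: list[DegRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tlog2fc\tpvalue\tis_deg\n")
        for r in records:
            fh.write(f"{r.gene}\t{r.log2fc:.6g}\t{r.pvalue:.6g}\t{r.is_deg}\n")
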