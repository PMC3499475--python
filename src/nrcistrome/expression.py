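"""Detection and differential-expression labeling of WT-vs-KO profiles.

Genes with a detectable mean signal in either genotype group are "hepatic";
detected genes are tested WT vs KO by a classical two-sided pooled-variance
Student t-test and labeled UIK (up-regulated in knockout) or DIK
(down-regulated in knockout) at p below alpha, with no multiple-testing
correction — a faithful-but-liberal raw-p rule.  Fold change is reported as
KO/WT on the linear scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

LABELS = ("UIK", "DIK", "unchanged", "undetected")


@dataclass
class ExpressionMatrix:
    """Genes x samples signal matrix with WT/KO group labels per sample."""

    values: pd.DataFrame
    groups: pd.Series  # index = sample ids, values in {"WT", "KO"}

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression signals must be nonnegative")
        self.groups = pd.Series(self.groups)
        if not set(self.groups.unique()) <= {"WT", "KO"}:
            raise ValidationError(f"unknown group labels: {sorted(set(self.groups) - {'WT', 'KO'})}")
        if list(self.groups.index) != list(self.values.columns):
            raise ValidationError("group labels must cover exactly the sample columns")
        for g in ("WT", "KO"):
            if int((self.groups == g).sum()) < 2:
                raise ValidationError(f"need >= 2 samples in group {g}")

    @property
    def wt(self) -> pd.DataFrame:
        return self.values.loc[:, self.groups[self.groups == "WT"].index]

    @property
    def ko(self) -> pd.DataFrame:
        return self.values.loc[:, self.groups[self.groups == "KO"].index]


def detect_hepatic(matrix: ExpressionMatrix, tau: float) -> set[str]:
    """Genes whose mean signal reaches ``tau`` in the WT or the KO group."""
    if tau < 0:
        raise ValidationError("detection threshold must be >= 0")
    if matrix.values.empty:
        raise ValidationError("empty expression matrix")
    detected = (matrix.wt.mean(axis=1) >= tau) | (matrix.ko.mean(axis=1) >= tau)
    return set(matrix.values.index[detected])


def student_t_test(wt_values, ko_values) -> tuple[float, float]:
    """Two-sided pooled-variance Student t-test; sign convention WT - KO.

    Degenerate zero-variance cases: equal means give (0, 1); unequal means
    are flagged with p = 0 and a warning.
    """
    wt = np.asarray(wt_values, dtype=float)
    ko = np.asarray(ko_values, dtype=float)
    if wt.size < 2 or ko.size < 2:
        raise ValidationError("each group needs >= 2 values")
    n1, n2 = wt.size, ko.size
    df = n1 + n2 - 2
    diff = wt.mean() - ko.mean()
    pooled = ((n1 - 1) * wt.var(ddof=1) + (n2 - 1) * ko.var(ddof=1)) / df
    se = float(np.sqrt(pooled * (1 / n1 + 1 / n2)))
    if se == 0:
        if diff == 0:
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means: degenerate t-test")
        return float(np.sign(diff) * np.inf), 0.0
    t = float(diff / se)
    p = float(2 * stats.t.sf(abs(t), df))
    return t, p


def classify_de(matrix: ExpressionMatrix, tau: float, alpha: float = 0.05) -> pd.DataFrame:
    """Label every gene UIK / DIK / unchanged / undetected.

    Undetected genes (below ``tau`` in both groups) are not tested.  Detected
    genes with p < alpha are UIK when the KO mean exceeds the WT mean, DIK
    when it falls below; everything else is unchanged.
    """
    if not (0 <= alpha <= 1):
        raise ValidationError("alpha must lie in [0, 1]")
    detected = detect_hepatic(matrix, tau)

    wt = matrix.wt.to_numpy(dtype=float)
    ko = matrix.ko.to_numpy(dtype=float)
    n1, n2 = wt.shape[1], ko.shape[1]
    df = n1 + n2 - 2
    mean_wt = wt.mean(axis=1)
    mean_ko = ko.mean(axis=1)
    pooled = ((n1 - 1) * wt.var(axis=1, ddof=1) + (n2 - 1) * ko.var(axis=1, ddof=1)) / df
    se = np.sqrt(pooled * (1 / n1 + 1 / n2))
    diff = mean_wt - mean_ko

    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        fold = np.where(mean_wt > 0, mean_ko / mean_wt, np.nan)
    t = np.where((se == 0) & (diff == 0), 0.0, t)
    degenerate = (se == 0) & (diff != 0)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} genes with zero pooled variance and unequal means")
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, 0.0, p)
    p = np.where((se == 0) & (diff == 0), 1.0, p)

    genes = matrix.values.index
    is_detected = genes.isin(detected)
    label = np.full(len(genes), "unchanged", dtype=object)
    label[(p < alpha) & (mean_ko > mean_wt)] = "UIK"
    label[(p < alpha) & (mean_ko < mean_wt)] = "DIK"
    label[~is_detected] = "undetected"

    out = pd.DataFrame(
        {
            "gene_id": genes,
            "mean_wt": mean_wt,
            "mean_ko": mean_ko,
            "fold_change": fold,
            "t": t,
            "p": p,
            "label": label,
        }
    ).set_index("gene_id", drop=False)
    out.index.name = None
    # undetected genes carry no test result
    out.loc[~is_detected, ["t", "p"]] = np.nan
    return out


def label_sets(de_results: pd.DataFrame) -> dict[str, set[str]]:
    """Gene sets per label from a classify_de table."""
    return {lab: set(de_results.loc[de_results["label"] == lab, "gene_id"]) for lab in LABELS}
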