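"""Map accuracy assessment from validation points.

Two estimators over a mapped-class x reference-class count matrix n_ij:

* simple (count-based): UA_i = n_ii / n_i., PA_j = n_jj / n_.j,
  OA = tr(n) / n_.. ;
* area-weighted (stratified by mapped class with area proportions W_i,
  the good-practice estimator for maps whose strata were sampled
  disproportionately): cell proportions p_ij = W_i n_ij / n_i., so
  OA = sum_i p_ii, UA_i = p_ii / p_i. (= n_ii / n_i.),
  PA_j = p_jj / p_.j, with standard errors

      SE(UA_i)^2 = UA_i (1 - UA_i) / (n_i. - 1)
      SE(OA)^2   = sum_i W_i^2 UA_i (1 - UA_i) / (n_i. - 1)
      SE(PA_j)^2 = (1/N_j^2) [ N_j^2 (1-PA_j)^2 UA_j (1-UA_j) / (n_j. - 1)
                   + PA_j^2 sum_{i!=j} N_i^2 q_ij (1-q_ij) / (n_i. - 1) ]

  where q_ij = n_ij / n_i., N_i is the mapped area of class i (any common
  scale; W_i works) and N_j = sum_i N_i q_ij the estimated reference area.

95% confidence half-widths are 1.96 SE.  All accuracies are kept at full
precision; rounding to printed precision is left to reporting code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import LabelRaster, SampleSet


class EmptyMatrixError(ValueError):
    """No in-extent validation points to cross-tabulate."""


class VarianceError(ValueError):
    """A stratum with n <= 1 sample admits no variance estimate."""


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows = mapped class, columns = reference class."""

    counts: pd.DataFrame  # index and columns share the class labels
    excluded: int = 0  # points dropped (out of extent / unmapped)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.counts.columns):
            raise ValueError("confusion matrix must be square with shared labels")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_counts(cls, counts, labels) -> "ConfusionMatrix":
        arr = np.asarray(counts, dtype=np.int64)
        return cls(pd.DataFrame(arr, index=list(labels), columns=list(labels)))

    @property
    def labels(self) -> list:
        return list(self.counts.index)

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass
class AccuracyReport:
    estimator: str  # "simple" | "area_weighted"
    overall: float
    users: pd.Series
    producers: pd.Series
    se_overall: float | None = None
    se_users: pd.Series | None = None
    se_producers: pd.Series | None = None
    z: float = 1.96

    def ci_overall(self) -> float | None:
        return None if self.se_overall is None else self.z * self.se_overall

    def ci_users(self) -> pd.Series | None:
        return None if self.se_users is None else self.z * self.se_users

    def ci_producers(self) -> pd.Series | None:
        return None if self.se_producers is None else self.z * self.se_producers


def build_confusion(pred: LabelRaster, validation: SampleSet,
                    labels: list[int] | None = None) -> ConfusionMatrix:
    """Cross-tabulate mapped vs reference class at validation points.

    Out-of-extent points and points mapped to nodata are excluded and
    counted in ``excluded``.
    """
    frame = validation.frame
    if frame.empty:
        raise EmptyMatrixError("no validation points")
    rc = validation.rowcols(pred.grid)
    mapped, ref = [], []
    excluded = 0
    for (r, c), lab, ok in zip(rc, frame["label"], frame["in_extent"]):
        if not ok or not pred.grid.contains_rowcol(r, c):
            excluded += 1
            continue
        m = int(pred.labels[r, c])
        if m == pred.nodata:
            excluded += 1
            continue
        mapped.append(m)
        ref.append(int(lab))
    if not mapped:
        raise EmptyMatrixError("no in-extent validation points")
    if labels is None:
        labels = sorted(set(mapped) | set(ref))
    tab = pd.crosstab(pd.Categorical(mapped, categories=labels),
                      pd.Categorical(ref, categories=labels), dropna=False)
    tab.index = pd.Index(labels)
    tab.columns = pd.Index(labels)
    return ConfusionMatrix(tab, excluded=excluded)


def simple_accuracies(cm: ConfusionMatrix) -> AccuracyReport:
    """Count-based user's / producer's / overall accuracy.

    Classes with an empty row or column get NaN (undefined), not zero.
    SEs use the binomial form on the respective totals.
    """
    n = cm.counts.to_numpy(dtype=float)
    diag = np.diag(n)
    rows = n.sum(axis=1)
    cols = n.sum(axis=0)
    total = n.sum()
    if total <= 0:
        raise EmptyMatrixError("empty confusion matrix")
    with np.errstate(invalid="ignore", divide="ignore"):
        ua = np.where(rows > 0, diag / np.where(rows > 0, rows, 1), np.nan)
        pa = np.where(cols > 0, diag / np.where(cols > 0, cols, 1), np.nan)
    oa = diag.sum() / total
    with np.errstate(invalid="ignore", divide="ignore"):
        se_ua = np.sqrt(ua * (1 - ua) / np.maximum(rows - 1, 1))
        se_pa = np.sqrt(pa * (1 - pa) / np.maximum(cols - 1, 1))
    se_oa = float(np.sqrt(oa * (1 - oa) / max(total - 1, 1)))
    idx = cm.counts.index
    return AccuracyReport(
        estimator="simple", overall=float(oa),
        users=pd.Series(ua, index=idx), producers=pd.Series(pa, index=idx),
        se_overall=se_oa,
        se_users=pd.Series(se_ua, index=idx),
        se_producers=pd.Series(se_pa, index=idx),
    )


def area_weighted_accuracies(cm: ConfusionMatrix, weights) -> AccuracyReport:
    """Stratified (area-weighted) accuracies with 95% CI half-widths.

    ``weights`` maps each mapped class to its proportion of mapped area W_i
    (pd.Series, dict, or array in row order).  W must cover every mapped
    class; the sum is expected to be 1 within 0.01 (printed tables round).
    """
    idx = cm.counts.index
    if isinstance(weights, dict):
        missing = [l for l in idx if l not in weights]
        if missing:
            raise ValueError(f"no area weight for mapped classes {missing}")
        w = np.array([float(weights[l]) for l in idx])
    else:
        w = np.asarray(pd.Series(weights).reindex(idx) if isinstance(weights, pd.Series)
                       else weights, dtype=float)
    if w.shape != (len(idx),):
        raise ValueError("one weight per mapped class required")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if abs(w.sum() - 1.0) > 0.01:
        raise ValueError(f"weights sum to {w.sum():.4f}, expected 1 within 0.01")

    n = cm.counts.to_numpy(dtype=float)
    rows = n.sum(axis=1)
    used = rows > 0
    if ((rows <= 1) & (w > 0)).any():
        raise VarianceError("every weighted stratum needs at least 2 samples")
    q = np.where(used[:, None], n / np.where(rows[:, None] > 0, rows[:, None], 1), 0.0)
    p = w[:, None] * q  # estimated cell proportions
    p_col = p.sum(axis=0)
    diag_p = np.diag(p)
    oa = float(diag_p.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        ua = np.where(used, np.diag(q), np.nan)
        pa = np.where(p_col > 0, diag_p / np.where(p_col > 0, p_col, 1), np.nan)

    nm1 = np.maximum(rows - 1, 1)
    se_ua = np.sqrt(ua * (1 - ua) / nm1)
    se_oa = float(np.sqrt(np.nansum(w ** 2 * ua * (1 - ua) / nm1)))
    # stratified producer's accuracy variance (reference totals estimated)
    k = len(idx)
    se_pa = np.full(k, np.nan)
    for j in range(k):
        Nj = p_col[j]  # on the W scale
        if not np.isfinite(pa[j]) or Nj <= 0:
            continue
        term1 = (w[j] ** 2) * ((1 - pa[j]) ** 2) * ua[j] * (1 - ua[j]) / nm1[j] \
            if np.isfinite(ua[j]) else 0.0
        term2 = 0.0
        for i in range(k):
            if i == j or rows[i] <= 0:
                continue
            term2 += (w[i] ** 2) * q[i, j] * (1 - q[i, j]) / nm1[i]
        se_pa[j] = np.sqrt((term1 + (pa[j] ** 2) * term2)) / Nj
    return AccuracyReport(
        estimator="area_weighted", overall=oa,
        users=pd.Series(ua, index=idx), producers=pd.Series(pa, index=idx),
        se_overall=se_oa,
        se_users=pd.Series(se_ua, index=idx),
        se_producers=pd.Series(se_pa, index=idx),
    )
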