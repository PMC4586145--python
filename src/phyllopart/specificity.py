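"""Expression quantification and specificity scoring.

The expression pipeline is a small state machine: raw fragment counts
are normalised to FPKM (fragments per kilobase of transcript per million
mapped fragments), FPKM values below 1 are floored to zero on the log2
scale, transcripts silent in every sample are removed, and the tau
specificity index is computed per transcript over the floored log2
values.

tau for a transcript with per-sample expression a_1..a_n is

    tau = (1 / (n - 1)) * sum_j (1 - a_j / max_j a_j)

and ranges from 0 (equal expression in every sample) to 1 (expression
in a single sample only). A tau of 0.8 means the mean expression in the
other samples is 20% of the expression in the top sample.
"""

from __future__ import annotations

import warnings
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as _st
from sklearn.decomposition import PCA as _PCA

__all__ = [
    "ExpressionMatrix",
    "fpkm",
    "floor_log2",
    "drop_all_zero",
    "tau",
    "tau_scores",
    "welch_t",
    "WelchResult",
    "pca",
    "PCAResult",
]

_STATES = ("counts", "fpkm", "log2fpkm")


class ExpressionMatrix:
    """Transcripts x samples expression table with a transform state.

    ``state`` records where the values sit in the chain
    counts -> fpkm -> log2fpkm; operations check it so that e.g. tau is
    never accidentally computed on raw counts. Values must be
    non-negative.
    """

    def __init__(self, data: pd.DataFrame, state: str = "counts"):
        if state not in _STATES:
            raise ValueError(f"unknown state {state!r}; one of {_STATES}")
        if (data.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        self.data = data
        self.state = state

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "transcript_id"
        out.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, state: str = "counts") -> "ExpressionMatrix":
        data = pd.read_csv(path, sep="\t", index_col=0)
        return cls(data, state=state)

    def __repr__(self) -> str:
        return (f"ExpressionMatrix({self.shape[0]} transcripts x "
                f"{self.shape[1]} samples, state={self.state!r})")


def fpkm(m: ExpressionMatrix, lengths: Mapping[str, int]) -> ExpressionMatrix:
    """Normalise fragment counts to FPKM.

    value = count / (length/1000) / (column_total/1e6), using each
    sample's column total as its library size. Columns with zero total
    yield all-zero columns. Users whose matrices are already FPKM (e.g.
    from an external quantifier) construct the matrix with state='fpkm'
    and skip this step.
    """
    if m.state != "counts":
        raise ValueError(f"fpkm expects state='counts', got {m.state!r}")
    missing = [t for t in m.transcript_ids if t not in lengths]
    if missing:
        raise ValueError(
            f"fpkm: no length for {len(missing)} transcripts "
            f"(first: {missing[0]})")
    lens_kb = np.array([lengths[t] for t in m.transcript_ids],
                       dtype=float) / 1000.0
    counts = m.data.to_numpy(dtype=float)
    totals = counts.sum(axis=0) / 1e6
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = counts / lens_kb[:, None] / totals[None, :]
    vals[:, totals == 0] = 0.0
    return ExpressionMatrix(
        pd.DataFrame(vals, index=m.data.index, columns=m.data.columns),
        state="fpkm")


def floor_log2(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform FPKM, flooring values below 1 to zero.

    FPKM < 1 maps to 0 (so does FPKM = 1, since log2(1) = 0); values
    >= 1 map to log2(value).
    """
    if m.state != "fpkm":
        raise ValueError(f"floor_log2 expects state='fpkm', got {m.state!r}")
    vals = m.data.to_numpy(dtype=float)
    out = np.where(vals >= 1.0, np.log2(np.maximum(vals, 1.0)), 0.0)
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
        state="log2fpkm")


def drop_all_zero(m: ExpressionMatrix) -> ExpressionMatrix:
    """Remove transcripts whose floored log2 expression is zero everywhere."""
    if m.state != "log2fpkm":
        raise ValueError(
            f"drop_all_zero expects state='log2fpkm', got {m.state!r}")
    keep = (m.data.to_numpy() != 0).any(axis=1)
    return ExpressionMatrix(m.data.loc[keep], state="log2fpkm")


def tau(values) -> float:
    """Tau specificity index of one expression profile.

    Requires at least two samples, no negative values, and at least one
    positive value (all-zero profiles are undefined and must be removed
    beforehand).
    """
    a = np.asarray(values, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise ValueError("tau: need a 1-D profile over >= 2 samples")
    if (a < 0).any():
        raise ValueError("tau: negative expression values")
    amax = a.max()
    if amax == 0:
        raise ValueError("tau: all-zero profile is undefined")
    return float((1.0 - a / amax).sum() / (a.size - 1))


def tau_scores(m: ExpressionMatrix) -> pd.Series:
    """Per-transcript tau over a floored-log2 expression matrix."""
    if m.state != "log2fpkm":
        raise ValueError(
            f"tau_scores expects state='log2fpkm', got {m.state!r}; "
            "apply fpkm() and floor_log2() first")
    vals = m.data.to_numpy(dtype=float)
    amax = vals.max(axis=1)
    if (amax == 0).any():
        raise ValueError(
            "tau_scores: all-zero rows present; apply drop_all_zero() first")
    scores = (1.0 - vals / amax[:, None]).sum(axis=1) / (vals.shape[1] - 1)
    return pd.Series(scores, index=m.data.index, name="tau")


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def welch_t(x, y) -> WelchResult:
    """Welch's unequal-variance two-sample t-test, two-sided.

    Returns the t statistic, Welch-Satterthwaite degrees of freedom and
    the two-sided p-value from Student's t distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t: each sample needs >= 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return WelchResult(0.0, float(x.size + y.size - 2), 1.0)
        raise ValueError("welch_t: both samples degenerate (zero variance)")
    sx, sy = vx / x.size, vy / y.size
    t = (x.mean() - y.mean()) / np.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (sx ** 2 / (x.size - 1) + sy ** 2 / (y.size - 1))
    p = float(2.0 * _st.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), p)


class PCAResult(NamedTuple):
    scores: pd.DataFrame      # samples x components
    loadings: pd.DataFrame    # transcripts x components
    explained_variance_ratio: np.ndarray


def pca(m: ExpressionMatrix, k: int, scale: bool = False) -> PCAResult:
    """Principal component analysis of samples over transcript space.

    Samples are the observations (as in clustering RNA-seq libraries);
    transcript values are mean-centred, and optionally unit-scaled when
    ``scale`` is true. ``k`` larger than the possible rank is truncated
    with a warning.
    """
    if m.state == "counts":
        raise ValueError("pca expects fpkm or log2fpkm values, not counts")
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("pca: need at least 2 transcripts and 2 samples")
    X = m.data.to_numpy(dtype=float).T  # samples x transcripts
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    k_max = min(X.shape)
    if k > k_max:
        warnings.warn(f"pca: k={k} exceeds max rank {k_max}; truncating")
        k = k_max
    model = _PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.samples, columns=comp_names),
        loadings=pd.DataFrame(model.components_.T, index=m.transcript_ids,
                              columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
    )
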