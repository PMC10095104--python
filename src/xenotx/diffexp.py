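"""TMM-normalized negative-binomial differential expression.

A deliberately small, auditable two-group pipeline for count matrices
(including the fractional counts produced by the ortholog splitter):

* library-size + trimmed-mean-of-M-values (TMM) scaling normalization;
* a single common dispersion phi (variance mu + phi mu^2) estimated by
  method of moments, pooled across genes;
* a per-gene likelihood-ratio test of equal group means against a
  chi-square(1) reference, which, unlike exact integer tests, accepts
  fractional counts.

Common dispersion (no tagwise or trended shrinkage) is a deliberate
simplification: the statistic feeds a downstream permutation-based node
scorer, which needs a signed, roughly calibrated gene ranking rather than
exact per-gene inference.

Exposed in two equivalent ways: the ``NegativeBinomialDE`` model object
(``.fit() -> DEResults`` with ``.summary()``) and the underlying
functions ``tmm_factors`` / ``estimate_common_dispersion`` / ``nb_test``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NormFactors",
    "tmm_factors",
    "estimate_common_dispersion",
    "nb_test",
    "NegativeBinomialDE",
    "DEResults",
]


@dataclass
class NormFactors:
    """Per-sample library sizes and TMM scaling factors (geo-mean 1)."""

    lib_size: pd.Series
    tmm: pd.Series

    @property
    def effective(self) -> pd.Series:
        """Effective library sizes = lib_size * tmm."""
        return self.lib_size * self.tmm


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """Weighted trimmed mean of M-values of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method weights: inverse asymptotic variance of M
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    # double trim: drop the most extreme M and A fractions (edgeR-style rank trim)
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = stats.rankdata(m, method="average")
    rank_a = stats.rankdata(a, method="average")
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0 ** f)


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: Optional[str] = None,
) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors for a genes x samples matrix.

    The reference is the sample whose 75th-percentile scaled count is
    closest to the mean of those percentiles (unless ``ref_sample`` is
    given).  Factors are renormalized to geometric mean 1.
    """
    if not 0 <= trim_m < 0.5 or not 0 <= trim_a < 0.5:
        raise ValueError("trims must lie in [0, 0.5)")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib == 0).any():
        empty = list(counts.columns[lib == 0])
        raise ValueError(f"all-zero samples: {empty}")
    if ref_sample is None:
        uq = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = list(counts.columns).index(ref_sample)
    ref = x[:, ref_idx]
    factors = np.array(
        [
            1.0 if j == ref_idx else _tmm_pair(x[:, j], ref, lib[j], lib[ref_idx], trim_m, trim_a)
            for j in range(x.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(
        lib_size=pd.Series(lib, index=counts.columns, name="lib_size"),
        tmm=pd.Series(factors, index=counts.columns, name="tmm"),
    )


def estimate_common_dispersion(
    counts: pd.DataFrame,
    groups: Sequence[str],
    norm: Optional[NormFactors] = None,
) -> float:
    """Pooled method-of-moments estimate of the common NB dispersion.

    Counts are scaled to a common effective library size; within each
    group, per-gene sample means m and variances v satisfy
    E[v] ~ m + phi m^2, so phi is estimated as
    sum(v - m) / sum(m^2) pooled over genes and groups, clamped at 0.
    """
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    for g in labels:
        if (groups == g).sum() < 2:
            raise ValueError(
                f"group {g!r} has a single sample; supply a dispersion explicitly"
            )
    if norm is None:
        norm = tmm_factors(counts)
    eff = norm.effective.to_numpy()
    scale = np.exp(np.mean(np.log(eff)))
    y = counts.to_numpy(dtype=float) / eff * scale
    num = 0.0
    den = 0.0
    for g in labels:
        sub = y[:, groups == g]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        keep = m > 0
        num += float(np.sum(v[keep] - m[keep]))
        den += float(np.sum(m[keep] ** 2))
    if den == 0:
        return 0.0
    return max(0.0, num / den)


def _nb_mle_loglik(y: np.ndarray, L: np.ndarray, phi: float, n_iter: int = 50):
    """Per-gene NB MLE of a single relative abundance q given dispersion phi.

    y: genes x samples, L: effective library sizes.  Returns (q, loglik)
    where loglik drops terms not involving the mean.  Solves the score
    equation sum_j (y - mu)/(1 + phi mu) = 0 by Newton steps on log q.
    """
    tot = y.sum(axis=1)
    q = tot / L.sum()
    pos = q > 0
    logq = np.log(np.where(pos, q, 1.0))
    if phi > 0:
        for _ in range(n_iter):
            mu = np.exp(logq)[:, None] * L[None, :]
            denom = 1.0 + phi * mu
            score = ((y - mu) / denom).sum(axis=1)
            # d score / d logq = -sum mu (1 + phi y) / (1+phi mu)^2  (negative)
            hess = -(mu * (1.0 + phi * y) / denom**2).sum(axis=1)
            step = np.where(pos, score / np.where(hess == 0, -1.0, hess), 0.0)
            step = np.clip(step, -5.0, 5.0)
            logq = logq - step
            if np.max(np.abs(step)) < 1e-12:
                break
    mu = np.where(pos, np.exp(logq), 0.0)[:, None] * L[None, :]
    if phi > 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(mu > 0, y * np.log(mu), 0.0) - (y + 1.0 / phi) * np.log1p(phi * mu)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(mu > 0, y * np.log(mu), 0.0) - mu
    q_out = np.where(pos, np.exp(logq), 0.0)
    return q_out, ll.sum(axis=1)


def nb_test(
    counts: pd.DataFrame,
    groups: Sequence[str],
    norm: NormFactors,
    dispersion: float,
    contrast: Optional[Tuple[str, str]] = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene NB likelihood-ratio test of equal means between two groups.

    ``contrast=(treatment, control)``; positive log2 fold change means
    higher in treatment.  Returns a GeneStat table with columns
    ``lfc, stat, p, mean_expr, flag`` indexed by gene.  Genes with all-zero
    counts get (lfc=0, stat=0, p=1) and an ``all_zero`` flag.  The signed
    statistic is sign(lfc) * sqrt(LR).
    """
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    if contrast is None:
        trt, ctl = labels[0], labels[1]
    else:
        trt, ctl = contrast
        if set((trt, ctl)) != set(labels):
            raise ValueError(f"contrast {contrast} does not match groups {labels}")

    y = counts.to_numpy(dtype=float)
    L = norm.effective.to_numpy()
    phi = float(dispersion)

    mask_t = groups == trt
    mask_c = groups == ctl
    q0, ll0 = _nb_mle_loglik(y, L, phi)
    qt, ll_t = _nb_mle_loglik(y[:, mask_t], L[mask_t], phi)
    qc, ll_c = _nb_mle_loglik(y[:, mask_c], L[mask_c], phi)
    lr = np.maximum(0.0, 2.0 * (ll_t + ll_c - ll0))
    p = stats.chi2.sf(lr, df=1)

    # fold change on mean normalized counts with a pseudocount
    scale = np.exp(np.mean(np.log(L)))
    ynorm = y / L * scale
    mt = ynorm[:, mask_t].mean(axis=1)
    mc = ynorm[:, mask_c].mean(axis=1)
    lfc = np.log2((mt + pseudocount) / (mc + pseudocount))
    stat = np.sign(lfc) * np.sqrt(lr)

    all_zero = y.sum(axis=1) == 0
    lfc[all_zero] = 0.0
    stat[all_zero] = 0.0
    p[all_zero] = 1.0

    return pd.DataFrame(
        {
            "lfc": lfc,
            "stat": stat,
            "p": p,
            "mean_expr": ynorm.mean(axis=1),
            "flag": np.where(all_zero, "all_zero", ""),
        },
        index=counts.index,
    )


class NegativeBinomialDE:
    """Two-group negative-binomial differential-expression model.

    Parameters
    ----------
    counts
        Genes x samples matrix (raw or fractional resolved counts).
    groups
        Group label per sample, two distinct labels.
    contrast
        ``(treatment, control)``; defaults to first-seen vs second-seen label.
    dispersion
        Common NB dispersion; estimated by method of moments when None.

    Examples
    --------
    >>> model = NegativeBinomialDE(counts, groups, contrast=("nicotine+DSS", "DSS"))
    >>> res = model.fit()
    >>> res.summary().head()
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        groups: Sequence[str],
        contrast: Optional[Tuple[str, str]] = None,
        dispersion: Optional[float] = None,
    ) -> None:
        if counts.shape[1] != len(groups):
            raise ValueError("one group label per sample required")
        self.counts = counts
        self.groups = np.asarray(groups)
        labels = list(pd.unique(self.groups))
        if len(labels) != 2:
            raise ValueError(f"exactly two groups required, got {labels}")
        self.contrast = contrast if contrast is not None else (labels[0], labels[1])
        self.dispersion = dispersion

    @classmethod
    def from_dataframe(
        cls,
        counts: pd.DataFrame,
        samples: pd.DataFrame,
        contrast: Optional[Tuple[str, str]] = None,
        dispersion: Optional[float] = None,
    ) -> "NegativeBinomialDE":
        """Build from a counts matrix and a sample sheet with columns
        ``sample`` and ``group`` (sample order need not match)."""
        samples = samples.set_index("sample").loc[list(counts.columns)]
        return cls(counts, samples["group"].to_numpy(), contrast=contrast, dispersion=dispersion)

    def fit(self) -> "DEResults":
        norm = tmm_factors(self.counts)
        phi = (
            self.dispersion
            if self.dispersion is not None
            else estimate_common_dispersion(self.counts, self.groups, norm)
        )
        table = nb_test(self.counts, self.groups, norm, phi, contrast=self.contrast)
        return DEResults(model=self, norm=norm, dispersion=float(phi), table=table)


@dataclass
class DEResults:
    """Fitted differential-expression results.

    ``table`` is the per-gene GeneStat frame (lfc, stat, p, mean_expr,
    flag); ``stats`` returns the signed statistic consumed by the node
    scorer.
    """

    model: NegativeBinomialDE
    norm: NormFactors
    dispersion: float
    table: pd.DataFrame

    @property
    def stats(self) -> pd.Series:
        return self.table["stat"]

    @property
    def contrast_label(self) -> str:
        trt, ctl = self.model.contrast
        return f"{trt} vs {ctl}"

    def summary(self, n: int = 10) -> pd.DataFrame:
        """Top genes by p-value with the fitted normalization alongside."""
        return self.table.sort_values(["p", "lfc"], kind="mergesort").head(n)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        sig = int((self.table["p"] < 0.05).sum())
        return (
            f"<DEResults contrast='{self.contrast_label}' genes={len(self.table)} "
            f"dispersion={self.dispersion:.4g} p<0.05: {sig}>"
        )
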