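"""Negative-binomial differential-expression stand-in and DE table import.

This is a deliberately simple, calibrated NB likelihood-ratio test in the
DESeq model family: median-of-ratios size factors, method-of-moments
per-transcript dispersion with a fitted 1/mean trend, conservative
"maximum" sharing between the raw and trended estimates, and a chi2(1)
likelihood-ratio p-value with Benjamini-Hochberg adjustment.  It is meant
to be directionally reliable and type-I safe, not to reproduce any
particular tool's p-values; externally computed DE tables can be imported
via :func:`load_de_table` when fidelity to a specific caller matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .stats import bh_adjust

__all__ = [
    "DEResult",
    "estimate_size_factors",
    "test_differential",
    "load_de_table",
    "write_de_table",
]

DE_COLUMNS = ["class", "baseMean", "log2FC", "pvalue", "padj", "call"]


@dataclass(frozen=True)
class DEResult:
    transcript_id: str
    strand_class: str  # sense / antisense / unknown
    base_mean: float
    log2_fold_change: float
    p_value: float
    adjusted_p: float
    call: str  # up / down / unchanged


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one per sample column).

    factor_j = median over transcripts, positive in every sample, of
    count_ij / geometric-mean_i.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no transcript has positive counts in every sample; "
            "use pooled normalisation or filter samples"
        )
    logs = np.log(mat[positive])
    log_geo = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geo, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _nb_loglik(k: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row sums of NB log-likelihood; safe at mu == 0 when k == 0."""
    a = alpha[:, None]
    inv = 1.0 / a
    with np.errstate(divide="ignore", invalid="ignore"):
        term = (
            gammaln(k + inv)
            - gammaln(inv)
            - gammaln(k + 1.0)
            + k * np.log(a * mu / (1.0 + a * mu))
            - inv * np.log1p(a * mu)
        )
    term = np.where((k == 0) & (mu == 0), 0.0, term)
    return np.nansum(term, axis=1)


def _nb_mle_q(k: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 60) -> np.ndarray:
    """MLE of the common size-factor-scaled mean q (mu_ij = s_j q_i).

    Fixed-point iteration on the score equation; exact in one step when
    alpha -> 0 (Poisson) and monotone convergent otherwise.
    """
    tot = k.sum(axis=1)
    q = tot / s.sum()
    a = alpha[:, None]
    for _ in range(n_iter):
        denom = (s[None, :] * (1.0 + a * k) / (1.0 + a * s[None, :] * q[:, None])).sum(axis=1)
        q_new = np.where(denom > 0, tot / denom, 0.0)
        if np.allclose(q_new, q, rtol=1e-10, atol=1e-12):
            q = q_new
            break
        q = q_new
    return q


def _dispersion_estimates(
    norm: np.ndarray,
    groups: list[np.ndarray],
    inv_s_mean: float,
    floor: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw method-of-moments dispersions and a fitted a0 + a1/mean trend."""
    num = np.zeros(norm.shape[0])
    wsum = 0.0
    for idx in groups:
        if idx.size < 2:
            continue
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a_c = (v - m * inv_s_mean) / m**2
        num += (idx.size - 1) * np.nan_to_num(a_c, nan=0.0, posinf=0.0, neginf=0.0)
        wsum += idx.size - 1
    raw = num / max(wsum, 1.0)
    base = norm.mean(axis=1)
    ok = (base > 0) & (raw > 0)
    if ok.sum() >= 10:
        x = np.column_stack([np.ones(ok.sum()), 1.0 / base[ok]])
        coef, *_ = np.linalg.lstsq(x, raw[ok], rcond=None)
        a0, a1 = max(coef[0], floor), max(coef[1], 0.0)
    elif ok.any():
        a0, a1 = max(float(np.median(raw[ok])), floor), 0.0
    else:
        a0, a1 = floor, 0.0
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(base, 1e-12)
    return np.clip(raw, 0.0, 50.0), np.clip(trend, floor, 50.0)


def test_differential(
    counts: pd.DataFrame,
    design: list[str],
    alpha: float = 0.05,
    strand_class: pd.Series | None = None,
    dispersion_floor: float = 1e-3,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-transcript NB likelihood-ratio test between two conditions.

    ``design`` labels each column of ``counts`` with its condition (two
    levels, each with at least two replicates).  The per-transcript
    dispersion is the larger of the raw method-of-moments estimate and the
    fitted mean-dispersion trend — a conservative sharing rule that keeps
    the chi2(1) likelihood-ratio p-values from being anti-conservative at
    small replicate numbers.  Returns a frame indexed by transcript id with
    columns ``class, baseMean, log2FC, pvalue, padj, call`` (log2FC is
    condition2 over condition1 in sorted label order).
    """
    design = list(design)
    if len(design) != counts.shape[1]:
        raise ValueError("design length must match the number of samples")
    levels = sorted(set(design))
    if len(levels) != 2:
        raise ValueError(f"need exactly two conditions, got {levels}")
    g1 = np.array([i for i, d in enumerate(design) if d == levels[0]])
    g2 = np.array([i for i, d in enumerate(design) if d == levels[1]])
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each condition needs at least two replicates")

    mat = counts.to_numpy(dtype=float)
    sizes = estimate_size_factors(counts).to_numpy()
    norm = mat / sizes[None, :]
    raw, trend = _dispersion_estimates(
        norm, [g1, g2], float(np.mean(1.0 / sizes)), dispersion_floor
    )
    disp = np.maximum(raw, trend)  # "maximum" sharing: conservative
    disp = np.clip(disp, dispersion_floor, 50.0)

    q0 = _nb_mle_q(mat, sizes, disp)
    q1 = _nb_mle_q(mat[:, g1], sizes[g1], disp)
    q2 = _nb_mle_q(mat[:, g2], sizes[g2], disp)
    ll0 = _nb_loglik(mat, sizes[None, :] * q0[:, None], disp)
    ll1 = _nb_loglik(mat[:, g1], sizes[g1][None, :] * q1[:, None], disp)
    ll2 = _nb_loglik(mat[:, g2], sizes[g2][None, :] * q2[:, None], disp)
    lr = np.maximum(2.0 * (ll1 + ll2 - ll0), 0.0)
    pvals = chi2.sf(lr, df=1)
    all_zero = mat.sum(axis=1) == 0
    pvals = np.where(all_zero, 1.0, pvals)
    padj = bh_adjust(pvals)

    lfc = np.log2((q2 + pseudocount) / (q1 + pseudocount))
    lfc = np.where(all_zero, 0.0, lfc)
    call = np.where(
        (padj < alpha) & (lfc > 0), "up", np.where((padj < alpha) & (lfc < 0), "down", "unchanged")
    )
    call = np.where(all_zero, "unchanged", call)
    cls = (
        strand_class.reindex(counts.index).fillna("unknown")
        if strand_class is not None
        else pd.Series("unknown", index=counts.index)
    )
    return pd.DataFrame(
        {
            "class": cls,
            "baseMean": norm.mean(axis=1),
            "log2FC": lfc,
            "pvalue": pvals,
            "padj": padj,
            "call": call,
        },
        index=counts.index.rename("transcript_id"),
    )


def write_de_table(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index_label="transcript_id")


def load_de_table(path, alpha: float = 0.05) -> pd.DataFrame:
    """Import an externally computed DE table (e.g. from a dedicated caller).

    Requires columns ``transcript_id, log2FC, pvalue, padj``; ``call`` is
    recomputed at the configured ``alpha`` and the padj >= pvalue
    invariant is enforced.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "log2FC", "pvalue", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    df = df.set_index("transcript_id")
    bad = df["padj"] < df["pvalue"] - 1e-12
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} rows have adjusted p below the raw p-value"
        )
    if "class" not in df.columns:
        df["class"] = "unknown"
    if "baseMean" not in df.columns:
        df["baseMean"] = np.nan
    df["call"] = np.where(
        (df["padj"] < alpha) & (df["log2FC"] > 0),
        "up",
        np.where((df["padj"] < alpha) & (df["log2FC"] < 0), "down", "unchanged"),
    )
    return df[DE_COLUMNS]
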