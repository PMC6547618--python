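"""Consensus differential expression for matched tumor-normal pairs.

A feature is called DE only when three different statistics agree at a
stringent FDR, and the per-patient signal is consistent:

1. moderated paired t on per-pair log fold changes, with empirical-Bayes
   shrinkage of the per-feature variance toward a prior estimated from all
   features (the limma-style hierarchical model, implemented from the
   standard formulas);
2. Wilcoxon signed-rank on the per-pair log fold changes (exact null for
   small cohorts, normal approximation with continuity correction
   otherwise);
3. a negative-binomial Wald test on raw counts with a tumor/normal effect
   and log-library-size offsets, with a moment dispersion estimate shrunk
   toward a trended mean-dispersion fit.

Benjamini-Hochberg q-values are computed per statistic; the consensus keeps
features passing the FDR threshold under all three.  Two per-patient
consistency criteria then apply: the direction of change must agree in more
than ``direction_frac`` of patients, and at least ``fold_frac`` of patients
must show a fold change beyond ``fold_threshold``.  miRNA mode additionally
gates on overall mean logCPM; mRNA mode gates on overall mean |logFC| and
relaxes both consistency fractions by 10 percentage points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import ExpressionMatrix, PairedCountMatrix, PatientPair
from .normalize import log_cpm, quantile_normalize

__all__ = [
    "DEConfig",
    "DEFeatureSet",
    "per_pair_logfc",
    "run_de_tests",
    "moderated_t_test",
    "wilcoxon_signed_rank",
    "nb_wald_test",
    "bh_fdr",
    "consensus_select",
    "consistency_filter",
    "select_de_features",
]

METHODS = ("modt", "wilcoxon", "nbwald")


@dataclass
class DEConfig:
    """Thresholds of the consensus DE pipeline.

    miRNA mode: FDR <= 1e-5 for all three statistics, overall mean logCPM
    >= 3, direction concordant in > 80% of patients, >= 2-fold change in
    >= 70% of patients.  mRNA mode swaps the expression gate for
    |mean logFC| > 0.5 and relaxes the consistency fractions to 70% / 60%.
    """

    mode: Literal["mirna", "mrna"] = "mirna"
    fdr_threshold: float = 1e-5
    min_avg_logcpm: float = 3.0
    min_abs_avg_logfc: float = 0.5
    direction_frac: float = 0.80
    fold_frac: float = 0.70
    fold_threshold: float = 2.0
    direction_strict: bool = True   # criterion (a): count > frac * N
    fold_strict: bool = False       # criterion (b): count >= frac * N
    min_cpm: float = 1.0            # low-expression prefilter
    min_frac_expressed: float = 0.25
    pseudocount: float = 0.5
    # Quantile normalization quantifies reported abundance; the tests and the
    # per-patient fold-change criteria run on logCPM by default, like the
    # count-based DE methods themselves.  QN forces every column onto one
    # reference distribution, so a feature already at the top rank cannot
    # show further upregulation — switch this on only deliberately.
    quantile_norm: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        for name in ("direction_frac", "fold_frac"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.fold_threshold <= 0:
            raise ValueError("fold_threshold must be positive")

    @classmethod
    def mirna(cls, **kw) -> "DEConfig":
        return cls(mode="mirna", **kw)

    @classmethod
    def mrna(cls, **kw) -> "DEConfig":
        kw.setdefault("direction_frac", 0.70)
        kw.setdefault("fold_frac", 0.60)
        return cls(mode="mrna", **kw)


class DEFeatureSet:
    """Called features plus every intermediate column, for audit.

    ``records`` has one row per tested feature with columns feature_id,
    avg_logcpm, avg_logfc, p/q per method, n_concordant, n_twofold, n_pairs,
    called, direction.  ``step_counts`` tallies features surviving each
    pipeline step.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        per_pair: pd.DataFrame,
        config: DEConfig,
        step_counts: dict[str, int],
    ):
        self.records = records
        self.per_pair = per_pair
        self.config = config
        self.step_counts = step_counts

    @property
    def called(self) -> pd.DataFrame:
        return self.records[self.records["called"]]

    def called_ids(self) -> list[str]:
        return list(self.called["feature_id"])

    def directions(self) -> dict[str, str]:
        return dict(zip(self.called["feature_id"], self.called["direction"]))

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def per_pair_logfc(expr: ExpressionMatrix, manifest: list[PatientPair]) -> pd.DataFrame:
    """Per-patient log2 fold change: logCPM(tumor) - logCPM(normal)."""
    cols = {}
    for pair in manifest:
        for sample in (pair.tumor_sample, pair.normal_sample):
            if sample not in expr.values.columns:
                raise ValueError(
                    f"sample {sample!r} of patient {pair.patient_id} missing from expression matrix"
                )
        cols[pair.patient_id] = (
            expr.values[pair.tumor_sample] - expr.values[pair.normal_sample]
        )
    return pd.DataFrame(cols, index=expr.values.index)


# --------------------------------------------------------------------------
# the three statistics


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the trigamma scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def moderated_t_test(diffs: pd.DataFrame) -> pd.Series:
    """Empirical-Bayes moderated paired t on per-pair log fold changes.

    Per-feature sample variances s^2 (df d1 = n-1) are modeled as scaled
    chi-square draws around a prior (s0^2, d0); the prior is estimated by
    moment matching on log s^2 (digamma/trigamma moments of log chi-square).
    The posterior variance (d0 s0^2 + d1 s^2) / (d0 + d1) feeds a t statistic
    with d0 + d1 degrees of freedom.
    """
    d = diffs.to_numpy(dtype=float)
    n = d.shape[1]
    if n < 3:
        raise ValueError("at least 3 pairs required")
    mean = d.mean(axis=1)
    s2 = np.maximum(d.var(axis=1, ddof=1), 1e-12)
    d1 = n - 1

    # moment matching on z = log s^2: E z = log s0^2 + psi(d1/2) - log(d1/2)
    #                                      - psi(d0/2) + log(d0/2)
    # var z = psi'(d1/2) + psi'(d0/2)
    z = np.log(s2)
    e = z - special.digamma(d1 / 2.0) + np.log(d1 / 2.0)
    evar = z.var(ddof=1) - special.polygamma(1, d1 / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_2 = np.exp(e.mean())

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = 1e8  # effectively normal
    else:
        s2_post = (d0 * s0_2 + d1 * s2) / (d0 + d1)
        df_total = d0 + d1
    t = mean / np.sqrt(s2_post / n)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.Series(p, index=diffs.index, name="p_modt")


def wilcoxon_signed_rank(diffs: pd.DataFrame, exact_max_n: int = 25) -> pd.Series:
    """Wilcoxon signed-rank on per-pair log fold changes, per feature.

    Zeros are dropped (standard Wilcoxon treatment); a feature whose pairs
    are all zero gets p = 1.  The exact null is used for n <= ``exact_max_n``
    evaluable pairs, otherwise the normal approximation with continuity
    correction.
    """
    d = diffs.to_numpy(dtype=float)
    n = d.shape[1]
    method = "exact" if n <= exact_max_n else "approx"
    p = np.ones(d.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, row in enumerate(d):
            row = row[row != 0.0]
            if row.size == 0:
                continue
            use = method if row.size <= exact_max_n else "approx"
            try:
                res = stats.wilcoxon(row, method=use, correction=(use == "approx"))
                p[i] = res.pvalue
            except ValueError:
                p[i] = 1.0
    return pd.Series(np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0),
                     index=diffs.index, name="p_wilcoxon")


def _pearson_dispersion(y: np.ndarray, mu: np.ndarray, resid_df: np.ndarray) -> np.ndarray:
    """Per-feature NB dispersion solving the Pearson moment equation.

    Finds alpha >= 0 with sum_s (y - mu)^2 / (mu (1 + alpha mu)) = resid_df,
    the standard quasi-likelihood moment condition; alpha = 0 when even the
    Poisson fit is underdispersed.
    """
    sq = (y - mu) ** 2
    alpha = np.zeros(y.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        f0 = np.where(mu > 0, sq / mu, 0.0).sum(axis=1) - resid_df
    active = f0 > 0
    a = np.full(y.shape[0], 0.1)
    for _ in range(40):
        denom = 1.0 + a[:, None] * mu
        f = np.where(mu > 0, sq / (mu * denom), 0.0).sum(axis=1) - resid_df
        fprime = -(np.where(mu > 0, sq / denom**2, 0.0)).sum(axis=1)
        step = np.where(fprime < 0, f / fprime, 0.0)
        a = np.clip(a - step, 1e-10, 1e4)
    alpha[active] = a[active]
    return alpha


def nb_wald_test(
    counts: PairedCountMatrix,
    trend_bins: int = 20,
    shrink_weight: float = 0.5,
) -> pd.Series:
    """Negative-binomial Wald test of the tumor/normal effect.

    The model per feature is log mu = beta0 + beta1 * tumor + log libsize;
    group rates have closed-form estimates (total counts over total library
    size), so beta1 is the log ratio of tumor to normal count rates.
    Dispersion comes from the Pearson moment equation, then is shrunk 50/50
    toward a trended fit (binned means of the raw estimates over mean
    expression).  The Wald variance is the delta-method variance of the
    log group-total rate, (sum mu + alpha sum mu^2) / (sum mu)^2 per group
    — the exact variance of the ratio estimator used, which exceeds the NB
    Fisher bound whenever library sizes are unequal.
    """
    y = counts.counts.to_numpy(dtype=float)
    samples = counts.sample_ids
    tumor = np.array(
        [s in {p.tumor_sample for p in counts.manifest} for s in samples]
    )
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")

    rate = {}
    for grp, mask in (("T", tumor), ("N", ~tumor)):
        rate[grp] = (y[:, mask].sum(axis=1) + 0.5) / lib[mask].sum()
    beta1 = np.log(rate["T"] / rate["N"])

    mu = np.where(tumor[None, :], rate["T"][:, None], rate["N"][:, None]) * lib[None, :]
    resid_df = np.full(y.shape[0], y.shape[1] - 2)
    alpha_raw = _pearson_dispersion(y, mu, resid_df)

    # loess-free dispersion trend: binned means over mean log expression
    mean_expr = np.log(mu.mean(axis=1) + 0.5)
    order = np.argsort(mean_expr)
    bins = np.array_split(order, min(trend_bins, max(1, y.shape[0] // 10)))
    centers, levels = [], []
    for idx in bins:
        if idx.size:
            centers.append(mean_expr[idx].mean())
            levels.append(alpha_raw[idx].mean())
    alpha_trend = np.interp(mean_expr, centers, levels)
    alpha = shrink_weight * alpha_trend + (1.0 - shrink_weight) * alpha_raw

    var_beta1 = np.zeros(y.shape[0])
    for mask in (tumor, ~tumor):
        m1 = mu[:, mask].sum(axis=1)
        m2 = (mu[:, mask] ** 2).sum(axis=1)
        var_beta1 += (m1 + alpha * m2) / m1**2
    z = beta1 / np.sqrt(var_beta1)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.Series(p, index=counts.counts.index, name="p_nbwald")


def run_de_tests(
    counts: PairedCountMatrix, expr: ExpressionMatrix
) -> pd.DataFrame:
    """All three statistics; returns columns p_modt, p_wilcoxon, p_nbwald."""
    if counts.n_pairs < 3:
        raise ValueError("at least 3 matched pairs required")
    diffs = per_pair_logfc(expr, counts.manifest)
    return pd.DataFrame(
        {
            "p_modt": moderated_t_test(diffs),
            "p_wilcoxon": wilcoxon_signed_rank(diffs),
            "p_nbwald": nb_wald_test(counts),
        }
    )


# --------------------------------------------------------------------------
# FDR, consensus, consistency


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def consensus_select(records: pd.DataFrame, cfg: DEConfig) -> pd.Series:
    """True where the feature passes the FDR threshold under all three methods."""
    ok = pd.Series(True, index=records.index)
    for m in METHODS:
        ok &= records[f"q_{m}"] <= cfg.fdr_threshold
    return ok


def consistency_filter(
    records: pd.DataFrame, per_pair: pd.DataFrame, cfg: DEConfig
) -> pd.DataFrame:
    """Apply the per-patient consistency criteria and expression gates.

    With N evaluable pairs a feature passes when (a) the majority direction
    covers more than ``direction_frac * N`` pairs (strict by default) and
    (b) at least ``fold_frac * N`` pairs change by ``fold_threshold``-fold or
    more.  Pairs with a per-pair logFC of exactly 0 count against both
    criteria.  The expression gate is mean logCPM >= ``min_avg_logcpm`` in
    miRNA mode and |mean logFC| > ``min_abs_avg_logfc`` in mRNA mode.
    """
    n_pairs = per_pair.shape[1]
    if n_pairs == 0:
        raise ValueError("no evaluable pairs")
    d = per_pair.loc[records["feature_id"]].to_numpy(dtype=float)
    n_pos = (d > 0).sum(axis=1)
    n_neg = (d < 0).sum(axis=1)
    n_concordant = np.maximum(n_pos, n_neg)
    n_twofold = (np.abs(d) >= np.log2(cfg.fold_threshold)).sum(axis=1)

    if cfg.direction_strict:
        pass_a = n_concordant > cfg.direction_frac * n_pairs
    else:
        pass_a = n_concordant >= cfg.direction_frac * n_pairs
    if cfg.fold_strict:
        pass_b = n_twofold > cfg.fold_frac * n_pairs
    else:
        pass_b = n_twofold >= cfg.fold_frac * n_pairs

    if cfg.mode == "mirna":
        gate = records["avg_logcpm"].to_numpy() >= cfg.min_avg_logcpm
    else:
        gate = np.abs(records["avg_logfc"].to_numpy()) > cfg.min_abs_avg_logfc

    majority_up = n_pos > n_neg
    majority_down = n_neg > n_pos
    decided = majority_up | majority_down
    consensus = (
        records["consensus"].to_numpy()
        if "consensus" in records.columns
        else np.ones(len(records), dtype=bool)
    )
    called = consensus & pass_a & pass_b & gate & decided
    direction = np.where(called & majority_up, "up",
                np.where(called & majority_down, "down", "none"))

    out = records.copy()
    out["n_concordant"] = n_concordant
    out["n_twofold"] = n_twofold
    out["n_pairs"] = n_pairs
    out["called"] = called
    out["direction"] = direction
    return out


def select_de_features(
    counts: PairedCountMatrix,
    cfg: Optional[DEConfig] = None,
) -> DEFeatureSet:
    """Run the full consensus pipeline on one matched count matrix.

    Steps: low-expression prefilter -> logCPM (+ quantile normalization in
    miRNA mode) -> three statistics -> per-method BH -> three-way consensus
    -> expression/fold gates and per-patient consistency.  Every intermediate
    quantity is retained in the returned records for audit.
    """
    cfg = cfg or DEConfig()
    step_counts: dict[str, int] = {"input": len(counts.feature_ids)}

    # low-expression prefilter on raw CPM
    raw = counts.counts.to_numpy(dtype=float)
    cpm = raw / raw.sum(axis=0, keepdims=True) * 1e6
    keep = (cpm > cfg.min_cpm).mean(axis=1) >= cfg.min_frac_expressed
    filtered = counts.subset_features(
        [f for f, k in zip(counts.feature_ids, keep) if k]
    )
    step_counts["prefilter"] = len(filtered.feature_ids)

    expr = log_cpm(filtered, cfg.pseudocount)
    if cfg.quantile_norm:
        expr = quantile_normalize(expr)

    diffs = per_pair_logfc(expr, filtered.manifest)
    pvals = run_de_tests(filtered, expr)

    records = pd.DataFrame(
        {
            "feature_id": filtered.feature_ids,
            "avg_logcpm": expr.values.mean(axis=1).to_numpy(),
            "avg_logfc": diffs.mean(axis=1).to_numpy(),
        },
        index=filtered.feature_ids,
    )
    for m in METHODS:
        records[f"p_{m}"] = pvals[f"p_{m}"]
        records[f"q_{m}"] = bh_fdr(pvals[f"p_{m}"].to_numpy())

    records["consensus"] = consensus_select(records, cfg)
    step_counts["consensus"] = int(records["consensus"].sum())

    records = consistency_filter(records, diffs, cfg)
    step_counts["called"] = int(records["called"].sum())

    order = [
        "feature_id", "avg_logcpm", "avg_logfc",
        "p_modt", "p_wilcoxon", "p_nbwald",
        "q_modt", "q_wilcoxon", "q_nbwald",
        "n_concordant", "n_twofold", "n_pairs", "consensus", "called", "direction",
    ]
    return DEFeatureSet(records[order], diffs, cfg, step_counts)
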