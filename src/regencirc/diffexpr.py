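"""Count normalization and differential expression calling.

Two designs are supported, matching the asymmetric study layout:

* replicated (the anchor species, n >= 2 per group): a conditional
  negative-binomial exact test on the group sums of library-size-equalized
  counts, with a single method-of-moments common dispersion and
  Benjamini-Hochberg FDR control;
* unreplicated (single sample per group): fold-change-only calls with a
  strict |log2FC| threshold and no p-values.

The NB model is parameterized as mean mu, variance mu + phi * mu^2; phi = 0
is the Poisson limit, in which the exact test reduces to the two-sided
exact binomial test on the split of the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 0.5
FC_THRESHOLD = 0.58  # strict |log2FC| cutoff for unreplicated designs
ALPHA = 0.05


@dataclass
class CountMatrix:
    """Features-by-samples raw counts with group labels ctrl / case."""

    counts: pd.DataFrame
    groups: dict[str, str]  # sample -> "ctrl" | "case"
    lib_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        bad = set(self.groups.values()) - {"ctrl", "case"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_sizes = self.lib_sizes.reindex(self.counts.columns).astype(float)
            if self.lib_sizes.isna().any() or (self.lib_sizes <= 0).any():
                raise ValueError("lib_sizes must be positive for every sample")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]

    @property
    def is_replicated(self) -> bool:
        return min(len(self.samples_in("ctrl")), len(self.samples_in("case"))) >= 2


def cpm(
    counts: pd.DataFrame,
    lib_sizes: pd.Series,
    pseudocount: float = PSEUDOCOUNT,
) -> tuple[pd.DataFrame, pd.Series]:
    """Counts-per-million and per-feature mean log2 CPM.

    Raw CPM columns sum to 1e6; the pseudocount enters only the log
    transform, scaled to CPM units by the mean library size.
    """
    if (lib_sizes <= 0).any():
        raise ValueError("lib_sizes must be positive")
    cpm_df = counts.div(lib_sizes, axis=1) * 1e6
    offset = pseudocount * 1e6 / float(lib_sizes.mean())
    log_cpm = np.log2(cpm_df.mean(axis=1) + offset)
    return cpm_df, log_cpm


def log2fc_unreplicated(
    cpm_case: float | np.ndarray | pd.Series,
    cpm_ctrl: float | np.ndarray | pd.Series,
    pseudocount: float = PSEUDOCOUNT,
):
    """log2((case + c) / (ctrl + c)) on CPM values; c guards zeros."""
    return np.log2((np.asarray(cpm_case, dtype=float) + pseudocount)
                   / (np.asarray(cpm_ctrl, dtype=float) + pseudocount))


def _normalized_counts(cm: CountMatrix) -> pd.DataFrame:
    """Counts rescaled to the mean library size (plain CPM-style scaling)."""
    target = float(cm.lib_sizes.mean())
    return cm.counts.div(cm.lib_sizes, axis=1) * target


def estimate_dispersion(cm: CountMatrix) -> float:
    """Common NB dispersion by the method of moments.

    Per feature, on library-size-normalized counts: pooled within-group
    variance s^2 and grand mean m over groups with >= 2 replicates give
    phi_f = max(0, (s^2 - m) / m^2); the estimate is the median of phi_f
    over features with m > 0.
    """
    groups = [g for g in ("ctrl", "case") if len(cm.samples_in(g)) >= 2]
    if not groups:
        raise ValueError("dispersion estimation requires >=2 replicates in a group")
    norm = _normalized_counts(cm)
    ss = pd.Series(0.0, index=norm.index)
    df = 0
    used_cols: list[str] = []
    for g in groups:
        cols = cm.samples_in(g)
        sub = norm[cols]
        ss += ((sub.sub(sub.mean(axis=1), axis=0)) ** 2).sum(axis=1)
        df += len(cols) - 1
        used_cols += cols
    s2 = ss / df
    m = norm[used_cols].mean(axis=1)
    mask = m > 0
    if not mask.any():
        return 0.0
    phi = np.maximum(0.0, (s2[mask] - m[mask]) / m[mask] ** 2)
    return float(np.median(phi))


def _split_log_pmf(total: int, n_ctrl: int, n_case: int, phi: float) -> np.ndarray:
    """Log joint pmf of (S_ctrl = a, S_case = T - a) for a = 0..T under the
    null: group sums are NB with means proportional to group size and
    common per-sample dispersion phi (so group dispersion phi / n_g)."""
    a = np.arange(total + 1)
    mu = total / (n_ctrl + n_case)  # per-sample null mean, conditioned on T
    if phi <= 1e-8:  # Poisson limit (avoids NB size overflow)
        return stats.poisson.logpmf(a, n_ctrl * mu) + stats.poisson.logpmf(
            total - a, n_case * mu
        )
    r1, r2 = n_ctrl / phi, n_case / phi
    p1 = r1 / (r1 + n_ctrl * mu)
    p2 = r2 / (r2 + n_case * mu)
    return stats.nbinom.logpmf(a, r1, p1) + stats.nbinom.logpmf(total - a, r2, p2)


def nb_exact_test(
    sum_ctrl: float,
    sum_case: float,
    n_ctrl: int,
    n_case: int,
    phi: float,
) -> float:
    """Conditional two-sided NB exact test on the split of the total.

    Given T = sum_ctrl + sum_case, the p-value sums the conditional
    probabilities of all splits at most as probable as the observed one.
    phi = 0 reduces to the two-sided exact binomial test with success
    probability n_case / (n_ctrl + n_case).
    """
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    if min(n_ctrl, n_case) < 1:
        raise ValueError("group sizes must be >= 1")
    if sum_ctrl < 0 or sum_case < 0:
        raise ValueError("group sums must be >= 0")
    a_obs = int(round(sum_ctrl))
    total = a_obs + int(round(sum_case))
    if total == 0:
        return 1.0
    logp = _split_log_pmf(total, n_ctrl, n_case, phi)
    # normalize in log space, then sum the tail of splits no more probable
    # than the observed one (small relative tolerance for float ties)
    logz = np.logaddexp.reduce(logp)
    prob = np.exp(logp - logz)
    p_obs = prob[a_obs]
    return float(min(1.0, prob[prob <= p_obs * (1.0 + 1e-10)].sum()))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de_replicated(
    cm: CountMatrix,
    alpha: float = ALPHA,
    phi: float | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """NB-exact-test differential expression for a replicated design.

    Returns one row per feature: log2fc (case vs ctrl, on mean CPM with a
    pseudocount), log_cpm, p_value, fdr and de_flag in {up, down, ns} with
    de_flag significant iff fdr < alpha.
    """
    if not cm.is_replicated:
        raise ValueError("replicated caller requires >=2 replicates per group")
    if cm.counts.empty:
        return pd.DataFrame(
            columns=["log2fc", "log_cpm", "p_value", "fdr", "de_flag"]
        )
    if phi is None:
        phi = estimate_dispersion(cm)
    ctrl_cols = cm.samples_in("ctrl")
    case_cols = cm.samples_in("case")
    cpm_df, log_cpm = cpm(cm.counts, cm.lib_sizes, pseudocount)
    lfc = log2fc_unreplicated(
        cpm_df[case_cols].mean(axis=1), cpm_df[ctrl_cols].mean(axis=1), pseudocount
    )
    norm = _normalized_counts(cm)
    sum_ctrl = norm[ctrl_cols].sum(axis=1)
    sum_case = norm[case_cols].sum(axis=1)
    pvals = np.array(
        [
            nb_exact_test(a, b, len(ctrl_cols), len(case_cols), phi)
            for a, b in zip(sum_ctrl, sum_case)
        ]
    )
    fdr = bh_fdr(pvals)
    flags = np.where(
        (fdr < alpha) & (lfc > 0), "up", np.where((fdr < alpha) & (lfc < 0), "down", "ns")
    )
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "log_cpm": log_cpm,
            "p_value": pvals,
            "fdr": fdr,
            "de_flag": flags,
        },
        index=cm.counts.index,
    )


def call_de_unreplicated(
    cm: CountMatrix,
    fc_threshold: float = FC_THRESHOLD,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Fold-change-only differential expression for one-vs-one designs.

    de_flag is up iff log2fc > +fc_threshold and down iff
    log2fc < -fc_threshold (strict comparisons); p-value and FDR columns
    are absent (NaN).
    """
    ctrl_cols = cm.samples_in("ctrl")
    case_cols = cm.samples_in("case")
    if len(ctrl_cols) != 1 or len(case_cols) != 1:
        raise ValueError("unreplicated caller requires exactly one sample per group")
    if fc_threshold < 0:
        raise ValueError("fc_threshold must be >= 0")
    cpm_df, log_cpm = cpm(cm.counts, cm.lib_sizes, pseudocount)
    lfc = log2fc_unreplicated(
        cpm_df[case_cols[0]], cpm_df[ctrl_cols[0]], pseudocount
    )
    lfc = pd.Series(lfc, index=cm.counts.index)
    flags = np.where(
        lfc > fc_threshold, "up", np.where(lfc < -fc_threshold, "down", "ns")
    )
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "log_cpm": log_cpm,
            "p_value": np.nan,
            "fdr": np.nan,
            "de_flag": flags,
        },
        index=cm.counts.index,
    )
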