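"""Enrichment and differential-TE statistics.

Two experiment layouts are analysed:

* FACS binning — per-variant TPM abundances across sort bins and biological
  replicates; a variant is called enriched in a bin when its TPM replicates
  in that bin exceed every other bin with all pairwise two-tailed t-tests
  below alpha (and the most-abundant-bin rule is reported alongside).
* temperature series — per-variant TE across expression temperatures; all
  temperature pairs are compared with two-tailed two-sample t-tests.

t-tests are pooled-variance Student tests by default.  For the per-variant
"any condition pair differs" flag, raw any-pair-below-alpha testing inflates
the per-variant false-positive rate well above alpha (six correlated pairs
for four temperatures), so the default flag applies a Holm correction across
the pairs within each variant, keeping the per-variant type-I error at
~alpha; ``correction="none"`` reproduces the uncorrected rule.  A
``df_override`` is available to force a non-standard t degrees-of-freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BinEnrichmentResult",
    "DifferentialTEResult",
    "pooled_t_test",
    "bin_enrichment",
    "differential_te",
    "te_strength_variance_summary",
]


def pooled_t_test(a, b, df_override: int | None = None) -> tuple[float, float]:
    """Two-tailed two-sample Student t-test with pooled variance.

    Degenerate groups are resolved deterministically: if both groups are
    constant, p = 1.0 when the means coincide and 0.0 otherwise.
    Returns ``(t, p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 replicates")
    sp2 = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / (a.size + b.size - 2)
    if sp2 == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf if a.mean() > b.mean() else -np.inf, 0.0
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    df = a.size + b.size - 2 if df_override is None else df_override
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def _holm(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def _benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        prev = min(prev, p[idx] * m / (rank + 1))
        adj[idx] = prev
    return adj


# ---------------------------------------------------------------------------
# FACS bin enrichment


@dataclass
class BinEnrichmentResult:
    variant_id: str
    mean_tpm: dict  # bin -> mean TPM over replicates
    most_abundant_bin: str
    p_values: dict  # bin -> {other_bin: p}
    enriched_bin: str | None
    significant: bool


def bin_enrichment(
    tpm_table: pd.DataFrame,
    alpha: float = 0.05,
    df_override: int | None = None,
) -> list[BinEnrichmentResult]:
    """Per-variant FACS-bin enrichment calls.

    ``tpm_table`` is long format with columns (variant_id, bin, replicate,
    tpm).  A variant absent from a (bin, replicate) is treated as TPM 0 —
    after sorting, absence from a bin is informative.  Each bin needs >= 2
    replicates overall.
    """
    required = {"variant_id", "bin", "replicate", "tpm"}
    if not required <= set(tpm_table.columns):
        raise ValueError(f"tpm_table must have columns {sorted(required)}")
    bins = list(pd.unique(tpm_table["bin"]))
    reps = sorted(pd.unique(tpm_table["replicate"]))
    for b in bins:
        n = tpm_table.loc[tpm_table["bin"] == b, "replicate"].nunique()
        if n < 2:
            raise ValueError(f"bin {b!r} has fewer than 2 replicates")

    wide = (
        tpm_table.pivot_table(
            index="variant_id", columns=["bin", "replicate"], values="tpm",
            fill_value=0.0, aggfunc="sum",
        )
        .reindex(columns=pd.MultiIndex.from_product([bins, reps]), fill_value=0.0)
    )
    results = []
    for vid, row in wide.iterrows():
        groups = {b: row[b].to_numpy(dtype=float) for b in bins}
        means = {b: float(g.mean()) for b, g in groups.items()}
        most = max(bins, key=lambda b: means[b])
        pvals: dict = {}
        enriched = None
        for b in bins:
            pvals[b] = {
                o: pooled_t_test(groups[b], groups[o], df_override)[1]
                for o in bins
                if o != b
            }
        candidates = [
            b
            for b in bins
            if all(p < alpha for p in pvals[b].values())
            and all(means[b] > means[o] for o in bins if o != b)
        ]
        if candidates:
            enriched = max(candidates, key=lambda b: means[b])
        results.append(
            BinEnrichmentResult(
                variant_id=str(vid),
                mean_tpm=means,
                most_abundant_bin=most,
                p_values=pvals,
                enriched_bin=enriched,
                significant=enriched is not None,
            )
        )
    return results


# ---------------------------------------------------------------------------
# differential TE across temperatures


@dataclass
class DifferentialTEResult:
    variant_id: str
    te_mean: dict  # condition -> mean
    te_sd: dict
    p_values: pd.DataFrame  # symmetric condition x condition matrix
    p_adjusted: pd.DataFrame
    max_difference: float  # percentage points
    max_difference_pair: tuple | None
    significant: bool


def differential_te(
    te_table: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "holm",
    df_override: int | None = None,
) -> list[DifferentialTEResult]:
    """Pairwise differential-TE tests per variant across conditions.

    ``te_table`` is long format with columns (variant_id, condition,
    replicate, te), TE in percent.  All condition pairs are tested with
    pooled two-tailed t-tests; the per-variant ``significant`` flag is set
    when any pair's corrected p-value falls below ``alpha``
    (``correction`` one of "holm", "bh", "none").  With a single condition
    the pair set is empty and the flag is False.
    """
    required = {"variant_id", "condition", "replicate", "te"}
    if not required <= set(te_table.columns):
        raise ValueError(f"te_table must have columns {sorted(required)}")
    if correction not in ("holm", "bh", "none"):
        raise ValueError("correction must be one of 'holm', 'bh', 'none'")
    conditions = list(pd.unique(te_table["condition"]))
    results = []
    for vid, sub in te_table.groupby("variant_id", sort=True):
        groups = {}
        for cond in conditions:
            vals = sub.loc[sub["condition"] == cond, "te"].to_numpy(dtype=float)
            if vals.size == 0:
                raise ValueError(f"variant {vid}: missing condition {cond!r}")
            if vals.size < 2 and len(conditions) > 1:
                raise ValueError(
                    f"variant {vid}: condition {cond!r} has fewer than 2 replicates"
                )
            groups[cond] = vals
        pmat = pd.DataFrame(np.nan, index=conditions, columns=conditions)
        pairs = list(combinations(conditions, 2))
        raw = []
        for a, b in pairs:
            _, p = pooled_t_test(groups[a], groups[b], df_override)
            raw.append(p)
            pmat.loc[a, b] = pmat.loc[b, a] = p
        if raw:
            if correction == "holm":
                adj = _holm(raw)
            elif correction == "bh":
                adj = _benjamini_hochberg(raw)
            else:
                adj = np.asarray(raw)
        else:
            adj = np.array([])
        amat = pd.DataFrame(np.nan, index=conditions, columns=conditions)
        for (a, b), pa in zip(pairs, adj):
            amat.loc[a, b] = amat.loc[b, a] = pa
        means = {c: float(g.mean()) for c, g in groups.items()}
        max_pair, max_diff = None, 0.0
        for a, b in pairs:
            d = abs(means[a] - means[b])
            if d >= max_diff:
                max_diff, max_pair = d, (a, b)
        results.append(
            DifferentialTEResult(
                variant_id=str(vid),
                te_mean=means,
                te_sd={c: float(g.std(ddof=1)) if g.size >= 2 else np.nan
                       for c, g in groups.items()},
                p_values=pmat,
                p_adjusted=amat,
                max_difference=max_diff,
                max_difference_pair=max_pair,
                significant=bool(adj.size and np.nanmin(adj) < alpha),
            )
        )
    return results


# ---------------------------------------------------------------------------
# TE variance vs strength


def te_strength_variance_summary(calls: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-variant (mean TE, SD, SD/mean) plus the Spearman rank correlation
    of mean TE with SD/mean.

    ``calls`` needs columns ``variant_id`` and ``te_replicates`` (list of
    replicate TE values, percent), as produced by
    :func:`qtermseq.pipeline.quantify_replicates`; alternatively ``te_mean``
    and ``te_sd`` columns are used directly.
    """
    if "te_replicates" in calls.columns:
        mean = calls["te_replicates"].map(lambda v: float(np.mean(v)))
        sd = calls["te_replicates"].map(
            lambda v: float(np.std(v, ddof=1)) if len(v) >= 2 else np.nan
        )
    elif {"te_mean", "te_sd"} <= set(calls.columns):
        mean, sd = calls["te_mean"], calls["te_sd"]
    else:
        raise ValueError("calls must carry te_replicates or te_mean/te_sd")
    out = pd.DataFrame(
        {
            "variant_id": calls["variant_id"],
            "te_mean": mean,
            "te_sd": sd,
            "sd_over_mean": sd / mean.replace(0, np.nan),
        }
    )
    valid = out.dropna(subset=["te_mean", "sd_over_mean"])
    if len(valid) >= 3 and valid["te_mean"].nunique() > 1:
        rho = float(
            sps.spearmanr(valid["te_mean"], valid["sd_over_mean"]).statistic
        )
    else:
        rho = float("nan")
    return out, rho
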