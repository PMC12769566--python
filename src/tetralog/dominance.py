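"""Subgenome expression-dominance classification for retained homoeolog pairs.

For each fully retained A/B pair, per tissue: the relative expression of the
B copy, RE_B = TPM(B) / (TPM(A) + TPM(B)), is computed per replicate and
averaged; pairs whose combined TPM falls below 1 in ANY sample are excluded
globally, and a tissue call is dropped when any replicate RE_B is a
significant outlier. Categories: A-dominant (0 <= RE_B <= 0.2), balanced
(0.2 < RE_B < 0.8), B-dominant (0.8 <= RE_B <= 1). Pairs whose non-excluded
tissue categories all agree are stable, otherwise dynamic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = ("A_dominant", "balanced", "B_dominant")
EXCLUDED = "excluded"


def relative_expression(tpm_a: float, tpm_b: float) -> tuple[float, float]:
    """(RE_A, RE_B); undefined when both TPMs are zero."""
    total = tpm_a + tpm_b
    if total <= 0:
        raise ValueError("relative expression undefined for zero combined TPM")
    return tpm_a / total, tpm_b / total


def flag_low_expression(tpm_a: pd.Series | np.ndarray,
                        tpm_b: pd.Series | np.ndarray,
                        threshold: float = 1.0) -> bool:
    """True iff the pair's combined TPM is strictly below ``threshold`` in at
    least one sample (such pairs are excluded from all dominance statistics)."""
    total = np.asarray(tpm_a, dtype=float) + np.asarray(tpm_b, dtype=float)
    return bool((total < threshold).any())


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value for sample size n."""
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def has_outlier(values: np.ndarray, alpha: float = 0.05,
                method: str = "grubbs") -> bool:
    """Significant-outlier screen across replicates.

    ``grubbs``: two-sided Grubbs test (valid for small n); automatically
    falls back to a Bonferroni-adjusted z-score rule for n > 25, where the
    Grubbs critical value is numerically indistinguishable from it.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        return False
    sd = values.std(ddof=1)
    if sd == 0:
        return False
    g = np.max(np.abs(values - values.mean())) / sd
    if method == "zscore" or (method == "grubbs" and n > 25):
        return g > stats.norm.ppf(1 - alpha / (2 * n))
    if method == "grubbs":
        return g > grubbs_critical(n, alpha)
    raise ValueError(f"unknown outlier method {method!r}")


def tissue_re(tpm_a: np.ndarray, tpm_b: np.ndarray, alpha: float = 0.05,
              outlier_method: str = "grubbs") -> float | None:
    """Final RE_B for one pair in one tissue: mean over replicate RE_B values,
    or None (excluded) when any replicate is a significant outlier."""
    tpm_a = np.asarray(tpm_a, dtype=float)
    tpm_b = np.asarray(tpm_b, dtype=float)
    if len(tpm_a) < 2:
        warnings.warn("single replicate; using its RE_B directly", stacklevel=2)
    re_b = tpm_b / (tpm_a + tpm_b)
    if has_outlier(re_b, alpha=alpha, method=outlier_method):
        return None
    return float(re_b.mean())


def classify_dominance(re_b: float) -> str:
    if not 0 <= re_b <= 1:
        raise ValueError(f"RE_B out of [0, 1]: {re_b}")
    if re_b <= 0.2:
        return "A_dominant"
    if re_b < 0.8:
        return "balanced"
    return "B_dominant"


def classify_stability(categories: list[str]) -> str | None:
    """Stable iff all non-excluded tissue categories agree; None when no
    tissue is assessable."""
    seen = [c for c in categories if c != EXCLUDED]
    if not seen:
        return None
    return "stable" if len(set(seen)) == 1 else "dynamic"


def dominance_calls(tpm: pd.DataFrame, samples: pd.DataFrame,
                    pairs: pd.DataFrame, alpha: float = 0.05,
                    low_expression_threshold: float = 1.0,
                    outlier_method: str = "grubbs"
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair per-tissue dominance calls plus per-pair stability labels.

    ``tpm``: genes x samples matrix. ``samples``: sample_id, tissue,
    replicate. ``pairs``: pair_id, gene_A, gene_B.

    Returns (calls, stability). ``calls`` has one row per retained,
    not-low-expressed pair and tissue with the final RE_B (NaN when the
    tissue was excluded by the replicate-outlier rule) and the category.
    """
    missing = (set(pairs["gene_A"]) | set(pairs["gene_B"])) - set(tpm.index)
    if missing:
        raise KeyError(f"pair genes absent from TPM matrix: {sorted(missing)[:5]}...")
    sample_ids = samples["sample_id"].tolist()
    tissue_cols = {t: grp["sample_id"].tolist()
                   for t, grp in samples.groupby("tissue", sort=False)}

    a_all = tpm.loc[pairs["gene_A"], sample_ids].to_numpy(dtype=float)
    b_all = tpm.loc[pairs["gene_B"], sample_ids].to_numpy(dtype=float)
    low = ((a_all + b_all) < low_expression_threshold).any(axis=1)

    col_pos = {s: i for i, s in enumerate(sample_ids)}
    call_rows, stab_rows = [], []
    for i, pair_id in enumerate(pairs["pair_id"]):
        if low[i]:
            continue
        categories = []
        for tissue, cols in tissue_cols.items():
            pos = [col_pos[c] for c in cols]
            re_b = tissue_re(a_all[i, pos], b_all[i, pos], alpha=alpha,
                             outlier_method=outlier_method)
            category = EXCLUDED if re_b is None else classify_dominance(re_b)
            categories.append(category)
            call_rows.append({"pair_id": pair_id, "tissue": tissue,
                              "re_b": np.nan if re_b is None else re_b,
                              "category": category})
        label = classify_stability(categories)
        if label is not None:
            stab_rows.append({"pair_id": pair_id, "stability": label,
                              "n_tissues": sum(c != EXCLUDED for c in categories)})
    calls = pd.DataFrame(call_rows, columns=["pair_id", "tissue", "re_b", "category"])
    stability = pd.DataFrame(stab_rows, columns=["pair_id", "stability", "n_tissues"])
    return calls, stability


def dominance_summary(calls: pd.DataFrame,
                      stability: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-tissue percentages of A-dominant / balanced / B-dominant among
    non-excluded pairs (each row sums to 100), plus an `overall` row; when
    ``stability`` is given, stable/dynamic percentages are appended as
    attrs."""
    assessable = calls[calls["category"] != EXCLUDED]
    if assessable.empty:
        raise ValueError("no assessable pairs")
    rows = []
    groups = list(assessable.groupby("tissue", sort=False))
    groups.append(("overall", assessable))
    for tissue, grp in groups:
        n = len(grp)
        counts = grp["category"].value_counts()
        rows.append({
            "tissue": tissue,
            "n_pairs": n,
            "A_dominant_pct": 100.0 * counts.get("A_dominant", 0) / n,
            "balanced_pct": 100.0 * counts.get("balanced", 0) / n,
            "B_dominant_pct": 100.0 * counts.get("B_dominant", 0) / n,
        })
    summary = pd.DataFrame(rows)
    if stability is not None and len(stability):
        stable_pct = 100.0 * (stability["stability"] == "stable").mean()
        summary.attrs["stable_pct"] = float(stable_pct)
        summary.attrs["dynamic_pct"] = float(100.0 - stable_pct)
    return summary
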