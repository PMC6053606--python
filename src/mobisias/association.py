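"""Association analyses between mobility features and SIAS scores.

Implements the study-style tables: per-epoch Pearson correlations between
per-participant mean daily staying time and SIAS, weekday/weekend
high-vs-low group comparisons (Welch unpaired t-test on mean daily
minutes), the entropy correlation, and the filtered transition-frequency
correlation table.  No multiple-testing correction is applied by default
(matching the original exploratory analysis); an optional
Benjamini-Hochberg flag is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .features import EPOCHS, FeatureTable
from .io import SIAS_CUTOFF
from .labeling import CLASSES, NON_TRANSITION_CLASSES

__all__ = [
    "pearson_with_p",
    "epoch_correlation_table",
    "group_comparison",
    "entropy_correlation",
    "transition_correlation_table",
    "participant_means",
]

DEFAULT_R_MIN = 0.2
DEFAULT_P_MAX = 0.05
TRANSITION_P_MAX = 0.01  # the transition table uses the stricter threshold


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-transform p-value.

    Requires equal lengths >= 3, finite values and nonzero variance in
    both; otherwise returns (nan, nan) — the caller flags the record as
    undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        return float("nan"), float("nan")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        m = np.isfinite(x) & np.isfinite(y)
        x, y = x[m], y[m]
        if x.size < 3:
            return float("nan"), float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _bh_adjust(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values (optional user flag)."""
    pv = p.to_numpy(dtype=float)
    n = np.isfinite(pv).sum()
    order = np.argsort(np.where(np.isfinite(pv), pv, np.inf))
    adj = np.full_like(pv, np.nan)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[:n][::-1]):
        rank = n - rank_from_end
        val = min(prev, pv[idx] * n / rank)
        adj[idx] = val
        prev = val
    return pd.Series(adj, index=p.index)


def participant_means(
    minutes: pd.DataFrame,
    day_type: str | None = None,
) -> pd.DataFrame:
    """Per-participant means of daily values, optionally for one day type.

    ``day_type`` is ``"weekday"``, ``"weekend"`` or None (all days).
    Days with no labeled interval contribute nothing.
    """
    df = minutes
    if day_type == "weekday":
        df = df[df["is_weekend"] == 0.0]
    elif day_type == "weekend":
        df = df[df["is_weekend"] == 1.0]
    elif day_type is not None:
        raise ValueError(f"unknown day_type {day_type!r}")
    return df.groupby(level="participant_id").mean()


def epoch_correlation_table(
    table: FeatureTable,
    sias: dict[str, int],
    epoch: str = "daily",
    day_type: str | None = None,
    r_min: float = DEFAULT_R_MIN,
    p_max: float = DEFAULT_P_MAX,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of mean daily staying minutes vs SIAS, per class."""
    if epoch not in EPOCHS:
        raise ValueError(f"unknown epoch {epoch!r}")
    means = participant_means(table.minutes, day_type)
    y = np.array([sias[p] for p in means.index])
    rows = []
    for cls in CLASSES:
        if cls == "Transition":
            continue
        x = means[f"min_{cls}_{epoch}"].to_numpy()
        r, p = pearson_with_p(x, y)
        rows.append(
            {
                "class": cls,
                "epoch": epoch,
                "r": r,
                "p": p,
                "n": len(y),
                "undefined": not np.isfinite(r),
            }
        )
    out = pd.DataFrame(rows).set_index("class")
    if bh_correct:
        out["p"] = _bh_adjust(out["p"])
    out["significant"] = (out["r"].abs() > r_min) & (out["p"] < p_max)
    return out


def group_comparison(
    table: FeatureTable,
    sias: dict[str, int],
    day_type: str,
    cutoff: int = SIAS_CUTOFF,
    equal_var: bool = False,
    p_max: float = DEFAULT_P_MAX,
) -> pd.DataFrame:
    """High-vs-low SIAS comparison of mean daily minutes per class.

    Welch's unpaired two-sample t-test by default (``equal_var=True`` for
    the pooled-variance variant).
    """
    means = participant_means(table.minutes, day_type)
    groups = np.array([("high" if sias[p] >= cutoff else "low") for p in means.index])
    if (groups == "high").sum() == 0 or (groups == "low").sum() == 0:
        raise ValueError("both SIAS groups must be non-empty")
    underpowered = (groups == "high").sum() < 2 or (groups == "low").sum() < 2
    rows = []
    for cls in CLASSES:
        if cls == "Transition":
            continue
        x = means[f"min_{cls}_daily"].to_numpy()
        hi, lo = x[groups == "high"], x[groups == "low"]
        if underpowered or np.ptp(x) == 0:
            t = p = float("nan")
        else:
            t, p = stats.ttest_ind(hi, lo, equal_var=equal_var)
        rows.append(
            {
                "class": cls,
                "day_type": day_type,
                "mean_high_min": float(hi.mean()),
                "mean_low_min": float(lo.mean()),
                "t": float(t),
                "p": float(p),
                "underpowered": underpowered,
            }
        )
    out = pd.DataFrame(rows).set_index("class")
    out["significant"] = out["p"] < p_max
    return out


def entropy_correlation(
    table: FeatureTable,
    sias: dict[str, int],
    day_type: str | None = None,
) -> dict:
    """Pearson record for mean daily location entropy vs SIAS."""
    means = participant_means(table.minutes, day_type)
    y = np.array([sias[p] for p in means.index])
    r, p = pearson_with_p(means["entropy"].to_numpy(), y)
    return {
        "feature": "entropy",
        "day_type": day_type or "all",
        "r": r,
        "p": p,
        "n": len(y),
        "undefined": not np.isfinite(r),
    }


def transition_correlation_table(
    table: FeatureTable,
    sias: dict[str, int],
    r_min: float = DEFAULT_R_MIN,
    p_max: float = TRANSITION_P_MAX,
    filtered: bool = True,
) -> pd.DataFrame:
    """Correlations of per-participant mean daily transition counts vs SIAS.

    Pairs never observed in the cohort are excluded.  With ``filtered``
    (default), only records with |r| > r_min and p < p_max are retained,
    mirroring the published table; pass ``filtered=False`` (or r_min=0,
    p_max=1) for all observed pairs.
    """
    feats = table.features
    per_part = feats.groupby(level="participant_id").mean()
    y = np.array([sias[p] for p in per_part.index])
    rows = []
    for a in NON_TRANSITION_CLASSES:
        for bcls in NON_TRANSITION_CLASSES:
            col = f"trans_{a}__{bcls}"
            obs = int(feats[col].sum())
            if obs == 0:
                continue
            r, p = pearson_with_p(per_part[col].to_numpy(), y)
            rows.append(
                {
                    "from": a,
                    "to": bcls,
                    "observations": obs,
                    "r": r,
                    "p": p,
                    "n": len(y),
                }
            )
    out = pd.DataFrame(rows, columns=["from", "to", "observations", "r", "p", "n"])
    if filtered and len(out):
        out = out[(out["r"].abs() > r_min) & (out["p"] < p_max)]
    return out.reset_index(drop=True)
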