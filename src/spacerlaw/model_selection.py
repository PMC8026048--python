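"""Pairwise loglikelihood-ratio model selection between heavy-tailed families.

Implements the Vuong-style normalized loglikelihood-ratio test used
throughout heavy-tailed fitting practice: for two fitted families with
pointwise log-likelihoods l1_j, l2_j on the same observations,

    R       = sum_j (l1_j - l2_j)
    sigma^2 = (1/n) sum_j [(l1_j - l2_j) - mean(l1 - l2)]^2
    p       = 2 * Phi_bar(|R| / (sigma * sqrt(n)))

A positive R favours the first family; the sign is only trusted when p is
below the significance threshold (default 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import FAMILIES, FitError, FitResult, fit_mle, log_pmf

__all__ = ["ComparisonResult", "loglik_ratio", "rank_candidates",
           "per_group_best_fit", "DEFAULT_CANDIDATES"]

#: candidate ordering of the ranking table: the reference truncated power law
#: against each alternative, in the conventional report order
DEFAULT_CANDIDATES = ("exponential", "stretched_exponential", "lognormal", "powerlaw")

REFERENCE_FAMILY = "truncated_powerlaw"


@dataclass
class ComparisonResult:
    """One pairwise family comparison (positive R favours ``family_1``)."""

    family_1: str
    family_2: str
    R: float
    sigma: float
    p_value: float
    n: float
    preferred: str  # family name or "indeterminate"
    error: Optional[str] = None


def loglik_ratio(fit1: FitResult, fit2: FitResult, data: Sequence[int],
                 weights: Optional[Sequence[float]] = None,
                 significance: float = 0.05,
                 one_sided: bool = False) -> ComparisonResult:
    """Normalized loglikelihood-ratio comparison of two fitted families.

    Both fits must have been produced from ``data`` with the same support
    minimum.  ``weights`` allows comparing fits to a weighted sample (model
    output) — n is then the total weight.
    """
    data = np.asarray(data)
    if data.size == 0:
        raise ValueError("empty data")
    if fit1.i_min != fit2.i_min:
        raise ValueError("fits use different i_min")
    keep = data >= fit1.i_min
    if weights is not None:
        weights = np.asarray(weights, dtype=float)[keep]
    data = data[keep]

    d = log_pmf(fit1.spec, data) - log_pmf(fit2.spec, data)
    if weights is None:
        n = float(data.size)
        R = float(np.sum(d))
        var = float(np.mean((d - np.mean(d)) ** 2))
    else:
        n = float(np.sum(weights))
        R = float(np.dot(weights, d))
        m = R / n
        var = float(np.dot(weights, (d - m) ** 2) / n)
    sigma = math.sqrt(max(var, 0.0))

    if sigma == 0.0:
        p = 1.0 if R == 0.0 else 0.0
    else:
        z = abs(R) / (sigma * math.sqrt(n))
        p = 2.0 * stats.norm.sf(z)
        if one_sided:
            p /= 2.0
    p = min(max(p, 0.0), 1.0)

    if p < significance and R != 0.0:
        preferred = fit1.spec.family if R > 0 else fit2.spec.family
    else:
        preferred = "indeterminate"
    return ComparisonResult(fit1.spec.family, fit2.spec.family,
                            R=R, sigma=sigma, p_value=p, n=n, preferred=preferred)


def rank_candidates(data: Sequence[int],
                    families: Sequence[str] = DEFAULT_CANDIDATES,
                    i_min: int = 1,
                    weights: Optional[Sequence[float]] = None,
                    support_max: Optional[int] = None,
                    significance: float = 0.05) -> list[ComparisonResult]:
    """Compare the truncated power law against each candidate family.

    Returns one :class:`ComparisonResult` per candidate, reference first in
    each pair, in the order given.  A candidate whose fit fails yields a row
    with the ``error`` field set rather than aborting the table.
    """
    families = [f for f in families if f != REFERENCE_FAMILY]
    if not families:
        raise ValueError("no candidate families to compare against")
    unknown = set(families) - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown families {sorted(unknown)}")
    ref = fit_mle(REFERENCE_FAMILY, data, i_min=i_min, weights=weights,
                  support_max=support_max)
    rows = []
    for fam in families:
        try:
            alt = fit_mle(fam, data, i_min=i_min, weights=weights,
                          support_max=support_max)
            rows.append(loglik_ratio(ref, alt, data, weights=weights,
                                     significance=significance))
        except (FitError, ValueError) as exc:
            rows.append(ComparisonResult(REFERENCE_FAMILY, fam, R=float("nan"),
                                         sigma=float("nan"), p_value=float("nan"),
                                         n=0.0, preferred="indeterminate",
                                         error=str(exc)))
    return rows


def comparisons_to_frame(rows: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Ranking table as a DataFrame (family, loglikelihood ratio, p-value)."""
    return pd.DataFrame({
        "family": [r.family_2 for r in rows],
        "loglikelihood_ratio": [r.R for r in rows],
        "p_value": [r.p_value for r in rows],
        "preferred": [r.preferred for r in rows],
        "error": [r.error or "" for r in rows],
    })


_POWERLAW_FAMILIES = {"truncated_powerlaw", "powerlaw"}


def per_group_best_fit(dataset, group_key: str = "sample",
                       min_obs: int = 30,
                       significance: float = 0.05) -> pd.DataFrame:
    """Best-fitting family per metagenome (or habitat) group.

    For every group, fits all five candidate families, records which wins by
    log-likelihood, whether the winner is a power-law family, and whether
    every pairwise comparison against the winner is individually significant
    (p < ``significance``).  Groups smaller than ``min_obs`` arrays are
    flagged ``insufficient`` rather than dropped, mirroring the low
    signal-to-noise regime of small metagenomes.

    Returns a DataFrame with one row per group: ``group``, ``n_arrays``,
    ``best_family``, ``powerlaw_best``, ``all_significant``, ``status``.
    """
    col = {"sample": "sample_id", "habitat": "habitat"}.get(group_key)
    if col is None:
        raise ValueError("group_key must be 'sample' or 'habitat'")
    df = dataset.to_frame()
    if df.empty:
        raise ValueError("empty dataset")
    records = []
    for group, sub in df.groupby(col, sort=True):
        counts = sub["spacer_count"].to_numpy()
        row = {"group": group, "n_arrays": len(counts),
               "best_family": "", "powerlaw_best": False,
               "all_significant": False, "status": "ok"}
        if len(counts) < min_obs:
            row["status"] = "insufficient"
            records.append(row)
            continue
        fits = {}
        for fam in FAMILIES:
            try:
                fits[fam] = fit_mle(fam, counts, min_obs=min_obs)
            except FitError:
                pass
        if not fits:
            row["status"] = "fit_failed"
            records.append(row)
            continue
        best = max(fits, key=lambda f: fits[f].loglikelihood)
        sig = all(
            loglik_ratio(fits[best], fits[f], counts,
                         significance=significance).p_value < significance
            for f in fits if f != best)
        row.update(best_family=best,
                   powerlaw_best=best in _POWERLAW_FAMILIES,
                   all_significant=bool(sig))
        records.append(row)
    return pd.DataFrame.from_records(records)


def proportion_vs_group_size(summary: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Proportion of groups with a power-law best fit, binned by group size.

    The aggregate curve behind the "fraction of metagenomes best fit by a
    power law vs number of arrays" view: log-spaced bins over group size,
    one row per non-empty bin.
    """
    ok = summary[summary["status"] == "ok"]
    if ok.empty:
        return pd.DataFrame(columns=["n_arrays_mid", "n_groups", "proportion_powerlaw"])
    sizes = ok["n_arrays"].to_numpy(dtype=float)
    edges = np.unique(np.geomspace(sizes.min(), sizes.max() + 1, n_bins + 1))
    idx = np.clip(np.digitize(sizes, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        if not sel.any():
            continue
        rows.append({
            "n_arrays_mid": float(np.sqrt(edges[b] * edges[b + 1])),
            "n_groups": int(sel.sum()),
            "proportion_powerlaw": float(ok["powerlaw_best"].to_numpy()[sel].mean()),
        })
    return pd.DataFrame(rows)
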