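"""Between-condition comparison of 4C profiles.

Profiles are first normalized by total captured-end weight over a large
region around the viewpoint (15 Mb by default, i.e. viewpoint +/- 7.5 Mb),
so that library-depth differences cancel.  Per window, the replicate mean
and SD within each condition and the difference of means are reported, with
an exact conditional count test for a per-window condition effect.

The count test conditions on the window's total raw count across the two
conditions: under the null of no condition effect the condition-A sum is
binomial with probability proportional to the effective library sizes
(dispersion 0).  A method-of-moments common-dispersion estimate across
windows is reported as a diagnostic; overdispersion beyond it is a
documented limitation of the dispersion-0 test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .capture_profile import CaptureProfile
from .contact_stats import bh_adjust

DEFAULT_NORMALIZATION_SPAN = 15_000_000  # bp, viewpoint +/- 7.5 Mb


@dataclass
class NormalizedProfileSet:
    """Regionally normalized replicate profiles for two (or more) conditions.

    ``tables`` maps condition -> list of window tables carrying both the raw
    count ``c`` and the scaled ``c_norm``; ``scale_factors`` maps
    (condition, replicate) -> multiplicative factor.
    """

    center: int
    span: int
    tables: Dict[str, List[pd.DataFrame]] = field(repr=False)
    scale_factors: Dict[tuple, float] = field(default_factory=dict)

    @property
    def conditions(self) -> List[str]:
        return list(self.tables)


def _regional_total(windows: pd.DataFrame, center: int, span: int) -> float:
    lo, hi = center - span / 2, center + span / 2
    sel = (windows["midpoint"] >= lo) & (windows["midpoint"] < hi)
    if not sel.any():
        raise ValueError("normalization region overlaps no windows")
    return float(windows.loc[sel, "c"].sum())


def normalize_regional(
    profiles: Dict[str, Sequence[CaptureProfile]],
    center: int,
    span: int = DEFAULT_NORMALIZATION_SPAN,
) -> NormalizedProfileSet:
    """Scale every sample so regional totals match the across-sample mean.

    Each sample is multiplied by target/total where ``total`` is its raw
    captured-end sum over [center - span/2, center + span/2) and ``target``
    is the mean of those totals.  A sample with zero regional total is an
    error naming the sample.  The operation is idempotent.
    """
    if not profiles or any(len(reps) < 1 for reps in profiles.values()):
        raise ValueError("need >=1 profile per condition")
    totals = {}
    for cond, reps in profiles.items():
        for prof in reps:
            t = _regional_total(prof.windows, center, span)
            if t == 0:
                raise ValueError(f"zero regional total for sample {cond}/{prof.replicate}")
            totals[(cond, prof.replicate)] = t
    target = float(np.mean(list(totals.values())))

    tables: Dict[str, List[pd.DataFrame]] = {}
    factors = {}
    for cond, reps in profiles.items():
        tables[cond] = []
        for prof in reps:
            scale = target / totals[(cond, prof.replicate)]
            factors[(cond, prof.replicate)] = scale
            tab = prof.windows.copy()
            tab["replicate"] = prof.replicate
            tab["c_norm"] = tab["c"] * scale
            tables[cond].append(tab)
    return NormalizedProfileSet(center=center, span=span, tables=tables,
                                scale_factors=factors)


@dataclass
class GroupContrast:
    """Per-window group means/SDs, mean difference, and count-test p/q."""

    condition_a: str
    condition_b: str
    dispersion: float
    table: pd.DataFrame = field(repr=False)


def group_stats(normalized: NormalizedProfileSet) -> pd.DataFrame:
    """Per-window mean and SD (n-1 denominator) per condition, and their difference.

    Delta = mean of the first condition minus mean of the second; with a
    single replicate the SD is reported missing.  Requires exactly two
    conditions on identical window grids.
    """
    conds = normalized.conditions
    if len(conds) != 2:
        raise ValueError(f"group_stats requires exactly 2 conditions, got {len(conds)}")
    a, b = conds
    out = normalized.tables[a][0][["window", "chrom", "start", "end", "midpoint", "distance"]].copy()
    for cond in conds:
        mat = np.column_stack([t["c_norm"].to_numpy() for t in normalized.tables[cond]])
        out[f"mean_{cond}"] = mat.mean(axis=1)
        out[f"sd_{cond}"] = mat.std(axis=1, ddof=1) if mat.shape[1] > 1 else np.nan
    out["delta"] = out[f"mean_{a}"] - out[f"mean_{b}"]
    return out


def exact_count_test(
    counts_a: np.ndarray, counts_b: np.ndarray, lib_a: float, lib_b: float
) -> float:
    """Two-sided exact conditional test for one unit's raw counts.

    Conditional on n = sum(counts_a) + sum(counts_b), the A-sum is
    Binomial(n, lib_a / (lib_a + lib_b)) under the null.  The p-value sums
    the probabilities of all outcomes no more probable than the observed one
    (minimum-likelihood two-sided rule).
    """
    ka = int(np.sum(counts_a))
    n = ka + int(np.sum(counts_b))
    if n == 0:
        return 1.0
    prob = lib_a / (lib_a + lib_b)
    pmf = stats.binom.pmf(np.arange(n + 1), n, prob)
    return float(min(pmf[pmf <= pmf[ka] * (1 + 1e-9)].sum(), 1.0))


def _moment_dispersion(mat: np.ndarray) -> float:
    """Method-of-moments common NB dispersion across units: phi in var = mu + phi mu^2."""
    mu = mat.mean(axis=1)
    var = mat.var(axis=1, ddof=1)
    keep = mu > 0
    if not keep.any() or mat.shape[1] < 2:
        return float("nan")
    phi = (var[keep] - mu[keep]) / mu[keep] ** 2
    return float(max(np.mean(phi), 0.0))


def nb_test(normalized: NormalizedProfileSet) -> GroupContrast:
    """Per-window exact conditional count test between two conditions.

    Uses raw (pre-normalization) integer counts; effective library sizes are
    the per-condition sums of regional totals implied by the scale factors.
    Returns per-window p and BH q, plus the pooled moment-dispersion
    diagnostic.  Non-integer counts are an error: the test needs raw counts.
    """
    conds = normalized.conditions
    if len(conds) != 2:
        raise ValueError(f"nb_test requires exactly 2 conditions, got {len(conds)}")
    a, b = conds
    mats = {}
    for cond in conds:
        raw = np.column_stack([t["c"].to_numpy() for t in normalized.tables[cond]])
        if not np.allclose(raw, np.round(raw)):
            raise ValueError("nb_test requires raw integer counts (pre-normalization)")
        mats[cond] = raw.astype(np.int64)
    # effective library size per condition: summed regional totals (inverse scale)
    libs = {
        cond: sum(1.0 / normalized.scale_factors[(cond, str(t["replicate"].iloc[0]))]
                  for t in normalized.tables[cond])
        for cond in conds
    }
    pvals = np.array([
        exact_count_test(mats[a][i], mats[b][i], libs[a], libs[b])
        for i in range(mats[a].shape[0])
    ])
    stats_tab = group_stats(normalized)
    stats_tab["p"] = pvals
    stats_tab["q"] = bh_adjust(np.clip(pvals, np.nextafter(0, 1), 1.0))
    pooled = np.hstack([mats[a], mats[b]])
    return GroupContrast(condition_a=a, condition_b=b,
                         dispersion=_moment_dispersion(pooled), table=stats_tab)
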