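"""Distance-decay fitting, residual z-scores, and replicate-consensus contact calls.

Contact frequency decays monotonically with genomic distance from the
viewpoint; specific chromatin contacts appear as windows whose capture
frequency exceeds the fitted decay.  The decay is fit by isotonic
(non-increasing) regression of window frequency on distance rank, separately
upstream and downstream of the viewpoint.  Residuals are standardized with a
robust MAD-based scale (so true contacts do not inflate the noise estimate),
giving per-window z-scores and one-sided upper-tail normal p-values, which
are Benjamini-Hochberg adjusted within each replicate.

A window is a consensus significant contact when z > 2 in every replicate
and the BH-adjusted p is < 0.05 in at least one replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from .capture_profile import CaptureProfile

logger = logging.getLogger(__name__)

MIN_WINDOWS_PER_SIDE = 5
SIGMA_FLOOR = 1e-6
MAD_SCALE = 1.4826  # consistency factor: MAD -> sigma under normality


@dataclass
class DecayFit:
    """Isotonic decay fit for one side of the viewpoint.

    ``table`` columns: window, distance, f, yhat, residual, z, p.  ``sigma``
    is the robust residual scale 1.4826 * MAD, floored at 1e-6.
    """

    side: str
    sigma: float
    table: pd.DataFrame = field(repr=False)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order.

    q_(i) = min_{j >= i} (m * p_(j) / j), clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _isotonic_decreasing(y: np.ndarray) -> np.ndarray:
    """Non-increasing least-squares fit of y against its index (PAVA)."""
    x = np.arange(len(y), dtype=float)
    return IsotonicRegression(increasing=False).fit_transform(x, y)


def fit_decay(profile: CaptureProfile, symmetric: bool = False) -> Dict[str, DecayFit]:
    """Fit the monotone decay and score residuals, per side of the viewpoint.

    Windows are ranked by absolute distance from the viewpoint and the
    frequency f is fit with a non-increasing isotonic regression on that
    rank (invariant to any monotone transform of distance).  Excluded and
    truncated windows are not fit.  With ``symmetric=True`` both sides are
    pooled by absolute distance into a single fit.

    Fewer than 5 usable windows on a side is an error; an all-zero side
    yields a zero fit with all z set to 0 (and a warning).
    """
    win = profile.windows
    usable = win[~win["excluded"] & ~win["truncated"]]
    if symmetric:
        sides = {"pooled": usable}
    else:
        sides = {
            "upstream": usable[usable["distance"] < 0],
            "downstream": usable[usable["distance"] > 0],
        }

    fits: Dict[str, DecayFit] = {}
    for side, sub in sides.items():
        if len(sub) < MIN_WINDOWS_PER_SIDE:
            raise ValueError(
                f"insufficient windows for decay fit: {len(sub)} on {side} side "
                f"(need >= {MIN_WINDOWS_PER_SIDE})"
            )
        order = np.argsort(np.abs(sub["distance"].to_numpy()), kind="stable")
        f = sub["f"].to_numpy()[order]
        if np.all(f == 0):
            logger.warning("all-zero capture frequencies on %s side; z set to 0", side)
            yhat = np.zeros_like(f)
            resid = np.zeros_like(f)
            z = np.zeros_like(f)
            sigma = SIGMA_FLOOR
        else:
            yhat = _isotonic_decreasing(f)
            resid = f - yhat
            sigma = max(MAD_SCALE * float(np.median(np.abs(resid - np.median(resid)))),
                        SIGMA_FLOOR)
            z = resid / sigma
        table = pd.DataFrame({
            "window": sub["window"].to_numpy()[order],
            "distance": sub["distance"].to_numpy()[order],
            "f": f,
            "yhat": yhat,
            "residual": resid,
            "z": z,
            # sf underflows to 0 for extreme z; keep p in (0, 1] for BH
            "p": np.clip(stats.norm.sf(z), 1e-300, 1.0),
        })
        fits[side] = DecayFit(side=side, sigma=sigma, table=table)
    return fits


def replicate_scores(profile: CaptureProfile, symmetric: bool = False) -> pd.DataFrame:
    """Per-window z, p and BH q for one replicate.

    The BH family is all non-excluded windows of the analyzed region
    (both sides together).
    """
    fits = fit_decay(profile, symmetric=symmetric)
    table = pd.concat([f.table for f in fits.values()], ignore_index=True)
    table = table.sort_values("window").reset_index(drop=True)
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["replicate"] = profile.replicate
    return table


@dataclass
class ContactCallSet:
    """Consensus contact calls across replicates.

    ``table`` has one row per non-excluded window with z_<rep>, q_<rep>
    columns and a ``consensus_significant`` flag.
    """

    z_threshold: float
    q_threshold: float
    replicates: List[str]
    table: pd.DataFrame = field(repr=False)

    def significant_windows(self) -> pd.DataFrame:
        return self.table[self.table["consensus_significant"]]


def score_contacts(
    profiles: Sequence[CaptureProfile],
    z_threshold: float = 2.0,
    q_threshold: float = 0.05,
    symmetric: bool = False,
) -> ContactCallSet:
    """Apply the replicate-consensus rule to >= 2 replicate profiles.

    A window is called significant iff z > ``z_threshold`` in ALL replicates
    and BH q < ``q_threshold`` in at least one.  Replicates must share an
    identical window grid.
    """
    if len(profiles) < 2:
        raise ValueError("consensus rule requires >=2 replicates")
    grids = [p.windows[["chrom", "start", "end"]].reset_index(drop=True) for p in profiles]
    for g in grids[1:]:
        if not g.equals(grids[0]):
            raise ValueError("replicate profiles have mismatched window grids")

    names = [p.replicate for p in profiles]
    if len(set(names)) != len(names):
        names = [f"rep{i + 1}" for i in range(len(profiles))]
    per_rep = []
    for name, prof in zip(names, profiles):
        sc = replicate_scores(prof, symmetric=symmetric)
        per_rep.append(sc.set_index("window")[["z", "q"]].rename(
            columns={"z": f"z_{name}", "q": f"q_{name}"}))
    merged = pd.concat(per_rep, axis=1, join="inner")

    z_cols = [f"z_{n}" for n in names]
    q_cols = [f"q_{n}" for n in names]
    merged["consensus_significant"] = (
        (merged[z_cols] > z_threshold).all(axis=1)
        & (merged[q_cols] < q_threshold).any(axis=1)
    )
    coords = profiles[0].windows.set_index("window")[["chrom", "start", "end", "distance", "f"]]
    table = coords.join(merged, how="inner").reset_index()
    return ContactCallSet(z_threshold, q_threshold, names, table)


def estimate_decay_exponent(
    profile: CaptureProfile,
    n_bins: int = 15,
    min_distance: float | None = None,
) -> float:
    """Estimate the power-law decay exponent alpha from window frequencies.

    Assumes contact frequency ~ A * d^-alpha.  Windows are grouped into
    log-spaced distance bins; the slope of log(mean f) on log(distance),
    weighted by windows per bin, gives -alpha.  Averaging within bins before
    taking logs keeps the estimator stable where per-window counts are small.
    Diagnostic for synthetic-data recovery checks, not part of contact calling.
    """
    win = profile.windows
    usable = win[~win["excluded"] & ~win["truncated"]]
    d = np.abs(usable["distance"].to_numpy(dtype=float))
    f = usable["f"].to_numpy(dtype=float)
    keep = d > 0
    d, f = d[keep], f[keep]
    if min_distance is not None:
        keep = d >= min_distance
        d, f = d[keep], f[keep]
    if len(d) < n_bins:
        raise ValueError("too few windows to estimate a decay exponent")
    edges = np.geomspace(d.min(), d.max() * (1 + 1e-9), n_bins + 1)
    idx = np.digitize(d, edges) - 1
    logd, logf, w = [], [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        mf = f[sel].mean()
        if mf <= 0:
            continue
        logd.append(np.log(d[sel]).mean())
        logf.append(np.log(mf))
        w.append(sel.sum())
    if len(logd) < 3:
        raise ValueError("too few populated distance bins to estimate a decay exponent")
    slope = np.polyfit(np.asarray(logd), np.asarray(logf), 1, w=np.sqrt(np.asarray(w)))[0]
    return -float(slope)
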