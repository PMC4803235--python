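"""Stopover-duration and longitude correlations with the habitat axes.

Ten pair-wise Spearman rank correlations (duration x PC1..PC5 and
longitude x PC1..PC5, scores taken at the 0.2 deg buffer), with a
Bonferroni-corrected per-test threshold (0.05 / 10 = 0.005) for the
family-wise significance flags.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr


class UndefinedRhoError(ValueError):
    pass


@dataclass
class CorrelationResult:
    pair: str
    rho: float
    p: float
    significant: bool  # after Bonferroni at family alpha


def bonferroni_alpha(family_alpha: float = 0.05, n_tests: int = 1) -> float:
    """Per-test significance threshold family_alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with average-rank ties; exact permutation P for n < 10.

    Small samples fall below the t-approximation's comfort zone, so the
    two-sided P there is an exact enumeration over all n! rank orderings.
    """
    n = len(x)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedRhoError("constant variable: rho undefined")
    if n >= 10:
        rho, p = spearmanr(x, y)
        return float(rho), float(p)
    rx, ry = rankdata(x), rankdata(y)
    rxc, ryc = rx - rx.mean(), ry - ry.mean()
    sx, sy = math.sqrt(float(rxc @ rxc)), math.sqrt(float(ryc @ ryc))
    rho = float(rxc @ ryc) / (sx * sy)
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = (ryc[perms] @ rxc) / (sx * sy)
    p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return rho, p


def duration_correlations(
    durations: np.ndarray | pd.Series,
    longitudes: np.ndarray | pd.Series,
    scores: pd.DataFrame,
    family_alpha: float = 0.05,
) -> list[CorrelationResult]:
    """The ten Spearman tests: {duration, longitude} x each PC score.

    Significance flags use bonferroni_alpha(family_alpha, 10) (0.005 for
    the default family of ten).  A constant variable makes only its own
    pair undefined (rho and P reported as NaN, flag False).
    """
    durations = np.asarray(durations, dtype=float)
    longitudes = np.asarray(longitudes, dtype=float)
    if len(durations) < 5:
        raise ValueError("need at least 5 stopovers")
    if len(durations) != len(scores) or len(longitudes) != len(scores):
        raise ValueError("durations, longitudes and scores must align")
    pc_cols = list(scores.columns)
    n_tests = 2 * len(pc_cols)
    thr = bonferroni_alpha(family_alpha, n_tests)
    out: list[CorrelationResult] = []
    for label, var in (("duration", durations), ("longitude", longitudes)):
        for pc in pc_cols:
            try:
                rho, p = _spearman(var, scores[pc].to_numpy(dtype=float))
            except UndefinedRhoError:
                out.append(CorrelationResult(f"{label}~{pc}", float("nan"), float("nan"), False))
                continue
            out.append(CorrelationResult(f"{label}~{pc}", rho, p, bool(p < thr)))
    return out


def correlations_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {"pair": [r.pair for r in results], "rho": [r.rho for r in results],
         "p": [r.p for r in results], "significant": [r.significant for r in results]}
    )
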