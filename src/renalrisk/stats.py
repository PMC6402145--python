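"""The two significance tests used by the cohort tables.

* :func:`chi2_yates` — chi-square test of association on a 2x2 table with the
  Yates continuity correction, Sum((|O - E| - 0.5)^2 / E) with the
  correction floored so that |O - E| - 0.5 never goes negative (which would
  otherwise inflate the statistic for near-null tables); p from the upper
  tail of chi-square with 1 df.
* :func:`chi2_trend` — Cochran-Armitage chi-square test for trend in
  proportions across ordered groups with equally spaced scores; the
  statistic is invariant to affine rescaling of the scores; two-sided p from
  chi-square with 1 df.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist

__all__ = ["chi2_yates", "chi2_trend"]


def chi2_yates(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Yates-corrected chi-square on the 2x2 table [[a, b], [c, d]].

    Returns ``(statistic, p)``.  Raises on negative counts or a zero row or
    column margin (the expectation is undefined there).
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    if (obs < 0).any():
        raise ValueError(f"counts must be non-negative, got {obs.tolist()}")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError(
            f"zero margin in 2x2 table {obs.tolist()}: test undefined"
        )
    n = obs.sum()
    expected = np.outer(row, col) / n
    corrected = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    stat = float((corrected**2 / expected).sum())
    return stat, float(_chi2_dist.sf(stat, 1))


def chi2_trend(
    successes: Sequence[int],
    totals: Sequence[int],
    scores: Optional[Sequence[float]] = None,
) -> tuple[float, float]:
    """Cochran-Armitage test for a linear trend in proportions.

    ``successes[i]`` of ``totals[i]`` in the i-th ordered group; groups with
    ``totals == 0`` are dropped before testing.  Default scores are the
    equally spaced integers 0, 1, 2, ...; custom scores give the same
    statistic under any affine transformation.  Returns ``(statistic, p)``.
    """
    x = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if x.shape != n.shape or x.ndim != 1:
        raise ValueError("successes and totals must be equal-length 1-d sequences")
    if (x < 0).any() or (n < x).any():
        raise ValueError("need 0 <= successes <= totals in every group")
    if scores is None:
        s = np.arange(len(n), dtype=float)
    else:
        s = np.asarray(scores, dtype=float)
        if s.shape != n.shape:
            raise ValueError("scores must match the number of groups")
    keep = n > 0
    x, n, s = x[keep], n[keep], s[keep]
    if len(n) < 2:
        raise ValueError("need at least 2 groups with non-zero totals")

    big_n = n.sum()
    p_bar = x.sum() / big_n
    t_obs = float((s * x).sum())
    t_exp = float(p_bar * (s * n).sum())
    var = p_bar * (1 - p_bar) * float((n * s**2).sum() - (n * s).sum() ** 2 / big_n)
    if var <= 0:  # all successes, no successes, or a single effective score
        return 0.0, 1.0
    stat = (t_obs - t_exp) ** 2 / var
    return float(stat), float(_chi2_dist.sf(stat, 1))
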