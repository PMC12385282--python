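"""Nonparametric comparison of abundance distributions across levels.

After unmixing, each concentration level contributes a distribution of
per-pixel residue abundances.  Whether consecutive levels differ is
assessed with the Mann-Whitney U test: exact null distribution for small
tie-free samples, otherwise the tie-corrected normal approximation with
continuity correction.  Pixels are treated as exchangeable observations;
spatial autocorrelation within a leaf makes the nominal p-values somewhat
liberal, which is a documented caveat rather than something the test
corrects for.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

__all__ = ["mann_whitney_u", "consecutive_level_tests", "GroupedSamples"]

_EXACT_MAX_N = 8  # exact null is enumerated when min(n) <= this and no ties


class GroupedSamples(dict):
    """Mapping of concentration level -> vector of per-pixel abundances."""

    def validate(self) -> None:
        if len(self) < 2:
            raise ValueError("need at least 2 groups for a comparison")
        for level, vals in self.items():
            if len(np.asarray(vals)) == 0:
                raise ValueError(f"group {level!r} is empty")


def mann_whitney_u(
    x, y, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U statistic (for x) and p-value.

    U is computed from rank sums with midrank tie handling, so
    ``U_x + U_y == n_x * n_y`` always holds.  The exact null distribution
    is used when ``min(n_x, n_y) <= 8`` and the pooled data are tie-free;
    otherwise the normal approximation with tie-corrected variance and
    continuity correction.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= _EXACT_MAX_N and not has_ties) \
        else "asymptotic"
    res = scipy.stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def consecutive_level_tests(
    groups: GroupedSamples | dict,
    ordered_levels=None,
    alpha: float = 0.05,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """U tests between each adjacent pair of concentration levels.

    One two-sided test per consecutive pair in concentration order; no
    multiplicity correction is applied (the per-pair alpha is reported
    as-is).  Returns a table with columns pair, level_low, level_high,
    n_low, n_high, U, p_value, significant.
    """
    if not isinstance(groups, GroupedSamples):
        groups = GroupedSamples(groups)
    groups.validate()
    levels = list(ordered_levels) if ordered_levels is not None \
        else sorted(groups.keys())
    if len(levels) < 2:
        raise ValueError("need at least 2 ordered levels")
    rows = []
    for lo, hi in zip(levels[:-1], levels[1:]):
        u, p = mann_whitney_u(groups[lo], groups[hi], alternative=alternative)
        rows.append({
            "pair": f"{lo} vs {hi}",
            "level_low": lo,
            "level_high": hi,
            "n_low": len(np.asarray(groups[lo])),
            "n_high": len(np.asarray(groups[hi])),
            "U": u,
            "p_value": p,
            "significant": p < alpha,
        })
    return pd.DataFrame(rows)
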