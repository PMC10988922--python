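"""Two-sample t-tests, significance stars, multiple-testing adjustment.

The t-test is written out in closed form rather than delegated, because the
concordance stage needs a defined answer for the degenerate case where both
replicate groups are constant and equal (t = 0, p = 1: no evidence of a
difference), which library implementations report as NaN.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

#: star thresholds, strict inequalities: p < 0.001 -> ***, < 0.01 -> **, < 0.05 -> *
STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def two_sample_ttest(
    group_a, group_b, variant: str = "student"
) -> tuple[float, float]:
    """Two-sample t statistic and two-sided p-value.

    ``student`` pools the two sample variances (classic equal-variance
    Student's t with ``n_a + n_b - 2`` degrees of freedom); ``welch`` uses
    unequal variances with Welch–Satterthwaite degrees of freedom.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValidationError("groups must be one-dimensional")
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValidationError("each group needs at least 2 values")
    if variant not in ("student", "welch"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if variant == "student":
        pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(pooled * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    else:
        se = math.sqrt(va / na + vb / nb)
        if se > 0:
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        else:
            df = na + nb - 2
    if se == 0.0:
        if ma == mb:
            return 0.0, 1.0
        return math.copysign(math.inf, ma - mb), 0.0
    t = (ma - mb) / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), p


def significance_stars(p: float) -> str:
    """Map a p-value to the asterisk convention (strict thresholds).

    ``p < 0.001`` -> ``***``; ``p < 0.01`` -> ``**``; ``p < 0.05`` -> ``*``;
    otherwise ``ns`` (no significant difference). Exactly 0.05 is ``ns``.
    """
    if not (0.0 <= p <= 1.0) or math.isnan(p):
        raise ValidationError(f"p-value out of [0, 1]: {p!r}")
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (reported alongside raw p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
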