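"""Corrected-AIC scoring of fitted model variants.

The corrected Akaike Information Criterion for a weighted least-squares fit
with ``m`` free parameters against ``n`` observations is

    AICc = 2 m + n ln(SSE / n) + 2 m (m + 1) / (n - m - 1),

assuming independent normally distributed errors.  Smaller is better; the
small-sample correction term penalizes parameter counts approaching the
observation count.  ``m`` counts kinetic parameters plus the free initial
conditions (two per experiment); the training design here yields n = 116
(four experiments x ten time points x three subpopulations, less the four
initial transconjugant values pinned to zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class ComparisonLedger:
    """AICc comparison table over fitted variants, best row flagged."""

    frame: pd.DataFrame  # variant, n_kinetic, m, sse, aicc, best

    @property
    def best_variant(self) -> str:
        return self.frame.loc[self.frame["best"], "variant"].iloc[0]

    def to_csv(self, path):
        self.frame.to_csv(path, index=False)


def aicc(sse: float, m: int, n: int) -> float:
    """Corrected AIC from a fitted SSE, parameter count and sample size."""
    if sse <= 0:
        raise ValueError("sse must be > 0")
    if n <= m + 1:
        raise ValueError("AICc requires n > m + 1 (correction term "
                         "undefined)")
    return 2 * m + n * math.log(sse / n) + 2 * m * (m + 1) / (n - m - 1)


def compare_variants(fits, n: int | None = None) -> ComparisonLedger:
    """Score fitted variants and flag the minimum-AICc row.

    ``fits`` is a list of FitResult (or any objects carrying ``variant``,
    ``free_names``/``free_vector`` or ``n_kinetic``, ``m``, ``sse`` and
    ``n_obs``).  All fits must target the same observation set; ``n``
    defaults to the fits' common ``n_obs``.  Ties in AICc break toward the
    variant with fewer free parameters, then first listed.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    if n is None:
        ns = {f.n_obs for f in fits}
        if len(ns) != 1:
            raise ValueError(f"fits disagree on observation count: {ns}")
        n = ns.pop()
    rows = []
    for f in fits:
        nk = (len(f.free_names) if hasattr(f, "free_names")
              else f.n_kinetic)
        rows.append({"variant": f.variant, "n_kinetic": nk, "m": f.m,
                     "sse": f.sse, "aicc": aicc(f.sse, f.m, n)})
    frame = pd.DataFrame(rows)
    order = frame.sort_values(["aicc", "m"], kind="stable").index
    frame["best"] = False
    frame.loc[order[0], "best"] = True
    return ComparisonLedger(frame=frame)
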