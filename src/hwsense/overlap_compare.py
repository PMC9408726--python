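"""Agreement between study heat-wave flags and NWS alert days.

Days are cross-tabulated into a 2x2 table (both flagged / study only /
NWS only / neither) and marginal homogeneity is tested with the McNemar
statistic, which depends only on the discordant cells b and c.  The
continuity-corrected form (|b - c| - 1)^2 / (b + c), with the numerator
clamped at zero, is the default; the correction matters because b and c
are day counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AlignmentError


@dataclass(frozen=True)
class OverlapTable:
    """Joint day counts: a = both flagged, b = study only, c = NWS only, d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("overlap cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class McNemarResult:
    chi2: float
    df: int
    pvalue: float


def build_overlap(study: pd.Series, nws: pd.Series) -> OverlapTable:
    """Cross-tabulate two aligned daily binary flag series."""
    if not pd.Index(study.index).equals(pd.Index(nws.index)):
        raise AlignmentError("build_overlap: series are not on the same dates")
    s = study.astype(bool).to_numpy()
    w = nws.astype(bool).to_numpy()
    return OverlapTable(
        a=int(np.sum(s & w)),
        b=int(np.sum(s & ~w)),
        c=int(np.sum(~s & w)),
        d=int(np.sum(~s & ~w)),
    )


def mcnemar(table: OverlapTable, continuity: bool = True) -> McNemarResult:
    """McNemar chi-square test on the discordant cells (df = 1).

    With the continuity correction, chi2 = (max(|b-c| - 1, 0))^2 / (b+c);
    without, (b-c)^2 / (b+c).  b + c = 0 leaves the statistic undefined.
    """
    b, c = table.b, table.c
    if b + c == 0:
        raise ValueError("mcnemar: no discordant pairs; statistic undefined")
    if continuity:
        num = max(abs(b - c) - 1, 0) ** 2
    else:
        num = (b - c) ** 2
    chi2 = num / (b + c)
    return McNemarResult(chi2=float(chi2), df=1, pvalue=float(stats.chi2.sf(chi2, df=1)))


def comparison_report(
    tables: dict[str, OverlapTable], continuity: bool = True
) -> pd.DataFrame:
    """Tidy per-region report: cells, chi2, df, p."""
    rows = []
    for region, t in sorted(tables.items()):
        res = mcnemar(t, continuity=continuity)
        rows.append(
            {
                "region": region,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "chi2": res.chi2,
                "df": res.df,
                "p": res.pvalue,
            }
        )
    return pd.DataFrame(rows)
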