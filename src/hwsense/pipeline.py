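"""End-to-end orchestration: thresholds -> flags -> fits -> ranking -> overlap.

This is the library face of the analysis; the command-line interface and
the examples are thin wrappers around :func:`run_analysis`.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import hri_preprocess, io_formats
from .hwd_engine import HWDefinition, compute_thresholds, flag_all, standard_definitions
from .nb_regression import ModelFit, fit_all_definitions, rank_definitions, rate_ratio
from .overlap_compare import OverlapTable, build_overlap, comparison_report


@dataclass
class AnalysisResult:
    results: pd.DataFrame                      # one row per (region, definition)
    fits: dict[tuple[str, str], ModelFit]
    ranking: dict[str, list[tuple[str, float]]]
    optimal: dict[str, str]                    # region -> definition id
    overlap: dict[str, OverlapTable]           # for the optimal definition
    mcnemar_report: pd.DataFrame
    censoring: dict[str, float]                # region -> censoring fraction


def run_analysis(
    climatology: pd.DataFrame,
    study_weather: pd.DataFrame,
    hri: pd.DataFrame,
    nws_flags: dict[str, pd.Series],
    populations: dict[str, float],
    definitions: list[HWDefinition] | None = None,
    impute_value: int = 3,
    continuity: bool = True,
    percentile_method: str = "linear",
) -> AnalysisResult:
    """Run the definition-sensitivity analysis on regional daily inputs.

    ``climatology`` and ``study_weather`` are regional frames with derived
    metric columns; ``hri`` is the delivered count product (censored flags
    set).  Definitions whose model cannot be fitted (degenerate flags, no
    convergence) are recorded with missing fit columns and excluded from
    the ranking.
    """
    definitions = definitions if definitions is not None else standard_definitions()
    def_map = {d.id: d for d in definitions}
    thresholds = compute_thresholds(climatology, definitions, method=percentile_method)
    flags, counts_tbl = flag_all(study_weather, definitions, thresholds)

    rows = []
    fits: dict[tuple[str, str], ModelFit] = {}
    ranking: dict[str, list[tuple[str, float]]] = {}
    optimal: dict[str, str] = {}
    overlap: dict[str, OverlapTable] = {}
    censoring: dict[str, float] = {}
    regions = sorted(study_weather["region"].unique())
    for region in regions:
        sub = study_weather[study_weather["region"] == region].sort_values("date")
        hri_region = (
            hri[hri["region"] == region].sort_values("date").set_index("date")[["count", "censored"]]
        )
        imputed, frac = hri_preprocess.impute_censored(hri_region, impute_value=impute_value)
        censoring[region] = frac
        counts = imputed["count"]
        region_flags = {d_id: s for (r, d_id), s in flags.items() if r == region}
        region_fits = fit_all_definitions(
            sub, region_flags, nws_flags[region], counts, populations[region], def_map
        )
        fits.update({(region, d_id): f for d_id, f in region_fits.items()})
        if region_fits:
            ranking[region], optimal[region] = rank_definitions(region_fits)
            overlap[region] = build_overlap(region_flags[optimal[region]], nws_flags[region])

        for d in definitions:
            hw_days = int(region_flags[d.id].sum())
            row = {
                "region": region,
                "definition_id": d.id,
                "metric": d.metric,
                "duration": d.duration,
                "threshold_type": d.threshold_type,
                "intensity": d.intensity,
                "threshold_c": thresholds[(region, d.id)],
                "hw_days": hw_days,
                "rr": float("nan"),
                "ci_lo": float("nan"),
                "ci_hi": float("nan"),
                "aic": float("nan"),
                "theta": float("nan"),
            }
            if d.id in region_fits:
                fit = region_fits[d.id]
                rr = rate_ratio(fit)
                row.update(
                    rr=rr.point, ci_lo=rr.lo, ci_hi=rr.hi, aic=fit.aic, theta=fit.theta
                )
            rows.append(row)

    report = comparison_report(overlap, continuity=continuity) if overlap else pd.DataFrame()
    return AnalysisResult(
        results=pd.DataFrame(rows)[io_formats.RESULT_COLUMNS],
        fits=fits,
        ranking=ranking,
        optimal=optimal,
        overlap=overlap,
        mcnemar_report=report,
        censoring=censoring,
    )
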