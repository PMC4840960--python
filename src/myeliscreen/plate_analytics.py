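"""Condition aggregation, percent-of-DAPT normalization, and plate QC.

Each test condition (compound x concentration) is screened in duplicate
wells with 4 imaged fields per well; the 8 usable fields are averaged
unweighted.  Condition means are then min-max normalized between the plate's
DMSO (0 %) and DAPT (100 %) control means ("% of DAPT").  Plate quality is
summarized by the Z'-factor, the DAPT/DMSO fiber-score/MBP-score window
(acceptance floor 1.3 - 0.2 = 1.1 at defaults), and the 3-SD-above-DMSO
false-positive line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import QCError, UndefinedScoreError
from .fiber_morphometrics import FieldScores
from .imaging_io import PlateLayout, ScoreTable, SCORE_COLUMNS


@dataclass
class ConditionSummary:
    """Per compound-concentration aggregate over the duplicate wells' fields."""

    compound_id: str
    concentration: float
    n_fields_used: int
    fiber_score_mean: float | None = None
    fiber_score_sem: float | None = None
    mbp_score_mean: float | None = None
    mbp_score_sem: float | None = None
    fiber_mbp_mean: float | None = None
    fiber_mbp_sem: float | None = None
    olig2_count_mean: float | None = None
    dapi_count_mean: float | None = None
    pct_dapt_myelination: float | None = None
    pct_dapt_olig2: float | None = None

    @property
    def dapi_olig2_ratio(self) -> float:
        if not self.olig2_count_mean:
            return float("inf")
        return (self.dapi_count_mean or 0.0) / self.olig2_count_mean


def _mean_sem(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return mean, sem


def aggregate_condition(
    fields: Sequence[FieldScores], compound_id: str, concentration: float
) -> ConditionSummary:
    """Average usable field scores for one condition (unweighted mean +/- SEM).

    Fields with no Olig2+ nuclei are excluded; a condition with zero usable
    fields is flagged by carrying ``None`` scores and ``n_fields_used == 0``.
    """
    usable = [f for f in fields if f.usable]
    if len(fields) > 8:
        raise ValueError(f"a condition has at most 8 fields, got {len(fields)}")
    dapi_mean = float(np.mean([f.n_dapi for f in fields])) if fields else None
    if not usable:
        return ConditionSummary(
            compound_id, concentration, 0, dapi_count_mean=dapi_mean
        )
    fiber_mean, fiber_sem = _mean_sem([f.fiber_score for f in usable])
    mbp_mean, mbp_sem = _mean_sem([f.mbp_score for f in usable])
    fm_mean, fm_sem = _mean_sem([f.fiber_mbp for f in usable])
    return ConditionSummary(
        compound_id,
        concentration,
        len(usable),
        fiber_mean,
        fiber_sem,
        mbp_mean,
        mbp_sem,
        fm_mean,
        fm_sem,
        olig2_count_mean=float(np.mean([f.n_olig2 for f in usable])),
        dapi_count_mean=dapi_mean,
    )


def percent_of_control(x: float, neg_mean: float, pos_mean: float) -> float:
    """Min-max normalize ``x`` between negative (0 %) and positive (100 %) control means."""
    if pos_mean == neg_mean:
        raise UndefinedScoreError("degenerate controls: positive mean equals negative mean")
    return 100.0 * (x - neg_mean) / (pos_mean - neg_mean)


def zprime(pos: Sequence[float], neg: Sequence[float]) -> float:
    """Z'-factor: 1 - 3(sd_pos + sd_neg)/|mean_pos - mean_neg| (sample SDs).

    Returns ``-inf`` when the group means coincide (undefined window).
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("zprime needs >= 2 values per group")
    sep = abs(pos.mean() - neg.mean())
    if sep == 0:
        return float("-inf")
    return 1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / sep


def gaussian_tail_pct(n_sd: float = 3.0) -> float:
    """One-sided Gaussian tail beyond ``n_sd`` SDs, as a percentage.

    This is the analytic false-positive bound implied by drawing a hit line
    ``n_sd`` SDs above the DMSO mean: for a Gaussian null, ~0.13 % of inactive
    conditions land above a 3-SD line.
    """
    return float(stats.norm.sf(n_sd) * 100.0)


@dataclass
class QCReport:
    plate_id: str
    zprime: float
    dapt_dmso_fiber_mbp: float
    dmso_mean: float
    dmso_sd: float
    dapt_mean: float
    dapt_sd: float
    three_sd_threshold: float
    passed: bool
    reasons: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "plate_id": self.plate_id,
            "zprime": self.zprime,
            "dapt_dmso_fiber_mbp": self.dapt_dmso_fiber_mbp,
            "dmso_mean": self.dmso_mean,
            "dmso_sd": self.dmso_sd,
            "dapt_mean": self.dapt_mean,
            "dapt_sd": self.dapt_sd,
            "three_sd_threshold": self.three_sd_threshold,
            "pass": self.passed,
            "reasons": self.reasons,
        }


def plate_qc(
    field_scores: Mapping[str, Sequence[FieldScores]],
    layout: PlateLayout,
    window_center: float = 1.3,
    window_halfwidth: float = 0.2,
) -> QCReport:
    """Per-plate quality control from the control wells.

    ``field_scores`` maps well -> the well's per-field scores.  The plate
    passes when the DAPT/DMSO fiber-score/MBP-score ratio clears the lower
    window edge (``window_center - window_halfwidth``; a high ratio is good)
    and the DAPT myelination mean clears the DMSO mean + 3 SD line.
    Myelination statistics are over control *fields*; Z' is computed on
    per-well mean myelination.
    """
    pos_wells = [w for w in layout.wells_by_role("positive_control") if w in field_scores]
    neg_wells = [w for w in layout.wells_by_role("negative_control") if w in field_scores]
    if not pos_wells or not neg_wells:
        raise QCError(f"plate {layout.plate_id}: missing control wells with field scores")

    def usable(wells: list[str]) -> list[FieldScores]:
        return [f for w in wells for f in field_scores[w] if f.usable]

    pos_fields, neg_fields = usable(pos_wells), usable(neg_wells)
    if not pos_fields or not neg_fields:
        raise QCError(f"plate {layout.plate_id}: control wells have no usable fields")

    dmso_fiber = np.array([f.fiber_score for f in neg_fields], dtype=float)
    dapt_fiber = np.array([f.fiber_score for f in pos_fields], dtype=float)
    dmso_mean, dmso_sd = float(dmso_fiber.mean()), float(dmso_fiber.std(ddof=1))
    dapt_mean, dapt_sd = float(dapt_fiber.mean()), float(dapt_fiber.std(ddof=1))
    three_sd = dmso_mean + 3.0 * dmso_sd

    dmso_fm = float(np.mean([f.fiber_mbp for f in neg_fields]))
    dapt_fm = float(np.mean([f.fiber_mbp for f in pos_fields]))
    ratio = dapt_fm / dmso_fm if dmso_fm > 0 else float("inf")

    well_means_pos = [
        float(np.mean([f.fiber_score for f in field_scores[w] if f.usable]))
        for w in pos_wells
        if any(f.usable for f in field_scores[w])
    ]
    well_means_neg = [
        float(np.mean([f.fiber_score for f in field_scores[w] if f.usable]))
        for w in neg_wells
        if any(f.usable for f in field_scores[w])
    ]
    zp = (
        zprime(well_means_pos, well_means_neg)
        if len(well_means_pos) >= 2 and len(well_means_neg) >= 2
        else float("nan")
    )

    reasons: list[str] = []
    floor = window_center - window_halfwidth
    if not ratio >= floor:
        reasons.append(
            f"DAPT/DMSO fiber-score/MBP-score {ratio:.3g} below acceptance floor {floor:g}"
        )
    if not dapt_mean > three_sd:
        reasons.append(
            f"DAPT myelination mean {dapt_mean:.4g} does not clear DMSO mean + 3 SD "
            f"({three_sd:.4g}); controls not well separated"
        )
    return QCReport(
        layout.plate_id,
        zp,
        ratio,
        dmso_mean,
        dmso_sd,
        dapt_mean,
        dapt_sd,
        three_sd,
        passed=not reasons,
        reasons=reasons,
    )


# ---------------------------------------------------------------------------
# Condition-vs-control statistics
# ---------------------------------------------------------------------------


def compare_conditions(
    groups: Mapping[str, Sequence[float]],
    method: str = "anova_dunnett",
    control: str = "DMSO",
) -> pd.DataFrame:
    """One-way ANOVA across groups plus each-vs-control post hoc comparisons.

    ``method`` is ``"anova_dunnett"`` (multivariate-t adjusted),
    ``"anova_bonferroni"`` (t-tests with p x m, capped at 1) or ``"ttest"``
    (unadjusted pairwise t-tests).  Returns a table with one ANOVA row and one
    row per comparison.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if control not in groups:
        raise ValueError(f"control group {control!r} not among groups")
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 values")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    others = [k for k in arrays if k != control]
    rows: list[dict] = []

    f_stat, f_p = stats.f_oneway(*arrays.values())
    rows.append({"comparison": "ANOVA", "statistic": float(f_stat), "p": float(f_p)})

    if method == "anova_dunnett":
        # Dunnett p-values are evaluated by Monte Carlo integration of the
        # multivariate t; seed it so identical inputs give identical tables
        res = stats.dunnett(
            *(arrays[k] for k in others), control=arrays[control],
            rng=np.random.default_rng(0),
        )
        for k, t, p in zip(others, res.statistic, res.pvalue):
            rows.append({"comparison": f"{k} vs {control}", "statistic": float(t), "p": float(p)})
    elif method in ("anova_bonferroni", "ttest"):
        m = len(others)
        for k in others:
            t, p = stats.ttest_ind(arrays[k], arrays[control])
            if method == "anova_bonferroni":
                p = min(1.0, p * m)
            rows.append({"comparison": f"{k} vs {control}", "statistic": float(t), "p": float(p)})
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(rows, columns=["comparison", "statistic", "p"])


# ---------------------------------------------------------------------------
# Screen-level normalization -> ScoreTable
# ---------------------------------------------------------------------------


def build_score_table(
    plates: Sequence[tuple[PlateLayout, Mapping[str, Sequence[FieldScores]]]],
) -> ScoreTable:
    """Normalize a whole screen into the published score-table layout.

    For each plate, control means anchor the normalization (same-plate
    controls only, no cross-plate pooling); %DAPT is computed on condition
    means and never re-averaged.
    """
    rows: list[dict] = []
    for layout, field_scores in plates:
        def condition_fields(wells: Sequence[str]) -> list[FieldScores]:
            return [f for w in wells if w in field_scores for f in field_scores[w]]

        pos = aggregate_condition(
            condition_fields(layout.wells_by_role("positive_control"))[:8], "DAPT", 1.0
        )
        neg = aggregate_condition(
            condition_fields(layout.wells_by_role("negative_control"))[:8], "DMSO", 0.0
        )
        if pos.n_fields_used == 0 or neg.n_fields_used == 0:
            raise QCError(f"plate {layout.plate_id}: controls have no usable fields")
        for (cid, conc), wells in layout.test_conditions().items():
            summary = aggregate_condition(condition_fields(wells), cid, conc)
            if summary.n_fields_used == 0:
                rows.append(
                    {
                        "compound_id": cid,
                        "concentration": conc,
                        "pct_dapt_myelination": float("nan"),
                        "fiber_mbp_score": float("nan"),
                        "pct_dapt_olig2": 0.0,
                        "dapi_olig2_ratio": float("inf"),
                        "n_fields_used": 0,
                    }
                )
                continue
            pct = percent_of_control(
                summary.fiber_score_mean, neg.fiber_score_mean, pos.fiber_score_mean
            )
            pct_olig2 = (
                100.0 * summary.olig2_count_mean / pos.olig2_count_mean
                if pos.olig2_count_mean
                else float("nan")
            )
            rows.append(
                {
                    "compound_id": cid,
                    "concentration": conc,
                    "pct_dapt_myelination": pct,
                    "fiber_mbp_score": summary.fiber_mbp_mean,
                    "pct_dapt_olig2": pct_olig2,
                    "dapi_olig2_ratio": summary.dapi_olig2_ratio,
                    "n_fields_used": summary.n_fields_used,
                }
            )
    return ScoreTable(pd.DataFrame(rows, columns=SCORE_COLUMNS))
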