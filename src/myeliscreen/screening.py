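"""Five-criterion hit-selection cascade and dose-response confirmation.

Stages (strictly nested: confirmed within refined within primary):

1. **Primary** — at *either* screened concentration, %DAPT myelination
   strictly above 50 % *or* fiber-score/MBP-score strictly above 1.5.
2/3. **Refined** — the Olig2+ count stays above 25 % of the DAPT Olig2+
   count, and the DAPI / Olig2+ nuclei ratio stays at or below 40 (excludes
   anti-proliferative compounds with inflated per-OL scores).
4. **Morphology** — a visual check of OL number and morphology.  This stage
   is deliberately semi-automated: refined hits are flagged for review and an
   operator decision map can exclude a compound; the cascade never
   auto-passes it.
5. **Confirmed** — at least two independent dose-response experiments fit a
   4PL curve with adequate fit quality and a positive span; the mean EC50
   across replicate experiments ranks the hit.

Ties exactly at a threshold fail (strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dose_response import DoseResponseFit, FourParamLogistic
from .errors import FormatError, NoFitError
from .imaging_io import ScoreTable

STAGES = ("not_hit", "primary", "refined", "flagged_morphology", "confirmed")
#: Cascade depth per stage (flagged_morphology is refined-pending-review).
STAGE_RANK = {"not_hit": 0, "primary": 1, "refined": 2, "flagged_morphology": 2, "confirmed": 3}


@dataclass
class HitCriteria:
    """Thresholds of the selection cascade (all strict)."""

    pct_dapt_min: float = 50.0
    fiber_mbp_min: float = 1.5
    olig2_pct_dapt_min: float = 25.0
    dapi_olig2_max: float = 40.0
    use_normalized_fiber_mbp: bool = False
    min_r2: float = 0.8
    require_converged: bool = True
    min_confirm_fits: int = 2


@dataclass
class HitCall:
    compound_id: str
    stage: str = "not_hit"
    criterion_results: dict[str, dict] = field(default_factory=dict)
    best_concentration: float | None = None
    mean_ec50_uM: float | None = None
    reasons: list[str] = field(default_factory=list)

    @property
    def rank(self) -> int:
        return STAGE_RANK[self.stage]


def _require_columns(df: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"score table missing column(s): {missing}")


def _as_df(table: ScoreTable | pd.DataFrame) -> pd.DataFrame:
    return table.data if isinstance(table, ScoreTable) else table


def call_primary_hits(
    table: ScoreTable | pd.DataFrame, criteria: HitCriteria | None = None
) -> list[HitCall]:
    """Apply the primary criteria per compound across its screened concentrations.

    A compound is a primary hit iff at any concentration
    ``pct_dapt_myelination > pct_dapt_min`` OR
    ``fiber_mbp_score > fiber_mbp_min``.  One :class:`HitCall` is returned
    per compound, in table order.
    """
    criteria = criteria or HitCriteria()
    df = _as_df(table)
    _require_columns(df, ["compound_id", "concentration", "pct_dapt_myelination", "fiber_mbp_score"])
    calls: list[HitCall] = []
    for cid, grp in df.groupby("compound_id", sort=False):
        call = HitCall(str(cid))
        best_pct = -np.inf
        for _, row in grp.iterrows():
            pct = float(row["pct_dapt_myelination"])
            fm = float(row["fiber_mbp_score"])
            pass_pct = pct > criteria.pct_dapt_min
            pass_fm = fm > criteria.fiber_mbp_min
            conc = float(row["concentration"])
            call.criterion_results[f"pct_dapt@{conc:g}"] = {
                "value": pct,
                "threshold": criteria.pct_dapt_min,
                "pass": bool(pass_pct),
            }
            call.criterion_results[f"fiber_mbp@{conc:g}"] = {
                "value": fm,
                "threshold": criteria.fiber_mbp_min,
                "pass": bool(pass_fm),
            }
            if (pass_pct or pass_fm) and pct > best_pct:
                best_pct = pct
                call.best_concentration = conc
        if call.best_concentration is not None:
            call.stage = "primary"
        calls.append(call)
    return calls


def refine_hits(
    primary: Sequence[HitCall],
    table: ScoreTable | pd.DataFrame,
    criteria: HitCriteria | None = None,
    operator_review: Mapping[str, bool] | None = None,
) -> list[HitCall]:
    """Apply the Olig2-depletion and anti-proliferation criteria to primary hits.

    Evaluated at each hit's best concentration.  Refined hits are marked
    ``flagged_morphology`` (refined, pending the visual criterion); an
    ``operator_review`` map (compound -> bool) resolves the flag — ``False``
    demotes the compound with an explicit reason, ``True`` marks it
    ``refined``.  Non-primary calls pass through unchanged.
    """
    criteria = criteria or HitCriteria()
    df = _as_df(table)
    _require_columns(df, ["compound_id", "concentration", "pct_dapt_olig2", "dapi_olig2_ratio"])
    out: list[HitCall] = []
    for call in primary:
        if call.stage == "not_hit":
            out.append(call)
            continue
        rows = df[
            (df["compound_id"] == call.compound_id)
            & (df["concentration"] == call.best_concentration)
        ]
        if not len(rows):
            call.reasons.append("no score row at best concentration")
            out.append(call)
            continue
        row = rows.iloc[0]
        pct_olig2 = float(row["pct_dapt_olig2"])
        ratio = float(row["dapi_olig2_ratio"])
        pass_olig2 = pct_olig2 > criteria.olig2_pct_dapt_min
        pass_ratio = ratio <= criteria.dapi_olig2_max
        call.criterion_results["olig2_pct_dapt"] = {
            "value": pct_olig2,
            "threshold": criteria.olig2_pct_dapt_min,
            "pass": bool(pass_olig2),
        }
        call.criterion_results["dapi_olig2_ratio"] = {
            "value": ratio,
            "threshold": criteria.dapi_olig2_max,
            "pass": bool(pass_ratio),
        }
        if not pass_olig2:
            call.reasons.append(
                f"Olig2+ count {pct_olig2:.3g}% of DAPT below {criteria.olig2_pct_dapt_min:g}% "
                "(Olig2 depletion)"
            )
        if not pass_ratio:
            call.reasons.append(
                f"DAPI/Olig2+ ratio {ratio:.3g} above {criteria.dapi_olig2_max:g} "
                "(anti-proliferative)"
            )
        if pass_olig2 and pass_ratio:
            decision = None if operator_review is None else operator_review.get(call.compound_id)
            if decision is False:
                call.stage = "primary"
                call.reasons.append("excluded at visual morphology review")
                call.criterion_results["morphology"] = {"value": "rejected", "pass": False}
            elif decision is True:
                call.stage = "refined"
                call.criterion_results["morphology"] = {"value": "approved", "pass": True}
            else:
                call.stage = "flagged_morphology"
                call.criterion_results["morphology"] = {"value": "pending", "pass": None}
        out.append(call)
    return out


def fit_dose_response(
    doses: Sequence[float],
    responses: Sequence[float],
    init: Sequence[float] | None = None,
) -> DoseResponseFit:
    """Fit a 4PL curve to one dose-response experiment (relative EC50)."""
    return FourParamLogistic(doses, responses).fit(init=init)


def confirm_hits(
    refined: Sequence[HitCall],
    dose_response_tables: Mapping[str, Sequence[pd.DataFrame]],
    criteria: HitCriteria | None = None,
) -> list[HitCall]:
    """Confirm refined hits from replicate dose-response experiments.

    Each table needs columns ``dose_uM`` and ``response``.  A hit is
    confirmed when at least ``min_confirm_fits`` independent experiments fit
    with ``r_squared >= min_r2``, convergence (if required) and a positive
    span; the mean EC50 over passing fits is reported.
    """
    criteria = criteria or HitCriteria()
    out: list[HitCall] = []
    for call in refined:
        if call.rank < 2:
            out.append(call)
            continue
        tables = dose_response_tables.get(call.compound_id)
        if not tables:
            call.reasons.append("no dose-response data provided")
            out.append(call)
            continue
        ec50s: list[float] = []
        n_pass = 0
        for tab in tables:
            try:
                fit = fit_dose_response(tab["dose_uM"].to_numpy(), tab["response"].to_numpy())
            except (NoFitError, ValueError) as exc:
                call.reasons.append(f"dose-response fit failed: {exc}")
                continue
            ok = (
                fit.r_squared >= criteria.min_r2
                and fit.span > 0
                and (fit.converged or not criteria.require_converged)
            )
            if ok:
                n_pass += 1
                ec50s.append(fit.ec50_uM)
            else:
                call.reasons.append(
                    f"fit rejected (r2={fit.r_squared:.3g}, span={fit.span:.3g}, "
                    f"converged={fit.converged})"
                )
        call.criterion_results["dose_response"] = {
            "value": n_pass,
            "threshold": criteria.min_confirm_fits,
            "pass": n_pass >= criteria.min_confirm_fits,
        }
        if n_pass >= criteria.min_confirm_fits:
            call.stage = "confirmed"
            call.mean_ec50_uM = float(np.mean(ec50s))
        out.append(call)
    return out


def hit_summary(calls: Sequence[HitCall]) -> dict[str, int]:
    """Counts per cascade depth (primary counts include deeper stages)."""
    return {
        "n_compounds": len(calls),
        "primary": sum(1 for c in calls if c.rank >= 1),
        "refined": sum(1 for c in calls if c.rank >= 2),
        "confirmed": sum(1 for c in calls if c.rank >= 3),
    }


def calls_to_frame(calls: Sequence[HitCall]) -> pd.DataFrame:
    rows = [
        {
            "compound_id": c.compound_id,
            "stage": c.stage,
            "best_concentration": c.best_concentration,
            "mean_ec50_uM": c.mean_ec50_uM,
            "reasons": "; ".join(c.reasons),
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["compound_id", "stage", "best_concentration", "mean_ec50_uM", "reasons"]
    )
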