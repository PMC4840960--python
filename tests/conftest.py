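import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from myeliscreen.synthdata import FieldSpec, PlantedHit, ScreenSpec, render_field, simulate_screen

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


#: compound ids and potencies of the hits planted into the library-scale screen
PLANTED_LIBRARY_HITS = [
    PlantedHit(f"C{i:04d}", effect_size=eff, ec50_uM=ec, hill_slope=hill)
    for i, eff, ec, hill in [
        (50, 3.0, 0.10, 1.0),
        (141, 2.8, 0.30, 1.0),
        (232, 3.0, 0.55, 1.0),
        (323, 2.5, 1.00, 1.0),
        (414, 3.5, 2.00, 1.0),
        (505, 3.0, 0.05, 1.5),
        (596, 2.6, 0.80, 0.8),
        (687, 3.2, 1.50, 1.0),
        (700, 2.4, 0.20, 1.2),
        (713, 3.0, 0.40, 1.0),
    ]
]


@pytest.fixture(scope="session")
def library_screen():
    """Score-mode simulated screen of the 727-compound library with 10 planted hits."""
    spec = ScreenSpec(n_compounds=727, planted_hits=list(PLANTED_LIBRARY_HITS))
    return spec, simulate_screen(spec, seed=11)


@pytest.fixture(scope="session")
def null_screen_pct():
    """%DAPT myelination values of 1000 hit-free simulated conditions."""
    spec = ScreenSpec(n_compounds=500)
    result = simulate_screen(spec, seed=41)
    return result.score_table.data["pct_dapt_myelination"].to_numpy()


@pytest.fixture(scope="session")
def default_field():
    """One rendered default co-culture field (512x512) plus its ground truth."""
    return render_field(FieldSpec(), seed=3)


def make_layout_frame(n_compounds: int = 44, concentration: float = 5.0) -> pd.DataFrame:
    """A valid 96-well layout: 4 DAPT + 4 DMSO controls, n compounds in duplicate."""
    rows = []
    for r in "ABCD":
        rows.append({"well": f"{r}12", "role": "positive_control", "compound_id": "DAPT",
                     "concentration_uM": 1.0})
    for r in "EFGH":
        rows.append({"well": f"{r}12", "role": "negative_control", "compound_id": "DMSO",
                     "concentration_uM": 0.0})
    test_wells = [f"{r}{c:02d}" for r in "ABCDEFGH" for c in range(1, 12)]
    for i in range(n_compounds):
        for dup in range(2):
            rows.append(
                {
                    "well": test_wells[2 * i + dup],
                    "role": "test",
                    "compound_id": f"C{i + 1:04d}",
                    "concentration_uM": concentration,
                }
            )
    return pd.DataFrame(rows)


def random_score_frame(rng: np.random.Generator, n_compounds: int = 8) -> pd.DataFrame:
    """A random normalized score table for cascade fuzzing."""
    rows = []
    for i in range(n_compounds):
        for conc in (5.0, 1.0):
            rows.append(
                {
                    "compound_id": f"X{i:03d}",
                    "concentration": conc,
                    "pct_dapt_myelination": rng.uniform(-50.0, 150.0),
                    "fiber_mbp_score": rng.uniform(0.0, 3.0),
                    "pct_dapt_olig2": rng.uniform(0.0, 250.0),
                    "dapi_olig2_ratio": rng.uniform(1.0, 60.0),
                    "n_fields_used": 8,
                }
            )
    return pd.DataFrame(rows)


def brute_force_stages(df: pd.DataFrame, criteria) -> dict[str, str]:
    """Naive row-filter oracle for the hit cascade (independent of the package path)."""
    out = {}
    for cid in df["compound_id"].unique():
        rows = df[df["compound_id"] == cid]
        passing = rows[
            (rows["pct_dapt_myelination"] > criteria.pct_dapt_min)
            | (rows["fiber_mbp_score"] > criteria.fiber_mbp_min)
        ]
        if len(passing) == 0:
            out[cid] = "not_hit"
            continue
        best = passing.loc[passing["pct_dapt_myelination"].idxmax()]
        refined = (
            best["pct_dapt_olig2"] > criteria.olig2_pct_dapt_min
            and best["dapi_olig2_ratio"] <= criteria.dapi_olig2_max
        )
        out[cid] = "refined" if refined else "primary"
    return out
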