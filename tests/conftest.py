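import pandas as pd
import pytest

from pbodykit import SimulationConfig, simulate_apms


@pytest.fixture(scope="session")
def apms_sim():
    """Seeded AP-MS simulation at the emulated study design (seed 1)."""
    config = SimulationConfig(seed=1)
    counts, controls, obs, truth = simulate_apms(config)
    return config, counts, controls, obs, truth


@pytest.fixture()
def toy_counts():
    """Two-protein, one-run count table for closed-form checks."""
    return pd.DataFrame(
        {
            "protein_id": ["A", "B"],
            "run_id": ["r1", "r1"],
            "condition": ["minus_glucose"] * 2,
            "spectral_count": [10, 10],
            "unique_peptides": [3, 3],
        }
    )


@pytest.fixture()
def toy_obs():
    return pd.DataFrame({"protein_id": ["A", "B"], "observability": [1.0, 2.0]})


# five-protein filter-cascade fixture:
# name: (unique peptides, runs identified, (minus score, plus score))
TOY_CASCADE_PROTEINS = {
    "A": (3, 3, (0.9, 0.2)),
    "B": (1, 5, (0.9, 0.9)),
    "C": (3, 1, (0.9, 0.9)),
    "D": (3, 2, (0.4, 0.3)),
    "E": (2, 2, (0.6, 0.1)),
}


def toy_cascade_tables():
    runs = [("m1", "minus_glucose"), ("m2", "minus_glucose"), ("m3", "minus_glucose"),
            ("p1", "plus_glucose"), ("p2", "plus_glucose")]
    rows = []
    for pid, (u, n_runs, _) in TOY_CASCADE_PROTEINS.items():
        for run, cond in runs[:n_runs]:
            rows.append(
                {"protein_id": pid, "run_id": run, "condition": cond,
                 "spectral_count": 5, "unique_peptides": u}
            )
    counts = pd.DataFrame(rows)
    scores = pd.DataFrame(
        [
            {"protein_id": pid, "condition": cond, "score": s}
            for pid, (_, _, pair) in TOY_CASCADE_PROTEINS.items()
            for cond, s in zip(["minus_glucose", "plus_glucose"], pair)
        ]
    )
    return counts, scores


@pytest.fixture()
def toy_cascade():
    return toy_cascade_tables()
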