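import numpy as np
import pandas as pd
import pytest

from symtraj.lexicons import DEFAULT_SUFFIXES, DEFAULT_SYMPTOM_TERMS
from symtraj.synthetic import SimConfig, generate_notes, generate_registry
from symtraj.textmining import expand_suffixes


@pytest.fixture(scope="session")
def dictionary():
    return expand_suffixes(DEFAULT_SYMPTOM_TERMS, DEFAULT_SUFFIXES)


@pytest.fixture(scope="session")
def planted_sim():
    """Small simulated cohort with one planted directed pair (R10 -> R17).

    R10 is made common so the pair is well powered even at 120 cases.
    """
    prevalences = {**SimConfig().baseline_code_prevalences, "R10": 0.15}
    cfg = SimConfig(
        n_cases=120,
        seed=42,
        planted_pairs=[("R10", "R17", 4.0, 0.9)],
        baseline_code_prevalences=prevalences,
    )
    registry, truth = generate_registry(cfg)
    return cfg, registry, truth


@pytest.fixture(scope="session")
def noisy_notes(planted_sim, dictionary):
    """Notes for the planted cohort at the default noise rates."""
    cfg, registry, truth = planted_sim
    notes, truth = generate_notes(registry, dictionary, cfg, truth)
    return cfg, registry, notes, truth


def brute_levenshtein(a: str, b: str) -> int:
    """Dynamic-programming Levenshtein with unit costs, no transposition.

    Test-side oracle, deliberately independent of the implementation path.
    """
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def make_events(rows):
    """Event frame from (patient_id, code, admission, discharge, type, encounter)."""
    df = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "event_code",
            "admission_date",
            "discharge_date",
            "diagnosis_type",
            "encounter_id",
        ],
    )
    df["admission_date"] = pd.to_datetime(df["admission_date"])
    df["discharge_date"] = pd.to_datetime(df["discharge_date"])
    return df


def make_patients(rows):
    """Patient frame from (patient_id, sex, birth, status, death-or-None)."""
    df = pd.DataFrame(
        rows, columns=["patient_id", "sex", "birth_date", "status_code", "death_date"]
    )
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    df["death_date"] = pd.to_datetime(df["death_date"])
    return df
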