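"""Synthetic registry, control pool and clinical-note generator.

Real nationwide registry/EHR data are person-sensitive and cannot be
shipped, so every downstream stage is exercised on simulated data with
known planted structure:

* ``n_cases`` pancreatic-cancer patients (code C25) with an index date, a
  five-year symptom history, and a two-component exponential survival
  mixture producing both a <=90-day and a >90-day median-survival group;
* a 10:1 (or larger) control pool in which every case's matching stratum
  (sex, birth year, index year) is guaranteed to contain at least ten
  controls with a hospital contact in the index year;
* event streams from a homogeneous per-code process modulated by an annual
  sinusoid (so that same-week seasonal matching is actually exercised);
* planted directed pairs ``(a, b, RR, direction_prob)``: carriers of ``a``
  acquire ``b`` with probability ``RR * q_b`` (``q_b`` the baseline
  probability of carrying ``b`` within the lookback window), placed after
  ``a``'s first occurrence with probability ``direction_prob``.  This
  closed-form calibration makes the expected exposed-vs-comparison
  relative risk equal the target without iterative tuning;
* templated English clinical notes embedding dictionary surface forms,
  corrupted by one edit / wrapped in a negated sentence / attributed to a
  relative at configurable rates, with gold character-offset annotations.

All randomness flows from ``SimConfig.seed``; identical configs produce
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    DAYS_PER_YEAR,
    EVENT_COLUMNS,
    PATIENT_COLUMNS,
    Registry,
    dedup_per_encounter,
    filter_diagnosis_types,
)
from .lexicons import CANCER_CODE, CONTACT_CODE, OTHER_PERSON_LEXICON
from .textmining import SymptomDictionary

DATA_START = pd.Timestamp("2000-01-01")
_EPOCH = pd.Timestamp("1970-01-01")

#: baseline per-patient-year rates; exp(-5 * 0.02) gives ~9.5% window prevalence
DEFAULT_PREVALENCES: dict[str, float] = {
    "R05": 0.02,
    "R10": 0.02,
    "R11": 0.02,
    "R17": 0.02,
    "R50": 0.02,
    "R52": 0.02,
    "R63": 0.02,
    "K56": 0.02,
}

_FILLERS = [
    "Routine review in clinic.",
    "Observation continued overnight.",
    "Plan discussed with the team.",
    "Bloods taken at arrival.",
]
_AFFIRM_TEMPLATES = [
    "Patient reports {m} during admission.",
    "Examination revealed {m}.",
    "Ongoing {m} since last visit.",
]
_NEGATED_TEMPLATES = [
    "No {m} at present.",
    "Patient denies {m}.",
]
_OTHER_TEMPLATES = [
    "{r} had {m} last year.",
    "{r} was treated for {m}.",
]
_NEG_OTHER_TEMPLATES = [
    "{r} denies {m}.",
]
_RELATIONS = sorted(OTHER_PERSON_LEXICON)


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Probabilities are per mention; rates are per patient-year; the survival
    mixture is ``(fraction_short, short_median_days, long_median_days)``
    with exponential components, so medians are analytic (ln 2 / lambda).
    """

    n_cases: int = 300
    control_pool_multiplier: int = 10
    years_span: float = 3.0
    lookback_years: float = 5.0
    planted_pairs: list[tuple[str, str, float, float]] = field(default_factory=list)
    baseline_code_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    seasonal_amplitude: float = 0.2
    contact_rate: float = 2.0
    note_rate: float = 0.5
    spelling_error_rate: float = 0.05
    negation_rate: float = 0.10
    other_person_rate: float = 0.05
    survival_mixture: tuple[float, float, float] = (0.35, 45.0, 250.0)
    other_status_fraction: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.control_pool_multiplier < 10:
            raise ValueError(
                "control_pool_multiplier must be >= 10 so every stratum can "
                "supply 10 matched controls per case"
            )
        for name in ("spelling_error_rate", "negation_rate", "other_person_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.seasonal_amplitude < 1.0:
            raise ValueError("seasonal_amplitude must be in [0, 1)")
        frac_short, short_med, long_med = self.survival_mixture
        if not 0.0 <= frac_short <= 1.0:
            raise ValueError("fraction_short must be in [0, 1]")
        if not short_med <= 90 < long_med:
            raise ValueError("survival mixture needs short_median <= 90 < long_median")
        for a, b, rr, dp in self.planted_pairs:
            if rr <= 0:
                raise ValueError(f"target RR must be > 0 for pair ({a}, {b})")
            if not 0.0 <= dp <= 1.0:
                raise ValueError(f"direction_prob must be in [0, 1] for ({a}, {b})")
            for c in (a, b):
                if c not in self.baseline_code_prevalences:
                    raise ValueError(
                        f"planted code {c} needs a baseline prevalence entry"
                    )
        for c, r in self.baseline_code_prevalences.items():
            if r < 0:
                raise ValueError(f"prevalence rate for {c} must be >= 0")

    def window_prevalence(self, code: str) -> float:
        """Probability of carrying ``code`` within the lookback window."""
        rate = self.baseline_code_prevalences[code]
        return 1.0 - float(np.exp(-rate * self.lookback_years))


@dataclass
class PlantedTruth:
    """Ground truth of a simulation run.

    ``pair_truth`` maps ``(code_a, code_b)`` to ``(true_RR,
    true_direction_prob)``; ``gold_mentions`` (filled by
    :func:`generate_notes`) has columns ``note_id, start, end, code,
    negated, other_person`` with 0-based half-open character offsets.
    """

    pair_truth: dict[tuple[str, str], tuple[float, float]]
    gold_mentions: pd.DataFrame | None = None


def _day(ts: pd.Timestamp) -> int:
    return (ts - _EPOCH).days


def _seasonal_offsets(rng, anchor_days, lo, hi, amplitude, size=None):
    """Float day offsets in [lo, hi) with annual-sinusoid date weighting.

    Rejection sampling against ``1 + A cos(2 pi (doy - 15) / 365.25)``:
    admissions peak mid-January, the simplest stand-in for winter-heavy
    hospital activity.
    """
    anchor_days = np.asarray(anchor_days, dtype=float)
    n = anchor_days.size if size is None else size
    out = np.empty(n)
    pending = np.arange(n)
    while pending.size:
        u = rng.uniform(lo, hi, pending.size)
        day = anchor_days[pending] + np.floor(u)
        doy = np.mod(day, DAYS_PER_YEAR)
        w = (1 + amplitude * np.cos(2 * np.pi * (doy - 15) / DAYS_PER_YEAR)) / (
            1 + amplitude
        )
        acc = rng.uniform(size=pending.size) < w
        out[pending[acc]] = u[acc]
        pending = pending[~acc]
    return out


def generate_registry(config: SimConfig) -> tuple[Registry, PlantedTruth]:
    """Simulate the registry: cases, matchable control pool, planted pairs.

    Returns a :class:`~symtraj.cohort.Registry` (patients + events frames,
    confirmed case ids, end-of-data date) and the :class:`PlantedTruth`.
    Deterministic under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([max(config.seed, 0), 0]))
    lb = config.lookback_years * DAYS_PER_YEAR
    n = config.n_cases
    amp = config.seasonal_amplitude
    codes = sorted(config.baseline_code_prevalences)

    # ---- case demographics -------------------------------------------------
    start_day = _day(DATA_START)
    index_day = start_day + np.floor(
        lb + rng.uniform(0, config.years_span * DAYS_PER_YEAR, n)
    ).astype(int)
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    age = rng.integers(55, 85, n)
    birth_day = index_day - np.floor(
        age * DAYS_PER_YEAR + rng.uniform(0, 365, n)
    ).astype(int)
    case_ids = np.array([f"C{i:05d}" for i in range(n)])

    ev_pid: list[np.ndarray] = []
    ev_code: list[np.ndarray] = []
    ev_adm: list[np.ndarray] = []
    ev_dis: list[np.ndarray] = []
    ev_dtype: list[np.ndarray] = []

    def _emit(pids, code_arr, adm, dis=None, dtype="B"):
        adm = np.asarray(adm, dtype=int)
        if dis is None:
            dis = adm + rng.integers(0, 4, adm.size)
        ev_pid.append(np.asarray(pids))
        ev_code.append(
            np.full(adm.size, code_arr) if np.isscalar(code_arr) else np.asarray(code_arr)
        )
        ev_adm.append(adm)
        ev_dis.append(np.asarray(dis, dtype=int))
        ev_dtype.append(np.full(adm.size, dtype))

    # cancer diagnosis at the index date
    _emit(case_ids, CANCER_CODE, index_day, dis=index_day, dtype="A")

    def _contacts(pids, anchor, lo, hi):
        counts = rng.poisson(config.contact_rate * config.lookback_years, len(pids))
        rep = np.repeat(np.arange(len(pids)), counts)
        off = _seasonal_offsets(rng, anchor[rep], lo, hi, amp)
        adm = anchor[rep] + np.floor(off).astype(int)
        dis = adm + rng.integers(0, 4, adm.size)
        _emit(pids[rep], CONTACT_CODE, adm, dis=dis, dtype="A")
        return rep, adm, dis

    _contacts(case_ids, index_day, -lb, 0.0)

    # ---- symptom presence and first-occurrence offsets (cases) ------------
    q = {c: config.window_prevalence(c) for c in codes}
    present = {c: rng.random(n) < q[c] for c in codes}
    # base first dates live in [-lb + 2, -2) so planted before/after placement
    # always has at least one day of room on either side
    first_off = {
        c: _seasonal_offsets(rng, index_day, -lb + 2, -2.0, amp) for c in codes
    }

    pair_truth: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b, rr, dp in config.planted_pairs:
        pair_truth[(a, b)] = (rr, dp)
        carriers = present[a].copy()
        p_b = min(1.0, rr * q[b])
        new_b = rng.random(n) < p_b
        fwd = rng.random(n) < dp
        u = rng.uniform(size=n)
        a_off = first_off[a]
        after = a_off + 1.0 + u * ((-1.0) - (a_off + 1.0))
        before = (-lb + 2) + u * ((a_off - 1.0) - (-lb + 2))
        planted_off = np.where(fwd, after, before)
        both = carriers & new_b
        present[b] = np.where(carriers, new_b, present[b])
        first_off[b] = np.where(both, planted_off, first_off[b])

    def _symptom_events(pids, anchor, present_map, first_map):
        for c in codes:
            mask = present_map[c]
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            adm = anchor[idx] + np.floor(first_map[c][idx]).astype(int)
            _emit(pids[idx], c, adm, dtype="B")
            extra = rng.poisson(0.3, idx.size)
            rep = np.repeat(np.arange(idx.size), extra)
            if rep.size:
                lo_e = first_map[c][idx][rep]
                off = lo_e + rng.uniform(size=rep.size) * (-1.0 - lo_e)
                _emit(pids[idx][rep], c,
                      anchor[idx][rep] + np.floor(off).astype(int), dtype="B")

    _symptom_events(case_ids, index_day, present, first_off)

    # ---- deaths ------------------------------------------------------------
    frac_short, short_med, long_med = config.survival_mixture
    is_short = rng.random(n) < frac_short
    scale = np.where(is_short, short_med, long_med) / np.log(2)
    surv_days = np.ceil(rng.exponential(scale)).astype(int)
    death_day = index_day + surv_days
    end_of_data_day = int(index_day.max() + np.ceil(3 * DAYS_PER_YEAR))
    dead = death_day <= end_of_data_day

    # ---- control pool ------------------------------------------------------
    n_ctrl = config.control_pool_multiplier * n
    ctrl_of = np.arange(n_ctrl) % n
    ctrl_ids = np.array([f"P{i:06d}" for i in range(n_ctrl)])
    ctrl_sex = sex[ctrl_of]
    by = pd.to_datetime(birth_day[ctrl_of], unit="D").year.values
    ctrl_birth_day = np.array(
        [_day(pd.Timestamp(year=int(y), month=1, day=1)) for y in np.unique(by)]
    )[np.searchsorted(np.unique(by), by)] + rng.integers(0, 365, n_ctrl)
    iy = pd.to_datetime(index_day[ctrl_of], unit="D").year.values
    jan1 = {int(y): _day(pd.Timestamp(year=int(y), month=1, day=1)) for y in np.unique(iy)}
    anchor_day = np.array([jan1[int(y)] for y in iy]) + rng.integers(0, 365, n_ctrl)

    # guaranteed index-year contact
    _emit(ctrl_ids, CONTACT_CODE, anchor_day, dtype="A")
    c_rep, c_adm, c_dis = _contacts(ctrl_ids, anchor_day, -lb, 0.0)

    # Control symptom codes are attached to existing lookback contacts (same
    # admission and discharge), as diagnoses are coded at encounters; this
    # also keeps a control's week-of-year discharge coverage independent of
    # which symptoms it carries, so seasonal comparison sampling stays
    # unbiased with respect to D2 status.
    order = np.argsort(c_rep, kind="stable")
    s_rep, s_adm, s_dis = c_rep[order], c_adm[order], c_dis[order]
    starts = np.searchsorted(s_rep, np.arange(n_ctrl))
    ends = np.searchsorted(s_rep, np.arange(n_ctrl) + 1)
    n_contacts = ends - starts

    ctrl_present = {c: rng.random(n_ctrl) < q[c] for c in codes}
    for c in codes:
        idx = np.flatnonzero(ctrl_present[c])
        if idx.size == 0:
            continue
        n_occ = 1 + rng.poisson(0.3, idx.size)
        rep = np.repeat(idx, n_occ)
        have = n_contacts[rep] > 0
        if have.any():
            pick = starts[rep[have]] + rng.integers(
                0, np.maximum(n_contacts[rep[have]], 1)
            )
            _emit(ctrl_ids[rep[have]], c, s_adm[pick], dis=s_dis[pick], dtype="B")
        if (~have).any():  # contact-free control: fall back to a free-standing date
            off = _seasonal_offsets(
                rng, anchor_day[rep[~have]], -lb + 2, -2.0, amp
            )
            _emit(ctrl_ids[rep[~have]], c,
                  anchor_day[rep[~have]] + np.floor(off).astype(int), dtype="B")

    # ---- other-status residue (exercises the 01/90 filter) -----------------
    n_other = int(round(config.other_status_fraction * n_ctrl))
    other_ids = np.array([f"X{i:04d}" for i in range(n_other)])
    if n_other:
        o_of = np.arange(n_other) % n
        _emit(other_ids, CONTACT_CODE,
              index_day[o_of] - rng.integers(1, int(lb), n_other), dtype="A")

    # ---- assemble events ---------------------------------------------------
    events = pd.DataFrame(
        {
            "patient_id": np.concatenate(ev_pid),
            "event_code": np.concatenate(ev_code),
            "adm_day": np.concatenate(ev_adm),
            "dis_day": np.concatenate(ev_dis),
            "diagnosis_type": np.concatenate(ev_dtype),
        }
    )
    events = events.sort_values(
        ["patient_id", "adm_day", "event_code"], kind="stable", ignore_index=True
    )
    events["encounter_id"] = [f"E{i:07d}" for i in range(len(events))]

    # same-encounter duplicate codes (the registry records a symptom twice)
    dup = events[events["event_code"].isin(codes)].sample(
        frac=0.03, random_state=int(rng.integers(2**31))
    )
    # referral/temporary (H/M) copies, removed again by preprocessing
    hm = events.sample(frac=0.04, random_state=int(rng.integers(2**31))).copy()
    hm["diagnosis_type"] = np.where(rng.random(len(hm)) < 0.5, "H", "M")
    hm["encounter_id"] = [f"E{i:07d}" for i in range(len(events), len(events) + len(hm))]

    events = pd.concat([events, dup, hm], ignore_index=True)
    events = events.sort_values(
        ["patient_id", "adm_day", "encounter_id", "event_code"],
        kind="stable",
        ignore_index=True,
    )
    events["admission_date"] = pd.to_datetime(events.pop("adm_day"), unit="D")
    events["discharge_date"] = pd.to_datetime(events.pop("dis_day"), unit="D")
    events = events[EVENT_COLUMNS]

    # ---- assemble patients -------------------------------------------------
    patients = pd.DataFrame(
        {
            "patient_id": np.concatenate([case_ids, ctrl_ids, other_ids]),
            "sex": np.concatenate([sex, ctrl_sex, sex[: n_other][:n_other] if n_other else sex[:0]]),
            "birth_date": pd.to_datetime(
                np.concatenate(
                    [birth_day, ctrl_birth_day, birth_day[:n_other] if n_other else birth_day[:0]]
                ),
                unit="D",
            ),
            "status_code": np.concatenate(
                [
                    np.where(dead, "90", "01"),
                    np.full(n_ctrl, "01"),
                    np.full(n_other, "30"),
                ]
            ),
            "death_day": np.concatenate(
                [
                    np.where(dead, death_day, -1),
                    np.full(n_ctrl, -1),
                    np.full(n_other, -1),
                ]
            ),
        }
    )
    patients["death_date"] = pd.to_datetime(
        patients.pop("death_day").replace(-1, np.nan), unit="D"
    )
    patients = patients[PATIENT_COLUMNS]

    registry = Registry(
        patients=patients,
        events=events,
        confirmed_case_ids=frozenset(case_ids.tolist()),
        end_of_data=pd.to_datetime(end_of_data_day, unit="D"),
        meta={"n_cases": n, "n_controls": n_ctrl, "seed": config.seed},
    )
    return registry, PlantedTruth(pair_truth=pair_truth)


def _one_edit(rng, form: str, forbidden: set[str]) -> str:
    """One random substitution, deletion or insertion on a letter position."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    positions = [i for i, ch in enumerate(form) if ch.isalpha()]
    for _ in range(8):
        i = int(positions[rng.integers(len(positions))])
        op = int(rng.integers(3))
        if op == 0:
            ch = letters[rng.integers(26)]
            if ch == form[i]:
                continue
            cand = form[:i] + ch + form[i + 1 :]
        elif op == 1 and len(positions) > 3:
            cand = form[:i] + form[i + 1 :]
        else:
            ch = letters[rng.integers(26)]
            cand = form[:i] + ch + form[i:]
        if cand not in forbidden:
            return cand
    return form


def generate_notes(
    registry: Registry,
    dictionary: SymptomDictionary,
    config: SimConfig,
    truth: PlantedTruth | None = None,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Templated clinical notes mirroring the registry's symptom events.

    One note is emitted per deduplicated symptom diagnosis event whose code
    has a dictionary surface form, dated at the admission day, so the notes
    channel carries the same planted temporal structure as the registry.
    Filler notes (no symptom content) top the stream up towards
    ``note_rate`` notes per patient-year.  Gold annotations record every
    planted mention with its negation/other-person flags and exact
    character offsets.
    """
    config.validate()
    if len(dictionary) == 0:
        raise ValueError("dictionary must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([max(config.seed, 0), 1]))

    forms_by_code: dict[str, list[str]] = {}
    for code in sorted(dictionary.codes()):
        forms = dictionary.base_forms(code)
        if forms:
            forms_by_code[code] = forms
    forbidden = set(dictionary.entries)

    ev = dedup_per_encounter(filter_diagnosis_types(registry.events))
    sym = ev[ev["event_code"].isin(forms_by_code)]
    sym = sym.sort_values(
        ["patient_id", "admission_date", "encounter_id"], kind="stable"
    )

    note_rows = []
    gold_rows = []
    n_sym_notes: dict[str, int] = {}
    seq = 0

    for rec in sym.itertuples():
        note_id = f"N{seq:06d}"
        seq += 1
        code = rec.event_code
        forms = forms_by_code[code]
        form = forms[rng.integers(len(forms))]
        negated = rng.random() < config.negation_rate
        other = rng.random() < config.other_person_rate
        corrupted = rng.random() < config.spelling_error_rate
        if corrupted:
            form = _one_edit(rng, form, forbidden)

        if negated and other:
            template = _NEG_OTHER_TEMPLATES[rng.integers(len(_NEG_OTHER_TEMPLATES))]
        elif negated:
            template = _NEGATED_TEMPLATES[rng.integers(len(_NEGATED_TEMPLATES))]
        elif other:
            template = _OTHER_TEMPLATES[rng.integers(len(_OTHER_TEMPLATES))]
        else:
            template = _AFFIRM_TEMPLATES[rng.integers(len(_AFFIRM_TEMPLATES))]
        relation = _RELATIONS[rng.integers(len(_RELATIONS))].capitalize()
        pre, post = template.replace("{r}", relation).split("{m}")

        parts = []
        if rng.random() < 0.7:
            parts.append(_FILLERS[rng.integers(len(_FILLERS))])
        prefix_len = sum(len(p) + 1 for p in parts)
        start = prefix_len + len(pre)
        parts.append(pre + form + post)
        if rng.random() < 0.5:
            parts.append(_FILLERS[rng.integers(len(_FILLERS))])
        text = " ".join(parts)

        note_rows.append((note_id, rec.patient_id, rec.admission_date, text))
        gold_rows.append((note_id, start, start + len(form), code, negated, other))
        n_sym_notes[rec.patient_id] = n_sym_notes.get(rec.patient_id, 0) + 1

    # filler-only notes up to the configured note rate
    target = config.note_rate * config.lookback_years
    pat = registry.patients.sort_values("patient_id")
    ev_dates = registry.events.groupby("patient_id")["admission_date"]
    first_date = ev_dates.min()
    last_date = ev_dates.max()
    for rec in pat.itertuples():
        lam = max(0.0, target - n_sym_notes.get(rec.patient_id, 0))
        n_extra = rng.poisson(lam)
        if rec.patient_id not in first_date.index:
            continue
        lo = _day(first_date[rec.patient_id])
        hi = max(_day(last_date[rec.patient_id]), lo + 1)
        for _ in range(n_extra):
            note_id = f"N{seq:06d}"
            seq += 1
            day = int(rng.integers(lo, hi))
            text = " ".join(
                _FILLERS[rng.integers(len(_FILLERS))]
                for _ in range(1 + rng.integers(2))
            )
            note_rows.append(
                (note_id, rec.patient_id, pd.to_datetime(day, unit="D"), text)
            )

    notes = pd.DataFrame(note_rows, columns=["note_id", "patient_id", "date", "text"])
    gold = pd.DataFrame(
        gold_rows, columns=["note_id", "start", "end", "code", "negated", "other_person"]
    )
    out_truth = PlantedTruth(
        pair_truth=dict(truth.pair_truth) if truth else {}, gold_mentions=gold
    )
    return notes, out_truth
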