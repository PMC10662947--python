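"""Calibration and recovery experiments on the synthetic study conditions.

These functions reproduce, at desk scale, the statistical behaviour the
pipeline is supposed to exhibit: recovery of planted relative risks by the
matched-comparison estimator, type-I calibration of the exact
directionality test, agreement of the stratified odds ratio with its
Mantel-Haenszel cross-check, end-to-end recovery of a planted symptom
chain, clean null runs, tagger performance on noise-free and noisy
corpora, and Kaplan-Meier medians on exponential survival.  They are used
by the test suite and by ``scripts/acceptance.py``.

Problem sizes (550-case cohorts for estimator recovery, 250-case null
cohorts, 20 replicates, 10 000 null simulations for the binomial test) are
chosen so each experiment finishes in seconds to a couple of minutes on
one CPU while keeping Monte-Carlo error well inside the tolerances being
checked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cohort as ch
from . import pairs as pr
from . import textmining as tm
from . import trajectories as tj
from .lexicons import DEFAULT_SUFFIXES, DEFAULT_SYMPTOM_TERMS, NEGATION_LEXICON, OTHER_PERSON_LEXICON
from .model import SymptomTrajectoryModel
from .synthetic import SimConfig, generate_notes, generate_registry


def _rep_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(2**31, size=n)]


# ---------------------------------------------------------------------------
# Relative-risk estimator recovery


def estimate_planted_rr(target_rr: float, seed: int, n_cases: int = 550) -> float:
    """One replicate: simulate, run the matched RR screen, return the estimate.

    The planted pair uses a common D1 (~95% window prevalence, giving >500
    exposed patients) and a ~9.5% baseline D2, with 10 comparison groups.
    """
    prev = {"R10": 0.60, "R17": 0.02, "R50": 0.02}
    cfg = SimConfig(
        n_cases=n_cases,
        seed=seed,
        planted_pairs=[("R10", "R17", target_rr, 0.9)],
        baseline_code_prevalences=prev,
    )
    registry, _ = generate_registry(cfg)
    patients = ch.filter_active(registry.patients)
    events = ch.filter_diagnosis_types(registry.events)
    events = events[events["patient_id"].isin(set(patients["patient_id"]))]
    cases = ch.select_cases(patients, events, registry.confirmed_case_ids)
    attrs = patients.set_index("patient_id")
    cases = cases.merge(
        attrs[["sex", "birth_date"]], left_on="patient_id", right_index=True
    )
    case_ev = ch.windowed_case_events(
        cases[["patient_id", "index_date"]], events, cfg.lookback_years
    )
    pool_pat = patients[patients["patient_id"].str.startswith("P")]
    pool_ev = ch.dedup_per_encounter(
        events[events["patient_id"].isin(set(pool_pat["patient_id"]))]
    )
    stats, _ = pr.registry_pair_statistics(
        cases, case_ev, pool_pat, pool_ev, ["R10", "R17"], n_groups=10, seed=seed + 1
    )
    (stat,) = [s for s in stats if s.d1 == "R10" and s.d2 == "R17"]
    if stat.n_exposed < 500:
        raise RuntimeError("replicate produced fewer than 500 exposed patients")
    return float(stat.effect)


def rr_recovery(target_rr: float, n_replicates: int = 20, seed: int = 0) -> dict:
    """Mean Eq.-3 estimate over replicates for one planted RR."""
    values = [
        estimate_planted_rr(target_rr, s) for s in _rep_seeds(seed, n_replicates)
    ]
    return {
        "target": target_rr,
        "mean": float(np.mean(values)),
        "values": values,
        "n": n_replicates,
    }


# ---------------------------------------------------------------------------
# Directionality test calibration


def directionality_null_rejection_rate(
    n_sims: int = 10_000, n_trials: int = 40, alpha: float = 0.05, seed: int = 0
) -> float:
    """Rejection rate of the two-sided exact test on fair-coin orderings."""
    rng = np.random.default_rng(seed)
    ks = rng.binomial(n_trials, 0.5, size=n_sims)
    p_by_k = {
        k: pr.directionality_test(pr.DirectionCounts(int(k), int(n_trials - k), 0))
        for k in np.unique(ks)
    }
    pvals = np.array([p_by_k[k] for k in ks])
    return float((pvals < alpha).mean())


# ---------------------------------------------------------------------------
# Stratified OR vs Mantel-Haenszel on 1:10 matched sets


def matched_set_or_experiment(
    n_sets: int = 200,
    ratio: int = 10,
    p_case: float = 0.35,
    p_control: float = 0.15,
    seed: int = 0,
) -> dict:
    """Conditional-logit and Mantel-Haenszel ORs on simulated matched sets."""
    rng = np.random.default_rng(seed)
    case = rng.random(n_sets) < p_case
    ctrl = rng.random(n_sets * ratio) < p_control
    cs = np.arange(n_sets)
    ks = np.repeat(np.arange(n_sets), ratio)
    or_cl, p_cl = pr.odds_ratio_pair(case, ctrl, cs, ks)
    or_mh, _ = pr.mantel_haenszel_or(case, ctrl, cs, ks)
    return {"or_conditional": or_cl, "or_mantel_haenszel": or_mh, "p": p_cl,
            "n_sets": n_sets}


# ---------------------------------------------------------------------------
# Tagger experiments


def _tag_corpus(notes: pd.DataFrame, dictionary: tm.SymptomDictionary):
    mentions_by_note = {}
    n_tokens = 0
    for rec in notes.itertuples():
        ms = tm.tag_note(rec.text, dictionary, note_id=rec.note_id)
        tm.flag_negations(ms, rec.text, NEGATION_LEXICON)
        tm.flag_other_person(ms, rec.text, OTHER_PERSON_LEXICON)
        mentions_by_note[rec.note_id] = ms
        n_tokens += len(tm.tokenize(rec.text))
    return mentions_by_note, n_tokens


def tagging_experiment(
    spelling_error_rate: float = 0.0,
    negation_rate: float = 0.0,
    other_person_rate: float = 0.0,
    n_cases: int = 80,
    seed: int = 0,
    harvest: bool = False,
) -> dict:
    """Tag a synthetic corpus and score it against its gold annotations.

    Returns corpus-level sensitivity/specificity (gold restricted to
    affirmed patient-own mentions, predictions to unflagged ones) plus the
    fraction of all tagged mentions that carry the negation flag.
    """
    cfg = SimConfig(
        n_cases=n_cases,
        seed=seed,
        spelling_error_rate=spelling_error_rate,
        negation_rate=negation_rate,
        other_person_rate=other_person_rate,
    )
    registry, truth = generate_registry(cfg)
    dictionary = tm.expand_suffixes(DEFAULT_SYMPTOM_TERMS, DEFAULT_SUFFIXES)
    notes, truth = generate_notes(registry, dictionary, cfg, truth)
    if harvest:
        corpus_tokens = set()
        for text in notes["text"]:
            corpus_tokens.update(t.text for t in tm.tokenize(text))
        dictionary.add_spelling_variants(
            tm.harvest_spelling_variants(dictionary.tokens(), corpus_tokens)
        )
    mentions_by_note, n_tokens = _tag_corpus(notes, dictionary)

    gold_by_note: dict[str, list] = {}
    for rec in truth.gold_mentions.itertuples():
        if not rec.negated and not rec.other_person:
            gold_by_note.setdefault(rec.note_id, []).append(
                (rec.start, rec.end, rec.code)
            )
    tp = fp = fn = 0
    n_flagged = n_tagged = 0
    for note_id, ms in mentions_by_note.items():
        counts = tm.confusion_counts(gold_by_note.get(note_id, []), ms, 0)
        tp, fp, fn = tp + counts.tp, fp + counts.fp, fn + counts.fn
        n_tagged += len(ms)
        n_flagged += sum(m.negated for m in ms)
    total = tm.ConfusionCounts(tp=tp, fp=fp, tn=n_tokens - tp - fp - fn, fn=fn)
    return {
        "sensitivity": total.sensitivity,
        "specificity": total.specificity,
        "n_gold": tp + fn,
        "n_tagged": n_tagged,
        "negated_fraction": n_flagged / n_tagged if n_tagged else float("nan"),
    }


# ---------------------------------------------------------------------------
# End-to-end chain recovery and null runs


CHAIN = ("R52", "R17", "K56")


def planted_chain_run(seed: int = 0, n_cases: int = 500):
    """Fit the registry model on a cohort with a planted R52→R17→K56 chain."""
    prev = {"R52": 0.30, "R17": 0.02, "K56": 0.02, "R10": 0.02,
            "R11": 0.02, "R50": 0.02}
    cfg = SimConfig(
        n_cases=n_cases,
        seed=seed,
        planted_pairs=[(CHAIN[0], CHAIN[1], 4.0, 0.9), (CHAIN[1], CHAIN[2], 4.0, 0.9)],
        baseline_code_prevalences=prev,
    )
    model = SymptomTrajectoryModel.from_synthetic(cfg, source="registry", min_support=20)
    return model.fit(seed=seed + 1)


def null_trajectory_runs(n_replicates: int = 20, seed: int = 0, n_cases: int = 250) -> dict:
    """Replicated no-plant runs at the 20-follower / corrected-0.05 thresholds.

    Returns the fraction of replicates emitting no length-3 trajectory and
    the overall fraction of pairs significant after Bonferroni correction
    (a null-soundness check on the co-occurrence screen).
    """
    clean = 0
    n_sig = n_pairs = 0
    for s in _rep_seeds(seed, n_replicates):
        cfg = SimConfig(n_cases=n_cases, seed=s)
        model = SymptomTrajectoryModel.from_synthetic(
            cfg, source="registry", min_support=20
        )
        res = model.fit(seed=s + 1)
        clean += len(res.trajectories) == 0
        finite = [
            st for st in res.pair_stats if np.isfinite(st.effect_p_corrected)
        ]
        n_pairs += len(finite)
        n_sig += sum(st.effect_p_corrected < 0.05 for st in finite)
    return {
        "clean_fraction": clean / n_replicates,
        "significant_pair_fraction": n_sig / n_pairs if n_pairs else 0.0,
        "n": n_replicates,
    }


# ---------------------------------------------------------------------------
# Survival


def km_median_experiment(
    true_median: float = 60.0, n: int = 200, seed: int = 0, censor_days: float | None = None
) -> float:
    """KM median on exponential survival with an analytic median."""
    rng = np.random.default_rng(seed)
    days = rng.exponential(true_median / np.log(2), size=n)
    ids = [f"p{i}" for i in range(n)]
    index = pd.Series(pd.Timestamp("2010-01-01"), index=ids)
    deaths = index + pd.to_timedelta(np.ceil(days), unit="D")
    end = (
        pd.Timestamp("2010-01-01") + pd.Timedelta(days=censor_days)
        if censor_days is not None
        else deaths.max()
    )
    median, _, _ = tj.median_survival(ids, index, pd.Series(deaths), end)
    return float(median)


def survival_split_experiment(seed: int = 0, n: int = 150) -> dict:
    """The 90-day classifier on planted short/long exponential groups."""
    rng = np.random.default_rng(seed)
    out = {}
    for name, med in (("short", 45.0), ("long", 250.0)):
        days = rng.exponential(med / np.log(2), size=n)
        ids = [f"{name}{i}" for i in range(n)]
        index = pd.Series(pd.Timestamp("2010-01-01"), index=ids)
        deaths = index + pd.to_timedelta(np.ceil(days), unit="D")
        median, cls, _ = tj.median_survival(ids, index, pd.Series(deaths), deaths.max())
        out[name] = {"median": float(median), "class": cls}
    return out
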