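"""Model/Results front end for the whole trajectory analysis.

:class:`SymptomTrajectoryModel` is built from a registry (and, for the
clinical-notes source, a note corpus plus symptom dictionary); ``fit()``
runs preprocessing, cohort matching, (optionally) text mining, the ordered
pair screen and trajectory construction, and returns a
:class:`SymptomTrajectoryResults` carrying the pair statistics, the
significant edge set, the survival-classified trajectories, coverage, a
per-symptom enrichment screen and a run manifest with every parameter and
Bonferroni family size.

    >>> model = SymptomTrajectoryModel.from_synthetic(SimConfig(...))
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cohort as ch
from . import pairs as pr
from . import textmining as tm
from . import trajectories as tj
from .lexicons import (
    CANCER_CODE,
    CONTACT_CODE,
    DEFAULT_SUFFIXES,
    DEFAULT_SYMPTOM_TERMS,
    NEGATION_LEXICON,
    OTHER_PERSON_LEXICON,
)

#: minimum follower counts used in the study design, per data source
DEFAULT_MIN_SUPPORT = {"registry": 100, "notes": 20}


class SymptomTrajectoryModel:
    """Temporal symptom-trajectory analysis of a cancer cohort.

    Parameters
    ----------
    registry : :class:`~symtraj.cohort.Registry`
        Patients + diagnosis events + confirmed case ids.
    notes, dictionary
        Clinical-note frame (``note_id, patient_id, date, text``) and
        :class:`~symtraj.textmining.SymptomDictionary`; required when
        ``source="notes"``.
    source : "registry" or "notes"
        Whether pair effects are Eq.-3 relative risks against seasonal
        matched comparison groups (registry) or conditional-logistic odds
        ratios over the 1:10 matched sets (notes).
    lookback_years, control_ratio, n_comparison_groups, alpha,
    survival_split_days
        Study-design constants; defaults are 5-year lookback, 10 controls
        per case, alpha 0.05 and a 90-day survival split.
    min_support
        Minimum trajectory followers; defaults to 100 (registry) / 20
        (notes).
    codes
        Symptom codes to screen; default: every level-3 code carried by at
        least ``min_code_cases`` cases (cancer and contact codes excluded).
    follower_mode
        "pre_only" (all trajectory codes before diagnosis) or "straddle".
    """

    def __init__(
        self,
        registry: ch.Registry,
        notes: pd.DataFrame | None = None,
        dictionary: tm.SymptomDictionary | None = None,
        source: str = "registry",
        lookback_years: float = 5.0,
        control_ratio: int = 10,
        n_comparison_groups: int = 10,
        alpha: float = 0.05,
        min_support: int | None = None,
        trajectory_length: int = 3,
        survival_split_days: float = 90.0,
        codes=None,
        min_code_cases: int = 5,
        follower_mode: str = "pre_only",
        harvest_variants: bool = True,
    ):
        if source not in ("registry", "notes"):
            raise ValueError("source must be 'registry' or 'notes'")
        if source == "notes" and notes is None:
            raise ValueError("notes source needs a note corpus")
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if control_ratio < 1 or n_comparison_groups < 1:
            raise ValueError("ratios must be >= 1")
        self.registry = registry
        self.notes = notes
        self.dictionary = dictionary
        self.source = source
        self.lookback_years = lookback_years
        self.control_ratio = control_ratio
        self.n_comparison_groups = n_comparison_groups
        self.alpha = alpha
        self.min_support = (
            DEFAULT_MIN_SUPPORT[source] if min_support is None else min_support
        )
        self.trajectory_length = trajectory_length
        self.survival_split_days = survival_split_days
        self.codes = codes
        self.min_code_cases = min_code_cases
        self.follower_mode = follower_mode
        self.harvest_variants = harvest_variants

    @classmethod
    def from_synthetic(cls, config, source: str = "registry", **kwargs):
        """Simulate a cohort with :mod:`symtraj.synthetic` and wrap it."""
        from .synthetic import generate_notes, generate_registry

        registry, truth = generate_registry(config)
        notes = dictionary = None
        if source == "notes":
            dictionary = tm.expand_suffixes(DEFAULT_SYMPTOM_TERMS, DEFAULT_SUFFIXES)
            notes, truth = generate_notes(registry, dictionary, config, truth)
        model = cls(
            registry,
            notes=notes,
            dictionary=dictionary,
            source=source,
            lookback_years=config.lookback_years,
            **kwargs,
        )
        model.truth = truth
        return model

    @classmethod
    def from_files(
        cls,
        registry_tsv,
        confirmed_ids,
        notes_jsonl=None,
        dictionary_tsv=None,
        **kwargs,
    ):
        from .io import read_notes_jsonl, read_registry_tsv

        registry = read_registry_tsv(registry_tsv, confirmed_ids)
        notes = read_notes_jsonl(notes_jsonl) if notes_jsonl else None
        dictionary = (
            tm.SymptomDictionary.from_tsv(dictionary_tsv) if dictionary_tsv else None
        )
        return cls(registry, notes=notes, dictionary=dictionary, **kwargs)

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0) -> "SymptomTrajectoryResults":
        """Run the full pipeline; deterministic under ``seed``."""
        rng = np.random.default_rng(seed)
        seed_controls = int(rng.integers(2**31))
        seed_pairs = int(rng.integers(2**31))
        manifest: dict = {
            "seed": seed,
            "source": self.source,
            "lookback_years": self.lookback_years,
            "control_ratio": self.control_ratio,
            "n_comparison_groups": self.n_comparison_groups,
            "alpha": self.alpha,
            "min_support": self.min_support,
            "trajectory_length": self.trajectory_length,
            "survival_split_days": self.survival_split_days,
            "follower_mode": self.follower_mode,
        }

        # --- preprocessing ------------------------------------------------
        patients = self.registry.patients
        manifest["n_patients_raw"] = len(patients)
        patients = ch.filter_active(patients)
        manifest["n_patients_active"] = len(patients)
        events = self.registry.events
        events = events[events["patient_id"].isin(set(patients["patient_id"]))]
        manifest["n_events_raw"] = len(events)
        events = ch.filter_diagnosis_types(events)
        manifest["n_events_typed"] = len(events)

        # --- cases and matched controls ----------------------------------
        cases = ch.select_cases(patients, events, self.registry.confirmed_case_ids)
        manifest["n_cases"] = len(cases)
        if cases.empty:
            raise ValueError("no confirmed cases in the registry")
        attrs = patients.set_index("patient_id")
        cases = cases.merge(
            attrs[["sex", "birth_date", "death_date"]],
            left_on="patient_id",
            right_index=True,
        )
        matched = ch.sample_controls(
            cases, patients, events, ratio=self.control_ratio, seed=seed_controls
        )
        manifest["n_matched_controls"] = matched["control_id"].nunique()

        case_events = ch.windowed_case_events(
            cases[["patient_id", "index_date"]], events, self.lookback_years
        )
        manifest["n_case_events_window"] = len(case_events)

        controls = matched.drop_duplicates("control_id")[
            ["control_id", "control_index_date"]
        ].rename(columns={"control_id": "patient_id", "control_index_date": "index_date"})
        control_events = ch.windowed_case_events(controls, events, self.lookback_years)

        index_dates = cases.set_index("patient_id")["index_date"]
        death_dates = cases.set_index("patient_id")["death_date"]
        end_of_data = self.registry.end_of_data or events["admission_date"].max()

        # --- per-source first occurrences and pair screen -----------------
        if self.source == "registry":
            first = ch.first_occurrences(case_events)
            control_first = ch.first_occurrences(control_events)
            codes = self._select_codes(first)
            manifest["codes"] = codes
            stats, fam = pr.registry_pair_statistics(
                cases,
                case_events,
                patients[patients["patient_id"].isin(set(controls["patient_id"]))],
                control_events,
                codes,
                n_groups=self.n_comparison_groups,
                seed=seed_pairs,
                alpha=self.alpha,
            )
            tagging_eval = None
            dictionary = None
        else:
            dictionary, mentions, tagging_eval = self._mine_notes(
                cases, controls, manifest
            )
            first = self._first_mentions(mentions, index_dates)
            control_index = controls.set_index("patient_id")["index_date"]
            control_first = self._first_mentions(mentions, control_index)
            codes = self._select_codes(first)
            manifest["codes"] = codes
            stats, fam = pr.matched_pair_statistics(
                first, control_first, matched, codes, alpha=self.alpha
            )
        manifest.update(fam)

        # --- trajectories --------------------------------------------------
        edges = tj.significant_pairs(stats, alpha=self.alpha)
        paths = tj.chain_trajectories(edges, self.trajectory_length)
        trajectories = tj.build_trajectories(
            paths,
            first,
            index_dates,
            death_dates,
            end_of_data,
            min_patients=self.min_support,
            split_days=self.survival_split_days,
            mode=self.follower_mode,
        )
        coverage, coverage_pct = (
            tj.trajectory_coverage(trajectories, cases["patient_id"])
            if len(cases)
            else (0.0, 0)
        )
        manifest["n_edges"] = len(edges)
        manifest["n_trajectories"] = len(trajectories)
        manifest["coverage_percent"] = coverage_pct

        enrichment = self._enrichment(first, control_first, matched, codes)

        return SymptomTrajectoryResults(
            model=self,
            pair_stats=stats,
            edges=edges,
            trajectories=trajectories,
            coverage=coverage,
            enrichment=enrichment,
            first_occurrences=first,
            control_first_occurrences=control_first,
            index_dates=index_dates,
            death_dates=death_dates,
            end_of_data=end_of_data,
            matched=matched,
            case_events=case_events,
            manifest=manifest,
            tagging_eval=tagging_eval,
            fitted_dictionary=dictionary,
        )

    # ------------------------------------------------------------------
    def _select_codes(self, first: pd.Series) -> list[str]:
        if self.codes is not None:
            return sorted(self.codes)
        counts = first.reset_index().groupby("event_code")["patient_id"].nunique()
        keep = counts[counts >= self.min_code_cases].index
        return sorted(c for c in keep if c not in (CANCER_CODE, CONTACT_CODE))

    def _mine_notes(self, cases, controls, manifest):
        """Fig-4 style pipeline: expand, harvest variants, tag, filter."""
        dictionary = self.dictionary or tm.expand_suffixes(
            DEFAULT_SYMPTOM_TERMS, DEFAULT_SUFFIXES
        )
        notes = self.notes
        cohort_ids = set(cases["patient_id"]) | set(controls["patient_id"])
        notes = notes[notes["patient_id"].isin(cohort_ids)]

        if self.harvest_variants:
            corpus_tokens = set()
            for text in notes["text"]:
                corpus_tokens.update(t.text for t in tm.tokenize(text))
            variants = tm.harvest_spelling_variants(dictionary.tokens(), corpus_tokens)
            dictionary.add_spelling_variants(variants)
            manifest["n_spelling_variants"] = len(variants)

        mentions = []
        for rec in notes.itertuples():
            ms = tm.tag_note(rec.text, dictionary, note_id=rec.note_id)
            tm.flag_negations(ms, rec.text, NEGATION_LEXICON)
            tm.flag_other_person(ms, rec.text, OTHER_PERSON_LEXICON)
            for m in ms:
                mentions.append(
                    (rec.patient_id, pd.Timestamp(rec.date), m.code,
                     m.negated, m.other_person)
                )
        mention_df = pd.DataFrame(
            mentions, columns=["patient_id", "date", "code", "negated", "other_person"]
        )
        manifest["n_mentions"] = len(mention_df)
        active = mention_df[~mention_df["negated"] & ~mention_df["other_person"]]
        manifest["n_mentions_active"] = len(active)
        return dictionary, active, None

    def _first_mentions(self, mentions: pd.DataFrame, index_dates: pd.Series) -> pd.Series:
        """First active mention per (patient, code) inside that patient's window."""
        df = mentions.merge(
            index_dates.rename("index_date"), left_on="patient_id", right_index=True
        )
        lo = df["index_date"] - pd.Timedelta(days=self.lookback_years * ch.DAYS_PER_YEAR)
        df = df[(df["date"] >= lo) & (df["date"] < df["index_date"])]
        out = df.groupby(["patient_id", "code"])["date"].min()
        out.index = out.index.set_names(["patient_id", "event_code"])
        return out

    def _enrichment(self, first, control_first, matched, codes) -> pd.DataFrame:
        """Per-symptom case-vs-control screen over the matched sets."""
        case_wide = first.unstack()
        ctrl_wide = control_first.unstack()
        case_ids = sorted(set(matched["case_id"]))
        ctrl_rows = matched.sort_values(["case_id", "control_id"], ignore_index=True)
        rows = []
        for code in codes:
            case_has = (
                case_wide[code].reindex(case_ids).notna().to_numpy()
                if code in case_wide.columns
                else np.zeros(len(case_ids), dtype=bool)
            )
            ctrl_has = (
                ctrl_wide[code].reindex(ctrl_rows["control_id"]).notna().to_numpy()
                if code in ctrl_wide.columns
                else np.zeros(len(ctrl_rows), dtype=bool)
            )
            try:
                or_, p = pr.symptom_enrichment(
                    case_has,
                    ctrl_has,
                    case_strata=np.asarray(case_ids, dtype=object),
                    control_strata=ctrl_rows["case_id"].to_numpy(object),
                )
            except pr.IncalculablePairError:
                or_, p = np.nan, np.nan
            rows.append(
                {"code": code, "n_cases": int(case_has.sum()),
                 "n_controls": int(ctrl_has.sum()), "odds_ratio": or_, "p": p}
            )
        out = pd.DataFrame(rows)
        if len(out):
            finite = out["p"].notna()
            out["p_corrected"] = np.nan
            out.loc[finite, "p_corrected"] = pr.bonferroni(
                out.loc[finite, "p"], int(finite.sum())
            )
        return out


class SymptomTrajectoryResults:
    """Fitted trajectory analysis: estimates, diagnostics, export, plots."""

    def __init__(
        self,
        model,
        pair_stats,
        edges,
        trajectories,
        coverage,
        enrichment,
        first_occurrences,
        control_first_occurrences,
        index_dates,
        death_dates,
        end_of_data,
        matched,
        case_events,
        manifest,
        tagging_eval=None,
        fitted_dictionary=None,
    ):
        self.model = model
        self.pair_stats = pair_stats
        self.edges = edges
        self.trajectories = trajectories
        self.coverage = coverage
        self.enrichment = enrichment
        self.first_occurrences = first_occurrences
        self.control_first_occurrences = control_first_occurrences
        self.index_dates = index_dates
        self.death_dates = death_dates
        self.end_of_data = end_of_data
        self.matched = matched
        self.case_events = case_events
        self.manifest = manifest
        self.tagging_eval = tagging_eval
        self.fitted_dictionary = fitted_dictionary

    @property
    def pair_table(self) -> pd.DataFrame:
        return pr.pair_stats_frame(self.pair_stats)

    @property
    def trajectory_table(self) -> pd.DataFrame:
        return tj.trajectories_frame(self.trajectories)

    def temporal_distribution(self, code: str):
        """Days-before-diagnosis distribution of one symptom per survival group."""
        return tj.temporal_distribution(
            code,
            self.case_events,
            self.index_dates,
            self.death_dates,
            split_days=self.model.survival_split_days,
            lookback_years=self.model.lookback_years,
        )

    def summary(self) -> str:
        m = self.manifest
        lines = [
            "Symptom trajectory analysis",
            "=" * 60,
            f"source: {m['source']}   seed: {m['seed']}",
            f"cases: {m['n_cases']}   matched controls: {m['n_matched_controls']}"
            f" (ratio {m['control_ratio']})",
            f"lookback: {m['lookback_years']} y   alpha: {m['alpha']}"
            f"   survival split: {m['survival_split_days']} d",
            f"codes screened: {len(m['codes'])}   effect family m={m['m_effect']}"
            f"   direction family m={m['m_direction']}",
            f"significant directed edges: {m['n_edges']}",
            f"trajectories (len {m['trajectory_length']}, >= {m['min_support']}"
            f" followers): {m['n_trajectories']}",
            f"case coverage by trajectories: {100 * self.coverage:.1f}%",
            "",
        ]
        sig = [
            s
            for s in self.pair_stats
            if np.isfinite(s.effect_p_corrected) and s.effect_p_corrected < m["alpha"]
        ]
        sig.sort(key=lambda s: (s.effect_p_corrected, s.d1, s.d2))
        if sig:
            lines.append("top significant pairs (corrected):")
            for s in sig[:10]:
                lines.append(
                    f"  {s.d1}→{s.d2}  effect={s.effect:5.2f}"
                    f"  p_corr={s.effect_p_corrected:.3g}"
                    f"  fwd/bwd/same={s.direction.n_forward}/"
                    f"{s.direction.n_backward}/{s.direction.n_same}"
                )
            lines.append("")
        if self.trajectories:
            lines.append("trajectories:")
            for t in sorted(
                self.trajectories, key=lambda t: -t.n_followers
            )[:15]:
                med = (
                    "not reached"
                    if not np.isfinite(t.median_survival_days)
                    else f"{t.median_survival_days:.0f} d"
                )
                lines.append(
                    f"  {t.label()}  n={t.n_followers}  median survival {med}"
                    f"  [{t.survival_class}]"
                )
        else:
            lines.append("trajectories: none at the current thresholds")
        return "\n".join(lines)

    def to_tsv(self, out_dir) -> None:
        """Write the pair, trajectory and enrichment tables plus the graph."""
        import json
        from pathlib import Path

        import networkx as nx

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.pair_table.to_csv(out / "pair_stats.tsv", sep="\t", index=False)
        self.trajectory_table.to_csv(out / "trajectories.tsv", sep="\t", index=False)
        self.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        graph = tj.to_graph(self.trajectories)
        with open(out / "trajectory_graph.json", "w") as fh:
            json.dump(nx.node_link_data(graph, edges="links"), fh, indent=1)
        with open(out / "manifest.json", "w") as fh:
            json.dump(_jsonable(self.manifest), fh, indent=1)

    def plot_trajectories(self, ax=None):
        """Edge-width trajectory graph (matplotlib); returns the axis."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        import networkx as nx

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 5))
        g = tj.to_graph(self.trajectories)
        if g.number_of_nodes() == 0:
            ax.set_axis_off()
            ax.set_title("no trajectories at current thresholds")
            return ax
        pos = nx.spring_layout(g, seed=0)
        weights = [1 + np.log1p(g[a][b]["weight"]) for a, b in g.edges]
        nx.draw_networkx(g, pos=pos, ax=ax, width=weights, node_color="#c6dbef")
        ax.set_axis_off()
        return ax


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.Timestamp):
        return obj.strftime("%Y-%m-%d")
    return obj
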