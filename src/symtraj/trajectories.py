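"""Directed symptom trajectories and survival stratification.

Significant forward-dominant pairs (effect > 1, corrected effect and
direction p-values below alpha, more forward than backward orderings)
become directed edges.  Trajectories are all simple paths of 3 or 4 codes
in which every *consecutive* pair is an edge — chain significance is
pairwise, the non-consecutive pairs are not required to be edges.

A patient *follows* a path when the first occurrences of its codes appear
in strictly increasing date order (same-day occurrences break the chain,
consistent with same-day pairs never counting as forward successes); in
the default pre-diagnosis mode all of them must also precede the cancer
index date.  Trajectory groups are classified by Kaplan-Meier median
survival from the index date, censored at end of data, with 90 days
separating the short- from the long-survival class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pairs import PairStat


@dataclass
class Trajectory:
    """An ordered code chain with its follower group and survival class."""

    codes: tuple[str, ...]
    n_followers: int
    follower_ids: tuple
    median_survival_days: float
    survival_class: str
    naive_median_days: float = np.nan

    def label(self) -> str:
        return "→".join(self.codes)


def significant_pairs(
    stats: list[PairStat], effect_threshold: float = 1.0, alpha: float = 0.05
) -> set[tuple[str, str]]:
    """Directed edges: effect above threshold, both corrected p-values < alpha,
    and strictly more forward than backward orderings."""
    edges = set()
    for s in stats:
        if (
            np.isfinite(s.effect)
            and s.effect > effect_threshold
            and np.isfinite(s.effect_p_corrected)
            and s.effect_p_corrected < alpha
            and np.isfinite(s.direction_p_corrected)
            and s.direction_p_corrected < alpha
            and s.direction.n_forward > s.direction.n_backward
        ):
            edges.add((s.d1, s.d2))
    return edges


def chain_trajectories(
    edges: set[tuple[str, str]], length: int = 3
) -> list[tuple[str, ...]]:
    """All simple paths of ``length`` nodes whose consecutive pairs are edges.

    Codes never repeat within a path, so 2-cycles cannot produce paths.
    Output is sorted for determinism.
    """
    if length not in (3, 4):
        raise ValueError("trajectory length must be 3 or 4")
    adj: dict[str, list[str]] = {}
    for a, b in sorted(edges):
        adj.setdefault(a, []).append(b)
    paths = []
    for a, b in sorted(edges):
        for c in adj.get(b, ()):
            if c in (a, b):
                continue
            if length == 3:
                paths.append((a, b, c))
            else:
                for d in adj.get(c, ()):
                    if d not in (a, b, c):
                        paths.append((a, b, c, d))
    return sorted(set(paths))


def count_followers(
    path,
    first_dates: pd.Series,
    index_dates: pd.Series | None = None,
    mode: str = "pre_only",
) -> tuple[int, list]:
    """Patients whose first occurrences of the path's codes strictly increase.

    Parameters
    ----------
    first_dates : MultiIndex (patient_id, code) Series of first-occurrence
        dates.
    index_dates : per-patient cancer index date, required for
        ``mode="pre_only"`` where every code must precede it.
    mode : ``"pre_only"`` (all codes before the index date) or
        ``"straddle"`` (order only; codes may fall after diagnosis).
    """
    if mode not in ("pre_only", "straddle"):
        raise ValueError("mode must be 'pre_only' or 'straddle'")
    wide = first_dates.unstack()
    for code in path:
        if code not in wide.columns:
            return 0, []
    cols = [wide[c] for c in path]
    ok = cols[0].notna()
    for prev, nxt in zip(cols, cols[1:]):
        ok &= nxt.notna() & (prev < nxt)
    if mode == "pre_only":
        if index_dates is None:
            raise ValueError("pre_only mode needs index dates")
        ix = index_dates.reindex(wide.index)
        ok &= cols[-1] < ix
    ids = sorted(wide.index[ok.fillna(False)])
    return len(ids), ids


def filter_support(trajectories: list[Trajectory], min_patients: int) -> list[Trajectory]:
    """Keep trajectories followed by at least ``min_patients`` patients."""
    if min_patients < 1:
        raise ValueError("min_patients must be >= 1")
    return [t for t in trajectories if t.n_followers >= min_patients]


def median_survival(
    follower_ids,
    index_dates: pd.Series,
    death_dates: pd.Series,
    end_of_data,
    split_days: float = 90.0,
) -> tuple[float, str, float]:
    """Kaplan-Meier median survival of a follower group, with its class.

    Survival is death minus index in days; patients alive at end of data
    are censored there.  Returns ``(median_days, class, naive_median)``
    where class is "short" iff the KM median is <= ``split_days``; a median
    the KM curve never reaches is reported as inf and classed "long".  The
    naive median over observed deaths only is emitted alongside for
    comparison.
    """
    ids = list(follower_ids)
    if not ids:
        raise ValueError("median survival needs at least one follower")
    end = pd.Timestamp(end_of_data)
    ix = index_dates.reindex(ids)
    dd = death_dates.reindex(ids)
    observed = dd.notna() & (dd <= end)
    stop = dd.where(observed, end)
    durations = (stop - ix).dt.days.astype(float).clip(lower=0.0)

    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed.astype(int))
    median = float(kmf.median_survival_time_)
    naive = float(np.median(durations[observed])) if observed.any() else np.nan
    cls = "short" if np.isfinite(median) and median <= split_days else "long"
    return median, cls, naive


def build_trajectories(
    paths,
    first_dates: pd.Series,
    index_dates: pd.Series,
    death_dates: pd.Series,
    end_of_data,
    min_patients: int,
    split_days: float = 90.0,
    mode: str = "pre_only",
) -> list[Trajectory]:
    """Count followers, apply the support threshold and attach survival."""
    out = []
    for path in paths:
        n, ids = count_followers(path, first_dates, index_dates, mode=mode)
        if n < min_patients:
            continue
        med, cls, naive = median_survival(
            ids, index_dates, death_dates, end_of_data, split_days
        )
        out.append(
            Trajectory(
                codes=tuple(path),
                n_followers=n,
                follower_ids=tuple(ids),
                median_survival_days=med,
                survival_class=cls,
                naive_median_days=naive,
            )
        )
    return out


def trajectory_coverage(trajectories: list[Trajectory], case_ids) -> tuple[float, int]:
    """Fraction (and rounded percent) of cases following >= 1 trajectory."""
    cases = set(case_ids)
    if not cases:
        raise ValueError("no cases")
    union: set = set()
    for t in trajectories:
        union.update(t.follower_ids)
    frac = len(union & cases) / len(cases)
    return frac, int(round(100 * frac))


def temporal_distribution(
    code: str,
    events: pd.DataFrame,
    index_dates: pd.Series,
    death_dates: pd.Series,
    split_days: float = 90.0,
    lookback_years: float = 5.0,
) -> dict:
    """Days-before-diagnosis distribution of a symptom, per survival group.

    ``events`` must already be lookback-windowed and per-encounter
    deduplicated; every remaining occurrence contributes one value.
    Patients are grouped by survival (death minus index <= / > split; alive
    counts as long).  Returns the per-group value arrays plus a quartile
    summary frame.
    """
    ev = events[events["event_code"] == code]
    ev = ev.merge(index_dates.rename("index_date"), left_on="patient_id", right_index=True)
    days_before = (ev["index_date"] - ev["admission_date"]).dt.days
    keep = (days_before > 0) & (days_before <= lookback_years * 365.25)
    ev = ev[keep].assign(days_before=days_before[keep])

    surv = (death_dates.reindex(index_dates.index) - index_dates).dt.days
    short_ids = set(surv.index[surv.notna() & (surv <= split_days)])
    grp = ev["patient_id"].map(lambda p: "short" if p in short_ids else "long")
    out = {
        "short": ev.loc[grp == "short", "days_before"].to_numpy(float),
        "long": ev.loc[grp == "long", "days_before"].to_numpy(float),
    }
    rows = []
    for name in ("short", "long"):
        v = out[name]
        if v.size:
            q1, q2, q3 = np.percentile(v, [25, 50, 75])
        else:
            q1 = q2 = q3 = np.nan
        rows.append({"group": name, "n": v.size, "q1": q1, "median": q2, "q3": q3})
    out["summary"] = pd.DataFrame(rows)
    return out


@dataclass
class SourceComparison:
    both: set
    registry_only: set
    notes_only: set
    table: pd.DataFrame


def compare_sources(registry_counts: dict, notes_counts: dict) -> SourceComparison:
    """Partition symptom codes by data source, with per-source patient counts."""
    r, n = set(registry_counts), set(notes_counts)
    codes = sorted(r | n)
    table = pd.DataFrame(
        {
            "code": codes,
            "registry_patients": [registry_counts.get(c, 0) for c in codes],
            "notes_patients": [notes_counts.get(c, 0) for c in codes],
        }
    )
    return SourceComparison(
        both=r & n, registry_only=r - n, notes_only=n - r, table=table
    )


def trajectories_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    rows = [
        {
            "trajectory": t.label(),
            "n_followers": t.n_followers,
            "median_survival_days": t.median_survival_days,
            "survival_class": t.survival_class,
            "naive_median_days": t.naive_median_days,
        }
        for t in trajectories
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "trajectory",
            "n_followers",
            "median_survival_days",
            "survival_class",
            "naive_median_days",
        ],
    )


def to_graph(trajectories: list[Trajectory]):
    """Trajectory chains as a networkx DiGraph (for node-link JSON / DOT)."""
    import networkx as nx

    g = nx.DiGraph()
    for t in trajectories:
        for a, b in zip(t.codes, t.codes[1:]):
            if g.has_edge(a, b):
                g[a][b]["weight"] += t.n_followers
            else:
                g.add_edge(a, b, weight=t.n_followers)
        for c in t.codes:
            node = g.nodes[c]
            node["n_trajectories"] = node.get("n_trajectories", 0) + 1
    return g
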