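"""Ordered disease-pair statistics.

For a directed pair (D1, D2) on the registry side:

* the *exposed group* is every case patient with at least one D1 event,
  anchored at the first D1 discharge;
* ``N`` *comparison groups* of identical size are sampled from the matched
  control pool; member ``i`` of each group shares sex and age band with
  exposed member ``i`` and has some hospital discharge in the same ISO
  week-of-year as that member's D1 discharge (the seasonal alignment);
* the relative risk is ``RR = C_exposed / mean_i(C_i)`` where ``C`` counts
  patients carrying D2;
* significance of the co-occurrence is a one-sided exact binomial tail
  with null probability ``mean_i(C_i) / n_exposed`` (one-sided, because
  trajectories only ever use RR > 1 pairs);
* directionality is a two-sided exact binomial test at p = 0.5 over
  patients with both codes — same-day patients enter the trial count but
  are not forward successes.

On the clinical-notes side the effect measure is an odds ratio from a
logistic regression of case/control status on ordered-pair exposure,
conditioned on the 1:10 matching strata (cross-checked against the
Mantel-Haenszel pooled OR).  Both test families are Bonferroni-corrected
separately, with family sizes recorded for auditability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import DAYS_PER_YEAR, StratumExhaustedError, MatchKey

logger = logging.getLogger(__name__)


class IncalculablePairError(ValueError):
    """The statistic cannot be computed for this pair (degenerate counts)."""


@dataclass
class PairCounts:
    """Counts feeding the relative-risk estimator for one ordered pair."""

    d1: str
    d2: str
    n_exposed: int
    c_exposed: int
    comparison_counts: list[int]

    def __post_init__(self):
        if not 0 <= self.c_exposed <= self.n_exposed:
            raise ValueError("need 0 <= c_exposed <= n_exposed")
        if len(self.comparison_counts) < 1:
            raise ValueError("need at least one comparison group")
        if any(c < 0 or c > self.n_exposed for c in self.comparison_counts):
            raise ValueError("comparison counts must lie in [0, n_exposed]")

    @property
    def n_comparison_groups(self) -> int:
        return len(self.comparison_counts)

    @property
    def mean_comparison(self) -> float:
        return float(np.mean(self.comparison_counts))


@dataclass
class DirectionCounts:
    """Ordering counts among patients carrying both codes of a pair."""

    n_forward: int
    n_backward: int
    n_same: int

    @property
    def total(self) -> int:
        return self.n_forward + self.n_backward + self.n_same


@dataclass
class PairStat:
    """Full statistics for one ordered code pair."""

    d1: str
    d2: str
    source: str
    n_exposed: int
    c_exposed: int
    mean_comparison: float
    effect: float
    effect_p: float
    direction: DirectionCounts
    direction_p: float = np.nan
    effect_p_corrected: float = np.nan
    direction_p_corrected: float = np.nan
    note: str = ""


def relative_risk(counts: PairCounts) -> float:
    """Eq.-3 relative risk: exposed count over mean comparison count."""
    mean_c = counts.mean_comparison
    if mean_c == 0:
        raise IncalculablePairError(
            f"({counts.d1}, {counts.d2}): all comparison counts are zero"
        )
    return counts.c_exposed / mean_c


def rr_binomial_test(counts: PairCounts) -> float:
    """One-sided exact binomial tail P(X >= c_exposed | n_exposed, p0).

    ``p0`` is the average probability of sampling a comparison patient with
    D2, ``mean(C_i) / n_exposed``.  A null probability of zero with a
    positive exposed count returns 0.0 by convention (logged).
    """
    if counts.n_exposed < 1:
        raise IncalculablePairError("empty exposed group")
    p0 = counts.mean_comparison / counts.n_exposed
    if p0 == 0:
        if counts.c_exposed > 0:
            logger.warning(
                "(%s, %s): null probability 0 with c_exposed=%d; p-value 0 by convention",
                counts.d1, counts.d2, counts.c_exposed,
            )
            return 0.0
        return 1.0
    return float(sps.binom.sf(counts.c_exposed - 1, counts.n_exposed, min(p0, 1.0)))


def directionality_test(direction: DirectionCounts) -> float:
    """Two-sided exact binomial test of forward orderings at p = 0.5.

    Same-day patients count as trials but never as forward successes.  The
    two-sided p-value is ``min(1, 2 * min(P(X <= k), P(X >= k)))`` with
    ``k = n_forward`` over ``total`` trials; at p = 0.5 this equals the
    minimum-likelihood exact test.
    """
    n = direction.total
    if n < 1:
        raise IncalculablePairError("no patients with both codes")
    k = direction.n_forward
    lower = sps.binom.cdf(k, n, 0.5)
    upper = sps.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Multiply each p-value by the family size ``m`` (default: list length), cap at 1."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m must cover all tests performed")
    return np.minimum(1.0, p * m)


# ---------------------------------------------------------------------------
# Odds ratios for matched case-control exposure


def _two_by_two(case_exposed, control_exposed) -> tuple[int, int, int, int]:
    ce = np.asarray(case_exposed, dtype=bool)
    ke = np.asarray(control_exposed, dtype=bool)
    return int(ce.sum()), int((~ce).sum()), int(ke.sum()), int((~ke).sum())


def odds_ratio_pair(
    case_exposure,
    control_exposure,
    case_strata=None,
    control_strata=None,
) -> tuple[float, float]:
    """Stratified odds ratio of case status on a per-patient exposure flag.

    With a single stratum (or no strata given) this is exactly the 2x2
    cross-product OR with a Wald p-value.  With multiple strata — here the
    1:10 matched sets — the exposure coefficient comes from a conditional
    (fixed-effects-by-stratum) logistic regression; strata that are missing
    cases or controls, or in which exposure does not vary, are dropped with
    a warning since they carry no information about the OR.

    Raises :class:`IncalculablePairError` when no informative stratum
    remains or a single-stratum table has an empty cell.
    """
    ce = np.asarray(case_exposure, dtype=bool)
    ke = np.asarray(control_exposure, dtype=bool)
    if case_strata is None and control_strata is None:
        case_strata = np.zeros(ce.size, dtype=int)
        control_strata = np.zeros(ke.size, dtype=int)
    cs = np.asarray(case_strata)
    ks = np.asarray(control_strata)

    strata = sorted(set(cs.tolist()) | set(ks.tolist()))
    if len(strata) == 1:
        a, b, c, d = _two_by_two(ce, ke)
        if min(a, b, c, d) == 0:
            raise IncalculablePairError("empty cell in single-stratum 2x2 table")
        or_ = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = np.log(or_) / se
        return float(or_), float(2 * sps.norm.sf(abs(z)))

    y_parts, x_parts, g_parts = [], [], []
    n_dropped = 0
    for s in strata:
        ce_s = ce[cs == s]
        ke_s = ke[ks == s]
        x_s = np.concatenate([ce_s, ke_s]).astype(float)
        if ce_s.size == 0 or ke_s.size == 0 or x_s.min() == x_s.max():
            n_dropped += 1
            continue
        y_parts.append(np.concatenate([np.ones(ce_s.size), np.zeros(ke_s.size)]))
        x_parts.append(x_s)
        g_parts.append(np.full(x_s.size, s))
    if n_dropped:
        logger.debug("dropped %d uninformative strata", n_dropped)
    if not y_parts:
        raise IncalculablePairError("no informative strata for odds ratio")

    y = np.concatenate(y_parts)
    x = np.concatenate(x_parts)[:, None]
    groups = np.concatenate(g_parts)
    from statsmodels.discrete.conditional_models import ConditionalLogit

    try:
        res = ConditionalLogit(y, x, groups=groups).fit(disp=False)
        beta = float(res.params[0])
        pval = float(res.pvalues[0])
        if not np.isfinite(beta):
            raise ValueError("non-finite estimate")
    except Exception as exc:  # separation or non-convergence
        logger.warning("conditional logit failed (%s); falling back to Mantel-Haenszel", exc)
        return mantel_haenszel_or(ce, ke, cs, ks)
    return float(np.exp(beta)), pval


def mantel_haenszel_or(
    case_exposure, control_exposure, case_strata=None, control_strata=None
) -> tuple[float, float]:
    """Mantel-Haenszel pooled OR over strata, with its chi-square null test.

    Serves as the internal cross-check for :func:`odds_ratio_pair`.
    """
    from statsmodels.stats.contingency_tables import StratifiedTable

    ce = np.asarray(case_exposure, dtype=bool)
    ke = np.asarray(control_exposure, dtype=bool)
    if case_strata is None:
        case_strata = np.zeros(ce.size, dtype=int)
        control_strata = np.zeros(ke.size, dtype=int)
    cs = np.asarray(case_strata)
    ks = np.asarray(control_strata)
    tables = []
    for s in sorted(set(cs.tolist()) | set(ks.tolist())):
        a, b, c, d = _two_by_two(ce[cs == s], ke[ks == s])
        tables.append(np.array([[a, b], [c, d]]))
    st = StratifiedTable(tables)
    or_ = float(st.oddsratio_pooled)
    if not np.isfinite(or_) or or_ == 0:
        raise IncalculablePairError("Mantel-Haenszel OR degenerate")
    return or_, float(st.test_null_odds().pvalue)


def symptom_enrichment(
    case_has_symptom, control_has_symptom, case_strata=None, control_strata=None
) -> tuple[float, float]:
    """Case-vs-control enrichment of a single symptom (stratified OR)."""
    return odds_ratio_pair(
        case_has_symptom, control_has_symptom, case_strata, control_strata
    )


# ---------------------------------------------------------------------------
# Exposed groups and seasonal matched comparison sampling


def build_exposed_group(case_events: pd.DataFrame, d1: str) -> pd.DataFrame:
    """Case patients with >= 1 D1 event, anchored at the first D1 discharge.

    Returns ``patient_id, anchor`` sorted by patient id; empty when no case
    carries D1 (the pair is then skipped upstream).
    """
    ev = case_events[case_events["event_code"] == d1]
    anchors = ev.groupby("patient_id")["discharge_date"].min()
    return anchors.rename("anchor").reset_index().sort_values(
        "patient_id", ignore_index=True
    )


def _iso_week(dates: pd.Series) -> np.ndarray:
    # week 53 folded into 52: the annual cycle is what matters and week-53
    # strata are too thin to match against
    return np.minimum(dates.dt.isocalendar().week.to_numpy(int), 52)


class ComparisonPool:
    """Index of comparison candidates keyed by (sex, age band, ISO week).

    A patient appears under every (sex, band, week) combination in which it
    has a hospital discharge, with age banded (default 10-year bands) at
    that discharge.
    """

    def __init__(self, patients: pd.DataFrame, events: pd.DataFrame, band_width: int = 10):
        self.band_width = band_width
        ev = events.merge(patients[["patient_id", "sex", "birth_date"]], on="patient_id")
        if ev.empty:
            self._index: dict[tuple, np.ndarray] = {}
            return
        week = _iso_week(ev["discharge_date"])
        age = (ev["discharge_date"] - ev["birth_date"]).dt.days // DAYS_PER_YEAR
        band = (age // band_width).astype(int)
        key = pd.DataFrame(
            {"sex": ev["sex"].values, "band": band.values, "week": week,
             "patient_id": ev["patient_id"].values}
        )
        self._index = {
            k: np.sort(g["patient_id"].unique())
            for k, g in key.groupby(["sex", "band", "week"])
        }

    def band_of(self, birth_date, on) -> int:
        days = (pd.Timestamp(on) - pd.Timestamp(birth_date)).days
        return int((days // DAYS_PER_YEAR) // self.band_width)

    def candidates(self, sex: str, band: int, week: int) -> np.ndarray:
        return self._index.get((sex, band, min(int(week), 52)), np.array([], dtype=object))


def sample_comparison_groups(
    exposed: pd.DataFrame,
    pool: ComparisonPool,
    n_groups: int,
    seed: int = 0,
) -> list[np.ndarray]:
    """``n_groups`` matched comparison groups, one member per exposed member.

    ``exposed`` needs columns ``patient_id, anchor, sex, birth_date``.
    Member *i* of every group matches exposed member *i* on sex and age
    band and has a discharge in the same ISO week-of-year as that member's
    anchor.  Sampling is without replacement within a group (reuse across
    groups allowed) and deterministic under ``seed``.

    Raises :class:`~symtraj.cohort.StratumExhaustedError` naming the
    member's stratum when no candidate remains.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    rng = np.random.default_rng(seed)
    members = exposed.sort_values("patient_id", ignore_index=True)
    keys = []
    for rec in members.itertuples():
        band = pool.band_of(rec.birth_date, rec.anchor)
        week = int(min(pd.Timestamp(rec.anchor).isocalendar().week, 52))
        keys.append((rec.sex, band, week, rec.patient_id))

    groups: list[np.ndarray] = []
    for _ in range(n_groups):
        used: set = set()
        chosen = []
        for sex, band, week, pid in keys:
            cand = pool.candidates(sex, band, week)
            avail = [c for c in cand if c not in used and c != pid]
            if not avail:
                raise StratumExhaustedError(
                    MatchKey(sex, -1, band * pool.band_width, week), 1, 0
                )
            pick = avail[rng.integers(len(avail))]
            used.add(pick)
            chosen.append(pick)
        groups.append(np.array(chosen, dtype=object))
    return groups


# ---------------------------------------------------------------------------
# Pair screens


def registry_pair_statistics(
    cases: pd.DataFrame,
    case_events: pd.DataFrame,
    pool_patients: pd.DataFrame,
    pool_events: pd.DataFrame,
    codes,
    n_groups: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[list[PairStat], dict]:
    """Eq.-3 RR screen over all ordered code pairs in the registry.

    ``cases`` carries ``patient_id, index_date, sex, birth_date``;
    ``case_events`` / ``pool_events`` are lookback-windowed, deduplicated
    event frames.  Directionality is tested for pairs with RR > 1 whose
    Bonferroni-corrected co-occurrence p-value is below ``alpha``; the two
    Bonferroni families (effect, direction) are corrected separately and
    their sizes returned in the meta dict.
    """
    codes = sorted(codes)
    rng = np.random.default_rng(seed)
    pool = ComparisonPool(pool_patients, pool_events)
    case_attrs = cases.set_index("patient_id")

    first = case_events.groupby(["patient_id", "event_code"])["admission_date"].min()
    has: dict[str, set] = {
        c: set(first.xs(c, level="event_code").index) if c in first.index.get_level_values(1)
        else set()
        for c in codes
    }
    pool_has: dict[str, set] = {
        c: set(pool_events.loc[pool_events["event_code"] == c, "patient_id"])
        for c in codes
    }

    stats: list[PairStat] = []
    for d1 in codes:
        exposed = build_exposed_group(case_events, d1)
        if exposed.empty:
            continue
        exposed = exposed.merge(
            case_attrs[["sex", "birth_date"]], left_on="patient_id", right_index=True
        )
        groups = sample_comparison_groups(
            exposed, pool, n_groups, seed=int(rng.integers(2**31))
        )
        n_exposed = len(exposed)
        exposed_ids = exposed["patient_id"].tolist()
        first_d1 = first.xs(d1, level="event_code")
        for d2 in codes:
            if d2 == d1:
                continue
            c_exp = sum(pid in has[d2] for pid in exposed_ids)
            comp = [int(sum(m in pool_has[d2] for m in g)) for g in groups]
            counts = PairCounts(d1, d2, n_exposed, c_exp, comp)
            both = has[d1] & has[d2]
            fwd = bwd = same = 0
            if both:
                f1 = first_d1.loc[sorted(both)]
                f2 = first.xs(d2, level="event_code").loc[sorted(both)]
                fwd = int((f1 < f2).sum())
                bwd = int((f1 > f2).sum())
                same = int((f1 == f2).sum())
            direction = DirectionCounts(fwd, bwd, same)
            try:
                rr = relative_risk(counts)
                p = rr_binomial_test(counts)
                note = ""
            except IncalculablePairError as exc:
                rr, p, note = np.nan, np.nan, str(exc)
            stats.append(
                PairStat(
                    d1=d1, d2=d2, source="registry",
                    n_exposed=n_exposed, c_exposed=c_exp,
                    mean_comparison=counts.mean_comparison,
                    effect=rr, effect_p=p, direction=direction, note=note,
                )
            )

    meta = _correct_families(stats, alpha)
    meta["n_groups"] = n_groups
    return stats, meta


def matched_pair_statistics(
    case_first: pd.Series,
    control_first: pd.Series,
    matched: pd.DataFrame,
    codes,
    alpha: float = 0.05,
    source: str = "notes",
) -> tuple[list[PairStat], dict]:
    """Stratified-OR screen over ordered symptom pairs for matched sets.

    ``case_first`` / ``control_first`` are MultiIndex (patient_id, code)
    Series of first-occurrence dates; ``matched`` maps ``case_id`` to its
    ``control_id`` rows (the 1:10 sets, which become the strata).
    Pair exposure = carrying both codes with D1 strictly first.
    """
    codes = sorted(codes)
    case_wide = case_first.unstack()
    ctrl_wide = control_first.unstack()
    case_ids = sorted(set(matched["case_id"]))
    case_wide = case_wide.reindex(case_ids)
    ctrl_rows = matched.sort_values(["case_id", "control_id"], ignore_index=True)
    ctrl_dates = ctrl_wide.reindex(ctrl_rows["control_id"])

    stats: list[PairStat] = []
    for d1 in codes:
        for d2 in codes:
            if d2 == d1:
                continue
            if d1 not in case_wide.columns or d2 not in case_wide.columns:
                continue
            cx = (case_wide[d1] < case_wide[d2]).to_numpy()
            if d1 in ctrl_dates.columns and d2 in ctrl_dates.columns:
                kx = (ctrl_dates[d1].to_numpy() < ctrl_dates[d2].to_numpy())
            else:
                kx = np.zeros(len(ctrl_rows), dtype=bool)
            f1, f2 = case_wide[d1], case_wide[d2]
            both = f1.notna() & f2.notna()
            direction = DirectionCounts(
                int((f1[both] < f2[both]).sum()),
                int((f1[both] > f2[both]).sum()),
                int((f1[both] == f2[both]).sum()),
            )
            try:
                or_, p = odds_ratio_pair(
                    cx, kx,
                    case_strata=np.asarray(case_ids, dtype=object),
                    control_strata=ctrl_rows["case_id"].to_numpy(object),
                )
                note = ""
            except IncalculablePairError as exc:
                or_, p, note = np.nan, np.nan, str(exc)
            stats.append(
                PairStat(
                    d1=d1, d2=d2, source=source,
                    n_exposed=int(f1.notna().sum()), c_exposed=int(cx.sum()),
                    mean_comparison=float(kx.sum()),
                    effect=or_, effect_p=p, direction=direction, note=note,
                )
            )
    meta = _correct_families(stats, alpha)
    return stats, meta


def _correct_families(stats: list[PairStat], alpha: float) -> dict:
    """Bonferroni-correct effect and direction families separately, in place."""
    tested = [s for s in stats if np.isfinite(s.effect_p)]
    m_effect = len(tested)
    for s in tested:
        s.effect_p_corrected = float(bonferroni([s.effect_p], m_effect)[0])
    eligible = [
        s
        for s in tested
        if s.effect > 1 and s.effect_p_corrected < alpha and s.direction.total >= 1
    ]
    m_direction = len(eligible)
    for s in eligible:
        s.direction_p = directionality_test(s.direction)
        s.direction_p_corrected = float(bonferroni([s.direction_p], m_direction)[0])
    return {"m_effect": m_effect, "m_direction": m_direction, "alpha": alpha}


def pair_stats_frame(stats: list[PairStat]) -> pd.DataFrame:
    """Flatten PairStat records into the canonical output table."""
    rows = [
        {
            "d1": s.d1,
            "d2": s.d2,
            "source": s.source,
            "n_exposed": s.n_exposed,
            "c_exposed": s.c_exposed,
            "mean_comparison": s.mean_comparison,
            "effect": s.effect,
            "effect_p": s.effect_p,
            "effect_p_corrected": s.effect_p_corrected,
            "n_forward": s.direction.n_forward,
            "n_backward": s.direction.n_backward,
            "n_same": s.direction.n_same,
            "direction_p": s.direction_p,
            "direction_p_corrected": s.direction_p_corrected,
            "note": s.note,
        }
        for s in stats
    ]
    return pd.DataFrame(rows)
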