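"""Comparative statistics for crossover counts in nondisjunction cohorts.

Covers the crossover-class fractions (with the meiosis-II detection
adjustment), the zero-crossover chromosome fraction, left/right arm
association, per-interval coefficient of exchange, cross-chromosome
crossover-count comparisons, and the two significance tests used
throughout: a two-proportion z test matching R's ``prop.test`` (Yates
continuity correction on by default, toggleable) and a Mann-Whitney
rank-sum test with exact enumeration at small n.

The detection adjustment exists because unequal information is inherited
per event class: a normal meiosis transmits one chromatid of four and an
MI error one chromatid of each homolog, so only half of single crossovers
are observable in either, whereas an MII error transmits both sisters of
one homolog and every inter-homolog crossover is observable.  Halving the
MII single-crossover fraction puts the classes on a common footing;
double-crossover fractions are deliberately left unadjusted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import ChromosomeMap

EXACT_MAX_N = 12

# chromatids sampled per meiosis: a normal progeny carries 1 of 4, an MI
# progeny 2 of 4 but only inter-homolog exchanges involving exactly one of
# them are visible (net detection 1/2), an MII progeny both sisters of one
# homolog (every inter-homolog exchange visible).
DETECTION_CORRECTION = {"NORMAL": 2.0, "MI": 2.0, "MII": 1.0}


@dataclass
class StatResult:
    statistic: float
    p_value: float
    tails: str
    method: str
    n: tuple

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError("p-value outside [0, 1]")


# -- crossover-class tabulations ------------------------------------------


def co_class_fractions(arm_counts: pd.DataFrame, adjust_mii: bool = True) -> pd.DataFrame:
    """Fractions of arms with 0/1/2 observed crossovers per event class.

    ``arm_counts`` columns: ``event, event_class, arm, n_co`` (counts of
    2 or more are binned as 2).  When ``adjust_mii`` the MII single-CO
    fraction is halved (reported in ``fraction_adjusted`` alongside the
    raw value; double-CO fractions are never adjusted and nothing is
    renormalized).
    """
    rows = []
    for cls, sub in arm_counts.groupby("event_class"):
        n_arms = len(sub)
        if n_arms == 0:
            continue
        capped = sub["n_co"].clip(upper=2)
        for k in (0, 1, 2):
            frac = float((capped == k).mean())
            adj = frac
            if adjust_mii and cls == "MII" and k == 1:
                adj = frac / 2.0
            rows.append(
                {
                    "event_class": cls,
                    "n_co": k,
                    "n_arms": n_arms,
                    "count": int((capped == k).sum()),
                    "fraction": frac,
                    "fraction_adjusted": adj,
                }
            )
    if not rows:
        raise ValueError("empty crossover-count table")
    return pd.DataFrame(rows)


def zero_co_chromosome_fraction(arm_counts: pd.DataFrame) -> float:
    """Fraction of events with zero observed crossovers on *both* arms."""
    per_event = arm_counts.groupby("event")["n_co"].sum()
    if per_event.empty:
        raise ValueError("no events")
    return float((per_event == 0).mean())


def arm_association(arm_counts: pd.DataFrame, left_arm: str, right_arm: str) -> pd.DataFrame:
    """P(right-arm CO >= 1) conditioned on the left arm having 0 vs >= 1
    crossovers, per event class, with group sizes."""
    wide = arm_counts.pivot_table(
        index=["event", "event_class"], columns="arm", values="n_co", aggfunc="sum"
    ).reset_index()
    rows = []
    for cls, sub in wide.groupby("event_class"):
        for cond, name in ((sub[left_arm] == 0, "left_0"), (sub[left_arm] >= 1, "left_1plus")):
            grp = sub[cond]
            rows.append(
                {
                    "event_class": cls,
                    "condition": name,
                    "n": int(len(grp)),
                    "p_right_co": float((grp[right_arm] >= 1).mean()) if len(grp) else np.nan,
                }
            )
    return pd.DataFrame(rows)


# -- two-proportion z test (prop.test-compatible) -------------------------


def two_proportion_z_test(x1: int, n1: int, x2: int, n2: int,
                          tails: str = "two", continuity: bool = True) -> StatResult:
    """Pooled two-proportion z test.

    With ``continuity`` the Yates correction is applied exactly as R's
    ``prop.test`` does (the correction is capped at |p1 - p2|).  ``tails``
    is ``"two"``, ``"greater"`` (p1 > p2) or ``"less"`` (p1 < p2); the
    one-tailed direction must be supplied by the caller.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("group sizes must be positive")
        if not 0 <= x <= n:
            raise ValueError("successes must lie in [0, n]")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    d = p1 - p2
    cc = min(0.5 * (1 / n1 + 1 / n2), abs(d)) if continuity else 0.0
    if se == 0.0:
        z = 0.0
    else:
        z = (abs(d) - cc) / se * (1 if d >= 0 else -1)
    if tails == "two":
        p = 2 * sps.norm.sf(abs(z))
    elif tails == "greater":
        p = sps.norm.sf(z)
    elif tails == "less":
        p = sps.norm.cdf(z)
    else:
        raise ValueError("tails must be two, greater or less")
    method = "two-proportion z" + (" (continuity corrected)" if continuity else "")
    return StatResult(float(z), float(min(p, 1.0)), tails, method, (n1, n2))


# -- Mann-Whitney ----------------------------------------------------------


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: #(a_i > b_j) + 0.5 * #(a_i == b_j)."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney_test(sample_a, sample_b, tails: str = "two") -> StatResult:
    """Mann-Whitney rank-sum test.

    Exact p by full enumeration of all group assignments of the pooled
    values when total n <= 12 (ties handled through the value-based U,
    so identical samples give p = 1 exactly); otherwise the normal
    approximation with tie correction and continuity correction, as in
    R's ``wilcox.test``.  ``tails``: ``"greater"`` means sample_a tends
    larger.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if tails not in ("two", "greater", "less"):
        raise ValueError("tails must be two, greater or less")
    u = _u_statistic(a, b)
    n1, n2 = a.size, b.size
    if n1 + n2 <= EXACT_MAX_N:
        pooled = np.concatenate([a, b])
        us = np.array(
            [
                _u_statistic(pooled[list(idx)],
                             pooled[[i for i in range(n1 + n2) if i not in set(idx)]])
                for idx in itertools.combinations(range(n1 + n2), n1)
            ]
        )
        eps = 1e-9
        p_ge = float((us >= u - eps).mean())
        p_le = float((us <= u + eps).mean())
        if tails == "greater":
            p = p_ge
        elif tails == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return StatResult(u, p, tails, "Mann-Whitney (exact enumeration)", (n1, n2))

    mean = n1 * n2 / 2.0
    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    sd = sqrt(var)
    if tails == "two":
        z = (abs(u - mean) - 0.5) / sd if sd > 0 else 0.0
        p = 2 * sps.norm.sf(max(z, 0.0))
    elif tails == "greater":
        z = (u - mean - 0.5) / sd if sd > 0 else 0.0
        p = sps.norm.sf(z)
    else:
        z = (u - mean + 0.5) / sd if sd > 0 else 0.0
        p = sps.norm.cdf(z)
    return StatResult(u, float(min(p, 1.0)), tails, "Mann-Whitney (normal approximation)", (n1, n2))


# -- coefficient of exchange ----------------------------------------------


def coefficient_of_exchange(
    call_midpoints: dict[str, np.ndarray] | pd.DataFrame,
    cmap: ChromosomeMap,
    n_events: int,
    event_class: str = "MI",
    bin_bp: int = 1_000_000,
    correct_detection: bool = True,
) -> pd.DataFrame:
    """Exchanges per meiosis per ``bin_bp`` interval along each arm.

    Observed crossover midpoints per bin are divided by the number of
    events assayed and multiplied by the chromatid-sampling detection
    correction (x2 for NORMAL and MI, x1 for MII; toggleable).
    """
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    if isinstance(call_midpoints, pd.DataFrame):
        mids = {
            str(arm): sub["midpoint"].to_numpy()
            for arm, sub in call_midpoints.groupby("chrom")
        }
    else:
        mids = {k: np.asarray(v) for k, v in call_midpoints.items()}
    factor = DETECTION_CORRECTION[event_class] if correct_detection else 1.0
    rows = []
    for arm in cmap.arms:
        edges = np.arange(0, arm.length + bin_bp, bin_bp)
        counts, _ = np.histogram(mids.get(arm.name, np.empty(0)), bins=edges)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            rows.append(
                {
                    "arm": arm.name,
                    "bin_start": int(lo),
                    "bin_end": int(min(hi, arm.length)),
                    "n_cos": int(c),
                    "exchange_per_meiosis": c / n_events * factor,
                }
            )
    return pd.DataFrame(rows)


# -- cross-chromosome comparison ------------------------------------------


def cross_chromosome_co_comparison(
    events: pd.DataFrame,
    tails: dict[tuple[int, int], str] | None = None,
    mi_only: bool = True,
) -> dict[str, StatResult | str]:
    """Mann-Whitney comparisons of the mean crossover count on the other
    assayed chromosomes between chromosome-2 crossover-count strata.

    ``events`` columns: ``event_class, chr2_n_co, other_mean_co``.  MII
    events are excluded by default (their observation probability
    differs).  ``tails`` maps (stratum_hi, stratum_lo) to the alternative
    for hi vs lo; defaults to a two-tailed 1-vs-0 comparison and
    one-tailed (greater) 2-vs-1 and 2-vs-0 comparisons.
    """
    if tails is None:
        tails = {(1, 0): "two", (2, 1): "greater", (2, 0): "greater"}
    df = events
    if mi_only:
        df = df[df["event_class"] == "MI"]
    strata = {k: df.loc[df["chr2_n_co"].clip(upper=2) == k, "other_mean_co"].to_numpy()
              for k in (0, 1, 2)}
    out: dict[str, StatResult | str] = {}
    for (hi, lo), tail in tails.items():
        key = f"{hi}_vs_{lo}"
        if strata[hi].size == 0 or strata[lo].size == 0:
            out[key] = "skipped: empty stratum"
            continue
        out[key] = mann_whitney_test(strata[hi], strata[lo], tails=tail)
    return out


def n_exact_partitions(n1: int, n2: int) -> int:
    """Number of group assignments enumerated in the exact test."""
    return comb(n1 + n2, n1)
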