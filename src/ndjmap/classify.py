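"""Division-of-origin calls (MI vs MII), monosomy-rescue flags, and cause
categories for nondisjunction events.

A meiosis-I error delivers one chromatid of *each* homolog to the egg, so
the progeny is heterozygous across the centromere; a meiosis-II error
delivers both sisters of *one* homolog, so the progeny is homozygous for a
single parental genotype there (crossovers are euchromatic, so the sisters
are identical pericentrically).  The division call therefore reads the
genotype state of the innermost segment on each arm within a pericentric
window (the heterochromatin plus a configurable slice of adjacent
euchromatin); discordant arms are surfaced as undetermined, never silently
resolved.

Monosomy rescue (mitotic duplication of a monosomic zygote's single
chromatid) also yields a homozygous track, and is only distinguishable
from MII NDJ when the duplicated chromatid was recombinant: then the track
switches directly between the two homozygous states with no heterozygous
segment anywhere.

Cause categories follow a strict precedence: no observable crossover
(missing chiasma), all crossovers distal (within the distal fraction of
the arm or chromosome), at least one pericentric crossover, and otherwise
a cause unrelated to recombination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import pandas as pd

from .calling import CrossoverCall, GenotypeSegmentation, HOM_STATES
from .genome import ChromosomeMap, TELOCENTRIC

MI = "MI"
MII = "MII"
UNDETERMINED = "undetermined"

NO_CO = "NO_CO"
DISTAL_CO = "DISTAL_CO"
PERICENTRIC_CO = "PERICENTRIC_CO"
OTHER = "OTHER"
CATEGORIES = (NO_CO, DISTAL_CO, PERICENTRIC_CO, OTHER)

RESCUE_NO = "no"
RESCUE_CANDIDATE = "candidate"
RESCUE_AMBIGUOUS = "MII-or-rescue-ambiguous"


@dataclass
class CategorizerConfig:
    distal_fraction: float = 0.24
    pericentric_eu_fraction: float = 0.15
    distal_scope: str = "per-arm"  # or "per-chromosome"
    pericentric_window_bp: int = 1_000_000  # euchromatin added to the het window

    def __post_init__(self) -> None:
        for f in (self.distal_fraction, self.pericentric_eu_fraction):
            if not 0.0 < f < 1.0:
                raise ValueError("fractions must lie in (0, 1)")
        if self.distal_scope not in ("per-arm", "per-chromosome"):
            raise ValueError("distal_scope must be per-arm or per-chromosome")

    def to_dict(self) -> dict:
        return {
            "distal_fraction": self.distal_fraction,
            "pericentric_eu_fraction": self.pericentric_eu_fraction,
            "distal_scope": self.distal_scope,
            "pericentric_window_bp": self.pericentric_window_bp,
        }


@dataclass
class DivisionCall:
    division: str  # MI | MII | undetermined
    pericentric_states: dict  # arm -> state (or None when uncovered)
    monosomy_rescue: str = RESCUE_NO
    reason: str = ""


def _pericentric_state(seg: GenotypeSegmentation, cmap: ChromosomeMap, window_bp: int) -> str | None:
    """State of the innermost (most centromere-proximal) segment whose SNPs
    reach into the pericentric window, or None without coverage there."""
    if not seg.segments:
        return None
    lo, hi = cmap.pericentric_window(seg.chrom, extra_bp=window_bp)
    if cmap.centromeric_end(seg.chrom) == "end":
        innermost = seg.segments[-1]
        return innermost.state if innermost.last_pos >= lo else None
    innermost = seg.segments[0]
    return innermost.state if innermost.first_pos < hi else None


def classify_division(
    segs: dict[str, GenotypeSegmentation],
    cmap: ChromosomeMap,
    config: CategorizerConfig | None = None,
) -> DivisionCall:
    """MI/MII call from pericentric genotype state, with the monosomy
    rescue flag from the chromosome-wide segmentation.

    ``segs`` maps arm name -> that arm's segmentation.  Heterozygosity
    across the centromere means MI; homozygosity for either parental
    genotype means MII.  Arms that disagree, or absent pericentric
    coverage on both arms, yield an undetermined call.
    """
    config = config or CategorizerConfig()
    states = {
        arm.name: _pericentric_state(segs[arm.name], cmap, config.pericentric_window_bp)
        if arm.name in segs
        else None
        for arm in cmap.arms
    }
    observed = {s for s in states.values() if s is not None}
    rescue = flag_monosomy_rescue(segs, cmap)
    if not observed:
        return DivisionCall(UNDETERMINED, states, rescue, reason="no pericentric coverage")
    if len(observed) > 1:
        return DivisionCall(
            UNDETERMINED, states, rescue, reason="discordant pericentric states between arms"
        )
    state = observed.pop()
    division = MI if state in ("HET", "P1") else MII
    return DivisionCall(division, states, rescue)


def flag_monosomy_rescue(segs: dict[str, GenotypeSegmentation], cmap: ChromosomeMap) -> str:
    """Monosomy-rescue status of a chromosome-wide segmentation.

    ``candidate``: no heterozygous segment anywhere and a direct
    HOM_P1<->HOM_P2 switch exists (within an arm or across the gap) —
    the unambiguous signature of a duplicated recombinant chromatid.
    ``MII-or-rescue-ambiguous``: fully homozygous in a single state.
    ``no``: any heterozygous segment.
    """
    ordered_states: list[str] = []
    for arm in cmap.arms:
        seg = segs.get(arm.name)
        if seg is None or not seg.segments:
            continue
        ordered_states.extend(seg.states)
    if not ordered_states:
        return RESCUE_NO
    if any(s not in HOM_STATES for s in ordered_states):
        return RESCUE_NO
    if len(set(ordered_states)) > 1:
        return RESCUE_CANDIDATE
    return RESCUE_AMBIGUOUS


def categorize_cause(
    calls: list[CrossoverCall],
    cmap: ChromosomeMap,
    config: CategorizerConfig | None = None,
) -> str:
    """Most probable NDJ cause with precedence
    NO_CO > DISTAL_CO > PERICENTRIC_CO > OTHER.

    DISTAL_CO requires every observed crossover to lie within the distal
    fraction (no medial or proximal crossovers at all); PERICENTRIC_CO
    requires at least one crossover in the heterochromatin or the adjacent
    euchromatin fraction.  Gap calls count as pericentric.
    """
    config = config or CategorizerConfig()
    if not calls:
        return NO_CO

    scope = "chromosome" if (
        config.distal_scope == "per-chromosome" or cmap.shape == TELOCENTRIC
    ) else "arm"

    def fraction(c: CrossoverCall) -> float:
        if c.chrom == "gap":
            return 1.0  # the gap is maximally proximal
        return cmap.fraction_from_telomere(c.chrom, c.midpoint, scope=scope)

    def pericentric(c: CrossoverCall) -> bool:
        if c.chrom == "gap":
            return True
        return cmap.is_pericentric(c.chrom, c.midpoint, eu_fraction=config.pericentric_eu_fraction)

    distal = [fraction(c) <= config.distal_fraction for c in calls]
    peri = [pericentric(c) for c in calls]
    if all(distal):
        if any(peri):
            warnings.warn(
                "crossover(s) simultaneously distal and pericentric under this "
                "map; distal precedence applied",
                stacklevel=2,
            )
        return DISTAL_CO
    if any(peri):
        return PERICENTRIC_CO
    return OTHER


def category_breakdown(events: pd.DataFrame, by: str | None = None) -> pd.DataFrame:
    """Fractions (with counts) of each cause category, optionally per
    group (e.g. per chromosome).  ``events`` needs a ``category`` column.
    """
    if events.empty:
        raise ValueError("empty cohort")
    groups = events.groupby(by) if by else [("all", events)]
    rows = []
    for name, sub in groups:
        n = len(sub)
        for cat in CATEGORIES:
            count = int((sub["category"] == cat).sum())
            rows.append({"group": name, "category": cat, "count": count, "fraction": count / n, "n": n})
    return pd.DataFrame(rows)


EVENTS_COLUMNS = [
    "sample", "division", "rescue_flag", "category",
    "n_calls_left", "n_calls_right", "n_calls_total",
]


def events_to_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=EVENTS_COLUMNS)
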