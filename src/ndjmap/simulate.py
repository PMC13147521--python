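"""Forward simulation of female meiosis, segregation errors, and pooled
backcross sequencing.

The generative model mirrors the experimental design used to recover
chromosome-2 nondisjunction (NDJ) progeny:

1. A female heterozygous for two isogenic backgrounds (P1 = Oregon R-like,
   P2 = w1118-like) forms a bivalent of four chromatids (two sisters per
   homolog).  Crossovers are placed in euchromatin; each crossover involves
   one of the four non-sister chromatid pairs chosen uniformly (no
   chromatid interference by default).
2. A segregation mode determines what a single progeny male inherits:
   NORMAL (one of the four chromatids), MI NDJ (one chromatid from each
   homolog), MII NDJ (both sister chromatids of one homolog), or monosomy
   rescue (one chromatid, mitotically duplicated).
3. The male is backcrossed to a homozygous-P2 stock.  There is no male
   recombination, so his two chromosome-2 copies segregate intact into
   sperm (Binomial(pool_size, 1/2) split).  Every pooled offspring also
   carries a P2 homolog from the mother, so the pool's P1-allele frequency
   at a SNP is (P1 copies transmitted) / (2 * pool_size): 0, ~0.25 or 0.5
   depending on the male's genotype at that SNP.
4. Reads are sampled per SNP with Poisson depth and a per-read error that
   flips the observed allele.

The module also contains the exhaustive-enumeration detection-probability
oracle: an inheritance outcome is *detectable* precisely when its noiseless
expected-frequency track is non-constant along the chromosome.
"""

from __future__ import annotations

import itertools
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ChromosomeMap

P1 = "P1"  # Oregon R-like; carries the "alt" allele at every panel SNP
P2 = "P2"  # w1118-like; carries the "ref" allele

NORMAL = "NORMAL"
MI_NDJ = "MI_NDJ"
MII_NDJ = "MII_NDJ"
MONOSOMY_RESCUE = "MONOSOMY_RESCUE"
MODES = (NORMAL, MI_NDJ, MII_NDJ, MONOSOMY_RESCUE)

# chromatid indices: 0,1 = sisters of homolog 1 (P1); 2,3 = sisters of
# homolog 2 (P2). Crossovers join one chromatid of each homolog.
NON_SISTER_PAIRS = ((0, 2), (0, 3), (1, 2), (1, 3))


@dataclass(frozen=True)
class ChromatidMosaic:
    """A chromatid as an ordered list of parental-origin segments.

    ``breakpoints`` are strictly increasing global bp positions at which
    the parental origin switches; ``origin_start`` is the origin of the
    segment beginning at the telomere of the left arm (global 0).
    """

    origin_start: str
    breakpoints: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.origin_start not in (P1, P2):
            raise ValueError("origin_start must be P1 or P2")
        bps = self.breakpoints
        if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
            raise ValueError("breakpoints must be strictly increasing")

    @property
    def is_recombinant(self) -> bool:
        return len(self.breakpoints) > 0

    def origin_at(self, pos) -> str:
        """Origin on the segment [breakpoint_k, breakpoint_{k+1}): a
        breakpoint position belongs to the segment to its right."""
        flips = bisect_right(self.breakpoints, pos)
        origin = self.origin_start
        return origin if flips % 2 == 0 else (P2 if origin == P1 else P1)

    def doses_at(self, positions: np.ndarray) -> np.ndarray:
        """P1-allele dose (0 or 1) of this chromatid at each position."""
        flips = np.searchsorted(np.asarray(self.breakpoints), positions, side="right")
        start = 1 if self.origin_start == P1 else 0
        return (start + flips) % 2 if start else flips % 2


def _origin_left_of(m: ChromatidMosaic, pos: int) -> str:
    flips = bisect_left(m.breakpoints, pos)
    return m.origin_start if flips % 2 == 0 else (P2 if m.origin_start == P1 else P1)


def _origin_right_of(m: ChromatidMosaic, pos: int) -> str:
    flips = bisect_right(m.breakpoints, pos)
    return m.origin_start if flips % 2 == 0 else (P2 if m.origin_start == P1 else P1)


def _exchange(a: ChromatidMosaic, b: ChromatidMosaic, pos: int,
              centromere_gpos: int) -> tuple[ChromatidMosaic, ChromatidMosaic]:
    """Reciprocal exchange at a crossover position.

    Chromatid identity follows the centromere (sisters are held there
    through meiosis I), so the exchanged piece is always the
    centromere-*distal* segment: global coordinates below ``pos`` when
    the crossover sits on the centromere's left, and above ``pos`` when
    it sits on the right.
    """

    def swap_tail(keep: ChromatidMosaic, donor: ChromatidMosaic) -> ChromatidMosaic:
        left = [x for x in keep.breakpoints if x < pos]
        tail = [x for x in donor.breakpoints if x > pos]
        bps = left + ([pos] if _origin_left_of(keep, pos) != _origin_right_of(donor, pos) else [])
        return ChromatidMosaic(keep.origin_start, tuple(bps + tail))

    def swap_head(keep: ChromatidMosaic, donor: ChromatidMosaic) -> ChromatidMosaic:
        head = [x for x in donor.breakpoints if x < pos]
        right = [x for x in keep.breakpoints if x > pos]
        bps = head + ([pos] if _origin_left_of(donor, pos) != _origin_right_of(keep, pos) else [])
        return ChromatidMosaic(donor.origin_start, tuple(bps + right))

    if pos > centromere_gpos:
        return swap_tail(a, b), swap_tail(b, a)
    return swap_head(a, b), swap_head(b, a)


@dataclass(frozen=True)
class Bivalent:
    """Four chromatids: (h1 sister a, h1 sister b, h2 sister a, h2 sister b),
    plus the crossover list that produced them."""

    chromatids: tuple[ChromatidMosaic, ChromatidMosaic, ChromatidMosaic, ChromatidMosaic]
    crossovers: tuple[tuple[int, tuple[int, int]], ...] = ()


def build_bivalent(co_positions, rng: np.random.Generator | None = None, pairs=None,
                   centromere_gpos: int = 0) -> Bivalent:
    """Install crossovers at sorted global positions on a fresh bivalent.

    Each crossover is assigned to one of the four non-sister chromatid
    pairs uniformly and independently unless ``pairs`` (indices into
    ``NON_SISTER_PAIRS``) is given explicitly.  ``centromere_gpos`` marks
    the centromere on the global axis; crossovers exchange the
    centromere-distal segment, so with the default of 0 every crossover
    behaves as if it lay right of the centromere (telocentric-style).
    """
    co_positions = [int(p) for p in co_positions]
    if sorted(co_positions) != co_positions:
        raise ValueError("crossover positions must be sorted")
    if len(set(co_positions)) != len(co_positions):
        raise ValueError("duplicate crossover positions")
    if pairs is None:
        if co_positions and rng is None:
            raise ValueError("rng required when pairs are not specified")
        pairs = [rng.integers(4) for _ in co_positions] if co_positions else []
    if len(pairs) != len(co_positions):
        raise ValueError("one chromatid pair per crossover required")

    cds = [ChromatidMosaic(P1), ChromatidMosaic(P1), ChromatidMosaic(P2), ChromatidMosaic(P2)]
    recorded = []
    for pos, k in zip(co_positions, pairs):
        i, j = NON_SISTER_PAIRS[int(k)]
        cds[i], cds[j] = _exchange(cds[i], cds[j], pos, centromere_gpos)
        recorded.append((pos, (i, j)))
    return Bivalent(tuple(cds), tuple(recorded))


def segregate(bivalent: Bivalent, mode: str, rng: np.random.Generator) -> tuple[ChromatidMosaic, ...]:
    """Inherited maternal chromatid(s) for one progeny under ``mode``."""
    c = bivalent.chromatids
    if mode == NORMAL:
        return (c[rng.integers(4)],)
    if mode == MI_NDJ:
        return (c[rng.integers(2)], c[2 + rng.integers(2)])
    if mode == MII_NDJ:
        h = rng.integers(2)
        return (c[2 * h], c[2 * h + 1])
    if mode == MONOSOMY_RESCUE:
        k = rng.integers(4)
        return (c[k], c[k])
    raise ValueError(f"unknown segregation mode {mode!r}")


# -- SNP panels and expected frequency tracks ----------------------------


def make_snp_panel(cmap: ChromosomeMap, spacing: int) -> pd.DataFrame:
    """Evenly spaced informative SNPs over all assembled sequence (both
    euchromatin and assembled pericentric heterochromatin; never the gap).

    Returns columns ``chrom`` (arm/contig name), ``pos`` (arm-local) and
    ``gpos`` (global).  The P1 stock carries the alt allele at every SNP.
    """
    rows = []
    for arm in cmap.arms:
        pos = np.arange(spacing // 2, arm.length, spacing, dtype=np.int64)
        gpos = cmap.to_global(arm.name, pos)
        rows.append(pd.DataFrame({"chrom": arm.name, "pos": pos, "gpos": gpos}))
    return pd.concat(rows, ignore_index=True).sort_values("gpos", ignore_index=True)


def expected_freq(inherited: tuple[ChromatidMosaic, ...], gpos: np.ndarray) -> np.ndarray:
    """Noiseless expected pooled alt-allele frequency at each position.

    Each maternal chromatid present in the male contributes dose/4: a
    two-chromatid male transmits one of them to every offspring, a
    one-chromatid (NORMAL-style) male transmits it to half the offspring,
    and every offspring carries a silent P2 homolog from the backcross
    mother.  Either way the expectation is 0.25 per P1 dose.
    """
    dose = np.zeros(len(gpos), dtype=np.int64)
    for cd in inherited:
        dose = dose + cd.doses_at(gpos)
    return dose * 0.25


def pooled_read_counts(
    inherited: tuple[ChromatidMosaic, ...],
    panel: pd.DataFrame,
    pool_size: int,
    mean_depth: float,
    seq_error: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate pooled-offspring read counts at each panel SNP.

    The sperm pool splits Binomial(pool_size, 1/2) between the male's two
    chromosome copies once per sample (no male recombination); for a
    single-chromatid male the alternative sperm class carries no
    informative maternal chromatid.  Depth is Poisson(mean_depth) and each
    read reports the wrong allele with probability ``seq_error``.
    """
    if pool_size <= 0:
        raise ValueError("pool_size must be positive")
    gpos = panel["gpos"].to_numpy()
    n = len(gpos)
    k = int(rng.binomial(pool_size, 0.5))  # offspring receiving "unit 1"
    if len(inherited) == 1:
        d1 = inherited[0].doses_at(gpos)
        p1_copies = k * d1
    elif len(inherited) == 2:
        d1 = inherited[0].doses_at(gpos)
        d2 = inherited[1].doses_at(gpos)
        p1_copies = k * d1 + (pool_size - k) * d2
    else:
        raise ValueError("a male carries one or two maternal chromatids")
    f = p1_copies / (2.0 * pool_size)
    p_read = f * (1.0 - seq_error) + (1.0 - f) * seq_error
    depth = rng.poisson(mean_depth, size=n)
    alt = rng.binomial(depth, p_read)
    return pd.DataFrame(
        {
            "chrom": panel["chrom"].to_numpy(),
            "pos": panel["pos"].to_numpy(),
            "ref_count": depth - alt,
            "alt_count": alt,
        }
    )


# -- crossover placement -------------------------------------------------


@dataclass
class SimulationConfig:
    """Study conditions for a simulated NDJ cohort.

    Defaults emulate the chromosome-2 experiment: a mode mixture matching
    the observed MI/MII split (49:14), ~1.05 crossovers per bivalent per
    arm (a ~107 cM chromosome), uniform crossover placement over
    euchromatin, 50-offspring pools, Poisson depth 30, per-read error
    0.005, and a 20 kb SNP panel (a scaled-down stand-in for the real
    ~294k-SNP panel).
    """

    n_events: int = 200
    mode_mixture: dict = field(
        default_factory=lambda: {MI_NDJ: 49 / 63, MII_NDJ: 14 / 63}
    )
    co_count_dist: dict = field(default_factory=lambda: {0: 0.15, 1: 0.65, 2: 0.20})
    pool_size: int = 50
    mean_depth: float = 30.0
    seq_error: float = 0.005
    snp_spacing: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.mode_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("mode mixture must sum to 1")
        if abs(sum(self.co_count_dist.values()) - 1.0) > 1e-9:
            raise ValueError("crossover-count distribution must sum to 1")
        for mode in self.mode_mixture:
            if mode not in MODES:
                raise ValueError(f"unknown mode {mode!r}")
        for r in (self.seq_error,):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "n_events": self.n_events,
            "mode_mixture": dict(self.mode_mixture),
            "co_count_dist": {int(k): v for k, v in self.co_count_dist.items()},
            "pool_size": self.pool_size,
            "mean_depth": self.mean_depth,
            "seq_error": self.seq_error,
            "snp_spacing": self.snp_spacing,
            "seed": self.seed,
        }


def draw_crossovers(config: SimulationConfig, cmap: ChromosomeMap, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Draw per-arm crossover counts and uniform euchromatic positions.

    Counts are independent across arms (no interference by default);
    positions never fall in heterochromatin or the unassembled gap.
    Returns (arm, arm-local position) sorted by global coordinate.
    """
    counts = sorted(config.co_count_dist)
    probs = [config.co_count_dist[k] for k in counts]
    out = []
    for arm_name, lo, hi in cmap.euchromatin_intervals():
        n = int(rng.choice(counts, p=probs))
        pos = sorted(int(p) for p in rng.integers(lo, hi, size=n))
        while len(set(pos)) != len(pos):  # vanishingly rare at bp resolution
            pos = sorted(int(p) for p in rng.integers(lo, hi, size=n))
        out.extend((arm_name, p) for p in pos)
    return sorted(out, key=lambda ap: cmap.to_global(ap[0], ap[1]))


# -- whole-sample simulation ---------------------------------------------


@dataclass
class SimulatedSample:
    """One simulated NDJ male with ground truth."""

    sample_id: str
    true_mode: str
    true_cos: list  # [(arm, local pos, pair index into NON_SISTER_PAIRS)]
    inherited: tuple[ChromatidMosaic, ...]
    counts: pd.DataFrame

    def true_detectable_transitions(self, cmap: ChromosomeMap) -> list[int]:
        """Global positions where the noiseless state track changes — the
        set of crossovers this sample's inheritance makes observable."""
        bps = sorted({b for cd in self.inherited for b in cd.breakpoints})
        out = []
        for b in bps:
            left = sum(1 for cd in self.inherited if cd.origin_at(b - 1) == P1)
            right = sum(1 for cd in self.inherited if cd.origin_at(b) == P1)
            if left != right:
                out.append(b)
        return out


def simulate_sample(
    sample_id: str,
    mode: str,
    config: SimulationConfig,
    cmap: ChromosomeMap,
    panel: pd.DataFrame,
    rng: np.random.Generator,
) -> SimulatedSample:
    cos = draw_crossovers(config, cmap, rng)
    gpositions = [cmap.to_global(a, p) for a, p in cos]
    pairs = [int(rng.integers(4)) for _ in cos]
    biv = build_bivalent(gpositions, pairs=pairs, centromere_gpos=cmap.centromere_gpos)
    inherited = segregate(biv, mode, rng)
    counts = pooled_read_counts(
        inherited, panel, config.pool_size, config.mean_depth, config.seq_error, rng
    )
    counts.insert(0, "sample", sample_id)
    true_cos = [(a, p, k) for (a, p), k in zip(cos, pairs)]
    return SimulatedSample(sample_id, mode, true_cos, inherited, counts)


def simulate_cohort(
    config: SimulationConfig,
    cmap: ChromosomeMap,
    rng: np.random.Generator | None = None,
) -> tuple[list[SimulatedSample], pd.DataFrame]:
    """Simulate a cohort; returns (samples, panel). Fully determined by
    ``config.seed`` when no generator is passed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    panel = make_snp_panel(cmap, config.snp_spacing)
    modes = list(config.mode_mixture)
    mode_p = [config.mode_mixture[m] for m in modes]
    samples = []
    for i in range(config.n_events):
        mode = str(rng.choice(modes, p=mode_p))
        samples.append(
            simulate_sample(f"s{i:05d}", mode, config, cmap, panel, rng)
        )
    return samples, panel


# -- detection-probability oracle ----------------------------------------


def _track_states(inherited, breakpoints) -> list[int]:
    """P1 dose of the inherited set on each interval between breakpoints."""
    pts = []
    if breakpoints:
        bps = sorted(breakpoints)
        pts = [bps[0] - 1] + [(a + b) // 2 for a, b in zip(bps, bps[1:])] + [bps[-1] + 1]
    else:
        pts = [0]
    return [sum(1 for cd in inherited if cd.origin_at(p) == P1) for p in pts]


def _inheritance_outcomes(bivalent: Bivalent, mode: str):
    c = bivalent.chromatids
    if mode == NORMAL:
        return [(c[k],) for k in range(4)]
    if mode == MI_NDJ:
        return [(c[i], c[j]) for i in (0, 1) for j in (2, 3)]
    if mode == MII_NDJ:
        return [(c[0], c[1]), (c[2], c[3])]
    if mode == MONOSOMY_RESCUE:
        return [(c[k], c[k]) for k in range(4)]
    raise ValueError(f"unknown segregation mode {mode!r}")


def _is_detectable(inherited) -> bool:
    bps = sorted({b for cd in inherited for b in cd.breakpoints})
    if not bps:
        return False
    states = _track_states(inherited, bps)
    return len(set(states)) > 1


def detection_probability(mode: str, co_positions, pairs=None, centromere_gpos: int = 0) -> float:
    """Fraction of equally likely inheritance outcomes whose noiseless
    expected-frequency track is non-constant, by exhaustive enumeration.

    ``pairs`` fixes the non-sister chromatid pair of each crossover;
    when omitted, the result marginalizes uniformly over all pair
    assignments.
    """
    co_positions = sorted(int(p) for p in co_positions)
    if not co_positions:
        return 0.0
    assignments = (
        [list(pairs)] if pairs is not None else itertools.product(range(4), repeat=len(co_positions))
    )
    detected = 0
    total = 0
    for assign in assignments:
        biv = build_bivalent(co_positions, pairs=list(assign), centromere_gpos=centromere_gpos)
        for outcome in _inheritance_outcomes(biv, mode):
            total += 1
            detected += _is_detectable(outcome)
    return detected / total


def mi_inheritance_class_probs(co_positions, pairs=None) -> dict[str, float]:
    """Exhaustive enumeration of MI NDJ inheritance classes.

    Classes: ``one_recombinant`` (one recombinant + one non-recombinant
    chromatid), ``reciprocal_recombinants`` (both recombinant), and
    ``both_nonrecombinant``.
    """
    co_positions = sorted(int(p) for p in co_positions)
    assignments = (
        [list(pairs)] if pairs is not None else itertools.product(range(4), repeat=len(co_positions))
    )
    tally = {"one_recombinant": 0, "reciprocal_recombinants": 0, "both_nonrecombinant": 0}
    total = 0
    for assign in assignments:
        biv = build_bivalent(co_positions, pairs=list(assign))
        for outcome in _inheritance_outcomes(biv, MI_NDJ):
            total += 1
            n_rec = sum(cd.is_recombinant for cd in outcome)
            key = ("both_nonrecombinant", "one_recombinant", "reciprocal_recombinants")[n_rec]
            tally[key] += 1
    return {k: v / total for k, v in tally.items()}


# -- other assayed chromosomes (X, 3) ------------------------------------


def simulate_other_chromosome_track(
    cmap: ChromosomeMap,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[ChromatidMosaic, list[tuple[str, int]], pd.DataFrame]:
    """A correctly segregating chromosome of the NDJ male (X or 3),
    simulated as a single maternal chromatid: the male is an ordinary
    heterozygote there, so the pooled track has two states with expected
    frequencies {0, 0.25}."""
    cos = draw_crossovers(config, cmap, rng)
    gpositions = [cmap.to_global(a, p) for a, p in cos]
    pairs = [int(rng.integers(4)) for _ in cos]
    biv = build_bivalent(gpositions, pairs=pairs, centromere_gpos=cmap.centromere_gpos)
    chromatid = segregate(biv, NORMAL, rng)[0]
    panel = make_snp_panel(cmap, config.snp_spacing)
    counts = pooled_read_counts(
        (chromatid,), panel, config.pool_size, config.mean_depth, config.seq_error, rng
    )
    return chromatid, cos, counts


# -- file output ----------------------------------------------------------


COUNTS_COLUMNS = ["sample", "chrom", "pos", "ref_count", "alt_count"]


def write_simulation(samples: list[SimulatedSample], out_dir, cmap: ChromosomeMap | None = None,
                     vcf: bool = False) -> dict:
    """Write counts and truth TSVs (and optionally a multi-sample VCF with
    AD fields); returns the paths written."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    counts_path = os.path.join(out_dir, "counts.tsv")
    truth_path = os.path.join(out_dir, "truth.tsv")
    if samples:
        counts = pd.concat([s.counts for s in samples], ignore_index=True)
    else:
        counts = pd.DataFrame(columns=COUNTS_COLUMNS)
    counts.to_csv(counts_path, sep="\t", index=False)

    truth_rows = []
    for s in samples:
        truth_rows.append(
            {
                "sample": s.sample_id,
                "true_mode": s.true_mode,
                "n_co": len(s.true_cos),
                "co_positions": ";".join(f"{a}:{p}:{k}" for a, p, k in s.true_cos),
                "inherited_breakpoints": ";".join(
                    ",".join(map(str, cd.breakpoints)) for cd in s.inherited
                ),
                "inherited_origin_start": ";".join(cd.origin_start for cd in s.inherited),
            }
        )
    pd.DataFrame(
        truth_rows,
        columns=["sample", "true_mode", "n_co", "co_positions",
                 "inherited_breakpoints", "inherited_origin_start"],
    ).to_csv(truth_path, sep="\t", index=False)

    paths = {"counts": counts_path, "truth": truth_path}
    if vcf:
        if cmap is None:
            raise ValueError("a ChromosomeMap is required to write a VCF")
        paths["vcf"] = write_vcf(samples, cmap, os.path.join(out_dir, "counts.vcf"))
    return paths


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def write_vcf(samples: list[SimulatedSample], cmap: ChromosomeMap, path) -> str:
    """Multi-sample VCF 4.2 with per-sample AD, via pysam."""
    import pysam

    header = pysam.VariantHeader()
    for arm in cmap.arms:
        header.contigs.add(arm.name, length=arm.length)
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for s in samples:
        header.add_sample(s.sample_id)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        if samples:
            wide_ref = {}
            wide_alt = {}
            for s in samples:
                key = s.counts.set_index(["chrom", "pos"])
                wide_ref[s.sample_id] = key["ref_count"]
                wide_alt[s.sample_id] = key["alt_count"]
            ref_df = pd.DataFrame(wide_ref).sort_index()
            alt_df = pd.DataFrame(wide_alt).reindex(ref_df.index)
            for (chrom, pos), refs in ref_df.iterrows():
                rec = out.new_record(
                    contig=str(chrom), start=int(pos), stop=int(pos) + 1,
                    alleles=("A", "T"),
                )
                alts = alt_df.loc[(chrom, pos)]
                for s in samples:
                    rec.samples[s.sample_id]["AD"] = (
                        int(refs[s.sample_id]), int(alts[s.sample_id])
                    )
                out.write(rec)
    return str(path)
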