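"""Genotype-state segmentation of allele-frequency tracks and crossover
calls.

A pooled-backcross track over one arm is a sequence of per-SNP
(ref_count, alt_count) pairs.  The male's genotype along the arm takes
one of three states — HOM_P2, HET and HOM_P1 — whose *idealized*
expected pooled alt-allele frequencies are 0, 0.25 and 0.5.  The
homozygous expectations are exact, but the heterozygous one is not: the
finite sperm pool splits Binomial(pool_size, 1/2) between the male's two
chromosome copies, so within one sample a heterozygous region sits at
k/(2·pool) or (pool−k)/(2·pool) depending on which chromatid carries the
P1 allele there.  Segmentation therefore runs in two passes: a first
Viterbi pass with the idealized frequencies, then an estimate of the
sample's split fraction from its heterozygous segments, and a second
pass over four emission sub-states {0, 0.5−q, q, 0.5} that collapse onto
the three genotype states.  Transitions between the two heterozygous
sub-states are never emitted as crossovers — both are the HET genotype,
matching the model in which reciprocal recombinant inheritance is
undetectable.

A "persistent change in allele frequency" is the maximum a posteriori
genotype path under binomial read emissions (expected frequencies
error-adjusted as ``f*(1-e) + (1-f)*e``) with a uniform per-transition
penalty, followed by merging of genotype segments shorter than
``min_segment_snps`` into their likelier neighbor.

Crossovers are emitted at genotype-segment boundaries.  The reported
flanking interval is a likelihood-support interval: every split point
whose profile log-likelihood is within ``boundary_support`` nats of the
best split is included, so the interval honestly covers breakpoint
uncertainty (it collapses to the two flanking SNPs where the states are
well separated).  A direct HOM_P1<->HOM_P2 transition cannot arise from
a single crossover in a two-chromatid sample and is flagged rather than
counted as an ordinary crossover — it is the monosomy-rescue
discriminator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ChromosomeMap, GeneticMapTable

THREE_STATE = (("HOM_P2", 0.0), ("HET", 0.25), ("HOM_P1", 0.5))
TWO_STATE = (("P2", 0.0), ("P1", 0.25))

HOM_STATES = {"HOM_P2", "HOM_P1"}

_Q_BOUNDS_THREE = (0.25, 0.42)
_Q_BOUNDS_TWO = (0.10, 0.45)


@dataclass
class SegmentationConfig:
    seq_error: float = 0.005
    switch_penalty: float = float(np.log(1e4))
    min_segment_snps: int = 10
    state_set: tuple = THREE_STATE
    calibrate_split: bool = True
    min_snps_for_calibration: int = 20
    boundary_support: float = 10.0  # nats of profile-likelihood support

    def __post_init__(self) -> None:
        if self.switch_penalty <= 0:
            raise ValueError("switch_penalty must be positive")
        if self.min_segment_snps < 1:
            raise ValueError("min_segment_snps must be >= 1")
        if self.boundary_support < 0:
            raise ValueError("boundary_support must be >= 0")

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.state_set)

    @property
    def n_states(self) -> int:
        return len(self.state_set)

    def adjust(self, freqs: np.ndarray) -> np.ndarray:
        """Error-adjusted expected alt frequencies, clipped away from 0/1
        so log-likelihoods stay finite."""
        e = self.seq_error
        f = np.asarray(freqs, dtype=float)
        return np.clip(f * (1 - e) + (1 - f) * e, 1e-12, 1 - 1e-12)

    def nominal_freqs(self) -> np.ndarray:
        return self.adjust([f for _, f in self.state_set])

    def sub_model(self, q: float) -> tuple[np.ndarray, np.ndarray]:
        """(adjusted sub-state freqs, genotype index per sub-state) for a
        split fraction q."""
        if self.n_states == 3:
            return self.adjust([0.0, 0.5 - q, q, 0.5]), np.array([0, 1, 1, 2])
        return self.adjust([0.0, q]), np.array([0, 1])

    def to_dict(self) -> dict:
        return {
            "seq_error": self.seq_error,
            "switch_penalty": self.switch_penalty,
            "min_segment_snps": self.min_segment_snps,
            "state_set": [[n, f] for n, f in self.state_set],
            "calibrate_split": self.calibrate_split,
            "min_snps_for_calibration": self.min_snps_for_calibration,
            "boundary_support": self.boundary_support,
        }


@dataclass
class Segment:
    state: str
    start_idx: int  # first SNP index (into the segmented track)
    end_idx: int    # last SNP index, inclusive
    first_pos: int
    last_pos: int
    n_snps: int
    mean_freq: float


@dataclass
class GenotypeSegmentation:
    chrom: str
    sample: str
    segments: list[Segment] = field(default_factory=list)
    # one (left_flank_pos, right_flank_pos) support interval per adjacent
    # segment boundary, aligned with zip(segments, segments[1:])
    boundary_intervals: list[tuple[int, int]] = field(default_factory=list)
    split_fraction: float = 0.25  # estimated heterozygous-state frequency

    @property
    def states(self) -> list[str]:
        return [s.state for s in self.segments]


@dataclass
class CrossoverCall:
    sample: str
    chrom: str
    left_flank: int   # leftmost supported split position
    right_flank: int  # rightmost supported split position
    midpoint: int
    state_from: str
    state_to: str
    double_switch: bool = False  # direct HOM_P1 <-> HOM_P2 transition

    def __post_init__(self) -> None:
        if not self.left_flank < self.right_flank:
            raise ValueError("flanking SNPs must bracket the call")


# -- Viterbi core ----------------------------------------------------------


def _emission_loglik(alt: np.ndarray, ref: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Binomial emission log-likelihood up to a state-independent constant:
    ``alt*log(p) + ref*log(1-p)``.  ``probs`` may be (k,) shared across
    samples or (n_samples, 1, k) per-sample; output broadcasts to
    (n_samples, n_snps, k)."""
    return alt[..., None] * np.log(probs) + ref[..., None] * np.log1p(-probs)


def viterbi_paths(alt: np.ndarray, ref: np.ndarray, probs: np.ndarray, switch_penalty: float) -> np.ndarray:
    """MAP state paths for a batch of tracks sharing one SNP panel.

    ``alt``/``ref`` have shape (n_samples, n_snps); returns int state
    indices of the same shape.  Vectorized over samples; the loop is over
    SNPs only, so large Monte-Carlo batches stay cheap.
    """
    alt = np.atleast_2d(alt)
    ref = np.atleast_2d(ref)
    n_samples, n_snps = alt.shape
    if n_snps == 0:
        return np.zeros((n_samples, 0), dtype=np.int8)
    ll = _emission_loglik(alt.astype(float), ref.astype(float), probs)
    k = ll.shape[-1]
    score = ll[:, 0, :].copy()
    back = np.zeros((n_samples, n_snps, k), dtype=np.int8)
    for t in range(1, n_snps):
        best_prev = np.argmax(score, axis=1)
        best_val = score[np.arange(n_samples), best_prev]
        cand = best_val[:, None] - switch_penalty
        stay_better = score >= cand
        new_score = np.where(stay_better, score, cand)
        back[:, t, :] = np.where(stay_better, np.arange(k)[None, :], best_prev[:, None])
        score = new_score + ll[:, t, :]
    states = np.zeros((n_samples, n_snps), dtype=np.int8)
    states[:, -1] = np.argmax(score, axis=1)
    for t in range(n_snps - 1, 0, -1):
        states[:, t - 1] = back[np.arange(n_samples), t, states[:, t]]
    return states


def _runs(path: np.ndarray) -> list[tuple[int, int, int]]:
    """(state, start, end_inclusive) runs of a 1-D state path."""
    if len(path) == 0:
        return []
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [len(path) - 1]))
    return [(int(path[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def merge_short_segments(path: np.ndarray, ll: np.ndarray, min_snps: int,
                         terminal_keep_advantage: float | None = None,
                         exempt_ends: tuple[bool, bool] = (True, True)) -> np.ndarray:
    """Merge runs shorter than ``min_snps`` into the neighboring state
    whose emission likelihood over the run's SNPs is higher ("cheaper"
    neighbor).  Repeats until no short run remains or only one run is
    left.

    A *terminal* short run at an exempt end of the track is kept when its
    emission advantage over the neighboring state exceeds
    ``terminal_keep_advantage``: unlike an interior excursion, a genuine
    crossover close to a telomere leaves only a short terminal segment,
    and erasing it despite transition-grade evidence would systematically
    lose telomere-proximal crossovers.  ``exempt_ends`` marks which track
    ends qualify (low-coordinate end, high-coordinate end); callers
    exempt telomeric ends only, because crossovers do not occur in the
    assembled pericentric heterochromatin that abuts the centromeric end.
    """
    path = path.copy()
    exempt: set[int] = set()  # run start indices proven to carry evidence
    while True:
        runs = _runs(path)
        if len(runs) <= 1:
            return path
        short = []
        for i, (st, s, e) in enumerate(runs):
            if e - s + 1 >= min_snps or s in exempt:
                continue
            at_exempt_end = (i == 0 and exempt_ends[0]) or (i == len(runs) - 1 and exempt_ends[1])
            if terminal_keep_advantage is not None and at_exempt_end:
                nb = runs[1][0] if i == 0 else runs[-2][0]
                advantage = (ll[s : e + 1, st] - ll[s : e + 1, nb]).sum()
                if advantage >= terminal_keep_advantage:
                    exempt.add(s)
                    continue
            short.append((e - s + 1, i))
        if not short:
            return path
        _, i = min(short)
        _, s, e = runs[i]
        options = []
        if i > 0:
            options.append(runs[i - 1][0])
        if i < len(runs) - 1:
            options.append(runs[i + 1][0])
        best = max(options, key=lambda st: ll[s : e + 1, st].sum())
        path[s : e + 1] = best


# -- split-fraction calibration -------------------------------------------


def estimate_split_fraction(alt: np.ndarray, ref: np.ndarray, geno_path: np.ndarray,
                            config: SegmentationConfig) -> float:
    """Estimate the heterozygous-state alt frequency (the sperm-split
    fraction k/(2*pool)) from the first-pass heterozygous segments.

    For three-state tracks each HET segment's error-corrected frequency
    is folded onto [0.25, 0.5) (its carrier chromatid is unknown) and the
    depth-weighted mean is taken; two-state tracks use the P1 segments
    directly.  Falls back to the idealized 0.25 when too few SNPs
    support the estimate.
    """
    het_idx = 1
    sel = geno_path == het_idx
    if sel.sum() < config.min_snps_for_calibration:
        return 0.25
    e = config.seq_error
    lo, hi = _Q_BOUNDS_THREE if config.n_states == 3 else _Q_BOUNDS_TWO
    if config.n_states == 3:
        # fold per segment, not per SNP: each HET run has one carrier
        total, weight = 0.0, 0.0
        for st, s, t in _runs(geno_path):
            if st != het_idx:
                continue
            d = float(alt[s : t + 1].sum() + ref[s : t + 1].sum())
            if d == 0:
                continue
            f_obs = float(alt[s : t + 1].sum()) / d
            f_corr = np.clip((f_obs - e) / (1 - 2 * e), 0.0, 0.5)
            total += max(f_corr, 0.5 - f_corr) * d
            weight += d
        if weight == 0:
            return 0.25
        q = total / weight
    else:
        d = float(alt[sel].sum() + ref[sel].sum())
        if d == 0:
            return 0.25
        f_obs = float(alt[sel].sum()) / d
        q = float(np.clip((f_obs - e) / (1 - 2 * e), 0.0, 1.0))
    return float(np.clip(q, lo, hi))


def _genotype_ll(ll_sub: np.ndarray, genotype_map: np.ndarray, n_geno: int) -> np.ndarray:
    """Per-SNP genotype log-likelihood: best sub-state of each genotype."""
    out = np.full(ll_sub.shape[:-1] + (n_geno,), -np.inf)
    for g in range(n_geno):
        cols = np.flatnonzero(genotype_map == g)
        out[..., g] = ll_sub[..., cols].max(axis=-1)
    return out


def _segment_path(alt: np.ndarray, ref: np.ndarray, config: SegmentationConfig,
                  exempt_ends: tuple[bool, bool] = (True, True)) -> tuple[np.ndarray, np.ndarray, float]:
    """Two-pass genotype path for one track.

    Returns (genotype path, per-SNP genotype log-likelihoods, estimated
    split fraction)."""
    nominal = config.nominal_freqs()
    path1 = viterbi_paths(alt, ref, nominal, config.switch_penalty)[0]
    q = 0.25
    if config.calibrate_split:
        q = estimate_split_fraction(alt, ref, path1, config)
    sub_freqs, geno_map = config.sub_model(q)
    sub_path = viterbi_paths(alt, ref, sub_freqs, config.switch_penalty)[0]
    geno_path = geno_map[sub_path]
    ll_sub = _emission_loglik(alt.astype(float)[None, :], ref.astype(float)[None, :], sub_freqs)[0]
    ll_geno = _genotype_ll(ll_sub, geno_map, config.n_states)
    geno_path = merge_short_segments(
        geno_path, ll_geno, config.min_segment_snps,
        terminal_keep_advantage=config.switch_penalty,
        exempt_ends=exempt_ends,
    )
    return geno_path, ll_geno, q


def _support_interval(ll_geno: np.ndarray, pos: np.ndarray, left, right,
                      delta: float) -> tuple[int, int]:
    """Profile-likelihood support interval for the boundary between two
    adjacent runs ``left=(state, s, e)`` and ``right=(state, s, e)``.

    Considers every split index j within the two runs (boundary between
    SNP j and j+1) and keeps those whose log-likelihood is within
    ``delta`` of the best; returns the bracketing SNP positions.
    """
    sl, s0, e0 = left
    sr, s1, e1 = right
    lo, hi = s0, e1
    diff = ll_geno[lo : hi + 1, sr] - ll_geno[lo : hi + 1, sl]
    # S(j) = const + sum_{i>j} diff_i; splits j in [lo-1 .. hi], we only
    # consider j in [s0 .. e1-1] so both sides keep >= 1 SNP of their run
    suffix = np.concatenate((np.cumsum(diff[::-1])[::-1], [0.0]))
    scores = suffix[1:]  # score of split after SNP (lo + j)
    n_splits = hi - lo  # splits between consecutive SNPs
    scores = scores[:n_splits]
    best = scores.max()
    keep = np.flatnonzero(scores >= best - delta)
    j_lo, j_hi = int(keep.min()), int(keep.max())
    return int(pos[lo + j_lo]), int(pos[lo + j_hi + 1])


# -- public segmentation API ----------------------------------------------


def segment_track(track: pd.DataFrame, config: SegmentationConfig | None = None,
                  sample: str = "", chrom: str = "",
                  exempt_ends: tuple[bool, bool] = (True, True)) -> GenotypeSegmentation:
    """Segment one sample's sorted per-SNP counts on one arm.

    ``track`` columns: ``pos, ref_count, alt_count`` (+ optional
    ``masked``; masked SNPs are skipped).  Returns maximal runs of
    inferred genotype state with a support interval per boundary; an
    empty track yields an empty segmentation.  ``exempt_ends`` marks the
    track ends where short terminal segments with transition-grade
    evidence are kept (telomeric ends; see merge_short_segments).
    """
    config = config or SegmentationConfig()
    if "masked" in track.columns:
        track = track[~track["masked"].astype(bool)]
    track = track.sort_values("pos")
    if track.empty:
        return GenotypeSegmentation(chrom=chrom, sample=sample)
    pos = track["pos"].to_numpy()
    alt = track["alt_count"].to_numpy()
    ref = track["ref_count"].to_numpy()
    path, ll_geno, q = _segment_path(alt, ref, config, exempt_ends=exempt_ends)

    depth = ref + alt
    with np.errstate(invalid="ignore"):
        freq = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    names = config.state_names
    runs = _runs(path)
    segments = [
        Segment(
            state=names[st],
            start_idx=s,
            end_idx=e,
            first_pos=int(pos[s]),
            last_pos=int(pos[e]),
            n_snps=e - s + 1,
            mean_freq=float(np.nanmean(freq[s : e + 1])),
        )
        for st, s, e in runs
    ]
    intervals = [
        _support_interval(ll_geno, pos, runs[i], runs[i + 1], config.boundary_support)
        for i in range(len(runs) - 1)
    ]
    return GenotypeSegmentation(
        chrom=chrom, sample=sample, segments=segments,
        boundary_intervals=intervals, split_fraction=q,
    )


def state_paths_batch(alt: np.ndarray, ref: np.ndarray, config: SegmentationConfig | None = None,
                      exempt_ends: tuple[bool, bool] = (True, True)) -> np.ndarray:
    """Batch variant returning merged genotype paths for many samples
    sharing one panel (used by Monte-Carlo checks)."""
    config = config or SegmentationConfig()
    alt = np.atleast_2d(alt)
    ref = np.atleast_2d(ref)
    n = alt.shape[0]
    nominal = config.nominal_freqs()
    path1 = viterbi_paths(alt, ref, nominal, config.switch_penalty)
    qs = np.full(n, 0.25)
    if config.calibrate_split:
        for i in range(n):
            qs[i] = estimate_split_fraction(alt[i], ref[i], path1[i], config)
    # pass 2 as one batched Viterbi over per-sample calibrated sub-states
    sub_list = [config.sub_model(q)[0] for q in qs]
    geno_map = config.sub_model(0.25)[1]
    sub_freqs = np.asarray(sub_list)[:, None, :]  # (n, 1, n_sub)
    sub_paths = viterbi_paths(alt, ref, sub_freqs, config.switch_penalty)
    geno = geno_map[sub_paths]
    ll_sub = _emission_loglik(alt.astype(float), ref.astype(float), sub_freqs)
    ll_geno = _genotype_ll(ll_sub, geno_map, config.n_states)
    out = np.empty_like(geno)
    for i in range(n):
        out[i] = merge_short_segments(
            geno[i], ll_geno[i], config.min_segment_snps,
            terminal_keep_advantage=config.switch_penalty,
            exempt_ends=exempt_ends,
        )
    return out


# -- calls -----------------------------------------------------------------


def calls_from_segmentation(seg: GenotypeSegmentation) -> list[CrossoverCall]:
    """One call per adjacent-segment boundary.  Direct HOM<->HOM
    transitions are flagged ``double_switch`` (they are impossible from a
    single crossover in a two-chromatid sample)."""
    calls = []
    for i, (left, right) in enumerate(zip(seg.segments, seg.segments[1:])):
        if i < len(seg.boundary_intervals):
            lf, rf = seg.boundary_intervals[i]
        else:
            lf, rf = left.last_pos, right.first_pos
        calls.append(
            CrossoverCall(
                sample=seg.sample,
                chrom=seg.chrom,
                left_flank=lf,
                right_flank=rf,
                midpoint=(lf + rf) // 2,
                state_from=left.state,
                state_to=right.state,
                double_switch=left.state in HOM_STATES and right.state in HOM_STATES,
            )
        )
    return calls


def call_cross_gap_event(seg_left: GenotypeSegmentation, seg_right: GenotypeSegmentation,
                         cmap: ChromosomeMap) -> CrossoverCall | None | str:
    """Compare the centromere-proximal states flanking the unassembled
    gap; a state change across the gap is an exchange that must have
    occurred in the (SNP-free) satellite interval.

    Returns a gap-interval call, ``None`` when the states agree, or the
    string ``"undetermined"`` when either arm lacks proximal coverage.
    """
    if not seg_left.segments or not seg_right.segments:
        return "undetermined"
    # left arm ascending local coords end at the centromere; right arm
    # starts there (metacentric convention enforced by ChromosomeMap)
    left_seg = seg_left.segments[-1]
    right_seg = seg_right.segments[0]
    if left_seg.state == right_seg.state:
        return None
    gap = cmap.gap_interval()
    left_flank = cmap.to_global(seg_left.chrom, left_seg.last_pos)
    right_flank = cmap.to_global(seg_right.chrom, right_seg.first_pos)
    mid = (gap[0] + gap[1]) // 2 if gap else (left_flank + right_flank) // 2
    return CrossoverCall(
        sample=seg_left.sample,
        chrom="gap",
        left_flank=int(left_flank),
        right_flank=int(right_flank),
        midpoint=int(mid),
        state_from=left_seg.state,
        state_to=right_seg.state,
        double_switch=left_seg.state in HOM_STATES and right_seg.state in HOM_STATES,
    )


def double_crossover_metrics(calls: list[CrossoverCall], gmap: GeneticMapTable) -> list[dict]:
    """bp and cM distances between same-arm adjacent crossover midpoints."""
    out = []
    by_arm: dict[str, list[CrossoverCall]] = {}
    for c in calls:
        by_arm.setdefault(c.chrom, []).append(c)
    for arm, arm_calls in by_arm.items():
        arm_calls = sorted(arm_calls, key=lambda c: c.midpoint)
        for a, b in zip(arm_calls, arm_calls[1:]):
            out.append(
                {
                    "sample": a.sample,
                    "arm": arm,
                    "left_midpoint": a.midpoint,
                    "right_midpoint": b.midpoint,
                    "bp_distance": b.midpoint - a.midpoint,
                    "cM_distance": abs(
                        gmap.bp_to_cM(arm, b.midpoint) - gmap.bp_to_cM(arm, a.midpoint)
                    ),
                }
            )
    return out


# -- table I/O -------------------------------------------------------------


CALLS_COLUMNS = ["sample", "chrom", "left_flank", "right_flank", "midpoint",
                 "state_from", "state_to", "double_switch"]


def calls_to_frame(calls: list[CrossoverCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": c.sample,
                "chrom": c.chrom,
                "left_flank": c.left_flank,
                "right_flank": c.right_flank,
                "midpoint": c.midpoint,
                "state_from": c.state_from,
                "state_to": c.state_to,
                "double_switch": c.double_switch,
            }
            for c in calls
        ],
        columns=CALLS_COLUMNS,
    )


def segmentation_to_frame(segs: list[GenotypeSegmentation]) -> pd.DataFrame:
    rows = []
    for seg in segs:
        for s in seg.segments:
            rows.append(
                {
                    "sample": seg.sample,
                    "chrom": seg.chrom,
                    "state": s.state,
                    "first_pos": s.first_pos,
                    "last_pos": s.last_pos,
                    "n_snps": s.n_snps,
                    "mean_freq": s.mean_freq,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sample", "chrom", "state", "first_pos", "last_pos", "n_snps", "mean_freq"],
    )
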