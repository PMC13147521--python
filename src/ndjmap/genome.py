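"""Chromosome geometry and coordinate systems.

Everything downstream of this module reasons about positions on a chromosome
that is either *metacentric* (two arms flanking an unassembled centromeric
satellite gap, like Drosophila chromosome 2) or *telocentric* (a single arm
with the centromere at one end, like the Drosophila X).

Two coordinate systems are used:

* **arm-local**: 0-based, half-open base-pair positions within one arm's
  assembly, exactly as a read aligner would report them for that contig.
  Each arm carries an orientation flag stating which end of its local axis
  is the telomere (dm6 stores 2L telomere->centromere but 2R
  centromere->telomere), so "distance from the telomere" is always
  well-defined without sign gymnastics.
* **global**: a single stitched axis running telomere(left arm) ->
  centromeric gap -> telomere(right arm), used by the simulator so that a
  chromatid is one ordered list of parental-origin segments.

The module also provides the two zone predicates used to categorize
crossovers (the distal fraction of an arm/chromosome, and the pericentric
heterochromatin plus a fraction of the adjacent euchromatin) and
piecewise-linear bp<->cM interpolation against a genetic-map anchor table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

TEL_TO_CEN = "telomere_to_centromere"
CEN_TO_TEL = "centromere_to_telomere"

METACENTRIC = "metacentric"
TELOCENTRIC = "telocentric"


@dataclass(frozen=True)
class ArmDefinition:
    """One chromosome arm assembly.

    Parameters
    ----------
    name:
        Contig label, e.g. ``"2L"``.
    length:
        Assembly length in base pairs.
    orientation:
        ``"telomere_to_centromere"`` if local coordinate 0 is the telomeric
        end, ``"centromere_to_telomere"`` if local coordinate 0 is the
        centromeric end.
    het_boundary:
        Arm-local position of the euchromatin / pericentric-heterochromatin
        boundary.  The heterochromatic side is always the centromeric side
        implied by ``orientation``.
    """

    name: str
    length: int
    orientation: str
    het_boundary: int

    def __post_init__(self) -> None:
        if self.orientation not in (TEL_TO_CEN, CEN_TO_TEL):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.length <= 0:
            raise ValueError("arm length must be positive")
        if not (0 < self.het_boundary <= self.length):
            raise ValueError("het_boundary must lie in (0, length]")

    def _check(self, pos) -> None:
        pos = np.asarray(pos)
        if np.any(pos < 0) or np.any(pos > self.length):
            raise ValueError(f"position outside arm {self.name}")

    def dist_from_telomere(self, pos):
        """Distance in bp from the telomeric end (scalar or array)."""
        self._check(pos)
        if self.orientation == TEL_TO_CEN:
            return pos
        return self.length - np.asarray(pos) if np.ndim(pos) else self.length - pos

    @property
    def euchromatin_length(self) -> int:
        """bp of euchromatin, i.e. distance from the telomere to het_boundary."""
        if self.orientation == TEL_TO_CEN:
            return self.het_boundary
        return self.length - self.het_boundary

    def euchromatin_interval(self) -> tuple[int, int]:
        """Arm-local half-open interval covered by euchromatin."""
        if self.orientation == TEL_TO_CEN:
            return (0, self.het_boundary)
        return (self.het_boundary, self.length)

    def heterochromatin_interval(self) -> tuple[int, int]:
        if self.orientation == TEL_TO_CEN:
            return (self.het_boundary, self.length)
        return (0, self.het_boundary)


@dataclass(frozen=True)
class ChromosomeMap:
    """Geometry of one chromosome: arms, shape, and the centromeric gap.

    Metacentric maps have exactly two arms in left-to-right genome order,
    the first oriented telomere->centromere and the second
    centromere->telomere, separated by ``gap_length`` bp of unassembled
    centromeric satellite.  Telocentric maps have a single arm and no gap.
    """

    name: str
    arms: tuple[ArmDefinition, ...]
    shape: str
    gap_length: int = 0

    def __post_init__(self) -> None:
        if self.shape == METACENTRIC:
            if len(self.arms) != 2:
                raise ValueError("metacentric map needs exactly two arms")
            if self.arms[0].orientation != TEL_TO_CEN or self.arms[1].orientation != CEN_TO_TEL:
                raise ValueError(
                    "metacentric arms must be ordered telomere->centromere, "
                    "centromere->telomere"
                )
        elif self.shape == TELOCENTRIC:
            if len(self.arms) != 1:
                raise ValueError("telocentric map has a single arm")
            if self.gap_length:
                raise ValueError("telocentric map has no centromeric gap")
        else:
            raise ValueError(f"unknown shape {self.shape!r}")

    # -- lookup -----------------------------------------------------------

    def arm(self, name: str) -> ArmDefinition:
        for a in self.arms:
            if a.name == name:
                return a
        raise KeyError(f"unknown arm {name!r} on chromosome {self.name}")

    @property
    def arm_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.arms)

    @property
    def total_length(self) -> int:
        return sum(a.length for a in self.arms) + self.gap_length

    # -- global axis ------------------------------------------------------

    def _global_offset(self, name: str) -> int:
        off = 0
        for a in self.arms:
            if a.name == name:
                return off
            off += a.length + self.gap_length
        raise KeyError(f"unknown arm {name!r}")

    def to_global(self, arm: str, pos):
        self.arm(arm)._check(pos)
        return self._global_offset(arm) + pos

    def to_arm(self, gpos) -> tuple[str, int]:
        off = 0
        for a in self.arms:
            if off <= gpos <= off + a.length:
                return a.name, gpos - off
            off += a.length + self.gap_length
        raise ValueError(f"global position {gpos} outside chromosome (or in gap)")

    def gap_interval(self) -> tuple[int, int] | None:
        """Global half-open interval of the unassembled centromeric gap."""
        if self.shape != METACENTRIC or self.gap_length == 0:
            return None
        lo = self.arms[0].length
        return (lo, lo + self.gap_length)

    @property
    def centromere_gpos(self) -> int:
        """Global position of the centromere (middle of the gap for a
        metacentric, the declared centromeric end for a telocentric)."""
        if self.shape == METACENTRIC:
            return self.arms[0].length + self.gap_length // 2
        a = self.arms[0]
        return 0 if a.orientation == CEN_TO_TEL else a.length

    def centromeric_end(self, arm: str) -> str:
        """Which local-coordinate end of the arm faces the centromere."""
        return "end" if self.arm(arm).orientation == TEL_TO_CEN else "start"

    # -- zone predicates --------------------------------------------------

    def fraction_from_telomere(self, arm: str, pos, scope: str = "arm") -> float:
        """Fraction of the arm (or whole chromosome) lying distal to ``pos``.

        Measured from the telomeric end: 0.0 at the telomere, rising toward
        the centromere.  ``scope="arm"`` normalizes by the arm length (the
        default for metacentric chromosomes); ``scope="chromosome"``
        normalizes by the total chromosome length (the natural reading for
        a telocentric chromosome, where arm and chromosome coincide).
        """
        a = self.arm(arm)
        d = a.dist_from_telomere(pos)
        if scope == "arm":
            return d / a.length
        if scope == "chromosome":
            return d / self.total_length
        raise ValueError(f"unknown scope {scope!r}")

    def is_pericentric(self, arm: str, pos, eu_fraction: float = 0.15) -> bool:
        """True iff ``pos`` is in pericentric heterochromatin or the
        most-proximal ``eu_fraction`` of the arm's adjacent euchromatin.

        The het boundary itself is assigned to the proximal (pericentric)
        zone.  ``eu_fraction`` is a fraction of *this arm's* euchromatin
        length.
        """
        a = self.arm(arm)
        d = a.dist_from_telomere(pos)
        cutoff = a.euchromatin_length * (1.0 - eu_fraction)
        return bool(d >= cutoff)

    def pericentric_window(self, arm: str, extra_bp: int = 1_000_000) -> tuple[int, int]:
        """Arm-local interval of the heterochromatin plus ``extra_bp`` of
        adjacent euchromatin (the window used to read centromere-proximal
        genotype state)."""
        a = self.arm(arm)
        lo, hi = a.heterochromatin_interval()
        if a.orientation == TEL_TO_CEN:
            return (max(0, lo - extra_bp), hi)
        return (lo, min(a.length, hi + extra_bp))

    def euchromatin_intervals(self) -> list[tuple[str, int, int]]:
        """Per-arm arm-local euchromatic intervals (used to place crossovers
        and the crossover-eligible part of SNP panels)."""
        return [(a.name, *a.euchromatin_interval()) for a in self.arms]


# -- spec-level convenience wrappers -------------------------------------


def chromosome_fraction_from_telomere(cmap: ChromosomeMap, arm: str, pos, scope: str | None = None) -> float:
    if scope is None:
        scope = "chromosome" if cmap.shape == TELOCENTRIC else "arm"
    return cmap.fraction_from_telomere(arm, pos, scope=scope)


def is_pericentric(cmap: ChromosomeMap, arm: str, pos, eu_fraction: float = 0.15) -> bool:
    return cmap.is_pericentric(arm, pos, eu_fraction=eu_fraction)


# -- genetic map ----------------------------------------------------------


class GeneticMapTable:
    """Per-arm monotone (bp, cM) anchors with piecewise-linear interpolation.

    Positions outside the anchored range are clamped to the terminal
    anchors' cM values.
    """

    def __init__(self, anchors: dict[str, tuple[np.ndarray, np.ndarray]]):
        if not anchors:
            raise ValueError("empty genetic-map table")
        self.anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for arm, (bp, cm) in anchors.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.size == 0:
                raise ValueError(f"no anchors for arm {arm}")
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"bp anchors must be strictly increasing on {arm}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM anchors must be non-decreasing on {arm}")
            self.anchors[arm] = (bp, cm)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMapTable":
        anchors = {}
        for arm, sub in df.groupby("arm"):
            sub = sub.sort_values("bp")
            anchors[str(arm)] = (sub["bp"].to_numpy(), sub["cM"].to_numpy())
        return cls(anchors)

    @classmethod
    def read_tsv(cls, path) -> "GeneticMapTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def bp_to_cM(self, arm: str, pos):
        if arm not in self.anchors:
            raise KeyError(f"genetic map does not cover arm {arm!r}")
        bp, cm = self.anchors[arm]
        return float(np.interp(pos, bp, cm)) if np.ndim(pos) == 0 else np.interp(pos, bp, cm)


def bp_to_cM(table: GeneticMapTable, arm: str, pos):
    return table.bp_to_cM(arm, pos)


# -- config I/O -----------------------------------------------------------


def chromosome_map_from_dict(d: dict) -> ChromosomeMap:
    arms = tuple(
        ArmDefinition(
            name=str(a["name"]),
            length=int(a["length"]),
            orientation=str(a["orientation"]),
            het_boundary=int(a["het_boundary"]),
        )
        for a in d["arms"]
    )
    return ChromosomeMap(
        name=str(d["name"]),
        arms=arms,
        shape=str(d["shape"]),
        gap_length=int(d.get("gap_length", 0)),
    )


def chromosome_map_to_dict(cmap: ChromosomeMap) -> dict:
    return {
        "name": cmap.name,
        "shape": cmap.shape,
        "gap_length": cmap.gap_length,
        "arms": [
            {
                "name": a.name,
                "length": a.length,
                "orientation": a.orientation,
                "het_boundary": a.het_boundary,
            }
            for a in cmap.arms
        ],
    }


def load_chromosome_map(path_or_stream) -> ChromosomeMap:
    if hasattr(path_or_stream, "read"):
        d = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            d = yaml.safe_load(fh)
    return chromosome_map_from_dict(d)


def save_chromosome_map(cmap: ChromosomeMap, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(chromosome_map_to_dict(cmap), fh, sort_keys=False)


def default_chr2_map() -> ChromosomeMap:
    """The shipped dm6-like chromosome-2 geometry (H3K9me3-style het
    boundaries as config constants)."""
    text = resources.files("ndjmap.data").joinpath("chr2_dm6.yaml").read_text()
    return load_chromosome_map(io.StringIO(text))


def default_chr2_genetic_map() -> GeneticMapTable:
    """Approximate standard-map anchors for chromosome 2 (~107 cM total)."""
    text = resources.files("ndjmap.data").joinpath("chr2_genetic_map.tsv").read_text()
    return GeneticMapTable.read_tsv(io.StringIO(text))
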