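"""Core domain types for multi-parent population (MPP) QTL mapping.

This module holds the shared vocabulary of the package:

* :class:`GeneticMap` — ordered marker positions in centiMorgans per
  chromosome, the coordinate system everything else lives in.
* :class:`MppDesign` — the crossing design: a set of founder parents and a
  list of biparental families (DH, F2 or RILn), each with its offspring.
* :class:`MarkerData` — founder and offspring marker genotypes aligned to
  the map.
* :class:`EvalGrid` — the 1-D grid of genome positions at which IBD
  probabilities are computed and QTL models are tested.

plus the Haldane map function and the grid builder.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing allele code.
MISSING = -1

#: Absolute tolerance (cM) when comparing map positions.
POSITION_TOL = 1e-9


class InputError(ValueError):
    """Invalid user-supplied data (bad values, inconsistent tables)."""


class ConfigError(ValueError):
    """Invalid or unsupported configuration (e.g. unknown population type)."""


class NumericalDegeneracyError(ArithmeticError):
    """The computation lost all probability mass (e.g. impossible data at
    genotyping error rate 0); advise a strictly positive error rate."""


# ---------------------------------------------------------------------------
# Map function
# ---------------------------------------------------------------------------

def haldane_cm_to_r(d: float) -> float:
    """Convert a genetic distance in cM to a recombination fraction.

    Uses the Haldane map function (no crossover interference):
    ``r = 0.5 * (1 - exp(-2 d / 100))``.

    Parameters
    ----------
    d : float
        Genetic distance in centiMorgans; must be finite and >= 0.

    Returns
    -------
    float
        Recombination fraction in ``[0, 0.5)``; strictly increasing in *d*.
    """
    d = float(d)
    if not np.isfinite(d) or d < 0:
        raise InputError(f"distance must be finite and non-negative, got {d!r}")
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticMap:
    """An ordered genetic map: markers with chromosome and position in cM.

    Within each chromosome positions must be non-decreasing and marker
    names unique.  Chromosome order is the order of first appearance.
    """

    markers: tuple[str, ...]
    chromosomes: tuple[str, ...]
    positions: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.markers) == len(self.chromosomes) == len(self.positions)):
            raise InputError("map columns have unequal lengths")
        if len(self.markers) == 0:
            raise InputError("genetic map is empty")
        if len(set(self.markers)) != len(self.markers):
            raise InputError("duplicate marker names in map")
        for chrom in self.chromosome_names:
            pos = self.chromosome_positions(chrom)
            if np.any(np.isnan(pos)) or np.any(pos < 0):
                raise InputError(f"chromosome {chrom}: positions must be >= 0")
            if np.any(np.diff(pos) < 0):
                raise InputError(f"chromosome {chrom}: positions must be non-decreasing")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        """Build from a DataFrame with columns ``marker, chromosome, position``."""
        required = {"marker", "chromosome", "position"}
        if not required.issubset(df.columns):
            raise InputError(f"map table needs columns {sorted(required)}")
        return cls(
            markers=tuple(str(m) for m in df["marker"]),
            chromosomes=tuple(str(c) for c in df["chromosome"]),
            positions=tuple(float(p) for p in df["position"]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": self.markers, "chromosome": self.chromosomes,
             "position": self.positions}
        )

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chromosome_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.chromosomes:
            seen.setdefault(c, None)
        return tuple(seen)

    def chromosome_indices(self, chrom: str) -> np.ndarray:
        """Indices (into map order) of the markers on *chrom*."""
        return np.flatnonzero(np.asarray(self.chromosomes, dtype=object) == chrom)

    def chromosome_positions(self, chrom: str) -> np.ndarray:
        return np.asarray(self.positions, dtype=float)[self.chromosome_indices(chrom)]


# ---------------------------------------------------------------------------
# Population types and design
# ---------------------------------------------------------------------------

_RIL_RE = re.compile(r"^RIL(\d+|INF)$", re.IGNORECASE)


@dataclass(frozen=True)
class PopType:
    """A supported biparental population type.

    ``kind`` is one of ``"DH"``, ``"F2"``, ``"RIL"``.  For RIL,
    ``selfing_n`` is the RILn generation index n >= 2 (n - 1 rounds of
    selfing after the F1), or ``None`` for a fully inbred RIL (RILinf).
    """

    kind: str
    selfing_n: int | None = None

    @classmethod
    def parse(cls, text: str) -> "PopType":
        t = text.strip().upper()
        if t == "DH":
            return cls("DH")
        if t == "F2":
            return cls("F2")
        m = _RIL_RE.match(t)
        if m:
            tok = m.group(1)
            if tok.upper() == "INF":
                return cls("RIL", None)
            n = int(tok)
            if not 2 <= n <= 8:
                raise ConfigError(
                    f"RIL{n} unsupported: supported types are DH, F2, RIL2..RIL8, "
                    "RILinf; precomputed IBD probabilities for other designs can be "
                    "supplied via the long-format IBD import"
                )
            return cls("RIL", n)
        raise ConfigError(
            f"unknown population type {text!r}: supported types are DH, F2, "
            "RIL2..RIL8, RILinf; for other designs import precomputed IBD "
            "probabilities via the long-format IBD import"
        )

    def __str__(self) -> str:
        if self.kind != "RIL":
            return self.kind
        return "RILinf" if self.selfing_n is None else f"RIL{self.selfing_n}"

    @property
    def residual_heterozygosity(self) -> float:
        """Expected heterozygosity at a locus under this scheme."""
        if self.kind == "F2":
            return 0.5
        if self.kind == "RIL" and self.selfing_n is not None:
            return 0.5 ** (self.selfing_n - 1)
        return 0.0  # DH, RILinf


@dataclass(frozen=True)
class Family:
    family_id: str
    parent1: str
    parent2: str
    pop_type: PopType
    genotypes: tuple[str, ...]


@dataclass(frozen=True)
class MppDesign:
    """Crossing design: founders and biparental families.

    Exposes the model symbols: ``n_founders`` (P), ``n_families`` (F) and
    per-family sizes n_k via ``family_sizes``.
    """

    founders: tuple[str, ...]
    families: tuple[Family, ...]

    def __post_init__(self) -> None:
        if len(set(self.founders)) != len(self.founders):
            raise InputError("duplicate founder ids")
        seen: dict[str, str] = {}
        for fam in self.families:
            if fam.parent1 == fam.parent2:
                raise InputError(f"family {fam.family_id}: parents must differ")
            for p in (fam.parent1, fam.parent2):
                if p not in self.founders:
                    raise InputError(
                        f"family {fam.family_id}: parent {p!r} not in founders"
                    )
            for g in fam.genotypes:
                if g in seen:
                    raise InputError(
                        f"genotype {g!r} assigned to families {seen[g]!r} "
                        f"and {fam.family_id!r}"
                    )
                seen[g] = fam.family_id

    @property
    def n_founders(self) -> int:
        return len(self.founders)

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def family_sizes(self) -> tuple[int, ...]:
        return tuple(len(f.genotypes) for f in self.families)

    @property
    def genotype_ids(self) -> tuple[str, ...]:
        return tuple(g for fam in self.families for g in fam.genotypes)

    def family_of(self) -> dict[str, str]:
        return {g: fam.family_id for fam in self.families for g in fam.genotypes}

    def founder_index(self, founder: str) -> int:
        return self.founders.index(founder)


# ---------------------------------------------------------------------------
# Marker data
# ---------------------------------------------------------------------------

@dataclass
class MarkerData:
    """Founder and offspring marker genotypes aligned to a GeneticMap.

    ``founder_alleles`` is a (n_founders, n_markers) int array of allele
    codes (founders are assumed homozygous, one code per marker).
    ``offspring_alleles`` is a (n_offspring, n_markers, 2) int array of
    genotype calls.  Missing values use the sentinel :data:`MISSING`.
    """

    founder_ids: tuple[str, ...]
    founder_alleles: np.ndarray
    offspring_ids: tuple[str, ...]
    offspring_alleles: np.ndarray

    def __post_init__(self) -> None:
        self.founder_alleles = np.asarray(self.founder_alleles, dtype=np.int64)
        self.offspring_alleles = np.asarray(self.offspring_alleles, dtype=np.int64)
        if self.founder_alleles.shape[0] != len(self.founder_ids):
            raise InputError("founder_alleles rows != founder ids")
        if self.offspring_alleles.shape[:1] != (len(self.offspring_ids),):
            raise InputError("offspring_alleles rows != offspring ids")
        if self.offspring_alleles.ndim != 3 or self.offspring_alleles.shape[2] != 2:
            raise InputError("offspring_alleles must have shape (n, markers, 2)")
        if self.founder_alleles.shape[1] != self.offspring_alleles.shape[1]:
            raise InputError("founder and offspring marker counts differ")

    @property
    def n_markers(self) -> int:
        return self.founder_alleles.shape[1]

    def founder_row(self, founder: str) -> np.ndarray:
        return self.founder_alleles[self.founder_ids.index(founder)]

    def offspring_rows(self, ids: tuple[str, ...]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.offspring_ids)}
        try:
            idx = [lookup[g] for g in ids]
        except KeyError as e:
            raise InputError(f"genotype {e.args[0]!r} absent from marker data") from e
        return self.offspring_alleles[idx]


# ---------------------------------------------------------------------------
# Evaluation grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalGrid:
    """Genome positions at which models are evaluated.

    Sorted by chromosome (map order) then position.  ``is_marker`` flags
    grid points coinciding (within :data:`POSITION_TOL` cM) with a mapped
    marker.
    """

    chromosomes: tuple[str, ...]
    positions: tuple[float, ...]
    is_marker: tuple[bool, ...]

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def chromosome_slice(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.chromosomes, dtype=object) == chrom)

    def index_of(self, chrom: str, position: float, tol: float = 1e-6) -> int:
        """Index of the grid point at (chrom, position), within *tol* cM."""
        for i in self.chromosome_slice(chrom):
            if abs(self.positions[i] - position) <= tol:
                return int(i)
        raise InputError(f"no grid position at {chrom}:{position} (tol {tol} cM)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chromosome": self.chromosomes, "position": self.positions,
             "is_marker": self.is_marker}
        )


def build_grid(gmap: GeneticMap, step_cM: float) -> EvalGrid:
    """Build the evaluation grid: regular *step_cM* spacing per chromosome.

    The grid is anchored at the first marker of each chromosome and
    advances in steps of *step_cM*, truncated at the last marker; the
    last-marker position is appended if the progression does not land on
    it.  Points within :data:`POSITION_TOL` of a mapped marker are flagged
    ``is_marker``.
    """
    if not step_cM > 0:
        raise InputError(f"step_cM must be > 0, got {step_cM}")
    chroms: list[str] = []
    positions: list[float] = []
    flags: list[bool] = []
    for chrom in gmap.chromosome_names:
        mpos = gmap.chromosome_positions(chrom)
        first, last = mpos[0], mpos[-1]
        span = last - first
        n_steps = int(np.floor(span / step_cM + POSITION_TOL))
        pts = [first + k * step_cM for k in range(n_steps + 1)]
        if last - pts[-1] > POSITION_TOL:
            pts.append(last)
        for p in pts:
            chroms.append(chrom)
            positions.append(float(p))
            flags.append(bool(np.any(np.abs(mpos - p) <= POSITION_TOL)))
    return EvalGrid(tuple(chroms), tuple(positions), tuple(flags))
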