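"""Core data containers shared across the package.

The containers are thin dataclasses over numpy arrays / pandas frames:
a :class:`GeneticMap` (ordered markers with genetic and physical
coordinates), a :class:`GenotypeMatrix` (RIL x marker numeric codes with
family labels), simulation ground truth (:class:`SimTruth`), field-trial
design parameters (:class:`FieldDesign`), and the result records produced
by the mapping procedures (:class:`ScanResult`, :class:`QTLRecord`,
:class:`QTLModel`).

Genotype codes follow the biparental RIL convention: 0 = homozygous for
the common (reference) parent allele, 1 = heterozygous, 2 = homozygous for
the family's alternative parent allele; missing calls are ``numpy.nan``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "GenotypeMatrix",
    "SimTruth",
    "FieldDesign",
    "ScanConfig",
    "ScanResult",
    "QTLRecord",
    "QTLModel",
]


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map.

    Markers must be sorted by (chromosome, position) and carry both a
    genetic position (cM, nondecreasing within chromosome) and a physical
    position (bp, positive, nondecreasing within chromosome).
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    genetic_pos: np.ndarray
    physical_pos: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_id", np.asarray(self.marker_id, dtype=object))
        object.__setattr__(self, "chromosome", np.asarray(self.chromosome, dtype=int))
        object.__setattr__(self, "genetic_pos", np.asarray(self.genetic_pos, dtype=float))
        object.__setattr__(self, "physical_pos", np.asarray(self.physical_pos, dtype=np.int64))
        n = len(self.marker_id)
        if not (len(self.chromosome) == len(self.genetic_pos) == len(self.physical_pos) == n):
            raise ValueError("map field lengths differ")
        if len(set(self.marker_id)) != n:
            raise ValueError("marker ids are not unique")
        if np.any(self.physical_pos <= 0):
            raise ValueError("physical positions must be positive")
        if np.any(self.genetic_pos < 0):
            raise ValueError("genetic positions must be nonnegative")
        for c in np.unique(self.chromosome):
            sel = self.chromosome == c
            g = self.genetic_pos[sel]
            p = self.physical_pos[sel]
            if np.any(np.diff(g) < 0) or np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted within chromosome {c}")

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chromosome)

    def index_of(self, marker: str) -> int:
        hits = np.flatnonzero(self.marker_id == marker)
        if hits.size == 0:
            raise KeyError(f"marker {marker!r} not in map")
        return int(hits[0])

    def subset(self, idx: np.ndarray) -> "GeneticMap":
        return GeneticMap(
            self.marker_id[idx],
            self.chromosome[idx],
            self.genetic_pos[idx],
            self.physical_pos[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.marker_id,
                "chromosome": self.chromosome,
                "genetic_pos_cm": self.genetic_pos,
                "physical_pos_bp": self.physical_pos,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        return cls(
            df["marker"].to_numpy(dtype=object),
            df["chromosome"].to_numpy(),
            df["genetic_pos_cm"].to_numpy(),
            df["physical_pos_bp"].to_numpy(),
        )


@dataclass
class GenotypeMatrix:
    """RIL x marker numeric genotype codes with family labels.

    ``codes`` is float-valued with entries in {0, 1, 2} and ``nan`` for
    missing. ``ref_alleles``/``alt_alleles`` (optional, one nucleotide per
    marker) record which physical allele each code refers to; ``imputed``
    (optional bool mask) flags cells filled by imputation.
    """

    codes: np.ndarray
    ril_ids: np.ndarray
    family: np.ndarray
    gmap: GeneticMap
    ref_parent: str = "B73"
    alt_parents: dict = field(default_factory=dict)
    ref_alleles: np.ndarray | None = None
    alt_alleles: np.ndarray | None = None
    imputed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        self.ril_ids = np.asarray(self.ril_ids, dtype=object)
        self.family = np.asarray(self.family, dtype=object)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (RIL x marker)")
        n, m = self.codes.shape
        if len(self.ril_ids) != n or len(self.family) != n:
            raise ValueError("row labels do not match code matrix")
        if m != self.gmap.n_markers:
            raise ValueError("marker count does not match map")
        vals = self.codes[~np.isnan(self.codes)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("codes must be in {0, 1, 2} or missing")

    @property
    def n_rils(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def families(self) -> list:
        seen: list = []
        for f in self.family:
            if f not in seen:
                seen.append(f)
        return seen

    def rows_of(self, family: str) -> np.ndarray:
        rows = np.flatnonzero(self.family == family)
        if rows.size == 0:
            raise KeyError(f"unknown family {family!r}")
        return rows

    def subset_rils(self, rows: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.codes[rows],
            self.ril_ids[rows],
            self.family[rows],
            self.gmap,
            self.ref_parent,
            dict(self.alt_parents),
            self.ref_alleles,
            self.alt_alleles,
            None if self.imputed is None else self.imputed[rows],
        )

    def subset_markers(self, cols: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.codes[:, cols],
            self.ril_ids,
            self.family,
            self.gmap.subset(cols),
            self.ref_parent,
            dict(self.alt_parents),
            None if self.ref_alleles is None else self.ref_alleles[cols],
            None if self.alt_alleles is None else self.alt_alleles[cols],
            None if self.imputed is None else self.imputed[:, cols],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.codes, columns=list(self.gmap.marker_id))
        df.insert(0, "family", self.family)
        df.insert(0, "ril", self.ril_ids)
        return df

    def to_csv(self, geno_path, map_path) -> None:
        """Write numeric codes (wide CSV) and the map sidecar."""
        self.to_frame().to_csv(geno_path, index=False)
        self.gmap.to_frame().to_csv(map_path, index=False)

    @classmethod
    def from_csv(cls, geno_path, map_path, ref_parent: str = "B73") -> "GenotypeMatrix":
        gmap = GeneticMap.from_frame(pd.read_csv(map_path))
        df = pd.read_csv(geno_path)
        codes = df[list(gmap.marker_id)].to_numpy(dtype=float)
        return cls(
            codes,
            df["ril"].to_numpy(dtype=object),
            df["family"].to_numpy(dtype=object),
            gmap,
            ref_parent=ref_parent,
        )


@dataclass
class SimTruth:
    """Ground truth of a simulated trait: QTL positions/effects and target h2.

    ``qtl`` holds ``(marker_index, additive_effect)`` pairs; the effect is in
    trait units per unit of the 0/1/2 allele code (so a homozygote
    substitution changes the trait by ``2 * effect``). ``h2`` is the fraction
    of phenotypic variance attributable to the QTL genetic values;
    ``family_offsets`` are fixed per-family mean shifts added on top.
    ``null_sd`` is the residual standard deviation used when ``h2 == 0``.
    """

    qtl: list
    h2: float
    family_offsets: dict = field(default_factory=dict)
    null_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if self.null_sd < 0:
            raise ValueError("null_sd must be nonnegative")
        self.qtl = [(int(i), float(a)) for i, a in self.qtl]

    def validate_for(self, geno: GenotypeMatrix) -> None:
        for i, _ in self.qtl:
            if not 0 <= i < geno.n_markers:
                raise ValueError(f"QTL marker index {i} outside map")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "qtl": [[i, a] for i, a in self.qtl],
                    "h2": self.h2,
                    "family_offsets": self.family_offsets,
                    "null_sd": self.null_sd,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            [(int(i), float(a)) for i, a in d["qtl"]],
            float(d["h2"]),
            dict(d.get("family_offsets", {})),
            float(d.get("null_sd", 1.0)),
        )


@dataclass(frozen=True)
class FieldDesign:
    """Augmented incomplete-block field design.

    Each block holds ``block_size`` plots of which ``checks_per_block`` are
    replicated check lines (the common parent plus one rotating founder);
    with 20 test lines + 2 checks per block ~10% of plots are checks. Year
    and block-within-year effects are independent normal deviates.
    """

    block_size: int = 22
    checks_per_block: int = 2
    years: Sequence = (1, 2)
    block_effect_sd: float = 1.0
    year_effect_sd: float = 1.0
    residual_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.checks_per_block < 1 or self.block_size <= self.checks_per_block:
            raise ValueError("need block_size > checks_per_block >= 1")
        if min(self.block_effect_sd, self.year_effect_sd, self.residual_sd) < 0:
            raise ValueError("effect standard deviations must be nonnegative")
        if len(self.years) < 1:
            raise ValueError("at least one year required")

    @property
    def check_fraction(self) -> float:
        return self.checks_per_block / self.block_size

    @property
    def entries_per_block(self) -> int:
        return self.block_size - self.checks_per_block


@dataclass(frozen=True)
class ScanConfig:
    """Configuration for permutation thresholds and stepwise selection.

    ``n_permutations`` defaults to 200 (single-family convention); joint
    linkage conventionally uses 1000 per-family permutations. ``lod_drop``
    sets the support-interval drop in LOD units. ``recompute_threshold``
    re-derives the permutation threshold after each accepted marker
    (default off: the unconditioned threshold is reused).
    """

    n_permutations: int = 200
    alpha: float = 0.05
    seed: int = 0
    lod_drop: float = 1.0
    recompute_threshold: bool = False
    max_steps: int | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.lod_drop <= 0:
            raise ValueError("lod_drop must be positive")


@dataclass
class ScanResult:
    """Per-marker scan output aligned with the genetic map.

    ``p_values``/``lod`` are ``nan`` for markers in the conditioned set.
    ``collinear`` flags markers whose residual variance (given the
    conditioned design) vanished; their p is recorded as 1.
    """

    gmap: GeneticMap
    p_values: np.ndarray
    lod: np.ndarray
    conditioned: list
    n_used: int
    collinear: np.ndarray

    def best_marker(self) -> int:
        """Index of the minimum-p marker; ties broken by (chromosome, position)."""
        p = self.p_values
        finite = ~np.isnan(p)
        if not finite.any():
            raise ValueError("scan contains no testable markers")
        pmin = np.nanmin(p)
        cand = np.flatnonzero(finite & (p == pmin))
        order = np.lexsort((self.gmap.physical_pos[cand], self.gmap.chromosome[cand]))
        return int(cand[order[0]])

    def to_frame(self) -> pd.DataFrame:
        df = self.gmap.to_frame()
        df["p_value"] = self.p_values
        df["lod"] = self.lod
        df["collinear"] = self.collinear
        return df


@dataclass
class QTLRecord:
    step: int
    marker_id: str
    family: str
    chromosome: int
    peak_position_mb: float
    p_value: float
    tpve: float
    effect_size: float
    interval_mb: tuple


@dataclass
class QTLModel:
    """Ordered QTL records from stepwise selection plus the final model fit."""

    records: list
    threshold: float
    final_r2: float
    nested_effects: pd.DataFrame | None = None

    @property
    def markers(self) -> list:
        return [r.marker_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "Step": r.step,
                    "Marker": r.marker_id,
                    "Family": r.family,
                    "Chr": r.chromosome,
                    "Peak position (Mb)": round(r.peak_position_mb, 1),
                    "P-value": r.p_value,
                    "TPVE (%)": round(r.tpve, 2),
                    "Effect size": r.effect_size,
                    "1 LOD interval (Mb)": f"{r.interval_mb[0]:.1f}-{r.interval_mb[1]:.1f}",
                }
            )
        cols = [
            "Step",
            "Marker",
            "Family",
            "Chr",
            "Peak position (Mb)",
            "P-value",
            "TPVE (%)",
            "Effect size",
            "1 LOD interval (Mb)",
        ]
        return pd.DataFrame(rows, columns=cols)
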