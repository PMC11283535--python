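"""Species populations from peak intensities and two-state K_d estimation.

Coexisting species in slow exchange give separate cross-peaks whose
intensities are proportional to the species populations.  Per residue,
the fraction of species s is I_s / Σ_t I_t; the population estimate is
the mean of those per-residue fractions over residues where every
species is observed, with the across-residue SD reported as dispersion.

With two species labelled bound/free and a ligand in large excess over
the protein, the dissociation constant follows from
K_d = L_total · p_free / p_bound (free ligand ≈ total); an exact
mass-balance correction is available when the protein concentration is
supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_RESIDUES = 20


@dataclass
class IntensityTable:
    """Per-(residue, species) peak intensities.

    ``data`` is indexed by residue number with one non-negative intensity
    column per species (NaN = unobserved).
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.data.shape[1] < 2:
            raise ValueError("need at least two species columns")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate residue rows")
        values = self.data.to_numpy(dtype=float)
        if np.nanmin(values) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def species_labels(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def from_csv(cls, path: str | Path) -> "IntensityTable":
        df = pd.read_csv(path)
        if "residue_number" not in df.columns:
            raise ValueError(f"{path}: missing residue_number column")
        return cls(df.set_index("residue_number"))

    def write_csv(self, path: str | Path) -> None:
        self.data.reset_index().to_csv(path, index=False)


@dataclass(frozen=True)
class SpeciesPopulations:
    """Fractional populations with across-residue dispersion."""

    fractions: dict[str, float]
    dispersion: dict[str, float]
    n_residues: int

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, not 1")
        if any(not 0.0 <= f <= 1.0 for f in self.fractions.values()):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class KdEstimate:
    """Two-state dissociation constant from bound/free populations."""

    kd_mM: float
    ligand_total_mM: float
    p_bound: float
    p_free: float
    excess_ligand_approximation: bool = True

    def __post_init__(self) -> None:
        if self.kd_mM <= 0:
            raise ValueError("kd must be positive")
        if abs(self.p_bound + self.p_free - 1.0) > 1e-9:
            raise ValueError("p_bound + p_free must equal 1")

    def summary(self) -> str:
        """One-significant-figure summary, e.g. 'Kd(MgT) ~ 2 mM'."""
        return f"Kd ~ {round_to_sig_figs(self.kd_mM, 1):g} mM"


def round_to_sig_figs(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def estimate_populations(
    table: IntensityTable,
    min_residues: int = DEFAULT_MIN_RESIDUES,
) -> SpeciesPopulations:
    """Mean per-residue intensity fractions over complete rows.

    Rows where any species is missing or the total intensity is zero are
    excluded; fewer than ``min_residues`` surviving rows is an error.
    Invariant under any global intensity scale factor.
    """
    data = table.data
    complete = data.notna().all(axis=1) & (data.sum(axis=1) > 0)
    rows = data[complete]
    n = len(rows)
    if n < min_residues:
        raise ValueError(f"only {n} complete residue rows; "
                         f"min_residues = {min_residues}")
    fractions_per_residue = rows.div(rows.sum(axis=1), axis=0)
    means = fractions_per_residue.mean(axis=0)
    means = means / means.sum()  # exact sum-to-one despite float rounding
    sds = fractions_per_residue.std(axis=0, ddof=1)
    return SpeciesPopulations(dict(means), dict(sds), n)


def estimate_kd(
    p_bound: float,
    p_free: float,
    ligand_total_mM: float,
    protein_total_mM: float | None = None,
) -> KdEstimate:
    """K_d from two-state bound/free populations at a known ligand total.

    Default: excess-ligand approximation K_d = L · p_free / p_bound.
    With ``protein_total_mM`` supplied, the free-ligand depletion is
    corrected exactly: L_free = L_total − p_bound·P_total.
    """
    if ligand_total_mM <= 0:
        raise ValueError("ligand_total must be positive")
    if p_bound <= 0:
        raise ValueError("no bound population")
    if p_free < 0:
        raise ValueError("p_free must be non-negative")
    total = p_bound + p_free
    if abs(total - 1.0) > 1e-9:
        logger.info("renormalising bound/free populations (sum %.6f)", total)
        p_bound, p_free = p_bound / total, p_free / total
    approx = protein_total_mM is None
    ligand_free = (ligand_total_mM if approx
                   else ligand_total_mM - p_bound * protein_total_mM)
    if ligand_free <= 0:
        raise ValueError("free-ligand correction leaves no free ligand")
    kd = ligand_free * p_free / p_bound
    return KdEstimate(kd, ligand_total_mM, p_bound, p_free, approx)


def kd_from_populations(
    populations: SpeciesPopulations,
    ligand_total_mM: float,
    bound_label: str,
    free_label: str,
    protein_total_mM: float | None = None,
) -> KdEstimate:
    """Convenience wrapper selecting bound/free species by label."""
    try:
        p_bound = populations.fractions[bound_label]
        p_free = populations.fractions[free_label]
    except KeyError as exc:
        raise ValueError(f"label {exc} not among "
                         f"{list(populations.fractions)}") from exc
    total = p_bound + p_free
    if total <= 0:
        raise ValueError("bound and free populations are both zero")
    return estimate_kd(p_bound / total, p_free / total, ligand_total_mM,
                       protein_total_mM)


def bound_fraction_from_kd(kd_mM: float, ligand_mM: float) -> float:
    """Two-state excess-ligand isotherm p_bound = L / (L + K_d)."""
    if kd_mM <= 0 or ligand_mM < 0:
        raise ValueError("kd must be positive and ligand non-negative")
    return ligand_mM / (ligand_mM + kd_mM)
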