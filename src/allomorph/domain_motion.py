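"""Interdomain-motion pipeline for two-domain structures.

The cap/core relationship of each structure is expressed relative to a
reference that has been *canonicalised*: rigidly moved so that the
centroid of its cap Cα atoms sits at the origin and the cap's principal
axes coincide with the coordinate axes.  Each structure is then
superposed on the reference twice — once on the shared cap Cα atoms and
once on the shared core Cα atoms — and the rotation carrying the
cap-aligned pose to the core-aligned pose is decomposed into intrinsic
pitch (closing), roll (twisting) and yaw (lateral) angles.  The total
rotation magnitude stands in for the interdomain hinge-closure angle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rigid_geometry import (
    DEFAULT_CONVENTION,
    EulerAngles,
    RigidTransform,
    euler_from_rotation,
    kabsch_superpose,
    principal_axes,
    rotation_angle,
)
from .structure_io import DomainDefinition, StructureModel, pair_shared_atoms, \
    select_domain_coords

logger = logging.getLogger(__name__)

CONFORMER_LABELS = ("open", "NAC_I", "NAC_III", "NAC_III_t", "closed",
                    "unassigned")
#: Euclidean (pitch, roll, yaw) distance beyond which no class is assigned.
DEFAULT_CENTROID_CUTOFF_DEG = 8.0


@dataclass(frozen=True)
class MotionResult:
    """Per-(structure, chain) interdomain motion summary.

    Angles in degrees, RMSD in Å.  ``hinge_angle`` is the total rotation
    magnitude; ``rmsd_to_reference_nonH`` the superposed RMSD over all
    shared protein non-hydrogen atoms.
    """

    structure_id: str
    chain: str
    pitch: float
    roll: float
    yaw: float
    hinge_angle: float
    rmsd_to_reference_nonH: float
    conformer_class: str = "unassigned"
    convention: str = DEFAULT_CONVENTION

    def __post_init__(self) -> None:
        if self.conformer_class not in CONFORMER_LABELS:
            raise ValueError(f"unknown conformer label "
                             f"{self.conformer_class!r}")


def canonicalize_reference(
    reference: StructureModel,
    domains: DomainDefinition | None = None,
    chain: str | None = None,
) -> StructureModel:
    """Rigidly move a reference so its cap principal frame is canonical.

    The returned model has the cap Cα centroid at the origin and the cap
    principal axes along +x (largest variance, the roll axis), +y (pitch)
    and +z (yaw), with axis signs fixed toward the core→cap centroid
    vector.  Idempotent to numerical precision.
    """
    domains = domains or DomainDefinition()
    cap, _ = select_domain_coords(reference, domains, "cap", "ca_only", chain)
    core, _ = select_domain_coords(reference, domains, "core", "ca_only", chain)
    cap_centroid = cap.mean(axis=0)
    orient = cap_centroid - core.mean(axis=0)
    axes, _ = principal_axes(cap, orient_toward=orient)
    coords = (reference.coordinates() - cap_centroid) @ axes
    return reference.with_coordinates(coords)


def _domain_superposition(structure: StructureModel,
                          reference: StructureModel,
                          domains: DomainDefinition,
                          which: str,
                          chain_s: str | None,
                          chain_r: str | None) -> RigidTransform:
    subset = domains.residues(which)
    mob, tgt, _ = pair_shared_atoms(structure, reference, "ca_only",
                                    chain_s, chain_r,
                                    residue_subset=subset)
    return kabsch_superpose(mob, tgt).transform


def interdomain_transform(
    structure: StructureModel,
    canonical_reference: StructureModel,
    domains: DomainDefinition | None = None,
    chain_s: str | None = None,
    chain_r: str | None = None,
) -> RigidTransform:
    """Rotation taking the cap-aligned pose to the core-aligned pose.

    Both superpositions use the Cα atoms shared between the structure and
    the (canonicalised) reference within each domain, so the result is
    expressed in the canonical cap frame.
    """
    domains = domains or DomainDefinition()
    cap_t = _domain_superposition(structure, canonical_reference, domains,
                                  "cap", chain_s, chain_r)
    core_t = _domain_superposition(structure, canonical_reference, domains,
                                   "core", chain_s, chain_r)
    return core_t.compose(cap_t.inverse())


def motion_profile(
    structure: StructureModel,
    canonical_reference: StructureModel,
    domains: DomainDefinition | None = None,
    chain_s: str | None = None,
    chain_r: str | None = None,
    centroids: dict[str, tuple[float, float, float]] | None = None,
    centroid_cutoff: float = DEFAULT_CENTROID_CUTOFF_DEG,
    convention: str = DEFAULT_CONVENTION,
) -> MotionResult:
    """Full motion summary of one structure chain against the reference."""
    domains = domains or DomainDefinition()
    transform = interdomain_transform(structure, canonical_reference, domains,
                                      chain_s, chain_r)
    euler = euler_from_rotation(transform.rotation, convention)
    hinge = rotation_angle(transform.rotation)
    mob, tgt, _ = pair_shared_atoms(structure, canonical_reference, "non_h",
                                    chain_s, chain_r)
    overlay = kabsch_superpose(mob, tgt)
    label = "unassigned"
    if centroids:
        label = classify_conformer(euler.as_tuple(), centroids,
                                   cutoff=centroid_cutoff)
    if chain_s is None:
        chain_s = structure.chain_ids[0]
    return MotionResult(structure.identifier, chain_s, euler.pitch,
                        euler.roll, euler.yaw, hinge, overlay.rmsd, label,
                        euler.convention)


def classify_conformer(
    angles: tuple[float, float, float] | EulerAngles,
    centroids: dict[str, tuple[float, float, float]],
    cutoff: float = DEFAULT_CENTROID_CUTOFF_DEG,
) -> str:
    """Nearest labelled centroid in (pitch, roll, yaw) space (degrees).

    Returns ``"unassigned"`` when the nearest centroid is farther than
    ``cutoff``.  Exact ties are broken by alphabetical label order and
    logged.
    """
    if not centroids:
        raise ValueError("empty centroid set")
    if isinstance(angles, EulerAngles):
        angles = angles.as_tuple()
    point = np.asarray(angles, dtype=float)
    dists = {label: float(np.linalg.norm(point - np.asarray(c, dtype=float)))
             for label, c in centroids.items()}
    best = min(dists.values())
    winners = sorted(lbl for lbl, d in dists.items() if d == best)
    if len(winners) > 1:
        logger.info("conformer tie at distance %.3f between %s; choosing %s",
                    best, winners, winners[0])
    if best > cutoff:
        return "unassigned"
    return winners[0]


def batch_landscape(
    structures: list[StructureModel],
    reference: StructureModel,
    domains: DomainDefinition | None = None,
    centroids: dict[str, tuple[float, float, float]] | None = None,
    chains: dict[str, list[str]] | None = None,
    chain_r: str | None = None,
    centroid_cutoff: float = DEFAULT_CENTROID_CUTOFF_DEG,
) -> pd.DataFrame:
    """Motion profiles for a batch of structures, one row per chain.

    Per-structure failures become rows with an ``error`` note rather than
    aborting the batch.  Duplicate structure identifiers are suffixed.
    Chains are handled independently; ``chains`` optionally restricts the
    chains evaluated per structure id.
    """
    domains = domains or DomainDefinition()
    canonical = canonicalize_reference(reference, domains, chain_r)
    rows = []
    seen: dict[str, int] = {}
    for structure in structures:
        sid = structure.identifier
        seen[sid] = seen.get(sid, 0) + 1
        if seen[sid] > 1:
            new_id = f"{sid}_{seen[sid]}"
            logger.warning("duplicate structure id %r renamed to %r",
                           sid, new_id)
            sid = new_id
        chain_list = (chains or {}).get(structure.identifier,
                                        structure.chain_ids)
        for chain in chain_list:
            base = {"structure_id": sid, "chain": chain}
            try:
                res = motion_profile(structure, canonical, domains, chain,
                                     chain_r, centroids, centroid_cutoff)
                rows.append({**base,
                             "pitch_deg": res.pitch, "roll_deg": res.roll,
                             "yaw_deg": res.yaw,
                             "hinge_angle_deg": res.hinge_angle,
                             "rmsd_nonH_A": res.rmsd_to_reference_nonH,
                             "conformer_class": res.conformer_class,
                             "error": ""})
            except (ValueError, KeyError) as exc:
                logger.warning("motion profile failed for %s chain %s: %s",
                               sid, chain, exc)
                rows.append({**base, "pitch_deg": np.nan, "roll_deg": np.nan,
                             "yaw_deg": np.nan, "hinge_angle_deg": np.nan,
                             "rmsd_nonH_A": np.nan,
                             "conformer_class": "unassigned",
                             "error": str(exc)})
    columns = ["structure_id", "chain", "pitch_deg", "roll_deg", "yaw_deg",
               "hinge_angle_deg", "rmsd_nonH_A", "conformer_class", "error"]
    return pd.DataFrame(rows, columns=columns)
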