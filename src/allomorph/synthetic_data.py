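"""Ground-truthed synthetic inputs for every pipeline stage.

Three generators emulate the study's data shapes without any downloads:

* two-domain Cα structures whose cap has been rotated relative to an
  open reference by known pitch/roll/yaw, with optional coordinate noise;
* multi-species shift tables drawn from a reporter library with stated
  state assignments and Gaussian shift noise;
* per-residue peak-intensity tables at stated species populations with
  log-normal intensity noise.

Each generator is a pure function of its parameters plus seed and
returns the artefact together with a :class:`SyntheticGroundTruth`
record of exactly what was applied, so recovery tests can compare
pipeline output against the truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .rigid_geometry import EulerAngles, principal_axes, rotation_from_euler
from .shift_analysis import ReporterLibrary, ShiftTable
from .populations_binding import IntensityTable
from .structure_io import ATOM_COLUMNS, DomainDefinition, StructureModel

#: Ideal α-helix Cα geometry: rise per residue (Å), radius (Å) and
#: rotation per residue (degrees).
HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
HELIX_TWIST_DEG = 100.0
#: Helix-bundle layout: antiparallel segments on a rectangular grid with
#: deliberately unequal spacings.  A single straight helix would have two
#: equal transverse variances, leaving the principal frame degenerate and
#: the rotation about the long axis poorly constrained under coordinate
#: noise; a compact bundle (like a real globular domain) gives three
#: well-separated variances and a well-conditioned superposition.
CAP_SEGMENTS, CAP_COLUMNS = 4, 2
CORE_SEGMENTS, CORE_COLUMNS = 6, 3
#: Segment spacing is looser than real helix packing: it sets the
#: transverse positional variances, and with them how well coordinate
#: noise is averaged out of the fitted domain rotations.
BUNDLE_DX = 24.0
BUNDLE_DY = 18.0


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """What the generator actually applied, for recovery tests."""

    seed: int
    angles: tuple[float, float, float] | None = None
    convention: str | None = None
    coordinate_noise_A: float | None = None
    populations: dict[str, float] | None = None
    shift_noise_ppm: float | None = None
    intensity_noise: str | None = None
    species_states: dict[str, dict[str, str]] | None = None

    def to_json(self) -> str:
        return json.dumps({k: v for k, v in asdict(self).items()
                           if v is not None}, indent=2, sort_keys=True)


def _helix(n: int) -> np.ndarray:
    """Ideal Cα helix along z (standard rise, radius and twist)."""
    i = np.arange(n, dtype=float)
    theta = np.radians(HELIX_TWIST_DEG) * i
    z = HELIX_RISE * i
    x = HELIX_RADIUS * np.cos(theta)
    y = HELIX_RADIUS * np.sin(theta)
    return np.column_stack([x, y, z])


def _bundle(n: int, n_segments: int, n_columns: int) -> np.ndarray:
    """Antiparallel bundle of ideal helical segments (one Cα trace).

    Segments are laid out on an ``n_columns``-wide rectangular grid with
    unequal x/y spacings so the three positional variances are distinct.
    Consecutive segments run antiparallel, as in a real helix bundle.
    """
    seg_len = -(-n // n_segments)  # ceil
    n_rows = -(-n_segments // n_columns)
    coords = []
    placed = 0
    for s in range(n_segments):
        take = min(seg_len, n - placed)
        if take <= 0:
            break
        seg = _helix(take)
        if s % 2 == 1:                       # antiparallel
            seg[:, 2] = seg[:, 2].max() - seg[:, 2]
        col, row = s % n_columns, s // n_columns
        seg[:, 0] += (col - (n_columns - 1) / 2.0) * BUNDLE_DX
        seg[:, 1] += (row - (n_rows - 1) / 2.0) * BUNDLE_DY
        coords.append(seg)
        placed += take
    return np.vstack(coords)


def _numbering(n_cap: int, n_core: int) -> tuple[list[int], list[int]]:
    """βPGM-like author numbering: core 1..15 then cap then core 88+."""
    pre = min(15, n_core)
    cap_start = pre + 1
    cap_numbers = list(range(cap_start, cap_start + n_cap))
    post_start = cap_start + n_cap
    core_numbers = list(range(1, pre + 1)) + \
        list(range(post_start, post_start + n_core - pre))
    return cap_numbers, core_numbers


def default_domains(n_cap: int = 72, n_core: int = 149) -> DomainDefinition:
    """Domain definition matching the generator's numbering scheme."""
    cap_numbers, core_numbers = _numbering(n_cap, n_core)
    pre = min(15, n_core)
    return DomainDefinition(
        cap_ranges=((cap_numbers[0], cap_numbers[-1]),),
        core_ranges=((1, pre), (core_numbers[pre], core_numbers[-1])),
    )


def make_two_domain_structure(
    n_cap: int = 72,
    n_core: int = 149,
    angles: EulerAngles = EulerAngles(0.0, 0.0, 0.0),
    noise_sigma: float = 0.0,
    seed: int = 0,
    identifier: str | None = None,
) -> tuple[StructureModel, SyntheticGroundTruth]:
    """Two-domain Cα trace with a known cap rotation.

    Each domain is a compact antiparallel helix bundle; the cap sits to
    the side of the hinge residue (the last core residue preceding the
    cap).  The whole model is first expressed in the canonical cap frame
    of the unrotated geometry; the cap is then rotated by exactly
    ``rotation_from_euler(angles)`` about the hinge Cα, and isotropic
    Gaussian noise of width ``noise_sigma`` (Å) is added to every atom.
    The open reference is the same call with angles (0, 0, 0) and zero
    noise.
    """
    if n_cap < 10 or n_core < 10:
        raise ValueError("need at least 10 residues per domain")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    cap_numbers, core_numbers = _numbering(n_cap, n_core)

    core = _bundle(n_core, CORE_SEGMENTS, CORE_COLUMNS)
    hinge_index = min(15, n_core) - 1        # Cα of the last pre-cap residue
    hinge = core[hinge_index]
    cap_local = _bundle(n_cap, CAP_SEGMENTS, CAP_COLUMNS)
    # Cap bundle axis along +x, offset from the hinge in +x/+y/+z so the
    # axis-orientation sign rule has a stable projection on every
    # canonical axis.
    cap = hinge + np.array([34.0, 8.0, 6.0]) + cap_local[:, [2, 0, 1]]

    # Canonicalise the unrotated geometry (same rules as the pipeline).
    cap_centroid = cap.mean(axis=0)
    axes, _ = principal_axes(cap, orient_toward=cap_centroid - core.mean(axis=0))
    cap = (cap - cap_centroid) @ axes
    core = (core - cap_centroid) @ axes
    hinge = (hinge - cap_centroid) @ axes

    R = rotation_from_euler(angles)
    cap = (cap - hinge) @ R.T + hinge

    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        cap = cap + rng.normal(0.0, noise_sigma, cap.shape)
        core = core + rng.normal(0.0, noise_sigma, core.shape)

    rows = []
    for num, pos in zip(cap_numbers, cap):
        rows.append(("A", num, "ALA", "CA", "C", "", 1.0, False, *pos))
    for num, pos in zip(core_numbers, core):
        rows.append(("A", num, "ALA", "CA", "C", "", 1.0, False, *pos))
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    atoms = atoms.sort_values("residue_number", kind="stable",
                              ignore_index=True)
    if identifier is None:
        identifier = (f"synthetic_p{angles.pitch:g}_r{angles.roll:g}"
                      f"_y{angles.yaw:g}_s{seed}")
    truth = SyntheticGroundTruth(seed=seed, angles=angles.as_tuple(),
                                 convention=angles.convention,
                                 coordinate_noise_A=noise_sigma)
    return StructureModel(identifier, atoms), truth


def make_species_shift_tables(
    library: ReporterLibrary,
    species_states: dict[str, dict[str, str]],
    noise_sigma_ppm: float = 0.0,
    n_residues: int = 221,
    seed: int = 0,
) -> tuple[list[ShiftTable], SyntheticGroundTruth]:
    """Shift tables for several species sharing a random baseline.

    ``species_states`` maps species label → {reporter: state}, e.g.
    ``{"sp1": {"A143": "cis", "I84": "NAC_III"}}``.  Reporter residues
    take their library cluster coordinates for the requested state;
    non-reporter residues take a per-residue baseline shared across all
    species, so cross-species correlations are high except where states
    differ.  Gaussian noise of width ``noise_sigma_ppm`` is added to
    every shift of every species independently.
    """
    if noise_sigma_ppm < 0:
        raise ValueError("noise_sigma_ppm must be non-negative")
    rng = np.random.default_rng(seed)
    residues = np.arange(1, n_residues + 1)
    base_hn = rng.normal(8.3, 0.45, n_residues)
    base_n = rng.normal(119.0, 4.0, n_residues)

    reporter_residue = {rep: int(library.points_for(rep)
                                 ["residue_number"].iloc[0])
                        for rep in library.reporters()}
    tables = []
    for label, states in species_states.items():
        hn = base_hn.copy()
        nn = base_n.copy()
        cb = np.full(n_residues, np.nan)
        for reporter, state in states.items():
            point = library.cluster(reporter, state)  # KeyError if missing
            residue = int(point["residue_number"])
            if residue > n_residues:
                raise ValueError(f"reporter residue {residue} beyond "
                                 f"n_residues={n_residues}")
            idx = residue - 1
            if np.isfinite(point["delta_HN"]):
                hn[idx] = point["delta_HN"]
            if np.isfinite(point["delta_N"]):
                nn[idx] = point["delta_N"]
            if np.isfinite(point["delta_CB"]):
                cb[idx] = point["delta_CB"]
        if noise_sigma_ppm > 0:
            hn = hn + rng.normal(0.0, noise_sigma_ppm, n_residues)
            nn = nn + rng.normal(0.0, noise_sigma_ppm, n_residues)
        data = pd.DataFrame({"residue_type": "A", "delta_HN": hn,
                             "delta_N": nn, "delta_CB": cb},
                            index=pd.Index(residues,
                                           name="residue_number"))
        tables.append(ShiftTable(label, data))
    truth = SyntheticGroundTruth(seed=seed, shift_noise_ppm=noise_sigma_ppm,
                                 species_states=species_states)
    return tables, truth


def make_intensity_table(
    populations: dict[str, float],
    n_residues: int = 60,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[IntensityTable, SyntheticGroundTruth]:
    """Peak-intensity table at stated populations with log-normal noise.

    intensity(residue, species) = base(residue) · population · exp(ε),
    ε ~ Normal(0, noise_sigma).  ``populations`` must sum to 1.
    """
    labels = list(populations)
    p = np.array([populations[k] for k in labels], dtype=float)
    if len(labels) < 2:
        raise ValueError("need at least two species")
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("populations must be non-negative and sum to 1")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=np.log(1e5), sigma=0.4, size=n_residues)
    eps = (rng.normal(0.0, noise_sigma, (n_residues, len(labels)))
           if noise_sigma > 0 else np.zeros((n_residues, len(labels))))
    values = base[:, None] * p[None, :] * np.exp(eps)
    data = pd.DataFrame(values, columns=labels,
                        index=pd.Index(np.arange(1, n_residues + 1),
                                       name="residue_number"))
    truth = SyntheticGroundTruth(seed=seed, populations=dict(populations),
                                 intensity_noise=f"lognormal({noise_sigma})")
    return IntensityTable(data), truth
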