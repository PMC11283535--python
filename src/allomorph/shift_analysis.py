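"""Backbone amide chemical-shift analysis.

Covers per-species shift tables (CSV and NMR-STAR 3.1 ingestion), the
weighted chemical-shift-perturbation profile

    Δδ = [(δ_HN,X − δ_HN,Y)² + (0.13 · (δ_N,X − δ_N,Y))²]^½,

reporter-residue state classification (A143/D180 for the cis/trans
peptide-bond isomer, I84/S88 for interdomain closure, A115 ¹HN for MgT
occupancy, P146 ¹³Cβ for cis-proline), and Pearson-correlation species
matching with a Fisher-z two-sample test.

The same 0.13 nitrogen weighting is used both for CSP profiles and as the
2-D distance metric for nearest-cluster classification, so a single
metric governs both analyses.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr

logger = logging.getLogger(__name__)

#: Nitrogen scaling of the weighted amide CSP.
NITROGEN_WEIGHT = 0.13
#: Cluster distance (ppm, weighted) beyond which classification is ambiguous.
DEFAULT_AMBIGUITY_CUTOFF_PPM = 0.25
#: I84 ¹HN boundary separating NAC III (≈7.00 ppm) from NAC IIIᵗ (≈7.17 ppm).
I84_HN_NAC3_BOUNDARY_PPM = (7.00 + 7.17) / 2.0
#: P146 ¹³Cβ reference values (ppm) for cis and trans proline.
PROLINE_CB_CIS_PPM = 35.0
PROLINE_CB_TRANS_PPM = 32.0
#: Library ¹HN upfield displacement of A115 on MgT binding, and the
#: default decision threshold (half the library displacement).
A115_MGT_DISPLACEMENT_PPM = 1.6
DEFAULT_MGT_THRESHOLD_PPM = A115_MGT_DISPLACEMENT_PPM / 2.0

ISOMER_REPORTERS = {"A143": 143, "D180": 180}
CLOSURE_REPORTERS = {"I84": 84, "S88": 88}
MGT_REPORTER_RESIDUE = 115

SHIFT_CSV_COLUMNS = ["residue_number", "residue_type", "delta_HN_ppm",
                     "delta_N_ppm", "delta_CB_ppm"]


@dataclass(frozen=True)
class ShiftRecord:
    """Backbone shifts of one residue (ppm)."""

    residue_number: int
    residue_type: str
    delta_HN: float
    delta_N: float
    delta_CB: float | None = None


@dataclass
class ShiftTable:
    """Per-residue ¹HN/¹⁵N (and optional ¹³Cβ) shifts for one species.

    ``data`` is indexed by residue number with columns ``residue_type``,
    ``delta_HN``, ``delta_N``, ``delta_CB`` (ppm; NaN where unobserved).
    """

    species_label: str
    data: pd.DataFrame = field(repr=False)
    accession: str | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate residue rows {dups} in "
                             f"{self.species_label!r}")
        for col in ("residue_type", "delta_HN", "delta_N", "delta_CB"):
            if col not in self.data.columns:
                if col == "delta_CB":
                    self.data["delta_CB"] = np.nan
                else:
                    raise ValueError(f"shift table missing column {col!r}")
        self.data = self.data.sort_index()
        hn = self.data["delta_HN"].dropna()
        nn = self.data["delta_N"].dropna()
        if ((hn < 5) | (hn > 12)).any() or ((nn < 100) | (nn > 140)).any():
            warnings.warn(f"{self.species_label}: amide shifts outside the "
                          "typical 5-12 ppm (1H) / 100-140 ppm (15N) windows",
                          stacklevel=2)

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_records(cls, species_label: str, records: list[ShiftRecord],
                     accession: str | None = None) -> "ShiftTable":
        df = pd.DataFrame(
            {"residue_type": [r.residue_type for r in records],
             "delta_HN": [r.delta_HN for r in records],
             "delta_N": [r.delta_N for r in records],
             "delta_CB": [np.nan if r.delta_CB is None else r.delta_CB
                          for r in records]},
            index=pd.Index([r.residue_number for r in records],
                           name="residue_number"))
        return cls(species_label, df, accession)

    def write_csv(self, path: str | Path) -> None:
        out = self.data.reset_index()
        out.columns = SHIFT_CSV_COLUMNS
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class CSPProfile:
    """Per-residue weighted Δδ (ppm) between two species.

    Residues missing in either table are absent, not zero.
    """

    pair: tuple[str, str]
    delta: pd.Series = field(repr=False)

    def max_residues(self, n: int = 10) -> pd.Series:
        return self.delta.sort_values(ascending=False).head(n)


@dataclass(frozen=True)
class CorrelationComparison:
    """Pearson agreement of a query species with one candidate."""

    candidate: str
    r_H: float
    r_N: float
    n: int
    z: float
    p: float


class ReporterLibrary:
    """Labelled reference cluster points for the reporter residues.

    Backed by a table with columns ``reporter`` (e.g. "I84"),
    ``residue_number``, ``state`` and the ppm coordinates ``delta_HN``,
    ``delta_N``, ``delta_CB`` (NaN where the library does not constrain
    that dimension).  The bundled library carries only coordinates that
    are published; everything else must be supplied by the user from
    assigned spectra.
    """

    COLUMNS = ["reporter", "residue_number", "state", "delta_HN", "delta_N",
               "delta_CB"]

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"library missing columns: {missing}")
        self.table = table.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReporterLibrary":
        df = pd.read_csv(path)
        df = df.rename(columns={"delta_HN_ppm": "delta_HN",
                                "delta_N_ppm": "delta_N",
                                "delta_CB_ppm": "delta_CB"})
        return cls(df)

    @classmethod
    def bundled(cls) -> "ReporterLibrary":
        """The library shipped with the package (published values only)."""
        with resources.as_file(resources.files("allomorph.data")
                               / "reporter_library.csv") as p:
            return cls.from_csv(p)

    def points_for(self, reporter: str) -> pd.DataFrame:
        return self.table[self.table["reporter"] == reporter]

    def cluster(self, reporter: str, state: str) -> pd.Series:
        rows = self.table[(self.table["reporter"] == reporter)
                          & (self.table["state"] == state)]
        if rows.empty:
            raise KeyError(f"library has no cluster for ({reporter}, {state})")
        return rows.iloc[0]

    def reporters(self) -> list[str]:
        return list(dict.fromkeys(self.table["reporter"]))


def read_shift_table(path: str | Path, format: str = "csv",
                     species_label: str | None = None,
                     accession: str | None = None) -> ShiftTable:
    """Read a per-residue shift table from CSV or NMR-STAR 3.1.

    CSV columns: residue_number, residue_type, delta_HN_ppm, delta_N_ppm
    and optionally delta_CB_ppm.  NMR-STAR ingestion extracts the H, N
    and CB rows of the ``_Atom_chem_shift`` loop.
    """
    path = Path(path)
    label = species_label or path.stem
    if format == "csv":
        df = pd.read_csv(path)
        required = ["residue_number", "residue_type", "delta_HN_ppm",
                    "delta_N_ppm"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        if "delta_CB_ppm" not in df.columns:
            df["delta_CB_ppm"] = np.nan
        if df["residue_number"].duplicated().any():
            raise ValueError(f"{path}: duplicate residue rows")
        data = df.rename(columns={"delta_HN_ppm": "delta_HN",
                                  "delta_N_ppm": "delta_N",
                                  "delta_CB_ppm": "delta_CB"})
        data = data.set_index("residue_number")[
            ["residue_type", "delta_HN", "delta_N", "delta_CB"]]
        return ShiftTable(label, data, accession)
    if format == "nmrstar":
        return _read_nmrstar(path, label, accession)
    raise ValueError(f"unknown shift-table format {format!r}")


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def _read_nmrstar(path: Path, label: str,
                  accession: str | None) -> ShiftTable:
    """Extract backbone H/N/CB shifts from an NMR-STAR 3.1 file.

    NMR-STAR is a STAR dialect, so the save-frame loops are read with
    gemmi's STAR parser.
    """
    import gemmi

    try:
        doc = gemmi.cif.read_file(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as NMR-STAR: {exc}") from exc
    tags = ["Comp_index_ID", "Comp_ID", "Atom_ID", "Val"]
    rows: list[list[str]] = []
    for block in doc:
        table = block.find("_Atom_chem_shift.", tags)
        rows.extend(list(r) for r in table)
        for item in block:
            frame = item.frame
            if frame is not None:
                rows.extend(list(r) for r in frame.find("_Atom_chem_shift.",
                                                        tags))
    if not rows:
        raise ValueError(f"{path}: no _Atom_chem_shift loop found")
    per_res: dict[int, dict[str, float | str]] = {}
    for seq, comp, atom, val in rows:
        if atom not in ("H", "HN", "N", "CB"):
            continue
        num = int(seq)
        entry = per_res.setdefault(num, {"residue_type":
                                         _THREE_TO_ONE.get(comp, "X")})
        key = {"H": "delta_HN", "HN": "delta_HN", "N": "delta_N",
               "CB": "delta_CB"}[atom]
        entry[key] = float(val)
    data = pd.DataFrame.from_dict(per_res, orient="index")
    data.index.name = "residue_number"
    for col in ("delta_HN", "delta_N", "delta_CB"):
        if col not in data.columns:
            data[col] = np.nan
    return ShiftTable(label, data, accession)


def weighted_distance(d_hn: float, d_n: float) -> float:
    """Weighted 2-D amide displacement [(ΔδHN)² + (0.13·ΔδN)²]^½ (ppm).

    NaN in either dimension drops that dimension (a one-dimensional
    library point constrains only the dimension it carries).
    """
    total = 0.0
    seen = False
    if np.isfinite(d_hn):
        total += d_hn ** 2
        seen = True
    if np.isfinite(d_n):
        total += (NITROGEN_WEIGHT * d_n) ** 2
        seen = True
    if not seen:
        return float("nan")
    return math.sqrt(total)


def weighted_csp(x: ShiftTable, y: ShiftTable) -> CSPProfile:
    """Weighted chemical-shift-perturbation profile between two species."""
    shared = x.data.index.intersection(y.data.index)
    dh = x.data.loc[shared, "delta_HN"] - y.data.loc[shared, "delta_HN"]
    dn = x.data.loc[shared, "delta_N"] - y.data.loc[shared, "delta_N"]
    delta = np.sqrt(dh ** 2 + (NITROGEN_WEIGHT * dn) ** 2)
    delta = delta.dropna()
    if delta.empty:
        raise ValueError(f"no shared residues between {x.species_label!r} "
                         f"and {y.species_label!r}")
    delta.name = "delta_ppm"
    return CSPProfile((x.species_label, y.species_label), delta)


def _nearest_cluster(table: ShiftTable, library: ReporterLibrary,
                     reporter: str, residue: int,
                     states: tuple[str, ...] | None = None
                     ) -> tuple[str, float] | None:
    if residue not in table.data.index:
        return None
    row = table.data.loc[residue]
    points = library.points_for(reporter)
    if states is not None:
        points = points[points["state"].isin(states)]
    best: tuple[str, float] | None = None
    for p in points.itertuples(index=False):
        d = weighted_distance(row["delta_HN"] - p.delta_HN,
                              row["delta_N"] - p.delta_N)
        if np.isnan(d):
            continue
        if best is None or d < best[1]:
            best = (p.state, d)
    return best


def _consensus(evidence: dict[str, tuple[str, float]],
               cutoff: float) -> str:
    votes = {state for state, dist in evidence.values() if dist <= cutoff}
    if len(votes) == 1:
        return votes.pop()
    return "ambiguous"


def classify_isomer_state(
    table: ShiftTable,
    library: ReporterLibrary,
    cutoff: float = DEFAULT_AMBIGUITY_CUTOFF_PPM,
) -> tuple[str, dict[str, tuple[str, float]]]:
    """cis/trans peptide-bond isomer state from the A143/D180 reporters.

    Each available reporter votes for its nearest labelled cluster under
    the weighted amide metric; the overall label requires agreement of
    all in-range reporters, otherwise ``"ambiguous"``.
    Returns (label, per-reporter (state, distance) evidence).
    """
    evidence: dict[str, tuple[str, float]] = {}
    for reporter, residue in ISOMER_REPORTERS.items():
        hit = _nearest_cluster(table, library, reporter, residue,
                               states=("cis", "trans"))
        if hit is not None:
            evidence[reporter] = hit
    if not evidence:
        raise ValueError("no isomer reporters (A143/D180) available in both "
                         "table and library")
    return _consensus(evidence, cutoff), evidence


def classify_closure_state(
    table: ShiftTable,
    library: ReporterLibrary,
    cutoff: float = DEFAULT_AMBIGUITY_CUTOFF_PPM,
    i84_boundary: float = I84_HN_NAC3_BOUNDARY_PPM,
) -> tuple[str, dict[str, tuple[str, float]]]:
    """Interdomain closure state from the I84/S88 hinge reporters.

    Nearest-cluster assignment over the closure states; when the
    consensus lands in the NAC III family and I84 ¹HN is observed, the
    sub-rule separates NAC_III (¹HN ≈ 7.00 ppm) from NAC_III_t
    (¹HN ≈ 7.17 ppm) at the configurable midpoint boundary.
    """
    states = ("open", "NAC_I", "NAC_III", "NAC_III_t", "closed")
    evidence: dict[str, tuple[str, float]] = {}
    for reporter, residue in CLOSURE_REPORTERS.items():
        hit = _nearest_cluster(table, library, reporter, residue,
                               states=states)
        if hit is not None:
            evidence[reporter] = hit
    if not evidence:
        raise ValueError("no closure reporters (I84/S88) available in both "
                         "table and library")
    # Consensus over families: the t-distinction is made by the sub-rule.
    fam_evidence = {rep: ("NAC_III_family" if st.startswith("NAC_III") else st,
                          d)
                    for rep, (st, d) in evidence.items()}
    label = _consensus(fam_evidence, cutoff)
    if label == "NAC_III_family":
        label = "NAC_III"
        if 84 in table.data.index:
            hn = table.data.loc[84, "delta_HN"]
            if np.isfinite(hn):
                label = "NAC_III" if hn < i84_boundary else "NAC_III_t"
    return label, evidence


def classify_proline_isomer(
    delta_CB: float,
    cis_reference: float = PROLINE_CB_CIS_PPM,
    trans_reference: float = PROLINE_CB_TRANS_PPM,
    tolerance: float = 1.0,
) -> str:
    """cis/trans proline call from a ¹³Cβ shift (cis ≈ 35.0 ppm)."""
    if not np.isfinite(delta_CB):
        raise ValueError("delta_CB must be finite")
    if abs(delta_CB - cis_reference) <= tolerance:
        return "cis"
    if abs(delta_CB - trans_reference) <= tolerance:
        return "trans"
    return "ambiguous"


def detect_mgt(
    table: ShiftTable,
    reference_table: ShiftTable,
    threshold: float = DEFAULT_MGT_THRESHOLD_PPM,
) -> tuple[str, float]:
    """MgT occupancy from the A115 ¹HN upfield displacement.

    Returns (label, displacement) where displacement is
    δ_HN(reference) − δ_HN(table) at residue 115 (positive = upfield in
    the query).  The query is called MgT_bound when the upfield
    displacement exceeds ``threshold`` (default: half the 1.6 ppm library
    displacement); ``indeterminate`` when A115 is unobserved.
    """
    r = MGT_REPORTER_RESIDUE
    if r not in table.data.index or r not in reference_table.data.index:
        return "indeterminate", float("nan")
    shift = float(table.data.loc[r, "delta_HN"])
    ref = float(reference_table.data.loc[r, "delta_HN"])
    if not (np.isfinite(shift) and np.isfinite(ref)):
        return "indeterminate", float("nan")
    displacement = ref - shift
    return ("MgT_bound" if displacement > threshold else "MgT_free",
            displacement)


def fisher_z_test(r1: float, n1: int, r2: float, n2: int
                  ) -> tuple[float, float]:
    """Two-sample z-test on independent Pearson correlations.

    Uses the Fisher transform z_r = atanh(r) with sampling variance
    1/(n−3): z = (z_r1 − z_r2) / sqrt(1/(n1−3) + 1/(n2−3)); the two-sided
    p-value comes from the standard normal.
    """
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("|r| must be < 1 for the Fisher transform")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("sample sizes must exceed 3")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * float(norm.sf(abs(z)))
    return z, p


def correlation_match(
    query: ShiftTable,
    candidates: list[ShiftTable],
    min_shared: int = 4,
) -> list[CorrelationComparison]:
    """Rank candidate species by shift correlation with the query.

    For each candidate, Pearson r is computed separately over the shared
    residues' ¹HN and ¹⁵N shifts; candidates are ranked by the
    conservative min(r_H, r_N).  Each entry carries the Fisher-z
    statistic of its min-r against the top-ranked candidate's (the top
    candidate has z = 0, p = 1 by construction).
    """
    scored = []
    for cand in candidates:
        shared = query.data.index.intersection(cand.data.index)
        sub_q = query.data.loc[shared, ["delta_HN", "delta_N"]]
        sub_c = cand.data.loc[shared, ["delta_HN", "delta_N"]]
        ok = sub_q.notna().all(axis=1) & sub_c.notna().all(axis=1)
        n = int(ok.sum())
        if n < min_shared:
            logger.info("skipping %s: only %d shared residues",
                        cand.species_label, n)
            continue
        r_h = float(pearsonr(sub_q.loc[ok, "delta_HN"],
                             sub_c.loc[ok, "delta_HN"]).statistic)
        r_n = float(pearsonr(sub_q.loc[ok, "delta_N"],
                             sub_c.loc[ok, "delta_N"]).statistic)
        scored.append((cand.species_label, r_h, r_n, n))
    if not scored:
        raise ValueError("no candidate shares at least "
                         f"{min_shared} residues with the query")
    scored.sort(key=lambda s: min(s[1], s[2]), reverse=True)
    top_r = min(scored[0][1], scored[0][2])
    top_n = scored[0][3]
    out = []
    for label, r_h, r_n, n in scored:
        r_min = min(r_h, r_n)
        if label == scored[0][0] or abs(r_min) >= 1.0 or abs(top_r) >= 1.0:
            z, p = (0.0, 1.0) if label == scored[0][0] else (float("nan"),
                                                             float("nan"))
        else:
            z, p = fisher_z_test(top_r, top_n, r_min, n)
        out.append(CorrelationComparison(label, r_h, r_n, n, z, p))
    return out
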