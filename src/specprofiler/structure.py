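"""Structural comparison and interface analysis.

Covers the structural-validation arm of the inhibitor campaign: Kabsch
superposition and target-aligned RMSD between design models and crystal
structures (including multi-copy asymmetric units), Shrake-Rupley
solvent-accessible surface area and the buried interface area of a
complex, Calpha distance mapping of lysine-specific chemical cross-links
(DSS/BS3 span ~30 A, DSG ~26 A), and docking-funnel statistics (mean of
the 100 best local and global docking scores).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

# ---------------------------------------------------------------------------
# structure model

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

# van der Waals radii (A) for heavy atoms; hydrogens are ignored by SASA.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90,
    "H": 1.20, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray
    occupancy: float = 1.0


@dataclass
class Residue:
    number: int
    icode: str
    name: str                     # three-letter code
    atoms: dict = field(default_factory=dict)   # atom name -> Atom
    het: bool = False

    @property
    def aa(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    @property
    def ca(self) -> np.ndarray | None:
        atom = self.atoms.get("CA")
        return atom.xyz if atom is not None else None

    @property
    def key(self) -> tuple:
        return (self.number, self.icode)


@dataclass
class StructureModel:
    chains: dict                  # chain id -> list[Residue]
    metadata: dict = field(default_factory=dict)

    def residues(self, chain: str, include_het: bool = False):
        if chain not in self.chains:
            raise KeyError(f"no chain {chain!r} in model")
        return [r for r in self.chains[chain] if include_het or not r.het]

    def ca_coords(self, chain: str) -> np.ndarray:
        coords = [r.ca for r in self.residues(chain) if r.ca is not None]
        return np.array(coords, dtype=float)

    def find_residue(self, chain: str, number: int, icode: str = "") -> Residue | None:
        for r in self.chains.get(chain, []):
            if r.number == number and r.icode == icode:
                return r
        return None

    def heavy_atoms(self, chains=None) -> tuple[np.ndarray, list[str]]:
        """Coordinates and elements of protein heavy atoms (waters/het excluded)."""
        coords, elements = [], []
        for cid, residues in self.chains.items():
            if chains is not None and cid not in chains:
                continue
            for res in residues:
                if res.het:
                    continue
                for atom in res.atoms.values():
                    if atom.element.upper() == "H":
                        continue
                    coords.append(atom.xyz)
                    elements.append(atom.element.upper())
        return np.array(coords, dtype=float), elements


def parse_structure(path) -> StructureModel:
    """Load a PDB or mmCIF file (first model).

    Waters and other non-polymer residues are kept but flagged ``het``;
    alternate locations collapse to the highest-occupancy conformer.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    chains: dict = {}
    for chain in st[0]:
        residues = []
        for res in chain:
            het = res.het_flag == "H" or res.name == "HOH" or res.name not in THREE_TO_ONE
            atoms: dict = {}
            for atom in res:
                if not np.isfinite([atom.pos.x, atom.pos.y, atom.pos.z]).all():
                    raise ValueError(f"{path}: non-finite coordinates in {res.name}")
                prev = atoms.get(atom.name)
                if prev is None or atom.occ > prev.occupancy:
                    atoms[atom.name] = Atom(
                        name=atom.name, element=atom.element.name.upper(),
                        xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=atom.occ)
            residues.append(Residue(number=res.seqid.num,
                                    icode=(res.seqid.icode or "").strip(),
                                    name=res.name, atoms=atoms, het=het))
        chains[chain.name] = residues
    return StructureModel(chains=chains, metadata={"source": str(path)})


def write_pdb(model: StructureModel, path) -> None:
    """Write the model in PDB format via gemmi."""
    import gemmi

    st = gemmi.Structure()
    st.name = str(model.metadata.get("source", "model"))
    md = gemmi.Model("1")
    for cid, residues in model.chains.items():
        chain = gemmi.Chain(cid)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            gres.het_flag = "H" if res.het else "A"
            for atom in res.atoms.values():
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.xyz)
                ga.occ = atom.occupancy
                gres.add_atom(ga)
            chain.add_residue(gres)
        md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


def transform_model(model: StructureModel, rotation: np.ndarray,
                    translation: np.ndarray) -> StructureModel:
    """Apply x -> R x + t to every atom; returns a new model."""
    chains = {}
    for cid, residues in model.chains.items():
        new_res = []
        for res in residues:
            atoms = {name: replace(a, xyz=rotation @ a.xyz + translation)
                     for name, a in res.atoms.items()}
            new_res.append(replace(res, atoms=atoms))
        chains[cid] = new_res
    return StructureModel(chains=chains, metadata=dict(model.metadata))


# ---------------------------------------------------------------------------
# superposition


def kabsch_superpose(x: np.ndarray, y: np.ndarray):
    """Least-squares rigid superposition of point set x onto y.

    Returns (rotation, translation, rmsd) with det(rotation) = +1 and
    rmsd the minimized root-mean-square deviation of (R x + t) from y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("point sets must have identical shape")
    if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 3:
        raise ValueError("need at least 3 points in 3D")
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    # collinear (or coincident) sets have no unique rotation
    if (np.linalg.matrix_rank(x0, tol=1e-8) < 2
            or np.linalg.matrix_rank(y0, tol=1e-8) < 2):
        raise ValueError("degenerate (collinear) point set")
    h = x0.T @ y0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = yc - rot @ xc
    diff = (x0 @ rot.T) - y0
    rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    return rot, trans, rmsd


def _matched_ca(model_a: StructureModel, chain_a: str,
                model_b: StructureModel, chain_b: str):
    """Calpha pairs matched by residue number + insertion code."""
    res_a = {r.key: r.ca for r in model_a.residues(chain_a) if r.ca is not None}
    res_b = {r.key: r.ca for r in model_b.residues(chain_b) if r.ca is not None}
    common = sorted(set(res_a) & set(res_b))
    xa = np.array([res_a[k] for k in common])
    xb = np.array([res_b[k] for k in common])
    return xa, xb


def aligned_partner_rmsd(model_a: StructureModel, model_b: StructureModel,
                         align_chain_pair: tuple, measure_chain_pair: tuple) -> float:
    """RMSD of one binding partner after superposing on the other.

    Superpose the align chains' Calpha sets (model_a onto model_b), then,
    WITHOUT refitting, measure the Calpha RMSD between the measure chains.
    This is how a design model's inhibitor placement is compared to the
    crystal structure after aligning the shared target protein.
    """
    xa, xb = _matched_ca(model_a, align_chain_pair[0], model_b, align_chain_pair[1])
    if len(xa) < 3:
        raise ValueError("fewer than 3 matched Calpha in the align chains")
    rot, trans, _ = kabsch_superpose(xa, xb)
    ma, mb = _matched_ca(model_a, measure_chain_pair[0], model_b, measure_chain_pair[1])
    if len(ma) < 3:
        raise ValueError("fewer than 3 matched Calpha in the measure chains")
    diff = (ma @ rot.T + trans) - mb
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))


def multi_copy_rmsd(model_a: StructureModel, model_b: StructureModel,
                    pairs: list) -> tuple[list[float], float]:
    """Per-copy aligned-partner RMSDs and their mean.

    ``pairs`` lists (align_chain_pair, measure_chain_pair) for each copy of
    the complex in the asymmetric unit.
    """
    values = [aligned_partner_rmsd(model_a, model_b, align, measure)
              for align, measure in pairs]
    return values, float(np.mean(values))


# ---------------------------------------------------------------------------
# solvent-accessible surface area


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sasa_from_coords(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
                     n_points: int = 960) -> np.ndarray:
    """Shrake-Rupley per-atom solvent-accessible areas.

    Each atom's solvent sphere (radius r_i + probe) is sampled at
    ``n_points`` test points; a point is accessible if it lies outside
    every neighbor's solvent sphere. Area_i = accessible fraction times
    4 pi (r_i + probe)^2.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) != len(radii):
        raise ValueError("coords must be (n, 3) with one radius per atom")
    n = len(coords)
    unit = _sphere_points(n_points)
    solv = radii + probe
    tree = cKDTree(coords)
    max_reach = 2 * solv.max()
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + solv[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > solv[j] ** 2
            if not accessible.any():
                break
        areas[i] = accessible.mean() * 4.0 * np.pi * solv[i] ** 2
    return areas


def shrake_rupley_sasa(model: StructureModel, probe: float = 1.4,
                       n_points: int = 960, chains=None,
                       default_radius: float | None = None) -> float:
    """Total SASA (A^2) of the model's protein heavy atoms."""
    coords, elements = model.heavy_atoms(chains=chains)
    if len(coords) == 0:
        raise ValueError("no heavy atoms selected")
    radii = []
    for el in elements:
        r = VDW_RADII.get(el, default_radius)
        if r is None:
            raise ValueError(f"no van der Waals radius for element {el!r}")
        radii.append(r)
    return float(sasa_from_coords(coords, np.array(radii), probe, n_points).sum())


def buried_surface_area(complex_model: StructureModel, side_a, side_b,
                        probe: float = 1.4, n_points: int = 960) -> float:
    """Two-sided buried area: SASA(A) + SASA(B) - SASA(AB).

    Both sides' lost areas are summed (the common "total BSA" convention);
    waters and heteroatoms are excluded throughout.
    """
    side_a, side_b = set(side_a), set(side_b)
    if not side_a or not side_b:
        raise ValueError("both sides must name at least one chain")
    if side_a & side_b:
        raise ValueError("sides must be disjoint")
    sasa_a = shrake_rupley_sasa(complex_model, probe, n_points, chains=side_a)
    sasa_b = shrake_rupley_sasa(complex_model, probe, n_points, chains=side_b)
    sasa_ab = shrake_rupley_sasa(complex_model, probe, n_points,
                                 chains=side_a | side_b)
    return sasa_a + sasa_b - sasa_ab


def interface_expansion(design_complex: StructureModel, reference_complex: StructureModel,
                        design_sides: tuple, reference_sides: tuple,
                        probe: float = 1.4, n_points: int = 960) -> float:
    """How much larger the designed interface is than the reference one.

    BSA(design complex) - BSA(reference complex), in A^2. The reference is
    typically the same target bound to a classic BH3 peptide.
    """
    bsa_design = buried_surface_area(design_complex, *design_sides,
                                     probe=probe, n_points=n_points)
    bsa_ref = buried_surface_area(reference_complex, *reference_sides,
                                  probe=probe, n_points=n_points)
    return bsa_design - bsa_ref


# ---------------------------------------------------------------------------
# chemical cross-links

REAGENT_SPACER = {"DSS": 11.4, "BS3": 11.4, "DSG": 7.7}   # A
REAGENT_LIMIT = {"DSS": 30.0, "BS3": 30.0, "DSG": 26.0}   # Calpha-Calpha, A


@dataclass
class CrossLinkRecord:
    """A lysine-lysine cross-link and its mapping onto a structure."""

    chain_a: str
    res_a: int
    chain_b: str
    res_b: int
    reagents: frozenset
    ca_distance: float | None = None
    satisfied: bool | None = None
    mappable: bool = True

    def __post_init__(self) -> None:
        self.reagents = frozenset(self.reagents)
        if not self.reagents:
            raise ValueError("a cross-link needs at least one reagent")
        unknown = self.reagents - set(REAGENT_LIMIT)
        if unknown:
            raise ValueError(f"unknown reagent(s): {sorted(unknown)}")

    @property
    def distance_limit(self) -> float:
        """Limit of the most permissive reagent that detected the link."""
        return max(REAGENT_LIMIT[r] for r in self.reagents)

    @property
    def support_level(self) -> int:
        return len(self.reagents)


def map_crosslinks(model: StructureModel, links: list[CrossLinkRecord],
                   chain_map: dict | None = None) -> list[CrossLinkRecord]:
    """Fill Calpha distances and satisfied flags for each cross-link.

    ``chain_map`` renames link chain ids to model chain ids. Links whose
    endpoints are unresolved in the model are flagged unmappable. Endpoints
    that are not lysine draw a warning (protein termini also cross-link)
    but are still mapped.
    """
    chain_map = chain_map or {}
    out = []
    for link in links:
        ca_pts = []
        for chain, resnum in ((link.chain_a, link.res_a), (link.chain_b, link.res_b)):
            res = model.find_residue(chain_map.get(chain, chain), resnum)
            if res is None or res.ca is None:
                ca_pts = None
                break
            if res.name != "LYS":
                warnings.warn(
                    f"cross-link endpoint {chain}/{resnum} is {res.name}, not LYS")
            ca_pts.append(res.ca)
        if ca_pts is None:
            out.append(replace(link, ca_distance=None, satisfied=None, mappable=False))
            continue
        dist = float(np.linalg.norm(ca_pts[0] - ca_pts[1]))
        out.append(replace(link, ca_distance=dist,
                           satisfied=dist <= link.distance_limit, mappable=True))
    return out


def crosslink_support_summary(mapped: list[CrossLinkRecord]) -> pd.DataFrame:
    """Satisfied/total counts by reagent-support level (3, 2, 1).

    Links detected by more reagents are higher confidence; the summary
    shows whether agreement with the structure tracks that confidence.
    Unmappable links are not counted.
    """
    rows = []
    usable = [l for l in mapped if l.mappable and l.satisfied is not None]
    for level in (3, 2, 1):
        group = [l for l in usable if l.support_level == level]
        satisfied = sum(1 for l in group if l.satisfied)
        rows.append({"support_level": level, "satisfied": satisfied,
                     "total": len(group),
                     "fraction": satisfied / len(group) if group else np.nan})
    return pd.DataFrame(rows).set_index("support_level")


def read_crosslink_tsv(path) -> list[CrossLinkRecord]:
    """TSV columns: chain_a, res_a, chain_b, res_b, reagents (comma-separated)."""
    df = pd.read_csv(path, sep="\t")
    return [CrossLinkRecord(chain_a=str(r.chain_a), res_a=int(r.res_a),
                            chain_b=str(r.chain_b), res_b=int(r.res_b),
                            reagents=frozenset(str(r.reagents).split(",")))
            for r in df.itertuples()]


def write_crosslink_tsv(links: list[CrossLinkRecord], path) -> None:
    rows = [{"chain_a": l.chain_a, "res_a": l.res_a, "chain_b": l.chain_b,
             "res_b": l.res_b, "reagents": ",".join(sorted(l.reagents)),
             "ca_distance": l.ca_distance, "satisfied": l.satisfied,
             "mappable": l.mappable} for l in links]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# docking funnels


@dataclass
class FunnelStats:
    """Docking-funnel summary.

    ``local_minimum`` / ``global_minimum`` are the mean ddG of the k
    lowest-scoring local / global docking records. The absolute binding
    energy is the local minimum; the relative binding energy is
    local - global (negative when local docking scores better, i.e. the
    bound pose sits in a funnel the global search does not find).
    """

    local_minimum: float
    global_minimum: float
    n_local_used: int
    n_global_used: int

    @property
    def absolute_binding_energy(self) -> float:
        return self.local_minimum

    @property
    def relative_binding_energy(self) -> float:
        return self.local_minimum - self.global_minimum


def funnel_stats(records: pd.DataFrame, k: int = 100) -> FunnelStats:
    """Mean ddG of the k best local and global docking records.

    ``records`` needs columns ``ddg`` and ``run`` ("local"/"global"); an
    ``rmsd`` column is carried by the usual score files but not used here.
    If a class has fewer than k records, all of them are averaged (with a
    warning).
    """
    if k < 1:
        raise ValueError("k must be positive")
    means, used = {}, {}
    for run in ("local", "global"):
        scores = records.loc[records["run"] == run, "ddg"].to_numpy(dtype=float)
        if scores.size == 0:
            raise ValueError(f"no {run} docking records")
        if scores.size < k:
            warnings.warn(f"only {scores.size} {run} records; averaging all of them")
        n_used = min(k, scores.size)
        means[run] = float(np.sort(scores)[:n_used].mean())
        used[run] = n_used
    return FunnelStats(local_minimum=means["local"], global_minimum=means["global"],
                       n_local_used=used["local"], n_global_used=used["global"])


def read_dock_tsv(path) -> pd.DataFrame:
    """TSV columns: ddg, rmsd, run."""
    df = pd.read_csv(path, sep="\t")
    missing = {"ddg", "rmsd", "run"} - set(df.columns)
    if missing:
        raise ValueError(f"dock table lacks columns: {sorted(missing)}")
    return df
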