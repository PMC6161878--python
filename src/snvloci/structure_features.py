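"""Structure-based loci features.

Given a variant residue mapped onto one or more homologous PDB structures,
this module computes the per-structure properties of the residue itself
(Kyte-Doolittle hydropathy, relative solvent accessibility, normalized
B-factor, backbone dihedrals / Ramachandran-core membership, binding-site
contacts) and of its structural neighborhood — all residues whose C-alpha
lies within a Euclidean radius (default 9 A) of the variant's C-alpha —
then aggregates the per-structure values across homologous structures into
the 11 structure-based features used by the classifier:

KDmean, RSAmax, nRSA, nNum, Bstddev, nB, nKD, nSC, nBinding, Binding, Mapreg.

Rationale for using several homologous structures: a single crystal
structure is one static snapshot; a binding event or a flexible segment may
be visible in one homolog and absent in another, so features are pooled
across all structures passing the homology threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
from scipy.spatial import cKDTree

from .tables import (
    DEFAULT_VDW_RADIUS,
    KYTE_DOOLITTLE,
    MAX_ASA_THEORETICAL,
    THREE_TO_ONE,
    vdw_radius,
)

__all__ = [
    "Atom", "Residue", "Chain", "Structure", "NeighborSet",
    "StructureFeatureSet", "AggregatedStructureFeatures",
    "parse_structure", "compute_asa", "relative_sa", "backbone_dihedrals",
    "in_core_region", "normalize_bfactors", "find_neighbors",
    "binding_site_types", "per_structure_features", "aggregate_structures",
]

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
DNA_NAMES = {"DA", "DC", "DG", "DT", "DI", "DU"}
RNA_NAMES = {"A", "C", "G", "U", "I", "N"}
METAL_ELEMENTS = {
    "LI", "NA", "K", "RB", "CS", "BE", "MG", "CA", "SR", "BA", "MN", "FE",
    "CO", "NI", "CU", "ZN", "CD", "HG", "AL", "GA", "PB", "PT", "AU", "AG",
    "MO", "W", "V", "CR",
}

# Default Ramachandran "core" boxes (degrees): alpha-helical and beta-sheet
# favored regions.
CORE_ALPHA = ((-180.0, -30.0), (-80.0, -5.0))
CORE_BETA = ((-180.0, -45.0), (90.0, 180.0))

DEFAULT_NEIGHBOR_RADIUS = 9.0
DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_SR_POINTS = 960
BINDING_CONTACT_CUTOFF = 4.5


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # (3,) Angstroms
    b_factor: float = 0.0
    occupancy: float = 1.0


@dataclass
class Residue:
    name: str  # 3-letter code
    number: int  # author numbering
    icode: str = ""
    atoms: List[Atom] = field(default_factory=list)
    chain_id: str = ""
    is_het: bool = False

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[Atom]:
        return self.atom("CA")

    @property
    def id(self) -> tuple:
        return (self.chain_id, self.number, self.icode)


@dataclass
class Chain:
    name: str
    residues: List[Residue] = field(default_factory=list)

    @property
    def polymer_type(self) -> str:
        """Classify by majority residue vocabulary: protein / dna / rna / other."""
        n_aa = sum(1 for r in self.residues if r.name in THREE_TO_ONE)
        n_dna = sum(1 for r in self.residues if r.name in DNA_NAMES)
        n_rna = sum(1 for r in self.residues if r.name in RNA_NAMES)
        best = max(n_aa, n_dna, n_rna)
        if best == 0 or best < len(self.residues) / 2:
            return "other"
        if best == n_aa:
            return "protein"
        return "dna" if n_dna >= n_rna else "rna"


@dataclass
class Structure:
    id: str
    chains: List[Chain] = field(default_factory=list)
    het_groups: List[Residue] = field(default_factory=list)

    def protein_chains(self) -> List[Chain]:
        return [c for c in self.chains if c.polymer_type == "protein"]

    def protein_residues(self) -> List[Residue]:
        return [r for c in self.protein_chains() for r in c.residues]

    def get_residue(self, chain_id: str, number: int, icode: str = "") -> Optional[Residue]:
        for chain in self.chains:
            if chain.name != chain_id:
                continue
            for res in chain.residues:
                if res.number == number and res.icode == icode:
                    return res
        return None


def parse_structure(pdb_text: str, structure_id: str = "") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Uses gemmi for record parsing; alternate locations are resolved to the
    highest-occupancy conformer per atom name, waters are dropped, and
    non-polymer (HETATM) groups are collected separately.
    """
    import gemmi

    if "ATOM" not in pdb_text and "HETATM" not in pdb_text:
        raise ValueError("no ATOM/HETATM records in input")
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no models in input")
    st.setup_entities()
    model = st[0]
    out = Structure(id=structure_id or st.name or "")
    for gchain in model:
        chain = Chain(name=gchain.name)
        for gres in gchain:
            if gres.name in WATER_NAMES:
                continue
            res = Residue(
                name=gres.name,
                number=gres.seqid.num,
                icode=(gres.seqid.icode or "").strip(),
                chain_id=gchain.name,
                is_het=gres.het_flag == "H",
            )
            best_alt: Dict[str, Atom] = {}
            best_occ: Dict[str, float] = {}
            for ga in gres:
                atom = Atom(
                    name=ga.name,
                    element=ga.element.name.upper(),
                    xyz=np.array([ga.pos.x, ga.pos.y, ga.pos.z], dtype=float),
                    b_factor=float(ga.b_iso),
                    occupancy=float(ga.occ),
                )
                if ga.name not in best_alt or atom.occupancy > best_occ[ga.name]:
                    best_alt[ga.name] = atom
                    best_occ[ga.name] = atom.occupancy
            res.atoms = list(best_alt.values())
            if not res.atoms:
                continue
            if res.is_het and res.name not in THREE_TO_ONE:
                out.het_groups.append(res)
            else:
                chain.residues.append(res)
        if chain.residues:
            out.chains.append(chain)
    if not out.chains and not out.het_groups:
        raise ValueError("no residues parsed from input")
    return out


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def compute_asa(
    structure: Structure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SR_POINTS,
    default_radius: float = DEFAULT_VDW_RADIUS,
) -> Dict[tuple, float]:
    """Shrake-Rupley accessible surface area (A^2) per protein residue.

    Each heavy atom is dressed with ``n_points`` quadrature points on its
    solvent-expanded sphere (vdW radius + probe); a point is accessible if
    no other expanded sphere covers it. Deterministic for a given point
    count. Hydrogens are ignored; unknown elements fall back to
    ``default_radius`` with a warning. Returns a dict keyed by residue id.
    """
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable quadrature")
    residues = structure.protein_residues()
    atoms = []
    owners = []
    for res in residues:
        for atom in res.atoms:
            if atom.element == "H":
                continue
            atoms.append(atom)
            owners.append(res.id)
    if not atoms:
        return {}
    coords = np.array([a.xyz for a in atoms])
    radii = np.empty(len(atoms))
    from .tables import VDW_RADII

    warned: Set[str] = set()
    for i, a in enumerate(atoms):
        el = a.element.upper()
        if el not in VDW_RADII and el not in warned:
            warnings.warn(f"unknown element {a.element!r}: using default vdW radius")
            warned.add(el)
        radii[i] = vdw_radius(a.element, default_radius)
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    unit = _sphere_points(n_points)
    asa: Dict[tuple, float] = {rid: 0.0 for rid in set(owners)}
    max_r = expanded.max()
    for i in range(len(atoms)):
        pts = coords[i] + expanded[i] * unit
        neighbor_idx = [
            j for j in tree.query_ball_point(coords[i], expanded[i] + max_r)
            if j != i
            and np.dot(coords[j] - coords[i], coords[j] - coords[i])
            < (expanded[i] + expanded[j]) ** 2
        ]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbor_idx:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > expanded[j] ** 2
            if not accessible.any():
                break
        frac = accessible.sum() / n_points
        asa[owners[i]] += frac * 4.0 * math.pi * expanded[i] ** 2
    return asa


def relative_sa(asa: float, residue_name: str) -> float:
    """ASA divided by the residue type's theoretical maximum (unclipped)."""
    one = THREE_TO_ONE.get(residue_name, residue_name)
    ref = MAX_ASA_THEORETICAL.get(one)
    if ref is None:
        return float("nan")
    return asa / ref


def _dihedral(p0, p1, p2, p3) -> Optional[float]:
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-8 or np.linalg.norm(n2) < 1e-8:
        return None  # collinear backbone, torsion undefined
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def backbone_dihedrals(structure: Structure, residue: Residue):
    """(phi, psi) in degrees for a residue; either may be ``None`` at chain
    termini or when backbone atoms are missing/degenerate."""
    chain = next((c for c in structure.chains if c.name == residue.chain_id), None)
    if chain is None:
        return None, None
    idx = next((i for i, r in enumerate(chain.residues) if r.id == residue.id), None)
    if idx is None:
        return None, None
    n, ca, c = residue.atom("N"), residue.atom("CA"), residue.atom("C")
    phi = psi = None
    if n is not None and ca is not None and c is not None:
        if idx > 0:
            prev_c = chain.residues[idx - 1].atom("C")
            if prev_c is not None:
                phi = _dihedral(prev_c.xyz, n.xyz, ca.xyz, c.xyz)
        if idx < len(chain.residues) - 1:
            next_n = chain.residues[idx + 1].atom("N")
            if next_n is not None:
                psi = _dihedral(n.xyz, ca.xyz, c.xyz, next_n.xyz)
    return phi, psi


def in_core_region(
    phi: Optional[float],
    psi: Optional[float],
    boxes: Sequence = (CORE_ALPHA, CORE_BETA),
) -> Optional[bool]:
    """Whether (phi, psi) falls in a favored Ramachandran box; ``None`` when
    either angle is undefined."""
    if phi is None or psi is None:
        return None
    for (phi_lo, phi_hi), (psi_lo, psi_hi) in boxes:
        if phi_lo <= phi <= phi_hi and psi_lo <= psi <= psi_hi:
            return True
    return False


def normalize_bfactors(structure: Structure) -> Dict[tuple, float]:
    """Per-residue normalized B-factor.

    Atom B-factors are z-scored within each chain (population SD; an SD of
    zero maps everything to 0), making values comparable across structures
    refined on different scales. The residue value is the mean z-score of
    its atoms.
    """
    out: Dict[tuple, float] = {}
    for chain in structure.chains:
        bs = np.array([a.b_factor for r in chain.residues for a in r.atoms])
        if bs.size == 0:
            continue
        mu = bs.mean()
        sd = bs.std()  # population SD
        for res in chain.residues:
            vals = np.array([a.b_factor for a in res.atoms])
            if sd == 0:
                out[res.id] = 0.0
            else:
                out[res.id] = float(((vals - mu) / sd).mean())
    return out


@dataclass
class NeighborSet:
    center: Residue
    radius: float
    members: List[Residue]


def find_neighbors(
    structure: Structure,
    residue: Residue,
    radius: float = DEFAULT_NEIGHBOR_RADIUS,
    metric: str = "ca",
) -> Optional[NeighborSet]:
    """Residues of any protein chain within ``radius`` A of the center.

    ``metric='ca'`` (default) measures C-alpha to C-alpha distance,
    boundary-inclusive; ``metric='heavy'`` uses the minimum heavy-atom pair
    distance. Returns ``None`` when the center residue has no C-alpha (all
    neighborhood features then go missing).
    """
    members: List[Residue] = []
    if metric == "ca":
        center_ca = residue.ca
        if center_ca is None:
            return None
        for other in structure.protein_residues():
            if other.id == residue.id:
                continue
            oca = other.ca
            if oca is None:
                continue
            if np.linalg.norm(oca.xyz - center_ca.xyz) <= radius:
                members.append(other)
    elif metric == "heavy":
        center_xyz = np.array([a.xyz for a in residue.atoms if a.element != "H"])
        if center_xyz.size == 0:
            return None
        for other in structure.protein_residues():
            if other.id == residue.id:
                continue
            oxyz = np.array([a.xyz for a in other.atoms if a.element != "H"])
            if oxyz.size == 0:
                continue
            d = np.sqrt(
                ((center_xyz[:, None, :] - oxyz[None, :, :]) ** 2).sum(-1)
            ).min()
            if d <= radius:
                members.append(other)
    else:
        raise ValueError(f"unknown neighborhood metric {metric!r}")
    return NeighborSet(center=residue, radius=radius, members=members)


def _is_metal_group(group: Residue) -> bool:
    return len(group.atoms) == 1 and group.atoms[0].element in METAL_ELEMENTS


def binding_site_types(
    structure: Structure,
    residues: Iterable[Residue],
    cutoff: float = BINDING_CONTACT_CUTOFF,
) -> Set[str]:
    """Binding-partner types contacted by any of the given residues.

    A contact is a heavy-atom pair within ``cutoff`` A (default 4.5).
    Types: ``metal`` (monoatomic metallic het group), ``ligand`` (any other
    non-water het group), ``nucleic`` (DNA/RNA chain atom), ``protein``
    (atom of a protein residue on a different chain).
    """
    residues = list(residues)
    if not residues:
        return set()
    query_atoms = np.array(
        [a.xyz for r in residues for a in r.atoms if a.element != "H"]
    )
    if query_atoms.size == 0:
        return set()
    tree = cKDTree(query_atoms)
    own_chains = {r.chain_id for r in residues}
    own_ids = {r.id for r in residues}
    types: Set[str] = set()

    def _contacts(xyz: np.ndarray) -> bool:
        return bool(tree.query_ball_point(xyz, cutoff))

    for group in structure.het_groups:
        kind = "metal" if _is_metal_group(group) else "ligand"
        if kind in types:
            continue
        for atom in group.atoms:
            if atom.element != "H" and _contacts(atom.xyz):
                types.add(kind)
                break
    for chain in structure.chains:
        ptype = chain.polymer_type
        if ptype in ("dna", "rna"):
            if "nucleic" in types:
                continue
            for res in chain.residues:
                if any(a.element != "H" and _contacts(a.xyz) for a in res.atoms):
                    types.add("nucleic")
                    break
        elif ptype == "protein" and chain.name not in own_chains:
            if "protein" in types:
                continue
            for res in chain.residues:
                if res.id in own_ids:
                    continue
                if any(a.element != "H" and _contacts(a.xyz) for a in res.atoms):
                    types.add("protein")
                    break
    return types


@dataclass
class StructureFeatureSet:
    """Per-structure feature values at a mapped variant residue."""

    kd: float = float("nan")
    rsa: float = float("nan")
    b_norm: float = float("nan")
    phi: Optional[float] = None
    psi: Optional[float] = None
    in_core: Optional[bool] = None
    binding_types: Set[str] = field(default_factory=set)
    n_num: int = 0
    n_rsa: float = float("nan")
    n_b: float = float("nan")
    n_kd: float = float("nan")
    n_sc: float = float("nan")
    n_binding_types: Set[str] = field(default_factory=set)


def per_structure_features(
    structure: Structure,
    residue: Residue,
    neighbor_conservation: Optional[Dict[tuple, float]] = None,
    radius: float = DEFAULT_NEIGHBOR_RADIUS,
    asa: Optional[Dict[tuple, float]] = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SR_POINTS,
) -> StructureFeatureSet:
    """All per-structure features for one mapped residue.

    ``neighbor_conservation`` maps residue ids to sequence-conservation
    values (used for nSC); ``asa`` may carry a precomputed per-residue ASA
    dict to avoid recomputation across loci of the same structure.
    """
    if asa is None:
        asa = compute_asa(structure, probe_radius=probe_radius, n_points=n_points)
    b_norm = normalize_bfactors(structure)
    phi, psi = backbone_dihedrals(structure, residue)
    fs = StructureFeatureSet(
        kd=KYTE_DOOLITTLE.get(residue.one_letter, float("nan")),
        rsa=relative_sa(asa.get(residue.id, float("nan")), residue.name),
        b_norm=b_norm.get(residue.id, float("nan")),
        phi=phi,
        psi=psi,
        in_core=in_core_region(phi, psi),
        binding_types=binding_site_types(structure, [residue]),
    )
    nbh = find_neighbors(structure, residue, radius=radius)
    if nbh is None or not nbh.members:
        fs.n_num = 0 if nbh is not None else 0
        return fs
    fs.n_num = len(nbh.members)
    rsas = [relative_sa(asa.get(m.id, float("nan")), m.name) for m in nbh.members]
    fs.n_rsa = float(np.nanmean(rsas)) if not all(np.isnan(rsas)) else float("nan")
    fs.n_b = float(np.mean([b_norm.get(m.id, np.nan) for m in nbh.members]))
    kds = [KYTE_DOOLITTLE.get(m.one_letter, np.nan) for m in nbh.members]
    fs.n_kd = float(np.nanmean(kds))
    if neighbor_conservation:
        scs = [neighbor_conservation.get(m.id, np.nan) for m in nbh.members]
        if not all(np.isnan(s) for s in scs):
            fs.n_sc = float(np.nanmean(scs))
    fs.n_binding_types = binding_site_types(structure, nbh.members)
    return fs


@dataclass
class AggregatedStructureFeatures:
    """The 11 structure-based features pooled over homologous structures."""

    KDmean: float = float("nan")
    RSAmax: float = float("nan")
    nRSA: float = float("nan")
    nNum: float = float("nan")
    Bstddev: float = float("nan")
    nB: float = float("nan")
    nKD: float = float("nan")
    nSC: float = float("nan")
    nBinding: float = float("nan")
    Binding: float = float("nan")
    Mapreg: float = float("nan")

    def as_dict(self) -> Dict[str, float]:
        return {k: getattr(self, k) for k in (
            "KDmean", "RSAmax", "nRSA", "nNum", "Bstddev", "nB", "nKD",
            "nSC", "nBinding", "Binding", "Mapreg",
        )}


def _nanmean(values) -> float:
    arr = np.array([v for v in values if v is not None], dtype=float)
    if arr.size == 0 or np.all(np.isnan(arr)):
        return float("nan")
    return float(np.nanmean(arr))


def aggregate_structures(
    sets: Sequence[StructureFeatureSet],
) -> AggregatedStructureFeatures:
    """Pool per-structure feature sets across homologs.

    Means are missing-aware; RSAmax takes the maximum; Bstddev is the
    population SD of the residue's normalized B across structures (0 for a
    single structure); binding counts use the union of types over
    structures; Mapreg is the majority core-region vote with ties resolved
    to 1 (core). An empty input yields an all-missing record.
    """
    agg = AggregatedStructureFeatures()
    if not sets:
        return agg
    agg.KDmean = _nanmean([s.kd for s in sets])
    rsas = [s.rsa for s in sets if not np.isnan(s.rsa)]
    agg.RSAmax = max(rsas) if rsas else float("nan")
    agg.nRSA = _nanmean([s.n_rsa for s in sets])
    agg.nNum = _nanmean([float(s.n_num) for s in sets])
    bs = np.array([s.b_norm for s in sets], dtype=float)
    bs = bs[~np.isnan(bs)]
    agg.Bstddev = float(bs.std()) if bs.size else float("nan")  # population SD
    agg.nB = _nanmean([s.n_b for s in sets])
    agg.nKD = _nanmean([s.n_kd for s in sets])
    agg.nSC = _nanmean([s.n_sc for s in sets])
    binding_union = set().union(*(s.binding_types for s in sets))
    n_binding_union = set().union(*(s.n_binding_types for s in sets))
    agg.Binding = float(len(binding_union))
    agg.nBinding = float(len(n_binding_union))
    votes = [s.in_core for s in sets if s.in_core is not None]
    if votes:
        agg.Mapreg = 1.0 if sum(votes) * 2 >= len(votes) else 0.0
    return agg
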