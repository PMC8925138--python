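"""Ground-truth inter-residue geometry from backbone coordinates.

For residues i, j with backbone atoms N, CA (alpha carbon) and a real or
virtual CB (beta carbon; glycine has none and gets an ideal-tetrahedral
reconstruction from N, CA, C):

* ``d[i,j]``     — CB_i–CB_j distance in Angstroms (symmetric, 0 diagonal);
* ``omega[i,j]`` — dihedral CA_i–CB_i–CB_j–CA_j in degrees (symmetric);
* ``theta[i,j]`` — dihedral N_i–CA_i–CB_i–CB_j in degrees (directional);
* ``phi[i,j]``   — planar angle CA_i–CB_i–CB_j in degrees, [0, 180]
  (directional).

Dihedrals follow the IUPAC right-handed convention (trans = 180 degrees) with
range (-180, 180].  Labels discretize these maps into 37/25/25/13 classes:
bin 0 is the shared no-contact class (d >= 20 A) that masks all four
objectives; distance bins 1-36 cover [2, 20) A in 0.5 A steps; omega/theta
bins 1-24 cover (-180, 180] in 15-degree steps; phi bins 1-12 cover (0, 180]
in 15-degree steps.  Binning is half-open [lo, hi) with the topmost angular
edge closed so +180 falls in the last bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateGeometryError,
    InsufficientStructureError,
    StructureParseError,
)

logger = logging.getLogger(__name__)

# trRosetta-convention virtual-CB coefficients applied to the unnormalized
# frame vectors u1 = (CA-N) x (C-CA), u2 = CA-N, u3 = C-CA.
_CB_A = -0.58273431
_CB_B = 0.56802827
_CB_C = -0.54067466

NO_CONTACT_DISTANCE = 20.0  # Angstroms
CLASH_DISTANCE = 2.0

CA_CA_WARN_BAND = (2.0, 4.5)  # loose physical band, warning only


@dataclass(frozen=True)
class BackboneStructure:
    """Per-residue backbone coordinates (Angstroms), CB virtual where absent."""

    n: np.ndarray       # (L, 3)
    ca: np.ndarray      # (L, 3)
    c: np.ndarray       # (L, 3)
    cb: np.ndarray      # (L, 3)
    residues: tuple[str, ...]  # three-letter codes

    def __post_init__(self):
        L = self.ca.shape[0]
        if L < 2:
            raise InsufficientStructureError(
                f"need at least 2 complete residues, got {L}"
            )
        for name in ("n", "ca", "c", "cb"):
            a = getattr(self, name)
            if a.shape != (L, 3) or not np.isfinite(a).all():
                raise StructureParseError(f"bad {name.upper()} coordinate array")
        gaps = np.linalg.norm(np.diff(self.ca, axis=0), axis=1)
        bad = (gaps < CA_CA_WARN_BAND[0]) | (gaps > CA_CA_WARN_BAND[1])
        if bad.any():
            logger.warning(
                "%d consecutive CA-CA distances outside %s A (chain breaks?)",
                int(bad.sum()), CA_CA_WARN_BAND,
            )

    @property
    def length(self) -> int:
        return self.ca.shape[0]


@dataclass(frozen=True)
class GeometryMaps:
    d: np.ndarray       # (L, L) Angstroms
    omega: np.ndarray   # (L, L) degrees
    theta: np.ndarray   # (L, L) degrees
    phi: np.ndarray     # (L, L) degrees
    valid: np.ndarray   # (L, L) bool; False on diagonal / degenerate pairs

    @property
    def length(self) -> int:
        return self.d.shape[0]


@dataclass(frozen=True)
class BinSpec:
    """Bin edges for the four objectives; bin 0 is the no-contact class."""

    d_edges: np.ndarray
    dihedral_edges: np.ndarray  # for omega and theta
    phi_edges: np.ndarray

    @classmethod
    def default(cls) -> "BinSpec":
        return cls(
            d_edges=np.arange(2.0, 20.0 + 1e-9, 0.5),      # 37 edges -> 36 bins
            dihedral_edges=np.arange(-180.0, 180.0 + 1e-9, 15.0),  # 24 bins
            phi_edges=np.arange(0.0, 180.0 + 1e-9, 15.0),  # 12 bins
        )

    def __post_init__(self):
        for e in (self.d_edges, self.dihedral_edges, self.phi_edges):
            if not np.all(np.diff(e) > 0):
                raise ValueError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> dict[str, int]:
        return {
            "dist": len(self.d_edges),          # 36 + no-contact = 37
            "omega": len(self.dihedral_edges),  # 24 + no-contact = 25
            "theta": len(self.dihedral_edges),
            "phi": len(self.phi_edges),         # 12 + no-contact = 13
        }


@dataclass(frozen=True)
class GeometryLabels:
    theta: np.ndarray
    phi: np.ndarray
    omega: np.ndarray
    dist: np.ndarray

    @property
    def length(self) -> int:
        return self.dist.shape[0]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in ("theta", "phi", "omega", "dist")}


# ---------------------------------------------------------------------------
# construction

def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal-tetrahedral CB from backbone N, CA, C (trRosetta coefficients).

    Works on single points (3,) or stacks (..., 3).  Equivariant under
    rigid-body transforms.
    """
    n, ca, c = (np.asarray(x, dtype=np.float64) for x in (n, ca, c))
    u2 = ca - n
    u3 = c - ca
    u1 = np.cross(u2, u3)
    if np.any(np.linalg.norm(u1, axis=-1) < 1e-8):
        raise DegenerateGeometryError("N, CA, C are collinear; no CB frame")
    return ca + _CB_A * u1 + _CB_B * u2 + _CB_C * u3


def _dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral in degrees, IUPAC sign, range (-180, 180]."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = (n1 * n2).sum(axis=-1)
    y = (m1 * n2).sum(axis=-1)
    ang = -np.degrees(np.arctan2(y, x))  # sign flip for right-handed convention
    return np.where(ang <= -180.0 + 1e-12, 180.0, ang)


def _planar_angle(p0, p1, p2) -> np.ndarray:
    """Angle at p1 between p0 and p2, degrees in [0, 180]."""
    u = p0 - p1
    v = p2 - p1
    cosang = (u * v).sum(axis=-1) / (
        np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def pair_geometries(s: BackboneStructure) -> GeometryMaps:
    """All-pair geometry maps; diagonal and degenerate pairs flagged invalid."""
    L = s.length
    cb = s.cb.astype(np.float64)
    ca = s.ca.astype(np.float64)
    n = s.n.astype(np.float64)
    diff = cb[:, None, :] - cb[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    valid = ~np.eye(L, dtype=bool)
    degenerate = (d < 1e-6) & valid
    if degenerate.any():
        logger.warning("%d coincident CB pairs flagged invalid", int(degenerate.sum()))
        valid &= ~degenerate

    ii, jj = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    flat_i, flat_j = ii.ravel(), jj.ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        # diagonal/degenerate entries produce NaN here; masked right after
        omega = _dihedral(ca[flat_i], cb[flat_i], cb[flat_j], ca[flat_j]).reshape(L, L)
        theta = _dihedral(n[flat_i], ca[flat_i], cb[flat_i], cb[flat_j]).reshape(L, L)
        phi = _planar_angle(ca[flat_i], cb[flat_i], cb[flat_j]).reshape(L, L)
    for m in (omega, theta, phi):
        m[~valid] = 0.0
    d[np.eye(L, dtype=bool)] = 0.0
    return GeometryMaps(d=d, omega=omega, theta=theta, phi=phi, valid=valid)


def _bin_values(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open [lo, hi) binning over the given edges, 1-based.

    The topmost edge is closed so a value exactly at the upper boundary lands
    in the last bin (used by the angular wrap at +180).
    """
    idx = np.searchsorted(edges, values, side="right")  # 0..len(edges)
    idx = np.where(np.isclose(values, edges[-1]), len(edges) - 1, idx)
    return idx


def discretize(g: GeometryMaps, bins: BinSpec | None = None) -> GeometryLabels:
    """Map geometry values to integer class labels (bin 0 = no contact)."""
    bins = bins or BinSpec.default()
    L = g.length
    contact = g.valid & (g.d < NO_CONTACT_DISTANCE)

    clash = contact & (g.d < CLASH_DISTANCE)
    if clash.any():
        logger.warning("%d pairs closer than %.1f A clamped into the first "
                       "distance bin", int(clash.sum()), CLASH_DISTANCE)
    d_clamped = np.clip(g.d, CLASH_DISTANCE, None)
    dist = np.where(contact, _bin_values(d_clamped, bins.d_edges), 0)

    omega = np.where(contact, _bin_values(g.omega, bins.dihedral_edges), 0)
    theta = np.where(contact, _bin_values(g.theta, bins.dihedral_edges), 0)
    phi = np.where(contact, _bin_values(g.phi, bins.phi_edges), 0)
    # exact lower-edge values (phi = 0, dihedral just above -180) stay >= 1
    for name, arr, top in (
        ("dist", dist, bins.n_bins["dist"]),
        ("omega", omega, bins.n_bins["omega"]),
        ("theta", theta, bins.n_bins["theta"]),
        ("phi", phi, bins.n_bins["phi"]),
    ):
        arr[contact] = np.clip(arr[contact], 1, top - 1)
    return GeometryLabels(
        theta=theta.astype(np.int64), phi=phi.astype(np.int64),
        omega=omega.astype(np.int64), dist=dist.astype(np.int64),
    )


def bin_centers(bins: BinSpec | None = None) -> dict[str, np.ndarray]:
    """Mid-points of bins 1..k-1 per objective (index 0 = no-contact, NaN)."""
    bins = bins or BinSpec.default()
    out = {}
    for name, edges in (("dist", bins.d_edges),
                        ("omega", bins.dihedral_edges),
                        ("theta", bins.dihedral_edges),
                        ("phi", bins.phi_edges)):
        mids = 0.5 * (edges[:-1] + edges[1:])
        out[name] = np.concatenate([[np.nan], mids])
    return out


def featurize(s: BackboneStructure, bins: BinSpec | None = None) -> GeometryLabels:
    """Structure -> labels in one call (the training-target featurizer)."""
    return discretize(pair_geometries(s), bins)


# ---------------------------------------------------------------------------
# PDB I/O (via biotite)

_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def read_backbone(path) -> BackboneStructure:
    """Read one chain's backbone from a PDB file.

    Uses the first model (warning if there are several), resolves altlocs by
    occupancy, drops residues missing any of N/CA/C with a warning, and
    builds a virtual CB for glycine or when CB is absent.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
    except Exception as exc:
        raise StructureParseError(f"cannot parse PDB file {path}: {exc}") from exc
    n_models = pdb.get_model_count()
    if n_models > 1:
        logger.warning("%s has %d models; using the first", path, n_models)
    try:
        atoms = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:
        raise StructureParseError(f"cannot read coordinates from {path}: {exc}") from exc
    atoms = atoms[
        struc.filter_amino_acids(atoms)
        & np.isin(atoms.res_name, sorted(_STANDARD_RESIDUES))
    ]
    if atoms.array_length() == 0:
        raise InsufficientStructureError(f"no standard amino-acid atoms in {path}")
    chains = np.unique(atoms.chain_id)
    if len(chains) > 1:
        logger.warning("%s has chains %s; using %s", path, list(chains), chains[0])
        atoms = atoms[atoms.chain_id == chains[0]]

    n_list, ca_list, c_list, cb_list, res_list = [], [], [], [], []
    for res_id in np.unique(atoms.res_id):
        res = atoms[atoms.res_id == res_id]
        coords = {}
        for name in ("N", "CA", "C", "CB"):
            sel = res[res.atom_name == name]
            if sel.array_length() > 0:
                coords[name] = sel.coord[0]
        if not all(k in coords for k in ("N", "CA", "C")):
            logger.warning("residue %d is missing a backbone atom; dropped", res_id)
            continue
        res_name = str(res.res_name[0])
        if "CB" not in coords or res_name == "GLY":
            coords["CB"] = virtual_cbeta(coords["N"], coords["CA"], coords["C"])
        n_list.append(coords["N"])
        ca_list.append(coords["CA"])
        c_list.append(coords["C"])
        cb_list.append(coords["CB"])
        res_list.append(res_name)
    if len(ca_list) < 2:
        raise InsufficientStructureError(
            f"{path}: fewer than 2 complete residues after filtering"
        )
    return BackboneStructure(
        n=np.asarray(n_list, dtype=np.float64),
        ca=np.asarray(ca_list, dtype=np.float64),
        c=np.asarray(c_list, dtype=np.float64),
        cb=np.asarray(cb_list, dtype=np.float64),
        residues=tuple(res_list),
    )
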