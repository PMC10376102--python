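"""Backbone geometry for multi-model structural ensembles.

Parses multi-model (NMR-style) PDB files into per-chain backbone
coordinate stacks, computes phi/psi dihedrals per model, and rebuilds
backbone coordinates from internal coordinates (natural-extension
placement) so that synthetic ensembles with known angles can be
round-tripped through the same measurement code.

Dihedral sign follows the IUPAC convention: 0 deg is cis, 180 deg is
trans, and the angle is positive for a clockwise rotation of the far
bond when viewed from the p2 -> p3 direction.  All angles are reported
in degrees in the half-open interval (-180, 180].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from Bio.Data.IUPACData import protein_letters_3to1
from Bio.PDB import PDBParser

__all__ = [
    "BACKBONE_ATOMS",
    "PeptideGeometry",
    "EnsembleStructure",
    "DihedralSeries",
    "GeometryError",
    "dihedral_angle",
    "backbone_dihedrals",
    "build_backbone",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
]

BACKBONE_ATOMS = ("N", "CA", "C")

_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}
_ONE_TO_THREE = {v: k.upper() for k, v in protein_letters_3to1.items()}


class GeometryError(ValueError):
    """Raised for degenerate geometry (coincident or collinear points)."""


@dataclass
class PeptideGeometry:
    """Ideal peptide bond lengths (angstrom) and bond angles (degrees)."""

    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    angle_c_n_ca: float = 121.7


@dataclass
class EnsembleStructure:
    """One chain's N/CA/C coordinates across the models of an ensemble.

    ``coords`` has shape (M, L, 3, 3): model, residue, atom (N, CA, C),
    xyz in angstrom.  Missing backbone atoms are stored as NaN and the
    affected residue is flagged in ``incomplete``; downstream label code
    treats dihedrals touching such atoms as undefined.
    """

    chain_id: str
    sequence: str
    coords: np.ndarray
    nonstandard: bool = False
    incomplete: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[2:] != (3, 3):
            raise ValueError("coords must have shape (M, L, 3, 3)")
        if self.coords.shape[1] != len(self.sequence):
            raise ValueError("coordinate length does not match sequence length")
        if self.coords.shape[0] < 1:
            raise ValueError("an ensemble needs at least one model")
        if self.incomplete is None:
            self.incomplete = np.isnan(self.coords).any(axis=(0, 2, 3))
        self.incomplete = np.asarray(self.incomplete, dtype=bool)

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def length(self) -> int:
        return self.coords.shape[1]


@dataclass
class DihedralSeries:
    """Per-model, per-residue phi/psi in degrees with explicit defined masks.

    phi[:, 0] and psi[:, -1] are always undefined (chain termini); other
    entries may be undefined where backbone atoms were missing or the
    geometry was degenerate.  Undefined entries hold NaN and are flagged
    False in the masks -- they are never silently zero.
    """

    chain_id: str
    phi: np.ndarray
    psi: np.ndarray
    phi_defined: np.ndarray
    psi_defined: np.ndarray

    @property
    def n_models(self) -> int:
        return self.phi.shape[0]

    @property
    def length(self) -> int:
        return self.phi.shape[1]


def _dihedral_batch(p1, p2, p3, p4):
    """Vectorised signed dihedral (degrees); NaN where degenerate."""
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b3 = np.asarray(p4, float) - np.asarray(p3, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.einsum("...i,...i", np.cross(n1, n2), b2 / b2n[..., None])
        x = np.einsum("...i,...i", n1, n2)
        ang = np.degrees(np.arctan2(y, x))
    bad = (
        (np.linalg.norm(b1, axis=-1) < 1e-10)
        | (b2n < 1e-10)
        | (np.linalg.norm(b3, axis=-1) < 1e-10)
        | (np.linalg.norm(n1, axis=-1) < 1e-10)
        | (np.linalg.norm(n2, axis=-1) < 1e-10)
    )
    ang = np.where(bad, np.nan, ang)
    # map an exact -180 into the (-180, 180] convention
    return np.where(ang == -180.0, 180.0, ang)


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral of four points, degrees in (-180, 180].

    Raises :class:`GeometryError` if consecutive points coincide or a
    triple is collinear (the angle is then undefined).
    """
    ang = float(_dihedral_batch(p1, p2, p3, p4))
    if np.isnan(ang):
        raise GeometryError("dihedral undefined: coincident or collinear points")
    return ang


def backbone_dihedrals(e: EnsembleStructure) -> DihedralSeries:
    """Compute phi/psi for every model of an ensemble.

    phi(i) = dihedral C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1).
    Degenerate or incomplete positions are flagged undefined per entry;
    the chain is never aborted for a local problem.
    """
    M, L = e.n_models, e.length
    N = e.coords[:, :, 0]
    CA = e.coords[:, :, 1]
    C = e.coords[:, :, 2]

    phi = np.full((M, L), np.nan)
    psi = np.full((M, L), np.nan)
    if L >= 2:
        phi[:, 1:] = _dihedral_batch(C[:, :-1], N[:, 1:], CA[:, 1:], C[:, 1:])
        psi[:, :-1] = _dihedral_batch(N[:, :-1], CA[:, :-1], C[:, :-1], N[:, 1:])
    return DihedralSeries(
        chain_id=e.chain_id,
        phi=phi,
        psi=psi,
        phi_defined=~np.isnan(phi),
        psi_defined=~np.isnan(psi),
    )


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Natural-extension placement: position d with |cd| = bond,
    angle(b,c,d) = angle and dihedral(a,b,c,d) = torsion."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    phi,
    psi,
    omega=None,
    geometry: PeptideGeometry | None = None,
) -> np.ndarray:
    """Build one model's N/CA/C coordinates (L, 3, 3) from torsions.

    phi[0] and psi[-1] are not geometrically realised (they are
    undefined at the termini) and may hold any value.  Recomputing
    dihedrals from the result reproduces the defined inputs to well
    below 1e-6 degrees.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    L = len(phi)
    if len(psi) != L:
        raise ValueError("phi and psi must have the same length")
    if omega is None:
        omega = np.full(L, 180.0)
    omega = np.asarray(omega, dtype=float)
    if len(omega) != L:
        raise ValueError("omega must match phi/psi length")
    g = geometry or PeptideGeometry()

    coords = np.empty((L, 3, 3))
    # first residue in the xy-plane
    coords[0, 0] = (0.0, 0.0, 0.0)
    coords[0, 1] = (g.bond_n_ca, 0.0, 0.0)
    tau = np.radians(g.angle_n_ca_c)
    coords[0, 2] = coords[0, 1] + g.bond_ca_c * np.array(
        [-np.cos(tau), np.sin(tau), 0.0]
    )
    for i in range(1, L):
        n_prev, ca_prev, c_prev = coords[i - 1]
        n_i = _place_atom(n_prev, ca_prev, c_prev, g.bond_c_n, g.angle_ca_c_n, psi[i - 1])
        ca_i = _place_atom(ca_prev, c_prev, n_i, g.bond_n_ca, g.angle_c_n_ca, omega[i - 1])
        c_i = _place_atom(c_prev, n_i, ca_i, g.bond_ca_c, g.angle_n_ca_c, phi[i])
        coords[i] = (n_i, ca_i, c_i)
    return coords


def _residue_one_letter(resname: str) -> tuple[str, bool]:
    one = _THREE_TO_ONE.get(resname.strip().upper())
    if one is None or one not in "ACDEFGHIKLMNPQRSTVWY":
        return "X", True
    return one, False


def read_multimodel_pdb(path, chains=None) -> list[EnsembleStructure]:
    """Read a multi-model PDB file into one ensemble per chain.

    Files without MODEL/ENDMDL records are treated as a single implicit
    model.  Only N, CA and C atoms are kept; altlocs resolve to the
    highest-occupancy conformer (first encountered on ties, the
    Biopython default).  Residues missing a backbone atom in some model
    are kept but flagged; a chain with no usable residue at all is
    rejected with a diagnostic.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no models found")

    chain_ids = [ch.id for ch in models[0]]
    if chains is not None:
        chain_ids = [c for c in chain_ids if c in set(chains)]

    out: list[EnsembleStructure] = []
    single_chain = len(chain_ids) == 1
    for cid in chain_ids:
        # residue ordering fixed by the first model (resseq + insertion code)
        first = models[0][cid]
        res_ids = [r.id for r in first if r.id[0] == " "]
        if not res_ids:
            continue
        letters, flags = zip(
            *(_residue_one_letter(first[rid].get_resname()) for rid in res_ids)
        )
        sequence = "".join(letters)
        nonstandard = any(flags)

        M, L = len(models), len(res_ids)
        coords = np.full((M, L, 3, 3), np.nan)
        for m, model in enumerate(models):
            if cid not in model:
                continue
            chain = model[cid]
            for i, rid in enumerate(res_ids):
                if rid not in chain:
                    continue
                residue = chain[rid]
                for a, name in enumerate(BACKBONE_ATOMS):
                    if name in residue:
                        coords[m, i, a] = residue[name].get_coord()
        incomplete = np.isnan(coords).any(axis=(0, 2, 3))
        if incomplete.all():
            raise ValueError(
                f"{path} chain {cid}: no residue has a complete backbone in "
                f"all models; chain rejected"
            )
        if incomplete.any():
            warnings.warn(
                f"{path} chain {cid}: {int(incomplete.sum())} residue(s) with "
                f"missing backbone atoms flagged",
                stacklevel=2,
            )
        out.append(
            EnsembleStructure(
                chain_id=path.stem if single_chain else f"{path.stem}:{cid}",
                sequence=sequence,
                coords=coords,
                nonstandard=nonstandard,
                incomplete=incomplete,
            )
        )
    return out


def write_multimodel_pdb(e: EnsembleStructure, path) -> None:
    """Write an ensemble as a minimal multi-model PDB file (N/CA/C only)."""
    lines = []
    if ":" in e.chain_id:
        chain_letter = e.chain_id.split(":")[-1][0]
    else:
        chain_letter = (e.chain_id.split("_")[-1] or "A")[0]
    for m in range(e.n_models):
        lines.append(f"MODEL     {m + 1:4d}")
        serial = 1
        for i, aa in enumerate(e.sequence):
            resname = _ONE_TO_THREE.get(aa, "UNK")
            for a, name in enumerate(BACKBONE_ATOMS):
                x, y, z = e.coords[m, i, a]
                if np.isnan(x):
                    continue
                lines.append(
                    f"ATOM  {serial:5d} {name:^4s} {resname:>3s} {chain_letter}"
                    f"{i + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                    f"          {name[0]:>2s}"
                )
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
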