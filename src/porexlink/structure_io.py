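"""Reading, writing and selecting PDB structures and conformer ensembles.

Multi-model PDB files are the single trajectory format of the package: each
``MODEL``/``ENDMDL`` block becomes one frame of a :class:`FrameEnsemble`, all
frames sharing one atom table.  Author residue numbering is authoritative and
never rewritten, so positions such as CFTR 341 or 1134 stay addressable
verbatim.

The module also builds the Cβ reference points used by every distance
computation downstream: explicit Cβ atoms where present, a deterministic
virtual Cβ (ideal tetrahedral geometry, 1.53 Å from Cα) for glycine or
Cβ-stripped residues, and a flagged Cα fallback when the backbone is
incomplete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

__all__ = [
    "PDBFormatError",
    "EnsembleError",
    "SelectionError",
    "FrameEnsemble",
    "SegmentMap",
    "RadiusTable",
    "DEFAULT_VDW_RADII",
    "BACKBONE_ATOMS",
    "read_structure",
    "write_structure",
    "cbeta_point",
    "virtual_cbeta",
    "select_segment",
]

ATOM_COLUMNS = ["serial", "name", "altloc", "resname", "chain", "resnum", "icode", "occupancy", "element"]
BACKBONE_ATOMS = ("N", "CA", "C", "O")

# HOLE-like united-atom van der Waals radii (Å); hydrogens are normally
# excluded from pore computations, the heavy-atom radii absorb them.
DEFAULT_VDW_RADII = {"C": 1.85, "N": 1.75, "O": 1.65, "S": 2.00, "P": 1.90, "H": 1.00}

CA_CB_BOND = 1.53  # Å, ideal Cα–Cβ bond length
TETRAHEDRAL_ANGLE = np.deg2rad(109.47)


class PDBFormatError(ValueError):
    """Raised when a PDB file cannot be parsed."""


class EnsembleError(ValueError):
    """Raised when MODEL blocks of a multi-model file disagree in atom content."""


class SelectionError(KeyError):
    """Raised when an atom/residue/segment selection resolves to nothing."""


@dataclass
class FrameEnsemble:
    """A conformer ensemble: one atom table shared by ``n_frames`` coordinate sets.

    Parameters
    ----------
    atoms
        DataFrame with columns ``serial, name, altloc, resname, chain, resnum,
        icode, occupancy, element``; one row per atom, order defines the
        coordinate order.
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in Å.
    frame_labels
        One label per frame (model number, snapshot index or time).
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    frame_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise EnsembleError("an ensemble needs at least one frame")
        if self.coords.shape[1] != len(self.atoms):
            raise EnsembleError(
                f"coordinate count {self.coords.shape[1]} does not match atom table ({len(self.atoms)})"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if not self.frame_labels:
            self.frame_labels = list(range(self.n_frames))
        if len(self.frame_labels) != self.n_frames:
            raise ValueError("frame_labels length does not match frame count")
        self.atoms = self.atoms.reset_index(drop=True)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        """Coordinates of frame ``i``, shape ``(n_atoms, 3)``."""
        return self.coords[i]

    def subset_atoms(self, index: np.ndarray) -> "FrameEnsemble":
        """Sub-ensemble keeping the atoms at positional ``index`` (order preserved)."""
        index = np.asarray(index)
        return FrameEnsemble(
            atoms=self.atoms.iloc[index].reset_index(drop=True),
            coords=self.coords[:, index],
            frame_labels=list(self.frame_labels),
        )

    def subset_frames(self, index) -> "FrameEnsemble":
        index = np.asarray(index)
        return FrameEnsemble(
            atoms=self.atoms,
            coords=self.coords[index],
            frame_labels=[self.frame_labels[i] for i in index],
        )

    def residue_index(self, chain: str, resnum: int, icode: str = "") -> np.ndarray:
        """Positional indices of the atoms of one residue."""
        a = self.atoms
        mask = (a["chain"] == chain) & (a["resnum"] == resnum) & (a["icode"] == icode)
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size == 0:
            raise SelectionError(f"residue {chain}{resnum}{icode} not found")
        return idx


def _atom_key(atom, residue, chain) -> tuple:
    het, resnum, icode = residue.id
    return (chain.id, resnum, icode.strip(), residue.resname.strip(), atom.get_name())


def _pick_altloc(atom):
    """Resolve a possibly disordered atom: highest occupancy, ties alphabetical."""
    if not atom.is_disordered():
        return atom
    children = sorted(
        atom.disordered_get_list(),
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
    )
    return children[0]


def read_structure(path, model_policy: str = "all-models", keep_hydrogens: bool = True) -> FrameEnsemble:
    """Read a (possibly multi-model) PDB file into a :class:`FrameEnsemble`.

    One frame per ``MODEL`` record (or a single frame if none).  Alternate
    locations are resolved to the highest-occupancy conformer (alphabetical
    altloc on ties).  All models must contain the same atoms in the same
    order.

    Parameters
    ----------
    path
        PDB file path.
    model_policy
        ``"all-models"`` (default) or ``"first-model"``.
    keep_hydrogens
        If False, hydrogen atoms are dropped on read.
    """
    if model_policy not in ("all-models", "first-model"):
        raise ValueError(f"unknown model_policy {model_policy!r}")
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        structure = parser.get_structure(Path(path).stem, str(path))
    except PDBConstructionException as exc:  # strict parser reports the line number
        raise PDBFormatError(f"cannot parse {path}: {exc}") from exc

    models = list(structure)
    if not models:
        raise PDBFormatError(f"{path} contains no coordinates")
    if model_policy == "first-model":
        models = models[:1]

    def extract(model):
        rows, xyz = [], []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    atom = _pick_altloc(atom)
                    element = (atom.element or "").strip().upper()
                    if not keep_hydrogens and element == "H":
                        continue
                    rows.append(
                        {
                            "serial": atom.get_serial_number(),
                            "name": atom.get_name(),
                            "altloc": atom.get_altloc().strip(),
                            "resname": residue.resname.strip(),
                            "chain": chain.id,
                            "resnum": residue.id[1],
                            "icode": residue.id[2].strip(),
                            "occupancy": atom.get_occupancy() if atom.get_occupancy() is not None else 1.0,
                            "element": element,
                        }
                    )
                    xyz.append(atom.get_coord())
        return rows, np.asarray(xyz, dtype=float)

    first_rows, first_xyz = extract(models[0])
    keys0 = [(r["chain"], r["resnum"], r["icode"], r["resname"], r["name"]) for r in first_rows]
    frames = [first_xyz]
    labels = [models[0].id + 1 if isinstance(models[0].id, int) else models[0].id]
    for model in models[1:]:
        rows, xyz = extract(model)
        keys = [(r["chain"], r["resnum"], r["icode"], r["resname"], r["name"]) for r in rows]
        if keys != keys0:
            missing = set(keys0) ^ set(keys)
            raise EnsembleError(
                f"model {model.id + 1} of {path} does not match model {labels[0]}: "
                f"{len(missing)} differing atoms, e.g. {sorted(missing)[:3]}"
            )
        frames.append(xyz)
        labels.append(model.id + 1)

    atoms = pd.DataFrame(first_rows, columns=ATOM_COLUMNS)
    return FrameEnsemble(atoms=atoms, coords=np.stack(frames), frame_labels=labels)


def write_structure(ensemble: FrameEnsemble, path) -> None:
    """Write an ensemble as (multi-model) PDB text, 3-decimal coordinates."""
    a = ensemble.atoms
    multi = ensemble.n_frames > 1
    with open(path, "w") as fh:
        for f in range(ensemble.n_frames):
            if multi:
                fh.write(f"MODEL     {f + 1:4d}\n")
            xyz = ensemble.coords[f]
            for i in range(ensemble.n_atoms):
                name = a.at[i, "name"]
                # PDB atom-name column convention: 1-char elements start in col 14
                if len(name) < 4 and len(str(a.at[i, "element"])) < 2:
                    name = f" {name}"
                fh.write(
                    "ATOM  {serial:5d} {name:<4s}{altloc:1s}{resname:<3s} {chain:1s}{resnum:4d}{icode:1s}   "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}\n".format(
                        serial=int(a.at[i, "serial"]) % 100000,
                        name=name,
                        altloc=a.at[i, "altloc"] or " ",
                        resname=a.at[i, "resname"],
                        chain=(a.at[i, "chain"] or "A")[:1],
                        resnum=int(a.at[i, "resnum"]),
                        icode=a.at[i, "icode"] or " ",
                        x=xyz[i, 0],
                        y=xyz[i, 1],
                        z=xyz[i, 2],
                        occ=float(a.at[i, "occupancy"]),
                        b=0.0,
                        element=str(a.at[i, "element"])[:2],
                    )
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal-geometry virtual Cβ from backbone N, Cα, C.

    The Cβ direction makes the tetrahedral angle (109.47°) with both the
    Cα→N and Cα→C bonds and sits on the L-amino-acid side of the backbone
    plane, at exactly 1.53 Å from Cα.
    """
    u1 = _unit(np.asarray(n, float) - ca)
    u2 = _unit(np.asarray(c, float) - ca)
    bis = _unit(u1 + u2)
    perp = _unit(np.cross(u1, u2))
    alpha = -np.cos(TETRAHEDRAL_ANGLE) / np.dot(bis, u1)
    if not 0 < alpha < 1:
        raise ValueError("degenerate backbone geometry for virtual Cβ construction")
    beta = np.sqrt(1.0 - alpha * alpha)
    direction = -alpha * bis + beta * perp
    return np.asarray(ca, float) + CA_CB_BOND * direction


def cbeta_point(
    ensemble: FrameEnsemble, chain: str, resnum: int, frame: int = 0, icode: str = ""
) -> tuple[np.ndarray, str]:
    """Cβ reference point of one residue in one frame.

    Returns ``(xyz, kind)`` where ``kind`` is ``"explicit"`` (a CB atom),
    ``"virtual"`` (constructed from N/Cα/C; always the case for glycine) or
    ``"ca_fallback"`` (backbone incomplete, Cα returned).
    """
    idx = ensemble.residue_index(chain, resnum, icode)
    names = ensemble.atoms["name"].to_numpy()[idx]
    xyz = ensemble.coords[frame, idx]
    by_name = {nm: xyz[i] for i, nm in enumerate(names)}
    if "CB" in by_name:
        return by_name["CB"], "explicit"
    if all(k in by_name for k in ("N", "CA", "C")):
        return virtual_cbeta(by_name["N"], by_name["CA"], by_name["C"]), "virtual"
    if "CA" in by_name:
        return by_name["CA"], "ca_fallback"
    raise SelectionError(f"residue {chain}{resnum}{icode} has neither CB nor CA")


@dataclass
class SegmentMap:
    """Named residue segments (TMHs, NBDs, MSDs ...) plus an optional membrane z-window.

    ``segments`` maps a name to a list of inclusive ``(chain, first, last)``
    residue ranges.  ``membrane_z`` is an axial ``(low, high)`` window in Å
    used to bound pore-profile walks.
    """

    segments: dict = field(default_factory=dict)
    membrane_z: tuple | None = None

    def __post_init__(self) -> None:
        for name, ranges in self.segments.items():
            if not ranges:
                raise ValueError(f"segment {name!r} is empty")
            seen = set()
            for chain, lo, hi in ranges:
                if lo > hi:
                    raise ValueError(f"segment {name!r}: range {lo}-{hi} is empty")
                span = {(chain, r) for r in range(int(lo), int(hi) + 1)}
                if seen & span:
                    raise ValueError(f"segment {name!r}: overlapping ranges")
                seen |= span
        if self.membrane_z is not None:
            lo, hi = self.membrane_z
            if not lo < hi:
                raise ValueError("membrane_z must be an increasing (low, high) pair")

    def __contains__(self, name: str) -> bool:
        return name in self.segments

    def names(self) -> list:
        return list(self.segments)

    def mask(self, atoms: pd.DataFrame, name: str) -> np.ndarray:
        """Boolean mask over an atom table selecting this segment's residues."""
        if name not in self.segments:
            raise SelectionError(f"unknown segment {name!r}; known: {sorted(self.segments)}")
        m = np.zeros(len(atoms), dtype=bool)
        chains = atoms["chain"].to_numpy()
        resnums = atoms["resnum"].to_numpy()
        for chain, lo, hi in self.segments[name]:
            m |= (chains == chain) & (resnums >= lo) & (resnums <= hi)
        return m

    @classmethod
    def from_yaml(cls, path) -> "SegmentMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        segments = {
            name: [(str(r[0]), int(r[1]), int(r[2])) for r in ranges]
            for name, ranges in (raw.get("segments") or {}).items()
        }
        mz = raw.get("membrane_z")
        return cls(segments=segments, membrane_z=tuple(mz) if mz else None)

    def to_yaml(self, path) -> None:
        raw = {
            "segments": {name: [list(r) for r in ranges] for name, ranges in self.segments.items()},
            "membrane_z": list(self.membrane_z) if self.membrane_z else None,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class RadiusTable:
    """Van der Waals radii per element (united-atom style), overridable by config."""

    radii: dict = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))
    default: float = 1.85  # unknown elements fall back to carbon

    def __post_init__(self) -> None:
        for el, r in self.radii.items():
            if not 0.5 < r < 3.0:
                raise ValueError(f"implausible vdW radius {r} Å for element {el!r}")

    def lookup(self, element: str) -> float:
        return self.radii.get(str(element).upper(), self.default)

    def for_atoms(self, atoms: pd.DataFrame) -> np.ndarray:
        return np.array([self.lookup(el) for el in atoms["element"]], dtype=float)

    def shrunk(self, delta: float) -> "RadiusTable":
        """A copy with every radius reduced by ``delta`` (for sensitivity checks)."""
        return RadiusTable(radii={el: r - delta for el, r in self.radii.items()},
                           default=self.default - delta)

    @classmethod
    def from_yaml(cls, path) -> "RadiusTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(radii={str(k).upper(): float(v) for k, v in raw.get("radii", {}).items()},
                   default=float(raw.get("default", 1.85)))


def select_segment(
    ensemble: FrameEnsemble, segment_map: SegmentMap, name: str, atom_filter: str = "heavy"
) -> FrameEnsemble:
    """Sub-ensemble of one named segment, preserving frame count and atom order.

    ``atom_filter``: ``CA`` | ``backbone`` (N, CA, C, O) | ``heavy`` | ``all``.
    """
    mask = segment_map.mask(ensemble.atoms, name)
    mask &= atom_filter_mask(ensemble.atoms, atom_filter)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"segment {name!r} with filter {atom_filter!r} selects no atoms")
    return ensemble.subset_atoms(idx)


def atom_filter_mask(atoms: pd.DataFrame, atom_filter: str) -> np.ndarray:
    names = atoms["name"].to_numpy()
    elements = atoms["element"].to_numpy()
    if atom_filter == "CA":
        return names == "CA"
    if atom_filter == "backbone":
        return np.isin(names, BACKBONE_ATOMS)
    if atom_filter == "heavy":
        return elements != "H"
    if atom_filter == "all":
        return np.ones(len(atoms), dtype=bool)
    raise ValueError(f"unknown atom_filter {atom_filter!r}")
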