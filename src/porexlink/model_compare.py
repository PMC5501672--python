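"""Rigid-body superposition, RMSD analyses and conformational clustering.

Superposition uses the Kabsch algorithm (SVD of the cross-covariance, proper
rotations only — reflections are forbidden by a determinant sign fix).  RMSD
is computed on unweighted coordinates of the chosen atom selection.

Cross-structure comparison (e.g. a model against a cryo-EM deposition of an
orthologue) goes through a :class:`CorrespondenceMap` built from a global
pairwise sequence alignment (affine gaps, BLOSUM62), so residue numbering
differences between species never matter.

Ensemble analyses: RMSD-vs-reference time series, plateau-based
equilibration detection (moving-window slope + range criterion), and
quality-threshold clustering of frames on the pairwise superposed-RMSD
matrix with centroid representatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.SeqUtils import seq1

from .structure_io import FrameEnsemble, SegmentMap, atom_filter_mask

__all__ = [
    "Superposition",
    "CorrespondenceMap",
    "RMSDSeries",
    "ClusterResult",
    "superpose",
    "superposed_rmsd",
    "pairwise_rmsd_matrix",
    "align_and_rmsd",
    "segment_rmsd",
    "rmsd_timeseries",
    "detect_equilibration",
    "cluster_frames",
]


@dataclass
class Superposition:
    """Optimal rigid-body fit of a mobile coordinate set onto a target."""

    rotation: np.ndarray  # 3x3, proper (det +1)
    translation: np.ndarray  # 3-vector
    rmsd: float
    n_atoms: int
    coverage: float = 1.0  # fraction of residues matched (alignment-guided fits)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, target: np.ndarray) -> Superposition:
    """Least-squares rigid fit of ``mobile`` onto ``target`` (Kabsch).

    Returns the proper rotation R and translation t minimising
    ``|R·mobile + t - target|``; ``rmsd`` is the minimised value.
    """
    A = np.asarray(mobile, float)
    B = np.asarray(target, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must be matched (n, 3) arrays")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms to superpose")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - ca, B - cb
    if np.linalg.matrix_rank(Ac, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) coordinate set")
    H = Ac.T @ Bc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    # evaluate the residual directly; the trace formula loses precision near zero
    resid = Ac @ R.T - Bc
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return superpose(a, b).rmsd


def pairwise_rmsd_matrix(frames: np.ndarray) -> np.ndarray:
    """All-against-all superposed RMSD of frames, shape (m, n, 3) -> (m, m).

    Each pair is refit independently (batched Kabsch via 3x3 SVDs).
    """
    X = np.asarray(frames, float)
    m, n, _ = X.shape
    Xc = X - X.mean(axis=1, keepdims=True)
    q = np.einsum("ink,ink->i", Xc, Xc)
    H = np.einsum("ina,jnb->ijab", Xc, Xc)
    S = np.linalg.svd(H, compute_uv=False)
    det = np.linalg.det(H)
    sign = np.where(det < 0, -1.0, 1.0)
    trace = S[..., 0] + S[..., 1] + sign * S[..., 2]
    msd = (q[:, None] + q[None, :] - 2.0 * trace) / n
    out = np.sqrt(np.maximum(msd, 0.0))
    np.fill_diagonal(out, 0.0)
    return out


def _chain_sequence(ensemble: FrameEnsemble, chain: str) -> tuple[str, list]:
    """One-letter sequence and residue ids of a chain, from its Cα rows."""
    a = ensemble.atoms
    rows = a[(a["chain"] == chain) & (a["name"] == "CA")]
    resids = list(zip(rows["resnum"], rows["icode"]))
    seq = "".join((seq1(rn) or "X") for rn in rows["resname"])
    return seq, resids


@dataclass
class CorrespondenceMap:
    """Ordered one-to-one residue matching between two structures.

    ``pairs`` is a list of ``((chainA, resnumA), (chainB, resnumB))`` tuples,
    order-preserving within each chain; ``coverage`` is the matched fraction
    of the shorter sequence.
    """

    pairs: list
    coverage: float = 1.0

    def __post_init__(self) -> None:
        a_side = [p[0] for p in self.pairs]
        b_side = [p[1] for p in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("correspondence must be one-to-one")

    def reversed(self) -> "CorrespondenceMap":
        return CorrespondenceMap(pairs=[(b, a) for a, b in self.pairs], coverage=self.coverage)

    @classmethod
    def identity(cls, ensemble: FrameEnsemble) -> "CorrespondenceMap":
        a = ensemble.atoms
        ca = a[a["name"] == "CA"]
        pairs = [((c, r), (c, r)) for c, r in zip(ca["chain"], ca["resnum"])]
        return cls(pairs=pairs, coverage=1.0)

    @classmethod
    def from_structures(
        cls,
        ens_a: FrameEnsemble,
        ens_b: FrameEnsemble,
        chain_pairs: list | None = None,
        open_gap_score: float = -10.0,
        extend_gap_score: float = -0.5,
    ) -> "CorrespondenceMap":
        """Build the map by global pairwise sequence alignment per chain pair.

        ``chain_pairs`` defaults to pairing the chains of the two structures
        in order of appearance.
        """
        if chain_pairs is None:
            chains_a = list(dict.fromkeys(ens_a.atoms["chain"]))
            chains_b = list(dict.fromkeys(ens_b.atoms["chain"]))
            chain_pairs = list(zip(chains_a, chains_b))
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = open_gap_score
        aligner.extend_gap_score = extend_gap_score
        pairs = []
        n_short = 0
        for ca_chain, cb_chain in chain_pairs:
            seq_a, res_a = _chain_sequence(ens_a, ca_chain)
            seq_b, res_b = _chain_sequence(ens_b, cb_chain)
            if not seq_a or not seq_b:
                continue
            n_short += min(len(seq_a), len(seq_b))
            aln = aligner.align(seq_a, seq_b)[0]  # BLOSUM62 covers the 'X' wildcard
            for (a0, a1), (b0, b1) in zip(*aln.aligned):
                for i, j in zip(range(a0, a1), range(b0, b1)):
                    pairs.append(((ca_chain, res_a[i][0]), (cb_chain, res_b[j][0])))
        coverage = len(pairs) / n_short if n_short else 0.0
        return cls(pairs=pairs, coverage=coverage)

    @classmethod
    def from_tsv(cls, path) -> "CorrespondenceMap":
        df = pd.read_csv(path, sep="\t", dtype={"chain_a": str, "chain_b": str})
        pairs = [
            ((str(r["chain_a"]), int(r["res_a"])), (str(r["chain_b"]), int(r["res_b"])))
            for _, r in df.iterrows()
        ]
        return cls(pairs=pairs)


_SELECTION_NAMES = {"CA": ("CA",), "backbone": ("N", "CA", "C", "O")}


def _mapped_coordinates(
    ens_a: FrameEnsemble,
    ens_b: FrameEnsemble,
    cmap: CorrespondenceMap,
    selection: str,
    frame_a: int,
    frame_b: int,
    residue_subset: set | None = None,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Matched coordinate arrays over mapped residues, common atom names only."""
    names = _SELECTION_NAMES.get(selection)
    if names is None:
        raise ValueError("selection must be 'CA' or 'backbone'")
    index_a = _residue_atom_index(ens_a, names)
    index_b = _residue_atom_index(ens_b, names)
    xa, xb, used = [], [], []
    for res_a, res_b in cmap.pairs:
        if residue_subset is not None and res_a not in residue_subset:
            continue
        atoms_a = index_a.get(res_a)
        atoms_b = index_b.get(res_b)
        if not atoms_a or not atoms_b:
            continue
        for nm in names:
            if nm in atoms_a and nm in atoms_b:
                xa.append(ens_a.coords[frame_a, atoms_a[nm]])
                xb.append(ens_b.coords[frame_b, atoms_b[nm]])
        used.append((res_a, res_b))
    if not xa:
        raise ValueError("empty atom intersection after selection")
    return np.array(xa), np.array(xb), used


def _residue_atom_index(ens: FrameEnsemble, names: tuple) -> dict:
    out: dict = {}
    a = ens.atoms
    mask = a["name"].isin(names)
    for i in np.flatnonzero(mask.to_numpy()):
        key = (a.at[i, "chain"], a.at[i, "resnum"])
        out.setdefault(key, {})[a.at[i, "name"]] = i
    return out


def align_and_rmsd(
    ens_a: FrameEnsemble,
    ens_b: FrameEnsemble,
    cmap: CorrespondenceMap | None = None,
    selection: str = "CA",
    frame_a: int = 0,
    frame_b: int = 0,
) -> Superposition:
    """Superpose structure A onto B over alignment-mapped selection atoms."""
    if cmap is None:
        cmap = CorrespondenceMap.from_structures(ens_a, ens_b)
    if not cmap.pairs:
        raise ValueError("correspondence map is empty")
    xa, xb, used = _mapped_coordinates(ens_a, ens_b, cmap, selection, frame_a, frame_b)
    sup = superpose(xa, xb)
    sup.coverage = cmap.coverage * (len(used) / len(cmap.pairs))
    return sup


def segment_rmsd(
    ens_a: FrameEnsemble,
    ens_b: FrameEnsemble,
    cmap: CorrespondenceMap,
    segment_map: SegmentMap,
    selection: str = "CA",
    frame_a: int = 0,
    frame_b: int = 0,
) -> pd.DataFrame:
    """Per-segment RMSD table with both fitting modes.

    ``rmsd_global``: one superposition on all mapped atoms, then per-segment
    deviation (captures rigid-body displacement of a segment).
    ``rmsd_local``: refit per segment (captures internal deformation only).
    Segments resolving to fewer than 3 mapped atoms are skipped with a warning.
    """
    xa_all, xb_all, _ = _mapped_coordinates(ens_a, ens_b, cmap, selection, frame_a, frame_b)
    global_fit = superpose(xa_all, xb_all)
    rows = []
    for name in segment_map.names():
        residues = set()
        seg_mask = segment_map.mask(ens_a.atoms, name)
        seg_res = set(zip(ens_a.atoms["chain"][seg_mask], ens_a.atoms["resnum"][seg_mask]))
        residues = {ra for ra, _ in cmap.pairs if ra in seg_res}
        try:
            xa, xb, used = _mapped_coordinates(
                ens_a, ens_b, cmap, selection, frame_a, frame_b, residue_subset=residues
            )
        except ValueError:
            xa = np.empty((0, 3))
        if len(xa) < 3:
            warnings.warn(f"segment {name!r}: fewer than 3 mapped atoms, skipped")
            continue
        moved = global_fit.apply(xa)
        rmsd_global = float(np.sqrt(np.mean(np.sum((moved - xb) ** 2, axis=1))))
        rmsd_local = superpose(xa, xb).rmsd
        rows.append(
            {"segment": name, "n_atoms": len(xa), "rmsd_global": rmsd_global, "rmsd_local": rmsd_local}
        )
    return pd.DataFrame(rows, columns=["segment", "n_atoms", "rmsd_global", "rmsd_local"])


@dataclass
class RMSDSeries:
    """Superposed RMSD of every frame against a fixed reference."""

    frame_labels: list
    rmsd: np.ndarray
    selection: str = "CA"
    reference: str = "first-frame"

    def __post_init__(self) -> None:
        self.rmsd = np.asarray(self.rmsd, float)
        if np.any(self.rmsd < 0):
            raise ValueError("rmsd values must be non-negative")


def _selection_coords(ensemble: FrameEnsemble, selection: str) -> np.ndarray:
    mask = atom_filter_mask(ensemble.atoms, selection)
    if not mask.any():
        raise ValueError(f"selection {selection!r} matches no atoms")
    return ensemble.coords[:, mask]


def rmsd_timeseries(
    ensemble: FrameEnsemble, reference: object = "first-frame", selection: str = "CA"
) -> RMSDSeries:
    """Per-frame superposed RMSD against first frame, last frame or external coords."""
    if ensemble.n_frames < 2:
        raise ValueError("need at least 2 frames for a time series")
    X = _selection_coords(ensemble, selection)
    if isinstance(reference, str):
        if reference == "first-frame":
            ref = X[0]
        elif reference == "last-frame":
            ref = X[-1]
        else:
            raise ValueError("reference must be 'first-frame', 'last-frame' or coordinates")
        ref_name = reference
    else:
        ref = np.asarray(reference, float)
        ref_name = "external"
    values = np.array([superpose(X[f], ref).rmsd for f in range(X.shape[0])])
    return RMSDSeries(frame_labels=list(ensemble.frame_labels), rmsd=values,
                      selection=selection, reference=ref_name)


def detect_equilibration(
    series: RMSDSeries, window: int = 20, slope_tol: float = 0.02, range_tol: float = 2.0
):
    """Earliest frame after which the RMSD series has plateaued.

    A window is "flat" when the linear slope of RMSD over it is within
    ``±slope_tol`` (Å/frame) and its range (max − min) is within
    ``range_tol`` (the ~2 Å plateau criterion).  Returns the start of the
    first flat window from which *every* subsequent window is also flat, or
    ``None`` if the series never settles.
    """
    v = series.rmsd
    n = len(v)
    if not 1 < window < n:
        raise ValueError("window must satisfy 1 < window < series length")
    x = np.arange(window, dtype=float)
    x = x - x.mean()
    denom = float(np.sum(x * x))
    starts = np.arange(0, n - window + 1)
    flat = np.empty(len(starts), dtype=bool)
    for s in starts:
        w = v[s : s + window]
        slope = float(np.sum(x * (w - w.mean()))) / denom
        flat[s] = abs(slope) <= slope_tol and (w.max() - w.min()) <= range_tol
    if not flat[-1]:
        return None
    # longest all-flat suffix
    t = len(flat) - 1
    while t > 0 and flat[t - 1]:
        t -= 1
    return int(starts[t])


@dataclass
class ClusterResult:
    """Partition of frames into conformational clusters with centroid frames."""

    assignment: np.ndarray  # frame -> cluster id (0-based, by extraction order)
    centroids: list  # representative frame index per cluster
    threshold: float
    selection: str

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cluster)


def cluster_frames(
    ensemble: FrameEnsemble,
    threshold: float = 2.0,
    selection: str = "backbone",
    rmsd_matrix: np.ndarray | None = None,
) -> ClusterResult:
    """Quality-threshold clustering of frames on pairwise superposed RMSD.

    Iteratively extracts the frame with the most unassigned neighbours within
    ``threshold`` (ties: lowest frame index) together with those neighbours as
    one cluster, until all frames are assigned.  The centroid of a cluster is
    its member minimising the total within-cluster RMSD (ties: lowest index).
    """
    if rmsd_matrix is None:
        rmsd_matrix = pairwise_rmsd_matrix(_selection_coords(ensemble, selection))
    m = rmsd_matrix.shape[0]
    close = rmsd_matrix <= threshold
    unassigned = np.ones(m, dtype=bool)
    assignment = np.full(m, -1, dtype=int)
    centroids = []
    cluster = 0
    while unassigned.any():
        counts = (close & unassigned).sum(axis=1)
        counts[~unassigned] = -1
        leader = int(np.argmax(counts))  # argmax ties -> lowest index
        members = np.flatnonzero(close[leader] & unassigned)
        assignment[members] = cluster
        unassigned[members] = False
        within = rmsd_matrix[np.ix_(members, members)].sum(axis=1)
        centroids.append(int(members[int(np.argmin(within))]))
        cluster += 1
    return ClusterResult(assignment=assignment, centroids=centroids,
                         threshold=threshold, selection=selection)
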