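"""Synthetic channel structures and observation tables with analytic ground truth.

Every pipeline stage is testable offline against constructions whose answers
are known exactly:

* **Ring-stack channels** — stacked rings of carbon atoms tracing a bundle
  radius profile ρ(z).  The pore radius along the axis is analytic:
  ``R(z) = min_j sqrt(ρ_j² + (z − z_j)²) − r_vdW``.
* **Helix-bundle channels** — α-helix-like backbones (Cα lattice of radius
  2.3 Å, 1.5 Å rise, 100° twist per residue) arranged as 6 pore-lining inner
  helices plus 6 outer helices around a common axis.  Each inner helix is
  phased so one Cα points exactly at the axis in the designated filter plane,
  and a glycine band around that residue keeps side-chain Cβ atoms away from
  the constriction; the minimal pore radius is then exactly
  ``ρ(z_f) − 2.3 − r_C`` by construction.  Two states (open/closed) differ by
  the bundle profile at the filter and by an axial spin of designated
  "gating" helices, emulating the helix rearrangements that open and close a
  channel.
* **Perturbed ensembles** — Gaussian atomic noise or rigid per-helix jitter
  standing in for MD snapshots; fully seeded.
* **Simulated cross-linking observations** — outcome tables derived from
  ground-truth state distances through the same span logic the predictor
  uses, with optional symmetric label noise across the crosslinked/none
  boundary.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import crosslink_model as xl
from .distance_analysis import series_from_scalar
from .structure_io import ATOM_COLUMNS, FrameEnsemble, SegmentMap, virtual_cbeta

__all__ = [
    "HelixSpec",
    "ChannelSpec",
    "ChannelTruth",
    "make_helix",
    "make_channel",
    "make_ring_channel",
    "ring_truth",
    "perturb_ensemble",
    "simulate_observations",
    "default_channel_spec",
]

CA_RADIUS = 2.3  # Å, Cα helical lattice radius (the documented helix envelope)
VDW_C = 1.85  # carbon united-atom radius used in the analytic pore truth


@dataclass
class HelixSpec:
    """An idealised α-helix on a cylindrical lattice.

    ``sequence`` is a list of 3-letter residue names (default poly-alanine);
    glycines carry no Cβ.  ``phase_deg`` rotates the helical phase and
    ``z_offset`` shifts the helix along its axis, so callers can place a
    chosen residue at an exact phase and height.
    """

    n_residues: int = 30
    rise: float = 1.5  # Å per residue
    twist: float = 100.0  # degrees per residue
    ca_radius: float = CA_RADIUS
    sequence: list | None = None
    phase_deg: float = 0.0
    z_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("n_residues must be >= 4")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if self.sequence is None:
            self.sequence = ["ALA"] * self.n_residues
        if len(self.sequence) != self.n_residues:
            raise ValueError("sequence length must equal n_residues")


# Backbone atom placement on the helical lattice, relative to the Cα position
# of the same residue: (lattice radius, phase offset in degrees, z offset).
# These reproduce plausible bond geometry (N-Cα ≈ 1.43 Å, Cα-C ≈ 1.49 Å) on
# the default lattice; the construction is an idealisation, not stereochemistry.
_LATTICE = {"N": (1.60, -26.0, -0.90), "C": (1.75, +26.0, +1.05)}
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def make_helix(spec: HelixSpec, chain: str = "A", start_resnum: int = 1) -> tuple[pd.DataFrame, np.ndarray]:
    """Build one helix along +z; returns (atom table, coordinates).

    Consecutive Cα atoms are ~3.8 Å apart (the chord of the default lattice);
    the Cα z-extent is exactly ``(n_residues − 1) · rise``.  Cβ atoms are
    placed by the same ideal tetrahedral construction used for virtual Cβ
    points, so explicit and virtual Cβ agree exactly.
    """
    rows, xyz = [], []
    serial = 1

    def cyl(radius: float, theta_deg: float, z: float) -> np.ndarray:
        t = np.deg2rad(theta_deg)
        return np.array([radius * np.cos(t), radius * np.sin(t), z])

    for i in range(spec.n_residues):
        theta = spec.phase_deg + i * spec.twist
        z = spec.z_offset + i * spec.rise
        resname = spec.sequence[i]
        ca = cyl(spec.ca_radius, theta, z)
        r_n, dth_n, dz_n = _LATTICE["N"]
        r_c, dth_c, dz_c = _LATTICE["C"]
        n_at = cyl(r_n, theta + dth_n, z + dz_n)
        c_at = cyl(r_c, theta + dth_c, z + dz_c)
        # carbonyl O points along the helix axis, slightly outward
        o_dir = np.array([0.25 * np.cos(np.deg2rad(theta + 26.0)), 0.25 * np.sin(np.deg2rad(theta + 26.0)), 0.97])
        o_at = c_at + 1.23 * o_dir / np.linalg.norm(o_dir)
        atoms = [("N", n_at), ("CA", ca), ("C", c_at), ("O", o_at)]
        if resname != "GLY":
            atoms.append(("CB", virtual_cbeta(n_at, ca, c_at)))
        for name, pos in atoms:
            rows.append(
                {
                    "serial": serial,
                    "name": name,
                    "altloc": "",
                    "resname": resname,
                    "chain": chain,
                    "resnum": start_resnum + i,
                    "icode": "",
                    "occupancy": 1.0,
                    "element": _ELEMENTS[name],
                }
            )
            xyz.append(pos)
            serial += 1
    return pd.DataFrame(rows, columns=ATOM_COLUMNS), np.asarray(xyz)


def _rho_interp(control_points: list) -> callable:
    zs = np.array([p[0] for p in control_points], float)
    rs = np.array([p[1] for p in control_points], float)
    if np.any(rs <= 0):
        raise ValueError("bundle radius must stay positive")
    order = np.argsort(zs)
    zs, rs = zs[order], rs[order]

    def rho(z):
        return np.interp(z, zs, rs)

    return rho


@dataclass
class ChannelSpec:
    """A two-state helix-bundle channel with analytic filter geometry.

    ``profile_open`` / ``profile_closed`` are piecewise-linear bundle radius
    control points ``(z, ρ)`` for the 6 inner (pore-lining) helices; the
    outer 6 helices sit ``outer_offset`` further out.  ``gating_helices``
    (indices into the inner ring) are additionally spun by
    ``gating_spin_deg`` about their own axes in the closed state.  A filter
    residue of every inner helix points exactly at the channel axis at
    ``filter_z``; residues within ``gly_band`` of it are glycine.
    """

    n_residues: int = 31
    rise: float = 1.5
    twist: float = 100.0
    profile_open: list = field(default_factory=lambda: [(-25, 16.65), (0, 6.65), (25, 16.65)])
    profile_closed: list = field(default_factory=lambda: [(-25, 14.95), (0, 4.95), (25, 14.95)])
    n_inner: int = 6
    n_outer: int = 6
    outer_offset: float = 5.0
    gating_helices: tuple = (1, 3, 5)
    gating_spin_deg: float = 35.0
    filter_z: float = 0.0
    gly_band: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 8:
            raise ValueError("need at least 8 residues per helix")

    def rho(self, state: str) -> callable:
        if state == "open":
            return _rho_interp(self.profile_open)
        if state == "closed":
            return _rho_interp(self.profile_closed)
        raise ValueError("state must be 'open' or 'closed'")


@dataclass
class ChannelTruth:
    """Ground-truth record emitted next to every generated channel."""

    state: str
    min_radius: float  # analytic pore radius at the filter
    filter_z: float
    reporter_distances: dict  # pair id -> exact Cβ–Cβ distance (Å)
    reporter_pairs: dict  # pair id -> ((chain, resnum), (chain, resnum))
    spec: dict = field(default_factory=dict)


def default_channel_spec() -> ChannelSpec:
    """The reference two-state channel: open filter radius 2.5 Å, closed 0.8 Å."""
    return ChannelSpec()


def make_channel(spec: ChannelSpec, state: str = "open") -> tuple[FrameEnsemble, ChannelTruth]:
    """Build one conformational state of the bundle, with its ground truth.

    The analytic minimal pore radius is ``ρ_state(filter_z) − 2.3 − 1.85``
    (inner Cα lattice plus carbon vdW), achieved exactly at the filter plane
    by the inward-pointing filter Cα ring.  Reporter Cβ–Cβ distances are
    read off the constructed coordinates and are exact.

    Raises a construction error when the bundle radius would make inner
    helices overlap (inter-axis distance below twice the helix envelope).
    """
    rho = spec.rho(state)
    j = spec.n_residues // 2  # filter residue index
    # steric check at the filter, the tightest point of the bundle
    min_sep = 2.0 * rho(spec.filter_z) * np.sin(np.pi / spec.n_inner)
    if min_sep < 2.0 * CA_RADIUS:
        raise ValueError(
            f"inner helices overlap: inter-axis distance {min_sep:.2f} Å < {2 * CA_RADIUS:.2f} Å"
        )

    sequence = ["ALA"] * spec.n_residues
    for k in range(j - spec.gly_band, j + spec.gly_band + 1):
        if 0 <= k < spec.n_residues:
            sequence[k] = "GLY"

    tables, coords_list = [], []
    chains = string.ascii_uppercase
    helices = []
    for h in range(spec.n_inner + spec.n_outer):
        inner = h < spec.n_inner
        if inner:
            azimuth = 360.0 * h / spec.n_inner
            offset = 0.0
        else:
            azimuth = 360.0 * (h - spec.n_inner) / spec.n_outer + 180.0 / spec.n_outer
            offset = spec.outer_offset
        spin = 0.0
        if state == "closed" and inner and h in spec.gating_helices:
            spin = spec.gating_spin_deg
        # phase chosen so residue j points at the channel axis (local θ = 180°)
        phase = 180.0 - j * spec.twist + spin
        hspec = HelixSpec(
            n_residues=spec.n_residues,
            rise=spec.rise,
            twist=spec.twist,
            sequence=list(sequence) if inner else ["ALA"] * spec.n_residues,
            phase_deg=phase,
            z_offset=spec.filter_z - j * spec.rise,
        )
        table, xyz = make_helix(hspec, chain=chains[h], start_resnum=1)
        # bend the helix radially outward along the state's bundle profile;
        # the shift is rigid per residue (evaluated at the residue's Cα z) so
        # internal residue geometry is preserved exactly
        ca_z = {
            int(table.at[i, "resnum"]): xyz[i, 2]
            for i in range(len(table))
            if table.at[i, "name"] == "CA"
        }
        res_z = np.array([ca_z[int(rn)] for rn in table["resnum"]])
        shifted = xyz.copy()
        shifted[:, 0] += rho(res_z) + offset
        t = np.deg2rad(azimuth)
        rot = np.array([[np.cos(t), -np.sin(t), 0.0], [np.sin(t), np.cos(t), 0.0], [0.0, 0.0, 1.0]])
        shifted = shifted @ rot.T
        tables.append(table)
        coords_list.append(shifted)
        helices.append(chains[h])

    atoms = pd.concat(tables, ignore_index=True)
    atoms["serial"] = np.arange(1, len(atoms) + 1)
    coords = np.concatenate(coords_list, axis=0)
    ensemble = FrameEnsemble(atoms=atoms, coords=coords[None], frame_labels=[state])

    truth_min = float(rho(spec.filter_z) - CA_RADIUS - VDW_C)
    reporter_pairs, reporter_distances = _reporters(ensemble, spec, j)
    truth = ChannelTruth(
        state=state,
        min_radius=truth_min,
        filter_z=spec.filter_z,
        reporter_distances=reporter_distances,
        reporter_pairs=reporter_pairs,
        spec={
            "n_inner": spec.n_inner,
            "n_outer": spec.n_outer,
            "n_residues": spec.n_residues,
            "filter_residue": j + 1,
            "gating_helices": list(spec.gating_helices),
            "state": state,
        },
    )
    return ensemble, truth


def _reporters(ensemble: FrameEnsemble, spec: ChannelSpec, j: int) -> tuple[dict, dict]:
    """Reporter Cβ pairs across the pore at several depths, with exact distances."""
    from .distance_analysis import ResiduePair, pair_distances

    chains = string.ascii_uppercase
    half = spec.n_inner // 2
    offsets = (-6, -3, 4, 7)
    pairs, ids = {}, {}
    out = {}
    for i, off in enumerate(offsets):
        a_chain = chains[i % spec.n_inner]
        b_chain = chains[(i + half) % spec.n_inner]  # the helix across the pore
        res = j + 1 + off
        pid = f"R{i + 1}_{a_chain}{res}-{b_chain}{res}"
        rp = ResiduePair(id=pid, chain_a=a_chain, res_a=res, chain_b=b_chain, res_b=res)
        series = pair_distances(ensemble, [rp], state="truth")[0]
        ids[pid] = ((a_chain, res), (b_chain, res))
        out[pid] = float(series.distances[0])
    return ids, out


def channel_segment_map(spec: ChannelSpec, half_width: float = 12.0) -> SegmentMap:
    """Segment map for a generated channel: per-helix segments + membrane window."""
    chains = string.ascii_uppercase
    segments = {
        f"H{h + 1}": [(chains[h], 1, spec.n_residues)] for h in range(spec.n_inner + spec.n_outer)
    }
    segments["membrane"] = [
        (chains[h], 1, spec.n_residues) for h in range(spec.n_inner + spec.n_outer)
    ]
    return SegmentMap(
        segments=segments,
        membrane_z=(spec.filter_z - half_width, spec.filter_z + half_width),
    )


def make_ring_channel(
    control_points: list,
    z_lo: float,
    z_hi: float,
    ring_spacing: float = 0.5,
    atoms_per_ring: int = 16,
    center_slope: float = 0.0,
) -> FrameEnsemble:
    """A channel of stacked carbon-atom rings following ρ(z).

    ``center_slope`` tilts the ring-centre line off the z axis (x = slope·z)
    to exercise the centre-tracking walk.  The analytic pore radius is given
    by :func:`ring_truth`.
    """
    rho = _rho_interp(control_points)
    zs = np.arange(z_lo, z_hi + 0.5 * ring_spacing, ring_spacing)
    angles = np.linspace(0, 2 * np.pi, atoms_per_ring, endpoint=False)
    rows, xyz = [], []
    serial = 1
    for ri, z in enumerate(zs):
        r = float(rho(z))
        for a in angles:
            rows.append(
                {
                    "serial": serial,
                    "name": "C",
                    "altloc": "",
                    "resname": "UNK",
                    "chain": "R",
                    "resnum": ri + 1,
                    "icode": "",
                    "occupancy": 1.0,
                    "element": "C",
                }
            )
            xyz.append([r * np.cos(a) + center_slope * z, r * np.sin(a), z])
            serial += 1
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    return FrameEnsemble(atoms=atoms, coords=np.asarray(xyz)[None], frame_labels=["ring"])


def ring_truth(control_points: list, z_lo: float, z_hi: float, ring_spacing: float = 0.5):
    """Analytic pore radius of an (untilted) ring-stack channel.

    For a probe centred on the axis at height z the nearest approach to ring
    j is ``sqrt(ρ_j² + (z − z_j)²)``; the pore radius subtracts the carbon
    vdW radius.  On-axis centring is optimal by symmetry.
    """
    rho = _rho_interp(control_points)
    zs = np.arange(z_lo, z_hi + 0.5 * ring_spacing, ring_spacing)
    rj = np.asarray(rho(zs), float)

    def truth(z):
        z = np.atleast_1d(np.asarray(z, float))
        d = np.sqrt(rj[None, :] ** 2 + (z[:, None] - zs[None, :]) ** 2)
        out = d.min(axis=1) - VDW_C
        return out if out.size > 1 else float(out[0])

    return truth


def perturb_ensemble(
    structure: FrameEnsemble,
    sigma: float,
    n_frames: int,
    seed: int = 0,
    mode: str = "iid-atomic",
) -> FrameEnsemble:
    """Noisy multi-frame ensemble around a single-frame structure.

    ``iid-atomic`` adds N(0, σ²I) to every atom independently;
    ``rigid-helix-jitter`` applies a small random rigid motion per chain
    (translation N(0, σ²I); rotation about the chain centroid with angle
    N(0, (2σ)²) degrees per Å of σ), preserving local geometry.
    Reproducible given ``seed``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    base = structure.coords[0]
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, base.shape[0], 3))
    if mode == "iid-atomic":
        frames[:] = base[None] + rng.normal(0.0, sigma, size=(n_frames, base.shape[0], 3)) if sigma > 0 else base[None]
    elif mode == "rigid-helix-jitter":
        chains = structure.atoms["chain"].to_numpy()
        chain_ids = list(dict.fromkeys(chains))
        for f in range(n_frames):
            frame = base.copy()
            for cid in chain_ids:
                idx = np.flatnonzero(chains == cid)
                centroid = base[idx].mean(axis=0)
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                angle = np.deg2rad(rng.normal(0.0, 2.0 * sigma))
                K = np.array(
                    [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
                )
                R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
                shift = rng.normal(0.0, sigma, 3)
                frame[idx] = (base[idx] - centroid) @ R.T + centroid + shift
            frames[f] = frame
    else:
        raise ValueError("mode must be 'iid-atomic' or 'rigid-helix-jitter'")
    return FrameEnsemble(
        atoms=structure.atoms,
        coords=frames,
        frame_labels=[f"frame{f}" for f in range(n_frames)],
    )


def simulate_observations(
    truth_distances: dict,
    panel: list | None = None,
    state_mix: float = 0.5,
    error_rate: float = 0.0,
    seed: int = 0,
    **classify_kwargs,
) -> pd.DataFrame:
    """Simulated cross-linking outcome table from ground-truth state distances.

    ``truth_distances`` maps pair id -> {state: distance}.  The noise-free
    outcome per (pair, reagent) applies the span classification to each
    state's distance and keeps the best across states (full > partial >
    none), downgrading full to partial when only a minority conformation
    (fraction < 0.5 under ``state_mix`` = fraction of the *first* state)
    supports it.  With probability ``error_rate`` the outcome is flipped
    across the crosslinked/none boundary (symmetric label noise).
    """
    if not 0 <= state_mix <= 1 or not 0 <= error_rate <= 1:
        raise ValueError("state_mix and error_rate must lie in [0, 1]")
    panel = xl.default_panel() if panel is None else panel
    panel = [r for r in panel if not r.monofunctional]
    rng = np.random.default_rng(seed)
    rows = []
    for pair_id in sorted(truth_distances):
        by_state = truth_distances[pair_id]
        states = list(by_state)
        fractions = {states[0]: state_mix} if len(states) == 1 else {
            states[0]: state_mix,
            **{s: (1.0 - state_mix) / (len(states) - 1) for s in states[1:]},
        }
        for reagent in panel:
            best = "none"
            best_rank = 0
            for s, d in by_state.items():
                call = xl.classify_pair(
                    series_from_scalar(pair_id, s, d), reagent, **classify_kwargs
                ).call
                outcome = {
                    "spontaneous_disulfide": "full",
                    "bridgeable_full": "full",
                    "bridgeable_partial": "partial",
                    "not_bridgeable": "none",
                }[call]
                if outcome == "full" and fractions.get(s, 0.0) < 0.5:
                    outcome = "partial"
                rank = {"none": 0, "partial": 1, "full": 2}[outcome]
                if rank > best_rank:
                    best, best_rank = outcome, rank
            if rng.random() < error_rate:
                best = "none" if best != "none" else ("partial", "full")[rng.integers(2)]
            rows.append({"pair_id": pair_id, "reagent": reagent.name, "outcome": best})
    return pd.DataFrame(rows, columns=["pair_id", "reagent", "outcome"])
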