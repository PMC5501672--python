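"""Channel pore-radius profiling by probe-sphere maximisation.

The pore radius R_pore(z) at an axial position z is the radius of the
largest sphere, centred in the plane perpendicular to the channel axis at z,
that touches no atom: for an in-plane centre p,

    R(p) = min_i ( |p - x_i| - r_i )

over all atoms i with van der Waals radii r_i, and R_pore(z) = max_p R(p).
The maximisation runs simulated annealing in the plane (several restarts)
followed by a deterministic Nelder–Mead polish, walking slice by slice along
the axis and seeding each slice from the previous centre.  Radii are capped
at ``r_max_cap`` ("pore exit"), and per-frame profiles are averaged over an
ensemble on a common z grid.

The narrowest point of the averaged profile is compared against the hydrated
Cl⁻ radius window (1.6–1.9 Å) to classify a conformation as conducting
(open), non-conducting (closed) or marginal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .structure_io import FrameEnsemble, RadiusTable, SegmentMap, atom_filter_mask

__all__ = [
    "AnnealParams",
    "ProfileParams",
    "SliceResult",
    "PoreProfile",
    "EnsembleProfile",
    "ConductanceCriteria",
    "slice_radius",
    "compute_profile",
    "ensemble_profile",
    "locate_minimum",
    "classify_conductance",
    "principal_axis",
    "write_profile_tsv",
    "profile_summary",
]


@dataclass
class AnnealParams:
    """Simulated-annealing schedule for the in-plane probe search."""

    n_iterations: int = 120
    initial_temperature: float = 1.0
    step_sigma: float = 0.6  # Å, in-plane proposal scale (multiplied by temperature)
    cooling: float = 0.96
    restarts: int = 3

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class ProfileParams:
    """Parameters of a pore-profile computation.

    ``axis`` is either an explicit 3-vector or ``"auto"`` (principal inertial
    axis of the Cα atoms inside the membrane window).  ``z_step`` is the slice
    spacing, ``z_margin`` extends the walk beyond the membrane window /
    atom extent, ``r_max_cap`` is the pore-exit sentinel radius.
    """

    axis: object = "auto"
    z_step: float = 0.5
    z_margin: float = 5.0
    r_max_cap: float = 15.0
    anneal: AnnealParams = field(default_factory=AnnealParams)
    seed: int = 0
    include_hydrogens: bool = False
    flip_axis: bool = False  # orient increasing z toward the intracellular side instead

    def __post_init__(self) -> None:
        if self.z_step <= 0:
            raise ValueError("z_step must be positive")
        if self.r_max_cap <= 0:
            raise ValueError("r_max_cap must be positive")


@dataclass
class SliceResult:
    radius: float
    center: np.ndarray  # 3-vector, the optimised probe centre
    capped: bool
    unbounded: bool = False


@dataclass
class PoreProfile:
    """Single-frame radius profile along the channel axis."""

    z: np.ndarray
    radius: np.ndarray
    center_path: np.ndarray  # (n_slices, 3)
    capped: np.ndarray  # bool per slice
    frame_label: object = None

    def __post_init__(self) -> None:
        if not (len(self.z) == len(self.radius) == len(self.center_path) == len(self.capped)):
            raise ValueError("profile arrays must have equal length")
        if len(self.z) > 1 and not np.all(np.diff(self.z) > 0):
            raise ValueError("z must be strictly increasing")


@dataclass
class EnsembleProfile:
    """Ensemble mean ± SD radius profile on a common z grid."""

    z: np.ndarray
    mean_radius: np.ndarray
    sd_radius: np.ndarray
    n_contributing: np.ndarray  # frames contributing per z (uncapped, in range)
    profiles: list = field(default_factory=list)
    single_frame_warning: bool = False


@dataclass
class ConductanceCriteria:
    """Hydrated chloride-ion radius window (Å) used to classify conductance."""

    r_ion_low: float = 1.6
    r_ion_high: float = 1.9

    def __post_init__(self) -> None:
        if not 0 < self.r_ion_low <= self.r_ion_high:
            raise ValueError("require 0 < r_ion_low <= r_ion_high")


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(n)))] = 1.0
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def slice_radius(
    coords: np.ndarray,
    radii: np.ndarray,
    point_seed: np.ndarray,
    plane_normal: np.ndarray,
    params: ProfileParams,
    rng: np.random.Generator | None = None,
) -> SliceResult:
    """Largest probe sphere centred in one plane.

    Maximises ``min_i(|p - x_i| - r_i)`` over in-plane points p within
    ``r_max_cap`` of the seed, by seeded simulated annealing plus a
    deterministic local polish.  The returned radius is never below the value
    at the seed and is capped at ``r_max_cap``.
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    seed = np.asarray(point_seed, float)
    cap = params.r_max_cap
    if rng is None:
        rng = np.random.default_rng(params.seed)

    # Atoms that can possibly constrain a probe centred within `cap` of the seed.
    d_seed = np.linalg.norm(coords - seed, axis=1)
    keep = d_seed - radii <= 2.0 * cap
    if not np.any(keep):
        return SliceResult(radius=cap, center=seed.copy(), capped=True, unbounded=True)
    atoms = coords[keep]
    r = radii[keep]

    u, v = _plane_basis(plane_normal)

    def f(xy: np.ndarray) -> float:
        p = seed + xy[0] * u + xy[1] * v
        # clamped at the cap so the search has no incentive to leave the pore
        return min(float(np.min(np.linalg.norm(atoms - p, axis=1) - r)), cap)

    an = params.anneal
    best_xy = np.zeros(2)
    best_val = f(best_xy)
    for restart in range(an.restarts):
        cur = np.zeros(2) if restart == 0 else rng.normal(0.0, 2.0, 2)
        nrm = np.linalg.norm(cur)
        if nrm > cap:
            cur *= cap / nrm
        cur_val = f(cur)
        if restart > 0 and cur_val < 0 <= best_val:
            # restart landed inside an atom (or beyond the wall): fall back
            cur = np.zeros(2)
            cur_val = f(cur)
        if cur_val > best_val:
            best_val, best_xy = cur_val, cur.copy()
        temp = an.initial_temperature
        for _ in range(an.n_iterations):
            prop = cur + rng.normal(0.0, an.step_sigma * max(temp, 0.1), 2)
            nrm = np.linalg.norm(prop)
            if nrm > cap:
                prop *= cap / nrm
            prop_val = f(prop)
            if prop_val < 0 <= cur_val:
                # never step from open space into atom overlap: this is what
                # keeps the walk inside the pore instead of tunnelling through
                # the wall into the bulk outside
                temp *= an.cooling
                continue
            delta = prop_val - cur_val
            if delta >= 0 or rng.random() < np.exp(delta / max(temp, 1e-9)):
                cur, cur_val = prop, prop_val
                if cur_val > best_val:
                    best_val, best_xy = cur_val, cur.copy()
            temp *= an.cooling

    # Deterministic polish; Nelder-Mead is robust to the kinks of a min-of-cones
    # surface.  Run twice so the simplex re-expands around the first optimum.
    for _ in range(2):
        res = minimize(
            lambda xy: -f(xy),
            best_xy,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 600},
        )
        if -res.fun > best_val:
            best_val, best_xy = -res.fun, res.x

    center = seed + best_xy[0] * u + best_xy[1] * v
    if best_val >= cap:
        return SliceResult(radius=cap, center=center, capped=True)
    return SliceResult(radius=max(best_val, 0.0), center=center, capped=False)


def principal_axis(
    ensemble: FrameEnsemble, frame: int = 0, segment_map: SegmentMap | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Channel axis as the principal inertial axis of Cα atoms.

    Uses the Cα atoms inside the segment named ``membrane`` when the map
    defines one, otherwise all Cα atoms (falling back to all atoms).  Returns
    ``(unit_axis, anchor_point)``; the sign is chosen so the axis points
    toward +z of the input frame.
    """
    mask = atom_filter_mask(ensemble.atoms, "CA")
    if not mask.any():
        mask = np.ones(ensemble.n_atoms, dtype=bool)
    if segment_map is not None and "membrane" in segment_map:
        seg = segment_map.mask(ensemble.atoms, "membrane")
        if (mask & seg).any():
            mask &= seg
    pts = ensemble.coords[frame][mask]
    center = pts.mean(axis=0)
    centered = pts - center
    cov = centered.T @ centered
    w, vec = np.linalg.eigh(cov)
    if w[-1] - w[0] < 1e-9:
        raise ValueError("degenerate atom distribution: no unique principal axis")
    axis = vec[:, -1]
    if axis[2] < 0:
        axis = -axis
    return axis, center


def compute_profile(
    ensemble: FrameEnsemble,
    params: ProfileParams,
    segment_map: SegmentMap | None = None,
    radius_table: RadiusTable | None = None,
    frame: int = 0,
) -> PoreProfile:
    """Pore radius profile of a single frame.

    Walks the axis from low to high z in ``z_step`` increments, seeding each
    slice's probe search from the previous slice's optimised centre, and trims
    the result to the maximal contiguous uncapped run containing the membrane
    window (or the narrowest slice when no window is given).  Deterministic
    given ``params.seed``.
    """
    radius_table = radius_table or RadiusTable()
    keep = np.ones(ensemble.n_atoms, dtype=bool)
    if not params.include_hydrogens:
        keep = ensemble.atoms["element"].to_numpy() != "H"
    coords = ensemble.coords[frame][keep]
    if coords.shape[0] == 0:
        raise ValueError("no atoms left after hydrogen exclusion")
    radii = radius_table.for_atoms(ensemble.atoms)[keep]

    if isinstance(params.axis, str) and params.axis == "auto":
        axis, anchor = principal_axis(ensemble, frame=frame, segment_map=segment_map)
    else:
        axis = np.asarray(params.axis, float)
        axis = axis / np.linalg.norm(axis)
        anchor = coords.mean(axis=0)
    if params.flip_axis:
        axis = -axis

    proj = (coords - anchor) @ axis
    if segment_map is not None and segment_map.membrane_z is not None:
        z_lo, z_hi = segment_map.membrane_z
        z_lo -= params.z_margin
        z_hi += params.z_margin
        window = segment_map.membrane_z
    else:
        z_lo, z_hi = proj.min() - params.z_margin, proj.max() + params.z_margin
        window = None

    z_grid = np.arange(z_lo, z_hi + 0.5 * params.z_step, params.z_step)
    results: list[SliceResult] = []
    prev_center = None
    prev_z = None
    for k, z in enumerate(z_grid):
        on_axis = anchor + z * axis
        if prev_center is not None:
            seed = prev_center + (z - prev_z) * axis
        else:
            seed = on_axis
        rng = np.random.default_rng([max(params.seed, 0), frame, k])
        res = slice_radius(coords, radii, seed, axis, params, rng=rng)
        results.append(res)
        if not res.capped:
            prev_center, prev_z = res.center, z
        else:
            prev_center, prev_z = None, None
    radius = np.array([r.radius for r in results])
    capped = np.array([r.capped for r in results])
    centers = np.stack([r.center for r in results])

    sel = _trim_run(z_grid, capped, radius, window)
    return PoreProfile(
        z=z_grid[sel],
        radius=radius[sel],
        center_path=centers[sel],
        capped=capped[sel],
        frame_label=ensemble.frame_labels[frame],
    )


def _trim_run(z: np.ndarray, capped: np.ndarray, radius: np.ndarray, window) -> slice:
    """Maximal contiguous uncapped run containing the membrane window (or the minimum)."""
    if capped.all():
        return slice(None)
    runs = []
    start = None
    for i, c in enumerate(capped):
        if not c and start is None:
            start = i
        elif c and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(capped)))
    if window is not None:
        mid = 0.5 * (window[0] + window[1])
    else:
        mid = z[np.argmin(np.where(capped, np.inf, radius))]
    for a, b in runs:
        if z[a] <= mid <= z[b - 1]:
            return slice(a, b)
    # fall back to the longest run
    a, b = max(runs, key=lambda r: r[1] - r[0])
    return slice(a, b)


def ensemble_profile(
    ensemble: FrameEnsemble,
    params: ProfileParams,
    segment_map: SegmentMap | None = None,
    radius_table: RadiusTable | None = None,
) -> EnsembleProfile:
    """Per-frame profiles interpolated onto a common z grid, with mean ± SD.

    The first frame's grid is the common grid; capped or out-of-range slices
    are excluded from the statistics (contribution counts reported).  SD is
    the population standard deviation.
    """
    profiles = [
        compute_profile(ensemble, params, segment_map, radius_table, frame=f)
        for f in range(ensemble.n_frames)
    ]
    z_ref = profiles[0].z
    vals = np.full((len(profiles), len(z_ref)), np.nan)
    for i, p in enumerate(profiles):
        ok = ~p.capped
        if ok.sum() == 0:
            continue
        zi, ri = p.z[ok], p.radius[ok]
        in_range = (z_ref >= zi[0]) & (z_ref <= zi[-1])
        vals[i, in_range] = np.interp(z_ref[in_range], zi, ri)
    n = np.sum(~np.isnan(vals), axis=0)
    keep = n > 0
    vals = vals[:, keep]
    mean = np.nanmean(vals, axis=0)
    sd = np.where(n[keep] > 1, np.nanstd(vals, axis=0), 0.0)
    return EnsembleProfile(
        z=z_ref[keep],
        mean_radius=mean,
        sd_radius=sd,
        n_contributing=n[keep],
        profiles=profiles,
        single_frame_warning=ensemble.n_frames < 2,
    )


def locate_minimum(profile: EnsembleProfile, window: tuple | None = None) -> tuple[float, float]:
    """Global minimum of the mean radius within a z window (ties -> smallest z)."""
    mask = np.ones(len(profile.z), dtype=bool)
    if window is not None:
        mask = (profile.z >= window[0]) & (profile.z <= window[1])
    if not mask.any():
        raise ValueError("window does not overlap the profile")
    z, r = profile.z[mask], profile.mean_radius[mask]
    i = int(np.argmin(r))  # argmin returns the first (lowest-z) minimum
    return float(z[i]), float(r[i])


def classify_conductance(
    profile: EnsembleProfile,
    criteria: ConductanceCriteria | None = None,
    window: tuple | None = None,
) -> str:
    """``open`` / ``closed`` / ``marginal`` against the hydrated-Cl⁻ radius window."""
    criteria = criteria or ConductanceCriteria()
    _, r_min = locate_minimum(profile, window)
    if r_min >= criteria.r_ion_high:
        return "open"
    if r_min < criteria.r_ion_low:
        return "closed"
    return "marginal"


def write_profile_tsv(profile: EnsembleProfile, path) -> None:
    import pandas as pd

    n_frames = len(profile.profiles) or 1
    pd.DataFrame(
        {
            "z": profile.z,
            "mean_radius": profile.mean_radius,
            "sd_radius": profile.sd_radius,
            "n_frames": profile.n_contributing,
            "capped_fraction": 1.0 - profile.n_contributing / n_frames,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")


def profile_summary(
    profile: EnsembleProfile,
    criteria: ConductanceCriteria | None = None,
    window: tuple | None = None,
) -> dict:
    z_min, r_min = locate_minimum(profile, window)
    return {
        "z_min": z_min,
        "min_radius": r_min,
        "classification": classify_conductance(profile, criteria, window),
        "n_frames": len(profile.profiles),
    }
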