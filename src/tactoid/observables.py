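"""Structural and convergence observables.

Implements the analysis suite used to characterise polyelectrolyte-
nanoplatelet complexes:

* complexation probability per bead, time-averaged number of complexed
  platelets <N> and the complexed charge-ratio beta_c;
* radius of gyration of the chain (optionally normalised by an
  undisturbed-chain reference Rg0);
* radial distribution function g(r) between platelet sites;
* the site-site structure factor, either directly

      S(q) = (1/N) sum_ij sin(q r_ij) / (q r_ij)

  or through g(r) with a sin(pi r/Rc)/(pi r/Rc) window that suppresses
  finite-box truncation ripple (S_w);
* the Bragg d-spacing d = 2 pi / q_max from the high-q stacking peak, and
  the Kratky presentation q^2 S(q);
* a heuristic shape classifier (compact stack / extended band / dissolved)
  for state-diagram sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import signal

from .state import BEAD, SITE, SystemState, minimum_image
from .trajectory import Trajectory

DEFAULT_EQUILIBRATION_FRACTION = 0.2


def default_contact_threshold(
    site_diameter: float = 1.0, bead_diameter: float = 0.4, margin: float = 0.7
) -> float:
    """Bead-site contact cutoff R_site + R_bead + margin (1.4 nm by default)."""
    return 0.5 * site_diameter + 0.5 * bead_diameter + margin


@dataclass
class ComplexationResult:
    pc_per_bead: np.ndarray  # (Nb,) probability each bead is complexed
    mean_complexed: float  # <N>, time-averaged complexed platelet count
    sem_complexed: float
    beta_c: float  # from the rounded <N>
    contact_threshold: float  # nm
    n_frames: int
    per_frame_complexed: np.ndarray = field(default=None, repr=False)


def _as_frames(traj: Union[Trajectory, SystemState]) -> tuple[np.ndarray, SystemState]:
    if isinstance(traj, SystemState):
        return traj.positions[None], traj
    return traj.frames, traj.state_at(0)


def complexation_probability(
    traj: Union[Trajectory, SystemState],
    threshold: Optional[float] = None,
    equilibration_fraction: float = DEFAULT_EQUILIBRATION_FRACTION,
) -> ComplexationResult:
    """Per-bead complexation probability and the complexed platelet count.

    A bead is complexed in a frame when its centre lies within ``threshold``
    of any platelet site centre (minimum image); a platelet is complexed
    when any of its sites is within ``threshold`` of any bead.  beta_c uses
    the rounded time-average <N> (plateau counting) with the platelet net
    charge and total chain charge taken from the stored topology.
    """
    frames, template = _as_frames(traj)
    if isinstance(traj, Trajectory):
        start = int(np.ceil(len(frames) * equilibration_fraction))
        frames = frames[start:] if len(frames) > 1 else frames
    if len(frames) == 0:
        raise ValueError("empty trajectory")
    groups = template.platelet_site_groups()
    beads = template.bead_indices
    if len(groups) == 0 or len(beads) == 0:
        raise ValueError("need at least one platelet and one bead")
    if threshold is None:
        threshold = default_contact_threshold(
            site_diameter=float(template.diameters[groups[0][0]]),
            bead_diameter=float(template.diameters[beads[0]]),
        )
    box = template.box_length
    sites = np.concatenate(groups)
    site_platelet = np.concatenate([np.full(len(g), i) for i, g in enumerate(groups)])
    n_p = len(groups)

    pc_counts = np.zeros(len(beads))
    per_frame_n = np.zeros(len(frames))
    for fi, pos in enumerate(frames):
        dr = minimum_image(pos[beads][:, None, :] - pos[sites][None, :, :], box)
        close = (dr**2).sum(axis=-1) < threshold**2  # (Nb, Nsites)
        pc_counts += close.any(axis=1)
        complexed = np.zeros(n_p, dtype=bool)
        hit = close.any(axis=0)
        complexed[site_platelet[hit]] = True
        per_frame_n[fi] = complexed.sum()

    mean_n = float(per_frame_n.mean())
    sem = float(per_frame_n.std(ddof=1) / math.sqrt(len(frames))) if len(frames) > 1 else 0.0
    zp = float(template.charges[groups[0]].sum())
    chain_charge = float(template.charges[beads].sum())
    if round(mean_n) == 0:
        beta_c = 0.0
    elif chain_charge != 0:
        beta_c = abs(round(mean_n) * zp / chain_charge)
    else:
        beta_c = float("nan")
    return ComplexationResult(
        pc_per_bead=pc_counts / len(frames),
        mean_complexed=mean_n,
        sem_complexed=sem,
        beta_c=beta_c,
        contact_threshold=threshold,
        n_frames=len(frames),
        per_frame_complexed=per_frame_n,
    )


@dataclass
class GyrationResult:
    rg: float  # nm, time-averaged
    rg_sem: float
    rg0: Optional[float]  # undisturbed-chain reference
    normalized: Optional[float]  # rg / rg0
    gyration_tensor_eigenvalues: np.ndarray  # nm^2, time-averaged, descending
    per_frame_rg: np.ndarray = field(default=None, repr=False)


def _unwrap_cluster(pos: np.ndarray, box: float) -> np.ndarray:
    """Undo periodic wrapping relative to the first particle.

    Valid for objects smaller than half the box in every direction.
    """
    return pos[0] + minimum_image(pos - pos[0], box)


def _unwrap_chain(pos: np.ndarray, box: float) -> np.ndarray:
    """Undo wrapping by accumulating minimum-image bond vectors along a chain."""
    steps = minimum_image(np.diff(pos, axis=0), box)
    out = np.empty_like(pos)
    out[0] = pos[0]
    out[1:] = pos[0] + np.cumsum(steps, axis=0)
    return out


def radius_of_gyration(
    traj: Union[Trajectory, SystemState],
    selection: Optional[np.ndarray] = None,
    rg0: Optional[float] = None,
    equilibration_fraction: float = DEFAULT_EQUILIBRATION_FRACTION,
    chain_unwrap: bool = True,
) -> GyrationResult:
    """Mass-uniform radius of gyration of a selection, frame-averaged.

    By default the selection is the polyelectrolyte; its coordinates are
    unwrapped along the chain contour so the result is meaningful across
    periodic boundaries.
    """
    frames, template = _as_frames(traj)
    if isinstance(traj, Trajectory) and len(frames) > 1:
        start = int(np.ceil(len(frames) * equilibration_fraction))
        frames = frames[start:]
    if selection is None:
        selection = template.bead_indices
    selection = np.asarray(selection)
    if len(selection) == 0:
        raise ValueError("empty selection")
    box = template.box_length

    rgs = np.empty(len(frames))
    eig_acc = np.zeros(3)
    for fi, pos in enumerate(frames):
        p = pos[selection]
        p = _unwrap_chain(p, box) if chain_unwrap else _unwrap_cluster(p, box)
        c = p - p.mean(axis=0)
        tensor = c.T @ c / len(c)
        eig = np.sort(np.linalg.eigvalsh(tensor))[::-1]
        eig_acc += eig
        rgs[fi] = math.sqrt(eig.sum())
    sem = float(rgs.std(ddof=1) / math.sqrt(len(rgs))) if len(rgs) > 1 else 0.0
    rg = float(rgs.mean())
    return GyrationResult(
        rg=rg,
        rg_sem=sem,
        rg0=rg0,
        normalized=None if rg0 is None else rg / rg0,
        gyration_tensor_eigenvalues=eig_acc / len(frames),
        per_frame_rg=rgs,
    )


def relative_shape_anisotropy(eigenvalues: np.ndarray) -> float:
    """kappa^2 from gyration-tensor eigenvalues: 0 = sphere, 1 = line."""
    l1, l2, l3 = eigenvalues
    tr = l1 + l2 + l3
    if tr == 0:
        return 0.0
    return 1.0 - 3.0 * (l1 * l2 + l2 * l3 + l3 * l1) / tr**2


def rdf(
    traj: Union[Trajectory, SystemState],
    selection: Optional[np.ndarray] = None,
    bin_width: float = 0.05,
    r_max: Optional[float] = None,
    equilibration_fraction: float = DEFAULT_EQUILIBRATION_FRACTION,
) -> pd.DataFrame:
    """Radial distribution function between particles of one selection.

    Standard minimum-image, shell-normalised histogram; columns ``r`` (bin
    centres, nm) and ``g``.  Defaults to all platelet sites.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    frames, template = _as_frames(traj)
    if isinstance(traj, Trajectory) and len(frames) > 1:
        start = int(np.ceil(len(frames) * equilibration_fraction))
        frames = frames[start:]
    if selection is None:
        selection = template.site_indices
    selection = np.asarray(selection)
    n = len(selection)
    if n < 2:
        raise ValueError("need at least two particles for g(r)")
    box = template.box_length
    if r_max is None:
        r_max = box / 2.0
    if r_max > box / 2.0 + 1e-9:
        raise ValueError("r_max must not exceed half the box length")

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    iu, ju = np.triu_indices(n, k=1)
    for pos in frames:
        p = pos[selection]
        dr = minimum_image(p[iu] - p[ju], box)
        d = np.sqrt((dr**2).sum(axis=1))
        counts += np.histogram(d, bins=edges)[0]
    counts /= len(frames)
    volume = box**3
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = 0.5 * n * (n - 1) * shell / volume
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"r": centers, "g": counts / ideal})


@dataclass
class StructureFactorResult:
    q_grid: np.ndarray  # nm^-1
    s_values: np.ndarray
    windowed: bool = False
    r_cut: Optional[float] = None  # window extent Rc, nm
    qmax: Optional[float] = None  # Bragg-peak position, filled by bragg_dspacing
    d_bragg: Optional[float] = None  # 2 pi / qmax

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"q": self.q_grid, "s": self.s_values})


def default_q_grid(box_length: float, n_points: int = 200, q_max: float = 20.0) -> np.ndarray:
    """Log-spaced q grid from the box-size limit 2 pi / L up to q_max."""
    return np.geomspace(2.0 * np.pi / box_length, q_max, n_points)


def structure_factor_direct(
    traj: Union[Trajectory, SystemState],
    q_grid: Optional[np.ndarray] = None,
    selection: Optional[np.ndarray] = None,
    equilibration_fraction: float = DEFAULT_EQUILIBRATION_FRACTION,
) -> StructureFactorResult:
    """Isotropic site-site structure factor by direct double summation.

    The self (i = j) term contributes exactly 1, so a single site gives
    S(q) = 1 and S(q) -> 1 at large q for any configuration.
    """
    frames, template = _as_frames(traj)
    if isinstance(traj, Trajectory) and len(frames) > 1:
        start = int(np.ceil(len(frames) * equilibration_fraction))
        frames = frames[start:]
    if selection is None:
        selection = template.site_indices
    selection = np.asarray(selection)
    n = len(selection)
    if n < 1:
        raise ValueError("need at least one site")
    if q_grid is None:
        q_grid = default_q_grid(template.box_length)
    q_grid = np.asarray(q_grid, dtype=float)

    s = np.zeros(len(q_grid))
    iu, ju = np.triu_indices(n, k=1)
    box = template.box_length
    for pos in frames:
        p = pos[selection]
        dr = minimum_image(p[iu] - p[ju], box)
        d = np.sqrt((dr**2).sum(axis=1))
        # sum over distinct pairs; np.sinc(x) = sin(pi x)/(pi x)
        pair_sum = np.sinc(np.outer(q_grid, d) / np.pi).sum(axis=1)
        s += (n + 2.0 * pair_sum) / n
    return StructureFactorResult(q_grid=q_grid, s_values=s / len(frames))


def structure_factor_windowed(
    gr_table: pd.DataFrame,
    n_sites: int,
    volume: float,
    r_cut: float,
    q_grid: Optional[np.ndarray] = None,
) -> StructureFactorResult:
    """Windowed structure factor S_w(q) from a g(r) table.

    Quadrature of the isotropic Fourier transform of g(r) - 1 with the
    sin(pi r/Rc)/(pi r/Rc) window, which removes the hard truncation of
    g(r) at the half-box distance.
    """
    r = np.asarray(gr_table["r"], dtype=float)
    g = np.asarray(gr_table["g"], dtype=float)
    if r_cut > r.max() + (r[1] - r[0]):
        raise ValueError("g(r) table does not extend to r_cut")
    mask = r <= r_cut
    r, g = r[mask], g[mask]
    if q_grid is None:
        q_grid = default_q_grid(volume ** (1.0 / 3.0))
    q_grid = np.asarray(q_grid, dtype=float)
    window = np.sinc(r / r_cut)  # sin(pi r/Rc) / (pi r/Rc)
    rho = n_sites / volume
    integrand = (g - 1.0) * r**2 * window  # (R,)
    sinc_qr = np.sinc(np.outer(q_grid, r) / np.pi)  # (Q, R)
    s = 1.0 + 4.0 * np.pi * rho * np.trapezoid(integrand[None, :] * sinc_qr, r, axis=1)
    return StructureFactorResult(q_grid=q_grid, s_values=s, windowed=True, r_cut=r_cut)


def bragg_dspacing(
    sf: StructureFactorResult,
    q_window: tuple[float, float] = (2.0, 4.0),
    prominence_fraction: float = 0.05,
) -> Optional[float]:
    """Bragg d-spacing 2 pi / q_max from the stacking peak of S(q).

    Searches for local maxima of S(q) inside ``q_window`` (default 2-4
    nm^-1, bracketing face-to-face clay stacking); a peak counts only if
    its prominence exceeds ``prominence_fraction`` of the local baseline
    (median S in the window).  Returns None ("no peak") otherwise, and
    stores q_max / d_bragg on the result object when found.
    """
    lo, hi = q_window
    mask = (sf.q_grid >= lo) & (sf.q_grid <= hi)
    if mask.sum() < 3:
        raise ValueError("q_window must contain at least 3 grid points")
    q = sf.q_grid[mask]
    s = sf.s_values[mask]
    baseline = max(abs(float(np.median(s))), 1e-12)
    peaks, props = signal.find_peaks(s, prominence=prominence_fraction * baseline)
    if len(peaks) == 0:
        return None
    best = peaks[np.argmax(s[peaks])]
    sf.qmax = float(q[best])
    sf.d_bragg = 2.0 * math.pi / sf.qmax
    return sf.d_bragg


def kratky_transform(sf: StructureFactorResult) -> pd.DataFrame:
    """Kratky presentation q^2 S(q); pointwise, no smoothing."""
    return pd.DataFrame({"q": sf.q_grid, "q2s": sf.q_grid**2 * sf.s_values})


@dataclass
class ShapeClassification:
    label: str  # compact_stack | extended_band | dissolved
    metrics: dict
    thresholds: dict


def classify_shape(
    traj: Union[Trajectory, SystemState],
    contact_threshold: Optional[float] = None,
    stack_spacing_max: float = 3.5,  # nm, platelet-centre NN distance for a stack
    dispersed_min: float = 10.0,  # nm, min centre separation to call dissolved
) -> ShapeClassification:
    """Heuristic complex-shape label from the platelet-centre geometry.

    * ``dissolved``  - no platelet is in contact with the chain;
    * ``compact_stack`` - complexed platelets whose nearest-neighbour
      centre spacing is tactoid-like (< ``stack_spacing_max``);
    * ``extended_band`` - complexed but loosely arranged along the chain.

    The thresholds and the measured metrics (nearest-neighbour spacing,
    relative shape anisotropy of the site cloud) are reported alongside
    the label.
    """
    frames, template = _as_frames(traj)
    pos = frames[-1]
    groups = template.platelet_site_groups()
    if len(groups) == 0:
        raise ValueError("no platelets in system")
    box = template.box_length
    centers = np.array([_unwrap_cluster(pos[g], box).mean(axis=0) for g in groups])

    state = template.copy()
    state.positions = pos.copy()
    if len(template.bead_indices) > 0:
        comp = complexation_probability(state, threshold=contact_threshold)
        n_complexed = int(round(comp.mean_complexed))
        contact = comp.contact_threshold
    else:  # chainless site cloud: classify on geometry alone
        n_complexed, contact = None, contact_threshold

    metrics: dict = {"n_complexed": n_complexed}
    all_sites = np.concatenate(groups)
    site_pos = _unwrap_cluster(pos[all_sites], box)
    c = site_pos - site_pos.mean(axis=0)
    eig = np.sort(np.linalg.eigvalsh(c.T @ c / len(c)))[::-1]
    metrics["shape_anisotropy"] = relative_shape_anisotropy(eig)

    if len(centers) >= 2:
        dr = minimum_image(centers[:, None] - centers[None, :], box)
        dist = np.sqrt((dr**2).sum(axis=-1))
        np.fill_diagonal(dist, np.inf)
        nn = dist.min(axis=1)
        metrics["median_nn_spacing"] = float(np.median(nn))
    else:
        metrics["median_nn_spacing"] = float("inf")

    thresholds = {
        "stack_spacing_max": stack_spacing_max,
        "dispersed_min": dispersed_min,
        "contact_threshold": contact,
    }
    nn = metrics["median_nn_spacing"]
    if n_complexed == 0 or (n_complexed is None and nn >= dispersed_min):
        label = "dissolved"
    elif nn < stack_spacing_max and len(centers) >= 2:
        label = "compact_stack"
    else:
        label = "extended_band"
    return ShapeClassification(label=label, metrics=metrics, thresholds=thresholds)
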