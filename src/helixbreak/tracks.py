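"""Surrogate track source: stochastic energy deposits and OH spawn points.

Replaces full track-structure particle transport with a configurable
stochastic process: parallel straight tracks along the short (z) axis of the
nucleus ellipsoid, entry points uniform over its cross-section, deposits
placed as a Poisson process along each chord with a Gaussian radial spread,
deposit energies i.i.d. from a truncated exponential.  Hydroxyl radicals are
spawned co-located with deposits, with expected count energy * G / 100 eV.

The number of tracks is chosen so that total deposited energy over the
nucleus water mass matches the requested dose; the track that crosses the
target is truncated at the deposit whose running total lands closest to it
(and dropped entirely when that is closer still).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ChromatinSegment, ContainerModel

EV_TO_J = 1.602176634e-19

# radical status codes (one-way transitions from ALIVE)
ALIVE = 0
SCAVENGED = 1
KILLED = 2
REACTED = 3
TIMED_OUT = 4
STATUS_NAMES = np.array(["alive", "scavenged", "killed", "reacted", "timed_out"])


@dataclass(frozen=True)
class IrradiationConfig:
    """Surrogate irradiation parameters.

    deposits_per_um is the LET-like knob: the mean linear density of
    deposition events along a track.  Energies follow a shifted exponential
    (min + Exp(mean - min)) so sub-5 eV and >37.5 eV deposits both occur.
    """

    dose_gy: float = 1.0
    deposits_per_um: float = 100.0
    energy_mean_ev: float = 45.0
    energy_min_ev: float = 1.0
    radial_sigma_nm: float = 2.0
    g_oh_per_100ev: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dose_gy < 0:
            raise ValueError("dose must be non-negative")
        if min(self.deposits_per_um, self.energy_mean_ev,
               self.radial_sigma_nm, self.g_oh_per_100ev) <= 0:
            raise ValueError("irradiation parameters must be positive")
        if not 0 < self.energy_min_ev < self.energy_mean_ev:
            raise ValueError("need 0 < energy_min_ev < energy_mean_ev")


@dataclass
class Deposits:
    positions: np.ndarray          # (N, 3) nm
    energy: np.ndarray             # (N,) eV
    track_id: np.ndarray           # (N,) int

    def __len__(self) -> int:
        return self.energy.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.positions[:, 0], "y": self.positions[:, 1],
            "z": self.positions[:, 2], "energy": self.energy,
            "track_id": self.track_id})


@dataclass
class Radicals:
    """OH radical population with one-way status transitions from alive."""

    positions: np.ndarray          # (N, 3) nm, updated during diffusion
    creation_time: np.ndarray     # (N,) ns
    status: np.ndarray            # (N,) int codes
    termination_time: np.ndarray = field(default=None)  # ns, NaN while alive

    def __post_init__(self) -> None:
        if self.termination_time is None:
            self.termination_time = np.full(self.status.size, np.nan)

    def __len__(self) -> int:
        return self.status.size

    @property
    def alive(self) -> np.ndarray:
        return self.status == ALIVE

    def status_counts(self) -> dict:
        return {name: int(np.sum(self.status == code))
                for code, name in enumerate(STATUS_NAMES)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.positions[:, 0], "y": self.positions[:, 1],
            "z": self.positions[:, 2], "t0": self.creation_time,
            "status": STATUS_NAMES[self.status]})


def _empty_events() -> tuple:
    return (Deposits(np.empty((0, 3)), np.empty(0), np.empty(0, dtype=int)),
            Radicals(np.empty((0, 3)), np.empty(0), np.empty(0, dtype=int)))


def fitted_container(segment: ChromatinSegment, margin_nm: float = 15.0,
                     total_bp: int | None = None) -> ContainerModel:
    """Desk-scale container: an ellipsoid snugly enclosing a straight segment.

    The x full-axis spans the fibre length plus margins; the transverse full
    axes are 2*margin_nm.  Dose is normalized over this volume, so the margin
    sets the effective bp density of the run.
    """
    if margin_nm <= 0:
        raise ValueError("margin must be positive")
    length_um = (segment.length_nm + 2 * margin_nm) / 1000.0
    trans_um = 2 * margin_nm / 1000.0
    return ContainerModel(
        nucleus_axes_um=(length_um, trans_um, trans_um),
        cytoplasm_axes_um=(2 * length_um, 2 * trans_um, 2 * trans_um),
        total_bp=total_bp if total_bp is not None else segment.n_bp,
        centre_nm=(segment.length_nm / 2.0, 0.0, 0.0))


def generate_tracks(container: ContainerModel, config: IrradiationConfig,
                    rng: np.random.Generator | None = None):
    """Sample deposits and OH spawn points for the requested dose.

    Returns ``(Deposits, Radicals)``.  Reproducible for a fixed config seed.
    """
    if container is None:
        raise ValueError("a container geometry is required")
    if config.dose_gy < 0:
        raise ValueError("dose must be non-negative")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.dose_gy == 0:
        return _empty_events()

    a, b, c = (ax * 1000.0 for ax in container.nucleus_axes_um)  # nm full axes
    # tracks run along z; entries uniform over the (x, y) cross-section of
    # the nucleus ellipsoid centred at container.centre_nm
    x0, y0, _ = container.centre_nm

    target_ev = config.dose_gy * container.nucleus_mass_kg / EV_TO_J

    pos_chunks, e_chunks, id_chunks = [], [], []
    total = 0.0
    track = 0
    scale = config.energy_mean_ev - config.energy_min_ev
    max_tracks = 10_000_000
    while total < target_ev and track < max_tracks:
        # entry point uniform over the elliptical cross-section (x, y)
        while True:
            u, v = rng.uniform(-1, 1, size=2)
            if u * u + v * v <= 1.0:
                break
        x = x0 + u * a / 2.0
        y = y0 + v * b / 2.0
        half_chord = (c / 2.0) * np.sqrt(max(0.0, 1.0 - u * u - v * v))
        chord_um = 2 * half_chord / 1000.0
        n_dep = rng.poisson(config.deposits_per_um * chord_um)
        if n_dep > 0:
            z = rng.uniform(-half_chord, half_chord, size=n_dep)
            e = config.energy_min_ev + rng.exponential(scale, size=n_dep)
            p = np.empty((n_dep, 3))
            p[:, 0] = x + rng.normal(0, config.radial_sigma_nm, size=n_dep)
            p[:, 1] = y + rng.normal(0, config.radial_sigma_nm, size=n_dep)
            p[:, 2] = z
            e_sum = e.sum()
            # the track that crosses the target is truncated at the deposit
            # whose running total lands closest to the target
            if total + e_sum >= target_ev:
                cum = total + np.cumsum(e)
                keep = int(np.argmin(np.abs(cum - target_ev))) + 1
                if abs(cum[keep - 1] - target_ev) > abs(total - target_ev):
                    keep = 0
                if keep:
                    pos_chunks.append(p[:keep])
                    e_chunks.append(e[:keep])
                    id_chunks.append(np.full(keep, track))
                    total = cum[keep - 1]
                track += 1
                break
            pos_chunks.append(p)
            e_chunks.append(e)
            id_chunks.append(np.full(n_dep, track))
            total += e_sum
        track += 1

    if not pos_chunks:
        deposits, radicals = _empty_events()
        return deposits, radicals
    deposits = Deposits(np.concatenate(pos_chunks),
                        np.concatenate(e_chunks),
                        np.concatenate(id_chunks))

    n_oh = rng.poisson(deposits.energy * config.g_oh_per_100ev / 100.0)
    spawn_pos = np.repeat(deposits.positions, n_oh, axis=0)
    n_rad = int(n_oh.sum())
    radicals = Radicals(spawn_pos.copy(), np.zeros(n_rad),
                        np.zeros(n_rad, dtype=int))
    return deposits, radicals


def dose_from_deposits(deposits: Deposits, container: ContainerModel) -> float:
    """Absorbed dose in Gy over the nucleus water mass."""
    if container is None or container.nucleus_volume_um3 <= 0:
        raise ValueError("container with positive volume required")
    return float(deposits.energy.sum() * EV_TO_J / container.nucleus_mass_kg)


def cull_radicals_at_creation(radicals: Radicals, segment: ChromatinSegment,
                              d_kill: float = 9.0) -> Radicals:
    """Kill radicals born farther than d_kill from every DNA molecule centre.

    Emulates the production-range cut: species created more than 9 nm (the
    maximum OH diffusion distance within the 5 ns chemical stage) from any
    DNA molecule centre cannot plausibly reach the fibre.  Bases count as
    molecule centres.  Mutates and returns ``radicals``.
    """
    if d_kill <= 0:
        raise ValueError("d_kill must be positive")
    if len(radicals) == 0:
        return radicals
    dist, _ = segment.all_site_tree.query(radicals.positions)
    far = (dist > d_kill) & radicals.alive
    radicals.status[far] = KILLED
    radicals.termination_time[far] = radicals.creation_time[far]
    return radicals
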