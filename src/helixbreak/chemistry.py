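"""Brownian OH-radical diffusion with histone scavenging.

Each surviving radical performs isotropic Gaussian steps (per-axis variance
2*D*dt) until the first of:

* it enters a histone sphere -> scavenged (histones are perfect sinks);
* it enters the encounter sphere of a backbone site (site radius plus a
  reaction radius) -> reacted, emitting one encounter event; the radical is
  consumed even if no strand break is later sampled from the event;
* the 5 ns chemical-stage clock runs out -> timed out.

Steps are discrete with no sub-step root finding: a step that ends inside a
histone or encounter sphere triggers the termination (a small, documented
bias that vanishes as dt -> 0; see the dt-convergence test).  Random
displacements are drawn for every radical at every step regardless of its
status, so paired runs that differ only in geometry (e.g. histones on/off)
see identical per-radical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import ChromatinSegment, KIND_NAMES
from .tracks import ALIVE, SCAVENGED, REACTED, TIMED_OUT, Radicals


@dataclass(frozen=True)
class ChemConfig:
    """Chemical-stage parameters.

    d_oh is the OH diffusion coefficient (2.8 nm^2/ns = 2.8e-9 m^2/s);
    t_chem the hard stage cutoff; reaction_radius_nm is added to each
    backbone site radius to form its encounter sphere.
    """

    d_oh_nm2_per_ns: float = 2.8
    dt_ns: float = 0.001
    t_chem_ns: float = 5.0
    reaction_radius_nm: float = 0.22

    def __post_init__(self) -> None:
        if self.d_oh_nm2_per_ns <= 0 or self.dt_ns <= 0:
            raise ValueError("d_oh and dt must be positive")
        if self.t_chem_ns < 0:
            raise ValueError("t_chem must be non-negative")
        if self.reaction_radius_nm < 0:
            raise ValueError("reaction radius must be non-negative")


@dataclass
class EncounterEvents:
    """Backbone encounter records (one per reacted radical)."""

    radical_id: np.ndarray
    site_index: np.ndarray     # index into the segment's site arrays
    time_ns: np.ndarray

    def __len__(self) -> int:
        return self.radical_id.size

    def to_frame(self, segment: ChromatinSegment) -> pd.DataFrame:
        s = self.site_index
        return pd.DataFrame({
            "radical_id": self.radical_id,
            "segment_id": np.full(s.size, segment.segment_id),
            "bp_index": segment.bp_index[s],
            "strand": segment.strand[s],
            "kind": KIND_NAMES[segment.kind[s]],
            "time_ns": self.time_ns})


def _encounter_check(segment: ChromatinSegment, tree: cKDTree,
                     radii_plus: np.ndarray, max_r: float,
                     points: np.ndarray) -> np.ndarray:
    """Return the hit backbone site index per point, or -1.

    A point is inside the encounter sphere of site j when
    ``|p - c_j| <= radius_j + reaction_radius``.  Among multiple overlapped
    spheres the closest centre wins (deterministic).
    """
    hit = np.full(points.shape[0], -1, dtype=np.int64)
    if points.size == 0:
        return hit
    dist, local = tree.query(points)
    maybe = dist <= max_r
    if not np.any(maybe):
        return hit
    backbone = segment.backbone_indices
    idx_maybe = np.flatnonzero(maybe)
    # nearest-centre candidate is a hit if within its own encounter radius
    near_ok = dist[maybe] <= radii_plus[local[maybe]]
    hit[idx_maybe[near_ok]] = backbone[local[maybe][near_ok]]
    # a nearer small sphere can miss while a slightly farther large sphere
    # hits: re-check the misses against a few more neighbours
    unresolved = idx_maybe[~near_ok]
    if unresolved.size:
        k = min(4, len(backbone))
        d4, l4 = tree.query(points[unresolved], k=k)
        d4 = np.atleast_2d(d4)
        l4 = np.atleast_2d(l4)
        inside = d4 <= radii_plus[l4]
        any_hit = inside.any(axis=1)
        first = inside.argmax(axis=1)
        rows = np.flatnonzero(any_hit)
        hit[unresolved[rows]] = backbone[l4[rows, first[rows]]]
    return hit


def diffuse(radicals: Radicals, segment: ChromatinSegment,
            config: ChemConfig = ChemConfig(), seed: int = 0):
    """Diffuse alive radicals to termination.

    Returns ``(EncounterEvents, radicals)``; ``radicals`` is mutated in
    place (positions advanced, statuses finalized).  At most one encounter
    per radical.  Deterministic for a fixed seed.
    """
    if segment is None:
        raise ValueError("an indexed chromatin segment is required")
    n = len(radicals)
    events_r, events_s, events_t = [], [], []
    n_steps = int(round(config.t_chem_ns / config.dt_ns)) if config.t_chem_ns > 0 else 0
    if n == 0 or n_steps == 0:
        was_alive = radicals.alive
        radicals.termination_time[was_alive] = config.t_chem_ns
        radicals.status[was_alive] = TIMED_OUT
        return (EncounterEvents(np.empty(0, int), np.empty(0, int), np.empty(0)),
                radicals)

    rng = np.random.default_rng(seed)
    tree = segment.backbone_tree
    radii_plus = segment.radius[segment.backbone_mask] + config.reaction_radius_nm
    max_r = float(radii_plus.max())
    have_histones = segment.histone_centres.shape[0] > 0
    if have_histones:
        htree = cKDTree(segment.histone_centres)
        hr = segment.histone_radius

    sigma = np.sqrt(2.0 * config.d_oh_nm2_per_ns * config.dt_ns)

    def terminate(idx: np.ndarray, status: int, t: float) -> None:
        radicals.status[idx] = status
        radicals.termination_time[idx] = t

    def check(idx: np.ndarray, t: float) -> np.ndarray:
        """Apply scavenging then encounter tests; return still-alive idx."""
        if idx.size == 0:
            return idx
        if have_histones:
            hd, _ = htree.query(radicals.positions[idx])
            scav = hd <= hr
            if np.any(scav):
                terminate(idx[scav], SCAVENGED, t)
                idx = idx[~scav]
        if idx.size:
            hit = _encounter_check(segment, tree, radii_plus, max_r,
                                   radicals.positions[idx])
            reacted = hit >= 0
            if np.any(reacted):
                events_r.extend(idx[reacted].tolist())
                events_s.extend(hit[reacted].tolist())
                events_t.extend([t] * int(reacted.sum()))
                terminate(idx[reacted], REACTED, t)
                idx = idx[~reacted]
        return idx

    alive_idx = np.flatnonzero(radicals.alive)
    # creation-time check: a radical born inside a histone or encounter
    # sphere terminates before taking any step
    alive_idx = check(alive_idx, 0.0)

    for step in range(n_steps):
        disp = rng.normal(0.0, sigma, size=(n, 3))
        if alive_idx.size == 0:
            continue  # keep consuming the stream for pairing determinism
        radicals.positions[alive_idx] += disp[alive_idx]
        alive_idx = check(alive_idx, (step + 1) * config.dt_ns)

    terminate(alive_idx, TIMED_OUT, config.t_chem_ns)
    order = np.argsort(events_r)
    events = EncounterEvents(np.asarray(events_r, dtype=int)[order],
                             np.asarray(events_s, dtype=int)[order],
                             np.asarray(events_t, dtype=float)[order])
    return events, radicals


def scavenging_effect(segment: ChromatinSegment, radicals: Radicals,
                      config: ChemConfig = ChemConfig(), seed: int = 0):
    """Paired histone-on / histone-off diffusion with a shared random stream.

    Returns a dict with encounter counts and the two event sets.  Because
    per-radical displacement streams are identical across arms and histones
    only ever absorb, the off-arm count is >= the on-arm count.
    """
    def clone(r: Radicals) -> Radicals:
        return Radicals(r.positions.copy(), r.creation_time.copy(),
                        r.status.copy(), r.termination_time.copy())

    ev_on, rad_on = diffuse(clone(radicals), segment, config, seed)
    ev_off, rad_off = diffuse(clone(radicals), segment.without_histones(),
                              config, seed)
    return {
        "encounters_with_histones": len(ev_on),
        "encounters_without_histones": len(ev_off),
        "events_with_histones": ev_on,
        "events_without_histones": ev_off,
        "radicals_with_histones": rad_on,
        "radicals_without_histones": rad_off,
    }
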