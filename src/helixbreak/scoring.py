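"""Direct and indirect strand-break scoring.

Direct damage: every energy deposit within R_dir (3.5 A) of its nearest
backbone molecule centre is assigned, in full, to that site; per-site
energies are accumulated over the whole irradiation first, pooled per
nucleotide (the phosphate + deoxyribose of one bp-strand form one
sugar-phosphate scoring unit), and a single Bernoulli trial per unit uses a
linear ramp probability: 0 below E_min (5 eV), 1 above E_max (37.5 eV),
linear in between.

Indirect damage: each OH-backbone encounter breaks the hit nucleotide with
probability P_OH (0.405), independently.

A position hit both ways keeps ONE break whose source is direct (direct is
resolved first, the duplicate indirect success is dropped); duplicate
successes of one source also collapse to a single break.  Base sites never
produce breaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemistry import EncounterEvents
from .geometry import ChromatinSegment
from .tracks import Deposits

BREAK_COLUMNS = ["segment_id", "bp_index", "strand", "source"]


@dataclass(frozen=True)
class ScoringParams:
    """Damage-model parameters (defaults: R_dir 0.35 nm, 5-37.5 eV ramp,
    P_OH 0.405)."""

    r_dir_nm: float = 0.35
    e_min_break_ev: float = 5.0
    e_max_break_ev: float = 37.5
    p_oh_break: float = 0.405

    def __post_init__(self) -> None:
        if self.r_dir_nm <= 0:
            raise ValueError("R_dir must be positive")
        if not 0 < self.e_min_break_ev < self.e_max_break_ev:
            raise ValueError("need 0 < E_min < E_max")
        if not 0 <= self.p_oh_break <= 1:
            raise ValueError("P_OH must be a probability")


def empty_breaks() -> pd.DataFrame:
    return pd.DataFrame({"segment_id": pd.Series(dtype=int),
                         "bp_index": pd.Series(dtype=int),
                         "strand": pd.Series(dtype=int),
                         "source": pd.Series(dtype=str)})


def accumulate_direct_energy(deposits: Deposits, segment: ChromatinSegment,
                             params: ScoringParams = ScoringParams()) -> np.ndarray:
    """Accumulated energy (eV) per site, over all deposits.

    Returns an array over ALL site indices (base entries stay zero).  Each
    deposit contributes its full energy to its nearest backbone site when
    that site lies within R_dir; otherwise it is unassigned.
    """
    energy = np.zeros(segment.bp_index.size)
    if len(deposits) == 0:
        return energy
    dist, local = segment.backbone_tree.query(deposits.positions)
    within = dist <= params.r_dir_nm
    sites = segment.backbone_indices[local[within]]
    np.add.at(energy, sites, deposits.energy[within])
    return energy


def direct_break_probability(e_site_ev, params: ScoringParams = ScoringParams()):
    """Linear-ramp break probability for an accumulated energy deposit.

    0 at or below E_min, 1 at or above E_max, (E - E_min)/(E_max - E_min)
    between.  Accepts scalars or arrays.
    """
    e = np.asarray(e_site_ev, dtype=float)
    if np.any(e < 0):
        raise ValueError("energy must be non-negative")
    p = (e - params.e_min_break_ev) / (params.e_max_break_ev - params.e_min_break_ev)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.isscalar(e_site_ev) else p


def score_direct_breaks(energy_per_site: np.ndarray, segment: ChromatinSegment,
                        params: ScoringParams = ScoringParams(),
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Bernoulli trials per sugar-phosphate unit on accumulated energies.

    The phosphate and deoxyribose energies of one (bp, strand) nucleotide
    are pooled before the ramp is applied; one trial per unit.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    bm = segment.backbone_mask
    unit = segment.bp_index[bm] * 2 + segment.strand[bm]
    e_unit = np.bincount(unit, weights=energy_per_site[bm],
                         minlength=2 * segment.n_bp)
    candidates = np.flatnonzero(e_unit > params.e_min_break_ev)
    if candidates.size == 0:
        return empty_breaks()
    p = direct_break_probability(e_unit[candidates], params)
    hit = candidates[rng.random(candidates.size) < p]
    return pd.DataFrame({
        "segment_id": np.full(hit.size, segment.segment_id),
        "bp_index": hit // 2,
        "strand": hit % 2,
        "source": np.full(hit.size, "direct")})


def score_indirect_breaks(encounters: EncounterEvents, segment: ChromatinSegment,
                          params: ScoringParams = ScoringParams(),
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Independent Bernoulli(P_OH) per encounter; duplicates collapse.

    The uniform for each trial is indexed by the radical id (a prefix of
    the generator's stream), so paired runs that share a radical population
    (e.g. histone scavenging on/off at one seed) reuse identical draws and
    differ only through which radicals reach the backbone.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = len(encounters)
    if n == 0:
        return empty_breaks()
    u = rng.random(int(encounters.radical_id.max()) + 1)
    success = u[encounters.radical_id] < params.p_oh_break
    sites = encounters.site_index[success]
    breaks = pd.DataFrame({
        "segment_id": np.full(sites.size, segment.segment_id),
        "bp_index": segment.bp_index[sites],
        "strand": segment.strand[sites],
        "source": np.full(sites.size, "indirect")})
    return breaks.drop_duplicates(["segment_id", "bp_index", "strand"],
                                  ignore_index=True)


def combine_breaks(*break_sets: pd.DataFrame) -> pd.DataFrame:
    """Merge break lists; at one position a direct break wins over indirect."""
    frames = [b for b in break_sets if len(b)]
    if not frames:
        return empty_breaks()
    allb = pd.concat(frames, ignore_index=True)
    # direct sorts before indirect, so keep="first" resolves collisions
    allb = allb.sort_values(BREAK_COLUMNS, kind="stable")
    allb = allb.drop_duplicates(["segment_id", "bp_index", "strand"],
                                keep="first")
    return allb.sort_values(["segment_id", "bp_index", "strand"],
                            ignore_index=True)
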