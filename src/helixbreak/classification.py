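"""Break clustering, DSB pairing, complexity/source classes and yields.

Clusters are maximal runs of breaks on one segment in which every pair of
consecutive break positions is separated by at most 100 unbroken bp (a gap
STRICTLY greater than 100 bp splits).  Within a cluster, opposite-strand
breaks at most d_DSB = 10 bp apart are paired into DSBs using a
maximum-cardinality matching realized deterministically (ascending |dbp|,
then ascending bp, never sacrificing cardinality).

Complexity: >= 2 DSBs -> DSBpp; one DSB plus at least one additional break
within d_DSB of either paired break -> DSBp; one DSB -> DSB; else
SSB_cluster.  The most complex applicable label always wins; clusters with
three or more DSBs still count as one DSBpp.

Source (DSB clusters only): all breaks direct -> DSBdir, all indirect ->
DSBind; otherwise remove every indirect break and re-pair: no surviving
DSB -> DSBhyb (the DSB vanishes without indirect damage), else DSBmix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

D_DSB_DEFAULT = 10
CLUSTER_GAP_BP = 100
DISTANT_GAP_BP = 10_000

COMPLEXITY_LABELS = ("SSB_cluster", "DSB", "DSBp", "DSBpp")
SOURCE_LABELS = ("DSBdir", "DSBind", "DSBhyb", "DSBmix")


@dataclass
class DamageCluster:
    segment_id: int
    bp_index: np.ndarray           # (k,) positions of the k breaks
    strand: np.ndarray             # (k,)
    source: np.ndarray             # (k,) 'direct'|'indirect'
    pairs: List[Tuple[int, int]] = field(default_factory=list)  # local indices
    complexity: str = "SSB_cluster"
    source_class: str | None = None

    @property
    def n_breaks(self) -> int:
        return self.bp_index.size

    @property
    def n_dsb(self) -> int:
        return len(self.pairs)

    @property
    def span_bp(self) -> Tuple[int, int]:
        return int(self.bp_index.min()), int(self.bp_index.max())

    def dsb_midpoints(self) -> np.ndarray:
        """Midpoint bp of each paired DSB (mean of the two break positions)."""
        return np.array([(self.bp_index[i] + self.bp_index[j]) / 2.0
                         for i, j in self.pairs])


def _max_matching_size(bp: np.ndarray, strand: np.ndarray, d_dsb: int) -> int:
    """Cardinality of the optimal opposite-strand pairing (|dbp| <= d_dsb)."""
    s0 = np.flatnonzero(strand == 0)
    s1 = np.flatnonzero(strand == 1)
    if s0.size == 0 or s1.size == 0:
        return 0
    adj = np.abs(bp[s0][:, None] - bp[s1][None, :]) <= d_dsb
    if not adj.any():
        return 0
    match = maximum_bipartite_matching(csr_matrix(adj), perm_type="column")
    return int((match >= 0).sum())


def pair_dsbs(bp: np.ndarray, strand: np.ndarray,
              d_dsb: int = D_DSB_DEFAULT) -> List[Tuple[int, int]]:
    """Pair opposite-strand breaks into DSBs.

    Returns local index pairs.  The pairing has maximum cardinality; among
    optimal pairings it is realized deterministically by accepting candidate
    pairs in ascending (|dbp|, min bp, strand-0 bp) order whenever doing so
    still allows the optimum on the remaining breaks.
    """
    bp = np.asarray(bp)
    strand = np.asarray(strand)
    target = _max_matching_size(bp, strand, d_dsb)
    if target == 0:
        return []
    cands = []
    for i in np.flatnonzero(strand == 0):
        for j in np.flatnonzero(strand == 1):
            d = abs(int(bp[i]) - int(bp[j]))
            if d <= d_dsb:
                cands.append((d, min(bp[i], bp[j]), int(bp[i]), i, j))
    cands.sort()
    used = np.zeros(bp.size, dtype=bool)
    pairs: List[Tuple[int, int]] = []
    for d, _, _, i, j in cands:
        if used[i] or used[j] or len(pairs) == target:
            continue
        trial = used.copy()
        trial[[i, j]] = True
        rest = ~trial
        if _max_matching_size(bp[rest], strand[rest], d_dsb) >= target - len(pairs) - 1:
            used = trial
            pairs.append((int(i), int(j)))
    return pairs


def segment_clusters(breaks: pd.DataFrame,
                     gap_bp: int = CLUSTER_GAP_BP) -> List[DamageCluster]:
    """Split sorted breaks into clusters at unbroken gaps > gap_bp.

    The unbroken run between breaks at bp1 < bp2 has length bp2 - bp1 - 1;
    clusters never span segments.
    """
    clusters: List[DamageCluster] = []
    if len(breaks) == 0:
        return clusters
    breaks = breaks.sort_values(["segment_id", "bp_index", "strand"],
                                ignore_index=True)
    for seg_id, grp in breaks.groupby("segment_id", sort=True):
        bp = grp["bp_index"].to_numpy()
        strand = grp["strand"].to_numpy()
        source = grp["source"].to_numpy()
        gaps = np.diff(bp) - 1
        starts = np.concatenate([[0], np.flatnonzero(gaps > gap_bp) + 1])
        ends = np.concatenate([starts[1:], [bp.size]])
        for a, b in zip(starts, ends):
            clusters.append(DamageCluster(
                segment_id=int(seg_id), bp_index=bp[a:b].copy(),
                strand=strand[a:b].copy(), source=source[a:b].copy()))
    return clusters


def complexity_class(cluster: DamageCluster,
                     d_dsb: int = D_DSB_DEFAULT) -> str:
    """Most complex applicable label given the cluster's paired DSBs."""
    if cluster.n_dsb >= 2:
        return "DSBpp"
    if cluster.n_dsb == 1:
        paired = {i for pair in cluster.pairs for i in pair}
        paired_bp = cluster.bp_index[list(paired)]
        for k in range(cluster.n_breaks):
            if k in paired:
                continue
            if np.min(np.abs(paired_bp - cluster.bp_index[k])) <= d_dsb:
                return "DSBp"
        return "DSB"
    return "SSB_cluster"


def source_class(cluster: DamageCluster, d_dsb: int = D_DSB_DEFAULT) -> str:
    """Source label of a DSB cluster (DSBdir/DSBind/DSBhyb/DSBmix).

    Mixed-source clusters are resolved by the removal test: delete all
    indirect breaks and re-pair; if no DSB survives the cluster is DSBhyb.
    """
    if cluster.n_dsb == 0:
        raise ValueError("source_class requires a cluster with >= 1 DSB")
    direct = cluster.source == "direct"
    if direct.all():
        return "DSBdir"
    if (~direct).all():
        return "DSBind"
    keep = direct
    if _max_matching_size(cluster.bp_index[keep], cluster.strand[keep],
                          d_dsb) == 0:
        return "DSBhyb"
    return "DSBmix"


def classify_clusters(breaks: pd.DataFrame, d_dsb: int = D_DSB_DEFAULT,
                      gap_bp: int = CLUSTER_GAP_BP) -> List[DamageCluster]:
    """Full clustering + pairing + labelling pass over a break table."""
    clusters = segment_clusters(breaks, gap_bp)
    for cl in clusters:
        cl.pairs = pair_dsbs(cl.bp_index, cl.strand, d_dsb)
        cl.complexity = complexity_class(cl, d_dsb)
        if cl.n_dsb:
            cl.source_class = source_class(cl, d_dsb)
    return clusters


def distant_dsb_filter(midpoints_bp: Sequence[float],
                       min_gap_bp: int = DISTANT_GAP_BP) -> int:
    """Count DSBs surviving the electrophoresis small-fragment loss filter.

    Left-to-right scan over sorted midpoints: a DSB is dropped when its
    midpoint lies closer than min_gap_bp to the last retained one; segment
    ends act as boundaries at infinite distance.
    """
    mids = np.sort(np.asarray(midpoints_bp, dtype=float))
    if mids.size <= 1:
        return int(mids.size)
    kept = 1
    last = mids[0]
    for m in mids[1:]:
        if m - last >= min_gap_bp:
            kept += 1
            last = m
    return kept


@dataclass
class YieldSummary:
    """Damage counts and per-Gy-per-Gbp yields for one run."""

    n_ssb: int
    n_dsb: int                 # total paired DSBs
    n_dsb_clusters: int
    n_dsbp: int
    n_dsbpp: int
    n_cdsb: int
    n_ncdsb: int
    n_distant_dsb: int
    n_dsbdir: int
    n_dsbind: int
    n_dsbhyb: int
    n_dsbmix: int
    dose_gy: float
    genome_gbp: float

    def _yield(self, count: int) -> float:
        denom = self.dose_gy * self.genome_gbp
        if denom == 0:
            return 0.0 if count == 0 else float("nan")
        return count / denom

    @property
    def ssb_yield(self) -> float:
        return self._yield(self.n_ssb)

    @property
    def dsb_yield(self) -> float:
        return self._yield(self.n_dsb)

    @property
    def ssb_dsb_ratio(self) -> float:
        return self.n_ssb / self.n_dsb if self.n_dsb else float("nan")

    @property
    def scavengeable_fraction(self) -> float:
        return scavengeable_fraction(self)

    @property
    def irreparable_fraction(self) -> float:
        tot = self.n_cdsb + self.n_ncdsb
        return self.n_cdsb / tot if tot else float("nan")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_ssb", "n_dsb", "n_dsb_clusters", "n_dsbp", "n_dsbpp", "n_cdsb",
            "n_ncdsb", "n_distant_dsb", "n_dsbdir", "n_dsbind", "n_dsbhyb",
            "n_dsbmix", "dose_gy", "genome_gbp")}
        d.update(ssb_yield=self.ssb_yield, dsb_yield=self.dsb_yield,
                 ssb_dsb_ratio=self.ssb_dsb_ratio,
                 scavengeable_fraction=self.scavengeable_fraction,
                 irreparable_fraction=self.irreparable_fraction)
        return d


def summarize_yields(clusters: List[DamageCluster], dose_gy: float,
                     genome_gbp: float,
                     distant_gap_bp: int = DISTANT_GAP_BP) -> YieldSummary:
    """Aggregate classified clusters into counts and yields.

    SSBs are counted as individual unpaired breaks.  N_cDSB follows
    N_DSBp + 2*N_DSBpp; N_ncDSB is the remaining paired-DSB count.  The
    distant-DSB filter runs per segment over DSB midpoints.
    """
    if dose_gy <= 0:
        raise ValueError("dose must be positive")
    if genome_gbp <= 0:
        raise ValueError("genome size must be positive")
    n_ssb = sum(cl.n_breaks - 2 * cl.n_dsb for cl in clusters)
    n_dsb = sum(cl.n_dsb for cl in clusters)
    dsb_clusters = [cl for cl in clusters if cl.n_dsb]
    n_dsbp = sum(cl.complexity == "DSBp" for cl in clusters)
    n_dsbpp = sum(cl.complexity == "DSBpp" for cl in clusters)
    n_cdsb = n_dsbp + 2 * n_dsbpp
    src = {lab: sum(cl.source_class == lab for cl in dsb_clusters)
           for lab in SOURCE_LABELS}
    mids: dict = {}
    for cl in dsb_clusters:
        mids.setdefault(cl.segment_id, []).extend(cl.dsb_midpoints())
    n_distant = sum(distant_dsb_filter(m, distant_gap_bp)
                    for m in mids.values())
    return YieldSummary(
        n_ssb=int(n_ssb), n_dsb=int(n_dsb),
        n_dsb_clusters=len(dsb_clusters), n_dsbp=int(n_dsbp),
        n_dsbpp=int(n_dsbpp), n_cdsb=int(n_cdsb),
        n_ncdsb=int(max(n_dsb - n_cdsb, 0)), n_distant_dsb=int(n_distant),
        n_dsbdir=src["DSBdir"], n_dsbind=src["DSBind"],
        n_dsbhyb=src["DSBhyb"], n_dsbmix=src["DSBmix"],
        dose_gy=float(dose_gy), genome_gbp=float(genome_gbp))


def scavengeable_fraction(summary: YieldSummary) -> float:
    """(N_DSBind + N_DSBhyb) / (N_DSBdir + N_DSBmix + N_DSBind + N_DSBhyb).

    DSBmix counts as non-scavengeable.  NaN when no DSB clusters exist.
    """
    denom = (summary.n_dsbdir + summary.n_dsbmix + summary.n_dsbind
             + summary.n_dsbhyb)
    if denom == 0:
        return float("nan")
    return (summary.n_dsbind + summary.n_dsbhyb) / denom
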