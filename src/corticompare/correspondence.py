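"""Closest Point Search (CPS) correspondence between vertex sets.

After registration the deformed source surface and the target surface
occupy the same space; CPS assigns every source vertex its Euclidean
nearest target vertex, which pairs the two pipelines' thickness arrays
on the hybrid template.  Matching is vertex-to-vertex and one-directional
(source -> target); exact ties break to the lowest target index.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.spatial import cKDTree

from .mesh_core import ScalarMap

log = logging.getLogger(__name__)


@dataclasses.dataclass
class Correspondence:
    match_index: np.ndarray      # (Nsrc,) target vertex per source vertex
    match_distance: np.ndarray   # (Nsrc,) mm

    def __post_init__(self):
        self.match_index = np.asarray(self.match_index, dtype=np.int64)
        self.match_distance = np.asarray(self.match_distance, dtype=np.float64)
        if np.any(self.match_distance < 0):
            raise ValueError("distances must be non-negative")


@dataclasses.dataclass
class HybridSubjectRecord:
    """Paired thickness arrays of one subject/timepoint on the hybrid template."""

    subject: str
    group: str
    timepoint: str
    thickness_cv: np.ndarray
    thickness_fs: np.ndarray

    def __post_init__(self):
        if len(self.thickness_cv) != len(self.thickness_fs):
            raise ValueError("paired thickness arrays must have equal length")


def closest_point_search(source_points: np.ndarray,
                         target_points: np.ndarray,
                         mutual: bool = False) -> Correspondence:
    """Global Euclidean nearest neighbour of every source point.

    kd-tree accelerated, but exact: candidate ties (equal squared
    distance) are resolved to the lowest target index, so the result
    equals a brute-force scan.  With ``mutual=True`` a ``mutual_mask``
    attribute marks matches that are also nearest in the reverse direction.
    """
    src = np.atleast_2d(np.asarray(source_points, float))
    tgt = np.atleast_2d(np.asarray(target_points, float))
    if len(src) == 0 or len(tgt) == 0:
        raise ValueError("closest_point_search requires non-empty point sets")
    tree = cKDTree(tgt)
    if len(tgt) == 1:
        dist = np.linalg.norm(src - tgt[0], axis=1)
        return Correspondence(np.zeros(len(src), dtype=int), dist)
    # k=2 query exposes exact ties cheaply; only tied points need the
    # full ball query to find the lowest-index equidistant target
    dists2, idxs2 = tree.query(src, k=2)
    dist, idx = dists2[:, 0].copy(), idxs2[:, 0].copy()
    tied = np.flatnonzero(dists2[:, 0] == dists2[:, 1])
    for i in tied:
        cand = tree.query_ball_point(src[i], dist[i] * (1 + 1e-12) + 1e-300)
        cd2 = np.einsum("ij,ij->i", tgt[cand] - src[i], tgt[cand] - src[i])
        best = min(c for c, dd in zip(cand, cd2) if dd == cd2.min())
        idx[i] = best
        dist[i] = np.sqrt(cd2.min())
    corr = Correspondence(idx, dist)
    if mutual:
        back = cKDTree(src).query(tgt)[1]
        corr.mutual_mask = back[corr.match_index] == np.arange(len(src))
    return corr


def transfer_thickness(smap: ScalarMap, corr: Correspondence) -> ScalarMap:
    """Pull a target-mesh scalar map onto the source mesh through CPS.

    Nearest-vertex transfer, no interpolation: output value at source
    vertex i is the map value at ``match_index[i]``.
    """
    if corr.match_index.max(initial=-1) >= len(smap.values):
        raise ValueError("correspondence indexes beyond scalar map length")
    return ScalarMap(smap.values[corr.match_index], mesh_id=smap.mesh_id)


def build_hybrid_dataset(cv_maps: dict, fs_maps: dict, corr: Correspondence,
                         groups: dict) -> list[HybridSubjectRecord]:
    """Pair per-subject thickness maps from both pipelines on the hybrid template.

    ``cv_maps`` / ``fs_maps`` map (subject, timepoint) to ScalarMap; the CV
    map lives natively on the hybrid (deformed source) template while the
    FS map is pulled through the registration's CPS correspondence.
    Subject/timepoints missing from either pipeline are skipped with a
    logged warning.
    """
    records = []
    for key in sorted(cv_maps):
        if key not in fs_maps:
            log.warning("skipping %s: missing from target pipeline", key)
            continue
        subject, timepoint = key
        fs_on_hybrid = transfer_thickness(fs_maps[key], corr)
        records.append(HybridSubjectRecord(
            subject=subject, group=groups.get(subject, ""),
            timepoint=timepoint,
            thickness_cv=np.asarray(cv_maps[key].values),
            thickness_fs=fs_on_hybrid.values))
    return records
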