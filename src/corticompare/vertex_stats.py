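"""Vertex-wise statistics on hybrid-template thickness maps.

Within-group cortical thinning (baseline vs follow-up) is tested with
paired t-tests per vertex; between-group cross-sectional differences with
Welch's two-sample t; p-value maps are thresholded by Benjamini-Hochberg
FDR (default alpha = 0.01).  The per-vertex "disease effect" for a group
contrast or time interval is the difference between the two pipelines'
thickness deltas, Delta_FS - Delta_CV: thinning deltas are negative, so a
negative disease effect means the target (Freesurfer-style) pipeline
registers more atrophy at that vertex.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats


@dataclasses.dataclass
class StatMap:
    statistic: np.ndarray       # per-vertex t
    p: np.ndarray               # per-vertex two-sided p
    delta: np.ndarray           # per-vertex mean difference, mm
    contrast: str
    n: tuple                    # sample size(s)
    zero_variance: np.ndarray = None   # flagged vertices (p forced to 1)


@dataclasses.dataclass
class DiseaseEffectMap:
    values: np.ndarray          # Delta_FS - Delta_CV per vertex, mm
    contrast: str


CATEGORIES = ("both", "civet_only", "freesurfer_only", "neither")


@dataclasses.dataclass
class OverlapMap:
    category: np.ndarray        # per-vertex label from CATEGORIES

    def counts(self) -> dict:
        return {c: int((self.category == c).sum()) for c in CATEGORIES}


def _stack(maps) -> np.ndarray:
    return np.vstack([np.asarray(getattr(m, "values", m), float) for m in maps])


def paired_t_map(maps_t0, maps_t1, contrast: str = "") -> StatMap:
    """Per-vertex paired t-test of matched subjects at two timepoints.

    delta is mean(t1 - t0) (negative = thinning).  Vertices with zero
    difference variance get t = 0, p = 1 and are flagged rather than
    dropped (they arise with noise-free synthetic data).
    """
    a = _stack(maps_t0)
    b = _stack(maps_t1)
    if a.shape != b.shape:
        raise ValueError("timepoints must contain the same subjects")
    n = a.shape[0]
    if n < 3:
        raise ValueError("paired t-test needs n >= 3")
    d = b - a
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    zero = sd == 0
    t = np.zeros_like(mean)
    t[~zero] = mean[~zero] / (sd[~zero] / np.sqrt(n))
    p = np.ones_like(mean)
    p[~zero] = 2 * stats.t.sf(np.abs(t[~zero]), df=n - 1)
    return StatMap(t, p, mean, contrast, (n,), zero_variance=zero)


def group_diff_map(maps_a, maps_b, contrast: str = "") -> StatMap:
    """Per-vertex Welch two-sample t-test; delta = mean(B) - mean(A)."""
    a = _stack(maps_a)
    b = _stack(maps_b)
    na, nb = a.shape[0], b.shape[0]
    if na < 3 or nb < 3:
        raise ValueError("group comparison needs n >= 3 per group")
    ma, mb = a.mean(0), b.mean(0)
    va, vb = a.var(0, ddof=1), b.var(0, ddof=1)
    se2 = va / na + vb / nb
    zero = se2 == 0
    t = np.zeros_like(ma)
    p = np.ones_like(ma)
    ok = ~zero
    t[ok] = (mb[ok] - ma[ok]) / np.sqrt(se2[ok])
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1) + 1e-300)
    p[ok] = 2 * stats.t.sf(np.abs(t[ok]), df=df[ok])
    return StatMap(t, p, mb - ma, contrast, (na, nb), zero_variance=zero)


def fdr_correct(pvals: np.ndarray, alpha: float = 0.01):
    """Benjamini-Hochberg step-up: returns (rejection mask, largest rejected p).

    threshold is None when nothing is rejected.
    """
    p = np.asarray(pvals, float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool), None
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = alpha * np.arange(1, m + 1) / m
    below = np.flatnonzero(ranked <= crit)
    if below.size == 0:
        return np.zeros(m, dtype=bool), None
    kmax = below.max()
    threshold = float(ranked[kmax])
    return p <= threshold, threshold


def disease_effect_map(delta_fs, delta_cv, contrast: str = "") -> DiseaseEffectMap:
    """Delta_FS - Delta_CV per vertex (antisymmetric under pipeline swap)."""
    dfs = np.asarray(getattr(delta_fs, "values", delta_fs), float)
    dcv = np.asarray(getattr(delta_cv, "values", delta_cv), float)
    if dfs.shape != dcv.shape:
        raise ValueError("delta maps must share the hybrid template")
    return DiseaseEffectMap(dfs - dcv, contrast)


def overlap_map(mask_cv: np.ndarray, mask_fs: np.ndarray) -> OverlapMap:
    """Categorize each vertex by which pipelines flagged it significant."""
    cv = np.asarray(mask_cv, bool)
    fs = np.asarray(mask_fs, bool)
    if cv.shape != fs.shape:
        raise ValueError("masks must share the hybrid template")
    cat = np.full(cv.shape, "neither", dtype="<U15")
    cat[cv & fs] = "both"
    cat[cv & ~fs] = "civet_only"
    cat[~cv & fs] = "freesurfer_only"
    return OverlapMap(cat)
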