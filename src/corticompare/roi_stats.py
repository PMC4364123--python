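"""ROI-level statistics: parcellation, aggregation, and the group cascade.

The 28-region registry mirrors the Harvard-Oxford cortical areas used for
AD cortical-thickness work (frontal / parietal / occipital / limbic /
temporal lobes).  Since the synthetic world has no volumetric anatomy, a
deterministic spherical parcellation stands in for the real atlas: 28
contiguous, left-right mirrored patches per hemisphere.

Group statistics: one-way ANOVA with Tukey-Kramer post-hocs (studentized
range with the unequal-n correction), Hedge's g effect sizes with the
small-sample factor J = 1 - 3/(4(n1+n2)-9) and z-comparison across
pipelines, thinning percentages, Pearson correlations per ROI, Steiger's
Z for dependent correlations sharing one variable, and Kendall's tau-b
with the Greiner relation r = sin(pi*tau/2).
"""

from __future__ import annotations

import dataclasses
import importlib.resources

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import studentized_range

from .mesh_core import TriangleMesh

GROUP_ORDER = ("CTR", "sMCI", "pMCI", "AD")

_FIXTURES = {
    "T1": "table1_demographics.csv",
    "T3": "table3_cross_sectional.csv",
    "T4": "table4_longitudinal.csv",
    "ROI28": "roi28_registry.csv",
    "QC23": "qc23_sulci.csv",
}


def load_fixture_table(table_id: str) -> pd.DataFrame:
    """Packaged transcription of a printed summary table (immutable copy)."""
    if table_id not in _FIXTURES:
        raise KeyError(f"unknown fixture table: {table_id!r}; "
                       f"known: {sorted(_FIXTURES)}")
    ref = importlib.resources.files("corticompare.fixtures") / _FIXTURES[table_id]
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_roi_registry() -> pd.DataFrame:
    reg = load_fixture_table("ROI28")
    assert len(reg) == 28
    return reg


# ---------------------------------------------------------------------------
# parcellation + aggregation

def _fibonacci_directions(k: int) -> np.ndarray:
    i = np.arange(k, dtype=float)
    phi = (1 + 5 ** 0.5) / 2
    z = 1 - 2 * (i + 0.5) / k
    theta = 2 * np.pi * i / phi
    r = np.sqrt(1 - z * z)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def build_synthetic_atlas(template: TriangleMesh, registry: pd.DataFrame,
                          seed: int = 0) -> np.ndarray:
    """Deterministic 28-patch spherical parcellation, mirrored across
    hemispheres.

    Patch seeds are quasi-uniform (Fibonacci lattice) directions with a
    small seeded jitter; each vertex joins its nearest seed direction, so
    patches are contiguous spherical Voronoi cells of comparable area.
    Returns a per-vertex roi_id array.
    """
    if len(registry) != 28:
        raise ValueError("registry must contain exactly 28 ROIs")
    rng = np.random.default_rng(seed)
    dirs = _fibonacci_directions(len(registry))
    dirs = dirs + rng.normal(scale=0.05, size=dirs.shape)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    roi_ids = registry["roi_id"].to_numpy()
    labels = np.empty(template.n_vertices, dtype=int)
    for hemi in np.unique(template.hemisphere):
        sel = template.hemisphere == hemi
        v = template.vertices[sel]
        center = v.mean(axis=0)
        u = v - center
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        if hemi == "right":      # mirror the parcellation left/right
            u = u * np.array([-1.0, 1.0, 1.0])
        nearest = np.argmax(u @ dirs.T, axis=1)
        labels[sel] = roi_ids[nearest]
    return labels


def roi_aggregate(maps: dict, atlas: np.ndarray, groups: dict,
                  area_weights: np.ndarray | None = None) -> pd.DataFrame:
    """Per-ROI mean thickness records from per-subject vertex maps.

    ``maps`` maps (subject, pipeline, timepoint) to a per-vertex array.
    Unweighted vertex means by default; pass per-vertex ``area_weights``
    (e.g. one third of incident triangle area) for area-weighted means.
    Returns the tidy ROITable: subject, group, pipeline, timepoint,
    roi_id, thickness.
    """
    atlas = np.asarray(atlas)
    roi_ids = np.unique(atlas)
    masks = {r: atlas == r for r in roi_ids}
    if any(not m.any() for m in masks.values()):
        raise ValueError("atlas contains an empty ROI")
    w = None if area_weights is None else np.asarray(area_weights, float)
    rows = []
    for (subject, pipeline, timepoint), arr in maps.items():
        vals = np.asarray(getattr(arr, "values", arr), float)
        for r in roi_ids:
            m = masks[r]
            mean = (np.average(vals[m], weights=w[m]) if w is not None
                    else float(vals[m].mean()))
            rows.append((subject, groups.get(subject, ""), pipeline,
                         timepoint, int(r), float(mean)))
    return pd.DataFrame(rows, columns=["subject", "group", "pipeline",
                                       "timepoint", "roi_id", "thickness"])


def vertex_area_weights(mesh: TriangleMesh) -> np.ndarray:
    """One third of incident triangle area per vertex (barycentric lumping)."""
    areas = mesh.face_areas()
    w = np.zeros(mesh.n_vertices)
    for c in range(3):
        np.add.at(w, mesh.faces[:, c], areas / 3.0)
    return w


# ---------------------------------------------------------------------------
# ANOVA + Tukey-Kramer

@dataclasses.dataclass
class TukeyResult:
    omnibus_p: float
    pairs: list                  # (group_i, group_j)
    q: np.ndarray                # studentized-range statistics
    p: np.ndarray                # Tukey-Kramer adjusted p per pair
    significant: np.ndarray      # p < alpha
    alpha: float


def tukey_kramer_summary(means, sds, ns, alpha: float = 0.05,
                         labels=None) -> TukeyResult:
    """Tukey-Kramer pairwise comparisons from group summary statistics.

    q_ij = |m_i - m_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)) with MSW the pooled
    within-group variance; p from the studentized range with k groups and
    N-k df.  Reduces to classic Tukey HSD at equal n.  Also returns the
    omnibus one-way ANOVA p computed from the same summaries.
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, int)
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    k = len(means)
    labels = list(labels) if labels is not None else list(range(k))
    N = int(ns.sum())
    dfw = N - k
    msw = float(np.sum((ns - 1) * sds ** 2) / dfw)
    grand = float(np.sum(ns * means) / N)
    msb = float(np.sum(ns * (means - grand) ** 2) / (k - 1))
    if msw == 0:
        raise ValueError("zero within-group variance")
    omnibus_p = float(stats.f.sf(msb / msw, k - 1, dfw))
    pairs, qs = [], []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            qs.append(abs(means[i] - means[j]) / se)
            pairs.append((labels[i], labels[j]))
    qs = np.array(qs)
    p = studentized_range.sf(qs, k, dfw)
    return TukeyResult(omnibus_p, pairs, qs, p, p < alpha, alpha)


def anova_tukey(table: pd.DataFrame, value_col: str = "thickness",
                group_col: str = "group", groups=GROUP_ORDER,
                alpha: float = 0.05, by_roi: bool = True):
    """One-way ANOVA with Tukey-Kramer post-hocs on a tidy ROITable.

    With ``by_roi`` (default) returns {roi_id: TukeyResult}; otherwise a
    single TukeyResult over the whole table.
    """
    def _one(df):
        stats_by_g = df.groupby(group_col)[value_col]
        means = stats_by_g.mean().reindex(groups)
        sds = stats_by_g.std(ddof=1).reindex(groups)
        ns = stats_by_g.size().reindex(groups)
        if means.isna().any():
            raise ValueError("a requested group has no records")
        return tukey_kramer_summary(means.to_numpy(), sds.to_numpy(),
                                    ns.to_numpy(), alpha, labels=groups)

    if not by_roi:
        return _one(table)
    return {int(r): _one(df) for r, df in table.groupby("roi_id")}


# ---------------------------------------------------------------------------
# effect sizes

@dataclasses.dataclass
class EffectSizeResult:
    g: float
    se_g: float
    J: float
    n1: int
    n2: int


def hedges_g(mean1, sd1, n1, mean2, sd2, n2) -> EffectSizeResult:
    """Hedge's g with small-sample correction J = 1 - 3/(4(n1+n2)-9).

    g = J * (mean1 - mean2) / s_pooled, with the df-weighted pooled SD;
    se_g^2 = (n1+n2)/(n1*n2) + g^2 / (2 (n1+n2)).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("hedges_g needs n >= 2 per group")
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("pooled SD is zero")
    J = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    g = J * (mean1 - mean2) / np.sqrt(sp2)
    se2 = (n1 + n2) / (n1 * n2) + g ** 2 / (2.0 * (n1 + n2))
    return EffectSizeResult(float(g), float(np.sqrt(se2)), float(J),
                            int(n1), int(n2))


def hedges_g_from_samples(x1, x2) -> EffectSizeResult:
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    return hedges_g(x1.mean(), x1.std(ddof=1), len(x1),
                    x2.mean(), x2.std(ddof=1), len(x2))


def compare_effect_sizes(g1: EffectSizeResult, g2: EffectSizeResult):
    """z-test for a difference between two pipelines' effect sizes.

    Treats the two g's as independent (cf. the paired-bootstrap
    alternative in :func:`paired_bootstrap_g_diff`, which respects that
    both derive from the same subjects).
    """
    z = (g1.g - g2.g) / np.sqrt(g1.se_g ** 2 + g2.se_g ** 2)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def paired_bootstrap_g_diff(x1a, x2a, x1b, x2b, n_boot: int = 2000,
                            seed: int = 0):
    """Bootstrap p for g(pipeline A) - g(pipeline B) on the same subjects.

    x1*/x2* are the two groups' measurements under each pipeline, aligned
    subject-by-subject across pipelines; subjects are resampled jointly.
    """
    rng = np.random.default_rng(seed)
    x1a, x2a = np.asarray(x1a, float), np.asarray(x2a, float)
    x1b, x2b = np.asarray(x1b, float), np.asarray(x2b, float)
    obs = hedges_g_from_samples(x1a, x2a).g - hedges_g_from_samples(x1b, x2b).g
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        i1 = rng.integers(0, len(x1a), len(x1a))
        i2 = rng.integers(0, len(x2a), len(x2a))
        diffs[b] = (hedges_g_from_samples(x1a[i1], x2a[i2]).g
                    - hedges_g_from_samples(x1b[i1], x2b[i2]).g)
    se = diffs.std(ddof=1)
    z = obs / se if se > 0 else 0.0
    return float(obs), float(z), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# thinning percentages

def thinning_percent(table: pd.DataFrame, mode: str = "longitudinal",
                     baseline: str = "BSL", followup: str = "M24") -> pd.DataFrame:
    """Thinning percentages per ROI and group.

    longitudinal: 100 * (M24 - BSL) / BSL per subject, then group-averaged;
    cross-sectional: 100 * (group mean - CTR mean) / CTR mean at baseline.
    """
    if mode == "longitudinal":
        wide = table.pivot_table(index=["subject", "group", "pipeline", "roi_id"],
                                 columns="timepoint", values="thickness")
        missing = wide[baseline].isna() | wide[followup].isna()
        wide = wide[~missing]
        pct = 100.0 * (wide[followup] - wide[baseline]) / wide[baseline]
        out = pct.groupby(level=["group", "pipeline", "roi_id"]).agg(
            ["mean", "std"]).reset_index()
        out.columns = ["group", "pipeline", "roi_id", "percent", "sd"]
        return out
    if mode == "cross":
        bsl = table[table.timepoint == baseline]
        gm = bsl.groupby(["pipeline", "roi_id", "group"])["thickness"].mean()
        rows = []
        for (pipeline, roi), sub in gm.groupby(level=["pipeline", "roi_id"]):
            ref = sub.xs((pipeline, roi, "CTR"))
            for grp in sub.index.get_level_values("group"):
                if grp == "CTR":
                    continue
                val = sub.xs((pipeline, roi, grp))
                rows.append((grp, pipeline, roi, 100.0 * (val - ref) / ref))
        return pd.DataFrame(rows, columns=["group", "pipeline", "roi_id",
                                           "percent"])
    raise ValueError("mode must be 'longitudinal' or 'cross'")


# ---------------------------------------------------------------------------
# correlations

@dataclasses.dataclass
class CorrelationResult:
    r: float
    n: int
    roi_id: int
    covariate: str
    p: float = np.nan
    tau: float = np.nan
    r_equivalent: float = np.nan


def pearson_by_roi(table: pd.DataFrame, covariates: pd.DataFrame,
                   covariate: str) -> list[CorrelationResult]:
    """Pearson r of ROI thickness vs a subject covariate, per ROI.

    ``covariates`` is indexed by subject.  Requires n >= 4 and a
    non-constant covariate.
    """
    out = []
    for roi, df in table.groupby("roi_id"):
        merged = df.set_index("subject").join(covariates, how="inner")
        x = merged["thickness"].to_numpy(float)
        y = merged[covariate].to_numpy(float)
        if len(x) < 4:
            raise ValueError("pearson_by_roi needs n >= 4")
        if np.std(y) == 0:
            raise ValueError(f"constant covariate {covariate!r}")
        r, p = stats.pearsonr(x, y)
        out.append(CorrelationResult(float(r), len(x), int(roi), covariate,
                                     p=float(p)))
    return out


def steiger_z(r1: float, r2: float, r12: float, n: int):
    """Steiger's Z1* for two dependent correlations sharing one variable.

    r1 = corr(X, Z), r2 = corr(Y, Z) share the covariate Z; r12 =
    corr(X, Y).  Fisher transforms are compared with the covariance term
    evaluated at the backtransformed average correlation.
    """
    for r in (r1, r2, r12):
        if not -1 < r < 1:
            raise ValueError("correlations must lie strictly in (-1, 1)")
    if n < 10:
        raise ValueError("steiger_z needs n >= 10")
    det = 1 + 2 * r1 * r2 * r12 - r1 ** 2 - r2 ** 2 - r12 ** 2
    if det < 0:
        raise ValueError("(r1, r2, r12) is not a valid correlation triple")
    z1 = np.arctanh(r1)
    z2 = np.arctanh(r2)
    rm = np.tanh((z1 + z2) / 2.0)
    num = r12 * (1 - 2 * rm ** 2) - 0.5 * rm ** 2 * (1 - 2 * rm ** 2 - r12 ** 2)
    s = min(num / (1 - rm ** 2) ** 2, 1 - 1e-12)
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - s)))
    return float(z), float(2 * stats.norm.sf(abs(z)))


_T4_PAIRS = {
    "flag_ctr_pmci": ("CTR", "pMCI"),
    "flag_smci_pmci": ("sMCI", "pMCI"),
    "flag_ctr_ad": ("CTR", "AD"),
    "flag_smci_ad": ("sMCI", "AD"),
}


def recompute_longitudinal_flags(alpha: float = 0.01,
                                 rounding: float = 0.005) -> pd.DataFrame:
    """Re-derive the longitudinal table's Tukey-Kramer flags from its own
    printed summaries (group Delta-means, sigmas, study n's).

    Because the summaries are printed to two decimals, a cell whose flag
    flips when every summary is perturbed within the rounding half-width
    (+-``rounding``) is marked ``marginal`` — agreement should be judged
    on the non-marginal cells.  Returns one row per (roi, pipeline, pair)
    with printed flag, recomputed flag and the marginal indicator.
    """
    t4 = load_fixture_table("T4")
    ns = [69, 37, 27, 52]
    cols = ["ctr", "smci", "pmci", "ad"]
    rows = []
    for _, rec in t4.iterrows():
        means = np.array([rec[f"{c}_dm"] for c in cols], float)
        sds = np.array([rec[f"{c}_sd"] for c in cols], float)
        res = tukey_kramer_summary(means, sds, ns, alpha, labels=GROUP_ORDER)
        sig = {pair: bool(s) for pair, s in zip(res.pairs, res.significant)}
        for col, pair in _T4_PAIRS.items():
            i, j = GROUP_ORDER.index(pair[0]), GROUP_ORDER.index(pair[1])
            # extremes of the rounding box for this pair: widen the gap
            # with smaller sds vs narrow it with larger sds
            lo_m, hi_m = means.copy(), means.copy()
            gap = np.sign(means[i] - means[j]) or 1.0
            hi_m[i] += rounding * gap
            hi_m[j] -= rounding * gap
            lo_m[i] -= rounding * gap
            lo_m[j] += rounding * gap
            most = tukey_kramer_summary(hi_m, np.maximum(sds - rounding, 1e-6),
                                        ns, alpha, labels=GROUP_ORDER)
            least = tukey_kramer_summary(lo_m, sds + rounding, ns, alpha,
                                         labels=GROUP_ORDER)
            k = res.pairs.index(pair)
            marginal = bool(most.significant[k]) != bool(least.significant[k])
            rows.append({
                "roi_id": int(rec["roi_id"]), "pipeline": rec["pipeline"],
                "pair": f"{pair[0]}_vs_{pair[1]}",
                "printed": bool(rec[col]), "recomputed": sig[pair],
                "marginal": marginal,
            })
    return pd.DataFrame(rows)


def kendall_with_conversion(x, y):
    """Kendall tau-b with its normal-approximation z and the Greiner
    conversion to a Pearson-scale coefficient r = sin(pi * tau / 2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 10:
        raise ValueError("kendall_with_conversion needs n >= 10")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("all-tied input")
    res = stats.kendalltau(x, y)
    tau = float(res.statistic)
    n = len(x)
    sigma = np.sqrt(2.0 * (2 * n + 5) / (9.0 * n * (n - 1)))
    z = tau / sigma
    return tau, float(z), float(np.sin(np.pi * tau / 2.0))
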