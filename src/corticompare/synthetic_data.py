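"""Synthetic two-pipeline cohorts with the statistical structure the
downstream analysis assumes.

The generator emulates a four-group design (CTR / stable MCI / progressive
MCI / AD; n = 69/37/27/52) observed at baseline, month 12 and month 24 by
two surface pipelines that see the same cortex at different mesh
resolutions and with a systematic thickness offset (the target pipeline
reads ~30% thinner).  Region-wise ground truth is sampled from the
published summary magnitudes: cross-sectional group offsets from the
baseline ROI table and two-year declines from the longitudinal ROI table
(both on the source-pipeline scale, which serves as the truth scale).
The printed sigma of each contrast is interpreted as the pooled
between-subject SD and split into a shared subject factor plus an
ROI-local residual, so ROIs correlate within subject.

Covariates: MMSE (baseline mean/SD and two-year change per the
demographics table, truncated to [0, 30] and integer-rounded) and
hippocampal volume (cm^3), both generated with configurable weak-to-medium
correlation to mean temporal-lobe thickness (default r = 0.4 in pMCI,
0.1 in CTR).

All generators are seed-deterministic.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .mesh_core import ScalarMap, TriangleMesh, build_cortex_template, build_icosphere
from .roi_stats import GROUP_ORDER, load_fixture_table, load_roi_registry
from .template_registration import ControlLattice, apply_ffd, make_lattice

# re-exported here because fixtures are part of the synthetic world's surface
__all__ = [
    "CohortDesign", "PipelineProfile", "GroundTruthCohort", "EffectConfig",
    "make_cohort", "render_pipeline_observation", "make_synthetic_warp",
    "load_fixture_table", "CIVET_PROFILE", "FREESURFER_PROFILE",
    "default_effect_config", "null_effect_config", "smooth_sphere_noise",
]

TIMEPOINTS = ("BSL", "M12", "M24")

#: fraction of the per-ROI SD carried by the shared subject factor
SUBJECT_FACTOR_SHARE = 0.6


@dataclasses.dataclass
class CohortDesign:
    groups: tuple = (("CTR", 69), ("sMCI", 37), ("pMCI", 27), ("AD", 52))
    timepoints: tuple = TIMEPOINTS
    seed: int = 0

    def __post_init__(self):
        if any(n <= 0 for _, n in self.groups):
            raise ValueError("group sizes must be positive")
        order = [TIMEPOINTS.index(t) for t in self.timepoints]
        if order != sorted(order):
            raise ValueError("timepoints must be ordered")


@dataclasses.dataclass
class PipelineProfile:
    """Observation model of one thickness pipeline."""

    name: str                       # "CV" (source) or "FS" (target)
    resolution_subdiv: int          # icosphere level per hemisphere
    thickness_scale: float = 1.0    # multiplicative bias vs truth scale
    additive_offset: float = 0.0    # mm
    measurement_noise_sd: float = 0.15   # mm, spatially smooth vertex noise
    longitudinal_noise_shrink: float = 1.0  # <1 shrinks noise at M12/M24
    shape_bias_amplitude: float = 0.0   # mm, systematic surface morphology
    # bias of this pipeline (the two algorithms reconstruct morphologically
    # different surfaces; registration exists to remove this)

    def __post_init__(self):
        if not (0 < self.thickness_scale <= 1.5):
            raise ValueError("thickness_scale must lie in (0, 1.5]")
        if self.measurement_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


# the source pipeline carries the truth scale; the target pipeline reads
# about 30% thinner and, emulating a longitudinal stream, has reduced
# follow-up variability
CIVET_PROFILE = PipelineProfile("CV", 6, 1.0, 0.0, 0.15, 1.0, 0.0)
FREESURFER_PROFILE = PipelineProfile("FS", 7, 0.70, 0.0, 0.15, 0.6, 2.0)


@dataclasses.dataclass
class EffectConfig:
    """Region-wise ground-truth magnitudes (truth scale, mm).

    cross_offsets / long_declines: DataFrames indexed by roi_id with one
    column per group; cross_sd / long_sd likewise hold between-subject and
    change SDs.  baseline_thickness is the common healthy baseline.
    hippo_r / mmse_r: per-group target correlations between the covariate
    and mean temporal-lobe thickness.
    """

    baseline_thickness: float
    cross_offsets: pd.DataFrame
    cross_sd: pd.DataFrame
    long_declines: pd.DataFrame
    long_sd: pd.DataFrame
    hippo_r: dict
    mmse_r: dict

    def check_rois(self, registry: pd.DataFrame) -> None:
        known = set(registry["roi_id"])
        for df in (self.cross_offsets, self.long_declines):
            unknown = set(df.index) - known
            if unknown:
                raise KeyError(f"effect config references unknown ROIs: "
                               f"{sorted(unknown)}")


def default_effect_config() -> EffectConfig:
    """Magnitudes sampled from the printed ROI tables (source-pipeline scale).

    Cross-sectional offsets use the baseline table's CTR-vs-group contrast
    means; per-ROI between-subject SD uses that table's CTR-vs-AD sigma.
    Two-year declines and change SDs come from the longitudinal table.
    The healthy baseline level (2.5 mm) is a package default: the printed
    tables report contrasts, not per-ROI absolute baselines.
    """
    t3 = load_fixture_table("T3")
    t4 = load_fixture_table("T4")
    cv3 = t3[t3.pipeline == "CV"].set_index("roi_id")
    cv4 = t4[t4.pipeline == "CV"].set_index("roi_id")
    cross = pd.DataFrame({
        "CTR": 0.0,
        "sMCI": cv3["ctr_smci_dm"],
        "pMCI": cv3["ctr_pmci_dm"],
        "AD": cv3["ctr_ad_dm"],
    })
    cross_sd = pd.DataFrame({g: cv3["ctr_ad_sd"] for g in GROUP_ORDER})
    decl = pd.DataFrame({g: cv4[f"{p}_dm"] for g, p in
                         zip(GROUP_ORDER, ["ctr", "smci", "pmci", "ad"])})
    decl_sd = pd.DataFrame({g: cv4[f"{p}_sd"] for g, p in
                            zip(GROUP_ORDER, ["ctr", "smci", "pmci", "ad"])})
    return EffectConfig(
        baseline_thickness=2.5,
        cross_offsets=cross, cross_sd=cross_sd,
        long_declines=decl, long_sd=decl_sd,
        hippo_r={"CTR": 0.1, "sMCI": 0.25, "pMCI": 0.4, "AD": 0.4},
        mmse_r={"CTR": 0.15, "sMCI": 0.2, "pMCI": 0.3, "AD": 0.3},
    )


def null_effect_config() -> EffectConfig:
    """All group offsets and declines zero (type-I error harness)."""
    cfg = default_effect_config()
    cfg.cross_offsets = cfg.cross_offsets * 0.0
    cfg.long_declines = cfg.long_declines * 0.0
    cfg.hippo_r = {g: 0.0 for g in GROUP_ORDER}
    cfg.mmse_r = {g: 0.0 for g in GROUP_ORDER}
    return cfg


@dataclasses.dataclass
class GroundTruthCohort:
    subjects: pd.DataFrame    # subject, group, mmse_*, hippocampal_volume
    thickness: pd.DataFrame   # tidy truth: subject, group, roi_id, timepoint, thickness
    design: CohortDesign
    effect_config: EffectConfig

    def group_of(self) -> dict:
        return dict(zip(self.subjects["subject"], self.subjects["group"]))

    def annual_thinning(self) -> pd.DataFrame:
        wide = self.thickness.pivot_table(
            index=["subject", "group", "roi_id"], columns="timepoint",
            values="thickness")
        out = ((wide["M24"] - wide["BSL"]) / 2.0).rename("mm_per_year")
        return out.reset_index()


def make_cohort(design: CohortDesign | None = None,
                effect_config: EffectConfig | None = None) -> GroundTruthCohort:
    """Sample a ground-truth cohort: per-subject true ROI thickness
    trajectories plus MMSE and hippocampal-volume covariates."""
    design = design or CohortDesign()
    cfg = effect_config or default_effect_config()
    registry = load_roi_registry()
    cfg.check_rois(registry)
    rng = np.random.default_rng(design.seed)
    roi_ids = registry["roi_id"].to_numpy()
    temporal = registry.loc[registry["lobe"] == "Temporal", "roi_id"].to_numpy()
    demo = load_fixture_table("T1").set_index("group")

    sub_rows, thick_rows = [], []
    for gname, n in design.groups:
        off = cfg.cross_offsets[gname].reindex(roi_ids).to_numpy()
        sd = cfg.cross_sd[gname].reindex(roi_ids).to_numpy()
        dec = cfg.long_declines[gname].reindex(roi_ids).to_numpy()
        dsd = cfg.long_sd[gname].reindex(roi_ids).to_numpy()
        a = SUBJECT_FACTOR_SHARE
        b = np.sqrt(1 - a ** 2)
        for i in range(n):
            sid = f"{gname}_{i:03d}"
            subj_factor = rng.standard_normal()
            bsl = (cfg.baseline_thickness + off
                   + sd * (a * subj_factor + b * rng.standard_normal(len(roi_ids))))
            bsl = np.maximum(bsl, 0.3)
            change_factor = rng.standard_normal()
            change = dec + dsd * (a * change_factor
                                  + b * rng.standard_normal(len(roi_ids)))
            tp_thick = {"BSL": bsl, "M12": bsl + 0.5 * change,
                        "M24": bsl + change}
            for tp in design.timepoints:
                for r, v in zip(roi_ids, tp_thick[tp]):
                    thick_rows.append((sid, gname, int(r), tp, float(max(v, 0.1))))
            # covariates tied to mean temporal-lobe baseline thickness
            tmask = np.isin(roi_ids, temporal)
            z_thick = float((bsl[tmask].mean()
                             - (cfg.baseline_thickness + off[tmask].mean()))
                            / max(sd[tmask].mean() * np.sqrt(
                                a ** 2 + b ** 2 / tmask.sum()), 1e-9))
            r_h = cfg.hippo_r.get(gname, 0.0)
            r_m = cfg.mmse_r.get(gname, 0.0)
            hippo_mu = {"CTR": 7.0, "sMCI": 6.3, "pMCI": 5.9, "AD": 5.4}.get(gname, 6.5)
            hippo = hippo_mu + 0.9 * (r_h * z_thick
                                      + np.sqrt(1 - r_h ** 2) * rng.standard_normal())
            mmse_b = demo.loc[gname, "mmse_bsl_mean"] + demo.loc[gname, "mmse_bsl_sd"] * (
                r_m * z_thick + np.sqrt(1 - r_m ** 2) * rng.standard_normal())
            dm = demo.loc[gname, "delta_mmse_mean"] + \
                demo.loc[gname, "delta_mmse_sd"] * rng.standard_normal()
            mmse_b = int(np.clip(round(mmse_b), 0, 30))
            mmse_24 = int(np.clip(round(mmse_b + dm), 0, 30))
            mmse_12 = int(np.clip(round(mmse_b + dm / 2.0), 0, 30))
            sub_rows.append((sid, gname, mmse_b, mmse_12, mmse_24,
                             float(max(hippo, 1.0))))
    subjects = pd.DataFrame(sub_rows, columns=[
        "subject", "group", "mmse_bsl", "mmse_m12", "mmse_m24",
        "hippocampal_volume"])
    thickness = pd.DataFrame(thick_rows, columns=[
        "subject", "group", "roi_id", "timepoint", "thickness"])
    return GroundTruthCohort(subjects, thickness, design, cfg)


# ---------------------------------------------------------------------------
# rendering observations

def smooth_sphere_noise(template: TriangleMesh, rng: np.random.Generator,
                        sd: float, coarse_subdiv: int = 1) -> np.ndarray:
    """Spatially smooth zero-mean vertex noise with marginal SD ``sd``.

    Low-frequency value noise: i.i.d. normals on a coarse icosphere are
    interpolated to the template with a Gaussian kernel over the 8
    nearest coarse nodes (per hemisphere direction sphere), then rescaled
    to unit variance.  Coarse level 1 (42 nodes) corresponds to an
    effective smoothness on the order of tens of millimetres on a
    brain-sized sphere.
    """
    if sd == 0:
        return np.zeros(template.n_vertices)
    coarse = build_icosphere(coarse_subdiv, 1.0).vertices
    vals = rng.standard_normal(len(coarse))
    tree = cKDTree(coarse)
    d0 = float(np.median(tree.query(coarse, k=2)[0][:, 1]))  # node spacing
    out = np.empty(template.n_vertices)
    for hemi in np.unique(template.hemisphere):
        sel = template.hemisphere == hemi
        v = template.vertices[sel]
        u = v - v.mean(axis=0)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        d, idx = tree.query(u, k=min(8, len(coarse)))
        w = np.exp(-(d / d0) ** 2)
        w /= w.sum(axis=1, keepdims=True)
        out[sel] = (w * vals[idx]).sum(axis=1)
    out -= out.mean()
    s = out.std()
    return out * (sd / s) if s > 0 else out


@dataclasses.dataclass
class RenderedObservation:
    profile: PipelineProfile
    template: TriangleMesh
    atlas: np.ndarray
    maps: dict           # (subject, timepoint) -> ScalarMap
    meshes: dict         # (subject, timepoint) -> TriangleMesh (optional)


def render_pipeline_observation(cohort: GroundTruthCohort,
                                profile: PipelineProfile,
                                atlas: np.ndarray,
                                template: TriangleMesh,
                                seed: int | None = None,
                                make_meshes: bool = False,
                                mesh_subjects: tuple = (),
                                deform_amplitude: float = 1.5
                                ) -> RenderedObservation:
    """Render per-subject vertex thickness maps as one pipeline sees them.

    vertex thickness = scale * true ROI thickness + offset + smooth noise.
    The noise SD shrinks by ``longitudinal_noise_shrink`` at follow-up
    timepoints (longitudinal-stream emulation).  Meshes (the template with
    a mild subject-specific smooth radial deformation) are built only for
    ``mesh_subjects`` or all subjects when ``make_meshes``.
    """
    if len(atlas) != template.n_vertices:
        raise ValueError("atlas is not defined on the profile's template")
    base_seed = cohort.design.seed if seed is None else seed
    rng = np.random.default_rng(
        [base_seed, *(ord(c) for c in profile.name), 7919])
    wide = cohort.thickness.pivot_table(
        index=["subject", "timepoint"], columns="roi_id", values="thickness")
    roi_cols = wide.columns.to_numpy()
    col_of = {int(r): i for i, r in enumerate(roi_cols)}
    vert_col = np.array([col_of[int(r)] for r in atlas])
    maps, meshes = {}, {}
    mesh_set = set(mesh_subjects) if not make_meshes else \
        set(cohort.subjects["subject"])
    radial_dir = _radial_directions(template)
    # deterministic per-pipeline morphology bias (independent of cohort seed)
    if profile.shape_bias_amplitude > 0:
        bias_rng = np.random.default_rng([*(ord(c) for c in profile.name), 4242])
        bias = smooth_sphere_noise(template, bias_rng,
                                   profile.shape_bias_amplitude / 2.0)
        bias = np.clip(bias, -profile.shape_bias_amplitude,
                       profile.shape_bias_amplitude)
    else:
        bias = np.zeros(template.n_vertices)
    for subject in cohort.subjects["subject"]:
        # always drawn so the map stream is independent of mesh_subjects
        bump = smooth_sphere_noise(template, rng, deform_amplitude / 2.0)
        if subject in mesh_set:
            bump = np.clip(bump, -deform_amplitude, deform_amplitude)
            verts = template.vertices + radial_dir * (bias + bump)[:, None]
            mesh = TriangleMesh(verts, template.faces.copy(),
                                template.hemisphere.copy())
        else:
            mesh = None
        for tp in cohort.design.timepoints:
            truth = wide.loc[(subject, tp)].to_numpy()[vert_col]
            shrink = 1.0 if tp == "BSL" else profile.longitudinal_noise_shrink
            noise = smooth_sphere_noise(
                template, rng, profile.measurement_noise_sd * shrink)
            vals = profile.thickness_scale * truth + profile.additive_offset + noise
            maps[(subject, tp)] = ScalarMap(np.maximum(vals, 0.0),
                                            mesh_id=profile.name)
            if mesh is not None:
                meshes[(subject, tp)] = mesh
    return RenderedObservation(profile, template, atlas, maps, meshes)


def _radial_directions(template: TriangleMesh) -> np.ndarray:
    dirs = np.empty_like(template.vertices)
    for hemi in np.unique(template.hemisphere):
        sel = template.hemisphere == hemi
        v = template.vertices[sel]
        u = v - v.mean(axis=0)
        dirs[sel] = u / np.linalg.norm(u, axis=1, keepdims=True)
    return dirs


# ---------------------------------------------------------------------------
# ground-truth warps for registration recovery

def make_synthetic_warp(seed: int, amplitude: float, bounds_lo, bounds_hi,
                        dims=(12, 12, 12), smooth_cells: float = 1.5
                        ) -> ControlLattice:
    """Random smooth FFD warp with max control displacement = amplitude (mm).

    Control displacements are white noise smoothed along the lattice and
    rescaled, so the warp is C2-smooth; at the default amplitude (well
    under a fifth of the object radius) it is invertible (positive spline
    Jacobian everywhere).  Returns the control-point parameterization;
    apply with :func:`corticompare.template_registration.apply_ffd`.
    """
    lo = np.asarray(bounds_lo, float)
    hi = np.asarray(bounds_hi, float)
    radius = 0.5 * float(np.max(hi - lo))
    lattice = make_lattice(lo, hi, dims=dims)
    rng = np.random.default_rng(seed)
    disp = rng.standard_normal(lattice.dims + (3,))
    for c in range(3):
        disp[..., c] = ndimage.gaussian_filter(disp[..., c], smooth_cells)
    peak = np.abs(disp).max()
    if peak > 0:
        disp *= amplitude / peak
    lattice.displacements = disp
    if amplitude >= 0.2 * radius:
        import warnings
        warnings.warn("warp amplitude >= 20% of object radius; "
                      "folding possible", stacklevel=2)
    return lattice


def ffd_jacobian_determinants(lattice: ControlLattice, points: np.ndarray,
                              h: float = 1e-4) -> np.ndarray:
    """Jacobian determinant of the FFD at sample points (central differences)."""
    points = np.asarray(points, float)
    J = np.empty((len(points), 3, 3))
    for a in range(3):
        dp = np.zeros(3)
        dp[a] = h
        plus = apply_ffd(lattice, points + dp)
        minus = apply_ffd(lattice, points - dp)
        J[:, :, a] = (plus - minus) / (2 * h)
    return np.linalg.det(J)
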