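"""Synthetic cohorts and hippocampus phantoms.

The study this pipeline targets — hippocampal sclerosis (HS) biomarkers
from left/right segmentation masks — cannot ship its patient MRI, so this
module generates every input the pipeline needs, at two fidelity levels:

* **Measurement level** (fast): per-scan left/right hippocampal volumes and
  surface-to-volume (S/V) ratios with planted statistical structure —
  healthy-control asymmetry-index (AI) distribution with a small negative
  mean (the right hippocampus tends to be slightly larger), standardized
  group shifts for left/right HS, volumes depending linearly on eTIV and
  age, and a same-day / within-a-year re-scan session structure for
  test-retest analyses.
* **Voxel level** (slow): hippocampus-like binary masks — a bent ellipsoid
  with controllable volume atrophy, surface "fraying" (a band-limited
  radial noise field), and optional fluid-cavity notches on the lateral
  body — for exercising the full mesh-based feature pipeline.

Construction of measurement scans guarantees the *observed* per-scan AI is
exactly Normal(group mean, ai_sd): a scan is built as lh = M(1+AI),
rh = M(1-AI) where AI = subject-level AI + a small antisymmetric re-scan
term and M carries a shared (bilateral) re-scan error. The shared/
antisymmetric split reproduces realistic per-side re-scan error (the
bilateral component dominates) without inflating the AI spread.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io import BinaryMask, GROUPS, LabelVolume, ScanRecord, get_dialect

__all__ = ["CohortConfig", "PhantomConfig", "generate_measurement_cohort",
           "generate_feature_ai_cohort", "generate_hippocampus_mask",
           "generate_labelled_subject"]

# Nominal levels for shape features that carry no planted group signal in
# measurement-level cohorts (values typical of an adult hippocampus).
_NEUTRAL_FEATURE_LEVELS: Dict[str, float] = {
    "sphericity": 0.45,
    "max_3d_diameter": 45.0,
    "max_2d_diameter_slice": 20.0,
    "max_2d_diameter_column": 42.0,
    "max_2d_diameter_row": 30.0,
    "major_axis_length": 40.0,
    "minor_axis_length": 15.0,
    "least_axis_length": 10.0,
    "elongation": 0.38,
    "flatness": 0.25,
}


@dataclass
class CohortConfig:
    """Measurement-level cohort generator settings.

    Group scan counts default to the emulated study's MRI counts (406
    healthy controls; 18/19/3 left/right/bilateral HS; 86 other
    epilepsies), with subject counts giving the matching repeat-scan
    surplus. ``vol_ai_effect_*`` / ``sv_ai_effect_*`` are standardized
    shifts (in units of the common AI SD) of the group AI mean relative to
    the healthy controls; defaults plant the study's reported left/right HS
    volume-asymmetry effect sizes. ``hc_mean_ai`` defaults to the reported
    healthy-control mean volume AI of -0.007.
    """

    # scans per group
    n_hc: int = 406
    n_hs_left: int = 18
    n_hs_right: int = 19
    n_hs_bilateral: int = 3
    n_epi_other: int = 86
    # subjects per group (None -> defaults when scan counts are default,
    # otherwise one subject per scan)
    n_hc_subjects: Optional[int] = None
    n_hs_left_subjects: Optional[int] = None
    n_hs_right_subjects: Optional[int] = None
    n_hs_bilateral_subjects: Optional[int] = None
    n_epi_other_subjects: Optional[int] = None

    # hippocampal volume model (bilateral mean M, mm^3)
    hc_volume_mean: float = 3500.0
    hc_volume_sd: float = 300.0
    beta_etiv: float = 200.0   # mm^3 per HC-SD of eTIV
    beta_age: float = -150.0   # mm^3 per HC-SD of age
    etiv_mean: float = 1.45e6  # mm^3
    etiv_sd: float = 1.4e5
    hc_age_mean: float = 32.3  # years
    hc_age_sd: float = 14.0
    patient_age_mean: float = 34.7
    patient_age_sd: float = 13.0

    # volume asymmetry index
    hc_mean_ai: float = -0.007
    ai_sd: float = 0.025
    vol_ai_effect_hs_left: float = -4.165
    vol_ai_effect_hs_right: float = 4.203
    vol_ai_effect_hs_bilateral: float = 0.0
    vol_ai_effect_epi_other: float = 0.0
    # absolute bilateral volume loss for HS groups (mm^3)
    hs_volume_loss: float = 250.0
    hs_bilateral_volume_loss: float = 400.0

    # surface-to-volume ratio (mm^-1)
    sv_mean: float = 0.65
    sv_sd: float = 0.04
    hc_mean_sv_ai: float = 0.0
    sv_ai_sd: float = 0.02
    sv_ai_effect_hs_left: float = 3.0
    sv_ai_effect_hs_right: float = -3.0
    sv_ai_effect_hs_bilateral: float = 0.0
    sv_ai_effect_epi_other: float = 0.0
    sv_bilateral_factor: float = 1.15  # bilateral HS raises S/V on both sides

    # re-scan noise: total per-side coefficient of variation, and the
    # antisymmetric (AI) component of it
    volume_rescan_cv: float = 0.035
    ai_rescan_sd: float = 0.005
    sv_rescan_cv: float = 0.012
    sv_ai_rescan_sd: float = 0.002

    # uninformative shape features: per-scan AI spread
    extra_feature_ai_sd: float = 0.02

    # session structure: HC subjects with a within-1-year repeat
    n_hc_repeat_sessions: int = 21
    hc_short_gap_days: Tuple[int, int] = (30, 300)
    hc_long_gap_days: Tuple[int, int] = (400, 1200)

    seed: int = 0

    def scan_counts(self) -> Dict[str, int]:
        return {"HC": self.n_hc, "HS-left": self.n_hs_left,
                "HS-right": self.n_hs_right, "HS-bilateral": self.n_hs_bilateral,
                "EPI-other": self.n_epi_other}

    def subject_counts(self) -> Dict[str, int]:
        defaults = {"HC": 354, "HS-left": 13, "HS-right": 17,
                    "HS-bilateral": 1, "EPI-other": 74}
        scans = self.scan_counts()
        default_scans = {"HC": 406, "HS-left": 18, "HS-right": 19,
                         "HS-bilateral": 3, "EPI-other": 86}
        explicit = {"HC": self.n_hc_subjects, "HS-left": self.n_hs_left_subjects,
                    "HS-right": self.n_hs_right_subjects,
                    "HS-bilateral": self.n_hs_bilateral_subjects,
                    "EPI-other": self.n_epi_other_subjects}
        out = {}
        for g in GROUPS:
            if explicit[g] is not None:
                n = explicit[g]
            elif scans[g] == default_scans[g]:
                n = defaults[g]
            else:
                n = scans[g]
            if not 0 <= n <= scans[g]:
                raise ValueError(f"{g}: subject count {n} exceeds scan count {scans[g]}")
            if scans[g] > 0 and n == 0:
                raise ValueError(f"{g}: scans without subjects")
            out[g] = n
        return out


def _clipped_normal(rng, mean, sd, lo, hi, size=None):
    return np.clip(rng.normal(mean, sd, size), lo, hi)


def _group_params(cfg: CohortConfig, group: str):
    """(vol AI mean, S/V AI mean, bilateral volume loss, S/V level factor)."""
    vol_eff = {"HC": 0.0, "HS-left": cfg.vol_ai_effect_hs_left,
               "HS-right": cfg.vol_ai_effect_hs_right,
               "HS-bilateral": cfg.vol_ai_effect_hs_bilateral,
               "EPI-other": cfg.vol_ai_effect_epi_other}[group]
    sv_eff = {"HC": 0.0, "HS-left": cfg.sv_ai_effect_hs_left,
              "HS-right": cfg.sv_ai_effect_hs_right,
              "HS-bilateral": cfg.sv_ai_effect_hs_bilateral,
              "EPI-other": cfg.sv_ai_effect_epi_other}[group]
    loss = {"HC": 0.0, "HS-left": cfg.hs_volume_loss,
            "HS-right": cfg.hs_volume_loss,
            "HS-bilateral": cfg.hs_bilateral_volume_loss,
            "EPI-other": 0.0}[group]
    sv_factor = cfg.sv_bilateral_factor if group == "HS-bilateral" else 1.0
    return (cfg.hc_mean_ai + vol_eff * cfg.ai_sd,
            cfg.hc_mean_sv_ai + sv_eff * cfg.sv_ai_sd,
            loss, sv_factor)


def generate_measurement_cohort(config: CohortConfig,
                                seed: Optional[int] = None) -> List[ScanRecord]:
    """Generate a full measurement-level cohort of ScanRecords.

    Deterministic given (config, seed); ``seed`` defaults to
    ``config.seed``. Every scan carries measures for ``volume`` and all 14
    shape features (volume-derived and S/V features carry the planted
    signal; the remaining features are uninformative noise).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    if min(cfg.scan_counts().values()) < 0:
        raise ValueError("negative group size")
    subj_counts = cfg.subject_counts()

    ai_subj_var = cfg.ai_sd ** 2 - cfg.ai_rescan_sd ** 2
    sv_ai_subj_var = cfg.sv_ai_sd ** 2 - cfg.sv_ai_rescan_sd ** 2
    if ai_subj_var <= 0 or sv_ai_subj_var <= 0:
        raise ValueError("rescan AI noise must be smaller than the total AI SD")
    ai_subj_sd = float(np.sqrt(ai_subj_var))
    sv_ai_subj_sd = float(np.sqrt(sv_ai_subj_var))
    vol_shared_cv = float(np.sqrt(max(cfg.volume_rescan_cv ** 2
                                      - cfg.ai_rescan_sd ** 2, 0.0)))
    sv_shared_cv = float(np.sqrt(max(cfg.sv_rescan_cv ** 2
                                     - cfg.sv_ai_rescan_sd ** 2, 0.0)))

    base_date = _dt.date(2016, 1, 1)
    records: List[ScanRecord] = []
    subject_counter = 0

    for group in GROUPS:
        n_scans = cfg.scan_counts()[group]
        n_subj = subj_counts[group]
        if n_scans == 0:
            continue
        mu_vol_ai, mu_sv_ai, vol_loss, sv_factor = _group_params(cfg, group)
        surplus = n_scans - n_subj
        # distribute extra scans one per subject, cycling when surplus
        # exceeds the subject count
        extras = np.zeros(n_subj, dtype=int)
        for k in range(surplus):
            extras[k % n_subj] += 1
        # HC: the first n_hc_repeat_sessions repeat subjects re-scan within
        # a year (forming sessions); later ones are long-gap follow-ups.
        n_short = cfg.n_hc_repeat_sessions if group == "HC" else n_subj

        if group == "HC":
            age_mean, age_sd, age_lo, age_hi = cfg.hc_age_mean, cfg.hc_age_sd, 6.0, 84.0
        else:
            age_mean, age_sd = cfg.patient_age_mean, cfg.patient_age_sd
            age_lo, age_hi = 11.0, 69.0

        repeat_rank = 0  # position among this group's repeat subjects
        for s in range(n_subj):
            subject_counter += 1
            subject_id = f"sub-{subject_counter:04d}"
            etiv = float(rng.normal(cfg.etiv_mean, cfg.etiv_sd))
            age0 = float(_clipped_normal(rng, age_mean, age_sd, age_lo, age_hi))
            z_etiv = (etiv - cfg.etiv_mean) / cfg.etiv_sd
            z_age = (age0 - cfg.hc_age_mean) / cfg.hc_age_sd
            m_subj = (cfg.hc_volume_mean - vol_loss
                      + cfg.beta_etiv * z_etiv + cfg.beta_age * z_age
                      + rng.normal(0.0, cfg.hc_volume_sd))
            ai_subj = float(rng.normal(mu_vol_ai, ai_subj_sd))
            sv_subj = float(rng.normal(cfg.sv_mean, cfg.sv_sd)) * sv_factor
            sv_ai_subj = float(rng.normal(mu_sv_ai, sv_ai_subj_sd))
            date0 = base_date + _dt.timedelta(days=int(rng.integers(0, 1461)))

            n_extra = int(extras[s])
            gaps = [0]
            if n_extra:
                if group != "HC":
                    gaps += [0] * n_extra  # patients re-scan the same day
                else:
                    lo, hi = (cfg.hc_short_gap_days if repeat_rank < n_short
                              else cfg.hc_long_gap_days)
                    gaps += [int(rng.integers(lo, hi + 1)) for _ in range(n_extra)]
                repeat_rank += 1

            for t, gap in enumerate(gaps):
                eps_sh = float(rng.normal(0.0, vol_shared_cv))
                ai = ai_subj + float(rng.normal(0.0, cfg.ai_rescan_sd))
                m_scan = m_subj * (1.0 + eps_sh)
                lh = m_scan * (1.0 + ai)
                rh = m_scan * (1.0 - ai)

                sv_sh = float(rng.normal(0.0, sv_shared_cv))
                sv_ai = sv_ai_subj + float(rng.normal(0.0, cfg.sv_ai_rescan_sd))
                sv_scan = sv_subj * (1.0 + sv_sh)
                sv_lh = sv_scan * (1.0 + sv_ai)
                sv_rh = sv_scan * (1.0 - sv_ai)

                mesh_lh, mesh_rh = 0.98 * lh, 0.98 * rh
                measures: Dict[str, Tuple[float, float]] = {
                    "volume": (lh, rh),
                    "voxel_volume": (lh, rh),
                    "mesh_volume": (mesh_lh, mesh_rh),
                    "surface_area": (sv_lh * mesh_lh, sv_rh * mesh_rh),
                    "surface_to_volume_ratio": (sv_lh, sv_rh),
                }
                for name, level in _NEUTRAL_FEATURE_LEVELS.items():
                    f_ai = float(rng.normal(0.0, cfg.extra_feature_ai_sd))
                    lvl = level * (1.0 + float(rng.normal(0.0, 0.03)))
                    measures[name] = (lvl * (1.0 + f_ai), lvl * (1.0 - f_ai))

                records.append(ScanRecord(
                    subject_id=subject_id,
                    scan_id=f"{subject_id}_ses-{t + 1:02d}",
                    scan_date=date0 + _dt.timedelta(days=gap),
                    group=group,
                    age=age0 + gap / 365.25,
                    etiv=etiv,
                    measures=measures,
                ))
    return records


def generate_feature_ai_cohort(n_hs: int, n_epi: int,
                               effects: Dict[str, float],
                               ai_sd: float = 0.02,
                               seed: int = 0) -> List[ScanRecord]:
    """Patient-only cohort with planted signal on chosen feature AIs.

    Every scan carries all 14 shape-feature measures; each feature's AI is
    Normal(0, ai_sd) for the all-other-epilepsies class and shifted by
    ``effects[feature] * ai_sd`` for the HS class (features absent from
    ``effects`` are pure noise). One scan per subject. Used to probe the
    feature-ranking classifier under a known ground truth.
    """
    rng = np.random.default_rng(seed)
    levels = dict(_NEUTRAL_FEATURE_LEVELS)
    levels.update({"volume": 3500.0, "voxel_volume": 3500.0,
                   "mesh_volume": 3430.0, "surface_area": 2230.0,
                   "surface_to_volume_ratio": 0.65})
    records: List[ScanRecord] = []
    for i in range(n_hs + n_epi):
        group = "HS-left" if i < n_hs else "EPI-other"
        measures = {}
        for name, level in levels.items():
            shift = effects.get(name, 0.0) * ai_sd if group != "EPI-other" else 0.0
            f_ai = float(rng.normal(shift, ai_sd))
            measures[name] = (level * (1.0 + f_ai), level * (1.0 - f_ai))
        records.append(ScanRecord(
            subject_id=f"pat-{i:04d}", scan_id=f"pat-{i:04d}_ses-01",
            scan_date=_dt.date(2018, 1, 1) + _dt.timedelta(days=i),
            group=group, age=35.0, etiv=1.45e6, measures=measures))
    return records


@dataclass
class PhantomConfig:
    """Voxel-level hippocampus phantom settings.

    The phantom is a bent ellipsoid (long axis anterior-posterior, tail
    curving inferiorly) whose radius is modulated by a smooth seeded noise
    field on the direction sphere ("fraying") and scaled so that
    ``atrophy`` is a *volume* factor. Optional spherical cavities notch the
    lateral body, mimicking fluid-filled cavities seen in sclerotic
    hippocampi. ``jitter`` translates the shape by a random sub-voxel
    offset, emulating re-scan repositioning.
    """

    semi_axes: Tuple[float, float, float] = (7.0, 18.0, 6.5)  # mm (x, y, z)
    bend: float = 0.5             # dimensionless centerline curvature
    atrophy: float = 1.0          # volume scale factor in (0, 1]
    fray_amplitude: float = 0.0   # relative radial modulation amplitude
    fray_frequency: float = 4.0   # angular frequency of the noise field
    n_cavities: int = 0
    cavity_radius: float = 2.5    # mm
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    jitter: float = 0.0           # mm, uniform translation amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.atrophy <= 1:
            raise ValueError("atrophy factor must be in (0, 1]")
        if self.fray_amplitude < 0:
            raise ValueError("fray amplitude must be non-negative")


def _fray_field(u: np.ndarray, cfg: PhantomConfig,
                rng: np.random.Generator) -> np.ndarray:
    """Band-limited noise on the unit sphere, approx zero mean / unit SD.

    Sum of 10 cosine plane waves cos(freq * pi * (d_j . u) + phi_j) with
    seeded random unit directions d_j and phases phi_j, scaled by
    sqrt(2 / n_waves).
    """
    n_waves = 10
    dirs = rng.normal(size=(n_waves, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    phases = rng.uniform(0, 2 * np.pi, size=n_waves)
    f = np.zeros(u.shape[:-1])
    for d, ph in zip(dirs, phases):
        f += np.cos(cfg.fray_frequency * np.pi * (u @ d) + ph)
    return f * np.sqrt(2.0 / n_waves)


def generate_hippocampus_mask(config: PhantomConfig,
                              grid_shape: Optional[Tuple[int, int, int]] = None,
                              mirror: bool = False) -> BinaryMask:
    """Voxelize a hippocampus-like implicit surface into a binary mask.

    ``mirror`` flips the x axis (anatomical mirroring for the right
    hemisphere). The grid is auto-sized to contain the shape unless given.
    Raises if the resulting mask is empty.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    a = np.asarray(cfg.semi_axes, dtype=float)
    sp = np.asarray(cfg.spacing, dtype=float)
    if grid_shape is None:
        margin = 1.45 + cfg.fray_amplitude
        half = a * margin + abs(cfg.bend) * a[2]
        grid_shape = tuple(int(np.ceil(2 * h / s)) + 3
                           for h, s in zip(half, sp))

    jitter = rng.uniform(-cfg.jitter, cfg.jitter, size=3) if cfg.jitter > 0 else np.zeros(3)
    axes = [(np.arange(n) - (n - 1) / 2.0) * s - j
            for n, s, j in zip(grid_shape, sp, jitter)]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    if mirror:
        x = -x

    z_eff = z - cfg.bend * a[2] * (y / a[1]) ** 2
    q = np.stack([x / a[0], y / a[1], z_eff / a[2]], axis=-1)
    r = np.linalg.norm(q, axis=-1)
    u = q / np.maximum(r, 1e-12)[..., None]

    radius = cfg.atrophy ** (1.0 / 3.0)
    if cfg.fray_amplitude > 0:
        radius = radius * np.clip(1.0 + cfg.fray_amplitude * _fray_field(u, cfg, rng),
                                  0.05, None)
    mask = r <= radius

    scale = cfg.atrophy ** (1.0 / 3.0)
    for _ in range(cfg.n_cavities):
        y_c = float(rng.uniform(-0.5, 0.5)) * a[1]
        z_c = cfg.bend * a[2] * (y_c / a[1]) ** 2
        x_c = a[0] * scale  # lateral surface of the body
        if mirror:
            x_c = -x_c
        d2 = (x - x_c) ** 2 + (y - y_c) ** 2 + (z - z_c) ** 2
        mask &= d2 > cfg.cavity_radius ** 2

    if not mask.any():
        raise ValueError("phantom left the grid: empty mask")
    return BinaryMask(mask=mask, spacing=tuple(sp))


def generate_labelled_subject(left: PhantomConfig, right: PhantomConfig,
                              dialect: str = "freesurfer-aseg",
                              gap_voxels: int = 8):
    """Build a two-hippocampus label volume plus its ground-truth record.

    The left phantom occupies the low-x half of the grid (canonical RAS:
    low x = anatomical left), the right phantom is mirrored into the
    high-x half. Returns ``(LabelVolume, truth)`` where ``truth`` records
    the planted per-side atrophy/fraying and the label IDs used.
    """
    if left.spacing != right.spacing:
        raise ValueError("left and right phantoms must share voxel spacing")
    d = get_dialect(dialect)
    lm = generate_hippocampus_mask(left, mirror=False)
    rm = generate_hippocampus_mask(right, mirror=True)
    shape_l, shape_r = lm.mask.shape, rm.mask.shape
    ny = max(shape_l[1], shape_r[1])
    nz = max(shape_l[2], shape_r[2])
    nx = shape_l[0] + gap_voxels + shape_r[0]
    labels = np.zeros((nx, ny, nz), dtype=np.int32)

    def _paste(sub: np.ndarray, x0: int, value: int) -> None:
        y0 = (ny - sub.shape[1]) // 2
        z0 = (nz - sub.shape[2]) // 2
        region = labels[x0:x0 + sub.shape[0], y0:y0 + sub.shape[1],
                        z0:z0 + sub.shape[2]]
        if np.any(region[sub] != 0):
            raise ValueError("structures overlap")
        region[sub] = value

    _paste(lm.mask, 0, d.left_hippocampus)
    _paste(rm.mask, shape_l[0] + gap_voxels, d.right_hippocampus)

    sp = lm.spacing
    affine = np.diag([sp[0], sp[1], sp[2], 1.0])
    vol = LabelVolume(labels=labels, spacing=sp, affine=affine)
    truth = {
        "dialect": dialect,
        "left": {"atrophy": left.atrophy, "fray_amplitude": left.fray_amplitude,
                 "n_cavities": left.n_cavities, "seed": left.seed},
        "right": {"atrophy": right.atrophy, "fray_amplitude": right.fray_amplitude,
                  "n_cavities": right.n_cavities, "seed": right.seed},
    }
    return vol, truth
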