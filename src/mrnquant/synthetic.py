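"""Synthetic dual-echo MR-neurography cohort generator.

Real nerve-imaging cohorts of this kind are not publicly deposited, so the
pipeline is driven by a generator that emulates the acquisition and the
statistical structure the analysis assumes:

* the forward signal model of spin-echo decay,
  ``S(TE) = rho * exp(-TE / T2_app)``, evaluated at the two echo times;
* a tibial nerve rendered as a filled disc on a homogeneous muscle-like
  background, with per-group distributions of T2, ρ and cross-sectional
  area at the thigh (slabs 1–2) and the lower leg (slabs 3–4), plus an
  independently drawn contralateral mid-to-distal thigh slab (slab 5);
* Rician noise, the standard model for magnitude MR images;
* clinical covariates (demographics, EDSS, symptom duration, nerve
  conduction values) matching a relapsing-remitting MS case group and a
  healthy control group.

Default group parameters encode the cohort this package emulates: cases show
lower nerve T2_app and higher ρ than controls at both the thigh and the
lower leg, a proximal-to-distal T2_app gradient in both groups, no ρ
gradient, and a thigh-only CSA increase.  Between-participant SDs are
back-computed from the group standard errors (SEM × √n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import GeometryError, InvalidParameterError
from .protocol import RIGHT_THIGH_SLAB, AcquisitionProtocol
from .relaxometry import DualEchoVolume, NerveMask

__all__ = [
    "GroupParams", "ClinicalTemplate", "CohortConfig", "ClinicalRecord",
    "ParticipantData", "predict_signal", "add_rician_noise", "disc_mask",
    "disc_radius_for_area", "generate_participant", "iter_cohort",
    "make_cohort", "clinical_table", "CASE_PARAMS", "CONTROL_PARAMS",
]

# Fixed sub-pixel anchor of the nerve center, in pixel units relative to the
# FOV center.  A generic (symmetry-breaking) offset guarantees that pixel
# center distances to the nerve center are all distinct, so the disc
# rasterizer can realize any integer pixel count and hence match any target
# CSA to within half a pixel's area.
_CENTER_ANCHOR_PX = (0.28713, 0.17094)


def predict_signal(rho, t2, te):
    """Forward spin-echo signal ``S(TE) = rho * exp(-TE / T2_app)``.

    Strictly decreasing in ``te``; equals ``rho`` at ``te = 0``.  Accepts
    scalars or arrays (broadcast).
    """
    rho = np.asarray(rho, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    te = np.asarray(te, dtype=float)
    if np.any(rho <= 0) or np.any(t2 <= 0):
        raise InvalidParameterError("rho and t2 must be positive")
    if np.any(te < 0):
        raise InvalidParameterError("te must be non-negative")
    out = rho * np.exp(-te / t2)
    return float(out) if out.ndim == 0 else out


def add_rician_noise(image: np.ndarray, sigma: float,
                     seed=None, rng: np.random.Generator | None = None
                     ) -> np.ndarray:
    """Corrupt a magnitude image with Rician noise of scale ``sigma``.

    Each pixel ``v`` is replaced by ``sqrt((v + g1)^2 + g2^2)`` with
    independent zero-mean Gaussians ``g1, g2`` of scale ``sigma`` — the
    magnitude of a complex signal with i.i.d. Gaussian channel noise.  At
    zero underlying signal this is a Rayleigh draw (mean ``sigma*sqrt(pi/2)``);
    at high SNR it approaches additive Gaussian noise.  ``sigma = 0`` returns
    the input unchanged.
    """
    if sigma < 0:
        raise InvalidParameterError("sigma must be non-negative")
    if sigma == 0:
        return image
    if rng is None:
        rng = np.random.default_rng(seed)
    g = rng.normal(0.0, sigma, size=(2,) + np.shape(image))
    return np.hypot(np.asarray(image, dtype=float) + g[0], g[1])


# ---------------------------------------------------------------------------
# disc geometry

def _pixel_centers(matrix: int, spacing: float) -> np.ndarray:
    # pixel i spans [i, i+1)*spacing; its center sits at (i + 0.5)*spacing
    return (np.arange(matrix) + 0.5) * spacing


def disc_mask(matrix: int, spacing: float, center: tuple[float, float],
              radius: float) -> np.ndarray:
    """Rasterize a filled disc: pixels whose center lies within ``radius``.

    ``center`` and ``radius`` are in mm within the FOV coordinate frame.
    Raises :class:`GeometryError` if the disc extends beyond the FOV or
    covers no pixel.
    """
    fov = matrix * spacing
    cx, cy = center
    if radius <= 0:
        raise GeometryError("disc radius must be positive")
    if cx - radius < 0 or cy - radius < 0 or cx + radius > fov or cy + radius > fov:
        raise GeometryError(
            f"nerve disc (center {center}, radius {radius:.2f} mm) exceeds FOV"
        )
    ax = _pixel_centers(matrix, spacing)
    # bounding box keeps the scan O(radius^2) instead of O(matrix^2)
    i0 = max(0, int((cx - radius) / spacing) - 1)
    i1 = min(matrix, int((cx + radius) / spacing) + 2)
    j0 = max(0, int((cy - radius) / spacing) - 1)
    j1 = min(matrix, int((cy + radius) / spacing) + 2)
    dx = ax[i0:i1, None] - cx
    dy = ax[None, j0:j1] - cy
    sub = dx * dx + dy * dy <= radius * radius
    out = np.zeros((matrix, matrix), dtype=bool)
    out[i0:i1, j0:j1] = sub
    if not out.any():
        raise GeometryError("disc covers no pixel at this resolution")
    return out


def disc_radius_for_area(area: float, spacing: float,
                         center: tuple[float, float], matrix: int
                         ) -> tuple[float, int]:
    """Radius whose rasterized disc area best matches ``area`` (mm²).

    The rasterized area is a step function of the radius with one-pixel
    steps when the center is generic; the returned radius realizes the pixel
    count closest to ``area / spacing²`` (at least 1).  Returns
    ``(radius_mm, pixel_count)``.
    """
    if area <= 0:
        raise InvalidParameterError("area must be positive")
    target = max(1, round(area / spacing ** 2))
    r0 = math.sqrt(area / math.pi)
    cx, cy = center
    ax = _pixel_centers(matrix, spacing)
    pad = r0 + 4 * spacing
    i0 = max(0, int((cx - pad) / spacing) - 1)
    i1 = min(matrix, int((cx + pad) / spacing) + 2)
    j0 = max(0, int((cy - pad) / spacing) - 1)
    j1 = min(matrix, int((cy + pad) / spacing) + 2)
    dx = ax[i0:i1, None] - cx
    dy = ax[None, j0:j1] - cy
    d = np.sort(np.sqrt(dx * dx + dy * dy).ravel())
    if len(d) <= target:
        raise GeometryError("target area exceeds the searchable neighborhood")
    k = target
    # back off to the nearest strict gap if distances tie at the cut
    while k > 1 and not d[k - 1] < d[k]:
        k -= 1
    radius = 0.5 * (d[k - 1] + d[k])
    return float(radius), int(k)


# ---------------------------------------------------------------------------
# cohort configuration

def _sd_from_sem(sem: float, n: int) -> float:
    return sem * math.sqrt(n)


@dataclass(frozen=True)
class GroupParams:
    """Per-group generative ground truth, split by anatomical region.

    Means are region-level population means; SDs are between-participant.
    T2 in ms, ρ in arbitrary units, CSA in mm².
    """

    t2_thigh: float
    t2_thigh_sd: float
    t2_lower: float
    t2_lower_sd: float
    rho_thigh: float
    rho_thigh_sd: float
    rho_lower: float
    rho_lower_sd: float
    csa_thigh: float
    csa_thigh_sd: float
    csa_lower: float
    csa_lower_sd: float

    def __post_init__(self):
        for name in ("t2_thigh", "t2_lower", "rho_thigh", "rho_lower",
                     "csa_thigh", "csa_lower"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
            if getattr(self, name + "_sd") < 0:
                raise InvalidParameterError(f"{name}_sd must be >= 0")

    @property
    def t2_gradient(self) -> float:
        """Configured proximal-minus-distal T2 difference (ms)."""
        return self.t2_thigh - self.t2_lower

    def zero_sd(self) -> "GroupParams":
        return replace(self, **{f: 0.0 for f in self.__dataclass_fields__
                                if f.endswith("_sd")})


#: Case group (relapsing-remitting MS, n = 35): lower T2_app, higher ρ,
#: thigh-only CSA increase; SDs from SEM × √35.
CASE_PARAMS = GroupParams(
    t2_thigh=66.1, t2_thigh_sd=_sd_from_sem(0.6, 35),
    t2_lower=62.1, t2_lower_sd=_sd_from_sem(0.7, 35),
    rho_thigh=473.2, rho_thigh_sd=_sd_from_sem(12.1, 35),
    rho_lower=461.2, rho_lower_sd=_sd_from_sem(11.4, 35),
    csa_thigh=17.3, csa_thigh_sd=_sd_from_sem(0.4, 35),
    csa_lower=9.1, csa_lower_sd=_sd_from_sem(0.4, 35),
)

#: Healthy control group (n = 30); SDs from SEM × √30.
CONTROL_PARAMS = GroupParams(
    t2_thigh=69.9, t2_thigh_sd=_sd_from_sem(0.6, 30),
    t2_lower=67.5, t2_lower_sd=_sd_from_sem(1.0, 30),
    rho_thigh=410.1, rho_thigh_sd=_sd_from_sem(6.1, 30),
    rho_lower=418.0, rho_lower_sd=_sd_from_sem(7.5, 30),
    csa_thigh=15.1, csa_thigh_sd=_sd_from_sem(0.3, 30),
    csa_lower=8.5, csa_lower_sd=_sd_from_sem(0.3, 30),
)

#: Nerve-conduction covariates: field -> (mean, SEM at n = 35)
_NCS_FIELDS = {
    "tibial_cmap": (21.3, 1.3),
    "tibial_ncv": (50.5, 0.9),
    "tibial_fwave": (49.4, 1.2),
    "tibial_dml": (3.5, 0.1),
    "peroneal_cmap": (7.6, 0.6),
    "peroneal_ncv": (49.2, 1.0),
    "peroneal_fwave": (47.8, 1.1),
    "peroneal_dml": (4.0, 0.1),
    "sural_snap": (15.2, 1.6),
    "sural_ncv": (52.3, 1.7),
}


@dataclass(frozen=True)
class ClinicalTemplate:
    """Distributions for demographic/clinical covariates of one group."""

    p_male: float
    age_mean: float
    age_sd: float
    weight_mean: float
    weight_sd: float
    height_mean: float
    height_sd: float
    has_clinical: bool = False  # EDSS, duration, NCS exist (cases only)
    edss_mean: float = 1.6
    edss_sd: float = _sd_from_sem(0.3, 35)
    # symptom duration (months): log-normal calibrated so the mean is ~98
    # months and ~29% of cases fall under 3 years
    duration_log_mean: float = math.log(60.0)
    duration_log_sd: float = 1.0
    ncs: dict = field(default_factory=lambda: dict(_NCS_FIELDS))

    def __post_init__(self):
        # normalize (mean, sem) pairs so configs round-trip through JSON
        object.__setattr__(self, "ncs", {
            k: (float(v[0]), float(v[1])) for k, v in self.ncs.items()
        })


CASE_CLINICAL = ClinicalTemplate(
    p_male=12 / 35, age_mean=37.7, age_sd=_sd_from_sem(2.2, 35),
    weight_mean=75.7, weight_sd=_sd_from_sem(2.8, 35),
    height_mean=173.8, height_sd=_sd_from_sem(1.7, 35),
    has_clinical=True,
)

CONTROL_CLINICAL = ClinicalTemplate(
    p_male=14 / 30, age_mean=36.8, age_sd=_sd_from_sem(2.3, 30),
    weight_mean=75.1, weight_sd=_sd_from_sem(2.4, 30),
    height_mean=174.3, height_sd=_sd_from_sem(1.6, 30),
    has_clinical=False,
)


@dataclass(frozen=True)
class CohortConfig:
    """Everything the generator needs besides the acquisition protocol."""

    n_case: int = 35
    n_control: int = 30
    case: GroupParams = CASE_PARAMS
    control: GroupParams = CONTROL_PARAMS
    case_clinical: ClinicalTemplate = CASE_CLINICAL
    control_clinical: ClinicalTemplate = CONTROL_CLINICAL
    #: Rician scale in signal units; default puts per-pixel SNR at the short
    #: echo in nerve tissue near 50
    noise_sigma: float = 8.0
    #: uniform in-plane jitter (± mm) of the per-participant nerve center
    center_jitter_mm: float = 4.0
    background_t2: float = 35.0  # muscle-like, ms
    background_rho: float = 380.0  # a.u.

    def __post_init__(self):
        if self.n_case < 1 or self.n_control < 1:
            raise InvalidParameterError("need at least one participant per group")
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be >= 0")
        if self.center_jitter_mm < 0:
            raise InvalidParameterError("center_jitter_mm must be >= 0")

    def noise_free(self) -> "CohortConfig":
        """Deterministic variant: zero noise, zero SDs, fixed nerve center."""
        return replace(self, noise_sigma=0.0, center_jitter_mm=0.0,
                       case=self.case.zero_sd(), control=self.control.zero_sd())

    def params_for(self, group: str) -> GroupParams:
        return {"case": self.case, "control": self.control}[group]

    def clinical_for(self, group: str) -> ClinicalTemplate:
        return {"case": self.case_clinical,
                "control": self.control_clinical}[group]


@dataclass
class ClinicalRecord:
    """One participant's demographic/clinical/electrophysiologic covariates.

    Controls carry no EDSS, symptom duration or nerve-conduction values
    (NaN): those are acquired in cases only.
    """

    participant_id: str
    group: str
    age: float
    sex: str  # "M" / "F"
    weight: float
    height: float
    edss: float = math.nan
    duration: float = math.nan  # months since diagnosis
    tibial_cmap: float = math.nan
    tibial_ncv: float = math.nan
    tibial_fwave: float = math.nan
    tibial_dml: float = math.nan
    peroneal_cmap: float = math.nan
    peroneal_ncv: float = math.nan
    peroneal_fwave: float = math.nan
    peroneal_dml: float = math.nan
    sural_snap: float = math.nan
    sural_ncv: float = math.nan

    @property
    def bmi(self) -> float:
        return self.weight / (self.height / 100.0) ** 2


@dataclass
class ParticipantData:
    """Everything generated for one participant."""

    participant_id: str
    group: str
    volumes: list  # DualEchoVolume per slab (1..4 left, 5 right)
    masks: list  # NerveMask per slab
    ground_truth: pd.DataFrame
    clinical: ClinicalRecord


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float = math.inf) -> float:
    if sd == 0:
        return float(min(max(mean, low), high))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if low < v < high:
            return float(v)
    raise InvalidParameterError(
        f"truncated normal ({mean}, {sd}) never landed in ({low}, {high})"
    )


def _draw_clinical(rng: np.random.Generator, template: ClinicalTemplate,
                   participant_id: str, group: str) -> ClinicalRecord:
    rec = ClinicalRecord(
        participant_id=participant_id,
        group=group,
        age=_truncated_normal(rng, template.age_mean, template.age_sd, 18, 90),
        sex="M" if rng.random() < template.p_male else "F",
        weight=_truncated_normal(rng, template.weight_mean, template.weight_sd,
                                 40, 160),
        height=_truncated_normal(rng, template.height_mean, template.height_sd,
                                 140, 210),
    )
    if template.has_clinical:
        edss = _truncated_normal(rng, template.edss_mean, template.edss_sd,
                                 0.0, 10.0)
        rec.edss = round(edss * 2) / 2  # EDSS is scored in half points
        dur = math.exp(rng.normal(template.duration_log_mean,
                                  template.duration_log_sd))
        rec.duration = float(min(max(dur, 5.0), 330.0))
        n_ref = 35  # the SEMs in the template refer to this cohort size
        for name, (mean, sem) in template.ncs.items():
            setattr(rec, name,
                    _truncated_normal(rng, mean, _sd_from_sem(sem, n_ref), 0.1))
    return rec


def _region_of_slab(slab_id: int, n_slabs_left: int) -> str:
    if slab_id == RIGHT_THIGH_SLAB:
        return "thigh"
    return "thigh" if slab_id <= (n_slabs_left + 1) // 2 else "lower"


def generate_participant(protocol: AcquisitionProtocol, config: CohortConfig,
                         group: str, seed, participant_id: str = "sub-01"
                         ) -> ParticipantData:
    """Generate one participant: volumes, masks, ground truth, covariates.

    Renders a filled nerve disc (per-region T2/ρ/CSA drawn once per
    participant) on a homogeneous muscle-like background, evaluates the
    forward model at both echo times, then adds Rician noise.  Slabs 1–4
    cover the left leg proximal→distal; slab 5 is an independent draw from
    the thigh distribution rendered at the right mid-to-distal thigh
    position (it reuses slab 2's global slice indices).  Deterministic for a
    given ``(protocol, config, group, seed)``.
    """
    rng = np.random.default_rng(seed)
    params = config.params_for(group)
    sp = protocol.pixel_spacing

    def draw_region(region: str) -> dict:
        t2 = _truncated_normal(rng, getattr(params, f"t2_{region}"),
                               getattr(params, f"t2_{region}_sd"), 1.0)
        rho = _truncated_normal(rng, getattr(params, f"rho_{region}"),
                                getattr(params, f"rho_{region}_sd"), 1.0)
        csa = _truncated_normal(rng, getattr(params, f"csa_{region}"),
                                getattr(params, f"csa_{region}_sd"),
                                protocol.pixel_area)
        return {"t2": t2, "rho": rho, "csa": csa}

    truth = {"thigh": draw_region("thigh"), "lower": draw_region("lower"),
             "right_thigh": draw_region("thigh")}

    anchor = (protocol.fov / 2 + _CENTER_ANCHOR_PX[0] * sp,
              protocol.fov / 2 + _CENTER_ANCHOR_PX[1] * sp)
    jit = config.center_jitter_mm
    center = (anchor[0] + rng.uniform(-jit, jit) if jit else anchor[0],
              anchor[1] + rng.uniform(-jit, jit) if jit else anchor[1])

    bg1 = predict_signal(config.background_rho, config.background_t2,
                         protocol.te1)
    bg2 = predict_signal(config.background_rho, config.background_t2,
                         protocol.te2)

    slab_ids = list(range(1, protocol.n_slabs_left + 1)) + [RIGHT_THIGH_SLAB]
    volumes, masks, rows = [], [], []
    for slab_id in slab_ids:
        key = ("right_thigh" if slab_id == RIGHT_THIGH_SLAB
               else _region_of_slab(slab_id, protocol.n_slabs_left))
        tr = truth[key]
        radius, _ = disc_radius_for_area(tr["csa"], sp, center, protocol.matrix)
        m2d = disc_mask(protocol.matrix, sp, center, radius)
        sig1 = predict_signal(tr["rho"], tr["t2"], protocol.te1)
        sig2 = predict_signal(tr["rho"], tr["t2"], protocol.te2)
        n_sl = protocol.slices_per_slab
        e1 = np.full((protocol.matrix, protocol.matrix, n_sl), bg1)
        e2 = np.full((protocol.matrix, protocol.matrix, n_sl), bg2)
        e1[m2d, :] = sig1
        e2[m2d, :] = sig2
        if config.noise_sigma > 0:
            e1 = add_rician_noise(e1, config.noise_sigma, rng=rng)
            e2 = add_rician_noise(e2, config.noise_sigma, rng=rng)
        offset = protocol.slab_slice_range(slab_id).start
        volumes.append(DualEchoVolume(
            image_te1=e1, image_te2=e2, te1=protocol.te1, te2=protocol.te2,
            pixel_spacing=sp, slab_id=slab_id, slice_offset=offset,
            participant_id=participant_id,
        ))
        masks.append(NerveMask(
            mask=np.repeat(m2d[:, :, None], n_sl, axis=2),
            slab_id=slab_id, provenance="synthetic",
        ))
        for local in range(n_sl):
            rows.append((participant_id, offset + local, slab_id,
                         tr["t2"], tr["rho"], tr["csa"], center[0], center[1],
                         config.background_t2, config.background_rho))

    ground_truth = pd.DataFrame(rows, columns=[
        "participant_id", "slice_index", "slab_id", "true_t2_ms",
        "true_rho_au", "true_csa_mm2", "nerve_center_x_mm",
        "nerve_center_y_mm", "background_t2_ms", "background_rho_au",
    ])
    clinical = _draw_clinical(rng, config.clinical_for(group),
                              participant_id, group)
    return ParticipantData(participant_id=participant_id, group=group,
                           volumes=volumes, masks=masks,
                           ground_truth=ground_truth, clinical=clinical)


def iter_cohort(protocol: AcquisitionProtocol, config: CohortConfig,
                seed: int) -> Iterator[ParticipantData]:
    """Yield participants one at a time (memory-friendly for large cohorts).

    Cases first (``case-001`` ...), then controls; every participant gets an
    independent child seed derived from ``seed``.
    """
    n_total = config.n_case + config.n_control
    children = np.random.SeedSequence(seed).spawn(n_total)
    for i in range(n_total):
        group = "case" if i < config.n_case else "control"
        idx = i + 1 if group == "case" else i - config.n_case + 1
        pid = f"{group}-{idx:03d}"
        yield generate_participant(protocol, config, group, children[i],
                                   participant_id=pid)


def make_cohort(protocol: AcquisitionProtocol, config: CohortConfig,
                seed: int) -> tuple[list[ParticipantData], pd.DataFrame]:
    """Materialize the full cohort plus its clinical covariate table."""
    participants = list(iter_cohort(protocol, config, seed))
    return participants, clinical_table(p.clinical for p in participants)


_CLINICAL_COLUMNS = [
    "participant_id", "group", "age", "sex", "weight", "height",
    "edss", "duration", *list(_NCS_FIELDS),
]


def clinical_table(records) -> pd.DataFrame:
    """Tabulate :class:`ClinicalRecord` objects, one row per participant."""
    return pd.DataFrame(
        [{c: getattr(r, c) for c in _CLINICAL_COLUMNS} for r in records],
        columns=_CLINICAL_COLUMNS,
    )
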