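"""Synthetic two-group DWI cohorts with known tensor fields.

The generator emulates an ex vivo two-group study (control vs IUGR,
n = 10/10 by default): an ellipsoidal "brain" of mildly anisotropic gray
matter with embedded anisotropic white-matter tracts, a focal effect region
where the growth-restricted group loses fractional anisotropy, and
neurobehavioral scores statistically coupled to regional FA through a
Gaussian copula.  Defaults are calibrated so that whole-brain mean FA is
close to 0.16 in controls and 0.15 in the restricted group (between-subject
SD about 0.02) and whole-brain ADC about 0.44e-3 mm^2/s — the magnitudes
reported for fixed perinatal rabbit brain.

Between-subject variation in FA has two components: one global
multiplicative factor per subject shared by every region (diffuse
maturation differences, which dominate the whole-brain FA spread) and a
small additive per-region FA jitter.  The regional component is kept small
in white matter, matching the near-zero spread of FA-threshold-masked WM
means seen in such cohorts.  ADC varies through an independent global
trace factor.

FA reduction preserves the tensor trace (lambda_2 and lambda_3 are raised
while lambda_1 is lowered), so the programmed group difference appears in
FA and the Westin shape coefficients but not in ADC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .gradients import GradientScheme, default_scheme
from .io import DWIVolume, SCORE_REGISTRY, SubjectRecord
from .tensor import TensorField, eigenvalues_to_fa

__all__ = [
    "Region",
    "BehaviorCoupling",
    "PhantomSpec",
    "GroundTruth",
    "SyntheticSubject",
    "CohortDataset",
    "default_spec",
    "focal_effect_spec",
    "null_spec",
    "generate_tensor_field",
    "generate_ground_truth",
    "simulate_dwi",
    "generate_cohort",
    "deviatoric_scale_for_fa",
    "max_feasible_fa",
]

BACKGROUND_DIFFUSIVITY = 1e-6  # mm^2/s; "air" voxels, effectively signal-void

# Birth weights (grams) reported for the rabbit model: control 47.0 +/- 9.3,
# growth-restricted 30.4 +/- 12.2.
BIRTH_WEIGHT = {"control": (47.0, 9.3), "IUGR": (30.4, 12.2)}


@dataclass
class Region:
    """A set of voxels sharing one baseline tensor."""

    region_id: str
    mask: np.ndarray  # bool, grid-shaped
    tissue_class: str  # "GM" | "WM" | "background"
    principal_direction: np.ndarray | None  # unit vector, or None for isotropic
    baseline_eigenvalues: tuple[float, float, float]  # descending, mm^2/s
    fa_jitter_sd: float = 0.0  # between-subject additive FA jitter, absolute

    def __post_init__(self) -> None:
        lam = np.asarray(self.baseline_eigenvalues, dtype=float)
        if lam.shape != (3,) or np.any(lam <= 0):
            raise ValueError(f"region {self.region_id}: eigenvalues must be 3 positive values")
        if np.any(np.diff(lam) > 0):
            raise ValueError(f"region {self.region_id}: eigenvalues must be sorted descending")
        if self.tissue_class not in ("GM", "WM", "background"):
            raise ValueError(f"region {self.region_id}: bad tissue class {self.tissue_class!r}")
        if self.fa_jitter_sd < 0:
            raise ValueError(f"region {self.region_id}: fa_jitter_sd must be >= 0")
        if self.principal_direction is not None:
            v = np.asarray(self.principal_direction, dtype=float)
            self.principal_direction = v / np.linalg.norm(v)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def baseline_fa(self) -> float:
        return float(eigenvalues_to_fa(np.asarray(self.baseline_eigenvalues)))


@dataclass
class BehaviorCoupling:
    score_name: str
    region_id: str
    target_correlation: float
    # location/scale of the latent score before discretization to the item's
    # registry scale; None picks a default from the registry.
    score_loc: float | None = None
    score_scale: float | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.target_correlation <= 1.0:
            raise ValueError("target_correlation must lie in [-1, 1]")
        if self.score_name not in SCORE_REGISTRY:
            raise ValueError(f"unknown score {self.score_name!r}")


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]  # mm
    regions: list[Region]
    group_effect: dict[str, float] = field(default_factory=dict)  # region -> dFA
    between_subject_sd: float = 0.04  # relative SD of the global FA factor
    between_subject_adc_sd: float = 0.18  # relative SD of the trace jitter
    noise_sigma: float = 0.01  # Rician scale, fraction of s0
    s0: float = 1.0
    background_s0_fraction: float = 0.0
    behavior_couplings: list[BehaviorCoupling] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region ids")
        total = np.zeros(self.grid_shape, dtype=int)
        for r in self.regions:
            if r.mask.shape != tuple(self.grid_shape):
                raise ValueError(f"region {r.region_id}: mask shape mismatch")
            total += r.mask
        if np.any(total > 1):
            raise ValueError("region voxel sets overlap")
        for rid, dfa in self.group_effect.items():
            region = self.region(rid)
            target = region.baseline_fa - dfa
            if dfa < 0 or target < 0:
                raise ValueError(
                    f"dFA={dfa} infeasible for region {rid} (baseline FA "
                    f"{region.baseline_fa:.3f})"
                )
            # raises if the reduced tensor would lose positivity
            deviatoric_scale_for_fa(np.asarray(region.baseline_eigenvalues), target)
        for c in self.behavior_couplings:
            self.region(c.region_id)

    def region(self, region_id: str) -> Region:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(f"no region {region_id!r}")

    @property
    def brain_mask(self) -> np.ndarray:
        out = np.zeros(self.grid_shape, dtype=bool)
        for r in self.regions:
            if r.tissue_class != "background":
                out |= r.mask
        return out

    @property
    def wm_mask(self) -> np.ndarray:
        out = np.zeros(self.grid_shape, dtype=bool)
        for r in self.regions:
            if r.tissue_class == "WM":
                out |= r.mask
        return out

    @property
    def effect_region_mask(self) -> np.ndarray:
        out = np.zeros(self.grid_shape, dtype=bool)
        for rid in self.group_effect:
            out |= self.region(rid).mask
        return out

    def expected_region_fa(self, region_id: str, group: str) -> float:
        """Ground-truth region FA for a zero-jitter subject of ``group``."""
        r = self.region(region_id)
        fa = r.baseline_fa
        if group == "IUGR" and region_id in self.group_effect:
            fa -= self.group_effect[region_id]
        return fa

    def expected_whole_brain_fa(self, group: str) -> float:
        """Voxel-weighted mean ground-truth FA over brain voxels."""
        num = n = 0.0
        for r in self.regions:
            if r.tissue_class == "background":
                continue
            k = int(r.mask.sum())
            num += k * self.expected_region_fa(r.region_id, group)
            n += k
        return num / n


# ---------------------------------------------------------------------------
# eigenvalue manipulation


def deviatoric_scale_for_fa(eigenvalues: np.ndarray, target_fa: float) -> np.ndarray:
    """Rescale the deviatoric part of ``eigenvalues`` to hit ``target_fa``.

    The trace is preserved exactly; lowering FA lowers lambda_1 and raises
    lambda_2, lambda_3 toward the mean.  Raises if the baseline is isotropic
    (target > 0 unreachable) or if the scaling would drive an eigenvalue
    negative.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    mean = lam.mean()
    dev = lam - mean
    dev_norm = float(np.linalg.norm(dev))
    if target_fa < 0 or target_fa >= math.sqrt(1.5):
        raise ValueError(f"target FA {target_fa} out of range")
    if target_fa == 0:
        return np.full(3, mean)
    if dev_norm == 0:
        raise ValueError("cannot raise FA of an isotropic baseline by deviatoric scaling")
    t = target_fa * mean * math.sqrt(3.0) / (dev_norm * math.sqrt(1.5 - target_fa**2))
    out = mean + t * dev
    if np.any(out < 0):
        raise ValueError(f"target FA {target_fa} infeasible: eigenvalue would go negative")
    return out


def max_feasible_fa(eigenvalues: np.ndarray) -> float:
    """Largest FA reachable from ``eigenvalues`` by deviatoric scaling.

    The bound is where the smallest eigenvalue hits zero under
    :func:`deviatoric_scale_for_fa`; isotropic input returns 0.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    mean = lam.mean()
    dev = lam - mean
    dev_norm = float(np.linalg.norm(dev))
    if dev_norm == 0:
        return 0.0
    t_max = mean / (mean - lam.min())
    return math.sqrt(1.5 / (1.0 + 3.0 * mean**2 / (dev_norm**2 * t_max**2)))


def _basis_from_direction(v: np.ndarray) -> np.ndarray:
    """Orthonormal 3x3 basis with first column ``v``."""
    v = v / np.linalg.norm(v)
    helper = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(v, helper)
    u /= np.linalg.norm(u)
    w = np.cross(v, u)
    return np.column_stack([v, u, w])


# ---------------------------------------------------------------------------
# generators


@dataclass
class GroundTruth:
    """What the generator knows before any noise is applied."""

    region_fa: dict[str, float]
    region_adc: dict[str, float]
    global_fa_factor: float
    region_fa_jitter: dict[str, float]
    trace_jitter: float
    brain_mask: np.ndarray
    wm_mask: np.ndarray
    effect_region_mask: np.ndarray
    tensor_field: TensorField | None = None

    def whole_brain_fa(self, spec: PhantomSpec) -> float:
        num = n = 0.0
        for r in spec.regions:
            if r.tissue_class == "background":
                continue
            k = int(r.mask.sum())
            num += k * self.region_fa[r.region_id]
            n += k
        return num / n


def _draw_subject_truth(
    spec: PhantomSpec, group: str, rng: np.random.Generator
) -> tuple[GroundTruth, dict[str, np.ndarray]]:
    """Draw one subject's region-level truth (no voxel arrays).

    Returns the :class:`GroundTruth` (tensor field unset) and the realized
    per-region eigenvalue triples.
    """
    trace_jitter = float(np.clip(rng.normal(1.0, spec.between_subject_adc_sd), 0.2, None))
    global_factor = float(np.clip(rng.normal(1.0, spec.between_subject_sd), 0.0, None))
    region_fa: dict[str, float] = {}
    region_adc: dict[str, float] = {}
    fa_jitter: dict[str, float] = {}
    region_lam: dict[str, np.ndarray] = {}

    for r in spec.regions:
        lam = np.asarray(r.baseline_eigenvalues, dtype=float)
        fa_eff = r.baseline_fa
        if group == "IUGR" and r.region_id in spec.group_effect:
            fa_eff -= spec.group_effect[r.region_id]
        e = float(rng.normal(0.0, r.fa_jitter_sd)) if r.fa_jitter_sd > 0 else 0.0
        target_fa = fa_eff * global_factor + e
        target_fa = float(np.clip(target_fa, 0.0, 0.999 * max_feasible_fa(lam)))
        jittered = deviatoric_scale_for_fa(lam, target_fa) * trace_jitter
        fa_jitter[r.region_id] = e
        region_lam[r.region_id] = jittered
        region_fa[r.region_id] = float(eigenvalues_to_fa(jittered))
        region_adc[r.region_id] = float(jittered.mean())

    truth = GroundTruth(
        region_fa=region_fa,
        region_adc=region_adc,
        global_fa_factor=global_factor,
        region_fa_jitter=fa_jitter,
        trace_jitter=trace_jitter,
        brain_mask=spec.brain_mask,
        wm_mask=spec.wm_mask,
        effect_region_mask=spec.effect_region_mask,
    )
    return truth, region_lam


def generate_ground_truth(spec: PhantomSpec, group: str, seed: int) -> GroundTruth:
    """Region-level ground truth only — no voxel field, no DWI.

    Fast enough for large Monte-Carlo studies of the generator itself; uses
    the same draw order as :func:`generate_tensor_field`, so the region FA
    values match a full generation under the same seed.
    """
    if group not in ("control", "IUGR"):
        raise ValueError(f"unknown group {group!r}")
    truth, _ = _draw_subject_truth(spec, group, np.random.default_rng(seed))
    return truth


def generate_tensor_field(
    spec: PhantomSpec, group: str, seed: int, keep_field: bool = True
) -> tuple[TensorField, GroundTruth]:
    """One subject's ground-truth tensor field.

    Per subject: one global FA factor (relative SD ``between_subject_sd``)
    scales the post-effect FA of every region, each region adds its own FA
    jitter (absolute SD ``Region.fa_jitter_sd``), and the whole brain draws
    one trace factor (relative SD ``between_subject_adc_sd``).  For the
    IUGR group, regions listed in ``group_effect`` first have their FA
    reduced by the programmed dFA.  Each region's FA target is realized
    exactly by trace-preserving deviatoric scaling, so the subject's true
    region FA is ``clip(fa_after_effect * global + jitter)``.  White-matter
    voxels share the region's programmed principal direction;
    isotropic-class regions get an independent random orientation per voxel.
    """
    if group not in ("control", "IUGR"):
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    shape = tuple(spec.grid_shape)

    eigenvalues = np.full(shape + (3,), BACKGROUND_DIFFUSIVITY)
    eigenvectors = np.zeros(shape + (3, 3))
    eigenvectors[..., :, :] = np.eye(3)

    truth, region_lam = _draw_subject_truth(spec, group, rng)

    for r in spec.regions:
        jittered = region_lam[r.region_id]
        idx = r.mask
        n_vox = int(idx.sum())
        if n_vox == 0:
            continue
        eigenvalues[idx] = jittered
        if r.principal_direction is not None:
            eigenvectors[idx] = _basis_from_direction(r.principal_direction)
        elif not np.allclose(jittered, jittered[0]):
            rots = Rotation.random(n_vox, rng=rng).as_matrix()
            eigenvectors[idx] = rots

    s0_map = np.where(truth.brain_mask, spec.s0, spec.s0 * spec.background_s0_fraction)
    tf = TensorField.from_eigensystem(
        eigenvalues, eigenvectors, s0_map, truth.brain_mask, np.asarray(spec.voxel_size)
    )
    if keep_field:
        truth.tensor_field = tf
    return tf, truth


def simulate_dwi(
    tensors: TensorField,
    scheme: GradientScheme,
    s0=None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    noise_model: str = "rician",
) -> DWIVolume:
    """Forward-simulate the DWI signal ``S_k = S0 exp(-b g^T D g)``.

    ``s0`` may be a scalar, a map, or None (use the field's own s0 map).
    Noise is Rician by default (magnitude of a complex Gaussian with scale
    ``noise_sigma`` in signal units); ``noise_model="gaussian"`` adds plain
    additive Gaussian noise instead.  Deterministic under a fixed seed.
    """
    if len(scheme) < 7:
        raise ValueError("scheme must have at least 7 measurements (6 DWI + 1 b=0)")
    if s0 is None:
        s0 = tensors.s0
    s0 = np.broadcast_to(np.asarray(s0, dtype=float), tensors.grid_shape)

    b = scheme.b_values
    g = scheme.directions
    # quadratic form g^T D g for every voxel and measurement
    quad = np.einsum("kj,...ji,ki->...k", g, tensors.tensors, g, optimize=True)
    signal = s0[..., None] * np.exp(-b * quad)

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        if noise_model == "rician":
            re = signal + rng.normal(0.0, noise_sigma, signal.shape)
            im = rng.normal(0.0, noise_sigma, signal.shape)
            signal = np.sqrt(re**2 + im**2)
        elif noise_model == "gaussian":
            signal = signal + rng.normal(0.0, noise_sigma, signal.shape)
        else:
            raise ValueError(f"unknown noise model {noise_model!r}")

    return DWIVolume(signal, tensors.voxel_size, scheme)


@dataclass
class SyntheticSubject:
    record: SubjectRecord
    dwi: DWIVolume
    truth: GroundTruth


@dataclass
class CohortDataset:
    subjects: list[SyntheticSubject]
    spec: PhantomSpec
    scheme: GradientScheme
    seed: int
    # per coupled score: (target correlation, achieved latent corr,
    # achieved discretized corr), measured against true region FA
    achieved_correlations: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    @property
    def records(self) -> list[SubjectRecord]:
        return [s.record for s in self.subjects]

    def group(self, label: str) -> list[SyntheticSubject]:
        return [s for s in self.subjects if s.record.group == label]


def _score_loc_scale(name: str) -> tuple[float, float]:
    kind, bounds = SCORE_REGISTRY[name]
    if kind in ("score", "count") and bounds is not None and np.isfinite(bounds[1]):
        lo, hi = bounds
        return (lo + hi) / 2.0, (hi - lo) / 4.0
    return 5.0, 2.5


def _discretize(latent: np.ndarray, name: str, loc: float, scale: float) -> np.ndarray:
    kind, bounds = SCORE_REGISTRY[name]
    value = loc + scale * latent
    if kind in ("score", "count"):
        value = np.round(value)
    if bounds is not None:
        value = np.clip(value, bounds[0], bounds[1] if np.isfinite(bounds[1]) else None)
    return value


def _region_fa_moments(spec: PhantomSpec, region_id: str) -> tuple[float, float]:
    """Population mean/SD of true region FA, pooled equally over both groups.

    True region FA is ``fa_after_effect * global + jitter`` with the global
    factor ~ N(1, between_subject_sd) and the jitter ~ N(0, fa_jitter_sd),
    so the pooled moments follow in closed form (clipping is negligible at
    the default calibration).
    """
    region = spec.region(region_id)
    fa_c = region.baseline_fa
    fa_i = fa_c - spec.group_effect.get(region_id, 0.0)
    mean = (fa_c + fa_i) / 2.0
    within = sum(
        f**2 * spec.between_subject_sd**2 + region.fa_jitter_sd**2 for f in (fa_c, fa_i)
    ) / 2.0
    between = (fa_c - fa_i) ** 2 / 4.0
    return mean, math.sqrt(within + between)


def generate_cohort(
    spec: PhantomSpec,
    n_per_group: int = 10,
    scheme: GradientScheme | None = None,
    seed: int = 0,
    noise_model: str = "rician",
    keep_truth_fields: bool = True,
) -> CohortDataset:
    """A full two-group cohort: DWIs, subject records, and ground truth.

    Behavioral scores for coupled items are drawn from a Gaussian copula:
    latent = r * z(FA) + sqrt(1 - r^2) * eps with z(FA) the subject's true
    coupled-region FA standardized by its population moments, then
    discretized to the item's scale.  Achieved correlations (latent and
    discretized) are recorded on the returned dataset.  All subjects share
    one grid, so identity registration is exact.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if scheme is None:
        scheme = default_scheme(30)
    ss = np.random.SeedSequence(seed)
    subjects: list[SyntheticSubject] = []
    coupled = {c.score_name: c for c in spec.behavior_couplings}
    moments = {
        c.score_name: _region_fa_moments(spec, c.region_id) for c in spec.behavior_couplings
    }
    score_rng = np.random.default_rng(ss.spawn(1)[0])
    latent_by_score: dict[str, list[float]] = {s: [] for s in coupled}
    fa_by_score: dict[str, list[float]] = {s: [] for s in coupled}

    child_seeds = ss.spawn(2 * n_per_group * 2)
    k = 0
    for group in ("control", "IUGR"):
        for i in range(n_per_group):
            tf, truth = generate_tensor_field(spec, group, child_seeds[k])
            dwi = simulate_dwi(
                tf,
                scheme,
                noise_sigma=spec.noise_sigma * spec.s0,
                seed=child_seeds[k + 1],
                noise_model=noise_model,
            )
            if not keep_truth_fields:
                truth.tensor_field = None
            k += 2

            mu, sd = BIRTH_WEIGHT[group]
            weight = float(np.clip(score_rng.normal(mu, sd), 5.0, None))
            scores: dict[str, float] = {}
            for name in SCORE_REGISTRY:
                if name in coupled:
                    c = coupled[name]
                    fa_true = truth.region_fa[c.region_id]
                    pm, psd = moments[name]
                    z_fa = (fa_true - pm) / psd if psd > 0 else 0.0
                    r = c.target_correlation
                    latent = r * z_fa + math.sqrt(1 - r**2) * score_rng.normal()
                    latent_by_score[name].append(latent)
                    fa_by_score[name].append(fa_true)
                else:
                    latent = score_rng.normal()
                loc, scale = _score_loc_scale(name)
                if name in coupled and coupled[name].score_loc is not None:
                    loc = coupled[name].score_loc
                if name in coupled and coupled[name].score_scale is not None:
                    scale = coupled[name].score_scale
                scores[name] = float(_discretize(np.asarray(latent), name, loc, scale))

            record = SubjectRecord(
                subject_id=f"{'C' if group == 'control' else 'R'}{i + 1:02d}",
                group=group,
                birth_weight=weight,
                scores=scores,
            )
            subjects.append(SyntheticSubject(record, dwi, truth))

    achieved: dict[str, tuple[float, float, float]] = {}
    for name, c in coupled.items():
        fa = np.asarray(fa_by_score[name])
        lat = np.asarray(latent_by_score[name])
        disc = np.asarray([s.record.scores[name] for s in subjects])
        with np.errstate(invalid="ignore"):
            r_lat = float(np.corrcoef(fa, lat)[0, 1]) if fa.std() > 0 else float("nan")
            r_disc = float(np.corrcoef(fa, disc)[0, 1]) if disc.std() > 0 else float("nan")
        achieved[name] = (c.target_correlation, r_lat, r_disc)

    return CohortDataset(subjects, spec, scheme, seed, achieved)


# ---------------------------------------------------------------------------
# geometry of the default phantom


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.indices(shape).astype(float)
    acc = np.zeros(shape)
    for g, c, a in zip(grids, center, semi_axes):
        acc += ((g - c) / a) ** 2
    return acc <= 1.0


def _cylinder(shape, axis: int, center2: tuple[float, float], radius: float) -> np.ndarray:
    grids = np.indices(shape).astype(float)
    other = [i for i in range(3) if i != axis]
    d2 = (grids[other[0]] - center2[0]) ** 2 + (grids[other[1]] - center2[1]) ** 2
    return d2 <= radius**2


def _prolate(adc: float, fa: float) -> tuple[float, float, float]:
    """Prolate eigenvalues (l, t, t) with given trace mean and FA."""
    delta = fa * math.sqrt(3.0 / (9.0 - 6.0 * fa**2))
    return (adc * (1 + 2 * delta), adc * (1 - delta), adc * (1 - delta))


# Tissue calibration (mm^2/s): gray matter ADC 0.44e-3 with FA 0.14, white
# matter ADC 0.42e-3 with FA 0.28.  With the default geometry (about 15% of
# brain voxels in tracts) this puts the whole-brain mean FA near 0.16 and the
# FA>0.2 mask mean near 0.27-0.28.
GM_ADC, GM_FA = 0.44e-3, 0.140
WM_ADC, WM_FA = 0.42e-3, 0.28

# Between-subject FA spread: the global factor produces most of the
# whole-brain SD (~0.016, i.e. "0.16 (0.02)" at two decimals); regional
# jitter is small, especially in WM, where masked group means are nearly
# identical across animals.
GLOBAL_FA_REL_SD = 0.04
GM_FA_JITTER_SD = 0.0165
WM_FA_JITTER_SD = 0.005


def _build_regions(grid_shape) -> list[Region]:
    shape = tuple(grid_shape)
    c = [(s - 1) / 2.0 for s in shape]
    semi = (0.41 * shape[0], 0.41 * shape[1], 0.345 * shape[2])
    brain = _ellipsoid(shape, c, semi)
    # the thicker x tract doubles as the focal effect region
    tract_x = _cylinder(shape, 0, (c[1], c[2] - 0.125 * shape[2]), 0.108 * shape[0]) & brain
    tract_y = _cylinder(shape, 1, (c[0], c[2] + 0.125 * shape[2]), 0.068 * shape[0]) & brain
    tract_y &= ~tract_x
    gm = brain & ~tract_x & ~tract_y
    gm_lam = _prolate(GM_ADC, GM_FA)
    wm_lam = _prolate(WM_ADC, WM_FA)
    return [
        Region("gm", gm, "GM", None, gm_lam, fa_jitter_sd=GM_FA_JITTER_SD),
        Region(
            "wm_tract_x", tract_x, "WM", np.array([1.0, 0.0, 0.0]), wm_lam,
            fa_jitter_sd=WM_FA_JITTER_SD,
        ),
        Region(
            "wm_tract_y", tract_y, "WM", np.array([0.0, 1.0, 0.0]), wm_lam,
            fa_jitter_sd=WM_FA_JITTER_SD,
        ),
    ]


def default_spec(grid_shape=(32, 32, 32), voxel_size=(0.35, 0.35, 0.35)) -> PhantomSpec:
    """The study-condition phantom: diffuse plus focal FA loss in IUGR.

    A diffuse dFA of 0.008 over gray matter and the y tract reproduces the
    global whole-brain FA difference (0.16 vs 0.15); the x tract carries a
    stronger focal loss (dFA 0.025).  One behavioral coupling ties the
    "head turn" score to the x tract's FA with r = 0.65.
    """
    regions = _build_regions(grid_shape)
    return PhantomSpec(
        grid_shape=tuple(grid_shape),
        voxel_size=tuple(voxel_size),
        regions=regions,
        group_effect={"gm": 0.008, "wm_tract_x": 0.025, "wm_tract_y": 0.008},
        behavior_couplings=[BehaviorCoupling("head_turn", "wm_tract_x", 0.65)],
    )


def focal_effect_spec(
    delta_fa: float = 0.03, grid_shape=(32, 32, 32), voxel_size=(0.35, 0.35, 0.35)
) -> PhantomSpec:
    """Effect only in the x tract (for localization experiments)."""
    return PhantomSpec(
        grid_shape=tuple(grid_shape),
        voxel_size=tuple(voxel_size),
        regions=_build_regions(grid_shape),
        group_effect={"wm_tract_x": delta_fa},
        behavior_couplings=[BehaviorCoupling("head_turn", "wm_tract_x", 0.65)],
    )


def null_spec(grid_shape=(32, 32, 32), voxel_size=(0.35, 0.35, 0.35)) -> PhantomSpec:
    """No group effect, no couplings: the two groups are exchangeable."""
    return PhantomSpec(
        grid_shape=tuple(grid_shape),
        voxel_size=tuple(voxel_size),
        regions=_build_regions(grid_shape),
        group_effect={},
        behavior_couplings=[],
    )
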