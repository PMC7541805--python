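"""Seeded synthetic multisite tumour phantoms with a linked blood-DNA model.

No patient imaging or sequencing data is distributable, so every stage of
the pipeline is exercised on generated cohorts that reproduce the
*structure* the analysis assumes: multi-lesion 3D SUV phantoms (spheres or
ellipsoids with per-lesion uniform uptake on a zero background), a monotone
stochastic link from a tumour feature to ctDNA, VAF sampling consistent
with the hGE/mL quantification, a detection false-negative process, and an
additive per-machine batch effect on a configurable feature subset.

The defaults emulate a DLBCL-like cohort: ~9 lesions per patient, lesion
radii with median 15 mm, per-lesion SUV with median 8, total metabolic
volumes of order 10^2–10^3 cm3, cfDNA around 10^4 hGE/mL and ctDNA around
10^3 hGE/mL, with a false-negative probability of 0.2.  The link drives
ctDNA from the total metabolic tumour surface (TMTS) — the tumour–host
interface where cytolysis releases DNA — with alternative drivers
selectable to probe the regression machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .blood import HGE_PG
from .exceptions import ValidationError
from .features import FEATURE_NAMES, FeatureConfig, extract_all
from .volumes import SuvVolume

__all__ = ["PhantomSpec", "LinkModel", "generate_phantom", "generate_cohort"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and uptake model of one synthetic patient volume.

    Lesion count is fixed (``lesion_count``) or ``max(1, Poisson(lambda))``;
    radii are lognormal in mm; lesions are spheres, or ellipsoids with axis
    ratios drawn uniformly from ``axis_ratio_range``; centres are placed
    uniformly in a body box with at least ``min_gap_mm`` between lesion
    surfaces; per-lesion SUV is lognormal and uniform within the lesion,
    background 0 (masks are ground truth; physiological background uptake
    is out of scope).
    """

    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    body_box_mm: tuple[float, float, float] = (360.0, 360.0, 560.0)
    lesion_count: int | None = None
    lesion_count_lambda: float = 9.0
    radius_log_median_mm: float = 15.0
    radius_log_sigma: float = 0.45
    radius_max_mm: float = 60.0
    shape: str = "ellipsoid"
    axis_ratio_range: tuple[float, float] = (0.7, 1.0)
    min_gap_mm: float = 8.0
    suv_log_median: float = 8.0
    suv_log_sigma: float = 0.35
    max_placement_tries: int = 2000

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError("spacing must be positive")
        if self.shape not in ("sphere", "ellipsoid"):
            raise ValidationError(f"shape must be sphere or ellipsoid, got {self.shape!r}")
        if self.min_gap_mm < 0:
            raise ValidationError("min_gap_mm must be >= 0")
        if self.lesion_count is not None and self.lesion_count < 1:
            raise ValidationError("fixed lesion_count must be >= 1")


@dataclass(frozen=True)
class LinkModel:
    """Stochastic link from realized PET features to blood DNA.

    ``log ctDNA = beta0 + beta1 * log(driver) + N(0, sigma^2)`` in hGE/mL,
    with ``driver`` one of the twelve features (default TMTS, cm2).
    cfDNA = ctDNA + an independent lognormal baseline, so ctDNA <= cfDNA
    and cfDNA correlates more weakly with the driver than ctDNA does.
    Mutation count is ``1 + Poisson(mutation_rate)`` and per-mutation VAFs
    are Beta-distributed around mean ctDNA/cfDNA, so nulls arise *only*
    through the false-negative probability ``p_fn`` and re-quantification
    recovers the drawn ctDNA in expectation.  Machine 2 measurements of
    ``batch_features`` are shifted additively by ``batch_shift_sd`` pooled
    standard deviations of the feature (a measurement artifact: the
    biology, and hence ctDNA, is driven by the unshifted values).
    """

    driver: str = "TMTS"
    beta0: float = 1.6
    beta1: float = 1.0
    sigma: float = 0.5
    cfdna_baseline_log_median: float = np.log(8000.0)
    cfdna_baseline_log_sigma: float = 0.6
    p_fn: float = 0.2
    mutation_rate: float = 2.0
    vaf_concentration: float = 200.0
    batch_features: tuple[str, ...] = ("TumBB", "Dmax", "itErosion", "medPCD")
    batch_shift_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.driver not in FEATURE_NAMES:
            raise ValidationError(f"unknown driver feature {self.driver!r}")
        if not 0.0 <= self.p_fn <= 1.0:
            raise ValidationError("p_fn must be in [0, 1]")
        unknown = [f for f in self.batch_features if f not in FEATURE_NAMES]
        if unknown:
            raise ValidationError(f"unknown batch features {unknown}")


def _draw_lesions(spec: PhantomSpec, rng: np.random.Generator) -> list[dict]:
    k = spec.lesion_count or max(1, int(rng.poisson(spec.lesion_count_lambda)))
    box = np.asarray(spec.body_box_mm)
    lesions: list[dict] = []
    tries = 0
    while len(lesions) < k:
        if tries >= spec.max_placement_tries:
            raise ValidationError(
                f"could not place {k} lesions with gap {spec.min_gap_mm} mm in body box "
                f"{spec.body_box_mm} after {tries} tries"
            )
        tries += 1
        r = min(float(rng.lognormal(np.log(spec.radius_log_median_mm), spec.radius_log_sigma)),
                spec.radius_max_mm)
        if spec.shape == "ellipsoid":
            ratios = rng.uniform(*spec.axis_ratio_range, size=3)
            ratios /= ratios.max()
            radii = r * ratios
        else:
            radii = np.full(3, r)
        if np.any(2 * radii >= box):
            continue
        centre = np.array([rng.uniform(radii[a], box[a] - radii[a]) for a in range(3)])
        r_outer = radii.max()
        clear = all(
            np.linalg.norm(centre - l["centre"]) >= r_outer + l["radii"].max() + spec.min_gap_mm
            for l in lesions
        )
        if not clear:
            continue
        lesions.append(
            {
                "centre": centre,
                "radii": radii,
                "suv": float(rng.lognormal(np.log(spec.suv_log_median), spec.suv_log_sigma)),
            }
        )
    return lesions


def generate_phantom(
    spec: PhantomSpec, seed: int | np.random.Generator
) -> tuple[SuvVolume, np.ndarray, list[dict]]:
    """Generate one phantom: (SUV volume, binary mask, ground-truth lesions).

    Deterministic for fixed (spec, seed).  Ground truth records each
    lesion's centre (mm), radii (mm) and uniform SUV level.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lesions = _draw_lesions(spec, rng)
    spacing = np.asarray(spec.spacing_mm)
    shape = tuple(int(np.ceil(b / s)) for b, s in zip(spec.body_box_mm, spacing))
    suv = np.zeros(shape, np.float32)
    mask = np.zeros(shape, bool)
    for lesion in lesions:
        centre, radii = lesion["centre"], lesion["radii"]
        lo = np.maximum(np.floor((centre - radii) / spacing).astype(int) - 1, 0)
        hi = np.minimum(np.ceil((centre + radii) / spacing).astype(int) + 2, shape)
        grids = np.meshgrid(
            *(np.arange(lo[a], hi[a]) * spacing[a] for a in range(3)), indexing="ij"
        )
        inside = (
            sum(((g - c) / r) ** 2 for g, c, r in zip(grids, centre, radii)) <= 1.0
        )
        region = tuple(slice(lo[a], hi[a]) for a in range(3))
        mask[region] |= inside
        suv[region] = np.where(inside, np.maximum(suv[region], lesion["suv"]), suv[region])
    if not mask.any():
        raise ValidationError("phantom voxelization produced an empty mask (lesions below grid resolution)")
    volume = SuvVolume(suv, tuple(spacing), (0.0, 0.0, 0.0))
    truth = [
        {"centre_mm": l["centre"].tolist(), "radii_mm": l["radii"].tolist(), "suv": l["suv"]}
        for l in lesions
    ]
    return volume, mask, truth


def generate_cohort(
    spec: PhantomSpec | None = None,
    link: LinkModel | None = None,
    n_patients: int = 50,
    seed: int = 0,
    disease: str = "DLBCL",
    feature_config: FeatureConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a full synthetic cohort: phantoms -> features -> blood DNA.

    Per patient: a phantom is voxelized and the twelve features extracted;
    ctDNA is drawn from the link model given the realized (unshifted)
    driver feature; cfDNA adds an independent baseline; mutation VAFs are
    sampled so that quantification recovers the drawn ctDNA in expectation;
    with probability ``p_fn`` the mutation list is emptied (null ctDNA);
    machines are assigned 1/2 alternately and the configured batch shift is
    added to machine-2 measurements.

    Returns ``(cohort, mutations, ground_truth)``.  ``cohort`` has one row
    per patient (features as measured, i.e. after batch shift, plus
    ``cfdna_pg_per_ml``/``cfdna_hge``/``ctdna_hge``/``n_mutations``);
    ``mutations`` one row per mutation call; ``ground_truth`` the per-patient
    lesion lists, drawn ctDNA and the applied shifts.
    """
    spec = spec or PhantomSpec()
    link = link or LinkModel()
    feature_config = feature_config or FeatureConfig()
    if n_patients < 4:
        raise ValidationError("a cohort needs n_patients >= 4")
    root = np.random.SeedSequence(seed)
    patient_seeds = root.spawn(n_patients)
    blood_rng = np.random.default_rng(root.spawn(1)[0])

    rows, truth_patients = [], []
    for i, pseed in enumerate(patient_seeds):
        volume, mask, lesion_truth = generate_phantom(spec, np.random.default_rng(pseed))
        fv = extract_all(volume, mask, feature_config)
        row = {"patient_id": f"P{i:03d}", "disease": disease, "machine": 1 + i % 2}
        row.update(fv.as_dict())
        rows.append(row)
        truth_patients.append({"patient_id": row["patient_id"], "lesions": lesion_truth})
    cohort = pd.DataFrame(rows)

    # measurement batch effect: additive shift on machine-2 values of the
    # configured features, scaled by the pooled (pre-shift) SD
    shifts = {}
    for feat in link.batch_features:
        sd = float(cohort[feat].std(ddof=1))
        shift = link.batch_shift_sd * sd
        shifts[feat] = shift
        cohort.loc[cohort["machine"] == 2, feat] += shift

    # blood-DNA link uses the biological (unshifted) driver values
    driver = np.array([r[link.driver] for r in rows], float)
    log_ct = link.beta0 + link.beta1 * np.log(driver) + blood_rng.normal(0, link.sigma, n_patients)
    ctdna = np.exp(log_ct)
    baseline = blood_rng.lognormal(
        link.cfdna_baseline_log_median, link.cfdna_baseline_log_sigma, n_patients
    )
    cfdna_hge = ctdna + baseline
    cohort["cfdna_pg_per_ml"] = cfdna_hge * HGE_PG
    cohort["cfdna_hge"] = cfdna_hge

    mean_vaf_target = ctdna / cfdna_hge
    detected = blood_rng.random(n_patients) >= link.p_fn
    mut_rows = []
    measured_ct = np.full(n_patients, np.nan)
    n_mut = np.zeros(n_patients, int)
    for i in range(n_patients):
        if not detected[i]:
            continue
        count = 1 + int(blood_rng.poisson(link.mutation_rate))
        m = mean_vaf_target[i]
        kappa = link.vaf_concentration
        vafs = blood_rng.beta(m * kappa, (1 - m) * kappa, size=count)
        for j, v in enumerate(vafs):
            mut_rows.append(
                {"patient_id": f"P{i:03d}", "variant_id": f"P{i:03d}_v{j}", "vaf": float(v)}
            )
        measured_ct[i] = float(vafs.mean()) * cfdna_hge[i]
        n_mut[i] = count
    cohort["ctdna_hge"] = measured_ct
    cohort["n_mutations"] = n_mut
    mutations = pd.DataFrame(mut_rows, columns=["patient_id", "variant_id", "vaf"])

    ground_truth = {
        "spec": asdict(spec),
        "link": asdict(link),
        "seed": seed,
        "patients": truth_patients,
        "drawn_ctdna_hge": ctdna.tolist(),
        "detected": detected.tolist(),
        "batch_shifts": shifts,
    }
    return cohort, mutations, ground_truth
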