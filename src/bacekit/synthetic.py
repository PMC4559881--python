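"""Seeded synthetic-data generators with attached ground truth.

Every generator is a pure function of (parameters, seed) and returns
its dataset together with a :class:`SyntheticGroundTruth` carrying the
generating parameters, so recovery tests can close the loop through the
analysis modules.

Emulated study conditions:

* one-compartment oral/i.v. PK profiles in mouse / rat / dog parameter
  regimes (clearance, terminal half-life and oral bioavailability in
  the ranges typical of a brain-penetrant small molecule);
* a rat dose-ranging study with a sigmoidal dose–response around an
  ED50 of 1.6 μmol/kg over the 0.3–30 μmol/kg dose grid;
* a dog CSF Aβ40 turnover study: predose baseline near 6000 pg/ml,
  suppression to roughly 20 % of baseline, recovery over ~120 h, with
  predose samples at −24 and −1 h and post-dose sampling to 168 h;
* H-DAB-like brightfield section images containing hematoxylin-stained
  nuclei and DAB-stained deposits in the three size classes, plus
  fluorescence channels with glia clusters optionally co-located with
  deposits.

Noise models: multiplicative lognormal with a given CV for
concentrations (keeps values non-negative), lognormal subject-level
baselines, and minimum-separation (Poisson-disk style) placement for
image objects to control overlap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skimage import color

from .profiles import ConcentrationTimeProfile
from .turnover import PkForcing, TurnoverModel, simulate_turnover

LN2 = math.log(2.0)


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Generating parameters and per-dataset truth for a synthetic dataset."""

    generator_name: str
    parameters: dict
    seed: int
    truth: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return str(o)

        s = json.dumps(asdict(self), indent=2, default=default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# PK profiles
# ---------------------------------------------------------------------------

#: species regimes: clearance (ml/min/kg), terminal half-life (h), oral
#: bioavailability, absorption rate (1/h) and the study i.v./p.o. doses
#: (μmol/kg).  V (l/kg) is derived as CL·t½/ln2 so that closed-loop NCA
#: recovery is self-consistent.
SPECIES_PRESETS = {
    "mouse": dict(cl_ml_min_kg=16.0, t_half_h=3.6, f_oral=0.37, ka=2.0,
                  dose_iv=2.0, dose_po=6.0, t_last_h=24.0),
    "rat": dict(cl_ml_min_kg=52.0, t_half_h=2.7, f_oral=0.92, ka=3.0,
                dose_iv=2.0, dose_po=6.0, t_last_h=48.0),
    "dog": dict(cl_ml_min_kg=0.4, t_half_h=36.2, f_oral=0.62, ka=1.5,
                dose_iv=2.0, dose_po=2.0, t_last_h=408.0),
}

#: relative sampling grid (fraction of t_last), densified near the peak
_REL_TIMES = np.array(
    [0.002, 0.004, 0.008, 0.012, 0.02, 0.03, 0.045, 0.065, 0.09, 0.12,
     0.16, 0.21, 0.27, 0.34, 0.42, 0.51, 0.61, 0.72, 0.85, 1.0]
)


def gen_pk_profile(
    species_preset: str = "rat",
    dose: float | None = None,
    route: str = "po",
    noise_cv: float = 0.0,
    seed: int = 0,
    times=None,
) -> tuple[ConcentrationTimeProfile, SyntheticGroundTruth]:
    """One-compartment PK profile in a species parameter regime."""
    preset = SPECIES_PRESETS[species_preset]
    rng = np.random.default_rng(seed)
    cl_l_h = preset["cl_ml_min_kg"] * 60.0 / 1000.0          # l/h/kg
    ke = LN2 / preset["t_half_h"]
    v = cl_l_h / ke                                          # l/kg
    if dose is None:
        dose = preset["dose_iv"] if route == "iv" else preset["dose_po"]
    if times is None:
        times = _REL_TIMES * preset["t_last_h"]
    times = np.asarray(times, dtype=float)
    if route == "iv":
        conc = dose / v * np.exp(-ke * times)
    else:
        forcing = PkForcing(dose_scaled=preset["f_oral"] * dose / v,
                            ka=preset["ka"], ke=ke)
        conc = forcing.conc(times)
    conc = conc * _lognormal_factor(rng, noise_cv, times.shape)
    profile = ConcentrationTimeProfile(
        subject_id=f"{species_preset}-{seed}",
        matrix="blood",
        times=times,
        concentrations=conc,
        dose=float(dose),
        route=route,
        unit="uM",
    )
    truth = SyntheticGroundTruth(
        generator_name="gen_pk_profile",
        parameters=dict(species_preset=species_preset, dose=dose, route=route,
                        noise_cv=noise_cv),
        seed=seed,
        truth=dict(cl_ml_min_kg=preset["cl_ml_min_kg"], ke=ke, v_l_kg=v,
                   t_half_h=preset["t_half_h"], f_oral=preset["f_oral"],
                   ka=preset["ka"]),
    )
    return profile, truth


# ---------------------------------------------------------------------------
# rat dose–response study
# ---------------------------------------------------------------------------

def gen_dose_response(
    ed50: float = 1.6,
    hill: float = 1.0,
    n_per_group: int = 5,
    noise_cv: float = 0.10,
    doses=(0.3, 1.0, 3.0, 10.0, 30.0),
    vehicle_level: float = 100.0,
    max_inhibition: float = 100.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, SyntheticGroundTruth]:
    """Rat-style dose-ranging study: vehicle + treated group means.

    The true group-level response is
    ``vehicle_level · (1 − max_inhibition/100 · d^h/(d^h + ed50^h))``;
    per-animal values get multiplicative lognormal noise and groups of
    ``n_per_group`` animals are averaged.  Returns (table, vehicle group
    mean, truth); the table has columns ``dose`` and ``response``.
    """
    rng = np.random.default_rng(seed)
    doses = np.asarray(doses, dtype=float)
    vehicle_mean = float(
        np.mean(vehicle_level * _lognormal_factor(rng, noise_cv, n_per_group))
    )
    rows = []
    for d in doses:
        frac = (d ** hill) / (d ** hill + ed50 ** hill)
        level = vehicle_level * (1.0 - max_inhibition / 100.0 * frac)
        group = level * _lognormal_factor(rng, noise_cv, n_per_group)
        rows.append({"dose": d, "response": float(np.mean(group)),
                     "group_n": n_per_group})
    truth = SyntheticGroundTruth(
        generator_name="gen_dose_response",
        parameters=dict(ed50=ed50, hill=hill, n_per_group=n_per_group,
                        noise_cv=noise_cv, doses=doses.tolist(),
                        vehicle_level=vehicle_level,
                        max_inhibition=max_inhibition),
        seed=seed,
        truth=dict(ed50=ed50, hill=hill),
    )
    return pd.DataFrame(rows), vehicle_mean, truth


# ---------------------------------------------------------------------------
# dog turnover study
# ---------------------------------------------------------------------------

#: default sampling skeleton of the dog study: predose at −24/−1 h,
#: post-dose sampling to 168 h
DOG_TIMES = np.array([-24.0, -1.0, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0,
                      36.0, 48.0, 72.0, 96.0, 120.0, 168.0])

#: default dog blood forcing: peak ≈ 0.7 μM shortly after dosing with a
#: long terminal phase (t½ ≈ 36 h)
DOG_FORCING = PkForcing(dose_scaled=0.74, ka=1.5, ke=LN2 / 36.2)

#: default dog CSF Aβ40 turnover: baseline 6000 pg/ml, clearance rate
#: 0.26 1/h, in vivo IC50 59 nM (0.059 μM), complete maximal blockade
DOG_TURNOVER = TurnoverModel(kin=0.26 * 6000.0, kout=0.26, ic50=0.059, imax=1.0)


@dataclass(frozen=True)
class DogSubject:
    blood: ConcentrationTimeProfile
    csf_times: np.ndarray
    csf_values: np.ndarray          #: pg/ml


@dataclass(frozen=True)
class DogStudy:
    subjects: tuple
    truth: SyntheticGroundTruth

    def mean_blood(self) -> ConcentrationTimeProfile:
        conc = np.mean([s.blood.concentrations for s in self.subjects], axis=0)
        return self.subjects[0].blood.with_(subject_id="mean", concentrations=conc)

    def mean_csf(self) -> tuple[np.ndarray, np.ndarray]:
        t = self.subjects[0].csf_times
        v = np.mean([s.csf_values for s in self.subjects], axis=0)
        return t, v


def gen_dog_study(
    turnover: TurnoverModel = DOG_TURNOVER,
    forcing: PkForcing = DOG_FORCING,
    n_subjects: int = 4,
    noise_cv: float = 0.10,
    baseline_cv: float = 0.10,
    times=DOG_TIMES,
    seed: int = 0,
) -> DogStudy:
    """Paired blood-PK + CSF-biomarker series for a dog cohort.

    Each subject gets a lognormal baseline around ``turnover.baseline``
    and multiplicative lognormal measurement noise on both blood and
    CSF samples.  Predose blood samples are 0 (drug-naive)."""
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    post = times >= 0
    subjects = []
    for i in range(n_subjects):
        r0 = turnover.baseline * float(_lognormal_factor(rng, baseline_cv, ()))
        model = TurnoverModel(kin=turnover.kout * r0, kout=turnover.kout,
                              ic50=turnover.ic50, imax=turnover.imax)
        blood_clean = forcing.conc(times) * post
        blood = blood_clean * _lognormal_factor(rng, noise_cv, times.shape) * post
        csf_clean = simulate_turnover(model, forcing, times, r0=r0)
        csf = csf_clean * _lognormal_factor(rng, noise_cv, times.shape)
        subjects.append(
            DogSubject(
                blood=ConcentrationTimeProfile(
                    subject_id=f"dog-{i + 1}", matrix="blood", times=times,
                    concentrations=blood, dose=1.1, route="po", unit="uM",
                ),
                csf_times=times,
                csf_values=csf,
            )
        )
    truth = SyntheticGroundTruth(
        generator_name="gen_dog_study",
        parameters=dict(n_subjects=n_subjects, noise_cv=noise_cv,
                        baseline_cv=baseline_cv,
                        forcing=dict(dose_scaled=forcing.dose_scaled,
                                     ka=forcing.ka, ke=forcing.ke)),
        seed=seed,
        truth=dict(kout=turnover.kout, ic50=turnover.ic50,
                   imax=turnover.imax, baseline=turnover.baseline),
    )
    return DogStudy(subjects=tuple(subjects), truth=truth)


# ---------------------------------------------------------------------------
# section images
# ---------------------------------------------------------------------------

#: radius ranges (px) whose rasterized disk areas fall inside each class
_CLASS_RADII = {
    "large_plaque": (19.5, 28.0),       # area > 1000 px
    "small_plaque": (9.2, 16.8),        # 200 < area <= 1000 px
    "intracellular": (3.8, 7.2),        # 25 <= area <= 200 px
}


def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _place_centers(rng, shape, radii, existing, margin=40, min_gap=6, max_tries=2000):
    """Minimum-separation placement; returns centers for the given radii."""
    centers = []
    placed = list(existing)
    for r in radii:
        for _ in range(max_tries):
            c = (rng.uniform(margin + r, shape[0] - margin - r),
                 rng.uniform(margin + r, shape[1] - margin - r))
            if all(math.hypot(c[0] - pc[0], c[1] - pc[1]) >= r + pr + min_gap
                   for pc, pr in placed):
                centers.append(c)
                placed.append((c, r))
                break
        else:
            raise RuntimeError("could not place objects without overlap; "
                               "reduce counts or enlarge the image")
    return centers, placed


@dataclass(frozen=True)
class SectionImageSet:
    """A synthetic H-DAB section with optional fluorescence channels."""

    rgb: np.ndarray                 #: uint8 (H, W, 3) brightfield image
    roi_mask: np.ndarray            #: boolean ROI (cortex surrogate)
    nuclei_mask: np.ndarray
    deposit_labels: np.ndarray      #: planted deposit label image
    deposit_classes: dict           #: label -> planted category
    gfap: np.ndarray | None
    iba1: np.ndarray | None
    glia_positions: dict            #: channel -> list of (row, col)
    truth: SyntheticGroundTruth


def gen_section_image(
    n_large: int = 5,
    n_small: int = 20,
    n_granules: int = 40,
    n_nuclei: int = 50,
    glia_coupling: float = 0.8,
    seed: int = 0,
    shape: tuple[int, int] = (768, 768),
    n_noise_specks: int = 0,
    fluorescence: bool = True,
    background_glia_rate: float = 4.0,
    nucleus_od: float = 0.8,
    deposit_od: float = 1.0,
) -> SectionImageSet:
    """Synthetic brightfield section with planted nuclei and deposits.

    Deposits are disks whose rasterized areas fall in the three class
    ranges; the planted category is recorded from the actual rendered
    pixel count, so the truth uses the same area rule as the pipeline.
    Deposits are kept detached from nuclei (beyond the default nuclear
    vicinity), non-overlapping, and away from the ROI border.

    With ``fluorescence``, GFAP and Iba1 channels are rendered; each
    plaque nucleates an adjacent glia cluster with probability
    ``glia_coupling``, plus a Poisson number of background clusters
    (rate ``background_glia_rate``) placed independently of deposits —
    so ``glia_coupling = 0`` decouples glia counts from plaque burden.
    """
    rng = np.random.default_rng(seed)
    hema_od = np.zeros(shape, dtype=float)
    dab_od = np.zeros(shape, dtype=float)
    nuclei_mask = np.zeros(shape, dtype=bool)
    labels = np.zeros(shape, dtype=np.int32)

    # nuclei first; deposits must stay > vicinity radius away from them
    nuc_radii = rng.uniform(5.5, 9.0, n_nuclei)
    nuc_centers, placed = _place_centers(rng, shape, nuc_radii, [], min_gap=4)
    for c, r in zip(nuc_centers, nuc_radii):
        m = _disk_mask(shape, c, r)
        nuclei_mask |= m
        hema_od[m] = nucleus_od
    # inflate nuclei radii so deposits clear exclusion + vicinity zones
    placed = [(c, r + 18.0) for c, r in placed]

    deposit_classes: dict[int, str] = {}
    next_label = 1
    spec = [("large_plaque", n_large), ("small_plaque", n_small),
            ("intracellular", n_granules)]
    from .imaging import classify_area

    for cls, n in spec:
        lo, hi = _CLASS_RADII[cls]
        radii = rng.uniform(lo, hi, n)
        centers, placed = _place_centers(rng, shape, radii, placed)
        for c, r in zip(centers, radii):
            # nudge the radius until the rasterized pixel count falls in
            # the requested class, so planted truth and the pipeline's
            # area rule agree by construction
            m = _disk_mask(shape, c, r)
            for _ in range(20):
                got = classify_area(int(m.sum()), False)
                if got == cls:
                    break
                order = ("rejected", "intracellular", "small_plaque", "large_plaque")
                r += 0.3 if order.index(got) < order.index(cls) else -0.3
                m = _disk_mask(shape, c, r)
            dab_od[m] = deposit_od
            labels[m] = next_label
            deposit_classes[next_label] = cls
            next_label += 1
    if n_noise_specks:
        radii = rng.uniform(1.0, 2.2, n_noise_specks)  # area < 25 px
        centers, placed = _place_centers(rng, shape, radii, placed)
        for c, r in zip(centers, radii):
            dab_od[_disk_mask(shape, c, r)] = deposit_od

    stack = np.stack([hema_od, dab_od, np.zeros(shape)], axis=-1)
    rgb = color.combine_stains(stack, color.rgb_from_hdx)
    rgb = (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8)

    roi = np.zeros(shape, dtype=bool)
    roi[10:-10, 10:-10] = True

    gfap = iba1 = None
    glia_positions: dict[str, list] = {"gfap": [], "iba1": []}
    if fluorescence:
        gfap = np.zeros(shape, dtype=np.uint8)
        iba1 = np.zeros(shape, dtype=np.uint8)
        plaque_labels = [l for l, c in deposit_classes.items()
                        if c in ("large_plaque", "small_plaque")]
        for chan_name, chan in (("gfap", gfap), ("iba1", iba1)):
            centers: list = []

            def _add(c, centers=centers, shape=shape):
                # keep clusters separated so counts equal placements
                c = (float(np.clip(c[0], 15, shape[0] - 15)),
                     float(np.clip(c[1], 15, shape[1] - 15)))
                if all(math.hypot(c[0] - p[0], c[1] - p[1]) >= 20 for p in centers):
                    centers.append(c)
                    return True
                return False

            for lab in plaque_labels:
                if rng.random() < glia_coupling:
                    rr, cc = np.nonzero(labels == lab)
                    for _ in range(50):
                        j = rng.integers(rr.size)
                        cand = (float(rr[j]) + rng.normal(0, 3),
                                float(cc[j]) + rng.normal(0, 3))
                        if _add(cand):
                            break
            for _ in range(rng.poisson(background_glia_rate)):
                for _ in range(50):
                    cand = (rng.uniform(30, shape[0] - 30),
                            rng.uniform(30, shape[1] - 30))
                    if _add(cand):
                        break
            for c in centers:
                r = rng.uniform(4.0, 7.0)
                chan[_disk_mask(shape, c, r)] = 200
            glia_positions[chan_name] = centers

    truth = SyntheticGroundTruth(
        generator_name="gen_section_image",
        parameters=dict(n_large=n_large, n_small=n_small, n_granules=n_granules,
                        n_nuclei=n_nuclei, glia_coupling=glia_coupling,
                        shape=list(shape), n_noise_specks=n_noise_specks,
                        background_glia_rate=background_glia_rate),
        seed=seed,
        truth=dict(
            counts={c: sum(1 for v in deposit_classes.values() if v == c)
                    for c in ("large_plaque", "small_plaque", "intracellular")},
            n_nuclei=n_nuclei,
            deposit_area_px=int((labels > 0).sum()),
            area_fraction_pct=100.0 * float((labels > 0)[roi].sum()) / float(roi.sum()),
            glia_counts={k: len(v) for k, v in glia_positions.items()},
        ),
    )
    return SectionImageSet(
        rgb=rgb, roi_mask=roi, nuclei_mask=nuclei_mask, deposit_labels=labels,
        deposit_classes=deposit_classes, gfap=gfap, iba1=iba1,
        glia_positions=glia_positions, truth=truth,
    )


def gen_pathology_cohort(
    n_animals: int = 8,
    glia_coupling: float = 1.0,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    burden_range: tuple[float, float] = (0.4, 2.4),
) -> pd.DataFrame:
    """Per-animal (plaque area %, glia counts) pairs through the full pipeline.

    Animals vary in deposit burden by a multiplier spanning
    ``burden_range``; each animal's section is generated and quantified
    with :func:`bacekit.imaging.quantify_section`, so the returned table
    contains measured, not planted, values.
    """
    from .imaging import quantify_section

    rng = np.random.default_rng(seed)
    rows = []
    mults = np.linspace(*burden_range, n_animals)
    for i, mult in enumerate(mults):
        section = gen_section_image(
            n_large=max(1, round(3 * mult)),
            n_small=max(1, round(8 * mult)),
            n_granules=round(10 * mult),
            n_nuclei=25,
            glia_coupling=glia_coupling,
            seed=int(rng.integers(2 ** 31)),
            shape=shape,
        )
        q = quantify_section(section.rgb, section.roi_mask,
                             gfap=section.gfap, iba1=section.iba1)
        rows.append({"animal": i, "area_pct": q.area_fraction_pct,
                     "gfap": q.glia_clusters["gfap"],
                     "iba1": q.glia_clusters["iba1"]})
    return pd.DataFrame(rows)
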