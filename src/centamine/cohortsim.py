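"""Synthetic cohort generator with known ground truth for every pipeline stage.

Two fidelity tiers share one configuration:

* **Tabular tier** — per-subject regional SBR/CM values with age and sex
  structure, graded parkinsonian deficits, cross-tracer linear links and
  longitudinal decline, plus additive per-record measurement noise.  Fast;
  drives all statistical-machinery tests.
* **Image tier** — the tabular truth rendered into volumes through the
  phantom forward model (paint, smooth, misalign, voxel noise).  Because the
  forward model is linear, the post-smoothing regional means — and hence the
  SBR values an ideal pipeline would measure — are computed exactly from the
  painted values (:func:`centamine.phantom.region_mean_matrix`) and recorded
  as image-tier ground truth.

Cohort structure emulates the reference data sets: a healthy-control cohort
(n = 227, ages 30-85, ~60% male) and a head-to-head cohort (68 subjects, 162
paired scans: 23 single-visit, 41 with 3 annual visits, 4 with 4 visits over
2 years).  Healthy regional mean SBRs, cross-tracer slopes/intercepts,
age/sex effect sizes and annual decline rates default to the published
reference-tracer values; disease severity reduces CM with a regional
gradient (post-commissural putamen most affected, caudate least).

Age and sex effects are imposed on the CM scale (where they are defined) and
mapped back to SBR via the scale anchor, CM = 100 * SBR / mu_HC.

All draws are deterministic functions of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, Volume
from .phantom import (
    DEFAULT_FWHM_MM,
    DEFAULT_HC_VALUES,
    region_mean_matrix,
    synthesize_scan,
)
from .tables import SbrTable
from .transform import AffineTransform

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "RenderedScan",
    "RenderResult",
    "simulate_cohort",
    "simulate_head2head",
    "simulate_longitudinal",
    "render_images",
]

REFERENCE_TRACER = "ioflupane"
SECOND_TRACER = "av133"

REPORT_REGIONS = (
    "striatum",
    "putamen",
    "caudate",
    "pre_commissural_putamen",
    "post_commissural_putamen",
)
# finest report regions, used to drive subregion painting in the image tier
_FINE_OF_SUBREGION = {
    "pre_caudate": "caudate",
    "post_caudate": "caudate",
    "pre_dorsal_putamen": "pre_commissural_putamen",
    "pre_ventral_putamen": "pre_commissural_putamen",
    "post_dorsal_putamen": "post_commissural_putamen",
    "post_ventral_putamen": "post_commissural_putamen",
}

# published healthy-control mean SBR per region (reference tracer)
DEFAULT_HC_MU = {
    "striatum": 1.41,
    "putamen": 1.56,
    "caudate": 1.23,
    "pre_commissural_putamen": 1.86,
    "post_commissural_putamen": 1.33,
}
# published cross-tracer head-to-head regression (second tracer vs reference)
DEFAULT_TRACER_MAPS = {
    SECOND_TRACER: {
        "striatum": (1.48, 0.81),
        "putamen": (1.93, 0.64),
        "caudate": (1.14, 0.79),
        "pre_commissural_putamen": (1.36, 0.98),
        "post_commissural_putamen": (2.38, 0.59),
    }
}
# deficit gradient: fraction of CM lost at full severity, most posterior worst
DEFAULT_REGION_GRADIENT = {
    "caudate": 0.55,
    "striatum": 0.68,
    "pre_commissural_putamen": 0.72,
    "putamen": 0.78,
    "post_commissural_putamen": 0.90,
}
# published annualized absolute CM change (reference tracer)
DEFAULT_DECLINE_CM_PER_YEAR = {
    "striatum": -3.3,
    "putamen": -3.1,
    "caudate": -3.7,
    "pre_commissural_putamen": -3.8,
    "post_commissural_putamen": -2.3,
}
# second-tracer measurement noise (SBR units, per side) pinned analytically so
# that the simulated head-to-head R^2 per region matches the published values
# (51-83% band); bilateral rows average the two sides, hence sigma/sqrt(2)
DEFAULT_NOISE_SIGMA = {
    REFERENCE_TRACER: 0.05,
    SECOND_TRACER: {
        "striatum": 0.41,
        "putamen": 0.44,
        "caudate": 0.31,
        "pre_commissural_putamen": 0.60,
        "post_commissural_putamen": 0.37,
    },
}


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic study, with published-value defaults."""

    n_healthy: int = 227
    n_pd: int = 0
    age_mean: float = 62.0
    age_sd: float = 11.8
    age_range: tuple[float, float] = (30.0, 85.0)
    frac_male: float = 137.0 / 227.0
    hc_mu_sbr: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_HC_MU))
    between_subject_cv: float = 0.15
    region_cv: float = 0.05
    side_cv: float = 0.02
    age_slope_cm: float = -0.24  # CM per year (-2.4% per decade)
    sex_offset_cm: float = -14.8  # CM, male minus female
    severity_range: tuple[float, float] = (0.3, 0.9)
    region_gradient: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_GRADIENT)
    )
    asymmetry: float = 0.15
    tracer_maps: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRACER_MAPS.items()}
    )
    noise_sigma: Mapping = field(
        default_factory=lambda: {
            REFERENCE_TRACER: DEFAULT_NOISE_SIGMA[REFERENCE_TRACER],
            SECOND_TRACER: dict(DEFAULT_NOISE_SIGMA[SECOND_TRACER]),
        }
    )
    decline_cm_per_year: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DECLINE_CM_PER_YEAR)
    )
    decline_subject_sd: float = 1.0
    # visit schedule: (number of subjects, visit times in years); applied in
    # subject order, remaining subjects get a single baseline visit
    visit_schedule: tuple[tuple[int, tuple[float, ...]], ...] = ()
    # image tier
    misalign_translation_mm: float = 5.0
    misalign_rotation_rad: float = 0.10
    misalign_scale: float = 0.05
    image_noise_sigma: float = 0.0
    fwhm_mm: float = DEFAULT_FWHM_MM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy + self.n_pd < 1:
            raise ValueError("cohort must contain at least one subject")
        for region, (a, _) in {
            r: ab for m in self.tracer_maps.values() for r, ab in m.items()
        }.items():
            if a <= 0:
                raise ValueError(f"true cross-tracer slope must be > 0 ({region})")
        if self.between_subject_cv < 0 or self.side_cv < 0 or self.region_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")

    @property
    def cm_intercept(self) -> float:
        """c_HC so that a 65-year-old, sex-average healthy subject sits at CM 100."""
        return 100.0 - self.age_slope_cm * 65.0 - self.sex_offset_cm * 0.5

    def sigma_for(self, tracer: str, region: str) -> float:
        sig = self.noise_sigma.get(tracer, 0.0)
        if isinstance(sig, Mapping):
            return float(sig.get(region, 0.0))
        return float(sig)

    @classmethod
    def dataset1(cls, **overrides) -> "CohortConfig":
        """Healthy reference cohort: 227 controls, single baseline visit."""
        return cls(**overrides)

    @classmethod
    def dataset2(cls, **overrides) -> "CohortConfig":
        """Head-to-head cohort: 68 subjects, 162 paired sessions over 2 years."""
        defaults = dict(
            n_healthy=2,
            n_pd=66,
            age_mean=64.0,
            age_sd=9.1,
            age_range=(33.0, 83.0),
            frac_male=43.0 / 68.0,
            visit_schedule=(
                (23, (0.0,)),
                (41, (0.0, 1.0, 2.0)),
                (4, (0.0, 2.0 / 3.0, 4.0 / 3.0, 2.0)),
            ),
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class GroundTruth:
    """Noise-free per-record truth, regenerable bit-identically from config."""

    subjects: pd.DataFrame  # subject, group, age, sex, severity, worse_side, ...
    truth: pd.DataFrame  # subject, tracer, session_years, region, side, true_sbr, true_cm
    config: CohortConfig


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, lo, hi)


def _measured_from_truth(truth: pd.DataFrame, config: CohortConfig,
                         rng: np.random.Generator) -> SbrTable:
    """Add measurement noise: independent per side, bilateral = side average."""
    df = truth.copy()
    df["value"] = df["true_sbr"]
    sided = df[df["side"] != "bilateral"].copy()
    sigma = np.array(
        [config.sigma_for(t, r) for t, r in zip(sided["tracer"], sided["region"])]
    )
    noise = rng.normal(0.0, 1.0, size=len(sided)) * sigma
    sided["value"] = sided["true_sbr"] + noise
    bilateral = (
        sided.groupby(["subject", "tracer", "session_years", "age", "sex",
                       "region"], as_index=False)["value"].mean()
    )
    bilateral["side"] = "bilateral"
    out = pd.concat(
        [sided, bilateral], ignore_index=True
    )[["subject", "tracer", "session_years", "age", "sex", "region", "side", "value"]]
    out = out.sort_values(
        ["subject", "tracer", "session_years", "region", "side"], kind="stable"
    ).reset_index(drop=True)
    return SbrTable(out)


def simulate_cohort(config: CohortConfig) -> tuple[SbrTable, GroundTruth]:
    """Draw a baseline cohort of reference-tracer SBRs with known truth."""
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_healthy + config.n_pd
    groups = ["healthy"] * config.n_healthy + ["pd"] * config.n_pd
    ages = _truncated_normal(rng, config.age_mean, config.age_sd,
                             *config.age_range, size=n)
    sexes = (rng.random(n) < config.frac_male).astype(int)
    severities = np.where(
        np.array(groups) == "pd",
        rng.uniform(*config.severity_range, size=n),
        0.0,
    )
    worse = np.where(rng.random(n) < 0.5, "left", "right")
    subj_factor = 1.0 + rng.normal(0.0, config.between_subject_cv, size=n)

    subjects = pd.DataFrame(
        {
            "subject": [f"S{i:04d}" for i in range(n)],
            "group": groups,
            "age": ages,
            "sex": sexes,
            "severity": severities,
            "worse_side": worse,
            "subject_factor": subj_factor,
        }
    )

    rows = []
    for _, s in subjects.iterrows():
        cm_pred = (
            config.age_slope_cm * s.age
            + config.sex_offset_cm * s.sex
            + config.cm_intercept
        )
        for region in config.hc_mu_sbr:
            region_factor = 1.0 + rng.normal(0.0, config.region_cv)
            g = config.region_gradient.get(region, 0.7)
            for side in ("left", "right"):
                side_factor = 1.0 + rng.normal(0.0, config.side_cv)
                d = s.severity * (
                    1.0 + (config.asymmetry if side == s.worse_side
                           else -config.asymmetry)
                )
                cm = cm_pred * s.subject_factor * region_factor * side_factor
                cm = cm * (1.0 - g * min(d, 1.0))
                rows.append(
                    {
                        "subject": s.subject,
                        "tracer": REFERENCE_TRACER,
                        "session_years": 0.0,
                        "age": s.age,
                        "sex": int(s.sex),
                        "region": region,
                        "side": side,
                        "true_cm": cm,
                        "true_sbr": cm / 100.0 * config.hc_mu_sbr[region],
                    }
                )
    truth = pd.DataFrame(rows)
    bilateral = (
        truth.groupby(["subject", "tracer", "session_years", "age", "sex",
                       "region"], as_index=False)[["true_cm", "true_sbr"]].mean()
    )
    bilateral["side"] = "bilateral"
    truth = pd.concat([truth, bilateral], ignore_index=True)
    truth = truth.sort_values(
        ["subject", "tracer", "session_years", "region", "side"], kind="stable"
    ).reset_index(drop=True)

    measured = _measured_from_truth(truth, config, np.random.default_rng([config.seed, 2]))
    return measured, GroundTruth(subjects, truth, config)


def simulate_longitudinal(
    base: GroundTruth, config: CohortConfig | None = None
) -> tuple[SbrTable, GroundTruth]:
    """Expand a baseline truth to the configured visit schedule with linear
    per-subject CM decline (group-specific rates)."""
    config = config or base.config
    if not config.visit_schedule:
        raise ValueError("config.visit_schedule is empty; nothing to expand")
    for _, times in config.visit_schedule:
        t = np.asarray(times, dtype=float)
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError(f"visit times must be strictly increasing: {times}")
    rng = np.random.default_rng([config.seed, 3])

    schedule: dict[str, tuple[float, ...]] = {}
    idx = 0
    subj_ids = base.subjects["subject"].tolist()
    for count, times in config.visit_schedule:
        for _ in range(count):
            if idx >= len(subj_ids):
                break
            schedule[subj_ids[idx]] = tuple(times)
            idx += 1
    for sid in subj_ids[idx:]:
        schedule[sid] = (0.0,)

    group_of = dict(zip(base.subjects["subject"], base.subjects["group"]))
    baseline = base.truth[base.truth["session_years"] == 0.0]

    rows = []
    for (subject, region), grp in baseline.groupby(["subject", "region"]):
        is_pd = group_of[subject] == "pd"
        rate = (
            config.decline_cm_per_year.get(region, 0.0)
            + rng.normal(0.0, config.decline_subject_sd)
            if is_pd
            else 0.0
        )
        mu = config.hc_mu_sbr.get(region)
        for _, rec in grp.iterrows():
            for t in schedule[subject]:
                cm = rec.true_cm + rate * t
                rows.append(
                    {
                        "subject": subject,
                        "tracer": rec.tracer,
                        "session_years": float(t),
                        "age": rec.age + t,
                        "sex": int(rec.sex),
                        "region": region,
                        "side": rec.side,
                        "true_cm": cm,
                        "true_sbr": cm / 100.0 * (mu if mu is not None else 1.0),
                    }
                )
    truth = pd.DataFrame(rows).sort_values(
        ["subject", "tracer", "session_years", "region", "side"], kind="stable"
    ).reset_index(drop=True)
    measured = _measured_from_truth(truth, config, np.random.default_rng([config.seed, 4]))
    return measured, GroundTruth(base.subjects, truth, config)


def simulate_head2head(
    base: GroundTruth,
    config: CohortConfig | None = None,
    tracer: str = SECOND_TRACER,
) -> tuple[SbrTable, GroundTruth]:
    """Add a second tracer linked to the reference truth by the per-region
    linear map, paired on (subject, session)."""
    config = config or base.config
    maps = config.tracer_maps.get(tracer)
    if maps is None:
        raise ValueError(f"no true cross-tracer map configured for {tracer!r}")
    ref = base.truth[base.truth["tracer"] == REFERENCE_TRACER]
    if ref.empty:
        raise ValueError("base truth contains no reference-tracer records")
    missing = set(ref["region"].unique()) - set(maps)
    if missing:
        raise ValueError(f"missing cross-tracer map for regions {sorted(missing)}")

    x = ref.copy()
    ab = np.array([maps[r] for r in x["region"]])
    x["true_sbr"] = ab[:, 0] * ref["true_sbr"].to_numpy() + ab[:, 1]
    x["true_cm"] = np.nan  # CM for a mapped tracer is defined via calibration
    x["tracer"] = tracer
    truth = pd.concat([base.truth, x], ignore_index=True).sort_values(
        ["subject", "tracer", "session_years", "region", "side"], kind="stable"
    ).reset_index(drop=True)
    measured = _measured_from_truth(truth, config, np.random.default_rng([config.seed, 5]))
    return measured, GroundTruth(base.subjects, truth, config)


# --------------------------------------------------------------------------
# image tier


@dataclass
class RenderedScan:
    volume: Volume
    subject: str
    tracer: str
    session_years: float
    age: float
    sex: int
    affine: AffineTransform

    @property
    def meta(self) -> dict:
        return {
            "subject": self.subject,
            "tracer": self.tracer,
            "session_years": self.session_years,
            "age": self.age,
            "sex": self.sex,
        }


@dataclass
class RenderResult:
    scans: list[RenderedScan]
    #: noise-free SBR an ideal pipeline would measure on each rendered scan
    #: (exact post-smoothing regional means from the linear forward model)
    image_truth: SbrTable


def _painted_values(
    atlas: RegionAtlas,
    config: CohortConfig,
    session_truth: pd.DataFrame,
    tracer: str,
) -> dict[str, float]:
    """Painted activity per base region for one session of one tracer.

    Subregion specific binding scales with the session's fine-region CM; for
    a mapped tracer the subregion SBR is pushed through the region's linear
    map (non-report subregions use the striatum map as a generic link).
    """
    cm = {
        (r.region, r.side): r.true_cm
        for r in session_truth.itertuples()
        if r.side in ("left", "right")
    }
    vals: dict = {}
    for name, hc_act in DEFAULT_HC_VALUES.items():
        info_sides = (
            ("left", "right")
            if name in _FINE_OF_SUBREGION
            or name in ("accumbens", "globus_pallidus", "ventral_pallidum")
            else (None,)
        )
        for side in info_sides:
            fine = _FINE_OF_SUBREGION.get(name)
            if side is None:
                vals[name] = hc_act
                continue
            frac = cm[(fine, side)] / 100.0 if fine is not None else 1.0
            sbr_ref = (hc_act - 1.0) * frac
            if tracer == REFERENCE_TRACER:
                sbr = sbr_ref
            else:
                maps = config.tracer_maps[tracer]
                a, b = maps.get(fine if fine is not None else "striatum",
                                maps["striatum"])
                sbr = a * sbr_ref + b
            vals[(name, side)] = 1.0 + sbr
    return vals


def _image_truth_sbr(
    atlas: RegionAtlas,
    mean_matrix: np.ndarray,
    codes: np.ndarray,
    counts: np.ndarray,
    painted: Mapping,
) -> dict[tuple[str, str], float]:
    """Exact noise-free SBR per (report region, side) for a painted vector."""
    from .phantom import values_by_code

    vals = values_by_code(atlas, painted)
    v = np.array([vals[c] for c in codes])
    mu = mean_matrix @ v
    code_index = {c: i for i, c in enumerate(codes)}
    wm = atlas.codes_for("cerebral_white_matter")
    wm_idx = [code_index[c] for c in wm]
    ref_mean = float(
        (mu[wm_idx] * counts[wm_idx]).sum() / counts[wm_idx].sum()
    )
    out: dict[tuple[str, str], float] = {}
    for region in REPORT_REGIONS:
        for side in ("left", "right", "bilateral"):
            idx = [code_index[c] for c in atlas.codes_for(region, side)]
            m = float((mu[idx] * counts[idx]).sum() / counts[idx].sum())
            out[(region, side)] = m / ref_mean - 1.0
    return out


def render_images(
    truth: GroundTruth,
    atlas: RegionAtlas,
    config: CohortConfig | None = None,
    tracers: Sequence[str] = (REFERENCE_TRACER,),
    subjects: Sequence[str] | None = None,
    misalign: bool = True,
) -> RenderResult:
    """Render one volume per (subject, session, tracer) through the phantom
    forward model, with per-session random misalignment, and record the exact
    image-tier SBR truth."""
    config = config or truth.config
    mean_matrix, codes, counts = region_mean_matrix(atlas, config.fwhm_mm)
    age_sex = truth.subjects.set_index("subject")[["age", "sex"]]

    sel = truth.truth
    if subjects is not None:
        sel = sel[sel["subject"].isin(list(subjects))]
    sessions = sel[["subject", "session_years"]].drop_duplicates().sort_values(
        ["subject", "session_years"]
    )

    scans: list[RenderedScan] = []
    truth_rows = []
    for k, (_, sess) in enumerate(sessions.iterrows()):
        ref_rows = sel[
            (sel["subject"] == sess.subject)
            & (sel["session_years"] == sess.session_years)
            & (sel["tracer"] == REFERENCE_TRACER)
        ]
        rng = np.random.default_rng([config.seed, 6, k])
        if misalign:
            aff = AffineTransform(
                translation=tuple(rng.uniform(-config.misalign_translation_mm,
                                              config.misalign_translation_mm, 3)),
                rotation=tuple(rng.uniform(-config.misalign_rotation_rad,
                                           config.misalign_rotation_rad, 3)),
                scale=tuple(rng.uniform(1.0 - config.misalign_scale,
                                        1.0 + config.misalign_scale, 3)),
            )
        else:
            aff = AffineTransform.identity()
        for tracer in tracers:
            painted = _painted_values(atlas, config, ref_rows, tracer)
            vol, _ = synthesize_scan(
                atlas,
                painted,
                fwhm_mm=config.fwhm_mm,
                noise_sigma=config.image_noise_sigma,
                affine=aff if misalign else None,
                seed=int(rng.integers(2**31)),
            )
            age = float(age_sex.loc[sess.subject, "age"]) + sess.session_years
            sex = int(age_sex.loc[sess.subject, "sex"])
            scans.append(
                RenderedScan(vol, sess.subject, tracer, float(sess.session_years),
                             age, sex, aff)
            )
            sbr = _image_truth_sbr(atlas, mean_matrix, codes, counts, painted)
            for (region, side), val in sbr.items():
                truth_rows.append(
                    {
                        "subject": sess.subject,
                        "tracer": tracer,
                        "session_years": float(sess.session_years),
                        "age": age,
                        "sex": sex,
                        "region": region,
                        "side": side,
                        "value": val,
                    }
                )
    if not scans:
        raise ValueError("no sessions selected for rendering")
    return RenderResult(scans, SbrTable(pd.DataFrame(truth_rows)))
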