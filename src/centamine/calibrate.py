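"""Three-level cross-tracer calibration onto the Centamine (CM) scale.

The CM scale is region-specific and anchored at two points: CM = 0% is the
absence of specific binding (SBR = 0 for the reference tracer) and CM = 100%
is the mean healthy-control SBR of the reference tracer, mu_HC.

* Level 1 estimates mu_HC per region from a healthy-control cohort of the
  reference tracer, fixing the anchors (0, mu_HC); an individual reference
  scan converts as CM = 100 * SBR / mu_HC.
* Level 2 maps a new tracer X via head-to-head data: per-region ordinary
  least squares SBR_X = a * SBR_ref + b, giving the X anchors
  SBR@CM0 = b and SBR@CM100 = a * mu_HC + b, so that
  CM = 100 * (SBR_X - b) / (a * mu_HC).
* Level 3 maps a further tracer Y against an already-mapped tracer X:
  SBR_Y = a_Y * SBR_X + b_Y, and Y's anchors are X's anchors pushed through
  that line, equivalent to composing the two linear maps onto the
  reference-tracer scale.

An independent lab calibrates its own pipeline by regressing provided CM
values on its own SBR output per region (pipeline calibration).

Repeated paired sessions are treated as independent data points by default
(with an optional one-pair-per-subject mode for sensitivity analyses), pairs
are matched within a 100-day window, and CM values are deliberately not
clipped: values below 0% or above 100% are legal.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .tables import CmTable, SbrTable

__all__ = [
    "REFERENCE_TRACER",
    "RegionAnchor",
    "Level1Anchors",
    "RegionMapping",
    "TracerMapping",
    "PipelineCalibration",
    "CalibrationError",
    "level1_anchors",
    "cm_reference",
    "fit_level2",
    "cm_mapped",
    "fit_level3",
    "calibrate_pipeline",
    "sbr_to_cm",
    "match_pairs",
]

REFERENCE_TRACER = "ioflupane"
DEFAULT_PAIR_WINDOW_YEARS = 100.0 / 365.25


class CalibrationError(ValueError):
    """Raised for degenerate or insufficient calibration inputs."""


@dataclass
class RegionAnchor:
    """Level-1 healthy-control statistics and scale anchors for one region."""

    region: str
    mu_hc: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise CalibrationError(f"{self.region}: need n >= 2 healthy scans")
        if not np.isfinite(self.mu_hc) or self.mu_hc <= 0:
            raise CalibrationError(f"{self.region}: mu_HC must be positive")

    @property
    def sbr_cm0(self) -> float:
        return 0.0

    @property
    def sbr_cm100(self) -> float:
        return self.mu_hc


@dataclass
class Level1Anchors:
    tracer: str
    regions: dict[str, RegionAnchor]

    def __getitem__(self, region: str) -> RegionAnchor:
        try:
            return self.regions[region]
        except KeyError:
            raise CalibrationError(f"no level-1 anchors for region {region!r}")


@dataclass
class RegionMapping:
    """Per-region head-to-head regression and the derived scale anchors."""

    region: str
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    r2: float
    n: int
    sbr_cm0: float
    sbr_cm100: float
    # composition with any upstream mapping, onto the reference-tracer scale
    composite_slope: float
    composite_intercept: float
    valid: bool = True


@dataclass
class TracerMapping:
    tracer: str
    upstream: str  # tracer the head-to-head regression was fitted against
    level: int  # 2 or 3
    regions: dict[str, RegionMapping]

    def __getitem__(self, region: str) -> RegionMapping:
        try:
            return self.regions[region]
        except KeyError:
            raise CalibrationError(f"no mapping for region {region!r}")


@dataclass
class PipelineCalibration:
    """Per-region linear map from a lab's own SBR directly to CM."""

    tracer: str
    level: int
    regions: dict[str, dict]  # region -> slope/intercept/r2/n
    alignment_mean_abs_cm: float


def _ols(x: np.ndarray, y: np.ndarray):
    if len(x) < 3:
        raise CalibrationError(f"need >= 3 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise CalibrationError("degenerate predictor: zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    b, a = model.params  # intercept, slope
    ci = model.conf_int(alpha=0.05)
    return float(a), float(b), (float(ci[1][0]), float(ci[1][1])), (
        float(ci[0][0]),
        float(ci[0][1]),
    ), float(model.rsquared), len(x)


def level1_anchors(hc: SbrTable, side: str = "bilateral") -> Level1Anchors:
    """Define the CM scale from healthy reference-tracer SBRs, per region."""
    tracers = hc.df["tracer"].unique()
    if len(tracers) != 1:
        raise CalibrationError(f"level 1 expects a single tracer, got {list(tracers)}")
    sub = hc.df[hc.df["side"] == side]
    regions: dict[str, RegionAnchor] = {}
    for region, grp in sub.groupby("region"):
        vals = grp["value"].to_numpy()
        if len(vals) < 2:
            raise CalibrationError(f"{region}: need n >= 2 healthy scans")
        regions[region] = RegionAnchor(
            region=str(region),
            mu_hc=float(vals.mean()),
            sd=float(vals.std(ddof=1)),
            n=len(vals),
        )
    if not regions:
        raise CalibrationError("no records for the requested side")
    return Level1Anchors(tracer=str(tracers[0]), regions=regions)


def cm_reference(sbr, anchors: Level1Anchors, region: str):
    """Reference-tracer conversion: CM = 100 * SBR / mu_HC."""
    anchor = anchors[region]
    return 100.0 * np.asarray(sbr, dtype=float) / anchor.mu_hc


def match_pairs(
    pairs: SbrTable,
    tracer_x: str,
    tracer_ref: str,
    side: str = "bilateral",
    window_years: float = DEFAULT_PAIR_WINDOW_YEARS,
    independent_sessions: bool = True,
) -> pd.DataFrame:
    """Match head-to-head sessions of two tracers per (subject, region).

    Each tracer-X record is paired with the closest-in-time reference record
    of the same subject and region within ``window_years``.  With
    ``independent_sessions=False`` only the earliest pair per subject is kept.
    """
    df = pairs.df[pairs.df["side"] == side]
    x = df[df["tracer"] == tracer_x]
    r = df[df["tracer"] == tracer_ref]
    if x.empty or r.empty:
        raise CalibrationError(
            f"head-to-head table must contain both {tracer_x!r} and {tracer_ref!r}"
        )
    merged = x.merge(
        r, on=["subject", "region"], suffixes=("_x", "_ref"), how="inner"
    )
    merged["dt"] = (merged["session_years_x"] - merged["session_years_ref"]).abs()
    merged = merged[merged["dt"] <= window_years]
    if merged.empty:
        raise CalibrationError("no pairs within the matching window")
    merged = (
        merged.sort_values("dt", kind="stable")
        .drop_duplicates(subset=["subject", "region", "session_years_x"], keep="first")
        .sort_index()
    )
    if not independent_sessions:
        merged = (
            merged.sort_values("session_years_x", kind="stable")
            .drop_duplicates(subset=["subject", "region"], keep="first")
        )
    return merged.reset_index(drop=True)


def fit_level2(
    pairs: SbrTable,
    anchors: Level1Anchors,
    tracer_x: str,
    side: str = "bilateral",
    window_years: float = DEFAULT_PAIR_WINDOW_YEARS,
    independent_sessions: bool = True,
) -> TracerMapping:
    """Map tracer X onto the CM scale from head-to-head data with the
    reference tracer: per-region OLS of X SBR on reference SBR."""
    matched = match_pairs(
        pairs, tracer_x, anchors.tracer, side, window_years, independent_sessions
    )
    regions: dict[str, RegionMapping] = {}
    for region, grp in matched.groupby("region"):
        a, b, a_ci, b_ci, r2, n = _ols(
            grp["value_ref"].to_numpy(), grp["value_x"].to_numpy()
        )
        mu = anchors[str(region)].mu_hc
        regions[str(region)] = RegionMapping(
            region=str(region),
            slope=a,
            intercept=b,
            slope_ci=a_ci,
            intercept_ci=b_ci,
            r2=r2,
            n=n,
            sbr_cm0=b,  # a * 0 + b
            sbr_cm100=a * mu + b,
            composite_slope=a,
            composite_intercept=b,
            valid=a > 0,
        )
    return TracerMapping(tracer=tracer_x, upstream=anchors.tracer, level=2,
                         regions=regions)


def cm_mapped(sbr, mapping: TracerMapping, region: str):
    """CM = 100 * (SBR - SBR@CM0) / (SBR@CM100 - SBR@CM0) for a mapped tracer."""
    rm = mapping[region]
    if not rm.valid:
        raise CalibrationError(f"{region}: mapping flagged invalid (slope <= 0)")
    gap = rm.sbr_cm100 - rm.sbr_cm0
    if gap <= 0:
        raise CalibrationError(f"{region}: anchor gap is not positive")
    return 100.0 * (np.asarray(sbr, dtype=float) - rm.sbr_cm0) / gap


def fit_level3(
    pairs_xy: SbrTable,
    mapping_x: TracerMapping,
    tracer_y: str,
    side: str = "bilateral",
    window_years: float = DEFAULT_PAIR_WINDOW_YEARS,
    independent_sessions: bool = True,
) -> TracerMapping:
    """Map tracer Y via head-to-head data with an already-mapped tracer X.

    Y's anchors are X's anchors pushed through the fitted line; the composite
    coefficients chain Y all the way to the reference-tracer scale.
    """
    matched = match_pairs(
        pairs_xy, tracer_y, mapping_x.tracer, side, window_years, independent_sessions
    )
    regions: dict[str, RegionMapping] = {}
    for region, grp in matched.groupby("region"):
        rmx = mapping_x[str(region)]
        if not rmx.valid:
            raise CalibrationError(f"{region}: upstream mapping invalid")
        a, b, a_ci, b_ci, r2, n = _ols(
            grp["value_ref"].to_numpy(), grp["value_x"].to_numpy()
        )
        regions[str(region)] = RegionMapping(
            region=str(region),
            slope=a,
            intercept=b,
            slope_ci=a_ci,
            intercept_ci=b_ci,
            r2=r2,
            n=n,
            sbr_cm0=a * rmx.sbr_cm0 + b,
            sbr_cm100=a * rmx.sbr_cm100 + b,
            composite_slope=a * rmx.composite_slope,
            composite_intercept=a * rmx.composite_intercept + b,
            valid=a > 0 and rmx.valid,
        )
    return TracerMapping(tracer=tracer_y, upstream=mapping_x.tracer, level=3,
                         regions=regions)


def sbr_to_cm(
    table: SbrTable,
    anchors: Level1Anchors,
    mapping: TracerMapping | None = None,
) -> CmTable:
    """Convert an SBR table to CM: reference tracer via the level-1 anchors,
    a mapped tracer via its level-2/3 mapping."""
    df = table.df.copy()
    out = np.empty(len(df))
    for region, grp in df.groupby("region"):
        idx = grp.index
        tracers = grp["tracer"].unique()
        for tracer in tracers:
            sel = idx[grp["tracer"] == tracer]
            vals = df.loc[sel, "value"].to_numpy()
            if tracer == anchors.tracer:
                out[sel] = cm_reference(vals, anchors, str(region))
            elif mapping is not None and tracer == mapping.tracer:
                out[sel] = cm_mapped(vals, mapping, str(region))
            else:
                raise CalibrationError(f"no calibration for tracer {tracer!r}")
    df["value"] = out
    return CmTable(df)


def calibrate_pipeline(
    own_sbr: SbrTable,
    provided_cm: CmTable,
    level: int = 1,
    side: str = "bilateral",
) -> PipelineCalibration:
    """Per-region OLS of provided CM values on a new pipeline's own SBR.

    This is how an independent lab maps its pipeline output directly into CM;
    the alignment report is the mean absolute CM difference after calibration.
    """
    own = own_sbr.df[own_sbr.df["side"] == side]
    prov = provided_cm.df[provided_cm.df["side"] == side]
    tracers = own["tracer"].unique()
    if len(tracers) != 1:
        raise CalibrationError("pipeline calibration expects a single tracer")
    merged = own.merge(
        prov,
        on=["subject", "tracer", "session_years", "region"],
        suffixes=("_own", "_cm"),
    )
    if merged.empty:
        raise CalibrationError("own and provided tables do not join on any record")
    regions: dict[str, dict] = {}
    abs_err = []
    for region, grp in merged.groupby("region"):
        a, b, a_ci, b_ci, r2, n = _ols(
            grp["value_own"].to_numpy(), grp["value_cm"].to_numpy()
        )
        fitted = a * grp["value_own"].to_numpy() + b
        err = np.abs(fitted - grp["value_cm"].to_numpy())
        abs_err.append(err)
        regions[str(region)] = {
            "slope": a,
            "intercept": b,
            "slope_ci": a_ci,
            "intercept_ci": b_ci,
            "r2": r2,
            "n": n,
        }
    return PipelineCalibration(
        tracer=str(tracers[0]),
        level=level,
        regions=regions,
        alignment_mean_abs_cm=float(np.concatenate(abs_err).mean()),
    )
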