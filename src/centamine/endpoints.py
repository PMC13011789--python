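"""Clinical endpoints on the CM scale: age/sex correction (CM*), dopaminergic
deficit classification with cross-tracer concordance, and annualized change.

Age/sex correction fits, on healthy-control CM values per region,

    CM = a_HC * age + b_HC * sex + c_HC        (sex: 0 female, 1 male)

and rescales an individual's CM to the expected value of a 65-year-old,
sex-average (sex = 0.5) person:

    CM* = CM * (a_HC*65 + b_HC*0.5 + c_HC) / (a_HC*age + b_HC*sex + c_HC).

Deficit classification thresholds the lowest-sided putamen CM* at 75%,
using a strict ``<`` at the boundary.  Cross-tracer agreement is summarized
as percent agreement and Cohen's kappa.  Annualized change is the mean of
per-subject OLS slopes of CM against years from baseline, reported both
absolute (CM/yr) and as a percentage of the group mean baseline CM.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .tables import CmTable

__all__ = [
    "AgeSexModel",
    "DeficitLabel",
    "fit_agesex",
    "cm_star",
    "cm_star_table",
    "classify_deficit",
    "classify_table",
    "concordance",
    "annual_change",
]

DEFAULT_DEFICIT_THRESHOLD = 75.0
ANCHOR_AGE = 65.0
ANCHOR_SEX = 0.5


class EndpointError(ValueError):
    pass


@dataclass
class RegionAgeSex:
    region: str
    a_age: float  # CM per year of age
    b_sex: float  # CM offset, male minus female
    c_intercept: float
    n: int
    r2: float

    def expected(self, age, sex):
        return (
            self.a_age * np.asarray(age, dtype=float)
            + self.b_sex * np.asarray(sex, dtype=float)
            + self.c_intercept
        )


@dataclass
class AgeSexModel:
    regions: dict[str, RegionAgeSex]

    def __getitem__(self, region: str) -> RegionAgeSex:
        try:
            return self.regions[region]
        except KeyError:
            raise EndpointError(f"no age/sex model for region {region!r}")


@dataclass
class DeficitLabel:
    subject: str
    tracer: str
    session_years: float
    label: str  # "deficit" | "no-deficit"
    deciding_value: float  # lowest-sided putamen CM*
    threshold: float


def fit_agesex(hc_cm: CmTable, side: str = "bilateral") -> AgeSexModel:
    """Per-region OLS of healthy-control CM on (age, sex)."""
    sub = hc_cm.df[hc_cm.df["side"] == side]
    regions: dict[str, RegionAgeSex] = {}
    for region, grp in sub.groupby("region"):
        if len(grp) < 4:
            raise EndpointError(f"{region}: need n >= 4 for the age/sex fit")
        age = grp["age"].to_numpy(dtype=float)
        sex = grp["sex"].to_numpy(dtype=float)
        if np.ptp(age) == 0:
            raise EndpointError(f"{region}: constant age column")
        if np.ptp(sex) == 0:
            raise EndpointError(f"{region}: single-sex cohort, sex effect unidentifiable")
        design = sm.add_constant(np.column_stack([age, sex]))
        fit = sm.OLS(grp["value"].to_numpy(dtype=float), design).fit()
        c, a, b = fit.params
        regions[str(region)] = RegionAgeSex(
            region=str(region), a_age=float(a), b_sex=float(b),
            c_intercept=float(c), n=len(grp), r2=float(fit.rsquared),
        )
    if not regions:
        raise EndpointError("no records for the requested side")
    return AgeSexModel(regions)


def cm_star(cm, age, sex, model: AgeSexModel, region: str):
    """Age/sex-corrected CM anchored to a 65-year-old, sex-average person."""
    rm = model[region]
    denom = rm.expected(age, sex)
    if np.any(np.asarray(denom) <= 0):
        raise EndpointError(
            f"{region}: expected CM non-positive at (age={age}, sex={sex}); "
            "model extrapolated beyond validity"
        )
    anchor = rm.expected(ANCHOR_AGE, ANCHOR_SEX)
    return np.asarray(cm, dtype=float) * anchor / denom


def cm_star_table(cm: CmTable, model: AgeSexModel) -> CmTable:
    """Apply :func:`cm_star` to every record whose region the model covers."""
    df = cm.df.copy()
    for region, grp in df.groupby("region"):
        df.loc[grp.index, "value"] = cm_star(
            grp["value"].to_numpy(), grp["age"].to_numpy(),
            grp["sex"].to_numpy(), model, str(region),
        )
    return CmTable(df)


def classify_deficit(
    cm_star_left: float,
    cm_star_right: float,
    threshold: float = DEFAULT_DEFICIT_THRESHOLD,
    subject: str = "",
    tracer: str = "",
    session_years: float = 0.0,
) -> DeficitLabel:
    """Deficit iff the lowest-sided putamen CM* is strictly below threshold."""
    for name, v in (("left", cm_star_left), ("right", cm_star_right)):
        if v is None or not np.isfinite(v):
            raise EndpointError(f"missing or non-finite {name} putamen CM*")
    deciding = min(float(cm_star_left), float(cm_star_right))
    label = "deficit" if deciding < threshold else "no-deficit"
    return DeficitLabel(subject, tracer, float(session_years), label,
                        deciding, float(threshold))


def classify_table(
    cm_star_values: CmTable,
    region: str = "putamen",
    threshold: float = DEFAULT_DEFICIT_THRESHOLD,
) -> pd.DataFrame:
    """Classify every (subject, tracer, session) using left/right ``region`` CM*."""
    df = cm_star_values.df
    sub = df[(df["region"] == region) & (df["side"].isin(["left", "right"]))]
    if sub.empty:
        raise EndpointError(f"no sided records for region {region!r}")
    rows = []
    for (subject, tracer, session), grp in sub.groupby(
        ["subject", "tracer", "session_years"]
    ):
        sides = dict(zip(grp["side"], grp["value"]))
        if "left" not in sides or "right" not in sides:
            raise EndpointError(
                f"missing side for {subject}/{tracer} at t={session}"
            )
        lab = classify_deficit(sides["left"], sides["right"], threshold,
                               subject, tracer, session)
        rows.append(
            {
                "subject": subject,
                "tracer": tracer,
                "session_years": session,
                "label": lab.label,
                "deciding_value": lab.deciding_value,
                "threshold": lab.threshold,
            }
        )
    return pd.DataFrame(rows)


def concordance(
    labels_a: pd.DataFrame, labels_b: pd.DataFrame
) -> tuple[float, float]:
    """Percent agreement and Cohen's kappa between two label sets.

    Label frames are joined on (subject, session_years); kappa uses chance
    agreement from the marginal label frequencies.  When both raters are
    constant and identical (p_e = 1), kappa is defined as 1.
    """
    merged = labels_a.merge(
        labels_b, on=["subject", "session_years"], suffixes=("_a", "_b")
    )
    if merged.empty:
        raise EndpointError("label sets share no (subject, session) keys")
    a = merged["label_a"].to_numpy()
    b = merged["label_b"].to_numpy()
    n = len(a)
    p_o = float((a == b).mean())
    cats = np.unique(np.concatenate([a, b]))
    p_e = float(
        sum((a == c).mean() * (b == c).mean() for c in cats)
    )
    if p_e >= 1.0:
        kappa = 1.0 if p_o == 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return 100.0 * p_o, float(kappa)


def annual_change(
    cm_long: CmTable,
    side: str = "bilateral",
    percent_denominator: str = "group_baseline_mean",
) -> pd.DataFrame:
    """Per-region annualized CM change from per-subject OLS slopes.

    Returns a frame with columns region, tracer, mean_slope_cm_per_year,
    percent_per_year, n_subjects.  ``percent_denominator`` selects the
    normalization of the percentage: the group mean baseline CM (default) or
    the mean of per-subject percent slopes ("per_subject").
    """
    df = cm_long.df[cm_long.df["side"] == side]
    rows = []
    for (region, tracer), grp in df.groupby(["region", "tracer"]):
        slopes, baselines, pct_slopes = [], [], []
        for _, subj in grp.groupby("subject"):
            t = subj["session_years"].to_numpy(dtype=float)
            y = subj["value"].to_numpy(dtype=float)
            if len(np.unique(t)) < 2:
                continue
            slope, intercept = np.polyfit(t, y, 1)
            slopes.append(slope)
            base = y[np.argmin(t)]
            baselines.append(base)
            if base != 0:
                pct_slopes.append(100.0 * slope / base)
        if not slopes:
            continue
        mean_slope = float(np.mean(slopes))
        if percent_denominator == "per_subject":
            pct = float(np.mean(pct_slopes)) if pct_slopes else np.nan
        else:
            pct = 100.0 * mean_slope / float(np.mean(baselines))
        rows.append(
            {
                "region": region,
                "tracer": tracer,
                "mean_slope_cm_per_year": mean_slope,
                "percent_per_year": pct,
                "n_subjects": len(slopes),
            }
        )
    if not rows:
        raise EndpointError("no subject has >= 2 timepoints")
    return pd.DataFrame(rows)
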