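"""Treatment-effect estimation for the factorial supplementation trial.

Three pooled contrasts are analysed (small arms make per-arm analysis
underpowered):

* ``vitD_vs_noD`` — everyone randomized to vitamin D vs everyone not;
* ``ca_vs_noCa`` — calcium vs no calcium, 4-arm participants only (the
  2-arm participants were not randomized to calcium);
* ``caD_vs_ca`` — calcium + vitamin D vs calcium alone.

Biomarker values are analysed on the natural-log scale; group summaries are
geometric means.  The core model is a repeated-measures linear mixed model
with a participant random intercept::

    ln(y) ~ visit + group + visit:group (+ covariates)

The visit-by-group interaction is the treatment effect on the log scale:
its exponential is the *relative effect*, (treated follow-up / treated
baseline) / (reference follow-up / reference baseline), read like a ratio
of ratios.  The *absolute effect* is the difference-in-differences of the
four group-by-visit geometric means, in OD units.  On complete data with a
participant random intercept these model-based quantities coincide with the
closed forms computed from the group geometric means.

The module is organised statsmodels-style: :class:`TreatmentEffectModel`
is built from a long participant-visit table and ``fit()`` returns a
:class:`TreatmentEffectResults` with estimates, Wald intervals and a
``summary()`` table; :func:`fit_treatment_model` is the one-call wrapper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = [
    "ContrastSpec",
    "EffectEstimate",
    "GroupVisitSummary",
    "build_contrasts",
    "geometric_mean_ci",
    "relative_effect_from_means",
    "absolute_effect_from_means",
    "TreatmentEffectModel",
    "TreatmentEffectResults",
    "fit_treatment_model",
    "confounder_screen",
    "effects_table",
    "summary_effects_from_group_means",
    "load_reference_group_means",
]


@dataclass(frozen=True)
class ContrastSpec:
    """One pooled treatment comparison and its arm-inclusion rule."""

    name: str
    treated_arms: frozenset[str]
    reference_arms: frozenset[str]
    excluded_arms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.treated_arms & self.reference_arms:
            raise ValueError("treated and reference arm sets overlap")

    def assign(self, arm: pd.Series) -> pd.Series:
        """Map arms to 'treated' / 'reference' / NaN (excluded)."""
        out = pd.Series(np.nan, index=arm.index, dtype=object)
        out[arm.isin(self.treated_arms)] = "treated"
        out[arm.isin(self.reference_arms)] = "reference"
        return out


def build_contrasts() -> dict[str, ContrastSpec]:
    """The trial's three pooled contrasts.

    Intention-to-treat: participants are classified by originally assigned
    arm.  The calcium contrast excludes all 2-arm participants, who received
    calcium without being randomized to it.
    """
    return {
        "vitD_vs_noD": ContrastSpec(
            "vitD_vs_noD",
            treated_arms=frozenset({"D", "CaD", "CaD2arm"}),
            reference_arms=frozenset({"P", "Ca", "Ca2arm"}),
        ),
        "ca_vs_noCa": ContrastSpec(
            "ca_vs_noCa",
            treated_arms=frozenset({"Ca", "CaD"}),
            reference_arms=frozenset({"P", "D"}),
            excluded_arms=frozenset({"Ca2arm", "CaD2arm"}),
        ),
        "caD_vs_ca": ContrastSpec(
            "caD_vs_ca",
            treated_arms=frozenset({"CaD", "CaD2arm"}),
            reference_arms=frozenset({"Ca", "Ca2arm"}),
        ),
    }


@dataclass(frozen=True)
class GroupVisitSummary:
    """Geometric mean and CI of one group at one visit."""

    group: str
    visit: str
    n: int
    geometric_mean: float
    ci_low: float
    ci_high: float


def geometric_mean_ci(values: Sequence[float], level: float = 0.95) -> tuple[int, float, float, float]:
    """Geometric mean with a t-based confidence interval on the log scale.

    Returns ``(n, gm, ci_low, ci_high)``; with a single value the CI is NaN.
    All values must be strictly positive (zeros must be excluded upstream).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    if np.any(v <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    ln = np.log(v)
    n = v.size
    gm = float(np.exp(ln.mean()))
    if n < 2:
        return n, gm, float("nan"), float("nan")
    se = ln.std(ddof=1) / np.sqrt(n)
    tq = stats.t.ppf(0.5 + level / 2, n - 1)
    return n, gm, float(np.exp(ln.mean() - tq * se)), float(np.exp(ln.mean() + tq * se))


def relative_effect_from_means(
    treated_base: float, treated_follow: float, ref_base: float, ref_follow: float
) -> float:
    """Ratio-of-ratios relative effect from four group geometric means.

    ``(treated_follow / treated_base) / (ref_follow / ref_base)``; a value of
    1.2 means the biomarker increased 20% more in the treated group than in
    the reference group.
    """
    vals = (treated_base, treated_follow, ref_base, ref_follow)
    if any(v <= 0 for v in vals):
        raise ValueError("relative effect requires positive group means")
    return (treated_follow / treated_base) / (ref_follow / ref_base)


def absolute_effect_from_means(
    treated_base: float, treated_follow: float, ref_base: float, ref_follow: float
) -> float:
    """Difference-in-differences absolute effect, in the outcome's OD units."""
    return (treated_follow - treated_base) - (ref_follow - ref_base)


@dataclass(frozen=True)
class EffectEstimate:
    """Treatment effect for one variable × zone × contrast."""

    variable: str
    zone: str
    contrast: str
    relative_effect: float
    ci_low: float
    ci_high: float
    p_value: float
    absolute_effect: float
    n_by_group_visit: Mapping[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.relative_effect <= 0:
            raise ValueError("relative_effect must be positive")
        if not (self.ci_low <= self.relative_effect <= self.ci_high):
            raise ValueError("CI does not bracket the relative effect")


class TreatmentEffectModel:
    """Repeated-measures mixed model for one biomarker variable and zone.

    Parameters
    ----------
    data
        Long participant-visit table with columns ``participant_id, arm,
        visit, variable, zone, value`` plus any covariate columns.  ``visit``
        is ``baseline`` / ``year1``; values must be positive (nonpositive
        rows are dropped with a count kept in ``n_dropped_nonpositive``).
    contrast
        The pooled comparison to estimate.
    variable, zone
        Which rows of ``data`` to analyse.
    covariates
        Covariate column names entered as fixed effects (e.g.
        ``["total_energy_kcal"]``).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        contrast: ContrastSpec,
        variable: str,
        zone: str = "whole",
        covariates: Sequence[str] = (),
    ) -> None:
        self.contrast = contrast
        self.variable = variable
        self.zone = zone
        self.covariates = list(covariates)

        d = data[(data["variable"] == variable) & (data["zone"] == zone)].copy()
        if d.empty:
            raise ValueError(f"no rows for variable={variable!r}, zone={zone!r}")
        d["group"] = contrast.assign(d["arm"])
        d = d[d["group"].notna()]
        d = d[d["value"].notna()]
        self.n_dropped_nonpositive = int((d["value"] <= 0).sum())
        d = d[d["value"] > 0]
        d["log_value"] = np.log(d["value"].astype(float))
        d["is_follow"] = (d["visit"] == "year1").astype(int)
        d["is_treated"] = (d["group"] == "treated").astype(int)
        # covariates enter z-scored: invariant for the interaction term,
        # and keeps the normal equations well conditioned for kcal-scale
        # columns
        for cov in self.covariates:
            col = d[cov].astype(float)
            sd = col.std(ddof=0)
            d[f"_z_{cov}"] = (col - col.mean()) / (sd if sd > 0 else 1.0)
        for g in ("treated", "reference"):
            if (d["group"] == g).sum() < 2:
                raise ValueError(
                    f"contrast {contrast.name!r}, {variable}/{zone}: "
                    f"fewer than 2 rows in the {g} stratum"
                )
        self.data = d.reset_index(drop=True)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        contrast: ContrastSpec,
        variable: str,
        zone: str = "whole",
        covariates: Sequence[str] = (),
    ) -> "TreatmentEffectModel":
        return cls(data, contrast, variable, zone, covariates)

    def group_visit_summaries(self, level: float = 0.95) -> list[GroupVisitSummary]:
        out = []
        for (group, visit), grp in self.data.groupby(["group", "visit"], sort=True):
            n, gm, lo, hi = geometric_mean_ci(grp["value"], level)
            out.append(GroupVisitSummary(group, visit, n, gm, lo, hi))
        return out

    def fit(self, reml: bool = True, level: float = 0.95) -> "TreatmentEffectResults":
        """Fit the mixed model and return the results object.

        Fixed effects: visit, group, visit×group and any covariates; random
        intercept per participant; Wald z interval ``exp(b ± z·SE)`` on the
        interaction and a two-sided Wald p-value.
        """
        formula = "log_value ~ is_follow * is_treated"
        for cov in self.covariates:
            formula += f" + Q('_z_{cov}')"
        model = smf.mixedlm(formula, self.data, groups=self.data["participant_id"])
        fit = None
        last_exc: Exception | None = None
        # lbfgs is fastest but can step through a singular point when the
        # random-intercept variance sits on the boundary; fall back then
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # boundary variances are expected
                    fit = model.fit(reml=reml, method=[method])
                break
            except np.linalg.LinAlgError as exc:
                last_exc = exc
        if fit is None:
            raise ValueError(
                f"singular mixed-model fit for contrast {self.contrast.name!r}, "
                f"{self.variable}/{self.zone}: {last_exc}"
            ) from last_exc
        term = "is_follow:is_treated"
        beta = float(fit.params[term])
        se = float(fit.bse[term])
        z = stats.norm.ppf(0.5 + level / 2)
        p = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else 0.0

        summaries = {(s.group, s.visit): s for s in self.group_visit_summaries(level)}
        try:
            gm = {k: s.geometric_mean for k, s in summaries.items()}
            abs_eff = absolute_effect_from_means(
                gm[("treated", "baseline")], gm[("treated", "year1")],
                gm[("reference", "baseline")], gm[("reference", "year1")],
            )
        except KeyError as exc:
            raise ValueError(
                f"contrast {self.contrast.name!r}: empty group-visit stratum {exc}"
            ) from None
        estimate = EffectEstimate(
            variable=self.variable,
            zone=self.zone,
            contrast=self.contrast.name,
            relative_effect=float(np.exp(beta)),
            ci_low=float(np.exp(beta - z * se)),
            ci_high=float(np.exp(beta + z * se)),
            p_value=p,
            absolute_effect=abs_eff,
            n_by_group_visit={k: s.n for k, s in summaries.items()},
        )
        return TreatmentEffectResults(self, fit, estimate, list(summaries.values()), level)


class TreatmentEffectResults:
    """Fitted treatment-effect results for one variable × zone × contrast.

    Attributes
    ----------
    estimate : EffectEstimate
        Relative effect (exp of the visit×group interaction), its Wald CI
        and p-value, and the difference-in-differences absolute effect.
    mixedlm : statsmodels MixedLMResults
        The underlying fit, for diagnostics.
    """

    def __init__(self, model, mixedlm, estimate, group_summaries, level):
        self.model = model
        self.mixedlm = mixedlm
        self.estimate = estimate
        self.group_summaries = group_summaries
        self.level = level

    @property
    def relative_effect(self) -> float:
        return self.estimate.relative_effect

    @property
    def absolute_effect(self) -> float:
        return self.estimate.absolute_effect

    @property
    def p_value(self) -> float:
        return self.estimate.p_value

    def conf_int(self) -> tuple[float, float]:
        return (self.estimate.ci_low, self.estimate.ci_high)

    def summary(self) -> pd.DataFrame:
        """Publication-style summary: group geometric means and the effect."""
        rows = []
        for s in sorted(self.group_summaries, key=lambda s: (s.group != "reference", s.visit)):
            rows.append(
                {
                    "variable": self.estimate.variable,
                    "zone": self.estimate.zone,
                    "contrast": self.estimate.contrast,
                    "group": s.group,
                    "visit": s.visit,
                    "n": s.n,
                    "geometric_mean": s.geometric_mean,
                    "gm_ci_low": s.ci_low,
                    "gm_ci_high": s.ci_high,
                    "relative_effect": self.estimate.relative_effect,
                    "rel_ci_low": self.estimate.ci_low,
                    "rel_ci_high": self.estimate.ci_high,
                    "p_value": self.estimate.p_value,
                    "absolute_effect": self.estimate.absolute_effect,
                }
            )
        return pd.DataFrame(rows)

    def __repr__(self) -> str:
        e = self.estimate
        return (
            f"<TreatmentEffectResults {e.variable}/{e.zone} {e.contrast}: "
            f"relative {e.relative_effect:.2f} "
            f"({e.ci_low:.2f}, {e.ci_high:.2f}), p={e.p_value:.2f}, "
            f"abs {e.absolute_effect:.1f}>"
        )


def fit_treatment_model(
    records: pd.DataFrame,
    contrast: ContrastSpec,
    variable: str,
    zone: str = "whole",
    covariates: Sequence[str] = (),
) -> EffectEstimate:
    """One-call wrapper: build the model, fit it, return the estimate."""
    return TreatmentEffectModel(records, contrast, variable, zone, covariates).fit().estimate


def confounder_screen(
    records: pd.DataFrame,
    contrast: ContrastSpec,
    variable: str,
    zone: str = "whole",
    candidates: Sequence[str] = (),
    threshold: float = 0.10,
) -> tuple[list[str], pd.DataFrame]:
    """Change-in-estimate confounder screen.

    Refits the mixed model adding each candidate covariate (and the full
    candidate set) and records the proportional change in the relative
    effect versus the base model.  Candidates whose individual inclusion
    changes the relative effect by at least ``threshold`` (default 10%) are
    retained.  Constant covariates are skipped with a warning.

    Returns ``(retained, change_log)`` where ``change_log`` has one row per
    candidate plus an ``<all>`` row.
    """
    base = fit_treatment_model(records, contrast, variable, zone)
    usable = []
    for cov in candidates:
        if cov not in records.columns:
            raise ValueError(f"candidate covariate {cov!r} not in records")
        sub = records[(records["variable"] == variable) & (records["zone"] == zone)]
        if sub[cov].nunique(dropna=True) < 2:
            warnings.warn(f"covariate {cov!r} has no variance; skipped")
            continue
        usable.append(cov)

    rows, retained = [], []
    for label, covs in [(c, [c]) for c in usable] + ([("<all>", usable)] if len(usable) > 1 else []):
        est = fit_treatment_model(records, contrast, variable, zone, covariates=covs)
        change = abs(est.relative_effect / base.relative_effect - 1.0)
        rows.append(
            {
                "covariate": label,
                "relative_effect_unadjusted": base.relative_effect,
                "relative_effect_adjusted": est.relative_effect,
                "proportional_change": change,
                "retained": label != "<all>" and change >= threshold,
            }
        )
        if label != "<all>" and change >= threshold:
            retained.append(label)
    return retained, pd.DataFrame(rows)


def effects_table(
    records: pd.DataFrame,
    contrasts: Mapping[str, ContrastSpec] | None = None,
    variables: Sequence[str] | None = None,
    zones: Sequence[str] | None = None,
    covariates: Sequence[str] = (),
    min_stratum_n: int = 3,
) -> pd.DataFrame:
    """Estimate every variable × zone × contrast and stack the summaries.

    Combinations that cannot be fit (empty strata) are skipped with a
    warning naming the contrast and stratum.
    """
    contrasts = contrasts or build_contrasts()
    variables = variables or sorted(records["variable"].unique())
    zones = zones or [z for z in ("whole", "upper40", "lower60", "phi_h") if z in set(records["zone"])]
    frames = []
    for variable in variables:
        for zone in zones:
            if records[(records["variable"] == variable) & (records["zone"] == zone)].empty:
                continue
            for contrast in contrasts.values():
                try:
                    res = TreatmentEffectModel(
                        records, contrast, variable, zone, covariates
                    ).fit()
                except ValueError as exc:
                    warnings.warn(str(exc))
                    continue
                if any(s.n < min_stratum_n for s in res.group_summaries):
                    warnings.warn(
                        f"{contrast.name} {variable}/{zone}: a stratum has n < {min_stratum_n}"
                    )
                frames.append(res.summary())
    if not frames:
        raise ValueError("no estimable variable × zone × contrast combinations")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# summary mode: closed-form effects from published group geometric means
# ---------------------------------------------------------------------------

def summary_effects_from_group_means(table: pd.DataFrame) -> pd.DataFrame:
    """Closed-form relative and absolute effects from group-level means.

    ``table`` must have one row per variable × zone × contrast × role with
    columns ``variable, zone, contrast, role ('treated'/'reference'),
    gm_baseline, gm_followup`` (extra columns pass through).  Used both for
    externally published summary tables and for this package's own grouped
    output.
    """
    required = {"variable", "zone", "contrast", "role", "gm_baseline", "gm_followup"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    rows = []
    for (variable, zone, contrast), grp in table.groupby(
        ["variable", "zone", "contrast"], sort=True
    ):
        roles = grp.set_index("role")
        if not {"treated", "reference"} <= set(roles.index):
            raise ValueError(
                f"{variable}/{zone}/{contrast}: need both treated and reference rows"
            )
        tb = float(roles.loc["treated", "gm_baseline"])
        tf = float(roles.loc["treated", "gm_followup"])
        rb = float(roles.loc["reference", "gm_baseline"])
        rf = float(roles.loc["reference", "gm_followup"])
        rows.append(
            {
                "variable": variable,
                "zone": zone,
                "contrast": contrast,
                "relative_effect": relative_effect_from_means(tb, tf, rb, rf),
                "absolute_effect": absolute_effect_from_means(tb, tf, rb, rf),
            }
        )
    return pd.DataFrame(rows)


def load_reference_group_means() -> pd.DataFrame:
    """Published group-level geometric means of the source trial.

    One row per variable × zone × contrast × role with baseline and 1-year
    follow-up geometric means, group sizes, and the reported relative and
    absolute effects; shipped as package data and used as the fixture for
    closed-form effect reproduction.
    """
    from importlib.resources import files

    path = files("cryptscore.data").joinpath("reference_group_means.csv")
    with path.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, comment="#")
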