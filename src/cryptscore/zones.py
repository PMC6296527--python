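"""Crypt-zone reduction, participant aggregation and scoring reliability.

A 50-segment hemicrypt profile is reduced to the crypt functional zones:
the whole crypt, the upper 40% (canonical differentiation zone, segments
31–50 counting from the base), the lower 60% (canonical proliferation zone,
segments 1–30), and ``phi_h``, the upper-40%-to-whole ratio.  Hemicrypts are
averaged arithmetically to one record per participant-visit; the natural-log
transform used downstream is applied only at the participant level, so group
summaries are geometric means.  Marker ratios (bax/bcl-2, bax/mib-1,
p21/mib-1) are computed per participant-visit, zone by zone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .imaging import SegmentProfile

__all__ = [
    "ZoneSummary",
    "zone_summary",
    "aggregate_participant",
    "marker_ratio",
    "icc_rescoring",
    "aggregate_table",
    "ratio_table",
    "RATIO_DEFS",
    "ZONES",
]

logger = logging.getLogger(__name__)

ZONES = ("whole", "upper40", "lower60")

#: ratio variables: name -> (numerator marker, denominator marker)
RATIO_DEFS: dict[str, tuple[str, str]] = {
    "bax_bcl2": ("bax", "bcl2"),
    "bax_mib1": ("bax", "mib1"),
    "p21_mib1": ("p21", "mib1"),
}


@dataclass(frozen=True)
class ZoneSummary:
    """Zone-level integrated OD for one marker at one participant-visit.

    ``phi_h`` is ``upper40 / whole`` and is NaN when the whole-crypt OD is
    zero (no labeling at all).
    """

    whole: float
    upper40: float
    lower60: float

    def __post_init__(self) -> None:
        if min(self.whole, self.upper40, self.lower60) < 0:
            raise ValueError("zone OD values must be nonnegative")
        if not np.isclose(self.whole, self.upper40 + self.lower60, rtol=1e-9, atol=1e-9):
            raise ValueError("whole must equal upper40 + lower60")

    @property
    def phi_h(self) -> float:
        if self.whole == 0:
            return float("nan")
        return self.upper40 / self.whole

    def as_dict(self) -> dict[str, float]:
        return {
            "whole": self.whole,
            "upper40": self.upper40,
            "lower60": self.lower60,
            "phi_h": self.phi_h,
        }


def zone_summary(profile: SegmentProfile, upper_fraction: float = 0.4) -> ZoneSummary:
    """Reduce a segment profile to whole / upper / lower zone totals.

    With 50 segments and ``upper_fraction = 0.4`` the upper zone is segments
    31–50 (the luminal differentiation zone) and the lower zone segments
    1–30.  ``n_segments * upper_fraction`` must be an integer so the split
    falls on a segment boundary.
    """
    n = profile.n_segments
    n_upper = upper_fraction * n
    if abs(n_upper - round(n_upper)) > 1e-9:
        raise ValueError(
            f"upper_fraction={upper_fraction} does not split {n} segments on a boundary"
        )
    split = n - int(round(n_upper))
    seg = profile.od_segments
    upper = float(seg[split:].sum())
    lower = float(seg[:split].sum())
    return ZoneSummary(whole=upper + lower, upper40=upper, lower60=lower)


def aggregate_participant(summaries: Sequence[ZoneSummary] | Iterable[ZoneSummary]) -> ZoneSummary:
    """Arithmetic mean of zone values over a participant-visit's hemicrypts.

    ``phi_h`` of the aggregate is recomputed from the aggregated upper40 and
    whole (a ratio of means, not a mean of ratios).
    """
    items = [
        zone_summary(s) if isinstance(s, SegmentProfile) else s for s in summaries
    ]
    if not items:
        raise ValueError("cannot aggregate an empty list of hemicrypt summaries")
    upper = float(np.mean([z.upper40 for z in items]))
    lower = float(np.mean([z.lower60 for z in items]))
    return ZoneSummary(whole=upper + lower, upper40=upper, lower60=lower)


def marker_ratio(numerator: ZoneSummary, denominator: ZoneSummary) -> dict[str, float]:
    """Elementwise per-zone ratio of two markers at one participant-visit.

    Returns ``{zone: ratio}`` over whole / upper40 / lower60; a zone with a
    zero denominator yields NaN with a logged warning rather than raising.
    """
    out: dict[str, float] = {}
    num, den = numerator.as_dict(), denominator.as_dict()
    for zone in ZONES:
        if den[zone] == 0:
            logger.warning("zero denominator OD in zone %r; ratio set to NaN", zone)
            out[zone] = float("nan")
        else:
            out[zone] = num[zone] / den[zone]
    return out


def icc_rescoring(original: Sequence[float], rescored: Sequence[float]) -> float:
    """Scoring-reliability intraclass correlation, ICC(3,1).

    Two-way mixed-effects, consistency, single-measurement form: hemicrypts
    are random rows, the two scoring passes fixed columns.  A systematic
    shift between passes does not reduce this ICC; only hemicrypt-by-pass
    disagreement does.
    """
    a = np.asarray(original, dtype=float)
    b = np.asarray(rescored, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("original and rescored must be equal-length 1-D vectors")
    n = a.size
    if n < 3:
        raise ValueError("at least 3 hemicrypt pairs are required")
    # perfect consistency (equal up to a constant shift): ICC is 1 by
    # definition; the ANOVA ratio would only return it up to roundoff
    if np.allclose(a - a.mean(), b - b.mean(), rtol=0.0, atol=1e-12 * max(1.0, np.abs(a).max())):
        return 1.0
    import pingouin as pg

    df = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["pass1", "pass2"], n),
            "score": np.concatenate([a, b]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pingouin warns on zero residual variance
        res = pg.intraclass_corr(df, targets="target", raters="rater", ratings="score")
    sel = res[res["Type"].isin(["ICC3", "ICC(C,1)"])]  # label differs across pingouin versions
    return float(sel["ICC"].iloc[0])


# ---------------------------------------------------------------------------
# table-level pipeline
# ---------------------------------------------------------------------------

def aggregate_table(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    upper_fraction: float = 0.4,
) -> pd.DataFrame:
    """Hemicrypt score table + participant metadata -> participant-visit table.

    Parameters
    ----------
    scores
        Long table with columns ``hemicrypt_id, marker_id, segment_index,
        od`` (segment_index 1..n plus the literal ``"whole"``), as written by
        the scoring CLI.
    metadata
        One row per hemicrypt: ``hemicrypt_id, participant_id, visit, arm,
        randomization`` plus any covariate columns (e.g.
        ``total_energy_kcal``).

    Returns
    -------
    Long participant-visit table with columns ``participant_id, visit, arm,
    randomization, variable, zone, value`` plus covariates; marker rows are
    followed by the per-participant marker-ratio rows of :data:`RATIO_DEFS`.
    """
    seg = scores[scores["segment_index"].astype(str) != "whole"].copy()
    seg["segment_index"] = seg["segment_index"].astype(int)

    records = []
    for (hid, marker), grp in seg.groupby(["hemicrypt_id", "marker_id"], sort=True):
        grp = grp.sort_values("segment_index")
        profile = SegmentProfile(
            hemicrypt_id=str(hid), marker_id=str(marker),
            od_segments=grp["od"].to_numpy(),
        )
        z = zone_summary(profile, upper_fraction)
        records.append({"hemicrypt_id": hid, "marker_id": marker, "summary": z})
    hemi = pd.DataFrame.from_records(records)
    if hemi.empty:
        raise ValueError("no hemicrypt segment rows to aggregate")

    meta_cols = [c for c in metadata.columns if c != "hemicrypt_id"]
    merged = hemi.merge(metadata, on="hemicrypt_id", how="left", validate="many_to_one")
    if merged["participant_id"].isna().any():
        missing = merged.loc[merged["participant_id"].isna(), "hemicrypt_id"].tolist()
        raise ValueError(f"hemicrypts without metadata: {missing[:5]}")

    covar_cols = [
        c for c in meta_cols
        if c not in ("participant_id", "visit", "arm", "randomization")
    ]
    rows = []
    keys = ["participant_id", "visit", "arm", "randomization"]
    for key, grp in merged.groupby(keys, sort=True):
        covars = {c: grp[c].iloc[0] for c in covar_cols}
        per_marker: dict[str, ZoneSummary] = {}
        for marker, mgrp in grp.groupby("marker_id", sort=True):
            per_marker[marker] = aggregate_participant(list(mgrp["summary"]))
        for marker, z in per_marker.items():
            for zone, value in z.as_dict().items():
                rows.append(dict(zip(keys, key)) | covars | {
                    "variable": marker, "zone": zone, "value": value,
                })
        for ratio_name, (num, den) in RATIO_DEFS.items():
            if num in per_marker and den in per_marker:
                ratios = marker_ratio(per_marker[num], per_marker[den])
                for zone, value in ratios.items():
                    rows.append(dict(zip(keys, key)) | covars | {
                        "variable": ratio_name, "zone": zone, "value": value,
                    })
    return pd.DataFrame(rows)


def ratio_table(records: pd.DataFrame) -> pd.DataFrame:
    """Append per-participant marker-ratio rows to a long marker table.

    ``records`` must have columns ``participant_id, visit, variable, zone,
    value`` (plus any id/covariate columns, carried through).  For each ratio
    in :data:`RATIO_DEFS` whose numerator and denominator are present at a
    participant-visit-zone, one ratio row is added.
    """
    id_cols = [c for c in records.columns if c not in ("variable", "value")]
    wide = records.pivot_table(
        index=id_cols, columns="variable", values="value", aggfunc="first"
    )
    out = [records]
    for name, (num, den) in RATIO_DEFS.items():
        if num not in wide.columns or den not in wide.columns:
            continue
        den_vals = wide[den]
        if (den_vals == 0).any():
            logger.warning(
                "%d zero denominators for ratio %s; set to NaN", int((den_vals == 0).sum()), name
            )
        ratio = wide[num] / den_vals.replace(0, np.nan)
        block = ratio.rename("value").reset_index()
        block["variable"] = name
        out.append(block[records.columns])
    return pd.concat(out, ignore_index=True)
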