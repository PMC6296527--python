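"""Synthetic crypt images and synthetic trial tables with known ground truth.

Two generators make every downstream stage testable without real slides:

* :func:`simulate_crypt_image` renders a single hemicrypt — an elongated,
  axis-aligned rounded rectangle with its base at the image bottom — with a
  planted axial optical-density profile, and returns the transmitted-light
  image, the traced outline, and the exact per-segment ground truth.
* :func:`simulate_trial` emulates the participant-level measurement table of
  a 2×2 factorial calcium / vitamin D supplementation trial with a women-only
  vitamin-D-on-background-calcium sub-randomization: six arms, two visits,
  lognormal biomarker values, a participant random intercept, a placebo
  drift, and multiplicative treatment effects at follow-up.

Hemicrypt-to-hemicrypt variability in the trial generator is collapsed into
a residual attenuated by ``1/sqrt(hemicrypts_per_visit)``; hemicrypt-level
realism is the image generator's job.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .imaging import HemicryptOutline, SegmentProfile, segment_index

__all__ = [
    "ARMS",
    "FOUR_ARM",
    "TWO_ARM",
    "STUDY_ARM_SIZES",
    "CryptSimParams",
    "TrialSimParams",
    "simulate_crypt_image",
    "simulate_trial",
]

#: treatment arms: full-factorial (4-arm) placebo / calcium / vitamin D /
#: both, plus the 2-arm sub-randomization in which every participant received
#: calcium and was randomized to vitamin D or not.
FOUR_ARM = ("P", "Ca", "D", "CaD")
TWO_ARM = ("Ca2arm", "CaD2arm")
ARMS = FOUR_ARM + TWO_ARM

#: arm sizes of the source trial's biomarker subsample (n = 104).
STUDY_ARM_SIZES: dict[str, int] = {
    "P": 12, "Ca": 16, "D": 17, "CaD": 17, "Ca2arm": 23, "CaD2arm": 19,
}

_PROFILE_KINDS = ("basal_gradient", "apical_gradient", "uniform")


@dataclass(frozen=True)
class CryptSimParams:
    """Parameters of one synthetic hemicrypt image.

    ``profile_kind`` shapes the planted axial OD density: ``basal_gradient``
    (signal concentrated toward the crypt base, mib-1-like),
    ``apical_gradient`` (toward the lumen, p21-like) or ``uniform``.
    ``total_od`` is the planted integrated OD of the whole hemicrypt.
    """

    image_height_px: int = 360
    image_width_px: int = 120
    crypt_length_px: int = 300
    crypt_width_px: int = 60
    profile_kind: str = "uniform"
    total_od: float = 100.0
    background_intensity: float = 200.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile_kind not in _PROFILE_KINDS:
            raise ValueError(f"profile_kind must be one of {_PROFILE_KINDS}")
        for name in ("image_height_px", "image_width_px", "crypt_length_px", "crypt_width_px"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.total_od < 0:
            raise ValueError("total_od must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.background_intensity <= 0:
            raise ValueError("background_intensity must be positive")
        if self.crypt_length_px + 2 * _MARGIN > self.image_height_px or (
            self.crypt_width_px + 2 * _MARGIN > self.image_width_px
        ):
            raise ValueError("crypt does not fit inside the image (2 px margin required)")


_MARGIN = 2  # blank border around the crypt, px


def _segment_weight_integrals(kind: str, n_segments: int) -> np.ndarray:
    """Integral of the axial OD density over each segment's t-interval.

    Densities on t in [0, 1]: uniform w(t) = 1; basal_gradient w(t) = 2(1-t);
    apical_gradient w(t) = 2t.  All integrate to 1 over [0, 1], so the
    returned weights sum to 1 and give each segment's share of the planted
    total OD (exactly T/n per segment in the uniform case).
    """
    edges = np.linspace(0.0, 1.0, n_segments + 1)
    a, b = edges[:-1], edges[1:]
    if kind == "uniform":
        return b - a
    if kind == "basal_gradient":
        return (b - a) * (2.0 - a - b)
    return (b - a) * (a + b)  # apical_gradient


def _crypt_outline(params: CryptSimParams) -> HemicryptOutline:
    H, W = params.image_height_px, params.image_width_px
    L, w = params.crypt_length_px, params.crypt_width_px
    r_bot = H - 1 - _MARGIN          # basal pixel row (image bottom side)
    r_top = r_bot - (L - 1)          # apical pixel row
    c0 = (W - w) // 2
    xl, xr = c0 - 0.5, c0 + w - 0.5
    yb, yt = r_bot + 0.5, r_top - 0.5
    ch = min(w // 4, L // 4, 8)      # chamfer of the luminal corners
    verts = (
        (xl, yb), (xr, yb),               # basal edge
        (xr, yt + ch), (xr - ch, yt),     # right border + corner
        (xl + ch, yt), (xl, yt + ch),     # apical edge end + left corner
    )
    return HemicryptOutline(
        vertices=verts, base_range=(0, 1), apex_range=(3, 4),
        hemicrypt_id=f"sim-{params.seed}", marker_id="other",
    )


def simulate_crypt_image(
    params: CryptSimParams, n_segments: int = 50
) -> tuple[np.ndarray, HemicryptOutline, SegmentProfile]:
    """Render a synthetic hemicrypt with planted per-segment ground truth.

    Each axial segment receives the analytic integral of the
    ``profile_kind`` density over its t-interval times ``total_od`` (so the
    uniform profile plants exactly ``total_od / n_segments`` per segment and
    the planted pixel ODs always sum to ``total_od``), spread evenly over
    the segment's pixels; the transmitted-light image is
    ``background_intensity * 10**(-od_px)`` plus optional Gaussian noise,
    clipped to ``[0, background_intensity]``.  The returned ground-truth
    profile is the sum of planted pixel OD within each of the ``n_segments``
    equal axial bins (segment 1 at the base).

    Returns
    -------
    image : float64 array of shape ``(image_height_px, image_width_px)``
    outline : HemicryptOutline enclosing exactly the planted crypt
    truth : SegmentProfile of the planted per-segment integrated OD
    """
    outline = _crypt_outline(params)
    shape = (params.image_height_px, params.image_width_px)
    mask = outline.raster_mask(shape)
    rows, cols = np.nonzero(mask)

    yb = max(y for _, y in outline.vertices)          # basal edge y
    yt = min(y for _, y in outline.vertices)          # apical edge y
    t = (yb - rows.astype(float)) / (yb - yt)
    t = np.clip(t, 0.0, np.nextafter(1.0, 0.0))

    seg_idx = segment_index(t, n_segments)
    counts = np.bincount(seg_idx, minlength=n_segments)
    if np.any(counts == 0):
        raise ValueError("crypt too short: an axial segment contains no pixels")
    truth = params.total_od * _segment_weight_integrals(params.profile_kind, n_segments)
    # spread each segment's share evenly over its pixels
    od_px = truth[seg_idx] / counts[seg_idx]

    image = np.full(shape, params.background_intensity, dtype=float)
    image[rows, cols] = params.background_intensity * np.power(10.0, -od_px)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        image = image + rng.normal(0.0, params.noise_sd, shape)
        image = np.clip(image, 0.0, params.background_intensity)

    profile = SegmentProfile(
        hemicrypt_id=outline.hemicrypt_id,
        marker_id=outline.marker_id,
        od_segments=truth,
    )
    return image, outline, profile


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

#: illustrative baseline geometric means (log scale) by marker × zone, on the
#: OD scale of the source trial's published group summaries.
_DEFAULT_BASELINE_LOG_MEAN: dict[tuple[str, str], float] = {
    ("mib1", "whole"): math.log(1150.0),
    ("mib1", "upper40"): math.log(47.0),
    ("mib1", "lower60"): math.log(1100.0),
    ("p21", "whole"): math.log(590.0),
    ("p21", "upper40"): math.log(310.0),
    ("p21", "lower60"): math.log(280.0),
    ("bax", "whole"): math.log(285.0),
    ("bax", "upper40"): math.log(60.0),
    ("bax", "lower60"): math.log(225.0),
    ("bcl2", "whole"): math.log(690.0),
    ("bcl2", "upper40"): math.log(140.0),
    ("bcl2", "lower60"): math.log(550.0),
}


@dataclass(frozen=True)
class TrialSimParams:
    """Parameters of a synthetic two-visit, six-arm biomarker trial.

    Log-scale value model for participant ``i`` in arm ``a`` at visit ``v``::

        ln y = mu[marker, zone] + b_i + 1{v = year1} * (ln drift + ln effect_a)
               + e_iv,   b_i ~ N(0, between_participant_sd²),
                         e_iv ~ N(0, within_participant_sd² / m)

    with ``m = hemicrypts_per_visit`` (the residual is the mean of that many
    hemicrypt scores).  ``true_relative_effect[a]`` is the multiplicative
    change at follow-up in arm ``a`` beyond the placebo drift; arms absent
    from the map have effect 1.  Defaults are the source trial's arm sizes
    and illustrative variance components (the trial did not publish variance
    components).
    """

    n_per_arm: Mapping[str, int] = field(default_factory=lambda: dict(STUDY_ARM_SIZES))
    baseline_log_mean: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_BASELINE_LOG_MEAN)
    )
    between_participant_sd: float = 0.35
    within_participant_sd: float = 1.1
    true_relative_effect: Mapping[str, float] = field(default_factory=dict)
    placebo_drift: float = 1.05
    hemicrypts_per_visit: int = 32
    energy_mean_kcal: float = 1500.0
    energy_sd_kcal: float = 450.0
    energy_arm_shift: Mapping[str, float] = field(default_factory=dict)
    energy_outcome_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for arm, n in self.n_per_arm.items():
            if arm not in ARMS:
                raise ValueError(f"unknown arm {arm!r}")
            if n < 1:
                raise ValueError("n_per_arm values must be positive")
        if self.between_participant_sd < 0 or self.within_participant_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        for arm, eff in self.true_relative_effect.items():
            if arm not in ARMS:
                raise ValueError(f"unknown arm {arm!r} in true_relative_effect")
            if eff <= 0:
                raise ValueError("relative effects must be positive")
        if self.placebo_drift <= 0:
            raise ValueError("placebo_drift must be positive")
        if self.hemicrypts_per_visit < 1:
            raise ValueError("hemicrypts_per_visit must be positive")


def simulate_trial(params: TrialSimParams) -> pd.DataFrame:
    """Simulate a participant-visit biomarker table.

    Returns a long table with one row per participant × visit × marker ×
    zone and columns ``participant_id, arm, randomization, visit, variable,
    zone, value, total_energy_kcal``.  Values are positive (lognormal);
    reproducible for a given ``params`` (all randomness flows from
    ``params.seed``).
    """
    rng = np.random.default_rng(params.seed)
    variables = list(params.baseline_log_mean.keys())

    arms = np.concatenate([np.repeat(a, n) for a, n in params.n_per_arm.items()])
    n_part = arms.size
    pid = np.array([f"S{i + 1:03d}" for i in range(n_part)])
    randomization = np.where(np.isin(arms, TWO_ARM), "two_arm", "four_arm")

    energy = rng.normal(params.energy_mean_kcal, params.energy_sd_kcal, n_part)
    energy += np.array([params.energy_arm_shift.get(a, 0.0) for a in arms])
    energy = np.clip(energy, 500.0, None)

    ln_drift = math.log(params.placebo_drift)
    ln_effect = np.array(
        [math.log(params.true_relative_effect.get(a, 1.0)) for a in arms]
    )
    resid_sd = params.within_participant_sd / math.sqrt(params.hemicrypts_per_visit)

    frames = []
    for var, zone in variables:
        mu = params.baseline_log_mean[(var, zone)]
        b = rng.normal(0.0, params.between_participant_sd, n_part)
        e = rng.normal(0.0, resid_sd, (n_part, 2))
        energy_term = params.energy_outcome_slope * (energy - params.energy_mean_kcal)
        ln_base = mu + b + energy_term + e[:, 0]
        ln_follow = mu + b + energy_term + ln_drift + ln_effect + e[:, 1]
        for visit, ln_y in (("baseline", ln_base), ("year1", ln_follow)):
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "arm": arms,
                        "randomization": randomization,
                        "visit": visit,
                        "variable": var,
                        "zone": zone,
                        "value": np.exp(ln_y),
                        "total_energy_kcal": energy,
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["variable", "zone", "participant_id", "visit"], kind="stable"
    ).reset_index(drop=True)


def study_sized_params(**overrides) -> TrialSimParams:
    """Trial parameters at the source study's arm sizes, with overrides."""
    return replace(TrialSimParams(), **overrides)
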