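"""Time-activity curves, mono-exponential biokinetic fits and residence times.

The canonical internal unit for organ activity is the fraction of injected
activity (FIA) in the VOI, decay-corrected to injection time; %IA/g is a
presentation unit handled at I/O.  Following the MIRD pamphlet-16 convention
for a three-time-point study, each decay-corrected organ curve is fitted
with a single exponential ``a0 * exp(-lambda_bio * t)`` extended to infinity
beyond the last sample, and the time-integrated activity coefficient
(residence time, hours) is the closed-form integral of the fitted curve
multiplied by physical decay:

    tau = a0 / (lambda_bio + lambda_phys)

``lambda_bio`` may be negative (organs still in the uptake phase, such as
the choroid plexuses) as long as the effective rate stays positive; a
non-positive effective rate makes the integral diverge and is an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .constants import MIN_PER_H
from .reference import Nuclide, Phantom, TOTAL_BODY, canonical_organ

__all__ = [
    "TimeActivityCurve",
    "MonoExpFit",
    "ResidenceTimeSet",
    "decay_correct",
    "decay_uncorrect",
    "fit_monoexp",
    "tiac",
    "marrow_residence_time",
    "partition_colon",
    "cohort_mean_taus",
]


class FitError(ValueError):
    """Raised when a mono-exponential fit is undefined or non-integrable."""


def decay_correct(raw_fia, t_min, nuclide: Nuclide):
    """Remove physical decay from a measurement taken ``t_min`` minutes p.i."""
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("time post-injection must be non-negative")
    return np.asarray(raw_fia, dtype=float) * np.exp(nuclide.lambda_phys * t / MIN_PER_H)


def decay_uncorrect(corrected_fia, t_min, nuclide: Nuclide):
    """Inverse of :func:`decay_correct`."""
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("time post-injection must be non-negative")
    return np.asarray(corrected_fia, dtype=float) * np.exp(-nuclide.lambda_phys * t / MIN_PER_H)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Decay-corrected activity measurements for one organ of one subject.

    ``t_min`` are minutes post-injection (strictly increasing), ``fia`` the
    fraction of injected activity in the VOI.  ``voi_mass_g`` is required
    for the per-gram procedures (red marrow, choroid plexuses).
    """

    subject_id: str
    organ: str
    t_min: tuple
    fia: tuple
    voi_mass_g: float | None = None
    decay_corrected: bool = True

    def __post_init__(self):
        t = np.asarray(self.t_min, dtype=float)
        a = np.asarray(self.fia, dtype=float)
        if t.size != a.size:
            raise ValueError("t_min and fia must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("fractional activities must be non-negative")
        if self.voi_mass_g is not None and self.voi_mass_g <= 0:
            raise ValueError("VOI mass must be positive")
        object.__setattr__(self, "organ", canonical_organ(self.organ))
        object.__setattr__(self, "t_min", tuple(float(x) for x in t))
        object.__setattr__(self, "fia", tuple(float(x) for x in a))

    @property
    def t_h(self) -> np.ndarray:
        return np.asarray(self.t_min) / MIN_PER_H

    def per_gram(self) -> "TimeActivityCurve":
        """The same curve expressed as fraction of injected activity per gram."""
        if self.voi_mass_g is None:
            raise ValueError(f"TAC for {self.organ} carries no VOI mass")
        return TimeActivityCurve(
            subject_id=self.subject_id,
            organ=self.organ,
            t_min=self.t_min,
            fia=tuple(a / self.voi_mass_g for a in self.fia),
            voi_mass_g=self.voi_mass_g,
            decay_corrected=self.decay_corrected,
        )


@dataclass(frozen=True)
class MonoExpFit:
    """Fitted biological clearance: ``fia(t) = a0 * exp(-lambda_bio * t)``.

    ``lambda_bio`` is per hour and may be negative (uptake phase).  ``r2``
    is the coefficient of determination of the fit on the configured scale.
    """

    a0: float
    lambda_bio: float
    r2: float

    def __post_init__(self):
        if self.a0 < 0:
            raise ValueError("fitted amplitude must be non-negative")

    def __call__(self, t_h):
        return self.a0 * np.exp(-self.lambda_bio * np.asarray(t_h, dtype=float))


def fit_monoexp(tac: TimeActivityCurve, r2_scale: str = "linear") -> MonoExpFit:
    """Least-squares mono-exponential fit of a decay-corrected curve.

    Nonlinear least squares on the linear scale, started from the
    log-linear closed form; with as many parameters as samples the fit
    interpolates exactly (r2 = 1).  ``r2_scale`` selects whether R^2 is
    evaluated on the linear (default) or log scale.
    """
    if not tac.decay_corrected:
        raise FitError("curve must be decay-corrected before fitting")
    t = tac.t_h
    a = np.asarray(tac.fia, dtype=float)
    if t.size < 2:
        raise FitError("at least two samples are required")
    if np.any(a <= 0):
        raise FitError("non-positive activities: mono-exponential fit undefined")

    # log-linear closed form as starting values (exact for 2 points)
    slope, intercept = np.polyfit(t, np.log(a), 1)
    a0_0, lam_0 = math.exp(intercept), -slope
    if t.size == 2:
        a0, lam = a0_0, lam_0
    else:
        try:
            (a0, lam), _ = curve_fit(
                lambda tt, a0, lam: a0 * np.exp(-lam * tt),
                t,
                a,
                p0=(a0_0, lam_0),
                maxfev=10000,
            )
        except RuntimeError as exc:  # pragma: no cover - pathological inputs
            raise FitError(f"mono-exponential fit failed to converge: {exc}")
    if a0 <= 0:
        raise FitError("fit produced a non-positive amplitude")

    pred = a0 * np.exp(-lam * t)
    if r2_scale == "log":
        res, obs = np.log(pred) - np.log(a), np.log(a)
    else:
        res, obs = pred - a, a
    ss_res = float(np.sum(res**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot < 1e-30:
        r2 = 1.0 if ss_res < 1e-24 else 0.0  # constant data: exact or degenerate
    else:
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return MonoExpFit(a0=float(a0), lambda_bio=float(lam), r2=r2)


def tiac(fit: MonoExpFit, nuclide: Nuclide) -> float:
    """Residence time (h): integral of the fitted curve times physical decay."""
    rate = fit.lambda_bio + nuclide.lambda_phys
    if fit.a0 == 0.0:
        return 0.0
    if rate <= 0:
        raise FitError(
            f"effective rate {rate:.4g}/h is non-positive: non-integrable tail"
        )
    return fit.a0 / rate


def marrow_residence_time(
    femora_voi: TimeActivityCurve,
    lumbar_voi: TimeActivityCurve,
    phantom: Phantom,
    nuclide: Nuclide,
) -> float:
    """Two-region red-marrow residence time.

    The per-gram TIAC of a femoral-head VOI and a lumbar-vertebrae VOI are
    averaged (reducing bias from marrow-uptake heterogeneity) and scaled by
    the reference phantom's red-marrow mass.
    """
    per_gram = []
    for voi in (femora_voi, lumbar_voi):
        if voi.voi_mass_g is None:
            raise ValueError(f"marrow VOI {voi.organ} carries no mass")
        per_gram.append(tiac(fit_monoexp(voi.per_gram()), nuclide))
    return 0.5 * (per_gram[0] + per_gram[1]) * phantom.mass("red_marrow")


def partition_colon(tau_colon: float, phantom: Phantom) -> tuple[float, float]:
    """Split a colon residence time between ULI and LLI wall by phantom mass."""
    m_uli = phantom.mass("uli_wall")
    m_lli = phantom.mass("lli_wall")
    tau_uli = tau_colon * m_uli / (m_uli + m_lli)
    return tau_uli, tau_colon - tau_uli


@dataclass(frozen=True)
class ResidenceTimeSet:
    """Residence times (h) per source region for one subject or cohort mean."""

    taus: dict
    administered_activity_mbq: float = float("nan")
    subject_id: str = ""

    def __post_init__(self):
        clean = {}
        for organ, tau in self.taus.items():
            if tau < 0:
                raise ValueError(f"negative residence time for {organ}")
            clean[canonical_organ(organ)] = float(tau)
        object.__setattr__(self, "taus", clean)

    def __getitem__(self, organ: str) -> float:
        return self.taus[canonical_organ(organ)]

    def __contains__(self, organ: str) -> bool:
        return canonical_organ(organ) in self.taus

    @property
    def whole_body(self) -> float | None:
        return self.taus.get(TOTAL_BODY)

    def scaled(self, factor: float) -> "ResidenceTimeSet":
        return ResidenceTimeSet(
            taus={o: t * factor for o, t in self.taus.items()},
            administered_activity_mbq=self.administered_activity_mbq,
            subject_id=self.subject_id,
        )

    def replace(self, **taus) -> "ResidenceTimeSet":
        new = dict(self.taus)
        new.update({canonical_organ(o): v for o, v in taus.items()})
        return ResidenceTimeSet(
            taus=new,
            administered_activity_mbq=self.administered_activity_mbq,
            subject_id=self.subject_id,
        )


def cohort_mean_taus(per_subject: list) -> tuple[ResidenceTimeSet, dict]:
    """Per-region arithmetic mean and sample SD (n-1) over subjects.

    With a single subject the SD is reported as 0.0 by convention.
    """
    if not per_subject:
        raise ValueError("at least one subject is required")
    regions = set(per_subject[0].taus)
    for s in per_subject[1:]:
        if set(s.taus) != regions:
            raise ValueError("subjects have mismatched source-region sets")
    means, sds = {}, {}
    for region in regions:
        vals = np.array([s.taus[region] for s in per_subject])
        means[region] = float(vals.mean())
        sds[region] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    activity = float(np.mean([s.administered_activity_mbq for s in per_subject]))
    return ResidenceTimeSet(taus=means, administered_activity_mbq=activity), sds
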