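"""FRAP processing: background and acquisition-photobleach correction,
0 %/100 % normalisation, and one-phase association fitting.

The normalisation follows the standard point-bleach convention: the ROI
trace is background-subtracted, divided by the (background-subtracted)
unbleached reference ROI scaled to its pre-bleach mean, then mapped linearly
so that the first post-bleach value is exactly 0 % and the highest
pre-bleach value exactly 100 %.  Recovery is modelled as the one-phase
association

    Y(x) = Y0 + (plateau − Y0) · (1 − exp(−K·x))

with x the time since the first post-bleach frame; the mobile fraction is
``plateau − Y0`` and the half-time of recovery ``t½ = ln 2 / K``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

LN2 = math.log(2.0)


class NoBleachError(ValueError):
    pass


@dataclass
class FRAPTrace:
    """Raw bleach-recovery series (times in seconds, arbitrary intensity units)."""

    time_s: np.ndarray
    roi: np.ndarray
    background: np.ndarray
    reference: Optional[np.ndarray]
    first_post_index: int
    truth: Optional[dict] = None        # set by the simulator, None for real data

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.roi = np.asarray(self.roi, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not 1 <= self.first_post_index < len(self.time_s):
            raise ValueError("first_post_index must leave ≥1 pre-bleach frame")
        for a in (self.roi, self.background):
            if not np.all(np.isfinite(a)):
                raise ValueError("intensities must be finite")

    @property
    def n_pre(self) -> int:
        return self.first_post_index

    @property
    def n_post(self) -> int:
        return len(self.time_s) - self.first_post_index

    @classmethod
    def from_csv(cls, path, first_post_index: int | None = None) -> "FRAPTrace":
        """Read columns ``time_s, roi, background[, reference]``.

        When ``first_post_index`` is not given it is inferred as the largest
        downward step in the ROI trace.
        """
        df = pd.read_csv(path)
        ref = df["reference"].to_numpy() if "reference" in df else None
        roi = df["roi"].to_numpy(dtype=float)
        if first_post_index is None:
            first_post_index = int(np.argmin(np.diff(roi))) + 1
        return cls(time_s=df["time_s"].to_numpy(), roi=roi,
                   background=df["background"].to_numpy(), reference=ref,
                   first_post_index=first_post_index)

    def to_csv(self, path) -> None:
        d = {"time_s": self.time_s, "roi": self.roi, "background": self.background}
        if self.reference is not None:
            d["reference"] = self.reference
        pd.DataFrame(d).to_csv(path, index=False)


@dataclass
class NormalizedTrace:
    """Relative fluorescence (%) against time since the bleach (s)."""

    x: np.ndarray                      # s, 0 at first post-bleach frame
    y: np.ndarray                      # %, 0 at first post-bleach frame
    first_post_index: int
    corrections: list[str] = field(default_factory=list)
    truth: Optional[dict] = None

    @property
    def post_x(self) -> np.ndarray:
        return self.x[self.first_post_index:]

    @property
    def post_y(self) -> np.ndarray:
        return self.y[self.first_post_index:]

    def plot(self, fit: "FRAPFitResult | None" = None, ax=None):
        """Plot the normalised recovery, optionally with a fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.x, self.y, "o", ms=4, label="normalised trace")
        if fit is not None and fit.converged and np.isfinite(fit.k):
            xx = np.linspace(0, self.post_x[-1], 200)
            ax.plot(xx, fit.predict(xx), "-",
                    label=f"fit: Fm={fit.mobile_fraction:.1f}%, "
                          f"t½={fit.t_half:.2f}s")
        ax.set_xlabel("time since bleach (s)")
        ax.set_ylabel("relative fluorescence (%)")
        ax.legend()
        return ax


def correct_and_normalize(trace: FRAPTrace) -> NormalizedTrace:
    """Background-correct, photobleach-correct against the reference ROI, and
    normalise so the first post-bleach value is 0 % and the highest
    pre-bleach value 100 %.

    Without a reference series the photobleach correction is skipped and
    flagged, never inferred from the bleached ROI itself.  A trace in which
    the highest pre-bleach value does not exceed the first post-bleach value
    raises :class:`NoBleachError`.
    """
    corrections = ["background"]
    sig = trace.roi - trace.background
    if trace.reference is not None:
        ref = trace.reference - trace.background
        pre_ref = ref[:trace.first_post_index].mean()
        if pre_ref <= 0 or np.any(ref == 0):
            raise ValueError("reference ROI does not exceed background")
        sig = sig / (ref / pre_ref)
        corrections.append("photobleach")
    pre_max = sig[:trace.first_post_index].max()
    post0 = sig[trace.first_post_index]
    if not pre_max > post0:
        raise NoBleachError("no bleach detected")
    # divide before scaling so the defining points are exactly 0 and 100
    y = (sig - post0) / (pre_max - post0) * 100.0
    x = trace.time_s - trace.time_s[trace.first_post_index]
    return NormalizedTrace(x=x, y=y, first_post_index=trace.first_post_index,
                           corrections=corrections, truth=trace.truth)


def one_phase_association(x: np.ndarray, y0: float, plateau: float,
                          k: float) -> np.ndarray:
    return y0 + (plateau - y0) * (1.0 - np.exp(-k * np.asarray(x, dtype=float)))


@dataclass
class FRAPFitResult:
    """One-phase association estimates for a single trace."""

    y0: float
    plateau: float
    k: float
    se: dict = field(default_factory=dict)
    r_squared: float = np.nan
    converged: bool = False
    flags: list[str] = field(default_factory=list)
    n_points: int = 0
    truth: Optional[dict] = None

    @property
    def mobile_fraction(self) -> float:
        return self.plateau - self.y0

    @property
    def t_half(self) -> float:
        return LN2 / self.k if self.k > 0 else np.nan

    def predict(self, x: np.ndarray) -> np.ndarray:
        return one_phase_association(x, self.y0, self.plateau, self.k)

    def summary(self) -> str:
        lines = [
            "One-phase association fit  Y = Y0 + (plateau - Y0)(1 - exp(-K x))",
            f"  n post-bleach points : {self.n_points}",
            f"  Y0                   : {self.y0:8.2f} %",
            f"  plateau              : {self.plateau:8.2f} %",
            f"  K                    : {self.k:8.4f} 1/s",
            f"  mobile fraction      : {self.mobile_fraction:8.2f} %",
            f"  half-time t1/2       : {self.t_half:8.3f} s",
            f"  R^2                  : {self.r_squared:8.4f}",
            f"  converged            : {self.converged}",
        ]
        if self.flags:
            lines.append(f"  flags                : {', '.join(self.flags)}")
        return "\n".join(lines)


class OnePhaseAssociation:
    """One-phase association model for a normalised recovery trace.

    Fit on the post-bleach points only, by nonlinear least squares with
    bounds Y0 ∈ [−20, 20] %, plateau ∈ [0, 150] %, K ∈ (0, 10] s⁻¹.
    ``fit()`` never raises on a refractory trace: non-convergence comes back
    as a flagged :class:`FRAPFitResult`.
    """

    BOUNDS = ([-20.0, 0.0, 1e-6], [20.0, 150.0, 10.0])

    def __init__(self, norm: NormalizedTrace):
        if norm.post_x.size < 5:
            raise ValueError("need at least 5 post-bleach points")
        self.norm = norm

    def _initial(self) -> list[float]:
        x, y = self.norm.post_x, self.norm.post_y
        y0 = float(np.clip(y[0], -20, 20))
        plateau = float(np.clip(np.mean(y[-3:]), 0, 150))
        half = y0 + 0.5 * (plateau - y0)
        above = np.flatnonzero(y >= half)
        t_half = x[above[0]] if above.size and x[above[0]] > 0 else (x[-1] / 4 or 1.0)
        k = float(np.clip(LN2 / t_half, 1e-6, 10.0))
        return [y0, plateau, k]

    def fit(self) -> FRAPFitResult:
        x, y = self.norm.post_x, self.norm.post_y
        flags = []
        if np.allclose(y, 0.0):
            return FRAPFitResult(y0=0.0, plateau=0.0, k=np.nan, converged=True,
                                 flags=["no recovery: K undefined"],
                                 r_squared=1.0, n_points=x.size,
                                 truth=self.norm.truth)
        try:
            popt, pcov = curve_fit(one_phase_association, x, y, p0=self._initial(),
                                   bounds=self.BOUNDS, maxfev=20000)
            converged = True
        except RuntimeError as e:
            return FRAPFitResult(y0=np.nan, plateau=np.nan, k=np.nan,
                                 converged=False, flags=[f"fit failed: {e}"],
                                 n_points=x.size, truth=self.norm.truth)
        resid = y - one_phase_association(x, *popt)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else np.nan
        se = np.sqrt(np.diag(pcov))
        if popt[2] <= 0:
            converged = False
            flags.append("non-positive rate constant")
        return FRAPFitResult(y0=float(popt[0]), plateau=float(popt[1]),
                             k=float(popt[2]),
                             se={"y0": se[0], "plateau": se[1], "k": se[2]},
                             r_squared=r2, converged=converged, flags=flags,
                             n_points=x.size, truth=self.norm.truth)


def fit_one_phase(norm: NormalizedTrace) -> FRAPFitResult:
    """Convenience wrapper: ``OnePhaseAssociation(norm).fit()``."""
    return OnePhaseAssociation(norm).fit()


def bleach_depth_flag(trace: FRAPTrace, threshold: float = 0.8) -> bool:
    """True when the bleach was too shallow: first post-bleach raw value above
    ``threshold`` × the pre-bleach mean (the aim is ~50 % bleaching)."""
    sig = trace.roi - trace.background
    pre = sig[:trace.first_post_index].mean()
    return bool(sig[trace.first_post_index] > threshold * pre)


def summarize_group(fits: list[FRAPFitResult], min_r_squared: float = 0.5) -> dict:
    """Group summary of mobile fractions and half-times.

    Excludes non-converged fits and fits with R² below ``min_r_squared``
    (each exclusion is listed with its reason); reports mean ± sd, CV (%)
    and — with n ≥ 8 — the D'Agostino–Pearson K2 normality verdict for both
    parameters.  Fewer than 3 usable fits yields an undefined-variance flag.
    """
    from .stats import coefficient_of_variation, dagostino_pearson_k2

    kept, excluded = [], []
    for i, f in enumerate(fits):
        if not f.converged:
            excluded.append({"index": i, "reason": "not converged"})
        elif np.isfinite(f.r_squared) and f.r_squared < min_r_squared:
            excluded.append({"index": i, "reason": f"R² {f.r_squared:.2f} < {min_r_squared}"})
        else:
            kept.append(f)
    out: dict = {"n": len(kept), "excluded": excluded, "flags": []}
    if len(kept) < 3:
        out["flags"].append("undefined variance: fewer than 3 usable fits")
    for name, vals in (("mobile_fraction", [f.mobile_fraction for f in kept]),
                       ("t_half", [f.t_half for f in kept])):
        v = np.array([x for x in vals if np.isfinite(x)])
        entry = {"mean": float(v.mean()) if v.size else np.nan,
                 "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan}
        entry["cv_percent"] = (coefficient_of_variation(v)
                               if v.size > 1 and v.mean() > 0 else np.nan)
        if v.size >= 8 and v.std() > 0:
            k2, p = dagostino_pearson_k2(v)
            entry["normality"] = {"k2": k2, "p": p, "normal": p > 0.05}
        out[name] = entry
    return out


def group_summary_table(groups: dict[str, list[FRAPFitResult]]) -> pd.DataFrame:
    """Tabulate :func:`summarize_group` across named conditions."""
    rows = []
    for name, fits in groups.items():
        s = summarize_group(fits)
        rows.append({
            "condition": name, "n": s["n"],
            "mobile_fraction_mean": s["mobile_fraction"]["mean"],
            "mobile_fraction_sd": s["mobile_fraction"]["sd"],
            "t_half_mean": s["t_half"]["mean"],
            "t_half_sd": s["t_half"]["sd"],
            "t_half_cv_percent": s["t_half"]["cv_percent"],
            "n_excluded": len(s["excluded"]),
        })
    return pd.DataFrame(rows)
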