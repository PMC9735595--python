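"""Plasma-stability kinetics: one-phase exponential decay and 4PL dose-response.

Two fits cover the whole study design:

* **One-phase decay** ``Y(t) = (Y0 − Plateau)·exp(−K·t) + Plateau`` with
  half-life ``t½ = ln 2 / K``, fitted to MS peak areas (plateau fixed at 0
  by default — the free peptide is eventually fully consumed) or to
  functional remaining-activity curves (plateau free by default — a
  residual active, protein-bound pool is expected).

* **Four-parameter logistic (4PL)** antibody-competition curves on
  log-concentration, yielding IC50; remaining activity at incubation time
  t compares IC50(t) with IC50(0).

Fits are deterministic: fixed initialization heuristics, fixed bounds, no
random restarts.  A fit that cannot support a half-life (non-decaying
data) is returned flagged "not determined", never as a fabricated number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from lmfit import Model

__all__ = [
    "DecayFit",
    "DoseResponseFit",
    "RemainingActivity",
    "one_phase_decay",
    "four_pl",
    "fit_one_phase_decay",
    "fit_ic50",
    "remaining_activity",
    "activity_half_life",
    "K_MIN",
    "K_MAX",
]

#: Rate-constant bounds, 1/min.  A fitted K at or below K_MIN means the
#: data do not decay on the observed window; no half-life is reported.
K_MIN = 1e-6
K_MAX = 10.0


def one_phase_decay(t, y0, plateau, k):
    """Y(t) = (Y0 − Plateau)·exp(−K·t) + Plateau."""
    return (y0 - plateau) * np.exp(-k * np.asarray(t, dtype=float)) + plateau


def four_pl(x, top, bottom, log_ic50, hill):
    """Descending 4PL on concentration x (hill < 0 for inhibition curves)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / 10.0 ** log_ic50) ** (-hill))


@dataclass
class DecayFit:
    """One-phase decay fit result."""

    y0: float
    plateau: float
    k: float
    half_life: Optional[float]  # minutes; None when not determined
    determined: bool
    plateau_mode: str
    stderr: dict = field(default_factory=dict)
    rss: float = float("nan")
    message: str = ""

    @property
    def half_life_stderr(self) -> Optional[float]:
        """Delta-method standard error of t½ = ln2/K."""
        se_k = self.stderr.get("k")
        if not self.determined or se_k is None or not np.isfinite(se_k):
            return None
        return math.log(2.0) / self.k**2 * se_k

    def to_dict(self) -> dict:
        return {
            "y0": self.y0, "plateau": self.plateau, "k_per_min": self.k,
            "half_life_min": self.half_life,
            "half_life_stderr_min": self.half_life_stderr,
            "determined": self.determined, "plateau_mode": self.plateau_mode,
            "stderr": self.stderr, "rss": self.rss, "message": self.message,
        }


def _initial_k(times: np.ndarray, values: np.ndarray) -> float:
    """Log-linear slope over the first decade of signal (K init heuristic)."""
    top = values.max()
    mask = (values > 0) & (values >= top / 10.0)
    if mask.sum() >= 2 and len(np.unique(times[mask])) >= 2:
        slope = np.polyfit(times[mask], np.log(values[mask]), 1)[0]
        if slope < 0:
            return float(np.clip(-slope, K_MIN * 10, K_MAX))
    return 1e-2


def fit_one_phase_decay(
    times: Sequence[float],
    values: Sequence[float],
    plateau_mode: str = "fixed-zero",
) -> DecayFit:
    """Least-squares one-phase decay fit.

    ``plateau_mode`` is ``"fixed-zero"`` (MS peak-area convention) or
    ``"free"`` (functional-activity convention; plateau bounded to
    [0, max(values)]).  Requires ≥3 distinct timepoints (≥4 for a free
    plateau) and non-negative values.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if np.any(y < 0):
        raise ValueError("values must be non-negative")
    if plateau_mode not in ("fixed-zero", "free"):
        raise ValueError(f"unknown plateau_mode {plateau_mode!r}")
    n_distinct = len(np.unique(t))
    needed = 4 if plateau_mode == "free" else 3
    if n_distinct < needed:
        raise ValueError(
            f"need >= {needed} distinct timepoints for plateau_mode="
            f"{plateau_mode!r}, got {n_distinct}"
        )

    order = np.argsort(t)
    t, y = t[order], y[order]
    top = y.max()
    if top <= 0:
        return DecayFit(
            y0=0.0, plateau=0.0, k=K_MIN, half_life=None, determined=False,
            plateau_mode=plateau_mode, message="all-zero signal",
        )

    model = Model(one_phase_decay)
    params = model.make_params()
    params["y0"].set(value=max(y[0], top * 1e-3), min=0.0, max=top * 10 + 1)
    if plateau_mode == "fixed-zero":
        params["plateau"].set(value=0.0, vary=False)
    else:
        params["plateau"].set(value=float(y.min()), min=0.0, max=float(top))
    params["k"].set(value=_initial_k(t, y), min=K_MIN, max=K_MAX)

    result = model.fit(y, params, t=t)
    k = float(result.params["k"].value)
    y0 = float(result.params["y0"].value)
    plateau = float(result.params["plateau"].value)
    stderr = {
        name: (float(p.stderr) if p.stderr is not None else None)
        for name, p in result.params.items() if p.vary
    }
    rss = float(np.sum(result.residual**2))
    determined = k > K_MIN * 1.01
    # a decay indistinguishable from flat: amplitude must actually move
    if plateau_mode == "free" and (y0 - plateau) <= 1e-9 * top:
        determined = False
    return DecayFit(
        y0=y0, plateau=plateau, k=k,
        half_life=(math.log(2.0) / k) if determined else None,
        determined=determined, plateau_mode=plateau_mode,
        stderr=stderr, rss=rss,
        message="" if determined else "non-decaying data: half-life not determined",
    )


@dataclass
class DoseResponseFit:
    """4PL antibody-competition fit result."""

    ic50: Optional[float]
    hill: float
    top: float
    bottom: float
    determined: bool
    constrained_top: bool
    constrained_bottom: bool
    stderr: dict = field(default_factory=dict)
    rss: float = float("nan")
    message: str = ""
    concentrations: tuple = ()
    responses: tuple = ()

    def no_inhibition_at_top_dose(self) -> bool:
        """True when even the highest tested concentration left the response
        above 50 on the normalized 0-100 scale — half-maximal inhibition was
        never reached anywhere in the tested range."""
        if len(self.concentrations) == 0:
            return False
        top_dose = max(self.concentrations)
        resp = [r for c, r in zip(self.concentrations, self.responses) if c == top_dose]
        return min(resp) > 50.0

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d.pop("concentrations"), d.pop("responses")
        return d


def fit_ic50(
    concentrations: Sequence[float],
    responses: Sequence[float],
    constrain_top: Optional[float] = None,
    constrain_bottom: Optional[float] = None,
) -> DoseResponseFit:
    """4PL fit of normalized competition responses (percent, 100 = vehicle).

    Requires ≥4 positive concentrations spanning ≥2 log10 units.  Data with
    no inhibition trend (responses not decreasing with dose) yield a fit
    flagged not determined instead of an extrapolated IC50.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and responses must be 1-D arrays of equal length")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    xu = np.unique(x)
    if len(xu) < 4:
        raise ValueError(f"need >= 4 distinct concentrations, got {len(xu)}")
    span = math.log10(xu.max() / xu.min())
    if span < 2.0:
        raise ValueError(f"concentrations must span >= 2 log10 units, span {span:.2f}")

    order = np.argsort(x)
    x, y = x[order], y[order]
    top0 = float(y.max()) if constrain_top is None else constrain_top
    bottom0 = float(y.min()) if constrain_bottom is None else constrain_bottom

    # inhibition must exist: responses at high dose below half-range
    trend = np.polyfit(np.log10(x), y, 1)[0]
    half = (top0 + bottom0) / 2.0
    if trend >= 0 or y[x == x.max()].min() > half + 0.25 * (top0 - bottom0):
        return DoseResponseFit(
            ic50=None, hill=0.0, top=top0, bottom=bottom0, determined=False,
            constrained_top=constrain_top is not None,
            constrained_bottom=constrain_bottom is not None,
            message="no inhibition: IC50 not determined",
            concentrations=tuple(x), responses=tuple(y),
        )

    # deterministic IC50 init: dose where response crosses half-range
    below = np.nonzero(y <= half)[0]
    ic50_init = float(x[below[0]]) if len(below) else float(np.sqrt(xu.min() * xu.max()))

    model = Model(four_pl)
    params = model.make_params()
    if constrain_top is None:
        params["top"].set(value=top0, min=bottom0, max=top0 * 2 + 10)
    else:
        params["top"].set(value=constrain_top, vary=False)
    if constrain_bottom is None:
        params["bottom"].set(value=bottom0, min=-10.0, max=top0)
    else:
        params["bottom"].set(value=constrain_bottom, vary=False)
    params["log_ic50"].set(
        value=math.log10(ic50_init),
        min=math.log10(xu.min()) - 2, max=math.log10(xu.max()) + 2,
    )
    params["hill"].set(value=-1.0, min=-5.0, max=-0.05)

    result = model.fit(y, params, x=x)
    ic50 = float(10.0 ** result.params["log_ic50"].value)
    top = float(result.params["top"].value)
    bottom = float(result.params["bottom"].value)
    stderr = {
        name: (float(p.stderr) if p.stderr is not None else None)
        for name, p in result.params.items() if p.vary
    }
    determined = top > bottom and np.isfinite(ic50) and ic50 > 0
    return DoseResponseFit(
        ic50=ic50 if determined else None,
        hill=float(result.params["hill"].value), top=top, bottom=bottom,
        determined=determined,
        constrained_top=constrain_top is not None,
        constrained_bottom=constrain_bottom is not None,
        stderr=stderr, rss=float(np.sum(result.residual**2)),
        message="" if determined else "degenerate 4PL fit: IC50 not determined",
        concentrations=tuple(x), responses=tuple(y),
    )


@dataclass
class RemainingActivity:
    """Activity remaining at incubation time t, from IC50(t) vs IC50(0).

    ``remaining_pct`` uses the convention in which activity falls as the
    IC50 rises: IC50(0)/IC50(t) × 100.  ``as_printed_pct`` is the literal
    inverse ratio IC50(t)/IC50(0) × 100 (a fold-change of IC50), emitted
    alongside for comparability with reports using that formula.
    """

    remaining_pct: Optional[float]
    as_printed_pct: Optional[float]
    determined: bool
    message: str = ""


def remaining_activity(
    fit_t: DoseResponseFit, fit_0: DoseResponseFit
) -> RemainingActivity:
    """Remaining activity (percent) at time t relative to t = 0."""
    if not fit_0.determined:
        raise ValueError("IC50 at t = 0 is not determined; cannot normalize")
    if not fit_t.determined:
        if fit_t.no_inhibition_at_top_dose():
            return RemainingActivity(0.0, None, True,
                                     "no inhibition at top dose: activity fully lost")
        return RemainingActivity(None, None, False,
                                 "IC50 at t not determined")
    return RemainingActivity(
        remaining_pct=fit_0.ic50 / fit_t.ic50 * 100.0,
        as_printed_pct=fit_t.ic50 / fit_0.ic50 * 100.0,
        determined=True,
    )


def activity_half_life(
    times: Sequence[float],
    remaining_pct: Sequence[float],
    plateau_mode: str = "free",
) -> DecayFit:
    """Half-life of functional-activity loss via one-phase decay.

    Plateau is free by default: covalently protein-bound peptide retains
    activity, so remaining-activity curves level off above zero.
    """
    return fit_one_phase_decay(times, remaining_pct, plateau_mode=plateau_mode)
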