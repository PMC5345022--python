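"""Reduction of pharmacology measurements.

Competition binding and functional dose-response data are reduced with a
four-parameter logistic (4PL) on log10 concentration,

    y(c) = basal + (emax - basal) / (1 + 10**(nH * (log10 EC50 - log10 c))),

fitted by least squares with a deterministic multi-start over the midpoint.
Competition IC50 values convert to inhibition constants with the
Cheng-Prusoff relation Ki = IC50 / (1 + [L]/KD), where [L] is the
radioligand concentration and KD its dissociation constant.  Raw assay
readouts (BRET ratios, luminescence counts) are normalised to a 0-100 %
scale between a basal and a full-reference response.  Hit classification
applies the screening activity criterion Ki <= 50 uM, with censored
entries (">100,000") counted as non-hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["DoseResponse", "BindingResult", "HitClassification",
           "fit_sigmoid", "cheng_prusoff", "normalize_bret", "normalize_cps",
           "classify_hits", "classify_efficacy"]

FLAT_SPAN = 5.0  # percent; below this the curve is flagged as flat


@dataclass
class DoseResponse:
    conc: np.ndarray          # mol/L
    response: np.ndarray      # percent
    ec50: float               # mol/L (IC50 for inhibition data)
    emax: float               # percent, plateau response
    hill: float
    basal: float              # percent
    se: dict = field(default_factory=dict)
    flat: bool = False
    ec50_in_range: bool = True
    direction: str = "activation"


@dataclass
class BindingResult:
    ki: float                 # nM
    ic50: float               # nM
    radioligand_conc: float   # nM
    kd: float                 # nM
    sem: float | None = None  # nM

    def __post_init__(self) -> None:
        if self.ki <= 0 or self.ki > self.ic50 * (1 + 1e-12):
            raise ValueError("Ki must be positive and not exceed IC50")


def _logistic4(logc, log_ec50, basal, emax, hill):
    return basal + (emax - basal) / (1.0 + 10.0 ** (hill * (log_ec50 - logc)))


def fit_sigmoid(conc, response, direction: str = "activation",
                fix_hill: bool = False) -> DoseResponse:
    """Fit a four-parameter logistic to a dose-response curve.

    ``conc`` in mol/L (>= 4 distinct values), ``response`` in percent.
    ``direction`` chooses the expected sign of the span (activation rises,
    inhibition falls); the midpoint start grid spans the tested range, so
    the optimisation is deterministic.  Degenerate, flat curves are fitted
    but flagged rather than rejected.
    """
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    if conc.ndim != 1 or conc.shape != response.shape:
        raise ValueError("conc and response must be 1-D arrays of equal length")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if direction not in {"activation", "inhibition"}:
        raise ValueError("direction must be 'activation' or 'inhibition'")

    logc = np.log10(conc)
    lo, hi = logc.min(), logc.max()
    rlo, rhi = float(response.min()), float(response.max())
    sign = 1.0 if direction == "activation" else -1.0
    basal0, emax0 = (rlo, rhi) if sign > 0 else (rhi, rlo)

    if fix_hill:
        def model(x, log_ec50, basal, emax):
            return _logistic4(x, log_ec50, basal, emax, sign * 1.0)
        p_extra, bounds_lo, bounds_hi = (), (lo - 4, -np.inf, -np.inf), (hi + 4, np.inf, np.inf)
    else:
        def model(x, log_ec50, basal, emax, hill):
            return _logistic4(x, log_ec50, basal, emax, hill)
        hill0 = sign * 1.0
        p_extra = (hill0,)
        h_bounds = (0.05, 10.0) if sign > 0 else (-10.0, -0.05)
        bounds_lo = (lo - 4, -np.inf, -np.inf, h_bounds[0])
        bounds_hi = (hi + 4, np.inf, np.inf, h_bounds[1])

    best = None
    diagnostics = []
    for start in np.linspace(lo, hi, 7):
        p0 = (start, basal0, emax0, *p_extra)
        try:
            popt, pcov = curve_fit(model, logc, response, p0=p0,
                                   bounds=(bounds_lo, bounds_hi), maxfev=20000)
        except (RuntimeError, ValueError) as exc:
            diagnostics.append(f"start {start:.2f}: {exc}")
            continue
        sse = float(((model(logc, *popt) - response) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        raise RuntimeError("4PL fit failed from every start: " + "; ".join(diagnostics))

    _, popt, pcov = best
    log_ec50, basal, emax = popt[0], popt[1], popt[2]
    hill = sign * 1.0 if fix_hill else popt[3]
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(len(popt), np.nan)
    names = ["log_ec50", "basal", "emax"] + ([] if fix_hill else ["hill"])
    span = emax - basal
    return DoseResponse(conc=conc, response=response, ec50=10.0 ** log_ec50,
                        emax=emax, hill=hill, basal=basal,
                        se=dict(zip(names, perr.tolist())),
                        flat=abs(span) < FLAT_SPAN,
                        ec50_in_range=bool(lo <= log_ec50 <= hi),
                        direction=direction)


def cheng_prusoff(ic50: float, L: float, kd: float) -> float:
    """Ki = IC50 / (1 + [L]/KD); all quantities in the same unit (nM).

    ``L`` may be zero (no-competition limit, Ki = IC50); IC50 and KD must
    be positive.
    """
    if ic50 <= 0 or kd <= 0 or L < 0:
        raise ValueError("ic50 and kd must be > 0 and L >= 0")
    return ic50 / (1.0 + L / kd)


def _normalize(values, basal_ref: float, full_ref: float) -> np.ndarray:
    span = full_ref - basal_ref
    if span == 0:
        raise ValueError("zero span between basal and full reference")
    return 100.0 * (np.asarray(values, dtype=float) - basal_ref) / span


def normalize_bret(ratios, basal_ref: float, full_ref: float) -> np.ndarray:
    """Scale raw BRET ratios to percent between the basal (0 %) and the
    full reference-agonist (100 %) response."""
    return _normalize(ratios, basal_ref, full_ref)


def normalize_cps(cps, buffer_ref: float, quinpirole_ref: float) -> np.ndarray:
    """Scale luminescence counts-per-second to percent between the buffer
    basal (0 %) and the reference-agonist maximum (100 %)."""
    return _normalize(cps, buffer_ref, quinpirole_ref)


@dataclass
class HitClassification:
    flags: list[tuple[str, str, bool]]     # (compound, screen class, hit)
    rate_by_class: dict[str, int]          # percent, rounded as printed
    overall_rate: int
    n_hits_by_class: dict[str, int]
    n_by_class: dict[str, int]


def _parse_ki(value) -> tuple[float | None, bool]:
    """Return (numeric Ki in nM or None, censored flag)."""
    if isinstance(value, str):
        v = value.strip().replace(",", "")
        if v.startswith(">"):
            return float(v[1:]), True
        return float(v), False
    return float(value), False


def classify_hits(ki_table, threshold: float = 50000.0) -> HitClassification:
    """Apply the activity criterion Ki <= ``threshold`` (nM) to a Ki table.

    ``ki_table`` rows are ``(compound, screen_class, ki)`` with ki numeric
    (nM) or a censored string such as ``">100,000"``; censored entries are
    lower bounds and count as non-hits (never imputed).  Rates are rounded
    to integer percent.
    """
    flags = []
    n_by_class: dict[str, int] = {}
    hits_by_class: dict[str, int] = {}
    for compound, cls, ki in ki_table:
        value, censored = _parse_ki(ki)
        hit = (not censored) and value <= threshold
        flags.append((compound, cls, hit))
        n_by_class[cls] = n_by_class.get(cls, 0) + 1
        hits_by_class[cls] = hits_by_class.get(cls, 0) + int(hit)
    rate_by_class = {cls: round(100.0 * hits_by_class[cls] / n_by_class[cls])
                     for cls in n_by_class}
    total = sum(n_by_class.values())
    total_hits = sum(hits_by_class.values())
    return HitClassification(flags=flags, rate_by_class=rate_by_class,
                             overall_rate=round(100.0 * total_hits / total),
                             n_hits_by_class=hits_by_class, n_by_class=n_by_class)


def classify_efficacy(gprot_emax: float, arrestin_emax: float,
                      full_threshold: float = 50.0,
                      floor: float = 7.0) -> str:
    """Classify a ligand from its pathway maxima (percent of reference).

    A compound with near-full activity in one pathway (E_max >= the 50 %
    threshold) but below-floor response in the other is a biased
    (functionally selective) agonist; significant but sub-threshold
    activity is partial agonism; below-floor in both pathways means no
    intrinsic activity in activation (an antagonist when it still binds).
    """
    g_active = gprot_emax >= floor
    a_active = arrestin_emax >= floor
    if gprot_emax >= full_threshold and not a_active:
        return "biased_agonist"
    if arrestin_emax >= full_threshold and not g_active:
        return "biased_agonist"
    if gprot_emax >= full_threshold or arrestin_emax >= full_threshold:
        return "full_agonist"
    if g_active or a_active:
        return "partial_agonist"
    return "antagonist"
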