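"""Volatile fatty acid profiles, stoichiometric CH4/CO2 prediction and ratios.

The stoichiometric CH4 prediction uses the classical fermentation-balance
form on the three-acid (acetate + propionate + butyrate) basis:

    CH4_VFA (mmol/mol VFA) = 0.5*C2 - 0.25*C3 + 0.5*C4

where C2, C3, C4 are molar proportions of acetate, propionate and butyrate
renormalized to a three-acid sum of 1000. The companion CO2 prediction
(0.5*C2 + 0.25*C3 + 1.5*C4) is an assumption of this implementation: it is
reported for completeness and never used as a validation target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InvalidParameterError,
    UndefinedRatioError,
    UndefinedStoichiometryError,
)

logger = logging.getLogger(__name__)

ACIDS = ("acetate", "propionate", "butyrate", "isobutyrate",
         "valerate", "isovalerate", "caproate")

#: Tolerance on the seven-acid sum of a proportion-mode profile (mmol/mol).
PROPORTION_SUM_TOL = 0.5


@dataclass
class VFAProfile:
    """Seven-acid VFA measurement for one bottle or cow.

    ``mode`` is ``"proportion"`` (values in mmol/mol, summing to 1000 over
    the seven acids) or ``"concentration"`` (values in mmol/L). ``total`` is
    the total VFA concentration in mmol/L and is carried in both modes.
    """

    acetate: float
    propionate: float
    butyrate: float
    isobutyrate: float = 0.0
    valerate: float = 0.0
    isovalerate: float = 0.0
    caproate: float = 0.0
    total: float = np.nan
    mode: str = "proportion"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("proportion", "concentration"):
            raise InvalidParameterError(f"unknown VFA mode {self.mode!r}")
        vals = self.values()
        if np.any(vals < 0):
            raise InvalidParameterError("VFA values must be nonnegative")
        if self.mode == "proportion":
            s = float(vals.sum())
            if abs(s - 1000.0) > PROPORTION_SUM_TOL:
                raise InvalidParameterError(
                    f"proportion-mode profile sums to {s}, expected 1000 +/- {PROPORTION_SUM_TOL}"
                )

    def values(self) -> np.ndarray:
        return np.array([getattr(self, a) for a in ACIDS], dtype=float)

    def proportions(self) -> "VFAProfile":
        """The profile re-expressed as mmol/mol over the seven acids."""
        if self.mode == "proportion":
            return self
        vals = self.values()
        s = vals.sum()
        if s <= 0:
            raise UndefinedStoichiometryError("all-zero VFA profile")
        props = vals / s * 1000.0
        return VFAProfile(*props, total=self.total, mode="proportion", meta=dict(self.meta))


def _renormalize_three(acetate: float, propionate: float, butyrate: float) -> np.ndarray:
    vals = np.array([acetate, propionate, butyrate], dtype=float)
    if np.any(vals < 0):
        raise InvalidParameterError("acid inputs must be nonnegative")
    s = vals.sum()
    if s <= 0:
        raise UndefinedStoichiometryError("stoichiometry undefined for all-zero acids")
    return vals / s * 1000.0


def ch4_vfa(acetate: float, propionate: float, butyrate: float) -> float:
    """Stoichiometric CH4 (mmol/mol VFA) from any common-scale acid values."""
    c2, c3, c4 = _renormalize_three(acetate, propionate, butyrate)
    return 0.5 * c2 - 0.25 * c3 + 0.5 * c4


def co2_vfa(acetate: float, propionate: float, butyrate: float) -> float:
    """Stoichiometric CO2 (mmol/mol VFA); adopted formula, see module docs."""
    c2, c3, c4 = _renormalize_three(acetate, propionate, butyrate)
    return 0.5 * c2 + 0.25 * c3 + 1.5 * c4


def vfa_ratios(profile: VFAProfile) -> dict:
    """Acetate:propionate, propionate:butyrate and lipogenic:glucogenic
    ((acetate + butyrate) / propionate) ratios."""
    p = profile.proportions()
    out = {}
    if p.propionate <= 0:
        raise UndefinedRatioError("acetate:propionate undefined (propionate = 0)")
    out["acetate_propionate"] = p.acetate / p.propionate
    if p.butyrate <= 0:
        raise UndefinedRatioError("propionate:butyrate undefined (butyrate = 0)")
    out["propionate_butyrate"] = p.propionate / p.butyrate
    out["lipogenic_glucogenic"] = (p.acetate + p.butyrate) / p.propionate
    return out


@dataclass
class StoichResult:
    ch4_vfa: float
    co2_vfa: float
    acetate_propionate: float
    propionate_butyrate: float
    lipogenic_glucogenic: float


def stoichiometry(profile: VFAProfile) -> StoichResult:
    """All stoichiometric predictions and ratios for one profile."""
    p = profile.proportions()
    ratios = vfa_ratios(p)
    return StoichResult(
        ch4_vfa=ch4_vfa(p.acetate, p.propionate, p.butyrate),
        co2_vfa=co2_vfa(p.acetate, p.propionate, p.butyrate),
        **ratios,
    )


def blank_correct_vfa(sample_total: float, blank_totals) -> float:
    """Net VFA production: sample total minus mean blank total (mmol/L).

    Molar proportions are deliberately left untouched — they are computed on
    the uncorrected measurement.
    """
    blank_totals = np.asarray(list(blank_totals), dtype=float)
    if blank_totals.size == 0:
        raise InvalidParameterError("at least one blank total required")
    net = float(sample_total - blank_totals.mean())
    if net < 0:
        logger.warning("blank-corrected VFA production %.3f floored at 0", net)
        net = 0.0
    return net


def group_ch4_vfa(profiles, method: str = "mean_proportions") -> float:
    """Group-level CH4_VFA, either from mean molar proportions
    (``"mean_proportions"``) or as the mean of per-profile values
    (``"per_profile"``)."""
    profiles = [p.proportions() for p in profiles]
    if not profiles:
        raise InvalidParameterError("at least one profile required")
    if method == "mean_proportions":
        c2 = np.mean([p.acetate for p in profiles])
        c3 = np.mean([p.propionate for p in profiles])
        c4 = np.mean([p.butyrate for p in profiles])
        return ch4_vfa(c2, c3, c4)
    if method == "per_profile":
        return float(np.mean([ch4_vfa(p.acetate, p.propionate, p.butyrate)
                              for p in profiles]))
    raise InvalidParameterError(f"unknown method {method!r}")
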