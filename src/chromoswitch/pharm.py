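"""Competitive E/Z receptor pharmacology with operational transduction.

The two photoisomers of an efficacy photoswitch bind the same site
competitively.  With no ligand depletion (free ~ total concentration), the
fractional occupancies at total switch concentration ``c`` and Z fraction
``fz`` follow the classical competitive-binding (Gaddum) expressions::

    rho_Z = (fz c / Kd_Z) / (1 + fz c / Kd_Z + (1 - fz) c / Kd_E)
    rho_E = ((1-fz) c / Kd_E) / (1 + fz c / Kd_Z + (1 - fz) c / Kd_E)

Receptor stimulus combines per-state intrinsic efficacies with the
constitutive tone ``basal`` (fraction of system maximum): free receptors
contribute ``basal``, receptors occupied by isomer *i* contribute
``max(basal + eff_i, 0)``.  A negative efficacy therefore encodes inverse
agonism — an occupied receptor is driven below its constitutive activity,
clamped at zero.  Stimulus is passed through Black–Leff-style operational
transduction with amplification ``tau`` and steepness ``n``::

    E* = (tau S)^n / ((tau S)^n + 1)

The amplification (receptor reserve) makes the plateau response depend on
the PSS composition only, not on total concentration, once occupancy nears
saturation — the basis of concentration-independent "chromocontrol".

Two rival wavelength/action-spectrum models are provided:

* efficacy switch:  bioactivity = a + b * (-log10(phi / (1 - phi)))
  — depends only on the E/Z ratio set by the PSS, never on concentration;
* affinity switch:  bioactivity = a + b * (-log10(phi * c_tot))
  — tracks the absolute concentration of the binding isomer, so doubling
  ``c_tot`` shifts every prediction by ``-b * log10(2)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd

from .photochem import PssCurve

__all__ = [
    "IsomerPharmacology",
    "OccupancyState",
    "SwitchClass",
    "DoseResponseSet",
    "IndependenceThreshold",
    "competitive_occupancy",
    "response",
    "plateau_response",
    "dose_response",
    "fdr",
    "independence_threshold",
    "action_spectrum_model",
    "classify_switch",
    "effective_potency",
    "analytic_response_ec50",
    "preset_from_potency",
    "get_preset",
    "PRESETS",
    "PHI_CLAMP_EPS",
]

#: Clamping epsilon for PSS fractions at 0 or 1 in the log-ratio models.
PHI_CLAMP_EPS = 1.0e-6


@dataclass(frozen=True)
class IsomerPharmacology:
    """Per-isomer binding and efficacy parameters plus receptor tone.

    Parameters
    ----------
    kd_E, kd_Z
        Equilibrium dissociation constants (M, > 0).  ``math.inf`` marks a
        non-binding isomer (the classical affinity-switch limit).
    eff_E, eff_Z
        Intrinsic efficacies in [-1, 1]; positive = agonist, 0 = silent
        (neutral) binder, negative = inverse agonist.
    basal
        Constitutive receptor tone as a stimulus fraction in [0, 1].
    hill_transduction
        Transduction steepness n >= 1.
    reserve_tau
        Operational amplification factor tau > 0 (receptor reserve).
    """

    kd_E: float
    kd_Z: float
    eff_E: float
    eff_Z: float
    basal: float = 0.0
    hill_transduction: float = 1.0
    reserve_tau: float = 10.0

    def __post_init__(self) -> None:
        if not (self.kd_E > 0 and self.kd_Z > 0):
            raise ValueError("dissociation constants must be > 0")
        for name in ("eff_E", "eff_Z"):
            if not (-1.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [-1, 1]")
        if not (0.0 <= self.basal <= 1.0):
            raise ValueError("basal must lie in [0, 1]")
        if self.hill_transduction < 1.0:
            raise ValueError("hill_transduction must be >= 1")
        if self.reserve_tau <= 0:
            raise ValueError("reserve_tau must be > 0")

    @property
    def affinity_ratio(self) -> float:
        """max(Kd) / min(Kd); inf for a one-isomer binder."""
        hi, lo = max(self.kd_E, self.kd_Z), min(self.kd_E, self.kd_Z)
        return math.inf if math.isinf(hi) else hi / lo


@dataclass(frozen=True)
class OccupancyState:
    """Fractional occupancies of the two isomers; ``rho_free`` is implied."""

    rho_E: np.ndarray | float
    rho_Z: np.ndarray | float

    def __post_init__(self) -> None:
        rE = np.asarray(self.rho_E, dtype=float)
        rZ = np.asarray(self.rho_Z, dtype=float)
        if np.any((rE < 0) | (rE > 1)) or np.any((rZ < 0) | (rZ > 1)):
            raise ValueError("occupancies must lie in [0, 1]")
        if np.any(rE + rZ > 1.0 + 1e-12):
            raise ValueError("total occupancy cannot exceed 1")

    @property
    def rho_free(self) -> np.ndarray | float:
        return 1.0 - np.asarray(self.rho_E) - np.asarray(self.rho_Z)


@dataclass(frozen=True)
class SwitchClass:
    """Switch-type classification outcome (see :func:`classify_switch`)."""

    label: Literal["ideal_efficacy", "nonideal_efficacy", "affinity", "inactive"]
    affinity_ratio: float
    potency_ok: bool


@dataclass
class DoseResponseSet:
    """Tidy dose–response table: columns ``conc_M``, ``response``, ``replicate``.

    ``meta`` carries generator ground truth (true responses, parameters,
    analytic EC50 where available) for recovery scoring.
    """

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"conc_M", "response", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"dose-response table missing columns {sorted(missing)}")
        if len(self.table) == 0:
            raise ValueError("dose-response table must be non-empty")


@dataclass(frozen=True)
class IndependenceThreshold:
    """Concentration threshold for PSS-only ("chromocontrol") behaviour."""

    c_min: float           # M, continuous solution
    kd_used: float         # M, occupancy half-saturation the multiples refer to
    multiple: int          # smallest integer m with m/(m+1) >= criterion
    multiple_continuous: float  # exact c_min / kd


# ---------------------------------------------------------------------------
# occupancy and response


def competitive_occupancy(c_tot, fz, pharm: IsomerPharmacology) -> OccupancyState:
    """Gaddum competitive occupancies of E and Z at total concentration ``c_tot``.

    ``c_tot`` and ``fz`` may be scalars or broadcastable arrays.  Free-ligand
    depletion is neglected (ligand in vast excess over receptor).
    """
    c = np.asarray(c_tot, dtype=float)
    f = np.asarray(fz, dtype=float)
    if np.any(c < 0):
        raise ValueError("c_tot must be >= 0")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("fz must lie in [0, 1]")
    xZ = f * c / pharm.kd_Z if not math.isinf(pharm.kd_Z) else np.zeros_like(f * c)
    xE = (1.0 - f) * c / pharm.kd_E if not math.isinf(pharm.kd_E) else np.zeros_like(f * c)
    denom = 1.0 + xZ + xE
    rho_Z = xZ / denom
    rho_E = xE / denom
    if np.isscalar(c_tot) and np.isscalar(fz):
        return OccupancyState(rho_E=float(rho_E), rho_Z=float(rho_Z))
    return OccupancyState(rho_E=rho_E, rho_Z=rho_Z)


def _stimulus(occ: OccupancyState, pharm: IsomerPharmacology):
    sZ = max(pharm.basal + pharm.eff_Z, 0.0)
    sE = max(pharm.basal + pharm.eff_E, 0.0)
    return (
        pharm.basal * np.asarray(occ.rho_free)
        + sZ * np.asarray(occ.rho_Z)
        + sE * np.asarray(occ.rho_E)
    )


def response(occ: OccupancyState, pharm: IsomerPharmacology):
    """Biological effect E* in [0, 1] from an occupancy state.

    Operational transduction of the clamped per-state stimulus (module
    docstring).  A saturating full agonist with tau = 10 approaches
    E* ~ 0.91; a saturating inverse agonist drives E* below the
    ligand-free constitutive level, down to 0.
    """
    S = _stimulus(occ, pharm)
    tS = (pharm.reserve_tau * S) ** pharm.hill_transduction
    E = tS / (tS + 1.0)
    if np.ndim(E) == 0:
        return float(E)
    return E


def plateau_response(pharm: IsomerPharmacology, fz: float) -> float:
    """Limiting effect as c -> infinity at fixed Z fraction ``fz``.

    At saturation the site partitions between isomers in proportion to
    ``fz / Kd_Z : (1 - fz) / Kd_E``.
    """
    wZ = 0.0 if math.isinf(pharm.kd_Z) else fz / pharm.kd_Z
    wE = 0.0 if math.isinf(pharm.kd_E) else (1.0 - fz) / pharm.kd_E
    tot = wZ + wE
    if tot == 0.0:  # nothing binds
        return response(OccupancyState(0.0, 0.0), pharm)
    occ = OccupancyState(rho_E=wE / tot, rho_Z=wZ / tot)
    return response(occ, pharm)


def dose_response(pharm: IsomerPharmacology, fz: float, c_grid) -> DoseResponseSet:
    """Noise-free effect E*(c) over a sorted positive concentration grid."""
    c = np.asarray(c_grid, dtype=float)
    if c.size == 0:
        raise ValueError("concentration grid must be non-empty")
    if np.any(c < 0) or np.any(np.diff(c) <= 0):
        raise ValueError("c_grid must be positive and strictly increasing")
    occ = competitive_occupancy(c, np.full_like(c, fz), pharm)
    E = response(occ, pharm)
    table = pd.DataFrame(
        {"conc_M": c, "response": np.asarray(E, float), "replicate": 0}
    )
    meta = {
        "fz": float(fz),
        "pharm": asdict(pharm),
        "ec50_true": analytic_response_ec50(pharm, fz),
    }
    return DoseResponseSet(table=table, meta=meta)


def fdr(pharm: IsomerPharmacology, fz_on: float, fz_off: float, c: float) -> float:
    """Functional dynamic range: E*(c, fz_on) - E*(c, fz_off) (signed)."""
    for f in (fz_on, fz_off):
        if not (0.0 <= f <= 1.0):
            raise ValueError("PSS fractions must lie in [0, 1]")
    e_on = response(competitive_occupancy(c, fz_on, pharm), pharm)
    e_off = response(competitive_occupancy(c, fz_off, pharm), pharm)
    return float(e_on - e_off)


def independence_threshold(
    pharm: IsomerPharmacology, tolerance: float = 0.83
) -> IndependenceThreshold:
    """Concentration above which bioactivity is set by the PSS alone.

    Convention: the target "nears saturation" when the total competitive
    occupancy by any E/Z mixture reaches ``tolerance`` (default 0.83).  For
    similar affinities the total occupancy is Langmuir in ``c / Kd``, so the
    continuous solution is ``c_min = Kd * tolerance / (1 - tolerance)`` and
    the smallest integer Kd multiple m satisfies m / (m + 1) >= tolerance
    (m = 5 at the default criterion).  For dissimilar affinities the larger
    Kd is used (conservative) with a warning.
    """
    if not (0.0 < tolerance < 1.0):
        raise ValueError("tolerance must lie in (0, 1)")
    kds = [k for k in (pharm.kd_E, pharm.kd_Z) if not math.isinf(k)]
    if not kds:
        raise ValueError("at least one isomer must bind")
    kd = max(kds)
    if pharm.affinity_ratio > 3.0:
        warnings.warn(
            "isomer affinities differ by more than 3x; threshold uses the "
            "weaker (larger) Kd and is only indicative",
            stacklevel=2,
        )
    ratio = tolerance / (1.0 - tolerance)
    m = math.ceil(ratio - 1e-12)
    return IndependenceThreshold(
        c_min=kd * ratio,
        kd_used=kd,
        multiple=m,
        multiple_continuous=ratio,
    )


# ---------------------------------------------------------------------------
# action-spectrum models


def _clamped_phi(fz) -> np.ndarray:
    phi = np.asarray(fz, dtype=float)
    if np.any((phi <= 0.0) | (phi >= 1.0)):
        warnings.warn(
            f"PSS fraction at 0 or 1 clamped to epsilon = {PHI_CLAMP_EPS:g} "
            "for the log-ratio model",
            stacklevel=3,
        )
    return np.clip(phi, PHI_CLAMP_EPS, 1.0 - PHI_CLAMP_EPS)


def action_spectrum_model(
    pss: PssCurve,
    model: Literal["efficacy", "affinity"],
    c_tot: float,
    scale: float = 1.0,
    offset: float = 0.0,
) -> np.ndarray:
    """Predicted bioactivity versus wavelength under a rival switch model.

    efficacy:  offset + scale * (-log10(phi / (1 - phi)))   (c-independent)
    affinity:  offset + scale * (-log10(phi * c_tot))       (shifts with c)
    """
    phi = _clamped_phi(pss.fz)
    if model == "efficacy":
        x = -np.log10(phi / (1.0 - phi))
    elif model == "affinity":
        if c_tot <= 0:
            raise ValueError("c_tot must be > 0 for the affinity model")
        x = -np.log10(phi * c_tot)
    else:
        raise ValueError(f"unknown model {model!r}")
    return offset + scale * x


# ---------------------------------------------------------------------------
# potency and classification


def analytic_response_ec50(pharm: IsomerPharmacology, fz: float) -> float | None:
    """Closed-form response EC50 at fixed ``fz`` (equal Kd, n = 1 only).

    With equal affinities the response is a Mobius function of c,
    E*(c) = (tau b K + tau s c) / (K (1 + tau b) + (1 + tau s) c)
    with mixture stimulus s = fz*max(b+eff_Z,0) + (1-fz)*max(b+eff_E,0),
    whose half-effect concentration is K (1 + tau b) / (1 + tau s).
    Returns None when the assumptions do not hold.
    """
    if pharm.hill_transduction != 1.0:
        return None
    if math.isinf(pharm.kd_E) or math.isinf(pharm.kd_Z):
        return None
    if abs(pharm.kd_E - pharm.kd_Z) > 1e-9 * pharm.kd_Z:
        return None
    K = pharm.kd_Z
    tau, b = pharm.reserve_tau, pharm.basal
    s = fz * max(b + pharm.eff_Z, 0.0) + (1.0 - fz) * max(b + pharm.eff_E, 0.0)
    return K * (1.0 + tau * b) / (1.0 + tau * s)


def effective_potency(pharm: IsomerPharmacology, isomer: Literal["E", "Z"]) -> float | None:
    """Half-effect concentration of a pure isomer (EC50 or IC50), numerically.

    Evaluates the pure-isomer dose–response from 0.1 pM to 1 mM and locates
    the concentration at half the baseline-to-plateau change.  Returns None
    for a non-binding or effect-silent isomer.
    """
    kd = pharm.kd_Z if isomer == "Z" else pharm.kd_E
    if math.isinf(kd):
        return None
    fz = 1.0 if isomer == "Z" else 0.0
    c = np.geomspace(1e-13, 1e-3, 600)
    E = np.asarray(response(competitive_occupancy(c, np.full_like(c, fz), pharm), pharm))
    e0 = response(OccupancyState(0.0, 0.0), pharm)
    e_plat = plateau_response(pharm, fz)
    if abs(e_plat - e0) < 1e-6:
        return None
    half = 0.5 * (e0 + e_plat)
    # monotone toward the plateau; interpolate on the ordered branch
    logc = np.log10(c)
    if e_plat > e0:
        return float(10.0 ** np.interp(half, E, logc))
    return float(10.0 ** np.interp(-half, -E, logc))


def classify_switch(
    pharm: IsomerPharmacology,
    potency_ceiling: float = 50e-9,
    affinity_ratio_max: float = 3.0,
    silent_eff: float = 0.05,
) -> SwitchClass:
    """Classify a photoswitch by the ideal-efficacy decision rules.

    * ``inactive`` — both isomers effect-silent (|eff| < ``silent_eff``);
    * ``affinity`` — isomer affinities differ by more than 10x;
    * ``ideal_efficacy`` — similar affinities (ratio <= ``affinity_ratio_max``),
      opposing efficacies (or one silent binder with the other |eff| >= 0.5),
      and both pure-isomer half-effect potencies below ``potency_ceiling``;
    * ``nonideal_efficacy`` — anything else.

    The silence check precedes the affinity check: a compound with no effect
    in either form is inactive regardless of its binding.
    """
    ratio = pharm.affinity_ratio
    effs = (abs(pharm.eff_E), abs(pharm.eff_Z))

    if max(effs) < silent_eff:
        return SwitchClass("inactive", ratio, False)

    potencies = [effective_potency(pharm, iso) for iso in ("E", "Z")]
    potency_ok = all(p is not None and p < potency_ceiling for p in potencies)

    if ratio > 10.0:
        return SwitchClass("affinity", ratio, potency_ok)

    opposing = pharm.eff_E * pharm.eff_Z < 0.0
    silent_pair = min(effs) < silent_eff and max(effs) >= 0.5
    if ratio <= affinity_ratio_max and (opposing or silent_pair) and potency_ok:
        return SwitchClass("ideal_efficacy", ratio, potency_ok)
    return SwitchClass("nonideal_efficacy", ratio, potency_ok)


# ---------------------------------------------------------------------------
# presets

#: Reference Z fraction at which preset potencies are anchored (the
#: Z-enriched PSS of the bundled calibrated spectra).
PRESET_FZ_REF = 0.95


def preset_from_potency(
    target_ec50: float,
    fz_ref: float = PRESET_FZ_REF,
    eff_E: float = -0.3,
    eff_Z: float = 1.0,
    basal: float = 0.02,
    tau: float = 10.0,
) -> IsomerPharmacology:
    """Equal-affinity pharmacology whose response EC50 at ``fz_ref`` is
    ``target_ec50``, by inverting the Mobius EC50 expression
    (:func:`analytic_response_ec50`)."""
    s = fz_ref * max(basal + eff_Z, 0.0) + (1.0 - fz_ref) * max(basal + eff_E, 0.0)
    kd = target_ec50 * (1.0 + tau * s) / (1.0 + tau * basal)
    return IsomerPharmacology(
        kd_E=kd, kd_Z=kd, eff_E=eff_E, eff_Z=eff_Z,
        basal=basal, hill_transduction=1.0, reserve_tau=tau,
    )


def _build_presets() -> dict[str, IsomerPharmacology]:
    presets = {
        # Z agonist / E inverse agonist efficacy switches anchored to the
        # measured 365-nm response potencies on the respective channel.
        "trpc4_azpico": preset_from_potency(3.0e-9),
        "trpc5_azpico": preset_from_potency(4.0e-9),
        "trpc5_azhc": preset_from_potency(6.4e-9),
        # AzHC binds but does nothing on TRPC4 in either form.
        "trpc4_azhc_inactive": IsomerPharmacology(
            kd_E=5.7e-8, kd_Z=5.7e-8, eff_E=0.0, eff_Z=0.0,
            basal=0.02, reserve_tau=10.0,
        ),
        # Hypothetical ideal affinity switch: only Z binds (agonist).
        "ideal_affinity_reference": IsomerPharmacology(
            kd_E=math.inf, kd_Z=3.0e-9, eff_E=0.0, eff_Z=1.0,
            basal=0.02, reserve_tau=10.0,
        ),
    }
    return presets


PRESETS: dict[str, IsomerPharmacology] = _build_presets()


def get_preset(name: str) -> IsomerPharmacology:
    """Look up a bundled pharmacology preset by name."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
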