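"""Free-energy landscapes and Michaelis-Menten kinetics under the BEP relation.

The two-step catalytic scheme E + S <-> ES -> E + P is described by the free
energy of substrate binding (``dG1``, kJ/mol) and the total free energy of the
reaction S -> P (``dGT``, kJ/mol); the second step carries the remainder
``dG2 = dGT - dG1``.  The Bronsted-Evans-Polanyi (BEP) relation maps each
step's driving force to its activation barrier, ``Ea = Ea0 + alpha * dG``, and
the Arrhenius law turns barriers into rate constants.  Folding the
pre-exponential factor and the equilibrium barrier into a single reference
rate constant ``k0`` gives

    k1  = k1_0 * g1**(-alpha1)          g1 = exp(dG1 / RT)
    k1r = k1_0 * g1**(1 - alpha1)
    k2  = k2_0 * (g1 / gT)**alpha2      gT = exp(dGT / RT)

so the forward/reverse ratio of each step, and the Haldane identity
``k1*k2 / (k1r*k2r) = exp(-dGT/RT)``, hold by construction.

Units: concentrations in uM, energies in kJ/mol, time in s; ``k1_0`` in
1/(uM s) and ``k2_0`` in 1/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "GAS_CONSTANT_KJ",
    "DEFAULT_TEMPERATURE",
    "ThermoLandscape",
    "RateConstants",
    "AssayCondition",
    "rate_constants",
    "michaelis_constant",
    "dG1_for_km",
    "activity",
]

#: Gas constant in kJ/(mol K).
GAS_CONSTANT_KJ = 8.314e-3

#: Conventional biochemical reference temperature (25 C), in K.
DEFAULT_TEMPERATURE = 298.15

# Reduced driving forces |dG/RT| beyond this would overflow/underflow the
# exponentials long before double precision saturates; reject early.
_MAX_REDUCED_ENERGY = 500.0

MECHANISMS = ("standard", "reversible", "competitive", "uncompetitive")


def _check_reduced(name: str, value: float) -> None:
    if not math.isfinite(value) or abs(value) > _MAX_REDUCED_ENERGY:
        raise ValueError(
            f"{name}/RT = {value:.3g} outside the numerically safe range "
            f"(+/-{_MAX_REDUCED_ENERGY:g}); rescale the landscape"
        )


@dataclass(frozen=True)
class ThermoLandscape:
    """Free-energy description of one enzyme.

    Parameters
    ----------
    dG1 : float
        Free energy of substrate binding E + S -> ES, kJ/mol.
    dGT : float
        Total free energy of S -> P, kJ/mol.  The release step carries
        ``dG2 = dGT - dG1``.
    alpha1, alpha2 : float
        BEP coefficients of the two steps, in (0, 1).  The reverse of step 1
        has coefficient ``1 - alpha1``; it is never stored.
    k1_0 : float
        Reference rate constant of step 1 at dG1 = 0, 1/(uM s).
    k2_0 : float
        Reference rate constant of step 2 at dG2 = 0, 1/s.
    temperature : float
        Absolute temperature, K.
    """

    dG1: float
    dGT: float
    alpha1: float = 0.5
    alpha2: float = 0.5
    k1_0: float = 1.0
    k2_0: float = 1.0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha1 < 1.0 and 0.0 < self.alpha2 < 1.0):
            raise ValueError("BEP coefficients must lie strictly in (0, 1)")
        if self.k1_0 <= 0 or self.k2_0 <= 0:
            raise ValueError("reference rate constants must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")
        _check_reduced("dG1", self.dG1 / self.RT)
        _check_reduced("dGT", self.dGT / self.RT)
        _check_reduced("dG2", self.dG2 / self.RT)

    @property
    def RT(self) -> float:
        """Thermal energy R*T in kJ/mol."""
        return GAS_CONSTANT_KJ * self.temperature

    @property
    def dG2(self) -> float:
        """Free energy of the release step ES -> E + P, kJ/mol (dGT - dG1)."""
        return self.dGT - self.dG1

    @property
    def g1(self) -> float:
        """exp(dG1/RT), the reduced equilibrium factor of step 1."""
        return math.exp(self.dG1 / self.RT)

    @property
    def g2(self) -> float:
        """exp(dG2/RT)."""
        return math.exp(self.dG2 / self.RT)

    @property
    def gT(self) -> float:
        """exp(dGT/RT)."""
        return math.exp(self.dGT / self.RT)

    @property
    def K(self) -> float:
        """Dimensionless ratio k2/(k1r) = k2_0*g1^(a1+a2-1)/(k1_0*gT^a2).

        Km factorises as g1*(1+K); when alpha1 + alpha2 = 1, K does not
        depend on dG1.
        """
        log_k = (
            math.log(self.k2_0 / self.k1_0)
            + (self.alpha1 + self.alpha2 - 1.0) * self.dG1 / self.RT
            - self.alpha2 * self.dGT / self.RT
        )
        _check_reduced("log K", log_k)
        return math.exp(log_k)

    def with_dG1(self, dG1: float) -> "ThermoLandscape":
        """Copy of this landscape with the binding free energy replaced."""
        return ThermoLandscape(
            dG1=dG1,
            dGT=self.dGT,
            alpha1=self.alpha1,
            alpha2=self.alpha2,
            k1_0=self.k1_0,
            k2_0=self.k2_0,
            temperature=self.temperature,
        )


@dataclass(frozen=True)
class RateConstants:
    """BEP-derived rate constants of the two-step scheme.

    ``k1`` [1/(uM s)] and ``k1r`` [1/s] are binding/unbinding; ``k2`` [1/s]
    and ``k2r`` [1/(uM s)] are product release and its reverse.  Instances
    satisfy the Haldane identity by construction.
    """

    k1: float
    k1r: float
    k2: float
    k2r: float

    def __post_init__(self) -> None:
        for name in ("k1", "k1r", "k2", "k2r"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"rate constant {name} must be finite and > 0, got {v!r}")

    def haldane_ratio(self) -> float:
        """(k1*k2)/(k1r*k2r); equals exp(-dGT/RT) for a consistent landscape."""
        return (self.k1 * self.k2) / (self.k1r * self.k2r)


@dataclass(frozen=True)
class AssayCondition:
    """Concentrations and mechanism tag for one rate evaluation.

    ``gamma`` is the degree of inhibition [I]/Ki (dimensionless); it only
    enters the competitive/uncompetitive rate laws.
    """

    S: float
    ET: float = 0.01
    P: float = 0.0
    mechanism: str = "standard"
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.S < 0 or self.P < 0 or self.ET < 0 or self.gamma < 0:
            raise ValueError("concentrations and gamma must be non-negative")
        if self.mechanism not in MECHANISMS:
            raise ValueError(
                f"unknown mechanism {self.mechanism!r}; expected one of {MECHANISMS}"
            )


def rate_constants(landscape: ThermoLandscape) -> RateConstants:
    """All four rate constants of the scheme, via BEP + Arrhenius.

    Exponentials are assembled in log space so that intermediate overflow
    cannot occur for landscapes that pass the range checks.
    """
    rt = landscape.RT
    x1 = landscape.dG1 / rt
    x2 = landscape.dG2 / rt
    a1, a2 = landscape.alpha1, landscape.alpha2
    lk1_0 = math.log(landscape.k1_0)
    lk2_0 = math.log(landscape.k2_0)
    return RateConstants(
        k1=math.exp(lk1_0 - a1 * x1),
        k1r=math.exp(lk1_0 + (1.0 - a1) * x1),
        k2=math.exp(lk2_0 - a2 * x2),
        k2r=math.exp(lk2_0 + (1.0 - a2) * x2),
    )


def michaelis_constant(landscape: ThermoLandscape) -> float:
    """Michaelis constant Km = g1*(1 + K) in uM.

    Algebraically identical to the kinetic definition (k1r + k2)/k1.
    """
    rt = landscape.RT
    # log-space: Km = exp(dG1/RT) * (1 + K); use log1p for the 1+K factor.
    log_km = landscape.dG1 / rt + math.log1p(landscape.K)
    _check_reduced("log Km", log_km)
    return math.exp(log_km)


def dG1_for_km(template: ThermoLandscape, km_target: float) -> float:
    """Binding free energy (kJ/mol) at which the landscape's Km equals a target.

    Km = g1*(1+K) is strictly increasing in dG1 (the derivative of log Km
    w.r.t. dG1/RT is 1 + (a1+a2-1)*K/(1+K) > 0 for alphas in (0,1)), so the
    inverse is unique.  Closed form when alpha1 + alpha2 = 1 (K constant);
    otherwise a bracketed root solve on log Km.
    """
    if km_target <= 0:
        raise ValueError("Km target must be positive")
    rt = template.RT
    a1, a2 = template.alpha1, template.alpha2
    if abs(a1 + a2 - 1.0) <= 1e-12:
        return rt * (math.log(km_target) - math.log1p(template.K))

    from scipy.optimize import brentq

    def log_km_err(dG1: float) -> float:
        ls = template.with_dG1(dG1)
        return (ls.dG1 / rt + math.log1p(ls.K)) - math.log(km_target)

    lo, hi = -100.0 * rt, 100.0 * rt
    while log_km_err(lo) > 0:
        lo *= 2.0
        if lo < -_MAX_REDUCED_ENERGY * rt * 0.9:
            raise ValueError("Km target unreachable within the safe dG1 range")
    while log_km_err(hi) < 0:
        hi *= 2.0
        if hi > _MAX_REDUCED_ENERGY * rt * 0.9:
            raise ValueError("Km target unreachable within the safe dG1 range")
    return float(brentq(log_km_err, lo, hi, xtol=1e-12))


def activity(landscape: ThermoLandscape, cond: AssayCondition) -> float:
    """Michaelis-Menten rate v = k2*[S]*[ET] / (Km + [S]) in uM/s.

    Only the standard mechanism is handled here; reversible and inhibited
    variants live in :mod:`enzact.mechanisms`.
    """
    if cond.mechanism != "standard":
        raise ValueError(
            f"activity() handles the standard mechanism only, got {cond.mechanism!r}; "
            "use enzact.mechanisms.rate()"
        )
    k2 = rate_constants(landscape).k2
    km = michaelis_constant(landscape)
    return k2 * cond.S * cond.ET / (km + cond.S)
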