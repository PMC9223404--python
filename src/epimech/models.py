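"""Tension and pressure model families and their linearized representations.

Two families of junction-tension laws are supported, both pi-periodic in the
junction orientation theta:

* the anisotropic spring family,  T(l, theta) = Lam0(theta) - Lam1(theta) * l,
  with Lam0(theta) = lambda0 * (1 + mu0 * cos 2(theta - phi0)) the anisotropic
  line tension and Lam1(theta) = lambda1 * (1 + mu1 * cos 2(theta - phi1)) the
  anisotropic junction spring constant (positive feedback between tension and
  junction shrinkage). Variants A..E drop anisotropies and/or the spring term:
  A is the full model; B sets mu1 = 0; C sets mu0 = mu1 = 0; D drops the
  spring term entirely; E is a constant tension lambda0.

* the conventional family,  T = Lam0(theta) + Gam(theta) * (L_i + L_j),
  combining line tension with cortical (perimeter) elasticity Gam(theta) =
  Gamma0 * (1 + muG * cos 2(theta - phiG)); variants drop either anisotropy.

Cell pressure follows P(A) = -k*A + P0 by default, with 1/A and exp(-A)
alternatives. The basal pressure P0 never enters estimation: around an
interior vertex the constant-pressure contributions of the surrounding cells
cancel exactly (closed loop), so only the k column is identifiable.

Every law is linear in a transformed coefficient set, e.g.
Lam0(theta) = lambda0 + lambda0' sin 2theta + lambda0'' cos 2theta with
lambda0' = lambda0 mu0 sin 2phi0, lambda0'' = lambda0 mu0 cos 2phi0; the
feature rows produced here are the corresponding design-matrix rows L_T, L_P.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace

import numpy as np

from .errors import ConfigurationError, DegenerateScaleError, DomainError
from .mesh import fold_angle

__all__ = [
    "ANISO_SPRING",
    "CONVENTIONAL",
    "ModelSpec",
    "ParameterSet",
    "LinearCoefficients",
    "tension",
    "pressure",
    "tension_features",
    "pressure_features",
    "from_polar",
    "to_polar",
    "all_aniso_spring_specs",
    "all_conventional_specs",
]

ANISO_SPRING = "anisotropic_spring"
CONVENTIONAL = "conventional"

# design-matrix column names per (family, variant); the leading column is the
# fixed-scale coefficient (lambda0 resp. Lambda0), the rest are estimated
_TENSION_COLUMNS = {
    (ANISO_SPRING, "A"): ("lambda0", "lambda0_s", "lambda0_c", "lambda1", "lambda1_s", "lambda1_c"),
    (ANISO_SPRING, "B"): ("lambda0", "lambda0_s", "lambda0_c", "lambda1"),
    (ANISO_SPRING, "C"): ("lambda0", "lambda1"),
    (ANISO_SPRING, "D"): ("lambda0", "lambda0_s", "lambda0_c"),
    (ANISO_SPRING, "E"): ("lambda0",),
    (CONVENTIONAL, "both_aniso"): ("Lambda0", "Lambda0_s", "Lambda0_c", "Gamma0", "Gamma_s", "Gamma_c"),
    (CONVENTIONAL, "line_aniso"): ("Lambda0", "Lambda0_s", "Lambda0_c", "Gamma0"),
    (CONVENTIONAL, "elasticity_aniso"): ("Lambda0", "Gamma0", "Gamma_s", "Gamma_c"),
    (CONVENTIONAL, "isotropic"): ("Lambda0", "Gamma0"),
}

_PRESSURE_FORMS = ("linear", "inverse", "exponential")


@dataclass(frozen=True)
class ModelSpec:
    """A (family, variant, pressure_form) triple naming one candidate model."""

    family: str = ANISO_SPRING
    variant: str = "A"
    pressure_form: str = "linear"

    def __post_init__(self):
        if (self.family, self.variant) not in _TENSION_COLUMNS:
            raise ConfigurationError(
                f"unknown model {self.family}/{self.variant}"
            )
        if self.pressure_form not in _PRESSURE_FORMS:
            raise ConfigurationError(f"unknown pressure form {self.pressure_form!r}")

    @property
    def tension_columns(self) -> tuple[str, ...]:
        return _TENSION_COLUMNS[(self.family, self.variant)]

    @property
    def n_free_parameters(self) -> int:
        """Free coefficients p entering AIC: tension columns minus the fixed
        scale, plus the pressure coefficient k."""
        return len(self.tension_columns) - 1 + 1

    @property
    def label(self) -> str:
        if self.family == ANISO_SPRING:
            return self.variant
        return f"conv:{self.variant}"

    def to_json_dict(self) -> dict:
        return {"family": self.family, "variant": self.variant,
                "pressure_form": self.pressure_form}

    @classmethod
    def from_json_dict(cls, d: dict) -> "ModelSpec":
        return cls(d.get("family", ANISO_SPRING), d.get("variant", "A"),
                   d.get("pressure_form", "linear"))

    @classmethod
    def from_label(cls, label: str, pressure_form: str = "linear") -> "ModelSpec":
        """Parse ``"A"``..``"E"`` or ``"conv:<variant>"``."""
        if label.startswith("conv:"):
            return cls(CONVENTIONAL, label.split(":", 1)[1], pressure_form)
        return cls(ANISO_SPRING, label.upper(), pressure_form)


def all_aniso_spring_specs(pressure_form: str = "linear") -> list[ModelSpec]:
    return [ModelSpec(ANISO_SPRING, v, pressure_form) for v in "ABCDE"]


def all_conventional_specs(pressure_form: str = "linear") -> list[ModelSpec]:
    return [ModelSpec(CONVENTIONAL, v, pressure_form)
            for v in ("both_aniso", "line_aniso", "elasticity_aniso", "isotropic")]


@dataclass
class ParameterSet:
    """Mechanical parameters; fields unused by a given ModelSpec are ignored.

    lambda0 doubles as the base line tension Lambda0 of the conventional
    family (with mu0/phi0 its anisotropy); Gamma0/muG/phiG parameterize the
    cortical elasticity. Orientations phi are in [0, pi).
    """

    lambda0: float = 1.0
    mu0: float = 0.0
    phi0: float = 0.0
    lambda1: float = 0.0
    mu1: float = 0.0
    phi1: float = 0.0
    Gamma0: float = 0.0
    muG: float = 0.0
    phiG: float = 0.0
    k: float = 1.0
    P0: float = 0.0
    A0: float = 1.0

    def to_json_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json_dict(cls, d: dict) -> "ParameterSet":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: float(v) for k, v in d.items() if k in known})

    def replace(self, **kw) -> "ParameterSet":
        return replace(self, **kw)


@dataclass
class LinearCoefficients:
    """Named linear coefficients for one ModelSpec plus the pressure modulus k."""

    spec: ModelSpec
    tension: dict[str, float]
    k: float

    def vector(self) -> np.ndarray:
        """Coefficient vector ordered as the tension feature columns, then k."""
        return np.array(
            [self.tension[c] for c in self.spec.tension_columns] + [self.k]
        )


# ---------------------------------------------------------------- features

def _sin_cos_2theta(theta):
    th = np.asarray(theta, dtype=float)
    return np.sin(2.0 * th), np.cos(2.0 * th)


def tension_features(spec: ModelSpec, l, theta, L_sum=None) -> np.ndarray:
    """Design-matrix rows for the tension law.

    Accepts scalars or equal-length arrays; returns shape (n_columns,) for
    scalars and (N, n_columns) for arrays. The dot product of a row with
    :func:`from_polar` coefficients reproduces :func:`tension` exactly.
    """
    l = np.asarray(l, dtype=float)
    s2, c2 = _sin_cos_2theta(theta)
    cols = []
    if spec.family == ANISO_SPRING:
        for name in spec.tension_columns:
            if name == "lambda0":
                cols.append(np.ones_like(l))
            elif name == "lambda0_s":
                cols.append(s2)
            elif name == "lambda0_c":
                cols.append(c2)
            elif name == "lambda1":
                cols.append(-l)
            elif name == "lambda1_s":
                cols.append(-l * s2)
            elif name == "lambda1_c":
                cols.append(-l * c2)
    else:
        if L_sum is None:
            raise ConfigurationError("conventional family requires L_sum")
        L = np.asarray(L_sum, dtype=float)
        for name in spec.tension_columns:
            if name == "Lambda0":
                cols.append(np.ones_like(l))
            elif name == "Lambda0_s":
                cols.append(s2)
            elif name == "Lambda0_c":
                cols.append(c2)
            elif name == "Gamma0":
                cols.append(L)
            elif name == "Gamma_s":
                cols.append(L * s2)
            elif name == "Gamma_c":
                cols.append(L * c2)
    out = np.stack(np.broadcast_arrays(*cols), axis=-1)
    return out


def pressure_features(spec: ModelSpec, A) -> np.ndarray:
    """The single pressure column: -A (linear), 1/A (inverse) or exp(-A)."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0.0):
        raise DomainError("cell area must be positive")
    if spec.pressure_form == "linear":
        col = -A
    elif spec.pressure_form == "inverse":
        col = 1.0 / A
    else:
        col = np.exp(-A)
    return col[..., np.newaxis]


# ---------------------------------------------------------- polar transforms

def from_polar(spec: ModelSpec, params: ParameterSet) -> LinearCoefficients:
    """Convert (mu, phi) anisotropy parameters to linear coefficients.

    lambda' = lambda mu sin 2phi and lambda'' = lambda mu cos 2phi for each
    anisotropic coefficient present in the variant.
    """
    t: dict[str, float] = {}
    p = params
    for name in spec.tension_columns:
        if name in ("lambda0", "Lambda0"):
            t[name] = p.lambda0
        elif name == "lambda0_s" or name == "Lambda0_s":
            t[name] = p.lambda0 * p.mu0 * math.sin(2 * p.phi0)
        elif name == "lambda0_c" or name == "Lambda0_c":
            t[name] = p.lambda0 * p.mu0 * math.cos(2 * p.phi0)
        elif name == "lambda1":
            t[name] = p.lambda1
        elif name == "lambda1_s":
            t[name] = p.lambda1 * p.mu1 * math.sin(2 * p.phi1)
        elif name == "lambda1_c":
            t[name] = p.lambda1 * p.mu1 * math.cos(2 * p.phi1)
        elif name == "Gamma0":
            t[name] = p.Gamma0
        elif name == "Gamma_s":
            t[name] = p.Gamma0 * p.muG * math.sin(2 * p.phiG)
        elif name == "Gamma_c":
            t[name] = p.Gamma0 * p.muG * math.cos(2 * p.phiG)
    return LinearCoefficients(spec, t, p.k)


def _polar_pair(scale: float, s: float, c: float) -> tuple[float, float]:
    """Invert (lambda mu sin2phi, lambda mu cos2phi) -> (mu, phi in [0,pi))."""
    r = math.hypot(s, c)
    if r == 0.0:
        return 0.0, 0.0  # orientation undefined; report 0 by convention
    mu = r / scale
    phi = fold_angle(0.5 * math.atan2(s, c))
    return mu, phi


def to_polar(coeffs: LinearCoefficients) -> ParameterSet:
    """Convert linear coefficients back to the polar parameterization."""
    spec, t = coeffs.spec, coeffs.tension
    if spec.family == ANISO_SPRING:
        lam0 = t["lambda0"]
        if lam0 <= 0.0:
            raise DegenerateScaleError("lambda0 must be positive for polar form")
        mu0, phi0 = _polar_pair(lam0, t.get("lambda0_s", 0.0), t.get("lambda0_c", 0.0))
        lam1 = t.get("lambda1", 0.0)
        if "lambda1_s" in t or "lambda1_c" in t:
            if lam1 <= 0.0:
                raise DegenerateScaleError("lambda1 must be positive for polar form")
            mu1, phi1 = _polar_pair(lam1, t.get("lambda1_s", 0.0), t.get("lambda1_c", 0.0))
        else:
            mu1, phi1 = 0.0, 0.0
        return ParameterSet(lambda0=lam0, mu0=mu0, phi0=phi0,
                            lambda1=lam1, mu1=mu1, phi1=phi1, k=coeffs.k)
    lam0 = t["Lambda0"]
    if lam0 <= 0.0:
        raise DegenerateScaleError("Lambda0 must be positive for polar form")
    mu0, phi0 = _polar_pair(lam0, t.get("Lambda0_s", 0.0), t.get("Lambda0_c", 0.0))
    g0 = t.get("Gamma0", 0.0)
    if "Gamma_s" in t or "Gamma_c" in t:
        if g0 <= 0.0:
            raise DegenerateScaleError("Gamma0 must be positive for polar form")
        muG, phiG = _polar_pair(g0, t.get("Gamma_s", 0.0), t.get("Gamma_c", 0.0))
    else:
        muG, phiG = 0.0, 0.0
    return ParameterSet(lambda0=lam0, mu0=mu0, phi0=phi0,
                        Gamma0=g0, muG=muG, phiG=phiG, k=coeffs.k)


# --------------------------------------------------------------- evaluation

def tension(spec: ModelSpec, params: ParameterSet, l, theta, L_sum=None):
    """Evaluate the junction tension law for one model.

    Implemented as the dot product of the linearized feature row with the
    linearized coefficients, so it agrees with the design matrix exactly.
    """
    coeffs = from_polar(spec, params).vector()[:-1]
    feats = tension_features(spec, l, theta, L_sum)
    out = feats @ coeffs
    return float(out) if np.ndim(out) == 0 else out


def pressure(spec: ModelSpec, params: ParameterSet, A):
    """Evaluate the pressure law P(A) (with the basal offset P0 added)."""
    col = pressure_features(spec, A)[..., 0]
    out = params.k * col + params.P0
    return float(out) if np.ndim(out) == 0 else out


# ------------------------------------------------------------- serialization

def config_to_json(spec: ModelSpec, params: ParameterSet) -> str:
    return json.dumps({"model": spec.to_json_dict(), "params": params.to_json_dict()},
                      indent=2)


def config_from_json(text: str) -> tuple[ModelSpec, ParameterSet]:
    d = json.loads(text)
    return (ModelSpec.from_json_dict(d.get("model", {})),
            ParameterSet.from_json_dict(d.get("params", {})))
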