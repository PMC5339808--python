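"""Candidate duration distributions for bout analysis.

Seven families defined on the tail domain ``x >= x_min``:

========================  ============================================  ======
family                    density (up to normalization)                 params
========================  ============================================  ======
``power_law``             x^-alpha                                      alpha
``exponential``           exp(-lam*x)                                   lam
``log_normal``            exp(-(ln x - mu)^2 / (2 sigma^2)) / x         mu, sigma
``weibull``               x^(beta-1) * exp(-lam * x^beta)               beta, lam
``trunc_power_law``       x^-alpha * exp(-lam*x)                        alpha, lam
``biexponential``         delta*Exp(lam) + (1-delta)*Exp(gamma)         lam, gamma, delta
``exp_plus_tpl``          delta*Exp(gamma) + (1-delta)*TPL(alpha, lam)  alpha, lam, gamma, delta
========================  ============================================  ======

Every component is individually normalized on ``[x_min, inf)`` so mixture
weights ``delta`` and ``1 - delta`` are probability masses.  ``x_min`` is a
domain bound selected upstream, not a free likelihood parameter, so it is not
counted in the parameter count used for BIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import special, stats

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "ParameterDomainError",
    "n_params",
    "log_pdf",
    "pdf",
    "cdf",
    "sf",
    "normalization_constant",
    "upper_incomplete_gamma",
    "log_upper_incomplete_gamma",
]

FAMILIES = (
    "power_law",
    "exponential",
    "log_normal",
    "weibull",
    "trunc_power_law",
    "biexponential",
    "exp_plus_tpl",
)

_PARAM_NAMES = {
    "power_law": ("alpha",),
    "exponential": ("lam",),
    "log_normal": ("mu", "sigma"),
    "weibull": ("beta", "lam"),
    "trunc_power_law": ("alpha", "lam"),
    "biexponential": ("lam", "gamma", "delta"),
    "exp_plus_tpl": ("alpha", "lam", "gamma", "delta"),
}


class ParameterDomainError(ValueError):
    """Raised when model parameters fall outside the family's domain."""


def n_params(family: str) -> int:
    """Number of free parameters counted in BIC (``x_min`` excluded)."""
    try:
        return len(_PARAM_NAMES[family])
    except KeyError:
        raise ParameterDomainError(f"unknown family {family!r}") from None


@dataclass(frozen=True)
class ModelSpec:
    """A distribution family with named parameters and lower bound ``x_min``."""

    family: str
    params: Mapping[str, float] = field(default_factory=dict)
    x_min: float = 1.0

    def __post_init__(self):
        validate_spec(self)

    def param_array(self) -> np.ndarray:
        return np.array([self.params[k] for k in _PARAM_NAMES[self.family]])

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": dict(self.params),
            "x_min": float(self.x_min),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(d["family"], dict(d["params"]), float(d["x_min"]))


def validate_spec(spec: ModelSpec) -> None:
    fam, p, xm = spec.family, spec.params, spec.x_min
    if fam not in FAMILIES:
        raise ParameterDomainError(f"unknown family {fam!r}")
    missing = set(_PARAM_NAMES[fam]) - set(p)
    if missing:
        raise ParameterDomainError(f"{fam}: missing parameters {sorted(missing)}")
    if not (xm > 0) or not math.isfinite(xm):
        raise ParameterDomainError(f"x_min must be positive and finite, got {xm}")
    if fam == "power_law" and not p["alpha"] > 1:
        raise ParameterDomainError("power_law requires alpha > 1")
    if fam == "exponential" and not p["lam"] > 0:
        raise ParameterDomainError("exponential requires lam > 0")
    if fam == "log_normal" and not p["sigma"] > 0:
        raise ParameterDomainError("log_normal requires sigma > 0")
    if fam == "weibull" and not (p["beta"] > 0 and p["lam"] > 0):
        raise ParameterDomainError("weibull requires beta > 0 and lam > 0")
    if fam == "trunc_power_law":
        if not (p["alpha"] > 0 or p["lam"] > 0) or p["lam"] < 0:
            raise ParameterDomainError("trunc_power_law requires lam >= 0 and alpha > 0")
        if p["lam"] == 0 and not p["alpha"] > 1:
            raise ParameterDomainError(
                "trunc_power_law with lam = 0 requires alpha > 1 (pure power law)"
            )
    if fam == "biexponential":
        if not (p["lam"] > 0 and p["gamma"] > 0):
            raise ParameterDomainError("biexponential requires lam > 0 and gamma > 0")
        if not 0 <= p["delta"] <= 1:
            raise ParameterDomainError("delta must lie in [0, 1]")
    if fam == "exp_plus_tpl":
        if not p["gamma"] > 0:
            raise ParameterDomainError("exp_plus_tpl requires gamma > 0")
        if p["lam"] < 0 or not p["alpha"] > 0:
            raise ParameterDomainError("exp_plus_tpl requires lam >= 0 and alpha > 0")
        if p["lam"] == 0 and not p["alpha"] > 1:
            raise ParameterDomainError("tpl component with lam = 0 requires alpha > 1")
        if not 0 <= p["delta"] <= 1:
            raise ParameterDomainError("delta must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Upper incomplete gamma for arbitrary real first argument
# ---------------------------------------------------------------------------

def _gamma_continued_fraction(s: float, z: float, eps: float = 1e-14,
                              max_iter: int = 10000) -> float:
    # Lentz's algorithm for Gamma(s, z) = e^{-z} z^s * CF; valid for z >~ 1
    # at any real s, where the upward recurrence would cancel.
    tiny = 1e-300
    b = z + 1.0 - s
    c = 1.0 / tiny
    d = 1.0 / b if b != 0 else 1.0 / tiny
    h = d
    for i in range(1, max_iter + 1):
        an = -i * (i - s)
        b += 2.0
        d = an * d + b
        if abs(d) < tiny:
            d = tiny
        c = b + an / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < eps:
            break
    return math.exp(-z + s * math.log(z)) * h


def upper_incomplete_gamma(s: float, z: float) -> float:
    """Upper incomplete gamma ``Gamma(s, z)`` for any real ``s`` and ``z > 0``.

    scipy's regularized ``gammaincc`` only covers ``s > 0``; the truncated
    power-law normalizer needs ``s = 1 - alpha`` which is typically negative.
    For small ``z`` the value is built by the upward recurrence
    ``Gamma(s, z) = (Gamma(s+1, z) - z**s * exp(-z)) / s`` starting from a
    positive shift; for ``z >= 1`` that recurrence cancels catastrophically
    and a continued-fraction evaluation is used instead.
    """
    if not z > 0:
        if z == 0 and s > 0:
            return float(special.gamma(s))
        raise ParameterDomainError(f"Gamma(s, z) requires z > 0 (s={s}, z={z})")
    if s > 0:
        return float(special.gammaincc(s, z) * special.gamma(s))
    if z >= 1.0:
        return _gamma_continued_fraction(s, z)
    k = int(math.ceil(-s))
    t = s + k  # in [0, 1)
    if t == 0.0:
        g = float(special.exp1(z))
    else:
        g = float(special.gammaincc(t, z) * special.gamma(t))
    ez = math.exp(-z)
    for _ in range(k):
        t -= 1.0
        g = (g - z ** t * ez) / t
    return g


def log_upper_incomplete_gamma(s: float, z: float) -> float:
    g = upper_incomplete_gamma(s, z)
    if not g > 0:
        raise ParameterDomainError(f"Gamma({s}, {z}) evaluated non-positive: {g}")
    return math.log(g)


# ---------------------------------------------------------------------------
# Per-family log-density and CDF building blocks (each normalized on the tail)
# ---------------------------------------------------------------------------

def _logpdf_power_law(x, alpha, xm):
    return math.log(alpha - 1) - math.log(xm) - alpha * (np.log(x) - math.log(xm))


def _cdf_power_law(x, alpha, xm):
    return 1.0 - (x / xm) ** (1.0 - alpha)


def _logpdf_exponential(x, lam, xm):
    return math.log(lam) - lam * (x - xm)


def _cdf_exponential(x, lam, xm):
    return -np.expm1(-lam * (x - xm))


def _logpdf_log_normal(x, mu, sigma, xm):
    log_tail = stats.norm.logsf((math.log(xm) - mu) / sigma)
    z = (np.log(x) - mu) / sigma
    return -np.log(x) - math.log(sigma) - 0.5 * math.log(2 * math.pi) \
        - 0.5 * z * z - log_tail


def _cdf_log_normal(x, mu, sigma, xm):
    a = stats.norm.sf((math.log(xm) - mu) / sigma)
    b = stats.norm.sf((np.log(x) - mu) / sigma)
    return 1.0 - b / a


def _logpdf_weibull(x, beta, lam, xm):
    return math.log(beta) + math.log(lam) + (beta - 1) * np.log(x) \
        - lam * (x ** beta - xm ** beta)


def _cdf_weibull(x, beta, lam, xm):
    return -np.expm1(-lam * (x ** beta - xm ** beta))


def _log_norm_tpl(alpha, lam, xm):
    # log of C = lam^{1-alpha} / Gamma(1-alpha, lam*xm)
    return (1.0 - alpha) * math.log(lam) - log_upper_incomplete_gamma(1.0 - alpha, lam * xm)


def _logpdf_tpl(x, alpha, lam, xm):
    if lam == 0:
        return _logpdf_power_law(x, alpha, xm)
    return _log_norm_tpl(alpha, lam, xm) - alpha * np.log(x) - lam * x


def _cdf_tpl(x, alpha, lam, xm):
    if lam == 0:
        return _cdf_power_law(x, alpha, xm)
    s = 1.0 - alpha
    log_den = log_upper_incomplete_gamma(s, lam * xm)
    z = np.atleast_1d(np.asarray(x, dtype=float)) * lam
    num = np.array([upper_incomplete_gamma(s, zi) for zi in z])
    out = 1.0 - num / math.exp(log_den)
    return out if np.ndim(x) else float(out[0])


def log_pdf(spec: ModelSpec, x):
    """Natural log of the normalized density at ``x`` (``x >= x_min``).

    Mixture families are combined with log-sum-exp for stability.
    """
    xv = np.asarray(x, dtype=float)
    if np.any(xv < spec.x_min):
        raise ParameterDomainError("log_pdf evaluated below x_min; pre-filter the data")
    p, xm = spec.params, spec.x_min
    fam = spec.family
    if fam == "power_law":
        out = _logpdf_power_law(xv, p["alpha"], xm)
    elif fam == "exponential":
        out = _logpdf_exponential(xv, p["lam"], xm)
    elif fam == "log_normal":
        out = _logpdf_log_normal(xv, p["mu"], p["sigma"], xm)
    elif fam == "weibull":
        out = _logpdf_weibull(xv, p["beta"], p["lam"], xm)
    elif fam == "trunc_power_law":
        out = _logpdf_tpl(xv, p["alpha"], p["lam"], xm)
    elif fam == "biexponential":
        out = _mix_logpdf(
            p["delta"],
            _logpdf_exponential(xv, p["lam"], xm),
            _logpdf_exponential(xv, p["gamma"], xm),
        )
    elif fam == "exp_plus_tpl":
        out = _mix_logpdf(
            p["delta"],
            _logpdf_exponential(xv, p["gamma"], xm),
            _logpdf_tpl(xv, p["alpha"], p["lam"], xm),
        )
    else:  # pragma: no cover - guarded by validate_spec
        raise ParameterDomainError(fam)
    return out if np.ndim(x) else float(out)


def _mix_logpdf(delta, log_a, log_b):
    if delta == 0:
        return np.asarray(log_b, dtype=float)
    if delta == 1:
        return np.asarray(log_a, dtype=float)
    stacked = np.stack([np.broadcast_to(log_a + math.log(delta), np.shape(log_b)),
                        np.asarray(log_b) + math.log(1 - delta)])
    return special.logsumexp(stacked, axis=0)


def pdf(spec: ModelSpec, x):
    return np.exp(log_pdf(spec, x))


def cdf(spec: ModelSpec, x):
    """P(X <= x) under the normalized tail density; 0 at ``x_min``."""
    xv = np.asarray(x, dtype=float)
    if np.any(xv < spec.x_min):
        raise ParameterDomainError("cdf evaluated below x_min")
    p, xm = spec.params, spec.x_min
    fam = spec.family
    if fam == "power_law":
        out = _cdf_power_law(xv, p["alpha"], xm)
    elif fam == "exponential":
        out = _cdf_exponential(xv, p["lam"], xm)
    elif fam == "log_normal":
        out = _cdf_log_normal(xv, p["mu"], p["sigma"], xm)
    elif fam == "weibull":
        out = _cdf_weibull(xv, p["beta"], p["lam"], xm)
    elif fam == "trunc_power_law":
        out = _cdf_tpl(xv, p["alpha"], p["lam"], xm)
    elif fam == "biexponential":
        out = p["delta"] * _cdf_exponential(xv, p["lam"], xm) \
            + (1 - p["delta"]) * _cdf_exponential(xv, p["gamma"], xm)
    elif fam == "exp_plus_tpl":
        out = p["delta"] * _cdf_exponential(xv, p["gamma"], xm) \
            + (1 - p["delta"]) * _cdf_tpl(xv, p["alpha"], p["lam"], xm)
    else:  # pragma: no cover
        raise ParameterDomainError(fam)
    out = np.clip(out, 0.0, 1.0)
    return out if np.ndim(x) else float(out)


def sf(spec: ModelSpec, x):
    """Survival P(X > x) = 1 - cdf."""
    return 1.0 - cdf(spec, x)


def normalization_constant(spec: ModelSpec):
    """Normalization constant(s) of the family's density on ``[x_min, inf)``.

    Scalar families return ``C``; mixtures return the pair ``(C1, C2)`` of
    per-component constants (the weights ``delta``/``1-delta`` are separate).
    """
    p, xm = spec.params, spec.x_min
    fam = spec.family

    def c_power(alpha):
        return (alpha - 1.0) * xm ** (alpha - 1.0)

    def c_exp(lam):
        return lam * math.exp(lam * xm)

    def c_tpl(alpha, lam):
        if lam == 0:
            return c_power(alpha)
        return math.exp(_log_norm_tpl(alpha, lam, xm))

    if fam == "power_law":
        return c_power(p["alpha"])
    if fam == "exponential":
        return c_exp(p["lam"])
    if fam == "trunc_power_law":
        return c_tpl(p["alpha"], p["lam"])
    if fam == "log_normal":
        # C such that pdf = C * exp(-(ln x - mu)^2/(2 sigma^2)) / x
        tail = stats.norm.sf((math.log(xm) - p["mu"]) / p["sigma"])
        return 1.0 / (p["sigma"] * math.sqrt(2 * math.pi) * tail)
    if fam == "weibull":
        return p["beta"] * p["lam"] * math.exp(p["lam"] * xm ** p["beta"])
    if fam == "biexponential":
        return c_exp(p["lam"]), c_exp(p["gamma"])
    if fam == "exp_plus_tpl":
        return c_exp(p["gamma"]), c_tpl(p["alpha"], p["lam"])
    raise ParameterDomainError(fam)  # pragma: no cover
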