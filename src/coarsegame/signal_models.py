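"""Signal distributions: the information system of the prescription game.

Each patient presents with a *signal* — the posterior probability ``p`` that
their infection is bacterial, given symptoms and immediate diagnostics.  Across
patients, ``p`` is distributed with density ``f(p)`` on [0, 1].  The density is
the game's information system: its mean is the prevalence of bacterial
infection ``P(B) = E(p)``, and its truncated means determine both the payoff
recursions and the stability of coarsened (dichotomized) signals.

Three families are supported:

* ``beta`` — flexible conjugate family, the standard parametric model for a
  distribution of probabilities;
* ``truncated-uniform`` — uniform on a sub-interval ``(lo, hi)`` of [0, 1],
  modelling signals that never exceed ``hi`` (``support_max = hi``);
* ``empirical-smoothed`` — a kernel density estimate built from observed
  posterior samples (e.g. classifier output on a patient cohort), smoothed on
  the logit scale to avoid boundary bias, with a small additive floor constant
  so the support is all of (0, 1).

The quantity used throughout the downstream game analysis is the *partial
expectation* ``PE(a) = ∫_a^1 p f(p) dp`` — the unnormalized expected posterior
of a treated patient when the treatment threshold is ``a``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, interpolate, special, stats

__all__ = [
    "SignalDistribution",
    "make_beta",
    "make_truncated_uniform",
    "make_empirical",
    "partial_mean",
    "sample",
    "parse_distribution_spec",
]

#: Absolute tolerance for adaptive quadrature used in density checks.
QUAD_ABS_TOL = 1e-10

#: Default additive floor constant for empirical densities.
DEFAULT_FLOOR = 1e-4

#: Grid size for the empirical inverse-CDF table.
_PPF_GRID = 4096


class SignalDistribution:
    """A continuous information system ``f(p)`` on [0, 1].

    Subclasses implement ``pdf``, ``cdf``, ``partial_mean`` and ``ppf``; all
    are vectorized over numpy arrays.  ``mean`` equals the prevalence of
    bacterial infection, ``P(B)``.
    """

    family: str = "abstract"
    params: tuple = ()
    #: supremum of the support; threshold searches are restricted to
    #: [0, support_max] because a threshold above the support never binds.
    support_max: float = 1.0

    @property
    def mean(self) -> float:
        """E(p) = P(B), the prior probability of bacterial infection."""
        raise NotImplementedError

    def pdf(self, p):
        raise NotImplementedError

    def cdf(self, p):
        raise NotImplementedError

    def sf(self, p):
        """Survival function 1 - F(p); overridden where the complement can be
        computed without cancellation."""
        return 1.0 - self.cdf(p)

    def ppf(self, q):
        raise NotImplementedError

    def partial_mean(self, a):
        """PE(a) = ∫_a^1 p f(p) dp (vectorized in ``a``)."""
        raise NotImplementedError

    def lower_partial_mean(self, a):
        """∫_0^a p f(p) dp; overridden where mean - PE(a) would cancel."""
        return self.mean - self.partial_mean(a)

    def sample(self, n: int, seed=None) -> np.ndarray:
        """Draw ``n`` i.i.d. signals by inverse-CDF transform."""
        if n < 1:
            raise ValueError("sample size must be >= 1")
        rng = np.random.default_rng(seed)
        return np.asarray(self.ppf(rng.uniform(size=n)), dtype=float)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        args = ", ".join(f"{v:g}" if isinstance(v, float) else str(v) for v in self.params)
        return f"{type(self).__name__}({args})"


@dataclass(repr=False)
class BetaSignal(SignalDistribution):
    """Beta(a, b) signal distribution."""

    a: float
    b: float
    family: str = field(default="beta", init=False)
    support_max: float = field(default=1.0, init=False)

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise ValueError("beta parameters must be positive")
        self.params = (self.a, self.b)
        self._frozen = stats.beta(self.a, self.b)

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    def pdf(self, p):
        return self._frozen.pdf(p)

    def cdf(self, p):
        return self._frozen.cdf(p)

    def ppf(self, q):
        return self._frozen.ppf(q)

    def sf(self, p):
        return special.betaincc(self.a, self.b, np.clip(p, 0.0, 1.0))

    def partial_mean(self, a):
        # p * Beta(a,b) density is mean * Beta(a+1, b) density, so the
        # truncated first moment reduces to a regularized incomplete beta;
        # the complement form stays accurate deep in the upper tail.
        a = np.clip(a, 0.0, 1.0)
        return self.mean * special.betaincc(self.a + 1.0, self.b, a)

    def lower_partial_mean(self, a):
        a = np.clip(a, 0.0, 1.0)
        return self.mean * special.betainc(self.a + 1.0, self.b, a)


@dataclass(repr=False)
class TruncatedUniformSignal(SignalDistribution):
    """Uniform density on (lo, hi) ⊆ [0, 1], zero elsewhere."""

    lo: float
    hi: float
    family: str = field(default="truncated-uniform", init=False)

    def __post_init__(self):
        if not (0.0 <= self.lo < self.hi <= 1.0):
            raise ValueError("require 0 <= lo < hi <= 1")
        self.params = (self.lo, self.hi)
        self.support_max = self.hi

    @property
    def mean(self) -> float:
        return 0.5 * (self.lo + self.hi)

    def pdf(self, p):
        p = np.asarray(p, dtype=float)
        out = np.where((p >= self.lo) & (p <= self.hi), 1.0 / (self.hi - self.lo), 0.0)
        return out if out.ndim else float(out)

    def cdf(self, p):
        p = np.asarray(p, dtype=float)
        out = np.clip((p - self.lo) / (self.hi - self.lo), 0.0, 1.0)
        return out if out.ndim else float(out)

    def ppf(self, q):
        return self.lo + np.asarray(q, dtype=float) * (self.hi - self.lo)

    def partial_mean(self, a):
        t = np.clip(a, self.lo, self.hi)
        out = (self.hi**2 - t**2) / (2.0 * (self.hi - self.lo))
        return out if np.ndim(out) else float(out)


class EmpiricalSignal(SignalDistribution):
    """Smoothed density estimated from observed posterior samples.

    A Gaussian KDE is fitted on the logit scale (so the estimate respects the
    (0, 1) boundaries) and transformed back; a small floor constant is then
    added and the density renormalized, giving support on all of (0, 1).  The
    CDF and partial expectation are tabulated on a dense logit-space grid and
    interpolated monotonically.
    """

    family = "empirical-smoothed"

    def __init__(self, posteriors: Sequence[float], floor_const: float = DEFAULT_FLOOR,
                 bandwidth="auto"):
        x = np.asarray(posteriors, dtype=float)
        if x.size < 10:
            raise ValueError("need at least 10 posterior samples")
        if np.any((x <= 0.0) | (x >= 1.0)) or np.any(~np.isfinite(x)):
            raise ValueError("posterior samples must lie strictly inside (0, 1)")
        if floor_const <= 0:
            raise ValueError("floor constant must be positive")
        self.params = (float(x.size), float(floor_const))
        self.support_max = 1.0
        self._floor = float(floor_const)

        z = special.logit(x)
        bw = "silverman" if bandwidth == "auto" else float(bandwidth)
        self._kde = stats.gaussian_kde(z, bw_method=bw)

        # Dense tabulation in logit space, where the KDE is smooth.
        h = np.sqrt(self._kde.covariance[0, 0])
        zg = np.linspace(z.min() - 8.0 * h, z.max() + 8.0 * h, 8192)
        fz = self._kde(zg)  # density in z; integrates to 1 over the real line
        pg = special.expit(zg)
        cdf0 = integrate.cumulative_trapezoid(fz, zg, initial=0.0)
        tail = 1.0 - cdf0[-1]  # truncated Gaussian tails (negligible at 8 sd)
        cdf0 = cdf0 / (cdf0[-1] + tail)
        mom0 = integrate.cumulative_trapezoid(pg * fz, zg, initial=0.0)
        self._mean0 = float(mom0[-1])
        self._zg, self._pg = zg, pg
        self._cdf0 = interpolate.PchipInterpolator(zg, np.maximum.accumulate(cdf0))
        self._mom0 = interpolate.PchipInterpolator(zg, np.maximum.accumulate(mom0))

        # Inverse-CDF table on a probability grid (for sampling).
        qs = np.linspace(0.0, 1.0, _PPF_GRID)
        pp = np.unique(np.concatenate([pg, np.linspace(0.0, 1.0, 2049)]))
        Fp = self.cdf(pp)
        keep = np.concatenate([[True], np.diff(Fp) > 0])
        self._ppf_interp = interpolate.PchipInterpolator(Fp[keep], pp[keep])
        self._ppf_q = qs

    @property
    def mean(self) -> float:
        # floor adds a uniform component of weight floor/(1+floor), mean 1/2
        return (self._mean0 + 0.5 * self._floor) / (1.0 + self._floor)

    def _raw_pdf(self, p):
        p = np.clip(np.asarray(p, dtype=float), 1e-300, 1.0 - 1e-16)
        z = special.logit(p)
        return self._kde(np.atleast_1d(z)).reshape(np.shape(z)) / (p * (1.0 - p))

    def pdf(self, p):
        scalar = np.ndim(p) == 0
        p = np.atleast_1d(np.asarray(p, dtype=float))
        out = (self._raw_pdf(p) + self._floor) / (1.0 + self._floor)
        out[(p < 0) | (p > 1)] = 0.0
        return float(out[0]) if scalar else out

    def cdf(self, p):
        scalar = np.ndim(p) == 0
        p = np.atleast_1d(np.clip(np.asarray(p, dtype=float), 0.0, 1.0))
        z = special.logit(np.clip(p, 1e-300, 1.0 - 1e-16))
        base = np.where(p <= 0.0, 0.0, np.where(p >= 1.0, 1.0,
                        np.clip(self._cdf0(z), 0.0, 1.0)))
        out = (base + self._floor * p) / (1.0 + self._floor)
        return float(out[0]) if scalar else out

    def partial_mean(self, a):
        scalar = np.ndim(a) == 0
        a = np.atleast_1d(np.clip(np.asarray(a, dtype=float), 0.0, 1.0))
        z = special.logit(np.clip(a, 1e-300, 1.0 - 1e-16))
        below = np.where(a <= 0.0, 0.0, np.where(a >= 1.0, self._mean0,
                         np.clip(self._mom0(z), 0.0, self._mean0)))
        out = (self._mean0 - below + self._floor * 0.5 * (1.0 - a**2)) / (1.0 + self._floor)
        return float(out[0]) if scalar else out

    def ppf(self, q):
        scalar = np.ndim(q) == 0
        q = np.atleast_1d(np.clip(np.asarray(q, dtype=float), 0.0, 1.0))
        p = np.clip(self._ppf_interp(q), 0.0, 1.0)
        # one bisection sweep against the true CDF to tighten the interpolant
        lo, hi = np.maximum(p - 1e-3, 0.0), np.minimum(p + 1e-3, 1.0)
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            high = self.cdf(mid) >= q
            hi = np.where(high, mid, hi)
            lo = np.where(high, lo, mid)
        out = 0.5 * (lo + hi)
        # fall back to the interpolant where the local bracket missed
        bad = np.abs(self.cdf(out) - q) > np.abs(self.cdf(p) - q)
        out = np.where(bad, p, out)
        return float(out[0]) if scalar else out


def make_beta(alpha: float, beta: float) -> SignalDistribution:
    """Beta(alpha, beta) signal distribution; mean alpha/(alpha+beta)."""
    return BetaSignal(float(alpha), float(beta))


def make_truncated_uniform(lo: float, hi: float) -> SignalDistribution:
    """Uniform signal distribution on (lo, hi); requires 0 <= lo < hi <= 1."""
    return TruncatedUniformSignal(float(lo), float(hi))


def make_empirical(posteriors: Sequence[float], floor_const: float = DEFAULT_FLOOR,
                   bandwidth="auto") -> SignalDistribution:
    """Smoothed empirical signal distribution from posterior samples.

    Parameters
    ----------
    posteriors
        Observed posterior probabilities, strictly inside (0, 1); at least 10.
    floor_const
        Additive density floor (default 1e-4) ensuring support (0, 1).
    bandwidth
        ``"auto"`` (Silverman's rule on the logit scale) or a positive float
        passed to :class:`scipy.stats.gaussian_kde`.
    """
    return EmpiricalSignal(posteriors, floor_const=floor_const, bandwidth=bandwidth)


def partial_mean(dist: SignalDistribution, a) -> float:
    """∫_a^1 p f(p) dp — expected posterior mass above threshold ``a``."""
    if np.any((np.asarray(a) < 0) | (np.asarray(a) > 1)):
        raise ValueError("threshold must lie in [0, 1]")
    return dist.partial_mean(a)


def sample(dist: SignalDistribution, n: int, seed=None) -> np.ndarray:
    """Reproducible i.i.d. draws from ``dist`` (inverse-CDF transform)."""
    return dist.sample(n, seed=seed)


def parse_distribution_spec(spec) -> SignalDistribution:
    """Build a distribution from a config mapping or a CLI string.

    Accepted forms: ``"beta:0.5,0.5"``, ``"uniform:0,0.5"``,
    ``"empirical:path.csv"`` or the mapping
    ``{"family": ..., "params": [...], "samples_file": ...}``.
    """
    if isinstance(spec, str):
        fam, _, rest = spec.partition(":")
        fam = fam.strip().lower()
        if fam == "beta":
            a, b = (float(v) for v in rest.split(","))
            return make_beta(a, b)
        if fam == "uniform":
            parts = [float(v) for v in rest.split(",")] if rest else [0.0, 1.0]
            return make_truncated_uniform(*parts)
        if fam == "empirical":
            return make_empirical(_read_samples(rest.strip()))
        raise ValueError(f"unknown distribution family: {fam!r}")
    fam = spec.get("family", "").lower()
    if fam == "beta":
        return make_beta(*spec["params"])
    if fam == "uniform":
        params = spec.get("params", [0.0, 1.0])
        return make_truncated_uniform(*params)
    if fam == "empirical":
        if "samples_file" in spec:
            values = _read_samples(spec["samples_file"])
        else:
            values = spec["params"]
        return make_empirical(values, floor_const=spec.get("floor_const", DEFAULT_FLOOR),
                              bandwidth=spec.get("bandwidth", "auto"))
    raise ValueError(f"unknown distribution family: {fam!r}")


def _read_samples(path: str) -> np.ndarray:
    """Read one probability per line (plain text or single-column CSV)."""
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip().split(",")[0]
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError:
                if values:  # non-numeric after data started: malformed
                    raise
                continue  # header line
    return np.asarray(values, dtype=float)
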