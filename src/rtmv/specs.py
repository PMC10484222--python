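"""Parameter specifications for the contaminated ex-Gaussian RT generator.

The generative model for a single simulated response time is

    RT = N(mu, sigma) + Exp(tau) + B(p) * U(a, b)

i.e. an ex-Gaussian (normal convolved with an exponential of mean ``tau``)
to which, with Bernoulli probability ``p``, a single uniform noise draw is
added.  All quantities are in milliseconds.  The defaults are the standard
simulation conditions for this class of study: mu=400, sigma=40, tau=200,
uniform noise on (0, 2000), a two-condition within-subject design with
30 subjects and 10 observations per subject per condition.
"""

from __future__ import annotations

from dataclasses import dataclass


class ParameterError(ValueError):
    """Raised when a spec is constructed with invalid parameters."""


@dataclass(frozen=True)
class ExGaussianSpec:
    """Ex-Gaussian RT distribution: N(mu, sigma) + Exp(mean=tau), in ms.

    The exponential component is parameterized by its *mean* (scale), not its
    rate: a rate of 200/ms would put the exponential mass at microseconds,
    which is physically absurd for response times, while a 200 ms mean yields
    the canonical ~600 ms mean RT.
    """

    mu: float = 400.0
    sigma: float = 40.0
    tau: float = 200.0

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.mu):
            raise ParameterError(f"mu must be finite, got {self.mu}")
        if not self.sigma > 0:
            raise ParameterError(f"sigma must be > 0, got {self.sigma}")
        if not self.tau > 0:
            raise ParameterError(f"tau must be > 0, got {self.tau}")

    @property
    def mean(self) -> float:
        return self.mu + self.tau

    @property
    def variance(self) -> float:
        return self.sigma**2 + self.tau**2


@dataclass(frozen=True)
class ContaminationSpec:
    """Additive uniform contamination applied to a Bernoulli(p) share of trials."""

    p: float = 0.0
    a: float = 0.0
    b: float = 2000.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ParameterError(f"p must be in [0, 1], got {self.p}")
        if self.a > self.b:
            raise ParameterError(f"need a <= b, got a={self.a}, b={self.b}")

    @property
    def mean_shift(self) -> float:
        """Expected shift of the grand mean: p * (a + b) / 2."""
        return self.p * (self.a + self.b) / 2.0


@dataclass(frozen=True)
class DesignSpec:
    """Within-subject two-condition design.

    ``mu_diff`` is a constant added to the normal component's mean in
    condition 2, so E[rt | cond 2] - E[rt | cond 1] = mu_diff.
    """

    n_subjects: int = 30
    n_obs: int = 10
    mu_diff: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ParameterError(f"n_subjects must be >= 2, got {self.n_subjects}")
        if self.n_obs < 1:
            raise ParameterError(f"n_obs must be >= 1, got {self.n_obs}")

    @property
    def n_trials(self) -> int:
        return self.n_subjects * 2 * self.n_obs
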