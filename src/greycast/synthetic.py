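"""Seedable generators of short positive count panels with known truth.

The generators emulate the data regime the grey–Markov pipeline targets —
short (4–16 point) strictly positive panels with a near-exponential trend
and proportional (multiplicative) fluctuation — and return the generating
parameters so that estimation can be checked against ground truth.  Noise
is multiplicative lognormal: counts are positive and their fluctuation
scales with level, which additive Gaussian noise would violate at small
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np

from .grey import affine_ode_solution
from .panel import SeriesPanel

__all__ = [
    "SyntheticSpec",
    "gen_linear_system_panel",
    "gen_gm11_series",
    "gen_crashlike_panel",
    "random_stable_system",
]

_MAX_RETRIES = 20


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth description of a coupled affine grey system.

    ``A_true`` must have spectral radius <= 0.5 so that sampling the
    continuous system at integer times stays well-conditioned and the
    background-value discretization bias stays below recovery tolerances.
    """

    A_true: np.ndarray
    B_true: np.ndarray
    x0: np.ndarray  # positive initial AGO state
    n: int
    noise_cv: float = 0.0
    seed: int = 0
    variable_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.A_true, dtype=float))
        B = np.asarray(self.B_true, dtype=float).ravel()
        x0 = np.asarray(self.x0, dtype=float).ravel()
        m = A.shape[0]
        if A.shape != (m, m) or B.size != m or x0.size != m:
            raise ValueError("inconsistent system dimensions")
        if not 4 <= self.n <= 16:
            raise ValueError(f"n must lie in 4..16, got {self.n}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if np.any(x0 <= 0):
            raise ValueError("initial AGO state must be positive")
        rad = max(abs(np.linalg.eigvals(A)))
        if rad > 0.5 + 1e-9:
            raise ValueError(f"spectral radius {rad:.3f} exceeds 0.5")
        object.__setattr__(self, "A_true", A)
        object.__setattr__(self, "B_true", B)
        object.__setattr__(self, "x0", x0)
        ids = self.variable_ids or tuple(
            ["dep"] + [f"F{i}" for i in range(1, m)]
        )
        if len(ids) != m:
            raise ValueError("variable_ids length does not match system size")
        object.__setattr__(self, "variable_ids", tuple(ids))

    @property
    def m(self) -> int:
        return self.A_true.shape[0]


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=shape)


def gen_linear_system_panel(
    spec: SyntheticSpec,
) -> tuple[SeriesPanel, dict[str, np.ndarray]]:
    """Panel sampled from ``dX1/dt = A X1 + B`` at integer times, plus truth.

    The exact affine-ODE solution is evaluated at ``t = 1..n``, differenced
    to the original scale, and multiplied by seeded lognormal noise with
    coefficient of variation ``noise_cv``.  A draw producing a non-positive
    value is retried (bounded) with a fresh sub-seed.
    """
    truth = {"A": spec.A_true.copy(), "B": spec.B_true.copy(), "x0": spec.x0.copy()}
    X1 = np.column_stack(
        [
            affine_ode_solution(spec.A_true, t - 1.0, spec.x0, spec.B_true)
            for t in range(1, spec.n + 1)
        ]
    )
    X0 = np.hstack([X1[:, :1], np.diff(X1, axis=1)])
    rng = np.random.default_rng(spec.seed)
    for attempt in range(_MAX_RETRIES):
        noisy = X0 * _lognormal_factors(rng, spec.noise_cv, X0.shape)
        if np.all(noisy[0] > 0) and np.all(noisy > 0):
            break
    else:
        raise RuntimeError(
            "could not generate a strictly positive panel; the noise-free "
            "system itself may produce non-positive increments"
        )
    years = tuple(range(2000, 2000 + spec.n))
    panel = SeriesPanel(
        years=years,
        dependent=tuple(noisy[0]),
        factors={
            fid: tuple(noisy[i])
            for i, fid in enumerate(spec.variable_ids)
            if i > 0
        },
        dependent_name=spec.variable_ids[0],
    )
    return panel, truth


def random_stable_system(
    m: int,
    seed: int,
    spectral_radius: float = 0.3,
    n: int = 10,
    noise_cv: float = 0.0,
) -> SyntheticSpec:
    """Random spec with the given size and spectral radius cap.

    Draws are rejected (deterministically, from the same seed stream) until
    the noise-free increments of the system are strictly positive, so the
    resulting panel is always a valid count panel.
    """
    rng = np.random.default_rng(seed)
    for _ in range(200):
        A = rng.normal(size=(m, m))
        rad = max(abs(np.linalg.eigvals(A)))
        A *= spectral_radius / rad
        B = rng.uniform(20.0, 50.0, size=m)
        x0 = rng.uniform(10.0, 30.0, size=m)
        X1 = np.column_stack(
            [affine_ode_solution(A, t - 1.0, x0, B) for t in range(1, n + 1)]
        )
        X0 = np.hstack([X1[:, :1], np.diff(X1, axis=1)])
        if np.all(X0 > 0):
            return SyntheticSpec(
                A_true=A, B_true=B, x0=x0, n=n, noise_cv=noise_cv, seed=seed
            )
    raise RuntimeError(
        f"no positive-increment system found for m={m}, seed={seed}"
    )


def gen_gm11_series(
    a: float,
    b: float,
    x1: float,
    n: int,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict[str, float]]:
    """Series generated from the GM(1,1) whitening solution, plus truth.

    ``a`` is the development coefficient (negative means growth), ``b`` the
    grey input, ``x1`` the first original-scale value.
    """
    if n < 4:
        raise ValueError(f"n must be >= 4, got {n}")
    if a == 0:
        raise ValueError("a = 0 is degenerate for GM(1,1)")
    if x1 <= 0:
        raise ValueError("x1 must be positive")
    t = np.arange(1, n + 1, dtype=float)
    x1_ago = (x1 - b / a) * np.exp(-a * (t - 1.0)) + b / a
    x0 = np.concatenate([[x1], np.diff(x1_ago)])
    rng = np.random.default_rng(seed)
    for _ in range(_MAX_RETRIES):
        noisy = x0 * _lognormal_factors(rng, noise_cv, x0.shape)
        if np.all(noisy > 0):
            return noisy, {"a": a, "b": b, "x1": x1}
    raise RuntimeError("could not generate a strictly positive series")


def gen_crashlike_panel(seed: int = 0) -> SeriesPanel:
    """A panel mimicking short annual crash-count data, for smoke tests.

    6–10 years; dependent in the hundreds-to-thousands; 6–8 factor series
    spanning units to hundreds, each a noisy share of the dependent.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 11))
    n_factors = int(rng.integers(6, 9))
    growth = rng.uniform(0.05, 0.20)
    base = rng.uniform(400.0, 900.0)
    trend = base * np.exp(growth * np.arange(n))
    dependent = trend * _lognormal_factors(rng, 0.15, n)
    dependent = np.maximum(dependent, 1.0)
    factors = {}
    for i in range(1, n_factors + 1):
        share = rng.uniform(0.005, 0.4)
        series = dependent * share * _lognormal_factors(rng, 0.25, n)
        factors[f"X{i}"] = tuple(np.round(np.maximum(series, 0.0), 0))
    start = int(rng.integers(1990, 2015))
    return SeriesPanel(
        years=tuple(range(start, start + n)),
        dependent=tuple(np.round(dependent, 0)),
        factors=factors,
        dependent_name="total",
    )
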