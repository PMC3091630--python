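"""Closed-form design calculus for paired-end breakpoint detection and resolution.

A structural variant fuses two reference coordinates (a, b) to a single query
position zeta (the *fusion point*).  A paired-end insert of mean length L
detects the breakpoint when it spans zeta; with N inserts on a genome of
length G the expected number of spanning inserts is the clonal coverage
c = N*L/G, and the spanning count is modelled as Poisson(c) with uniform
offsets (the Clarke-Carbon framework).

All formulas here treat the insert length as fixed; the spread sigma only
enters the simulator (:mod:`seqdesign.montecarlo`), which also serves as the
independent oracle certifying every closed form in this module.

Notation
--------
c        clonal coverage N*L/G (dimensionless)
m        minimum number of spanning inserts required to call a detection
         (1 for the pure Clarke-Carbon setting, 2 to guard against
         chimeric inserts, as in empirical PEM pipelines)
|Theta|  resolution-ambiguity: the width of the interval to which a
         detected fusion point is localized (intersection of the spanning
         inserts), in bp.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = [
    "HUMAN_GENOME_LENGTH",
    "InsertLibrary",
    "DesignQuery",
    "ResolutionStats",
    "MixDesign",
    "clonal_coverage",
    "detection_probability",
    "expected_resolution",
    "resolution_probability",
    "resolution_probability_mix",
    "resolution_stats",
    "optimal_mix",
    "required_inserts",
    "mappable_scale",
]

#: Default genome length for the "human" preset (bp).
HUMAN_GENOME_LENGTH = 3.0e9


def _check_min_inserts(min_inserts: int) -> int:
    if min_inserts not in (1, 2):
        raise ValueError(f"min_inserts must be 1 or 2, got {min_inserts!r}")
    return int(min_inserts)


@dataclass(frozen=True)
class InsertLibrary:
    """One paired-end insert library.

    Parameters
    ----------
    mean_length : float
        Mean insert length L in bp.
    length_sd : float, default 0
        Insert-length spread sigma in bp.  Informational for the closed
        forms (which treat length as fixed); active in the simulator.
    n_inserts : float, default 0
        Number of uniquely mapped paired-end inserts N.
    """

    mean_length: float
    length_sd: float = 0.0
    n_inserts: float = 0.0

    def __post_init__(self) -> None:
        if not self.mean_length > 0:
            raise ValueError("mean_length must be positive")
        if self.length_sd < 0:
            raise ValueError("length_sd must be non-negative")
        if self.n_inserts < 0:
            raise ValueError("n_inserts must be non-negative")

    def coverage(self, genome_length: float) -> float:
        """Clonal coverage c = N*L/G of this library on a genome of length G."""
        return clonal_coverage(self.n_inserts, self.mean_length, genome_length)


@dataclass(frozen=True)
class DesignQuery:
    """A breakpoint-design question: how much sequencing for a given target.

    epsilon is the tolerated failure probability: the design aims to detect
    a fraction 1 - epsilon of all breakpoints.  resolution_target is the
    desired localization s in bp.  mapping_rate f is the fraction of
    sequenced inserts whose both ends map unambiguously; every insert count
    is scaled by 1/f on output.
    """

    genome_length: float
    sv_length: float
    epsilon: float
    resolution_target: float
    mapping_rate: float = 1.0
    min_inserts: int = 1

    def __post_init__(self) -> None:
        if not self.genome_length > 0:
            raise ValueError("genome_length must be positive")
        if not 0 < self.mapping_rate <= 1:
            raise ValueError("mapping_rate must be in (0, 1]")
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must be in (0, 1)")
        if not self.resolution_target > 0:
            raise ValueError("resolution_target must be positive")
        if not self.sv_length > 0:
            raise ValueError("sv_length must be positive")
        _check_min_inserts(self.min_inserts)


@dataclass(frozen=True)
class ResolutionStats:
    """Summary of a single-library design: coverage, detection, ambiguity."""

    coverage: float
    p_detect: float
    expected_ambiguity: float


@dataclass(frozen=True)
class MixDesign:
    """An allocation of an insert budget across libraries and its payoff."""

    libraries: tuple[InsertLibrary, ...]
    prob_resolved: float

    @property
    def total_inserts(self) -> float:
        return sum(lib.n_inserts for lib in self.libraries)


def clonal_coverage(n_inserts: float, mean_length: float, genome_length: float) -> float:
    """Clonal coverage c = N*L/G: expected number of inserts spanning a point."""
    if not genome_length > 0:
        raise ValueError("genome_length must be positive")
    if not mean_length > 0:
        raise ValueError("mean_length must be positive")
    if n_inserts < 0:
        raise ValueError("n_inserts must be non-negative")
    return n_inserts * mean_length / genome_length


def detection_probability(coverage, min_inserts: int = 1):
    """Probability that >= min_inserts inserts span a fusion point.

    With spanning counts ~ Poisson(c) this is the Clarke-Carbon formula
    1 - exp(-c) for min_inserts=1, and the two-insert Poisson tail
    1 - exp(-c) - c*exp(-c) for min_inserts=2.

    Accepts a scalar or array coverage; returns the matching shape.
    """
    m = _check_min_inserts(min_inserts)
    c = np.asarray(coverage, dtype=float)
    if np.any(c < 0):
        raise ValueError("coverage must be non-negative")
    if m == 1:
        p = -np.expm1(-c)
    else:
        p = -np.expm1(-c) - c * np.exp(-c)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.isscalar(coverage) else p


def expected_resolution(lib: InsertLibrary, genome_length: float, min_inserts: int = 1) -> float:
    """Expected resolution-ambiguity E|Theta| of a detected fusion point, in bp.

    Conditional on detection (>= min_inserts spanning inserts), the spanning
    inserts localize zeta to the interval between the right-most left
    endpoint and the left-most right endpoint.  With k spanning inserts and
    uniform offsets each side of that interval has expected length L/(k+1),
    so by symmetry E|Theta| = 2*E(A) where A is the distance from zeta to
    the nearest right endpoint.  Averaging the Poisson spanning count over
    k >= m gives the closed form

        E|Theta| = 2*L * P(Pois(c) >= m+1) / (c * P(Pois(c) >= m))

    which decays as 2L/c for large c and tends to 2L/(m+1) as c -> 0.
    """
    m = _check_min_inserts(min_inserts)
    if lib.n_inserts <= 0:
        raise ValueError("expected resolution is conditional on detection; n_inserts must be > 0")
    c = lib.coverage(genome_length)
    L = lib.mean_length
    # P(Pois(c) >= m) == regularized lower incomplete gamma P(m, c)
    num = special.gammainc(m + 1, c)
    den = special.gammainc(m, c)
    return 2.0 * L * num / (c * den)


def _gamma2_cdf(x):
    """P(Exp + Exp <= x) for unit-rate exponentials: 1 - e^-x - x e^-x."""
    return special.gammainc(2, np.maximum(x, 0.0))


def resolution_probability(
    libraries, s: float, genome_length: float, min_inserts: int = 1
):
    """Pr(|Theta| <= s): probability a breakpoint is detected *and* localized to s bp.

    General multi-library closed form under the Poisson model.  Split the
    libraries at s: a spanning insert of length L <= s localizes zeta to at
    most s bp by itself, so "short" libraries contribute through their
    pooled coverage c_short alone.  Libraries with L > s resolve to s only
    through an endpoint pair: one right endpoint within u bp of zeta and
    one left endpoint within s - u.  Endpoints of each long library fall as
    a Poisson process of rate N_i/G per bp near zeta, so the pair event has
    probability Gamma(2)-CDF(lambda*s) with lambda = sum(N_i)/G over long
    libraries (independent of the long lengths themselves).

    min_inserts=2 additionally requires two spanning inserts for the short
    -library term (the endpoint-pair term already involves two inserts).

    This is the closed form behind the paper-style two-library cases
    (s < L1; L1 <= s < L2; s >= L2) and degenerates to
    :func:`detection_probability` of the pooled coverage when every library
    is shorter than s.
    """
    m = _check_min_inserts(min_inserts)
    libs = list(libraries)
    if not libs:
        raise ValueError("at least one library is required")
    if not s > 0:
        raise ValueError("resolution target s must be positive")
    if not genome_length > 0:
        raise ValueError("genome_length must be positive")
    G = genome_length
    c_short = sum(l.n_inserts * l.mean_length for l in libs if l.mean_length <= s) / G
    long_libs = [l for l in libs if l.mean_length > s]
    c_long = sum(l.n_inserts * l.mean_length for l in long_libs) / G
    lam_s = s * sum(l.n_inserts for l in long_libs) / G
    pair = float(_gamma2_cdf(lam_s))
    if m == 1:
        p = -math.expm1(-c_short) + math.exp(-c_short) * pair
    else:
        p = (
            -math.expm1(-c_short)
            - c_short * math.exp(-c_short) * math.exp(-c_long)
            + math.exp(-c_short) * pair
        )
    return min(max(p, 0.0), 1.0)


def resolution_probability_mix(
    libraries, s: float, genome_length: float, min_inserts: int = 1
) -> float:
    """Two-library (or degenerate single-library) form of :func:`resolution_probability`.

    Designs with three or more insert lengths are rejected: a mix of the
    target resolution s and the longest available length dominates any
    such design (see :func:`optimal_mix`), so they are never needed.
    """
    libs = sorted(libraries, key=lambda l: l.mean_length)
    if len(libs) > 2:
        raise ValueError(
            "more than two insert lengths are never needed: an optimal design "
            "mixes the target resolution s with the longest available insert"
        )
    return resolution_probability(libs, s, genome_length, min_inserts)


def resolution_stats(
    lib: InsertLibrary, genome_length: float, min_inserts: int = 1
) -> ResolutionStats:
    """Coverage, detection probability and expected ambiguity for one library."""
    c = lib.coverage(genome_length)
    return ResolutionStats(
        coverage=c,
        p_detect=detection_probability(c, min_inserts),
        expected_ambiguity=expected_resolution(lib, genome_length, min_inserts),
    )


def _mix_objective(n1, total, s, max_length, genome_length, min_inserts):
    """Vectorized Pr(|Theta|<=s) for the (s, max_length) two-library design."""
    n1 = np.asarray(n1, dtype=float)
    n2 = total - n1
    G = genome_length
    if max_length <= s:  # both lengths resolve by spanning alone: pooled detection
        c = (n1 * s + n2 * max_length) / G
        return detection_probability(c, min_inserts) if n1.ndim else float(
            detection_probability(float(c), min_inserts)
        )
    c_short = n1 * s / G
    c_long = n2 * max_length / G
    lam_s = n2 * s / G
    pair = _gamma2_cdf(lam_s)
    if min_inserts == 1:
        p = -np.expm1(-c_short) + np.exp(-c_short) * pair
    else:
        p = (
            -np.expm1(-c_short)
            - c_short * np.exp(-c_short) * np.exp(-c_long)
            + np.exp(-c_short) * pair
        )
    return np.clip(p, 0.0, 1.0)


def optimal_mix(
    total_inserts: float,
    s: float,
    max_length: float,
    genome_length: float,
    min_inserts: int = 1,
    grid_step: float | None = None,
) -> MixDesign:
    """Best split of an insert budget between lengths s and max_length.

    Only these two lengths need to be considered: an insert shorter than s
    contributes to Pr(|Theta| <= s) solely through coverage, so length s
    maximizes its value per insert; an insert longer than s contributes
    solely through its endpoint density plus detection coverage, so the
    longest available length dominates.  The split N1 in [0, N] is found by
    grid search (default step N/1000, endpoints included) followed by a
    local continuous refinement, mirroring the smooth unimodal objective.
    """
    m = _check_min_inserts(min_inserts)
    if not s > 0 or not max_length > 0:
        raise ValueError("s and max_length must be positive")
    if total_inserts < 0:
        raise ValueError("total_inserts must be non-negative")
    if s > max_length:
        warnings.warn(
            "target resolution s exceeds the longest available insert; the two "
            "design lengths degenerate to one (single max_length library)",
            stacklevel=2,
        )
        lib = InsertLibrary(max_length, 0.0, total_inserts)
        p = resolution_probability([lib], s, genome_length, m) if total_inserts else 0.0
        return MixDesign((lib,), p)
    if total_inserts == 0:
        return MixDesign(
            (InsertLibrary(s, 0.0, 0.0), InsertLibrary(max_length, 0.0, 0.0)), 0.0
        )
    N = float(total_inserts)
    step = float(grid_step) if grid_step else max(1.0, round(N / 1000.0))
    grid = np.unique(np.concatenate([np.arange(0.0, N, step), [N]]))
    probs = np.atleast_1d(_mix_objective(grid, N, s, max_length, genome_length, m))
    best = int(np.argmax(probs))
    n1_best, p_best = float(grid[best]), float(probs[best])
    # continuous refinement around the best grid point
    lo = max(0.0, n1_best - step)
    hi = min(N, n1_best + step)
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda n1: -float(_mix_objective(np.array([n1]), N, s, max_length, genome_length, m)[0]),
            bounds=(lo, hi),
            method="bounded",
        )
        for cand in {math.floor(res.x), math.ceil(res.x)}:
            cand = min(max(float(cand), 0.0), N)
            p = float(_mix_objective(np.array([cand]), N, s, max_length, genome_length, m)[0])
            if p > p_best:
                n1_best, p_best = cand, p
    return MixDesign(
        (
            InsertLibrary(s, 0.0, n1_best),
            InsertLibrary(max_length, 0.0, N - n1_best),
        ),
        p_best,
    )


def required_inserts(query: DesignQuery, mean_length: float) -> int:
    """Smallest number of sequenced inserts detecting 1 - epsilon of breakpoints.

    Inverts the detection formula for the mapped-insert count N (closed form
    for min_inserts=1, bisection for min_inserts=2, tolerance one insert)
    and scales by 1/mapping_rate for the sequencing requirement.
    """
    if not mean_length > 0:
        raise ValueError("mean_length must be positive")
    if mean_length >= query.sv_length:
        raise ValueError(
            "insert length must be smaller than the target SV length (size "
            f"constraint l > L violated: L={mean_length}, l={query.sv_length})"
        )
    G, L, eps, m = query.genome_length, mean_length, query.epsilon, query.min_inserts
    target = 1.0 - eps
    if m == 1:
        c_star = -math.log(eps)
    else:
        # solve exp(-c) * (1 + c) = eps
        f = lambda c: math.exp(-c) * (1.0 + c) - eps
        hi = 1.0
        while f(hi) > 0:
            hi *= 2.0
        c_star = optimize.brentq(f, 0.0, hi, xtol=1e-12)
    n = max(0, math.ceil(c_star * G / L - 1e-9))
    # settle integer boundary to one-insert tolerance
    while n > 0 and detection_probability(clonal_coverage(n - 1, L, G), m) >= target:
        n -= 1
    while detection_probability(clonal_coverage(n, L, G), m) < target:
        n += 1
    return mappable_scale(n, query.mapping_rate)


def mappable_scale(n_required: float, mapping_rate: float) -> int:
    """Sequenced-insert count N/f needed for n_required mapped inserts."""
    if not 0 < mapping_rate <= 1:
        raise ValueError("mapping_rate must be in (0, 1]")
    if n_required < 0:
        raise ValueError("n_required must be non-negative")
    value = n_required / mapping_rate
    nearest = round(value)
    if abs(value - nearest) < 1e-9:
        return int(nearest)
    return int(math.ceil(value))
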