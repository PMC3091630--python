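"""Monte-Carlo oracle and synthetic paired-end simulator for breakpoint design.

Simulates random insert placement around a fusion point (optionally with
Gaussian insert-length jitter, truncated at 1 bp) and measures detection
frequency, mean resolution-ambiguity and the frequency of resolving to a
target s.  With zero jitter the estimates converge to the closed forms in
:mod:`seqdesign.sv`; the simulator is therefore the certification oracle
for every formula there.

The ambiguity of a detected fusion point is computed with the empirical
rule used on real paired-end data: for each spanning insert of length l,
let x_l be the distance of its left endpoint from the left end of the
right-most spanning insert and x_r the distance of its right endpoint from
the right end of the left-most one; the per-insert resolution is
l - (x_l + x_r) and the reported ambiguity is the mean over spanning
inserts (equal to the width of the interval between the right-most left
endpoint and the left-most right endpoint).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sv import InsertLibrary, _check_min_inserts

__all__ = ["SimConfig", "SimResult", "simulate_fusion_point", "empirical_ambiguity", "planted_sv_testbed"]

# floating-point guard when comparing ambiguities against a target s (bp)
_RESOLVE_EPS = 1e-6


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a fusion-point simulation (seeded, reproducible)."""

    genome_length: float
    libraries: tuple[InsertLibrary, ...]
    n_trials: int = 100_000
    seed: int = 0
    min_inserts: int = 2

    def __post_init__(self) -> None:
        if not self.genome_length > 0:
            raise ValueError("genome_length must be positive")
        if not self.n_trials > 0:
            raise ValueError("n_trials must be positive")
        _check_min_inserts(self.min_inserts)
        object.__setattr__(self, "libraries", tuple(self.libraries))


@dataclass(frozen=True)
class SimResult:
    """Empirical estimates with normal-approximation standard errors."""

    p_detect_hat: float
    p_detect_se: float
    mean_ambiguity_hat: float
    ambiguity_se: float
    p_resolved_hat: dict[float, tuple[float, float]] = field(default_factory=dict)
    n_trials: int = 0
    n_detected: int = 0


def _truncated_lengths(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal(mean, sd) insert lengths truncated below at 1 bp (resampled)."""
    out = rng.normal(mean, sd, size)
    bad = out < 1.0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < 1.0
    return out


def simulate_fusion_point(config: SimConfig, s_values=()) -> SimResult:
    """Simulate spanning inserts at a fusion point over config.n_trials trials.

    Per trial and library the number of candidate inserts near the fusion
    point is Poisson with the exact genome-wide rate; offsets are uniform.
    Detection requires >= config.min_inserts spanning inserts (across all
    libraries); ambiguity follows the empirical per-insert rule.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_trials
    G = config.genome_length
    k = np.zeros(n, dtype=np.int64)
    max_left = np.full(n, -np.inf)
    min_right = np.full(n, np.inf)
    for lib in config.libraries:
        N, L, sd = lib.n_inserts, lib.mean_length, lib.length_sd
        if N <= 0:
            continue
        # left endpoints within W bp left of zeta can span; W covers 7 sigma
        W = L + 7.0 * sd
        counts = rng.poisson(N * W / G, n)
        tot = int(counts.sum())
        u = rng.uniform(-W, 0.0, tot)  # left endpoint relative to zeta
        ell = _truncated_lengths(rng, L, sd, tot) if sd > 0 else np.full(tot, L)
        right = u + ell
        span = right > 0.0
        tid = np.repeat(np.arange(n), counts)[span]
        k += np.bincount(tid, minlength=n)
        np.maximum.at(max_left, tid, u[span])
        np.minimum.at(min_right, tid, right[span])
    detected = k >= config.min_inserts
    nd = int(detected.sum())
    p = nd / n
    p_se = float(np.sqrt(p * (1.0 - p) / n))
    if nd > 0:
        amb = min_right[detected] - max_left[detected]
        amb_mean = float(amb.mean())
        amb_se = float(amb.std(ddof=1) / np.sqrt(nd)) if nd > 1 else float("nan")
    else:
        amb = np.empty(0)
        amb_mean = float("nan")
        amb_se = float("nan")
    resolved = {}
    for s in s_values:
        hits = detected.copy()
        hits[detected] &= amb <= s + _RESOLVE_EPS
        ps = float(hits.mean())
        resolved[float(s)] = (ps, float(np.sqrt(ps * (1.0 - ps) / n)))
    return SimResult(
        p_detect_hat=p,
        p_detect_se=p_se,
        mean_ambiguity_hat=amb_mean,
        ambiguity_se=amb_se,
        p_resolved_hat=resolved,
        n_trials=n,
        n_detected=nd,
    )


def empirical_ambiguity(spanning_inserts, fusion_offset: float) -> float:
    """Resolution-ambiguity from explicit spanning inserts, in bp.

    spanning_inserts is a sequence of (left_offset, length) pairs, each of
    which must span fusion_offset.  Applies the per-insert rule
    l - (x_l + x_r) and averages over inserts.
    """
    inserts = list(spanning_inserts)
    if not inserts:
        raise ValueError("at least one spanning insert is required")
    lefts = np.array([i[0] for i in inserts], dtype=float)
    lengths = np.array([i[1] for i in inserts], dtype=float)
    rights = lefts + lengths
    if np.any(lefts > fusion_offset) or np.any(rights < fusion_offset):
        raise ValueError("every insert must span the fusion point")
    x_l = lefts.max() - lefts
    x_r = rights - rights.min()
    return float((lengths - (x_l + x_r)).mean())


def planted_sv_testbed(
    genome_length: float,
    sv_lengths,
    libraries,
    seed: int = 0,
    min_inserts: int = 2,
) -> pd.DataFrame:
    """Genome-wide placement experiment with planted fusion points.

    Fusion points are placed uniformly (away from the genome ends by the
    longest insert) and inserts are scattered genome-wide for each library.
    An SV of length l is admissible for a library only when l exceeds the
    library's mean insert length (the size constraint l > L); SVs
    admissible for no library are flagged rather than counted undetected.

    Returns a table with one row per planted SV: position, admissibility,
    spanning-insert count (over admissible libraries), detection flag and
    ambiguity (NaN when undetected).
    """
    _check_min_inserts(min_inserts)
    rng = np.random.default_rng(seed)
    sv_lengths = np.asarray(list(sv_lengths), dtype=float)
    if np.any(sv_lengths <= 0):
        raise ValueError("sv_lengths must be positive")
    libs = list(libraries)
    margin = max((l.mean_length + 7.0 * l.length_sd for l in libs), default=0.0)
    if genome_length <= 2.0 * margin:
        raise ValueError("genome_length too small for the given insert lengths")
    positions = rng.uniform(margin, genome_length - margin, sv_lengths.size)
    placed = []
    for lib in libs:
        n = int(lib.n_inserts)
        lefts = rng.uniform(0.0, genome_length, n)
        lengths = (
            _truncated_lengths(rng, lib.mean_length, lib.length_sd, n)
            if lib.length_sd > 0
            else np.full(n, lib.mean_length)
        )
        order = np.argsort(lefts)
        placed.append((lib, lefts[order], lengths[order]))
    rows = []
    for i, (pos, sv_len) in enumerate(zip(positions, sv_lengths)):
        admissible_libs = [p for p in placed if p[0].mean_length < sv_len]
        admissible = bool(admissible_libs) if libs else False
        span_left = []
        span_right = []
        for lib, lefts, lengths in admissible_libs:
            w = lib.mean_length + 7.0 * lib.length_sd
            lo, hi = np.searchsorted(lefts, [pos - w, pos])
            cand_l = lefts[lo:hi]
            cand_r = cand_l + lengths[lo:hi]
            mask = cand_r >= pos
            span_left.append(cand_l[mask])
            span_right.append(cand_r[mask])
        span_left = np.concatenate(span_left) if span_left else np.empty(0)
        span_right = np.concatenate(span_right) if span_right else np.empty(0)
        n_span = int(span_left.size)
        detected = admissible and n_span >= min_inserts
        ambiguity = float(span_right.min() - span_left.max()) if detected else float("nan")
        rows.append(
            {
                "sv_id": f"sv{i:04d}",
                "sv_length": float(sv_len),
                "position": float(pos),
                "admissible": admissible,
                "n_spanning": n_span,
                "detected": bool(detected),
                "ambiguity": ambiguity,
            }
        )
    return pd.DataFrame(rows)
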