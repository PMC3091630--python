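"""Synthetic transcriptome with a known ground-truth expression law.

Raw expression values are drawn by inverse-transform sampling from the
same two-parameter family the depth planner fits,

    f(x) proportional to (x + delta_D)^-alpha   on [nu_floor, 1],

then normalized to a probability vector nu (the pure power law is
non-normalizable at 0, hence the floor).  Reads are sampled multinomially
at a chosen depth; sub-sampling an existing run is hypergeometric
(without replacement), matching the subsetting of a fixed sequencing run.
All operations are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tx import TranscriptCounts

__all__ = ["ExpressionLaw", "draw_expression", "sample_reads", "subsample", "transcript_ids"]


@dataclass(frozen=True)
class ExpressionLaw:
    """Ground-truth expression distribution for the synthetic transcriptome.

    alpha is the power-law slope (> 1), delta_d the noise-floor parameter
    flattening the density below ~delta_d, nu_floor the truncation point
    of the raw support.
    """

    n_transcripts: int
    alpha: float = 2.0
    delta_d: float = 1e-4
    seed: int = 0
    nu_floor: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        if not self.alpha > 1:
            raise ValueError("alpha must exceed 1")
        if self.delta_d < 0:
            raise ValueError("delta_d must be non-negative")
        if not 0 < self.nu_floor < 1:
            raise ValueError("nu_floor must be in (0, 1)")

    def raw_cdf(self, x) -> np.ndarray:
        """Analytic CDF of the raw (pre-normalization) draws on [nu_floor, 1]."""
        x = np.clip(np.asarray(x, dtype=float), self.nu_floor, 1.0)
        a = 1.0 - self.alpha
        lo = (self.nu_floor + self.delta_d) ** a
        hi = (1.0 + self.delta_d) ** a
        return ((x + self.delta_d) ** a - lo) / (hi - lo)


def transcript_ids(n: int) -> list[str]:
    """Stable synthetic transcript identifiers t00000, t00001, ..."""
    return [f"t{i:05d}" for i in range(n)]


def draw_expression(law: ExpressionLaw) -> np.ndarray:
    """Draw a normalized expression vector nu (sums to 1) under the law.

    Inverse-transform sampling of the truncated (x + delta)^-alpha density,
    followed by normalization of the vector to sum 1.
    """
    rng = np.random.default_rng(law.seed)
    u = rng.random(law.n_transcripts)
    a = 1.0 - law.alpha
    lo = (law.nu_floor + law.delta_d) ** a
    hi = (1.0 + law.delta_d) ** a
    x = (lo + u * (hi - lo)) ** (1.0 / a) - law.delta_d
    return x / x.sum()


def sample_reads(nu, depth: int, seed: int = 0, ids=None) -> TranscriptCounts:
    """Multinomial read sample of the transcriptome at a given depth.

    Zero-count transcripts are omitted from the result; total_reads equals
    the requested depth.
    """
    nu = np.asarray(nu, dtype=float)
    if depth < 0:
        raise ValueError("depth must be non-negative")
    if nu.size == 0 or np.any(nu < 0):
        raise ValueError("nu must be a non-empty non-negative vector")
    if abs(nu.sum() - 1.0) > 1e-6:
        raise ValueError("nu must sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(depth), nu / nu.sum())
    if ids is None:
        ids = transcript_ids(nu.size)
    observed = {ids[i]: int(c) for i, c in enumerate(counts) if c > 0}
    return TranscriptCounts(counts=observed, total_reads=int(depth))


def subsample(counts: TranscriptCounts, k: int, seed: int = 0) -> TranscriptCounts:
    """Hypergeometric sub-sample of k mapped reads, without replacement."""
    total = counts.mapped_reads
    if k < 0 or k > total:
        raise ValueError(f"k must lie in [0, {total}], got {k}")
    keys = sorted(counts.counts)
    colors = np.array([counts.counts[t] for t in keys], dtype=np.int64)
    rng = np.random.default_rng(seed)
    sub = rng.multivariate_hypergeometric(colors, int(k))
    observed = {t: int(c) for t, c in zip(keys, sub) if c > 0}
    return TranscriptCounts(counts=observed, total_reads=int(k))
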