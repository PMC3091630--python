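"""Transcript-detection depth planning from a pilot RNA-seq run.

A pilot run of r reads gives per-transcript counts a_t and normalized
expression nu_t = a_t / sum(a).  The probability that a transcript of
normalized expression nu is seen at least once among N reads is
1 - (1 - nu)^N, so the expected detected fraction at depth N is the
integral of that curve against the p.d.f. f(nu) of expression values
across transcripts.

A pilot under-samples the low-abundance tail of f: below the *reliable
point* nu_r -- the expression level detected with 95% probability at the
pilot depth -- the empirical histogram collapses.  Following the
power-law-with-noise view of expression distributions, the tail is
repaired by (i) fitting a power law f ~ beta * nu^-alpha to the
well-sampled high-expression bins, (ii) fitting the two remaining
parameters of the noise model

    f(nu) = C * (nu + delta_D)^-alpha

(delta_D a noise/decay parameter, C a normalization), and (iii)
splicing: empirical mass at and above nu_r, model mass below,
renormalized to a proper p.d.f.  The corrected p.d.f. then supports
depth predictions well beyond the pilot.

The two remaining parameters are identified as follows: C is least-squares
matched to the occupied bins just above nu_r (the shallowest reliable
bins), while delta_D is pinned by conservation of total expression -- the
nu values of all transcripts sum to 1, so the model tail below nu_r must
carry exactly the read mass that the reliably observed transcripts do
not.  A shallow pilot cannot see the curvature of the noise floor
directly (nu_r lies above delta_D), but it does know how many reads its
reliable transcripts account for, and that balance determines the tail.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TranscriptCounts",
    "ExpressionPDF",
    "DetectionCurve",
    "normalized_expression",
    "detection_prob",
    "reliable_point",
    "empirical_pdf",
    "fit_power_law",
    "correct_pdf",
    "predict_detection",
    "required_depth",
    "cross_sample_predict",
]


@dataclass
class TranscriptCounts:
    """Per-transcript read counts from a pilot run.

    total_reads may exceed the mapped sum (unmapped reads); it defaults to
    the mapped sum.  lengths (bp) are carried through when a counts file
    provides them but play no role in the design math.
    """

    counts: dict[str, int]
    total_reads: int | None = None
    lengths: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for t, a in self.counts.items():
            if a < 1 or int(a) != a:
                raise ValueError(f"count for {t!r} must be a positive integer, got {a!r}")
        mapped = sum(self.counts.values())
        if self.total_reads is None:
            self.total_reads = mapped
        elif self.total_reads < mapped:
            raise ValueError("total_reads cannot be smaller than the mapped read sum")

    @property
    def mapped_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def n_transcripts(self) -> int:
        return len(self.counts)


@dataclass
class ExpressionPDF:
    """Log-binned p.d.f. of normalized expression, with fitted parameters.

    density holds per-bin probability mass (sums to 1 over the bins);
    centers are geometric bin midpoints.  alpha/log_beta come from the
    high-expression power-law regression, delta_d and model_scale from the
    noise-model fit, nu_r is the reliable point of the source pilot.
    """

    bin_edges: np.ndarray
    density: np.ndarray
    total_reads: int | None = None
    alpha: float | None = None
    log_beta: float | None = None
    delta_d: float | None = None
    nu_r: float | None = None
    corrected: bool = False
    model_scale: float | None = None
    observed_nu: np.ndarray | None = None

    @property
    def centers(self) -> np.ndarray:
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)


@dataclass(frozen=True)
class DetectionCurve:
    """Detection probability vs normalized expression at a fixed depth."""

    depth: int
    nu: np.ndarray
    prob: np.ndarray
    expected_fraction: float
    cross_sample: bool = False


def normalized_expression(counts: TranscriptCounts) -> dict[str, float]:
    """nu_t = a_t / sum(a): likelihood a random mapped read came from t."""
    total = counts.mapped_reads
    if total <= 0:
        raise ValueError("no mapped reads: counts are empty")
    return {t: a / total for t, a in counts.counts.items()}


def detection_prob(nu, depth):
    """P(transcript of normalized expression nu is sampled in depth reads).

    1 - (1 - nu)^depth, computed stably; accepts scalars or arrays.
    """
    nu_arr = np.asarray(nu, dtype=float)
    if np.any((nu_arr < 0) | (nu_arr > 1)):
        raise ValueError("nu must lie in [0, 1]")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = -np.expm1(depth * np.log1p(-nu_arr))
    p = np.where(nu_arr >= 1.0, 1.0 if depth > 0 else 0.0, p)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.isscalar(nu) else p


def reliable_point(total_reads: int, prob: float = 0.95) -> float:
    """Expression level detected with probability `prob` by a run of r reads.

    Solves 1 - (1 - nu)^r = prob, i.e. nu_r = 1 - (1 - prob)^(1/r).
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if not 0 < prob < 1:
        raise ValueError("prob must be in (0, 1)")
    return 1.0 - (1.0 - prob) ** (1.0 / total_reads)


def empirical_pdf(counts: TranscriptCounts, n_bins: int = 50) -> ExpressionPDF:
    """Log-binned empirical p.d.f. of nu over the observed transcripts.

    Per-bin mass is the fraction of observed transcripts whose nu falls in
    the bin; bins are log-spaced over [min nu, max nu].
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    nu = np.array(sorted(normalized_expression(counts).values()))
    if nu.size < 2:
        raise ValueError("degenerate p.d.f.: at least two observed transcripts required")
    lo, hi = float(nu[0]), float(nu[-1])
    if lo == hi:
        lo, hi = lo * 0.999, hi * 1.001
    edges = np.geomspace(lo, hi, n_bins + 1)
    mass, _ = np.histogram(nu, bins=edges)
    return ExpressionPDF(
        bin_edges=edges,
        density=mass / nu.size,
        total_reads=counts.total_reads,
        nu_r=reliable_point(counts.total_reads),
        observed_nu=nu,
    )


def fit_power_law(pdf: ExpressionPDF, high_expr_threshold: float | None = None):
    """OLS power-law fit log f(nu) = log(beta) - alpha*log(nu) on high-expression bins.

    The regression uses occupied bins with center above the threshold
    (default 10 * nu_r, keeping it in the well-sampled regime) and the
    per-width density mass/width, whose log-log slope is -alpha for a
    power law.  Sets pdf.alpha and pdf.log_beta; returns (alpha, log_beta).
    """
    if high_expr_threshold is None:
        if pdf.nu_r is None:
            raise ValueError("no threshold given and pdf has no reliable point")
        high_expr_threshold = 10.0 * pdf.nu_r
    centers = pdf.centers
    mask = (pdf.density > 0) & (centers >= high_expr_threshold)
    if int(mask.sum()) < 3:
        raise ValueError(
            "insufficient data: fewer than 3 occupied bins above the "
            f"high-expression threshold {high_expr_threshold:g}"
        )
    x = np.log(centers[mask])
    y = np.log(pdf.density[mask] / pdf.widths[mask])
    fit = stats.linregress(x, y)
    pdf.alpha = float(-fit.slope)
    pdf.log_beta = float(fit.intercept)
    return pdf.alpha, pdf.log_beta


def _model_bin_mass(edges: np.ndarray, scale: float, delta: float, alpha: float) -> np.ndarray:
    """Integral of scale*(nu+delta)^-alpha over each bin of `edges`."""
    a = 1.0 - alpha
    lo = edges[:-1] + delta
    hi = edges[1:] + delta
    if abs(a) < 1e-12:
        integral = np.log(hi / lo)
    else:
        integral = (hi**a - lo**a) / a
    return scale * integral


def correct_pdf(
    pdf: ExpressionPDF,
    total_reads: int | None = None,
    *,
    target_depth: float | None = None,
    nu_min: float | None = None,
    fit_window: tuple[float, float] = (1.0, 10.0),
    reliable_nu: float | None = None,
) -> ExpressionPDF:
    """Splice the noise model below the reliable point of an empirical p.d.f.

    Bins at or above nu_r keep their empirical mass; bins below nu_r --
    extended down to nu_min with the same geometric spacing -- take mass
    from the fitted noise model C*(nu+delta_D)^-alpha (alpha comes from
    the prior high-expression regression).  C = exp(log_beta): the model
    reduces to the fitted power law beta*nu^-alpha at high nu, so
    continuity with the regression fixes the normalization (a
    least-squares match to the occupied bins in
    [nu_r*fit_window[0], nu_r*fit_window[1]] is the fallback when no
    intercept is available).  delta_D is solved from the read-mass
    balance: since the nu of all transcripts sum to 1, the model tail
    must carry the read mass 1 - R left over by the reliably observed
    transcripts (R = sum of nu over observed transcripts with nu >= nu_r).
    The spliced density is renormalized to sum to 1.

    nu_min defaults to 1/(10*target_depth) when a target depth is given
    (covering everything detectable at the depths under study), else
    nu_r/1000.  If the balance has no solution within the model family the
    correction falls back to the nearest boundary (pure power law, or the
    flat-tail limit) with a warning.
    """
    if pdf.alpha is None:
        raise ValueError("fit_power_law must be run before correcting the p.d.f.")
    r = total_reads if total_reads is not None else pdf.total_reads
    if r is None:
        raise ValueError("total_reads is required (none stored on the pdf)")
    nu_r = reliable_nu if reliable_nu is not None else reliable_point(r)
    if nu_min is None:
        nu_min = 1.0 / (10.0 * target_depth) if target_depth else nu_r / 1000.0
    edges = pdf.bin_edges
    mass = pdf.density.astype(float)
    if nu_r <= edges[0]:
        # pilot deep enough that every occupied bin is reliable: no-op splice
        return replace(
            pdf,
            bin_edges=edges.copy(),
            density=mass / mass.sum(),
            total_reads=r,
            nu_r=nu_r,
            corrected=True,
        )
    alpha = pdf.alpha
    centers = pdf.centers
    # --- extended grid down to nu_min -----------------------------------------
    ratio = edges[1] / edges[0]
    new_lo = [edges[0]]
    while new_lo[-1] > nu_min and new_lo[-1] / ratio > 0:
        new_lo.append(new_lo[-1] / ratio)
    ext = np.array(new_lo[1:][::-1])
    new_edges = np.concatenate([ext, edges])
    new_centers = np.sqrt(new_edges[:-1] * new_edges[1:])
    model_bins = new_centers < nu_r
    seg = np.concatenate([new_edges[:-1][model_bins], new_edges[1:][model_bins][-1:]])
    # --- normalization C: continuity with the high-expression power law ------
    if pdf.log_beta is not None:
        def scale_for(delta: float) -> float:
            return math.exp(pdf.log_beta)
    else:
        # fallback: least-squares match to the occupied bins near nu_r
        win_lo, win_hi = nu_r * fit_window[0], nu_r * fit_window[1]
        fit_mask = (mass > 0) & (centers >= win_lo) & (centers <= win_hi)
        if int(fit_mask.sum()) < 3:
            fit_mask = (mass > 0) & (centers >= win_lo)
        if not fit_mask.any():
            raise ValueError(
                "no occupied bins at or above the reliable point to anchor the fit"
            )
        win_edges = (edges[:-1][fit_mask], edges[1:][fit_mask])
        log_win_mass = np.log(mass[fit_mask])

        def scale_for(delta: float) -> float:
            a = 1.0 - alpha
            lo = win_edges[0] + delta
            hi = win_edges[1] + delta
            integral = np.log(hi / lo) if abs(a) < 1e-12 else (hi**a - lo**a) / a
            return float(np.exp(np.mean(log_win_mass - np.log(integral))))

    # --- delta_D from read-mass balance ---------------------------------------
    # reliable read mass R: sum of nu over observed transcripts with nu >= nu_r
    if pdf.observed_nu is not None:
        obs = np.asarray(pdf.observed_nu, dtype=float)
        reliable_read_mass = float(obs[obs >= nu_r].sum())
        total_read_mass = float(obs.sum())
        n_obs = float(obs.size)
    else:  # binned approximation when raw values are unavailable
        per_transcript = float(np.dot(mass, centers))  # ~ 1/n_observed
        read_mass = mass * centers
        reliable_read_mass = float(read_mass[centers >= nu_r].sum()) / per_transcript
        total_read_mass = 1.0
        n_obs = 1.0 / per_transcript
    tail_target = max(total_read_mass - reliable_read_mass, 0.0)
    seg_centers = np.sqrt(seg[:-1] * seg[1:])

    def tail_read_mass(delta: float) -> float:
        # model masses are per observed transcript; read mass is absolute
        return n_obs * float(
            np.dot(_model_bin_mass(seg, scale_for(delta), delta, alpha), seg_centers)
        )

    delta_lo, delta_hi = 0.0, 1.0
    f_lo = tail_read_mass(delta_lo) - tail_target
    f_hi = tail_read_mass(delta_hi) - tail_target
    if f_lo <= 0.0:
        # even the pure power law carries too little tail mass: use it as-is
        delta = 0.0
        if f_lo < -0.1 * max(tail_target, 1e-12):
            warnings.warn(
                "read-mass balance unreachable within the noise-model family; "
                "falling back to pure power-law extrapolation",
                stacklevel=2,
            )
    elif f_hi >= 0.0:
        delta = delta_hi
        warnings.warn(
            "read-mass balance unreachable within the noise-model family; "
            "using the flat-tail limit",
            stacklevel=2,
        )
    else:
        delta = float(
            optimize.brentq(lambda d: tail_read_mass(d) - tail_target, delta_lo, delta_hi, xtol=1e-15)
        )
    scale = scale_for(delta)
    new_mass = np.concatenate([np.zeros(ext.size), mass])
    new_mass[model_bins] = _model_bin_mass(seg, scale, delta, alpha)
    new_mass = np.clip(new_mass, 0.0, None)
    new_mass /= new_mass.sum()
    return ExpressionPDF(
        bin_edges=new_edges,
        density=new_mass,
        total_reads=r,
        alpha=alpha,
        log_beta=pdf.log_beta,
        delta_d=delta,
        nu_r=nu_r,
        corrected=True,
        model_scale=scale,
    )


def predict_detection(pdf: ExpressionPDF, depth: int) -> DetectionCurve:
    """Detection curve and expected detected fraction at a sequencing depth.

    expected_fraction = sum over bins of mass(nu) * (1 - (1-nu)^depth),
    evaluated at geometric bin centers.
    """
    centers = pdf.centers
    prob = detection_prob(centers, depth)
    ef = float(np.dot(pdf.density, prob))
    return DetectionCurve(depth=int(depth), nu=centers, prob=prob, expected_fraction=ef)


def required_depth(pdf: ExpressionPDF, epsilon: float, max_depth: int = 10**15) -> int:
    """Smallest read depth detecting a fraction >= 1 - epsilon of transcripts.

    Integer bisection on the monotone expected detected fraction.  If the
    target is unreachable below max_depth (possible only through numerical
    saturation of the p.d.f. support) the asymptotic cap is returned with
    a warning instead of looping.
    """
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must be in (0, 1)")
    target = 1.0 - epsilon
    if predict_detection(pdf, 0).expected_fraction >= target:
        return 0
    hi = 1
    while predict_detection(pdf, hi).expected_fraction < target:
        hi *= 2
        if hi >= max_depth:
            warnings.warn(
                "detection target unreachable below max_depth; returning the cap",
                stacklevel=2,
            )
            return max_depth
    lo = hi // 2
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if predict_detection(pdf, mid).expected_fraction >= target:
            hi = mid
        else:
            lo = mid
    return hi


def cross_sample_predict(pdf_source: ExpressionPDF, depth: int) -> DetectionCurve:
    """Predict detection in a *different* sample from this sample's p.d.f.

    Identical computation to :func:`predict_detection`; the returned curve
    is flagged cross_sample so that reports label the prediction as
    borrowed from a related sample (expression p.d.f.s are often conserved
    across tissues, but such predictions tend to over-predict at high
    depth when the source law is shifted toward high expression).
    """
    curve = predict_detection(pdf_source, depth)
    return replace(curve, cross_sample=True)
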