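"""Gaussian-process recursive Bayesian edge tracing of a single boundary.

A boundary is modelled as a Gaussian process over lateral position (in
microns, so the kernel lengthscale is anatomical rather than pixel-grid
dependent). Starting from two manually supplied endpoint pixels, the
tracer repeatedly (a) fits the GP posterior to the accepted edge pixels,
(b) scores edge-map candidates on the next batch of unvisited columns,
advancing inward from both endpoints, (c) accepts the best-scoring
candidate per column, and (d) refits, until the span is exhausted. The
result is the posterior predictive mean and SD on every column: a
sub-pixel, uncertainty-quantified functional form for the edge.

Candidate scores combine gradient evidence (the KDE-based cumulative
weight of the pixel's edge strength) with the GP model density at the
candidate row, via a weighted geometric mean. Everything is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    BoundaryTrace,
    BScan,
    CrossingBoundariesError,
    DegenerateBandwidthWarning,
    EdgeMap,
    InvalidParameterError,
    LowEvidenceError,
    NumericalConditioningError,
    Segmentation,
)
from .preprocess import build_edge_map, denoise_median, enhance_clahe

_JITTER = 1e-10


@dataclass
class GPConfig:
    """Free parameters of the tracer; lengthscale is lateral microns."""

    kernel_lengthscale: float = 500.0  # um
    kernel_variance: float = 400.0  # px^2
    observation_noise_sd: float = 1.0  # px
    credible_multiplier: float = 3.0
    score_weight: float = 0.5  # weight on gradient evidence vs model density
    batch_columns: int = 15
    kde_bandwidth: str | float = "scott"
    band_min_px: float = 6.0  # floor on the candidate half-band
    # minimum gradient evidence weight to accept a pixel; weaker columns are
    # treated as occluded and left to the posterior interpolant
    min_evidence: float = 0.9

    def __post_init__(self) -> None:
        if min(
            self.kernel_lengthscale,
            self.kernel_variance,
            self.observation_noise_sd,
            self.batch_columns,
            self.band_min_px,
        ) <= 0:
            raise InvalidParameterError("GPConfig parameters must be positive")
        if self.credible_multiplier < 1:
            raise InvalidParameterError("credible_multiplier must be >= 1")
        if not 0 <= self.score_weight <= 1:
            raise InvalidParameterError("score_weight must be in [0, 1]")
        if not 0 <= self.min_evidence < 1:
            raise InvalidParameterError("min_evidence must be in [0, 1)")


def _sq_exp(xa: np.ndarray, xb: np.ndarray, variance: float, lengthscale: float) -> np.ndarray:
    d = xa[:, None] - xb[None, :]
    return variance * np.exp(-0.5 * (d / lengthscale) ** 2)


def gp_posterior(
    observations: list[tuple[float, float]],
    config: GPConfig,
    query_columns: np.ndarray,
    lateral_scale: float = 1.0,
    prior_mean: float | np.ndarray = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Squared-exponential GP predictive mean and SD at the query columns.

    Observations are (column, row) pairs; columns are converted to microns
    via ``lateral_scale`` before the kernel is applied. ``prior_mean`` is a
    constant mean applied to observations and queries alike. With no
    observations the prior (``prior_mean``, sqrt(kernel_variance)) is
    returned.
    """
    q = np.asarray(query_columns, dtype=float) * lateral_scale
    mu = float(prior_mean)
    if len(observations) == 0:
        return np.full(q.shape, mu), np.full(q.shape, np.sqrt(config.kernel_variance))

    cols = np.array([c for c, _ in observations], dtype=float)
    if len(np.unique(cols)) != len(cols):
        raise NumericalConditioningError("duplicate observation columns")
    x = cols * lateral_scale
    y = np.array([r for _, r in observations], dtype=float)
    mu_x = np.full_like(x, mu)

    k_xx = _sq_exp(x, x, config.kernel_variance, config.kernel_lengthscale)
    k_xx[np.diag_indices_from(k_xx)] += config.observation_noise_sd**2 + _JITTER
    try:
        chol = np.linalg.cholesky(k_xx)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericalConditioningError("singular GP covariance") from exc
    k_qx = _sq_exp(q, x, config.kernel_variance, config.kernel_lengthscale)
    alpha = np.linalg.solve(chol.T, np.linalg.solve(chol, y - mu_x))
    mean = mu + k_qx @ alpha
    v = np.linalg.solve(chol, k_qx.T)
    var = config.kernel_variance - np.sum(v**2, axis=0)
    sd = np.sqrt(np.clip(var, 0.0, None))
    return mean, sd


def kde_gradient_density(gradient_values, bandwidth: str | float = "scott"):
    """Gaussian KDE over gradient magnitudes; returns a callable density.

    All-identical inputs trigger :class:`DegenerateBandwidthWarning` and a
    narrow point-mass surrogate is returned instead.
    """
    vals = np.asarray(gradient_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise InvalidParameterError("need at least 2 finite values for a KDE")
    if np.ptp(vals) == 0:
        warnings.warn(
            "all gradient values identical; using a point-mass density",
            DegenerateBandwidthWarning,
        )
        center = float(vals[0])
        width = max(abs(center), 1.0) * 1e-9

        def point_mass(x):
            x = np.atleast_1d(np.asarray(x, dtype=float))
            return stats.norm.pdf(x, loc=center, scale=width)

        return point_mass
    kde = stats.gaussian_kde(vals, bw_method=bandwidth)
    return lambda x: kde(np.atleast_1d(np.asarray(x, dtype=float)))


def _evidence_from_map(edge_map: EdgeMap, bandwidth: str | float, max_sample: int = 4000):
    """Monotone evidence weight for a gradient value: KDE-based CDF.

    High-gradient pixels are rare under the map's gradient distribution, so
    the cumulative weight P(G <= g) ranks candidates by edge strength on a
    (0, 1) scale.
    """
    vals = edge_map.gradient[edge_map.gradient > 0]
    if vals.size < 2:
        return lambda g: np.ones_like(np.asarray(g, dtype=float))
    if vals.size > max_sample:
        vals = np.sort(vals)[:: vals.size // max_sample + 1]
    if np.ptp(vals) == 0:
        v0 = float(vals[0])
        return lambda g: np.where(np.asarray(g, dtype=float) >= v0, 1.0, 1e-12)
    kde = stats.gaussian_kde(vals, bw_method=bandwidth)
    grid = np.linspace(0.0, float(vals.max()) * 1.05, 512)
    dens = kde(grid)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) * 0.5 * np.diff(grid))])
    cdf /= cdf[-1]
    # tiny slope keeps the weight strictly increasing past the grid end
    return lambda g: np.interp(np.asarray(g, dtype=float), grid, cdf) + 1e-9 * np.asarray(g)


def score_candidates(
    column: int,
    edge_map: EdgeMap,
    posterior_mean: float,
    posterior_sd: float,
    config: GPConfig,
    evidence=None,
) -> list[tuple[int, float]]:
    """Score edge-pixel candidates in the posterior credible band of a column.

    Candidates are column-local maxima of the edge map with nonzero support
    within ``credible_multiplier * posterior_sd`` (floored at
    ``band_min_px``) of the posterior mean; each is refined to sub-pixel
    position by parabolic interpolation of the gradient profile. The score
    is a weighted geometric mean of the gradient evidence weight and the
    Gaussian model density at the row.
    """
    if posterior_sd < 0:
        raise InvalidParameterError("posterior_sd must be >= 0")
    h = edge_map.gradient.shape[0]
    half = max(config.credible_multiplier * posterior_sd, config.band_min_px)
    lo = max(0, int(np.ceil(posterior_mean - half)))
    hi = min(h - 1, int(np.floor(posterior_mean + half)))
    if hi < lo:
        return []
    col = edge_map.gradient[:, column]
    rows = np.arange(lo, hi + 1)
    g = col[rows]
    up = np.where(rows > 0, col[np.maximum(rows - 1, 0)], 0.0)
    down = np.where(rows < h - 1, col[np.minimum(rows + 1, h - 1)], 0.0)
    keep = (g > 0) & (g >= up) & (g >= down) & ((g > up) | (g > down))
    if not np.any(keep):
        return []
    rows, g = rows[keep], g[keep]
    # parabolic sub-pixel refinement of each local maximum
    r_sub = rows.astype(float)
    inner = (rows > 0) & (rows < h - 1)
    gm = col[np.clip(rows - 1, 0, h - 1)]
    gp = col[np.clip(rows + 1, 0, h - 1)]
    denom = gm - 2.0 * g + gp
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (gm - gp) / denom, 0.0)
    r_sub = np.where(inner, rows + np.clip(shift, -0.5, 0.5), r_sub)
    if evidence is None:
        evidence = _evidence_from_map(edge_map, config.kde_bandwidth)
    w = np.clip(np.asarray(evidence(g), dtype=float), 1e-300, 1.0 - 1e-12)
    strong = w >= config.min_evidence
    if not np.any(strong):
        return []
    rows, g, r_sub, w = rows[strong], g[strong], r_sub[strong], w[strong]
    sd_eff = max(posterior_sd, 1.5)  # keep the density informative near data
    dens = stats.norm.pdf(r_sub, loc=posterior_mean, scale=sd_eff)
    dens = np.clip(dens, 1e-300, None)
    a = config.score_weight
    # evidence enters as odds so near-saturated cumulative weights still
    # discriminate between strong and very strong edges
    scores = (w / (1.0 - w)) ** a * dens ** (1.0 - a)
    return [(float(r), float(s)) for r, s in zip(r_sub, scores)]


def trace_boundary(
    edge_map: EdgeMap,
    endpoints: tuple[tuple[int, float], tuple[int, float]],
    config: GPConfig | None = None,
    lateral_scale: float = 1.0,
) -> BoundaryTrace:
    """Trace one boundary between two endpoint pixels.

    The endpoints enter as the initial observations and the prior mean is
    the straight chord between them. The recursion advances symmetrically
    inward from both endpoints in batches of ``batch_columns`` columns,
    accepting the best-scoring candidate per column (columns with no
    candidate in the credible band are skipped and later covered by the
    posterior interpolant). Raises :class:`LowEvidenceError` when more than
    half of the interior columns yield no candidate.
    """
    if config is None:
        config = GPConfig()
    (c0, r0), (c1, r1) = endpoints
    if c0 == c1:
        raise InvalidParameterError("endpoint columns must differ")
    if c0 > c1:
        (c0, r0), (c1, r1) = (c1, r1), (c0, r0)
    h, w = edge_map.gradient.shape
    if not (0 <= c0 < w and 0 <= c1 < w and 0 <= r0 < h and 0 <= r1 < h):
        raise InvalidParameterError("endpoints outside the image")

    span = np.arange(c0, c1 + 1)
    chord = np.interp(span, [c0, c1], [r0, r1])

    def chord_at(col):
        return float(np.interp(col, [c0, c1], [r0, r1]))

    # the GP models residuals from the endpoint chord (zero prior mean)
    evidence = _evidence_from_map(edge_map, config.kde_bandwidth)
    observations: list[tuple[float, float]] = [(c0, 0.0), (c1, 0.0)]
    no_candidate = 0

    left, right = c0 + 1, c1 - 1
    while left <= right:
        batch: list[int] = []
        for _ in range(config.batch_columns):
            if left > right:
                break
            batch.append(left)
            left += 1
        for _ in range(config.batch_columns):
            if left > right:
                break
            batch.append(right)
            right -= 1
        batch_arr = np.array(batch)
        means_resid, sds = gp_posterior(observations, config, batch_arr, lateral_scale)
        for col, mr, s in zip(batch, means_resid, sds):
            m = mr + chord_at(col)
            cands = score_candidates(col, edge_map, m, s, config, evidence=evidence)
            if not cands:
                no_candidate += 1
                continue
            # deterministic tie-breaking: score, then proximity to the mean,
            # then the smaller row
            best = min(cands, key=lambda rs: (-rs[1], abs(rs[0] - m), rs[0]))
            observations.append((col, float(best[0]) - chord_at(col)))

    interior = max(len(span) - 2, 1)
    if no_candidate > 0.5 * interior:
        raise LowEvidenceError(
            f"{no_candidate}/{interior} columns had no edge candidate in band"
        )

    means_resid, sds = gp_posterior(observations, config, span, lateral_scale)
    obs_abs = sorted((int(c), float(r) + chord_at(c)) for c, r in observations)
    return BoundaryTrace(
        columns=span, rows=means_resid + chord, sd=sds, accepted_observations=obs_abs
    )


def suggest_endpoints(edge_map: EdgeMap, margin_cols: int = 3) -> tuple[tuple[int, float], tuple[int, float]]:
    """Convenience heuristic (extension, not part of the traced method):
    strongest column-averaged edge response at the two image margins."""
    g = edge_map.gradient
    left = g[:, :margin_cols].mean(axis=1)
    right = g[:, -margin_cols:].mean(axis=1)
    return (0, float(np.argmax(left))), (g.shape[1] - 1, float(np.argmax(right)))


def segment_bscan(
    scan: BScan,
    rpe_endpoints: tuple[tuple[int, float], tuple[int, float]],
    cs_endpoints: tuple[tuple[int, float], tuple[int, float]],
    config: GPConfig | None = None,
    median_window: int = 5,
    clip_limit: float = 0.002,
    tiles: tuple[int, int] = (4, 4),
    smoothing_scale: float = 2.0,
    min_component_px: int = 10,
) -> Segmentation:
    """Full single-scan pipeline: preprocess, trace both junctions, validate.

    The RPE-C junction is traced on a bright-to-dark edge map (hyperreflective
    RPE band above darker choroid) and the C-S junction on a dark-to-bright
    map (choroid above brighter sclera). Raises
    :class:`CrossingBoundariesError` if the traces cross anywhere on their
    common span.
    """
    pre = enhance_clahe(denoise_median(scan, median_window), clip_limit, tiles)
    rpe_map = build_edge_map(pre, "bright_to_dark", smoothing_scale, min_component_px)
    cs_map = build_edge_map(pre, "dark_to_bright", smoothing_scale, min_component_px)
    cfg = config or GPConfig()
    rpe = trace_boundary(rpe_map, rpe_endpoints, cfg, scan.lateral_scale)
    cs = trace_boundary(cs_map, cs_endpoints, cfg, scan.lateral_scale)
    seg = Segmentation(
        rpe_c=rpe, c_s=cs, scales=(scan.lateral_scale, scan.axial_scale),
        fovea_column=scan.fovea_column,
    )
    lo, hi = seg.common_span()
    cols = np.arange(lo, hi + 1)
    rpe_rows = np.interp(cols, rpe.columns, rpe.rows)
    cs_rows = np.interp(cols, cs.columns, cs.rows)
    if np.any(cs_rows <= rpe_rows):
        raise CrossingBoundariesError("traced C-S junction crosses the RPE-C junction")
    return seg
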