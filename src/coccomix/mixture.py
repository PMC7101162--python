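"""Count-informed Bayesian normal-mixture deconvolution by Gibbs sampling.

The model: pooled thickness measurements ``x_1..x_N`` arise from ``K``
morphotype components,

    x_i | z_i = k  ~  Normal(mu_k, 1/tau_k)
    mu_k           ~  Normal(m0, 1/p0)        (p0 a precision)
    tau_k          ~  Gamma(a0, rate b0)      (one per component)
    g_k            ~  Gamma(alpha_k, scale 1),  g_k := max(g_k, floor)
    pi             =  g / sum(g)              (normalised-gamma Dirichlet)

with the Dirichlet hyperpriors ``alpha`` taken from the SEM morphotype
counts, so the weight prior carries the observed relative abundances.
Component standard deviations are derived from the sampled precisions as
``sigma = 1/sqrt(tau)``. The Gibbs sweep updates the assignments ``z``
from the categorical full conditional, then ``mu``, ``tau`` and ``g``
from their conjugate full conditionals. For three or more components the
sampler state is relabelled every sweep so the means are ascending
(label-switching control: component j is the j-th thinnest, and the j-th
Dirichlet hyperprior stays attached to that rank); two-component models
are left unsorted.

Point estimates are posterior medians; uncertainty is the central 68%
credible interval (16th-84th percentiles), roughly a one-standard-
deviation margin of error. Convergence is monitored with the split
Gelman-Rubin statistic across independent chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numba
import numpy as np
import pandas as pd

from .config import MixtureConfig, PipelineConfig
from .preprocess import filter_rare, remove_outliers

logger = logging.getLogger("coccomix")

__all__ = [
    "sd_from_precision",
    "run_gibbs",
    "gelman_rubin",
    "summarize_posterior",
    "GibbsDraws",
    "PosteriorSummary",
    "NormalMixtureModel",
    "MixtureResults",
]


def sd_from_precision(precision):
    """Standard deviation from precision: sigma = precision ** (-1/2)."""
    arr = np.asarray(precision, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("precision must be > 0")
    out = arr ** -0.5
    return float(out) if np.isscalar(precision) else out


@dataclass(frozen=True)
class GibbsDraws:
    """Retained per-chain draws of the mixture state.

    Arrays have shape ``(chains, retained_draws, k)``. ``mu`` is in um,
    ``precision`` in um^-2, ``weights`` lie on the simplex. When
    ``sorted_means`` is True the components of every retained draw were
    relabelled to ascending mean (ties broken by ascending sigma) with
    precision and weights permuted consistently.
    """

    mu: np.ndarray
    precision: np.ndarray
    weights: np.ndarray
    sorted_means: bool
    data_min: float
    data_max: float

    @property
    def sigma(self) -> np.ndarray:
        return self.precision ** -0.5

    @property
    def k(self) -> int:
        return self.mu.shape[2]

    @property
    def chains(self) -> int:
        return self.mu.shape[0]


def _kmeans_1d(x: np.ndarray, k: int, n_iter: int = 25):
    """Deterministic 1-D Lloyd clustering seeded at spread quantiles.

    Returns cluster centres (ascending) and their data fractions; used
    only to initialise the sampler chains.
    """
    centres = np.quantile(x, (np.arange(k) + 0.5) / k)
    for _ in range(n_iter):
        assign = np.argmin(np.abs(x[:, None] - centres[None, :]), axis=1)
        for j in range(k):
            members = x[assign == j]
            if members.size:
                centres[j] = members.mean()
        centres.sort()
    assign = np.argmin(np.abs(x[:, None] - centres[None, :]), axis=1)
    fractions = np.bincount(assign, minlength=k) / x.size
    return centres, fractions


def _match_fractions(fractions: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Permutation of clusters whose sizes best match target weights.

    Brute-force over permutations (k <= 4 in practice); minimises the
    summed absolute difference between cluster fractions and the prior
    abundance weights, so each component starts on the cluster its
    count prior most plausibly describes.
    """
    from itertools import permutations

    k = len(target)
    if k > 6:  # guard: factorial blow-up; fall back to sorted order
        return np.arange(k)
    best, best_cost = None, np.inf
    for perm in permutations(range(k)):
        cost = float(np.abs(fractions[list(perm)] - target).sum())
        if cost < best_cost - 1e-12:
            best, best_cost = perm, cost
    return np.array(best)


def run_gibbs(data: Sequence[float], config: MixtureConfig) -> GibbsDraws:
    """Run the Gibbs sampler and return the retained draws.

    All chains are advanced jointly (state arrays carry a leading chain
    axis) by a single PRNG seeded from ``config.seed``, so runs are
    bit-reproducible. Chains differ through their randomised initial
    means (data quantiles plus jitter).
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("data must be a nonempty 1-D sequence")
    if not np.isfinite(x).all():
        raise ValueError("data must be finite")
    config.validate()
    k, n_chains, n = config.k, config.chains, x.size
    if k > np.unique(x).size:
        raise ValueError(
            f"k={k} exceeds the number of distinct data values "
            f"({np.unique(x).size})"
        )
    rng = np.random.default_rng(config.seed)
    alpha = np.asarray(config.alpha, dtype=float)
    scale = x.std() if x.std() > 0 else max(abs(x.mean()), 1.0)
    var0 = x.var() if x.var() > 0 else scale ** 2

    floor = config.gamma_floor
    sort_means = config.resolved_sort_means

    # Mean-prior locations. Mean-sorted fits identify component j as the
    # j-th thinnest, so each rank receives an anchor derived from the
    # abundance-implied quantiles of the pooled data: the raw anchor of
    # rank j is the pooled quantile at the midpoint of its cumulative-
    # abundance segment (where the component mean sits in the fully-
    # separated limit), shrunk halfway toward the weighted anchor centre
    # (where every mean sits in the single-component limit). Unsorted
    # fits have exchangeable components — permuting the hyperpriors must
    # only relabel the fit — so all components share one location, the
    # sample mean.
    w = alpha / alpha.sum()
    cum = np.concatenate([[0.0], np.cumsum(w)])
    raw_anchors = np.quantile(x, (cum[:-1] + cum[1:]) / 2)
    anchor_centre = float(w @ raw_anchors)
    if config.prior_mean_location is not None:
        m0 = np.full(k, float(config.prior_mean_location))
    elif sort_means:
        m0 = anchor_centre + 0.5 * (raw_anchors - anchor_centre)
    else:
        m0 = np.full(k, float(x.mean()))
    p0 = config.prior_mean_precision
    if p0 is None:
        p0 = 1.0 / var0
    a0 = config.precision_shape
    b0 = config.precision_rate
    if b0 is None:
        # centre the precision prior on the abundance-implied
        # within-component variance: pooled variance minus the
        # between-anchor variance of the unshrunk (fully-separated)
        # anchors, floored at a quarter of the pooled variance so the
        # prior stays proper when anchors span the whole spread. The
        # decomposition uses sorted weights so the (scalar, shared)
        # rate is invariant under permutations of the hyperpriors.
        ws = np.sort(w)
        cums = np.concatenate([[0.0], np.cumsum(ws)])
        a_sym = np.quantile(x, (cums[:-1] + cums[1:]) / 2)
        var_between = float(ws @ (a_sym - ws @ a_sym) ** 2)
        var_within = max(var0 - var_between, 0.25 * var0)
        b0 = a0 * var_within

    # initial state: cluster centres from a short 1-D Lloyd (k-means)
    # pass, with clusters assigned to components so cluster sizes match
    # the prior abundances as closely as possible (this keeps the
    # initialisation covariant under permutations of alpha), plus
    # per-chain jitter for over-dispersed starts
    centres, fractions = _kmeans_1d(x, k)
    slot_centres = centres[_match_fractions(fractions, w)]
    mu = slot_centres[None, :] + \
        rng.normal(0.0, 0.5 * scale, size=(n_chains, k))
    tau = np.full((n_chains, k), 1.0 / var0)
    g = np.maximum(np.tile(alpha, (n_chains, 1)), floor)
    pi = g / g.sum(axis=1, keepdims=True)

    if sort_means:
        # identify labels from the start: component j is the j-th thinnest
        order0 = np.argsort(mu, axis=1)
        mu = np.take_along_axis(mu, order0, axis=1)

    n_keep = config.n_retained
    out_mu = np.empty((n_chains, n_keep, k))
    out_tau = np.empty((n_chains, n_keep, k))
    out_pi = np.empty((n_chains, n_keep, k))

    _gibbs_kernel(
        x, alpha, m0, float(p0), float(a0), float(b0), float(floor),
        sort_means, config.iterations, config.burn_in, config.thinning,
        mu, tau, g, int(config.seed) & 0xFFFFFFFF,
        out_mu, out_tau, out_pi,
    )

    bad = ~(np.isfinite(out_mu).all(axis=(0, 2))
            & np.isfinite(out_tau).all(axis=(0, 2))
            & np.isfinite(out_pi).all(axis=(0, 2)))
    if bad.any():
        first = int(np.argmax(bad))
        raise FloatingPointError(
            "non-finite sampler state at iteration "
            f"{config.burn_in + first * config.thinning}"
        )
    return GibbsDraws(
        mu=out_mu, precision=out_tau, weights=out_pi,
        sorted_means=sort_means,
        data_min=float(x.min()), data_max=float(x.max()),
    )


@numba.njit(cache=True)
def _gibbs_kernel(x, alpha, m0, p0, a0, b0, floor, sort_means,
                  iterations, burn_in, thinning, mu, tau, g, seed,
                  out_mu, out_tau, out_pi):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_chains, k = mu.shape
    n = x.size
    tiny = 2.2250738585072014e-308
    pi = np.empty((n_chains, k))
    for c in range(n_chains):
        tot = 0.0
        for j in range(k):
            tot += g[c, j]
        for j in range(k):
            pi[c, j] = g[c, j] / tot
    lw = np.empty(k)
    cum = np.empty(k)
    n_k = np.empty(k)
    s_x = np.empty(k)
    s_x2 = np.empty(k)
    kept = 0
    for it in range(iterations):
        for c in range(n_chains):
            for j in range(k):
                lw[j] = np.log(pi[c, j]) + 0.5 * np.log(tau[c, j])
                n_k[j] = 0.0
                s_x[j] = 0.0
                s_x2[j] = 0.0
            # assignments z | pi, mu, tau (categorical per datum),
            # accumulating per-component counts and sums on the fly
            for i in range(n):
                mx = -np.inf
                for j in range(k):
                    d = x[i] - mu[c, j]
                    cum[j] = lw[j] - 0.5 * tau[c, j] * d * d
                    if cum[j] > mx:
                        mx = cum[j]
                tot = 0.0
                for j in range(k):
                    tot += np.exp(cum[j] - mx)
                    cum[j] = tot
                u = np.random.random() * tot
                zi = k - 1
                for j in range(k):
                    if u <= cum[j]:
                        zi = j
                        break
                n_k[zi] += 1.0
                s_x[zi] += x[i]
                s_x2[zi] += x[i] * x[i]
            for j in range(k):
                # mu | z, tau (normal full conditional)
                post_prec = p0 + n_k[j] * tau[c, j]
                post_mean = (p0 * m0[j] + tau[c, j] * s_x[j]) / post_prec
                mu_j = np.random.normal(post_mean, 1.0 / np.sqrt(post_prec))
                mu[c, j] = mu_j
                # tau | z, mu (gamma full conditional)
                ss = s_x2[j] - 2.0 * mu_j * s_x[j] + n_k[j] * mu_j * mu_j
                if ss < 0.0:
                    ss = 0.0
                t = np.random.gamma(a0 + 0.5 * n_k[j],
                                    1.0 / (b0 + 0.5 * ss))
                tau[c, j] = t if t > tiny else tiny
            if sort_means:
                # relabel the state so means are ascending (ties broken
                # by ascending sigma, i.e. descending tau); each
                # Dirichlet hyperprior alpha_j thereby stays attached to
                # the j-th thinnest component, which is what controls
                # label switching
                for a in range(1, k):
                    b = a
                    while b > 0 and (
                        mu[c, b] < mu[c, b - 1]
                        or (mu[c, b] == mu[c, b - 1]
                            and tau[c, b] > tau[c, b - 1])
                    ):
                        mu[c, b], mu[c, b - 1] = mu[c, b - 1], mu[c, b]
                        tau[c, b], tau[c, b - 1] = tau[c, b - 1], tau[c, b]
                        n_k[b], n_k[b - 1] = n_k[b - 1], n_k[b]
                        b -= 1
            # weights by the floored normalised-gamma construction
            tot = 0.0
            for j in range(k):
                gj = np.random.gamma(alpha[j] + n_k[j], 1.0)
                if gj < floor:
                    gj = floor
                g[c, j] = gj
                tot += gj
            for j in range(k):
                pi[c, j] = g[c, j] / tot
        if it >= burn_in and (it - burn_in) % thinning == 0:
            for c in range(n_chains):
                for j in range(k):
                    out_mu[c, kept, j] = mu[c, j]
                    out_tau[c, kept, j] = tau[c, j]
                    out_pi[c, kept, j] = pi[c, j]
            kept += 1


def gelman_rubin(chains) -> float:
    """Split Gelman-Rubin R-hat for one scalar parameter.

    ``chains`` is an array-like of shape ``(n_chains, n_draws)``. Each
    chain is split in half before computing the between/within variance
    ratio, so a single chain can also be diagnosed. Returns exactly 1.0
    when the between-chain variance is zero with positive within-chain
    variance; returns NaN (flagged, not silently 1) when every chain has
    zero variance but the chain means differ.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("chains must be a 2-D array (n_chains, n_draws)")
    n_chain, n_draw = arr.shape
    if n_draw < 4 and n_chain < 2:
        raise ValueError("need at least 2 chains or 4 draws")
    half = n_draw // 2
    if half >= 2:
        arr = np.concatenate([arr[:, :half], arr[:, half:2 * half]], axis=0)
    m, n = arr.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 sequences of length >= 2")
    chain_means = arr.mean(axis=1)
    chain_vars = arr.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w == 0.0:
        if b == 0.0:
            return 1.0
        logger.warning("Gelman-Rubin: zero within-chain variance with "
                       "distinct chain means; diagnostic undefined")
        return float("nan")
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-component posterior medians, 68% bounds and R-hat diagnostics.

    Arrays have length ``k``; ``mu_lo``/``mu_hi`` are the 16th/84th
    percentiles of the pooled mean draws (for ``credible_mass=0.68``),
    and the sigma summaries are computed from per-draw ``1/sqrt(tau)``,
    never from summarised precisions.
    """

    mu_median: np.ndarray
    mu_lo: np.ndarray
    mu_hi: np.ndarray
    sigma_median: np.ndarray
    sigma_lo: np.ndarray
    sigma_hi: np.ndarray
    rhat_mu: np.ndarray
    rhat_sigma: np.ndarray
    credible_mass: float = 0.68

    def __post_init__(self):
        if np.any(self.mu_lo > self.mu_median) or np.any(self.mu_median > self.mu_hi):
            raise ValueError("credible bounds must bracket the median")

    @property
    def k(self) -> int:
        return len(self.mu_median)

    def to_frame(self) -> pd.DataFrame:
        """Summary table shaped like the per-sample results tables."""
        return pd.DataFrame({
            "component": np.arange(1, self.k + 1),
            "mu_lo": self.mu_lo, "mu_median": self.mu_median,
            "mu_hi": self.mu_hi,
            "sigma_lo": self.sigma_lo, "sigma_median": self.sigma_median,
            "sigma_hi": self.sigma_hi,
            "rhat_mu": self.rhat_mu, "rhat_sigma": self.rhat_sigma,
        }).set_index("component")


def summarize_posterior(
    draws: GibbsDraws, credible_mass: float = 0.68
) -> PosteriorSummary:
    """Median and central credible interval of the pooled retained draws."""
    if not 0 < credible_mass < 1:
        raise ValueError("credible_mass must be in (0, 1)")
    lo_q = (1 - credible_mass) / 2
    quantiles = [lo_q, 0.5, 1 - lo_q]
    k = draws.k
    mu_pool = draws.mu.reshape(-1, k)
    sigma = draws.sigma
    sigma_pool = sigma.reshape(-1, k)
    mu_lo, mu_med, mu_hi = np.quantile(mu_pool, quantiles, axis=0)
    s_lo, s_med, s_hi = np.quantile(sigma_pool, quantiles, axis=0)
    rhat_mu = np.array([gelman_rubin(draws.mu[:, :, j]) for j in range(k)])
    rhat_sigma = np.array([gelman_rubin(sigma[:, :, j]) for j in range(k)])
    return PosteriorSummary(
        mu_median=mu_med, mu_lo=mu_lo, mu_hi=mu_hi,
        sigma_median=s_med, sigma_lo=s_lo, sigma_hi=s_hi,
        rhat_mu=rhat_mu, rhat_sigma=rhat_sigma,
        credible_mass=credible_mass,
    )


class NormalMixtureModel:
    """Finite normal mixture with a count-informed Dirichlet weight prior.

    Parameters
    ----------
    data : sequence of float
        Pooled per-coccolith mean thickness values (um), already
        outlier-filtered (use :meth:`from_sample` to apply the standard
        preprocessing).
    config : MixtureConfig
        Sampler configuration; ``config.alpha`` carries the prior
        relative-abundance information (SEM counts for field samples).
    morphotypes : sequence of str, optional
        Morphotype labels in the same order as ``config.alpha``; purely
        provenance, used to label outputs.

    Examples
    --------
    >>> from coccomix import MixtureConfig, NormalMixtureModel
    >>> cfg = MixtureConfig.desk(k=2, alpha=(20, 80), seed=7)
    >>> model = NormalMixtureModel(thickness_values, cfg)   # doctest: +SKIP
    >>> res = model.fit()                                   # doctest: +SKIP
    >>> print(res.summary())                                # doctest: +SKIP
    """

    def __init__(self, data, config: MixtureConfig, *, morphotypes=None):
        self.data = np.asarray(data, dtype=float)
        self.config = config
        if morphotypes is not None and len(morphotypes) != config.k:
            raise ValueError("morphotypes must have length k")
        self.morphotypes = tuple(morphotypes) if morphotypes else None

    @classmethod
    def from_sample(
        cls,
        thickness: Sequence[float],
        counts: Mapping[str, int],
        pipeline: PipelineConfig | None = None,
        config: MixtureConfig | None = None,
    ) -> "NormalMixtureModel":
        """Build a model from raw thickness values and SEM counts.

        Applies the standard preprocessing: single-pass Tukey outlier
        removal on the thickness values and exclusion of morphotypes with
        relative abundance below the rare threshold. The Dirichlet
        hyperpriors are the retained morphotype counts, in the input
        order of ``counts``.
        """
        pipeline = pipeline or PipelineConfig()
        kept, _ = remove_outliers(thickness, pipeline.outlier_multiplier)
        retained = filter_rare(counts, pipeline.rare_threshold)
        morphs = [m for m in counts if m in retained]
        alpha = tuple(float(counts[m]) for m in morphs)
        base = config or MixtureConfig()
        cfg = base.replace(k=len(alpha), alpha=alpha)
        return cls(kept, cfg, morphotypes=morphs)

    def fit(self, seed: int | None = None) -> "MixtureResults":
        """Run the Gibbs sampler and return a results object."""
        cfg = self.config if seed is None else self.config.replace(seed=seed)
        draws = run_gibbs(self.data, cfg)
        return MixtureResults(self, cfg, draws)


class MixtureResults:
    """Posterior draws and summaries of a fitted mixture model."""

    def __init__(self, model: NormalMixtureModel, config: MixtureConfig,
                 draws: GibbsDraws):
        self.model = model
        self.config = config
        self.draws = draws
        self._summary_cache: dict[float, PosteriorSummary] = {}
        frac = self.frac_mu_below_data_min
        if np.any(frac > 0.001):
            logger.warning(
                "component mean draws fall below the smallest measured "
                "value (fractions per component: %s); the assumed number "
                "of components may be wrong for this sample",
                np.array2string(frac, precision=4),
            )

    @property
    def frac_mu_below_data_min(self) -> np.ndarray:
        """Fraction of retained mean draws below the data minimum.

        A persistently positive fraction reproduces the known failure
        mode where a component's sampled mean drifts below every
        measured value (sometimes negative): the component is not
        supported by the data and the fit should not be trusted.
        """
        return (self.draws.mu < self.draws.data_min).mean(axis=(0, 1))

    def posterior_summary(self, credible_mass: float = 0.68) -> PosteriorSummary:
        if credible_mass not in self._summary_cache:
            self._summary_cache[credible_mass] = summarize_posterior(
                self.draws, credible_mass
            )
        return self._summary_cache[credible_mass]

    @property
    def rhat_mu(self) -> np.ndarray:
        return self.posterior_summary().rhat_mu

    @property
    def rhat_sigma(self) -> np.ndarray:
        return self.posterior_summary().rhat_sigma

    def converged(self, threshold: float = 1.1) -> bool:
        """True when every reported parameter has R-hat below threshold."""
        s = self.posterior_summary()
        rhats = np.concatenate([s.rhat_mu, s.rhat_sigma])
        return bool(np.isfinite(rhats).all() and (rhats < threshold).all())

    def component_labels(self) -> list[str]:
        """Component labels by alpha provenance.

        For unsorted (two-component) fits components correspond to the
        ``alpha`` input order, hence to ``model.morphotypes``. For
        mean-sorted fits the mapping from sorted components back to
        morphotypes rests on the prior-abundance input order and is
        ambiguous when abundances are similar; biological labelling is
        left to the caller.
        """
        if self.model.morphotypes is not None:
            return list(self.model.morphotypes)
        return [f"component_{j + 1}" for j in range(self.config.k)]

    def thickness_by_morphotype(self, credible_mass: float = 0.68
                                ) -> dict[str, float]:
        """Posterior-median mean thickness keyed by component label."""
        s = self.posterior_summary(credible_mass)
        return dict(zip(self.component_labels(), s.mu_median))

    def to_frame(self) -> pd.DataFrame:
        """Tidy draw archive: chain, draw, component, mu, sigma, weight."""
        c, t, k = self.draws.mu.shape
        idx = np.indices((c, t, k)).reshape(3, -1)
        return pd.DataFrame({
            "chain": idx[0] + 1,
            "draw": idx[1],
            "component": idx[2] + 1,
            "mu": self.draws.mu.ravel(),
            "sigma": self.draws.sigma.ravel(),
            "weight": self.draws.weights.ravel(),
        })

    def summary(self, credible_mass: float = 0.68) -> str:
        """Human-readable fit summary (one block per component)."""
        s = self.posterior_summary(credible_mass)
        labels = self.component_labels()
        lines = [
            "Count-informed normal mixture (Gibbs)",
            f"  n = {self.model.data.size}, k = {self.config.k}, "
            f"chains = {self.config.chains}, retained draws/chain = "
            f"{self.config.n_retained}",
            f"  alpha = {tuple(self.config.alpha)}, sorted means = "
            f"{self.draws.sorted_means}",
            f"  {100 * credible_mass:.0f}% credible intervals "
            "(central percentiles of pooled draws)",
            "",
            f"  {'component':<12}{'mu_lo':>9}{'mu_med':>9}{'mu_hi':>9}"
            f"{'sig_lo':>9}{'sig_med':>9}{'sig_hi':>9}{'rhat_mu':>9}",
        ]
        for j, lab in enumerate(labels):
            lines.append(
                f"  {lab:<12}{s.mu_lo[j]:>9.4f}{s.mu_median[j]:>9.4f}"
                f"{s.mu_hi[j]:>9.4f}{s.sigma_lo[j]:>9.4f}"
                f"{s.sigma_median[j]:>9.4f}{s.sigma_hi[j]:>9.4f}"
                f"{s.rhat_mu[j]:>9.3f}"
            )
        frac = self.frac_mu_below_data_min
        if np.any(frac > 0.001):
            lines.append("")
            lines.append(
                "  WARNING: mean draws below the smallest measured value "
                f"(per-component fractions {np.round(frac, 4).tolist()})"
            )
        return "\n".join(lines)

    def plot_trace(self, path=None):
        """Per-parameter trace plot, one line per chain."""
        from .plotting import plot_trace

        return plot_trace(self, path=path)
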