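"""Gene-level enrichment inference in the style of the casTLE framework.

Each gene's guide enrichments are compared to an empirical null learned from
the control guides (safe-targeting and non-targeting).  The null density f0
is a Gaussian kernel density estimate.  A gene-level effect theta is the
maximum effect a guide can experience; individual guides realize a uniform
fraction of it (variable guide efficacy), so the per-guide density under
effect theta is

    f(x | theta) = (1/|theta|) * integral_0^{|theta|} f0(x - sgn(theta) t) dt

The reported effect is the grid argmax of the summed per-guide log
densities, the score is the likelihood ratio 2*[L(effect) - L(0)] clipped at
zero, the effect interval is the 2-unit profile-likelihood region, and the
p-value comes from resampling pseudo-genes from the pool of all
gene-targeting guide enrichments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.stats import gaussian_kde

from .countio import DEFAULT_PSEUDOCOUNT, guide_log_enrichment
from .simulate import CountTable

__all__ = [
    "CastleConfig",
    "NullModel",
    "fit_null",
    "gene_log_likelihood",
    "estimate_gene_effect",
    "permutation_pvalue",
    "analyze_round",
    "EnrichmentModel",
    "EnrichmentResults",
]

# below this |theta| the uniform mixture is numerically the null density
_THETA_EPS = 1e-4
_PERM_CHUNK = 1000


@dataclass(frozen=True)
class CastleConfig:
    """Statistical configuration for one round of analysis."""

    pseudocount: float = DEFAULT_PSEUDOCOUNT
    grid_min: float = -15.0
    grid_max: float = 15.0
    grid_step: float = 0.1
    n_perm: int = 10_000
    seed: int = 0
    min_controls: int = 20
    kde_floor: float = -30.0

    def effect_grid(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step)) + 1
        grid = np.linspace(self.grid_min, self.grid_max, n)
        if not (grid[0] < 0.0 < grid[-1]):
            raise ValueError("effect grid must span negative and positive values")
        # snap the closest point to exactly zero so theta=0 is on the grid
        grid[np.argmin(np.abs(grid))] = 0.0
        return grid

    @property
    def p_floor(self) -> float:
        return 1.0 / (self.n_perm + 1)


@dataclass
class NullModel:
    """Empirical null of control-guide enrichments (Gaussian KDE).

    The density and its cumulative integral are tabulated on a fine grid;
    log f0 is floored at ``floor`` so it is finite on the whole real line.
    """

    control_stats: np.ndarray
    bandwidth: float
    grid: np.ndarray
    log_density: np.ndarray
    cdf: np.ndarray
    floor: float = -30.0

    def logpdf(self, x) -> np.ndarray:
        out = np.interp(x, self.grid, self.log_density, left=self.floor, right=self.floor)
        return np.maximum(out, self.floor)

    def cdf_at(self, x) -> np.ndarray:
        return np.interp(x, self.grid, self.cdf, left=0.0, right=self.cdf[-1])


def fit_null(
    control_stats: Sequence[float],
    min_controls: int = 20,
    n_grid: int = 4001,
    floor: float = -30.0,
) -> NullModel:
    """Fit the control-guide null density (Gaussian KDE, Scott's rule)."""
    stats = np.asarray(control_stats, dtype=float)
    stats = stats[np.isfinite(stats)]
    if len(stats) < min_controls:
        raise ValueError(
            f"need >= {min_controls} control statistics, got {len(stats)}"
        )
    spread = stats.std(ddof=1)
    if spread == 0:  # degenerate controls: nudge so the KDE is proper
        stats = stats + np.linspace(-1e-9, 1e-9, len(stats))
    kde = gaussian_kde(stats)
    bw = float(kde.factor * stats.std(ddof=1))
    lo = stats.min() - 5.0 * bw
    hi = stats.max() + 5.0 * bw
    grid = np.linspace(lo, hi, n_grid)
    dens = kde(grid)
    logf = np.maximum(np.log(np.maximum(dens, np.exp(floor))), floor)
    cdf = np.concatenate([[0.0], cumulative_trapezoid(dens, grid)])
    return NullModel(
        control_stats=stats,
        bandwidth=bw,
        grid=grid,
        log_density=logf,
        cdf=cdf,
        floor=floor,
    )


def _log_mixture_density(
    x: np.ndarray, null: NullModel, thetas: np.ndarray
) -> np.ndarray:
    """Matrix of log f(x_i | theta_j), shape (len(x), len(thetas)).

    The uniform-efficacy integral is a difference of the tabulated
    cumulative-trapezoid CDF: for theta != 0,
    f(x|theta) = (F0(x) - F0(x - theta)) / theta (positive for both signs).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    thetas = np.asarray(thetas, dtype=float)
    out = np.empty((len(x), len(thetas)))
    small = np.abs(thetas) < _THETA_EPS
    if small.any():
        out[:, small] = null.logpdf(x)[:, None]
    big = ~small
    if big.any():
        th = thetas[big]
        fx = null.cdf_at(x)[:, None]
        fshift = null.cdf_at(x[:, None] - th[None, :])
        dens = (fx - fshift) / th[None, :]
        tiny = np.exp(null.floor)
        out[:, big] = np.maximum(np.log(np.maximum(dens, tiny)), null.floor)
    return out


def gene_log_likelihood(
    stats: Sequence[float], null: NullModel, theta: float
) -> float:
    """Sum of per-guide log densities under gene effect ``theta``."""
    stats = np.asarray(stats, dtype=float)
    if stats.size == 0:
        raise ValueError("no guide statistics for gene")
    return float(_log_mixture_density(stats, null, np.array([theta])).sum())


def _score_from_profile(profile: np.ndarray, thetas: np.ndarray, i_zero: int):
    best_val = profile.max()
    ties = np.flatnonzero(profile == best_val)
    # deterministic tie-break: smallest |theta|, then the negative one
    best = min(ties, key=lambda i: (abs(thetas[i]), thetas[i]))
    effect = float(thetas[best])
    score = max(0.0, 2.0 * (best_val - profile[i_zero]))
    inside = thetas[profile >= best_val - 2.0]
    return effect, score, float(inside.min()), float(inside.max())


def estimate_gene_effect(
    stats: Sequence[float],
    null: NullModel,
    grid: np.ndarray | None = None,
) -> tuple[float, float, float, float]:
    """Grid maximum-likelihood effect, likelihood-ratio score and 2-unit
    profile interval for one gene."""
    if grid is None:
        grid = CastleConfig().effect_grid()
    grid = np.asarray(grid, dtype=float)
    if not (grid.min() < 0.0 < grid.max()) or not np.any(grid == 0.0):
        raise ValueError("effect grid must contain 0 and span both signs")
    stats = np.asarray(stats, dtype=float)
    if stats.size == 0:
        raise ValueError("no guide statistics for gene")
    i_zero = int(np.flatnonzero(grid == 0.0)[0])
    profile = _log_mixture_density(stats, null, grid).sum(axis=0)
    return _score_from_profile(profile, grid, i_zero)


def _permuted_scores(
    pool_profile: np.ndarray,
    n_guides: int,
    n_perm: int,
    i_zero: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Scores of ``n_perm`` pseudo-genes of ``n_guides`` statistics sampled
    with replacement from the pool (rows of ``pool_profile``)."""
    n_pool = pool_profile.shape[0]
    scores = np.empty(n_perm)
    for start in range(0, n_perm, _PERM_CHUNK):
        stop = min(start + _PERM_CHUNK, n_perm)
        idx = rng.integers(0, n_pool, size=(stop - start, n_guides))
        profiles = pool_profile[idx].sum(axis=1)  # (chunk, n_theta)
        scores[start:stop] = np.maximum(
            0.0, 2.0 * (profiles.max(axis=1) - profiles[:, i_zero])
        )
    return scores


def permutation_pvalue(
    observed_score: float,
    n_guides: int,
    pool: Sequence[float],
    null: NullModel,
    n_perm: int,
    rng: np.random.Generator,
    grid: np.ndarray | None = None,
) -> float:
    """Permutation p-value: p = (1 + #{perm score >= observed}) / (N + 1)."""
    pool = np.asarray(pool, dtype=float)
    if len(pool) < n_guides:
        raise ValueError("permutation pool smaller than the gene's guide count")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if grid is None:
        grid = CastleConfig().effect_grid()
    i_zero = int(np.flatnonzero(grid == 0.0)[0])
    pool_profile = _log_mixture_density(pool, null, grid)
    perm = _permuted_scores(pool_profile, n_guides, n_perm, i_zero, rng)
    return float((1 + np.sum(perm >= observed_score)) / (n_perm + 1))


class EnrichmentModel:
    """Gene-level enrichment model for one selection round of a screen.

    Parameters
    ----------
    table : CountTable
        Guide counts including the reference (naive) sample.
    round_sample, reference_sample : str
        Sample names; each selection round is compared to the naive library.
    config : CastleConfig
    """

    def __init__(
        self,
        table: CountTable,
        round_sample: str,
        reference_sample: str = "naive",
        config: CastleConfig | None = None,
    ) -> None:
        self.table = table
        self.round_sample = round_sample
        self.reference_sample = reference_sample
        self.config = config or CastleConfig()

    def fit(self) -> "EnrichmentResults":
        cfg = self.config
        x = guide_log_enrichment(
            self.table, self.round_sample, self.reference_sample, cfg.pseudocount
        )
        guides = self.table.guides.set_index("guide_id").loc[x.index]
        is_control = guides["category"].isin(("safe", "nontargeting")).to_numpy()
        is_gene = (guides["category"] == "gene").to_numpy()
        null = fit_null(
            x.to_numpy()[is_control], min_controls=cfg.min_controls, floor=cfg.kde_floor
        )
        grid = cfg.effect_grid()
        i_zero = int(np.flatnonzero(grid == 0.0)[0])

        pool_values = x.to_numpy()[is_gene]
        pool_genes = guides["gene_id"].to_numpy()[is_gene]
        pool_profile = _log_mixture_density(pool_values, null, grid)

        gene_rows: dict[str, np.ndarray] = {}
        for i, g in enumerate(pool_genes):
            gene_rows.setdefault(g, []).append(i)

        rng = np.random.default_rng(cfg.seed)
        records = []
        perm_cache: dict[int, np.ndarray] = {}
        for gene, rows in gene_rows.items():
            profile = pool_profile[rows].sum(axis=0)
            effect, score, lo, hi = _score_from_profile(profile, grid, i_zero)
            records.append((gene, len(rows), effect, score, lo, hi))
        # pseudo-gene null scores, one set per distinct guide count
        for k in sorted({r[1] for r in records}):
            perm_cache[k] = np.sort(
                _permuted_scores(pool_profile, k, cfg.n_perm, i_zero, rng)
            )
        result = pd.DataFrame(
            records,
            columns=["gene", "n_guides", "effect", "score", "effect_min", "effect_max"],
        )
        p = np.empty(len(result))
        for i, (k, s) in enumerate(zip(result["n_guides"], result["score"])):
            perm = perm_cache[k]
            n_ge = len(perm) - np.searchsorted(perm, s, side="left")
            p[i] = (1 + n_ge) / (cfg.n_perm + 1)
        result["p_value"] = p
        result = result[
            ["gene", "n_guides", "effect", "score", "p_value", "effect_min", "effect_max"]
        ].sort_values("gene", ignore_index=True)
        return EnrichmentResults(
            table=result,
            null=null,
            config=cfg,
            round_sample=self.round_sample,
            reference_sample=self.reference_sample,
            guide_enrichments=x,
        )


@dataclass
class EnrichmentResults:
    """Fitted gene-level results for one selection round."""

    table: pd.DataFrame
    null: NullModel
    config: CastleConfig
    round_sample: str
    reference_sample: str
    guide_enrichments: pd.Series = field(repr=False, default=None)

    def summary(self) -> str:
        t = self.table
        top = t.sort_values(["score", "gene"], ascending=[False, True]).head(10)
        lines = [
            f"Gene-level enrichment: {self.round_sample} vs {self.reference_sample}",
            f"genes: {len(t)}   controls: {len(self.null.control_stats)}   "
            f"null bandwidth: {self.null.bandwidth:.4f}   "
            f"permutations: {self.config.n_perm}",
            "",
            top.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out["round"] = self.round_sample
        out.to_csv(path, sep="\t", index=False)


def analyze_round(
    table: CountTable,
    round_sample: str,
    reference_sample: str = "naive",
    config: CastleConfig | None = None,
) -> pd.DataFrame:
    """One-call wrapper: fit the model and return the per-gene result table
    (gene, n_guides, effect, score, p_value, effect_min, effect_max)."""
    return EnrichmentModel(table, round_sample, reference_sample, config).fit().table
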