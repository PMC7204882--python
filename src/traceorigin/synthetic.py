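"""Synthetic multi-site trace-element datasets for testing and simulation.

Emulates the statistical structure the assignment workflow assumes: each
capture site has a site-specific mean vector of 20 log element/Ca ratios
(shared within-site covariance), juvenile sample sizes matching a realistic
trapping effort across 10 valley sites, and fall "problem birds" drawn as a
mixture of library sites plus displaced immigrant distributions.

Geographic realism is encoded by placing site means along a one-dimensional
"valley axis" with spacings proportional to the real inter-site distances,
so nearby sites have nearby fingerprints and misclassification concentrates
among neighbours, as observed in field data.  Ratios are generated
lognormally (concentrations are positive and right-skewed); per-bird Ca is
drawn lognormally and multiplied back so the raw table carries plausible
concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import DEFAULT_ELEMENTS, ElementPanel, SampleTable

__all__ = ["SynthConfig", "ProblemBirds", "generate_library",
           "generate_problem_birds", "site_log_means"]

#: default 10 sites with juvenile sample sizes reflecting trapping effort
DEFAULT_SITES = ("Kelowna", "Hullcar", "Salmon Arm", "Armstrong", "Mara",
                 "Vernon", "Oliver", "Osoyoos", "Penticton", "Keremeos")
DEFAULT_SITE_N = (20, 10, 10, 9, 9, 18, 10, 8, 6, 5)

#: positions along the north-south valley axis (0 = northernmost), scaled
#: to [0, 1] proportionally to road distances between the real sites
DEFAULT_POSITIONS = (0.53, 0.18, 0.08, 0.13, 0.00,
                     0.26, 0.92, 1.00, 0.79, 0.90)


@dataclass
class SynthConfig:
    """Generator settings.

    ``delta`` multiplies all between-site mean differences (log-ratio
    units); ``sigma_within`` is the within-site SD of each log ratio, so
    ``delta / sigma_within`` sets the Mahalanobis separation of the axis
    endpoints.  ``jitter`` adds a small site-specific off-axis offset so
    sites are not perfectly collinear.  ``immigrant_displacement`` is in
    pooled within-site SD units.
    """

    sites: tuple[str, ...] = DEFAULT_SITES
    site_n: tuple[int, ...] = DEFAULT_SITE_N
    site_positions: tuple[float, ...] = DEFAULT_POSITIONS
    elements: tuple[str, ...] = tuple(e for e in DEFAULT_ELEMENTS if e != "Ca")
    calcium_symbol: str = "Ca"
    delta: float = 10.0
    sigma_within: float = 0.3
    jitter: float = 0.10
    ca_mean: float = 2.65e5
    ca_cv: float = 0.10
    mixture_weights: tuple[float, ...] | None = None
    immigrant_fraction: float = 0.4
    immigrant_displacement: float = 10.0
    p_vineyard: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sites) != len(self.site_n):
            raise ValueError("sites and site_n must have equal length")
        if len(self.sites) != len(self.site_positions):
            raise ValueError("sites and site_positions must have equal length")
        if self.sigma_within <= 0:
            raise ValueError("sigma_within must be positive")
        if self.immigrant_displacement < 0:
            raise ValueError("immigrant displacement must be non-negative")
        if not 0.0 <= self.immigrant_fraction <= 1.0:
            raise ValueError("immigrant_fraction must lie in [0, 1]")
        if self.mixture_weights is not None:
            w = np.asarray(self.mixture_weights, dtype=float)
            if len(w) != len(self.sites) or (w < 0).any() or w.sum() <= 0:
                raise ValueError("invalid mixture weights")

    @property
    def panel(self) -> ElementPanel:
        return ElementPanel(elements=(self.calcium_symbol, *self.elements),
                            calcium_symbol=self.calcium_symbol)

    @property
    def n_juveniles(self) -> int:
        return int(sum(self.site_n))

    def site_weights(self) -> np.ndarray:
        if self.mixture_weights is None:
            return np.full(len(self.sites), 1.0 / len(self.sites))
        w = np.asarray(self.mixture_weights, dtype=float)
        return w / w.sum()


def _structure(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic geographic structure: (base, u, site_jitter, t_centred).

    ``base`` is the element-wise typical log ratio, ``u`` the unit
    "valley axis" direction in element space, ``site_jitter`` small
    site-specific off-axis offsets, ``t_centred`` the centred axis
    positions.
    """
    p = len(cfg.elements)
    k = len(cfg.sites)
    base = np.linspace(-9.0, -3.0, p)       # typical log element/Ca levels
    rng = np.random.default_rng([int(cfg.seed) % (2**31), 101])
    u = rng.normal(size=p)
    u /= np.linalg.norm(u)
    jitter = rng.normal(0.0, cfg.jitter / np.sqrt(p), size=(k, p))
    t = np.asarray(cfg.site_positions, dtype=float)
    return base, u, jitter, t - t.mean()


def site_log_means(cfg: SynthConfig) -> np.ndarray:
    """(k, p) site mean vectors in log-ratio space, deterministic in seed.

    mu_s = base + delta * (t_s * u + j_s) with t_s the centred axis
    position, u a fixed random unit direction and j_s a small site jitter.
    delta = 0 collapses all site means onto the base profile.
    """
    base, u, jitter, t = _structure(cfg)
    return base[None, :] + cfg.delta * (t[:, None] * u[None, :] + jitter)


def _draw_birds(cfg: SynthConfig, rng: np.random.Generator,
                log_means: np.ndarray) -> np.ndarray:
    """Concentration rows for one bird per row of ``log_means``."""
    n, p = log_means.shape
    log_ratio = log_means + rng.normal(0.0, cfg.sigma_within, size=(n, p))
    ratios = np.exp(log_ratio)
    s2 = np.log1p(cfg.ca_cv**2)
    ca = np.exp(rng.normal(np.log(cfg.ca_mean) - s2 / 2.0, np.sqrt(s2), size=n))
    conc = np.empty((n, p + 1))
    conc[:, 0] = ca
    conc[:, 1:] = ratios * ca[:, None]
    return conc


def _to_table(cfg: SynthConfig, conc: np.ndarray, meta: dict) -> SampleTable:
    cols = [cfg.calcium_symbol, *cfg.elements]
    df = pd.DataFrame(conc, columns=cols)
    for key, val in meta.items():
        df[key] = val
    return SampleTable(df, cfg.panel)


def generate_library(cfg: SynthConfig) -> SampleTable:
    """Juvenile fingerprint-library table: known-origin summer birds."""
    means = site_log_means(cfg)
    rng = np.random.default_rng([int(cfg.seed) % (2**31), 1])
    rows = np.repeat(np.arange(len(cfg.sites)), cfg.site_n)
    conc = _draw_birds(cfg, rng, means[rows])
    sites = np.repeat(cfg.sites, cfg.site_n)
    ids = [f"{s}-J{i:03d}" for i, s in enumerate(sites)]
    return _to_table(cfg, conc, {
        "bird_id": ids, "site": sites, "age_class": "juvenile",
        "season": "summer", "context": "library",
    })


@dataclass
class ProblemBirds:
    """Fall problem-bird table plus the generator's hidden ground truth."""

    table: SampleTable
    true_origin: pd.Series  # site name or "immigrant", indexed like table


def generate_problem_birds(cfg: SynthConfig, n_total: int = 118) -> ProblemBirds:
    """Fall-caught birds of unknown origin: library-site mixture + immigrants.

    Each bird is drawn from a library site (per the mixture weights) or,
    with probability ``immigrant_fraction``, from a virtual unsampled site
    on the same geographic gradient, ``immigrant_displacement`` pooled SD
    units beyond a sampled axis endpoint.  The true origin of every bird is
    returned as hidden ground truth for recovery tests.
    """
    means = site_log_means(cfg)
    base, u, _, t = _structure(cfg)
    p = len(cfg.elements)
    rng = np.random.default_rng([int(cfg.seed) % (2**31), 2])
    is_imm = rng.random(n_total) < cfg.immigrant_fraction
    site_idx = rng.choice(len(cfg.sites), size=n_total, p=cfg.site_weights())
    bird_means = means[site_idx].copy()
    # Immigrants are birds from virtual unsampled sites along the same
    # geographic gradient, beyond the sampled endpoints of the valley axis
    # by the configured number of pooled SDs (each with its own off-axis
    # jitter).  Displacing in a uniformly random direction of the full
    # 20-element space instead would be chemically implausible: unsampled
    # sources vary along the same element gradients the sampled ones do.
    for i in np.flatnonzero(is_imm):
        if cfg.delta > 0:
            g = cfg.immigrant_displacement * cfg.sigma_within / cfg.delta
            t_imm = (t.min() - g) if rng.random() < 0.5 else (t.max() + g)
            j_imm = rng.normal(0.0, cfg.jitter / np.sqrt(p), size=p)
            bird_means[i] = base + cfg.delta * (t_imm * u + j_imm)
        else:  # no geographic structure: displace in a random direction
            direction = rng.normal(size=p)
            direction /= np.linalg.norm(direction)
            bird_means[i] = base + cfg.immigrant_displacement * cfg.sigma_within * direction
    conc = _draw_birds(cfg, rng, bird_means)
    truth = np.where(is_imm, "immigrant", np.asarray(cfg.sites)[site_idx])
    age = np.where(rng.random(n_total) < 20.0 / 118.0, "adult_lt1y", "adult_1plus")
    context = np.where(rng.random(n_total) < cfg.p_vineyard,
                       "vineyard_orchard", "dairy_feedlot")
    ids = [f"PB-{i:03d}" for i in range(n_total)]
    table = _to_table(cfg, conc, {
        "bird_id": ids, "site": "unknown_fall", "age_class": age,
        "season": "fall", "context": context,
    })
    return ProblemBirds(table=table,
                        true_origin=pd.Series(truth, name="true_origin"))
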