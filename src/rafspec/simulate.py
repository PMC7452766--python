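"""Synthetic community datasets with known ground truth.

The generator emulates a hierarchical elevational sampling design: locations
regularly spaced along an elevational gradient, a fixed set of host plant
species with a fixed number of sampled individuals per species per location,
location-level environmental covariates trending with elevation, and
per-sample sequencing depths drawn from a truncated lognormal.

Community counts follow the same hurdle generative structure that the
inference module fits: a probit occurrence process and a lognormal abundance
process, each with its own fixed effects and rank-2 location latent factors.
Three scenarios control the planted host specialization:

* ``none`` — no host effects at all,
* ``uniform`` — a fraction of OTUs are specialists with a constant host
  effect along the gradient,
* ``changing`` — specialists additionally carry a host x elevation
  interaction, so specialization strength varies with elevation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import GUILDS, CommunityDataset, GuildMap, OtuTable
from .jsdm import ModelSpec, build_design

#: The five focal host plants of the emulated design.
DEFAULT_HOSTS = (
    "Bistorta_vivipara",
    "Dryas_octopetala",
    "Salix_arctica",
    "Saxifraga_oppositifolia",
    "Silene_acaulis",
)

#: Guild mixture mirroring a 231-OTU community split 78/63/90.
DEFAULT_GUILD_PROPORTIONS = {
    "mycorrhizal": 78 / 231,
    "endophytic": 63 / 231,
    "unclassified": 90 / 231,
}

SCENARIOS = ("none", "uniform", "changing")


@dataclass
class DesignConfig:
    """Sampling-design settings.

    Defaults reproduce the emulated study layout: 18 locations spanning
    33-479 m elevation, 5 hosts x 5 individuals per location (450 samples),
    and sequencing depths with median ~1.2e3 reads in [1e2, 2e4].
    """

    n_locations: int = 18
    elevation_range: tuple[float, float] = (33.0, 479.0)
    hosts: tuple[str, ...] = DEFAULT_HOSTS
    individuals_per_host: int = 5
    dropout_rate: float = 0.0
    seed: int = 0
    depth_meanlog: float = float(np.log(1240.0))
    depth_sdlog: float = 0.75
    depth_range: tuple[int, int] = (100, 20000)

    def __post_init__(self) -> None:
        if self.n_locations < 2:
            raise ValueError("n_locations must be >= 2")
        if self.individuals_per_host < 1:
            raise ValueError("individuals_per_host must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


# Location-level covariate trends: value = a + b * elevation + noise.
# Qualitative shapes only: soil water, active-layer depth and vegetation
# cover decline with elevation; pH varies mildly.
_COVARIATE_TRENDS = {
    # name: (intercept, slope per m, noise sd, clip lo, clip hi)
    "soil_ph": (6.2, -0.0004, 0.20, 4.0, 8.5),
    "soil_water": (45.0, -0.045, 5.0, 2.0, 90.0),
    "active_layer_depth": (75.0, -0.08, 6.0, 10.0, 150.0),
    "vegetation_cover": (92.0, -0.12, 8.0, 1.0, 100.0),
}


def generate_design(cfg: DesignConfig) -> pd.DataFrame:
    """Generate the per-sample metadata frame for a sampling design."""
    rng = np.random.default_rng(cfg.seed)
    elevations = np.linspace(*cfg.elevation_range, cfg.n_locations)
    loc_ids = [f"L{i + 1:02d}" for i in range(cfg.n_locations)]

    loc_cov = {}
    for name, (a, b, sd, lo, hi) in _COVARIATE_TRENDS.items():
        vals = a + b * elevations + sd * rng.standard_normal(cfg.n_locations)
        loc_cov[name] = np.clip(vals, lo, hi)

    rows = []
    for li, loc in enumerate(loc_ids):
        for host in cfg.hosts:
            for ind in range(1, cfg.individuals_per_host + 1):
                abbr = host[:6]
                rows.append({
                    "sample_id": f"{loc}_{abbr}_{ind}",
                    "location_id": loc,
                    "host_species": host,
                    "individual_id": f"{loc}_{abbr}_{ind}",
                    "elevation": elevations[li],
                    **{k: loc_cov[k][li] for k in _COVARIATE_TRENDS},
                })
    frame = pd.DataFrame(rows)
    n = len(frame)
    # truncated lognormal sequencing depth, redrawing out-of-range values
    lo, hi = cfg.depth_range
    depth = np.exp(cfg.depth_meanlog + cfg.depth_sdlog * rng.standard_normal(n))
    for _ in range(100):
        bad = (depth < lo) | (depth > hi)
        if not bad.any():
            break
        depth[bad] = np.exp(
            cfg.depth_meanlog + cfg.depth_sdlog * rng.standard_normal(bad.sum())
        )
    frame["seq_depth"] = np.clip(np.round(depth), lo, hi).astype(np.int64)
    if cfg.dropout_rate > 0:
        keep = rng.random(n) >= cfg.dropout_rate
        frame = frame.loc[keep].reset_index(drop=True)
    frame["location_id"] = pd.Categorical(frame["location_id"], categories=loc_ids)
    frame["host_species"] = pd.Categorical(
        frame["host_species"], categories=list(cfg.hosts)
    )
    return frame[[
        "sample_id", "location_id", "host_species", "individual_id",
        "elevation", "soil_ph", "soil_water", "active_layer_depth",
        "vegetation_cover", "seq_depth",
    ]]


@dataclass
class GenerativeParams:
    """True parameters of one simulated community.

    Coefficient matrices are indexed by the columns of the full (m3)
    standardized design, so they compare directly to fitted coefficients.
    Host effects are treatment contrasts against the first host.
    """

    scenario: str
    hosts: tuple[str, ...]
    otu_ids: list[str]
    columns: list[str]
    beta_pa: np.ndarray          # (J, p) occurrence coefficients (probit scale)
    beta_abund: np.ndarray       # (J, p) log-count coefficients
    loadings_pa: np.ndarray      # (J, K)
    loadings_abund: np.ndarray   # (J, K)
    sigma_abund: np.ndarray      # (J,)
    specialist: np.ndarray       # (J,) bool
    specialist_host: list[str | None]
    guilds: list[str]
    n_factors: int

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def host_effect_columns(self) -> list[str]:
        return [c for c in self.columns
                if c.startswith("host[") and ":" not in c]


@dataclass
class GroundTruth:
    """Generative parameters plus realized latent state of one dataset."""

    params: GenerativeParams
    eta_pa: np.ndarray           # (L, K) realized occurrence factors
    eta_abund: np.ndarray        # (L, K)
    location_ids: list[str] = field(default_factory=list)

    @property
    def specialist(self) -> np.ndarray:
        return self.params.specialist


def _round_robin_guilds(n_otus: int, proportions: dict[str, float]) -> list[str]:
    """Deterministic largest-deficit round-robin guild assignment."""
    total = sum(proportions.values())
    targets = {g: proportions.get(g, 0.0) / total for g in GUILDS}
    counts = {g: 0 for g in GUILDS}
    labels = []
    for i in range(n_otus):
        deficits = {g: targets[g] * (i + 1) - counts[g] for g in GUILDS}
        g = max(GUILDS, key=lambda g: deficits[g])
        counts[g] += 1
        labels.append(g)
    return labels


def _design_columns(hosts: tuple[str, ...]) -> list[str]:
    # columns of the full m3 design for this host set
    frame = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(len(hosts))],
        "location_id": pd.Categorical(["L"] * len(hosts)),
        "host_species": pd.Categorical(list(hosts), categories=list(hosts)),
        "individual_id": [f"s{i}" for i in range(len(hosts))],
        "elevation": np.linspace(0, 1, len(hosts)),
        "soil_ph": 6.0, "soil_water": 30.0, "active_layer_depth": 50.0,
        "vegetation_cover": 50.0, "seq_depth": 1000,
    })
    return build_design(frame, ModelSpec(True, True)).columns


def scenario_presets(
    scenario: str,
    n_otus: int,
    seed: int = 0,
    *,
    specialist_fraction: float = 0.3,
    hosts: tuple[str, ...] = DEFAULT_HOSTS,
    guild_proportions: dict[str, float] | None = None,
    specialist_guild: str | None = None,
    n_factors: int = 2,
) -> GenerativeParams:
    """Draw generative parameters for one specialization scenario.

    Under ``uniform`` and ``changing``, floor(specialist_fraction * n_otus)
    OTUs are planted specialists, each receiving a host effect of magnitude
    >= 1 on the probit scale on one randomly chosen (non-reference) host.
    ``specialist_guild`` restricts specialist planting to OTUs of one guild.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    rng = np.random.default_rng(seed)
    columns = _design_columns(hosts)
    p = len(columns)
    J = n_otus
    col = {c: i for i, c in enumerate(columns)}
    host_cols = [c for c in columns if c.startswith("host[") and ":" not in c]
    inter_cols = [c for c in columns if ":elevation" in c]

    guilds = _round_robin_guilds(J, guild_proportions or DEFAULT_GUILD_PROPORTIONS)

    beta_pa = np.zeros((J, p))
    beta_pa[:, col["intercept"]] = rng.normal(-0.5, 0.7, J)
    beta_pa[:, col["elevation"]] = rng.normal(0.0, 0.5, J)
    beta_pa[:, col["elevation_sq"]] = rng.normal(-0.15, 0.25, J)
    for c in ("soil_ph", "soil_water", "active_layer_depth", "vegetation_cover"):
        beta_pa[:, col[c]] = rng.normal(0.0, 0.25, J)
    beta_pa[:, col["log_seq_depth"]] = rng.normal(0.3, 0.1, J)

    beta_ab = np.zeros((J, p))
    beta_ab[:, col["intercept"]] = rng.normal(3.0, 0.5, J)
    beta_ab[:, col["elevation"]] = rng.normal(0.0, 0.25, J)
    beta_ab[:, col["elevation_sq"]] = rng.normal(-0.05, 0.15, J)
    for c in ("soil_ph", "soil_water", "active_layer_depth", "vegetation_cover"):
        beta_ab[:, col[c]] = rng.normal(0.0, 0.15, J)
    beta_ab[:, col["log_seq_depth"]] = rng.normal(0.5, 0.15, J)

    specialist = np.zeros(J, dtype=bool)
    specialist_host: list[str | None] = [None] * J
    if scenario in ("uniform", "changing"):
        n_spec = int(np.floor(specialist_fraction * J))
        if specialist_guild is not None:
            pool = np.flatnonzero(np.array(guilds) == specialist_guild)
        else:
            pool = np.arange(J)
        if n_spec > pool.size:
            raise ValueError("not enough eligible OTUs for the specialist fraction")
        chosen = rng.choice(pool, size=n_spec, replace=False)
        specialist[chosen] = True
        for j in chosen:
            hc = host_cols[rng.integers(len(host_cols))]
            specialist_host[j] = hc[len("host["):-1]
            beta_pa[j, col[hc]] = rng.uniform(1.0, 2.0)
            beta_ab[j, col[hc]] = rng.uniform(0.5, 1.0)
            if scenario == "changing":
                ic = f"{hc}:elevation"
                sign = rng.choice([-1.0, 1.0])
                beta_pa[j, col[ic]] = sign * rng.uniform(0.5, 1.0)
                beta_ab[j, col[ic]] = sign * rng.uniform(0.3, 0.6)

    loadings_pa = rng.normal(0.0, 0.5, (J, n_factors))
    loadings_ab = rng.normal(0.0, 0.5, (J, n_factors))
    sigma = rng.uniform(0.5, 1.2, J)

    return GenerativeParams(
        scenario=scenario,
        hosts=tuple(hosts),
        otu_ids=[f"OTU_{j + 1:04d}" for j in range(J)],
        columns=columns,
        beta_pa=beta_pa,
        beta_abund=beta_ab,
        loadings_pa=loadings_pa,
        loadings_abund=loadings_ab,
        sigma_abund=sigma,
        specialist=specialist,
        specialist_host=specialist_host,
        guilds=guilds,
        n_factors=n_factors,
    )


def simulate_dataset(
    frame: pd.DataFrame,
    params: GenerativeParams,
    seed: int = 0,
) -> tuple[CommunityDataset, GroundTruth]:
    """Simulate hurdle-structured counts for a design frame.

    Presence: z = 1{X beta + Lambda eta + eps > 0}, eps ~ N(0, 1).
    Counts, where present: round(exp(X beta' + Lambda' eta' + eps')) with
    eps' ~ N(0, sigma_j^2), floored at 1 so counts >= 1 exactly where the
    presence indicator is 1.
    """
    rng = np.random.default_rng(seed)
    design = build_design(frame, ModelSpec(True, True))
    if design.columns != params.columns:
        raise ValueError("design frame incompatible with generative parameters "
                         "(host set or covariates differ)")
    X = design.X
    n = X.shape[0]
    J = params.n_otus
    K = params.n_factors
    loc_codes = frame["location_id"].cat.codes.to_numpy()
    loc_levels = [str(c) for c in frame["location_id"].cat.categories]
    L = len(loc_levels)

    eta_pa = rng.standard_normal((L, K))
    eta_ab = rng.standard_normal((L, K))

    mu_pa = X @ params.beta_pa.T + eta_pa[loc_codes] @ params.loadings_pa.T
    presence = (mu_pa + rng.standard_normal((n, J))) > 0

    mu_ab = (X @ params.beta_abund.T
             + eta_ab[loc_codes] @ params.loadings_abund.T
             + params.sigma_abund[None, :] * rng.standard_normal((n, J)))
    counts = np.round(np.exp(np.clip(mu_ab, None, 18.0)))
    counts = np.maximum(counts, 1.0)
    counts = np.where(presence, counts, 0.0).astype(np.int64)

    table = OtuTable(list(frame["sample_id"]), list(params.otu_ids), counts)
    guilds = GuildMap(dict(zip(params.otu_ids, params.guilds)))
    ds = CommunityDataset(table, frame.copy(), guilds)
    truth = GroundTruth(params=params, eta_pa=eta_pa, eta_abund=eta_ab,
                        location_ids=loc_levels)
    return ds, truth


def simulate_scenario(
    scenario: str,
    n_otus: int = 40,
    seed: int = 0,
    design: DesignConfig | None = None,
    **preset_kwargs,
) -> tuple[CommunityDataset, GroundTruth]:
    """Convenience wrapper: design + presets + simulation from one seed."""
    ss = np.random.SeedSequence([int(seed), 7])
    s_design, s_params, s_data = (int(s.generate_state(1)[0] % 2**31)
                                  for s in ss.spawn(3))
    cfg = design or DesignConfig()
    cfg = DesignConfig(**{**cfg.__dict__, "seed": s_design})
    frame = generate_design(cfg)
    params = scenario_presets(scenario, n_otus, seed=s_params,
                              hosts=cfg.hosts, **preset_kwargs)
    return simulate_dataset(frame, params, seed=s_data)
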