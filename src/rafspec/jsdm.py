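"""Hurdle joint species distribution models fitted by Gibbs sampling.

The community model has two parts sharing one fixed-effect design and a
latent-factor random effect of sampling location:

* occurrence part — multivariate probit: for sample i and species j,
  y*_ij = x_i' beta_j + lambda_j' eta_{loc(i)} + eps_ij, eps ~ N(0, 1),
  with y_ij = 1{y*_ij > 0}; fitted by truncated-normal data augmentation
  with conjugate updates for coefficients, loadings and factors.
* abundance part — Gaussian regression of log read counts on the same
  design, restricted to cells where the species is present, with per-species
  residual variance sigma_j^2 (inverse-gamma conjugate update).

Three nested fixed-effect structures encode the specialization hypotheses:
m1 has environmental covariates only (no specialization), m2 adds host plant
species as a categorical effect (uniform specialization), m3 adds the
host x elevation interaction (specialization changing along the gradient).

Priors: N(0, 5^2) per regression coefficient on standardized covariates,
N(0, 1) on loadings and factors, inverse-gamma(2, 1) on residual variances.
The probit residual variance is fixed at 1 for identification. Loadings and
factors are sign/rotation unidentified; every exposed quantity depends on
them only through Lambda Lambda' and Lambda eta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from .community import CommunityDataset

#: Environmental covariates present in every model, in design order.
ENV_COLUMNS = (
    "elevation",
    "elevation_sq",
    "soil_ph",
    "soil_water",
    "active_layer_depth",
    "vegetation_cover",
    "log_seq_depth",
)

BETA_PRIOR_VAR = 25.0
SIGMA_PRIOR_SHAPE = 2.0
SIGMA_PRIOR_SCALE = 1.0


@dataclass(frozen=True)
class ModelSpec:
    """One of the three nested specialization hypotheses.

    m1: environment only; m2: + host species; m3: + host x elevation.
    """

    include_host: bool = False
    include_host_elevation: bool = False

    def __post_init__(self) -> None:
        if self.include_host_elevation and not self.include_host:
            raise ValueError("host x elevation interaction requires the host term")

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        table = {
            "m1": cls(False, False),
            "m2": cls(True, False),
            "m3": cls(True, True),
        }
        try:
            return table[name]
        except KeyError:
            raise ValueError(f"unknown model name {name!r}; expected m1, m2 or m3")

    @property
    def name(self) -> str:
        if self.include_host_elevation:
            return "m3"
        return "m2" if self.include_host else "m1"

    @property
    def complexity(self) -> int:
        return {"m1": 0, "m2": 1, "m3": 2}[self.name]


@dataclass
class DesignMatrix:
    """Fixed-effect design with stored standardization state.

    Continuous covariates are standardized to mean 0, sd 1 on the fitting
    data; the squared elevation term is computed from standardized elevation
    and then itself standardized. Host species is coded as treatment
    contrasts against the first host level (first appearance order); the
    interaction columns multiply each contrast by standardized elevation.
    """

    X: np.ndarray
    columns: list[str]
    groups: dict[str, str]
    center: dict[str, float]
    scale: dict[str, float]
    host_levels: list[str]
    spec: ModelSpec

    @property
    def p(self) -> int:
        return len(self.columns)

    def transform(self, frame: pd.DataFrame) -> np.ndarray:
        """Build the design for new samples reusing stored standardization."""
        return _assemble_design(frame, self.spec, self)[0]

    def group_columns(self, group: str) -> list[int]:
        return [i for i, c in enumerate(self.columns) if self.groups[c] == group]


def build_design(frame: pd.DataFrame, spec: ModelSpec) -> DesignMatrix:
    """Construct the standardized fixed-effect design for a sample frame."""
    X, columns, groups, center, scale, host_levels = _assemble_design(
        frame, spec, None
    )
    return DesignMatrix(X, columns, groups, center, scale, host_levels, spec)


def _assemble_design(frame, spec, fitted: DesignMatrix | None):
    n = len(frame)
    host = frame["host_species"]
    if fitted is not None:
        host_levels = fitted.host_levels
        unseen = set(host.astype(str)) - set(host_levels)
        if unseen:
            raise ValueError(f"unseen host level(s) at prediction time: {unseen}")
        center, scale = fitted.center, fitted.scale
    else:
        host_levels = [str(h) for h in pd.unique(host.astype(str))]
        center, scale = {}, {}

    raw = {
        "elevation": frame["elevation"].to_numpy(dtype=float),
        "soil_ph": frame["soil_ph"].to_numpy(dtype=float),
        "soil_water": frame["soil_water"].to_numpy(dtype=float),
        "active_layer_depth": frame["active_layer_depth"].to_numpy(dtype=float),
        "vegetation_cover": frame["vegetation_cover"].to_numpy(dtype=float),
        "log_seq_depth": np.log(frame["seq_depth"].to_numpy(dtype=float)),
    }

    def standardize(name, values):
        if fitted is None:
            center[name] = float(np.mean(values))
            sd = float(np.std(values))
            scale[name] = sd if sd > 0 else 1.0
        return (values - center[name]) / scale[name]

    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    elev_std = standardize("elevation", raw["elevation"])
    cols["elevation"] = elev_std
    cols["elevation_sq"] = standardize("elevation_sq", elev_std**2)
    for name in ("soil_ph", "soil_water", "active_layer_depth",
                 "vegetation_cover", "log_seq_depth"):
        cols[name] = standardize(name, raw[name])

    groups = {"intercept": "intercept",
              "elevation": "elevation", "elevation_sq": "elevation",
              "soil_ph": "soil", "soil_water": "soil",
              "active_layer_depth": "soil", "vegetation_cover": "soil",
              "log_seq_depth": "depth"}

    if spec.include_host:
        host_str = host.astype(str).to_numpy()
        for level in host_levels[1:]:
            cname = f"host[{level}]"
            cols[cname] = (host_str == level).astype(float)
            groups[cname] = "host"
        if spec.include_host_elevation:
            for level in host_levels[1:]:
                cname = f"host[{level}]:elevation"
                cols[cname] = cols[f"host[{level}]"] * elev_std
                groups[cname] = "host"

    columns = list(cols)
    X = np.column_stack([cols[c] for c in columns])
    return X, columns, groups, center, scale, host_levels


@dataclass
class McmcConfig:
    """Sampler settings; recorded verbatim in every fit."""

    n_chains: int = 2
    n_warmup: int = 1000
    n_samples: int = 500
    thin: int = 5
    n_factors: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chains", "n_warmup", "n_samples", "thin"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_factors < 0:
            raise ValueError("n_factors must be >= 0")


@dataclass
class PosteriorDraws:
    """Stacked posterior draws for one hurdle part.

    Arrays are (chains * draws, ...); ``n_chains`` and ``n_per_chain``
    describe the chain structure for diagnostics.
    """

    beta: np.ndarray            # (D, J, p)
    loadings: np.ndarray        # (D, J, K)
    factors: np.ndarray         # (D, L, K)
    sigma: np.ndarray | None    # (D, J) abundance part only
    n_chains: int
    n_per_chain: int
    columns: list[str]
    location_ids: list[str]
    flags: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def by_chain(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape(self.n_chains, self.n_per_chain, *arr.shape[1:])


@dataclass
class HurdleFit:
    """Joint fit of the occurrence and abundance parts on one dataset."""

    spec: ModelSpec
    design: DesignMatrix
    pa: PosteriorDraws | None
    abund: PosteriorDraws | None
    config: McmcConfig
    location_ids: list[str]
    otu_ids: list[str]
    convergence: dict = field(default_factory=dict)


def _chain_seeds(seed: int, n_chains: int, salt: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence([seed, salt])
    return [np.random.default_rng(s) for s in ss.spawn(n_chains)]


def _location_constant_columns(X: np.ndarray, loc_idx: np.ndarray,
                               n_locations: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices of design columns constant within every location, and the
    (locations x columns) matrix of their per-location values."""
    cols = []
    W = []
    for c in range(X.shape[1]):
        vals = np.empty(n_locations)
        ok = True
        for l in range(n_locations):
            members = loc_idx == l
            if not members.any():
                vals[l] = 0.0
                continue
            v = X[members, c]
            if np.ptp(v) > 1e-12:
                ok = False
                break
            vals[l] = v[0]
        if ok:
            cols.append(c)
            W.append(vals)
    return np.array(cols, dtype=int), (np.array(W).T if W
                                       else np.empty((n_locations, 0)))


def _confounding_sweep(beta, lam, eta, cols, W, rng):
    """Gibbs move along the likelihood-invariant direction that trades
    location-constant fixed effects against the latent factors.

    For location-constant covariate columns, eta -> eta - W D with the
    compensation beta[:, cols] -> beta[:, cols] + lam D' leaves every linear
    predictor unchanged, so the conditional of the translation D under the
    N(0, BETA_PRIOR_VAR) / N(0, 1) priors is Gaussian and can be sampled
    exactly. Without this move the sampler random-walks along the ridge.
    """
    q = cols.size
    K = lam.shape[1]
    if q == 0 or K == 0:
        return
    B = beta[:, cols]                                # (J, q)
    LtL = lam.T @ lam                                # (K, K)
    prec = (np.kron(np.eye(q), LtL) / BETA_PRIOR_VAR
            + np.kron(W.T @ W, np.eye(K))
            + 1e-10 * np.eye(q * K))
    rhs = (-(B.T @ lam) / BETA_PRIOR_VAR + W.T @ eta).ravel()   # (q*K,)
    Lc = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs)
    d = mean + np.linalg.solve(Lc.T, rng.standard_normal(q * K))
    D = d.reshape(q, K)
    beta[:, cols] += lam @ D.T
    eta -= W @ D


def _sample_mvn_batch(prec: np.ndarray, rhs: np.ndarray, rng) -> np.ndarray:
    """Draw from N(prec^-1 rhs, prec^-1) for a batch of (J, p, p) precisions."""
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs[..., None])[..., 0]
    z = rng.standard_normal(rhs.shape)
    # solve L' x = z  (upper-triangular system, batched)
    pert = np.linalg.solve(np.swapaxes(L, -1, -2), z[..., None])[..., 0]
    return mean + pert


def fit_pa_probit(
    Y: np.ndarray,
    X: np.ndarray,
    loc_idx: np.ndarray,
    n_locations: int,
    cfg: McmcConfig,
    columns: list[str] | None = None,
    location_ids: list[str] | None = None,
) -> PosteriorDraws:
    """Gibbs sampler for the multivariate probit occurrence part.

    ``Y`` is (n, J) binary, ``X`` (n, p), ``loc_idx`` maps samples to
    sampling locations. Deterministic given ``cfg.seed``.
    """
    Y = np.asarray(Y, dtype=float)
    if not np.isin(Y, (0.0, 1.0)).all():
        raise ValueError("occurrence matrix must be binary")
    n, J = Y.shape
    p = X.shape[1]
    K = cfg.n_factors
    degenerate = (Y.sum(axis=0) == 0) | (Y.sum(axis=0) == n)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} species column(s) are all-absent or "
            "all-present; the prior regularizes their fit",
            stacklevel=2,
        )

    loc_members = [np.flatnonzero(loc_idx == l) for l in range(n_locations)]
    prior_prec_diag = np.concatenate(
        [np.full(p, 1.0 / BETA_PRIOR_VAR), np.ones(K)]
    )
    const_cols, W_const = _location_constant_columns(X, loc_idx, n_locations)

    lower = np.where(Y > 0, 0.0, -np.inf)
    upper = np.where(Y > 0, np.inf, 0.0)

    chains_beta, chains_lam, chains_eta = [], [], []
    for rng in _chain_seeds(cfg.seed, cfg.n_chains, salt=1):
        beta = np.zeros((J, p))
        lam = 0.1 * rng.standard_normal((J, K)) if K else np.zeros((J, 0))
        eta = np.zeros((n_locations, K))

        n_iter = cfg.n_warmup + cfg.n_samples * cfg.thin
        keep_beta = np.empty((cfg.n_samples, J, p))
        keep_lam = np.empty((cfg.n_samples, J, K))
        keep_eta = np.empty((cfg.n_samples, n_locations, K))
        kept = 0
        for it in range(n_iter):
            H = eta[loc_idx]                      # (n, K)
            ranef = H @ lam.T if K else 0.0       # (n, J)
            # latent truncated normals
            mu = X @ beta.T + ranef
            a = ndtr(lower - mu)
            b = ndtr(upper - mu)
            u = a + rng.random((n, J)) * (b - a)
            u = np.clip(u, 1e-12, 1.0 - 1e-12)
            z = mu + np.clip(ndtri(u), -8.0, 8.0)
            # joint (beta_j, lambda_j) | z, eta: one conjugate block per
            # species. Updating them together matters because location-level
            # covariate columns correlate with H, which would otherwise
            # create a slowly mixing ridge. The precision is shared across
            # species (residual variance 1, common augmented design).
            G = np.concatenate([X, H], axis=1) if K else X   # (n, p+K)
            prec = G.T @ G + np.diag(prior_prec_diag)
            Lc = np.linalg.cholesky(prec)
            rhs = G.T @ z                          # (p+K, J)
            mean = np.linalg.solve(prec, rhs)
            pert = np.linalg.solve(Lc.T, rng.standard_normal((p + K, J)))
            coef = (mean + pert).T                 # (J, p+K)
            beta, lam = coef[:, :p], coef[:, p:]
            if K:
                # factors | z, beta, lambda, per location
                r = z - X @ beta.T                 # (n, J)
                LtL = lam.T @ lam                  # (K, K)
                for l, members in enumerate(loc_members):
                    if members.size == 0:
                        eta[l] = rng.standard_normal(K)
                        continue
                    prec_e = np.eye(K) + members.size * LtL
                    rhs_e = lam.T @ r[members].sum(axis=0)
                    Le = np.linalg.cholesky(prec_e)
                    mean_e = np.linalg.solve(prec_e, rhs_e)
                    eta[l] = mean_e + np.linalg.solve(
                        Le.T, rng.standard_normal(K)
                    )
                beta = np.ascontiguousarray(beta)
                _confounding_sweep(beta, lam, eta, const_cols, W_const, rng)
            if it >= cfg.n_warmup and (it - cfg.n_warmup) % cfg.thin == 0:
                keep_beta[kept] = beta
                keep_lam[kept] = lam
                keep_eta[kept] = eta
                kept += 1
        chains_beta.append(keep_beta[:kept])
        chains_lam.append(keep_lam[:kept])
        chains_eta.append(keep_eta[:kept])

    return PosteriorDraws(
        beta=np.concatenate(chains_beta),
        loadings=np.concatenate(chains_lam),
        factors=np.concatenate(chains_eta),
        sigma=None,
        n_chains=cfg.n_chains,
        n_per_chain=chains_beta[0].shape[0],
        columns=list(columns) if columns is not None else [f"x{i}" for i in range(p)],
        location_ids=(list(location_ids) if location_ids is not None
                      else [str(l) for l in range(n_locations)]),
        flags={"degenerate_columns": np.flatnonzero(degenerate).tolist()},
    )


def fit_abundance_lognormal(
    logY: np.ndarray,
    present: np.ndarray,
    X: np.ndarray,
    loc_idx: np.ndarray,
    n_locations: int,
    cfg: McmcConfig,
    columns: list[str] | None = None,
    location_ids: list[str] | None = None,
) -> PosteriorDraws:
    """Gibbs sampler for the lognormal abundance part, conditional on presence.

    ``logY`` holds log counts where ``present`` is True; absent cells
    contribute nothing to the likelihood. Species with < 3 present cells are
    fitted but flagged low-information (the prior dominates); species never
    present get a pure prior draw.
    """
    present = np.asarray(present, dtype=bool)
    logY = np.where(present, np.asarray(logY, dtype=float), 0.0)
    n, J = present.shape
    p = X.shape[1]
    K = cfg.n_factors
    M = present.astype(float)
    n_present = M.sum(axis=0)
    low_info = np.flatnonzero(n_present < 3).tolist()

    eye_K = np.eye(K) if K else np.zeros((0, 0))
    prior_prec_diag = np.concatenate(
        [np.full(p, 1.0 / BETA_PRIOR_VAR), np.ones(K)]
    )
    loc_members = [np.flatnonzero(loc_idx == l) for l in range(n_locations)]
    const_cols, W_const = _location_constant_columns(X, loc_idx, n_locations)
    # per-location present-cell counts per species, for factor updates
    C = np.zeros((n_locations, J))
    for l, members in enumerate(loc_members):
        C[l] = M[members].sum(axis=0)

    chains_beta, chains_lam, chains_eta, chains_sig = [], [], [], []
    for rng in _chain_seeds(cfg.seed, cfg.n_chains, salt=2):
        beta = np.zeros((J, p))
        lam = 0.1 * rng.standard_normal((J, K)) if K else np.zeros((J, 0))
        eta = np.zeros((n_locations, K))
        sig2 = np.ones(J)

        n_iter = cfg.n_warmup + cfg.n_samples * cfg.thin
        keep = {k: [] for k in ("beta", "lam", "eta", "sig")}
        for it in range(n_iter):
            H = eta[loc_idx]
            # joint (beta_j, lambda_j) | rest: one conjugate normal block per
            # species on the augmented design [X H] restricted to present
            # cells (precisions differ across species through the mask and
            # sigma_j, so the solves are batched).
            G = np.concatenate([X, H], axis=1) if K else X   # (n, p+K)
            GtG = np.einsum("ij,ip,iq->jpq", M, G, G)
            prec = GtG / sig2[:, None, None] + np.diag(prior_prec_diag)
            rhs = np.einsum("ip,ij->jp", G, logY * M) / sig2[:, None]
            coef = _sample_mvn_batch(prec, rhs, rng)          # (J, p+K)
            beta, lam = coef[:, :p], coef[:, p:]
            fitted = X @ beta.T                   # (n, J)
            if K:
                # factors | rest
                r = (logY - fitted) * M
                S = np.zeros((n_locations, J))
                for l, members in enumerate(loc_members):
                    if members.size:
                        S[l] = r[members].sum(axis=0)
                w = 1.0 / sig2
                for l in range(n_locations):
                    prec_e = eye_K + np.einsum(
                        "j,jk,jl->kl", C[l] * w, lam, lam
                    )
                    rhs_e = lam.T @ (S[l] * w)
                    Le = np.linalg.cholesky(prec_e)
                    mean_e = np.linalg.solve(prec_e, rhs_e)
                    eta[l] = mean_e + np.linalg.solve(
                        Le.T, rng.standard_normal(K)
                    )
                beta = np.ascontiguousarray(beta)
                _confounding_sweep(beta, lam, eta, const_cols, W_const, rng)
                fitted = X @ beta.T
                H = eta[loc_idx]
            ranef = H @ lam.T if K else 0.0
            # sigma^2 | rest
            resid = (logY - fitted - ranef) * M
            ssr = np.einsum("ij,ij->j", resid, resid)
            shape = SIGMA_PRIOR_SHAPE + n_present / 2.0
            rate = SIGMA_PRIOR_SCALE + ssr / 2.0
            sig2 = rate / rng.gamma(shape, 1.0, size=J)
            if it >= cfg.n_warmup and (it - cfg.n_warmup) % cfg.thin == 0:
                keep["beta"].append(beta.copy())
                keep["lam"].append(lam.copy())
                keep["eta"].append(eta.copy())
                keep["sig"].append(np.sqrt(sig2))
        chains_beta.append(np.array(keep["beta"]))
        chains_lam.append(np.array(keep["lam"]))
        chains_eta.append(np.array(keep["eta"]))
        chains_sig.append(np.array(keep["sig"]))

    return PosteriorDraws(
        beta=np.concatenate(chains_beta),
        loadings=np.concatenate(chains_lam),
        factors=np.concatenate(chains_eta),
        sigma=np.concatenate(chains_sig),
        n_chains=cfg.n_chains,
        n_per_chain=chains_beta[0].shape[0],
        columns=list(columns) if columns is not None else [f"x{i}" for i in range(p)],
        location_ids=(list(location_ids) if location_ids is not None
                      else [str(l) for l in range(n_locations)]),
        flags={"low_information": low_info},
    )


def _location_index(frame: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    codes = frame["location_id"].cat.codes.to_numpy()
    levels = [str(c) for c in frame["location_id"].cat.categories]
    # restrict to levels actually present, preserving order
    present_levels = [levels[c] for c in sorted(set(codes))]
    remap = {old: new for new, old in enumerate(sorted(set(codes)))}
    return np.array([remap[c] for c in codes]), present_levels


def fit_hurdle(
    ds: CommunityDataset,
    spec: ModelSpec,
    cfg: McmcConfig,
    parts: tuple[str, ...] = ("pa", "abund"),
) -> HurdleFit:
    """Fit both hurdle parts of one model to a community dataset."""
    if ds.n_otus < 2:
        raise ValueError("community model requires at least 2 OTUs")
    design = build_design(ds.samples, spec)
    loc_idx, location_ids = _location_index(ds.samples)
    n_locations = len(location_ids)
    Y = (ds.table.counts > 0).astype(float)

    pa = abund = None
    if "pa" in parts:
        pa = fit_pa_probit(Y, design.X, loc_idx, n_locations, cfg,
                           design.columns, location_ids)
    if "abund" in parts:
        with np.errstate(divide="ignore"):
            logY = np.where(Y > 0, np.log(np.maximum(ds.table.counts, 1)), 0.0)
        abund = fit_abundance_lognormal(
            logY, Y > 0, design.X, loc_idx, n_locations, cfg,
            design.columns, location_ids,
        )
    fit = HurdleFit(spec, design, pa, abund, cfg, location_ids,
                    list(ds.table.otu_ids))
    if cfg.n_chains >= 2:
        fit.convergence = psrf_diagnostics(fit)
    return fit


# ---------------------------------------------------------------------------
# Prediction and pointwise likelihood
# ---------------------------------------------------------------------------

def _linear_predictor(draws: PosteriorDraws, X: np.ndarray,
                      loc_idx: np.ndarray | None) -> np.ndarray:
    """(D, n, J) linear predictor; conditional on factors when loc_idx given."""
    mu = np.einsum("np,djp->dnj", X, draws.beta)
    if loc_idx is not None and draws.loadings.shape[-1] > 0:
        H = draws.factors[:, loc_idx, :]           # (D, n, K)
        mu = mu + np.einsum("dnk,djk->dnj", H, draws.loadings)
    return mu


def _resolve_locations(draws: PosteriorDraws, frame: pd.DataFrame) -> np.ndarray:
    lookup = {lid: i for i, lid in enumerate(draws.location_ids)}
    locs = frame["location_id"].astype(str)
    unknown = set(locs) - set(lookup)
    if unknown:
        raise ValueError(
            f"unknown location(s) for conditional prediction: {sorted(unknown)}"
        )
    return np.array([lookup[l] for l in locs])


def predict_occurrence(
    fit: HurdleFit, frame: pd.DataFrame, use_location_effect: bool = True
) -> np.ndarray:
    """Per-draw occurrence probabilities, (draws, samples, OTUs).

    With ``use_location_effect`` the posterior location factors enter the
    predictor; otherwise the factors are integrated out analytically,
    Phi(x'beta / sqrt(1 + ||lambda_j||^2)).
    """
    if fit.pa is None:
        raise ValueError("fit has no occurrence part")
    X = fit.design.transform(frame)
    if use_location_effect:
        loc_idx = _resolve_locations(fit.pa, frame)
        return ndtr(_linear_predictor(fit.pa, X, loc_idx))
    mu = _linear_predictor(fit.pa, X, None)
    denom = np.sqrt(1.0 + np.sum(fit.pa.loadings**2, axis=-1))  # (D, J)
    return ndtr(mu / denom[:, None, :])


def predict_abundance(
    fit: HurdleFit, frame: pd.DataFrame, use_location_effect: bool = True
) -> np.ndarray:
    """Per-draw expected log count conditional on presence, (draws, n, J)."""
    if fit.abund is None:
        raise ValueError("fit has no abundance part")
    X = fit.design.transform(frame)
    if use_location_effect:
        loc_idx = _resolve_locations(fit.abund, frame)
        return _linear_predictor(fit.abund, X, loc_idx)
    return _linear_predictor(fit.abund, X, None)


def pointwise_loglik(fit: HurdleFit, ds: CommunityDataset) -> dict[str, np.ndarray]:
    """Pointwise log-likelihood arrays for WAIC, one unit per (sample, OTU) cell.

    Occurrence units cover every cell (Bernoulli log-mass under the probit
    probability); abundance units cover present cells only (normal
    log-density of the log count). The two parts form separate unit sets.
    """
    if list(ds.table.otu_ids) != fit.otu_ids:
        raise ValueError("dataset OTUs do not match the fit")
    out: dict[str, np.ndarray] = {}
    Y = (ds.table.counts > 0).astype(float)
    if fit.pa is not None:
        X = fit.design.transform(ds.samples)
        loc_idx = _resolve_locations(fit.pa, ds.samples)
        mu = _linear_predictor(fit.pa, X, loc_idx)
        ll = np.where(Y[None] > 0, norm.logcdf(mu), norm.logcdf(-mu))
        out["pa"] = ll.reshape(ll.shape[0], -1)
    if fit.abund is not None:
        X = fit.design.transform(ds.samples)
        loc_idx = _resolve_locations(fit.abund, ds.samples)
        mu = _linear_predictor(fit.abund, X, loc_idx)
        present = ds.table.counts > 0
        logy = np.log(np.maximum(ds.table.counts, 1))
        resid = logy[None] - mu
        sig = fit.abund.sigma[:, None, :]
        ll = -0.5 * np.log(2 * np.pi) - np.log(sig) - 0.5 * (resid / sig) ** 2
        D = ll.shape[0]
        out["abund"] = ll[:, present].reshape(D, -1)
    return out


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

def split_psrf(chains: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction factor.

    ``chains`` is (n_chains, n_draws, ...); each chain is split in half and
    the classical R-hat of the resulting sequences is returned per scalar
    parameter. Parameters with zero total variance report 1.0.
    """
    m, n = chains.shape[:2]
    if m < 2:
        raise ValueError("PSRF requires at least 2 chains")
    half = n // 2
    seqs = np.concatenate(
        [chains[:, :half], chains[:, half : 2 * half]], axis=0
    )  # (2m, half, ...)
    means = seqs.mean(axis=1)
    variances = seqs.var(axis=1, ddof=1)
    W = variances.mean(axis=0)
    B = half * means.var(axis=0, ddof=1)
    var_hat = (half - 1) / half * W + B / half
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    return np.where(W <= 0, 1.0, rhat)


def psrf_diagnostics(fit: HurdleFit) -> dict:
    """Max/median split-R-hat over regression coefficients, per hurdle part."""
    out: dict = {}
    for part_name in ("pa", "abund"):
        draws = getattr(fit, part_name)
        if draws is None:
            continue
        if draws.n_chains < 2:
            raise ValueError("PSRF requires at least 2 chains")
        rhat = split_psrf(draws.by_chain("beta"))
        entry = {"max_psrf_beta": float(np.nanmax(rhat)),
                 "median_psrf_beta": float(np.nanmedian(rhat))}
        if draws.sigma is not None:
            rs = split_psrf(draws.by_chain("sigma"))
            entry["max_psrf_sigma"] = float(np.nanmax(rs))
        out[part_name] = entry
    return out
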