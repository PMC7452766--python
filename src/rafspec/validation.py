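"""Simulation studies validating the inference pipeline end to end.

Each study simulates communities under a known specialization scenario,
runs the same analysis a user would (5% prevalence filter, hurdle fits,
WAIC, design-stratified cross-validation), and scores how well the known
ground truth is recovered. The default study size (40 OTUs, 12 locations,
5 hosts, 3 individuals per host) is a reduced version of the full sampling
design that keeps the hierarchical structure intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import CommunityDataset, filter_by_prevalence
from .evaluate import compare_models, cross_validate, make_cv_folds, waic_from_fit
from .jsdm import McmcConfig, ModelSpec, fit_hurdle
from .simulate import DesignConfig, simulate_scenario
from .specialization import network_specialization_summary, variance_partition

#: Reduced study design used by the validation studies.
STUDY_DESIGN = dict(n_locations=12, individuals_per_host=3)
STUDY_N_OTUS = 40


def _study_dataset(scenario: str, seed: int, **preset_kwargs):
    ds, truth = simulate_scenario(
        scenario, n_otus=STUDY_N_OTUS, seed=seed,
        design=DesignConfig(**STUDY_DESIGN), **preset_kwargs,
    )
    table = filter_by_prevalence(ds.table, 0.05)
    kept = np.array([ds.table.otu_ids.index(o) for o in table.otu_ids])
    return CommunityDataset(table, ds.samples, ds.guilds), truth, kept


def host_effect_recovery(seed: int = 1,
                         mcmc: McmcConfig | None = None) -> dict:
    """Fit m2 to scenario-uniform data; score host-effect recovery.

    Returns the correlation between true and posterior-mean host contrasts
    (occurrence part) and the 95% credible-interval coverage over all fixed
    effects pooled.
    """
    ds, truth, kept = _study_dataset("uniform", seed)
    cfg = mcmc or McmcConfig(n_chains=2, n_warmup=800, n_samples=500,
                             thin=2, n_factors=2, seed=seed + 1000)
    fit = fit_hurdle(ds, ModelSpec.from_name("m2"), cfg, parts=("pa",))
    cols = fit.design.columns
    hidx = [i for i, c in enumerate(cols) if c.startswith("host[")]
    tcols = [truth.params.columns.index(c) for c in cols]
    truth_beta = truth.params.beta_pa[kept][:, tcols]

    est = fit.pa.beta.mean(axis=0)[:, hidx].ravel()
    tru = truth_beta[:, hidx].ravel()
    corr = float(np.corrcoef(est, tru)[0, 1])

    lo = np.quantile(fit.pa.beta, 0.025, axis=0)
    hi = np.quantile(fit.pa.beta, 0.975, axis=0)
    coverage = float(((truth_beta >= lo) & (truth_beta <= hi)).mean())
    return {"host_effect_correlation": corr,
            "ci95_coverage": coverage,
            "n_otus": ds.n_otus,
            "n_samples": ds.n_samples}


@dataclass
class ScenarioReplicate:
    """Model-comparison outcome for one simulated community."""

    seed: int
    waic_m1: float
    waic_m2: float
    mean_auc_m1: float
    mean_auc_m2: float
    improvement_proportion: float
    specialization_supported: bool
    waic_and_mean_auc_favor_m2: bool
    top_decile_all_specialists: bool | None


def scenario_replicate(scenario: str, seed: int,
                       k_folds: int = 5) -> ScenarioReplicate:
    """Full m1-vs-m2 comparison (occurrence part) on one simulated community."""
    ds, truth, kept = _study_dataset(scenario, seed)
    waic_cfg = McmcConfig(n_chains=1, n_warmup=400, n_samples=300, thin=1,
                          n_factors=2, seed=seed + 501)
    cv_cfg = McmcConfig(n_chains=1, n_warmup=300, n_samples=400, thin=1,
                        n_factors=2, seed=seed + 502)
    folds = make_cv_folds(ds.samples, k=k_folds, seed=seed + 503)
    scores, cvs = {}, {}
    for name in ("m1", "m2"):
        spec = ModelSpec.from_name(name)
        fit = fit_hurdle(ds, spec, waic_cfg, parts=("pa",))
        scores[name] = waic_from_fit(fit, ds)["pa"]
        cvs[name] = cross_validate(ds, spec, cv_cfg, folds, parts=("pa",))
    comp = compare_models(scores, cvs, metric="auc")

    diff = cvs["m2"].auc - cvs["m1"].auc
    top_decile = None
    specialist = truth.params.specialist[kept]
    if specialist.any():
        n_top = max(1, ds.n_otus // 10)
        order = np.argsort(np.where(np.isnan(diff), -np.inf, diff))[::-1]
        top_decile = bool(specialist[order[:n_top]].all())
    return ScenarioReplicate(
        seed=seed,
        waic_m1=scores["m1"].waic,
        waic_m2=scores["m2"].waic,
        mean_auc_m1=cvs["m1"].mean_auc,
        mean_auc_m2=cvs["m2"].mean_auc,
        improvement_proportion=comp["improvement_proportion"]["m2>m1"],
        specialization_supported=bool(comp["specialization_supported"]),
        waic_and_mean_auc_favor_m2=bool(
            scores["m2"].waic < scores["m1"].waic
            and cvs["m2"].mean_auc > cvs["m1"].mean_auc),
        top_decile_all_specialists=top_decile,
    )


def scenario_study(scenario: str, base_seed: int = 1,
                   n_replicates: int = 10) -> list[ScenarioReplicate]:
    """Replicated scenario-recovery study over derived seeds."""
    seeds = [int(s.generate_state(1)[0] % 2**31)
             for s in np.random.SeedSequence([base_seed, 11]).spawn(n_replicates)]
    return [scenario_replicate(scenario, s) for s in seeds]


def guild_contrast(seed: int = 1, mcmc: McmcConfig | None = None) -> dict:
    """Variance-partition contrast when only endophytes carry host effects.

    Simulates a community in which host specialists are planted exclusively
    among endophyte-labelled OTUs, fits the uniform-specialization model and
    compares the mean host-group variance fraction between guilds.
    """
    ds, truth, kept = _study_dataset("uniform", seed,
                                     specialist_guild="endophytic",
                                     specialist_fraction=0.25)
    cfg = mcmc or McmcConfig(n_chains=2, n_warmup=500, n_samples=300,
                             thin=1, n_factors=2, seed=seed + 2000)
    fit = fit_hurdle(ds, ModelSpec.from_name("m2"), cfg)
    out = {}
    for part in ("pa", "abund"):
        vp = variance_partition(fit, part)
        summ = network_specialization_summary(vp, ds.guilds).set_index("guild")
        out[part] = {
            "endophytic_host_fraction":
                float(summ.loc["endophytic", "mean_host_fraction"]),
            "mycorrhizal_host_fraction":
                float(summ.loc["mycorrhizal", "mean_host_fraction"]),
        }
    return out
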