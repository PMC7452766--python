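"""Model evaluation: WAIC, design-stratified cross-validation, selection rules.

WAIC is computed from pointwise posterior log-likelihoods,
waic = -2 (lppd - p_waic) with lppd = sum_u log mean_d exp(ll_du) and
p_waic = sum_u var_d(ll_du). Because the scale convention of community-level
WAIC reports varies, both the raw sum over units and the per-unit mean are
exposed; model ranking is invariant to the choice.

Cross-validation follows the sampling design: within each (location, host)
group the individuals are dealt round-robin into k folds, so every training
set contains individuals from every location and held-out communities are
predicted conditional on the location's posterior random effect. Predictive
power is summarized per species by AUC on held-out presence-absence and by
a signed R^2 (sign(rho) * rho^2) on held-out log counts where present.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata

from .community import CommunityDataset
from .jsdm import (
    HurdleFit,
    McmcConfig,
    ModelSpec,
    fit_hurdle,
    pointwise_loglik,
    predict_abundance,
    predict_occurrence,
)

WAIC_TIE_TOL = 1e-6


@dataclass
class ModelScore:
    """WAIC decomposition for one model and unit set."""

    lppd: float
    p_waic: float
    waic: float
    n_units: int
    normalization: str = "sum"

    def as_mean(self) -> "ModelScore":
        if self.normalization == "mean":
            return self
        u = self.n_units
        return ModelScore(self.lppd / u, self.p_waic / u, self.waic / u,
                          u, "mean")


def waic(loglik: np.ndarray, normalization: str = "sum") -> ModelScore:
    """WAIC from a (draws, units) pointwise log-likelihood array."""
    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 2:
        raise ValueError("loglik must be (draws, units)")
    D, U = loglik.shape
    if D < 2:
        raise ValueError("WAIC requires at least 2 posterior draws")
    if normalization not in ("sum", "mean"):
        raise ValueError("normalization must be 'sum' or 'mean'")
    lppd = float(np.sum(logsumexp(loglik, axis=0) - np.log(D)))
    p_waic = float(np.sum(np.var(loglik, axis=0, ddof=1)))
    score = ModelScore(lppd, p_waic, -2.0 * (lppd - p_waic), U, "sum")
    return score.as_mean() if normalization == "mean" else score


def make_cv_folds(frame: pd.DataFrame, k: int = 5, seed: int = 0) -> pd.Series:
    """Assign samples to folds, stratified by (location, host) group.

    Within each group the individuals are randomly permuted and dealt
    round-robin from a random starting fold, so group fold counts differ by
    at most one and size-k groups hit every fold exactly once.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(frame) == 0:
        raise ValueError("empty sample frame")
    rng = np.random.default_rng(seed)
    fold = pd.Series(0, index=frame["sample_id"].astype(str), dtype=int,
                     name="fold")
    grouped = frame.groupby(["location_id", "host_species"], observed=True,
                            sort=True)
    for _, grp in grouped:
        ids = grp["sample_id"].astype(str).to_numpy()
        perm = rng.permutation(len(ids))
        start = int(rng.integers(k))
        for pos, idx in enumerate(perm):
            fold[ids[idx]] = (start + pos) % k + 1
    return fold


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC: (concordant + 0.5 ties) / (n1 * n0).

    Returns NaN when either class is empty (undefined).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    pos = labels > 0
    n1 = int(pos.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def signed_r2(obs: np.ndarray, pred: np.ndarray) -> float:
    """Signed squared Pearson correlation, sign(rho) * rho^2.

    Admits negative values (anti-predictive models score below zero);
    returns 0 when either vector is constant and NaN for < 3 pairs.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("obs and pred must have equal length")
    if obs.size < 3:
        return float("nan")
    if np.std(obs) == 0 or np.std(pred) == 0:
        return 0.0
    rho = float(np.corrcoef(obs, pred)[0, 1])
    return float(np.sign(rho) * rho**2)


@dataclass
class CvResult:
    """Pooled held-out predictive metrics for one model.

    Per-species AUC (occurrence) and signed R^2 (abundance conditional on
    presence) are computed on predictions pooled across folds; undefined
    metrics (single-class labels, < 3 present held-out cells) are NaN and
    excluded from means.
    """

    model: str
    otu_ids: list[str]
    auc: np.ndarray
    r2: np.ndarray
    fold_key: str
    n_undefined_auc: int = 0
    n_undefined_r2: int = 0
    never_present: list[str] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        vals = self.auc[~np.isnan(self.auc)]
        return float(vals.mean()) if vals.size else float("nan")

    @property
    def mean_r2(self) -> float:
        vals = self.r2[~np.isnan(self.r2)]
        return float(vals.mean()) if vals.size else float("nan")


def _fold_key(folds: pd.Series) -> str:
    h = hashlib.sha256()
    for sid, f in folds.sort_index().items():
        h.update(f"{sid}:{f};".encode())
    return h.hexdigest()[:16]


def cross_validate(
    ds: CommunityDataset,
    spec: ModelSpec,
    cfg: McmcConfig,
    folds: pd.Series,
    parts: tuple[str, ...] = ("pa", "abund"),
) -> CvResult:
    """Stratified k-fold cross-validation of one hurdle model.

    Each fold is refitted on the remaining folds and the held-out samples
    are predicted conditioning on the location posterior random effects
    (every location appears in every training set under the stratified fold
    design). Predictions are pooled across folds before computing per-OTU
    metrics.
    """
    sample_ids = ds.table.sample_ids
    missing = [s for s in sample_ids if s not in folds.index]
    if missing:
        raise ValueError(f"fold assignment missing sample(s): {missing[:3]}")
    n, J = ds.table.counts.shape
    pred_occ = np.full((n, J), np.nan)
    pred_logab = np.full((n, J), np.nan)
    never_present: set[str] = set()

    fold_of = folds.loc[sample_ids].to_numpy()
    for f in np.unique(fold_of):
        test_mask = fold_of == f
        train_ids = [s for s, m in zip(sample_ids, test_mask) if not m]
        test_ids = [s for s, m in zip(sample_ids, test_mask) if m]
        train_ds = ds.select_samples(train_ids)
        test_frame = ds.select_samples(test_ids).samples
        absent_in_train = (train_ds.table.counts > 0).sum(axis=0) == 0
        never_present.update(
            o for o, a in zip(ds.table.otu_ids, absent_in_train) if a
        )
        fit = fit_hurdle(train_ds, spec, cfg, parts=parts)
        rows = np.flatnonzero(test_mask)
        if "pa" in parts:
            occ = predict_occurrence(fit, test_frame, use_location_effect=True)
            pred_occ[rows] = occ.mean(axis=0)
        if "abund" in parts:
            ab = predict_abundance(fit, test_frame, use_location_effect=True)
            pred_logab[rows] = ab.mean(axis=0)

    presence = ds.table.counts > 0
    auc_vals = np.full(J, np.nan)
    r2_vals = np.full(J, np.nan)
    if "pa" in parts:
        for j in range(J):
            auc_vals[j] = auc(presence[:, j].astype(int), pred_occ[:, j])
    if "abund" in parts:
        logy = np.log(np.maximum(ds.table.counts, 1))
        for j in range(J):
            m = presence[:, j]
            if m.sum() >= 3:
                r2_vals[j] = signed_r2(logy[m, j], pred_logab[m, j])
    return CvResult(
        model=spec.name,
        otu_ids=list(ds.table.otu_ids),
        auc=auc_vals,
        r2=r2_vals,
        fold_key=_fold_key(folds),
        n_undefined_auc=int(np.isnan(auc_vals).sum()) if "pa" in parts else J,
        n_undefined_r2=int(np.isnan(r2_vals).sum()) if "abund" in parts else J,
        never_present=sorted(never_present),
    )


def improvement_proportion(base: CvResult, focal: CvResult,
                           metric: str = "auc") -> float:
    """Proportion of species with strictly higher held-out metric in ``focal``.

    Ties count as no improvement; species undefined under either model are
    excluded.
    """
    if base.fold_key != focal.fold_key:
        raise ValueError("cross-validation results use different folds")
    a = getattr(base, metric)
    b = getattr(focal, metric)
    ok = ~(np.isnan(a) | np.isnan(b))
    if not ok.any():
        return float("nan")
    return float(np.mean(b[ok] > a[ok]))


def compare_models(
    scores: dict[str, ModelScore],
    cvs: dict[str, CvResult] | None = None,
    metric: str = "auc",
) -> dict:
    """Model-selection table over the nested models m1 (subset of) m2 (subset of) m3.

    The WAIC winner is the lowest-WAIC model, with ties (within 1e-6)
    resolved to the simpler model. When cross-validation results are given,
    per-criterion winners for mean predictive power and pairwise improvement
    proportions are reported too. Specialization is declared supported when
    m2 beats m1 on every available criterion (lower WAIC; higher mean
    predictive power; improvement proportion > 0.5), and changing
    specialization when m3 likewise beats m2.
    """
    order = [m for m in ("m1", "m2", "m3") if m in scores]
    if len(order) < 2:
        raise ValueError("need at least two models to compare")
    if cvs is not None:
        units = {m: len(cvs[m].otu_ids) for m in cvs}
        if len(set(units.values())) > 1:
            raise ValueError("cross-validation results cover different unit counts")

    waic_vals = {m: scores[m].waic for m in order}
    best = order[0]
    for m in order[1:]:
        if waic_vals[m] < waic_vals[best] - WAIC_TIE_TOL:
            best = m

    out: dict = {
        "models": order,
        "waic": waic_vals,
        "best_by_waic": best,
    }

    def beats(simpler: str, richer: str) -> bool:
        if richer not in order or simpler not in order:
            return False
        ok = waic_vals[richer] < waic_vals[simpler] - WAIC_TIE_TOL
        if cvs is not None and simpler in cvs and richer in cvs:
            mean_s = getattr(cvs[simpler], f"mean_{metric}")
            mean_r = getattr(cvs[richer], f"mean_{metric}")
            prop = improvement_proportion(cvs[simpler], cvs[richer], metric)
            out.setdefault("mean_predictive", {})[simpler] = mean_s
            out["mean_predictive"][richer] = mean_r
            out.setdefault("improvement_proportion", {})[
                f"{richer}>{simpler}"] = prop
            ok = ok and (mean_r > mean_s) and (prop > 0.5)
        return ok

    out["specialization_supported"] = beats("m1", "m2")
    out["changing_specialization_supported"] = beats("m2", "m3")
    if cvs is not None:
        means = {m: getattr(cvs[m], f"mean_{metric}") for m in order if m in cvs}
        if means:
            best_mean = max(means, key=lambda m: means[m])
            out["best_by_mean_predictive"] = best_mean
    return out


def waic_from_fit(fit: HurdleFit, ds: CommunityDataset,
                  normalization: str = "sum") -> dict[str, ModelScore]:
    """WAIC of each hurdle part of a fit, scored on its own unit set."""
    ll = pointwise_loglik(fit, ds)
    return {part: waic(arr, normalization) for part, arr in ll.items()}
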