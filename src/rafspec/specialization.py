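"""Host-specialization quantification at network and species level.

Network level: the explained variance of each species is partitioned among
covariate groups — host (including host x elevation), elevation (linear +
squared), soil (pH, water content, active-layer depth, vegetation cover),
sequencing depth — and the location random effect. The community mean of the
host fraction is the network-level specialization headline; comparing it
between guilds contrasts, e.g., endophytic against mycorrhizal fungi.

Species level: specialization is scored as AUC(m2) - AUC(m1), the gain in
held-out occurrence predictive power from adding the host term, reported
alongside per-host prevalences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import CommunityDataset, GuildMap
from .evaluate import CvResult
from .jsdm import HurdleFit

#: Covariate groups entering the partition (plus the location random effect).
PARTITION_GROUPS = ("host", "elevation", "soil", "depth")


@dataclass
class VariancePartition:
    """Per-species fractions of explained variance by covariate group."""

    part: str                      # "pa" or "abund"
    fractions: pd.DataFrame        # (OTUs x groups + "random"), rows sum to 1
    community_mean: pd.Series

    @property
    def groups(self) -> list[str]:
        return list(self.fractions.columns)


def variance_partition(fit: HurdleFit, part: str = "pa") -> VariancePartition:
    """Partition explained variance among covariate groups and the random effect.

    Per posterior draw and species, each group's linear score f_g = X_g b_g
    is computed over the fitting samples; group g is attributed
    Var(f_g) + sum_{h != g} cov(f_g, f_h), i.e. covariances are split
    equally between the two groups involved. The location random-effect
    variance is ||lambda_j||^2 (unit-variance factors). Negative
    attributions are clipped to zero and fractions renormalized to sum to 1.
    The intercept contributes no variance across samples and is excluded.
    """
    draws = getattr(fit, part, None)
    if draws is None:
        raise ValueError(f"fit has no {part!r} part")
    X = fit.design.X
    present_groups = [g for g in PARTITION_GROUPS
                      if fit.design.group_columns(g)]
    n = X.shape[0]
    D, J, _ = draws.beta.shape
    G = len(present_groups)

    # group scores per draw/species: T[g] has shape (D, n, J)
    scores = np.empty((G, D, n, J))
    for gi, g in enumerate(present_groups):
        idx = fit.design.group_columns(g)
        scores[gi] = np.einsum("ni,dji->dnj", X[:, idx], draws.beta[:, :, idx])
    scores -= scores.mean(axis=2, keepdims=True)
    # pairwise sample covariances between group scores, (G, G, D, J)
    denom = max(n - 1, 1)
    cov = np.einsum("gdnj,hdnj->ghdj", scores, scores) / denom
    attribution = cov.sum(axis=1)                     # row sums, (G, D, J)
    attribution = np.clip(attribution, 0.0, None)
    random_var = np.sum(draws.loadings**2, axis=-1)   # (D, J)
    total = attribution.sum(axis=0) + random_var
    total = np.where(total <= 0, 1.0, total)
    frac_groups = attribution / total                 # (G, D, J)
    frac_random = random_var / total
    cols = list(present_groups) + ["random"]
    mean_frac = np.concatenate(
        [frac_groups.mean(axis=1), frac_random.mean(axis=0)[None]], axis=0
    ).T                                               # (J, G+1)
    fractions = pd.DataFrame(mean_frac, index=fit.otu_ids, columns=cols)
    # renormalize residual numerical drift
    fractions = fractions.div(fractions.sum(axis=1), axis=0)
    return VariancePartition(part, fractions, fractions.mean(axis=0))


def species_specialization(
    cv_m1: CvResult,
    cv_m2: CvResult,
    guilds: GuildMap | None = None,
) -> pd.DataFrame:
    """Per-species specialization scores AUC(m2) - AUC(m1), ranked descending.

    Both cross-validation results must come from the same folds and data.
    Scores are undefined (NaN) where either AUC is undefined.
    """
    if cv_m1.fold_key != cv_m2.fold_key:
        raise ValueError("cross-validation results use different fold assignments")
    if cv_m1.otu_ids != cv_m2.otu_ids:
        raise ValueError("cross-validation results cover different OTU sets")
    df = pd.DataFrame({
        "otu_id": cv_m1.otu_ids,
        "auc_m1": cv_m1.auc,
        "auc_m2": cv_m2.auc,
    })
    df["score"] = df["auc_m2"] - df["auc_m1"]
    if guilds is not None:
        df["guild"] = [guilds[o] for o in df["otu_id"]]
    df = df.sort_values("score", ascending=False, na_position="last")
    df["rank"] = np.where(df["score"].notna(),
                          np.arange(1, len(df) + 1), np.nan)
    return df.reset_index(drop=True)


def host_prevalence_table(ds: CommunityDataset,
                          otus: list[str] | None = None) -> pd.DataFrame:
    """Per-host prevalence of each OTU: fraction of that host's individuals
    in which the OTU was found. Column order follows the host level order."""
    otus = list(otus) if otus is not None else list(ds.table.otu_ids)
    unknown = [o for o in otus if o not in ds.table.otu_ids]
    if unknown:
        raise ValueError(f"unknown OTU id(s): {unknown[:3]}")
    hosts = [str(h) for h in ds.samples["host_species"].cat.categories
             if h in set(ds.samples["host_species"].astype(str))]
    presence = pd.DataFrame(
        (ds.table.counts > 0).astype(float),
        index=ds.samples["host_species"].astype(str).to_numpy(),
        columns=ds.table.otu_ids,
    )
    out = pd.DataFrame(index=otus, columns=hosts, dtype=float)
    for h in hosts:
        out[h] = presence.loc[h, otus].mean(axis=0).to_numpy()
    return out


def network_specialization_summary(
    vp: VariancePartition, guilds: GuildMap
) -> pd.DataFrame:
    """Mean host-group variance fraction per guild, with OTU counts."""
    labels = [guilds[o] for o in vp.fractions.index]
    df = vp.fractions.copy()
    df["guild"] = labels
    host_col = "host" if "host" in vp.fractions.columns else None
    rows = []
    for guild in ("mycorrhizal", "endophytic", "unclassified"):
        sub = df[df["guild"] == guild]
        rows.append({
            "guild": guild,
            "n_otus": len(sub),
            "mean_host_fraction": (float(sub[host_col].mean())
                                   if host_col and len(sub) else float("nan")),
            **{f"mean_{g}_fraction": (float(sub[g].mean()) if len(sub)
                                      else float("nan"))
               for g in vp.fractions.columns if g != host_col},
        })
    return pd.DataFrame(rows)
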