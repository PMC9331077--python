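"""Clonality-aware mutation-frequency estimation and dose contrasts.

Mutation frequency (MF) is the number of unique somatic mutations divided by
the number of duplex base pairs sequenced.  A mutation observed in more than
one duplex molecule of the same sample is a clonal expansion: it counts once
toward MF, while the clone-inclusive MF sums molecule multiplicities.

Dose contrasts come from a binomial GLM with logit link on per-animal
aggregates (mutations out of duplex bp), dose as a factor, Wald tests of each
exposed dose against control, and Holm-Sidak multiplicity correction applied
within each stratum independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .panel import PanelTarget
from .records import DepthTable, MutationRecord, SampleMeta

logger = logging.getLogger(__name__)


@dataclass
class MfEstimate:
    scope: str
    n_mutations: int
    n_mutations_clonal: int
    duplex_bp: int
    mf: float
    mf_clonal: float
    sd: float | None = None  # SD of per-sample MFs, for multi-sample scopes


@dataclass
class DoseContrast:
    stratum: str
    dose_a: float
    dose_b: float
    estimate: float  # log-odds difference
    wald_z: float
    p_raw: float
    p_adjusted: float


def deduplicate(
    mutations: list[MutationRecord],
) -> tuple[list[MutationRecord], int]:
    """Collapse per-sample duplicate calls; return (unique records, clonal extra).

    Uniqueness key is (sample_id, chrom, pos, ref, alt).  Duplicate entries
    merge their multiplicities, so the clone-inclusive count
    ``sum(multiplicity)`` is preserved.  ``clonal_extra`` is the number of
    molecules beyond one per unique mutation.
    """
    merged: dict[tuple, MutationRecord] = {}
    total = 0
    for m in mutations:
        total += m.multiplicity
        prev = merged.get(m.key)
        if prev is None:
            merged[m.key] = MutationRecord(
                m.sample_id, m.target, m.chrom, m.pos, m.ref, m.alt,
                m.multiplicity, m.tri_context,
            )
        else:
            prev.multiplicity += m.multiplicity
    unique = list(merged.values())
    return unique, total - len(unique)


# ---- grouped MF estimation -------------------------------------------------

_GROUP_KEYS = ("cohort", "dose", "sample", "target", "region_class", "chromatin")


def _mutation_frame(
    mutations: list[MutationRecord],
    metadata: list[SampleMeta],
    panel: list[PanelTarget] | None,
) -> pd.DataFrame:
    dose_of = {m.sample_id: m.dose for m in metadata}
    df = pd.DataFrame(
        [(m.sample_id, m.target, m.multiplicity) for m in mutations],
        columns=["sample_id", "target", "multiplicity"],
    )
    df["dose"] = df["sample_id"].map(dose_of)
    if panel is not None:
        region = {t.name: t.region_class for t in panel}
        chromatin = {t.name: t.chromatin for t in panel}
        df["region_class"] = df["target"].map(region)
        df["chromatin"] = df["target"].map(chromatin)
    return df


def _depth_frame(
    depths: DepthTable, metadata: list[SampleMeta], panel: list[PanelTarget] | None
) -> pd.DataFrame:
    df = depths.to_frame()
    dose_of = {m.sample_id: m.dose for m in metadata}
    df["dose"] = df["sample_id"].map(dose_of)
    if panel is not None:
        df["region_class"] = df["target"].map({t.name: t.region_class for t in panel})
        df["chromatin"] = df["target"].map({t.name: t.chromatin for t in panel})
    return df


def compute_mf(
    mutations: list[MutationRecord],
    depths: DepthTable,
    metadata: list[SampleMeta],
    groupby: str | list[str] = "cohort",
    panel: list[PanelTarget] | None = None,
) -> list[MfEstimate]:
    """Pooled MF per group: summed unique counts over summed duplex bp.

    ``groupby`` is one of {cohort, dose, sample, target, region_class,
    chromatin} or a list combining them (e.g. ``["dose", "region_class"]``).
    Mutations are expected deduplicated; multiplicities feed the
    clone-inclusive estimate.  For scopes pooling several samples the SD of
    per-sample MFs is reported.
    """
    keys = [groupby] if isinstance(groupby, str) else list(groupby)
    for k in keys:
        if k not in _GROUP_KEYS:
            raise ValueError(f"unknown groupby key {k!r}")
    if ("region_class" in keys or "chromatin" in keys) and panel is None:
        raise ValueError("region_class/chromatin grouping requires the panel")

    mut = _mutation_frame(mutations, metadata, panel)
    dep = _depth_frame(depths, metadata, panel)
    mut["sample"] = mut["sample_id"]
    dep["sample"] = dep["sample_id"]
    if "cohort" in keys:
        mut["cohort"] = "cohort"
        dep["cohort"] = "cohort"

    grouped_bp = dep.groupby(keys)["duplex_bp"].sum()
    estimates = []
    for group_vals, bp in grouped_bp.items():
        group_vals = group_vals if isinstance(group_vals, tuple) else (group_vals,)
        label = "/".join(f"{v:g}" if isinstance(v, float) else str(v) for v in group_vals)
        if bp <= 0:
            raise ValueError(f"group {label}: zero duplex bp")
        mask = np.ones(len(mut), dtype=bool)
        for k, v in zip(keys, group_vals):
            mask &= (mut[k] == v).to_numpy()
        sub = mut[mask]
        n_unique = len(sub)
        n_clonal = int(sub["multiplicity"].sum())
        # per-sample SD when the scope pools >1 sample
        sd = None
        dep_mask = np.ones(len(dep), dtype=bool)
        for k, v in zip(keys, group_vals):
            dep_mask &= (dep[k] == v).to_numpy()
        samples = dep[dep_mask].groupby("sample_id")["duplex_bp"].sum()
        if len(samples) > 1:
            per_sample_counts = sub.groupby("sample_id").size().reindex(samples.index, fill_value=0)
            sd = float((per_sample_counts / samples).std(ddof=1))
        estimates.append(
            MfEstimate(
                scope=label,
                n_mutations=n_unique,
                n_mutations_clonal=n_clonal,
                duplex_bp=int(bp),
                mf=n_unique / bp,
                mf_clonal=n_clonal / bp,
                sd=sd,
            )
        )
    return estimates


def estimates_to_frame(estimates: list[MfEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in estimates])


def fold_change(mf_dose: float, mf_control: float) -> float:
    """MF ratio relative to control."""
    if mf_control <= 0:
        raise ValueError("control MF must be positive")
    return mf_dose / mf_control


def percent_reduction(mf_reference: float, mf_reduced: float) -> float:
    """Percent decrease of ``mf_reduced`` relative to ``mf_reference``."""
    if mf_reference <= 0:
        raise ValueError("reference MF must be positive")
    return 100.0 * (mf_reference - mf_reduced) / mf_reference


# ---- dose contrasts --------------------------------------------------------


def holm_sidak(p_values) -> np.ndarray:
    """Step-down Holm-Sidak adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm-sidak")[1]


def per_animal_counts(
    mutations: list[MutationRecord],
    depths: DepthTable,
    metadata: list[SampleMeta],
    panel: list[PanelTarget] | None = None,
    stratify_by: str | None = None,
) -> pd.DataFrame:
    """Per-animal (optionally per-stratum) unique-mutation counts and depths."""
    keys = ["sample"] if stratify_by is None else ["sample", stratify_by]
    mut = _mutation_frame(mutations, metadata, panel)
    dep = _depth_frame(depths, metadata, panel)
    mut["sample"] = mut["sample_id"]
    dep["sample"] = dep["sample_id"]
    bp = dep.groupby(keys)["duplex_bp"].sum()
    n = mut.groupby(keys).size().reindex(bp.index, fill_value=0)
    out = pd.DataFrame({"n_mutations": n, "duplex_bp": bp}).reset_index()
    out = out.rename(columns={"sample": "sample_id"})
    out["dose"] = out["sample_id"].map({m.sample_id: m.dose for m in metadata})
    if stratify_by is None:
        out["stratum"] = "all"
    else:
        out = out.rename(columns={stratify_by: "stratum"})
    return out


def _fit_binomial_glm(df: pd.DataFrame, factors: list[str]):
    """Binomial GLM of (mutations, bp - mutations) on categorical factors.

    Treatment coding with the first (sorted) level as reference; coefficient
    columns are named ``C(<factor>)[T.<level>]``.
    """
    endog = np.column_stack(
        [df["n_mutations"].to_numpy(float), (df["duplex_bp"] - df["n_mutations"]).to_numpy(float)]
    )
    cols = {"Intercept": np.ones(len(df))}
    for factor in factors:
        levels = sorted(df[factor].unique())
        for lev in levels[1:]:
            cols[f"C({factor})[T.{lev}]"] = (df[factor] == lev).to_numpy(float)
    exog = pd.DataFrame(cols, index=df.index)
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    return model.fit()


def fit_binomial_dose_model(counts: pd.DataFrame) -> list[DoseContrast]:
    """Wald contrasts of each exposed dose vs control, per stratum.

    ``counts`` must have columns sample_id, dose, stratum, n_mutations,
    duplex_bp (one row per animal x stratum; see :func:`per_animal_counts`).
    Fits, within each stratum, a logit-link binomial GLM of mutations out of
    duplex bp on dose as a factor; the Holm-Sidak correction is applied to
    the dose contrasts within each stratum independently.  Groups with zero
    mutations get a 0.5-count continuity correction (logged).
    """
    doses = sorted(counts["dose"].unique())
    if len(doses) < 2:
        raise ValueError("need at least two dose groups")
    control = doses[0]
    results: list[DoseContrast] = []
    for stratum, sub in counts.groupby("stratum"):
        sub = sub.copy()
        sub["n_mutations"] = sub["n_mutations"].astype(float)
        sub["duplex_bp"] = sub["duplex_bp"].astype(float)
        zero_groups = [
            d for d, g in sub.groupby("dose") if g["n_mutations"].sum() == 0
        ]
        if zero_groups:
            logger.warning(
                "stratum %s: zero-mutation dose groups %s; applying 0.5-count "
                "continuity correction", stratum, zero_groups,
            )
            zmask = sub["dose"].isin(zero_groups)
            sub.loc[zmask, "n_mutations"] = sub.loc[zmask, "n_mutations"] + 0.5
            sub.loc[zmask, "duplex_bp"] = sub.loc[zmask, "duplex_bp"] + 1
        res = _fit_binomial_glm(sub, ["dose"])
        contrasts = []
        for d in doses[1:]:
            name = f"C(dose)[T.{d}]"
            if name not in res.params.index:
                continue
            est = float(res.params[name])
            se = float(res.bse[name])
            z = est / se if se > 0 else 0.0
            p = float(2.0 * norm.sf(abs(z)))
            contrasts.append((d, est, z, p))
        adj = holm_sidak([c[3] for c in contrasts])
        for (d, est, z, p), pa in zip(contrasts, adj):
            results.append(
                DoseContrast(
                    stratum=str(stratum), dose_a=float(d), dose_b=float(control),
                    estimate=est, wald_z=z, p_raw=p, p_adjusted=float(pa),
                )
            )
    return results


def gc_group_test(
    counts: pd.DataFrame,
    panel: list[PanelTarget],
    gc_threshold: float | None = None,
) -> tuple[float, float]:
    """Type II Wald chi-square for a binary GC-content grouping of targets.

    ``counts`` must have per-animal x per-target rows (columns sample_id,
    dose, target -> stratum column named 'stratum', n_mutations, duplex_bp).
    Targets are split at ``gc_threshold`` (default: the panel mean GC
    fraction) into low/high groups; a binomial GLM with dose and GC-group
    factors is fitted and the Wald chi-square for the GC-group term (given
    dose is in the model, i.e. Type II) is returned with its p-value.
    """
    gc_of = {t.name: t.gc_fraction for t in panel}
    if gc_threshold is None:
        gc_threshold = float(np.mean(list(gc_of.values())))
    df = counts.copy()
    df["gc_group"] = df["stratum"].map(
        lambda t: "high" if gc_of[t] > gc_threshold else "low"
    )
    if df["gc_group"].nunique() < 2:
        raise ValueError("all targets fall in one GC group at this threshold")
    res = _fit_binomial_glm(df, ["dose", "gc_group"])
    term = "C(gc_group)[T.low]"
    wt = res.wald_test(f"{term} = 0", scalar=True)
    return float(wt.statistic), float(wt.pvalue)
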