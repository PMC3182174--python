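"""End-to-end orchestration of the three proteomics experiments.

* Experiment 1 — label-free spectral counting at a single age: count
  correction, quantifiability filtering, Kruskal-Wallis screening, pairwise
  exact Mann-Whitney contrasts, permutation verification of the cutoff,
  effect classification and sample-structure summaries.
* Experiment 2 — labeled age contrasts (9 d vs 11 d) within each group,
  normalized to the group's own day-7 reference, with z-transformation and
  the dual missing-value replacement rule.
* Experiment 3 — the bridged full factorial relative to the common day-7
  low-genotype control reference, analyzed with a per-protein mixed-model
  ANOVA and Benjamini-Hochberg FDR.
* Metabolites — two-way factorial ANOVA on log2 lipid/glucose with a Levene
  check and Dixon outlier screening.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import factorial_models as fm
from . import label_quant as lq
from . import multivariate as mv
from . import nonparam_stats as nps
from . import spectral_quant as sq
from .design import Design
from .errors import ConfigurationError
from .label_quant import RatioExperiment
from .spectral_quant import CountMatrix
from .synthetic_data import SimConfig

CONTRASTS = [("CL", "KL"), ("CH", "KH"), ("CL", "CH")]


def config_hash(cfg: dict) -> str:
    return hashlib.sha1(yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class Experiment1Report:
    per_protein: pd.DataFrame
    summary: dict
    cutoff: nps.CutoffVerification
    cluster: mv.ClusterResult | None = None
    pca: mv.PcaResult | None = None
    filter_report: dict = field(default_factory=dict)


def run_experiment1(
    m: CountMatrix,
    d: Design,
    alpha: float = 0.1,
    iters: int = 1000,
    seed: int | None = 0,
    same_group_required: bool = False,
    with_multivariate: bool = True,
) -> Experiment1Report:
    """Spectral-count differential-abundance analysis across the four groups."""
    corrected = sq.correct_counts(m)
    filt = sq.quantifiability_filter(m, d, same_group_required=same_group_required)
    report = sq.protein_count_report(m, filt)
    quant = corrected.values.loc[filt.passed[filt.passed].index]
    labels = d.group_labels(list(quant.columns))
    kw_p = nps.battery_pvalues(quant, labels, battery="kw")
    rows = []
    for prot in quant.index:
        row = {"protein": prot, "p_kw": float(kw_p.loc[prot])}
        pvals = {}
        for g1, g2 in CONTRASTS:
            x = quant.loc[prot, d.samples_in_group(g1)].to_numpy()
            y = quant.loc[prot, d.samples_in_group(g2)].to_numpy()
            res = nps.exact_mwu(x, y, rng=seed)
            key = f"{g1}/{g2}"
            pvals[key] = res.p_two_sided
            row[f"p_{g1}_{g2}".lower()] = res.p_two_sided
            row[f"rs_{g1}".lower() + ("_b" if (g1, g2) == ("CL", "CH") else "")] = res.rank_sum_1
            row[f"rs_{g2}".lower() + ("_b" if (g1, g2) == ("CL", "CH") else "")] = res.rank_sum_2
        if row["p_kw"] <= alpha:
            row["effect"] = nps.classify_effect(
                pvals["CL/KL"], pvals["CH/KH"], pvals["CL/CH"], alpha=alpha
            )
        else:
            row["effect"] = "none"
        rows.append(row)
    per_protein = pd.DataFrame(rows).set_index("protein")
    cutoff = nps.verify_cutoff(quant, d, alpha=alpha, iters=iters, seed=seed, battery="kw")
    counts = per_protein["effect"].value_counts().to_dict()
    summary = {
        "n_quantifiable": report["n_quantifiable"],
        "n_regulated": int((per_protein["effect"] != "none").sum()),
        "effect_counts": {k: int(v) for k, v in counts.items()},
        "cutoff_verified": bool(cutoff.verified),
        "empirical_fpr": cutoff.empirical_fpr,
    }
    cluster = pca_res = None
    if with_multivariate:
        logt = sq.log2_abundance(corrected).values.loc[quant.index]
        cluster = mv.hca(logt)
        pca_res = mv.pca(quant)
    return Experiment1Report(per_protein, summary, cutoff, cluster, pca_res, report)


@dataclass
class Experiment2Report:
    per_protein: pd.DataFrame  # long: group, protein, p, retained, reason
    summary: dict


def run_experiment2(
    exp: RatioExperiment,
    d: Design,
    alpha: float = 0.1,
    min_present: int = 3,
    weights: str = "peptides",
    seed: int | None = 0,
    age_pair: tuple[int, int] | None = None,
) -> Experiment2Report:
    """Within-group age contrasts on label ratios, own day-7 reference.

    For each group the comparisons internal to that group are bridged to the
    group's lowest-age samples, values are z-transformed per protein over
    the contrast samples, eligibility requires presence in ``min_present``
    replicates of at least one age cell, and the 9 d vs 11 d difference is
    tested with the dual +/-0.5 replacement Mann-Whitney rule.
    """
    ages = sorted(d.frame["age"].unique())
    if len(ages) < 3 and age_pair is None:
        raise ConfigurationError("age contrast needs three ages or an explicit age_pair")
    a9, a11 = age_pair if age_pair is not None else (ages[1], ages[2])
    rows = []
    groups = sorted(d.frame["group"].unique())
    for g in groups:
        member_set = set(d.frame.index[d.frame["group"] == g])
        comps = [c for c in exp.comparisons if set(c.members) <= member_set]
        if not comps:
            continue
        ids = {c.id for c in comps}
        sub = RatioExperiment(
            comparisons=comps,
            ratios=exp.ratios[exp.ratios["comparison"].isin(ids)],
            reference_samples=d.samples_in_group(g, ages[0]),
            reference_label=f"{g}{ages[0]}",
        )
        bridged = lq.bridge_to_reference(sub, weights=weights)
        s9 = [s for s in d.samples_in_group(g, a9) if s in bridged.values.columns]
        s11 = [s for s in d.samples_in_group(g, a11) if s in bridged.values.columns]
        contrast_vals = bridged.values[s9 + s11]
        z, constant = lq.z_transform(contrast_vals)
        elig = lq.presence_filter(contrast_vals, d, min_present=min_present,
                                  groups=[(g, a9), (g, a11)])
        for prot in z.index:
            if constant.loc[prot]:
                rows.append({"group": g, "protein": prot, "p": np.nan,
                             "retained": False, "reason": "constant"})
                continue
            if not elig.loc[prot].any():
                rows.append({"group": g, "protein": prot, "p": np.nan,
                             "retained": False, "reason": "insufficient presence"})
                continue
            res = nps.dual_imputation_test(
                z.loc[prot, s9].to_numpy(),
                z.loc[prot, s11].to_numpy(),
                alpha=alpha,
                min_present=min_present,
                rng=seed,
            )
            rows.append(
                {
                    "group": g,
                    "protein": prot,
                    "p": res.p_final,
                    "retained": bool(res.retained and res.p_final <= alpha),
                    "reason": res.reason,
                }
            )
    per_protein = pd.DataFrame(rows)
    summary = {
        g: int(per_protein.query("group == @g")["retained"].sum()) for g in groups
    }
    return Experiment2Report(per_protein, summary)


@dataclass
class Experiment3Report:
    effects: pd.DataFrame  # long per protein x effect with q
    summary: dict
    values: pd.DataFrame


def run_experiment3(
    exp: RatioExperiment,
    d: Design,
    fdr_alpha: float = 0.05,
    min_present: int = 4,
    weights: str = "peptides",
    ss_type: int = 2,
) -> Experiment3Report:
    """Bridged full-factorial mixed ANOVA with per-effect FDR.

    Only proteins present in all ``min_present`` replicates of at least one
    group x age cell enter the model, mirroring the stricter completeness
    rule of the factorial analysis.
    """
    bridged = lq.bridge_to_reference(exp, weights=weights)
    cells = lq.presence_filter(bridged.values, d, min_present=min_present)
    eligible = cells.any(axis=1)
    values = bridged.values.loc[eligible[eligible].index]
    effects = fm.mixed_anova_all(values, d, ss_type=ss_type, fdr_alpha=fdr_alpha)
    if effects.empty:
        return Experiment3Report(effects, {"n_significant_proteins": 0}, values)
    sig = effects[effects["significant"]]
    summary = {
        "n_proteins_tested": int(values.shape[0]),
        "n_significant_proteins": int(sig["protein"].nunique()),
        "per_effect": sig.groupby("effect")["protein"].nunique().to_dict(),
    }
    return Experiment3Report(effects, summary, values)


@dataclass
class MetaboliteReport:
    anova: fm.AnovaResult
    levene: tuple[float, float]
    dixon: fm.DixonResult
    n_excluded: int
    data: pd.DataFrame


def run_metabolites(
    df: pd.DataFrame,
    log2_input: bool = False,
    ss_type: int = 2,
    outlier_alpha: float = 0.05,
) -> MetaboliteReport:
    """Two-way factorial analysis of a per-bee metabolite table.

    ``df`` needs columns ``genotype``, ``treatment``, ``value``.  Raw-scale
    input (``log2_input=True``) is log2-transformed first.  A Dixon ratio
    test screens for one extreme value (excluded when rejected, n <= 30),
    then Levene's check and the factorial ANOVA run on the remaining data.
    """
    data = df.copy()
    if log2_input:
        if (data["value"] <= 0).any():
            raise ConfigurationError("value: log2 transform requires positive values")
        data["value"] = np.log2(data["value"])
    n = len(data)
    if 3 <= n <= 30:
        dixon = fm.dixon_outlier(data["value"].to_numpy(), alpha=outlier_alpha)
    else:
        dixon = fm.DixonResult(0.0, np.nan, "high", False, "not-applicable", np.nan, True)
    n_excluded = 0
    if dixon.rejected:
        idx = (data["value"] - dixon.suspect).abs().idxmin()
        data = data.drop(index=idx)
        n_excluded = 1
    group = data["genotype"].astype(str) + data["treatment"].astype(str)
    levene = fm.levene_check(data["value"], group)
    anova = fm.two_way_anova(data["value"], data["genotype"], data["treatment"], ss_type=ss_type)
    return MetaboliteReport(anova, levene, dixon, n_excluded, data)


def simulate_all(cfg: SimConfig):
    """Convenience bundle: count matrix, ratio experiment and metabolites."""
    from . import synthetic_data as sd

    cm, d1, t1 = sd.simulate_count_matrix(cfg)
    exp, d2, t2 = sd.simulate_ratio_experiment(cfg)
    met = sd.simulate_metabolites(cfg)
    return (cm, d1, t1), (exp, d2, t2), met
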