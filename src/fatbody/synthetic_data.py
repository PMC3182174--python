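"""Synthetic data with planted genotype / treatment / age effects.

Every downstream stage of the pipeline is testable without external data
because the generators here emulate the statistical structure the analyses
assume:

* overdispersed (gamma-Poisson, i.e. negative-binomial) spectral counts for
  4 groups x 5 replicates, with a fraction of proteins carrying genotype
  and/or treatment shifts on the log2 scale and distinct-peptide counts that
  grow monotonically with expected abundance so the quantifiability filters
  have realistic bite;
* a full-factorial group x age labeled design observed only through
  partially overlapping duplex/triplex comparisons that share a day-7
  low-genotype control reference, with multiplicative lognormal measurement
  noise and missing-at-random proteins per comparison;
* per-bee metabolite values on the log2 scale with additive genotype and
  treatment shifts.

All generation is a pure function of :class:`SimConfig`: a single integer
seed drives one root ``SeedSequence`` whose spawned children give each
generator an independent stream, so the same seed yields byte-identical
outputs regardless of which generators are invoked.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import GROUPS, Design, split_group
from .errors import ConfigurationError
from .label_quant import Comparison, RatioExperiment, PEPTIDE_COLUMNS, RATIO_COLUMNS
from .spectral_quant import CountMatrix

__all__ = [
    "SimConfig",
    "Truth",
    "simulate_count_matrix",
    "simulate_ratio_experiment",
    "simulate_metabolites",
    "default_bridging_layout",
    "expand_to_peptides",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Proportions are fractions of proteins carrying each planted effect;
    ``effect_log2fc`` is the absolute planted log2 fold change (random sign
    per protein); ``count_mean`` / ``dispersion`` parameterize the
    negative-binomial count model (variance = mu(1 + dispersion * mu));
    ``ratio_sd`` is the SD of the log2-ratio measurement noise (and of the
    log2-scale metabolite noise); ``missing_rate`` drops a protein from a
    labeled comparison completely at random.
    """

    seed: int
    n_proteins: int = 300
    groups: tuple[str, ...] = GROUPS
    n_replicates: int = 5
    ages: tuple[int, ...] = (7, 9, 11)
    frac_genotype_effect: float = 0.1
    frac_treatment_effect: float = 0.1
    frac_age_effect: float = 0.1
    effect_log2fc: float = 1.0
    count_mean: float = 50.0
    dispersion: float = 0.05
    ratio_sd: float = 0.3
    missing_rate: float = 0.1

    def __post_init__(self) -> None:
        if int(self.seed) != self.seed:
            raise ConfigurationError("seed: must be an integer")
        if self.n_proteins < 1:
            raise ConfigurationError(f"n_proteins: must be positive (got {self.n_proteins})")
        if self.n_replicates < 2:
            raise ConfigurationError(f"n_replicates: must be >= 2 (got {self.n_replicates})")
        for name in ("frac_genotype_effect", "frac_treatment_effect", "frac_age_effect", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}: proportion outside [0, 1] (got {v})")
        if self.effect_log2fc < 0:
            raise ConfigurationError(f"effect_log2fc: must be >= 0 (got {self.effect_log2fc})")
        for name in ("count_mean",):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name}: must be positive (got {getattr(self, name)})")
        for name in ("dispersion", "ratio_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: must be >= 0 (got {getattr(self, name)})")
        for g in self.groups:
            split_group(g)

    def _streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(3)
        names = ("counts", "ratios", "metabolites")
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class Truth:
    """Planted ground truth.

    ``flags`` is indexed by protein with boolean effect flags and the signed
    log2 shifts (``genotype_shift`` applies to the H genotype,
    ``treatment_shift`` to the K treatment, ``age_slope`` per age step).
    ``sample_values`` (ratio experiments only) holds each sample's true log2
    abundance relative to the reference baseline.
    """

    flags: pd.DataFrame
    sample_values: pd.DataFrame | None = None


def _protein_ids(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(1, n + 1)]


def _plant_effects(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_proteins
    flags = pd.DataFrame(index=_protein_ids(n))
    for name, frac in (
        ("genotype", cfg.frac_genotype_effect),
        ("treatment", cfg.frac_treatment_effect),
        ("age", cfg.frac_age_effect),
    ):
        has = rng.random(n) < frac
        sign = rng.choice([-1.0, 1.0], size=n)
        flags[f"has_{name}_effect"] = has
        shift = np.where(has, sign * cfg.effect_log2fc, 0.0)
        col = "age_slope" if name == "age" else f"{name}_shift"
        flags[col] = shift
    return flags


def _true_log2_offset(flags: pd.DataFrame, group: str, age_index: int) -> np.ndarray:
    treatment, genotype = split_group(group)
    off = np.zeros(len(flags))
    if genotype == "H":
        off = off + flags["genotype_shift"].to_numpy()
    if treatment == "K":
        off = off + flags["treatment_shift"].to_numpy()
    off = off + flags["age_slope"].to_numpy() * age_index
    return off


def simulate_count_matrix(cfg: SimConfig) -> tuple[CountMatrix, Design, Truth]:
    """Overdispersed spectral counts for a single-age multi-group design.

    Counts follow a gamma-Poisson mixture with per-protein baseline
    abundances lognormal around ``count_mean`` and group means shifted by
    the planted log2 effects.  Distinct-peptide counts are drawn from a
    per-protein peptide pool as a saturating, monotone function of the
    realized count (a protein observed at all has at least one peptide).
    """
    rng = cfg._streams()["counts"]
    flags = _plant_effects(cfg, rng)
    proteins = list(flags.index)
    design = Design.from_groups(cfg.groups, cfg.n_replicates, ages=(cfg.ages[0],))
    base_log2 = np.log2(cfg.count_mean) + rng.normal(0.0, 1.0, cfg.n_proteins)
    pool = 2 + rng.poisson(3.0, cfg.n_proteins)  # distinct-peptide repertoire
    counts = {}
    peptides = {}
    for sample in design.samples:
        group = design.frame.at[sample, "group"]
        mu = 2.0 ** (base_log2 + _true_log2_offset(flags, group, 0))
        if cfg.dispersion > 0:
            lam = rng.gamma(1.0 / cfg.dispersion, cfg.dispersion * mu)
        else:
            lam = mu
        c = rng.poisson(lam)
        frac = -np.expm1(-c / pool)  # 1 - exp(-count/pool), saturating
        extra = rng.binomial(pool - 1, frac)
        p = np.where(c > 0, 1 + extra, 0)
        counts[sample] = c
        peptides[sample] = p
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=proteins),
        peptides=pd.DataFrame(peptides, index=proteins),
    )
    return cm, design, Truth(flags=flags)


def default_bridging_layout(
    groups: tuple[str, ...] = GROUPS,
    ages: tuple[int, ...] = (7, 9, 11),
    n_replicates: int = 4,
    reference_group: str = "CL",
) -> list[Comparison]:
    """The duplex/triplex layout of the labeled experiments.

    Per replicate: one triplex per group spanning the three ages (lowest age
    first, serving as the within-run denominator), plus day-7 bridge runs
    that make the groups mutually comparable through the reference group's
    day-7 sample: duplexes KH/CL, CL/CH, CH/KL and triplexes KL/KH/CL,
    KH/CH/CL (reference listed last in the run but placed on the lowest
    channel here, i.e. first member).
    """
    a0 = min(ages)
    ref = reference_group
    others = [g for g in groups if g != ref]
    layout: list[Comparison] = []
    for r in range(1, n_replicates + 1):
        for g in groups:
            members = tuple(f"{g}{a}_r{r}" for a in sorted(ages))
            layout.append(Comparison(f"{g}_ages_r{r}", members))
        if len(others) == 3:
            kl, ch, kh = (f"{g}{a0}_r{r}" for g in ("KL", "CH", "KH"))
            c0 = f"{ref}{a0}_r{r}"
            layout += [
                Comparison(f"bridge_KHCL_r{r}", (c0, kh)),
                Comparison(f"bridge_CLCH_r{r}", (c0, ch)),
                Comparison(f"bridge_CHKL_r{r}", (ch, kl)),
                Comparison(f"bridge_KLKHCL_r{r}", (c0, kl, kh)),
                Comparison(f"bridge_KHCHCL_r{r}", (c0, kh, ch)),
            ]
        else:  # non-canonical groups: chain everything to the reference
            for g in others:
                layout.append(
                    Comparison(f"bridge_{g}_r{r}", (f"{ref}{a0}_r{r}", f"{g}{a0}_r{r}"))
                )
    return layout


def simulate_ratio_experiment(
    cfg: SimConfig,
    layout: list[Comparison] | None = None,
) -> tuple[RatioExperiment, Design, Truth]:
    """Labeled log2 ratios over a comparison graph with planted effects.

    Each comparison reports, per protein, observed log2 ratios equal to the
    true log2 abundance difference of its members plus independent
    ``N(0, ratio_sd)`` noise; a protein is dropped from a whole comparison
    with probability ``missing_rate``.  The returned truth stores each
    sample's true log2 abundance relative to the reference baseline (the
    reference group's lowest age, which is identically 0).
    """
    if cfg.n_replicates < 2:
        raise ConfigurationError("n_replicates: must be >= 2")
    rng = cfg._streams()["ratios"]
    flags = _plant_effects(cfg, rng)
    proteins = np.array(flags.index)
    design = Design.from_groups(cfg.groups, cfg.n_replicates, ages=tuple(sorted(cfg.ages)))
    if layout is None:
        layout = default_bridging_layout(cfg.groups, cfg.ages, cfg.n_replicates)
    ages_sorted = sorted(cfg.ages)
    # true per-sample log2 values relative to the reference baseline
    true_vals = {}
    for sample in design.samples:
        row = design.frame.loc[sample]
        age_index = ages_sorted.index(row["age"])
        true_vals[sample] = _true_log2_offset(flags, row["group"], age_index)
    sample_values = pd.DataFrame(true_vals, index=proteins)
    a0 = ages_sorted[0]
    reference_samples = [s for s in design.samples
                         if design.frame.at[s, "group"] == "CL"
                         and design.frame.at[s, "age"] == a0]
    if not reference_samples:  # non-canonical groups: first group is reference
        g0 = cfg.groups[0]
        reference_samples = design.samples_in_group(g0, a0)
    exp = RatioExperiment(
        comparisons=list(layout),
        ratios=pd.DataFrame(columns=RATIO_COLUMNS),
        reference_samples=reference_samples,
        reference_label=f"CL{a0}",
    )
    exp.validate_connectivity()
    records = []
    n = cfg.n_proteins
    for comp in layout:
        present = rng.random(n) >= cfg.missing_rate
        n_pep = 2 + rng.poisson(2.0, n)
        for sample, base in comp.edges:
            true_diff = sample_values[sample].to_numpy() - sample_values[base].to_numpy()
            noise = rng.normal(0.0, cfg.ratio_sd, n) if cfg.ratio_sd > 0 else 0.0
            obs = true_diff + noise
            for i in np.nonzero(present)[0]:
                records.append(
                    (comp.id, sample, base, proteins[i], obs[i], n_pep[i])
                )
    exp.ratios = pd.DataFrame(records, columns=RATIO_COLUMNS)
    return exp, design, Truth(flags=flags, sample_values=sample_values)


def expand_to_peptides(
    exp: RatioExperiment,
    seed: int,
    peptide_scatter: float = 0.1,
    ppm_sd: float = 2.5,
) -> pd.DataFrame:
    """Expand protein-level ratios into a peptide-level record table.

    Each protein ratio becomes ``n_peptides`` peptide records whose log2
    ratios scatter around the protein ratio with mean-preserving (centered)
    deviations, so averaging the peptides recovers the protein ratio
    exactly.  Calibrated mass errors are drawn ``N(0, ppm_sd)``; records
    beyond the 5 ppm gate occur at a realistic rate.  Useful to exercise the
    peptide-level input path end to end on synthetic data.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for row in exp.ratios.itertuples(index=False):
        k = int(row.n_peptides)
        dev = rng.normal(0.0, peptide_scatter, k)
        dev -= dev.mean()
        ppm = rng.normal(0.0, ppm_sd, k)
        for j in range(k):
            rows.append(
                (
                    row.comparison,
                    row.sample,
                    row.base,
                    row.protein,
                    f"{row.protein}_pep{j + 1}",
                    row.log2_ratio + dev[j],
                    ppm[j],
                )
            )
    return pd.DataFrame(rows, columns=PEPTIDE_COLUMNS)


def simulate_metabolites(
    cfg: SimConfig,
    effects: dict[str, float] | None = None,
    n_per_group: dict[str, int] | int | None = None,
    baseline: float = 10.0,
) -> pd.DataFrame:
    """Per-bee metabolite values on the log2 scale.

    ``value = baseline + genotype_shift(H) + treatment_shift(K) + N(0, ratio_sd)``.
    ``effects`` maps ``"genotype"`` / ``"treatment"`` to additive log2
    shifts (defaults 0).  Group sizes default to ``cfg.n_replicates`` and
    may be given per group to mirror unbalanced field collections.
    """
    effects = effects or {}
    rng = cfg._streams()["metabolites"]
    if n_per_group is None:
        sizes = {g: cfg.n_replicates for g in cfg.groups}
    elif isinstance(n_per_group, int):
        sizes = {g: n_per_group for g in cfg.groups}
    else:
        sizes = dict(n_per_group)
    for g, n in sizes.items():
        if n < 2:
            raise ConfigurationError(f"n_per_group: group {g} needs n >= 2 (got {n})")
    rows = []
    bee = 0
    for g in cfg.groups:
        treatment, genotype = split_group(g)
        mu = baseline
        if genotype == "H":
            mu += effects.get("genotype", 0.0)
        if treatment == "K":
            mu += effects.get("treatment", 0.0)
        for _ in range(sizes[g]):
            bee += 1
            rows.append(
                {
                    "bee": f"bee{bee:03d}",
                    "genotype": genotype,
                    "treatment": treatment,
                    "group": g,
                    "value": mu + rng.normal(0.0, cfg.ratio_sd),
                }
            )
    return pd.DataFrame(rows)
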