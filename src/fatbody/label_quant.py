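"""Isotope-label ratio processing: peptide filters, protein ratios, bridging.

Dimethyl labeling measures up to three samples per MS run as channel
intensity ratios.  A full genotype x treatment x age factorial can therefore
only be observed as a set of partially overlapping duplex/triplex
comparisons.  This module turns peptide-level log2 ratios into a complete
protein x sample log2-abundance table relative to a reference sample by

1. discarding peptides with a calibrated mass error above 5 ppm,
2. averaging peptide ratios into protein ratios per comparison,
3. solving, per protein, the weighted least-squares system
   ``value(a) - value(b) = observed_ratio(a, b)`` over the comparison graph
   with the reference fixed at 0 (chain summation when the graph is a tree),
4. z-transforming per protein for the rank-based age contrasts.

Within a triplex run only the two ratios against the lowest channel enter
the system; the third pairwise ratio is arithmetically derived from them and
would double-count evidence.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .design import Design
from .errors import ConfigurationError, GraphConnectivityError

__all__ = [
    "Comparison",
    "RatioExperiment",
    "NormalizedAbundance",
    "filter_peptides",
    "peptides_to_protein",
    "bridge_to_reference",
    "z_transform",
    "presence_filter",
]

#: columns of a protein-level ratio table
RATIO_COLUMNS = ["comparison", "sample", "base", "protein", "log2_ratio", "n_peptides"]

#: columns of a peptide-level ratio table
PEPTIDE_COLUMNS = [
    "comparison",
    "sample",
    "base",
    "protein",
    "peptide",
    "log2_ratio",
    "ppm_error",
]


@dataclass(frozen=True)
class Comparison:
    """One labeled MS run: 2 (duplex) or 3 (triplex) member samples.

    The first member carries the lowest-mass label and serves as the
    within-run denominator; ratios are reported for every later member
    against it.
    """

    id: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) not in (2, 3):
            raise ConfigurationError(
                f"comparison {self.id}: needs 2 or 3 members, got {len(self.members)}"
            )
        if len(set(self.members)) != len(self.members):
            raise ConfigurationError(f"comparison {self.id}: duplicate members")

    @property
    def edges(self) -> list[tuple[str, str]]:
        """(sample, base) pairs measured in this run."""
        base = self.members[0]
        return [(m, base) for m in self.members[1:]]


@dataclass
class RatioExperiment:
    """A set of labeled comparisons with per-protein log2 ratios.

    ``ratios`` is a long table with columns :data:`RATIO_COLUMNS`; each row is
    one protein's log2 ratio of ``sample`` over ``base`` in one comparison,
    with the number of contributing peptides.  ``reference_samples`` lists the
    sample ids pinned to 0 on the relative log2 scale (several aliquots of
    the same reference pool may appear in different runs).
    """

    comparisons: list[Comparison]
    ratios: pd.DataFrame
    reference_samples: list[str]
    reference_label: str = "reference"

    def __post_init__(self) -> None:
        missing = set(RATIO_COLUMNS) - set(self.ratios.columns)
        if missing:
            raise ConfigurationError(f"ratios: missing columns {sorted(missing)}")
        if not self.reference_samples:
            raise ConfigurationError("reference_samples: at least one required")

    @property
    def samples(self) -> list[str]:
        out: list[str] = []
        for c in self.comparisons:
            for m in c.members:
                if m not in out:
                    out.append(m)
        return out

    @property
    def proteins(self) -> list[str]:
        return sorted(self.ratios["protein"].unique())

    def graph(self) -> nx.Graph:
        """Samples as nodes, measured comparisons as edges."""
        g = nx.Graph()
        g.add_nodes_from(self.samples)
        for c in self.comparisons:
            for a, b in c.edges:
                g.add_edge(a, b, comparison=c.id)
        return g

    def validate_connectivity(self) -> None:
        """Raise if some sample cannot reach any reference sample."""
        g = self.graph()
        reachable: set[str] = set()
        for ref in self.reference_samples:
            if ref in g:
                reachable |= nx.node_connected_component(g, ref)
        unreachable = sorted(set(self.samples) - reachable)
        if unreachable:
            raise GraphConnectivityError(
                f"samples unreachable from reference {self.reference_label}: "
                f"{unreachable}"
            )


@dataclass
class NormalizedAbundance:
    """Protein x sample log2 values relative to the reference.

    ``values`` is NaN where a protein was not measured or could not be
    bridged; ``presence`` is the corresponding boolean mask; reference
    columns are identically 0 wherever the protein was observed in the
    reference's run.  ``unbridged`` records (protein, sample) pairs that were
    measured but lie in a graph component without a reference node.
    """

    values: pd.DataFrame
    presence: pd.DataFrame
    reference_samples: list[str]
    unbridged: list[tuple[str, str]] = field(default_factory=list)


def filter_peptides(records: pd.DataFrame, max_ppm: float = 5.0) -> pd.DataFrame:
    """Drop peptide records with absolute calibrated mass error > ``max_ppm``.

    The rule is a strict inequality: a record at exactly ``max_ppm`` is kept.
    The number of removed records is stored in ``attrs['n_removed']``.
    """
    keep = records["ppm_error"].abs() <= max_ppm
    out = records.loc[keep].copy()
    out.attrs["n_removed"] = int((~keep).sum())
    return out


def peptides_to_protein(records: pd.DataFrame, min_distinct_peptides: int = 2) -> pd.DataFrame:
    """Average peptide log2 ratios into protein log2 ratios per comparison.

    Proteins identified by fewer than ``min_distinct_peptides`` distinct
    peptides across the whole experiment are eliminated (single-peptide
    identifications are unreliable).  Within a comparison a surviving
    protein's ratio is the arithmetic mean of its peptide ratios; the peptide
    count is kept as a precision weight for bridging.
    """
    distinct = records.groupby("protein")["peptide"].nunique()
    keep = distinct.index[distinct >= min_distinct_peptides]
    kept = records[records["protein"].isin(keep)]
    grouped = kept.groupby(["comparison", "sample", "base", "protein"], sort=False)
    out = grouped["log2_ratio"].agg(["mean", "size"]).reset_index()
    out = out.rename(columns={"mean": "log2_ratio", "size": "n_peptides"})
    return out[RATIO_COLUMNS]


def bridge_to_reference(exp: RatioExperiment, weights: str = "peptides") -> NormalizedAbundance:
    """Resolve every sample's log2 value relative to the reference per protein.

    For each protein, the observed edges form a (sub)graph of the comparison
    graph.  Within each connected component containing a reference node the
    sample values solve the weighted least-squares system
    ``value(a) - value(b) = ratio(a, b)`` with reference nodes fixed at 0 and
    weights equal to the number of contributing peptides (or unit weights
    with ``weights='unit'``).  On a tree this reduces to summing ratios along
    the path to the reference; on graphs with redundant edges it reconciles
    inconsistencies in the least-squares sense.  Components without a
    reference node are left unresolved and reported as unbridged.
    """
    if weights not in ("peptides", "unit"):
        raise ConfigurationError(f"weights: expected 'peptides' or 'unit', got {weights!r}")
    samples = exp.samples
    refs = set(exp.reference_samples)
    proteins = exp.proteins
    values = pd.DataFrame(np.nan, index=proteins, columns=samples)
    unbridged: list[tuple[str, str]] = []
    for prot, sub in exp.ratios.groupby("protein", sort=False):
        g = nx.Graph()
        for row in sub.itertuples(index=False):
            w = float(row.n_peptides) if weights == "peptides" else 1.0
            if g.has_edge(row.sample, row.base):
                # repeated measurement of the same edge: pool as a
                # weighted-average ratio with summed weight, minding the
                # stored orientation
                old = g[row.sample][row.base]
                r = row.log2_ratio if old["a"] == row.sample else -row.log2_ratio
                tot = old["w"] + w
                old["ratio"] = (old["ratio"] * old["w"] + r * w) / tot
                old["w"] = tot
            else:
                g.add_edge(
                    row.sample,
                    row.base,
                    ratio=row.log2_ratio,
                    w=w,
                    a=row.sample,
                    b=row.base,
                )
        for comp in nx.connected_components(g):
            comp_refs = comp & refs
            if not comp_refs:
                unbridged.extend((prot, s) for s in sorted(comp))
                continue
            unknowns = sorted(comp - refs)
            for r in comp_refs:
                values.at[prot, r] = 0.0
            if not unknowns:
                continue
            col = {s: i for i, s in enumerate(unknowns)}
            rows_a, rows_b = [], []
            for _, _, data in g.subgraph(comp).edges(data=True):
                a, b = data["a"], data["b"]  # stored orientation
                arow = np.zeros(len(unknowns))
                if a in col:
                    arow[col[a]] = 1.0
                if b in col:
                    arow[col[b]] = -1.0
                sw = np.sqrt(data["w"])
                rows_a.append(arow * sw)
                # the stored ratio is value(a) - value(b)
                rows_b.append(data["ratio"] * sw)
            a_mat = np.vstack(rows_a)
            b_vec = np.asarray(rows_b)
            sol, *_ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
            for s, i in col.items():
                values.at[prot, s] = sol[i]
    presence = values.notna()
    return NormalizedAbundance(values, presence, list(exp.reference_samples), unbridged)


def z_transform(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-protein z-scores over present samples (n-1 denominator).

    Proteins with fewer than two present values or zero variance cannot be
    standardized; they are flagged constant and their z-row is all-NaN so
    downstream tests skip them.
    """
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    n_present = values.notna().sum(axis=1)
    constant = (n_present < 2) | (sd == 0) | sd.isna()
    z = values.sub(mean, axis=0).div(sd, axis=0)
    z[constant] = np.nan
    return z, constant.rename("constant")


def presence_filter(
    values: pd.DataFrame,
    d: Design,
    min_present: int = 3,
    groups: list[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Per-protein, per-(group, age) presence eligibility.

    Returns a boolean DataFrame indexed by protein whose columns are
    ``(group, age)`` pairs; an entry is True when the protein is present in
    at least ``min_present`` replicates of that cell.  A protein is eligible
    for a two-cell contrast when at least one of the two cells is True
    (the criterion requires presence in "one group").
    """
    cells = groups
    if cells is None:
        cells = sorted(
            {(g, a) for g, a in zip(d.frame["group"], d.frame["age"])}
        )
    out = {}
    for g, a in cells:
        cols = [s for s in d.samples_in_group(g, a) if s in values.columns]
        out[(g, a)] = values[cols].notna().sum(axis=1) >= min_present
    return pd.DataFrame(out)
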