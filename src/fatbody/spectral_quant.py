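"""Spectral-count quantification: normalization and quantifiability filters.

Spectral counts are semi-quantitative integer abundance proxies.  Counts are
normalized per sample by the sample's total spectral count ("corrected"
counts), log2-transformed for multivariate analysis, and screened by two
set-cardinality rules before any testing:

* count rule — a spectral count of at least ``min_count`` in at least
  ``min_count_reps`` replicates of one group;
* peptide rule — at least ``min_peptides`` distinct peptide identifications
  in at least ``min_pep_reps`` replicates of one group.

Proteins sharing identical peptide sets cannot be distinguished by spectral
counting; they are tracked as redundancy groups and collapsed to a single
representative for multivariate analyses while per-protein test output keeps
all members with a shared-evidence flag.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import Design
from .errors import ConfigurationError, EmptySampleError

__all__ = [
    "CountMatrix",
    "AbundanceTable",
    "FilterResult",
    "correct_counts",
    "log2_abundance",
    "quantifiability_filter",
    "protein_count_report",
]


@dataclass
class CountMatrix:
    """Protein x sample spectral counts plus distinct-peptide counts.

    ``counts`` and ``peptides`` are integer DataFrames with identical index
    (protein accessions) and columns (sample ids).  A missing protein/sample
    cell is a count of 0, not NA: spectral counting observes absence as zero.
    ``redundancy_groups`` partitions proteins sharing identical peptide sets;
    singletons may be omitted.
    """

    counts: pd.DataFrame
    peptides: pd.DataFrame
    redundancy_groups: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.peptides.index) or not (
            self.counts.columns.equals(self.peptides.columns)
        ):
            raise ConfigurationError("counts/peptides: index or columns differ")
        c = self.counts.to_numpy()
        p = self.peptides.to_numpy()
        if (c < 0).any() or (p < 0).any():
            raise ConfigurationError("counts/peptides: negative entries")
        if ((p == 0) & (c > 0)).any():
            raise ConfigurationError(
                "counts/peptides: nonzero count with zero peptide evidence"
            )
        seen: set[str] = set()
        for grp in self.redundancy_groups:
            for prot in grp:
                if prot in seen:
                    raise ConfigurationError(
                        f"redundancy_groups: protein {prot} in two groups"
                    )
                seen.add(prot)

    @property
    def proteins(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def redundancy_map(self) -> pd.Series:
        """Protein -> representative accession of its redundancy group.

        The representative is the lexicographically smallest member; proteins
        outside any declared group represent themselves.
        """
        rep = {p: p for p in self.proteins}
        for grp in self.redundancy_groups:
            head = min(grp)
            for p in grp:
                rep[p] = head
        return pd.Series(rep, name="representative")


@dataclass
class AbundanceTable:
    """Corrected (or log2) spectral-count abundances with provenance."""

    values: pd.DataFrame
    scale: str  # 'corrected' | 'log2'
    provenance: dict = field(default_factory=dict)


def correct_counts(m: CountMatrix) -> AbundanceTable:
    """Divide each count by its sample's total spectral count.

    Normalizes for variation in total protein amount loaded per sample; every
    column of the result sums to 1 over the proteins present before any
    filtering.  A sample with a zero total cannot be normalized.
    """
    totals = m.counts.sum(axis=0)
    empty = totals.index[totals == 0].tolist()
    if empty:
        raise EmptySampleError(f"zero total spectral count in sample(s) {empty}")
    values = m.counts / totals
    return AbundanceTable(values, "corrected", {"source": "correct_counts"})


def log2_abundance(table: AbundanceTable) -> AbundanceTable:
    """log2 of corrected values; zeros become missing (no pseudocount)."""
    if table.scale != "corrected":
        raise ConfigurationError("scale: log2_abundance expects corrected values")
    with np.errstate(divide="ignore"):
        values = np.log2(table.values.where(table.values > 0))
    prov = dict(table.provenance, log2=True)
    return AbundanceTable(values, "log2", prov)


@dataclass
class FilterResult:
    passed: pd.Series  # bool per protein
    count_groups: pd.Series  # list of groups satisfying the count rule
    peptide_groups: pd.Series  # list of groups satisfying the peptide rule
    params: dict


def quantifiability_filter(
    m: CountMatrix,
    d: Design,
    min_count: int = 3,
    min_count_reps: int = 3,
    min_peptides: int = 2,
    min_pep_reps: int = 4,
    same_group_required: bool = False,
) -> FilterResult:
    """Apply the two quantifiability rules per protein.

    A protein passes iff some group satisfies the count rule and some group
    satisfies the peptide rule.  By default the two rules may be satisfied by
    different groups; ``same_group_required=True`` demands a single group
    satisfying both.
    """
    for name, v in (
        ("min_count", min_count),
        ("min_count_reps", min_count_reps),
        ("min_peptides", min_peptides),
        ("min_pep_reps", min_pep_reps),
    ):
        if int(v) != v or v < 1:
            raise ConfigurationError(f"{name}: must be a positive integer (got {v})")
    groups = d.groups
    for g in groups:
        n = len(d.samples_in_group(g))
        if n < min_pep_reps:
            raise ConfigurationError(
                f"min_pep_reps: group {g} has only {n} replicates (< {min_pep_reps})"
            )
    count_ok = {}
    pep_ok = {}
    for g in groups:
        cols = d.samples_in_group(g)
        count_ok[g] = (m.counts[cols] >= min_count).sum(axis=1) >= min_count_reps
        pep_ok[g] = (m.peptides[cols] >= min_peptides).sum(axis=1) >= min_pep_reps
    count_ok = pd.DataFrame(count_ok)
    pep_ok = pd.DataFrame(pep_ok)
    if same_group_required:
        passed = (count_ok & pep_ok).any(axis=1)
    else:
        passed = count_ok.any(axis=1) & pep_ok.any(axis=1)
    listify = lambda df: df.apply(lambda row: list(df.columns[row]), axis=1)
    return FilterResult(
        passed=passed,
        count_groups=listify(count_ok),
        peptide_groups=listify(pep_ok),
        params={
            "min_count": min_count,
            "min_count_reps": min_count_reps,
            "min_peptides": min_peptides,
            "min_pep_reps": min_pep_reps,
            "same_group_required": same_group_required,
        },
    )


def protein_count_report(m: CountMatrix, filt: FilterResult) -> dict:
    """Summary of the filter outcome, including redundancy-group collapse."""
    passed = filt.passed
    rep = m.redundancy_map()
    n_pass = int(passed.sum())
    collapsed = rep[passed[passed].index].nunique() if n_pass else 0
    return {
        "n_proteins": len(passed),
        "n_quantifiable": n_pass,
        "n_failed": int((~passed).sum()),
        "n_quantifiable_nonredundant": int(collapsed),
        "params": filt.params,
    }
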