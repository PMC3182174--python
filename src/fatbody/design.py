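"""Experimental design: mapping samples to genotype, treatment, age, replicate.

The four canonical groups cross dsRNA treatment (C = *gfp* control,
K = *irs* knockdown) with pollen-hoarding genotype (L = low, H = high):
CL, KL, CH, KH.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError

GROUPS = ("CL", "KL", "CH", "KH")

#: group label -> (treatment, genotype)
GROUP_FACTORS = {
    "CL": ("C", "L"),
    "KL": ("K", "L"),
    "CH": ("C", "H"),
    "KH": ("K", "H"),
}


def split_group(group: str) -> tuple[str, str]:
    """Return (treatment, genotype) for a two-letter group label."""
    if len(group) != 2 or group[0] not in "CK" or group[1] not in "LH":
        raise ConfigurationError(f"groups: unrecognized group label {group!r}")
    return group[0], group[1]


@dataclass
class Design:
    """Sample metadata table.

    ``frame`` is indexed by sample id with columns ``genotype`` (H/L),
    ``treatment`` (C/K), ``age`` (days), ``replicate`` (int) and a derived
    ``group`` column (treatment letter + genotype letter).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"genotype", "treatment", "age", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ConfigurationError(f"design: missing columns {sorted(missing)}")
        if "group" not in self.frame.columns:
            self.frame = self.frame.assign(
                group=self.frame["treatment"].astype(str)
                + self.frame["genotype"].astype(str)
            )
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].tolist()
            raise ConfigurationError(f"design: duplicate sample ids {dupes}")

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    @property
    def groups(self) -> list[str]:
        return sorted(self.frame["group"].unique())

    def samples_in_group(self, group: str, age: int | None = None) -> list[str]:
        mask = self.frame["group"] == group
        if age is not None:
            mask &= self.frame["age"] == age
        return list(self.frame.index[mask])

    def group_labels(self, samples: list[str]) -> pd.Series:
        return self.frame.loc[samples, "group"]

    def subset(self, samples: list[str]) -> "Design":
        return Design(self.frame.loc[samples].copy())

    @classmethod
    def from_groups(
        cls,
        groups: tuple[str, ...] = GROUPS,
        n_replicates: int = 5,
        ages: tuple[int, ...] = (7,),
    ) -> "Design":
        """Build a full design with one sample per group x age x replicate.

        Sample ids follow the ``<group><age>_r<replicate>`` convention
        (``CL7_r1``) when several ages are present and ``<group>_r<replicate>``
        for a single-age design.
        """
        rows = []
        multi_age = len(ages) > 1
        for g in groups:
            treatment, genotype = split_group(g)
            for age in ages:
                for r in range(1, n_replicates + 1):
                    sid = f"{g}{age}_r{r}" if multi_age else f"{g}_r{r}"
                    rows.append(
                        {
                            "sample": sid,
                            "genotype": genotype,
                            "treatment": treatment,
                            "age": age,
                            "replicate": r,
                        }
                    )
        frame = pd.DataFrame(rows).set_index("sample")
        return cls(frame)

    def to_tsv(self, path) -> None:
        self.frame.reset_index().rename(columns={"index": "sample"}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read_tsv(cls, path) -> "Design":
        frame = pd.read_csv(path, sep="\t", comment="#").set_index("sample")
        return cls(frame)
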