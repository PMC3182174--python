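"""Packaged reference table of published rank sums and exact p-values.

The fixture ships the per-protein results of the label-free genotype x
knockdown comparison (three two-group contrasts at n = 5 per group):
published two-sided Mann-Whitney p-values, the paired rank sums for each
contrast, and the published effect class (G, T or G&T).  It serves as a
regression target: the exact enumeration in :mod:`fatbody.nonparam_stats`
must reproduce every printed p-value from the printed rank sums, and the
effect classifier must reproduce the printed class column.
"""
from importlib.resources import files

import pandas as pd

_PATH = files("fatbody").joinpath("data/reference_ranksum_table.tsv")

#: (p-value column, first rank-sum column, second rank-sum column) per contrast
CONTRAST_COLUMNS = {
    "CL/KL": ("p_cl_kl", "rs_cl_a", "rs_kl"),
    "CH/KH": ("p_ch_kh", "rs_ch_a", "rs_kh"),
    "CL/CH": ("p_cl_ch", "rs_cl_b", "rs_ch_b"),
}


def load_reference_table() -> pd.DataFrame:
    """Return the published rank-sum/p-value table (49 proteins)."""
    with _PATH.open() as fh:
        return pd.read_csv(fh, sep="\t")
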