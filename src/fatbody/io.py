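"""TSV readers/writers for the package's tables.

Count matrices use paired ``<sample>:count`` / ``<sample>:peptides``
columns; all other tables are plain one-header-line TSV.  Writers accept an
optional header mapping emitted as ``# key=value`` comment lines, which the
readers skip.
"""
from __future__ import annotations

import pandas as pd

from .errors import ConfigurationError
from .label_quant import Comparison, RatioExperiment, RATIO_COLUMNS
from .spectral_quant import AbundanceTable, CountMatrix


def _write_with_header(df: pd.DataFrame, path, header: dict | None, index: bool) -> None:
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=index)


def write_count_matrix(m: CountMatrix, path, header: dict | None = None) -> None:
    out = pd.DataFrame(index=m.counts.index)
    for s in m.samples:
        out[f"{s}:count"] = m.counts[s]
        out[f"{s}:peptides"] = m.peptides[s]
    out.index.name = "protein"
    _write_with_header(out.reset_index(), path, header, index=False)


def read_count_matrix(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", comment="#").set_index("protein")
    counts, peptides = {}, {}
    for col in df.columns:
        if ":" not in col:
            raise ConfigurationError(f"count matrix: column {col!r} lacks a ':count'/':peptides' suffix")
        sample, kind = col.rsplit(":", 1)
        {"count": counts, "peptides": peptides}[kind][sample] = df[col]
    c = pd.DataFrame(counts)
    p = pd.DataFrame(peptides)
    if list(c.columns) != list(p.columns):
        raise ConfigurationError("count matrix: unpaired count/peptide columns")
    return CountMatrix(counts=c.astype(int), peptides=p.astype(int))


def write_abundance(table: AbundanceTable, path, header: dict | None = None) -> None:
    hdr = dict(header or {})
    hdr["scale"] = table.scale
    out = table.values.copy()
    out.index.name = "protein"
    _write_with_header(out.reset_index(), path, hdr, index=False)


def read_abundance(path, scale: str = "corrected") -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", comment="#").set_index("protein")
    return AbundanceTable(df, scale, {"source": str(path)})


def write_values(values: pd.DataFrame, path, header: dict | None = None, index_name: str = "protein") -> None:
    out = values.copy()
    out.index.name = index_name
    _write_with_header(out.reset_index(), path, header, index=False)


def read_values(path, index_name: str = "protein") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#").set_index(index_name)


def write_ratio_experiment(exp: RatioExperiment, ratio_path, manifest_path, header: dict | None = None) -> None:
    _write_with_header(exp.ratios, ratio_path, header, index=False)
    rows = [
        {
            "comparison": c.id,
            "members": ",".join(c.members),
            "reference": int(any(m in exp.reference_samples for m in c.members)),
        }
        for c in exp.comparisons
    ]
    manifest = pd.DataFrame(rows)
    manifest.attrs["reference_samples"] = exp.reference_samples
    hdr = dict(header or {})
    hdr["reference_samples"] = ",".join(exp.reference_samples)
    hdr["reference_label"] = exp.reference_label
    _write_with_header(manifest, manifest_path, hdr, index=False)


def _read_header(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                out[k.strip()] = v.strip()
    return out


def read_manifest(manifest_path) -> tuple[list[Comparison], list[str], str]:
    """Comparison layout, reference samples and reference label."""
    hdr = _read_header(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t", comment="#")
    comparisons = [
        Comparison(r["comparison"], tuple(r["members"].split(",")))
        for _, r in manifest.iterrows()
    ]
    refs = hdr.get("reference_samples", "")
    reference_samples = [s for s in refs.split(",") if s]
    if not reference_samples:
        raise ConfigurationError("manifest: missing '# reference_samples=' header line")
    return comparisons, reference_samples, hdr.get("reference_label", "reference")


def read_ratio_experiment(ratio_path, manifest_path) -> RatioExperiment:
    ratios = pd.read_csv(ratio_path, sep="\t", comment="#")
    missing = set(RATIO_COLUMNS) - set(ratios.columns)
    if missing:
        raise ConfigurationError(f"ratio table: missing columns {sorted(missing)}")
    comparisons, reference_samples, label = read_manifest(manifest_path)
    return RatioExperiment(
        comparisons=comparisons,
        ratios=ratios,
        reference_samples=reference_samples,
        reference_label=label,
    )


def read_peptide_records(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_metabolites(df: pd.DataFrame, path, header: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def read_metabolites(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
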