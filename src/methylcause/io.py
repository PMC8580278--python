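"""Plain-text readers and writers for every table the pipeline exchanges.

All writers emit a leading ``#`` comment line declaring the column schema;
all readers skip comment lines, so writer -> reader round-trips are exact.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .containers import MethylationMatrix

PHENO_COLUMNS = [
    "id", "sex", "age_w1", "age_w2", "status_w1", "status_w2",
    "packyears_w1", "packyears_w2", "case", "matchset",
]


def _write_with_header(df: pd.DataFrame, path, sep: str, index_label: str) -> None:
    path = Path(path)
    cols = [index_label] + list(df.columns)
    with open(path, "w") as fh:
        fh.write("# columns: " + sep.join(map(str, cols)) + "\n")
        df.to_csv(fh, sep=sep, index_label=index_label)


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    _write_with_header(pheno, path, ",", "id")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col="id", float_precision="round_trip")


def write_genotypes(geno: pd.DataFrame, path) -> None:
    _write_with_header(geno, path, "\t", "id")


def read_genotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="id", float_precision="round_trip")


def write_methylation(meth: MethylationMatrix, path) -> None:
    """Site rows: site_id, chr, pos, gene, then one beta column per sample."""
    tab = pd.concat(
        [meth.annotation[["chr", "pos", "gene"]], meth.beta], axis=1
    )
    _write_with_header(tab, path, "\t", "site_id")


def read_methylation(path) -> MethylationMatrix:
    tab = pd.read_csv(path, sep="\t", comment="#", index_col="site_id", float_precision="round_trip")
    ann = tab[["chr", "pos", "gene"]].copy()
    ann["gene"] = ann["gene"].fillna("")
    ann["gene_region"] = ""
    beta = tab.drop(columns=["chr", "pos", "gene"])
    return MethylationMatrix(beta, ann)


def write_table(df: pd.DataFrame, path, index_label: str = "id") -> None:
    _write_with_header(df, path, "\t", index_label)


def read_table(path, index_label: str = "id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_label, float_precision="round_trip")


def write_summary_stats(df: pd.DataFrame, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# columns: " + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")


def write_truth(truth, path) -> None:
    """Planted parameters as YAML (arrays as lists keyed by site id)."""
    payload = {
        "theta_direct": float(truth.theta_direct),
        "theta_med": float(truth.theta_med),
        "mediator_sites": [str(s) for s in truth.mediator_sites],
        "tau": {str(s): float(t) for s, t in zip(truth.site_ids, truth.tau)},
        "mu0": {str(s): float(t) for s, t in zip(truth.site_ids, truth.mu0)},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_truth(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
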