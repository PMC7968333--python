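"""Plain-text readers and writers for the pipeline's data formats.

All formats are deliberately simple text: pedigree CSV (id, sire, dam
with 0 = unknown parent), a PLINK-style .ped/.map dialect and a plain
0/1/2 genotype matrix with SNP map, weather CSV (ISO-8601 hour, dry-bulb
and dew-point deg C), and the phenotype/event CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinship import Pedigree


def write_pedigree_csv(ped: Pedigree, path):
    ped.to_frame(unknown=0).to_csv(path, index=False)


def read_pedigree_csv(path) -> Pedigree:
    return Pedigree.from_frame(pd.read_csv(path), unknown=0)


def write_weather_csv(weather: pd.DataFrame, path):
    out = weather.copy()
    out["time"] = pd.to_datetime(out["time"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, float_format="%.3f")


def read_weather_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["time"] = pd.to_datetime(df["time"])
    return df


def write_phenotypes_csv(records: pd.DataFrame, path):
    records.to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in df.columns:
        if c.endswith("_date"):
            df[c] = pd.to_datetime(df[c])
    return df


def write_genotype_matrix(genotypes, snp_map: pd.DataFrame, ids, prefix):
    """Plain 0/1/2 matrix (one row per animal, first column id) plus map."""
    prefix = Path(prefix)
    g = pd.DataFrame(np.asarray(genotypes), columns=snp_map["snp"])
    g.insert(0, "id", np.asarray(ids))
    g.to_csv(prefix.with_suffix(".geno.csv"), index=False)
    snp_map.to_csv(prefix.with_suffix(".map.csv"), index=False)


def read_genotype_matrix(prefix):
    prefix = Path(prefix)
    g = pd.read_csv(prefix.with_suffix(".geno.csv"))
    snp_map = pd.read_csv(prefix.with_suffix(".map.csv"))
    ids = g["id"].to_numpy()
    return g.drop(columns="id").to_numpy(dtype=np.int8), snp_map, ids


_PED_ALLELES = {0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B"), -1: ("0", "0")}


def write_plink(genotypes, snp_map: pd.DataFrame, ids, prefix):
    """Whitespace-delimited PLINK .ped/.map text dialect.

    Genotypes are exported as two alleles per SNP (A = reference,
    B = alternative, 0 = missing); family id and parents are written as
    zeros, as in a bare genotype export.
    """
    prefix = Path(prefix)
    g = np.asarray(genotypes, dtype=int)
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, animal in enumerate(np.asarray(ids)):
            alleles = []
            for code in g[i]:
                a, b = _PED_ALLELES.get(int(code), ("0", "0"))
                alleles += [a, b]
            fh.write(" ".join(["0", str(animal), "0", "0", "0", "-9", *alleles]) + "\n")
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, row in snp_map.iterrows():
            fh.write(f"{row['chrom']} {row['snp']} 0 {row['bp']}\n")


def read_plink(prefix):
    """Read the .ped/.map dialect written by :func:`write_plink`."""
    prefix = Path(prefix)
    snp_map = pd.read_csv(
        prefix.with_suffix(".map"), sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "bp"],
    ).drop(columns="cm")
    rows, ids = [], []
    code = {("A", "A"): 0, ("A", "B"): 1, ("B", "A"): 1, ("B", "B"): 2, ("0", "0"): -1}
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            ids.append(parts[1])
            al = parts[6:]
            rows.append([code[(al[2 * j], al[2 * j + 1])] for j in range(len(al) // 2)])
    geno = np.asarray(rows, dtype=np.int8)
    return geno, snp_map, np.asarray(ids)


def read_bed(path) -> pd.DataFrame:
    """Read a BED-like annotation table (chrom, start, end, name; tab or
    whitespace separated, half-open [start, end) coordinates)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "start", "end", "name"])
    return df


def write_fit_json(results, path):
    """Serialise variance components, SEs, logL and AIC of a fit."""
    if hasattr(results, "params"):
        payload = results.params.as_dict()
    else:
        payload = {
            "sigma_a_sq": results.sigma_a_sq,
            "sigma_e_sq": results.sigma_e_sq,
            **{f"se_{k}": v for k, v in results.se.items()},
        }
    payload.update({"loglike": results.loglike, "aic": results.aic,
                    "n_iter": results.n_iter, "converged": results.converged})
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
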