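"""File dialects the pipeline reads and writes.

All inputs and outputs are plain text: per-knockdown TSVs with a manifest,
a drug-by-gene matrix (TSV or GCT 1.2), a growth (GRmax) table, and
long-format result TSVs.  Drug matrix column names may carry a cell line
as ``drug@cellline``; a bare name is assigned the default cell line.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .contextualize import KnockdownDataset
from .npa import DrugProfile, PerturbationResult

__all__ = [
    "read_knockdown",
    "read_knockdown_manifest",
    "write_knockdowns",
    "read_drug_matrix",
    "write_drug_matrix",
    "read_growth",
    "split_drug_column",
    "write_results_tsv",
    "write_results_json",
]

DEFAULT_CELL_LINE = "MCF7"


# -- knockdowns -------------------------------------------------------------

def read_knockdown(path: str | Path, target: str) -> KnockdownDataset:
    """One knockdown TSV with columns gene, log2FC, pvalue (case-insensitive)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    rename = {}
    for want in ("gene", "log2fc", "pvalue"):
        match = next((c for c in df.columns if c.lower() == want), None)
        if match is None:
            raise ValueError(f"{path}: missing column {want!r}")
        rename[match] = want
    df = df.rename(columns=rename)[["gene", "log2fc", "pvalue"]]
    return KnockdownDataset(target=target, records=df)


def read_knockdown_manifest(path: str | Path) -> list[KnockdownDataset]:
    """Manifest TSV (target, path) with paths relative to the manifest."""
    path = Path(path)
    mf = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for row in mf.itertuples():
        p = Path(row.path)
        if not p.is_absolute():
            p = path.parent / p
        out.append(read_knockdown(p, target=row.target))
    return out


def write_knockdowns(kds: list[KnockdownDataset], outdir: str | Path) -> Path:
    """Write one TSV per knockdown plus the manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for kd in kds:
        fname = f"kd_{kd.target}.tsv"
        kd.records.to_csv(outdir / fname, sep="\t", index=False)
        rows.append({"target": kd.target, "path": fname})
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


# -- drug matrices ----------------------------------------------------------

def split_drug_column(name: str) -> tuple[str, str]:
    """'drug@cellline' -> (drug, cellline); bare names get the default line."""
    if "@" in name:
        drug, cell = name.split("@", 1)
        return drug, cell
    return name, DEFAULT_CELL_LINE


def read_drug_matrix(path: str | Path) -> list[DrugProfile]:
    """Genes-by-drugs matrix as TSV, or GCT 1.2 (detected by its #1.2 header)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        df = pd.read_csv(path, sep="\t", skiprows=2)
        df = df.drop(columns=[c for c in ("Description",) if c in df.columns])
        df = df.rename(columns={df.columns[0]: "gene"})
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
        df = df.rename(columns={df.columns[0]: "gene"})
    df = df.set_index("gene")
    return [
        DrugProfile(drug=str(col), values={g: float(v) for g, v in df[col].items()})
        for col in df.columns
    ]


def write_drug_matrix(profiles: list[DrugProfile], path: str | Path) -> None:
    genes = sorted({g for p in profiles for g in p.values})
    df = pd.DataFrame(
        {p.drug: [p.values.get(g, float("nan")) for g in genes] for p in profiles},
        index=pd.Index(genes, name="gene"),
    )
    df.to_csv(path, sep="\t")


# -- growth -----------------------------------------------------------------

def read_growth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    rename = {}
    for want in ("drug", "dose", "grmax"):
        match = next((c for c in df.columns if c.lower() == want), None)
        if match is None:
            raise ValueError(f"{path}: missing column {want!r}")
        rename[match] = want
    return df.rename(columns=rename)[["drug", "dose", "grmax"]]


# -- results ----------------------------------------------------------------

def write_results_tsv(results: list[PerturbationResult], path: str | Path) -> None:
    """Long-format per-node coefficients with CIs and network-level rows."""
    rows = []
    for r in results:
        for node in sorted(r.coefficients):
            rows.append(
                {
                    "drug": r.drug,
                    "node": node,
                    "coefficient": r.coefficients[node],
                    "ci_low": r.ci_low.get(node, float("nan")),
                    "ci_high": r.ci_high.get(node, float("nan")),
                    "defined": node not in r.undefined_nodes,
                }
            )
        rows.append(
            {
                "drug": r.drug,
                "node": "__network__",
                "coefficient": r.amplitude,
                "ci_low": float("nan"),
                "ci_high": float("nan"),
                "defined": True,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_results_json(results: list[PerturbationResult], path: str | Path) -> None:
    payload = {
        r.drug: {
            "coefficients": {k: r.coefficients[k] for k in sorted(r.coefficients)},
            "ci_low": {k: r.ci_low[k] for k in sorted(r.ci_low)},
            "ci_high": {k: r.ci_high[k] for k in sorted(r.ci_high)},
            "amplitude": r.amplitude,
            "pvalue": r.pvalue,
            "undefined_nodes": sorted(r.undefined_nodes),
        }
        for r in results
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
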