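"""Packaged reference data: the curated interaction table and gene rosters.

The package ships the curated causal-interaction table (70 BEL-subset
statements among metastasis suppressors and their regulators), the roster
of seventeen metastasis suppressor genes, the eleven transcription factors
with their knockdown dataset identifiers, and the free-text alias table.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources as _res

import pandas as pd

from .bel import BackboneGraph, CausalStatement, build_backbone, parse_statement

__all__ = [
    "load_interactions",
    "load_statements",
    "load_aliases",
    "msg_symbols",
    "tf_symbols",
    "load_roles",
    "load_backbone",
    "EXTRA_SYMBOLS",
]

#: Symbols that occur in the curated statements but belong to neither the
#: MSG roster nor the TF roster (literature-added regulators and effectors).
EXTRA_SYMBOLS = (
    "SAP1A", "SATB1", "SNAI1", "RELA", "MTA3",
    "TNFSF10", "RUNX2", "TGFB1", "CASP8", "MAP2K3",
)


def _data_path(name: str):
    return _res.files("rcrnet.data").joinpath(name)


def _read_tsv(name: str) -> pd.DataFrame:
    with _res.as_file(_data_path(name)) as p:
        return pd.read_csv(p, sep="\t", comment="#", dtype=str)


@lru_cache(maxsize=None)
def load_interactions() -> pd.DataFrame:
    """The curated interaction table (subject, object, reference, statement)."""
    return _read_tsv("interactions.tsv")


@lru_cache(maxsize=None)
def load_aliases() -> dict[str, str]:
    """Free-text name -> symbol map, keyed casefolded."""
    df = _read_tsv("aliases.tsv")
    return {str(n).casefold(): str(s) for n, s in zip(df["name"], df["symbol"])}


def load_statements() -> list[CausalStatement]:
    """Parse every curated statement in the packaged table."""
    df = load_interactions()
    aliases = load_aliases()
    return [
        parse_statement(row.statement, evidence=row.reference,
                        aliases=aliases, provenance="curated")
        for row in df.itertuples()
    ]


@lru_cache(maxsize=None)
def msg_symbols() -> tuple[str, ...]:
    """The seventeen metastasis suppressor gene symbols."""
    return tuple(_read_tsv("msg_genes.tsv")["symbol"])


@lru_cache(maxsize=None)
def tf_symbols() -> tuple[str, ...]:
    """The eleven transcription-factor symbols."""
    return tuple(_read_tsv("tf_genes.tsv")["symbol"])


def tf_datasets() -> dict[str, str]:
    df = _read_tsv("tf_genes.tsv")
    return dict(zip(df["symbol"], df["dataset"]))


def load_roles() -> dict[str, str]:
    """Symbol -> role (MSG, TF, other) over all documented symbols."""
    roles = {s: "MSG" for s in msg_symbols()}
    roles.update({s: "TF" for s in tf_symbols()})
    roles.update({s: "other" for s in EXTRA_SYMBOLS})
    return roles


def load_backbone(on_conflict: str = "keep_direct") -> BackboneGraph:
    """Build the curated functional layer from the packaged table.

    The packaged table asserts MAPK14 -> CASP8 with both signs (see the
    comments in the table); the default policy keeps the sign backed by the
    direct mechanistic statement.
    """
    return build_backbone(load_statements(), roles=load_roles(), on_conflict=on_conflict)
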