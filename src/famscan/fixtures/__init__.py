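"""Transcribed worked-example tables shipped with the package.

See ``README.md`` in this directory for provenance notes and known
inconsistencies between the source table and the surrounding text.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str, **kw) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", **kw)


def load_table1() -> pd.DataFrame:
    """Grapevine family gene catalog: locus, position, new-gene/curated flags."""
    df = _read("table1_catalog.tsv", dtype={"curated": int})
    df["new_flag"] = df["new_flag"].fillna("")
    df["new_gene"] = df["new_flag"].isin(["v0", "v1"])
    return df


def load_triage_counts() -> pd.DataFrame:
    """Candidate-region triage class counts (no-domain / nonfunctional / functional)."""
    df = _read("triage_counts.tsv")
    df["subset_of"] = df["subset_of"].fillna("")
    return df


def load_subclass_memberships() -> pd.DataFrame:
    """Per-gene subclass and clade memberships of the 90-gene catalog."""
    df = _read("subclass_counts_source.tsv", dtype={"clade": "string"})
    df["clade"] = df["clade"].fillna("")
    df["subfamily"] = df["subfamily"].fillna("")
    return df
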