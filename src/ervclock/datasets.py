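"""Packaged reference tables.

Two kinds of data ship with the package:

* transcriptions of the published HML10 locus table and per-locus component
  ages (the integration-dating summary), used as fixtures by the dating and
  locus modules;
* small synthetic auxiliary tables (a stand-in PBS library, GRCh37 chromosome
  lengths) consumed by the simulator, the PBS scanner and the CLI defaults.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .seqio import ProviralLocus, parse_locus_row


def _data_path(name: str):
    return resources.files("ervclock.data").joinpath(name)


def load_reference_locus_table() -> pd.DataFrame:
    """The published HML10 locus table: name, printed coordinate string,
    printed length and genomic context, one row per locus (duplicated
    C4 integrations are separate rows)."""
    with resources.as_file(_data_path("table1_loci.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_reference_loci() -> list[ProviralLocus]:
    """Parse the packaged locus table through :func:`parse_locus_row`."""
    frame = load_reference_locus_table()
    return [
        parse_locus_row(f"{row.name_} | {row.coordinates} | {row.context}")
        for row in frame.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def load_reference_age_components() -> pd.DataFrame:
    """Published per-locus integration-age components (My), one row per
    (locus, method) cell, with the divergent-gag exclusion flagged."""
    with resources.as_file(_data_path("table2_ages.tsv")) as p:
        frame = pd.read_csv(p, sep="\t")
    frame["excluded"] = frame["excluded"].fillna("") == "yes"
    frame["note"] = frame["note"].fillna("")
    return frame


def load_grch37_chromosome_lengths() -> pd.Series:
    """GRCh37 chromosome lengths (bp), indexed by chromosome name."""
    with resources.as_file(_data_path("chrom_lengths_grch37.tsv")) as p:
        frame = pd.read_csv(p, sep="\t", dtype={"chrom": str})
    return frame.set_index("chrom")["length_bp"]


def load_pbs_library() -> list[tuple[str, str]]:
    """The packaged PBS library as ordered (tRNA code, sequence) pairs.

    This is a small synthetic stand-in (lysine entry first, plus decoys);
    a user library can be supplied anywhere a library is accepted.
    """
    with resources.as_file(_data_path("pbs_library_synthetic.tsv")) as p:
        frame = pd.read_csv(p, sep="\t")
    return [(str(r.trna), str(r.pbs)) for r in frame.itertuples(index=False)]
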