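"""Packaged reference data: the printed panel tables, descriptor values,
known-anomaly whitelist, and the reconstructed EcoRI chain.

The EcoRI chain is not distributed as machine-readable text anywhere in the
source material; it is reconstructed here by stitching the 25 overlapping
original blocking peptides (plus the initiator M that the peptide set starts
after) and should be treated as a reconstruction, not a database sequence.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .seqcore import Interval, ProteinChain, stitch_chain

#: Parents of the three-per-parent short (N/M/C) peptide family.
SHORT_PARENTS = ["BP6", "BP7", "BP9", "BP10", "BP11",
                 "BP12", "BP13", "BP14", "BP15", "BP22"]

#: Short peptides whose printed sequence deviates from the N/M/C window rule
#: and is taken from the table instead (ad hoc choices in the source design).
SHORT_OVERRIDES = ["BP12N", "BP12M", "BP22M", "BP22C"]

#: Parents of the randomized (composition-preserving shuffle) peptides.
RANDOMIZED_PARENTS = ["BP7", "BP10", "BP13"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("piakit").joinpath("data", name).open() as handle:
        return pd.read_csv(handle, sep="\t", comment="#")


@lru_cache(maxsize=None)
def panel_table() -> pd.DataFrame:
    """The printed 85-peptide panel (id, category, parent, coords, sequence)."""
    return _read("paper_panel.tsv")


@lru_cache(maxsize=None)
def golden_descriptors() -> pd.DataFrame:
    """Printed descriptor values for all 85 peptides, indexed by id."""
    return _read("golden_descriptors.tsv").set_index("id")


@lru_cache(maxsize=None)
def anomalies() -> pd.DataFrame:
    """Whitelist of printed cells the toolkit knowingly does not reproduce."""
    return _read("anomalies.tsv")


def anomalous_cells() -> set[tuple[str, str]]:
    """(peptide id, field) pairs excluded from golden comparisons."""
    return {(r.id, r.field) for r in anomalies().itertuples()}


def printed_windows(category: str = "original") -> list[tuple[str, Interval]]:
    """(id, printed interval) pairs for a positioned category, table order."""
    rows = panel_table()
    rows = rows[rows.category.str.startswith(category)]
    return [(r.id, Interval(int(r.printed_start), int(r.printed_end)))
            for r in rows.itertuples()]


def printed_sequences(category: str | None = None) -> dict[str, str]:
    rows = panel_table()
    if category is not None:
        rows = rows[rows.category.str.startswith(category)]
    return dict(zip(rows.id, rows.sequence))


def staggered_length_map() -> dict[str, int]:
    """Per-junction peptide length, keyed by staggered id (printed lengths)."""
    rows = panel_table()
    rows = rows[rows.category == "staggered"]
    return {r.id: len(r.sequence) for r in rows.itertuples()}


def ecori_fasta_path():
    """Path to the packaged reconstructed-chain FASTA (for CLI use)."""
    return resources.files("piakit").joinpath("data", "ecori_chain.fasta")


@lru_cache(maxsize=None)
def ecori_chain() -> ProteinChain:
    """The EcoRI chain (M1-K277) stitched from the original peptide set."""
    rows = panel_table()
    rows = rows[rows.category == "original"]
    peptides = [(Interval(int(r.printed_start), int(r.printed_end)), r.sequence)
                for r in rows.itertuples()]
    return stitch_chain(peptides, known_prefix="M", name="EcoRI")
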