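"""Bundled reference data.

Gene-table fixtures transcribed from the published annotations of the four
newly sequenced pteromalid wasp mitogenomes (GenBank MT712139-MT712142):
*Muscidifurax similadanacus*, *M. sinesensilla*, *Nasonia vitripennis* and
*Pachycrepoideus vindemmiae*.  Coordinates, strands and start/stop codons
follow the deposited annotation; sequences are not bundled (fetch the
accessions for sequence-level work).
"""

from __future__ import annotations

from importlib import resources

from .annotation_io import MitogenomeRecord, parse_gene_table

__all__ = [
    "PTEROMALID_IDS",
    "load_record",
    "load_all_records",
    "PUBLISHED_FULL_GENOME_COMPOSITION",
]

#: short key -> bundled fixture id
PTEROMALID_IDS = {
    "M_similadanacus": "MT712139_Muscidifurax_similadanacus",
    "M_sinesensilla": "MT712140_Muscidifurax_sinesensilla",
    "N_vitripennis": "MT712141_Nasonia_vitripennis",
    "P_vindemmiae": "MT712142_Pachycrepoideus_vindemmiae",
}

#: Published full-genome base percentages (A, T, G, C) for the four genomes,
#: as reported alongside the deposited annotations; inputs for skew
#: computations when the raw sequences are not at hand.
PUBLISHED_FULL_GENOME_COMPOSITION = {
    "M_similadanacus": {"A": 42.5, "T": 41.0, "G": 7.5, "C": 9.0},
    "M_sinesensilla": {"A": 43.4, "T": 40.7, "G": 7.1, "C": 8.8},
    "N_vitripennis": {"A": 43.5, "T": 39.6, "G": 7.5, "C": 9.4},
    "P_vindemmiae": {"A": 44.2, "T": 41.1, "G": 6.6, "C": 8.2},
}

#: Published tRNA-region base percentages for P. vindemmiae (the one region
#: with a negative AT skew among the four genomes).
PUBLISHED_PVIN_TRNA_COMPOSITION = {"A": 44.2, "T": 44.7, "G": 4.4, "C": 6.7}


def load_record(key: str) -> MitogenomeRecord:
    """Load one bundled pteromalid record by short key or full fixture id."""
    fixture = PTEROMALID_IDS.get(key, key)
    path = resources.files("mitocompare.data").joinpath(f"{fixture}.tsv")
    if not path.is_file():
        raise KeyError(f"no bundled record {key!r}; "
                       f"known keys: {sorted(PTEROMALID_IDS)}")
    return parse_gene_table(path.read_text())


def load_all_records() -> dict[str, MitogenomeRecord]:
    """All four bundled pteromalid records, keyed by short key."""
    return {k: load_record(k) for k in PTEROMALID_IDS}
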