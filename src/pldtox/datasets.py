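"""Packaged reference datasets.

``load_eukaryote_tree``/``load_pld_presence`` return the package's curated
summary of where the two metazoan-bearing PLD-toxin families (ST-like and
Aquatic) occur across eukaryotes, at phylum/class resolution: a rooted partial
eukaryote species tree with labelled major clades (M Metazoa, C Cnidaria,
D Deuterostomia, P Protostomia, S Spiralia, E Ecdysozoa, A Arthropoda,
H Hexapoda) and a matching presence/absence matrix transcribed from published
taxonomic distributions of the family.  Taxa whose presence rests on
transcriptome data only (Mollusca, Malacostraca) are encoded as present.

Running :func:`pldtox.loss_analysis.dollo_losses` on these data with the gain
placed at the root quantifies the gene-loss burden a pure vertical-descent
model must absorb for each family.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io_formats import SpeciesTree, read_newick, read_presence_matrix

__all__ = ["load_eukaryote_tree", "load_pld_presence"]


def _data_text(name: str) -> str:
    return resources.files("pldtox").joinpath("data", name).read_text()


def load_eukaryote_tree() -> SpeciesTree:
    """Rooted partial eukaryote species tree (31 tips, labelled major clades)."""
    return read_newick(_data_text("eukaryote_tree.nwk"))


def load_pld_presence() -> pd.DataFrame:
    """Presence/absence of the ST-like and Aquatic families per taxon."""
    import io

    return read_presence_matrix(io.StringIO(_data_text("eukaryote_presence.tsv")))
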