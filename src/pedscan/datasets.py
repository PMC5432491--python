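"""Built-in study data: the documented Tapidor/Ningyou7 breeding pedigree
and the published per-pair IBD tallies used in worked examples.

Tapidor (European winter oilseed rape) descends from Regent x Bienvenu;
Regent from Liho x Bronowski.  Ningyou7 (Chinese semi-winter) descends
from Chuanyou2 x Ningyou1; Chuanyou2 from Shengliyoucai x Chengduai.
Chengduai is *Brassica rapa*, i.e. carries only the A genome.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .io import PedigreeGraph

#: parent -> offspring crosses with breeding-cycle index (1 = earlier cross).
PEDIGREE_EDGES = [
    # Tapidor pedigree
    ("Liho", "Regent", 1),
    ("Bronowski", "Regent", 1),
    ("Regent", "Tapidor", 2),
    ("Bienvenu", "Tapidor", 2),
    # Ningyou7 pedigree
    ("Shengliyoucai", "Chuanyou2", 1),
    ("Chengduai", "Chuanyou2", 1),
    ("Chuanyou2", "Ningyou7", 2),
    ("Ningyou1", "Ningyou7", 2),
]

#: Final cultivar of each pedigree.
PEDIGREE_FINAL = {"Tapidor": "Tapidor", "Ningyou7": "Ningyou7"}

#: Members of each pedigree panel (five cultivars each).
PEDIGREE_PANELS = {
    "Tapidor": ["Liho", "Bronowski", "Regent", "Bienvenu", "Tapidor"],
    "Ningyou7": ["Shengliyoucai", "Chengduai", "Chuanyou2", "Ningyou1", "Ningyou7"],
}


def study_pedigree() -> PedigreeGraph:
    """The two-pedigree breeding DAG of the Tapidor/Ningyou7 study."""
    g = nx.DiGraph()
    for parent, offspring, cycle in PEDIGREE_EDGES:
        g.add_edge(parent, offspring, cycle=cycle)
    ped = PedigreeGraph(g)
    ped.set_species("Chengduai", "A")  # B. rapa, A genome only
    return ped


def published_pair_ibd() -> pd.DataFrame:
    """Published per-pair IBD block counts and total sizes (Mb) for the
    ancestor-vs-final-cultivar comparisons of both pedigrees."""
    rows = [
        ("Tapidor", "Liho", "Tapidor", 6, 6.6),
        ("Tapidor", "Bronowski", "Tapidor", 41, 26.0),
        ("Tapidor", "Regent", "Tapidor", 31, 78.5),
        ("Tapidor", "Bienvenu", "Tapidor", 48, 158.4),
        ("Ningyou7", "Shengliyoucai", "Ningyou7", 54, 248.5),
        ("Ningyou7", "Chengduai", "Ningyou7", 26, 34.8),
        ("Ningyou7", "Chuanyou2", "Ningyou7", 70, 417.7),
        ("Ningyou7", "Ningyou1", "Ningyou7", 77, 377.2),
    ]
    return pd.DataFrame(
        rows,
        columns=["pedigree", "ancestor", "descendant", "n_ibd", "total_size_mb"],
    )
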