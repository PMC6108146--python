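"""The 66-gene breast-cancer panel screened against the target gene.

The panel covers xenobiotic transport, proteolysis, steroid-receptor and
AKT/PI3K/WNT/Notch signalling, cell cycle, DNA damage and repair, adhesion,
angiogenesis, and lineage transcription factors — the functional classes a
breast-tumour association screen is expected to span.
"""

from __future__ import annotations

import pathlib
from typing import Iterable

#: Gene symbols (HGNC), alphabetical.
PANEL_66: tuple[str, ...] = (
    "ABCB1", "ABCG2", "ADAM23", "AKT1", "APC", "AR", "ATM", "BCL2", "BIRC5",
    "BRCA1", "BRCA2", "CCNA1", "CCND1", "CCND2", "CCNE1", "CDH13", "CDK2",
    "CDKN1A", "CDKN1C", "CDKN2A", "CST6", "CTNNB1", "CTSD", "EGF", "ERBB2",
    "ESR1", "ESR2", "FOXA1", "GATA3", "HIC1", "ID1", "IGF1", "IGF1R",
    "IGFBP3", "IL6", "JUN", "KRT19", "MAPK1", "MAPK3", "MAPK8", "MGMT",
    "MKI67", "MLH1", "MMP2", "MMP9", "MYC", "NME1", "NOTCH1", "NR3C1", "PGR",
    "PLAU", "PRDM2", "PTEN", "PYCARD", "RARB", "RASSF1", "RB1", "SERPINE1",
    "SFN", "SFRP1", "SLIT2", "THBS1", "TP53", "TP73", "VEGFA", "XBP1",
)


def read_panel_file(path: str | pathlib.Path) -> list[str]:
    """Read a gene panel: one symbol per line, '#' comments and blanks ignored."""
    genes: list[str] = []
    for line in pathlib.Path(path).read_text().splitlines():
        symbol = line.split("#", 1)[0].strip()
        if symbol:
            genes.append(symbol)
    return genes


def write_panel_file(genes: Iterable[str], path: str | pathlib.Path) -> None:
    pathlib.Path(path).write_text("\n".join(genes) + "\n")
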