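"""Published reference measurements used for validation and worked examples.

``PGK1_FAS2_AQUA`` holds absolute-quantification (AQUA) measurements of
eight acetylation sites on yeast 3-phosphoglycerate kinase (Pgk1) and
fatty acid synthase (Fas2) after treatment of lysate with 100 mM
acetyl-phosphate: the measured occupancy in percent (``s_acp``) and the
SILAC L/H fold change of the acetylated peptide (``ratio``).  From these
two inputs the pipeline derives the initial occupancy ``s0 = s_acp/ratio``
and the degree of chemical acetylation ``c = s_acp - s0``.
"""

from __future__ import annotations

from typing import NamedTuple


class AquaMeasurement(NamedTuple):
    protein: str
    peptide: str
    s_acp: float  # occupancy (%) after 100 mM acetyl-phosphate
    ratio: float  # SILAC L/H fold change of the acetylated peptide


PGK1_FAS2_AQUA: tuple = (
    AquaMeasurement("Pgk1", "AAGFLLEK(ac)ELK", 0.023, 80.8),
    AquaMeasurement("Pgk1", "AGAEIVPK(ac)LMEK", 0.095, 41.5),
    AquaMeasurement("Pgk1", "FAAGTK(ac)ALLDEVVK", 0.119, 27.7),
    AquaMeasurement("Fas2", "QVLDVDPVYKDVA(ac)PTGPK", 0.032, 108.3),
    AquaMeasurement("Fas2", "LIEPELFNGYNPE(ac)K", 0.092, 33.5),
    AquaMeasurement("Fas2", "GATLYIP(ac)ALR", 0.068, 11.3),
    AquaMeasurement("Fas2", "SEGNPVIGVFQ(ac)FLTGHPK", 0.016, 5.3),
    AquaMeasurement("Fas2", "AND(ac)NESATINEMMK", 0.181, 1.7),
)
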