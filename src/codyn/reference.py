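"""Published reference values from the AD11 anti-NGF mouse time-course study
(case = AD11 transgenic, control = VH littermates; GEO series GSE63617;
timepoints 1, 3, 6, 15 months).

These are printed result tables, used as *inputs* to the report/summary
operations (e.g. in worked examples and cross-checks); they are not computed
by this package.  ``AD11_QUADRUPLETS`` lists every complex of size > 3 whose
published quadruplet is not (0, 0, 0, 0).  ``AD11_DISTANCES`` lists the
published distance rows (d per timepoint with its z-score against the
1000-random-complex null).
"""

from __future__ import annotations

TIMEPOINTS = ("1", "3", "6", "15")

# complex name -> (size, quadruplet over months 1, 3, 6, 15)
AD11_QUADRUPLETS: dict[str, tuple[int, tuple[int, int, int, int]]] = {
    "Parvulin-associated-pre-rRNP-complex": (40, (1, 0, 0, -1)),
    "20S-proteasome": (14, (1, 0, 0, 0)),
    "immunoproteasome": (14, (1, 0, 0, 0)),
    "B-Ksr1-MEK-MAPK-14-3-3-complex": (8, (0, 0, -1, 0)),
    "Gata1-Fog1-MeCP1-complex": (8, (0, 1, 0, 0)),
    "Drosha-complex": (7, (1, 0, 0, 0)),
    "BLOC-1-biogenesis-of-lysosome-related-organelles": (6, (0, 0, -1, 0)),
    "Metallothionein-3-complex": (6, (0, 0, 0, -1)),
    "Brd4-Rfc-complex": (5, (1, 0, 0, 0)),
    "MCM-complex": (5, (1, -1, 0, 0)),
    "Agap11-AP3-complex": (4, (1, 0, 0, 0)),
    "Kif3-cadherin-catenin-complex": (4, (1, 0, 0, 0)),
    "Sarcoglycan-sarcospan-syntrophin-dystrobrevin": (4, (0, 0, 1, 0)),
    "Wave-2-complex-Rac-activated": (4, (-1, 0, 0, 0)),
}

# complex name -> (size, d per timepoint, z per timepoint)
AD11_DISTANCES: dict[str, tuple[int, tuple[float, ...], tuple[float, ...]]] = {
    "immunoproteasome": (14, (0.26, 0.14, 0.2, 0.16), (2.22, -2.45, -0.22, 0.19)),
    "Mediator-complex": (7, (0.29, 0.2, 0.16, 0.11), (2.10, 0.09, -1.00, 1.17)),
    "Wave-2-complex-Rac-activated": (4, (0.33, 0.07, 0.33, 0.36), (1.98, -1.85, 1.97, 3.39)),
    "p97-Ufd1-Npl4-IP3-receptor-complex": (4, (0.34, 0.21, 0.16, 0.20), (2.14, 0.31, -0.56, 0.86)),
    "Tis7-Sin3-Hdac1-Ncor1-Sap30-complex": (4, (0.34, 0.2, 0.12, 0.03), (2.14, 0.16, -1.16, -1.81)),
    "Axin-Dvl-Gsk-Frat1-complex": (4, (0.28, 0.33, 0.13, 0.1), (1.20, 2.17, -1.01, -0.7)),
    "PYR-complex": (10, (0.19, 0.16, 0.17, 0.27), (-0.67, -1.22, -0.98, 3.20)),
    "PU,1-associated-protein-complex": (4, (0.21, 0.21, 0.21, 0.3), (0.11, 0.31, 0.18, 2.44)),
    "TFIID-complex": (7, (0.25, 0.15, 0.17, 0.2), (1.09, -1.16, -0.76, 2.15)),
    "ORC-complex-origin-recognition-complex": (4, (0.21, 0.18, 0.27, 0.27), (0.11, -0.14, 1.07, 1.97)),
}

WAVE2_Z_SCORES: tuple[float, ...] = AD11_DISTANCES["Wave-2-complex-Rac-activated"][2]
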