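"""The default catalog of the 48 human nuclear-receptor genes.

The human genome encodes 48 ligand-activated transcription factors of the
nuclear-receptor superfamily; screening restricts disease-intersection
candidates to this family. Users may substitute their own catalog file
(one symbol per line) anywhere a catalog is accepted.
"""

from __future__ import annotations

DEFAULT_NR_CATALOG: tuple[str, ...] = (
    # NR0: DAX-like
    "NR0B1", "NR0B2",
    # NR1: thyroid hormone receptor-like
    "THRA", "THRB",
    "RARA", "RARB", "RARG",
    "PPARA", "PPARD", "PPARG",
    "NR1D1", "NR1D2",
    "RORA", "RORB", "RORC",
    "NR1H2", "NR1H3", "NR1H4",
    "NR1I2", "NR1I3", "VDR",
    # NR2: retinoid X receptor-like
    "HNF4A", "HNF4G",
    "RXRA", "RXRB", "RXRG",
    "NR2C1", "NR2C2",
    "NR2E1", "NR2E3",
    "NR2F1", "NR2F2", "NR2F6",
    # NR3: estrogen receptor-like
    "ESR1", "ESR2",
    "ESRRA", "ESRRB", "ESRRG",
    "NR3C1", "NR3C2", "PGR", "AR",
    # NR4: nerve growth factor IB-like
    "NR4A1", "NR4A2", "NR4A3",
    # NR5: steroidogenic factor-like
    "NR5A1", "NR5A2",
    # NR6: germ cell nuclear factor
    "NR6A1",
)

assert len(DEFAULT_NR_CATALOG) == 48
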