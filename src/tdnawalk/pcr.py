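"""PCR arithmetic for the two-phase walking reaction."""

from __future__ import annotations


def linear_phase_enrichment(linear_cycles: int) -> float:
    """Fold enrichment of transgene-containing template over background after
    the high-temperature linear phase.

    During the linear phase only the transgene-specific primer binds, adding
    one copy of each transgene-containing fragment per cycle while background
    molecules are not amplified: after c cycles the template is present at
    1 + c times its starting abundance (19x after the standard 18 cycles).
    """
    if linear_cycles < 0:
        raise ValueError("cycle count must be non-negative")
    return float(1 + linear_cycles)
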