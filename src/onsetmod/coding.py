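"""Genotype-to-score maps for the three single-locus genetic models.

On minor-allele dosage d in {0,1,2}: additive keeps d, dominant scores
carriers (d >= 1), recessive scores minor-allele homozygotes (d == 2).
``reference='major'`` flips the dosage first (d -> 2 - d), which lets a
"dominant" model group genotypes around the major allele instead —
needed because modifier alleles can act through either orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CODING_MODES = ("additive", "dominant", "recessive")


@dataclass(frozen=True)
class GeneticCoding:
    mode: str = "dominant"
    reference: str = "minor"  # which allele the coding counts

    def __post_init__(self):
        if self.mode not in CODING_MODES:
            raise ValueError(f"unknown coding mode {self.mode!r}")
        if self.reference not in ("minor", "major"):
            raise ValueError(f"reference must be 'minor' or 'major', got {self.reference!r}")


def code_genotype(dosage: np.ndarray, mode: str = "dominant", reference: str = "minor") -> np.ndarray:
    """Apply a genetic coding to a minor-allele dosage vector (NaN preserved)."""
    GeneticCoding(mode, reference)  # validate
    d = np.asarray(dosage, dtype=float)
    if reference == "major":
        d = 2.0 - d
    if mode == "additive":
        out = d.copy()
    elif mode == "dominant":
        out = (d >= 1).astype(float)
    else:  # recessive
        out = (d == 2).astype(float)
    out[np.isnan(d)] = np.nan
    return out
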