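"""Single-position substitution scans of a seed peptide.

A scan takes a seed (e.g. the 7-mer polyproline PPPPPPP) and a substitute
alphabet (e.g. {A, G, R}) and generates every variant differing from the
seed at exactly one position.  Against a screen dataset the scan becomes
a position x residue matrix of aggregated intensities whose maximum cell
identifies the strongest-binding variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ScreenDataset


@dataclass
class SubstitutionScan:
    seed: str
    substitutes: tuple[str, ...]
    variants: list[tuple[int, str, str]]  # (1-based position, residue, sequence)

    @property
    def sequences(self) -> list[str]:
        return [seq for _, _, seq in self.variants]


def generate_scan(seed: str, substitutes: "list[str] | tuple[str, ...] | str") -> SubstitutionScan:
    """All single-position variants, position-major then substitute order.

    A substitute equal to the seed residue at a position would reproduce
    the seed and is excluded; the seed itself serves as the reference.
    """
    if not seed:
        raise ValueError("empty seed peptide")
    substitutes = tuple(substitutes)
    if not substitutes:
        raise ValueError("empty substitute set")
    variants = []
    for pos, residue in enumerate(seed):
        for sub in substitutes:
            if sub == residue:
                continue
            variants.append((pos + 1, sub, seed[:pos] + sub + seed[pos + 1 :]))
    if not variants:
        raise ValueError("scan is empty: every substitute equals the seed residue")
    return SubstitutionScan(seed=seed, substitutes=substitutes, variants=variants)


@dataclass
class ScanResult:
    matrix: pd.DataFrame  # index: position 1..L, columns: substitutes
    seed_intensity: float | None
    best_position: int
    best_residue: str
    best_sequence: str
    best_intensity: float
    missing: list[str] = field(default_factory=list)


def scan_matrix(scan: SubstitutionScan, dataset: ScreenDataset, channel: str) -> ScanResult:
    """Aggregate intensities of every scan variant into the scan matrix.

    Variants absent from the dataset leave their cell missing (NaN, never
    zero) and are reported with a warning.  The maximum is taken in
    position-major, then substitute, order so ties resolve
    deterministically.
    """
    agg = dataset.aggregated
    sel = agg[agg["channel"] == channel].set_index("peptide")["intensity"]
    matrix = pd.DataFrame(
        np.nan,
        index=pd.Index(range(1, len(scan.seed) + 1), name="position"),
        columns=list(scan.substitutes),
    )
    missing = []
    best: tuple[float, int, str, str] | None = None
    for pos, residue, seq in scan.variants:
        if seq in sel.index:
            value = float(sel.loc[seq])
            matrix.loc[pos, residue] = value
            if best is None or value > best[0]:
                best = (value, pos, residue, seq)
        else:
            missing.append(seq)
    if missing:
        warnings.warn(f"{len(missing)} scan variants missing from dataset", stacklevel=2)
    if best is None:
        raise ValueError("no scan variant present in the dataset")
    seed_intensity = float(sel.loc[scan.seed]) if scan.seed in sel.index else None
    value, pos, residue, seq = best
    return ScanResult(
        matrix=matrix,
        seed_intensity=seed_intensity,
        best_position=pos,
        best_residue=residue,
        best_sequence=seq,
        best_intensity=value,
        missing=missing,
    )
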