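"""Sum physicochemical properties of array peptides.

The property-versus-intensity analyses use additive per-residue scales:
net side-chain charge at pH 7.4, Kyte-Doolittle hydrophobicity,
Pace-Scholtz helix propensity (kcal/mol) and average residue molecular
weight.  Because the array peptides are N-acetylated and surface-attached
via a C-terminal beta-alanine linker, the default charge scale gives the
termini no charge and the weight scale adds only the acetyl mass.  Scales
are plain data (``data/scales.yaml``) and fully pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

from .io import ScreenDataset


@dataclass(frozen=True)
class PropertyScale:
    name: str
    units: str
    values: dict[str, float]
    n_terminal: float = 0.0
    c_terminal: float = 0.0
    description: str = ""


def load_scales(source: str | None = None) -> dict[str, PropertyScale]:
    """Load the bundled (or a user-supplied) scale collection."""
    if source is None:
        text = resources.files("protopep.data").joinpath("scales.yaml").read_text()
    else:
        with open(source) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    scales = {}
    for key, entry in raw.items():
        scales[key] = PropertyScale(
            name=entry["name"],
            units=entry["units"],
            values={str(k): float(v) for k, v in entry["values"].items()},
            n_terminal=float(entry.get("n_terminal", 0.0)),
            c_terminal=float(entry.get("c_terminal", 0.0)),
            description=entry.get("description", ""),
        )
    return scales


def sum_property(sequence: str, scale: PropertyScale) -> float:
    """Sum of per-residue values plus the terminal adjustments.

    Additive: with zero terminal adjustments the property of a
    concatenation is the sum of the parts, and it depends only on residue
    composition, not order.
    """
    if not sequence:
        raise ValueError("empty sequence")
    total = scale.n_terminal + scale.c_terminal
    for residue in sequence:
        try:
            total += scale.values[residue]
        except KeyError:
            raise ValueError(
                f"residue {residue!r} not covered by scale {scale.name!r}"
            ) from None
    return total


def property_table(
    dataset: ScreenDataset, scales: "list[PropertyScale] | dict[str, PropertyScale] | None" = None
) -> pd.DataFrame:
    """Per-(peptide, channel) table of all sum properties plus intensity."""
    if scales is None:
        scales = load_scales()
    if isinstance(scales, dict):
        scales = list(scales.values())
    table = dataset.aggregated.copy()
    peptides = table["peptide"].unique()
    for scale in scales:
        per_pep = {p: sum_property(p, scale) for p in peptides}
        table[scale.name] = table["peptide"].map(per_pep)
    return table
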