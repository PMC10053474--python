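"""Photometric-table I/O and screen-dataset assembly.

Scanner software exports one row per spot with per-channel fluorescence
intensities in arbitrary units.  Two tab-separated dialects are read:

``long``
    columns ``spot_id  channel  intensity`` (optional ``background``,
    ``flag``) — the dialect this package writes;
``gpr``
    a GenePix-results-like wide table with ``Row``/``Column`` coordinates
    and per-wavelength columns ``F<wl> Median`` / ``B<wl> Median``, which
    is melted into the long form with the wavelength as channel label.

A :class:`ScreenDataset` joins an intensity table with the array manifest
so that every signal carries its peptide, library and RNA channel, plus a
per-peptide aggregated view (default: median across replicate spots).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import ArrayDesign

LONG_REQUIRED = ["spot_id", "channel", "intensity"]


def read_photometric_table(path: str, dialect: str = "long") -> pd.DataFrame:
    """Read a photometric table into the normalized long form.

    Malformed content (missing columns, negative intensities, duplicate
    (spot, channel) rows) raises ``ValueError`` naming the offending rows
    (1-based file line numbers, header = line 1).
    """
    if dialect == "long":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in LONG_REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
    elif dialect == "gpr":
        df = pd.read_csv(path, sep="\t", comment="#")
        coord_cols = [c for c in ("Row", "Column") if c in df.columns]
        if len(coord_cols) != 2:
            raise ValueError(f"{path}: gpr dialect requires Row and Column columns")
        fg = {m.group(1): c for c in df.columns for m in [re.match(r"^F(\w+) Median$", c)] if m}
        bg = {m.group(1): c for c in df.columns for m in [re.match(r"^B(\w+) Median$", c)] if m}
        if not fg:
            raise ValueError(f"{path}: no 'F<wavelength> Median' columns found")
        frames = []
        for wl, col in sorted(fg.items()):
            part = pd.DataFrame(
                {
                    "spot_id": [
                        f"R{r}C{c}" for r, c in zip(df["Row"], df["Column"])
                    ],
                    "channel": wl,
                    "intensity": df[col].astype(float),
                }
            )
            if wl in bg:
                part["background"] = df[bg[wl]].astype(float)
            frames.append(part)
        df = pd.concat(frames, ignore_index=True)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df["channel"] = df["channel"].astype(str)
    bad = df.index[df["intensity"] < 0]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]
        raise ValueError(f"{path}: negative intensity at line(s) {lines}")
    dup = df.duplicated(subset=["spot_id", "channel"])
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup][:10]]
        raise ValueError(f"{path}: duplicate (spot, channel) at line(s) {lines}")
    return df.reset_index(drop=True)


def write_intensity_table(table: pd.DataFrame, path: str) -> None:
    """Write a long-form intensity table (round-trips through the reader)."""
    cols = LONG_REQUIRED + [c for c in ("background", "flag") if c in table.columns]
    table[cols].to_csv(path, sep="\t", index=False)


@dataclass
class ScreenDataset:
    """Joined spot intensities with peptide and library annotations.

    ``spots`` has one row per (spot, RNA channel) signal; ``aggregated``
    one row per (peptide, channel) with the aggregation statistic applied
    across replicate copies.
    """

    spots: pd.DataFrame  # spot_id,row,col,peptide,library_id,copy,channel,intensity
    aggregated: pd.DataFrame  # peptide,library_id,channel,intensity,n_spots
    channel_map: dict[str, str]
    aggregator: str = "median"
    missing_spots: list[str] = field(default_factory=list)

    @property
    def channels(self) -> list[str]:
        return sorted(self.spots["channel"].unique())


def build_screen_dataset(
    design: ArrayDesign,
    intensities: pd.DataFrame,
    channel_map: dict[str, str] | None = None,
    aggregator: str = "median",
    missing_tolerance: float = 0.0,
    background_subtract: bool = False,
) -> ScreenDataset:
    """Join an intensity table with the array manifest.

    ``channel_map`` translates raw channel labels (dye/wavelength) to RNA
    channel names; ``None`` keeps the labels as-is.  Intensity rows whose
    spot id is absent from the manifest fail the join; they are tolerated
    only up to ``missing_tolerance`` as a fraction of all rows.  Manifest
    spots with no intensity in some channel are recorded in
    ``missing_spots`` but never fatal.
    """
    table = intensities.copy()
    if channel_map is not None:
        unknown = set(table["channel"].unique()) - set(channel_map)
        if unknown:
            raise ValueError(f"channels {sorted(unknown)} missing from channel map")
        table["channel"] = table["channel"].map(channel_map)
    if background_subtract:
        if "background" not in table.columns:
            raise ValueError("background subtraction requested but no background column")
        table["intensity"] = (table["intensity"] - table["background"]).clip(lower=0.0)

    manifest = design.spots
    unresolvable = ~table["spot_id"].isin(manifest["spot_id"])
    if unresolvable.any():
        frac = unresolvable.mean()
        if frac > missing_tolerance:
            examples = sorted(table.loc[unresolvable, "spot_id"].unique()[:5])
            raise ValueError(
                f"{unresolvable.sum()} intensity rows ({frac:.1%}) have spot ids "
                f"not in the manifest (e.g. {examples})"
            )
        table = table.loc[~unresolvable]

    spots = manifest.merge(
        table[["spot_id", "channel", "intensity"]], on="spot_id", how="inner"
    )
    channels = list(table["channel"].unique())
    missing: list[str] = []
    if len(spots) < len(manifest) * len(channels):
        present = set(zip(spots["spot_id"], spots["channel"]))
        missing = sorted(
            f"{s}/{c}"
            for s in manifest["spot_id"]
            for c in channels
            if (s, c) not in present
        )

    grouped = spots.groupby(["peptide", "library_id", "channel"], sort=True)["intensity"]
    aggregated = grouped.agg(intensity=aggregator, n_spots="count").reset_index()
    return ScreenDataset(
        spots=spots.reset_index(drop=True),
        aggregated=aggregated,
        channel_map=channel_map or {c: c for c in table["channel"].unique()},
        aggregator=aggregator,
        missing_spots=missing,
    )


def channel_summary(dataset: ScreenDataset, level: str = "spot") -> pd.DataFrame:
    """Per (library, RNA channel) signal statistics: n, mean, sample sd."""
    if level == "spot":
        df = dataset.spots
    elif level == "peptide":
        df = dataset.aggregated
    else:
        raise ValueError(f"level must be 'spot' or 'peptide', not {level!r}")
    if df.empty:
        raise ValueError("empty dataset")
    out = (
        df.groupby(["library_id", "channel"], sort=True)["intensity"]
        .agg(n="count", mean="mean", sd=lambda x: x.std(ddof=1))
        .reset_index()
    )
    return out
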