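"""Fragment interaction scoring and binding-signature tables.

The core statistic of the screen.  Every contiguous fragment m of the
library peptides is associated with the set of fluorescent signals I_m of
all peptides containing it (a peptide counts once however often m occurs
inside it), and ranked by the interaction score

    R_m = mean(I_m) / sd(I_m)

with the sample (ddof=1) standard deviation.  R_m rewards fragments whose
carrier peptides light up consistently: a homogeneous bright signal set
scores high, a heterogeneous one is penalized through its sd.

Ranked fragments are arranged into cumulative signature columns: column n
holds all fragments of lengths k_min..n sorted by descending R_m, so that
comparing consecutive columns shows how short signatures are displaced by
longer ones as the considered fragment length grows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ScreenDataset

SCORE_COLUMNS = ["fragment", "length", "support", "mean", "sd", "R"]


def enumerate_fragments(sequence: str, k_min: int = 1, k_max: int | None = None) -> set[str]:
    """All distinct contiguous substrings with length in [k_min, k_max]."""
    if k_max is None:
        k_max = len(sequence)
    if not (1 <= k_min <= k_max <= len(sequence)):
        raise ValueError(
            f"invalid k range [{k_min}, {k_max}] for sequence of length {len(sequence)}"
        )
    return {
        sequence[i : i + k]
        for k in range(k_min, k_max + 1)
        for i in range(len(sequence) - k + 1)
    }


def _sort_scores(df: pd.DataFrame) -> pd.DataFrame:
    """Descending R; ties broken longer-first, then lexicographically."""
    return df.sort_values(
        by=["R", "length", "fragment"], ascending=[False, False, True]
    ).reset_index(drop=True)


def score_fragments(
    dataset: ScreenDataset,
    channel: str,
    library_id: str | None = None,
    k_min: int = 3,
    k_max: int | None = None,
    min_support: int = 3,
    level: str = "spot",
    occurrence_weighted: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every fragment of the selected library/channel slice.

    Returns ``(scores, gated)``: scores has columns fragment, length,
    support, mean, sd, R for every fragment with support >= min_support
    and sd > 0, sorted by descending R; fragments failing the gate are
    reported in ``gated`` with a reason, never scored as infinite.

    ``level='spot'`` (default) pools every replicate spot signal into I_m;
    ``level='peptide'`` uses the per-peptide aggregated intensities.  With
    ``occurrence_weighted=True`` a peptide's signal enters I_m once per
    occurrence of m instead of once per peptide.
    """
    df = dataset.spots if level == "spot" else dataset.aggregated
    if df.empty:
        raise ValueError("empty dataset")
    if channel not in set(df["channel"]):
        raise ValueError(f"channel {channel!r} not present in dataset")
    sel = df[df["channel"] == channel]
    if library_id is not None:
        sel = sel[sel["library_id"] == library_id]
        if sel.empty:
            raise ValueError(f"library {library_id!r} not present in dataset")

    peptides = pd.unique(sel["peptide"])
    k_hi = k_max or max(len(p) for p in peptides)
    frag_rows: list[tuple[str, str, int]] = []
    for p in peptides:
        frags = enumerate_fragments(p, k_min, min(k_hi, len(p)))
        if occurrence_weighted:
            frag_rows.extend(
                (p, f, len(re.findall(f"(?={re.escape(f)})", p))) for f in frags
            )
        else:
            frag_rows.extend((p, f, 1) for f in frags)
    pairs = pd.DataFrame(frag_rows, columns=["peptide", "fragment", "weight"])
    merged = pairs.merge(sel[["peptide", "intensity"]], on="peptide")
    if occurrence_weighted:
        merged = merged.loc[merged.index.repeat(merged["weight"])]

    stats = merged.groupby("fragment", sort=True)["intensity"].agg(
        support="count", mean="mean", sd=lambda x: x.std(ddof=1)
    )
    stats = stats.reset_index()
    stats["length"] = stats["fragment"].str.len()
    stats["sd"] = stats["sd"].fillna(0.0)

    ok = (stats["support"] >= min_support) & (stats["sd"] > 0)
    scores = stats.loc[ok].copy()
    scores["R"] = scores["mean"] / scores["sd"]
    scores = _sort_scores(scores[SCORE_COLUMNS])

    gated = stats.loc[~ok, ["fragment", "length", "support", "mean", "sd"]].copy()
    gated["reason"] = np.where(
        gated["support"] < min_support, f"support < {min_support}", "sd == 0"
    )
    return scores, gated.reset_index(drop=True)


@dataclass
class SignatureTable:
    """Cumulative-length ranked signature columns.

    ``columns[n]`` holds the top fragments among all scored fragments of
    length k_min..n, in descending R order.
    """

    columns: dict[int, pd.DataFrame]
    k_min: int
    top_n: int

    def label(self, n: int) -> str:
        return f"{self.k_min}mer" if n == self.k_min else f"{self.k_min}-{n}mer"

    @property
    def lengths(self) -> list[int]:
        return sorted(self.columns)

    def to_wide(self) -> pd.DataFrame:
        data = {
            self.label(n): self.columns[n]["fragment"].reset_index(drop=True)
            for n in self.lengths
        }
        return pd.DataFrame(data)


def build_signature_table(scores: pd.DataFrame, top_n: int = 25) -> SignatureTable:
    """Arrange scored fragments into cumulative signature columns."""
    if scores.empty:
        raise ValueError("no scored fragments")
    k_min = int(scores["length"].min())
    k_max = int(scores["length"].max())
    ordered = _sort_scores(scores)
    columns = {
        n: ordered[ordered["length"] <= n].head(top_n).reset_index(drop=True)
        for n in range(k_min, k_max + 1)
    }
    return SignatureTable(columns=columns, k_min=k_min, top_n=top_n)


def displacement_analysis(table: SignatureTable) -> pd.DataFrame:
    """Track which top fragments survive from each column to the next.

    One row per column transition with the fragments retained, displaced
    (present in the top-N of column n but not of column n+1) and entering.
    """
    lengths = table.lengths
    if len(lengths) < 2:
        raise ValueError("displacement analysis needs at least two columns")
    rows = []
    for a, b in zip(lengths, lengths[1:]):
        prev = list(table.columns[a]["fragment"])
        nxt = set(table.columns[b]["fragment"])
        displaced = [f for f in prev if f not in nxt]
        rows.append(
            {
                "from_column": table.label(a),
                "to_column": table.label(b),
                "retained": [f for f in prev if f in nxt],
                "displaced": displaced,
                "entered": [f for f in table.columns[b]["fragment"] if f not in set(prev)],
            }
        )
    return pd.DataFrame(rows)


def composition_trend(table: SignatureTable, residues: set[str]) -> pd.DataFrame:
    """Mean count of the given residues among each column's top fragments."""
    rows = []
    for n in table.lengths:
        frags = table.columns[n]["fragment"]
        counts = [sum(f.count(r) for r in residues) for f in frags]
        rows.append(
            {
                "column": table.label(n),
                "max_length": n,
                "mean_residue_count": float(np.mean(counts)) if counts else 0.0,
                "n_fragments": len(counts),
            }
        )
    return pd.DataFrame(rows)
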