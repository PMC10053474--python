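"""Combinatorial peptide libraries and replicated, randomized array layouts.

A library is the full combinatorial enumeration of peptides of a fixed
length over a protocode amino-acid alphabet (e.g. all 4^7 = 16,384 7-mers
over {G,P,A,R}).  Libraries are printed onto a logical array grid with a
fixed number of replicate spots per peptide, allocated at seeded-random
positions to avoid local incubation effects.  Sequences are stored N->C;
the N-terminal acetyl cap and the C-terminal beta-alanine linker are
chemistry metadata, not sequence characters.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MANIFEST_COLUMNS = ["spot_id", "row", "col", "peptide", "library_id", "copy"]


@dataclass
class PeptideLibrary:
    library_id: str
    alphabet: tuple[str, ...]
    length: int
    peptides: list[str]
    copies: int = 1

    def __post_init__(self) -> None:
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError(f"{self.library_id}: duplicate alphabet symbols")
        n_max = len(self.alphabet) ** self.length
        if len(self.peptides) > n_max:
            raise ValueError(f"{self.library_id}: more peptides than {n_max} possible")
        if len(set(self.peptides)) != len(self.peptides):
            raise ValueError(f"{self.library_id}: duplicate peptide sequences")
        allowed = set(self.alphabet)
        for p in self.peptides:
            if len(p) != self.length or any(r not in allowed for r in p):
                raise ValueError(f"{self.library_id}: invalid peptide {p!r}")

    def __len__(self) -> int:
        return len(self.peptides)


def enumerate_library(
    alphabet: "list[str] | tuple[str, ...] | str",
    length: int,
    library_id: str | None = None,
    copies: int = 1,
    cap: int = 10**7,
) -> PeptideLibrary:
    """Enumerate all |alphabet|^length peptides in lexicographic order."""
    alphabet = tuple(alphabet)
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    if len(set(alphabet)) != len(alphabet):
        raise ValueError("duplicate alphabet symbols")
    if length < 1:
        raise ValueError("length must be >= 1")
    n = len(alphabet) ** length
    if n > cap:
        raise ValueError(f"{n} peptides exceeds the cap of {cap}")
    letters = sorted(alphabet)
    peptides = ["".join(t) for t in itertools.product(letters, repeat=length)]
    return PeptideLibrary(
        library_id=library_id or "".join(letters) + f"_{length}mer",
        alphabet=alphabet,
        length=length,
        peptides=peptides,
        copies=copies,
    )


def subset_library(library: PeptideLibrary, n: int, seed: int) -> PeptideLibrary:
    """Seeded uniform subsample of ``n`` peptides without replacement."""
    if n > len(library.peptides):
        raise ValueError(f"cannot take {n} of {len(library.peptides)} peptides")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(library.peptides), size=n, replace=False))
    return PeptideLibrary(
        library_id=library.library_id,
        alphabet=library.alphabet,
        length=library.length,
        peptides=[library.peptides[i] for i in idx],
        copies=library.copies,
    )


@dataclass
class ArrayDesign:
    """Randomized, replicated placement of library peptides on a grid."""

    spots: pd.DataFrame  # columns: spot_id, row, col, peptide, library_id, copy
    seed: int
    n_rows: int
    n_cols: int
    pitch_um: float = 60.0
    acetyl_n_terminus: bool = True
    beta_alanine_linker: bool = True
    library_ids: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if list(self.spots.columns) != MANIFEST_COLUMNS:
            raise ValueError(f"manifest columns must be {MANIFEST_COLUMNS}")
        coords = list(zip(self.spots["row"], self.spots["col"]))
        if len(set(coords)) != len(coords):
            raise ValueError("duplicate spot coordinates")
        if self.spots["spot_id"].duplicated().any():
            raise ValueError("duplicate spot ids")

    def to_manifest(self, path: str) -> None:
        self.spots.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_manifest(cls, path: str, **meta) -> "ArrayDesign":
        spots = pd.read_csv(path, sep="\t", dtype={"peptide": str, "library_id": str})
        missing = set(MANIFEST_COLUMNS) - set(spots.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        spots = spots[MANIFEST_COLUMNS]
        design = cls(
            spots=spots,
            seed=meta.pop("seed", -1),
            n_rows=int(spots["row"].max()) + 1,
            n_cols=int(spots["col"].max()) + 1,
            library_ids=sorted(spots["library_id"].unique()),
            **meta,
        )
        design.validate()
        return design


def layout_array(
    libraries: list[PeptideLibrary],
    seed: int,
    copies: dict[str, int] | None = None,
    n_rows: int | None = None,
    n_cols: int | None = None,
) -> ArrayDesign:
    """Place every (peptide, copy) on a seeded-random grid position.

    ``copies`` overrides each library's own replicate count.  The default
    grid is the smallest near-square grid holding all spots.  The same
    inputs and seed always produce a byte-identical manifest.
    """
    entries: list[tuple[str, str, int]] = []
    for lib in libraries:
        c = (copies or {}).get(lib.library_id, lib.copies)
        for peptide in lib.peptides:
            for k in range(c):
                entries.append((peptide, lib.library_id, k))
    total = len(entries)
    if total == 0:
        raise ValueError("no spots to lay out")
    if n_cols is None:
        n_cols = math.ceil(math.sqrt(total))
    if n_rows is None:
        n_rows = math.ceil(total / n_cols)
    if n_rows * n_cols < total:
        raise ValueError(f"grid {n_rows}x{n_cols} too small for {total} spots")
    rng = np.random.default_rng(seed)
    order = rng.permutation(total)
    spots = pd.DataFrame(
        [entries[i] for i in order], columns=["peptide", "library_id", "copy"]
    )
    positions = np.arange(total)
    spots.insert(0, "spot_id", [f"S{i:06d}" for i in positions])
    spots.insert(1, "row", positions // n_cols)
    spots.insert(2, "col", positions % n_cols)
    design = ArrayDesign(
        spots=spots[MANIFEST_COLUMNS],
        seed=seed,
        n_rows=n_rows,
        n_cols=n_cols,
        library_ids=[lib.library_id for lib in libraries],
    )
    design.validate()
    return design
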