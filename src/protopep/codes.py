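"""Protocode model: two-base proto-genetic-codes and their fusion to the SGC.

The model partitions (most of) the canonical amino acids into four
*protocodes*: a dominant and a recessive code over the A/U base pair and a
dominant and a recessive code over the G/C base pair.  Within each base
pair the dominant and recessive protocodes compete for the same eight
two-base codons (e.g. Phe vs Leu for UUU, Pro vs Ser for CCC).

The *combinatorial fusion* of the protocodes into the standard genetic
code (SGC) is driven by transition mutations A<->G and U<->C:

* dominant amino acids keep their original codons and additionally gain
  the third-position transition mutants;
* recessive amino acids are re-assigned ("take what's left") to free
  codons reachable by a first-position transition, or a simultaneous
  first-and-third-position transition, chosen so that the reverse
  complementarity between partner codons within the recessive protocode is
  preserved;
* placeholders X1, X1* and X2 are members that disappeared: deletion of X1
  turns UAA/UAG into stop codons, X1*'s codon is taken over by Leu, and
  X2's mutants become the UGA stop and the late-entrant Trp codon UGG.
  Met (AUG) and Trp (UGG) entered the code after fusion, which is why the
  third-position mutant of Ile's AUA is ceded rather than kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml
from Bio.Data.CodonTable import unambiguous_rna_by_id

RNA_BASES = ("A", "C", "G", "U")
TRANSITION = {"A": "G", "G": "A", "U": "C", "C": "U"}
COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")
PLACEHOLDERS = {"X1", "X1*", "X2"}

#: non-placeholder membership required of each protocode
EXPECTED_MEMBERS = {
    "AU-dominant": {"K", "F", "N", "I", "Y"},
    "AU-recessive": {"E", "L", "D", "V", "Q", "H"},
    "GC-dominant": {"G", "P", "A", "R"},
    "GC-recessive": {"S", "T", "C", "R"},
}

RULE_RETAINED = "retained"
RULE_THIRD = "third-position transition"
RULE_FIRST = "first-position transition"
RULE_FIRST_THIRD = "first-and-third-position transition"
RULE_INHERITED = "inherited from deleted competitor"


def transition_mutant(codon: str, positions: Iterable[int]) -> str:
    """Apply A<->G / U<->C transitions at the given 0-based positions."""
    bases = list(codon)
    for pos in positions:
        bases[pos] = TRANSITION[bases[pos]]
    return "".join(bases)


def reverse_complement(codon: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(codon))


class ProtocodeError(ValueError):
    """Raised when a protocode configuration violates an invariant."""


@dataclass(frozen=True)
class ProtocodeMember:
    symbol: str
    codons: frozenset[str]
    deleted: bool = False


@dataclass
class Protocode:
    """One proto-genetic-code over a complementary base pair."""

    name: str
    base_alphabet: tuple[str, str]
    members: list[ProtocodeMember]
    complement_pairs: list[tuple[str, str]]
    dominance: str  # "dominant" | "recessive"

    @property
    def assignments(self) -> dict[str, frozenset[str]]:
        return {m.symbol: m.codons for m in self.members}

    def member(self, symbol: str) -> ProtocodeMember:
        for m in self.members:
            if m.symbol == symbol:
                return m
        raise KeyError(symbol)

    def validate(self) -> None:
        allowed = set(self.base_alphabet)
        if len(allowed) != 2 or any(b not in RNA_BASES for b in allowed):
            raise ProtocodeError(f"{self.name}: invalid base alphabet {self.base_alphabet}")
        if COMPLEMENT[self.base_alphabet[0]] != self.base_alphabet[1]:
            raise ProtocodeError(f"{self.name}: bases {self.base_alphabet} are not complementary")
        seen: dict[str, str] = {}
        for m in self.members:
            if m.symbol not in CANONICAL_AA | PLACEHOLDERS:
                raise ProtocodeError(f"{self.name}: unknown amino-acid symbol {m.symbol!r}")
            if not m.codons:
                raise ProtocodeError(f"{self.name}: member {m.symbol} has no codons")
            for codon in m.codons:
                if len(codon) != 3 or any(b not in allowed for b in codon):
                    raise ProtocodeError(
                        f"{self.name}: codon {codon} of {m.symbol} uses a base outside "
                        f"the {'/'.join(self.base_alphabet)} alphabet"
                    )
                if codon in seen:
                    raise ProtocodeError(
                        f"{self.name}: codon {codon} assigned to both {seen[codon]} and {m.symbol}"
                    )
                seen[codon] = m.symbol
        expected = EXPECTED_MEMBERS.get(self.name)
        if expected is not None:
            actual = {m.symbol for m in self.members} - PLACEHOLDERS
            if actual != expected:
                raise ProtocodeError(
                    f"{self.name}: members {sorted(actual)} != expected {sorted(expected)}"
                )
        symbols = {m.symbol for m in self.members}
        for a, b in self.complement_pairs:
            if a not in symbols or b not in symbols:
                raise ProtocodeError(f"{self.name}: complement pair ({a},{b}) names a non-member")
            codons_b = self.member(b).codons
            if not any(reverse_complement(c) in codons_b for c in self.member(a).codons):
                raise ProtocodeError(
                    f"{self.name}: complement pair ({a},{b}) has no reverse-complement codons"
                )


@dataclass
class SGCTable:
    """The standard genetic code: 64 RNA codons, stops mapped to '*'."""

    forward: dict[str, str]

    @classmethod
    def standard(cls) -> "SGCTable":
        table = unambiguous_rna_by_id[1]
        forward = dict(table.forward_table)
        for stop in table.stop_codons:
            forward[stop] = "*"
        return cls(forward=forward)

    @property
    def stop_codons(self) -> set[str]:
        return {c for c, aa in self.forward.items() if aa == "*"}

    def codons_of(self, aa: str) -> set[str]:
        return {c for c, a in self.forward.items() if a == aa}

    def validate(self) -> None:
        if len(self.forward) != 64:
            raise ProtocodeError(f"SGC table has {len(self.forward)} codons, expected 64")
        if self.stop_codons != {"UAA", "UAG", "UGA"}:
            raise ProtocodeError(f"unexpected stop codons {sorted(self.stop_codons)}")


def load_protocodes(source: str | None = None) -> dict[str, Protocode]:
    """Load and validate the four protocodes from a YAML configuration.

    With ``source=None`` the configuration bundled with the package is
    used.  Loading fails loudly on any invariant violation (duplicate
    codon, base outside the alphabet, unknown symbol, broken complement
    pair, wrong membership).
    """
    if source is None:
        text = resources.files("protopep.data").joinpath("protocodes.yaml").read_text()
    else:
        with open(source) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    codes: dict[str, Protocode] = {}
    for entry in raw["protocodes"]:
        members = []
        for symbol, value in entry["members"].items():
            if isinstance(value, dict):
                codons, deleted = value["codons"], bool(value.get("deleted", False))
            else:
                codons, deleted = value, False
            members.append(ProtocodeMember(str(symbol), frozenset(codons), deleted))
        code = Protocode(
            name=entry["name"],
            base_alphabet=tuple(entry["bases"]),
            members=members,
            complement_pairs=[tuple(p) for p in entry["complement_pairs"]],
            dominance=entry["dominance"],
        )
        code.validate()
        if code.name in codes:
            raise ProtocodeError(f"duplicate protocode name {code.name}")
        codes[code.name] = code
    if len(codes) != 4:
        raise ProtocodeError(f"expected 4 protocodes, got {len(codes)}")
    return codes


@dataclass
class FusionOutcome:
    """Fusion result for one member of one protocode."""

    protocode: str
    symbol: str
    dominant: bool
    deleted: bool
    original: frozenset[str]
    fused: set[str] = field(default_factory=set)
    rules: dict[str, str] = field(default_factory=dict)  # codon -> rule applied
    ceded: dict[str, str] = field(default_factory=dict)  # codon -> late entrant aa
    released: set[str] = field(default_factory=set)  # deleted members only
    errors: list[str] = field(default_factory=list)


@dataclass
class FusionResult:
    outcomes: list[FusionOutcome]

    def outcome(self, protocode: str, symbol: str) -> FusionOutcome:
        for o in self.outcomes:
            if o.protocode == protocode and o.symbol == symbol:
                return o
        raise KeyError((protocode, symbol))

    @property
    def errors(self) -> list[str]:
        return [e for o in self.outcomes for e in o.errors]


def _late_entrants(sgc: SGCTable) -> dict[str, str]:
    """Codons of the late-entrant amino acids Met and Trp."""
    return {c: aa for c, aa in sgc.forward.items() if aa in ("M", "W")}


def apply_fusion(
    protocodes: Mapping[str, Protocode], sgc: SGCTable | None = None
) -> FusionResult:
    """Fuse the protocodes toward the SGC via Watson-Crick transitions.

    Dominant members keep their codons and gain third-position transition
    mutants (mutants landing on a late-entrant codon are recorded as
    ceded).  Recessive members take what's left: for each original codon
    the first-position and first-and-third-position mutants that are still
    free are claimed, which preserves the recessive complement pairing
    (both members of a pair claim their first-and-third mutants).  Deleted
    members release their codons; non-stop released codons pass to the
    recessive competitor holding the same original codon.
    """
    sgc = sgc or SGCTable.standard()
    sgc.validate()
    late = _late_entrants(sgc)
    stops = sgc.stop_codons

    outcomes: list[FusionOutcome] = []
    occupied: set[str] = set(stops) | set(late)

    # --- dominant pass -------------------------------------------------
    dominant_codes = [p for p in protocodes.values() if p.dominance == "dominant"]
    recessive_codes = [p for p in protocodes.values() if p.dominance == "recessive"]
    for code in dominant_codes:
        for m in code.members:
            if not m.codons:
                raise ProtocodeError(f"{code.name}: {m.symbol} has an empty codon set")
            out = FusionOutcome(code.name, m.symbol, True, m.deleted, m.codons)
            for codon in sorted(m.codons):
                mutant = transition_mutant(codon, [2])
                if m.deleted:
                    out.released.update({codon, mutant})
                    continue
                out.fused.add(codon)
                out.rules[codon] = RULE_RETAINED
                if mutant in late:
                    out.ceded[mutant] = late[mutant]
                elif mutant in stops:
                    out.errors.append(f"mutant {mutant} of {codon} is a stop codon")
                else:
                    out.fused.add(mutant)
                    out.rules[mutant] = RULE_THIRD
            occupied.update(out.fused)
            outcomes.append(out)

    # --- recessive pass ------------------------------------------------
    deleted_dominant = [o for o in outcomes if o.deleted]
    for code in recessive_codes:
        for m in code.members:
            out = FusionOutcome(code.name, m.symbol, False, m.deleted, m.codons)
            for codon in sorted(m.codons):
                first = transition_mutant(codon, [0])
                first_third = transition_mutant(codon, [0, 2])
                if m.deleted:
                    out.released.update({first, first_third})
                    continue
                claimed = False
                for mutant, rule in ((first, RULE_FIRST), (first_third, RULE_FIRST_THIRD)):
                    if mutant not in occupied:
                        out.fused.add(mutant)
                        out.rules[mutant] = rule
                        occupied.add(mutant)
                        claimed = True
                if not claimed:
                    out.errors.append(
                        f"no free codon reachable from {codon} "
                        f"(tried {first}, {first_third})"
                    )
                # inheritance: a deleted dominant competitor that held this
                # same codon releases it (and its third-position mutant)
                for dead in deleted_dominant:
                    if codon in dead.original:
                        for rel in sorted(dead.released - stops - set(late)):
                            if rel not in occupied:
                                out.fused.add(rel)
                                out.rules[rel] = RULE_INHERITED
                                occupied.add(rel)
            if m.deleted:
                # classify released codons of deleted recessive members
                for rel in sorted(out.released):
                    if rel in late:
                        out.ceded[rel] = late[rel]
            outcomes.append(out)
    return FusionResult(outcomes=outcomes)


@dataclass
class ValidationRow:
    protocode: str
    symbol: str
    status: str  # "pass" | "fail"
    mismatches: set[str]
    note: str = ""


@dataclass
class ValidationReport:
    rows: list[ValidationRow]

    @property
    def passed(self) -> bool:
        return all(r.status == "pass" for r in self.rows)

    def row(self, protocode: str, symbol: str) -> ValidationRow:
        for r in self.rows:
            if r.protocode == protocode and r.symbol == symbol:
                return r
        raise KeyError((protocode, symbol))


def validate_against_sgc(result: FusionResult, sgc: SGCTable | None = None) -> ValidationReport:
    """Check each fused codon set against the SGC.

    Amino acids pass when their fused codons are a subset of their SGC
    codons.  Deleted placeholders are checked for stop-codon emergence
    (X1 must yield the UAA and UAG stops; X2's released codons must be the
    UGA stop plus the Trp codon).
    """
    sgc = sgc or SGCTable.standard()
    rows: list[ValidationRow] = []
    for out in result.outcomes:
        if out.deleted:
            emerged_stops = out.released & sgc.stop_codons
            non_stop = out.released - sgc.stop_codons
            unexplained = {c for c in non_stop if c not in _late_entrants(sgc)}
            if out.symbol == "X1":
                ok = emerged_stops == {"UAA", "UAG"}
                note = f"stop codons emerged: {sorted(emerged_stops)}"
            else:
                # every released codon must become a stop, go to a late
                # entrant, or be inherited by a recessive competitor
                inherited = {
                    c
                    for o in result.outcomes
                    for c, rule in o.rules.items()
                    if rule == RULE_INHERITED
                }
                unexplained -= inherited
                ok = not unexplained
                note = (
                    f"stops {sorted(emerged_stops)}; "
                    f"ceded {sorted(out.ceded)}; unexplained {sorted(unexplained)}"
                )
            rows.append(
                ValidationRow(out.protocode, out.symbol, "pass" if ok else "fail", unexplained, note)
            )
            continue
        sgc_codons = sgc.codons_of(out.symbol)
        mismatches = out.fused - sgc_codons
        status = "pass" if not mismatches and not out.errors else "fail"
        note = "; ".join(out.errors)
        rows.append(ValidationRow(out.protocode, out.symbol, status, mismatches, note))
    return ValidationReport(rows=rows)
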